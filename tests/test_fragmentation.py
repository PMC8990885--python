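import math

import numpy as np
import pytest
from scipy import stats

from carbonmc import (
    WATER,
    generate_event,
    sample_energy_angle,
    sample_fragment_set,
    sample_target_nucleus,
    scale_angle,
    scale_energy,
)
from carbonmc.fragmentation import (
    E_CAL,
    E_EXP_MAX,
    THETA_MAX,
    map_target,
    scale_target_energy,
    target_probabilities,
)
from carbonmc.materials import Material, MaterialComponent
from carbonmc.species import SPECIES
from carbonmc.xs import sigma_c_on_h, sigma_nonelastic


class TestProductionTables:
    def test_cumulative_monotone_ends_at_one(self, tables):
        for targ in ("H", "C", "O"):
            cum = tables.cumulative(targ)
            assert np.all(np.diff(cum) >= 0)
            assert cum[-1] == 1.0

    def test_species_set_is_complete(self, tables):
        for targ in ("H", "C", "O"):
            assert set(tables.species_names(targ)) == set(SPECIES)

    @pytest.mark.parametrize(
        "targ,species,printed",
        [("H", "4He", 26.0), ("C", "2H", 7.5), ("O", "3H", 5.1)],
    )
    def test_marginal_frequencies_recover_table(self, tables, rng, targ,
                                                species, printed):
        n = 1_000_000
        draws = tables.sample_species(targ, rng, size=n)
        frac = np.mean(draws == species)
        p = tables.production[targ][species]
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3.0 * sigma
        # the normalized table value stays close to the printed percentage
        assert p * 100.0 == pytest.approx(printed, rel=0.02)

    def test_source_tags_cover_unmeasured_cells(self, tables):
        assert tables.sources[("H", "n")] == "fluka-filled"
        assert tables.sources[("H", "11B")] == "fluka-filled"
        assert tables.sources[("C", "n")] == "fluka-filled"
        assert tables.sources[("C", "4He")] == "measured"


class TestTargetSampling:
    def test_single_element_material(self, rng):
        graphite = Material("graphite", 1.7,
                            (MaterialComponent("C", 1.0, 12.011, 6, 1.0),))
        assert sample_target_nucleus(graphite, 95.0, rng) == "C"

    def test_water_probabilities_match_formula(self):
        # P(H) = 2 sigma_data / (2 sigma_data + sigma_K(O))
        probs = target_probabilities(WATER, 95.0)
        sH = sigma_c_on_h(95.0)
        sO = sigma_nonelastic("O", 95.0)
        expected = 2.0 * sH / (2.0 * sH + sO)
        assert probs["H"] == pytest.approx(expected, rel=1e-12)
        assert probs["H"] + probs["O"] == pytest.approx(1.0, rel=1e-12)

    def test_water_draw_frequencies(self, rng):
        n = 1_000_000
        draws = sample_target_nucleus(WATER, 95.0, rng, size=n)
        pH = target_probabilities(WATER, 95.0)["H"]
        frac = np.mean(draws == "H")
        assert abs(frac - pH) < 3.0 * math.sqrt(pH * (1 - pH) / n)

    def test_nearest_table_mapping(self):
        assert map_target("N") == "O"
        assert map_target("Ca") == "O"
        assert map_target("H") == "H"


class TestFragmentSetSampling:
    def test_projectile_budget_never_exceeded(self, rng):
        for targ in ("H", "C", "O"):
            for _ in range(300):
                ev = sample_fragment_set(targ, 200.0, rng)
                assert 1 <= ev.sum_A <= 12
                assert ev.sum_Z <= 6

    def test_target_side_single_fragment_capped(self, rng):
        for _ in range(300):
            ev = sample_fragment_set("H", 200.0, rng)
            tside = [f for f in ev.fragments if f.origin == "target"]
            assert len(tside) == 1
            assert tside[0].A <= 1  # hydrogen target can only yield nucleons

    def test_charged_multiplicity_band(self, rng):
        """Mean charged fragments per event stays in the 2-4 band across
        therapeutic energies."""
        for E in (100.0, 250.0, 400.0):
            mult = np.mean(
                [generate_event(WATER, E, rng).n_charged for _ in range(3000)]
            )
            assert 2.0 <= mult <= 4.0

    def test_resample_rate_below_half(self, rng):
        for E in (100.0, 400.0):
            evs = [generate_event(WATER, E, rng) for _ in range(3000)]
            rate = np.mean([e.resamples > 0 for e in evs])
            assert rate < 0.5


class TestEnergyAngleSampling:
    def test_projectile_4he_mean_energy(self, rng):
        n = 200_000
        E, th = sample_energy_angle("4He", "C", "projectile", rng, size=n)
        # Gaussian component mean 83 MeV/u (truncation shift < 1%)
        sem = E.std() / math.sqrt(n)
        assert abs(E.mean() - 83.0) < max(3.0 * sem, 0.01 * 83.0)
        assert np.all(E > 0) and np.all((th >= 0) & (th <= THETA_MAX))

    def test_target_exponential_theta_mean(self, rng, tables):
        n = 200_000
        p = tables.params("C", "4He")
        _, th = sample_energy_angle("4He", "C", "target", rng, size=n)
        a = p.alpha_th
        expect = 1.0 / a - THETA_MAX / (math.exp(a * THETA_MAX) - 1.0)
        sem = th.std() / math.sqrt(n)
        assert abs(th.mean() - expect) < 3.0 * sem

    def test_target_exponential_energy_truncated(self, rng, tables):
        n = 100_000
        p = tables.params("O", "7Li")
        E, _ = sample_energy_angle("7Li", "O", "target", rng, size=n)
        assert np.all((E > 0) & (E <= E_EXP_MAX))
        a = p.alpha_E
        expect = 1.0 / a - E_EXP_MAX / (math.exp(a * E_EXP_MAX) - 1.0)
        sem = E.std() / math.sqrt(n)
        assert abs(E.mean() - expect) < 3.0 * sem

    def test_hydrogen_mixture_matches_component_cdfs(self, rng, tables):
        """2D histogram of the two-component mixture for 1H on carbon
        against exact per-bin probabilities from the separable CDFs."""
        n = 300_000
        p = tables.params("C", "1H")
        E, th = sample_energy_angle("1H", "C", "projectile", rng, size=n)
        e_edges = np.array([0, 20, 40, 60, 80, 100, 120, 160, 1e9])
        t_edges = np.array([0, 5, 10, 20, 30, 45, 90, 180.0])

        def cdf_exp(x, a, L):
            x = np.clip(x, 0, L)
            return (1 - np.exp(-a * x)) / (1 - np.exp(-a * L))

        def cdf_gauss(x, mu, sig, lo, hi):
            z = stats.norm.cdf
            return (z((np.clip(x, lo, hi) - mu) / sig) - z((lo - mu) / sig)) / (
                z((hi - mu) / sig) - z((lo - mu) / sig)
            )

        we = p.w_exp / (p.w_exp + p.w_gauss)
        pe_E = np.diff(cdf_exp(e_edges, p.alpha_E, E_EXP_MAX))
        pe_t = np.diff(cdf_exp(t_edges, p.alpha_th, THETA_MAX))
        pg_E = np.diff(cdf_gauss(e_edges, p.E_mean, p.sigma_E, 0, np.inf))
        pg_t = np.diff(cdf_gauss(t_edges, p.th_mean, p.sigma_th, 0, 180.0))
        expected = n * (we * np.outer(pe_E, pe_t)
                        + (1 - we) * np.outer(pg_E, pg_t))
        observed = np.histogram2d(E, th, bins=[e_edges, t_edges])[0]
        keep = expected > 10
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        assert stats.chi2.sf(chi2, keep.sum() - 1) > 0.01


class TestScalingLaws:
    def test_energy_identity_limits(self):
        assert scale_energy(50.0, 95.0, None) == pytest.approx(50.0, rel=1e-12)
        # R = 1 (previous fragments at projectile energy) -> pure E/95 factor
        prev = [(200.0, 4.0)]
        assert scale_energy(80.0, 200.0, prev) == pytest.approx(
            80.0 * 200.0 / 95.0, rel=1e-12
        )

    def test_three_fragment_worked_event(self):
        """Scripted independent evaluation of the correlation chain."""
        E_proj, c = 200.0, 0.4
        draws = [(90.0, 4.0), (80.0, 6.0), (70.0, 2.0)]
        scaled, prev = [], []
        for E95, A in draws:
            if prev:
                sEA = sum(e * a for e, a in prev)
                sA = sum(a for _, a in prev)
                R = (sEA / sA) / E_proj
            else:
                R = 1.0
            expect = E95 * (E_proj / 95.0) * (1.0 - c * (1.0 - R))
            got = scale_energy(E95, E_proj, prev)
            assert got == pytest.approx(expect, rel=1e-12)
            prev.append((got, A))
            scaled.append(got)

    def test_angle_scaling(self):
        assert scale_angle(10.0, 95.0, "4He") == pytest.approx(10.0, rel=1e-12)
        assert scale_angle(10.0, 380.0, "4He") == pytest.approx(5.0, rel=1e-12)
        assert scale_angle(10.0, 380.0, "1H") == 10.0
        assert scale_angle(10.0, 380.0, "n") == 10.0
        assert scale_angle(10.0, 380.0, "2H") == pytest.approx(5.0, rel=1e-12)

    def test_target_energy_scaling_no_correlation(self):
        assert scale_target_energy(40.0, 190.0) == pytest.approx(80.0, rel=1e-12)


class TestGenerateEvent:
    def test_energy_conserved_every_event(self, rng):
        for _ in range(500):
            ev = generate_event(WATER, 300.0, rng)
            assert ev.total_kinetic <= 12.0 * 300.0 + 1e-9
            assert ev.sum_A <= 12 and ev.sum_Z <= 6

    def test_projectile_mean_energy_tracks_beam(self, rng, tables):
        """Projectile fragments keep the beam's energy per nucleon on
        average (checked for 4He against the scaled table mean)."""
        E_proj = 200.0
        es = []
        for _ in range(4000):
            ev = generate_event(WATER, E_proj, rng, target="O")
            es += [f.E for f in ev.projectile_fragments if f.species == "4He"]
        expect = tables.params("O", "4He").E_mean * E_proj / E_CAL
        assert np.mean(es) == pytest.approx(expect, rel=0.10)

    def test_dominant_light_species(self, rng):
        from collections import Counter

        cnt = Counter()
        for _ in range(3000):
            ev = generate_event(WATER, 95.0, rng)
            cnt.update(f.species for f in ev.fragments if f.Z > 0)
        top3 = {s for s, _ in cnt.most_common(3)}
        assert top3 == {"1H", "2H", "4He"}
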
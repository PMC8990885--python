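import numpy as np
import pytest

from carbonmc import (
    analytic_bragg_curve,
    build_sobp,
    csda_range,
    depth_dose,
    find_bragg_peak,
    gamma_index,
    lateral_profile,
    make_water_phantom,
)
from carbonmc.engine import DoseGrid
from carbonmc.errors import AmbiguousPeakError, InvalidGeometryError
from carbonmc.qa import Profile1D


def _dose_on(shape=(16, 16, 16), voxel_mm=(5, 5, 5), fill=None):
    dims = tuple(s * v / 10.0 for s, v in zip(shape, voxel_mm))
    grid = make_water_phantom(dims, voxel_mm)
    dose = np.zeros(shape) if fill is None else np.asarray(fill, dtype=float)
    return DoseGrid(grid=grid, dose=dose, unc=np.zeros(shape))


class TestProfiles:
    def test_uniform_field_gives_flat_depth_profile(self):
        d = _dose_on(fill=np.ones((16, 16, 16)))
        prof = depth_dose(d)
        assert np.allclose(prof.values, prof.values[0])

    def test_fubini_depth_integral(self):
        rng = np.random.default_rng(0)
        field = rng.random((8, 8, 8))
        d = _dose_on((8, 8, 8), fill=field)
        prof = depth_dose(d)
        vol_integral = field.sum() * d.grid.voxel_volume
        assert prof.values.sum() * prof.bin_width == pytest.approx(
            vol_integral, rel=1e-12
        )

    def test_lateral_profile_symmetry_and_consistency(self):
        shape = (17, 17, 8)
        x = np.arange(shape[0]) - 8
        y = np.arange(shape[1]) - 8
        r2 = x[:, None] ** 2 + y[None, :] ** 2
        field = np.repeat(np.exp(-r2 / 20.0)[:, :, None], shape[2], axis=2)
        d = _dose_on(shape, fill=field)
        prof = lateral_profile(d, depth_cm=2.0)
        np.testing.assert_allclose(prof.values, prof.values[::-1], rtol=1e-9)
        # profile integral equals the depth-dose value at that slice
        dd = depth_dose(d)
        k = int(np.argmin(np.abs(dd.coords - 2.0)))
        assert prof.values.sum() * prof.bin_width == pytest.approx(
            dd.values[k], rel=1e-12
        )

    def test_depth_outside_grid_rejected(self):
        d = _dose_on(fill=np.ones((16, 16, 16)))
        with pytest.raises(InvalidGeometryError):
            lateral_profile(d, depth_cm=99.0)


class TestBraggPeakFinder:
    def test_parabola_vertex_recovered_exactly(self):
        z = np.linspace(0.05, 10.0, 100)
        vertex = 6.283
        prof = Profile1D(z, -((z - vertex) ** 2) + 50.0)
        assert find_bragg_peak(prof) == pytest.approx(vertex, abs=1e-6)

    def test_noisy_peak_within_one_bin(self):
        rng = np.random.default_rng(4)
        z = np.arange(0.025, 12.0, 0.05)
        peak = 8.6
        clean = np.exp(-0.5 * ((z - peak) / 0.15) ** 2) + 0.1
        noisy = clean + rng.normal(0.0, 0.01, len(z))
        assert abs(find_bragg_peak(Profile1D(z, noisy)) - peak) < 0.05

    def test_monotone_profile_raises(self):
        z = np.linspace(0.1, 5.0, 50)
        with pytest.raises(AmbiguousPeakError):
            find_bragg_peak(Profile1D(z, z * 2.0))
        with pytest.raises(AmbiguousPeakError):
            find_bragg_peak(Profile1D(z, np.ones_like(z)))


class TestSOBP:
    def test_single_layer_reproduces_prescription_at_peak(self):
        z = np.arange(0.025, 12.0, 0.05)
        kern = analytic_bragg_curve(200.0, z)
        pk = float(z[np.argmax(kern)])
        plan = build_sobp([200.0], (pk - 0.026, pk + 0.026), 2.0, z)
        k = int(np.argmin(np.abs(z - pk)))
        assert plan.predicted.values[k] == pytest.approx(2.0, rel=0.02)

    def test_31_layer_plateau_flat_within_3_percent(self):
        """Thirty-one layers spanning 219-277.5 MeV/u produce a 2 Gy
        plateau over 10-15 cm depth flat to +-3%."""
        z = np.arange(0.025, 20.0, 0.05)
        plan = build_sobp(np.linspace(219.0, 277.5, 31), (10.0, 15.0), 2.0, z)
        m = (z >= 10.0) & (z <= 15.0)
        rel = plan.predicted.values[m] / 2.0
        assert rel.min() > 0.97
        assert rel.max() < 1.03

    def test_prescription_linearity(self):
        z = np.arange(0.025, 16.0, 0.05)
        E = np.linspace(219.0, 250.0, 8)
        p1 = build_sobp(E, (10.0, 12.0), 1.0, z)
        p2 = build_sobp(E, (10.0, 12.0), 2.0, z)
        np.testing.assert_allclose(p2.weights, 2.0 * p1.weights,
                                   rtol=1e-6, atol=1e-12)

    def test_infeasible_target_rejected(self):
        z = np.arange(0.025, 30.0, 0.05)
        with pytest.raises(InvalidGeometryError):
            build_sobp([219.0], (10.0, 25.0), 2.0, z)

    def test_flatness_improves_with_layer_count(self):
        z = np.arange(0.025, 20.0, 0.05)
        m = (z >= 10.0) & (z <= 15.0)
        devs = []
        for nl in (6, 12, 31):
            plan = build_sobp(np.linspace(219.0, 277.5, nl), (10.0, 15.0),
                              2.0, z)
            devs.append(np.abs(plan.predicted.values[m] / 2.0 - 1.0).max())
        assert devs[0] > devs[1] > devs[2]


def _blob(shape, center, sigma, amp=1.0):
    axes = [np.arange(s) for s in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    r2 = sum((g - c) ** 2 for g, c in zip((X, Y, Z), center))
    return amp * np.exp(-r2 / (2.0 * sigma**2))


class TestGammaIndex:
    def test_identity_comparison(self):
        field = _blob((16, 16, 16), (8, 8, 8), 4.0)
        ref = _dose_on((16, 16, 16), fill=field)
        ev = _dose_on((16, 16, 16), fill=field.copy())
        res = gamma_index(ref, ev)
        assert res.pass_rate == 100.0
        assert res.mean_gamma == 0.0

    def test_uniform_two_percent_scaling(self):
        ref = _dose_on((8, 8, 8), fill=np.ones((8, 8, 8)))
        ev = _dose_on((8, 8, 8), fill=np.full((8, 8, 8), 1.02))
        res = gamma_index(ref, ev, dta_mm=2.0, dd_percent=3.0, subvoxel=1)
        vals = res.gamma[np.isfinite(res.gamma)]
        np.testing.assert_allclose(vals, 2.0 / 3.0, rtol=1e-9)
        assert res.pass_rate == 100.0

    def test_shift_failure_localized_at_gradient(self):
        # steep-gradient synthetic field shifted 4 mm along z
        shape = (8, 8, 40)
        z = np.arange(shape[2])
        fld = 1.0 / (1.0 + np.exp((z - 20.0) / 1.5))
        field = np.broadcast_to(fld, shape).copy()
        shifted = np.broadcast_to(
            1.0 / (1.0 + np.exp((z - 24.0) / 1.5)), shape
        ).copy()
        ref = _dose_on(shape, voxel_mm=(5, 5, 1), fill=field)
        ev = _dose_on(shape, voxel_mm=(5, 5, 1), fill=shifted)
        res = gamma_index(ref, ev, dta_mm=2.0, dd_percent=3.0, subvoxel=1)
        g = res.gamma
        fails = np.nonzero(np.nan_to_num(g) > 1.0)
        assert len(fails[2]) > 0
        assert np.all(np.abs(fails[2] - 22) < 8)  # only near the gradient

    def test_exhaustive_oracle_equivalence(self):
        """Local-search γ equals a brute-force exhaustive oracle on every
        voxel of a 16^3 grid pair (fields chosen so γ < 3 everywhere)."""
        shape = (16, 16, 16)
        ref_f = _blob(shape, (8, 8, 8), 5.0)
        ev_f = 1.01 * _blob(shape, (8.6, 8, 8), 5.0)
        ref = _dose_on(shape, fill=ref_f)
        ev = _dose_on(shape, fill=ev_f)
        res = gamma_index(ref, ev, dta_mm=3.0, dd_percent=3.0,
                          cutoff_percent=10.0, subvoxel=1)
        oracle = _gamma_oracle(ref, ev, 3.0, 3.0, 10.0)
        both = np.isfinite(res.gamma)
        np.testing.assert_allclose(res.gamma[both], oracle[both], rtol=1e-9)

    def test_axis_swap_invariance(self):
        shape = (12, 12, 12)
        rng = np.random.default_rng(7)
        a = _blob(shape, (6, 6, 6), 4.0)
        b = a * (1.0 + 0.02 * rng.standard_normal(shape))
        r1 = gamma_index(_dose_on(shape, fill=a), _dose_on(shape, fill=b),
                         subvoxel=1)
        r2 = gamma_index(_dose_on(shape, fill=a.transpose(2, 0, 1)),
                         _dose_on(shape, fill=b.transpose(2, 0, 1)),
                         subvoxel=1)
        assert r1.pass_rate == pytest.approx(r2.pass_rate, abs=1e-9)
        assert r1.mean_gamma == pytest.approx(r2.mean_gamma, rel=1e-9)

    def test_monotone_in_criteria(self):
        shape = (12, 12, 12)
        a = _blob(shape, (6, 6, 6), 4.0)
        b = 1.05 * _blob(shape, (6.8, 6, 6), 4.0)
        ra = _dose_on(shape, fill=a)
        rb = _dose_on(shape, fill=b)
        g1 = gamma_index(ra, rb, dta_mm=2.0, dd_percent=2.0, subvoxel=1)
        g2 = gamma_index(ra, rb, dta_mm=3.0, dd_percent=2.0, subvoxel=1)
        g3 = gamma_index(ra, rb, dta_mm=2.0, dd_percent=4.0, subvoxel=1)
        assert g2.mean_gamma <= g1.mean_gamma
        assert g3.mean_gamma <= g1.mean_gamma


def _gamma_oracle(ref, ev, dta_mm, dd_percent, cutoff_percent):
    """O(N*M) exhaustive γ: for every reference voxel above cutoff, the
    minimum over ALL evaluation voxels (no search radius)."""
    grid = ref.grid
    shape = grid.shape
    axes = [grid.voxel_centers(i) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    dref = ref.dose.ravel()
    dev = ev.dose.ravel()
    dmax = ref.dose.max()
    dd_abs = dd_percent / 100.0 * dmax
    dta_cm = dta_mm / 10.0
    out = np.full(dref.shape, np.nan)
    above = np.nonzero(dref >= cutoff_percent / 100.0 * dmax)[0]
    n2 = (coords**2).sum(axis=1)
    for i in above:
        r2 = n2[i] + n2 - 2.0 * coords @ coords[i]
        g2 = r2 / dta_cm**2 + (dref[i] - dev) ** 2 / dd_abs**2
        out[i] = np.sqrt(g2.min())
    return out.reshape(shape)
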
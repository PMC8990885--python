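"""The Monte Carlo trunk: primaries, stepping, interactions, dose scoring.

Tracks are advanced in vectorized cohorts (structure-of-arrays over a
batch) with adaptive steps limited by the voxel crossing and by a maximum
fractional energy loss. Continuous energy loss (with optional Gaussian
straggling) is deposited in the voxel where the step starts; multiple
Coulomb scattering deflects the direction at the end of each step. Nuclear
interactions are triggered by a per-track exponential free-path counter in
units of mean free paths, re-evaluated against the local attenuation every
step so density changes are handled exactly. Non-elastic events consume the
carbon primary and queue its charged fragments; neutrons are scored in the
energy ledger but not transported.

Every energy sink is bookkept so the run closes its energy ledger:
deposited + escaped + neutron-carried + nuclear deficit (kinetic energy a
non-elastic event does not hand to fragments) + secondary absorption equals
the injected energy up to float rounding.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import fragmentation as frag
from .em import EMConfig, M_U, BOHR_COEFF, get_table
from .errors import ConfigurationError
from .materials import Material, VoxelGrid
from .species import SPECIES
from .xs import CCFitParams, mass_attenuation, sample_elastic

__all__ = [
    "BeamSpec",
    "TransportConfig",
    "DoseGrid",
    "RunSummary",
    "sample_free_path",
    "run",
]

MEV_TO_J = 1.602176634e-13
_EPS_PUSH = 1e-6  # cm, nudge across voxel boundaries


@dataclass
class BeamSpec:
    """Mono-energetic pencil beam definition."""

    species: str = "12C"
    energy: float = 200.0          # MeV/u
    position: tuple = (0.0, 0.0, 0.0)   # cm
    direction: tuple = (0.0, 0.0, 1.0)
    sigma_mm: float = 0.0          # transverse Gaussian spot sigma
    energy_spread: float = 0.0     # fractional Gaussian sigma
    n_primaries: int = 1000
    seed: int = 20220325

    def __post_init__(self):
        if self.n_primaries < 1:
            raise ConfigurationError("n_primaries must be >= 1")
        if self.sigma_mm < 0:
            raise ConfigurationError("spot sigma must be >= 0")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ConfigurationError("beam direction must be non-zero")
        self.direction = tuple(d / n)


@dataclass
class TransportConfig:
    em: EMConfig = field(default_factory=EMConfig)
    nuclear: bool = True
    elastic_fraction: float = 0.25  # elastic/non-elastic ratio on hydrogen
    secondary_fragmentation: str = "off"  # 'off' | 'attenuate'
    cc_params: CCFitParams = field(default_factory=CCFitParams)
    n_batches: int = 10

    def __post_init__(self):
        if self.secondary_fragmentation not in ("off", "attenuate"):
            raise ConfigurationError("secondary_fragmentation: 'off' or 'attenuate'")
        if self.elastic_fraction < 0:
            raise ConfigurationError("elastic_fraction must be >= 0")


@dataclass
class DoseGrid:
    """Absorbed dose (Gy per primary) on a voxel grid, with the standard
    error of the batch means as statistical uncertainty."""

    grid: VoxelGrid
    dose: np.ndarray
    unc: np.ndarray

    def total_energy_mev(self, n_primaries: int) -> float:
        mass_g = self.grid.density * self.grid.voxel_volume
        return float((self.dose * mass_g).sum()) * n_primaries * 1e-3 / MEV_TO_J


@dataclass
class RunSummary:
    n_primaries: int
    ledger: dict
    n_nonelastic: int = 0
    n_elastic: int = 0
    total_charged_fragments: int = 0
    total_resamples: int = 0

    @property
    def mean_charged_multiplicity(self) -> float:
        return self.total_charged_fragments / max(self.n_nonelastic, 1)

    @property
    def ledger_closure(self) -> float:
        """|sum of sinks - injected| / injected."""
        inj = self.ledger["injected"]
        sinks = sum(v for k, v in self.ledger.items() if k != "injected")
        return abs(sinks - inj) / inj if inj else 0.0


def sample_free_path(mu_rho: float, rho: float, rng: np.random.Generator) -> float:
    """Exponential free path (cm) with mean 1/(mu_rho * rho); infinite when
    the attenuation vanishes."""
    mu = mu_rho * rho
    if mu <= 0:
        return math.inf
    return rng.exponential(1.0 / mu)


class _SpeciesTables:
    """Stacked per-species stopping/attenuation lookups on one log grid."""

    def __init__(self, names, material: Material, cfg: TransportConfig):
        self.names = list(names)
        self.index = {n: i for i, n in enumerate(self.names)}
        # neutrons are never transported; give them a placeholder table
        ref = get_table("1H", material)
        tabs = [get_table(n, material) if SPECIES[n].Z > 0 else ref
                for n in self.names]
        self.loge = np.log(tabs[0].energy)
        self.dlog = self.loge[1] - self.loge[0]
        self.S = np.stack([t.stopping for t in tabs])
        self.A = np.array([SPECIES[n].A for n in self.names], dtype=float)
        self.Z = np.array([SPECIES[n].Z for n in self.names], dtype=float)
        self.fmcs = np.array([cfg.em.f_mcs_for(n) for n in self.names])
        egrid = np.exp(self.loge)
        mur = np.zeros_like(egrid)
        if cfg.nuclear:
            lo = np.searchsorted(egrid, 10.0)  # no nuclear model below ~10 MeV/u
            mur[lo:] = [
                mass_attenuation(material, "12C", min(e, 450.0),
                                 elastic_fraction=cfg.elastic_fraction,
                                 params=cfg.cc_params)
                for e in egrid[lo:]
            ]
        self.murho_12c = mur

    def _locate(self, E):
        x = np.clip(np.log(np.maximum(E, 1e-12)), self.loge[0], self.loge[-1])
        u = (x - self.loge[0]) / self.dlog
        i = np.minimum(u.astype(np.int64), len(self.loge) - 2)
        return i, u - i

    def stopping(self, spid, E):
        i, f = self._locate(E)
        return self.S[spid, i] * (1.0 - f) + self.S[spid, i + 1] * f

    def murho(self, E):
        i, f = self._locate(E)
        return self.murho_12c[i] * (1.0 - f) + self.murho_12c[i + 1] * f


def _basis(d: np.ndarray):
    """Two unit vectors orthogonal to each row of d."""
    ref = np.where(np.abs(d[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(ref, d)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    return e1, e2


def _rotate(d: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """Rotate unit vector d away from itself by polar angle theta, azimuth phi."""
    dd = d.reshape(1, 3)
    e1, e2 = _basis(dd)
    st, ct = math.sin(theta), math.cos(theta)
    out = ct * dd[0] + st * (math.cos(phi) * e1[0] + math.sin(phi) * e2[0])
    return out / np.linalg.norm(out)


class _Ledger(dict):
    def add(self, key, val):
        self[key] = self.get(key, 0.0) + float(val)


def run(beam: BeamSpec, grid: VoxelGrid, cfg: TransportConfig | None = None):
    """Transport ``beam`` through ``grid``; returns (DoseGrid, RunSummary).

    Deterministic for a fixed (seed, primary count, batch count). Only
    carbon primaries carry the nuclear interaction model.
    """
    cfg = cfg or TransportConfig()
    if not grid.materials:
        raise ConfigurationError("grid has no materials")
    if cfg.nuclear and beam.species != "12C":
        raise ConfigurationError("the nuclear model supports carbon primaries only")
    material = grid.materials[0]
    tables = frag.default_tables()
    stabs = _SpeciesTables(list(SPECIES), material, cfg)

    ledger = _Ledger()
    summary = RunSummary(n_primaries=beam.n_primaries, ledger=ledger)
    n_batches = min(cfg.n_batches, beam.n_primaries)
    sizes = np.full(n_batches, beam.n_primaries // n_batches)
    sizes[: beam.n_primaries % n_batches] += 1
    children = np.random.SeedSequence(beam.seed).spawn(n_batches)

    edep_total = np.zeros(grid.shape)
    mu_sum = np.zeros(grid.shape)   # per-primary batch means, for uncertainty
    mu2_sum = np.zeros(grid.shape)

    for bsize, child in zip(sizes, children):
        rng = np.random.default_rng(child)
        edep_b = np.zeros(grid.shape)
        _run_batch(int(bsize), rng, beam, grid, material, cfg, stabs, tables,
                   edep_b, ledger, summary)
        edep_total += edep_b
        mu = edep_b / bsize
        mu_sum += mu
        mu2_sum += mu * mu

    mass_g = grid.density * grid.voxel_volume
    conv = np.where(mass_g > 0, MEV_TO_J * 1e3 / np.maximum(mass_g, 1e-300), 0.0)
    dose = edep_total / beam.n_primaries * conv
    if n_batches > 1:
        var = np.maximum(mu2_sum / n_batches - (mu_sum / n_batches) ** 2, 0.0)
        sem = np.sqrt(var / (n_batches - 1))
    else:
        sem = np.zeros(grid.shape)
    unc = sem * conv
    return DoseGrid(grid=grid, dose=dose, unc=unc), summary


def _run_batch(n, rng, beam, grid, material, cfg, stabs, tables, edep, ledger,
               summary):
    d0 = np.asarray(beam.direction)
    pos = np.tile(np.asarray(beam.position, dtype=float), (n, 1))
    if beam.sigma_mm > 0:
        e1, e2 = _basis(d0.reshape(1, 3))
        off = rng.normal(0.0, beam.sigma_mm / 10.0, size=(n, 2))
        pos += off[:, :1] * e1 + off[:, 1:] * e2
    dirs = np.tile(d0, (n, 1))
    E = np.full(n, float(beam.energy))
    if beam.energy_spread > 0:
        E *= 1.0 + beam.energy_spread * rng.normal(size=n)
        E = np.maximum(E, cfg.em.cutoff_mev_u)
    spid = np.full(n, stabs.index[beam.species], dtype=np.int64)
    ledger.add("injected", (E * stabs.A[spid]).sum())

    secondaries: list[tuple] = []
    _transport(pos, dirs, E, spid, True, rng, grid, material, cfg, stabs,
               tables, edep, ledger, summary, secondaries)
    while secondaries:
        sp = np.array([s[0] for s in secondaries], dtype=np.int64)
        p = np.array([s[1] for s in secondaries])
        d = np.array([s[2] for s in secondaries])
        e = np.array([s[3] for s in secondaries])
        secondaries = []
        _transport(p, d, e, sp, False, rng, grid, material, cfg, stabs,
                   tables, edep, ledger, summary, secondaries)


def _transport(pos, dirs, E, spid, primary, rng, grid, material, cfg, stabs,
               tables, edep, ledger, summary, secondaries):
    n = len(E)
    if n == 0:
        return
    A = stabs.A[spid]
    nuclear = cfg.nuclear and (primary or cfg.secondary_fragmentation == "attenuate")
    nmfp = rng.exponential(size=n) if nuclear else np.full(n, np.inf)
    alive = np.ones(n, dtype=bool)
    origin = grid.origin
    h = grid.voxel_size
    shape = np.array(grid.shape)
    fmax = cfg.em.max_frac_eloss
    cutoff = cfg.em.cutoff_mev_u
    x0 = material.radiation_length
    za = material.mean_ZA
    flat = edep.reshape(-1)
    rho_flat = grid.density.reshape(-1)
    strides = np.array([grid.shape[1] * grid.shape[2], grid.shape[2], 1],
                       dtype=np.int64)

    while alive.any():
        idx = np.nonzero(alive)[0]
        p = pos[idx]
        iv = np.floor((p - origin) / h).astype(np.int64)
        inside = np.all((iv >= 0) & (iv < shape), axis=1)
        if not inside.all():
            out = idx[~inside]
            ledger.add("escaped", (E[out] * A[out]).sum())
            alive[out] = False
            idx = idx[inside]
            if idx.size == 0:
                continue
            p = pos[idx]
            iv = iv[inside]
        ivflat = iv @ strides
        rho = rho_flat[ivflat]
        e = E[idx]
        a = A[idx]
        etot = e * a
        dedx = np.maximum(stabs.stopping(spid[idx], e) * rho, 1e-30)  # MeV/cm
        d = dirs[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            lo = (origin + iv * h - p) / d
            hi = (origin + (iv + 1) * h - p) / d
        tbox = np.where(d > 0, hi, np.where(d < 0, lo, np.inf))
        tgeo = np.maximum(tbox.min(axis=1), 0.0) + _EPS_PUSH
        step = np.minimum(tgeo, fmax * etot / dedx)

        interact = np.zeros(len(idx), dtype=bool)
        if nuclear:
            mur = (stabs.murho(e) if primary
                   else _secondary_murho(stabs, spid[idx], e, material, cfg))
            dm = mur * rho * step
            interact = dm >= nmfp[idx]
            with np.errstate(invalid="ignore"):
                fhit = np.where(interact, nmfp[idx] / np.maximum(dm, 1e-300), 1.0)
            step = step * fhit
            nmfp[idx] -= np.where(interact, nmfp[idx], dm)

        de = dedx * step
        if cfg.em.straggling:
            zarr = stabs.Z[spid[idx]]
            gam = 1.0 + e / M_U
            beta2 = 1.0 - 1.0 / gam**2
            zeff = zarr * (1.0 - np.exp(-125.0 * np.sqrt(beta2) / zarr ** (2.0 / 3.0)))
            relf = (1.0 - beta2 / 2.0) / (1.0 - beta2)
            var = BOHR_COEFF * zeff**2 * za * rho * step * relf
            de = de + np.sqrt(var) * rng.standard_normal(len(idx))
        de = np.clip(de, 0.0, etot)
        enew = (etot - de) / a
        stopping = enew < cutoff
        interact &= ~stopping  # a track that would stop mid-step just stops
        de = np.where(stopping, etot, de)

        np.add.at(flat, ivflat, de)
        ledger.add("deposited", de.sum())
        E[idx] = np.where(stopping, 0.0, enew)
        pos[idx] = p + d * step[:, None]

        moving = ~stopping & (step > 0)
        if moving.any():
            t = step * rho / x0
            gam = 1.0 + enew / M_U
            b2 = 1.0 - 1.0 / gam**2
            pbeta = a * M_U * gam * b2
            with np.errstate(divide="ignore", invalid="ignore"):
                sig = (14.1 / np.maximum(pbeta, 1e-12)
                       * stabs.Z[spid[idx]]
                       * np.sqrt(np.maximum(t, 0.0))
                       * (1.0 + np.log10(np.maximum(t, 1e-300)) / 9.0))
            sig = np.where((t > 0) & moving,
                           np.maximum(sig, 0.0) * stabs.fmcs[spid[idx]], 0.0)
            tx = sig * rng.standard_normal(len(idx))
            ty = sig * rng.standard_normal(len(idx))
            e1, e2 = _basis(d)
            nd = d + tx[:, None] * e1 + ty[:, None] * e2
            nd /= np.linalg.norm(nd, axis=1, keepdims=True)
            dirs[idx] = nd

        alive[idx[stopping]] = False
        if nuclear and interact.any():
            for i in idx[interact]:
                if primary:
                    _handle_primary_interaction(
                        int(i), pos, dirs, E, spid, alive, nmfp, rng, material,
                        cfg, tables, stabs, flat, strides, grid, ledger,
                        summary, secondaries)
                else:
                    ledger.add("secondary_absorbed", E[i] * A[i])
                    alive[i] = False


def _secondary_murho(stabs, spid, e, material, cfg):
    out = np.zeros(len(spid))
    for k in range(len(spid)):
        name = stabs.names[spid[k]]
        if SPECIES[name].Z == 0:
            continue
        try:
            out[k] = mass_attenuation(material, name, float(e[k]),
                                      params=cfg.cc_params)
        except Exception:
            out[k] = 0.0
    return out


def _handle_primary_interaction(i, pos, dirs, E, spid, alive, nmfp, rng,
                                material, cfg, tables, stabs, flat, strides,
                                grid, ledger, summary, secondaries):
    e_u = float(E[i])
    a = float(stabs.A[spid[i]])
    # cross-section tables live on 10-450 MeV/u; clamp the lookup energy
    target = frag.sample_target_nucleus(material, min(max(e_u, 10.0), 450.0),
                                        rng, cfg.cc_params)
    p_el = cfg.elastic_fraction / (1.0 + cfg.elastic_fraction)
    if target == "H" and rng.random() < p_el:
        out = sample_elastic(rng, e_u * a, A=a)
        summary.n_elastic += 1
        phi = rng.uniform(0.0, 2.0 * math.pi)
        d_in = dirs[i].copy()
        dirs[i] = _rotate(d_in, out.theta_l, phi)
        E[i] = out.E_l_prime / a
        nmfp[i] = rng.exponential()
        _emit(out.E_l_p, "1H", pos[i], _rotate(d_in, out.phi_l, phi + math.pi),
              cfg, stabs, flat, strides, grid, ledger, secondaries)
        return
    ev = frag.generate_event(material, e_u, rng, tables, cfg.cc_params,
                             target=target)
    summary.n_nonelastic += 1
    summary.total_resamples += ev.resamples
    summary.total_charged_fragments += ev.n_charged
    ledger.add("nuclear_deficit", e_u * a - ev.total_kinetic)
    d_in = dirs[i].copy()
    for f in ev.fragments:
        if f.Z == 0:
            ledger.add("neutron", f.kinetic)
            continue
        _emit(f.kinetic, f.species, pos[i], _rotate(d_in, f.theta, f.phi),
              cfg, stabs, flat, strides, grid, ledger, secondaries)
    alive[i] = False


def _emit(kinetic_mev, species, position, direction, cfg, stabs, flat, strides,
          grid, ledger, secondaries):
    """Queue one charged secondary, or deposit it locally if below cutoff."""
    a = SPECIES[species].A
    e_u = kinetic_mev / a
    if e_u < cfg.em.cutoff_mev_u:
        iv = grid.index_of(position)
        if np.all((iv >= 0) & (iv < np.array(grid.shape))):
            flat[int(iv @ strides)] += kinetic_mev
            ledger.add("deposited", kinetic_mev)
        else:
            ledger.add("escaped", kinetic_mev)
        return
    secondaries.append((stabs.index[species], position.copy(),
                        np.asarray(direction, dtype=float), e_u))
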
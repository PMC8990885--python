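"""Non-elastic event generation: the data-driven fragmentation model.

A non-elastic interaction of a carbon projectile is simulated in four steps:

1. choose the struck target nucleus from the cumulative distribution
   P_i = n_i sigma_i / sigma_tot over the material's elements (data-fit
   cross-sections for H and C targets, geometric Kox scaling otherwise);
2. draw the emitted fragment species from the packaged per-target cumulative
   production table: projectile-side species are drawn sequentially until
   either the projectile's 12-nucleon budget is exhausted or a draw would
   overshoot the remaining mass/charge budget, which closes the set with
   the leftover nucleons in an untracked bound residual; one target-side
   fragment is drawn per event (see docs/methods.md);
3. sample each fragment's (E, theta) at the 95 MeV/u calibration energy from
   a two-component distribution: a forward-peaked Gaussian for projectile
   fragments and a decaying exponential for target fragments, with
   hydrogen-like species (n, 1H, 2H, 3H) drawn from the full two-component
   mixture because the two contributions overlap for them;
4. rescale energies to the actual projectile energy, E_i = E95 * (E/95) *
   (1 - k) with the correlation term k = c (1 - R), c = 0.4, and angles by
   theta_i = theta95 * sqrt(95/E), the angle scaling skipped for protons and
   neutrons. The whole set is redrawn until the total fragment kinetic
   energy does not exceed the projectile kinetic energy.

All tabulated distributions were calibrated on 95 MeV/u thin-target
fragmentation measurements (H, C and O targets); other target elements are
mapped to the nearest packaged table by mass number while their interaction
probability still uses the actual nuclide's cross-section.
"""
from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import ConfigurationError, InvalidMaterialError, SamplingFailureError
from .materials import Material
from .species import HYDROGEN_LIKE, SPECIES, get_element, get_species
from .xs import CCFitParams, DEFAULT_CC, sigma_nonelastic

__all__ = [
    "E_CAL",
    "C_CORRELATION",
    "EmissionParams",
    "FragTables",
    "default_tables",
    "sample_target_nucleus",
    "sample_fragment_set",
    "sample_energy_angle",
    "scale_energy",
    "scale_angle",
    "generate_event",
    "Fragment",
    "EventRecord",
]

E_CAL = 95.0          # MeV/u, calibration energy of the packaged tables
C_CORRELATION = 0.4   # correlation factor of the energy rescaling
E_EXP_MAX = 95.0      # MeV/u, truncation of the exponential energy component
THETA_MAX = 180.0     # degrees
MAX_RESAMPLES = 1000

_SQRT2PI = math.sqrt(2.0 * math.pi)


def _phi(x: float) -> float:
    """Standard normal CDF."""
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@dataclass(frozen=True)
class EmissionParams:
    """Parameters of the two-component (E, theta) emission distribution for
    one (target, species) pair; component weights integrated over the
    truncated support are precomputed for mixture sampling."""

    A1: float
    A2: float
    E_mean: float     # MeV/u
    sigma_E: float    # MeV/u
    th_mean: float    # degrees (0 for all packaged rows)
    sigma_th: float   # degrees
    alpha_E: float    # 1/(MeV/u)
    alpha_th: float   # 1/degree
    w_exp: float = field(init=False)
    w_gauss: float = field(init=False)

    def __post_init__(self):
        if min(self.sigma_E, self.sigma_th, self.alpha_E, self.alpha_th) <= 0:
            raise ConfigurationError("emission widths/slopes must be > 0")
        we = (
            self.A1
            * (1.0 - math.exp(-self.alpha_E * E_EXP_MAX)) / self.alpha_E
            * (1.0 - math.exp(-self.alpha_th * THETA_MAX)) / self.alpha_th
        )
        wg = (
            self.A2
            * self.sigma_E * _SQRT2PI * _phi(self.E_mean / self.sigma_E)
            * self.sigma_th * _SQRT2PI
            * (_phi((THETA_MAX - self.th_mean) / self.sigma_th)
               - _phi(-self.th_mean / self.sigma_th))
        )
        object.__setattr__(self, "w_exp", we)
        object.__setattr__(self, "w_gauss", wg)


class FragTables:
    """Packaged production probabilities and emission parameters."""

    def __init__(self, production: dict, emission: dict, sources: dict):
        self.production = production  # target -> {species: fraction}
        self.emission = emission      # (target, species) -> EmissionParams
        self.sources = sources        # (target, species) -> tag
        self._cum = {}
        self._names = {}
        for targ, probs in production.items():
            names = list(probs)
            p = np.array([probs[n] for n in names], dtype=float)
            if np.any(p < 0):
                raise ConfigurationError(f"negative probability in {targ} table")
            p = p / p.sum()
            cum = np.cumsum(p)
            cum[-1] = 1.0
            self.production[targ] = dict(zip(names, p))
            self._cum[targ] = cum
            self._names[targ] = names

    @classmethod
    def load(cls) -> "FragTables":
        prod_path = resources.files("carbonmc.data") / "production_probabilities.tsv"
        emis_path = resources.files("carbonmc.data") / "emission_params.tsv"
        production: dict = {}
        sources: dict = {}
        for line in prod_path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            targ, sp, prob, src = line.split("\t")
            get_species(sp)
            production.setdefault(targ, {})[sp] = float(prob)
            sources[(targ, sp)] = src.strip()
        emission: dict = {}
        for line in emis_path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            emission[(f[0], f[1])] = EmissionParams(*[float(x) for x in f[2:10]])
        return cls(production, emission, sources)

    @property
    def targets(self) -> list[str]:
        return list(self.production)

    def cumulative(self, target: str) -> np.ndarray:
        return self._cum[target]

    def species_names(self, target: str) -> list[str]:
        return self._names[target]

    def sample_species(self, target: str, rng: np.random.Generator, size=None):
        """Direct draw(s) from the cumulative production distribution."""
        cum = self._cum[target]
        names = self._names[target]
        if size is None:
            return names[bisect_right(cum, rng.random())]
        idx = np.searchsorted(cum, rng.random(size), side="right")
        return np.asarray(names)[np.minimum(idx, len(names) - 1)]

    def params(self, target: str, species: str) -> EmissionParams:
        try:
            return self.emission[(target, species)]
        except KeyError:
            raise ConfigurationError(
                f"no emission parameters for {species} on {target}"
            ) from None


_DEFAULT: FragTables | None = None


def default_tables() -> FragTables:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = FragTables.load()
    return _DEFAULT


#: Elements without a dedicated measured table are mapped to the nearest
#: packaged target by mass number (ties go to the heavier table).
def map_target(element: str) -> str:
    if element in ("H", "C", "O"):
        return element
    A = get_element(element).A
    candidates = [("H", 1.008), ("C", 12.011), ("O", 15.999)]
    return min(candidates, key=lambda t: (abs(t[1] - A), -t[1]))[0]


def target_probabilities(
    material: Material, E_mev_u: float, params: CCFitParams = DEFAULT_CC
) -> dict[str, float]:
    """P_i = n_i sigma_i / sigma_tot over the material's elements."""
    if not material.composition:
        raise InvalidMaterialError("material has no composition")
    w = np.array(
        [
            c.number_fraction * sigma_nonelastic(c.symbol, E_mev_u, params=params)
            for c in material.composition
        ]
    )
    tot = w.sum()
    if tot <= 0:
        raise InvalidMaterialError("all cross-sections vanish")
    return {c.symbol: float(x) for c, x in zip(material.composition, w / tot)}


def sample_target_nucleus(
    material: Material,
    E_mev_u: float,
    rng: np.random.Generator,
    params: CCFitParams = DEFAULT_CC,
    size: int | None = None,
):
    """Choose the struck element with P_i = n_i sigma_i / sigma_tot."""
    probs = target_probabilities(material, E_mev_u, params)
    syms = list(probs)
    if len(syms) == 1:
        return syms[0] if size is None else np.full(size, syms[0])
    cum = np.cumsum(list(probs.values()))
    if size is None:
        return syms[min(bisect_right(cum, rng.random()), len(syms) - 1)]
    idx = np.minimum(np.searchsorted(cum, rng.random(size), side="right"),
                     len(syms) - 1)
    return np.asarray(syms)[idx]


def _sample_gaussian(p: EmissionParams, rng) -> tuple[float, float]:
    # truncated normals: E > 0; theta in [0, 180] (folding == truncation
    # for the packaged th_mean = 0 rows)
    while True:
        E = p.E_mean + p.sigma_E * rng.standard_normal()
        if E > 0.0:
            break
    while True:
        th = abs(p.th_mean + p.sigma_th * rng.standard_normal())
        if th <= THETA_MAX:
            break
    return E, th


def _sample_exponential(p: EmissionParams, rng) -> tuple[float, float]:
    # inverse-CDF truncated exponentials on (0, E_EXP_MAX] and (0, 180]
    uE = rng.random()
    E = -math.log(1.0 - uE * (1.0 - math.exp(-p.alpha_E * E_EXP_MAX))) / p.alpha_E
    ut = rng.random()
    th = -math.log(1.0 - ut * (1.0 - math.exp(-p.alpha_th * THETA_MAX))) / p.alpha_th
    return E, th


def sample_energy_angle(
    species: str,
    target: str,
    origin: str,
    rng: np.random.Generator,
    tables: FragTables | None = None,
    size: int | None = None,
):
    """Draw (E95 [MeV/u], theta95 [degrees]) at the calibration energy.

    Hydrogen-like species (n, 1H, 2H, 3H) are drawn from the full
    two-component mixture regardless of origin; all other species use the
    Gaussian component when ``origin == 'projectile'`` and the exponential
    component when ``origin == 'target'``. With ``size`` set, returns two
    arrays (vectorized path, statistically identical to the scalar one).
    """
    tables = tables or default_tables()
    if origin not in ("projectile", "target"):
        raise ConfigurationError(f"origin must be projectile/target, not {origin!r}")
    p = tables.params(target, species)
    mixture = species in HYDROGEN_LIKE
    if size is None:
        E, th, _ = _sample_ea(p, mixture, origin, rng)
        return E, th
    return _sample_energy_angle_vec(p, mixture, origin, rng, size)


def _sample_ea(p: EmissionParams, mixture: bool, origin: str, rng):
    """Scalar draw; also reports whether the exponential (target-like)
    component supplied the value."""
    if mixture:
        use_exp = rng.random() < p.w_exp / (p.w_exp + p.w_gauss)
    else:
        use_exp = origin == "target"
    E, th = (_sample_exponential if use_exp else _sample_gaussian)(p, rng)
    return E, th, use_exp


def _sample_energy_angle_vec(p, mixture, origin, rng, size):
    if mixture:
        use_exp = rng.random(size) < p.w_exp / (p.w_exp + p.w_gauss)
    else:
        use_exp = np.full(size, origin == "target")
    E = np.empty(size)
    th = np.empty(size)
    ng = int((~use_exp).sum())
    if ng:
        Eg = p.E_mean + p.sigma_E * rng.standard_normal(ng)
        while True:
            bad = Eg <= 0
            if not bad.any():
                break
            Eg[bad] = p.E_mean + p.sigma_E * rng.standard_normal(int(bad.sum()))
        tg = np.abs(p.th_mean + p.sigma_th * rng.standard_normal(ng))
        while True:
            bad = tg > THETA_MAX
            if not bad.any():
                break
            tg[bad] = np.abs(p.th_mean + p.sigma_th * rng.standard_normal(int(bad.sum())))
        E[~use_exp] = Eg
        th[~use_exp] = tg
    ne = int(use_exp.sum())
    if ne:
        E[use_exp] = (
            -np.log(1.0 - rng.random(ne) * (1.0 - math.exp(-p.alpha_E * E_EXP_MAX)))
            / p.alpha_E
        )
        th[use_exp] = (
            -np.log(1.0 - rng.random(ne) * (1.0 - math.exp(-p.alpha_th * THETA_MAX)))
            / p.alpha_th
        )
    return E, th


def scale_energy(
    E95: float,
    E_proj: float,
    prev: list[tuple[float, float]] | None = None,
    c: float = C_CORRELATION,
) -> float:
    """Rescale a projectile-fragment calibration energy to beam energy E_proj:
    E_i = E95 * (E_proj/95) * (1 - k), k = c (1 - R), with R the A-weighted
    mean per-nucleon energy of the previously scaled fragments over E_proj.
    ``prev`` holds (E_j [MeV/u], A_j) pairs; empty/None gives R = 1 (k = 0)."""
    if E_proj <= 0:
        raise ConfigurationError("E_proj must be > 0")
    if prev:
        sumEA = sum(e * a for e, a in prev)
        sumA = sum(a for _, a in prev)
        R = (sumEA / sumA) / E_proj
    else:
        R = 1.0
    k = c * (1.0 - R)
    out = E95 * (E_proj / E_CAL) * (1.0 - k)
    if out < 0.0:
        import warnings

        warnings.warn("negative scaled energy clamped to 0", stacklevel=2)
        return 0.0
    return out


def scale_target_energy(E95: float, E_proj: float) -> float:
    """Target fragments rescale with the same linear factor, no correlation."""
    if E_proj <= 0:
        raise ConfigurationError("E_proj must be > 0")
    return E95 * (E_proj / E_CAL)


def scale_angle(theta95: float, E_proj: float, species: str) -> float:
    """theta_i = theta95 * sqrt(95/E_proj); protons and neutrons are left
    unscaled (their emission angle is nearly energy-independent)."""
    if E_proj <= 0:
        raise ConfigurationError("E_proj must be > 0")
    if species in ("n", "1H"):
        return theta95
    return min(theta95 * math.sqrt(E_CAL / E_proj), THETA_MAX)


@dataclass
class Fragment:
    species: str
    origin: str       # 'projectile' | 'target'
    E: float          # MeV/u
    theta: float      # rad, polar angle w.r.t. projectile direction
    phi: float        # rad, azimuth

    @property
    def Z(self) -> int:
        return SPECIES[self.species].Z

    @property
    def A(self) -> int:
        return SPECIES[self.species].A

    @property
    def kinetic(self) -> float:
        """Total kinetic energy, MeV."""
        return self.E * self.A


@dataclass
class EventRecord:
    """One non-elastic fragmentation event."""

    target: str
    fragments: list[Fragment]
    resamples: int = 0

    @property
    def projectile_fragments(self) -> list[Fragment]:
        return [f for f in self.fragments if f.origin == "projectile"]

    @property
    def sum_Z(self) -> int:
        return sum(f.Z for f in self.projectile_fragments)

    @property
    def sum_A(self) -> int:
        return sum(f.A for f in self.projectile_fragments)

    @property
    def total_kinetic(self) -> float:
        """MeV summed over every fragment (neutrons included)."""
        return sum(f.kinetic for f in self.fragments)

    @property
    def n_charged(self) -> int:
        return sum(1 for f in self.fragments if f.Z > 0)


def _draw_species_sets(
    target: str, tables: FragTables, rng, guard: list[int]
) -> tuple[list[str], list[str]]:
    cum = tables.cumulative(target)
    names = tables.species_names(target)
    el = get_element(target)
    proj: list[str] = []
    remA, remZ = 12, 6
    while remA > 0:
        sp = SPECIES[names[bisect_right(cum, rng.random())]]
        if sp.A > remA or sp.Z > remZ:
            # a draw that overshoots the remaining mass/charge budget closes
            # the set; leftover nucleons form an untracked bound residual
            break
        proj.append(sp.name)
        remA -= sp.A
        remZ -= sp.Z
    while True:
        sp = SPECIES[names[bisect_right(cum, rng.random())]]
        if sp.A <= el.A + 0.5 and sp.Z <= el.Z:
            break
        guard[0] += 1
        if guard[0] > MAX_RESAMPLES:
            raise SamplingFailureError("target-side species draw budget exhausted")
    return proj, [sp.name]


def sample_fragment_set(
    target: str,
    E_proj: float,
    rng: np.random.Generator,
    tables: FragTables | None = None,
) -> EventRecord:
    """Draw the species content of one event (no kinematics yet).

    Projectile-side species are drawn from the cumulative table until the
    12-nucleon budget is exhausted or a draw would exceed the remaining
    mass/charge budget (which closes the set). One target-side species is
    drawn subject to the target's own A/Z limits. Kinematics (and the
    energy-conservation resampling loop) are applied by
    :func:`generate_event`.
    """
    tables = tables or default_tables()
    table_key = map_target(target)
    guard = [0]
    proj, targ = _draw_species_sets(table_key, tables, rng, guard)
    frags = [Fragment(s, "projectile", 0.0, 0.0, 0.0) for s in proj]
    frags += [Fragment(s, "target", 0.0, 0.0, 0.0) for s in targ]
    return EventRecord(target=target, fragments=frags)


def generate_event(
    material: Material,
    E_proj: float,
    rng: np.random.Generator,
    tables: FragTables | None = None,
    params: CCFitParams = DEFAULT_CC,
    target: str | None = None,
) -> EventRecord:
    """Generate one complete non-elastic event on ``material`` (or on a fixed
    ``target`` element). The projectile carbon is consumed by the event.

    The full set (species, energies, angles) is redrawn until the total
    fragment kinetic energy does not exceed the projectile kinetic energy;
    mass and charge conservation on the projectile side hold by
    construction of the species draw.
    """
    tables = tables or default_tables()
    if target is None:
        target = sample_target_nucleus(material, E_proj, rng, params)
    table_key = map_target(target)
    budget = 12.0 * E_proj
    guard = [0]
    for attempt in range(MAX_RESAMPLES + 1):
        proj_names, targ_names = _draw_species_sets(table_key, tables, rng, guard)
        frags: list[Fragment] = []
        prev: list[tuple[float, float]] = []
        total = 0.0
        for name in proj_names:
            p = tables.params(table_key, name)
            E95, th95, from_exp = _sample_ea(p, name in HYDROGEN_LIKE,
                                             "projectile", rng)
            if from_exp:
                # the exponential component is the target-like contribution:
                # scale linearly, keep it out of the correlation chain
                E = scale_target_energy(E95, E_proj)
            else:
                E = scale_energy(E95, E_proj, prev)
                prev.append((E, float(SPECIES[name].A)))
            th = scale_angle(th95, E_proj, name)
            frags.append(
                Fragment(name, "projectile", E, math.radians(th),
                         rng.uniform(0.0, 2.0 * math.pi))
            )
            total += E * SPECIES[name].A
        for name in targ_names:
            E95, th95 = sample_energy_angle(name, table_key, "target", rng, tables)
            E = scale_target_energy(E95, E_proj)
            th = scale_angle(th95, E_proj, name)
            frags.append(
                Fragment(name, "target", E, math.radians(th),
                         rng.uniform(0.0, 2.0 * math.pi))
            )
            total += E * SPECIES[name].A
        if total <= budget:
            return EventRecord(target=target, fragments=frags, resamples=attempt)
    raise SamplingFailureError(
        f"energy conservation not reached in {MAX_RESAMPLES} resamples"
    )
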
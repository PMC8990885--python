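"""Observables and QA: profiles, Bragg-peak finding, SOBP weights, γ-index.

The γ comparison uses the standard combined dose-difference /
distance-to-agreement metric with GLOBAL dose normalization (percent of the
reference maximum) and a low-dose cutoff on the reference grid. The search
is a local exhaustive scan over a (3 x DTA)-radius neighborhood on the
evaluation grid, optionally refined on a sub-voxel lattice by trilinear
interpolation around the best coarse offset.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import nnls

from .em import get_table, straggling_sigma
from .errors import (
    AmbiguousPeakError,
    ConfigurationError,
    InvalidGeometryError,
)
from .engine import DoseGrid
from .materials import WATER

__all__ = [
    "Profile1D",
    "depth_dose",
    "lateral_profile",
    "find_bragg_peak",
    "analytic_bragg_curve",
    "SOBPPlan",
    "build_sobp",
    "GammaResult",
    "gamma_index",
]


@dataclass
class Profile1D:
    coords: np.ndarray       # bin centers, cm
    values: np.ndarray
    axis: str = "z"
    description: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.coords) <= 0):
            raise ConfigurationError("profile grid must be strictly increasing")

    @property
    def bin_width(self) -> float:
        return float(self.coords[1] - self.coords[0])


_AXES = {"x": 0, "y": 1, "z": 2}


def depth_dose(dose: DoseGrid, axis: str = "z") -> Profile1D:
    """Transversally integrated dose vs depth: sum_xy D * dx * dy (Gy cm^2)."""
    ia = _AXES[axis]
    others = tuple(i for i in range(3) if i != ia)
    area = float(np.prod([dose.grid.voxel_size[i] for i in others]))
    vals = dose.dose.sum(axis=others) * area
    return Profile1D(dose.grid.voxel_centers(ia), vals, axis=axis,
                     description="transverse-integrated depth dose")


def lateral_profile(dose: DoseGrid, depth_cm: float, axis: str = "x",
                    beam_axis: str = "z") -> Profile1D:
    """1D transverse profile at the slice nearest ``depth_cm``, integrated
    over the remaining transverse axis (Gy cm)."""
    ib = _AXES[beam_axis]
    ia = _AXES[axis]
    if ia == ib:
        raise ConfigurationError("lateral axis must differ from beam axis")
    centers = dose.grid.voxel_centers(ib)
    lo = dose.grid.origin[ib]
    hi = lo + dose.grid.extent[ib]
    if not (lo <= depth_cm <= hi):
        raise InvalidGeometryError(f"depth {depth_cm} cm outside grid [{lo}, {hi}]")
    k = int(np.argmin(np.abs(centers - depth_cm)))
    iother = next(i for i in range(3) if i not in (ia, ib))
    sl = [slice(None)] * 3
    sl[ib] = k
    plane = dose.dose[tuple(sl)]
    # after slicing, the remaining axes keep their relative order
    sum_axis = 0 if iother < ia else 1
    vals = plane.sum(axis=sum_axis) * dose.grid.voxel_size[iother]
    return Profile1D(dose.grid.voxel_centers(ia), vals, axis=axis,
                     description=f"lateral profile at depth {centers[k]:.3f} cm")


def find_bragg_peak(profile: Profile1D) -> float:
    """Coordinate (cm) of the profile's global maximum, refined by a
    three-point parabola. Raises if the maximum is flat or at an edge."""
    v = profile.values
    if len(v) < 3 or np.all(v == v[0]):
        raise AmbiguousPeakError("profile is flat or too short")
    k = int(np.argmax(v))
    if k == 0 or k == len(v) - 1:
        raise AmbiguousPeakError("maximum at profile edge (monotone profile?)")
    y0, y1, y2 = v[k - 1], v[k], v[k + 1]
    denom = y0 - 2.0 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return float(profile.coords[k] + delta * profile.bin_width)


def analytic_bragg_curve(energy_mev_u: float, z_cm: np.ndarray,
                         species: str = "12C",
                         energy_spread: float = 0.003) -> np.ndarray:
    """Deterministic depth-dose kernel for SOBP design: stopping power along
    the CSDA slowing-down, Gaussian-blurred by the integrated range
    straggling plus the range spread of a fractional beam ``energy_spread``
    (default 0.3%, emulating the delivery system's momentum spread and
    ripple filter; set 0 for an ideal mono-energetic kernel). Arbitrary
    units proportional to Gy cm^2 per primary; no nuclear attenuation
    (kernels are normalized away in the weight fit)."""
    tab = get_table(species, WATER)
    R0 = tab.range_at(energy_mev_u)  # g/cm^2 == cm in unit-density water
    # residual energy at depth, then stopping power there
    z = np.asarray(z_cm, dtype=float)
    res = np.maximum(R0 - z, 0.0)
    Ez = tab.energy_at_range(res)
    dose = np.where(res > 0, tab.stopping_at(Ez), 0.0)
    # integrated range straggling: var = int (dOmega^2/ds) / (dE/ds)^3 * A dE
    Egrid = tab.energy[tab.energy <= max(energy_mev_u, tab.energy[1])]
    sig_step = straggling_sigma(species, Egrid, 1.0, WATER)  # MeV per sqrt(cm)
    S = tab.stopping_at(Egrid)
    from .species import SPECIES as _SP

    a = _SP[species].A
    integrand = sig_step**2 / S**3 * a
    var = np.trapezoid(integrand, Egrid)
    if energy_spread > 0:
        dE = 1e-3 * energy_mev_u
        drde = (tab.range_at(energy_mev_u + dE)
                - tab.range_at(energy_mev_u - dE)) / (2.0 * dE)
        var += (drde * energy_spread * energy_mev_u) ** 2
    sigma = max(np.sqrt(var), 1e-4)
    # Gaussian convolution on the uniform z grid
    dz = z[1] - z[0]
    half = int(np.ceil(4 * sigma / dz))
    kx = np.arange(-half, half + 1) * dz
    kern = np.exp(-0.5 * (kx / sigma) ** 2)
    kern /= kern.sum()
    return np.convolve(dose, kern, mode="same")


@dataclass
class SOBPPlan:
    """Energy layers and fitted weights producing a flat dose plateau."""

    energies: np.ndarray            # MeV/u, strictly increasing
    weights: np.ndarray             # >= 0, arbitrary fluence units
    target_interval: tuple          # (z_lo, z_hi) cm
    prescription: float             # plateau dose, same units as kernels
    predicted: Profile1D | None = field(default=None)

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.energies) <= 0):
            raise ConfigurationError("energies must be strictly increasing")
        if np.any(self.weights < 0):
            raise ConfigurationError("weights must be >= 0")


def build_sobp(energies, target_interval, prescription, z_cm,
               kernels=None, species: str = "12C",
               flatness_iters: int = 20) -> SOBPPlan:
    """Fit non-negative layer weights so the summed depth dose is flat at
    ``prescription`` over ``target_interval``.

    The solver is non-negative least squares on the layer kernel matrix
    sampled inside the target interval, followed by ``flatness_iters``
    Lawson-style residual-reweighting passes that push the solution toward
    the minimax (flattest worst-case) plateau; the best iterate is kept.

    ``kernels``: optional (n_layers, len(z)) matrix of per-layer depth-dose
    curves; computed from :func:`analytic_bragg_curve` when omitted.
    """
    energies = np.sort(np.asarray(energies, dtype=float))
    z = np.asarray(z_cm, dtype=float)
    z_lo, z_hi = target_interval
    if len(energies) < 1:
        raise ConfigurationError("need at least one energy layer")
    if kernels is None:
        kernels = np.stack([analytic_bragg_curve(e, z, species) for e in energies])
    else:
        kernels = np.asarray(kernels, dtype=float)
    tab = get_table(species, WATER)
    if tab.range_at(energies[-1]) < z_hi:
        raise InvalidGeometryError(
            f"target end {z_hi} cm beyond deepest layer range "
            f"{tab.range_at(energies[-1]):.2f} cm")
    mask = (z >= z_lo) & (z <= z_hi)
    if not mask.any():
        raise InvalidGeometryError("no depth samples inside the target interval")
    Amat = kernels[:, mask].T
    b = np.full(mask.sum(), float(prescription))
    w, _ = nnls(Amat, b)
    best_w, best_dev = w, np.abs(Amat @ w - b).max()
    rw = np.ones(len(b))
    for _ in range(max(flatness_iters, 0)):
        r = Amat @ w - b
        rw = rw * (np.abs(r) + 1e-6 * abs(b.mean()))
        rw /= rw.mean()
        sw = np.sqrt(rw)
        w, _ = nnls(Amat * sw[:, None], b * sw)
        dev = np.abs(Amat @ w - b).max()
        if dev < best_dev:
            best_w, best_dev = w, dev
    w = best_w
    pred = Profile1D(z, kernels.T @ w, axis="z", description="SOBP prediction")
    return SOBPPlan(energies=energies, weights=w, target_interval=(z_lo, z_hi),
                    prescription=float(prescription), predicted=pred)


@dataclass
class GammaResult:
    gamma: np.ndarray        # per-voxel γ (NaN below cutoff)
    pass_rate: float         # percent of evaluated voxels with γ <= 1
    mean_gamma: float
    max_gamma: float
    dta_mm: float
    dd_percent: float
    cutoff_percent: float


def gamma_index(ref: DoseGrid, eval_: DoseGrid, dta_mm: float = 2.0,
                dd_percent: float = 3.0, cutoff_percent: float = 5.0,
                subvoxel: int = 3) -> GammaResult:
    """γ-index of ``eval_`` against ``ref`` (global dose normalization).

    Both grids must share geometry. The per-voxel γ is the minimum over
    spatial offsets within 3 x DTA of
    sqrt(|Δr|²/DTA² + ΔD²/(dd% of ref max)²); offsets are scanned on the
    voxel lattice and refined on a 1/``subvoxel`` sub-lattice around the
    best coarse offset (``subvoxel=1`` disables refinement, making the
    search exactly exhaustive on voxel centers).
    """
    g1, g2 = ref.grid, eval_.grid
    if g1.shape != g2.shape or not np.allclose(g1.voxel_size, g2.voxel_size) \
            or not np.allclose(g1.origin, g2.origin):
        raise InvalidGeometryError("γ comparison requires matching grids")
    D_ref = ref.dose
    D_ev = eval_.dose
    dmax = float(D_ref.max())
    if dmax <= 0:
        raise ConfigurationError("reference dose is empty")
    dd_abs = dd_percent / 100.0 * dmax
    dta_cm = dta_mm / 10.0
    vox = g1.voxel_size
    reach = 3.0 * dta_cm
    nr = [int(np.floor(reach / vox[i])) for i in range(3)]

    gamma2 = np.full(g1.shape, np.inf)
    best = [np.zeros(g1.shape, dtype=np.int8) for _ in range(3)]
    for ox in range(-nr[0], nr[0] + 1):
        for oy in range(-nr[1], nr[1] + 1):
            for oz in range(-nr[2], nr[2] + 1):
                r2 = ((ox * vox[0]) ** 2 + (oy * vox[1]) ** 2
                      + (oz * vox[2]) ** 2)
                if r2 > reach**2:
                    continue
                shifted = _shift(D_ev, (ox, oy, oz))
                g2v = r2 / dta_cm**2 + (D_ref - shifted) ** 2 / dd_abs**2
                upd = g2v < gamma2
                gamma2 = np.where(upd, g2v, gamma2)
                if subvoxel > 1:
                    for k, o in enumerate((ox, oy, oz)):
                        best[k][upd] = o

    if subvoxel > 1:
        gamma2 = _refine(D_ref, D_ev, gamma2, best, vox, dta_cm, dd_abs,
                         subvoxel)

    gam = np.sqrt(gamma2)
    evalmask = D_ref >= cutoff_percent / 100.0 * dmax
    gmask = gam[evalmask]
    out = np.where(evalmask, gam, np.nan)
    if gmask.size == 0:
        raise ConfigurationError("no voxels above the low-dose cutoff")
    return GammaResult(
        gamma=out,
        pass_rate=float(100.0 * np.mean(gmask <= 1.0)),
        mean_gamma=float(gmask.mean()),
        max_gamma=float(gmask.max()),
        dta_mm=dta_mm, dd_percent=dd_percent, cutoff_percent=cutoff_percent,
    )


def _shift(arr: np.ndarray, off) -> np.ndarray:
    """Shifted view of arr sampling arr[i+off]; out-of-grid -> +inf dose
    difference (edge voxels simply cannot match there)."""
    out = np.full_like(arr, np.inf)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for k, o in enumerate(off):
        n = arr.shape[k]
        if o >= 0:
            dst[k] = slice(0, n - o)
            src[k] = slice(o, n)
        else:
            dst[k] = slice(-o, n)
            src[k] = slice(0, n + o)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _refine(D_ref, D_ev, gamma2, best, vox, dta_cm, dd_abs, subvoxel):
    """Trilinear sub-voxel scan in the +-1 voxel cube around the best
    coarse offset of every voxel."""
    shape = D_ref.shape
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    base = [ii + best[0], jj + best[1], kk + best[2]]
    steps = np.arange(-subvoxel, subvoxel + 1) / subvoxel
    for sx in steps:
        for sy in steps:
            for sz in steps:
                coords = [base[0] + sx, base[1] + sy, base[2] + sz]
                vals = map_coordinates(D_ev, coords, order=1, mode="nearest")
                r2 = ((best[0] + sx) * vox[0]) ** 2 \
                    + ((best[1] + sy) * vox[1]) ** 2 \
                    + ((best[2] + sz) * vox[2]) ** 2
                g2v = r2 / dta_cm**2 + (D_ref - vals) ** 2 / dd_abs**2
                gamma2 = np.minimum(gamma2, g2v)
    return gamma2
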
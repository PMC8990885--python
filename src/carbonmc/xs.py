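"""Nuclear cross-sections, attenuation coefficients, and elastic kinematics.

Non-elastic cross-sections are built from a single energy-dependent fit to
carbon-carbon reaction data,

    sigma(E) = K * (1 - exp(-E/E_c)) * (p0 + p1*E + exp(p2 - p3*E)),

with E the TOTAL projectile kinetic energy in MeV and K a dimensionless
ratio of Kox reaction cross-sections that rescales the carbon-carbon fit to
any projectile/target pair (K = 1 for carbon on carbon). Hydrogen targets
are the exception: their cross-section comes from a dedicated fit table
(the reaction channel on hydrogen is poorly described by the geometric
scaling), nearly constant above 250 MeV/u.

Elastic scattering is modeled only for carbon on hydrogen, with the
deflection sampled isotropically in the center-of-mass frame and the
two-body kinematics mapping (theta_c, E_l) to lab-frame angles/energies.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import (
    ConfigurationError,
    InvalidAngleError,
    InvalidEnergyError,
    InvalidMaterialError,
)
from .materials import Material
from .species import get_element, get_species

__all__ = [
    "CCFitParams",
    "sigma_cc",
    "kox_sigma",
    "scaling_K",
    "sigma_c_on_h",
    "sigma_nonelastic",
    "mass_attenuation",
    "ElasticOutcome",
    "elastic_kinematics",
    "sample_elastic",
]

MB_TO_CM2 = 1e-27
N_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class CCFitParams:
    """Fit parameters of the carbon-carbon non-elastic cross-section."""

    E_c: float = 30.0       # MeV
    p0: float = 762.0       # mb
    p1: float = 14.0e-4     # mb/MeV
    p2: float = 6.7         # dimensionless
    p3: float = 13.4e-3     # 1/MeV

    def __post_init__(self):
        if min(self.E_c, self.p0, self.p1, self.p2, self.p3) <= 0:
            raise ConfigurationError("all fit parameters must be positive")


DEFAULT_CC = CCFitParams()


def sigma_cc(E_total_mev, params: CCFitParams = DEFAULT_CC):
    """Carbon-carbon non-elastic cross-section (mb) vs total kinetic energy."""
    E = np.asarray(E_total_mev, dtype=float)
    if np.any(E < 0):
        raise InvalidEnergyError("total energy must be >= 0")
    out = (1.0 - np.exp(-E / params.E_c)) * (
        params.p0 + params.p1 * E + np.exp(params.p2 - params.p3 * E)
    )
    return float(out) if out.ndim == 0 else out


# Energy-dependent transparency parameter of the Kox parameterization,
# interpolated in lab kinetic energy per nucleon; rises from ~0 at Fermi
# energies and saturates above ~200 MeV/u.
_KOX_C_E = np.array([10.0, 30.0, 100.0, 200.0, 300.0, 2000.0])
_KOX_C = np.array([0.0, 1.0, 1.9, 2.05, 2.1, 2.1])
_R0_FM = 1.1
_A_SURF = 1.85
_RC_FM = 1.3
_E2_MEV_FM = 1.44  # e^2/(4 pi eps0)


def kox_sigma(proj: str, targ: str, E_mev_u) -> np.ndarray | float:
    """Kox geometric reaction cross-section (mb).

    ``proj``/``targ`` are species or element names; ``E_mev_u`` is the lab
    kinetic energy per projectile nucleon. The parameterization is symmetric
    under projectile-target exchange at fixed E per nucleon.
    """
    Ap, Zp = _nuclide(proj)
    At, Zt = _nuclide(targ)
    E = np.asarray(E_mev_u, dtype=float)
    ap3, at3 = Ap ** (1.0 / 3.0), At ** (1.0 / 3.0)
    c = np.interp(E, _KOX_C_E, _KOX_C)
    radius = ap3 + at3 + _A_SURF * ap3 * at3 / (ap3 + at3) - c
    # non-relativistic CM energy from total lab kinetic energy
    Ecm = E * Ap * At / (Ap + At)
    Bc = Zp * Zt * _E2_MEV_FM / (_RC_FM * (ap3 + at3))
    out = (
        np.pi
        * _R0_FM**2
        * np.maximum(radius, 0.0) ** 2
        * np.maximum(1.0 - Bc / np.maximum(Ecm, 1e-12), 0.0)
        * 10.0  # fm^2 -> mb
    )
    return float(out) if out.ndim == 0 else out


def _nuclide(name: str) -> tuple[float, int]:
    """Accept either a fragment species ('4He') or an element symbol ('O')."""
    try:
        sp = get_species(name)
        return float(sp.A), sp.Z
    except ConfigurationError:
        el = get_element(name)
        return el.A, el.Z


def scaling_K(proj: str, targ: str, E_mev_u) -> np.ndarray | float:
    """Ratio of Kox cross-sections to carbon-carbon; identically 1 for C-C."""
    return kox_sigma(proj, targ, E_mev_u) / kox_sigma("12C", "C", E_mev_u)


def _load_h_table() -> tuple[np.ndarray, np.ndarray]:
    path = resources.files("carbonmc.data") / "c_on_h_xs_synthetic.tsv"
    data = np.loadtxt(str(path))
    return data[:, 0], data[:, 1]


_H_TABLE = None


def sigma_c_on_h(E_mev_u) -> np.ndarray | float:
    """Carbon-on-hydrogen non-elastic cross-section (mb), from the packaged
    fit table (synthetic stand-in reproducing the measured high-energy
    plateau; see docs/methods.md). Clamped with a warning outside
    10-450 MeV/u."""
    global _H_TABLE
    if _H_TABLE is None:
        _H_TABLE = _load_h_table()
    grid, vals = _H_TABLE
    E = np.asarray(E_mev_u, dtype=float)
    if np.any(E < grid[0]) or np.any(E > grid[-1]):
        warnings.warn(
            f"energy outside [{grid[0]}, {grid[-1]}] MeV/u; cross-section clamped",
            stacklevel=2,
        )
    out = np.interp(E, grid, vals)
    return float(out) if out.ndim == 0 else out


def sigma_nonelastic(targ_element: str, E_mev_u, proj: str = "12C",
                     params: CCFitParams = DEFAULT_CC):
    """Assembled non-elastic cross-section (mb) of a carbon projectile on one
    target element at E MeV/u: data fit for H and C, Kox-scaled fit otherwise."""
    Ap, _ = _nuclide(proj)
    E_total = np.asarray(E_mev_u, dtype=float) * Ap
    if targ_element == "H":
        return sigma_c_on_h(E_mev_u)
    if targ_element == "C" and proj == "12C":
        return sigma_cc(E_total, params)
    return scaling_K(proj, targ_element, E_mev_u) * sigma_cc(E_total, params)


def mass_attenuation(
    material: Material,
    proj: str = "12C",
    E_mev_u: float = 95.0,
    elastic_fraction: float = 0.0,
    params: CCFitParams = DEFAULT_CC,
) -> float:
    """Nuclear mass attenuation coefficient mu/rho (cm^2/g),

        mu/rho = sum_i N_A w_i sigma_t^i / A_i,

    with sigma_t the total (elastic + non-elastic) cross-section per element.
    The elastic channel exists only on hydrogen, as ``elastic_fraction`` of
    the hydrogen-target non-elastic value.
    """
    if not material.composition:
        raise InvalidMaterialError("material has no composition")
    total = 0.0
    for comp in material.composition:
        sig = sigma_nonelastic(comp.symbol, E_mev_u, proj, params)
        if comp.symbol == "H":
            sig = sig * (1.0 + elastic_fraction)
        total += N_AVOGADRO * comp.mass_fraction * sig * MB_TO_CM2 / comp.A
    if total <= 0:
        raise InvalidMaterialError("all cross-sections vanish")
    return float(total)


@dataclass(frozen=True)
class ElasticOutcome:
    """Lab-frame outcome of one carbon-on-hydrogen elastic collision."""

    theta_l: float   # projectile lab angle, rad
    E_l_prime: float  # projectile kinetic energy after, MeV
    phi_l: float     # recoil proton lab angle, rad
    E_l_p: float     # recoil proton kinetic energy, MeV


def elastic_kinematics(theta_c: float, E_l: float, A: float = 12.0) -> ElasticOutcome:
    """Two-body elastic kinematics for a projectile of mass number A on a
    unit-mass (hydrogen) target, non-relativistic lab/CM relations:

        cos(theta_l) = (A + cos th_c) / sqrt(A^2 + 2A cos th_c + 1)
        E_l'         = [(1+alpha) + (1-alpha) cos th_c]/2 * E_l
        cos(phi_l)   = sqrt((1 + cos th_c)/2)
        E_l^p        = 2A E_l (1 - cos th_c)/(A+1)^2

    with alpha = (A-1)^2/(A+1)^2. Kinetic energy is conserved exactly.
    """
    if not (0.0 <= theta_c <= np.pi):
        raise InvalidAngleError(f"theta_c={theta_c} outside [0, pi]")
    if E_l <= 0:
        raise InvalidEnergyError("E_l must be > 0")
    ct = np.cos(theta_c)
    denom = np.sqrt(A * A + 2.0 * A * ct + 1.0)
    theta_l = float(np.arccos(np.clip((A + ct) / denom, -1.0, 1.0)))
    alpha = (A - 1.0) ** 2 / (A + 1.0) ** 2
    E_lp = 0.5 * ((1.0 + alpha) + (1.0 - alpha) * ct) * E_l
    E_p = 2.0 * A * E_l * (1.0 - ct) / (A + 1.0) ** 2
    phi_l = float(np.arccos(np.clip(np.sqrt((1.0 + ct) / 2.0), -1.0, 1.0)))
    return ElasticOutcome(theta_l, float(E_lp), phi_l, float(E_p))


def sample_elastic(rng: np.random.Generator, E_l: float, A: float = 12.0) -> ElasticOutcome:
    """Draw one elastic collision with the CM deflection isotropic
    (cos theta_c uniform on [-1, 1])."""
    cos_tc = rng.uniform(-1.0, 1.0)
    return elastic_kinematics(float(np.arccos(cos_tc)), E_l, A)
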
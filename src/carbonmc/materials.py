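"""Materials, voxelized phantoms, and CT-number density calibration.

Coordinate convention (fixed package-wide): right-handed axes, beam default
along +z, world origin at the center of the phantom entrance face (z = 0).
Voxel indexing is 0-based with half-open intervals [edge, next edge).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidGeometryError
from .species import ELEMENTS

__all__ = [
    "MaterialComponent",
    "Material",
    "WATER",
    "VoxelGrid",
    "make_water_phantom",
    "DensityCalibration",
    "hu_to_density",
]


@dataclass(frozen=True)
class MaterialComponent:
    symbol: str          # element symbol
    mass_fraction: float  # w_i
    A: float             # mass number (g/mol)
    Z: int               # atomic number
    number_fraction: float  # n_i, atoms of this element per formula unit total


@dataclass(frozen=True)
class Material:
    """Elemental composition and density of a transport medium.

    Number fractions are stored explicitly because target-nucleus sampling
    weights each element's cross-section by its occurrence n_i, not by mass.
    """

    name: str
    density: float  # g/cm^3
    composition: tuple[MaterialComponent, ...]

    def __post_init__(self):
        if self.density <= 0:
            raise ConfigurationError(f"density must be > 0, got {self.density}")
        if not self.composition:
            raise ConfigurationError("material needs at least one component")
        w = sum(c.mass_fraction for c in self.composition)
        if abs(w - 1.0) > 1e-6:
            raise ConfigurationError(f"mass fractions sum to {w}, not 1")
        for c in self.composition:
            if c.A < 1 or c.Z < 1:
                raise ConfigurationError(f"bad nuclide in {self.name}: {c}")

    @property
    def mean_ZA(self) -> float:
        """Electrons per atomic mass unit, sum_i w_i Z_i / A_i."""
        return sum(c.mass_fraction * c.Z / c.A for c in self.composition)

    @property
    def mean_I_eV(self) -> float:
        """Bragg-additivity mean excitation energy (water overridden to 78 eV)."""
        num = sum(
            c.mass_fraction * c.Z / c.A * np.log(ELEMENTS[c.symbol].I_eV)
            for c in self.composition
        )
        return float(np.exp(num / self.mean_ZA))

    @property
    def radiation_length(self) -> float:
        """g/cm^2, from 1/X0 = sum_i w_i / X0_i."""
        return 1.0 / sum(
            c.mass_fraction / ELEMENTS[c.symbol].X0 for c in self.composition
        )


def _water() -> Material:
    # 2:1 H:O number fractions; mass fractions 0.1119 / 0.8881.
    return Material(
        name="water",
        density=1.0,
        composition=(
            MaterialComponent("H", 0.1119, 1.008, 1, 2.0 / 3.0),
            MaterialComponent("O", 0.8881, 15.999, 8, 1.0 / 3.0),
        ),
    )


WATER = _water()


@dataclass
class VoxelGrid:
    """Uniform voxel grid with per-voxel material index and density.

    origin: world coordinates (cm) of the corner of voxel (0, 0, 0); with the
    package convention the entrance face center is at (0, 0, 0) world, so
    origin = (-Lx/2, -Ly/2, 0).
    """

    origin: np.ndarray          # (3,) cm
    voxel_size: np.ndarray      # (3,) cm
    shape: tuple[int, int, int]
    materials: list[Material] = field(default_factory=list)
    material_index: np.ndarray = None  # (nx, ny, nz) uint8
    density: np.ndarray = None         # (nx, ny, nz) g/cm^3

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if np.any(self.voxel_size <= 0):
            raise InvalidGeometryError(f"voxel size must be > 0: {self.voxel_size}")
        if any(n <= 0 for n in self.shape):
            raise InvalidGeometryError(f"grid shape must be positive: {self.shape}")
        if self.material_index is None:
            self.material_index = np.zeros(self.shape, dtype=np.uint8)
        if self.density is None:
            rho = self.materials[0].density if self.materials else 1.0
            self.density = np.full(self.shape, rho, dtype=float)
        if np.any(self.density < 0):
            raise InvalidGeometryError("negative voxel density")

    @property
    def extent(self) -> np.ndarray:
        """Physical size (cm) along each axis."""
        return self.voxel_size * np.asarray(self.shape)

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    def index_of(self, pos: np.ndarray) -> np.ndarray:
        """World position(s) (cm) -> integer voxel indices (floor)."""
        return np.floor((np.asarray(pos) - self.origin) / self.voxel_size).astype(
            np.int64
        )

    def center_of(self, idx: np.ndarray) -> np.ndarray:
        """Voxel indices -> world coordinates of voxel centers."""
        return self.origin + (np.asarray(idx) + 0.5) * self.voxel_size

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def total_mass(self) -> float:
        """Grams of material on the grid."""
        return float(self.density.sum() * self.voxel_volume)


def make_water_phantom(dims_cm=(10.0, 10.0, 40.0), voxel_mm=(0.5, 0.5, 0.5)) -> VoxelGrid:
    """Uniform water box; default is the 10 x 10 x 40 cm reference phantom
    with cubic 0.5 mm voxels, beam entrance face at z = 0."""
    dims = np.asarray(dims_cm, dtype=float)
    vox = np.asarray(voxel_mm, dtype=float) / 10.0  # mm -> cm
    if np.any(dims <= 0) or np.any(vox <= 0):
        raise InvalidGeometryError("phantom dimensions and voxel size must be > 0")
    n = dims / vox
    shape = tuple(int(round(x)) for x in n)
    if np.any(np.abs(n - np.round(n)) > 1e-6):
        raise InvalidGeometryError(
            f"dimensions {dims_cm} cm not divisible by voxel {voxel_mm} mm"
        )
    origin = np.array([-dims[0] / 2.0, -dims[1] / 2.0, 0.0])
    return VoxelGrid(origin=origin, voxel_size=vox, shape=shape, materials=[WATER])


@dataclass(frozen=True)
class DensityCalibration:
    """Piecewise-linear CT-number (HU) to mass-density curve."""

    hu: tuple[float, ...]
    density: tuple[float, ...]

    def __post_init__(self):
        if len(self.hu) < 2 or len(self.hu) != len(self.density):
            raise ConfigurationError("calibration needs >= 2 (HU, density) knots")
        h = np.asarray(self.hu)
        d = np.asarray(self.density)
        if np.any(np.diff(h) <= 0):
            raise ConfigurationError("HU knots must be strictly increasing")
        if np.any(d < 0) or np.any(np.diff(d) < 0):
            raise ConfigurationError("densities must be non-negative, non-decreasing")


#: Two-knot default: air at -1000 HU, water at 0 HU. CT curves are not part
#: of the packaged data; users supply their own for anything quantitative.
DEFAULT_CALIBRATION = DensityCalibration(hu=(-1000.0, 0.0), density=(0.00121, 1.0))


def hu_to_density(calib: DensityCalibration, hu) -> np.ndarray | float:
    """Piecewise-linear interpolation, clamped at the end knots."""
    out = np.interp(hu, calib.hu, calib.density)
    return float(out) if np.isscalar(hu) else out
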
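"""Domain types for voxel Monte-Carlo light transport in tissue.

Conventions used throughout:

* lengths are millimetres, optical coefficients mm⁻¹;
* fluence rate is dimensionless, expressed in multiples of the source exit
  intensity ``I₀ = P / (π · radius²)`` so that the value immediately in front
  of the emission disc is of order one;
* coordinate frame is right-handed stereotaxic: x lateral, y anterior,
  z dorsal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["OpticalProperties", "VoxelGrid", "SourceSpec", "Photon", "FluenceMap"]


def _unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n == 0.0:
        raise ValueError(f"{name} must be a non-zero finite vector")
    return v / n


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous tissue optical properties at a single wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (mm⁻¹).
    mu_s : float
        Scattering coefficient (mm⁻¹).  This is the *full* scattering
        coefficient used together with the anisotropy ``g``; see
        :meth:`from_reduced` when only the reduced coefficient
        ``mu_s' = mu_s (1 − g)`` is known.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering
        deflection), −1 < g < 1.
    n : float
        Refractive index of the tissue.
    """

    mu_a: float
    mu_s: float
    g: float = 0.0
    n: float = 1.37

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must satisfy -1 < g < 1")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.mu_t <= 0:
            raise ValueError("total attenuation mu_a + mu_s must be positive")

    @property
    def mu_t(self) -> float:
        """Total attenuation coefficient mu_a + mu_s (mm⁻¹)."""
        return self.mu_a + self.mu_s

    @property
    def mu_s_reduced(self) -> float:
        """Reduced (transport) scattering coefficient mu_s·(1 − g) (mm⁻¹)."""
        return self.mu_s * (1.0 - self.g)

    @property
    def mu_eff(self) -> float:
        """Effective attenuation sqrt(3·mu_a·(mu_a + mu_s')) of diffusion theory (mm⁻¹)."""
        return float(np.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_reduced)))

    @property
    def transport_mfp(self) -> float:
        """Transport mean free path 1/(mu_a + mu_s') (mm)."""
        return 1.0 / (self.mu_a + self.mu_s_reduced)

    @classmethod
    def from_reduced(cls, mu_a: float, mu_s_reduced: float, g: float = 0.9, n: float = 1.37) -> "OpticalProperties":
        """Build from a *reduced* scattering coefficient.

        Tissue-optics tables frequently report ``mu_s' = mu_s (1 − g)``; a
        Henyey-Greenstein Monte-Carlo then needs ``mu_s = mu_s'/(1 − g)``.
        """
        if not -1.0 < g < 1.0:
            raise ValueError("anisotropy g must satisfy -1 < g < 1")
        return cls(mu_a=mu_a, mu_s=mu_s_reduced / (1.0 - g), g=g, n=n)


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned isotropic voxel grid.

    ``origin`` is the *corner* of voxel (0,0,0); voxel (i,j,k) spans
    ``origin + [i,j,k]·voxel_size`` to ``origin + [i+1,j+1,k+1]·voxel_size``.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if any(s < 1 for s in shape):
            raise ValueError("grid shape entries must be >= 1")

    @classmethod
    def centered(cls, center, extent_mm: float, voxel_size: float) -> "VoxelGrid":
        """Cubic grid of physical edge ``extent_mm`` centred on ``center``."""
        n = int(round(extent_mm / voxel_size))
        center = np.asarray(center, dtype=float)
        origin = center - 0.5 * n * voxel_size
        return cls(shape=(n, n, n), voxel_size=voxel_size, origin=tuple(origin))

    @property
    def extent(self) -> np.ndarray:
        """Physical edge lengths (mm)."""
        return np.asarray(self.shape, dtype=float) * self.voxel_size

    @property
    def voxel_volume(self) -> float:
        """Voxel volume (mm³)."""
        return self.voxel_size**3

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        o = np.asarray(self.origin)
        return bool(np.all(p >= o) and np.all(p < o + self.extent))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis (mm)."""
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.voxel_size


@dataclass(frozen=True)
class SourceSpec:
    """Disc source emitting into a cone, in tissue.

    ``half_angle`` is the emission-cone half angle *inside the tissue*
    (radians); for a fiber of numerical aperture NA in a medium of index n it
    is ``asin(NA / n)``.  Emission is uniform over the disc and uniform in
    solid angle within the cone.
    """

    center: tuple[float, float, float]
    normal: tuple[float, float, float]
    radius: float
    half_angle: float

    def __post_init__(self) -> None:
        normal = _unit(self.normal, "normal")
        object.__setattr__(self, "normal", tuple(normal))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if self.radius <= 0:
            raise ValueError("source radius must be positive")
        if not 0.0 <= self.half_angle < np.pi / 2:
            raise ValueError("half_angle must be in [0, pi/2)")

    @property
    def area(self) -> float:
        """Emission-disc area π·radius² (mm²)."""
        return float(np.pi * self.radius**2)

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Two unit vectors spanning the disc plane (deterministic choice)."""
        n = np.asarray(self.normal)
        helper = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(n, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return e1, e2


@dataclass
class Photon:
    """Monte-Carlo photon packet state."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(self.direction)
        if not np.isclose(nrm, 1.0, atol=1e-9):
            raise ValueError("photon direction must be a unit vector")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("photon weight must be in [0, 1]")


@dataclass
class FluenceMap:
    """Voxelised fluence rate in units of the source exit intensity I₀.

    ``values[i, j, k]`` is the fluence rate in voxel (i,j,k) divided by
    ``I₀ = P/(π·r²)``, the mean intensity over the emission disc.  A value of
    1.0 therefore means "as bright as the fiber exit face".
    """

    grid: VoxelGrid
    values: np.ndarray
    n_photons: int
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("fluence array shape does not match grid shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fluence values must be finite")
        if np.any(self.values < 0):
            raise ValueError("fluence values must be non-negative")

    @property
    def max(self) -> float:
        return float(self.values.max())

    def replace(self, **kw) -> "FluenceMap":
        return dataclasses.replace(self, **kw)
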
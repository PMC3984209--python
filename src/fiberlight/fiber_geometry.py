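"""Fiber pose model: from a physical fiber pose to a Monte-Carlo source.

A side-firing fiber has a 45°-bevelled, mirror-coated tip that redirects all
light perpendicular to the fiber axis.  The pose is described by the tip
position, the insertion-axis direction, a rotation angle ``phi`` about that
axis and a signed translation along it.  ``make_source`` converts a pose into
the disc :class:`~fiberlight.optics.SourceSpec` consumed by the transport
engine.

Frame: right-handed stereotaxic, x lateral, y anterior, z dorsal.  The
default insertion axis is tilted 57° from vertical in the x–z plane,
pointing down into the brain.  ``phi = 0`` maps the emission normal onto the
horizontal perpendicular to the axis that points laterally (+x side);
positive ``phi`` rotates it right-handedly about the (downward) axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from fiberlight.optics import SourceSpec

__all__ = ["FiberConfig", "default_insertion_axis", "make_source", "sweep_configs"]


def default_insertion_axis(angle_from_vertical_deg: float = 57.0) -> tuple[float, float, float]:
    """Unit insertion axis tilted ``angle`` from vertical in the x–z plane, pointing down."""
    a = math.radians(angle_from_vertical_deg)
    return (math.sin(a), 0.0, -math.cos(a))


@dataclass(frozen=True)
class FiberConfig:
    """Pose and optics of the stimulation fiber.

    Parameters
    ----------
    tip : position of the fiber tip (mm).
    axis : unit insertion-axis vector; default 57° from vertical.
    phi : rotation about the axis (degrees, [0, 360)).
    depth_offset : signed translation along the axis (mm); positive moves the
        emission point deeper (further along ``axis``).
    core_diameter : fiber core diameter (mm).
    NA : numerical aperture (defined in air).
    mode : ``"side_firing"`` (emission ⊥ axis) or ``"axial"`` (emission
        along the axis, i.e. a plain flat-cleaved fiber).
    emission_offset : distance of the emission-disc centre from the fiber
        axis along the emission normal (mm), side-firing mode only.  Default
        (``None``) is one core radius — side-fired light exits through the
        cylindrical surface of the fiber, not on its axis.  Set 0 to place
        the disc on the axis.
    """

    tip: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = field(default_factory=default_insertion_axis)
    phi: float = 0.0
    depth_offset: float = 0.0
    core_diameter: float = 0.2
    NA: float = 0.37
    mode: str = "side_firing"
    emission_offset: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        nrm = np.linalg.norm(ax)
        if nrm == 0 or not np.isfinite(nrm):
            raise ValueError("axis must be a non-zero finite vector")
        object.__setattr__(self, "axis", tuple(ax / nrm))
        object.__setattr__(self, "phi", float(self.phi) % 360.0)
        if self.core_diameter <= 0:
            raise ValueError("core_diameter must be positive")
        if self.NA <= 0:
            raise ValueError("NA must be positive")
        if self.mode not in ("side_firing", "axial"):
            raise ValueError("mode must be 'side_firing' or 'axial'")
        if self.emission_offset is not None and self.emission_offset < 0:
            raise ValueError("emission_offset must be non-negative")

    @property
    def effective_emission_offset(self) -> float:
        """Radial offset of the emission disc from the axis (mm)."""
        if self.mode == "axial":
            return 0.0
        return self.core_diameter / 2.0 if self.emission_offset is None else self.emission_offset


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis`` (right-handed)."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


def reference_perpendicular(axis) -> np.ndarray:
    """The ``phi = 0`` emission direction: lateral (+x) projected off the axis."""
    a = np.asarray(axis, dtype=float)
    lateral = np.array([1.0, 0.0, 0.0])
    perp = lateral - np.dot(lateral, a) * a
    nrm = np.linalg.norm(perp)
    if nrm < 1e-12:  # axis along x: fall back to +y
        perp = np.array([0.0, 1.0, 0.0]) - np.dot(np.array([0.0, 1.0, 0.0]), a) * a
        nrm = np.linalg.norm(perp)
    return perp / nrm


def make_source(config: FiberConfig, n_tissue: float = 1.37) -> SourceSpec:
    """Convert a fiber pose into the emission-disc source for the MC engine.

    The emission disc has the core radius.  In ``axial`` mode it sits at
    ``tip + depth_offset·axis`` with its normal along the axis.  In
    ``side_firing`` mode the normal is perpendicular to the axis, oriented by
    ``phi``, and the disc centre is additionally displaced by
    ``emission_offset`` (one core radius by default) along that normal — the
    point where light leaves the fiber surface.  The in-tissue cone
    half-angle is ``asin(NA/n_tissue)`` — NA is conserved across the
    fiber–tissue interface, so the divergence inside tissue is reduced by the
    tissue index.
    """
    if config.NA >= n_tissue:
        raise ValueError("NA must be smaller than the tissue refractive index")
    axis = np.asarray(config.axis)
    center = np.asarray(config.tip, dtype=float) + config.depth_offset * axis
    if config.mode == "axial":
        normal = axis
    else:
        normal = _rotate_about(reference_perpendicular(axis), axis, math.radians(config.phi))
        center = center + config.effective_emission_offset * normal
    return SourceSpec(
        center=tuple(center),
        normal=tuple(normal),
        radius=config.core_diameter / 2.0,
        half_angle=math.asin(config.NA / n_tissue),
    )


def sweep_configs(base: FiberConfig, phis, depth_offsets) -> list[FiberConfig]:
    """Cartesian sweep over rotation angles and axial translations.

    Returns configs ordered by (phi, offset), each labelled
    ``"phi<deg>_dz<mm>"`` so downstream tables are self-describing.
    """
    phis = list(phis)
    depth_offsets = list(depth_offsets)
    if not phis or not depth_offsets:
        raise ValueError("phis and depth_offsets must be non-empty")
    out = []
    for phi in phis:
        for dz in depth_offsets:
            out.append(replace(base, phi=float(phi), depth_offset=float(dz),
                               label=f"phi{float(phi):g}_dz{float(dz):g}"))
    return out
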
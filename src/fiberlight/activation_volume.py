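"""Activated-tissue volumes from fluence maps.

ChR2-expressing neurons reach half-maximum firing rate near a fluence of
0.5 mW/mm² of blue light.  Given a fluence map in units of the source exit
intensity I₀ and a physical I₀ in mW/mm², a voxel counts as activated when
its fluence exceeds the threshold:

    activated  ⇔  Φ/I₀ > threshold / I₀.

Volumes are voxel counts times voxel volume; overlap between two fiber poses
is the intersection volume normalised by, depending on ``mode``, the mean of
the two volumes, their union, or the smaller of the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union

from fiberlight.optics import FluenceMap, VoxelGrid

__all__ = ["ActivationMask", "threshold_volume", "overlap_fraction", "isocontour_slices",
           "CHR2_HALF_MAX_FLUENCE"]

log = logging.getLogger(__name__)

#: fluence (mW/mm²) at which ChR2 neurons fire at half their maximum rate
CHR2_HALF_MAX_FLUENCE = 0.5


@dataclass
class ActivationMask:
    """Boolean voxel set above the activation-fluence threshold."""

    grid: VoxelGrid
    mask: np.ndarray
    source_intensity: float
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid.shape):
            raise ValueError("mask shape does not match grid shape")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume(self) -> float:
        """Activated volume (mm³)."""
        return self.n_voxels * self.grid.voxel_volume


def threshold_volume(fluence: FluenceMap, source_intensity: float,
                     threshold: float = CHR2_HALF_MAX_FLUENCE,
                     normalization: str = "exit") -> ActivationMask:
    """Threshold a normalized fluence map at a physical activation fluence.

    Parameters
    ----------
    fluence : map in units of I₀.
    source_intensity : physical source intensity (mW/mm²); its meaning
        depends on ``normalization``.
    threshold : activation fluence (mW/mm²); default the ChR2 half-maximum.
    normalization : reference to which ``source_intensity`` is attached.
        ``"exit"`` — the disc-mean exit intensity I₀ = P/(π r²), the map's
        native unit.  ``"peak"`` — the fluence *at the source*, i.e. the map
        is first rescaled so its maximum is one ("intensity at the source
        normalized to one"); because of backscatter build-up the fluence at
        the source exceeds I₀ by a few tens of percent in brain-like tissue.
    """
    if source_intensity <= 0:
        raise ValueError("source_intensity must be positive")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if normalization not in ("exit", "peak"):
        raise ValueError("normalization must be 'exit' or 'peak'")
    values = fluence.values
    if normalization == "peak":
        peak = values.max()
        if peak <= 0:
            raise ValueError("cannot peak-normalize an all-zero fluence map")
        values = values / peak
    rel = threshold / source_intensity
    mask = values > rel
    if not mask.any():
        log.warning(
            "threshold %.3g mW/mm2 at source intensity %.3g mW/mm2 exceeds "
            "the maximum fluence (%.3g relative units); activation mask is empty",
            threshold, source_intensity, values.max(),
        )
    return ActivationMask(grid=fluence.grid, mask=mask,
                          source_intensity=float(source_intensity),
                          threshold=float(threshold))


def overlap_fraction(a: ActivationMask, b: ActivationMask, mode: str = "mean") -> float:
    """Spatial overlap of two activation masks, in [0, 1].

    ``mode`` selects the normaliser of the intersection volume:
    ``"mean"`` (default) the mean of the two volumes — for masks congruent
    under rotation/translation this equals either volume; ``"jaccard"`` the
    union; ``"min"`` the smaller volume.
    """
    if a.grid != b.grid:
        raise ValueError("masks must share an identical grid")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise ValueError("overlap is undefined for two empty masks")
    inter = int(np.logical_and(a.mask, b.mask).sum())
    if mode == "mean":
        return inter / ((na + nb) / 2.0)
    if mode == "jaccard":
        return inter / int(np.logical_or(a.mask, b.mask).sum())
    if mode == "min":
        return inter / min(na, nb) if min(na, nb) > 0 else 0.0
    raise ValueError(f"unknown overlap mode {mode!r}")


def isocontour_slices(mask: ActivationMask, axis: int, coordinate: float) -> list[np.ndarray]:
    """Closed boundary contours of the mask on one grid-aligned slice.

    ``axis`` (0, 1, or 2) and ``coordinate`` (mm) select the plane; the voxel
    layer whose centre is nearest the coordinate is contoured.  Contours
    follow the exact voxel boundaries (union of voxel squares), so a single
    active voxel yields a 4-sided contour of area ``voxel_size²``.  Each
    contour is a closed (N, 2) array of the two in-plane coordinates in mm,
    ordered as the remaining axes; interior holes are returned as separate
    closed polylines.
    """
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    coords = mask.grid.axis_coords(axis)
    half = mask.grid.voxel_size / 2
    if not (coords[0] - half <= coordinate <= coords[-1] + half):
        raise ValueError("plane does not intersect the grid")
    layer_idx = int(np.argmin(np.abs(coords - coordinate)))
    plane = np.take(mask.mask, layer_idx, axis=axis)
    if not plane.any():
        return []
    in_plane_axes = [ax for ax in (0, 1, 2) if ax != axis]
    o0 = mask.grid.origin[in_plane_axes[0]]
    o1 = mask.grid.origin[in_plane_axes[1]]
    vs = mask.grid.voxel_size
    cells = [box(o0 + i * vs, o1 + j * vs, o0 + (i + 1) * vs, o1 + (j + 1) * vs)
             for i, j in zip(*np.nonzero(plane))]
    union = unary_union(cells)
    polys = getattr(union, "geoms", [union])
    out = []
    for poly in polys:
        out.append(np.asarray(poly.exterior.coords))
        for ring in poly.interiors:
            out.append(np.asarray(ring.coords))
    return out
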
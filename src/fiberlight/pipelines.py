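"""End-to-end drivers chaining fiber geometry → Monte-Carlo → volumes/overlaps.

These reproduce the simulation-side figures of the study: activated-volume
vs. source intensity for a 200 µm NA 0.37 fiber, pairwise overlap of
45°-rotated side-firing poses at 2.2 mW/mm², and overlap of two poses
translated 300 µm along the fiber axis at 8.9 mW/mm².

The drivers threshold with ``normalization="peak"``: fluence maps are
rescaled so the value at the source is one before the physical tip intensity
is applied ("intensity values at the source normalized to one"); see
docs/methods.md for why this convention is used for the study figures.

Seed policy for sweeps: each fiber configuration gets an independent seed
derived from the base seed and its label (CRC-32 mix, reduced mod 2³¹), so
different poses are statistically independent while the whole sweep is
reproducible from the base seed.
"""

from __future__ import annotations

import zlib
from dataclasses import replace

import numpy as np
import pandas as pd

from fiberlight.activation_volume import (
    CHR2_HALF_MAX_FLUENCE,
    overlap_fraction,
    threshold_volume,
)
from fiberlight.fiber_geometry import FiberConfig, make_source, sweep_configs
from fiberlight.mc_engine import run_mc
from fiberlight.optics import FluenceMap, OpticalProperties, VoxelGrid

__all__ = [
    "BRAIN_OPTICS_473NM",
    "default_grid",
    "derive_seed",
    "simulate_fiber",
    "run_figure_volumes",
    "contour_table",
    "run_rotation_sweep",
    "run_translation_pair",
    "STUDY_INTENSITIES",
]

#: optical properties of mouse brain tissue at 473 nm.  The literature value
#: 4.37 mm⁻¹ is the *reduced* scattering coefficient μs′ = μs(1−g); with the
#: Henyey-Greenstein anisotropy g = 0.9 the full coefficient is
#: μs = μs′/(1−g) = 43.7 mm⁻¹ (see docs/methods.md for the convention
#: analysis).  μa = 0.48 mm⁻¹, n = 1.37.
BRAIN_OPTICS_473NM = OpticalProperties.from_reduced(mu_a=0.48, mu_s_reduced=4.37, g=0.9, n=1.37)

#: source exit intensities (mW/mm²) used across the stimulation experiments
STUDY_INTENSITIES = (1.4, 2.2, 3.2, 8.9)

#: default number of photons per simulation (desk-scale)
DEFAULT_N_PHOTONS = 10_000_000


def default_grid(config: FiberConfig, extent_mm: float = 2.0, voxel_size: float = 0.01) -> VoxelGrid:
    """10 µm isotropic voxels over a cube centred on the fiber tip."""
    return VoxelGrid.centered(config.tip, extent_mm, voxel_size)


def derive_seed(base_seed: int, label: str) -> int:
    """Independent per-configuration seed, stable across runs (< 2³¹)."""
    return (int(base_seed) * 1_000_003 + zlib.crc32(label.encode())) % (2**31 - 1)


def simulate_fiber(config: FiberConfig, seed: int,
                   optics: OpticalProperties = BRAIN_OPTICS_473NM,
                   grid: VoxelGrid | None = None,
                   n_photons: int = DEFAULT_N_PHOTONS) -> FluenceMap:
    """Run one Monte-Carlo simulation for a fiber pose."""
    if grid is None:
        grid = default_grid(config)
    source = make_source(config, n_tissue=optics.n)
    fm = run_mc(source, grid, optics, n_photons, seed)
    fm.meta["fiber"] = {"phi": config.phi, "depth_offset": config.depth_offset,
                        "mode": config.mode, "label": config.label}
    return fm


def run_figure_volumes(seed: int,
                       intensities=STUDY_INTENSITIES,
                       threshold: float = CHR2_HALF_MAX_FLUENCE,
                       config: FiberConfig | None = None,
                       optics: OpticalProperties = BRAIN_OPTICS_473NM,
                       n_photons: int = DEFAULT_N_PHOTONS,
                       fluence: FluenceMap | None = None,
                       normalization: str = "peak") -> pd.DataFrame:
    """Activated volume vs. source intensity from a single simulation.

    One MC run is thresholded at each intensity (the normalized fluence map
    is intensity-independent).  Returns a table with columns
    ``intensity_mw_mm2``, ``threshold_mw_mm2``, ``volume_mm3``, ``n_voxels``.
    """
    if config is None:
        config = FiberConfig()
    if fluence is None:
        fluence = simulate_fiber(config, derive_seed(seed, "volumes"),
                                 optics=optics, n_photons=n_photons)
    rows = []
    for i0 in intensities:
        m = threshold_volume(fluence, i0, threshold, normalization=normalization)
        rows.append({"intensity_mw_mm2": i0, "threshold_mw_mm2": threshold,
                     "volume_mm3": m.volume, "n_voxels": m.n_voxels})
    return pd.DataFrame(rows)


def contour_table(fluence: FluenceMap,
                  intensities=STUDY_INTENSITIES,
                  threshold: float = CHR2_HALF_MAX_FLUENCE,
                  axis: int = 1, coordinate: float | None = None,
                  normalization: str = "peak") -> pd.DataFrame:
    """Boundary contours of the activated region on one slice, per intensity.

    Mirrors the nested-oval rendering of the activated volumes: for each
    source intensity, the activation-mask boundary on the chosen slice
    (default: the plane through the grid centre, normal to y) as polyline
    vertices in mm.  Long format: intensity, contour index, vertex index,
    and the two in-plane coordinates.
    """
    from fiberlight.activation_volume import isocontour_slices

    if coordinate is None:
        coordinate = float(fluence.grid.origin[axis] + fluence.grid.extent[axis] / 2)
    in_plane = [a for a in (0, 1, 2) if a != axis]
    names = [f"coord{in_plane[0]}_mm", f"coord{in_plane[1]}_mm"]
    rows = []
    for i0 in intensities:
        mask = threshold_volume(fluence, i0, threshold, normalization=normalization)
        for ci, poly in enumerate(isocontour_slices(mask, axis=axis, coordinate=coordinate)):
            for vi, (c0, c1) in enumerate(poly):
                rows.append({"intensity_mw_mm2": i0, "contour": ci, "vertex": vi,
                             names[0]: c0, names[1]: c1})
    return pd.DataFrame(rows)


def run_rotation_sweep(seed: int,
                       phis=tuple(range(0, 360, 45)),
                       source_intensity: float = 2.2,
                       threshold: float = CHR2_HALF_MAX_FLUENCE,
                       base: FiberConfig | None = None,
                       optics: OpticalProperties = BRAIN_OPTICS_473NM,
                       n_photons: int = DEFAULT_N_PHOTONS,
                       modes=("mean", "jaccard", "min"),
                       normalization: str = "peak") -> pd.DataFrame:
    """Pairwise overlap of adjacent rotation angles of the side-firing fiber.

    Each angle is simulated with an independent derived seed; adjacent pairs
    (cyclically, if the sweep spans the full turn) are compared at the given
    source intensity.  Returns one row per adjacent pair and overlap mode.
    """
    if base is None:
        base = FiberConfig()
    configs = sweep_configs(base, phis, [base.depth_offset])
    masks = []
    for cfg in configs:
        fm = simulate_fiber(cfg, derive_seed(seed, cfg.label), optics=optics,
                            n_photons=n_photons)
        masks.append(threshold_volume(fm, source_intensity, threshold,
                                      normalization=normalization))
    phis = [c.phi for c in configs]
    pairs = list(zip(range(len(configs) - 1), range(1, len(configs))))
    full_turn = len(configs) > 2 and np.isclose((phis[-1] - phis[0]) % 360,
                                                360 - (phis[1] - phis[0]))
    if full_turn:
        pairs.append((len(configs) - 1, 0))
    rows = []
    for ia, ib in pairs:
        for mode in modes:
            rows.append({
                "phi_a": phis[ia], "phi_b": phis[ib],
                "intensity_mw_mm2": source_intensity, "mode": mode,
                "overlap": overlap_fraction(masks[ia], masks[ib], mode=mode),
                "volume_a_mm3": masks[ia].volume, "volume_b_mm3": masks[ib].volume,
            })
    return pd.DataFrame(rows)


def run_translation_pair(seed: int,
                         shift_mm: float = 0.3,
                         source_intensity: float = 8.9,
                         threshold: float = CHR2_HALF_MAX_FLUENCE,
                         base: FiberConfig | None = None,
                         optics: OpticalProperties = BRAIN_OPTICS_473NM,
                         n_photons: int = DEFAULT_N_PHOTONS,
                         modes=("mean", "jaccard", "min"),
                         normalization: str = "peak") -> pd.DataFrame:
    """Overlap of two poses translated ``shift_mm`` along the fiber axis."""
    if base is None:
        base = FiberConfig()
    cfg_a, cfg_b = sweep_configs(base, [base.phi], [0.0, shift_mm])
    masks = []
    for cfg in (cfg_a, cfg_b):
        fm = simulate_fiber(cfg, derive_seed(seed, cfg.label), optics=optics,
                            n_photons=n_photons)
        masks.append(threshold_volume(fm, source_intensity, threshold,
                                      normalization=normalization))
    rows = []
    for mode in modes:
        rows.append({
            "shift_mm": shift_mm, "intensity_mw_mm2": source_intensity, "mode": mode,
            "overlap": overlap_fraction(masks[0], masks[1], mode=mode),
            "volume_a_mm3": masks[0].volume, "volume_b_mm3": masks[1].volume,
        })
    return pd.DataFrame(rows)
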
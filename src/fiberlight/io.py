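"""Configuration files, HDF5 round-tripping and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import yaml

from fiberlight.activation_volume import ActivationMask
from fiberlight.fiber_geometry import FiberConfig
from fiberlight.optics import FluenceMap, OpticalProperties, VoxelGrid

__all__ = [
    "load_config",
    "parse_config",
    "save_fluence",
    "load_fluence",
    "save_mask",
    "RunManifest",
]


def parse_config(cfg: dict) -> dict:
    """Build domain objects from a configuration mapping.

    Expected keys: ``optics`` (mu_a, mu_s, g, n — or mu_s_reduced instead of
    mu_s), ``source`` (FiberConfig fields), ``grid`` (shape, voxel_size_mm,
    origin — or extent_mm for a cube centred on the fiber tip),
    ``n_photons``, ``seed``.
    """
    opt = dict(cfg.get("optics", {}))
    if "mu_s_reduced" in opt:
        optics = OpticalProperties.from_reduced(
            mu_a=opt["mu_a"], mu_s_reduced=opt.pop("mu_s_reduced"),
            g=opt.get("g", 0.9), n=opt.get("n", 1.37))
    else:
        optics = OpticalProperties(**opt)
    src = dict(cfg.get("source", {}))
    for key in ("tip", "axis"):
        if key in src:
            src[key] = tuple(src[key])
    fiber = FiberConfig(**src)
    g = dict(cfg.get("grid", {}))
    if "extent_mm" in g:
        grid = VoxelGrid.centered(fiber.tip, g["extent_mm"], g.get("voxel_size_mm", 0.01))
    else:
        grid = VoxelGrid(shape=tuple(g["shape"]), voxel_size=g["voxel_size_mm"],
                         origin=tuple(g.get("origin", (0.0, 0.0, 0.0))))
    return {
        "optics": optics,
        "fiber": fiber,
        "grid": grid,
        "n_photons": int(cfg.get("n_photons", 10_000_000)),
        "seed": int(cfg["seed"]),
    }


def load_config(path) -> dict:
    """Load and parse a YAML (or JSON) simulation config."""
    text = Path(path).read_text()
    return parse_config(yaml.safe_load(text))


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_fluence(fm: FluenceMap, path) -> Path:
    """Write a fluence map to HDF5 (dataset ``fluence`` + grid/run attrs)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("fluence", data=fm.values, compression="gzip", shuffle=True)
        d.attrs["voxel_size_mm"] = fm.grid.voxel_size
        d.attrs["origin_mm"] = np.asarray(fm.grid.origin)
        d.attrs["n_photons"] = fm.n_photons
        d.attrs["seed"] = fm.seed
        d.attrs["units"] = "multiples of source exit intensity I0"
        scalars = {k: v for k, v in fm.meta.items() if np.isscalar(v)}
        d.attrs["meta_json"] = json.dumps(scalars)
    return path


def load_fluence(path) -> FluenceMap:
    with h5py.File(path, "r") as f:
        d = f["fluence"]
        grid = VoxelGrid(shape=d.shape, voxel_size=float(d.attrs["voxel_size_mm"]),
                         origin=tuple(d.attrs["origin_mm"]))
        meta = json.loads(d.attrs.get("meta_json", "{}"))
        return FluenceMap(grid=grid, values=d[...], n_photons=int(d.attrs["n_photons"]),
                          seed=int(d.attrs["seed"]), meta=meta)


def save_mask(mask: ActivationMask, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("mask", data=mask.mask, compression="gzip")
        d.attrs["voxel_size_mm"] = mask.grid.voxel_size
        d.attrs["origin_mm"] = np.asarray(mask.grid.origin)
        d.attrs["source_intensity_mw_mm2"] = mask.source_intensity
        d.attrs["threshold_mw_mm2"] = mask.threshold
        d.attrs["volume_mm3"] = mask.volume
    return path


@dataclasses.dataclass
class RunManifest:
    """Record of a pipeline run: config hash, seeds and output checksums.

    Re-running with the seeds in the manifest reproduces every stochastic
    output bit-for-bit.
    """

    config: dict
    seed: int
    version: str = ""
    outputs: dict = dataclasses.field(default_factory=dict)
    created: str = dataclasses.field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def add_output(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[path.name] = digest

    def write(self, path) -> Path:
        path = Path(path)
        from fiberlight import __version__
        payload = {
            "config": self.config,
            "config_hash": config_hash(self.config),
            "seed": self.seed,
            "version": self.version or __version__,
            "outputs": self.outputs,
            "created": self.created,
        }
        path.write_text(json.dumps(payload, indent=2, default=str))
        return path
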
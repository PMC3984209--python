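"""Quick-look figures: fluence slices with activation contours, IOI overlays."""

from __future__ import annotations

import numpy as np

from fiberlight.activation_volume import ActivationMask, isocontour_slices
from fiberlight.ioi_analysis import ActivationMap
from fiberlight.optics import FluenceMap

__all__ = ["plot_fluence_slice", "plot_activation_overlay"]


def plot_fluence_slice(fm: FluenceMap, axis: int = 1, coordinate: float = 0.0,
                       masks: list[ActivationMask] | None = None, ax=None,
                       log_floor: float = 1e-4):
    """Log-scaled fluence on one grid slice, with optional mask boundary contours."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    coords = fm.grid.axis_coords(axis)
    layer = int(np.argmin(np.abs(coords - coordinate)))
    img = np.take(fm.values, layer, axis=axis)
    in_plane = [a for a in (0, 1, 2) if a != axis]
    ext = [fm.grid.origin[in_plane[1]],
           fm.grid.origin[in_plane[1]] + fm.grid.extent[in_plane[1]],
           fm.grid.origin[in_plane[0]],
           fm.grid.origin[in_plane[0]] + fm.grid.extent[in_plane[0]]]
    im = ax.imshow(np.log10(np.maximum(img, log_floor)), origin="lower",
                   extent=ext, cmap="inferno")
    for mask in masks or []:
        for poly in isocontour_slices(mask, axis=axis, coordinate=coordinate):
            ax.plot(poly[:, 1], poly[:, 0], "k-", lw=0.8)
    ax.set_xlabel("mm")
    ax.set_ylabel("mm")
    ax.figure.colorbar(im, ax=ax, label="log10 fluence (I0 units)")
    return ax


def plot_activation_overlay(amap: ActivationMap, background: np.ndarray | None = None,
                            ax=None):
    """Significant-pixel mask over an anatomical background image."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if background is not None:
        ax.imshow(background, cmap="gray")
    overlay = np.zeros((*amap.mask.shape, 4))
    overlay[amap.mask] = (1.0, 0.1, 0.1, 0.55)
    ax.imshow(overlay)
    ax.set_title(f"p < {amap.alpha:g}, area {amap.area:.3g} mm$^2$")
    ax.set_axis_off()
    return ax
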
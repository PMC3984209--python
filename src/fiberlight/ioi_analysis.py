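"""Activation-map analysis for intrinsic optical imaging trials.

The chain mirrors standard evoked-IOI practice: average the hemodynamic
response over trials of one condition, normalize every pixel's time course
to its own pre-stimulus mean, optionally smooth each frame with a Gaussian
(σ = 4 px by default in the drivers), then compute a pixelwise two-sample
Welch t-test between the pre-stimulus frames and a post-onset response
window.  Significant pixels (p < α, uncorrected) form the activation mask
whose pixel count gives the activated area; the mask-averaged time course
gives the peak reflectance change.  Across stimulation intensities the
area-vs-intensity relation is fitted linearly and the amplitude-vs-intensity
relation logarithmically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from fiberlight.ioi_synth import AcquisitionProtocol, IOITrialSet

__all__ = [
    "NormalizedStack",
    "ActivationMap",
    "FitResult",
    "average_and_normalize",
    "spatial_filter",
    "t_map",
    "t_map_trials",
    "activation_area",
    "peak_amplitude",
    "fit_intensity_response",
    "response_map",
    "halfmax_recovery_area",
    "mask_centroid",
    "DEFAULT_RESPONSE_WINDOW",
]

#: default t-test response window, 0-based half-open frame range: the first
#: 16 post-onset frames (0–4 s), covering the hemodynamic peak
DEFAULT_RESPONSE_WINDOW = (8, 24)


@dataclass
class NormalizedStack:
    """Trial-averaged stack with per-pixel pre-stimulus mean normalized to 1."""

    data: np.ndarray            # (frames, rows, cols)
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = (self.protocol.n_frames, *self.protocol.image_shape)
        if self.data.shape != expected:
            raise ValueError(f"stack shape {self.data.shape} != {expected}")
        pre = self.data[: self.protocol.n_prestim].mean(axis=0)
        if not np.allclose(pre, 1.0, atol=1e-9):
            raise ValueError("pre-stimulus mean must be 1 per pixel")


@dataclass
class ActivationMap:
    """Pixelwise t/p maps with the significant-pixel mask and its area."""

    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    alpha: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def area(self) -> float:
        """Significant area (mm²)."""
        return float(self.mask.sum()) * self.pixel_size**2


@dataclass(frozen=True)
class FitResult:
    """Least-squares intensity-response fit."""

    model: str                      # "linear" | "logarithmic"
    intercept: float
    slope: float
    r_squared: float
    f_pvalue: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        xt = np.log(x) if self.model == "logarithmic" else x
        return self.intercept + self.slope * xt


def average_and_normalize(trials: IOITrialSet, condition: str = "stim") -> NormalizedStack:
    """Average trials of one condition and normalize each pixel's pre-stimulus mean to 1."""
    sel = trials.select(condition)
    if sel.shape[0] < 1:
        raise ValueError(f"no trials of condition {condition!r}")
    mean = sel.mean(axis=0)
    pre = mean[: trials.protocol.n_prestim].mean(axis=0)
    if np.any(pre <= 0) or not np.all(np.isfinite(pre)):
        raise ValueError("degenerate input: non-positive pre-stimulus mean")
    return NormalizedStack(data=mean / pre[None, :, :], protocol=trials.protocol)


def spatial_filter(stack: NormalizedStack, sigma: float) -> NormalizedStack:
    """Gaussian-smooth every frame with an isotropic kernel of SD ``sigma`` pixels.

    ``sigma = 0`` is the identity; the kernel is normalized, so constant
    frames (and the pre-stimulus normalization) are preserved exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return NormalizedStack(data=stack.data.copy(), protocol=stack.protocol)
    out = ndimage.gaussian_filter(stack.data, sigma=(0.0, sigma, sigma), mode="nearest")
    return NormalizedStack(data=out, protocol=stack.protocol)


def t_map(stack: NormalizedStack, response_window: tuple[int, int] = DEFAULT_RESPONSE_WINDOW,
          alpha: float = 0.05, correction: str | None = None) -> ActivationMap:
    """Pixelwise Welch t-test of pre-stimulus frames against a response window.

    ``response_window`` is a 0-based half-open frame range that must start at
    or after the end of the pre-stimulus period; both samples need at least
    two frames.  p-values are two-sided and by default uncorrected (pixels
    with p < α form the mask, as in conventional IOI thresholding);
    ``correction="bh"`` applies a Benjamini-Hochberg false-discovery-rate
    adjustment across pixels before thresholding.
    """
    lo, hi = int(response_window[0]), int(response_window[1])
    n_pre = stack.protocol.n_prestim
    if lo < n_pre:
        raise ValueError("response window must not overlap the pre-stimulus frames")
    if hi - lo < 2 or n_pre < 2:
        raise ValueError("both t-test windows need at least 2 frames")
    if hi > stack.protocol.n_frames:
        raise ValueError("response window exceeds the trial length")
    pre = stack.data[:n_pre]
    resp = stack.data[lo:hi]
    t, p = stats.ttest_ind(pre, resp, axis=0, equal_var=False)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    if correction == "bh":
        p = stats.false_discovery_control(p.ravel()).reshape(p.shape)
    elif correction is not None:
        raise ValueError("correction must be None or 'bh'")
    return ActivationMap(t=t, p=p, mask=p < alpha, alpha=float(alpha),
                         pixel_size=stack.protocol.pixel_size)


def t_map_trials(trials: IOITrialSet, condition: str = "stim",
                 response_window: tuple[int, int] = DEFAULT_RESPONSE_WINDOW,
                 alpha: float = 0.05) -> ActivationMap:
    """Per-trial variant of :func:`t_map`.

    Instead of treating frames of the trial-averaged stack as samples, each
    trial contributes one per-pixel response (its response-window mean minus
    its pre-stimulus mean, in pre-stimulus-normalized units) and a one-sample
    t-test against zero is run across trials.
    """
    lo, hi = int(response_window[0]), int(response_window[1])
    n_pre = trials.protocol.n_prestim
    if lo < n_pre:
        raise ValueError("response window must not overlap the pre-stimulus frames")
    if hi - lo < 1:
        raise ValueError("response window must contain at least 1 frame")
    sel = trials.select(condition)
    if sel.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    pre = sel[:, :n_pre].mean(axis=1)
    if np.any(pre <= 0):
        raise ValueError("degenerate input: non-positive pre-stimulus mean")
    delta = sel[:, lo:hi].mean(axis=1) / pre - 1.0
    t, p = stats.ttest_1samp(delta, 0.0, axis=0)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    return ActivationMap(t=t, p=p, mask=p < alpha, alpha=float(alpha),
                         pixel_size=trials.protocol.pixel_size)


def activation_area(amap: ActivationMap, pixel_size: float | None = None) -> float:
    """Activated area (mm²): significant-pixel count × pixel_size²."""
    px = amap.pixel_size if pixel_size is None else float(pixel_size)
    return float(amap.mask.sum()) * px**2


def peak_amplitude(stack: NormalizedStack, mask: np.ndarray) -> float:
    """Peak fractional reflectance change (%) of the mask-averaged time course.

    The time course is averaged over the mask pixels; the signed extremum of
    (value − 1) over the post-stimulus frames is returned in percent
    (negative for a reflectance decrease).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("peak_amplitude is undefined for an empty mask")
    ts = stack.data[:, mask].mean(axis=1)
    post = ts[stack.protocol.n_prestim:] - 1.0
    k = int(np.argmax(np.abs(post)))
    return float(post[k] * 100.0)


def fit_intensity_response(x, y, model: str = "linear") -> FitResult:
    """Least-squares fit of an intensity-response relation.

    ``model="linear"`` fits ``y = a + b·x``; ``model="logarithmic"`` fits
    ``y = a + b·ln(x)`` (all x must be positive).  Returns coefficients, the
    determination coefficient R² and the overall F-test p-value (identical to
    the slope t-test for a single regressor).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if model == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic model requires all x > 0")
        xt = np.log(x)
    elif model == "linear":
        xt = x
    else:
        raise ValueError("model must be 'linear' or 'logarithmic'")
    if np.ptp(xt) == 0:
        raise ValueError("degenerate predictor: all x equal")
    res = stats.linregress(xt, y)
    return FitResult(model=model, intercept=float(res.intercept), slope=float(res.slope),
                     r_squared=float(res.rvalue**2), f_pvalue=float(res.pvalue))


# ---------------------------------------------------------------------------
# ground-truth recovery helpers
# ---------------------------------------------------------------------------

def response_map(stack: NormalizedStack,
                 response_window: tuple[int, int] = DEFAULT_RESPONSE_WINDOW) -> np.ndarray:
    """Mean fractional response per pixel over the response window (signed)."""
    lo, hi = response_window
    return stack.data[lo:hi].mean(axis=0) - 1.0


def halfmax_recovery_area(stack: NormalizedStack,
                          response_window: tuple[int, int] = DEFAULT_RESPONSE_WINDOW,
                          smooth_sigma: float = 4.0,
                          correct_smoothing: bool = True) -> float:
    """Area (mm²) of the half-maximum footprint of the measured response.

    The window-averaged response map is smoothed to estimate the peak
    response robustly, then thresholded at half the peak magnitude.
    Smoothing a Gaussian bump of SD σ widens its half-maximum footprint from
    ``2π ln2 σ²`` to ``2π ln2 (σ² + s²)`` pixels; with ``correct_smoothing``
    the exact ``2π ln2 s²`` term is subtracted again, so for bumps wider than
    the smoothing the estimator is unbiased up to boundary noise.
    """
    r = response_map(stack, response_window)
    if smooth_sigma > 0:
        r = ndimage.gaussian_filter(r, smooth_sigma, mode="nearest")
    peak = np.abs(r).max()
    if peak == 0:
        return 0.0
    sign = np.sign(r.flat[np.argmax(np.abs(r))])
    fp = (r * sign) >= peak / 2.0
    area_px = float(fp.sum())
    if correct_smoothing and smooth_sigma > 0:
        area_px = max(area_px - 2.0 * np.pi * np.log(2.0) * smooth_sigma**2, 0.0)
    return area_px * stack.protocol.pixel_size**2


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Centroid (row, col) of a boolean mask in pixel coordinates."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("centroid of an empty mask is undefined")
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())
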
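"""Synthetic intrinsic-optical-imaging (IOI) trial sets with known ground truth.

The generator emulates the acquisition used for optogenetically evoked
cortical maps: 20-second trials of 80 camera frames at 4 Hz, with 8
pre-stimulus frames, a 250 ms blue-light stimulus starting at frame 9, and
20 stimulus plus 20 blank trials in randomized order.  The evoked response
is a localized *decrease* in reflectance (deoxyhemoglobin signal) of order
−0.01 % to −0.03 % relative to baseline, shaped in time by a gamma-variate
hemodynamic response function (HRF) and in space by a Gaussian bump, with
i.i.d. multiplicative Gaussian pixel noise.

Because the ground truth (bump centre, width, amplitude, HRF timing) is
known in closed form, the analysis pipeline can be validated quantitatively:
the half-maximum footprint of the expected response is the disc of radius
``σ·√(2 ln 2)`` around the centre.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.optimize import brentq

__all__ = [
    "AcquisitionProtocol",
    "GroundTruthActivation",
    "IOITrialSet",
    "hrf_timecourse",
    "generate_trials",
    "write_stack",
    "read_stack",
    "halfmax_footprint_area",
    "noise_sigma_for_snr",
    "response_snr",
]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Trial structure of the IOI acquisition."""

    n_frames: int = 80
    frame_rate: float = 4.0
    n_prestim: int = 8
    stim_duration: float = 0.25
    n_trials_stim: int = 20
    n_trials_blank: int = 20
    image_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.01  # mm per pixel

    def __post_init__(self) -> None:
        if self.n_prestim >= self.n_frames:
            raise ValueError("n_prestim must be smaller than n_frames")
        if min(self.n_frames, self.n_prestim, self.n_trials_stim, self.n_trials_blank) < 1:
            raise ValueError("frame and trial counts must be >= 1")
        if self.pixel_size <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel_size and frame_rate must be positive")

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each frame from trial start (s)."""
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def stim_onset_time(self) -> float:
        """Stimulus onset (s): immediately after the pre-stimulus frames."""
        return self.n_prestim / self.frame_rate

    @property
    def n_trials(self) -> int:
        return self.n_trials_stim + self.n_trials_blank


@dataclass(frozen=True)
class GroundTruthActivation:
    """Ground-truth response injected into synthetic stim trials.

    ``peak_amplitude`` is the fractional reflectance change at the spatial
    centre at the HRF peak; negative values model the deoxygenation dip
    (e.g. −2.2e-4 for a −0.022 % response).
    """

    center: tuple[float, float] = (64.0, 64.0)   # (row, col), pixels
    spatial_sigma: float = 12.0                  # pixels
    peak_amplitude: float = -2.2e-4
    hrf_peak_time: float = 2.5                   # s after stimulus onset
    hrf_fwhm: float = 3.0                        # s
    baseline: float = 1.0                        # arbitrary reflectance units
    noise_sigma: float = 1e-3                    # fractional, per pixel per frame
    drift_total: float = 0.0                     # fractional linear drift over a trial

    def __post_init__(self) -> None:
        if self.spatial_sigma <= 0:
            raise ValueError("spatial_sigma must be positive")
        if self.hrf_peak_time <= 0 or self.hrf_fwhm <= 0:
            raise ValueError("hrf_peak_time and hrf_fwhm must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")


@dataclass
class IOITrialSet:
    """4-D trial stack (trial × frame × row × col) plus metadata."""

    data: np.ndarray
    protocol: AcquisitionProtocol
    labels: np.ndarray          # "stim" / "blank" per trial, acquisition order
    seed: int
    truth: GroundTruthActivation | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        expected = (self.protocol.n_trials, self.protocol.n_frames, *self.protocol.image_shape)
        if self.data.shape != expected:
            raise ValueError(f"data shape {self.data.shape} != protocol shape {expected}")
        if len(self.labels) != self.protocol.n_trials:
            raise ValueError("labels length does not match trial count")
        if np.any(self.data <= 0):
            raise ValueError("reflectance values must be positive")

    def select(self, condition: str) -> np.ndarray:
        """Trials of one condition ("stim" or "blank"), shape (n, frames, H, W)."""
        if condition not in ("stim", "blank"):
            raise ValueError("condition must be 'stim' or 'blank'")
        return self.data[self.labels == condition]


# ---------------------------------------------------------------------------
# HRF kernel
# ---------------------------------------------------------------------------

def _gamma_shape_for_fwhm(ratio: float) -> float:
    """Shape parameter a of k(x) = x^a·e^{a(1−x)} whose FWHM/t_peak equals ``ratio``."""

    def fwhm(a: float) -> float:
        c = np.log(0.5) / a
        f = lambda x: np.log(x) + 1.0 - x - c
        lo = brentq(f, 1e-9, 1.0 - 1e-12)
        hi = brentq(f, 1.0 + 1e-12, 50.0)
        return hi - lo

    return brentq(lambda a: fwhm(a) - ratio, 0.05, 400.0)


def hrf_kernel(t: np.ndarray, peak_time: float, fwhm: float) -> np.ndarray:
    """Gamma-variate HRF kernel, 0 for t ≤ 0, normalized to 1 at ``peak_time``."""
    a = _gamma_shape_for_fwhm(fwhm / peak_time)
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / peak_time
    out[pos] = np.power(x, a) * np.exp(a * (1.0 - x))
    return out


def hrf_timecourse(protocol: AcquisitionProtocol, truth: GroundTruthActivation) -> np.ndarray:
    """Per-frame multiplicative factor of the evoked response at the bump centre.

    Exactly 1.0 on every pre-stimulus frame; ``1 + peak_amplitude·k(t)``
    afterwards, where ``k`` is the gamma-variate kernel peaking at
    ``hrf_peak_time`` after stimulus onset.
    """
    tau = protocol.frame_times - protocol.stim_onset_time
    k = hrf_kernel(tau, truth.hrf_peak_time, truth.hrf_fwhm)
    k[: protocol.n_prestim] = 0.0
    return 1.0 + truth.peak_amplitude * k


def spatial_profile(protocol: AcquisitionProtocol, truth: GroundTruthActivation) -> np.ndarray:
    """Gaussian spatial response profile, 1 at the centre (rows × cols)."""
    rows = np.arange(protocol.image_shape[0])[:, None]
    cols = np.arange(protocol.image_shape[1])[None, :]
    r2 = (rows - truth.center[0]) ** 2 + (cols - truth.center[1]) ** 2
    return np.exp(-r2 / (2.0 * truth.spatial_sigma**2))


def halfmax_footprint_area(truth: GroundTruthActivation, protocol: AcquisitionProtocol,
                           units: str = "mm2") -> float:
    """Closed-form area of the half-maximum response footprint.

    Pixels whose expected response magnitude is at least half the peak lie in
    the disc of radius ``σ·√(2 ln 2)``; area = ``2π ln 2 · σ²`` pixels².
    """
    area_px = 2.0 * np.pi * np.log(2.0) * truth.spatial_sigma**2
    if units == "px2":
        return float(area_px)
    if units == "mm2":
        return float(area_px * protocol.pixel_size**2)
    raise ValueError("units must be 'mm2' or 'px2'")


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def generate_trials(protocol: AcquisitionProtocol, truth: GroundTruthActivation,
                    seed: int) -> IOITrialSet:
    """Generate a full randomized trial set (deterministic for a given seed).

    Stim trials carry ``baseline · (1 + A·k(t)·G(x,y))`` with the HRF
    time course ``k`` and Gaussian spatial profile ``G``; blank trials carry
    the flat baseline.  Both receive independent multiplicative Gaussian
    noise of SD ``noise_sigma`` per pixel per frame, and an optional global
    linear drift of ``drift_total`` over the trial (for robustness tests).
    """
    rng = np.random.default_rng(seed)
    labels = np.array(["stim"] * protocol.n_trials_stim + ["blank"] * protocol.n_trials_blank)
    rng.shuffle(labels)

    k = hrf_timecourse(protocol, truth) - 1.0            # (frames,), 0 pre-stim
    g = spatial_profile(protocol, truth)                  # (H, W)
    response = 1.0 + k[:, None, None] * g[None, :, :]     # (frames, H, W)

    shape = (protocol.n_trials, protocol.n_frames, *protocol.image_shape)
    data = np.empty(shape, dtype=np.float64)
    is_stim = labels == "stim"
    data[is_stim] = truth.baseline * response[None, :, :, :]
    data[~is_stim] = truth.baseline
    if truth.drift_total != 0.0:
        ramp = 1.0 + truth.drift_total * np.arange(protocol.n_frames) / (protocol.n_frames - 1)
        data *= ramp[None, :, None, None]
    if truth.noise_sigma > 0:
        data *= 1.0 + rng.normal(0.0, truth.noise_sigma, size=shape)
        np.clip(data, truth.baseline * 1e-6, None, out=data)
    return IOITrialSet(data=data, protocol=protocol, labels=labels, seed=int(seed),
                       truth=truth)


def response_snr(protocol: AcquisitionProtocol, truth: GroundTruthActivation,
                 response_window: tuple[int, int] = (8, 24)) -> float:
    """Detection SNR at the bump centre for a window-averaged response.

    Defined as the expected window-mean response magnitude at the centre
    pixel of the trial-averaged stack divided by its standard error:
    ``|A|·k̄·√(n_trials·n_win)/noise_sigma`` with ``k̄`` the mean HRF kernel
    over the response window.
    """
    lo, hi = response_window
    k = hrf_timecourse(protocol, truth) - 1.0
    kbar = float(np.abs(k[lo:hi] / truth.peak_amplitude).mean()) if truth.peak_amplitude else 0.0
    n = truth.noise_sigma
    if n == 0:
        return float("inf")
    return abs(truth.peak_amplitude) * kbar * np.sqrt(protocol.n_trials_stim * (hi - lo)) / n


def noise_sigma_for_snr(protocol: AcquisitionProtocol, truth: GroundTruthActivation,
                        snr: float, response_window: tuple[int, int] = (8, 24)) -> float:
    """Noise level that yields a given :func:`response_snr`."""
    ref = GroundTruthActivation(**{**asdict(truth), "noise_sigma": 1.0})
    return response_snr(protocol, ref, response_window) / snr


# ---------------------------------------------------------------------------
# disk round-trip
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = 1


def write_stack(trials: IOITrialSet, path) -> Path:
    """Write a trial set as one 16-bit multi-page TIFF per trial plus a JSON sidecar.

    Frames are affinely quantized to uint16 (`lo` + `step`·code); the scale is
    recorded in the sidecar, so reading back reproduces the data to within
    half a quantization step.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lo = float(trials.data.min())
    hi = float(trials.data.max())
    step = (hi - lo) / 65535.0 if hi > lo else 1.0
    for t in range(trials.protocol.n_trials):
        codes = np.round((trials.data[t] - lo) / step).astype(np.uint16)
        tifffile.imwrite(path / f"trial_{t:03d}.tif", codes)
    sidecar = {
        "schema_version": _SCHEMA_VERSION,
        "protocol": asdict(trials.protocol),
        "labels": trials.labels.tolist(),
        "seed": trials.seed,
        "scale": {"lo": lo, "step": step},
        "truth": asdict(trials.truth) if trials.truth is not None else None,
    }
    (path / "stack.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(path) -> IOITrialSet:
    """Read a trial set written by :func:`write_stack`."""
    path = Path(path)
    sidecar = json.loads((path / "stack.json").read_text())
    proto_kw = sidecar["protocol"]
    proto_kw["image_shape"] = tuple(proto_kw["image_shape"])
    protocol = AcquisitionProtocol(**proto_kw)
    lo, step = sidecar["scale"]["lo"], sidecar["scale"]["step"]
    data = np.empty((protocol.n_trials, protocol.n_frames, *protocol.image_shape))
    for t in range(protocol.n_trials):
        data[t] = tifffile.imread(path / f"trial_{t:03d}.tif").astype(np.float64) * step + lo
    truth = None
    if sidecar.get("truth"):
        tkw = sidecar["truth"]
        tkw["center"] = tuple(tkw["center"])
        truth = GroundTruthActivation(**tkw)
    return IOITrialSet(data=np.clip(data, 1e-12, None), protocol=protocol,
                       labels=np.array(sidecar["labels"]), seed=sidecar["seed"],
                       truth=truth)
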
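"""Denoising, global conductivity waveform extraction, and volume comparison.

Sign convention: reconstructed conductivity change is negative on inhalation
(air is resistive), so the global waveform is the *negated* sum of in-mask
pixel values — it then co-moves with inspired volume and plots side-by-side
with spirometer volume-time curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.stats import pearsonr

from .errors import (
    AlignmentError,
    ContractError,
    InvalidMaskError,
    TooShortError,
)

__all__ = [
    "VolumeCurve",
    "ConductivityCurve",
    "denoise",
    "global_waveform",
    "pcc_by_volume_segment",
    "align",
]

#: zero-phase Butterworth order used by :func:`denoise` (doubled by filtfilt)
FILTER_ORDER = 4
CUTOFF_HZ = {"forced": 8.0, "guided": 1.5}


def _validate_curve(times: np.ndarray, values: np.ndarray):
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.ndim != 1 or times.shape != values.shape:
        raise ContractError("curve times and values must be matching 1-D arrays")
    if times.size >= 2 and np.any(np.diff(times) <= 0):
        raise ContractError("curve times must be strictly increasing")
    if not np.all(np.isfinite(values)):
        raise ContractError("curve contains non-finite values")
    return times, values


@dataclass
class VolumeCurve:
    """Volume-time curve in litres (relative to its own minimum for display)."""

    times: np.ndarray
    volume: np.ndarray

    def __post_init__(self):
        self.times, self.volume = _validate_curve(self.times, self.volume)

    @property
    def fps(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))

    @property
    def values(self) -> np.ndarray:  # uniform accessor across curve types
        return self.volume


@dataclass
class ConductivityCurve:
    """Global conductivity signal over time (arbitrary units, volume-co-moving)."""

    times: np.ndarray
    values: np.ndarray
    fps: float = 0.0

    def __post_init__(self):
        self.times, self.values = _validate_curve(self.times, self.values)
        if self.fps <= 0 and self.times.size >= 2:
            self.fps = 1.0 / float(np.median(np.diff(self.times)))


def _lowpass_despike(x: np.ndarray, fps: float, cutoff: float, axis: int = 0):
    n = x.shape[axis]
    if n < 3 * (2 * FILTER_ORDER + 1):
        raise TooShortError(
            f"series of {n} samples is too short for order-{FILTER_ORDER} "
            "zero-phase filtering"
        )
    x = signal.medfilt(x, kernel_size=[3 if ax == axis else 1 for ax in range(x.ndim)])
    nyq = fps / 2.0
    if cutoff >= 0.95 * nyq:
        # frame rate too low for the nominal cutoff; the median filter already
        # removed spikes and no band above the cutoff exists to suppress
        return x
    sos = signal.butter(FILTER_ORDER, cutoff / nyq, output="sos")
    return signal.sosfiltfilt(sos, x, axis=axis)


def denoise(series, mode: str = "forced"):
    """Despike (median, window 3) then zero-phase low-pass filter a series.

    ``mode="forced"`` uses an 8 Hz cutoff (preserves fast-exhale content at
    50 fps); ``mode="guided"`` uses 1.5 Hz (the paced signal lives at 0.2 Hz).
    Accepts a :class:`ConductivityCurve`, :class:`VolumeCurve` or an
    :class:`~eitlung.reconstruct.ImageSeries` and returns the same type.
    """
    if mode not in CUTOFF_HZ:
        raise ContractError(f"unknown denoise mode {mode!r}")
    cutoff = CUTOFF_HZ[mode]
    from .reconstruct import ImageSeries  # local import to avoid cycle

    if isinstance(series, ImageSeries):
        flat = series.values.reshape(series.values.shape[0], -1)
        out = _lowpass_despike(flat, series.fps, cutoff, axis=0)
        out = out.reshape(series.values.shape) * series.inside_mask[None, :, :]
        return ImageSeries(out, series.inside_mask, series.fps, series.times)
    if isinstance(series, VolumeCurve):
        return VolumeCurve(series.times, _lowpass_despike(series.volume, series.fps, cutoff))
    if isinstance(series, ConductivityCurve):
        return ConductivityCurve(
            series.times, _lowpass_despike(series.values, series.fps, cutoff), series.fps
        )
    raise ContractError(f"cannot denoise object of type {type(series).__name__}")


def global_waveform(imgs, mask: str = "all-inside") -> ConductivityCurve:
    """Sum the (sign-flipped) pixel conductivity changes into a global curve.

    ``mask="all-inside"`` sums every inside-body pixel (the default "global"
    waveform); ``mask="lung"`` restricts to pixels labelled as lung by the
    image's ROI labels when present.
    """
    if imgs.values.shape[0] == 0:
        raise ContractError("empty image series")
    if mask == "all-inside":
        m = imgs.inside_mask
    elif mask == "lung":
        labels = getattr(imgs, "roi_labels", None)
        if labels is None:
            raise InvalidMaskError("image series carries no ROI labels for mask='lung'")
        m = labels != "none"
    else:
        raise InvalidMaskError(f"unknown mask {mask!r}")
    if not np.any(m):
        raise InvalidMaskError("mask selects no pixels")
    vals = -imgs.values[:, m].sum(axis=1)
    return ConductivityCurve(imgs.times, vals, imgs.fps)


def _resample_to(volume: VolumeCurve, conductivity: ConductivityCurve):
    t0 = max(volume.times[0], conductivity.times[0])
    t1 = min(volume.times[-1], conductivity.times[-1])
    if t1 <= t0:
        raise AlignmentError("volume and conductivity curves do not overlap in time")
    sel = (volume.times >= t0) & (volume.times <= t1)
    t = volume.times[sel]
    v = volume.volume[sel]
    c = np.interp(t, conductivity.times, conductivity.values)
    return t, v, c


def pcc_by_volume_segment(
    volume: VolumeCurve,
    conductivity: ConductivityCurve,
    segment_edges=(0.0, 1.0, 2.0, 3.0, 4.0),
) -> dict:
    """Pearson correlation per 1-L volume segment of the exhale limb.

    The conductivity curve is linearly resampled onto the volume grid (the
    spirometer is the time master).  Samples are attributed to a segment
    [a, b) by the exhaled volume above curve minimum, restricted to the exhale
    limb (times at or after the volume maximum).  Segments with fewer than 3
    samples map to NaN.
    """
    t, v, c = _resample_to(volume, conductivity)
    exhale = np.arange(t.size) >= int(np.argmax(v))
    v_rel = v - v.min()
    out = {}
    edges = list(segment_edges)
    for a, b in zip(edges[:-1], edges[1:]):
        sel = exhale & (v_rel >= a) & (v_rel < b)
        if sel.sum() < 3 or np.std(v[sel]) == 0 or np.std(c[sel]) == 0:
            out[(a, b)] = float("nan")
        else:
            out[(a, b)] = float(pearsonr(v[sel], c[sel])[0])
    return out


def align(spiro: VolumeCurve, eit: ConductivityCurve, max_lag: float = 2.0) -> float:
    """Lag (s) maximizing the normalized cross-correlation, sub-sample refined.

    Positive lag means the EIT curve trails the spirometer: shifting the EIT
    times by ``-lag`` aligns the curves.
    """
    t0 = max(spiro.times[0], eit.times[0])
    t1 = min(spiro.times[-1], eit.times[-1])
    if t1 - t0 < 2.0:
        raise AlignmentError("curves must overlap by at least 2 s")
    fps = max(spiro.fps, eit.fps)
    t = np.arange(t0, t1, 1.0 / fps)
    a = np.interp(t, spiro.times, spiro.volume)
    b = np.interp(t, eit.times, eit.values)
    if np.std(a) == 0 or np.std(b) == 0:
        raise AlignmentError("alignment undefined for zero-variance signal")
    max_k = int(round(max_lag * fps))
    lags = np.arange(-max_k, max_k + 1)
    ncc = np.full(lags.size, -np.inf)
    for j, k in enumerate(lags):
        # b delayed by k samples relative to a: compare b[k:] with a[:-k]
        if k >= 0:
            bb, aa = b[k:], a[: a.size - k]
        else:
            bb, aa = b[: b.size + k], a[-k:]
        if bb.size < 3 or np.std(aa) == 0 or np.std(bb) == 0:
            continue
        ncc[j] = np.corrcoef(aa, bb)[0, 1]
    i = int(np.argmax(ncc))
    lag = float(lags[i])
    if 0 < i < ncc.size - 1 and np.isfinite(ncc[i - 1]) and np.isfinite(ncc[i + 1]):
        y0, y1, y2 = ncc[i - 1], ncc[i], ncc[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:  # parabolic sub-sample refinement
            lag += 0.5 * (y0 - y2) / denom
    return lag / fps
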
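"""Guided-breathing (paced, 12 bpm) analysis: amplitude maps, activation,
regional inhomogeneity (coefficient of variation) and longitudinal trends.

The guided paradigm replaces effort-dependent forced maneuvers with paced
periodic breathing, so all quantities are narrow-band at the pacing
frequency.  The per-voxel amplitude is, by default, the magnitude of the
Hann-windowed, detrended DFT at the bin nearest the breathing frequency
(robust to slow drift); a median peak-to-peak alternative is retained.
Activated voxels exceed a relative amplitude threshold, making activation
counts invariant to breathing depth while total amplitude is not.  The
coefficient of variation (population SD / mean over activated voxels) in a
lung or quadrant indexes regional ventilation inhomogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.stats import linregress, pearsonr

from .errors import (
    ContractError,
    DegenerateRegressionError,
    InvalidFrequencyError,
    TooShortError,
    UndefinedCVError,
    UndefinedNormalizationError,
)
from .reconstruct import ImageSeries
from .waveform import ConductivityCurve

__all__ = [
    "GuidedResult",
    "LongitudinalSeries",
    "TrendResult",
    "amplitude_map",
    "activated_and_total",
    "regional_cv",
    "spectrum",
    "longitudinal_trend",
    "subject_normalize",
    "analyze_guided",
]

LUNG_REGIONS = {"L": ("AL", "PL"), "R": ("AR", "PR")}


def _region_mask(roi_labels: np.ndarray, region: str) -> np.ndarray:
    if region in LUNG_REGIONS:
        return np.isin(roi_labels, LUNG_REGIONS[region])
    if region in ("AL", "PL", "AR", "PR"):
        return roi_labels == region
    raise ContractError(f"unknown region {region!r}")


def _windowed_fft(x: np.ndarray, fps: float, axis: int = 0):
    """Linearly detrended, Hann-windowed one-sided DFT magnitude.

    Scaled by 2/sum(window) so a bin-aligned cosine of amplitude ``a``
    produces a peak of height ``a``.
    """
    n = x.shape[axis]
    t = np.arange(n)
    x = np.moveaxis(np.asarray(x, dtype=float), axis, 0)
    # linear detrend per series
    A = np.column_stack([np.ones(n), t])
    coef, *_ = np.linalg.lstsq(A, x.reshape(n, -1), rcond=None)
    xd = x.reshape(n, -1) - A @ coef
    win = np.hanning(n)
    mag = np.abs(np.fft.rfft(xd * win[:, None], axis=0)) * (2.0 / win.sum())
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)
    return freqs, mag.reshape((freqs.size,) + x.shape[1:])


def amplitude_map(imgs: ImageSeries, f_breath: float, method: str = "spectral") -> np.ndarray:
    """Per-voxel breathing-frequency amplitude map (32x32, nonnegative).

    ``spectral``: DFT magnitude at the bin nearest ``f_breath`` (Hann
    window, linear detrend, amplitude-calibrated).  ``p2p``: median
    peak-to-peak over whole breathing cycles.
    """
    if f_breath <= 0 or f_breath >= imgs.fps / 2:
        raise InvalidFrequencyError(
            f"breathing frequency {f_breath} Hz outside (0, Nyquist={imgs.fps / 2}) Hz"
        )
    n = imgs.n_frames
    if n < 3 * imgs.fps / f_breath:
        raise TooShortError("need at least 3 breathing cycles")
    if method == "spectral":
        freqs, mag = _windowed_fft(imgs.values, imgs.fps)
        k = int(np.argmin(np.abs(freqs - f_breath)))
        amp = mag[k]
    elif method == "p2p":
        cyc = int(round(imgs.fps / f_breath))
        n_cyc = n // cyc
        chunks = imgs.values[: n_cyc * cyc].reshape(n_cyc, cyc, *imgs.values.shape[1:])
        amp = np.median(chunks.max(axis=1) - chunks.min(axis=1), axis=0)
    else:
        raise ContractError(f"unknown amplitude method {method!r}")
    return amp * imgs.inside_mask


def activated_and_total(
    amp_map: np.ndarray, roi_labels: np.ndarray, act_frac: float = 0.25
) -> dict:
    """Activated-voxel count and total amplitude per quadrant and per lung.

    Activated voxels exceed ``act_frac`` of the map maximum; the threshold is
    relative per acquisition, so counts are invariant to uniform amplitude
    scaling (breathing depth) while totals are not.
    """
    amp = np.asarray(amp_map, dtype=float)
    thresh = act_frac * amp.max()
    active = amp > thresh
    out = {}
    for region in ("AL", "PL", "AR", "PR", "L", "R"):
        sel = _region_mask(roi_labels, region) & active
        out[region] = {
            "activated_count": int(sel.sum()),
            "total_amplitude": float(amp[sel].sum()),
        }
    return out


def regional_cv(
    amp_map: np.ndarray, roi_labels: np.ndarray, region: str,
    act_frac: float | None = None,
) -> float:
    """Coefficient of variation (population SD / mean) of a region's voxel
    amplitudes — the ventilation-inhomogeneity index.

    By default every voxel of the region contributes: a ventilation defect
    lowers local amplitudes, and excluding weak voxels would hide exactly the
    inhomogeneity the index exists to measure.  Pass ``act_frac`` to restrict
    to activated voxels instead.  For longitudinal comparisons the ROI labels
    should come from a common (baseline) session so membership is fixed.
    """
    amp = np.asarray(amp_map, dtype=float)
    sel = _region_mask(roi_labels, region)
    if act_frac is not None:
        sel &= amp > act_frac * amp.max()
    vals = amp[sel]
    if vals.size < 2:
        raise UndefinedCVError(f"region {region} has {vals.size} activated voxel(s)")
    mean = vals.mean()
    if mean == 0:
        raise UndefinedCVError(f"region {region} has zero mean amplitude")
    return float(vals.std() / mean)  # population SD (ddof=0)


def spectrum(curve: ConductivityCurve, min_duration: float = 30.0):
    """Hann-windowed, detrended magnitude spectrum of a conductivity curve.

    Returns (frequencies Hz, magnitudes); frequency resolution 1/duration.
    """
    duration = curve.times[-1] - curve.times[0]
    if duration < min_duration:
        raise TooShortError(f"need >= {min_duration} s of data, got {duration:.1f} s")
    freqs, mag = _windowed_fft(curve.values, curve.fps)
    return freqs, mag


@dataclass
class GuidedResult:
    """Bundle of the guided-paradigm outputs for one acquisition."""

    amplitude_map: np.ndarray
    roi_labels: np.ndarray
    activation: dict
    cv: dict
    spectrum_freqs: np.ndarray
    spectrum_left: np.ndarray
    spectrum_right: np.ndarray


def analyze_guided(
    imgs: ImageSeries, breathing_rate_bpm: float = 12.0, act_frac: float = 0.25,
    amp_min_frac: float = 0.10, method: str = "spectral",
    roi_labels: np.ndarray | None = None,
) -> GuidedResult:
    """Full guided-paradigm analysis of a reconstructed image series.

    Pass ``roi_labels`` from a baseline session for longitudinal
    comparisons; otherwise ROIs are segmented from this acquisition's
    amplitude map.
    """
    from .indicators import segment_rois

    f = breathing_rate_bpm / 60.0
    amp = amplitude_map(imgs, f, method=method)
    labels = roi_labels if roi_labels is not None else segment_rois(amp, amp_min_frac=amp_min_frac)
    activation = activated_and_total(amp, labels, act_frac)
    cv = {}
    for region in ("L", "R", "AL", "PL", "AR", "PR"):
        try:
            cv[region] = regional_cv(amp, labels, region)
        except UndefinedCVError:
            cv[region] = float("nan")
    spectra = {}
    for side in ("L", "R"):
        sel = _region_mask(labels, side)
        wave = ConductivityCurve(imgs.times, -imgs.values[:, sel].sum(axis=1), imgs.fps)
        spectra[side] = spectrum(wave, min_duration=0.0)
    return GuidedResult(
        amplitude_map=amp,
        roi_labels=labels,
        activation=activation,
        cv=cv,
        spectrum_freqs=spectra["L"][0],
        spectrum_left=spectra["L"][1],
        spectrum_right=spectra["R"][1],
    )


@dataclass
class LongitudinalSeries:
    """C.V. values across monitoring sessions for one region."""

    days: np.ndarray
    cv: np.ndarray
    region: str = "L"

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.cv = np.asarray(self.cv, dtype=float)
        if self.days.shape != self.cv.shape or self.days.size < 3:
            raise ContractError("need >= 3 (day, cv) sessions")


@dataclass
class TrendResult:
    slope: float  # per day
    stderr: float
    pvalue: float
    pcc: float
    intercept: float
    leverage: np.ndarray = dc_field(repr=False, default=None)
    outlier_sessions: np.ndarray = dc_field(repr=False, default=None)

    def summary(self) -> str:
        star = "***" if self.pvalue < 0.001 else "**" if self.pvalue < 0.01 else "*" if self.pvalue < 0.05 else "n.s."
        return (
            f"C.V. trend: slope {self.slope:+.4g}/day (SE {self.stderr:.3g}), "
            f"p = {self.pvalue:.3g} [{star}], PCC = {self.pcc:.3f}"
        )


def longitudinal_trend(series: LongitudinalSeries) -> TrendResult:
    """OLS of C.V. on time with a two-sided t-test on the slope.

    Sessions with leverage above 3x the mean hat value are flagged as
    potential outliers in the diagnostics.
    """
    t = series.days
    if np.unique(t).size < 2:
        raise DegenerateRegressionError("all session times identical")
    res = linregress(t, series.cv)
    X = np.column_stack([np.ones_like(t), t])
    H = X @ np.linalg.solve(X.T @ X, X.T)
    lev = np.diag(H)
    flagged = np.flatnonzero(lev > 3 * lev.mean())
    return TrendResult(
        slope=float(res.slope),
        stderr=float(res.stderr),
        pvalue=float(res.pvalue),
        pcc=float(res.rvalue),
        intercept=float(res.intercept),
        leverage=lev,
        outlier_sessions=flagged,
    )


def subject_normalize(values_by_subject: dict) -> dict:
    """Within-subject max-normalization across sessions/modes.

    Each subject's values are divided by that subject's own maximum, so the
    maximum maps to 1 and modes become comparable across subjects.
    Idempotent.
    """
    out = {}
    for sid, vals in values_by_subject.items():
        v = np.asarray(vals, dtype=float)
        m = v.max()
        if m <= 0:
            raise UndefinedNormalizationError(f"subject {sid} has no positive values")
        out[sid] = v / m
    return out
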
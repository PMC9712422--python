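"""Spirometry indicators, voxel-wise functional maps and lung ROIs.

Five indicators are extracted from a (predicted or measured) volume-time
curve, analogues of the standard spirometry quantities for maneuvers that
need not be maximal effort:

* MVE  - maximal volume engaged: max minus min of the curve (cf. FVC);
* EV1  - volume exhaled in the first second from exhalation onset (cf. FEV1);
* EV1/MVE ratio (cf. FEV1/FVC);
* MEF  - maximum expiratory flow: peak |dV/dt| on the exhale limb (cf. PEF);
* EF25-75 - mean flow while exhaling from 25% to 75% of MVE (cf. FEF25-75).

Exhalation onset is located by back-extrapolation: the tangent at the point
of steepest descent is intersected with the horizontal line through the
curve maximum, the standard spirometry construction.

The same indicators evaluated per voxel on the (sign-flipped) conductivity
waveforms give functional maps; voxels poorly correlated with the global
waveform or of small amplitude are zeroed.  Lung clusters are split into
anterior/posterior left/right quadrants (AL, PL, AR, PR) on the caudal-view
grid (anterior = top row, subject's left = viewer's right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import pearsonr

from .errors import (
    ContractError,
    DegenerateCurveError,
    NoExhaleError,
    SegmentationFailureError,
    TruncatedCurveError,
)
from .reconstruct import ImageSeries
from .waveform import ConductivityCurve, VolumeCurve

__all__ = [
    "IndicatorSet",
    "FunctionalMap",
    "INDICATOR_NAMES",
    "detect_exhale_onset",
    "compute_indicators",
    "functional_map",
    "segment_rois",
    "roi_summary",
]

INDICATOR_NAMES = ("mve", "ev1", "ev1_over_mve", "mef", "ef25_75")
ROI_NAMES = ("AL", "PL", "AR", "PR")


@dataclass(frozen=True)
class IndicatorSet:
    """The five spirometry indicators plus the detected exhalation onset."""

    mve: float
    ev1: float
    ev1_over_mve: float
    mef: float
    ef25_75: float
    exhale_onset: float

    def __getitem__(self, name: str) -> float:
        if name not in INDICATOR_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in INDICATOR_NAMES}


@dataclass
class FunctionalMap:
    """Per-voxel indicator values with quality mask and ROI labels."""

    grid: np.ndarray  # (32, 32)
    zero_mask: np.ndarray  # True where the quality rule suppressed the voxel
    roi_labels: np.ndarray  # (32, 32) of {AL, PL, AR, PR, none}
    indicator: str = "mve"

    def __post_init__(self):
        if np.any(self.grid[self.zero_mask] != 0):
            raise ContractError("suppressed voxels must be exactly zero")


def detect_exhale_onset(curve: VolumeCurve) -> float:
    """Back-extrapolated exhalation onset time (s).

    The tangent at the time of steepest descent of the curve is intersected
    with the horizontal line at the curve maximum; the result is clamped to
    [time of maximum, time of steepest descent].
    """
    v = curve.volume
    t = curve.times
    i_max = int(np.argmax(v))
    if i_max == v.size - 1 or np.all(np.diff(v) >= 0):
        raise NoExhaleError("curve has no exhalation (maximum at the last sample)")
    dv = np.gradient(v, t)
    # steepest descent on or after the maximum
    i_sd = i_max + int(np.argmin(dv[i_max:]))
    slope = dv[i_sd]
    if slope >= 0:
        raise NoExhaleError("no descending limb after the curve maximum")
    t0 = t[i_sd] + (v[i_max] - v[i_sd]) / slope
    return float(np.clip(t0, t[i_max], t[i_sd]))


def _interp_at(t, v, tq):
    return float(np.interp(tq, t, v))


def compute_indicators(curve: VolumeCurve, fps: float | None = None) -> IndicatorSet:
    """Extract the five spirometry indicators from a volume curve.

    EV1 uses linear interpolation between samples; 25%/75% exhaled-volume
    crossing times are also located by linear interpolation, so time-located
    quantities are accurate to one sample at the curve's frame rate.
    """
    t, v = curve.times, curve.volume
    mve = float(v.max() - v.min())
    if mve == 0:
        raise DegenerateCurveError("constant curve: MVE = 0, indicators undefined")
    t0 = detect_exhale_onset(curve)
    if t0 + 1.0 > t[-1]:
        raise TruncatedCurveError(
            f"curve ends {t[-1] - t0:.2f} s after exhale onset; EV1 needs 1 s"
        )
    ev1 = _interp_at(t, v, t0) - _interp_at(t, v, t0 + 1.0)
    ev1 = float(min(max(ev1, 0.0), mve))

    # exhale limb: from the curve maximum to the end
    i_max = int(np.argmax(v))
    dv = np.gradient(v, t)
    mef = float(np.max(np.abs(dv[i_max:])))

    # 25%/75% exhaled crossings on the exhale limb
    v_max = v.max()
    exhaled = v_max - v[i_max:]
    te = t[i_max:]
    t25 = _crossing_time(te, exhaled, 0.25 * mve)
    t75 = _crossing_time(te, exhaled, 0.75 * mve)
    if t75 is None or t25 is None or t75 <= t25:
        ef = float("nan")
    else:
        ef = 0.5 * mve / (t75 - t25)
    return IndicatorSet(
        mve=mve,
        ev1=ev1,
        ev1_over_mve=ev1 / mve,
        mef=mef,
        ef25_75=ef,
        exhale_onset=t0,
    )


def _crossing_time(t, x, level):
    """First time x crosses `level` from below, linearly interpolated."""
    above = x >= level
    if not np.any(above):
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    frac = (level - x[i - 1]) / (x[i] - x[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def functional_map(
    imgs: ImageSeries,
    global_curve: ConductivityCurve,
    indicator: str = "mve",
    rho_min: float = 0.5,
    amp_min_frac: float = 0.10,
    roi_labels: np.ndarray | None = None,
) -> FunctionalMap:
    """Evaluate one indicator on every voxel's conductivity waveform.

    A voxel is zeroed when its waveform correlates with the global curve
    below ``rho_min`` OR its peak-to-peak amplitude is below ``amp_min_frac``
    of the largest voxel amplitude (the conservative OR quality gate).  A
    voxel with no detectable exhale is zeroed, not fatal.  Values are in
    conductivity units.
    """
    if indicator not in INDICATOR_NAMES:
        raise ContractError(f"unknown indicator {indicator!r}")
    if abs(imgs.fps - global_curve.fps) > 1e-9:
        raise ContractError("image series and global curve frame rates differ")
    n, h, w = imgs.values.shape
    wave = -imgs.values.reshape(n, h * w)  # sign-flip: co-moves with volume
    amp = wave.max(axis=0) - wave.min(axis=0)
    amp_thresh = amp_min_frac * amp.max()
    g = global_curve.values
    g_sd = g.std()
    grid = np.zeros(h * w)
    zero = np.ones(h * w, dtype=bool)
    inside = imgs.inside_mask.ravel()
    for i in np.flatnonzero(inside):
        if amp[i] < amp_thresh or amp[i] == 0:
            continue
        if g_sd == 0 or wave[:, i].std() == 0:
            continue
        if pearsonr(wave[:, i], g)[0] < rho_min:
            continue
        try:
            ind = compute_indicators(VolumeCurve(imgs.times, wave[:, i]))
        except (NoExhaleError, DegenerateCurveError, TruncatedCurveError):
            continue
        val = ind[indicator]
        if np.isnan(val):
            continue
        grid[i] = val
        zero[i] = False
    grid = grid.reshape(h, w)
    zero = zero.reshape(h, w)
    if roi_labels is None:
        amp_map = (amp * inside).reshape(h, w)
        roi_labels = segment_rois(amp_map, amp_min_frac=amp_min_frac)
    return FunctionalMap(grid=grid, zero_mask=zero, roi_labels=roi_labels, indicator=indicator)


def segment_rois(amplitude_map: np.ndarray, amp_min_frac: float = 0.10) -> np.ndarray:
    """Partition the two largest amplitude clusters into AL/PL/AR/PR.

    4-connected components above ``amp_min_frac`` of the map maximum; the
    cluster whose centroid column is on the viewer's right is the subject's
    *left* lung (caudal view); each cluster splits into anterior (rows above
    its own centroid row) and posterior halves.
    """
    amp = np.asarray(amplitude_map, dtype=float)
    if np.any(amp < 0):
        raise ContractError("amplitude map must be nonnegative")
    mask = amp > amp_min_frac * amp.max()
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    lab, n = ndimage.label(mask, structure=structure)
    if n < 2:
        raise SegmentationFailureError(
            f"found {n} amplitude cluster(s); need 2 lungs above threshold"
        )
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    top2 = np.argsort(-sizes)[:2] + 1
    cents = ndimage.center_of_mass(mask, lab, index=list(top2))
    # larger centroid column = viewer right = subject's left lung
    order = np.argsort([c[1] for c in cents])
    right_lung, left_lung = top2[order[0]], top2[order[1]]
    labels = np.full(amp.shape, "none", dtype="<U4")
    for lung_id, side in ((left_lung, "L"), (right_lung, "R")):
        rows, cols = np.nonzero(lab == lung_id)
        crow = rows.mean()
        anterior = rows < crow
        labels[rows[anterior], cols[anterior]] = "A" + side
        labels[rows[~anterior], cols[~anterior]] = "P" + side
    return labels


def roi_summary(fmap: FunctionalMap) -> dict:
    """Per-ROI mean over contributing (non-zeroed) voxels and their count."""
    out = {}
    for roi in ROI_NAMES:
        sel = (fmap.roi_labels == roi) & ~fmap.zero_mask
        cnt = int(sel.sum())
        out[roi] = {
            "mean": float(fmap.grid[sel].mean()) if cnt else float("nan"),
            "count": cnt,
        }
    return out
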
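"""Synthetic cohorts, breathing paradigms and noisy EIT acquisitions.

This module is the test harness standing in for human trials: it generates
virtual subjects with realistic anthropometrics, their volume-time curves
under four forced breathing paradigms (full/mid inhale x fast/slow exhale)
and a 12-bpm guided paradigm, maps volume to a time-varying lung conductivity
field whose volume-conductivity slope is affine in the weight-height ratio
and chest circumference, and simulates noisy 208-channel belt acquisitions.

Key built-in relations (the ground truth downstream stages must recover):

* conductivity decreases on inhalation: ``dsigma_e(t) = -k_s * w_e * V(t)``
  with ``w_e`` the lung-region weight of element e;
* the subject slope ``k_s = kappa0 / (c1 + c2*(W/H) + c3*Chest)``, so the
  volume-per-conductivity slope grows with W/H and chest circumference;
* ventilation defects scale ``w_e`` in one lung quadrant by a factor in
  [0, 1], lowering local amplitude and raising regional inhomogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .errors import (
    ConfigurationError,
    ContractError,
    EITLungValidationError,
    NumericalFailureError,
)
from .forward import (
    CEMSystem,
    ConductivityField,
    DrivePattern,
    VoltageFrame,
    VoltageFrameSeries,
)
from .mesh import Mesh
from .waveform import VolumeCurve

__all__ = [
    "Subject",
    "Paradigm",
    "VentilationDefect",
    "LungGeometry",
    "GroundTruth",
    "generate_cohort",
    "volume_trajectory",
    "sigma_from_volume",
    "simulate_clean",
    "add_measurement_noise",
    "reference_frame",
    "simulate_acquisition",
    "spirometer_curve",
]

#: exhale time constants (s); fast is tuned so a full/fast maneuver has
#: EV1/MVE = 1 - exp(-1/0.62) ~ 0.80, a normal FEV1/FVC
TAU_EXHALE = {"fast": 0.62, "slow": 2.5}
INHALE_DURATION_S = 2.0

#: subject-slope law constants: k_s = KAPPA0 / (C1 + C2*(W/H) + C3*Chest)
KAPPA0 = 1.0
C1 = 5.0
C2 = 40.0  # per (kg/cm)
C3 = 0.05  # per cm


@dataclass(frozen=True)
class Subject:
    """A virtual subject's anthropometrics."""

    id: str
    age: float
    sex: str
    height: float  # cm
    weight: float  # kg
    chest: float  # cm
    predicted_fvc: float  # L

    def __post_init__(self):
        for name in ("height", "weight", "chest", "predicted_fvc"):
            if getattr(self, name) <= 0:
                raise EITLungValidationError(f"{name} must be positive for {self.id}")

    @property
    def w_h(self) -> float:
        """Weight-height ratio (kg/cm)."""
        return self.weight / self.height

    @property
    def slope_denominator(self) -> float:
        return C1 + C2 * self.w_h + C3 * self.chest

    @property
    def k_sigma(self) -> float:
        """Conductivity change per litre inhaled (positive magnitude)."""
        return KAPPA0 / self.slope_denominator


@dataclass(frozen=True)
class Paradigm:
    """Breathing paradigm.

    ``forced``: raised-cosine inhale over 2 s to full (predicted FVC) or mid
    (half of it) capacity, then exponential exhale with a fast (0.62 s) or
    slow (2.5 s) time constant.  ``guided``: paced sinusoidal breathing at
    ``breathing_rate`` bpm with a deep (1.5 L) or shallow (0.5 L) tidal
    volume.
    """

    kind: str = "forced"
    inhale_depth: str = "full"  # forced: full|mid; guided: deep|shallow
    exhale_speed: str = "fast"  # forced only: fast|slow
    breathing_rate: float = 12.0  # guided only, breaths/min
    tidal_volume: float | None = None  # guided override, L
    duration: float = 10.0  # s
    fps: float = 50.0

    def __post_init__(self):
        if self.kind not in ("forced", "guided"):
            raise EITLungValidationError(f"unknown paradigm kind {self.kind!r}")
        if not 0 < self.fps <= 50:
            raise EITLungValidationError("fps must be in (0, 50]")
        if self.kind == "forced":
            if self.inhale_depth not in ("full", "mid"):
                raise EITLungValidationError("forced inhale_depth must be full|mid")
            if self.exhale_speed not in TAU_EXHALE:
                raise EITLungValidationError("exhale_speed must be fast|slow")
        else:
            if self.breathing_rate <= 0:
                raise EITLungValidationError("guided breathing_rate must be positive")
            if self.inhale_depth not in ("deep", "shallow") and self.tidal_volume is None:
                raise EITLungValidationError(
                    "guided inhale_depth must be deep|shallow or tidal_volume set"
                )
        if self.duration <= 0:
            raise EITLungValidationError("duration must be positive")


@dataclass(frozen=True)
class VentilationDefect:
    """Scale local ventilation amplitude in one lung quadrant by ``factor``."""

    region: str  # AL | PL | AR | PR
    factor: float

    def __post_init__(self):
        if self.region not in ("AL", "PL", "AR", "PR"):
            raise EITLungValidationError(f"unknown region {self.region!r}")
        if not 0 <= self.factor <= 1:
            raise EITLungValidationError("defect factor must be in [0, 1]")


@dataclass(frozen=True)
class LungGeometry:
    """Two elliptic lung regions in normalized mesh coordinates.

    Posterior of center (negative y, anterior being +y), subject's left at
    +x.  The right lung is 20% larger in area by default, reflecting the
    heart occupying part of the left thorax.
    """

    left_center: tuple = (0.35, -0.15)
    left_semi: tuple = (0.22, 0.30)
    right_center: tuple = (-0.35, -0.15)
    right_semi: tuple = (0.22 * np.sqrt(1.2), 0.30 * np.sqrt(1.2))

    def pixel_roi_labels(self, mesh: Mesh, rasterizer) -> np.ndarray:
        """Ground-truth AL/PL/AR/PR pixel labels for simulation studies.

        A pixel takes the quadrant contributing the most element area to it
        (via the rasterizer's overlap matrix); pixels whose lung coverage is
        under a quarter of their body coverage stay 'none'.
        """
        elem_labels = self.element_region(mesh)
        n = rasterizer.grid_n
        coverage = np.asarray(rasterizer.P.sum(axis=1)).ravel()
        masses = {}
        for q in ("AL", "PL", "AR", "PR"):
            masses[q] = np.asarray(rasterizer.P @ (elem_labels == q).astype(float))
        stack = np.stack([masses[q] for q in ("AL", "PL", "AR", "PR")])
        total_lung = stack.sum(axis=0)
        best = np.argmax(stack, axis=0)
        labels = np.full(n * n, "none", dtype="<U4")
        keep = total_lung > 0.25 * np.maximum(coverage, 1e-300)
        names = np.array(["AL", "PL", "AR", "PR"])
        labels[keep] = names[best[keep]]
        return labels.reshape(n, n)

    def element_region(self, mesh: Mesh) -> np.ndarray:
        """Per-element quadrant label: AL/PL/AR/PR or 'none'."""
        c = mesh.element_centroids
        labels = np.full(mesh.n_elements, "none", dtype="<U4")
        for side, (cx, cy), (sx, sy) in (
            ("L", self.left_center, self.left_semi),
            ("R", self.right_center, self.right_semi),
        ):
            inside = ((c[:, 0] - cx) / sx) ** 2 + ((c[:, 1] - cy) / sy) ** 2 <= 1.0
            ant = c[:, 1] > cy
            labels[inside & ant] = "A" + side
            labels[inside & ~ant] = "P" + side
        return labels


@dataclass
class GroundTruth:
    """True volume curve, per-element conductivity-change series and slope."""

    volume_curve: VolumeCurve
    sigma_series: np.ndarray  # (n_frames, n_elements), change vs zero-volume
    slope_true: float  # L per unit global (area-weighted, negated) dsigma
    subject: Subject
    defects: tuple = ()
    element_weights: np.ndarray | None = None

    def __post_init__(self):
        if self.sigma_series.shape[0] != self.volume_curve.times.shape[0]:
            raise ContractError("sigma series and volume curve time grids differ")


# --------------------------------------------------------------------- cohort
def _trunc(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(n: int, seed: int = 0) -> list[Subject]:
    """Generate ``n`` virtual adults with correlated anthropometrics.

    Height ~ N(170, 10) cm on [145, 200]; weight ~ N(70, 12) kg on [40, 120];
    chest = 0.52*height + N(0, 4) cm on [70, 130]; age ~ N(35, 12) y on
    [18, 80].  Predicted FVC is the affine law 0.0576*height - 0.025*age -
    4.34 L clipped to [3, 6] L, spanning the 3.25-5.5 L range with mean near
    4.5 L.
    """
    if n < 1:
        raise EITLungValidationError(f"cohort size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    height = _trunc(rng, 170, 10, 145, 200, n)
    weight = _trunc(rng, 70, 12, 40, 120, n)
    chest = np.clip(0.52 * height + rng.normal(0, 4, n), 70, 130)
    age = _trunc(rng, 35, 12, 18, 80, n)
    sex = rng.choice(["M", "F"], size=n)
    pfvc = np.clip(0.0576 * height - 0.025 * age - 4.34, 3.0, 6.0)
    return [
        Subject(
            id=f"S{i+1:03d}",
            age=float(age[i]),
            sex=str(sex[i]),
            height=float(height[i]),
            weight=float(weight[i]),
            chest=float(chest[i]),
            predicted_fvc=float(pfvc[i]),
        )
        for i in range(n)
    ]


# ------------------------------------------------------------------ paradigms
def volume_trajectory(subject: Subject, paradigm: Paradigm) -> VolumeCurve:
    """True inspired-volume trajectory V(t) in litres for one maneuver."""
    n = int(round(paradigm.duration * paradigm.fps)) + 1
    t = np.arange(n) / paradigm.fps
    if paradigm.kind == "forced":
        v_insp = subject.predicted_fvc * (1.0 if paradigm.inhale_depth == "full" else 0.5)
        tau = TAU_EXHALE[paradigm.exhale_speed]
        v = np.where(
            t <= INHALE_DURATION_S,
            v_insp * 0.5 * (1 - np.cos(np.pi * t / INHALE_DURATION_S)),
            v_insp * np.exp(-(t - INHALE_DURATION_S) / tau),
        )
    else:
        if paradigm.tidal_volume is not None:
            vt = paradigm.tidal_volume
        else:
            vt = 1.5 if paradigm.inhale_depth == "deep" else 0.5
        f = paradigm.breathing_rate / 60.0
        v = 0.5 * vt * (1 - np.cos(2 * np.pi * f * t))
    return VolumeCurve(t, v)


# ------------------------------------------------------- conductivity mapping
def sigma_from_volume(
    mesh: Mesh,
    subject: Subject,
    volume_curve: VolumeCurve,
    defects=(),
    lungs: LungGeometry | None = None,
) -> GroundTruth:
    """Map a volume trajectory to a per-element conductivity-change series.

    ``dsigma_e(t) = -k_s * w_e * V(t)`` with lung weights ``w_e`` (defect
    factors applied per quadrant) and the anthropometric slope law ``k_s``.
    ``slope_true`` is litres per unit of the global area-weighted negated
    conductivity change, i.e. the slope a downstream regression should find.
    """
    lungs = lungs or LungGeometry()
    labels = lungs.element_region(mesh)
    if not np.any(labels != "none"):
        raise ConfigurationError(
            "mesh has no elements inside the lung regions; refine the mesh or "
            "adjust LungGeometry"
        )
    w = (labels != "none").astype(float)
    for d in defects:
        w[labels == d.region] *= d.factor
    k_s = subject.k_sigma
    sigma_series = -k_s * np.outer(volume_curve.volume, w)
    lung_area = float(np.sum(mesh.element_areas * w))
    if lung_area <= 0:
        raise ConfigurationError("defects removed all ventilated lung area")
    slope_true = 1.0 / (k_s * lung_area)
    return GroundTruth(
        volume_curve=volume_curve,
        sigma_series=sigma_series,
        slope_true=slope_true,
        subject=subject,
        defects=tuple(defects),
        element_weights=w,
    )


# ---------------------------------------------------------------- acquisition
def _min_volume_frames(volume: np.ndarray) -> np.ndarray:
    vmin, vmax = volume.min(), volume.max()
    tol = 0.02 * (vmax - vmin) if vmax > vmin else 0.0
    return np.flatnonzero(volume <= vmin + tol)


def simulate_clean(
    mesh: Mesh,
    truth: GroundTruth,
    pattern: DrivePattern | None = None,
    baseline_sigma: float = 1.0,
) -> VoltageFrameSeries:
    """Noise-free acquisition: solve the CEM per frame on baseline + dsigma(t)."""
    pattern = pattern or DrivePattern()
    system = CEMSystem(mesh, pattern)
    n_frames = truth.sigma_series.shape[0]
    values = np.empty((n_frames, pattern.n_channels))
    base = np.full(mesh.n_elements, baseline_sigma)
    for i in range(n_frames):
        try:
            fld = ConductivityField(base + truth.sigma_series[i])
            values[i] = system.solve(fld, truth.volume_curve.times[i]).values
        except (NumericalFailureError, ContractError) as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
    return VoltageFrameSeries(values, truth.volume_curve.times, truth.volume_curve.fps)


def add_measurement_noise(
    series: VoltageFrameSeries, truth: GroundTruth, noise_snr_db: float, seed: int
) -> VoltageFrameSeries:
    """Add white Gaussian noise scaled to an SNR on the difference signal.

    SNR is defined against the RMS of (frame - reference) over all frames and
    channels, the physically informative part of the signal in
    time-difference imaging.
    """
    if not noise_snr_db > 0:
        raise EITLungValidationError("noise_snr_db must be positive (or np.inf)")
    if np.isinf(noise_snr_db):
        return series
    ref_idx = _min_volume_frames(truth.volume_curve.volume)
    ref = series.values[ref_idx].mean(axis=0)
    diff = series.values - ref
    p_signal = float(np.mean(diff**2))
    sd = np.sqrt(p_signal / 10 ** (noise_snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noisy = series.values + rng.normal(0.0, sd, series.values.shape)
    return VoltageFrameSeries(noisy, series.times, series.fps)


def reference_frame(series: VoltageFrameSeries, truth: GroundTruth) -> VoltageFrame:
    """Average of the frames acquired within 2% (of range) of minimum volume."""
    idx = _min_volume_frames(truth.volume_curve.volume)
    vals = series.values[idx]
    # identical frames average to themselves bit-exactly
    ref = vals[0] if np.all(vals == vals[0]) else vals.mean(axis=0)
    return VoltageFrame(ref, float(series.times[idx[0]]))


def simulate_acquisition(
    mesh: Mesh,
    truth: GroundTruth,
    pattern: DrivePattern | None = None,
    noise_snr_db: float = np.inf,
    seed: int = 0,
    baseline_sigma: float = 1.0,
):
    """Simulate a noisy acquisition; returns (series, end-expiration reference)."""
    clean = simulate_clean(mesh, truth, pattern, baseline_sigma)
    noisy = add_measurement_noise(clean, truth, noise_snr_db, seed)
    return noisy, reference_frame(noisy, truth)


def spirometer_curve(truth: GroundTruth, seed: int = 0, noise_sd: float = 0.02) -> VolumeCurve:
    """Co-registered spirometer channel: true volume plus N(0, 0.02 L) noise."""
    rng = np.random.default_rng(seed)
    v = truth.volume_curve.volume + rng.normal(0.0, noise_sd, truth.volume_curve.volume.shape)
    return VolumeCurve(truth.volume_curve.times, v)
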
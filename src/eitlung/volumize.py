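"""Anthropometric-interaction regression predicting volume from conductivity.

Per subject, the relation between the global conductivity change and the
inspired volume is linear but with a subject-dependent slope.  The slope
correlates with the weight-height ratio (W/H) and chest circumference, so a
single cross-subject model with product terms

    V = b0 + b1*ds + b2*ds*(W/H) + b3*ds*Chest + b4*(W/H) + b5*Chest

predicts volume without per-subject calibration.  Weight itself is never a
regressor (it is nearly collinear with W/H).  The anthropometric main
effects (b4, b5) are optional intercept terms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import (
    CollinearityError,
    ContractError,
    DegenerateFitError,
    EITLungValidationError,
    UndefinedMetricError,
    UnfittedModelError,
)
from .phantom import Subject
from .waveform import ConductivityCurve, VolumeCurve

__all__ = [
    "Dataset",
    "VolumeModel",
    "fit_per_subject",
    "split_train_test",
    "fit_volume_model",
    "predict_volume",
    "metrics",
]

BASIS_NAMES = ("const", "dsig", "dsig_wh", "dsig_chest", "wh", "chest")

#: relative ridge jitter added to the normal equations for conditioning
RIDGE_JITTER = 1e-10


@dataclass
class Dataset:
    """Regression samples: one row per time point of a maneuver.

    Columns: ``subject_id``, ``dsig`` (denoised global conductivity value),
    ``volume_L`` (measured volume), ``trial``, ``paradigm``.
    """

    df: pd.DataFrame

    REQUIRED = ("subject_id", "dsig", "volume_L", "trial", "paradigm")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ContractError(f"dataset is missing columns {missing}")

    @classmethod
    def from_samples(cls, rows) -> "Dataset":
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))

    @classmethod
    def from_curves(
        cls, subject_id: str, conductivity: ConductivityCurve, volume: VolumeCurve,
        trial: int = 0, paradigm: str = "forced",
    ) -> "Dataset":
        """One maneuver's co-registered samples (curves share a time grid)."""
        if conductivity.times.shape != volume.times.shape or not np.allclose(
            conductivity.times, volume.times
        ):
            raise ContractError("curves must share a time grid; resample first")
        return cls(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "dsig": conductivity.values,
                    "volume_L": volume.volume,
                    "trial": trial,
                    "paradigm": paradigm,
                }
            )
        )

    def subjects(self):
        return list(self.df["subject_id"].unique())

    def restrict(self, subject_id: str) -> "Dataset":
        return Dataset(self.df[self.df["subject_id"] == subject_id].reset_index(drop=True))

    def concat(self, other: "Dataset") -> "Dataset":
        return Dataset(pd.concat([self.df, other.df], ignore_index=True))

    def __len__(self):
        return len(self.df)


def fit_per_subject(dataset: Dataset):
    """OLS line of volume on conductivity for a single subject.

    Returns ``(slope, intercept, pcc)``.
    """
    if len(dataset.subjects()) != 1:
        raise EITLungValidationError("fit_per_subject expects data from exactly one subject")
    if len(dataset) < 3:
        raise DegenerateFitError("need at least 3 samples for a per-subject fit")
    x = dataset.df["dsig"].to_numpy()
    y = dataset.df["volume_L"].to_numpy()
    if np.std(x) == 0:
        raise DegenerateFitError("zero conductivity variance; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    pcc = pearsonr(x, y)[0] if np.std(y) > 0 else np.nan
    return float(slope), float(intercept), float(pcc)


def split_train_test(
    dataset: Dataset, n_holdout_subjects: int = 2, holdout_fraction: float = 0.10,
    seed: int = 0,
):
    """Held-out-subject + random-sample split.

    The test side is all samples from ``n_holdout_subjects`` randomly chosen
    subjects plus a simple random ``holdout_fraction`` (ceiling) of the
    remaining samples; the rest is training.  Disjoint by construction.
    """
    subjects = dataset.subjects()
    if len(subjects) < max(4, n_holdout_subjects + 1):
        raise EITLungValidationError(
            f"need more subjects than the {n_holdout_subjects} held out (got {len(subjects)})"
        )
    rng = np.random.default_rng(seed)
    held = set(rng.choice(subjects, size=n_holdout_subjects, replace=False))
    is_held = dataset.df["subject_id"].isin(held).to_numpy()
    remaining_idx = np.flatnonzero(~is_held)
    # ceiling on the exact fraction (round first: 0.1*240 is 24.000...004 in fp)
    k = int(np.ceil(np.round(holdout_fraction * remaining_idx.size, 9)))
    extra = rng.choice(remaining_idx, size=k, replace=False)
    test_mask = is_held.copy()
    test_mask[extra] = True
    train = Dataset(dataset.df[~test_mask].reset_index(drop=True))
    test = Dataset(dataset.df[test_mask].reset_index(drop=True))
    return train, test


def _design(dsig, subjects_df, include_main_effects=True):
    wh = subjects_df["wh"].to_numpy()
    chest = subjects_df["chest"].to_numpy()
    cols = [np.ones_like(dsig), dsig, dsig * wh, dsig * chest]
    names = list(BASIS_NAMES[:4])
    if include_main_effects:
        cols += [wh, chest]
        names += list(BASIS_NAMES[4:])
    return np.column_stack(cols), names


@dataclass
class VolumeModel:
    """Fitted anthropometric-interaction volume model.

    Coefficients follow the documented basis order ``BASIS_NAMES``; main
    effects may be absent when fitted with ``include_main_effects=False``.
    """

    coefficients: np.ndarray | None = None
    basis: tuple = BASIS_NAMES
    include_main_effects: bool = True
    diagnostics: dict = dc_field(default_factory=dict)

    @property
    def fitted(self) -> bool:
        return self.coefficients is not None

    def _require_fitted(self):
        if not self.fitted:
            raise UnfittedModelError("volume model has not been fitted")

    def predict_samples(self, dsig: np.ndarray, subject: Subject) -> np.ndarray:
        self._require_fitted()
        dsig = np.asarray(dsig, dtype=float)
        sub = pd.DataFrame({"wh": [subject.w_h] * dsig.size, "chest": [subject.chest] * dsig.size})
        X, _ = _design(dsig, sub, self.include_main_effects)
        return X @ self.coefficients

    def summary(self) -> str:
        self._require_fitted()
        lines = [
            "Anthropometric-interaction volume model",
            "=" * 47,
            f"{'term':<12}{'coefficient':>15}",
            "-" * 27,
        ]
        for name, c in zip(self.basis, self.coefficients):
            lines.append(f"{name:<12}{c:>15.6g}")
        d = self.diagnostics
        lines.append("-" * 27)
        lines.append(f"n_train = {d.get('n_train', 'n/a')}, "
                     f"residual SD = {d.get('residual_sd', float('nan')):.4g} L")
        return "\n".join(lines)

    def to_json(self, path):
        self._require_fitted()
        payload = {
            "basis": list(self.basis),
            "coefficients": list(map(float, self.coefficients)),
            "include_main_effects": self.include_main_effects,
            "diagnostics": {k: float(v) for k, v in self.diagnostics.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "VolumeModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            coefficients=np.array(p["coefficients"], dtype=float),
            basis=tuple(p["basis"]),
            include_main_effects=p["include_main_effects"],
            diagnostics=p["diagnostics"],
        )


def fit_volume_model(
    train: Dataset, cohort: list[Subject], include_main_effects: bool = True
) -> VolumeModel:
    """Least-squares fit of the 6-term interaction basis via normal equations.

    A relative ridge jitter of 1e-10 is added for conditioning.  Raises
    :class:`CollinearityError` naming the offending basis columns when the
    design is rank deficient beyond what the jitter can absorb.
    """
    if len(train) < 10 or len(train.subjects()) < 2:
        raise EITLungValidationError("need >= 10 samples spanning >= 2 subjects")
    by_id = {s.id: s for s in cohort}
    missing = [sid for sid in train.subjects() if sid not in by_id]
    if missing:
        raise ContractError(f"subjects {missing} not present in cohort table")
    sub = pd.DataFrame(
        {
            "wh": [by_id[s].w_h for s in train.df["subject_id"]],
            "chest": [by_id[s].chest for s in train.df["subject_id"]],
        }
    )
    dsig = train.df["dsig"].to_numpy()
    y = train.df["volume_L"].to_numpy()
    X, names = _design(dsig, sub, include_main_effects)
    # collinearity screen on the column-scaled design
    scale = np.linalg.norm(X, axis=0)
    if np.any(scale == 0):
        bad = [names[i] for i in np.flatnonzero(scale == 0)]
        raise CollinearityError(f"all-zero design columns: {bad}")
    Xs = X / scale
    svals = np.linalg.svd(Xs, compute_uv=False)
    if svals[-1] / svals[0] < 1e-8:
        _, _, Vt = np.linalg.svd(Xs)
        null = np.abs(Vt[-1])
        bad = [names[i] for i in np.flatnonzero(null > 0.3)]
        raise CollinearityError(
            f"design is rank deficient; near-collinear columns: {bad}"
        )
    # normal equations on the column-scaled design (conditioning), with the
    # documented relative ridge jitter; coefficients unscaled afterwards
    XtX = Xs.T @ Xs
    coef_s = np.linalg.solve(
        XtX + RIDGE_JITTER * np.eye(XtX.shape[0]), Xs.T @ y
    )
    coef = coef_s / scale
    resid = y - X @ coef
    model = VolumeModel(
        coefficients=coef,
        basis=tuple(names),
        include_main_effects=include_main_effects,
        diagnostics={
            "n_train": float(len(train)),
            "residual_sd": float(np.std(resid)),
            "residual_variance": float(np.var(resid)),
        },
    )
    return model


def predict_volume(model: VolumeModel, curve: ConductivityCurve, subject: Subject) -> VolumeCurve:
    """Apply the fitted basis pointwise to a conductivity curve."""
    pred = model.predict_samples(curve.values, subject)
    return VolumeCurve(curve.times, pred)


def metrics(predicted: VolumeCurve, measured: VolumeCurve):
    """(PCC, NRMSE %) of a predicted against a measured volume curve.

    NRMSE is the RMSE divided by the measured range, in percent.
    """
    if predicted.times.shape != measured.times.shape or not np.allclose(
        predicted.times, measured.times
    ):
        raise ContractError("curves must share a time grid")
    rng_ = measured.volume.max() - measured.volume.min()
    if rng_ == 0:
        raise UndefinedMetricError("measured curve has zero range; NRMSE undefined")
    rmse = float(np.sqrt(np.mean((predicted.volume - measured.volume) ** 2)))
    pcc = float(pearsonr(predicted.volume, measured.volume)[0])
    return pcc, 100.0 * rmse / rng_
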
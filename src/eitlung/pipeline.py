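"""End-to-end pipeline: simulate -> denoise -> reconstruct -> waveform ->
volume prediction -> indicators / guided analysis.

Randomness is a single per-run seed forked into independent stage streams by
documented labels, so adding a stage never perturbs another stage's draws.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np

from . import __version__
from .errors import EITLungError
from .forward import CEMSystem, ConductivityField, DrivePattern
from .guided import analyze_guided
from .indicators import INDICATOR_NAMES, compute_indicators, functional_map, roi_summary
from .io import RunConfig, write_cohort, write_curve, write_image_series
from .mesh import build_thorax_mesh
from .phantom import (
    LungGeometry,
    Paradigm,
    generate_cohort,
    sigma_from_volume,
    simulate_acquisition,
    spirometer_curve,
    volume_trajectory,
)
from .reconstruct import Rasterizer, reconstruct_series
from .volumize import Dataset, fit_volume_model, metrics, predict_volume, split_train_test
from .waveform import denoise, global_waveform

__all__ = ["pipeline_run", "default_lambda"]

#: stage labels -> seed-stream fork keys (order is part of the format)
STAGE_KEYS = {"cohort": 1, "acquisition": 2, "spirometer": 3, "split": 4}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage 31-bit seed forked from the run seed."""
    ss = np.random.SeedSequence([int(seed), STAGE_KEYS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def default_lambda(J: np.ndarray, prior: str = "noser", factor: float = 0.02) -> float:
    """Default imaging regularization: ``factor`` x the largest prior-whitened
    singular value of J.

    0.02 keeps the two lung clusters separable in the amplitude maps while
    still suppressing measurement noise at the SNRs a belt system delivers.
    """
    if prior == "noser":
        d = np.sqrt(np.clip(np.einsum("ij,ij->j", J, J), 1e-300, None))
        J = J / d[None, :]
    return factor * float(np.linalg.norm(J, 2))


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {k: repr(getattr(config, k)) for k in sorted(config.__dataclass_fields__)}
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def pipeline_run(config: RunConfig, outdir: str) -> dict:
    """Run the full pipeline described by ``config`` into ``outdir``.

    Returns the report dictionary (also written as ``report.json``).
    Identical config + seed produce identical outputs.
    """
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"stages": []}

    def stage(name):
        report["stages"].append(name)

    try:
        stage("mesh")
        mesh = build_thorax_mesh(
            config.mesh_shape, config.mesh_elements, config.electrode_coverage,
            axis_ratio=config.axis_ratio,
        )
        pattern = DrivePattern(current_amplitude=config.current_amplitude)
        system = CEMSystem(mesh, pattern)
        J = system.jacobian(ConductivityField.homogeneous(mesh))
        lam = config.lam if config.lam is not None else default_lambda(J, config.prior)
        rasterizer = Rasterizer(mesh)

        if config.paradigm_kind == "guided":
            result = _run_guided(config, mesh, pattern, J, lam, rasterizer, outdir, stage)
        else:
            result = _run_forced(config, mesh, pattern, J, lam, rasterizer, outdir, stage)
        report.update(result)
    except EITLungError as exc:
        raise type(exc)(f"pipeline stage '{report['stages'][-1]}' failed: {exc}") from exc

    report["manifest"] = {
        "eitlung_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "lambda": lam,
    }
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def _acquire(config, mesh, pattern, subject, paradigm, defects, seed):
    vc = volume_trajectory(subject, paradigm)
    truth = sigma_from_volume(mesh, subject, vc, defects)
    series, ref = simulate_acquisition(
        mesh, truth, pattern, noise_snr_db=config.noise_snr_db, seed=seed
    )
    return truth, series, ref


def _run_forced(config, mesh, pattern, J, lam, rasterizer, outdir, stage):
    paradigm = Paradigm(
        kind="forced", inhale_depth=config.inhale_depth,
        exhale_speed=config.exhale_speed, duration=config.duration, fps=config.fps,
    )
    stage("simulate")
    cohort = generate_cohort(config.n_calibration_subjects + 1, stage_seed(config.seed, "cohort"))
    write_cohort(os.path.join(outdir, "cohort.csv"), cohort)
    acq_seed = stage_seed(config.seed, "acquisition")
    spiro_seed = stage_seed(config.seed, "spirometer")

    dataset = None
    per_subject = {}
    for i, subj in enumerate(cohort):
        truth, series, ref = _acquire(config, mesh, pattern, subj, paradigm, (), acq_seed + i)
        stage_label = f"reconstruct[{subj.id}]"
        stage(stage_label)
        imgs = reconstruct_series(J, series, ref, lam, config.prior, rasterizer=rasterizer)
        imgs = denoise(imgs, "forced")
        curve = denoise(global_waveform(imgs), "forced")
        spiro = spirometer_curve(truth, spiro_seed + i)
        per_subject[subj.id] = (subj, truth, imgs, curve, spiro)
        ds = Dataset.from_curves(subj.id, curve, spiro, trial=0, paradigm=_paradigm_name(paradigm))
        dataset = ds if dataset is None else dataset.concat(ds)

    stage("fit-volume")
    train, test = split_train_test(dataset, n_holdout_subjects=min(2, len(cohort) - 2),
                                   seed=stage_seed(config.seed, "split"))
    model = fit_volume_model(train, cohort)
    model.to_json(os.path.join(outdir, "model.json"))

    stage("predict")
    target_id = cohort[-1].id
    subj, truth, imgs, curve, spiro = per_subject[target_id]
    predicted = predict_volume(model, curve, subj)
    pcc, nrmse = metrics(predicted, spiro)
    write_curve(os.path.join(outdir, "predicted_volume.tsv"), predicted)
    write_curve(os.path.join(outdir, "conductivity.tsv"), curve)
    write_image_series(os.path.join(outdir, "images"), imgs,
                       {"lambda": lam, "prior": config.prior})

    stage("indicators")
    inds = compute_indicators(predicted)
    maps = {}
    # simulated acquisitions carry their true lung geometry; label ROIs from it
    labels = LungGeometry().pixel_roi_labels(mesh, rasterizer)
    for name in INDICATOR_NAMES:
        fmap = functional_map(imgs, curve, name, config.rho_min, config.amp_min_frac,
                              roi_labels=labels)
        maps[name] = roi_summary(fmap)
        np.savetxt(os.path.join(outdir, f"map_{name}.csv"), fmap.grid,
                   delimiter=",", fmt="%.17g")
    return {
        "paradigm": _paradigm_name(paradigm),
        "target_subject": target_id,
        "prediction": {"pcc": pcc, "nrmse_percent": nrmse},
        "indicators": inds.as_dict(),
        "regional": maps,
    }


def _run_guided(config, mesh, pattern, J, lam, rasterizer, outdir, stage):
    paradigm = Paradigm(
        kind="guided", inhale_depth=config.inhale_depth if config.inhale_depth in ("deep", "shallow") else "deep",
        breathing_rate=config.breathing_rate, duration=config.duration, fps=config.fps,
    )
    stage("simulate")
    cohort = generate_cohort(1, stage_seed(config.seed, "cohort"))
    subj = cohort[0]
    truth, series, ref = _acquire(config, mesh, pattern, subj, paradigm, (),
                                  stage_seed(config.seed, "acquisition"))
    stage("reconstruct")
    imgs = reconstruct_series(J, series, ref, lam, config.prior, rasterizer=rasterizer)
    imgs = denoise(imgs, "guided")
    stage("guided-analysis")
    res = analyze_guided(imgs, paradigm.breathing_rate, config.act_frac, config.amp_min_frac)
    np.savetxt(os.path.join(outdir, "amplitude_map.csv"), res.amplitude_map,
               delimiter=",", fmt="%.17g")
    np.savetxt(
        os.path.join(outdir, "spectrum.csv"),
        np.column_stack([res.spectrum_freqs, res.spectrum_left, res.spectrum_right]),
        delimiter=",", header="freq_hz,left,right", comments="",
    )
    return {
        "paradigm": f"guided-{paradigm.breathing_rate:g}bpm",
        "subject": subj.id,
        "activation": res.activation,
        "cv": res.cv,
    }


def _paradigm_name(p: Paradigm) -> str:
    if p.kind == "forced":
        return f"{p.inhale_depth}-{p.exhale_speed}"
    return f"guided-{p.breathing_rate:g}bpm"
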
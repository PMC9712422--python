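# eitlung

Lung-function analysis for a portable 16-electrode electrical impedance
tomography (EIT) belt, built as a fully simulated, testable pipeline: from
boundary-voltage frames, through time-difference conductivity imaging, to
spirometry-style indicators and regional ventilation-inhomogeneity indices.

## The problem

Spirometry is the standard lung-function test, but it demands maximal-effort
forced breathing and a clinic visit. A chest belt with 16 electrodes can
image the conductivity change of the thorax while a subject breathes: lung
tissue becomes more resistive as it fills with air, so the reconstructed
conductivity change tracks inspired volume. Two obstacles stand between the
raw belt data and spirometry-grade numbers:

1. **Calibration.** The conductivity-to-volume slope differs between
   subjects. It correlates strongly with the weight-height ratio (W/H) and
   chest circumference, so a single regression with interaction terms

   V = b₀ + b₁·Δσ + b₂·Δσ·(W/H) + b₃·Δσ·Chest + b₄·(W/H) + b₅·Chest

   predicts volume for *unseen* subjects from their anthropometrics alone —
   no per-subject spirometer calibration.

2. **Effort dependence.** Forced maneuvers are hard for impaired patients.
   A paced ("guided") breathing paradigm at 12 breaths/min is
   close to effortless; voxel amplitude maps at the pacing frequency, the
   count of activated voxels, total amplitude, and the coefficient of
   variation (C.V. = SD/mean of voxel amplitudes in a lung region) then
   quantify global and regional function, and longitudinal C.V. trends
   track deterioration and recovery.

No human data ships with this package. Instead a first-class synthetic
module (`eitlung.phantom`) generates virtual cohorts, four forced breathing
paradigms (full/mid inhale × fast/slow exhale), the guided paradigm,
subject-dependent conductivity-volume slopes, regional ventilation defects
and noisy acquisitions — everything needed to exercise and falsify the
pipeline.

## What is inside

| module | contents |
| --- | --- |
| `eitlung.mesh` | deterministic triangulated thorax cross-section, 16 equally spaced electrode arcs |
| `eitlung.forward` | complete-electrode-model FEM forward solver, adjacent-drive 208-channel protocol, adjoint Jacobian |
| `eitlung.phantom` | virtual subjects, breathing paradigms, conductivity ground truth, noisy acquisitions |
| `eitlung.reconstruct` | one-step Tikhonov/NOSER time-difference reconstruction onto a 32×32 grid |
| `eitlung.waveform` | despike + zero-phase low-pass denoising, global conductivity curves, per-volume-segment PCC, curve alignment |
| `eitlung.volumize` | per-subject fits, train/test splitting, the anthropometric-interaction volume model, PCC/NRMSE metrics |
| `eitlung.indicators` | MVE, EV1, EV1/MVE, MEF, EF25-75 extraction; voxel functional maps; AL/PL/AR/PR lung ROIs |
| `eitlung.guided` | amplitude maps, activated voxels, totals, spectra, regional C.V., longitudinal trend tests |
| `eitlung.io` / `eitlung.cli` / `eitlung.pipeline` | plain-text formats, YAML run configs, `eitlung` command-line verbs, end-to-end runs |

The five indicators are the belt-side analogues of FVC, FEV1, FEV1/FVC, PEF
and FEF25-75: MVE = max − min of the volume curve; EV1 = volume exhaled in
the first second after the back-extrapolated exhalation onset; MEF = peak
|dV/dt| on the exhale limb; EF25-75 = mean flow between 25% and 75% of
exhaled MVE.

## Worked example

```python
from eitlung import RunConfig, pipeline_run

cfg = RunConfig(seed=42, mesh_elements=400, fps=25, duration=8,
                n_calibration_subjects=4)
report = pipeline_run(cfg, "demo_out")

p = report["prediction"]
print(f"volume PCC   : {p['pcc']:.3f}")
print(f"volume NRMSE : {p['nrmse_percent']:.1f}%")
for k, v in report["indicators"].items():
    print(f"{k:>13s} : {v:.3f}")
```

prints

```
volume PCC   : 1.000
volume NRMSE : 1.0%
          mve : 4.436
          ev1 : 3.560
 ev1_over_mve : 0.803
          mef : 7.177
      ef25_75 : 3.380
```

The run simulates five virtual subjects performing a full-inhale/fast-exhale
maneuver, reconstructs their conductivity films, fits the interaction
regression on four of them (plus a 10% random sample holdout), and predicts
the fifth subject's volume-time curve from their EIT waveform and
anthropometrics alone. The PCC/NRMSE compare that prediction with the
subject's simulated spirometer; the indicator block is standard spirometry
reading of the predicted curve — e.g. EV1/MVE ≈ 0.80 is the healthy
FEV1/FVC analogue built into the phantom's fast-exhale time constant
(τ = 0.62 s, since 1 − e^(−1/0.62) ≈ 0.80). `demo_out/` also receives the
functional maps, the fitted model JSON (`model.json` with the six basis
coefficients) and per-ROI summaries.

The same flow is available from the shell:

```bash
eitlung simulate --out frames.tsv --mesh-out mesh.txt --duration 8 --fps 25
eitlung reconstruct --frames frames.tsv --mesh mesh.txt --out imgs/
eitlung waveform --imgs imgs/ --out curve.tsv
eitlung run --config config.yaml --out report/
```

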
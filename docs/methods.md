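# Methods

This note records the models, numerical choices and known limitations behind
`eitlung`, in the order data flows through the pipeline.

## Geometry and forward model

The belt plane is a 2D convex domain — a circle or an ellipse with the major
axis left-right — scaled to diameter 2 (normalized units; real chest size
enters only through the volume regression, never the geometry). Sixteen
electrode arcs sit equally spaced along the boundary arc length; electrode 1
is centred on the anterior midline and numbering proceeds toward the
subject's left. All images and maps use the caudal-view convention:
anterior at the top row, the subject's left on the viewer's right.

Meshing is deterministic: boundary nodes at equal arc-length intervals
(a multiple of 16 so arcs tile exactly), interior nodes on concentric scaled
rings, Delaunay triangulation of that fixed point set. The boundary is
sampled 1.5× denser than uniform-element spacing would suggest, because the
electrode contact layer otherwise dominates the discretization error: with
2-3 nodes per electrode the channel voltages differed by 2.8% between 800-
and 3200-element meshes; at 1.5× oversampling (4-5 nodes per arc) the
discrepancy is 0.8%. Interior node count is chosen from Euler's relation
(E = 2·N_int + n_b − 2) so the element count matches the request exactly.

The electrical model is the complete electrode model (CEM): P1 finite
elements for the interior potential, per-electrode contact impedance
(default 0.01 Ω·m), prescribed net current per electrode, and a Lagrange
multiplier pinning the electrode potentials to zero sum. The drive protocol
is adjacent-adjacent: current (1 mApp) between neighbouring pairs
(i, i+1 mod 16), voltages on the 13 neighbouring pairs not touching the
drive, 16 × 13 = 208 channels in injection-major order. Because the CEM
system is symmetric, one sparse factorization per conductivity serves all
16 injection patterns, and those same 16 unit-current fields double as the
adjoint fields: the conductivity Jacobian is
J[m, e] = −area_e · ∇u_drive·∇u_meas on each triangle. Reciprocity holds to
solver round-off (~1e−14) and the Jacobian matches brute-force finite
differences to <1e−3 relative; both are regression-tested.

## Synthetic subjects and acquisitions

The phantom module is the study population. Anthropometrics are truncated
normals — height N(170, 10) cm on [145, 200], weight N(70, 12) kg on
[40, 120], chest = 0.52·height + N(0, 4) cm on [70, 130], age N(35, 12) y on
[18, 80] — and predicted FVC is the affine law 0.0576·height − 0.025·age −
4.34 L clipped to [3, 6] L, giving a cohort mean near 4.5 L over roughly
3.2-5.6 L, the physiologic adult range.

Breathing paradigms:

* **forced** — raised-cosine inhale over 2 s to the inspired volume (full:
  predicted FVC; mid: half of it), then exponential exhale
  V = V_insp·e^(−t/τ) with τ_fast = 0.62 s (so EV1/MVE ≈ 0.80, a normal
  FEV1/FVC) and τ_slow = 2.5 s;
* **guided** — V(t) = (V_T/2)(1 − cos 2πft) at f = 12/60 Hz, tidal volume
  1.5 L (deep) or 0.5 L (shallow).

Volume maps to conductivity as Δσ_e(t) = −k_s·w_e·V(t): conductivity
*drops* on inhalation (air is resistive); downstream waveforms are negated
so they co-move with volume. The lung weight w_e is 1 inside two posterior
ellipses (the right one 20% larger in area, the heart crowding the left
thorax), scaled by a defect factor in a quadrant when a ventilation defect
is configured, 0 elsewhere. The subject slope is
k_s = κ₀ / (c₁ + c₂·(W/H) + c₃·Chest) with κ₀ = 1, c₁ = 5, c₂ = 40 per
(kg/cm), c₃ = 0.05 per cm — chosen so the volume-per-conductivity slope is
affine in W/H and chest circumference, qualitatively matching the strong
slope-anthropometrics correlations the regression is designed to exploit,
and so that baseline-relative conductivity changes stay in the 2-15% range.
The generator records `slope_true` (litres per unit of negated,
area-weighted global Δσ) for exact recovery tests.

Acquisition noise is additive white Gaussian on the voltage frames, scaled
to a requested SNR against the RMS of the *difference* signal
(frame − reference), the informative quantity in time-difference imaging.
The reference frame is the average of frames within 2% (of the volume
range) of minimum volume — end expiration. A co-registered "spirometer"
channel is the true volume plus N(0, 0.02 L) noise.

What the phantom does **not** emulate: cardiac-related conductivity
oscillations, electrode movement/contact drift, belt-position and posture
changes, anatomical thorax boundaries, 3D current spread (a single belt
plane cannot see the whole lung). Passing tests therefore demonstrate the
pipeline's correctness and noise behaviour, not clinical accuracy on
humans.

## Reconstruction

One-step linearized difference imaging:
x̂ = (JᵀJ + λ²R)⁻¹ Jᵀ (v − v_ref), with R = I or diag(JᵀJ) (NOSER, the
default). The operator is Cholesky-factorized once per J/λ and applied to
every frame. Default λ = 0.02 × the largest prior-whitened singular value
of J: strong enough to suppress realistic measurement noise, weak enough
that the two lung clusters stay separable in amplitude maps (at 0.05 the
clusters merge at the 10% segmentation threshold). `select_hyperparameter`
instead matches a noise-figure target (ratio of white-noise amplification
to sample-signal amplification in the whitened SVD basis) by bisection on
log λ; an unbracketable target falls back to 0.05 × the largest whitened
singular value with a logged warning.

Element images are rasterized onto a 32×32 grid over the bounding square by
exact triangle-pixel polygon clipping: P[p, e] is the intersection area, so
the pixel sum equals the area-weighted element sum to round-off (a tested
invariant) and interior pixels receive smooth, area-proportional values.
Pixels with zero overlap form the outside-body mask and are exactly zero in
every frame.

## Waveforms and denoising

Denoising is a 3-sample median despike followed by a zero-phase (forward-
backward) order-4 Butterworth low-pass: 8 Hz cutoff for forced maneuvers
(fast exhales have content up to a few Hz at 50 fps), 1.5 Hz for guided
(signal at 0.2 Hz). If the frame rate is too low for the nominal cutoff
(cutoff ≥ 0.95 × Nyquist) the low-pass is skipped — there is no band above
it to remove. The global conductivity curve is the negated sum of in-mask
pixel values (all inside-body pixels by default; a lung-mask variant
exists). Segment-wise volume-conductivity PCC resamples the conductivity
curve onto the volume grid (the spirometer is the time master), restricts
to the exhale limb (samples at or after the volume maximum), bins by
exhaled volume into 1-L segments and reports Pearson r per populated
segment (≥3 samples; NaN otherwise). Curve alignment maximizes the per-lag
normalized cross-correlation with parabolic sub-sample refinement — a
single globally-normalized correlation biased lags toward zero on short
curves.

## Volume regression

Per subject, volume on conductivity is an ordinary least-squares line
(slope, intercept, PCC). The cross-subject model uses the six-term basis
{1, Δσ, Δσ·(W/H), Δσ·Chest, W/H, Chest}; weight itself is never a regressor
(it is nearly collinear with W/H). The anthropometric main effects are
intercept terms and can be disabled. The solve is normal equations on the
column-normalized design with a relative ridge jitter of 1e−10; without
column scaling the squared condition number of the raw design (chest ~90 vs
Δσ ~0.1) made the jitter bias coefficients by ~1%. Rank deficiency beyond
the jitter (condition > 1e8) raises a collinearity error naming the
near-null-space columns. The train/test protocol holds out all samples of
two random subjects plus a random ceil(10%) of the remaining samples —
at 14 subjects × 20 samples that is 64/280 ≈ 22.9% test. NRMSE is RMSE
divided by the measured range, in percent.

Because the generator's slope law lies exactly in the basis span (the lung
area is a fixed geometric constant across subjects), noise-free recovery is
exact to the jitter (~1e−8 relative), including for subjects never seen in
training — the no-per-subject-calibration property the regression exists
for.

## Indicators and functional maps

Exhalation onset is back-extrapolated: intersect the tangent at the
steepest descent of the curve with the horizontal through the curve
maximum, clamped between the two — standard spirometry practice. EV1 uses
linear interpolation at t₀ and t₀ + 1 s; MEF is the peak |dV/dt| (central
differences) on the exhale limb; EF25-75 = (MVE/2)/(t₇₅ − t₂₅) with the
25%/75% exhaled-volume crossings linearly interpolated. At 50 fps all five
indicators are exact to one-sample discretization against closed forms
(tested on a piecewise-linear fixture and on exponentials).

Voxel-level functional maps evaluate the same indicators on each voxel's
sign-flipped waveform, in conductivity units (a volume-scaled variant would
multiply by the subject's fitted slope; the per-voxel scale is not itself
calibrated). A voxel is zeroed when its correlation with the global curve
is below ρ_min = 0.5 **or** its peak-to-peak amplitude is below 10% of the
largest voxel amplitude — OR is the conservative reading of the quality
gate — or when no exhale is detectable on it. Lung ROI segmentation
thresholds an amplitude map at 10% of maximum, takes the two largest
4-connected components, labels the cluster with the right-most centroid as
the subject's left lung, and splits each cluster at its own centroid row
into anterior/posterior — giving AL, PL, AR, PR.

Segmentation caveat: reconstructed forced-maneuver maps blur the two lungs
into one connected component at practical mesh sizes, so per-acquisition
segmentation is reliable for guided maps but not forced ones. Simulation
studies (and the built-in pipeline, which knows its own phantom geometry)
therefore use ground-truth pixel labels projected from the phantom's lung
ellipses; `segment_rois` remains the tool for data whose geometry is
unknown.

## Guided-paradigm analysis

The per-voxel amplitude is the magnitude of the Hann-windowed, linearly
detrended DFT at the bin nearest the pacing frequency, scaled by 2/Σw so a
bin-aligned cosine of amplitude a reads a; a median peak-to-peak alternative
is kept for comparison. Activated voxels exceed 25% of the map maximum —
a *relative* threshold, which is why activation counts are invariant to
breathing depth while total amplitude is not. Spectra use the same
windowing, with frequency resolution 1/duration.

The coefficient of variation uses the population SD over the mean of voxel
amplitudes in a region (lung or quadrant). It is computed over **all** ROI
voxels, not activated voxels only: a ventilation defect lowers exactly its
own voxels' amplitudes, and gating on activation would remove them from the
statistic it is meant to move (measured on the phantom: an AL defect of
factor 0.4 *lowered* activated-only left-lung C.V. from 0.39 to 0.33 while
raising the all-voxel C.V. from 0.59 to 0.71). For longitudinal
comparisons the ROI labels must come from a common baseline session so
membership is fixed. The longitudinal trend is OLS of C.V. on time with a
two-sided t-test on the slope; sessions with leverage above 3× the mean hat
value are flagged. Within-subject max-normalization (each subject's values
divided by their own maximum) makes depths/sessions comparable across
subjects and is idempotent.

A linearity note: the acceptance-level check that deep:shallow (1.5 L vs
0.5 L) amplitude ratios equal 3 within 2% per voxel is performed on
linearized acquisitions (v = v_ref + JΔσ), the small-signal regime in which
the imaging chain is exactly linear. Full CEM physics adds forward-model
saturation at deep tidal volumes (Δσ up to ~6% of baseline), spreading
per-voxel ratios by ~±10% while leaving aggregate ratios near 3.07 and
activation counts exactly depth-invariant; both full-physics quantities are
reported alongside.

## Determinism, problem sizes, limitations

Every stochastic step (cohorts, noise, splits, trend replicates) takes a
seed; the pipeline forks one run seed into per-stage streams by fixed
labels, so adding a stage never perturbs another's draws, and identical
config + seed reproduce byte-identical outputs. Default study sizes —
400-element meshes for imaging runs, 800 for reciprocity, 300 for the
finite-difference Jacobian check, 50 fps / 8 s forced and 10 fps / 30-60 s
guided acquisitions, 100 noise-trial pairs for defect detection — keep the
full test suite and the acceptance script in the tens of seconds on one
CPU while leaving all checked properties well inside their tolerances.

Known limitations: 2D single-plane model; linear one-step reconstruction
(no iterative or trained inverse); no cardiac signal, electrode-error or
posture modelling; voxel indicator maps in conductivity units; ROI
segmentation needs separable lung clusters; the regression's exactness on
phantoms follows from the generator's affine slope law — real thoraxes owe
no such obligation to the basis.
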
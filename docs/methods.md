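# Methods

This note records the models, conventions and numerical choices behind
`headkin`, and what the synthetic data does and does not establish.

## Rotation conventions

All computation uses 3×3 rotation matrices acting on column vectors. A
head-pose rotation maps head-frame coordinates into its reference frame
(columns are the head axes expressed in that frame), so a change of
reference frame — e.g. camera to global via the extrinsics — is a plain
left-multiplication, and an anatomical re-definition of the head frame
is a right-multiplication. Euler angles (intrinsic z-y′-x″
yaw–pitch–roll, degrees) exist for display only; near gimbal lock
(|pitch| ≥ 89°) roll is set to 0 and the output flagged.

Orthogonality is checked to 1e-8 (Frobenius) and never silently
repaired: noisy input must go through `project_to_rotation` (SVD
polar projection) explicitly, which surfaces corrupt orientation files
instead of hiding them. The matrix log uses the sin-based formula up to
1.9 rad and a stable quaternion extraction beyond, where the skew part
degenerates; at the cut locus (angle π, where the log is two-valued)
the branch with the first nonzero axis component positive is returned.

A practical measurement note: `arccos` resolves a zero angle only to
about √ε ≈ 2·10⁻⁸ rad in double precision, so exact-equality assertions
in the test suite are made in the Frobenius norm (for small angles
‖R₁−R₂‖_F ≈ √2·θ), which is strictly sharper.

## Reference orientations from markers

Five skull landmarks (left/right external auditory meatus EAM,
left/right inferior orbital rim IOR, nasion SNA) define the head's
anatomical coordinate system on the Frankfort plane: origin at the EAM
midpoint, y toward the left EAM, z perpendicular to the plane
(superior) using the IOR midpoint as the anterior reference, x anterior
within the plane.

Processing order: gaps ≤ 10 ms are linearly interpolated (longer gaps
are an error); each coordinate channel is low-pass filtered with a
zero-lag Butterworth — a half-order filter run forward and backward, so
"fourth order" means net order 4 and the amplitude gain at the cutoff
is 1/2 (two −3 dB passes); edges use odd-symmetric extension of 3×
the net order, and no cutoff-correction factor is applied (biomechanics
conventions differ; this one is fixed and documented). The default
cutoff is 50 Hz at 1000 Hz sampling; `select_cutoff_residual`
implements classic residual analysis — RMS raw-minus-filtered residual
per candidate cutoff, straight line fitted to the upper half of the
grid (where the residual is noise-dominated and nearly linear), chosen
cutoff = lowest grid value whose residual falls below the line's
zero-frequency intercept, which estimates the noise RMS. With a truly
noiseless signal the intercept is ~0 and the chosen cutoff simply moves
to where Butterworth roll-off distortion vanishes; a brickwall-style
"any cutoff just above the signal band" intuition does not hold for
real filters. An FFT check (highest frequency above 10% of the peak
non-DC magnitude) guards against a cutoff below genuine signal content.

Per-frame orientation comes from a Kabsch rigid fit of all five markers
against a per-participant reference geometry (the marker cloud in the
first frames' anatomical frame, averaged over 10 frames); this uses the
nasion redundancy marker and degrades gracefully under noise, and it
agrees with the direct 4-marker construction exactly on noiseless data.

Impact windows are half-open, [impact−20 ms, impact+80 ms), which
yields exactly 100 capture frames at 1000 Hz; the six 50 Hz video
frames at 0, 20, …, 100 ms map to the nearest in-window capture sample
(indices 0, 20, 40, 60, 80 and 99 — the 100 ms frame is clamped). The
half-open convention is what makes the six-video/hundred-capture frame
pairing internally consistent.

## Alignment and smoothing

Pose models express orientation in the camera frame and define the head
frame their own way. The pipeline first maps predictions to the global
frame (R̂_HG = R_GC R̂_HC), then estimates the constant anatomical
offset per sequence as the Karcher mean of the framewise relative
errors δᵢ = R̂ᵢᵀRᵢ, iterating μ ← μ·exp(meanᵢ log(μᵀδᵢ)) from the first
element to tolerance 1e-9 (≤100 iterations). Uniqueness requires
concentration; dispersion beyond a geodesic ball of radius π/2 around
the chordal mean is rejected rather than averaged. Aligned predictions
are R̂ᵢ·Δ̂ with Δ̂ the mean of the δᵢ — the convention is pinned by the
exact-recovery property: a noiseless constant right offset is cancelled
to machine precision for offsets up to at least 40°.

Smoothing maps the sequence into the tangent space at its Karcher mean
(a single chart comfortably holds the ≤ ~40° window excursions),
convolves each component with a discrete Gaussian of width σ frames
(truncation 4σ; kernels renormalised at the edges — six-frame sequences
make reflection padding distortive), and maps back. σ = 0 is the
identity; constant sequences are fixed points. The sweep smooths,
aligns, and scores mean GE and mean IGE pooled over the supplied
sequences; the selected σ minimises their equal-weight sum by default
(`ge`, `ige`, `sum` are config options), ties toward smaller σ. The
default processing order is smooth-then-align — at six frames the
offset estimate is less noise-sensitive after smoothing — with
align-then-smooth available as a switch; IGE is identical either way.
When run without a sweep, the face-profile default width is σ = 1.5
frames and the body-profile default σ = 0.5.

## Error metrics and statistics

GE is the geodesic distance between reference and prediction per frame;
IGE compares the magnitudes of consecutive-frame rotations,
|d(R_prev,R) − d(R̂_prev,R̂)|, and is invariant to constant left/right
compositions on either sequence — in particular to the alignment step.
Both are reported in degrees; summaries pool per frame (not per-trial
means of means); per-trial means feed the paired statistics. Euler-angle
MAE is deliberately not offered. IGE values attach to the later frame
of each pair, so the first visibility sample of a sequence never enters
incremental analyses.

The statistical battery is nonparametric throughout (pose-error
distributions are heavily right-skewed; a Shapiro–Wilk gate is computed
and reported but rank tests are the default regardless): Wilcoxon
signed-rank for front-vs-side camera comparisons, paired on per-trial
mean errors (the same physical trial seen by both cameras);
Mann–Whitney U for linear-vs-rotational trial types on per-trial means;
Cliff's δ as effect size; Pearson r and a nonparametric Bland–Altman
(median bias, 2.5/97.5 percentile limits under the linear-interpolation
percentile rule) for rotation-magnitude agreement. Exact null
distributions are used for small samples (Wilcoxon n ≤ 25, Mann–Whitney
n_a·n_b ≤ 400, tie-free), tie-corrected normal approximations otherwise;
the test suite verifies both against full enumeration and checks the
empirical level under seeded nulls. Raw p-values are reported — no
multiple-testing correction — and the report says so. Visibility bins
are half-open with the last bin closed; empty bins are reported with
n = 0; per-20 ms time steps carry phase labels (pre-impact 0 ms, impact
20 ms, post-impact 40–100 ms).

Detection metrics use continuous (x, y, w, h) boxes with top-left
origin and area w·h (no +1 convention), greedy descending-IoU
one-to-one matching (optimal for single-subject frames), threshold 0.3.
Visible face area subtracts the exact occluder union (coordinate
compression); ratios are normalised by the per-camera maximum over the
dataset (config-switchable), so the best frame of each camera maps to 1.

## The synthetic heading-trial generator

The generator emulates the study design that motivated the pipeline:
10 participants × (5 linear + 5 rotational) headers × 2 cameras, 1000
Hz capture, six 50 Hz video frames per 100 ms window. Per trial:

* **Motion** — a Gaussian-shaped pitch (flexion) pulse of width 55 ms
  peaking 10 ms after impact, with peak amplitude drawn uniformly from
  22–36°; rotational trials add a smoothstep yaw ramp to 45° over
  300 ms starting at impact (the redirect happens after contact, so the
  in-window peak excursion stays at the drawn amplitude); a ≤ 2° roll
  pulse in the follow-through. All channels are C²-smooth.
* **Markers** — a canonical head-frame cloud (EAMs at y = ±70 mm, IORs
  anterior at x = 75 mm, all four in the z = 0 Frankfort plane, nasion
  above it), rotated by each frame, carried along a smooth ~80 mm
  forward path, with 0.5 mm isotropic noise. These geometry numbers are
  invented, config-overridable defaults constrained only by the
  coplanarity the frame construction assumes.
* **Visibility** — each frame's intended ratio is a per-trial baseline
  drawn U(0.2, 1) (partial turns, hands and arms persist across a
  100 ms window; it is a property of the trial and is shared by both
  camera views), times a Gaussian occlusion dip centred on the impact
  frame (depth U(0.3, 0.95) per trial, width 15 ms — the ball), times a
  yaw-dependent self-occlusion factor for the side camera on rotational
  trials, minus ≤ 4% per-frame jitter. The ratios are realised as an
  actual face box plus an occluder covering the complementary area, so
  recomputing visibility from the boxes reproduces them. Ground-truth
  head boxes and jittered detections (miss rate 30% below 0.2
  visibility, 2% otherwise, 1% spurious boxes) feed the detection
  metrics.
* **Predictions** — per model profile, R̂ᵢ = R_GCᵀ(Rᵢ·Δ·exp(εᵢ)) with a
  constant offset Δ (15° about a profile-specific axis) and iid
  body-frame tangent noise of per-axis σ(v) = σ0 + σ1(1−v) degrees.
  Right-sided noise makes the χ₃ closed form for mean GE
  (σ·2√(2/π)) exact and offset recovery clean. The three built-in
  profiles — (σ0, σ1) = (2°, 14°), (2.2°, 8°), (2.9°, 1°) — emulate a
  strongly face-dependent estimator, a moderate one, and a body-context
  model whose error barely reacts to facial occlusion; they were chosen
  once to land single-digit mean errors with the face/body ordering and
  occlusion sensitivity seen in practice.

Everything derives from one seed through spawned generators;
regeneration is byte-identical.

**What passing tests show, and what they do not.** The generator's
noise is exactly the model the metrics assume (iid tangent
perturbations about a constant offset), so parameter-recovery results
are clean closure checks of the pipeline, not evidence about any real
estimator: real prediction errors are temporally correlated, biased
toward specific poses, and occasionally catastrophically wrong
(flipped poses), none of which the generator emulates. Marker noise is
additive and isotropic — no skin-motion artefact, no marker swaps.
Visibility is rectangle-based, not mask-based. Consequently the
dataset-structure checks (visibility-binned error gradients, the
impact-phase IGE peak, profile ordering) validate that the *analysis
machinery* surfaces structure that is present, and nothing more.

One interaction deserves emphasis because it shaped the generator: a
noise spike confined to a single frame of a six-frame window is largely
removed by σ = 1.5 tangent-space smoothing (kernel centre weight
≈ 0.28), and any near-constant error component is absorbed by the
per-sequence alignment. A visibility–error gradient therefore only
survives the full pipeline when low visibility *persists* across
frames — which is why the generator has a per-trial visibility baseline
and why the visibility-bin and phase-structure analyses are computed on
aligned but unsmoothed errors (the structure belongs to the raw
estimator; assessing it before temporal filtering keeps single-frame
occlusions in their own bin). The structural results are stable across
seeds under these conditions.

## Problem sizes

Monte-Carlo sizes were chosen so sampling error is comfortably below
each assertion's margin: 10³ draws for oracle agreement, 10⁵ for
density/χ₃ calibrations (relative SE ≈ 0.2%), 500 trials for offset
recovery, 2000 replicates for test-level calibration (SE ≈ 0.5
percentage points), 100 seeds for majority-vote structure checks, and
the full 200-record default dataset for the dataset-level analyses.

## Known limitations

* The Karcher-mean alignment assumes the offset dominates the noise;
  sequences more dispersed than a π/2 ball are rejected, not averaged.
* Six-frame sequences make the offset estimate noisy (≈ σ/√6 per axis);
  the generator's recovery bounds account for this, but users should
  pool Δ̂ across trials of the same model before interpreting it.
* The smoothing sweep optimises pooled mean errors; per-trial optima
  can differ.
* No angular velocity/acceleration estimation: 50 Hz video undersamples
  impact dynamics, and IGE is deliberately the only dynamic measure.
* The C3D container is not read; marker input is the TSV format
  documented in `headkin.io`.
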
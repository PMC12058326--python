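# Methods

`kinetrf` implements a stimulus-reconstruction ("backward") temporal
response function analysis for co-speech gesture: it asks how well the slow
amplitude envelope of a speaker's voice can be linearly reconstructed from
the kinematics of their moving body, and whether the answer depends on how
motion is encoded. The package contains the full analysis chain — kinematic
feature extraction, envelope extraction, ridge-regularized lagged decoding
with fold-based cross-validation, and mixed-effects model comparison — plus
a synthetic gesture–speech generator with known, gravity-asymmetric
coupling, so that every stage can be validated end to end without access to
a motion-capture corpus.

## The decoding model

The decoder is a linear map from time-lagged multichannel kinematics to the
envelope:

    env(t) ≈ b + Σ_c Σ_τ w[c, τ] · kin_c(t + τ),    τ ∈ [−1000, +200] ms

Negative lags mean the motion *precedes* the envelope sample; at the 30 Hz
analysis rate the default window contributes 37 lags per channel. Weights
are estimated by ridge regression on per-channel z-scored inputs,
`(XᵀX + λI)w = Xᵀ(y − ȳ)`, with λ selected from a decade grid
(10⁻³…10⁶ by default) by inner leave-one-fold-out cross-validation on the
training folds. Performance is the Pearson correlation between the
predicted and actual envelope on held-out, contiguous ~15 s folds;
recordings shorter than 30 s cannot be cross-validated. Training is pooled
across recordings within a condition, and by default every fold rotates
through the test role. For efficiency, per-fold Gram matrices are
precomputed so that any train/test split is a sum of blocks and each ridge
solve is one Cholesky factorization.

Two statistical subtleties of this scheme are worth knowing:

- **Guard bands.** Each held-out fold is scored on its interior, trimming
  one lag-window width at each edge. Edge rows share feature windows with
  adjacent training rows; combined with the short-range autocorrelation
  that anti-alias resampling imprints on the envelope, they would otherwise
  leak a little of the training fit into the held-out score.
- **Rotation correlation.** With full fold rotation, each rotation's
  decoder is trained on the other rotations' test folds, so fold scores are
  not independent: condition-level mean correlations are overdispersed
  relative to the within-fold variance, and downstream significance tests
  that assume independent fold scores become anticonservative. Where
  calibrated inference matters (the type-I-error check below), the package
  scores a single held-out fold per file (`n_rotations=1`), which restores
  independence at the cost of fewer scores.

## Kinematic features

Dense marker sets are pooled into a 20-segment body model by per-frame
averaging (an editable `segment -> markers` YAML ships with the package;
the grouping for any particular marker set is a modelling choice).
Derivatives are taken at the raw frame rate by central differences with
one-sided endpoints and then anti-alias resampled to 30 Hz. The two
first-derivative encodings carry identical per-axis magnitude and differ
only in direction: `velocity` is the signed per-axis derivative, `speed`
its per-channel absolute value. Speed is deliberately the per-axis
magnitude rather than the 3-D Euclidean norm so that the encoding factor
can be crossed with single-axis models. Acceleration (second derivative,
always signed) feeds the orientation-inversion analysis, where mirroring
the body along an axis is simply negating that axis's channels of the
*test* features.

## Speech envelope

The amplitude envelope is the Hilbert analytic-signal magnitude, low-passed
with a zero-phase 4th-order Butterworth at 10 Hz, then resampled to 30 Hz
(filter-before-decimate). This is the standard construction for the
prosodic envelope; the < 10 Hz band carries the syllabic and phrasal
intensity fluctuations the decoder targets.

## The synthetic generator

The generator emulates a gesturing speaker whose voice amplitude is driven
by gravity-asymmetric arm movement. Its assumptions, not its realism, are
the point: it produces data in which the *direction* of vertical motion is
informative by construction, so the analysis chain must detect exactly the
effect pattern it is designed for.

- **Strokes.** Each of the six arm segments receives Poisson-timed stroke
  events per axis (default 0.6 s⁻¹ per segment per axis). A stroke is a
  Gaussian velocity pulse (sd 120 ms — ballistic gesture tempo) whose
  integral is the stroke's net displacement; magnitudes are |N(1, 0.3)|.
  Vertical strokes are downward with probability ½, and downward strokes
  carry `asym_gamma` (default 2) times the impulse of upward ones —
  encoding the asymmetry of working with versus against gravity.
  Horizontal and depth strokes are sign-symmetric.
- **Trunk and head.** Non-arm segments receive a 1 Hz low-passed,
  0.3-gain copy of mean arm velocity (passive momentum transfer) plus
  independent slow sway (velocity sd 0.1). The sway matters: without it,
  trunk channels are a deterministic function of arm motion, and because
  decoding z-scores every channel, a speed decoder could recover signed
  vertical information from them.
- **Envelope.** `env = baseline + K ∗ (g_v·Σ(−v_y) + g_hs·Σ|v_x| +
  g_hsig·Σv_x) + noise`, sums over arm segments, with `K` a causal kernel
  (Gaussian bump peaking 150 ms after the motion, support 0–600 ms —
  inside the decoder window). The vertical term is *signed* and
  downward-positive: downward strokes raise vocal amplitude. Combined with
  the stroke asymmetry this makes direction decodable — a velocity decoder
  recovers the coupling exactly while a speed decoder only exploits the
  correlation between |v| and v that the asymmetry induces. The symmetric
  horizontal term (|v_x|) rewards the speed encoding; the small signed
  horizontal term models mild lateral (handedness) asymmetry and is what
  gives horizontal inversion a real, if small, generalization cost. The
  baseline (resting vocal amplitude, default 60) keeps the envelope
  positive so the nonnegativity floor is essentially never active and the
  coupling stays linear; noise is white Gaussian (sd 13).

Default gains (vertical 1.0, horizontal symmetric 0.27, horizontal signed
0.15, depth 0) and the noise level were calibrated once so that the default
condition realizes the intended pattern at the reference scale of 8 files
× 2 minutes: vertical velocity decoding around r ≈ 0.55 with a
velocity-over-speed advantage ≈ 0.15, horizontal decoding near the chance
floor with the two encodings matched, and a large vertical-inversion cost
against a small horizontal one. A deliberately high white-noise share keeps
the *chance* component of condition means small: chance correlations scale
with the smooth (kernel-filtered) share of unexplained envelope variance,
and a smoother residual would make small between-condition differences
unstable at this corpus size.

What the generator does **not** emulate: articulated-skeleton kinematics
(segments move independently; no joint constraints), physically accurate
biomechanics, speech acoustics beyond the envelope, pauses/turn-taking
structure, and any nonlinear or non-stationary motion–speech coupling.
Passing tests therefore demonstrate that the pipeline recovers linear
lagged couplings with directional asymmetries under realistic noise — not
that such couplings have any particular strength in real gesture data.

## Experiments

**Experiment 1 (Axis × Encoding).** Six decoders — {horizontal, vertical,
depth} × {velocity, speed}, 20 channels each — run on identical folds with
the identical λ-selection procedure, so cells differ only in the feature
transform. λ is tuned once per cell on the first rotation's training folds.
Expected pattern on default synthetic data: a large velocity advantage on
the vertical axis and none on the horizontal.

**Experiment 2 (orientation inversion).** One decoder family trained on
all 60 signed acceleration channels; every held-out fold is scored three
times — preserved, horizontally mirrored, vertically mirrored test
features (training features bit-identical across the three). Vertical
mirroring reverses the sign of the dominant coupling, collapsing (indeed
inverting) performance; horizontal mirroring costs only the small signed
horizontal component.

## Statistics

Per-fold correlations are the dependent variable in linear mixed-effects
models with a random intercept per recording, fitted by maximum likelihood
(REML would invalidate likelihood ratios between fixed-effect structures).
The stepwise ladder — intercept-only, main effects, interaction — reports
Δ AIC (AIC = −2·logLik + 2k, counting fixed effects plus the two variance
parameters), Δ log-likelihood, and χ² LRT p-values on the added fixed
degrees of freedom. Pairwise contrasts are Wald tests on the winning
model's fixed-effect covariance, Bonferroni-adjusted with the family size
equal to the number of planned pairwise comparisons per factor (recorded in
the output). Correlations are modeled untransformed by default; a Fisher-z
option exists. When the random-intercept variance estimate collapses to
zero, statsmodels cannot represent the boundary, and the fit falls back to
OLS — which is exactly the mixed model's maximum likelihood at that
boundary, so the ladder stays valid.

A type-I-error check accompanies the interaction test: under an
exchangeable null configuration (no stroke asymmetry, equal weak signed
coupling on all three axes) the interaction LRT should reject at the
nominal rate. The reduced replicate design for this check uses 24 files ×
60 s × 6 segments, a single held-out fold per file (see *Rotation
correlation* above), and weak per-axis coupling, so that realized coupling
variation across a small corpus — a genuine feature of finite data —
does not dominate the rejection rate. Measured: ≈ 6% at α = 0.05 over 200
replicates.

## Numerical choices and degenerate inputs

- Ridge at λ = 0 on a rank-deficient design falls back to the
  pseudoinverse with a warning.
- Z-scoring guards zero-variance columns (sd set to 1).
- λ ties in tuning resolve to the smaller λ.
- Pearson correlation on zero-variance input raises rather than silently
  returning 0.
- Marker-table gaps of ≤ 5 frames are linearly interpolated; longer or
  edge gaps reject the file.
- Resampling is polyphase with linear-trend padding; only downsampling is
  supported (the analysis rate is below every capture rate of interest).
- Fold boundaries come from near-equal integer splits of
  ⌊duration / 15 s⌋ folds; every fold is at least 10 s.

## Problem sizes

The test suite and the acceptance script run the reference condition at 8
files × 120 s, the noiseless-recovery check at 2 × 120 s, the chance floor
at 20 × (2 × 60 s), and the null calibration at 200 replicates of 24 ×
60 s with 6 segments. These sizes were chosen so the whole analysis runs
comfortably on a laptop while leaving each property's expected margin
several times its sampling noise.

## Known limitations

- The decoder is linear; nonlinear motion–speech dependencies (e.g. the
  rectified couplings a speed encoding would excel at) are outside its
  reach by design.
- Full-rotation CV p-values are anticonservative (see above); they are
  reported as-is because the condition effects of interest here are orders
  of magnitude beyond the miscalibration, but marginal effects should be
  re-tested with single-fold scoring.
- The mixed model includes only a file-level random intercept; fold-level
  clustering across conditions scored on the same fold is unmodeled.
- BVH support covers the standard HIERARCHY/MOTION dialect with Euler
  rotation channels; scaling channels and non-standard extensions are not
  parsed.
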
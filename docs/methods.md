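# Methods

This note documents the generative model, the analysis pipeline, the
numerical and design choices behind them, and what the synthetic validation
does and does not establish.

## Generative model

One simulated subject consists of a trial table and a voxel-by-trial
amplitude matrix. The design is three retrieval conditions (spatial,
temporal, pair), `trials_per_condition` trials each (default 80), dealt
round-robin over `n_runs` runs (default 5) and shuffled within run, so
every run contains each condition whenever trials-per-condition ≥ runs.

Response times are truncated-normal per condition (lower bound 200 ms — no
plausible speeded response is faster), with default means 1284 / 1384 /
1183 ms (spatial / temporal / pair) and a common 200 ms within-subject SD.
The means are the observed behavioral values of the retrieval task the
package models; the trial-to-trial SD is not reported for that task (only
across-subject SEs are), so 200 ms was chosen as a typical single-trial
spread for speeded recognition. A Bernoulli fraction of trials (default
16%, the observed forget rate of the hardest condition) is flagged
incorrect and excluded from every analysis stage, exercising the
correct-trials-only filter.

Amplitudes follow, per voxel `v`, trial `t`:

    D[v,t] = baseline + μ_cond(t) + β_pat · w_cond(t)[v]
             + β_rt · (RT_t − mean RT) · g[v] + ε[v,t]

with `ε ~ N(0, σ²)` i.i.d. (default σ = 1, arbitrary signal units — the
package deliberately treats amplitude units as arbitrary, since single-trial
estimates may be raw betas or percent signal change). Three structural
choices make the components cleanly dissociable:

- `w_cond` (one fixed vector per condition per subject) is **zero-mean
  across voxels** and unit-norm, so distributed patterns contribute nothing
  to the spatial mean — mean-signal removal should not touch them;
- `g` is the **uniform** unit-norm vector, so RT coupling is a global gain,
  exactly the regional-modulation confound RT residualization targets,
  carrying no distributed pattern;
- `μ_cond` are uniform per-condition offsets, a pure spatial-mean signal.

A configuration with all three effects zero is the null scenario.

### What the generator does not emulate

No spatial or temporal autocorrelation, motion or physiological noise,
voxel-wise variance heterogeneity, nonlinear RT–amplitude coupling, or
encoding-phase structure. Passing the validation below therefore shows that
the *procedures* are correctly implemented and statistically calibrated
under a well-specified model — not that real tissue obeys that model. In
particular, real confounds need not be spatially uniform, in which case
mean-signal removal is only a partial control.

## Optional BOLD path

For users starting from timeseries rather than amplitudes, a forward model
sums, within each run, trial amplitude × canonical double-gamma hemodynamic
response (peak ≈ 5 s, undershoot at ~15 s, ratio 1/6; peak-normalized)
sampled at the repetition time (default 2.5 s), with jittered inter-trial
fixation (truncated exponential on 0.5–13 s). The inverse is a beta-series
GLM: one convolved regressor per trial plus per-run intercept and linear
drift, solved by OLS. The double-gamma is used as the fixed forward basis
because a generative simulator needs one; flexible-shape bases are
estimation devices, not forward models. Near-collinear trial regressors
(|r| > 0.9999) abort estimation with the offending trial pairs named,
since such betas are numerically meaningless. Noiselessly, estimation
inverts simulation to machine precision; with noise, the estimated-on-true
slope stays within 10% of unity at 200 trials (validated in the tests).

## Confound corrections

Both corrections are orthogonal projections of the voxel-by-trial matrix,
computed per subject over all correct trials, applied before any training.

**Mean-signal removal** projects each trial column off the unit-normalized
voxel-wise mean response `m̂`: `D' = D − m̂ m̂ᵀ D`. Normalizing `m` is
required for `m̂ m̂ᵀ` to be a projector; without it the operation is not
idempotent and can amplify signal. If `‖m‖ < 1e-12` there is nothing to
remove and the operator is the identity (warned).

**RT residualization** removes, from each voxel's trial series, the
component linearly explained by the mean-centered RT vector — equivalently
per-voxel simple regression residuals with the voxel mean retained.
Centering matters: projecting on raw (all-positive) RT would also strip
most of each voxel's mean, conflating the two corrections. Zero RT variance
degenerates to the identity (warned). A published formulation of this
correction writes the projector as the annihilator `E − r(rᵀr)⁻¹rᵀ`
*subtracted* from the data (`D' = D − PD`), which taken literally retains
only the RT-spanned component; the residualizing form implemented here
matches the stated intent of controlling for RT. The literal form is kept
behind `mode="literal"` for comparison.

Orientation is fixed as rows = voxels, columns = trials; the mean projector
acts on the voxel dimension, the RT projector on the trial dimension. Both
operators record diagnostics (worst relative residual alignment /
covariance, contract ≤ 1e-8) and are exposed as scikit-learn transformers
operating on `(trials, voxels)` arrays, so a projector can also be
estimated on training rows only (`correction_scope="train"`) for users who
prefer a strictly-no-test-influence variant; the default estimates from all
correct trials, since neither projector uses condition labels.

## Per-subject decoding

Correct trials are labeled target-versus-rest; the larger class is randomly
down-sampled (without replacement) to balance classes before any training;
a stratified random 80/20 split reserves held-out test trials; C for the
linear SVM is selected from 11 decade steps over 1e-10…1 by
cross-validation whose folds are the run partitions of the *training*
trials (runs grouped contiguously when they do not match the fold count);
ties break toward the smallest C (strongest regularization) for
reproducibility; the final model is refit on all training trials and scored
once on the untouched test set. Features are z-scored per voxel with
training-set statistics. The SVM is LIBLINEAR's L2-regularized squared-hinge
primal solver (its default formulation), chosen over the dual hinge solver
because the latter converges poorly on permuted-label data at liberal C;
`loss="hinge"` is available. Down-sampling, splitting and solver seeds all
derive from one integer seed, making a subject's result bit-reproducible.

No information leaks from test trials into down-sampling composition, C
selection, or standardization (asserted by test: corrupting held-out
features changes neither the chosen C nor the learned weights).

## Group inference

Subject accuracies are summarized by a one-sample t against 50%. The null
is built by within-subject label permutation: shuffle each subject's
condition labels among their correct trials (class counts preserved, labels
never crossing subjects — between-subject exchange is not meaningful),
re-run the entire per-subject scheme including C selection, recompute t;
one-sided add-one p = (1 + #{perm t ≥ observed t}) / (1 + n_perm), so p is
never zero. Zero between-subject variance yields a signed-infinite t with a
warning (t = 0 if exactly at chance).

Because re-tuning C inside thousands of permutations is computationally
dominant, a fast mode (`tune="fixed"`) uses one fixed C — default 1e-3, the
grid value the full cross-validation most often selects on pilot
simulations of these scenarios — for the observed *and* every permuted
statistic, preserving exchangeability. Repetition-heavy validation studies
use this mode; single analyses default to full tuning.

## Scenarios and calibration

Four named scenarios inject exactly one component each (`pattern_driven`,
`mean_driven`, `rt_driven`, `null`) at 17 subjects, 40 voxels, 80
trials/condition, unit noise, and test all three corrections. Expected
verdicts: pattern-driven signal survives everything; mean-driven dies only
under mean removal; RT-driven dies under RT residualization (its
mean-removal cell is construction-dependent — a uniform RT gain is also a
mean signal — and is not asserted); null stays at chance throughout.

Effect sizes (pattern 1.1, mean offset 0.18 on the pair condition, RT
coupling 0.012 units/ms) were calibrated once during development, by pilot
simulation, so that every asserted-significant cell carries near-certain
power at n = 17 while raw decoding stays in the low-to-mid 60% range —
well away from ceiling, so the inference machinery is exercised in a
realistic regime. The RT scenario saturates near 58% raw regardless of
coupling strength: its decodable signal is bounded by the ratio of
between-condition to within-condition RT variation, which the behavioral
means fix. RT-residualized accuracies sit slightly *below* 50% on null
data: residualizing across the whole trial set couples train and test
trials weakly and negatively. The permutation null reproduces the same
bias, so inference is unaffected — a concrete illustration of why verdicts
compare against the permutation distribution rather than against 50%.

### Validation studies and problem sizes

The test suite validates, at sizes chosen to keep a full run on one CPU
within minutes while preserving statistical meaning:

- **Chance calibration** — 200 null subjects through the fully tuned
  pipeline; mean accuracy within 50 ± 2%.
- **Type-I error** — 100 independent 8-subject null cohorts, 20
  trials/condition, 200 permutations each, fixed-C mode; the binomial 95%
  CI of the rejection rate must cover 5%.
- **Dissociation recovery** — 20 seeded repetitions of all four scenarios
  with 55 permutations per cell; every asserted cell must match its
  expected verdict in ≥ 90% of repetitions. With 55 permutations the
  achievable one-sided level is 2/56 ≈ 0.036 — the usual conservativeness
  of discrete permutation p-values — which keeps the false-positive rate of
  the six not-significant cells comfortably inside the 90% criterion;
  per-cell assertion is used because a joint all-cells-correct event has
  probability ≈ 0.95⁶ ≈ 0.74 per repetition at exact level 0.05 even under
  a perfect implementation.
- **Operator contracts** — RT residualization equals independent per-voxel
  regression residuals to 1e-8; mean-removed columns are orthogonal to the
  mean pattern to 1e-8; both idempotent.
- **GLM round trip** — exact noiseless inversion; slope within [0.9, 1.1]
  under noise.

`scripts/acceptance.py` re-derives the chance calibration, the type-I
error rate, and the mean-projection selectivity (corrected accuracy at
chance on mean-driven data, raw accuracy verified above chance) from a
single command-line seed.

## Numerical choices and degenerate inputs

- Tolerances: 1e-8 (relative) for projection contracts; 1e-12 norm /
  variance thresholds for degenerate projectors; 1e-6 for the noiseless GLM
  round trip.
- Tie-breaks: smallest C on CV ties; sorted index order after balancing and
  splitting.
- Degenerate CV folds: a single-class validation fold is scored on the
  labels present (warned); a single-class training fold is skipped (NaN);
  all folds degenerate raises a tuning error.
- Splits that would empty a class's train or test partition raise data
  errors rather than silently clipping.
- All randomness flows through `numpy.random.Generator`; subject seeds are
  31-bit integers spawned from a master seed.

## Known limitations

- The noise model is white; real single-trial estimates are temporally and
  spatially correlated, so absolute accuracies here do not predict real
  effect sizes.
- RT residualization is linear and single-covariate by design; nonlinear
  difficulty effects or additional nuisances (motion, pupil) are out of
  scope.
- The mean projector removes one spatial dimension per subject; with very
  few voxels this is a substantial fraction of the feature space.
- Scenario verdicts with 55–200 permutations resolve p no finer than
  ~0.005; use 3000 permutations (the `--n-perm` flag or `n_perm` argument)
  for reportable p-values.
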
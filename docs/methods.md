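# Methods

This note documents the models implemented by `mtsdecode`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not establish.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Task model

A session interleaves three rules of a delayed match-to-sample task with
four isoluminant colors and four cardinal motion directions, each feature
set partitioned into two opposed pairs so a non-matching test always shows
the pair partner.  Epochs: sample 1000 ms, delay uniform 800–1600 ms, test
250 ms, response window 600 ms.

The trial pool enumerates, per rule, every sample assignment crossed with
the admissible tests.  For the single-feature rules this gives 32 entries
per repeat (half targets).  The conjunction rule has three non-target
configurations (color-, motion-, complete-mismatch); to keep the target
probability at exactly 1/2 *and* every mismatch type equally likely among
non-targets, each sample's full match enters the pool three times against
one copy of each mismatch — the full-match configuration is deliberately
over-represented relative to a flat enumeration, which cannot satisfy both
constraints at once.

Trials are drawn without replacement from the shuffled pool; an incorrect
(optionally also an aborted) trial re-enters at a uniformly random later
position and is re-tested, while the failed attempt stays in the record.
A session therefore ends with every pool entry answered correctly exactly
once, plus the error attempts.

## Behavioral observer

The generative observer is an equal-variance Gaussian signal-detection
model.  Each task-relevant feature contributes one evidence draw,
`N(d', 1)` if the test matches the sample on that feature and `N(0, 1)`
otherwise, with per-feature sensitivities `d'_color` and `d'_motion`.
Single-feature rules threshold the single evidence; the conjunction rule
thresholds the **minimum** of the two evidences, since both features must
match.  This choice reproduces the qualitative behavioral signature of
conjunction matching: discriminating a target from a single-feature
mismatch is harder than from a complete mismatch.  The default criterion
sits halfway between the non-match and match evidence means (d'/2;
min(d'_c, d'_m)/2 for conjunctions); an absolute criterion and a lapse
rate (default 0.02, responding at random) are configurable.

Reaction times are shifted log-normal, `shift + LogNormal(mu, sigma)`
with defaults shift = 250 ms, mu = log 120, sigma = 0.5, giving a median
press near 370 ms — in the range typical for this task class — and a
small natural fraction below 300 ms, so the downstream fast-RT exclusion
rule is exercised.  Decided presses falling beyond the 600 ms response
window are recorded as no-response.

d′ is computed with the log-linear correction (add 0.5 to each cell, 1 to
each denominator) applied *unconditionally*, not only at extreme rates;
this keeps the estimator continuous and finite everywhere at the cost of
a small shrinkage toward zero.  Published analyses rarely state their
correction convention, so absolute d′ magnitudes may differ slightly from
any particular report; contrasts and tests are insensitive to this.

## LFP synthesis

Voltage is additive: per-channel 1/f noise (FFT-shaped white noise,
normalized to unit SD, default amplitude 1 µV), one shared common-mode 1/f
source (0.5 µV), a 50 Hz line component (0.2 µV), a Gaussian evoked
response at every stimulus onset (peak 2 µV at 60 ms, SD 30 ms), and the
injected effect components.

A component is a Hann-ramp plateau envelope (default ramps 20 ms)
multiplying a phase-locked 24 Hz carrier, scaled by per-channel weights,
and gated by its selectivity: feature-identity components use one channel
pattern per feature level (random orthonormal directions at unit
per-channel RMS, so levels never collide and are linearly separable);
match components are added only where the test matches the searched-for
feature; motor components lock to the response event.  The carrier
matters: a raw plateau concentrates energy near DC, and the zero-phase
1 Hz high-pass used downstream would smear that energy symmetrically in
time, leaking feature information into pre-stimulus bins and biasing
onsets *early*.  With the carrier the component lives inside the 1–80 Hz
analysis band and the leak disappears (verified by a spectral test and by
chance-level pre-stimulus decoding).

The generator returns a ground-truth record (per-trial onsets and channel
patterns per component) sufficient to re-render the noiseless effect
signal; subtracting it reproduces the effect-free session generated from
the same seed exactly.

What the generator does **not** emulate: spiking activity, oscillatory
dynamics beyond 1/f background, cross-channel noise correlations beyond a
single common mode, non-stationarities (drift, impedance changes), eye
movements, and amplitude/latency variability of the injected effects
across trials.  Passing validation on this data shows the *analysis chain*
is correct and calibrated; it does not show the effects exist in any real
recording.

## Preprocessing

Filter chain, in order: 50 Hz IIR notch (quality factor 35), 4th-order
Butterworth low-pass at 150 Hz, polyphase resampling to 250 Hz, 4th-order
Butterworth band-pass 1–80 Hz.  All stages are zero-phase
(forward-backward), because phase distortion would bias onset latencies;
the filter realizations themselves are unspecified in the analyses this
package follows, and these are standard LFP practice.  The low-pass
precedes resampling even though partially redundant with the band-pass.
Event indices are remapped by rounding to the nearest output sample
(relative latencies preserved within one sample).  Clipping detection
flags a channel pinned at ≥ 0.99 of the rail for ≥ 5 consecutive samples
(both defaults configurable; no published values exist).  Epoch bins are
centered on samples, 0 ms = locking event; epochs are never truncated at
the response.

## Decoding

Balancing reduces every cell of the label × covariate cross-tabulation to
the global minimum count by seeded subsampling, making the label exactly
independent of each covariate (chi-square association identically zero)
and chance equal to 1/n_classes.  An empty cell raises by default; a
drop-cell mode exists for exploratory use.

Cross-validation is a stratified 20-fold partition (every trial tested
exactly once, class counts per fold within one).  Features per time bin
are all channels over a ±2-sample window (maximum 5 samples = 20 ms at
250 Hz), clipped at epoch edges with the realized width recorded.
Training trials of the same class are randomly partitioned into groups of
five and averaged into pseudo-trials (a remainder of ≥ 2 is averaged, a
singleton passes through); test trials are never averaged.

The classifier is a linear hinge-loss SVM, C = 1.  Multiclass problems
use one-vs-one majority voting with ties broken by summed pairwise
decision values, matching the default of the libSVM solver family.
Features are z-scored per column using statistics of the averaged
training pseudo-trials (applied unchanged to test trials); this is a
documented choice — whether the original analyses standardized is
unknown, and it can be disabled (`DecoderSpec(standardize=False)`).

### Solver implementation

The SVM is solved in-package by numba-compiled dual coordinate descent —
the liblinear algorithm (random visiting order from a deterministic
xorshift stream, active-set shrinking, projected-gradient stop) with the
bias as an appended constant feature.  The test suite verifies weight
agreement with `sklearn.svm.LinearSVC(loss="hinge", dual=True)` to 1e-5
and end-to-end agreement of decoding timecourses against a
scikit-learn-backed reference path.  Two performance structures matter:
within a fold, each class pair's dual solution warm-starts the next time
bin (adjacent windows share 4 of 5 samples), and the windowed Gram matrix
of the pseudo-trials is maintained incrementally as the window slides —
valid because the per-column standardization statistics depend only on
the absolute (channel, sample) feature, not on the window.  Iterations
are capped at 30 passes (tolerance 1e-3); separable problems converge
well before this, and on label-shuffled (inseparable) null problems the
cap only truncates tail polishing of an essentially random decision rule.

## Permutation inference

Each of the N null runs (default 500; validation studies use 30–100)
re-executes the entire analysis — fresh balancing exclusions, fresh
splits, fresh pseudo-trial groupings — and then uniformly permutes the
labels of the averaged training pseudo-trials; test labels are untouched.
Significance per bin is a one-sided z-test of the observed fold-mean
accuracy against the null mean and SD.  The normal approximation is the
only reading consistent with a 10⁻⁴ threshold: a few hundred permutations
cannot resolve such tail probabilities empirically (an
empirical-percentile mode exists for the display band).  The decoding
onset is the center of the earliest 40 ms window in which *every* bin is
significant; on the 4 ms grid that window spans 11 bins inclusive, so
onsets lie on the grid.  No additional multiple-comparison correction is
applied across time bins — the fixed per-bin α plus the 40 ms run
criterion *is* the control, kept deliberately.

Between-condition contrasts compare the two groups of 20 fold accuracies
bin-wise with two-sample t-tests at a Bonferroni-corrected α = 0.05/3 and
report maximal significant runs ≥ 40 ms.  Fold accuracies are treated as
independent samples; they are not (folds share training data), and the
resulting optimism is documented rather than corrected, keeping the
statistic comparable to common practice.  Per-fold onsets are computed
against the fold-averaged null (a per-fold null would be equally
defensible); folds without a qualifying window are excluded from
distribution tests and reported.

### Onset resolution

For an injected latency L, the recovered onset is expected in
[L, L + 24 ms]: +20 ms from reporting the 40 ms window's center, up to
+4 ms because ramp-up makes the earliest bins marginal, and −8 ms at most
because the ±2-sample feature window can reach into the effect — the
Hann ramp keeps pre-L windows below detectability, and the carrier keeps
filtering from smearing signal earlier.  The validation studies confirm
this band empirically across L ∈ {80, 120, 200} ms.

## Validation study conditions

Fixed in `mtsdecode.studies`, chosen once as realistic desk-scale
sessions: native rate 500 Hz; observer d′ = 2.5 per feature (so ~85% of
pool entries are answered correctly on first attempt and balanced cells
stay well above the 20-trial minimum for 20 folds); abort rate 3%.

* **Null calibration** — all three rules, one pool repeat (≈ 200 trial
  attempts), 24 channels, 100 bins (−100…300 ms), outcome decoding
  balanced on test color, 100-run null, 20 replicate seeds.
* **Onset recovery / selectivity** — color-task-only sessions, six pool
  repeats, 8 channels, 72 bins (−40…248 ms), color-identity component at
  amplitude 5 (five times the per-channel noise SD), 30-run nulls, 20
  seeds per latency; the same sessions decoded under motion labels form
  the selectivity control.
* **Match dissociation** — conjunction-only sessions, three pool repeats,
  8 channels; a color-match component (160 ms) restricted to
  correct-rejection trials.  The companion outcome decoding contrasts
  hits with complete-mismatch rejections, i.e. component-free trials: no
  motor component was injected, so this must stay at chance, and it is
  the informative version of the control — an outcome contrast that
  included the component-bearing half-match rejections would simply
  re-detect the match signal itself, not a motor signal.
* **Behavior recovery** — observer d′_color = 1, d′_motion = 2, lapse 0
  and a fast RT distribution (so recorded outcomes reflect the decision
  model alone, which is what the estimator is asked to recover); ≈ 2000
  trials per single-feature rule for the point estimates, 16
  conjunction sessions for the paired bias test at α = 0.005.

The shuffle band shown in figures and used in the calibration study is
the normal-theory 99.9% interval (mean ± 3.29 SD of the ensemble).  An
empirical-percentile band is available but with ≤ a few hundred runs it
clamps to the extreme order statistics and realizes only ~98% coverage —
the normal band is the estimator that actually delivers the nominal
level.

## Known limitations

* The observer has no sequential dependencies, motivation drift, or
  reward sensitivity; re-entry position is uniform.
* Injected effects are deterministic in amplitude and latency given the
  trial; trial-to-trial latency jitter would blur recovered onsets in a
  way the validation does not probe.
* The independence assumption in fold-wise t-tests (above) makes
  between-condition contrasts anticonservative.
* Single-channel maps reuse the all-channel balancing and splits per
  channel; array-geometry statistics are out of scope.
* With very small classes the stratified splitter refuses; the explicit
  `allow_small` mode permits folds with missing classes for exploration
  only.
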
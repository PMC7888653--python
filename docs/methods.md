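# Methods

This note records the models, the defaults and why they were chosen, what
the synthetic data does and does not emulate, and the numerical choices a
maintainer would otherwise have to reverse-engineer.

## Trial engine

A set presents one target among three controls on a four-pot carousel.
Scoring follows the run protocol: the final pass of each run decides
target indication (true positive) vs none (false negative); every
incorrect call indicts one distinct control and counts one false
positive; controls presented default to 3 per set. Because a set ended by
a second false call can leave controls unpresented, `TrialRecord` carries
an explicit `controls_presented_override`, and `summary_from_counts`
builds a summary directly from recorded tallies when a published count
cannot be reconstructed from per-run outcomes (this is how Midas's 6
FP / 20 controls is represented; her per-run table alone shows 7
incorrect calls over 21 controls, and no mechanical rule reconciles the
two).

Chance statistics: `chance_prob_consecutive(k, n) = (1/n)^k` and
`binomial_tail_misses(n, p, m)`, the lower binomial tail of the miss
count. The per-set null success probability defaults to 1/2 — the null is
a random yes/no decision per set, and Bin(8, 1/2) with ≤1 miss gives
0.0352, matching the printed 0.035; p is a parameter, not a constant.

The trial simulator draws per-presentation behaviour: the dog indicates
the target with probability `dog_sensitivity` and any control with
probability `1 − dog_specificity`, sniffing pots in order; a false call
replaces that control with a blank (blanks are never indicated — the
simulator treats them as odorless), a second false call ends the set, and
a no-indication pass is re-run up to `max_runs = 4` passes (the most
observed in a recorded set). Default operating point (0.7, 0.9) was
chosen to produce set-level outcome patterns of the same order as the
recorded trials; it is a scenario default, not an estimate.

## VOC statistics

*Screening* is rank-based and therefore invariant to per-compound
monotone rescaling. `rank_sum_test` uses exact enumeration when the
pooled sample is ≤ 10 without ties, otherwise the mid-rank normal
approximation with tie and continuity corrections (scipy's
`mannwhitneyu` supplies both paths; the table-wide screen uses its
vectorized form). Degenerate all-tied comparisons return p = 1. An
exhaustive sweep shows the approximation tracks exact enumeration to at
worst 0.0375 for group sizes ≥ 3 (typically ~0.02). No multiplicity
adjustment is applied anywhere, matching the raw-p usage the chain
emulates; `screen` keeps nested flags at the liberal model-building
cutoff (p ≤ α, default 0.2) and the display cutoff (p < 0.05).

*Model building* interprets "SIS-penalized regression" as the standard
two-stage methodology: marginal ranking to at most n/log(n) predictors
(one-step standardized marginal logistic score, equivalent to ranking by
|corr(x, y)|), then a folded-concave-penalized logistic regression —
SCAD by default (a = 3.7), MCP and lasso available — solved by local
linear approximation around a lasso initializer with a glmnet-style
IRLS + coordinate-descent inner solver (numba-compiled; warm starts along
a 12-point geometric lambda path down to 0.02·λ_max). The tuning
parameter minimizes stratified k-fold cross-validated deviance (k = 10
by default, reduced automatically when a class is smaller than k). Model
fitting uses log1p-transformed abundances: GC-MS areas span orders of
magnitude and a logistic model on raw areas is numerically dominated by
the largest peaks; screening is unaffected because it is rank-based.

*Firth refit*: Newton iterations on the hat-adjusted score
U*_j = Σ_i (y_i − p_i + h_i(½ − p_i)) x_ij with step-halving on the
penalized likelihood ℓ + ½ log det(X'WX); convergence at score norm
10⁻⁶; a singular information matrix falls back to a flagged ridge. The
intercept-only estimate has the closed form logit((s + ½)/(n + 1)),
verified exhaustively for n ≤ 30.

*Jackknife ROC*: the full chain — prevalence filter, screen, SIS +
penalized selection, Firth refit — is repeated without each held-out
sample (a flag restores the cheaper variant that predicts from the
penalized fit directly). A fold whose selection is empty contributes a
constant 0.5: an intercept-only model carries no ranking information,
and using the training prevalence instead would leak the held-out label
(the training mean shifts against it by 1/(n−1), which alone drives null
AUC to 0). AUC is the trapezoid of the ROC and equals pairwise
concordance with half-credit for ties (tested against brute-force pair
counting).

On null data the jackknife AUC is mildly pessimistic (below 0.5 in some
replicates) — the familiar leave-one-out anti-bias when noise features
are selected; across 20 replicates at n = 60 its mean is statistically
indistinguishable from 0.5, which is the honest-evaluation property this
design exists to demonstrate.

## Microbiome

Phase 1 flags species whose mean relative abundance across blank
extraction controls is ≥ `ratio_threshold` (default 1.0) times their
mean across true samples *and* that appear in at least
`min_control_fraction` (default 1/3, i.e. 2 of 6) of the controls; both
knobs are exposed because the upstream protocol referenced for this
phase states no formula, and per-species evidence (ratio, control
prevalence) is recorded for audit. Phase 2 computes mid-rank Spearman
correlation on relative abundances across true samples only (reagent
covariation is a property of real specimens; blanks would inflate it)
and flags non-indicator species with ρ strictly > 0.30 against any
indicator; constant species have undefined ρ and are never flagged.
Phase 3 is a genus-token blacklist; the packaged default lists genera
routinely reported as kit contaminants and is user-overridable, as is
the indicator panel (ten species in the emulated design). Phases are
computed on the original table so their union is order-independent;
removal never drops samples.

Rarefaction draws exactly `depth` (default 2,700) reads per sample
without replacement (multivariate hypergeometric); below-depth samples
are dropped and reported, mirroring the one control the emulated study
lost. Bray-Curtis comes from scipy (`pdist`), with all-zero sample pairs
defined as distance 0 with a warning. Unweighted UniFrac delegates to
scikit-bio on a user-supplied newick tree (every table species must be a
tip; unrooted trees are midpoint-rooted with a warning). PCoA is the
Gower double-centering eigendecomposition implemented directly — axes
with non-positive eigenvalues are reported but omitted from coordinates —
and is cross-checked in the tests against scikit-bio's implementation
and against closed-form simplex geometry. Differential abundance reuses
the rank-sum test on relative abundances and reports mean percent
abundance over species-positive samples per group (0 when a group has
none). `profile_separation` reproduces the unsupervised-clustering view:
average-linkage hierarchical clustering of log(relative + 10⁻⁶)
profiles, with the silhouette of the cohort labels as the separation
statistic.

## ANN emulator

Architecture and training follow the emulated protocol: 205 inputs (the
10–14 minute window; the default chromatogram grid spans [0, 31) min
with spacing 31/1589 so the half-open window holds exactly 205 points),
32 sigmoid hidden units, 2 outputs for canine-indicated positive /
negative; online per-exemplar backpropagation with momentum (0.1 / 0.03),
Fisher-Yates shuffling each epoch, targets encoded 0.1/0.9 ("scale
margin" read as the standard anti-saturation margin), stop at RMS ≤ 0.15.
Weights initialize uniform in [−0.5, 0.5] from the seed. Normalization
is one global min/max over the training matrix (not per-feature), stored
in the model and reapplied at inference. The single-hidden-layer epoch
loop is numba-compiled; gradients are verified against central finite
differences. Divergence (RMS rising 10 consecutive epochs) halts with a
warning.

Skeletonization retains, per retained node, the `keep_per_layer`
largest-|w| incoming weights, working backward from the chosen output;
an input's saliency is the maximum retained-path product of |w| and its
sign the product of signs along that path. With no pruning this equals
the exhaustive all-paths computation (tested). Pruning by |w| follows
the protocol's "less significant weights" wording; an
activation-weighted criterion was considered and left out as the
protocol gives no formula.

The auto-associator is a 205-32-205 bottleneck trained on
canine-negative spectra only, with a tighter default RMS target (0.01,
up to 5,000 epochs): at the classifier's 0.15 target the net only learns
the class mean, whereas the nearest-exemplar ("database lookup")
behaviour — each training spectrum reconstructing closer to itself than
to any other — requires sample-specific reconstruction. The anomaly
threshold is calibrated on the training set as the 99.5th percentile of
absolute residuals, and flagged regions must span at least two grid
points (real elutes are several points wide; single-point excursions are
noise). With this calibration, in-distribution spectra essentially never
produce a flagged region (median 0 per training sample) while planted
anomalies, several times larger, always do. The concordance report
merges skeleton-dominant retention times and difference-spectrum apexes
into regions (gap tolerance 0.1 min) and labels each region by which
method(s) flagged it.

## Synthetic data: what it emulates, what it does not

Defaults are the emulated study's conditions: 12 cancer / 38 control
samples (6/30 for the GC-MS subset), six blank extraction controls, ten
indicator contaminant species, seven differential VOCs, rarefaction
depth 2,700, and the planted chromatogram features listed in the README.

* **Chromatograms**: truncated-Gaussian peaks (4σ support, so zero-noise
  traces are exactly baseline away from peaks) with per-sample
  log-normal amplitude jitter (σ = 0.25) for inter-individual
  variability, plus additive Gaussian baseline noise. Not emulated:
  retention-time drift, baseline wander, co-elution, detector
  saturation — so peak-localization accuracy here bounds ideal-case,
  not real-instrument, performance.
* **VOC tables**: log-normal abundances censored at a per-compound
  detection limit placed at the `zero_inflation` quantile of the null
  distribution; null compounds are zero with exactly that probability,
  while differential compounds (alternating elevated/reduced, log-effect
  2.0) shift both abundance and detection rate together, as real
  detection-limited GC-MS features do. This reproduces the emulated
  study's structure (seven compounds significant at p < 0.05 from
  6 + 30 samples; near-separable classes). Effect sizes are scenario
  calibrations, not estimates of real VOC differences.
* **Taxa tables**: indicator and contaminant species share a per-sample
  log-normal reagent load (inducing Spearman ρ ≈ 0.7 among them and
  dominance in blanks); biological species are Poisson–log-normal with
  four differential species at log-effect 1.5 — strong enough for
  individual significance, weak enough that whole-profile clustering
  does not separate the cohorts, the qualitative pattern the microbiome
  arm is expected to reproduce. One control sample is generated below
  rarefaction depth.
* **Trials**: per-presentation Bernoulli behaviour; no learning dynamics
  across the reward-scheme switch, no inter-set correlation.

Passing tests on this generator demonstrate that each analysis recovers
the structure it assumes — they do not validate performance on real
instruments or cohorts.

## Problem sizes in the test suite and acceptance script

The suite runs the jackknife null calibration at n = 60 with 200
compounds over 20 replicates, the planted-AUC check on the 50-sample
default design with the full 1,157-compound volatilome, selection
consistency at n = 200 over 20 seeds, and the ANN recovery loop over 10
seeds at 100 chromatograms; the acceptance script reduces the null
calibration to 10 replicates. These sizes keep full runs to a few
minutes while leaving each statistical check its stated replication.
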
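# Methods

## Scope and data model

`driverscan` operates on four plain-text inputs: element sets as BED4/BED12
(one element = a named union of intervals), a somatic mutation table
(`chrom  pos0  ref  alt  donor_id`, 0-based positions; a thin VCF converter
is provided), a per-element feature matrix as TSV, and per-mutation raw
functional scores per scheme. All coordinates are 0-based half-open
throughout; mutation positions are converted to this convention at ingest
and strand is ignored everywhere (burden and features are
strand-symmetric). Excluded-region masks (BED3) are subtracted from
elements before any counting or feature computation; the surviving bases
define the effective length L, and elements with L = 0 are carried through
as untestable but excluded from fitting and testing.

## Background elements

Training elements are sampled from callable space with lengths drawn (with
replacement) from the pooled test-element length distribution and
multiplied by 3, so that background windows are long enough to carry stable
counts. Sampling draws a chromosome with probability proportional to its
callable bp, then a placement uniform over all positions that fit inside a
single callable run; candidates overlapping any test-element base are
rejected and redrawn, with a retry budget of 100 per requested element.
Fixed-width genome bins (e.g. 1 Mb) are also available for model
evaluation; trailing partial bins are dropped so every bin has identical
length, which keeps the exposure constant across bins. Binning is done
before masking; the excluded regions are then subtracted from each bin like
from any other element.

## Features

Three families are computed per element: fractions of overlapping 2-mers
and 3-mers of the element sequence, the mean signal of per-base tracks over
covered bases only, and the fraction of element bases intersecting peak
BED sets. k-mer windows are counted within each (masked) interval
separately — windows never span interval junctions, because junction k-mers
are artifacts of concatenation — and windows containing N are skipped;
k-mer counting uses the masked sequence for consistency with count
masking. Track access is abstracted behind an interval-query interface
with a TSV dialect (`chrom start end value`) and an optional bigWig
backend, so no binary file is required anywhere in the test path. Missing
values are imputed with 0 first; for the lasso/GLM path only, features are
then robust-scaled, (x − median)/IQR, with median and IQR fit on training
rows (scikit-learn's RobustScaler: linear-interpolation quartiles, zero IQR
replaced by 1). The GBM consumes unscaled, imputed features, as trees are
scale-invariant.

## Counting

A mutation is counted for every element whose masked intervals contain its
position (half-open, so a position equal to an interval end does not
count); overlapping elements each receive the mutation, and indels count
once at their start position. The assignment uses a sweep over
start-sorted intervals with an active set, verified against per-base
brute-force oracles. Donors whose genome-wide burden exceeds a
configurable cutoff (default 30 mutations/Mb) are dropped from the roster
before counting; the cohort size N is the roster size and includes donors
with zero mutations.

## Background models

**Stability selection.** The response per training element is
logit((y + ½)/(N·L)). The lasso penalty α is fixed once by a 5-fold
cross-validated lasso (50 log-spaced candidates, minimum-CV-error rule, no
1-SE rule) on a 33% subset of the training rows, on an RNG stream
independent of the subsampling stream. Each of 500 repeats then fits an
L1-penalised least squares on a fresh 10% subsample with per-feature
penalties α/b_i, b_i drawn i.i.d. uniform on [0.5, 1] (the standard
stability-selection "weakness"); this is solved as an ordinary lasso on
X·diag(b) with coefficients mapped back as w = b·v. A feature counts as
selected in a repeat when |w_i| ≥ 0.001 on the original scale; its
importance is the fraction of repeats selected, and features with
importance > 0.5 enter the GLM.

**Binomial GLM.** y ~ B(n, p) with n = round(N·L) and p = expit(Xβ),
fitted by IRLS on the aggregated (successes, failures) response so that
trial counts up to ~10^10 are handled as rates and never expanded.

**Boosted Poisson model.** XGBoost with objective `count:poisson`,
eta 0.05, max_depth 8, subsample 0.6, max_delta_step 1.2, up to 5000
rounds with early stopping after 5 non-improving rounds on a seeded 20%
validation split. The per-element margin offset is ln(N·L) plus the log of
the pooled training rate Σy/Σ(N·L); folding this intercept into the margin
starts boosting at the intercept-only solution instead of forcing the
ensemble to descend ~10 log-units of rate, which the capped per-tree steps
would take thousands of rounds to do. The intercept is stored with the
model and applied identically at prediction, so the fitted model class is
unchanged. Single-threaded training is used for bit-reproducibility.
Feature importance is total gain, reported both as shares summing to 1 and
rescaled to a [0, 1] scale relative to the top feature.

Model evaluation uses k-fold CV with R² and Pearson's r (SEM across
folds): standard folds (train on k−1) for bin-style element sets, inverted
folds (train on 1, test on k−1) for very large training sets.

## Significance

The overdispersion test is the Cameron–Trivedi auxiliary regression:
z_i = ((y_i − ŷ_i)² − y_i)/ŷ_i regressed on ŷ_i through the origin on the
training set; the slope estimates θ in the NB2 parameterisation
Var = μ + θμ² (truncated at 0) and its one-sided t test gives p. A
heteroskedasticity-robust (HC0) standard error is used because Var(z_i)
varies with ŷ_i; simulated size at nominal 0.01 is ≈ 0.007 over a
log-normal spread of means, i.e. very close to nominal and slightly
conservative.

Each element's balanced count y_b = √(y·n_d) is tested as
P(Y ≥ ⌈y_b⌉) under Binomial(round(N·L), ŷ/(N·L)), or under NB2(ŷ, s·θ)
when the overdispersion test rejects at p ≤ 0.01 and θ > 0 (s = 3 for
lymphoma cohorts — a configuration flag, never inferred from data). Tails
are computed through the regularised incomplete beta/gamma functions —
stable for N·L up to ~10^10 — and the ceiling is the conservative
integerisation of the non-integer balanced count. Benjamini–Hochberg
correction is applied per cohort; elements with raw cohort q below the
gate (default 0.25) are re-tested with y_f = w·y_b, where the functional
weight w averages S_scheme/S_T over schemes that scored at least one of
the element's mutations, and elements with no scored mutation keep w = 1
(missing annotation is never penalised). Cohort- and global-level BH on
the function-adapted p follow, and global q < 0.1 defines the driver list.

Raw scores are ranked cohort-wide per scheme (rank 1 = most impactful,
average ranks for ties, mutations without a score under a scheme are
absent from that scheme's ranking), so the phred transform is invariant to
any monotone rescaling of a scheme's raw output.

## Synthetic cohorts

The generator emulates a moderately-to-highly mutated adult solid tumour
cohort. Defaults, chosen once as realistic study conditions: N = 200
donors; 5000 test and 5000 training elements placed on separate synthetic
chromosomes; element lengths lognormal with median 3 kb and σ_log 0.4
(gene-CDS-to-enhancer scale); a baseline of 10 mutations/Mb/donor, the
upper-middle of adult solid tumours (colorectal, oesophageal, lung run
≈ 5–15 SNVs/Mb) and well below the 30/Mb hypermutator cutoff; ten
standard-normal covariates with log-rate effects
(0.15, −0.15, 0.10, −0.10, 0.05, −0.05, 0.02, −0.02, 0, 0), giving the
few-fold smooth background variation that real covariates explain. Counts
are Poisson with rate N·L·r·exp(x·effects), or NB2 via a gamma mixture
when θ_true > 0. Spiked driver elements multiply the rate by a fold
change; each mutation is placed uniformly on its element (duplicate sites
allowed) and assigned a uniform donor, so n_d follows the occupancy of y
balls in N bins. Raw scores are standard normal per scheme, with driver
mutations shifted on the raw-score scale (+k·sd), so the rank transform is
exercised honestly. A `truth.json` manifest records every parameter and
per-element rate, sufficient to recompute all generated quantities.

What the generator does *not* emulate: trinucleotide signatures, local
hotspots, donor burden heterogeneity beyond uniform assignment (a
per-donor multiplier hook exists in the design but uniform assignment is
the default), or correlated features. Passing tests therefore demonstrate
the statistical machinery under a smooth, correctly specified background —
not robustness to real-genome covariate misspecification.

## Calibration of discrete-count p-values

Burden p-values are survival functions of integer counts and are therefore
stochastically *conservative*: P(p ≤ t) ≤ t, with a deficit of roughly the
local pmf magnitude (~0.4/√μ for a Poisson null at mean μ). At desk-scale
cohort sizes this deficit is far larger than the resolution of a two-sided
Kolmogorov–Smirnov test at n = 5000 (critical D ≈ 0.023 at α = 0.01), and
heterogeneity of per-element means averages, but does not remove, the
deficit. Raising μ shrinks the discreteness but inflates a second
conservative term: donor collisions make n_d < y, so the balanced count
drifts below y by ≈ y²/(4N) counts. With N = 200 there is no mean count at
which both effects fit inside the KS budget, so formal KS uniformity of
raw p-values is not achievable for this test statistic — the relevant
guarantees, which the acceptance suite does verify, are that null cohorts
yield (essentially) zero driver calls at global q < 0.1 and that realized
false discoveries stay within the BH bound. The corresponding KS assertion
is kept in the acceptance suite as an honest record of this property.

## Numerical choices and edge cases

* Ties in ranking: average ranks. Zero IQR: replaced by 1. Constant
  features: centred, undivided, never selected.
* All-zero responses fit at the boundary with a warning (GLM) or predict
  ≈ 0 with a warning (GBM).
* p = 1 whenever the effective count is 0; ŷ ≥ N·L under the binomial
  branch is an input error.
* θ ← max(θ, 0); an NB branch with θ ≤ 0 degenerates to the Poisson/
  binomial tail.
* All randomness flows from one root seed, split into named streams
  (SHA-256 of `seed:name`, reduced below 2³¹); reruns are byte-identical.
* Benchmark pooling across cohorts is micro-average (sum TP/FP/FN, then
  ratios); macro-averaging is available behind a flag. Methods with zero
  calls report undefined (not zero) precision; an empty lower-bound recall
  denominator reports undefined recall.

## Limitations

The GLM path assumes independent binomial counts given features; it has no
dispersion parameter of its own and relies on the NB switch at test time.
The functional weight scale w = S/S_T reads the element score as the mean
over *mutated* donors (the only reading under which w ≈ 1 for typical
elements); scores averaged over all cohort donors would shrink w by the
mutated fraction and effectively disable up-weighting. Feature-importance
outputs describe the synthetic or user-supplied matrix at hand, not any
curated compendium of genome-wide tracks.
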
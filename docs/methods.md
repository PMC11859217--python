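# Methods

This note documents the models implemented in `comboratio`, the
assumptions they make, the parameters that matter, and the places where a
genuinely open design choice had to be made.

## Single-compartment model (`comboratio.pk`)

The plasma concentration of a component after extravascular dosing is
modelled as

    C(t) = Kc * (exp(-ke t) - exp(-ka t)),      ka, ke > 0  [1/h], Kc [mg/L]

with `Kc = ka F Y0 / (Vd (ka - ke))` absorbing dose `Y0`, bioavailability
`F` and distribution volume `Vd`.  The exponential ordering is chosen so
the curve is nonnegative for `ka > ke` (absorption faster than
elimination), consistent with every fitted curve the package reproduces.
Assumptions: first-order absorption and elimination, a single well-mixed
compartment, no dosing interval (single administration), and concentration
profiles summarized by per-time means.

**Identifiability.**  The biexponential is invariant under exchanging
`(ka, ke)` with a sign flip of `Kc` ("flip-flop" kinetics).  The fitter
normalizes every result to the conventional branch `Kc > 0, ka > ke` and
sets `flip_flop_warning` when the optimizer's raw optimum lay on the
exchanged branch.  One published post-improvement parameter set (the
scutellarin triple with ka = 0.052 < ke = 0.106) sits on the exchanged
branch as printed; ratio computations on it use the magnitude-equivalent
conventional branch and flag the exchange.

**Fitting.**  `scipy.optimize.least_squares` on the per-time mean
concentrations (optionally replicate-weighted), initialized by curve
stripping: `ke0` from the log-linear slope of the last three positive
points, `ka0 = 10 ke0`, `Kc0` from the observed peak over the unit-curve
peak.  Five multiplicatively perturbed restarts (seeded) guard against
local minima.  Goodness of fit is the ordinary coefficient of
determination about the observed mean.  `|ka - ke| < 1e-8 ka` switches the
prediction to the analytic limiting form `Kc ka t exp(-ka t)` for
numerical continuity at the degenerate point.

**Quantity and dose ratios.**  The in-vivo quantity ratio

    Q_i : Q_j = Kc_i (ka_i - ke_i) ka_j / (Kc_j (ka_j - ke_j) ka_i)

assumes `Vd` and `F` are common to the two components (both default to 1;
per-component values are retained when set on the fits).  Administered
dose ratios update multiplicatively: `new = old * q_new / q_old`.  This is
the unique linear mapping consistent with both case studies packaged here
(2:1 → 2.40:1 with 12.83 → 15.39, and 1.61:1 → 0.992:1 with
0.543 → 0.334).  Reports round ratios to two decimals; full precision is
kept internally.

## Combination Index (`comboratio.synergy`)

Monotherapy dose–response pairs are fitted with the median-effect
linearization `logit(fa) = m log D - m log Dm` by least squares; observed
fractions are clipped to [0.01, 0.99] before the logit so that extreme
table rows (0% or 100%) remain usable.  The equipotent dose at effect `fa`
is `Dm (fa/(1-fa))^(1/m)`, and

    CI = sum over drugs of (D)combo / (D)alone(fa),

generalizing to any number of drugs by summation.  Classification uses an
additive band of ±1e-6 around CI = 1 (CI is continuous; exact equality is
measure-zero).  Plasma concentrations may stand in for doses — the
package's time-course tables do exactly that.

The package reproduces the CI *formula* and classification, not the
specific CI values printed in the source tables, whose derivation from the
printed data is not recoverable.  In the pipeline, a drug without its own
monotherapy table gets a surrogate median-effect fit from its combination
concentration–effect pairs; when those are confounded by the time course
(non-positive slope), the Hill slope is borrowed from a monotherapy-fitted
reference drug (the standard similar-shape assumption of mutually
exclusive drugs) with the drug's median combination concentration as `Dm`.
CI series computed through these surrogates are internally consistent but
not comparable to in-vitro CI magnitudes.

## Dose–effect classifier (`comboratio.net`)

Architecture (smallest faithful instance of the alternating
convolution/pooling template for 3-feature inputs): standardized input
vector of per-record component concentrations (time as an optional extra
feature, off by default) → 1-D valid convolution, 16 filters, kernel 2,
ReLU → max-pool of width 2 where the sequence length permits → dense 16,
ReLU → single sigmoid output.  Implemented directly in numpy with exact
analytic gradients; training is plain mini-batch SGD (batch 32) on binary
cross-entropy, fully reproducible from the config seed.  Learning rate
and epoch count are the two hyperparameters exposed to the tuner
(log-scaled learning rate in [1e-5, 1e-2], integer epochs in [100, 1000]).

**Desired Effect Threshold.**  The DET is the probability cutoff that
declares a state effective (ties count as effective).  It is initialized
at 0.5 with step 0.01 and clamped to [0.05, 0.95]; it moves up by one step
when validation accuracy improves and down when it degrades.

**Contribution weights.**  Mean absolute gradient of the output
probability with respect to each *standardized* input over the dataset,
normalized to sum to one.  Standardized (rather than raw) gradients make
the importance ranking invariant to each component's measurement scale —
otherwise a component with a small SD in mg/L would be inflated purely by
units.  All-zero gradients fall back to uniform weights with a warning.

**Concentration adjustment.**  To raise the DET-classified effective
fraction by `delta`, one multiplicative factor per component (shared
across records, bounded to [0.1, 10]) is searched on a log scale along the
saliency-weighted gradient-sign direction; bisection finds the smallest
step achieving the target, i.e. the adjustment with minimal squared
log-deviation from unit factors along that direction.  Labels are never
modified.  If the target is unreachable at the factor bounds the
adjustment raises an infeasibility error carrying the best achieved
fraction.  With finitely many records the achieved fraction is a step
function; a deviation beyond ±0.01 of the target triggers a warning
rather than an error.

## Hippopotamus optimizer (`comboratio.hippo`)

Two phases per iteration under greedy acceptance (a move is kept only if
it improves fitness), so best-so-far fitness is monotone non-increasing
and all positions stay clamped inside the bounds.

* *Exploration*: the first half of the herd moves toward the dominant
  member, `x + y1 ∘ (D - I1 x)` with `y1 ~ U(0,1)` per dimension and
  `I1 ∈ {1, 2}`; the second half moves relative to the mean `MG` of a
  uniformly random sub-herd — toward `D - I2 MG` while the schedule
  variable `T = exp(-iter/iterations)` exceeds the threshold (0.6), and
  afterwards either toward `MG - D` or by uniform re-sampling of the box.
  The move-scale vectors `h` are drawn from a five-scenario set
  (`I r + (1-q)`, `2r - 1`, `r`, `I r + q`, scalar `r`) following the
  algorithm's published conventions, which the source presentation leaves
  undefined.
* *Predator defense*: a predator is sampled uniformly in the box; the
  candidate is `RL ∘ predator + (c - d cos 2πg)^(-1) / D` with `RL` a
  Mantegna Lévy flight (index 1.5, step scale 0.05), `c ~ U(2,4)`,
  `d ~ U(1,1.5)`, `g ~ U(-1,1)`, and `D` the per-dimension distance to the
  predator; when the predator's fitness does not beat the hippo's, the
  denominator becomes `2D + r9`.

The original algorithm's third (escape) phase — a shrinking local search —
is implemented behind `enable_escape_phase`, off by default to match the
two-phase presentation the package follows.  The hyperparameter adapter
minimizes validation binary cross-entropy.

## Record generator (`comboratio.data`)

The generator stands in for the study's deep generative augmentation and
preserves exactly the properties that augmentation was validated on:
means, variances, and Pearson correlations.

* **Marginals**: zero-truncated normals whose post-truncation mean and SD
  match each table cell.  The coefficient of variation of a zero-truncated
  normal depends only on the standardized truncation point and is bounded
  above by 1; the underlying parameters are recovered by 1-D bisection
  (mean always matched exactly).  A few published cells print SD/mean
  above the attainable bound (e.g. 0.45 ± 0.48); for those the generator
  matches the mean and takes the nearest attainable SD, with a warning.
* **Dependence**: a Gaussian copula per time point.  Default pairwise
  correlations follow the published augmented-data values where a pair was
  published (PHB–M1 0.576, PHB–M2 0.418) and 0.5 otherwise; matrices are
  repaired to PSD by eigenvalue clipping.  Sampling uses antithetic normal
  pairs — identical copula, sharply reduced Monte-Carlo error in the
  moments.
* **Response**: by default an independent Bernoulli at each time point's
  printed inhibition rate.  Two coupled modes support classifier studies:
  a logistic link on a linear score of the standardized concentrations,
  and a deterministic threshold on the same score, both calibrated with a
  single global intercept so the overall effective fraction matches the
  table's pooled rate.  A single global intercept (rather than per-time
  calibration) keeps the label a function of the concentrations the
  classifier actually sees.  The default steepness (8 per pooled SD of the
  score) leaves an irreducible label-noise floor of about 5% — the
  maximal-electroshock endpoint is treated as near-deterministic given
  the concentration state, so held-out accuracy is a statement about the
  classifier rather than about the noise floor.
* **Scale**: 99 records per time point by default, expanding an
  8-time-point table to 792 records — the augmented-study scale.

What the generator does *not* emulate: temporal autocorrelation within a
subject (records are exchangeable within a time point), measurement-error
structure of the LC-MS/MS assay, inter-animal covariance between time
points, and any dose–response mechanism beyond the configured link.
Passing tests therefore demonstrate correctness of the pipeline's
machinery on data with the tables' first- and second-moment structure, not
predictive validity on new animals.

`validate_correlations` compares generated records against either a
reference record set (pooled correlations) or the copula target itself —
in the latter case correlations are computed within each time point and
averaged, because pooled correlations are additionally inflated by the
shared time trend of the means and would not estimate the copula
parameter.

## Pipeline (`comboratio.pipeline`)

Stage 1 fits (or injects) the ratio-pair profiles, derives the initial
quantity and dose ratios, computes the CI series, and trains the
classifier on generated records (85/15 stratified-by-shuffle split,
matching the 671/119 division of the 792-record study set).  Stage 2
applies the concentration adjustment for the configured efficacy gain
(default 5%), refits the PK models on the adjusted per-time means,
updates the dose ratio through the exact identity
`new = old * q_new/q_old`, recomputes the CI series at the post-gain
inhibition rates (initial rate + delta, the pattern the source tables
follow), and flags the per-time CI change.  A parameter-injection mode
accepts published coefficients directly, separating formula verification
from fit verification.  Reports carry no wall-clock data, so identical
seeds produce byte-identical output files.

**Problem sizes.**  Library defaults (99 records per time point, 150-400
epochs, tuner populations of 6-30) are desk-scale choices that keep a full
pipeline run in the seconds-to-minutes range on one CPU; all of them are
ordinary config fields.

## Known limitations

* Single-compartment, single-dose kinetics only; no multi-compartment,
  Michaelis–Menten, or repeated-dosing support.
* The CI tables printed in the source studies cannot be reproduced from
  the printed data; the package reproduces formula and classification.
  One printed comparison (the epilepsy case at 24 h) shows a CI increase
  where the accompanying text claims a decrease across all periods; the
  packaged fixtures keep the printed numbers.
* Contribution weights are gradient saliency — a local, model-dependent
  importance measure; correlated inputs can redistribute importance among
  themselves.
* The concentration adjustment searches a single direction in log-factor
  space; it is exact for monotone single-component problems and a
  well-behaved heuristic otherwise.
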
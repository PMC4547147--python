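# Methods

This note records the model, the numerical choices, and the design
decisions behind `brlearn`, in the spirit of a statistical software
methods appendix.

## Model and score

A cohort is a table of `n` patient records with a binary diagnostic
target (`Pos`/`Neg` by convention) and categorical predictors; continuous
biomarkers enter only after supervised discretization. Any candidate rule
model induces a partition of the records — for the global search, the
cross-product of the selected parents' values; for the tree search, the
leaves. The partition is scored by the marginal likelihood of the target
given the partition under independent uniform Dirichlet priors
(K2-style, all hyperparameters 1):

    score = Σ_g  log Γ(C) − log Γ(C + N_g) + Σ_c log Γ(1 + n_gc)

with `C = 2`, group totals `N_g` and class counts `n_gc`. The score is
decomposable over groups, so each greedy move is evaluated by a local
difference. An empty group scores 0, so unobserved value combinations
are neutral. With the uniform prior the score is invariant to class
relabelling and favours partitions whose groups are class-pure without
an explicit penalty term — complexity control comes entirely from the
marginal-likelihood averaging.

The choice of uniform Dirichlet(1) hyperparameters (rather than a
BDeu-style equivalent sample size) is a design decision: it is the
simplest prior consistent with the rule statistics below, and it makes
exhaustive-enumeration oracle tests exact.

## EBD discretization

For each continuous predictor the candidate thresholds are the midpoints
between adjacent distinct sorted values whose class count vectors
differ. A subset of candidates defining `I` intervals is scored by

    −(I − 1) · log λ  +  Σ_intervals interval score,

the interval score being the same Dirichlet(1) marginal likelihood
applied to the interval's class counts. The optimum over all `2^B`
subsets is found by an `O(B²)` dynamic program over candidate positions;
ties (within an absolute tolerance of 1e-9) break toward fewer
intervals, then the lexicographically smaller threshold tuple, making
the output deterministic. `λ > 0` is the prior weight penalizing
cut-points: larger λ, fewer intervals (a tested monotonicity). The
default λ = 3.5 matches the package's emulated analysis setting; the
sweep helper evaluates 0.5–4.0 in steps of 0.5 and keeps the lowest λ
achieving the best pooled cross-validation accuracy (AUC breaks ties —
the selection metric is a design decision, as is pooling).

Intervals are left-open/right-closed, rendered in the clinical dialect
`≤ a`, `(a to b]`, `> b`; a variable with no cut-points maps everything
to the single label `any`.

## Searches

**Global.** The first parent is the highest-scoring single predictor;
each later step adds the predictor whose inclusion most improves the
cross-product partition score, requiring strict improvement (tolerance
1e-9), capped at 8 parents. Rules are emitted for observed combinations
only; a default catch-all rule (majority class, posterior 0.5 when it
covers nothing) guarantees that unseen records still match exactly one
rule.

**Tree (local structure).** Recursively, each node evaluates every
variable unused on its path; the split replacing the node's leaf score
by the sum of its children's leaf scores is accepted only on strict
improvement. Recursion stops at pure nodes, at depth 8, or when no
split improves the score. Leaves predict their majority class; ties
fall back to the training majority, then to the negative class.
Greedy selection ties break toward fewer levels, then variable name —
the tie policy exists purely to make learning deterministic.

Both searches share the per-step strict-improvement property (tested),
and both yield mutually exclusive, exhaustive rule sets — the tree by
construction, the global search via the default rule.

## Rule statistics

For a rule predicting class `c` with coverage `TP` (covered records of
class `c`) and `FP` (covered records of the other class):

* posterior `= (TP + 1) / (TP + FP + 2)`, the Beta(1,1) posterior mean
  of the rule's class probability;
* p-value: one-sided upper-tail Fisher exact,
  `P(X ≥ TP)` for `X ~ Hypergeom(N, K, TP + FP)` with `K` the cohort
  total of the predicted class — the probability of covering at least
  this many predicted-class records by chance. Computed via scipy's
  log-gamma hypergeometric tail and verified against exact rational
  summation up to `N = 200`.

Both formulas are inferred, not quoted: they reproduce, to the printed
precision, every one of the 13 (Prob, P) pairs of the published
pediatric cardiomyopathy rule model when fed its printed TP/FP counts
and class totals (51 controls / 32 cases), which is the adopted ground
truth. A zero-coverage rule scores posterior 0.5 and p = 1 (no
evidence). Statistics are stored at full precision; the text format
rounds Prob and P to 3 decimals for display, which is why a parsed text
model can carry `P = 0.0`.

## Cross-validation

Folds are class-stratified: each class is shuffled (seeded) and dealt so
per-class and overall fold sizes both differ by at most one (the
remainder always goes to the currently smallest folds). By default the
entire pipeline — EBD included — is refit inside each training fold, so
cut-points never see test rows; `paper_mode` instead fits the
discretization once on the full table before splitting, reproducing the
common (leakier) protocol of discretize-then-validate. Metrics are
pooled over the concatenated held-out predictions (per-fold values are
also reported); AUC is the Mann–Whitney statistic with midrank ties,
scored by the matching rule's posterior (its complement for
negative-predicting rules). The default seed is 20150813.

## Synthetic cohorts

The generator emulates the structure of an 83-patient pediatric cMRI
biomarker cohort: exactly 32 positives and 51 negatives (counts are
exact, not sampled), ~30 predictors — age (uniform on [0, 22]), gender,
binary MDE status, 24 continuous biomarkers (ventricular volumes,
ejection fractions, indexed dimensions, stroke volume index, heart
rate, output) — plus five derived Low/Normal/High "Range" variables
computed from the volume biomarkers by the 2-SD rule against age- and
gender-specific reference means (values exactly at ±2 SD count as
Normal; five age bands over [0, 22]). The class signal is (a) MDE drawn
class-conditionally at rates 17/32 versus 1/51 — the only
class-conditional rates recoverable from the emulated model's printed
coverage — and (b) fixed mean shifts, in reference-SD units, for a
handful of biomarkers (dilated volumes +0.7…+0.9 SD, ejection fractions
−0.8/−0.9 SD, SVI +0.3 SD), chosen once as clinically plausible
cardiomyopathy physiology and strong enough that a Bayes-optimal
classifier sits near 85% accuracy at the default composition.

The reference table itself is synthetic — plausible pediatric volume
means growing monotonically with age, SD ≈ 16% of the mean, fixed by a
seed — and stands in for published normal-range tables that are not
distributed here.

`implant_rule_model` converts a rule model into a generative "region
mechanism": each non-default rule's condition region receives a
class-conditional allocation weight equal to its (TP, FP); records are
assigned to regions by exact largest-remainder proportioning and their
conditioned variables forced (MDE set directly; Range conditions sample
the underlying volume from the truncated reference normal; interval
conditions sample a truncated normal within the interval). Generated
coverage counts then converge to the scaled printed counts; zero-coverage
rules are left neutral.

What passing tests on these cohorts do **not** show: the generator's
class-conditional distributions are Normal and conditionally independent
given class and region, with none of the correlation structure,
measurement error, or diagnostic-subtype heterogeneity of real cMRI
data, so recovery results bound behaviour under the emulated mechanism
only — not clinical performance. Headline cross-validation numbers on
real data are not reproducible without the original cohort, which is
not public.

## Problem sizes and determinism

Default experiment sizes were chosen so the full pipeline stays
interactive on one CPU: the root-recovery experiment uses 100 seeds at
n = 2000 (≈ 1.3 s per fit, dominated by the EBD dynamic program over
~25 biomarkers); convergence checks use n ∈ {830, 8300}; enumeration
oracles cap at 12 candidate boundaries (4096 subsets) and depth-2 trees.
Every stochastic component is driven by an explicit integer seed through
`numpy.random.default_rng`; identical configurations produce
byte-identical cohort CSV files.

## Known limitations

* Binary targets only; the multi-class diagnostic subtypes of a real
  cardiomyopathy cohort are out of scope.
* The global search scores the full cross-product partition, so with
  many parents most rules cover no records and defer to the default
  rule; the tree search is the practical choice beyond a few parents.
* No missing-data handling by design: a blank cell is an input error,
  never imputed.
* The Fisher p-values are per-rule and unadjusted; no multiplicity
  correction across rules is applied or intended.
* Candidate cut-points are class-boundary midpoints; a cut strictly
  interior to a run of identical class composition is never considered
  (such cuts cannot improve the score under this score family).
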
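# Methods

## The analysis problem

Each phone call yields a D-dimensional acoustic feature vector tied to a
participant and a timestamp; each monitored day may carry a self-report of
mood (9-point scale, −3 depressed … +3 manic, with half-steps at ±0.5),
activity (7-point, 0 = normal) and sleep (bedtime and wake-up clock
times).  Two families of binary classification tasks are run: diagnostic
group contrasts (BD vs HC, BD vs UR, UR vs HC) using every call, and
affective-state contrasts within patients (mania vs euthymia, depression
vs euthymia, increased/decreased vs neutral activity, insomnia vs normal
sleep, and a broader mania — increased mood AND activity AND sleep < 360
minutes — versus all other labeled days) using only calls whose calendar
day has a self-report.

## Labeling rules

Mood bands: euthymia is mood ∈ {−0.5, 0, 0.5}; depression mood < −0.5;
mania mood > 0.5.  Activity: increased > 0, decreased < 0, neutral = 0.
Insomnia: strictly fewer than 360 minutes between bedtime and the next
wake-up (wrapping midnight).  Values are validated against the discrete
scales after rounding to one decimal, so the ±0.5 boundaries never hinge
on float equality.  All calls on a day inherit the day's single label;
days with calls but no report are excluded from state contrasts.  Two
conventions the data model forces us to fix ourselves: a report with
bedtime equal to wake-up counts as 0 minutes of sleep, not 1440 (taking a
degenerate report at face value rather than maximising sleep), and
duplicate (participant, date) reports are rejected at ingest rather than
resolved.

## Cross-validation protocol

Folds are assigned at the participant level (five folds, sizes differing
by at most one participant, seeded shuffle), because every call of a
participant shares the participant's group label: row-level folds let a
model recognise the *person* (their stable vocal fingerprint) instead of
the condition, inflating performance.  The package keeps a `fold_unit="row"`
switch purely to demonstrate that inflation; disjointness of train and
test participant sets is asserted at runtime in the honest mode.

Per fold: features are standardised to zero mean / unit variance using
training-fold statistics only (population variance; a feature constant
within the fold keeps scale 1 and maps to 0), the training rows are
rebalanced (below), a 100-tree random forest (scikit-learn defaults
beyond the tree count) is fitted, and the untouched test rows are scored;
predicted labels use a 50% probability threshold.  Metrics are computed
over the pooled test rows of each fold and summarised as the unweighted
mean and sample (n−1) SD across folds.  A test fold containing a single
class has no defined AUC (and no sensitivity or specificity for the
absent class); such values are recorded as missing and excluded from the
mean/SD rather than imputed at 0.5.

User-dependent (personalised) models run the same per-fold protocol
within one patient's rows, using stratified row-level splits.  A patient
is eligible with at least 2 rows of each class and at least 5 rows
overall; the fold count drops to the minority-class count when five
stratified folds are infeasible (never below 2).  Rare states (mania on
~3% of days) make this reduction common.  Per-patient fold means are
averaged (unweighted) across patients for the summary.  Temporal blocking
instead of random row splits would be a defensible alternative; random
stratified splits are the default here and the choice is visible in one
place (`run_user_dependent`).

## Rebalancing

Training folds are rebalanced only for feature-based models; the
label-only baselines see the raw training label distribution (a
majority-vote baseline on artificially balanced labels would degenerate
to a coin flip, contradicting what it is meant to measure).  The scheme:
if the minority class is below one third of the training fold, SMOTE it
up to the smallest integer m′ with m′/(m′ + n_majority) ≥ 1/3 ("33%" read
as exactly one third; the ceiling is computed with an integer-exact
adjustment), then undersample the majority to m′; with milder skew,
undersample straight to the minority count; equal classes are left alone.
SMOTE synthesises x + u·(x_nn − x) with u ~ U(0,1) and x_nn one of the
k = 5 nearest minority neighbours (Euclidean, computed on the
already-standardised features).  A minority of exactly one row cannot be
interpolated and falls back to undersampling only (logged); a
single-class training fold skips rebalancing and yields a constant
classifier with a warning.  Test rows are never resampled.

## Metrics

F1 is computed as TP / (TP + (FP + FN)/2), identical to the harmonic mean
of precision and recall.  AUC is the Mann–Whitney pairwise probability
(ties half-weighted), equal to the trapezoidal area under the ROC curve;
ROC points for reporting aggregate all test scores and labels across
folds (and across patients in the personalised mode).

### B10, the dependence Bayes factor

B10 tests whether predicted and true labels are statistically dependent
in the 2×2 confusion table — a measure that remains interpretable under
heavy class imbalance, where accuracy does not.  Under multinomial
sampling of the four cells, the independence model M0 factorises the cell
probabilities into row and column probabilities with uniform Beta(1,1)
priors; the dependence model M1 is the saturated multinomial whose
Dirichlet(1,1,1,1) default prior is converted into an intrinsic prior
conditional on M0 using a training sample of size t.  The intrinsic
construction collapses to a finite mixture

    m1(x) = Σ_z  m0(z) · DirMult(x | 1 + z),

summing over all 2×2 tables z with total t, where m0(z) is the null prior
predictive and DirMult the Dirichlet-multinomial posterior predictive.
B10 = ln m1(x)/m0(x), reported on the natural-log scale to match the
interpretation bands (< 0 evidence against dependence, 1–3 positive, 3–5
strong, > 5 decisive).  We set t equal to the observed total; the sum is
enumerated exactly (log-space, streaming logsumexp) while the number of
training tables is at most 10⁶ (t ≲ 180) and otherwise estimated by a
seeded Monte-Carlo draw of z from the null predictive (default 20 000
draws, empirically within ~0.05 of the exact log value at that size).
Tables with an all-zero margin (e.g. a constant predictor) have no
defined B10 and are reported missing.  The hierarchical definition —
sample null parameters, a training table, then Dirichlet-posterior
multinomial parameters — is kept in the test suite as an independent
Monte-Carlo oracle for the collapsed sum.

## Permutation test

For group contrasts, significance of the cross-validated AUC is assessed
by shuffling the group labels *between participants* (each participant's
calls inherit the permuted label, conserving group sizes at the
participant level) and re-running the entire pipeline — folds,
standardisation, rebalancing, fitting — per permutation; the statistic is
the fold-mean AUC.  The exceedance p-value is #{null ≥ observed}/B with
no +1 correction, so 6 of 200 exceedances prints exactly p = 0.03;
zero exceedances is reported as the bound p < 1/B rather than 0.  The
one-tail decision at level α compares the observed AUC with the (1−α)
empirical quantile of the null sample.  Replicate seeds derive from the
master seed by counter.

## Synthetic cohorts

The generator emulates the data-generating structure the analysis
assumes.  Each feature value is

    group shift + fingerprint + state shift (BD only) + N(0, noise_sd)

with the group shift applied to a random signed subset of features
(default one quarter), UR receiving half the BD shift (the intermediate-
phenotype hypothesis), fingerprints i.i.d. N(0, fingerprint_sd) per
participant and feature, and each active daily state (mood band, activity
deviation, insomnia — drawn independently per the labeling dimensions)
adding its own sparse shift.  Self-report values are drawn from the
generating state's defining band, so labels round-trip through the
labeling module exactly.  Calls per day are Poisson; follow-up length is
uniform on a configurable range; a fraction of monitored days lose their
self-report.

Defaults mirror the emulated study's scale: 121/21/38 participants in
BD/UR/HC, follow-up 10–300 days (mean ≈ 155), ≈ 4 calls/day (≈ 10⁵ call
entries), 64 features (configurable up to the full 6552-dimensional
acoustic set), state prevalences mania 0.03 / depression 0.12 / increased
activity 0.29 / decreased activity 0.23 / insomnia 0.19, and 40% of BD
days without a report (the emulated study had voice data on ~79k patient
calls but state labels on only ~45k).  Unspecified magnitudes
(fingerprint_sd = noise_sd = 1, group_effect = 1, state_effect = 0.5)
were fixed once at values giving realistic, imperfect separability.

What the generator deliberately does not model: real acoustic feature
distributions (heavy tails, cross-feature correlation), serial or
within-day correlation of calls (calls are conditionally independent
given the day's state), medication or demographic confounding, and
non-random missingness of self-reports.  Passing tests therefore
demonstrate the *procedural* correctness and calibration of the pipeline
(leakage control, rebalancing arithmetic, null behaviour of the
permutation test, the fingerprint mechanism behind personalised-model
superiority), not that real voice data would achieve any particular AUC.

## Problem sizes in the test and acceptance runs

Tests and the acceptance script use deliberately small cohorts chosen as
desk-scale working conditions: baseline-identity checks use 17–28
participants with 20–40 follow-up days; the permutation-calibration study
uses 200 null cohorts of 10 participants with 49 permutations each and a
4-tree forest (the calibration of an exchangeability test does not depend
on classifier strength); the effect-size and fingerprint scenarios use
16–40 participants with 30–70 days and 16 features.  The random-baseline
AUC is measured on a ~6500-row state dataset so its Monte-Carlo noise is
well inside ±0.02.

## Known limitations

- The intrinsic-prior Bayes factor's absolute value depends on the
  training-sample size convention (t = n here); different choices shift
  values by O(1) while preserving sign and ordering.
- The majority-vote baseline's printed *accuracy* depends on how folds
  weight observations and is not structurally forced; only its
  sensitivity/specificity/AUC identities are.
- User-dependent splits are random and stratified, not temporal; with
  strong within-person autocorrelation of real voice features this is
  optimistic.
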
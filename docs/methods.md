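# Methods

## The problem

Accurate visual encoding models — functions predicting a brain region's
response to a stimulus — normally require thousands of stimulus–response
pairs per person, which only densely-sampled fMRI designs provide. For a
*novel* individual scanned for minutes rather than dozens of hours, the
question is how to get a model that is both accurate and *personalized*,
i.e. one that preserves that person's idiosyncratic response pattern
instead of regressing to the population mean.

`enscode` implements and evaluates the ensemble answer: predict the new
subject's region-level response to stimulus *S* as a linear combination
of *reference* subjects' model predictions,

```
LE_i(S) = β_{i,0} + Σ_{j ∈ refs(i)} β_{i,j} · r̂_j(S)
```

where `r̂_j(S)` is reference subject *j*'s encoding-model prediction and
the coefficients are fitted by ordinary least squares on a small sample
of the query subject's *single-trial* responses. Within a cohort the
ensembles are built leave-one-out; an out-of-cohort query uses every
reference. The zero-data baseline is the *average ensemble*, the
unweighted mean of reference predictions.

## Model components and their assumptions

**Readout models** (`encoding`). Each per-subject, per-region encoding
model is a linear readout `w·f(S) + b` on a fixed stimulus feature
vector. Feature extraction is deliberately outside the trainable path:
features are abstract inputs, standing in for the representation a deep
backbone would produce. Readouts are trained by mini-batch gradient
descent on the MSE of single-trial responses (batch size 32), with early
stopping when the Pearson correlation on a repeat-averaged validation
set stops improving; the weights at the best validation correlation are
kept. Two initializations: `random` (w ~ N(0, 1/d)) and `group_average`
(mean of reference readouts — the warm start that makes "fine-tuned"
small-data models). Defaults: lr 0.03, max 500 epochs, patience 10
validation checks (one per epoch); the optimizer is plain gradient
descent for bit-reproducibility, with an Adam-style option behind the
same config. Learning rate and epoch budget are exposed configuration,
chosen for stable convergence on unit-variance features, not claimed to
match any particular reference training run.

**Ensembles** (`ensemble`). The design matrix of the linear ensemble is
the reference predictions on `n_train` seeded-sampled training stimuli
plus an intercept column; targets are the query's measured single-trial
responses (never repeat-averaged). No standardization is applied — the
reference predictions share units. Rank-deficient designs (duplicate or
constant references) are solved by minimum-norm least squares with a
logged warning rather than an error. Unregularized OLS with 7 references
is noisy below n_train ≈ 30; the implementation refuses
n_train < p + 1 and leaves the instability of the 10–50 range visible in
sweep results rather than hiding it behind a ridge penalty.

**Splits** (`datamodel`). Training points are single-trial; validation
and test responses are the mean of *exactly two* repeats — when three
exist, two are chosen uniformly at random under a named seed — so the
noise level of averaged responses is homogeneous across stimuli. One
repeat pair is chosen per (subject, stimulus) and reused across regions,
because response maps are averaged jointly. Test stimuli come only from
the shared pool with ≥ 2 repeats for every subject, giving every subject
the identical test set that inter-subject comparisons require. Default
protocol sizes: 200 test and 50 validation stimuli.

## Evaluation

*Prediction accuracy* is the Pearson correlation between predicted and
measured (repeat-averaged) responses over the test set. *Inter-subject
correlation* (ISC) matrices hold the pairwise Pearson correlations of
subjects' response vectors — computed separately for measured responses
and for model predictions. *Prediction consistency* is the Pearson
correlation between the pooled upper triangles of the ISC-prediction and
ISC-measurement matrices (pooled across regions, so an 8-subject,
4-region cohort contributes 4 × 28 points; a per-region mode exists).
Significance is a one-tailed permutation test — the ISC-measurement
vector is permuted against the fixed ISC-prediction vector, default
10,000 permutations — with the add-one estimator
p = (1 + #{r_perm ≥ r_obs}) / (1 + N) and caller-supplied Bonferroni
correction.

Undefined correlations (zero-variance inputs) propagate as flagged NaN,
never as silent zeros. One documented convention extends this to *near*
degeneracy: a pooled ISC vector whose standard deviation is ≤ 0.005 is
flagged undefined. This encodes the fact that the leave-one-out average
ensemble predicts near-identical vectors for every subject — its
pairwise ISCs agree to a few 1e-4 (all > 0.99) — so a correlation
computed on that numerical residue would be meaningless; informative ISC
vectors spread an order of magnitude or more above the cutoff.

*Noise ceilings*: across-subject (a subject's test vector vs the mean of
all other subjects') and within-subject in two flavours — mean of two
repeats vs the third (three-repeat designs) or one repeat vs another
(two-repeat designs). Under the Gaussian generator these have closed
forms, e.g. two noisy replicates of a signal with variance s² and noise
σ² correlate at s²/(s²+σ²) in expectation, and the mean-of-two-vs-third
variant at s²/√((s²+σ²)(s²+σ²/2)); the acceptance checks verify both.

*Model comparison statistics*: exact Wilcoxon matched-pairs signed-rank
tests against a reference model (exact distribution for n ≤ 25; a
6-subject or 8-subject cohort is far inside that range), Friedman's
chi-square on within-subject ranks with Benjamini–Hochberg-adjusted
pairwise post-hocs, and Welch's unequal-variance t for two-sample
contrasts. These route through scipy/statsmodels and are cross-checked
in the tests against brute-force enumeration (all 2^8 sign flips), the
rank formula, and a hand-worked step-up procedure.

A note on pair counts: for k subjects the number of unordered pairs is
k(k−1)/2 — 28 for an 8-subject cohort and 15 for a 6-subject cohort.
Published figure captions in this literature occasionally misprint the
8-subject count (e.g. "(7 × 8)/2 = 23"); this package computes k(k−1)/2.

## The synthetic cohort generator

`simulate` draws cohorts from the simplest generative model exhibiting
the two axes the framework cares about — shared vs idiosyncratic signal,
and measurement noise:

- features f(S) ~ N(0, I_d), i.i.d. per stimulus;
- per region, a shared tuning vector w_g ~ N(0, σ_g²/d · I) and
  per-subject offsets u_j ~ N(0, σ_u²/d · I);
- noiseless signal r_j(S) = (w_g + u_j)·f(S); each of 1–3 repeats adds
  ε ~ N(0, σ_ε²) (Student-t noise available as an option);
- the first `n_shared` stimuli are shown to everyone; the rest are
  partitioned round-robin as subject-exclusive, as in densely-sampled
  designs where most images are subject-specific;
- optionally the last subject's signal is a *known* linear mixture
  (intercept*, β*) of the others' signals, giving ground truth for
  coefficient recovery; optionally stimuli carry animal-face /
  human-face / other labels realized as feature bumps plus per-subject
  preference offsets, giving a planted inter-individual preference.

One named RNG stream per concern (features, readouts, noise, labels)
makes the cohort a pure function of its config and keeps e.g. the repeat
count from perturbing the features.

**Default parameter point** (chosen as the regime the framework
targets, and the conditions under which its qualitative claims are
reproduced): 8 subjects, 4 regions, 1000 stimuli (300 shared), 3
repeats, d = 8, σ_g = 1.0, σ_u = 0.2, σ_ε = 0.7. The reasoning:

- σ_ε ≈ 0.7 puts single-trial SNR near 2, typical of region-average
  GLM betas;
- σ_u = 0.2 makes idiosyncratic differences *reliable*: their imprint on
  pairwise ISC (≈ σ_gσ_u/√d ≈ 0.07) clearly exceeds the ISC sampling
  noise of a 200-stimulus test set (≈ 0.03). Much smaller σ_u leaves
  inter-individual structure below sampling noise, and the
  consistency-vs-ensemble-size phenomenon disappears into leakage that
  all ensemble sizes share;
- d = 8 means seven leave-one-out references span ~7/8 of a novel
  subject's tuning space, so the linear ensemble approaches the
  densely-trained ("oracle") model's accuracy — the regime in which
  ensembling existing models is a substitute for dense data collection.

With these defaults the generator reproduces, at desk scale: the
small-data accuracy hierarchy (group-average-initialized beats random
initialization at tiny n; the linear ensemble at n = 300 is within 0.02
of the oracle models), across-subject NC above within-subject NC,
average-ensemble ISC-prediction ≈ 1 with undefined consistency, and
prediction consistency increasing with ensemble size (≈ 0.47 at one
reference to ≈ 0.69 at seven, seed-averaged).

**What the generator does not emulate** — and therefore what passing
tests do *not* show about real data: naturalistic image statistics and
feature extraction (features are i.i.d. Gaussian; real deep features are
correlated and heavy-tailed), nonlinear stimulus–response structure,
hemodynamics and preprocessing artifacts, session/scanner domain shifts,
and voxel-level heterogeneity within regions (responses enter
pre-aggregated per region). Reference models here are noiseless latent
readouts; real densely-trained models carry estimation error, which
would loosen the ensemble–oracle equivalence and lower all ISC values.

## Experiment protocols

`experiments` reproduces the study protocols at desk scale: a
training-size sweep (models × grid × seeds, with per-cell Wilcoxon flags
against the reference models), an ensemble-size sweep (m references
sampled per query; accuracy and pooled consistency per size), subsample
reliability (metric distributions over seeded test-set subsamples, with
degenerate draws counted, relative error vs the full-data value), top-k
stimulus ranking (descending predicted response, ties broken
lexicographically by stimulus id), and the preference analysis: per
subject × face region, Welch's t of measured responses to animal-face vs
human-face stimuli against the (n_animal − n_human)/(n_animal + n_human)
ratio in the model's top-10 predicted stimuli, correlated across points.
Every protocol is a pure function of (cohort, reference readouts,
config, seeds) and bit-reproduces its tables.

Problem sizes used by the test suite and the acceptance script (chosen
as the package's desk-scale defaults): sweeps use 10–20 seeds, 2–4
regions and grids up to n_train = 300; closed-form noise-ceiling checks
use 50 cohorts at d = 128 with 600 test stimuli, where the plug-in
variance-ratio forms are accurate to a few 1e-3 (at small d the realized
tuning-vector norm fluctuates, biasing the ratio by ~0.3/d; small-d unit
tests condition on the realized vector instead); permutation calibration
uses 1000 replicates × 1000 permutations.

## Numerical conventions and degenerate inputs

- OLS via `numpy.linalg.lstsq` (minimum-norm on rank deficiency, warned).
- Pearson correlations of zero-variance vectors: NaN + flag, excluded
  from aggregates; near-degenerate pooled ISC vectors (sd ≤ 0.005)
  likewise flagged in consistency.
- Zero-variance validation responses: correlation undefined → training
  falls back to the fixed epoch budget and says so in the trace.
- Wilcoxon with all-zero differences: degenerate flag (NaN p).
- Friedman with identical models: statistic 0, pairwise p = 1.
- All randomness flows through `numpy.random.SeedSequence` spawning;
  derived seeds are stable across processes (no builtin `hash`).
- Row ordering on save is fixed (subject, region, stimulus, repeat), so
  saving a cohort twice yields identical bytes.

## Known limitations

- Unregularized OLS with 7 references is unstable for n_train ≲ 30;
  results in that range are reported, not smoothed.
- The consistency permutation test assumes exchangeable ISC entries
  under the null; ISC entries sharing a subject are weakly dependent, so
  the test is approximate (calibration under an independent-entry null
  is verified; the dependent case is not).
- The near-degeneracy cutoff (sd ≤ 0.005) is a convention; analyses of
  models whose genuine ISC spread is that small would be flagged
  undefined rather than estimated.
- Desk-scale cohorts cannot reproduce any published accuracy value from
  real fMRI data; only the qualitative ordering and the generator's own
  closed forms are claimed.
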
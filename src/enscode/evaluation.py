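"""Model assessment: accuracy, inter-subject correlation, consistency,
noise ceilings and model-comparison statistics.

Two complementary views of model quality are computed.  *Prediction
accuracy* is the Pearson correlation between a model's predicted and the
measured (repeat-averaged) responses over the shared test stimuli.
*Prediction consistency* asks whether a model preserves inter-individual
differences: the pairwise inter-subject correlations (ISC) of predicted
responses are correlated, across all subject pairs and regions, with the
ISC of the measured responses; significance comes from a one-tailed
permutation test (default 10,000 permutations of the ISC-measurement
vector) with Bonferroni correction across a caller-supplied number of
comparisons.  An ensemble that simply averages references predicts
near-identical vectors for everyone — its ISC-prediction entries are all
~1, its consistency undefined — which is exactly the failure mode the
metric exists to expose.

Noise ceilings bound the attainable accuracy from response
repeatability: across-subject (a subject's test responses vs the mean of
everyone else's) and within-subject in two flavours — the mean of two
repeats against a third (three-repeat designs) or one repeat against
another (two-repeat designs).

Correlations over zero-variance vectors are undefined and propagate as
NaN with an explicit flag — never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from enscode.datamodel import Cohort, DatasetSplit


def prediction_accuracy(predicted: np.ndarray, measured: np.ndarray) -> float:
    """Pearson r between predicted and measured responses.

    Returns NaN (undefined) when either vector has zero variance;
    callers exclude NaNs from aggregates.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {measured.shape}")
    if predicted.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if not (np.all(np.isfinite(predicted)) and np.all(np.isfinite(measured))):
        raise ValueError("non-finite values in accuracy inputs")
    if predicted.std() == 0.0 or measured.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(predicted, measured)[0, 1])


@dataclass
class ISCMatrix:
    """Pairwise Pearson correlations between subjects over test stimuli."""

    subject_ids: list[str]
    values: np.ndarray
    source: str  # "measurement" | "prediction"
    region_id: str = ""

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle entries in row-major pair order."""
        iu = np.triu_indices(len(self.subject_ids), k=1)
        return self.values[iu]

    @property
    def n_pairs(self) -> int:
        k = len(self.subject_ids)
        return k * (k - 1) // 2


def isc_matrix(
    responses: dict[str, np.ndarray], source: str, region_id: str = ""
) -> ISCMatrix:
    """Inter-subject correlation matrix over a shared test stimulus set.

    ``responses`` maps subject → response vector, all aligned to the same
    test stimuli.  Entries for zero-variance vectors are NaN.
    """
    subjects = list(responses)
    if len(subjects) < 2:
        raise ValueError("ISC needs at least 2 subjects")
    vecs = [np.asarray(responses[s], dtype=float) for s in subjects]
    n = {v.shape for v in vecs}
    if len(n) != 1:
        raise ValueError("subject response vectors are not aligned")
    k = len(subjects)
    values = np.full((k, k), np.nan)
    for i in range(k):
        values[i, i] = 1.0
        for j in range(i + 1, k):
            if vecs[i].std() == 0.0 or vecs[j].std() == 0.0:
                r = float("nan")
            else:
                r = float(np.corrcoef(vecs[i], vecs[j])[0, 1])
            values[i, j] = values[j, i] = r
    return ISCMatrix(subject_ids=subjects, values=values, source=source, region_id=region_id)


@dataclass
class ConsistencyResult:
    """Prediction-consistency correlation with permutation inference."""

    r: float
    p_one_tailed: float
    n_pairs: int
    n_permutations: int
    corrected_p: float
    undefined: bool = False


def prediction_consistency(
    isc_pred: list[ISCMatrix],
    isc_meas: list[ISCMatrix],
    n_permutations: int = 10_000,
    seed: int = 0,
    n_comparisons_for_bonferroni: int = 1,
    degenerate_sd: float = 0.005,
) -> ConsistencyResult:
    """Correlate ISC-prediction with ISC-measurement across subject pairs.

    Upper triangles of the per-region ISC matrices are pooled into one
    vector per source (so a 4-region, 8-subject cohort contributes
    4 x 28 points) and Pearson-correlated.  The one-tailed p-value is
    estimated by randomly permuting the ISC-measurement vector against
    the fixed ISC-prediction vector, with the add-one estimator
    p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations); the corrected
    p is Bonferroni (multiplied by ``n_comparisons_for_bonferroni``,
    capped at 1).

    When either pooled vector is (near-)constant the correlation is
    undefined and the result is flagged rather than reported as 0.  The
    near-degeneracy cutoff ``degenerate_sd`` encodes the convention that
    ISC vectors "all 1 or near 1" — the leave-one-out average ensemble,
    whose pairwise prediction correlations agree to a few 1e-4 — carry no
    inter-individual signal, so correlating their numerical residue
    against the measured ISC would be meaningless.  Informative ISC
    vectors spread an order of magnitude or more above the default
    cutoff.
    """
    if len(isc_pred) != len(isc_meas):
        raise ValueError("need one ISC-prediction matrix per ISC-measurement matrix")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pred = np.concatenate([m.upper_triangle() for m in isc_pred])
    meas = np.concatenate([m.upper_triangle() for m in isc_meas])
    if pred.shape != meas.shape:
        raise ValueError("mismatched subject sets between prediction and measurement ISC")
    keep = np.isfinite(pred) & np.isfinite(meas)
    pred, meas = pred[keep], meas[keep]
    n = pred.size
    if n < 3 or pred.std() <= degenerate_sd or meas.std() <= degenerate_sd:
        return ConsistencyResult(
            r=float("nan"),
            p_one_tailed=float("nan"),
            n_pairs=int(n),
            n_permutations=n_permutations,
            corrected_p=float("nan"),
            undefined=True,
        )
    r_obs = float(np.corrcoef(pred, meas)[0, 1])

    rng = np.random.default_rng(seed)
    # vectorized permutations: each row of `perm` is a shuffled measurement vector
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    perm = meas[order]
    pz = (pred - pred.mean()) / pred.std()
    perm_c = perm - perm.mean(axis=1, keepdims=True)
    perm_sd = perm_c.std(axis=1)
    r_perm = (perm_c @ pz) / (n * perm_sd)
    p = float((1 + np.sum(r_perm >= r_obs)) / (1 + n_permutations))
    return ConsistencyResult(
        r=r_obs,
        p_one_tailed=p,
        n_pairs=int(n),
        n_permutations=n_permutations,
        corrected_p=min(1.0, p * n_comparisons_for_bonferroni),
    )


@dataclass
class NoiseCeiling:
    subject_id: str
    region_id: str
    kind: str  # "across_subject" | "within_subject_nsd" | "within_subject_neurogen"
    value: float


def across_subject_nc(split: DatasetSplit, subject_id: str, region_id: str) -> NoiseCeiling:
    """Correlation of a subject's test responses with the mean of the others'.

    Averaging the other subjects' responses suppresses their noise and
    idiosyncrasies, so this ceiling exceeds the within-subject one when
    the shared signal dominates.
    """
    others = [s for s in split.cohort.subject_ids if s != subject_id]
    if not others:
        raise ValueError("across-subject noise ceiling needs at least 2 subjects")
    _, own, _ = split.test_xy(subject_id, region_id)
    other_mean = np.mean([split.test_xy(s, region_id)[1] for s in others], axis=0)
    return NoiseCeiling(
        subject_id=subject_id,
        region_id=region_id,
        kind="across_subject",
        value=prediction_accuracy(other_mean, own),
    )


def within_subject_nc(
    cohort: Cohort,
    subject_id: str,
    region_id: str,
    test_ids: list[str],
    style: str,
) -> NoiseCeiling:
    """Within-subject noise ceiling from repeated measurements.

    style="nsd": Pearson r between the mean of two measured repeats and
    the third, over the test stimuli (requires 3 repeats each).
    style="neurogen": Pearson r between two measured repeats (requires 2).
    Repeats are taken in repeat_index order, so the estimate is
    deterministic.
    """
    need = {"nsd": 3, "neurogen": 2}.get(style)
    if need is None:
        raise ValueError(f"unknown noise-ceiling style {style!r}")
    r = cohort.responses
    r = r[
        (r["subject_id"] == subject_id)
        & (r["region_id"] == region_id)
        & (r["stimulus_id"].isin(test_ids))
    ]
    counts = r.groupby("stimulus_id")["repeat_index"].nunique()
    deficient = sorted(set(test_ids) - set(counts[counts >= need].index))
    if deficient:
        raise ValueError(
            f"style {style!r} needs {need} repeats per test stimulus; "
            f"deficient stimuli: {deficient[:10]}"
        )
    wide = r.pivot_table(index="stimulus_id", columns="repeat_index", values="response")
    wide = wide.loc[test_ids]
    reps = [wide.iloc[:, i].to_numpy() for i in range(need)]
    if style == "nsd":
        a, b = (reps[0] + reps[1]) / 2.0, reps[2]
    else:
        a, b = reps[0], reps[1]
    return NoiseCeiling(
        subject_id=subject_id,
        region_id=region_id,
        kind=f"within_subject_{style}",
        value=prediction_accuracy(a, b),
    )


def compare_to_reference_wilcoxon(
    accuracies_model: np.ndarray, accuracies_reference: np.ndarray
) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test against a reference model.

    Exact two-tailed p for small samples (n <= 25); pairs with zero
    difference are dropped (Wilcoxon convention).  Returns
    (statistic, p); p is NaN when every difference is zero (degenerate).
    """
    a = np.asarray(accuracies_model, dtype=float)
    b = np.asarray(accuracies_reference, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("paired vectors of equal length >= 5 required")
    diffs = a - b
    if np.all(diffs == 0.0):
        return 0.0, float("nan")
    method = "exact" if a.size <= 25 else "auto"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def compare_models_friedman_fdr(
    accuracies: np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """Friedman omnibus test plus BH-FDR-adjusted pairwise comparisons.

    ``accuracies`` is a subjects × models matrix.  The omnibus statistic
    is the Friedman chi-square on within-subject ranks (midranks for
    ties); post-hoc, every model pair is compared with the exact Wilcoxon
    signed-rank test and the p-values are Benjamini–Hochberg adjusted.
    Returns (statistic, p, k × k adjusted-p matrix with NaN diagonal).
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.ndim != 2 or acc.shape[1] < 3:
        raise ValueError("need a subjects x models matrix with >= 3 models")
    if acc.shape[0] < 5:
        raise ValueError("need >= 5 subjects")
    k = acc.shape[1]
    if np.all(acc == acc[:, [0]]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.friedmanchisquare(*[acc[:, j] for j in range(k)])
    raw = []
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    for i, j in pairs:
        if np.all(acc[:, i] == acc[:, j]):
            raw.append(1.0)
        else:
            raw.append(
                float(
                    stats.wilcoxon(
                        acc[:, i], acc[:, j], alternative="two-sided", method="exact"
                    ).pvalue
                )
            )
    adj = multipletests(raw, method="fdr_bh")[1]
    mat = np.full((k, k), np.nan)
    for (i, j), q in zip(pairs, adj):
        mat[i, j] = mat[j, i] = q
    return float(stat), float(p), mat


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t test (two-tailed)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (convenience wrapper)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
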
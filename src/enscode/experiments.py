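"""Experiment protocols: training-size and ensemble-size sweeps,
subsampling reliability, top-k stimulus ranking and the animal-vs-human
preference analysis.

Every protocol is a pure function of (cohort, reference readouts, config,
seeds): re-running with the same inputs bit-reproduces all result tables.
The reference readouts passed in play the role of densely-trained
per-subject models; in synthetic studies they are the simulator's oracle
readouts.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from enscode.datamodel import Cohort, DatasetSplit, SplitSizingError, StimulusSet, build_split
from enscode.encoding import ReadoutModel, predict, train_readout
from enscode.ensemble import (
    AverageEnsembleModel,
    LinearEnsembleModel,
    build_loo_ensembles,
    fit_linear_ensemble,
    predict_ensemble,
)
from enscode.evaluation import (
    isc_matrix,
    prediction_accuracy,
    prediction_consistency,
    welch_t,
)

logger = logging.getLogger(__name__)

MODEL_NAMES = ("scratch", "finetuned", "linear_ensemble", "average_ensemble", "oracle")


@dataclass
class SweepResult:
    """Tabular result of a sweep.

    ``cells`` has one row per (seed, train/ensemble size, region, subject,
    model) with the test accuracy; ``stats`` holds per-cell comparison
    statistics (e.g. Wilcoxon vs the reference model);
    ``consistency`` holds per (seed, size) pooled consistency values.
    """

    axis: str  # "train_size" | "ensemble_size"
    grid: list[int]
    cells: pd.DataFrame
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    consistency: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if list(self.grid) != sorted(set(self.grid)):
            raise ValueError("sweep grid must be strictly increasing")


def _stable_key(*parts) -> int:
    """Deterministic across processes (unlike built-in str hashing)."""
    return zlib.crc32("|".join(str(p) for p in parts).encode())


def _derive_seed(base: int, *keys: int) -> int:
    return int(np.random.SeedSequence([base, *keys]).generate_state(1)[0] % (2**31))


def run_train_size_sweep(
    cohort: Cohort,
    reference_readouts: dict[str, dict[str, ReadoutModel]],
    models: set[str],
    grid: list[int],
    seeds: list[int],
    region_ids: list[str] | None = None,
    n_val: int = 50,
    n_test: int = 200,
    hyper=None,
) -> SweepResult:
    """Accuracy of each model at each training-set size, per seed.

    For every seed a fresh split is drawn; scratch and finetuned readouts
    are trained at every grid size, linear ensembles are OLS-fitted at
    every feasible grid size, and the average ensemble (which uses no
    training data) and the reference ("oracle") models are evaluated
    once.  Per (seed, region, size, model) a Wilcoxon signed-rank test of
    the across-subject accuracies against the reference model is
    attached when the reference model is evaluated.  Infeasible grid
    points are skipped with a log entry.
    """
    unknown = set(models) - set(MODEL_NAMES)
    if unknown:
        raise ValueError(f"unknown model names: {sorted(unknown)}")
    regions = region_ids or cohort.region_ids
    rows: list[dict] = []

    for seed in seeds:
        split = build_split(cohort, None, n_val, n_test, seed)
        for g in regions:
            refs = reference_readouts[g]
            ref_list = list(refs.values())
            for s in cohort.subject_ids:
                _, measured, _ = split.test_xy(s, g)
                test_stim = split.cohort.stimuli.subset(split.test_stimulus_ids)
                others = [refs[o] for o in refs if o != s]

                def record(model: str, size: int, predicted: np.ndarray) -> None:
                    rows.append(
                        {
                            "seed": seed,
                            "region_id": g,
                            "subject_id": s,
                            "model": model,
                            "train_size": size,
                            "accuracy": prediction_accuracy(predicted, measured),
                        }
                    )

                if "oracle" in models:
                    record("oracle", -1, predict(refs[s], test_stim))
                if "average_ensemble" in models:
                    avg = AverageEnsembleModel(s, g, [o.subject_id for o in others])
                    record("average_ensemble", 0, predict_ensemble(avg, ref_list, test_stim))
                for n in grid:
                    for model in ("scratch", "finetuned", "linear_ensemble"):
                        if model not in models:
                            continue
                        cell_seed = _derive_seed(seed, _stable_key(model, g, s, n))
                        try:
                            if model == "linear_ensemble":
                                ens = fit_linear_ensemble(
                                    ref_list, split, s, g, n, cell_seed
                                )
                                pred = predict_ensemble(ens, ref_list, test_stim)
                            else:
                                readout, _ = train_readout(
                                    split,
                                    s,
                                    g,
                                    init="random" if model == "scratch" else "group_average",
                                    reference_readouts=None if model == "scratch" else others,
                                    hyper=hyper,
                                    seed=cell_seed,
                                    n_train=n,
                                )
                                pred = predict(readout, test_stim)
                        except SplitSizingError as exc:
                            logger.info(
                                "skipping %s at n=%d for (%s, %s): %s", model, n, s, g, exc
                            )
                            continue
                        record(model, n, pred)

    cells = pd.DataFrame(rows)
    stat_rows: list[dict] = []
    if "oracle" in models and not cells.empty:
        for (seed, g), chunk in cells.groupby(["seed", "region_id"]):
            ref_acc = (
                chunk[chunk["model"] == "oracle"].set_index("subject_id")["accuracy"]
            )
            for (model, n), sub in chunk[chunk["model"] != "oracle"].groupby(
                ["model", "train_size"]
            ):
                acc = sub.set_index("subject_id")["accuracy"].reindex(ref_acc.index)
                if acc.isna().any() or len(acc) < 5:
                    continue
                from enscode.evaluation import compare_to_reference_wilcoxon

                w, p = compare_to_reference_wilcoxon(acc.to_numpy(), ref_acc.to_numpy())
                stat_rows.append(
                    {
                        "seed": seed,
                        "region_id": g,
                        "model": model,
                        "train_size": n,
                        "wilcoxon_statistic": w,
                        "wilcoxon_p": p,
                        "significant_vs_reference": bool(p < 0.05) if np.isfinite(p) else False,
                    }
                )
    return SweepResult(
        axis="train_size", grid=sorted(set(grid)), cells=cells, stats=pd.DataFrame(stat_rows)
    )


def run_ensemble_size_sweep(
    cohort: Cohort,
    reference_readouts: dict[str, dict[str, ReadoutModel]],
    sizes: list[int],
    seeds: list[int],
    n_train: int = 300,
    region_ids: list[str] | None = None,
    n_val: int = 50,
    n_test: int = 200,
) -> SweepResult:
    """Accuracy and consistency as a function of ensemble size.

    For each size m and seed, every query subject's linear ensemble is
    fitted on m references sampled without replacement from the other
    subjects; accuracies are recorded per subject × region, and the
    pooled (across regions) prediction consistency per (seed, m).
    """
    regions = region_ids or cohort.region_ids
    if any(m < 1 for m in sizes):
        raise ValueError("ensemble sizes must be >= 1")
    if any(m > len(cohort.subject_ids) - 1 for m in sizes):
        raise ValueError("ensemble size cannot exceed n_subjects - 1")

    rows: list[dict] = []
    consis_rows: list[dict] = []
    for seed in seeds:
        split = build_split(cohort, None, n_val, n_test, seed)
        for m in sizes:
            isc_pred_mats, isc_meas_mats = [], []
            for g in regions:
                refs = reference_readouts[g]
                ref_list = list(refs.values())
                preds: dict[str, np.ndarray] = {}
                meas: dict[str, np.ndarray] = {}
                test_stim = split.cohort.stimuli.subset(split.test_stimulus_ids)
                for s in cohort.subject_ids:
                    others = [o for o in refs if o != s]
                    rng = np.random.default_rng(_derive_seed(seed, m, _stable_key(g, s)))
                    chosen = sorted(rng.choice(others, size=m, replace=False).tolist())
                    subset = [refs[o] for o in chosen]
                    ens = fit_linear_ensemble(
                        subset, split, s, g, n_train, _derive_seed(seed, m + 1000)
                    )
                    preds[s] = predict_ensemble(ens, subset, test_stim)
                    _, meas[s], _ = split.test_xy(s, g)
                    rows.append(
                        {
                            "seed": seed,
                            "ensemble_size": m,
                            "region_id": g,
                            "subject_id": s,
                            "model": "linear_ensemble",
                            "accuracy": prediction_accuracy(preds[s], meas[s]),
                        }
                    )
                isc_pred_mats.append(isc_matrix(preds, "prediction", g))
                isc_meas_mats.append(isc_matrix(meas, "measurement", g))
            res = prediction_consistency(
                isc_pred_mats, isc_meas_mats, n_permutations=1000, seed=_derive_seed(seed, m)
            )
            consis_rows.append(
                {
                    "seed": seed,
                    "ensemble_size": m,
                    "consistency_r": res.r,
                    "p_one_tailed": res.p_one_tailed,
                    "undefined": res.undefined,
                }
            )
    return SweepResult(
        axis="ensemble_size",
        grid=sorted(set(sizes)),
        cells=pd.DataFrame(rows),
        consistency=pd.DataFrame(consis_rows),
    )


def subsample_reliability(
    split: DatasetSplit,
    metric: str,
    predictions: dict[str, dict[str, np.ndarray]] | None = None,
    n_draws: int = 1000,
    fraction: float = 0.8,
    seed: int = 0,
    region_ids: list[str] | None = None,
) -> dict:
    """Stability of ISC-measurement / consistency under test subsampling.

    Repeatedly subsamples ``fraction`` of the test stimuli and recomputes
    the chosen metric, reporting per-draw relative error against the
    full-data value.  ``metric="isc_measurement"`` tracks the pooled
    pairwise ISC of measured responses (per-draw mean absolute relative
    error over pairs); ``metric="consistency"`` tracks the pooled
    consistency r and needs ``predictions[region][subject]`` aligned to
    the split's test stimuli.  Degenerate draws (undefined correlations)
    are flagged and counted, not silently included.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if metric not in {"isc_measurement", "consistency"}:
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "consistency" and predictions is None:
        raise ValueError("consistency reliability needs model predictions")
    regions = region_ids or split.cohort.region_ids
    n_test = len(split.test_stimulus_ids)
    k = max(3, int(round(fraction * n_test)))
    rng = np.random.default_rng(seed)

    meas = {g: split.test_responses(g) for g in regions}

    def metric_value(idx: np.ndarray) -> float:
        meas_mats = [
            isc_matrix({s: v[idx] for s, v in meas[g].items()}, "measurement", g)
            for g in regions
        ]
        if metric == "isc_measurement":
            return float(np.mean([m.upper_triangle() for m in meas_mats]))
        pred_mats = [
            isc_matrix({s: predictions[g][s][idx] for s in meas[g]}, "prediction", g)
            for g in regions
        ]
        res = prediction_consistency(pred_mats, meas_mats, n_permutations=1, seed=0)
        return float("nan") if res.undefined else res.r

    full_idx = np.arange(n_test)
    full = metric_value(full_idx)
    draws = []
    n_degenerate = 0
    for _ in range(n_draws):
        idx = rng.choice(n_test, size=k, replace=False)
        v = metric_value(np.sort(idx))
        if not np.isfinite(v):
            n_degenerate += 1
            continue
        draws.append(v)
    draws_arr = np.asarray(draws)
    rel_err = np.abs(draws_arr - full) / abs(full) if full != 0 else np.abs(draws_arr - full)
    return {
        "metric": metric,
        "fraction": fraction,
        "full_value": full,
        "n_draws": n_draws,
        "n_degenerate": n_degenerate,
        "values": draws_arr,
        "relative_errors": rel_err,
        "mean_relative_error": float(rel_err.mean()) if len(rel_err) else float("nan"),
        "cv": float(draws_arr.std() / abs(draws_arr.mean()))
        if len(draws_arr) and draws_arr.mean() != 0
        else float("nan"),
    }


def top_k_stimuli(predictor, stimuli: StimulusSet, k: int) -> list[str]:
    """IDs of the k stimuli with the highest predicted response.

    ``predictor`` is a ReadoutModel or any callable mapping a StimulusSet
    to a response vector.  Ties are broken by lexicographic stimulus_id,
    so constant predictors rank alphabetically.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > stimuli.n_stimuli:
        raise ValueError(f"k={k} exceeds the {stimuli.n_stimuli} available stimuli")
    scores = predictor(stimuli) if callable(predictor) else predict(predictor, stimuli)
    order = sorted(range(stimuli.n_stimuli), key=lambda i: (-scores[i], str(stimuli.ids[i])))
    return [str(stimuli.ids[i]) for i in order[:k]]


@dataclass
class PreferenceResult:
    """Per subject × region animal-vs-human preference readings."""

    subject_id: str
    region_id: str
    t_stat: float
    ratio: float


def preference_ratio(labels: list[str]) -> float:
    """(n_animal - n_human) / (n_animal + n_human); NaN when neither occurs."""
    n_a = sum(1 for x in labels if x == "animal_face")
    n_h = sum(1 for x in labels if x == "human_face")
    if n_a + n_h == 0:
        return float("nan")
    return (n_a - n_h) / (n_a + n_h)


def preference_analysis(
    split: DatasetSplit,
    ensembles: dict[str, dict[str, LinearEnsembleModel | AverageEnsembleModel]],
    reference_readouts: dict[str, dict[str, ReadoutModel]],
    face_regions: list[str],
    k: int = 10,
) -> tuple[list[PreferenceResult], float, float]:
    """Do model-preferred stimuli track measured category preferences?

    Per subject × face region: (1) Welch's t on the measured test
    responses to animal_face vs human_face stimuli, and (2) the
    animal-vs-human ratio within the model's top-k predicted stimuli.
    Returns the per-point results plus the Pearson r (two-tailed p)
    between t-statistics and ratios across all retained points; points
    whose top-k contains neither label are dropped with a warning.
    """
    stimuli = split.cohort.stimuli
    if stimuli.labels is None:
        raise ValueError("preference analysis requires labeled stimuli")
    test_stim = stimuli.subset(split.test_stimulus_ids)
    label_by_id = dict(zip(test_stim.ids, test_stim.labels))

    results: list[PreferenceResult] = []
    for g in face_regions:
        ref_list = list(reference_readouts[g].values())
        for s, model in ensembles[g].items():
            _, measured, ids = split.test_xy(s, g)
            lab = np.array([label_by_id[i] for i in ids], dtype=object)
            a = measured[lab == "animal_face"]
            h = measured[lab == "human_face"]
            if len(a) < 2 or len(h) < 2:
                logger.warning("(%s, %s): too few labeled test stimuli; dropped", s, g)
                continue
            t, _ = welch_t(a, h)
            top = top_k_stimuli(
                lambda st, m=model, rl=ref_list: predict_ensemble(m, rl, st), test_stim, k
            )
            ratio = preference_ratio([label_by_id[i] for i in top])
            if not np.isfinite(ratio):
                logger.warning(
                    "(%s, %s): top-%d contains no animal/human faces; dropped", s, g, k
                )
                continue
            results.append(PreferenceResult(s, g, t, ratio))
    if len(results) < 3:
        return results, float("nan"), float("nan")
    t_vals = np.array([r.t_stat for r in results])
    ratios = np.array([r.ratio for r in results])
    if t_vals.std() == 0.0 or ratios.std() == 0.0:
        return results, float("nan"), float("nan")
    r, p = stats.pearsonr(t_vals, ratios)
    return results, float(r), float(p)
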
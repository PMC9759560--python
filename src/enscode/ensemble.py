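"""Linear and average ensembles of reference subjects' encoding models.

The linear ensemble predicts a query subject *i*'s response to stimulus S
as an intercept plus a weighted sum of reference subjects' encoding-model
predictions,

    LE_i(S) = beta_{i,0} + sum_{j in refs} beta_{i,j} * rhat_j(S),

with the coefficients fitted by ordinary least squares against the query
subject's *single-trial* measured training responses on a seeded random
sample of training stimuli.  The average ensemble needs no data from the
query subject at all: it is the unweighted mean of the reference
predictions.  Within a cohort, ensembles are built leave-one-out (each
subject's references are all the other subjects); for an out-of-cohort
query every reference readout is used.

The design matrix is not standardized before OLS — the reference
predictions share units — and rank-deficient designs (e.g. duplicated
reference models) are solved by the minimum-norm least-squares solution
with a logged warning rather than failing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from enscode.datamodel import DatasetSplit, SplitSizingError, StimulusSet
from enscode.encoding import ReadoutModel, predict

logger = logging.getLogger(__name__)


@dataclass
class LinearEnsembleModel:
    """OLS-fitted linear combination of reference model predictions."""

    query_subject: str
    region_id: str
    reference_subjects: list[str]
    intercept: float
    coefficients: np.ndarray
    n_train_used: int = 0
    leave_one_out: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        if len(self.coefficients) != len(self.reference_subjects):
            raise ValueError(
                f"{len(self.coefficients)} coefficients for "
                f"{len(self.reference_subjects)} reference subjects"
            )
        if self.leave_one_out and self.query_subject in self.reference_subjects:
            raise ValueError(
                f"query subject {self.query_subject!r} appears in its own reference set"
            )


@dataclass
class AverageEnsembleModel:
    """Unweighted mean of reference model predictions (zero training data)."""

    query_subject: str
    region_id: str
    reference_subjects: list[str]

    def __post_init__(self) -> None:
        if len(self.reference_subjects) < 1:
            raise ValueError("average ensemble requires at least one reference subject")


def _reference_matrix(
    reference_readouts: list[ReadoutModel],
    reference_subjects: list[str],
    region_id: str,
    features: np.ndarray,
) -> np.ndarray:
    """Columns = each reference subject's predictions on the feature rows."""
    by_subject = {
        r.subject_id: r for r in reference_readouts if r.region_id == region_id
    }
    cols = []
    for s in reference_subjects:
        if s not in by_subject:
            raise KeyError(
                f"no readout for reference subject {s!r} in region {region_id!r}"
            )
        r = by_subject[s]
        cols.append(features @ r.weights + r.bias)
    return np.column_stack(cols)


def fit_linear_ensemble(
    reference_readouts: list[ReadoutModel],
    split: DatasetSplit,
    query_subject: str,
    region_id: str,
    n_train: int,
    seed: int,
    leave_one_out: bool = True,
) -> LinearEnsembleModel:
    """Fit ensemble coefficients by OLS on the query's single-trial data.

    ``n_train`` single-trial (stimulus, repeat) training entries of the
    query subject are sampled without replacement with ``seed``; the
    design matrix holds the reference readouts' predictions on those
    stimuli plus an intercept column, and the target is the query's
    measured single-trial responses (never repeat-averaged).  Solved by
    minimum-norm least squares; a rank-deficient design logs a warning.
    """
    reference_subjects = [r.subject_id for r in reference_readouts if r.region_id == region_id]
    if leave_one_out:
        reference_subjects = [s for s in reference_subjects if s != query_subject]
    p = len(reference_subjects)
    if p < 1:
        raise ValueError(f"no reference readouts for region {region_id!r}")
    if n_train < p + 1:
        raise SplitSizingError(
            f"n_train={n_train} is below the {p + 1} samples needed to fit "
            f"{p} coefficients plus an intercept"
        )
    rng = np.random.default_rng(seed)
    X_feat, y, _ = split.train_xy(query_subject, region_id, limit=n_train, rng=rng)
    R = _reference_matrix(reference_readouts, reference_subjects, region_id, X_feat)
    design = np.column_stack([np.ones(len(y)), R])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        logger.warning(
            "rank-deficient ensemble design (rank %d < %d) for (%s, %s); "
            "using minimum-norm least squares",
            rank,
            design.shape[1],
            query_subject,
            region_id,
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return LinearEnsembleModel(
        query_subject=query_subject,
        region_id=region_id,
        reference_subjects=reference_subjects,
        intercept=float(beta[0]),
        coefficients=beta[1:],
        n_train_used=len(y),
        leave_one_out=leave_one_out,
    )


def predict_ensemble(
    model: LinearEnsembleModel | AverageEnsembleModel,
    reference_readouts: list[ReadoutModel],
    stimuli: StimulusSet,
) -> np.ndarray:
    """Evaluate an ensemble on a stimulus set, order-preserving."""
    R = _reference_matrix(
        reference_readouts, model.reference_subjects, model.region_id, stimuli.features
    )
    if isinstance(model, LinearEnsembleModel):
        return model.intercept + R @ model.coefficients
    return R.mean(axis=1)


def build_loo_ensembles(
    cohort_readouts: dict[str, ReadoutModel],
    split: DatasetSplit,
    region_id: str,
    n_train: int,
    seed: int,
) -> dict[str, LinearEnsembleModel]:
    """One leave-one-out linear ensemble per subject.

    Each subject's ensemble is fitted from the other subjects' readouts
    only.  Per-subject fitting seeds are spawned deterministically from
    ``seed`` in subject order, so the whole map is reproducible.
    """
    subjects = list(cohort_readouts)
    if len(subjects) < 2:
        raise ValueError("leave-one-out ensembles need at least 2 subjects with readouts")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(subjects)) % (2**31)
    readout_list = [cohort_readouts[s] for s in subjects]
    out: dict[str, LinearEnsembleModel] = {}
    for s, child in zip(subjects, child_seeds):
        out[s] = fit_linear_ensemble(
            readout_list, split, s, region_id, n_train, int(child), leave_one_out=True
        )
    return out
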
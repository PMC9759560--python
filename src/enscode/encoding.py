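"""Per-subject, per-region linear readout encoding models.

A readout maps a stimulus feature vector to one region's scalar response,
``response = w · f(S) + b``.  Readouts are trained by mini-batch gradient
descent on the mean squared error over single-trial training responses
(batch size 32 by default), with early stopping when the Pearson
correlation between predicted and measured responses on the repeat-
averaged validation set stops improving; the weights at the best
validation correlation are returned.  Two initialization modes are
supported: ``random`` (weights ~ N(0, 1/d)) for scratch/dense training,
and ``group_average`` (the element-wise mean of reference subjects'
readouts) for fine-tuning-style warm starts.

The feature extractor is deliberately outside the trainable path:
features are fixed inputs, so a "readout" here plays the role of the
final linear layer of a deep encoding model whose backbone is frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from enscode.datamodel import DatasetSplit, StimulusSet


@dataclass
class ReadoutModel:
    """Linear map from stimulus features to one region's response."""

    subject_id: str
    region_id: str
    weights: np.ndarray
    bias: float
    init_mode: str = "random"  # "random" | "group_average" | "oracle"
    n_train_used: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.bias = float(self.bias)
        if not np.all(np.isfinite(self.weights)) or not math.isfinite(self.bias):
            raise ValueError(
                f"readout ({self.subject_id}, {self.region_id}) has non-finite parameters"
            )


@dataclass
class TrainingTrace:
    """One epoch of training: MSE on train, Pearson r on validation.

    ``val_correlation`` is NaN when the validation responses have zero
    variance (correlation undefined).
    """

    epoch: int
    train_mse: float
    val_correlation: float


@dataclass
class TrainingConfig:
    """Hyper-parameters for readout training.

    lr : gradient-descent step size.
    batch_size : mini-batch size (32, the convention for this model family).
    max_epochs : hard epoch budget; also the fallback budget when the
        validation correlation is undefined.
    patience : number of validation evaluations (one per epoch) without
        improvement before stopping.
    optimizer : "sgd" (plain mini-batch gradient descent, the default for
        reproducibility) or "adam" (adaptive moments).
    """

    lr: float = 0.03
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 10
    optimizer: str = "sgd"

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainingConfig":
        import json

        return cls(**json.loads(Path(path).read_text()))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def random_init(d: int, rng: np.random.Generator) -> np.ndarray:
    """Random readout weights, Normal(0, 1/d) so w·f has unit-order scale."""
    return rng.normal(0.0, 1.0 / math.sqrt(d), size=d)


def group_average_readout(readouts: list[ReadoutModel]) -> ReadoutModel:
    """Element-wise mean of reference readouts (weights and biases).

    All readouts must share the region and feature dimension.  This is
    the warm start used for fine-tuned models: initialize a new subject's
    readout at the average of the densely-trained reference readouts.
    """
    if not readouts:
        raise ValueError("group_average_readout requires at least one readout")
    d = readouts[0].weights.shape[0]
    region = readouts[0].region_id
    for r in readouts:
        if r.weights.shape[0] != d:
            raise ValueError(
                f"mixed feature dimensions: {d} vs {r.weights.shape[0]} "
                f"(subject {r.subject_id!r})"
            )
        if r.region_id != region:
            raise ValueError(f"mixed regions: {region!r} vs {r.region_id!r}")
    w = np.mean([r.weights for r in readouts], axis=0)
    b = float(np.mean([r.bias for r in readouts]))
    return ReadoutModel(
        subject_id="group_average",
        region_id=region,
        weights=w,
        bias=b,
        init_mode="group_average",
    )


def predict(readout: ReadoutModel, stimuli: StimulusSet) -> np.ndarray:
    """Predicted responses ``w·f + b`` for each stimulus, order-preserving."""
    if stimuli.feature_dim != readout.weights.shape[0]:
        raise ValueError(
            f"feature dim mismatch: stimuli have d={stimuli.feature_dim}, "
            f"readout expects d={readout.weights.shape[0]}"
        )
    return stimuli.features @ readout.weights + readout.bias


def train_readout(
    split: DatasetSplit,
    subject_id: str,
    region_id: str,
    init: str = "random",
    reference_readouts: list[ReadoutModel] | None = None,
    hyper: TrainingConfig | None = None,
    seed: int = 0,
    n_train: int | None = None,
) -> tuple[ReadoutModel, list[TrainingTrace]]:
    """Train one subject × region readout on single-trial responses.

    Mini-batch gradient descent on MSE; each epoch ends with a Pearson
    correlation check on the repeat-averaged validation set.  Training
    stops when the correlation has not improved for ``hyper.patience``
    evaluations and the weights at the best correlation are returned.
    When the validation responses have zero variance the correlation is
    undefined (flagged NaN in the trace) and training falls back to the
    fixed ``max_epochs`` budget, returning the final weights.

    ``n_train`` caps the number of single-trial samples used (sampled
    without replacement with ``seed``), emulating small-data regimes.
    Deterministic given (split, init, seed, hyper).
    """
    hyper = hyper or TrainingConfig()
    ss = np.random.SeedSequence(seed)
    init_rng, sample_rng, batch_rng = (np.random.default_rng(c) for c in ss.spawn(3))

    X, y, _ = split.train_xy(subject_id, region_id, limit=n_train, rng=sample_rng)
    if len(y) == 0:
        raise ValueError(f"empty training set for ({subject_id!r}, {region_id!r})")
    Xv, yv, _ = split.validation_xy(subject_id, region_id)
    d = X.shape[1]

    if init == "group_average":
        if not reference_readouts:
            raise ValueError("group_average init requires reference_readouts")
        g = group_average_readout(reference_readouts)
        if g.weights.shape[0] != d:
            raise ValueError("reference readouts do not match the cohort feature dimension")
        w, b = g.weights.copy(), g.bias
    elif init == "random":
        w, b = random_init(d, init_rng), 0.0
    else:
        raise ValueError(f"unknown init mode {init!r}")

    n = len(y)
    val_defined = np.std(yv) > 0.0 if len(yv) else False
    best_corr = -np.inf
    best_w, best_b, stale = w.copy(), b, 0
    traces: list[TrainingTrace] = []

    # adam state (unused for plain sgd)
    m_w = np.zeros(d)
    v_w = np.zeros(d)
    m_b = v_b = 0.0
    t_step = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    for epoch in range(hyper.max_epochs):
        order = batch_rng.permutation(n)
        for start in range(0, n, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            Xb, yb = X[idx], y[idx]
            resid = Xb @ w + b - yb
            gw = (2.0 / len(idx)) * (Xb.T @ resid)
            gb = (2.0 / len(idx)) * resid.sum()
            if hyper.optimizer == "adam":
                t_step += 1
                m_w = beta1 * m_w + (1 - beta1) * gw
                v_w = beta2 * v_w + (1 - beta2) * gw**2
                m_b = beta1 * m_b + (1 - beta1) * gb
                v_b = beta2 * v_b + (1 - beta2) * gb**2
                mh_w = m_w / (1 - beta1**t_step)
                vh_w = v_w / (1 - beta2**t_step)
                mh_b = m_b / (1 - beta1**t_step)
                vh_b = v_b / (1 - beta2**t_step)
                w = w - hyper.lr * mh_w / (np.sqrt(vh_w) + eps)
                b = b - hyper.lr * mh_b / (np.sqrt(vh_b) + eps)
            else:
                w = w - hyper.lr * gw
                b = b - hyper.lr * gb

        train_mse = float(np.mean((X @ w + b - y) ** 2))
        val_corr = _pearson(Xv @ w + b, yv) if val_defined else float("nan")
        traces.append(TrainingTrace(epoch=epoch, train_mse=train_mse, val_correlation=val_corr))

        if val_defined:
            if val_corr > best_corr:
                best_corr, best_w, best_b, stale = val_corr, w.copy(), b, 0
            else:
                stale += 1
                if stale >= hyper.patience:
                    break
        else:
            best_w, best_b = w.copy(), b  # fixed-budget fallback

    model = ReadoutModel(
        subject_id=subject_id,
        region_id=region_id,
        weights=best_w,
        bias=best_b,
        init_mode=init,
        n_train_used=n,
    )
    return model, traces


# ---------------------------------------------------------------------------
# serialization


def save_readouts(readouts: list[ReadoutModel], path: str | Path) -> Path:
    """Write readouts as a delimited table (subject, region, bias, w0..)."""
    path = Path(path)
    d = readouts[0].weights.shape[0]
    rows = []
    for r in sorted(readouts, key=lambda r: (r.subject_id, r.region_id)):
        if r.weights.shape[0] != d:
            raise ValueError("cannot serialize readouts with mixed feature dimensions")
        rows.append(
            {
                "subject_id": r.subject_id,
                "region_id": r.region_id,
                "init_mode": r.init_mode,
                "n_train_used": r.n_train_used,
                "bias": r.bias,
                **{f"w{i}": r.weights[i] for i in range(d)},
            }
        )
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    return path


def load_readouts(path: str | Path) -> list[ReadoutModel]:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    wcols = sorted(
        [c for c in df.columns if c.startswith("w") and c[1:].isdigit()],
        key=lambda c: int(c[1:]),
    )
    out = []
    for _, row in df.iterrows():
        out.append(
            ReadoutModel(
                subject_id=str(row["subject_id"]),
                region_id=str(row["region_id"]),
                weights=row[wcols].to_numpy(dtype=float),
                bias=float(row["bias"]),
                init_mode=str(row.get("init_mode", "random")),
                n_train_used=int(row.get("n_train_used", 0)),
            )
        )
    return out
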
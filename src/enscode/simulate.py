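"""Synthetic multi-subject cohorts with controlled shared / idiosyncratic
structure.

The generator emulates the statistical skeleton of a densely-sampled
visual fMRI cohort: every subject's region response is driven by a
stimulus feature vector through a linear tuning profile that decomposes
into a component shared by the whole cohort and a subject-idiosyncratic
offset,

    r_j(S) = (w_g + u_j) . f(S),        w_g ~ N(0, sigma_g^2/d I),
                                        u_j ~ N(0, sigma_u^2/d I),

and each of 1-3 repeated measurements adds i.i.d. Gaussian noise
eps ~ N(0, sigma_eps^2).  Features are i.i.d. standard normal, so the
noiseless single-trial signal variance is sigma_g^2 + sigma_u^2 and all
the closed-form noise-ceiling and accuracy targets used in the tests
follow from variance bookkeeping.  A designated query subject can
optionally be constructed as a *known* linear mixture of the other
subjects' signals (intercept* + sum beta*_j r_j), giving ground truth
for ensemble-coefficient recovery.

Default parameters describe the regime the framework targets: regional
tuning is largely conserved across individuals (sigma_g = 1.0) with a
real but modest idiosyncratic component (sigma_u = 0.2, ~4% of signal
variance — enough to carry reliable inter-individual differences above
test-set sampling noise) and single-trial measurement noise of the same
order as the signal (sigma_eps = 0.7, SNR ~ 2), with 8 subjects, 4
regions and 3 repeats per stimulus as in densely-sampled designs.  The
feature space is deliberately low-dimensional (d = 8) so that the 7
reference tuning vectors of a leave-one-out ensemble span most of a
novel subject's predictable signal — the regime in which ensembles of
existing models rival a densely-trained individual model.

Seeding uses one named RNG stream per concern (features, readouts,
noise, labels) so that e.g. changing the number of repeats does not
perturb the stimulus features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from enscode.datamodel import Cohort, StimulusSet
from enscode.encoding import ReadoutModel

LABEL_VOCABULARY = ["animal_face", "human_face", "other"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    n_subjects, n_regions : cohort dimensions.
    n_stimuli : total distinct stimuli; the first ``n_shared_stimuli``
        are shown to every subject, the remainder are partitioned
        round-robin as subject-exclusive stimuli.
    feature_dim : length d of the abstract stimulus feature vectors.
    shared_signal_sd / idiosyncratic_signal_sd / noise_sd :
        sigma_g, sigma_u, sigma_eps above (response units).
    repeats : measurements per (subject, stimulus), 1-3.
    query_mixing : optional (intercept*, beta* vector of length
        n_subjects-1); when set, the last subject's noiseless signal is
        that fixed linear mixture of the other subjects' signals.
    label_fractions : optional (frac_animal, frac_human); labeled
        stimuli get a feature bump of ``face_contrast`` on feature 0
        (animal) or 1 (human), and per subject x region preference
        offsets ~ N(0, face_preference_sd^2) are added to those two
        weights, planting recoverable inter-individual preferences.
    noise_df : degrees of freedom for Student-t measurement noise
        (None = Gaussian), for heavier-tailed robustness checks.
    """

    n_subjects: int = 8
    n_regions: int = 4
    n_stimuli: int = 1000
    n_shared_stimuli: int = 300
    feature_dim: int = 8
    shared_signal_sd: float = 1.0
    idiosyncratic_signal_sd: float = 0.2
    noise_sd: float = 0.7
    repeats: int = 3
    query_mixing: tuple[float, list[float]] | None = None
    label_fractions: tuple[float, float] | None = None
    face_contrast: float = 2.0
    face_preference_sd: float = 0.0
    noise_df: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shared_signal_sd, self.idiosyncratic_signal_sd, self.noise_sd) < 0:
            raise ValueError("signal/noise standard deviations must be >= 0")
        if not 0 < self.n_shared_stimuli <= self.n_stimuli:
            raise ValueError("need 0 < n_shared_stimuli <= n_stimuli")
        if self.repeats not in (1, 2, 3):
            raise ValueError("repeats must be 1, 2 or 3")
        if self.query_mixing is not None:
            _, beta = self.query_mixing
            if len(beta) != self.n_subjects - 1:
                raise ValueError("query_mixing beta must have length n_subjects - 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        raw = json.loads(Path(path).read_text())
        if raw.get("query_mixing") is not None:
            icpt, beta = raw["query_mixing"]
            raw["query_mixing"] = (float(icpt), list(map(float, beta)))
        if raw.get("label_fractions") is not None:
            raw["label_fractions"] = tuple(raw["label_fractions"])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Latent quantities behind a synthetic cohort.

    ``weights[region][subject]`` is that subject's noiseless tuning
    vector w_g + u_j (for a mixed query subject, the induced mixture
    vector); ``biases`` likewise.  ``shared_weights[region]`` is w_g.
    """

    config: SyntheticConfig
    weights: dict[str, dict[str, np.ndarray]]
    biases: dict[str, dict[str, float]]
    shared_weights: dict[str, np.ndarray]
    query_subject: str | None = None
    mixing: tuple[float, np.ndarray] | None = None
    subject_ids: list[str] = field(default_factory=list)
    region_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "subject_ids": self.subject_ids,
            "region_ids": self.region_ids,
            "query_subject": self.query_subject,
            "mixing": None
            if self.mixing is None
            else [self.mixing[0], list(map(float, self.mixing[1]))],
            "weights": {
                g: {s: list(map(float, w)) for s, w in by_s.items()}
                for g, by_s in self.weights.items()
            },
            "biases": self.biases,
            "shared_weights": {g: list(map(float, w)) for g, w in self.shared_weights.items()},
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


def _subject_ids(n: int) -> list[str]:
    return [f"S{i + 1}" for i in range(n)]


def _region_ids(n: int) -> list[str]:
    canonical = ["FFA1", "EBA", "PPA", "V1v", "OFA", "FFA2"]
    return canonical[:n] + [f"R{i + 1}" for i in range(len(canonical), n)]


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a synthetic cohort and its ground truth, deterministically."""
    cfg = config
    d = cfg.feature_dim
    ss = np.random.SeedSequence(cfg.seed)
    feat_rng, readout_rng, noise_rng, label_rng = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    subjects = _subject_ids(cfg.n_subjects)
    regions = _region_ids(cfg.n_regions)
    stim_ids = np.array([f"stim{i:05d}" for i in range(cfg.n_stimuli)], dtype=object)
    features = feat_rng.standard_normal((cfg.n_stimuli, d))

    labels = None
    vocab: list[str] = []
    if cfg.label_fractions is not None:
        fa, fh = cfg.label_fractions
        u = label_rng.random(cfg.n_stimuli)
        labels = np.where(u < fa, "animal_face", np.where(u < fa + fh, "human_face", "other"))
        labels = labels.astype(object)
        vocab = list(LABEL_VOCABULARY)
        if d < 2:
            raise ValueError("labeled cohorts need feature_dim >= 2")
        features = features.copy()
        features[labels == "animal_face", 0] += cfg.face_contrast
        features[labels == "human_face", 1] += cfg.face_contrast

    shared = np.zeros(cfg.n_stimuli, dtype=bool)
    shared[: cfg.n_shared_stimuli] = True
    stimuli = StimulusSet(
        ids=stim_ids, features=features, labels=labels, shared=shared, label_vocabulary=vocab
    )

    # round-robin assignment of exclusive stimuli
    seen_by: dict[str, list[int]] = {s: list(range(cfg.n_shared_stimuli)) for s in subjects}
    for k, idx in enumerate(range(cfg.n_shared_stimuli, cfg.n_stimuli)):
        seen_by[subjects[k % cfg.n_subjects]].append(idx)

    weights: dict[str, dict[str, np.ndarray]] = {}
    biases: dict[str, dict[str, float]] = {}
    shared_w: dict[str, np.ndarray] = {}
    for g in regions:
        w_g = readout_rng.normal(0.0, cfg.shared_signal_sd / np.sqrt(d), size=d)
        shared_w[g] = w_g
        weights[g] = {}
        biases[g] = {}
        for s in subjects:
            u_j = readout_rng.normal(0.0, cfg.idiosyncratic_signal_sd / np.sqrt(d), size=d)
            w = w_g + u_j
            if cfg.face_preference_sd > 0 and labels is not None:
                w = w.copy()
                w[0] += readout_rng.normal(0.0, cfg.face_preference_sd)
                w[1] += readout_rng.normal(0.0, cfg.face_preference_sd)
            weights[g][s] = w
            biases[g][s] = 0.0

    query_subject = None
    mixing = None
    if cfg.query_mixing is not None:
        icpt, beta = cfg.query_mixing
        beta = np.asarray(beta, dtype=float)
        query_subject = subjects[-1]
        refs = subjects[:-1]
        for g in regions:
            weights[g][query_subject] = np.sum(
                [b * weights[g][s] for b, s in zip(beta, refs)], axis=0
            )
            biases[g][query_subject] = float(icpt)
        mixing = (float(icpt), beta)

    rows = []
    for s in subjects:
        idx = np.asarray(seen_by[s], dtype=int)
        F = features[idx]
        for g in regions:
            signal = F @ weights[g][s] + biases[g][s]
            for rep in range(cfg.repeats):
                if cfg.noise_df is not None:
                    eps = noise_rng.standard_t(cfg.noise_df, size=len(idx)) * cfg.noise_sd
                else:
                    eps = noise_rng.normal(0.0, cfg.noise_sd, size=len(idx))
                obs = signal + eps
                rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": s,
                            "region_id": g,
                            "stimulus_id": stim_ids[idx],
                            "repeat_index": rep,
                            "response": obs,
                        }
                    )
                )
    responses = pd.concat(rows, ignore_index=True)
    cohort = Cohort(
        stimuli=stimuli, responses=responses, subject_ids=subjects, region_ids=regions
    )
    truth = GroundTruth(
        config=cfg,
        weights=weights,
        biases=biases,
        shared_weights=shared_w,
        query_subject=query_subject,
        mixing=mixing,
        subject_ids=subjects,
        region_ids=regions,
    )
    return cohort, truth


def oracle_readouts(
    ground_truth: GroundTruth, region_id: str | None = None
) -> dict[str, ReadoutModel] | dict[str, dict[str, ReadoutModel]]:
    """Export the latent tuning vectors as noiseless ReadoutModels.

    These are the desk-scale surrogate for reference models trained on a
    subject's full densely-sampled dataset.  With ``region_id`` given,
    returns subject → ReadoutModel for that region; otherwise a nested
    region → subject → ReadoutModel map.
    """

    def for_region(g: str) -> dict[str, ReadoutModel]:
        return {
            s: ReadoutModel(
                subject_id=s,
                region_id=g,
                weights=ground_truth.weights[g][s],
                bias=ground_truth.biases[g][s],
                init_mode="oracle",
            )
            for s in ground_truth.subject_ids
        }

    if region_id is not None:
        return for_region(region_id)
    return {g: for_region(g) for g in ground_truth.region_ids}
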
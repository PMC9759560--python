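"""Cohort data structures, dataset splits and on-disk formats.

A *cohort* is a multi-subject stimulus–response table: per
(subject, region, stimulus, repeat) one scalar response (a GLM-beta-like
value, arbitrary units) together with a per-stimulus feature vector and an
optional category label.  Splits follow the densely-sampled fMRI
convention: training points are single-trial responses (never averaged),
while validation and test responses are the mean of exactly two repeats —
when a stimulus was measured three times, two of the three repeats are
chosen at random (seeded) so that the signal-to-noise properties are
homogeneous across stimuli.  Test stimuli are drawn from the stimuli
shared across all subjects, so the same test set supports inter-subject
comparisons.

On disk a cohort is two headered delimited tables (CSV or TSV, chosen by
file extension) plus a JSON manifest; rows are written in a fixed sort
order so saves are byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

RESPONSE_COLUMNS = ["subject_id", "region_id", "stimulus_id", "repeat_index", "response"]


class CohortValidationError(ValueError):
    """A cohort table violates an invariant.

    ``violations`` enumerates the offending rows/keys so callers can fix
    their tables.
    """

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("cohort validation failed:\n  " + "\n  ".join(self.violations))


class SplitSizingError(ValueError):
    """Not enough eligible stimuli to build the requested split."""


def _feature_columns(d: int) -> list[str]:
    return [f"f{i}" for i in range(d)]


@dataclass
class StimulusSet:
    """Stimuli with feature vectors and optional category labels.

    Parameters
    ----------
    ids
        Unique stimulus identifiers, length n.
    features
        Array (n, d) of abstract feature values (stand-ins for the image
        features an encoding model's backbone would extract).
    labels
        Optional length-n array of category strings (e.g. ``animal_face``,
        ``human_face``, ``other``); ``None`` when unlabeled.
    shared
        Boolean length-n mask: stimulus available to every subject.
    label_vocabulary
        Closed vocabulary for ``labels``; inferred when omitted.
    """

    ids: np.ndarray
    features: np.ndarray
    labels: np.ndarray | None = None
    shared: np.ndarray | None = None
    label_vocabulary: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.features = np.asarray(self.features, dtype=float)
        n = len(self.ids)
        violations: list[str] = []
        if self.features.ndim != 2 or self.features.shape[0] != n:
            raise CohortValidationError(
                [f"features must be (n_stimuli, d); got {self.features.shape} for {n} stimuli"]
            )
        if self.features.shape[1] < 1:
            violations.append("feature dimension must be positive")
        if len(np.unique(self.ids)) != n:
            dup = pd.Series(self.ids).value_counts()
            violations.extend(f"duplicate stimulus_id {s!r}" for s in dup[dup > 1].index)
        if not np.all(np.isfinite(self.features)):
            violations.append("non-finite feature values")
        if self.shared is None:
            self.shared = np.ones(n, dtype=bool)
        else:
            self.shared = np.asarray(self.shared, dtype=bool)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if not self.label_vocabulary:
                self.label_vocabulary = sorted({str(x) for x in self.labels if not pd.isna(x)})
            bad = {
                str(x)
                for x in self.labels
                if not pd.isna(x) and str(x) not in self.label_vocabulary
            }
            violations.extend(f"label {b!r} outside vocabulary" for b in sorted(bad))
        if violations:
            raise CohortValidationError(violations)
        self._index = {s: i for i, s in enumerate(self.ids)}

    @property
    def n_stimuli(self) -> int:
        return len(self.ids)

    @property
    def feature_dim(self) -> int:
        return int(self.features.shape[1])

    def features_for(self, stimulus_ids: Sequence[str]) -> np.ndarray:
        """Feature matrix for the given stimuli, order-preserving."""
        idx = [self._index[s] for s in stimulus_ids]
        return self.features[idx]

    def subset(self, stimulus_ids: Sequence[str]) -> "StimulusSet":
        idx = [self._index[s] for s in stimulus_ids]
        return StimulusSet(
            ids=self.ids[idx],
            features=self.features[idx],
            labels=None if self.labels is None else self.labels[idx],
            shared=self.shared[idx],
            label_vocabulary=list(self.label_vocabulary),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=_feature_columns(self.feature_dim))
        df.insert(0, "stimulus_id", self.ids)
        df.insert(1, "shared", self.shared.astype(int))
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        return df


@dataclass
class Cohort:
    """A multi-subject stimulus–response dataset.

    ``responses`` is a long-format table with columns
    (subject_id, region_id, stimulus_id, repeat_index, response); the key
    (subject, region, stimulus, repeat) is unique and every response is
    finite.  ``subject_ids`` / ``region_ids`` fix the canonical ordering
    used throughout (reference-subject order of ensemble coefficients,
    ISC matrix order, ...).
    """

    stimuli: StimulusSet
    responses: pd.DataFrame
    subject_ids: list[str]
    region_ids: list[str]

    def __post_init__(self) -> None:
        self.responses = self.responses[RESPONSE_COLUMNS].copy()
        self.responses["repeat_index"] = self.responses["repeat_index"].astype(int)
        self.responses["response"] = self.responses["response"].astype(float)
        self.validate()

    def validate(self) -> None:
        violations: list[str] = []
        r = self.responses
        dup = r.duplicated(subset=["subject_id", "region_id", "stimulus_id", "repeat_index"])
        if dup.any():
            for _, row in r[dup].iterrows():
                violations.append(
                    "duplicate response key "
                    f"({row.subject_id}, {row.region_id}, {row.stimulus_id}, {row.repeat_index})"
                )
        bad = ~np.isfinite(r["response"].to_numpy())
        if bad.any():
            for i in np.flatnonzero(bad)[:10]:
                row = r.iloc[i]
                violations.append(
                    f"non-finite response at ({row.subject_id}, {row.region_id}, "
                    f"{row.stimulus_id}, {row.repeat_index})"
                )
        known = set(self.stimuli.ids)
        unknown = set(r["stimulus_id"]) - known
        violations.extend(f"response references unknown stimulus {s!r}" for s in sorted(unknown))
        present = r.groupby(["subject_id", "region_id"]).size()
        for s in self.subject_ids:
            for g in self.region_ids:
                if (s, g) not in present.index:
                    violations.append(f"subject {s!r} has no records for region {g!r}")
        counts = r.groupby(["subject_id", "stimulus_id"])["repeat_index"].nunique()
        over = counts[counts > 3]
        for (s, st), k in over.items():
            violations.append(f"subject {s!r} stimulus {st!r} has {k} repeats (max 3)")
        if violations:
            raise CohortValidationError(violations)

    @property
    def feature_dim(self) -> int:
        return self.stimuli.feature_dim

    def repeat_counts(self) -> pd.Series:
        """Repeats per (subject_id, stimulus_id), regions collapsed."""
        return self.responses.groupby(["subject_id", "stimulus_id"])["repeat_index"].nunique()


@dataclass
class DatasetSplit:
    """Train / validation / test views of a cohort.

    ``train`` lists single-trial (subject, stimulus, repeat) entries;
    ``validation`` and ``test`` hold repeat-averaged responses (mean of
    exactly two repeats) in long format
    (subject_id, region_id, stimulus_id, response).  Test stimuli are
    identical across subjects.  The split keeps a reference to its source
    cohort so design matrices can be assembled directly.
    """

    cohort: Cohort
    train: pd.DataFrame
    validation: pd.DataFrame
    test: pd.DataFrame
    test_stimulus_ids: list[str]
    rng_seed: int

    def train_xy(
        self, subject_id: str, region_id: str, limit: int | None = None, rng=None
    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Single-trial training design for one subject × region.

        Returns (features X, responses y, stimulus ids).  When ``limit``
        is given, rows are subsampled without replacement with ``rng``.
        """
        t = self.train[self.train["subject_id"] == subject_id]
        merged = t.merge(
            self.cohort.responses[self.cohort.responses["region_id"] == region_id],
            on=["subject_id", "stimulus_id", "repeat_index"],
            how="inner",
        )
        if limit is not None:
            if limit > len(merged):
                raise SplitSizingError(
                    f"requested {limit} training samples for subject {subject_id!r}, "
                    f"only {len(merged)} single-trial entries available"
                )
            rng = np.random.default_rng(self.rng_seed) if rng is None else rng
            keep = rng.choice(len(merged), size=limit, replace=False)
            merged = merged.iloc[np.sort(keep)]
        ids = merged["stimulus_id"].tolist()
        return self.cohort.stimuli.features_for(ids), merged["response"].to_numpy(), ids

    def _avg_xy(self, table: pd.DataFrame, subject_id: str, region_id: str):
        t = table[(table["subject_id"] == subject_id) & (table["region_id"] == region_id)]
        t = t.sort_values("stimulus_id")
        ids = t["stimulus_id"].tolist()
        return self.cohort.stimuli.features_for(ids), t["response"].to_numpy(), ids

    def validation_xy(self, subject_id: str, region_id: str):
        return self._avg_xy(self.validation, subject_id, region_id)

    def test_xy(self, subject_id: str, region_id: str):
        """Repeat-averaged test responses, ordered by ``test_stimulus_ids``."""
        t = self.test[(self.test["subject_id"] == subject_id) & (self.test["region_id"] == region_id)]
        t = t.set_index("stimulus_id").loc[self.test_stimulus_ids]
        return (
            self.cohort.stimuli.features_for(self.test_stimulus_ids),
            t["response"].to_numpy(),
            list(self.test_stimulus_ids),
        )

    def test_responses(self, region_id: str) -> dict[str, np.ndarray]:
        """Map subject → repeat-averaged test response vector (aligned)."""
        return {
            s: self.test_xy(s, region_id)[1] for s in self.cohort.subject_ids
        }


def _select_repeat_pairs(
    counts: pd.DataFrame, rng: np.random.Generator
) -> dict[tuple[str, str], tuple[int, int]]:
    """For each (subject, stimulus) row pick the two repeats to average.

    Two repeats are used as-is; of three, two are chosen uniformly at
    random without replacement.
    """
    pairs: dict[tuple[str, str], tuple[int, int]] = {}
    for (s, st), reps in counts.items():
        reps = sorted(reps)
        if len(reps) == 2:
            chosen = reps
        else:
            chosen = sorted(rng.choice(reps, size=2, replace=False).tolist())
        pairs[(s, st)] = (int(chosen[0]), int(chosen[1]))
    return pairs


def _averaged_table(
    cohort: Cohort,
    subject_stimuli: dict[str, list[str]],
    pairs: dict[tuple[str, str], tuple[int, int]],
) -> pd.DataFrame:
    resp = cohort.responses.set_index(
        ["subject_id", "stimulus_id", "repeat_index", "region_id"]
    )["response"].sort_index()
    rows = []
    for s, stim_ids in subject_stimuli.items():
        for st in stim_ids:
            a, b = pairs[(s, st)]
            va = resp.loc[(s, st, a)]
            vb = resp.loc[(s, st, b)]
            mean = (va + vb) / 2.0
            for g, v in mean.items():
                rows.append((s, g, st, float(v)))
    return pd.DataFrame(rows, columns=["subject_id", "region_id", "stimulus_id", "response"])


def build_split(
    cohort: Cohort, n_train: int | None, n_val: int, n_test: int, seed: int
) -> DatasetSplit:
    """Construct a train/validation/test split with repeat-averaging.

    Test stimuli are sampled from the shared stimuli having at least two
    repeats for *every* subject; validation stimuli per subject from that
    subject's remaining ≥2-repeat stimuli.  Validation/test responses are
    the mean of exactly two repeats (a random two of three, chosen with
    ``seed``).  Training entries are the remaining single-trial records;
    when ``n_train`` is given, that many are sampled per subject.

    Raises :class:`SplitSizingError` when the cohort cannot fill the
    requested sizes, reporting the available counts.
    """
    ss = np.random.SeedSequence(seed)
    test_sel_rng, pair_rng, val_sel_rng, train_sel_rng = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    counts = cohort.repeat_counts()  # (subject, stimulus) -> n repeats
    shared_ids = set(cohort.stimuli.ids[cohort.stimuli.shared])

    # test pool: shared stimuli with >= 2 repeats for every subject
    eligible_test = []
    for st in sorted(shared_ids):
        ok = all(
            (s, st) in counts.index and counts.loc[(s, st)] >= 2 for s in cohort.subject_ids
        )
        if ok:
            eligible_test.append(st)
    if len(eligible_test) < n_test:
        raise SplitSizingError(
            f"need {n_test} test stimuli but only {len(eligible_test)} shared stimuli "
            "have >= 2 repeats for every subject"
        )
    test_ids = sorted(
        test_sel_rng.choice(np.asarray(eligible_test, dtype=object), size=n_test, replace=False)
    )

    # validation pool per subject: own >= 2-repeat stimuli outside the test set
    val_ids: dict[str, list[str]] = {}
    for s in cohort.subject_ids:
        own = counts.loc[s]
        pool = sorted(set(own[own >= 2].index) - set(test_ids))
        if len(pool) < n_val:
            raise SplitSizingError(
                f"subject {s!r}: need {n_val} validation stimuli, only {len(pool)} "
                "eligible (>= 2 repeats, outside the test set)"
            )
        val_ids[s] = sorted(
            val_sel_rng.choice(np.asarray(pool, dtype=object), size=n_val, replace=False)
        )

    # one repeat-pair choice per (subject, stimulus): response maps are
    # averaged jointly, so the same two presentations serve all regions
    repeat_sets = cohort.responses.groupby(["subject_id", "stimulus_id"])["repeat_index"].unique()
    needed = {}
    for s in cohort.subject_ids:
        for st in list(test_ids) + list(val_ids[s]):
            needed[(s, st)] = repeat_sets.loc[(s, st)]
    pairs = _select_repeat_pairs(pd.Series(needed), pair_rng)

    test_table = _averaged_table(cohort, {s: list(test_ids) for s in cohort.subject_ids}, pairs)
    val_table = _averaged_table(cohort, val_ids, pairs)

    # training pool: all single-trial records on stimuli outside val/test
    train_rows = []
    for s in cohort.subject_ids:
        held_out = set(test_ids) | set(val_ids[s])
        own = cohort.responses[cohort.responses["subject_id"] == s]
        pool = (
            own[~own["stimulus_id"].isin(held_out)][["subject_id", "stimulus_id", "repeat_index"]]
            .drop_duplicates()
            .sort_values(["stimulus_id", "repeat_index"])
        )
        if n_train is not None:
            if len(pool) < n_train:
                raise SplitSizingError(
                    f"subject {s!r}: need {n_train} training entries, only {len(pool)} "
                    "single-trial records remain outside validation/test"
                )
            keep = train_sel_rng.choice(len(pool), size=n_train, replace=False)
            pool = pool.iloc[np.sort(keep)]
        train_rows.append(pool)
    train_table = pd.concat(train_rows, ignore_index=True)

    return DatasetSplit(
        cohort=cohort,
        train=train_table,
        validation=val_table,
        test=test_table,
        test_stimulus_ids=[str(t) for t in test_ids],
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# on-disk format


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def save_cohort(cohort: Cohort, out_dir: str | Path, delimiter_ext: str = "csv") -> Path:
    """Write a cohort as two delimited tables plus a JSON manifest.

    Rows are sorted by (subject, region, stimulus, repeat) / stimulus_id
    so the output is byte-stable.  Returns the manifest path;
    ``load_cohort`` of that path reproduces the cohort exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stim_path = out_dir / f"stimuli.{delimiter_ext}"
    resp_path = out_dir / f"responses.{delimiter_ext}"
    manifest_path = out_dir / "manifest.json"

    stim = cohort.stimuli.to_frame().sort_values("stimulus_id")
    resp = cohort.responses.sort_values(
        ["subject_id", "region_id", "stimulus_id", "repeat_index"]
    )
    try:
        stim.to_csv(stim_path, sep=_delimiter_for(stim_path), index=False)
        resp.to_csv(resp_path, sep=_delimiter_for(resp_path), index=False)
        manifest = {
            "stimuli_file": stim_path.name,
            "responses_file": resp_path.name,
            "feature_dim": cohort.feature_dim,
            "label_vocabulary": cohort.stimuli.label_vocabulary,
            "subject_ids": cohort.subject_ids,
            "region_ids": cohort.region_ids,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing cohort under {out_dir}: {exc}") from exc
    return manifest_path


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from its JSON manifest.

    Raises :class:`CohortValidationError` naming each violation (missing
    columns, duplicate keys, non-finite responses, unknown stimuli).
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    stim_path = base / manifest["stimuli_file"]
    resp_path = base / manifest["responses_file"]
    stim = pd.read_csv(stim_path, sep=_delimiter_for(stim_path))
    resp = pd.read_csv(resp_path, sep=_delimiter_for(resp_path))

    missing = [c for c in RESPONSE_COLUMNS if c not in resp.columns]
    if missing:
        raise CohortValidationError([f"responses table missing column {c!r}" for c in missing])
    d = int(manifest["feature_dim"])
    fcols = _feature_columns(d)
    missing_f = [c for c in ["stimulus_id", *fcols] if c not in stim.columns]
    if missing_f:
        raise CohortValidationError([f"stimuli table missing column {c!r}" for c in missing_f])

    labels = stim["label"].to_numpy(dtype=object) if "label" in stim.columns else None
    shared = stim["shared"].to_numpy(dtype=bool) if "shared" in stim.columns else None
    stimuli = StimulusSet(
        ids=stim["stimulus_id"].astype(str).to_numpy(dtype=object),
        features=stim[fcols].to_numpy(dtype=float),
        labels=labels,
        shared=shared,
        label_vocabulary=list(manifest.get("label_vocabulary", [])),
    )
    resp = resp.copy()
    resp["subject_id"] = resp["subject_id"].astype(str)
    resp["region_id"] = resp["region_id"].astype(str)
    resp["stimulus_id"] = resp["stimulus_id"].astype(str)
    subject_ids = [str(s) for s in manifest.get("subject_ids", sorted(resp["subject_id"].unique()))]
    region_ids = [str(g) for g in manifest.get("region_ids", sorted(resp["region_id"].unique()))]
    return Cohort(stimuli=stimuli, responses=resp, subject_ids=subject_ids, region_ids=region_ids)
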
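import numpy as np
import pandas as pd
import pytest

from enscode.datamodel import Cohort, StimulusSet, build_split
from enscode.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A fast 4-subject cohort used across unit tests."""
    return SyntheticConfig(
        n_subjects=4,
        n_regions=2,
        n_stimuli=320,
        n_shared_stimuli=160,
        feature_dim=8,
        repeats=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    cohort, _ = small_cohort
    return build_split(cohort, None, n_val=30, n_test=60, seed=42)


def toy_cohort(
    n_subjects=2,
    n_regions=1,
    n_stimuli=10,
    repeats=2,
    d=3,
    seed=0,
    response_fn=None,
):
    """Hand-rolled cohort with explicit repeat structure for oracle checks."""
    rng = np.random.default_rng(seed)
    ids = np.array([f"t{i:03d}" for i in range(n_stimuli)], dtype=object)
    features = rng.standard_normal((n_stimuli, d))
    stimuli = StimulusSet(ids=ids, features=features)
    subjects = [f"S{i + 1}" for i in range(n_subjects)]
    regions = [f"R{i + 1}" for i in range(n_regions)]
    rows = []
    for s in subjects:
        for g in regions:
            for i, st in enumerate(ids):
                for rep in range(repeats):
                    if response_fn is None:
                        v = rng.normal()
                    else:
                        v = response_fn(s, g, features[i], rep)
                    rows.append((s, g, st, rep, v))
    responses = pd.DataFrame(
        rows, columns=["subject_id", "region_id", "stimulus_id", "repeat_index", "response"]
    )
    return Cohort(
        stimuli=stimuli, responses=responses, subject_ids=subjects, region_ids=regions
    )
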
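import numpy as np
import pandas as pd
import pytest

from enscode.datamodel import build_split
from enscode.encoding import ReadoutModel
from enscode.ensemble import build_loo_ensembles, fit_linear_ensemble
from enscode.experiments import (
    preference_analysis,
    preference_ratio,
    run_ensemble_size_sweep,
    run_train_size_sweep,
    subsample_reliability,
    top_k_stimuli,
)
from enscode.simulate import SyntheticConfig, generate_cohort, oracle_readouts


@pytest.fixture(scope="module")
def sweep_setup(small_cohort):
    cohort, truth = small_cohort
    refs = {g: oracle_readouts(truth, g) for g in cohort.region_ids}
    return cohort, truth, refs


class TestTopK:
    def test_constant_predictor_ranks_lexicographically(self, small_cohort):
        cohort, _ = small_cohort
        r = ReadoutModel("S1", "FFA1", np.zeros(cohort.feature_dim), 1.0)
        top = top_k_stimuli(r, cohort.stimuli, 5)
        assert top == sorted(map(str, cohort.stimuli.ids))[:5]

    def test_monotone_predictor_follows_feature_order(self, small_cohort):
        cohort, _ = small_cohort
        w = np.zeros(cohort.feature_dim)
        w[0] = 1.0
        r = ReadoutModel("S1", "FFA1", w, 0.0)
        top = top_k_stimuli(r, cohort.stimuli, 3)
        order = np.argsort(-cohort.stimuli.features[:, 0])
        assert top == [str(cohort.stimuli.ids[i]) for i in order[:3]]

    def test_matches_full_sort_oracle(self, small_cohort):
        cohort, _ = small_cohort
        rng = np.random.default_rng(1)
        r = ReadoutModel("S1", "FFA1", rng.standard_normal(cohort.feature_dim), 0.3)
        scores = cohort.stimuli.features @ r.weights + r.bias
        full = [
            str(cohort.stimuli.ids[i])
            for i in sorted(range(len(scores)), key=lambda i: (-scores[i], str(cohort.stimuli.ids[i])))
        ]
        assert top_k_stimuli(r, cohort.stimuli, 20) == full[:20]

    def test_k_validation(self, small_cohort):
        cohort, _ = small_cohort
        r = ReadoutModel("S1", "FFA1", np.zeros(cohort.feature_dim), 0.0)
        with pytest.raises(ValueError, match="positive"):
            top_k_stimuli(r, cohort.stimuli, 0)
        with pytest.raises(ValueError, match="exceeds"):
            top_k_stimuli(r, cohort.stimuli, cohort.stimuli.n_stimuli + 1)


class TestPreferenceRatio:
    def test_formula_arithmetic(self):
        labels = ["animal_face"] * 7 + ["human_face"] * 3
        assert preference_ratio(labels) == pytest.approx(0.4)

    def test_all_other_is_undefined(self):
        assert np.isnan(preference_ratio(["other"] * 10))


class TestTrainSizeSweep:
    def test_deterministic_and_well_formed(self, sweep_setup):
        cohort, truth, refs = sweep_setup
        kw = dict(
            models={"linear_ensemble", "average_ensemble", "oracle"},
            grid=[30],
            seeds=[0],
            region_ids=["FFA1"],
            n_val=20,
            n_test=50,
        )
        a = run_train_size_sweep(cohort, refs, **kw)
        b = run_train_size_sweep(cohort, refs, **kw)
        pd.testing.assert_frame_equal(a.cells, b.cells)
        assert set(a.cells["model"]) == {"linear_ensemble", "average_ensemble", "oracle"}
        # average ensemble appears once per subject regardless of grid (size 0)
        avg = a.cells[a.cells.model == "average_ensemble"]
        assert (avg["train_size"] == 0).all()
        assert len(avg) == len(cohort.subject_ids)

    def test_ensemble_not_worse_than_scratch_at_moderate_n(self, sweep_setup):
        cohort, truth, refs = sweep_setup
        res = run_train_size_sweep(
            cohort,
            refs,
            models={"scratch", "linear_ensemble"},
            grid=[100],
            seeds=[0, 1, 2],
            region_ids=["FFA1"],
            n_val=20,
            n_test=50,
        )
        mean_acc = res.cells.groupby("model")["accuracy"].mean()
        assert mean_acc["linear_ensemble"] >= mean_acc["scratch"]

    def test_unknown_model_rejected(self, sweep_setup):
        cohort, truth, refs = sweep_setup
        with pytest.raises(ValueError, match="unknown model"):
            run_train_size_sweep(cohort, refs, models={"bogus"}, grid=[10], seeds=[0])


class TestEnsembleSizeSweep:
    def test_grid_validation(self, sweep_setup):
        cohort, truth, refs = sweep_setup
        with pytest.raises(ValueError, match=">= 1"):
            run_ensemble_size_sweep(cohort, refs, sizes=[0], seeds=[0])
        with pytest.raises(ValueError, match="n_subjects"):
            run_ensemble_size_sweep(cohort, refs, sizes=[len(cohort.subject_ids)], seeds=[0])

    def test_full_size_equals_leave_one_out_reference_sets(self, sweep_setup):
        """Sampling n_subjects-1 references is exactly the LOO construction."""
        cohort, truth, refs = sweep_setup
        split = build_split(cohort, None, 20, 50, seed=3)
        g = "FFA1"
        loo = build_loo_ensembles(refs[g], split, g, n_train=50, seed=3)
        for s in cohort.subject_ids:
            others = [refs[g][o] for o in refs[g] if o != s]
            direct = fit_linear_ensemble(others, split, s, g, n_train=50, seed=99)
            assert set(direct.reference_subjects) == set(loo[s].reference_subjects)
            # same references + same seed -> identical coefficients
            again = fit_linear_ensemble(
                list(refs[g].values()), split, s, g, n_train=50, seed=99
            )
            np.testing.assert_array_equal(direct.coefficients, again.coefficients)

    def test_records_accuracy_and_consistency_per_cell(self, sweep_setup):
        cohort, truth, refs = sweep_setup
        res = run_ensemble_size_sweep(
            cohort, refs, sizes=[1, 3], seeds=[0], n_train=60, n_val=20, n_test=50
        )
        assert set(res.cells["ensemble_size"]) == {1, 3}
        assert len(res.consistency) == 2
        assert res.cells["accuracy"].notna().all()


class TestSubsampleReliability:
    def test_full_fraction_zero_error(self, small_cohort, small_split):
        res = subsample_reliability(
            small_split, "isc_measurement", n_draws=20, fraction=1.0, seed=0
        )
        np.testing.assert_allclose(res["relative_errors"], 0.0, atol=1e-12)

    def test_deterministic_per_seed(self, small_split):
        a = subsample_reliability(small_split, "isc_measurement", n_draws=30, fraction=0.7, seed=4)
        b = subsample_reliability(small_split, "isc_measurement", n_draws=30, fraction=0.7, seed=4)
        np.testing.assert_array_equal(a["values"], b["values"])
        assert np.isfinite(a["cv"])

    def test_error_shrinks_with_fraction(self, small_split):
        lo = subsample_reliability(small_split, "isc_measurement", n_draws=60, fraction=0.5, seed=1)
        hi = subsample_reliability(small_split, "isc_measurement", n_draws=60, fraction=0.9, seed=1)
        assert hi["mean_relative_error"] < lo["mean_relative_error"]

    def test_consistency_metric_needs_predictions(self, small_split):
        with pytest.raises(ValueError, match="predictions"):
            subsample_reliability(small_split, "consistency", n_draws=5, fraction=0.8)


class TestPreferenceAnalysis:
    @staticmethod
    def _labeled_setup(seed):
        cfg = SyntheticConfig(
            n_subjects=4,
            n_regions=2,
            n_stimuli=400,
            n_shared_stimuli=240,
            feature_dim=8,
            label_fractions=(0.3, 0.3),
            face_preference_sd=0.6,
            repeats=2,
            seed=seed,
        )
        cohort, truth = generate_cohort(cfg)
        split = build_split(cohort, None, 30, 120, seed=seed)
        refs = {g: oracle_readouts(truth, g) for g in cohort.region_ids}
        ens = {
            g: build_loo_ensembles(refs[g], split, g, n_train=60, seed=seed)
            for g in cohort.region_ids
        }
        return split, ens, refs

    def test_planted_preference_recovered(self):
        """Subjects with stronger animal-face tuning should show both larger
        measured animal-vs-human t statistics and more animal faces in their
        model's top-k — a positive correlation across subject x region points."""
        rs = []
        for seed in range(8):
            split, ens, refs = self._labeled_setup(seed)
            _, r, _ = preference_analysis(
                split, ens, refs, face_regions=list(refs), k=10
            )
            if np.isfinite(r):
                rs.append(r)
        assert len(rs) >= 6
        assert np.mean(rs) > 0.2

    def test_unlabeled_cohort_rejected(self, small_cohort, small_split):
        cohort, truth = small_cohort
        refs = {g: oracle_readouts(truth, g) for g in cohort.region_ids}
        ens = {
            g: build_loo_ensembles(refs[g], small_split, g, n_train=30, seed=0)
            for g in cohort.region_ids
        }
        with pytest.raises(ValueError, match="labeled"):
            preference_analysis(small_split, ens, refs, face_regions=list(refs))
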
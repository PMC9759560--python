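import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enscode.datamodel import build_split
from enscode.evaluation import (
    ISCMatrix,
    across_subject_nc,
    benjamini_hochberg,
    compare_models_friedman_fdr,
    compare_to_reference_wilcoxon,
    isc_matrix,
    prediction_accuracy,
    prediction_consistency,
    welch_t,
    within_subject_nc,
)
from enscode.simulate import SyntheticConfig, generate_cohort

from conftest import toy_cohort


class TestPredictionAccuracy:
    def test_perfect_and_anti_correlation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert prediction_accuracy(x, x) == pytest.approx(1.0)
        assert prediction_accuracy(-x, x) == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov / (a.std() * b.std())
        assert prediction_accuracy(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        assert np.isnan(prediction_accuracy(np.ones(5), np.arange(5.0)))

    def test_shape_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            prediction_accuracy(np.ones(4), np.ones(5))
        with pytest.raises(ValueError, match="at least 3"):
            prediction_accuracy(np.ones(2), np.ones(2))

    @settings(derandomize=True, max_examples=25)
    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        r = prediction_accuracy(x, y)
        assert prediction_accuracy(a * x + b, y) == pytest.approx(r, abs=1e-9)
        assert prediction_accuracy(-a * x + b, y) == pytest.approx(-r, abs=1e-9)


class TestISC:
    def test_identical_subjects_all_ones(self):
        v = np.array([0.3, -1.0, 2.0, 0.1])
        m = isc_matrix({"S1": v, "S2": v.copy(), "S3": v.copy()}, "prediction")
        np.testing.assert_allclose(m.upper_triangle(), 1.0)

    def test_definitional_consistency_with_pairwise_accuracy(self):
        rng = np.random.default_rng(2)
        resp = {s: rng.standard_normal(30) for s in ["S1", "S2", "S3"]}
        m = isc_matrix(resp, "measurement")
        for i, j in itertools.combinations(range(3), 2):
            si, sj = m.subject_ids[i], m.subject_ids[j]
            assert m.values[i, j] == pytest.approx(
                prediction_accuracy(resp[si], resp[sj]), abs=1e-12
            )
        np.testing.assert_allclose(m.values, m.values.T)

    def test_independent_long_vectors_near_zero(self):
        rng = np.random.default_rng(3)
        n = 2000
        m = isc_matrix(
            {"a": rng.standard_normal(n), "b": rng.standard_normal(n)}, "measurement"
        )
        assert abs(m.values[0, 1]) < 3 / np.sqrt(n)

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            isc_matrix({"S1": np.ones(4)}, "prediction")


def _sym(vec: np.ndarray, k: int) -> np.ndarray:
    m = np.eye(k)
    m[np.triu_indices(k, 1)] = vec
    return m + np.triu(m, 1).T


def _isc_from_vec(vec, k, source, region="R1"):
    return ISCMatrix(
        subject_ids=[f"S{i}" for i in range(k)], values=_sym(np.asarray(vec), k),
        source=source, region_id=region,
    )


class TestConsistency:
    def test_identical_vectors_r_one_min_p(self):
        rng = np.random.default_rng(4)
        vec = rng.uniform(-0.5, 0.9, size=15)
        res = prediction_consistency(
            [_isc_from_vec(vec, 6, "prediction")],
            [_isc_from_vec(vec, 6, "measurement")],
            n_permutations=1000,
            seed=0,
        )
        assert res.r == pytest.approx(1.0)
        assert res.p_one_tailed == pytest.approx(1 / 1001)

    def test_six_subjects_one_region_pools_15_pairs(self):
        rng = np.random.default_rng(5)
        res = prediction_consistency(
            [_isc_from_vec(rng.uniform(-1, 1, 15), 6, "prediction")],
            [_isc_from_vec(rng.uniform(-1, 1, 15), 6, "measurement")],
            n_permutations=1000,
            seed=0,
        )
        assert res.n_pairs == 15

    def test_near_constant_prediction_isc_flagged_undefined(self):
        rng = np.random.default_rng(6)
        pred = 0.999 + 1e-4 * rng.standard_normal(28)  # avg-ensemble regime
        meas = rng.uniform(0, 1, 28)
        res = prediction_consistency(
            [_isc_from_vec(pred, 8, "prediction")],
            [_isc_from_vec(meas, 8, "measurement")],
            n_permutations=1000,
            seed=0,
        )
        assert res.undefined
        assert np.isnan(res.r)

    def test_bonferroni_capped_at_one(self):
        rng = np.random.default_rng(7)
        res = prediction_consistency(
            [_isc_from_vec(rng.uniform(-1, 1, 15), 6, "prediction")],
            [_isc_from_vec(rng.uniform(-1, 1, 15), 6, "measurement")],
            n_permutations=1000,
            seed=1,
            n_comparisons_for_bonferroni=50,
        )
        assert res.corrected_p <= 1.0
        assert res.corrected_p >= res.p_one_tailed


class TestNoiseCeilings:
    def test_identical_subjects_across_nc_is_one(self):
        cohort = toy_cohort(
            n_subjects=3,
            n_stimuli=12,
            repeats=2,
            seed=9,
            response_fn=lambda s, g, f, rep: float(f[0]),  # same signal, no noise
        )
        split = build_split(cohort, None, 2, 6, seed=0)
        nc = across_subject_nc(split, "S1", "R1")
        assert nc.value == pytest.approx(1.0)

    def test_zero_noise_within_nc_is_one(self):
        cohort = toy_cohort(
            n_subjects=2,
            n_stimuli=12,
            repeats=3,
            seed=10,
            response_fn=lambda s, g, f, rep: float(f[0] + 2 * f[1]),
        )
        ids = list(cohort.stimuli.ids[:8])
        for style in ("nsd", "neurogen"):
            nc = within_subject_nc(cohort, "S1", "R1", ids, style)
            assert nc.value == pytest.approx(1.0)

    def test_insufficient_repeats_listed(self):
        cohort = toy_cohort(n_stimuli=8, repeats=2)
        with pytest.raises(ValueError, match="deficient"):
            within_subject_nc(cohort, "S1", "R1", list(cohort.stimuli.ids[:4]), "nsd")

    def test_across_nc_exceeds_within_nc_when_signal_is_mostly_shared(self):
        """Averaging 7 other subjects suppresses noise more than a single
        repeat pair can, so the across-subject ceiling is higher on average."""
        diffs = []
        for seed in range(12):
            cfg = SyntheticConfig(
                n_subjects=8,
                n_regions=1,
                n_stimuli=220,
                n_shared_stimuli=200,
                feature_dim=8,
                repeats=3,
                seed=seed,
            )
            cohort, _ = generate_cohort(cfg)
            split = build_split(cohort, None, 10, 120, seed=seed)
            across = across_subject_nc(split, "S1", "FFA1").value
            within = within_subject_nc(
                cohort, "S1", "FFA1", split.test_stimulus_ids, "nsd"
            ).value
            diffs.append(across - within)
        assert np.mean(diffs) > 0


class TestWilcoxon:
    @staticmethod
    def _exact_two_tailed(d: np.ndarray) -> float:
        """Brute-force enumeration of all sign assignments of |d| ranks."""
        d = d[d != 0]
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        n = len(d)
        w_obs = ranks[d > 0].sum()
        ws = []
        for signs in itertools.product([0, 1], repeat=n):
            ws.append(ranks[np.array(signs, dtype=bool)].sum())
        ws = np.array(ws)
        p_low = np.mean(ws <= w_obs)
        p_high = np.mean(ws >= w_obs)
        return min(1.0, 2 * min(p_low, p_high))

    def test_all_positive_shifts_hit_minimal_exact_p(self):
        base = np.linspace(0.1, 0.8, 8)
        stat, p = compare_to_reference_wilcoxon(base + 0.05, base)
        assert p == pytest.approx(2 / 2**8)

    def test_matches_sign_flip_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a = rng.standard_normal(8)
            b = rng.standard_normal(8)
            _, p = compare_to_reference_wilcoxon(a, b)
            assert p == pytest.approx(self._exact_two_tailed(a - b), abs=1e-12)

    def test_identical_vectors_degenerate(self):
        x = np.linspace(0, 1, 6)
        stat, p = compare_to_reference_wilcoxon(x, x.copy())
        assert np.isnan(p)


class TestFriedmanFdr:
    def test_identical_models_zero_statistic(self):
        acc = np.tile(np.linspace(0.2, 0.9, 8)[:, None], (1, 3))
        stat, p, adj = compare_models_friedman_fdr(acc)
        assert stat == 0.0
        assert np.all(np.isnan(np.diag(adj)))

    def test_statistic_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(12)
        acc = rng.standard_normal((8, 3))
        acc[:, 0] += 3.0  # one dominant model, continuous values: no ties
        stat, _, _ = compare_models_friedman_fdr(acc)
        n, k = acc.shape
        ranks = np.argsort(np.argsort(acc, axis=1), axis=1) + 1.0
        rbar = ranks.mean(axis=0)
        expected = 12 * n / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2) ** 2)
        assert stat == pytest.approx(expected, abs=1e-10)

    def test_bh_adjustment_step_up_by_hand(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        # hand-worked step-up: sorted p (0.005, 0.04, 0.06), m=3
        # q3 = 0.06, q2 = min(0.04*3/2, q3) = 0.06, q1 = min(0.005*3, q2) = 0.015
        np.testing.assert_allclose(
            benjamini_hochberg([0.04, 0.005, 0.06]), [0.06, 0.015, 0.06]
        )

    def test_shape_requirements(self):
        with pytest.raises(ValueError, match="3 models"):
            compare_models_friedman_fdr(np.ones((8, 2)))
        with pytest.raises(ValueError, match="5 subjects"):
            compare_models_friedman_fdr(np.ones((3, 3)))


class TestWelch:
    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(13)
        a, b = rng.standard_normal(12) + 0.5, rng.standard_normal(9)
        t, _ = welch_t(a, b)
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert t == pytest.approx((a.mean() - b.mean()) / se, abs=1e-12)
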
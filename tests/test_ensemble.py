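"""TSS scoring, threshold search, cross-validation ledger, ensemble averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oakmap.ensemble import (
    ALGORITHMS,
    ConfusionCounts,
    FittedRun,
    RunEvaluation,
    best_threshold_tss,
    cross_validate_region,
    ensemble_predict,
    evaluations_to_frame,
    exclude_unstable_algorithms,
    tss,
)
from oakmap.prep import PresenceAbsenceSet


class TestTss:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((50, 0, 50, 0), 1.0),  # perfect classifier
            ((45, 10, 40, 5), 0.7),  # 0.9 + 0.8 - 1
            ((10, 10, 10, 10), 0.0),  # chance-level
            ((0, 50, 0, 50), -1.0),  # perfectly inverted
        ],
    )
    def test_forced_arithmetic(self, counts, expected):
        tp, fp, tn, fn = counts
        assert tss(ConfusionCounts(tp, fp, tn, fn)) == pytest.approx(expected)

    def test_constant_classifier_scores_zero(self):
        # predict-all-positive: sensitivity 1, specificity 0
        assert tss(ConfusionCounts(tp=30, fp=70, tn=0, fn=0)) == pytest.approx(0.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="no positive"):
            tss(ConfusionCounts(tp=0, fp=5, tn=5, fn=0))
        with pytest.raises(ValueError, match="no negative"):
            tss(ConfusionCounts(tp=5, fp=0, tn=0, fn=5))

    @given(
        tp=st.integers(1, 50), fn=st.integers(0, 50),
        tn=st.integers(1, 50), fp=st.integers(0, 50),
    )
    @settings(derandomize=True, max_examples=50)
    def test_bounded_in_minus_one_one(self, tp, fn, tn, fp):
        val = tss(ConfusionCounts(tp, fp, tn, fn))
        assert -1.0 <= val <= 1.0


def exhaustive_best_tss(scores, labels, step=0.01):
    """Independent exhaustive search over the threshold grid."""
    best = (None, -2.0)
    for i in range(int(round(1.0 / step)) + 1):
        thr = round(i * step, 10)
        pred = scores >= thr
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        sens = tp / (labels == 1).sum()
        spec = ((labels == 0).sum() - fp) / (labels == 0).sum()
        val = sens + spec - 1
        if val > best[1] + 1e-12:
            best = (thr, val)
    return best


class TestBestThreshold:
    def test_four_point_toy_matches_exhaustive_search(self):
        scores = np.array([0.1, 0.4, 0.6, 0.9])
        labels = np.array([0, 0, 1, 1])
        thr, val = best_threshold_tss(scores, labels)
        o_thr, o_val = exhaustive_best_tss(scores, labels)
        assert val == pytest.approx(1.0)
        assert (thr, val) == (pytest.approx(o_thr), pytest.approx(o_val))

    def test_random_scores_match_exhaustive_search(self, rng):
        scores = rng.random(60)
        labels = (rng.random(60) < 0.5).astype(int)
        thr, val = best_threshold_tss(scores, labels)
        o_thr, o_val = exhaustive_best_tss(scores, labels)
        assert thr == pytest.approx(o_thr)
        assert val == pytest.approx(o_val)

    def test_separable_scores_return_smallest_separating_threshold(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        thr, val = best_threshold_tss(scores, labels)
        assert val == 1.0
        assert thr == pytest.approx(0.21)  # smallest grid point above 0.2

    def test_labels_independent_of_scores_near_zero(self, rng):
        scores = rng.random(4000)
        labels = (rng.random(4000) < 0.5).astype(int)
        _, val = best_threshold_tss(scores, labels)
        assert abs(val) < 0.1  # Monte-Carlo bound for n=4000

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            best_threshold_tss(np.array([0.1, 0.9]), np.array([1, 1]))


def make_pa_set(n=40, k=3, separable=True, permuted=False, seed=0):
    rng = np.random.default_rng(seed)
    names = ["u", "v"]

    def table(label):
        shift = 3.0 if (separable and label) else 0.0
        X = rng.standard_normal((n, 2)) + shift
        return pd.DataFrame(
            {"row": np.arange(n), "col": np.arange(n), "u": X[:, 0], "v": X[:, 1]}
        )

    pres = table(1)
    if permuted:
        # scramble the association: absences drawn from the same distribution
        reps = [table(1) for _ in range(k)]
    else:
        reps = [table(0) for _ in range(k)]
    return PresenceAbsenceSet(0, pres, reps, names)


class TestCrossValidate:
    def test_ledger_bookkeeping(self):
        data = make_pa_set(n=20, k=3)
        evals, runs = cross_validate_region(data, algorithms=("glm", "rf"), n_repeats=2, seed=1)
        frame = evaluations_to_frame(evals)
        assert len(frame) == 2 * 3 * 2  # algorithms x replicates x repeats
        assert (frame.groupby("algorithm").size() == 6).all()
        assert len(runs) == int(frame["converged"].sum())

    def test_separable_data_yields_perfect_tss(self):
        data = make_pa_set(n=30, k=2, separable=True)
        evals, _ = cross_validate_region(data, algorithms=("glm", "rf"), n_repeats=2, seed=2)
        frame = evaluations_to_frame(evals)
        assert frame["tss"].median() == pytest.approx(1.0)

    def test_permuted_labels_yield_near_zero_tss(self):
        data = make_pa_set(n=100, k=2, permuted=True, seed=3)
        evals, _ = cross_validate_region(data, algorithms=("glm",), n_repeats=5, seed=3)
        frame = evaluations_to_frame(evals)
        assert abs(frame["tss"].median()) < 0.25  # null distribution at n=100

    def test_identical_seed_reproduces_ledger(self):
        data = make_pa_set(n=24, k=2)
        a = evaluations_to_frame(cross_validate_region(data, ("glm", "rf"), 2, seed=7)[0])
        b = evaluations_to_frame(cross_validate_region(data, ("glm", "rf"), 2, seed=7)[0])
        pd.testing.assert_frame_equal(a, b)


class FixedModel:
    """Stub estimator returning a constant probability surface."""

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        out = np.full((len(X), 2), 1 - self.p)
        out[:, 1] = self.p
        return out


def fixed_run(p, tss_value, alg="rf", region=0):
    ev = RunEvaluation(region, alg, 1, 1, tss_value, 0.5, True)
    return FittedRun(evaluation=ev, model=FixedModel(p), variable_names=["AT", "CMD"])


class TestEnsemblePredict:
    def test_single_run_identity(self, stack):
        raster = ensemble_predict(stack, [fixed_run(0.3, 0.9)])
        finite = np.isfinite(raster.values)
        assert np.allclose(raster.values[finite], 0.3)

    def test_equal_weights_give_arithmetic_mean(self, stack):
        raster = ensemble_predict(stack, [fixed_run(0.2, 0.5), fixed_run(0.8, 0.5)])
        finite = np.isfinite(raster.values)
        assert np.allclose(raster.values[finite], 0.5)

    def test_tss_weighted_mean_forced_arithmetic(self, stack):
        # (0.5*0.2 + 1.0*0.8) / 1.5 = 0.6
        raster = ensemble_predict(stack, [fixed_run(0.2, 0.5), fixed_run(0.8, 1.0)])
        finite = np.isfinite(raster.values)
        assert np.allclose(raster.values[finite], 0.6)

    def test_weight_scale_invariance_and_bounds(self, stack):
        runs = [fixed_run(0.2, 0.25), fixed_run(0.8, 0.75)]
        scaled = [fixed_run(0.2, 0.5), fixed_run(0.8, 1.5)]
        # tss > 1 never occurs in practice; used here only to scale weights
        a = ensemble_predict(stack, runs).values
        b = ensemble_predict(stack, scaled).values
        finite = np.isfinite(a)
        np.testing.assert_allclose(a[finite], b[finite])
        assert (a[finite] >= 0.2 - 1e-12).all() and (a[finite] <= 0.8 + 1e-12).all()

    def test_negative_tss_runs_get_zero_weight(self, stack):
        raster = ensemble_predict(stack, [fixed_run(0.9, 0.8), fixed_run(0.1, -0.5)])
        finite = np.isfinite(raster.values)
        assert np.allclose(raster.values[finite], 0.9)

    def test_all_zero_weights_rejected(self, stack):
        with pytest.raises(ValueError, match="zero"):
            ensemble_predict(stack, [fixed_run(0.5, 0.0), fixed_run(0.5, -0.2)])

    def test_region_restriction_masks_other_regions(self, stack):
        raster = ensemble_predict(stack, [fixed_run(0.4, 0.9, region=1)], region_id=1)
        inside = stack.region_id == 1
        assert np.isfinite(raster.values[inside]).all()
        assert np.isnan(raster.values[~inside]).all()


class TestExcludeUnstable:
    def ledger(self, rows):
        return pd.DataFrame(rows, columns=["region", "algorithm", "replicate", "repeat", "tss", "threshold", "converged"])

    def test_all_converged_all_retained(self):
        rows = [(r, a, 1, 1, 0.8, 0.5, True) for r in (0, 1) for a in ALGORITHMS]
        retained, report = exclude_unstable_algorithms(self.ledger(rows))
        assert retained == {0: sorted(ALGORITHMS), 1: sorted(ALGORITHMS)}

    def test_fully_failed_algorithm_dropped_only_where_it_failed(self):
        rows = [(0, "gbm", 1, 1, np.nan, np.nan, False), (0, "rf", 1, 1, 0.9, 0.5, True),
                (1, "gbm", 1, 1, 0.8, 0.5, True), (1, "rf", 1, 1, 0.9, 0.5, True)]
        retained, _ = exclude_unstable_algorithms(self.ledger(rows))
        assert retained == {0: ["rf"], 1: ["gbm", "rf"]}

    def test_threshold_moves_verdict(self):
        # 2 of 5 runs converge -> fraction 0.4
        rows = [(0, "ann", i, 1, 0.5, 0.5, i < 2) for i in range(5)]
        rows += [(0, "rf", i, 1, 0.9, 0.5, True) for i in range(5)]
        retained_default, _ = exclude_unstable_algorithms(self.ledger(rows), 0.5)
        retained_loose, _ = exclude_unstable_algorithms(self.ledger(rows), 0.3)
        assert retained_default[0] == ["rf"]
        assert retained_loose[0] == ["ann", "rf"]

    def test_region_with_no_survivor_raises(self):
        rows = [(0, "rf", 1, 1, np.nan, np.nan, False)]
        with pytest.raises(ValueError, match="region 0"):
            exclude_unstable_algorithms(self.ledger(rows))
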
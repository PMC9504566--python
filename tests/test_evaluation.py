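"""Metrics vs brute-force oracles, thresholds, alarms, agreement, importance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shockwatch.evaluation import (AlarmRecord, bland_altman, bootstrap_ci,
                                   compute_auprc, compute_auroc,
                                   earliness_comparison, permutation_importance,
                                   select_threshold, sens_spec_at,
                                   time_to_first_alarm)
from shockwatch.models import RiskTrajectory


# --- independent oracles ----------------------------------------------------

def auroc_by_pair_enumeration(scores, labels):
    """P(pos > neg) + P(tie)/2 over all positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def auprc_by_threshold_enumeration(scores, labels):
    """Average precision: sum of precision x recall-increment over the ranked
    list, enumerating every distinct threshold."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    s = np.asarray(scores)[order]
    y = np.asarray(labels)[order]
    n_pos = y.sum()
    ap, tp, fp = 0.0, 0, 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        recall_prev = tp / n_pos
        tp += int(y[i:j].sum())
        fp += int((1 - y[i:j]).sum())
        precision = tp / (tp + fp)
        ap += precision * (tp / n_pos - recall_prev)
        i = j
    return ap


def threshold_by_exhaustive_scan(scores, labels, min_spec):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    uniq = np.unique(scores)
    cands = np.concatenate(([uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]))
    best_t, best_sens = float("inf"), 0.0
    for t in cands:
        sens, spec = sens_spec_at(scores, labels, t)
        if spec > min_spec and (sens > best_sens or (sens == best_sens and t < best_t)):
            best_t, best_sens = float(t), sens
    return best_t if best_sens > 0.0 else float("inf")


binary_instances = st.integers(5, 50).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 20).map(lambda v: v / 20.0), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ls: 0 < sum(ls) < len(ls)),
    )
)


class TestAuroc:
    def test_hand_case(self):
        assert compute_auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation_and_all_ties(self):
        assert compute_auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert compute_auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auroc([0.1, 0.2], [1, 1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(binary_instances)
    def test_matches_pair_enumeration_oracle(self, inst):
        scores, labels = inst
        assert compute_auroc(scores, labels) == pytest.approx(
            auroc_by_pair_enumeration(scores, labels), abs=1e-12)


class TestAuprc:
    def test_perfect_separation(self):
        assert compute_auprc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_equal_prevalence(self):
        assert compute_auprc([0.5] * 10, [1, 0, 0, 0, 1, 0, 0, 0, 0, 0]) == pytest.approx(0.2)

    def test_small_hand_case_matches_enumeration(self):
        scores = [0.9, 0.7, 0.6, 0.4, 0.2]
        labels = [1, 0, 1, 0, 0]
        assert compute_auprc(scores, labels) == pytest.approx(
            auprc_by_threshold_enumeration(scores, labels), abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            compute_auprc([0.1, 0.2], [0, 0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(binary_instances)
    def test_matches_threshold_enumeration_oracle(self, inst):
        scores, labels = inst
        assert compute_auprc(scores, labels) == pytest.approx(
            auprc_by_threshold_enumeration(scores, labels), abs=1e-12)


class TestSelectThreshold:
    def test_forces_zero_false_positives_when_needed(self):
        # 10 negatives topping at 0.8; positives at 0.9 and 0.4
        scores = [0.1, 0.2, 0.3, 0.4, 0.5, 0.55, 0.6, 0.7, 0.75, 0.8, 0.9, 0.4]
        labels = [0] * 10 + [1, 1]
        t = select_threshold(scores, labels, 0.9)
        assert 0.8 < t <= 0.9
        sens, spec = sens_spec_at(np.array(scores), np.array(labels), t)
        assert sens == 0.5 and spec == 1.0

    def test_perfect_separation_gives_full_sensitivity(self):
        t = select_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.9)
        assert 0.2 < t <= 0.8
        assert sens_spec_at(np.array([0.1, 0.2, 0.8, 0.9]),
                            np.array([0.0, 0.0, 1.0, 1.0]), t) == (1.0, 1.0)

    def test_unattainable_specificity_returns_inf_with_warning(self):
        with pytest.warns(UserWarning, match="specificity"):
            t = select_threshold([0.5, 0.5, 0.5, 0.5], [0, 0, 1, 1], 0.9)
        assert t == np.inf

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(binary_instances, st.sampled_from([0.5, 0.8, 0.9]))
    def test_matches_exhaustive_scan_oracle(self, inst, min_spec):
        scores, labels = inst
        assert select_threshold(scores, labels, min_spec) == pytest.approx(
            threshold_by_exhaustive_scan(scores, labels, min_spec))


class TestBootstrap:
    def _data(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        labels = (rng.random(n) < 0.3).astype(float)
        scores = np.clip(labels * 0.3 + rng.normal(0.4, 0.2, n), 0, 1)
        return scores, labels

    def test_same_seed_identical_interval(self):
        s, l = self._data()
        a = bootstrap_ci(compute_auroc, s, l, B=200, seed=4)
        b = bootstrap_ci(compute_auroc, s, l, B=200, seed=4)
        assert a == b

    def test_interval_contains_point_estimate(self):
        s, l = self._data()
        lo, hi = bootstrap_ci(compute_auroc, s, l, B=400, seed=1)
        assert lo <= compute_auroc(s, l) <= hi

    def test_width_shrinks_roughly_as_root_n(self):
        s1, l1 = self._data(n=150, seed=2)
        s4, l4 = self._data(n=600, seed=2)
        w1 = np.diff(bootstrap_ci(compute_auroc, s1, l1, B=400, seed=3))[0]
        w4 = np.diff(bootstrap_ci(compute_auroc, s4, l4, B=400, seed=3))[0]
        assert w4 < w1 * 0.75  # ~0.5 expected, generous tolerance

    def test_small_B_rejected(self):
        s, l = self._data()
        with pytest.raises(ValueError):
            bootstrap_ci(compute_auroc, s, l, B=10, seed=0)


class TestAlarms:
    def _traj(self, risks, times=None):
        times = times if times is not None else np.arange(len(risks)) * 60.0
        return RiskTrajectory(patient_id="P1", t=np.asarray(times, float),
                              risk=np.asarray(risks, float))

    def test_first_crossing_is_reported(self):
        rec = time_to_first_alarm(self._traj([0.1, 0.2, 0.95]), 0.9)
        assert rec.first_alarm_t == 120.0 and not rec.censored

    def test_no_crossing_within_horizon_is_censored_with_sentinel(self):
        rec = time_to_first_alarm(self._traj([0.1, 0.2, 0.3]), 0.9)
        assert rec.censored and rec.first_alarm_t > 360.0

    def test_crossing_after_horizon_is_censored(self):
        rec = time_to_first_alarm(self._traj([0.1] * 7 + [0.99],
                                             times=np.arange(8) * 60.0), 0.9)
        assert rec.censored

    def test_zero_threshold_alarms_at_first_fragment(self):
        rec = time_to_first_alarm(self._traj([0.1, 0.2]), 0.0)
        assert rec.first_alarm_t == 0.0


class TestEarliness:
    def _alarm(self, pid, t, censored=False):
        return AlarmRecord(pid, t if not censored else 361.0, censored)

    def test_plain_delta(self):
        res = earliness_comparison([self._alarm("a", 60.0)], [self._alarm("a", 180.0)],
                                   {"a"})
        assert res.per_patient[0]["delta_min"] == 120.0
        assert res.total_delta_min == 120.0

    def test_censored_manual_contributes_lower_bound(self):
        res = earliness_comparison([self._alarm("a", 120.0)],
                                   [self._alarm("a", 0, censored=True)], {"a"})
        row = res.per_patient[0]
        assert row["bound"] == "lower" and row["delta_min"] == 240.0

    def test_identical_trajectories_give_zero_deltas(self):
        dev = [self._alarm(p, 60.0) for p in "abc"]
        man = [self._alarm(p, 60.0) for p in "abc"]
        res = earliness_comparison(dev, man, set("abc"))
        assert res.total_delta_min == 0.0 and res.min_delta_min == 0.0

    def test_mismatched_patient_sets_rejected(self):
        with pytest.raises(ValueError, match="different patients"):
            earliness_comparison([self._alarm("a", 60.0)], [self._alarm("b", 60.0)])

    def test_censoring_conservation(self):
        dev = [self._alarm("a", 60.0), self._alarm("b", 0, censored=True),
               self._alarm("c", 300.0)]
        man = [self._alarm(p, 100.0) for p in "abc"]
        res = earliness_comparison(dev, man, set("abc"))
        assert res.n_device_alarmed + sum(
            r["device_t"] > 360 for r in res.per_patient) == 3


class TestBlandAltman:
    def test_identical_vectors_give_zero_agreement_band(self):
        res = bland_altman([100, 110, 120], [100, 110, 120])
        assert (res.mean_diff, res.loa_low, res.loa_high) == (0.0, 0.0, 0.0)

    def test_hand_case(self):
        res = bland_altman([100, 110, 120], [98, 112, 118])
        assert res.mean_diff == pytest.approx(0.667, abs=0.01)
        assert res.loa_low == pytest.approx(-3.86, abs=0.01)
        assert res.loa_high == pytest.approx(5.19, abs=0.01)

    def test_translation_equivariance(self):
        a = np.array([100.0, 105.0, 99.0, 101.0])
        b = np.array([99.0, 104.0, 100.0, 103.0])
        base = bland_altman(a, b)
        shifted = bland_altman(a + 7.5, b)
        assert shifted.mean_diff == pytest.approx(base.mean_diff + 7.5)
        assert shifted.loa_low == pytest.approx(base.loa_low + 7.5)
        assert shifted.loa_high == pytest.approx(base.loa_high + 7.5)

    def test_limits_symmetric_about_mean(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(100, 5, 30), rng.normal(100, 5, 30)
        res = bland_altman(a, b)
        assert res.loa_high - res.mean_diff == pytest.approx(res.mean_diff - res.loa_low)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2])


class TestPermutationImportance:
    class _LinearModel:
        """Scores = sigmoid(first feature); ignores everything else."""

        def predict_fragments(self, X, names):
            return 1 / (1 + np.exp(-X[:, 0]))

    def test_driving_feature_ranks_first_and_ignored_feature_near_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 3))
        y = (X[:, 0] > 0).astype(float)
        ranking = permutation_importance(self._LinearModel(), X, y,
                                         ("f0", "f1", "f2"), seed=0)
        assert ranking[0][0] == "f0" and ranking[0][1] > 0.3
        others = dict(ranking)
        assert abs(others["f1"]) < 0.05 and abs(others["f2"]) < 0.05

    def test_same_seed_identical_ranking(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 4))
        y = (X[:, 1] + 0.3 * rng.normal(size=100) > 0).astype(float)
        a = permutation_importance(self._LinearModel(), X, y, ("a", "b", "c", "d"), seed=9)
        b = permutation_importance(self._LinearModel(), X, y, ("a", "b", "c", "d"), seed=9)
        assert a == b

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            permutation_importance(self._LinearModel(), np.zeros((5, 1)),
                                   np.array([0, 1, 0, 1, 0.0]), ("x",), seed=0)
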
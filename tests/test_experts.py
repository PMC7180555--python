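"""Expert pool simulation: the three expert kinds, costs, collaboration."""

import numpy as np
import pytest
from scipy import stats

from comeal import (
    Dictionary,
    FeatureInstance,
    UncertaintyVector,
    broadcast_labeled_data,
    expert_cost_from_confidence,
    make_imperfect_expert,
    make_on_demand_expert,
    make_perfect_expert,
    update_uncertainty_all,
)
from comeal.experts import ExpertPool, _per_label_error
from comeal.synthgen import ConfigurationError
from tests.conftest import make_labeled_pool

LABELS = ("a", "b", "c")


def truth_from(pool: Dictionary):
    table = {i.uid: i.label for i in pool}
    return lambda x: table[x.uid]


@pytest.fixture
def pools():
    rng = np.random.default_rng(0)
    means = {"a": -4.0, "b": 0.0, "c": 4.0}
    init = make_labeled_pool(rng, means, n=40)
    eval_pool = make_labeled_pool(rng, means, n=30, uid_start=5000)
    return init, eval_pool


@pytest.fixture
def hard_pools():
    """Overlapping classes: a few-shot expert has substantial error."""
    rng = np.random.default_rng(1)
    means = {"a": -1.5, "b": 0.0, "c": 1.5}
    init = make_labeled_pool(rng, means, n=60)
    eval_pool = make_labeled_pool(rng, means, n=60, uid_start=5000)
    return init, eval_pool


class TestPerfectExpert:
    def test_zero_error_returns_ground_truth(self, pools):
        init, _ = pools
        e = make_perfect_expert(truth_from(init), 0.0, 10.0, LABELS, seed=0)
        assert all(e.query(x) == x.label for x in init)

    def test_full_error_binary_always_flips(self, pools):
        init, _ = pools
        e = make_perfect_expert(truth_from(init), 1.0, 10.0, ("a", "b"), seed=0)
        for x in init:
            if x.label in ("a", "b"):
                assert e.query(x) == ("b" if x.label == "a" else "a")

    def test_flip_rate_calibrated(self, pools):
        """Empirical flip fraction within a binomial CI of the configured rate."""
        init, _ = pools
        rate, n = 0.05, 10_000
        e = make_perfect_expert(truth_from(init), rate, 10.0, LABELS, seed=1)
        x = init[0]
        flips = sum(e.query(x) != x.label for _ in range(n))
        lo, hi = stats.binom.ppf([0.005, 0.995], n, rate)
        assert lo <= flips <= hi

    def test_not_updatable(self, pools):
        init, eval_pool = pools
        e = make_perfect_expert(truth_from(init), 0.0, 10.0, LABELS, seed=0)
        pool = ExpertPool([e], LABELS)
        before = dict(e.uncertainty.values)
        broadcast_labeled_data(list(init)[:10], pool)
        update_uncertainty_all(pool, eval_pool)
        assert e.uncertainty.values == before and e.unit_cost == 10.0

    def test_rejects_bad_error_rate(self, pools):
        init, _ = pools
        with pytest.raises(ConfigurationError):
            make_perfect_expert(truth_from(init), 1.5, 10.0, LABELS)


class TestImperfectExpert:
    def test_full_fraction_on_separable_data_is_confident(self, pools):
        init, eval_pool = pools
        e = make_imperfect_expert(init, 1.0, eval_pool, base_cost=5.0, seed=0)
        assert all(u < 5.0 for u in e.uncertainty.values.values())

    def test_label_absent_from_sample_scores_100(self, pools):
        init, eval_pool = pools
        only_ab = Dictionary([i for i in init if i.label != "c"], role="related_labeled")
        e = make_imperfect_expert(only_ab, 1.0, eval_pool, base_cost=5.0, seed=0)
        assert e.uncertainty["c"] == 100.0

    def test_more_data_does_not_raise_mean_uncertainty(self, hard_pools):
        init, eval_pool = hard_pools
        deltas = []
        for seed in range(10):
            lo = make_imperfect_expert(init, 0.05, eval_pool, 5.0, seed=seed)
            hi = make_imperfect_expert(init, 0.5, eval_pool, 5.0, seed=seed)
            deltas.append(hi.uncertainty.mean() - lo.uncertainty.mean())
        assert np.mean(deltas) <= 1e-9

    def test_rejects_bad_fraction(self, pools):
        init, eval_pool = pools
        with pytest.raises(ConfigurationError):
            make_imperfect_expert(init, 0.0, eval_pool, 5.0)


class TestOnDemandExpert:
    def test_abstention_closure(self, pools):
        init, eval_pool = pools
        e = make_on_demand_expert(init, ("a",), eval_pool, seed=0)
        answers = {e.query(x) for x in eval_pool}
        assert answers <= {"a", None}

    def test_full_scope_never_abstains(self, pools):
        init, eval_pool = pools
        e = make_on_demand_expert(init, LABELS, eval_pool, seed=0)
        assert all(e.query(x) is not None for x in eval_pool)

    def test_confident_labels_more_accurate(self, pools):
        init, eval_pool = pools
        accs_in, accs_out = [], []
        for seed in range(10):
            e = make_on_demand_expert(init, ("a",), eval_pool, n_other=3, seed=seed)
            preds = e.raw_predict(eval_pool.X)
            truth = eval_pool.y
            accs_in.append(np.mean([p == t for p, t in zip(preds, truth) if t == "a"]))
            accs_out.append(np.mean([p == t for p, t in zip(preds, truth) if t != "a"]))
        assert np.mean(accs_in) > np.mean(accs_out)

    def test_rejects_empty_scope(self, pools):
        init, eval_pool = pools
        with pytest.raises(ConfigurationError):
            make_on_demand_expert(init, (), eval_pool)


class TestCost:
    def test_full_confidence_costs_base(self):
        u = UncertaintyVector.uniform(LABELS, 0.0)
        assert expert_cost_from_confidence(u, 10.0) == 10.0

    def test_zero_confidence_is_free(self):
        u = UncertaintyVector.uniform(LABELS, 100.0)
        assert expert_cost_from_confidence(u, 10.0) == 0.0

    def test_hand_computed(self):
        u = UncertaintyVector({"a": 20.0, "b": 40.0})
        assert expert_cost_from_confidence(u, 10.0) == pytest.approx(7.0)

    def test_cost_monotone_in_confidence(self):
        """Elementwise-lower uncertainty never lowers the cost."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            u1 = rng.uniform(0, 100, 4)
            u2 = np.clip(u1 + rng.uniform(0, 40, 4), 0, 100)  # u2 >= u1
            c1 = expert_cost_from_confidence(UncertaintyVector(dict(zip("wxyz", u1))), 3.0)
            c2 = expert_cost_from_confidence(UncertaintyVector(dict(zip("wxyz", u2))), 3.0)
            assert c1 >= c2 - 1e-12


class TestCollaboration:
    def test_empty_batch_is_identity(self, pools):
        init, eval_pool = pools
        e = make_imperfect_expert(init, 0.1, eval_pool, 5.0, seed=0)
        pool = ExpertPool([e], LABELS)
        n_before = len(e._train)
        broadcast_labeled_data([], pool)
        assert len(e._train) == n_before

    def test_update_is_idempotent(self, pools):
        init, eval_pool = pools
        e = make_imperfect_expert(init, 0.2, eval_pool, 5.0, seed=0)
        pool = ExpertPool([e], LABELS)
        update_uncertainty_all(pool, eval_pool)
        once = dict(e.uncertainty.values)
        update_uncertainty_all(pool, eval_pool)
        assert e.uncertainty.values == once

    def test_perfect_eval_accuracy_scores_zero(self, pools):
        init, eval_pool = pools
        e = make_imperfect_expert(init, 1.0, eval_pool, 5.0, seed=0)
        # a full-data learner on this separable world is perfect on eval
        if all(u == 0.0 for u in e.uncertainty.values.values()):
            assert e.unit_cost == e.base_cost

    def test_stub_predictor_error_count(self, pools):
        _, eval_pool = pools
        four_a = Dictionary([i for i in eval_pool if i.label == "a"][:4], role="related_labeled")
        preds = ["a", "a", "a", "b"]  # wrong on 1 of 4
        u = _per_label_error(lambda X: preds, four_a, ("a",), trained_labels=("a",))
        assert u["a"] == pytest.approx(25.0)

    def test_broadcast_reduces_out_of_scope_uncertainty(self, pools):
        """Correct labels conveyed for unfamiliar classes shrink an on-demand
        expert's uncertainty there (10 seeds, separable data)."""
        init, eval_pool = pools
        rng = np.random.default_rng(99)
        deltas = []
        for seed in range(10):
            e = make_on_demand_expert(init, ("a",), eval_pool, n_other=1, seed=seed)
            before = np.mean([e.uncertainty["b"], e.uncertainty["c"]])
            batch = make_labeled_pool(np.random.default_rng(seed + 500),
                                      {"b": 0.0, "c": 4.0}, n=30, uid_start=9000)
            pool = ExpertPool([e], LABELS)
            broadcast_labeled_data(list(batch), pool)
            update_uncertainty_all(pool, eval_pool)
            after = np.mean([e.uncertainty["b"], e.uncertainty["c"]])
            deltas.append(after - before)
        assert np.mean(deltas) < 0

    def test_collaboration_preserves_or_improves_mean_uncertainty(self, hard_pools):
        """Statistical check over 20 seeds: broadcasting correct labels does
        not worsen updatable experts' mean uncertainty."""
        init, eval_pool = hard_pools
        deltas = []
        for seed in range(20):
            e = make_imperfect_expert(init, 0.05, eval_pool, 5.0, seed=seed)
            before = e.uncertainty.mean()
            batch = make_labeled_pool(np.random.default_rng(seed + 700),
                                      {"a": -1.5, "b": 0.0, "c": 1.5}, n=20, uid_start=7000)
            pool = ExpertPool([e], LABELS)
            broadcast_labeled_data(list(batch), pool)
            update_uncertainty_all(pool, eval_pool)
            deltas.append(e.uncertainty.mean() - before)
        # mean improvement, and no blow-up in any seed
        assert np.mean(deltas) <= 0.0
        t = stats.ttest_1samp(deltas, 0.0, alternative="less")
        assert t.pvalue < 0.05 or np.allclose(deltas, 0.0)


def test_pool_rejects_duplicate_ids(pools):
    init, eval_pool = pools
    e1 = make_imperfect_expert(init, 0.5, eval_pool, 5.0, seed=0, expert_id="dup")
    e2 = make_imperfect_expert(init, 0.5, eval_pool, 5.0, seed=1, expert_id="dup")
    with pytest.raises(ConfigurationError):
        ExpertPool([e1, e2], LABELS)
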
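"""Driver loop, variants, baselines, and scenario construction."""

import dataclasses

import numpy as np
import pytest

from comeal import (
    RunConfig,
    WorldConfig,
    build_scenario,
    run_driver,
    run_stl_baseline,
)
from comeal.driver import PoolSpec, SCENARIOS
from comeal.synthgen import ConfigurationError


def tiny_world(seed=0, **kw):
    kw.setdefault("n_subjects", 3)
    kw.setdefault("n_locations", 2)
    return WorldConfig(seed=seed, **kw)


def tiny_scenario(scenario="context_change", seed=0, n_per_class=40, pool_spec=None, **kw):
    kwargs = {"pool_spec": pool_spec} if pool_spec is not None else {}
    return build_scenario(scenario, tiny_world(seed, **kw), seed=seed,
                          n_per_class=n_per_class, **kwargs)


class TestBuildScenario:
    def test_context_change_leave_one_out(self):
        data = tiny_scenario()
        assert len(data.related) == 2  # 3 subjects -> 2 related domains
        assert data.X_L is not None and len(data.X_L) == 0
        assert len(data.X_U) > 0 and all(i.label is None for i in data.X_U)
        assert set(data.hidden_truth) == {i.uid for i in data.X_U}

    def test_user_need_change_new_labels_absent_from_sources(self):
        data = tiny_scenario("user_need_change")
        new = set(data.label_set[-2:])
        for src in data.related:
            assert not (set(src.labels_present()) & new)
        assert new <= set(data.hidden_truth.values())

    def test_configuration_change_prior_covers_label_subset(self):
        data = tiny_scenario("configuration_change")
        covered = set(data.X_L.labels_present())
        assert covered and covered < set(data.label_set)

    @pytest.mark.parametrize("seed", range(10))
    def test_configuration_prior_lowers_covered_label_uncertainty(self, seed):
        from comeal import RandomForestLearner, learner_uncertainty
        data = tiny_scenario("configuration_change", seed=seed)
        model = RandomForestLearner(seed=0).fit(data.X_L)
        u = learner_uncertainty(model, data.X_U, data.label_set)
        covered = set(data.X_L.labels_present())
        uncovered = set(data.label_set) - covered
        assert np.mean([u[l] for l in covered]) < np.mean([u[l] for l in uncovered])

    def test_infeasible_world_rejected(self):
        with pytest.raises(ConfigurationError):
            build_scenario("context_change", WorldConfig(n_subjects=1), seed=0)
        with pytest.raises(ConfigurationError):
            build_scenario("configuration_change", WorldConfig(n_locations=1), seed=0)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigurationError):
            build_scenario("weather_change", tiny_world(), seed=0)


class TestRunDriver:
    def test_vacuous_threshold_means_zero_query_rounds(self):
        data = tiny_scenario()
        cfg = RunConfig(u_th=1.0, seed=0)  # 100-point threshold everywhere
        r = run_driver(data.related, data.X_L, data.X_U, data.label_set, data.pool, cfg, data.eval_pool)
        assert len(r.rounds) == 1  # only the initialization trace
        assert r.ledger.total_cost == 0.0

    def test_terminates_at_budget(self):
        data = tiny_scenario(pool_spec=PoolSpec(perfect_error=0.0))
        cfg = RunConfig(u_th=0.001, budget_fraction=0.2, seed=0)
        r = run_driver(data.related, data.X_L, data.X_U, data.label_set, data.pool, cfg, data.eval_pool)
        queried = sum(len(t.queried_uids) for t in r.rounds)
        assert queried == int(np.ceil(0.2 * len(data.X_U)))

    def test_budget_one_exhausts_pool_with_unreachable_threshold(self):
        data = tiny_scenario(n_per_class=20, pool_spec=PoolSpec(perfect_error=0.0))
        cfg = RunConfig(u_th=0.001, budget_fraction=1.0, seed=0)
        r = run_driver(data.related, data.X_L, data.X_U, data.label_set, data.pool, cfg, data.eval_pool)
        assert r.rounds[-1].n_unlabeled == 0

    def test_round_monotonicity_and_conservation(self):
        data = tiny_scenario()
        cfg = RunConfig(seed=0, budget_fraction=0.2)
        r = run_driver(data.related, data.X_L, data.X_U, data.label_set, data.pool, cfg, data.eval_pool)
        for prev, cur in zip(r.rounds, r.rounds[1:]):
            assert cur.n_labeled > prev.n_labeled
            assert cur.n_unlabeled < prev.n_unlabeled
            assert cur.n_labeled + cur.n_unlabeled == prev.n_labeled + prev.n_unlabeled
        assert r.ledger.total_cost == pytest.approx(sum(rec.cost for rec in r.ledger.records))

    def test_full_reproducibility(self):
        traces = []
        for _ in range(2):
            data = tiny_scenario(seed=4)
            cfg = RunConfig(seed=4, budget_fraction=0.2)
            r = run_driver(data.related, data.X_L, data.X_U, data.label_set, data.pool, cfg, data.eval_pool)
            traces.append((r.accuracy_trace(), r.ledger.total_cost,
                           [t.queried_uids for t in r.rounds]))
        assert traces[0] == traces[1]

    def test_empty_pool_rejected(self):
        from comeal.experts import ExpertPool
        data = tiny_scenario()
        cfg = RunConfig(seed=0)
        with pytest.raises(ConfigurationError):
            run_driver(data.related, data.X_L, data.X_U, data.label_set,
                       ExpertPool([], data.label_set), cfg, data.eval_pool)

    def test_cal_star_auto_labels_ahead_of_queries(self):
        data = tiny_scenario("configuration_change", seed=1)
        base = run_driver(data.related, data.X_L, data.X_U, data.label_set, data.pool,
                          RunConfig(variant="CAL", seed=1), data.eval_pool)
        data2 = tiny_scenario("configuration_change", seed=1)
        star = run_driver(data2.related, data2.X_L, data2.X_U, data2.label_set, data2.pool,
                          RunConfig(variant="CAL_star", seed=1), data2.eval_pool)
        assert star.rounds[0].n_labeled >= base.rounds[0].n_labeled


class TestSTL:
    def test_identical_sources_accuracy_non_decreasing(self):
        """With sources matching the target, more source data never hurts
        (averaged over 10 seeds)."""
        firsts, lasts = [], []
        for seed in range(10):
            data = tiny_scenario(seed=seed, subject_shift_scale=0.0)
            cfg = RunConfig(variant="STL", budget_fraction=0.3, seed=seed)
            r = run_stl_baseline(data.related, data.X_L, data.X_U, data.label_set, cfg, data.eval_pool)
            accs = [a for a in r.accuracy_trace() if not np.isnan(a)]
            firsts.append(accs[0])
            lasts.append(accs[-1])
        assert np.mean(lasts) >= np.mean(firsts) - 0.01

    def test_no_rounds_without_sources(self):
        data = tiny_scenario()
        with pytest.raises(ConfigurationError):
            run_stl_baseline([], data.X_L, data.X_U, data.label_set,
                             RunConfig(variant="STL"), data.eval_pool)

    def test_far_shifted_source_degrades_late_accuracy(self):
        """Once similar data is exhausted, adding the far-shifted source's
        instances stops helping (10 seeds)."""
        import comeal.data as cd
        deltas = []
        for seed in range(10):
            data = tiny_scenario(seed=seed)
            # push one source far away in feature space
            far = data.related[1]
            shifted = cd.Dictionary(
                [dataclasses.replace(i, features=i.features + 25.0) for i in far],
                role="related_labeled", domain_id=far.domain_id)
            related = [data.related[0], shifted]
            cfg = RunConfig(variant="STL", budget_fraction=1.0, K=40, seed=seed)
            r = run_stl_baseline(related, data.X_L, data.X_U, data.label_set, cfg, data.eval_pool)
            accs = [a for a in r.accuracy_trace() if not np.isnan(a)]
            mid, end = accs[len(accs) // 2], accs[-1]
            deltas.append(end - mid)
        assert np.mean(deltas) <= 0.01


class TestQualitativeOrderings:
    """Smaller-N versions of the study comparisons (full-size in acceptance)."""

    def test_collaboration_never_needs_more_perfect_queries(self):
        diffs = []
        for seed in range(6):
            counts = {}
            for variant in ("CAL", "NCAL"):
                data = tiny_scenario(seed=seed, n_per_class=100)
                cfg = RunConfig(variant=variant, seed=seed)
                r = run_driver(data.related, data.X_L, data.X_U, data.label_set,
                               data.pool, cfg, data.eval_pool)
                counts[variant] = r.queries_of_kind("perfect")
            diffs.append(counts["NCAL"] - counts["CAL"])
        assert np.mean(diffs) >= 0

    def test_on_demand_experts_relieve_perfect_expert(self):
        diffs = []
        for seed in range(5):
            counts = {}
            for n_od in (0, 4):
                data = build_scenario("context_change", tiny_world(seed), seed=seed,
                                      n_per_class=60,
                                      pool_spec=PoolSpec(n_on_demand=n_od))
                cfg = RunConfig(seed=seed)
                r = run_driver(data.related, data.X_L, data.X_U, data.label_set,
                               data.pool, cfg, data.eval_pool)
                counts[n_od] = r.queries_of_kind("perfect")
            diffs.append(counts[0] - counts[4])
        assert np.mean(diffs) >= 0


@pytest.mark.parametrize("scenario", SCENARIOS)
def test_every_scenario_runs_end_to_end(scenario):
    data = tiny_scenario(scenario, seed=2)
    cfg = RunConfig(seed=2, budget_fraction=0.1)
    r = run_driver(data.related, data.X_L, data.X_U, data.label_set, data.pool, cfg, data.eval_pool)
    assert 0.0 <= r.final_accuracy <= 1.0
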
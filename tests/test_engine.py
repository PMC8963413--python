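"""Simulation engine: tick pipeline, determinism, summaries, oracles."""

import dataclasses

import numpy as np
import pytest

from panicsim import (
    InterventionConfig,
    ModelParams,
    NeedsSpec,
    NetworkParams,
    SimulationConfig,
    TimeSeries,
    run,
    run_replicates,
    summarize,
)
from conftest import make_config


def zero_need_config(**kwargs):
    return make_config(**kwargs).replace(
        needs=NeedsSpec(m0_mean=0.0, m0_sd=0.0, s0_mean=0.0, s0_sd=0.0))


def series_of(counts, horizon=None):
    counts = np.asarray(counts)
    h = horizon or len(counts)
    zeros = np.zeros(h)
    return TimeSeries(tick=np.arange(1, h + 1), buyer_count=counts,
                      stock=zeros, mean_emotion=zeros, posts_true=zeros,
                      posts_rumor=zeros, replenished=np.zeros(h, dtype=bool))


class TestZeroNeedLimit:
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_no_needs_no_buyers_and_full_stock(self, seed):
        series = run(zero_need_config(seed=seed))
        assert np.all(series.buyer_count == 0)
        assert np.all(series.stock == 1.0)


class TestDeterminism:
    def test_same_seed_identical_series(self, small_config):
        a, b = run(small_config), run(small_config)
        for field in ("buyer_count", "stock", "mean_emotion",
                      "posts_true", "posts_rumor", "replenished"):
            np.testing.assert_array_equal(getattr(a, field),
                                          getattr(b, field))

    def test_same_seed_byte_identical_csv(self, small_config, tmp_path):
        paths = [tmp_path / "a.csv", tmp_path / "b.csv"]
        for path in paths:
            run(small_config).to_csv(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seeds_generally_differ(self, small_config):
        a = run(small_config)
        b = run(small_config.replace(seed=small_config.seed + 1))
        assert not np.array_equal(a.buyer_count, b.buyer_count)


class TestSaturation:
    def test_low_safety_high_material_saturates_without_intervention(self):
        config = make_config(s_mean=0.2, m_mean=0.8, n_agents=300, horizon=15)
        series = run(config)
        n = config.network.n_agents
        assert series.buyer_count.max() == n
        # saturation persists: no stop
        assert series.buyer_count[-1] == n
        assert not summarize(series).stopped


class TestSummarize:
    def test_all_zero_series(self):
        s = summarize(series_of(np.zeros(10, dtype=int)))
        assert (s.max_buyers, s.t_max, s.stopped, s.t_stop) == (0, 1, True, 1)

    def test_saturating_series_never_stops(self):
        counts = np.array([0, 200, 1000] + [1000] * 7)
        s = summarize(series_of(counts))
        assert s.max_buyers == 1000
        assert s.t_max == 3
        assert not s.stopped and s.t_stop is None

    def test_stopped_series_records_first_sustained_zero(self):
        counts = np.array([0, 800, 400] + [0] * 7)
        s = summarize(series_of(counts))
        assert s.stopped and s.t_stop == 4
        assert s.max_buyers == 800 and s.t_max == 2

    def test_transient_zero_is_not_a_stop(self):
        counts = np.array([0, 800, 0, 50] + [0] * 5 + [10])
        s = summarize(series_of(counts))
        assert not s.stopped


class TestReplicates:
    def test_single_replicate_equals_run(self, small_config):
        [(series, _)] = run_replicates(small_config, 1)
        np.testing.assert_array_equal(series.buyer_count,
                                      run(small_config).buyer_count)

    def test_replicates_use_consecutive_seeds(self, small_config):
        results = run_replicates(small_config, 3)
        expected = run(small_config.replace(seed=small_config.seed + 2))
        np.testing.assert_array_equal(results[2][0].buyer_count,
                                      expected.buyer_count)

    def test_zero_need_replicates_all_quiet(self):
        results = run_replicates(zero_need_config(), 4)
        assert all(s.max_buyers == 0 for _, s in results)


class TestStateInvariants:
    def test_all_agent_quantities_stay_in_range(self):
        config = make_config(s_mean=0.8, m_mean=0.8, horizon=20,
                             interventions=InterventionConfig(
                                 supply_enabled=True,
                                 review_guidance_enabled=True,
                                 official_enabled=True,
                                 counseling_enabled=True))
        series = run(config, record_agents=True)
        for key in ("M", "E", "A"):
            values = series.agents[key]
            assert values.min() >= 0.0 and values.max() <= 1.0
        assert set(np.unique(series.agents["state"])) <= {0.0, 1.0}
        assert series.stock.min() >= 0.0

    def test_buyer_count_matches_recomputed_states(self):
        series = run(make_config(horizon=12), record_agents=True)
        d_a = ModelParams().d_a
        recomputed = (series.agents["A"] >= d_a).sum(axis=1)
        np.testing.assert_array_equal(series.buyer_count, recomputed)
        np.testing.assert_array_equal(series.buyer_count,
                                      series.agents["state"].sum(axis=1))

    def test_stock_non_increasing_without_supply_monitoring(self):
        series = run(make_config(s_mean=0.5, m_mean=0.8, horizon=20))
        assert np.all(np.diff(series.stock) <= 1e-12)

    def test_supply_monitoring_bounds_the_stock(self):
        # with q_move >= d_sd, the post-replenishment stock never falls
        # below the threshold
        config = make_config(
            s_mean=0.5, m_mean=0.8, horizon=20,
            interventions=InterventionConfig(supply_enabled=True, q_move=1.0))
        series = run(config)
        assert series.stock.min() >= min(1.0, ModelParams().d_sd) - 1e-12


class TestNullEffectEquivalence:
    """A disabled mechanism is tick-for-tick identical to an enabled
    mechanism whose parameters are zeroed."""

    CASES = [
        (InterventionConfig(official_enabled=False),
         InterventionConfig(official_enabled=True, gov_strength=0.0)),
        (InterventionConfig(counseling_enabled=False),
         InterventionConfig(counseling_enabled=True, str_pr=0.0)),
        (InterventionConfig(supply_enabled=False),
         InterventionConfig(supply_enabled=True, q_move=0.0)),
    ]

    @pytest.mark.parametrize("disabled,zeroed", CASES)
    def test_equivalence(self, disabled, zeroed):
        base = make_config(s_mean=0.5, m_mean=0.6, horizon=15)
        a = run(base.replace(interventions=disabled))
        b = run(base.replace(interventions=zeroed))
        for field in ("buyer_count", "stock", "mean_emotion"):
            np.testing.assert_array_equal(getattr(a, field),
                                          getattr(b, field))


class TestReviewMechanics:
    def test_post_classification_matches_recorded_series(self):
        config = make_config(
            s_mean=0.5, m_mean=0.6, horizon=15,
            interventions=InterventionConfig(review_guidance_enabled=True))
        series = run(config, record_agents=True)
        model = ModelParams()
        for t in range(len(series)):
            buyers = series.agents["state"][t] == 1
            attitudes = series.agents["A"][t][buyers]
            rumors = int(np.sum((attitudes - model.d_a)
                                * (model.d_sd - series.stock[t]) < 0))
            assert series.posts_rumor[t] == rumors
            assert series.posts_true[t] == buyers.sum() - rumors

    @pytest.mark.parametrize("t_exam,expected_first_change", [(0, 2), (2, 4)])
    def test_review_delay_defers_first_neighbor_influence(
            self, t_exam, expected_first_change):
        # without official response, a non-buyer's M can only move when a
        # delivered post influences it: first delivery is at 2 + t_exam
        config = make_config(
            s_mean=0.5, m_mean=0.5, horizon=8,
            interventions=InterventionConfig(review_guidance_enabled=True,
                                             t_exam=t_exam))
        series = run(config, record_agents=True)
        m, state = series.agents["M"], series.agents["state"]
        changed_tick = None
        for t in range(1, len(series)):
            non_buyers = state[t - 1] == 0
            if np.any(m[t][non_buyers] != m[t - 1][non_buyers]):
                changed_tick = t + 1  # ticks are 1-based
                break
        assert changed_tick == expected_first_change


def _single_agent_oracle(m0, s0, model, ivc, horizon):
    """Independent scalar recursion for one isolated agent."""
    onset = 2  # "next_update" convention
    M, S = m0, s0
    E = min(max(model.alpha * M + model.beta * S, 0.0), 1.0)
    A = abs(1.0 - E) * (model.alpha * M + model.beta * (1.0 - S)) + abs(E) * E
    state = 1 if A >= model.d_a else 0
    Q = 1.0
    out = [(M, E, A, state, Q)]
    for t in range(2, horizon + 1):
        q_prev = Q
        Q = max(Q - state / 1, 0.0)
        if ivc.supply_enabled and Q < model.d_sd:
            Q += ivc.q_move
        if state == 1:
            q_i = max(q_prev - 1.0, 0.0)
            M = M + model.mu * (model.d_sd - q_i)
        i_gov = (ivc.gov_strength * ivc.tr_gov
                 if ivc.official_enabled and t >= onset + ivc.t_timely_g
                 else 0.0)
        M = min(max(M - model.lambda1 * i_gov, 0.0), 1.0)
        pr = (ivc.str_pr * ivc.tr_ol
              if ivc.counseling_enabled and t >= onset + ivc.t_timely_p
              else 0.0)
        E = min(max(model.alpha * M + model.beta * S + 0.0
                    - model.lambda2 * pr, 0.0), 1.0)
        A = (abs(1.0 - E) * (model.alpha * M + model.beta * (1.0 - S))
             + abs(E) * E)
        state = 1 if A >= model.d_a else 0
        out.append((M, E, A, state, Q))
    return np.array(out)


class TestSingleAgentOracle:
    SETTINGS = [
        (0.9, 0.2, ModelParams(), InterventionConfig()),
        (0.7, 0.6, ModelParams(),
         InterventionConfig(official_enabled=True, gov_strength=1.0,
                            tr_gov=1.0, t_timely_g=1)),
        (0.65, 0.5,
         ModelParams(alpha=0.7, beta=0.3, mu=0.5, d_sd=0.5, d_a=0.55,
                     lambda2=0.3),
         InterventionConfig(counseling_enabled=True, str_pr=1.0, tr_ol=0.9,
                            t_timely_p=2)),
        (0.8, 0.1, ModelParams(d_sd=0.8),
         InterventionConfig(supply_enabled=True, q_move=0.7)),
        (1.0, 0.0, ModelParams(),
         InterventionConfig(supply_enabled=True, official_enabled=True,
                            counseling_enabled=True, gov_strength=0.5,
                            tr_gov=0.5, t_timely_g=0, t_timely_p=1)),
    ]

    @pytest.mark.parametrize("m0,s0,model,ivc", SETTINGS)
    def test_engine_matches_hand_rolled_recursion(self, m0, s0, model, ivc):
        horizon = 12
        config = SimulationConfig(
            network=NetworkParams(n_agents=1, m_attach=0, leader_fraction=0),
            model=model,
            needs=NeedsSpec(m0_mean=m0, m0_sd=0.0, s0_mean=s0, s0_sd=0.0,
                            con_sd=0.0),
            interventions=dataclasses.replace(ivc),
            horizon=horizon, seed=0)
        series = run(config, record_agents=True)
        expected = _single_agent_oracle(m0, s0, model, ivc, horizon)
        np.testing.assert_array_equal(series.agents["M"][:, 0], expected[:, 0])
        np.testing.assert_array_equal(series.agents["E"][:, 0], expected[:, 1])
        np.testing.assert_array_equal(series.agents["A"][:, 0], expected[:, 2])
        np.testing.assert_array_equal(series.agents["state"][:, 0],
                                      expected[:, 3])
        np.testing.assert_array_equal(series.stock, expected[:, 4])


class TestStochasticOrderings:
    def test_peak_buyers_increase_with_material_need(self):
        means = {}
        for m_mean in (0.2, 0.5, 0.8):
            peaks = [run(make_config(s_mean=0.5, m_mean=m_mean, n_agents=200,
                                     horizon=10, seed=s)).buyer_count.max()
                     for s in range(30)]
            means[m_mean] = np.mean(peaks)
        assert means[0.8] >= means[0.5] >= means[0.2]

    def test_supply_monitoring_shortens_stop_time(self):
        # comprehensive plan (with supply) vs the same plan without
        # supply monitoring, in the high-material-need regime
        def mean_stop(supply):
            iv = InterventionConfig(
                supply_enabled=supply, review_guidance_enabled=True,
                official_enabled=True, counseling_enabled=True)
            stops = []
            for s in range(10):
                cfg = make_config(s_mean=0.2, m_mean=0.8, horizon=30,
                                  seed=s, interventions=iv)
                summary = summarize(run(cfg))
                stops.append(summary.t_stop if summary.stopped
                             else cfg.horizon + 1)
            return np.mean(stops)

        assert mean_stop(True) <= mean_stop(False)
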
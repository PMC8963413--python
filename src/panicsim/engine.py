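"""Seeded simulation runs: tick loop, replication, capture, summary.

One run executes a synchronous tick pipeline over the whole population.
Per tick t >= 2:

1. deplete the stock by last tick's buyers;
2. supply-monitoring check / replenishment (if enabled);
3. assign random purchase ranks among last tick's buyers;
4. buyers compute perceived stock and self-experience, non-buyers
   receive the (possibly review-delayed) neighbor-post influence;
5. material-need update, including any active official response;
6. herd pressure from last tick's neighbor states;
7. emotion update, including any active counseling effect;
8. emotion weights and attitude;
9. buying states and the buyer count.

Randomness is split into independent sub-streams (network build,
initial draws, per-tick order permutations and post draws) spawned from
one master seed, so toggling an intervention never perturbs unrelated
draws.  Replicate r uses seed ``base_seed + r`` and regenerates both
the network and the initial draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import sparse

from . import dynamics, interventions
from .config import ConfigError, SimulationConfig
from .network import SocialNetwork, generate_network

__all__ = ["TimeSeries", "RunSummary", "run", "run_replicates", "summarize"]


@dataclass
class TimeSeries:
    """Per-tick population aggregates of one run (tick 1..horizon)."""

    tick: np.ndarray
    buyer_count: np.ndarray
    stock: np.ndarray
    mean_emotion: np.ndarray
    posts_true: np.ndarray
    posts_rumor: np.ndarray
    replenished: np.ndarray
    # per-agent trajectories (horizon x N arrays keyed "M","E","A","state"),
    # populated only when run(..., record_agents=True)
    agents: dict | None = None

    def __len__(self) -> int:
        return len(self.tick)

    @property
    def n_replenishments(self) -> int:
        return int(self.replenished.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tick": self.tick,
            "buyer_count": self.buyer_count,
            "stock": self.stock,
            "mean_emotion": self.mean_emotion,
            "posts_true": self.posts_true,
            "posts_rumor": self.posts_rumor,
            "replenished": self.replenished.astype(int),
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


@dataclass
class RunSummary:
    """Headline statistics of one run."""

    max_buyers: int
    t_max: int
    stopped: bool
    t_stop: int | None
    n_replenishments: int
    final_buyers: int

    def to_dict(self) -> dict:
        return {
            "max_buyers": self.max_buyers,
            "t_max": self.t_max,
            "stopped": self.stopped,
            "t_stop": self.t_stop,
            "n_replenishments": self.n_replenishments,
            "final_buyers": self.final_buyers,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def summarize(series: TimeSeries) -> RunSummary:
    """Peak, time-to-peak and the sustained-zero stop time of a run.

    "Stopped" requires the buyer count to be zero from some tick
    through the end of the horizon, not just a transient dip.
    """
    counts = np.asarray(series.buyer_count)
    if len(counts) == 0:
        raise ValueError("cannot summarize an empty series")
    max_buyers = int(counts.max())
    t_max = int(series.tick[int(np.argmax(counts))])
    stopped = counts[-1] == 0
    t_stop: int | None = None
    if stopped:
        nonzero = np.flatnonzero(counts)
        last_nonzero = int(nonzero[-1]) if len(nonzero) else -1
        t_stop = int(series.tick[last_nonzero + 1]) if last_nonzero + 1 < len(counts) else None
        if t_stop is None:  # all-zero tail impossible here, but keep safe
            stopped = False
    return RunSummary(
        max_buyers=max_buyers,
        t_max=t_max,
        stopped=bool(stopped),
        t_stop=t_stop,
        n_replenishments=series.n_replenishments,
        final_buyers=int(counts[-1]),
    )


def _adjacency(network: SocialNetwork) -> sparse.csr_matrix:
    n = network.n_agents
    rows, cols = [], []
    for u, v in network.graph.edges():
        rows.append(u)
        cols.append(v)
        rows.append(v)
        cols.append(u)
    data = np.ones(len(rows), dtype=np.float64)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def run(config: SimulationConfig,
        network: SocialNetwork | None = None,
        record_agents: bool = False) -> TimeSeries:
    """Execute one seeded run and return its full time series.

    With ``record_agents`` the returned series also carries the full
    per-agent trajectories of M, E, A and the buying state (debug /
    verification mode).
    """
    if not isinstance(config, SimulationConfig):
        raise ConfigError("run() expects a SimulationConfig")
    model = config.model
    iv = config.interventions
    n = config.network.n_agents
    horizon = config.horizon

    ss_network, ss_init, ss_tick = np.random.SeedSequence(config.seed).spawn(3)
    if network is None:
        network = generate_network(config.network,
                                   np.random.default_rng(ss_network))
    rng_init = np.random.default_rng(ss_init)
    rng_tick = np.random.default_rng(ss_tick)

    adj = _adjacency(network)
    deg = np.maximum(np.asarray(adj.sum(axis=1)).ravel(), 1.0)
    trust = interventions.trust_vector(network.roles, iv)

    state = dynamics.initial_state(config.needs, n, model, rng_init)
    M, S, con = state["M"], state["S"], state["con"]
    E, A = state["E"], state["A"]
    buying = state["state"].astype(np.float64)

    q = 1.0  # one unit: enough for everyone to buy basics once

    ticks = np.arange(1, horizon + 1)
    buyer_count = np.zeros(horizon, dtype=np.int64)
    stock = np.zeros(horizon)
    mean_emotion = np.zeros(horizon)
    posts_true = np.zeros(horizon, dtype=np.int64)
    posts_rumor = np.zeros(horizon, dtype=np.int64)
    replenished = np.zeros(horizon, dtype=bool)

    delivery_delay = interventions.post_delivery_delay(iv)
    pending_influence: dict[int, np.ndarray] = {}

    trace: dict[str, list] | None = None
    if record_agents:
        trace = {"M": [], "E": [], "A": [], "state": []}

    def record_and_publish(t: int) -> None:
        """Record tick aggregates, then publish this tick's posts."""
        idx = t - 1
        buyer_count[idx] = int(buying.sum())
        stock[idx] = q
        mean_emotion[idx] = float(E.mean())
        if trace is not None:
            trace["M"].append(M.copy())
            trace["E"].append(np.asarray(E, dtype=float).copy())
            trace["A"].append(np.asarray(A, dtype=float).copy())
            trace["state"].append(buying.copy())
        # Buyers publish their experience; each post carries the
        # publisher's current attitude.
        if iv.post_probability >= 1.0:
            posting = buying == 1
        else:
            posting = (buying == 1) & (rng_tick.random(n) < iv.post_probability)
        n_posting = int(posting.sum())
        if iv.review_guidance_enabled:
            itype = interventions.classify_post(A, q, model.d_sd, model.d_a)
            tf = interventions.authenticity_factor(itype, model.gamma)
            posts_rumor[idx] = int(np.sum(posting & (itype == interventions.INFO_RUMOR)))
            posts_true[idx] = n_posting - posts_rumor[idx]
        else:
            tf = np.ones(n)
            posts_true[idx] = n_posting
        if n_posting and t + delivery_delay <= horizon:
            contrib = np.where(posting, (A - model.d_a) * trust * tf, 0.0)
            numer = adj @ contrib
            denom = adj @ posting.astype(np.float64)
            influence = np.divide(numer, denom,
                                  out=np.zeros(n), where=denom > 0)
            pending_influence[t + delivery_delay] = influence

    record_and_publish(1)

    for t in range(2, horizon + 1):
        prev_buying = buying
        prev_q = q
        ni_prev = int(prev_buying.sum())

        # (1) depletion, (2) supply monitoring
        q = dynamics.deplete_materials(q, ni_prev, n)
        if iv.supply_enabled:
            q, fired = interventions.replenish(q, model.d_sd, iv.q_move)
            replenished[t - 1] = fired

        # (3) purchase ranks, (4) perceived stock and self-experience
        self_exp = np.zeros(n)
        if ni_prev:
            buyers_idx = np.flatnonzero(prev_buying == 1)
            ranks = rng_tick.permutation(ni_prev) + 1
            q_seen = prev_q if iv.perceived_stock == "previous" else q
            q_i = dynamics.perceived_materials(q_seen, ranks, n)
            self_exp[buyers_idx] = model.mu * (model.d_sd - q_i)

        # delayed neighbor-post influence for last tick's non-buyers
        i_net = pending_influence.pop(t, None)
        if i_net is None:
            i_net = np.zeros(n)

        # (5) material-need update with official response
        i_gov = interventions.official_effect(iv, t)
        M = dynamics.material_need_update(M, prev_buying, self_exp, i_net,
                                          i_gov, model)

        # (6) herd pressure, (7) emotion with counseling
        n_buying_neighbors = adj @ prev_buying
        F = dynamics.herd_pressure(n_buying_neighbors, deg, con)
        pr = interventions.counseling_effect(iv, t)
        E = dynamics.emotion(M, S, F, pr, model)

        # (8) attitude, (9) state
        A = dynamics.attitude(M, S, E, model)
        buying = dynamics.buying_state(A, model.d_a).astype(np.float64)

        record_and_publish(t)

    return TimeSeries(
        tick=ticks,
        buyer_count=buyer_count,
        stock=stock,
        mean_emotion=mean_emotion,
        posts_true=posts_true,
        posts_rumor=posts_rumor,
        replenished=replenished,
        agents=({key: np.vstack(rows) for key, rows in trace.items()}
                if trace is not None else None),
    )


def run_replicates(config: SimulationConfig,
                   replicates: int | None = None
                   ) -> list[tuple[TimeSeries, RunSummary]]:
    """Run R replicates; replicate r uses seed base_seed + r."""
    if replicates is None:
        replicates = config.replicates
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    results = []
    for r in range(replicates):
        series = run(config.replace(seed=config.seed + r))
        results.append((series, summarize(series)))
    return results


def iter_replicates(config: SimulationConfig,
                    replicates: int) -> Iterator[tuple[TimeSeries, RunSummary]]:
    """Lazy variant of :func:`run_replicates`."""
    for r in range(replicates):
        series = run(config.replace(seed=config.seed + r))
        yield series, summarize(series)
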
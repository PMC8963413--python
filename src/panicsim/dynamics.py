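"""Per-tick behavioural update rules.

Each agent i carries a material need M_i(t), a constant safety need
S_i(t) = S0, a panic emotion E_i(t), an attitude A_i(t) toward buying,
a conformity Con(i) and a binary buying state.  The attitude is a
convex combination of need pressure and emotion,

    A = theta1 * (alpha * M + beta * (1 - S)) + theta2 * E,

with emotion-derived weights theta1 = |1 - E|, theta2 = |E|: the more
panicked an agent is, the less its rational needs matter.  Crossing the
threshold d_A flips the agent into the buying state; the state is
recomputed every tick, so agents can also calm down and stop buying.

All functions operate element-wise on scalars or NumPy arrays, so the
engine can apply them to the whole population at once while unit tests
exercise them on single values.
"""

from __future__ import annotations

import numpy as np

from .config import ModelParams, NeedsSpec

__all__ = [
    "clipped_normal",
    "emotion_weights",
    "attitude",
    "buying_state",
    "assign_orders",
    "perceived_materials",
    "self_experience",
    "neighbor_influence",
    "material_need_update",
    "safety_need",
    "herd_pressure",
    "emotion",
    "deplete_materials",
]


def clipped_normal(mean: float, sd: float, size: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Normal draws mapped into [0, 1]: values > 1 become 1, < 0 become 0."""
    if sd == 0.0:
        return np.full(size, np.clip(mean, 0.0, 1.0))
    return np.clip(rng.normal(mean, sd, size), 0.0, 1.0)


def emotion_weights(E):
    """Weights (theta1, theta2) = (|1 - E|, |E|) of need vs. emotion."""
    E = np.asarray(E, dtype=float)
    theta1 = np.abs(1.0 - E)
    theta2 = np.abs(E)
    if theta1.ndim == 0:
        return float(theta1), float(theta2)
    return theta1, theta2


def attitude(M, S, E, params: ModelParams):
    """Attitude toward panic buying, in [0, 1].

    A = theta1 * (alpha*M + beta*(1-S)) + theta2 * E.  A low safety
    need S means the agent feels unsafe going without supplies, hence
    the (1 - S) term: scarcity-anxious agents lean toward buying.
    """
    theta1, theta2 = emotion_weights(E)
    need = params.alpha * np.asarray(M) + params.beta * (1.0 - np.asarray(S))
    A = theta1 * need + theta2 * np.asarray(E)
    return float(A) if np.ndim(A) == 0 else A


def buying_state(A, d_a: float):
    """1 if the attitude reaches the panic-buying threshold (inclusive)."""
    state = np.asarray(A) >= d_a
    return int(state) if state.ndim == 0 else state.astype(np.int8)


def assign_orders(previous_buyers: np.ndarray,
                  rng: np.random.Generator) -> dict[int, int]:
    """Uniformly random purchase ranks 1..k over last tick's buyers."""
    buyers = np.asarray(previous_buyers, dtype=np.int64)
    ranks = rng.permutation(len(buyers)) + 1
    return {int(node): int(rank) for node, rank in zip(buyers, ranks)}


def perceived_materials(q_prev, order, n_agents: int):
    """Stock a buyer sees: Q(t-1) minus the share taken by earlier buyers.

    Q_i = Q(t-1) - order_i / N, floored at zero.  Defined only for
    agents that bought in the previous tick.
    """
    q_i = np.maximum(np.asarray(q_prev, dtype=float)
                     - np.asarray(order, dtype=float) / n_agents, 0.0)
    return float(q_i) if q_i.ndim == 0 else q_i


def self_experience(prev_state, q_i, params: ModelParams):
    """Need shift from what a buyer saw on the shelves.

    Zero for non-buyers; otherwise mu * (d_SD - Q_i): positive (need
    grows) when perceived stock is below the supply-demand threshold,
    negative (need relaxes) when shelves look full.
    """
    prev_state = np.asarray(prev_state)
    value = np.where(prev_state == 1,
                     params.mu * (params.d_sd - np.asarray(q_i, dtype=float)),
                     0.0)
    return float(value) if value.ndim == 0 else value


def neighbor_influence(attitudes, trusts, d_a: float, tf=None):
    """Mean trust-weighted attitude excess of buying neighbors (Eq-6 style).

    I_net = sum_j (A_j - d_A) * TR(j) [* TF_j] / k over the k buying
    neighbors j; zero when an agent has no buying neighbors.  ``tf`` is
    the per-post authenticity factor under review and guidance (rumors
    contribute with inverted sign).
    """
    attitudes = np.asarray(attitudes, dtype=float)
    if attitudes.size == 0:
        return 0.0
    trusts = np.broadcast_to(np.asarray(trusts, dtype=float), attitudes.shape)
    contrib = (attitudes - d_a) * trusts
    if tf is not None:
        contrib = contrib * np.broadcast_to(np.asarray(tf, dtype=float),
                                            attitudes.shape)
    return float(np.sum(contrib) / attitudes.size)


def material_need_update(prev_m, prev_state, self_exp, i_net, i_gov: float,
                         params: ModelParams):
    """Next material need, clamped to [0, 1].

    Buyers update from their own shelf experience, non-buyers from the
    information of buying neighbors; an active official response
    subtracts lambda1 * I_gov from everyone.
    """
    prev_state = np.asarray(prev_state)
    m = np.where(prev_state == 1,
                 np.asarray(prev_m, dtype=float) + np.asarray(self_exp, dtype=float),
                 np.asarray(prev_m, dtype=float) + np.asarray(i_net, dtype=float))
    m = np.clip(m - params.lambda1 * i_gov, 0.0, 1.0)
    return float(m) if m.ndim == 0 else m


def safety_need(s0):
    """Safety need is pinned to its initial official-news-driven value."""
    return s0


def herd_pressure(n_buying_neighbors, n_neighbors, con):
    """Conformity-weighted share of neighbors that were buying last tick."""
    f = (np.asarray(n_buying_neighbors, dtype=float)
         / np.asarray(n_neighbors, dtype=float)) * np.asarray(con, dtype=float)
    return float(f) if f.ndim == 0 else f


def emotion(M, S, F, pr: float, params: ModelParams):
    """Panic emotion, clamped to [0, 1].

    E = alpha*M + beta*S + F - lambda2*PR: internal need pressure plus
    herd pressure, damped by an active psychological-counseling effect.
    """
    e = (params.alpha * np.asarray(M, dtype=float)
         + params.beta * np.asarray(S, dtype=float)
         + np.asarray(F, dtype=float)
         - params.lambda2 * pr)
    e = np.clip(e, 0.0, 1.0)
    return float(e) if e.ndim == 0 else e


def deplete_materials(q_prev: float, ni_prev: int, n_agents: int) -> float:
    """Stock after last tick's buyers each took 1/N of a unit, floored at 0."""
    return max(float(q_prev) - ni_prev / n_agents, 0.0)


def initial_state(needs: NeedsSpec, n_agents: int, params: ModelParams,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw M0, S0, Con and compute the tick-1 emotion/attitude/state.

    No prior tick exists, so herd pressure is zero and no intervention
    is active yet.
    """
    m0 = clipped_normal(needs.m0_mean, needs.m0_sd, n_agents, rng)
    s0 = clipped_normal(needs.s0_mean, needs.s0_sd, n_agents, rng)
    con = clipped_normal(needs.con_mean, needs.con_sd, n_agents, rng)
    e = emotion(m0, s0, 0.0, 0.0, params)
    a = attitude(m0, s0, e, params)
    state = buying_state(a, params.d_a)
    return {"M": m0, "S": s0, "con": con, "E": e, "A": a, "state": state}
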
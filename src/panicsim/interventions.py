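"""The five social-intervention mechanisms as composable effects.

* Supply monitoring: replenish the stock by ``q_move`` whenever it
  falls below the supply-demand threshold.
* Information review + guidance (one switch; review is the
  prerequisite for guidance): each buyer's post is classified as rumor
  or truth by comparing its buying tendency against actual scarcity;
  guidance multiplies the post's influence by +/-gamma and delays its
  delivery by ``t_exam`` ticks.
* Official response: a persistent, trust-scaled reduction of material
  need, starting after the response delay.
* Psychological counseling: a persistent, trust-scaled damping of
  panic emotion, starting after the counseling delay.

Delayed effects share one onset convention: the disturbance starts at
tick 1, a mechanism with delay d first affects updates at tick 2 + d,
and persists every tick thereafter.
"""

from __future__ import annotations

import numpy as np

from .config import InterventionConfig, ModelParams

__all__ = [
    "replenish",
    "classify_post",
    "authenticity_factor",
    "official_effect",
    "counseling_effect",
    "effect_onset_tick",
    "trust_vector",
]

INFO_RUMOR = 1
INFO_TRUE = 2


def replenish(q: float, d_sd: float, q_move: float) -> tuple[float, bool]:
    """Top up the stock when it is below the supply-demand threshold.

    Returns the (possibly) replenished stock and whether a
    replenishment event fired.  The threshold comparison is strict:
    Q >= d_SD leaves the stock untouched.
    """
    if q < d_sd:
        return q + q_move, True
    return q, False


def classify_post(a_j, q: float, d_sd: float, d_a: float):
    """Rumor-or-truth review of a buyer's post.

    A post carries its publisher's attitude.  It is truthful when the
    buying tendency matches actual scarcity: (A_j - d_A) * (d_SD - Q)
    >= 0 marks truth (2), a negative product marks a rumor (1).
    """
    product = (np.asarray(a_j, dtype=float) - d_a) * (d_sd - q)
    itype = np.where(product < 0.0, INFO_RUMOR, INFO_TRUE)
    return int(itype) if itype.ndim == 0 else itype


def authenticity_factor(info_type, gamma: float):
    """+gamma for true posts, -gamma for rumors."""
    tf = np.where(np.asarray(info_type) == INFO_RUMOR, -gamma, gamma)
    return float(tf) if tf.ndim == 0 else tf


def effect_onset_tick(delay: int, convention: str = "next_update") -> int:
    """First tick at which a mechanism with the given delay acts.

    Under "next_update" a mechanism with delay d first acts at tick
    2 + d (it reacts to the tick-1 disturbance and enters the first
    update that can use it); under "event_plus_delay" at tick 1 + d.
    """
    return (2 if convention == "next_update" else 1) + delay


def official_effect(config: InterventionConfig, tick: int) -> float:
    """I_gov(t): Gov * TR_gov once the response delay has elapsed."""
    if not config.official_enabled:
        return 0.0
    if tick < effect_onset_tick(config.t_timely_g, config.effect_onset):
        return 0.0
    return config.gov_strength * config.tr_gov


def counseling_effect(config: InterventionConfig, tick: int) -> float:
    """PR(t): Str_PR * TR_ol once the counseling delay has elapsed."""
    if not config.counseling_enabled:
        return 0.0
    if tick < effect_onset_tick(config.t_timely_p, config.effect_onset):
        return 0.0
    return config.str_pr * config.tr_ol


def trust_vector(roles: np.ndarray, config: InterventionConfig) -> np.ndarray:
    """Per-node trust TR(j): opinion leaders vs. ordinary netizens."""
    return np.where(np.asarray(roles, dtype=bool),
                    config.tr_ol, config.tr_ordinary)


def post_delivery_delay(config: InterventionConfig) -> int:
    """Ticks between publication and influence on need updates.

    A post published at tick s influences need updates at tick
    s + 1 + t_exam under review; without review there is no exam delay.
    """
    return 1 + (config.t_exam if config.review_guidance_enabled else 0)
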
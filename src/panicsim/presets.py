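"""Preset experiment definitions and replicated study drivers.

The scenario library covers the standard study grid: the five
need-level baselines, the single-mechanism studies (supply monitoring,
information review & guidance, official response including low-trust
and delayed variants, psychological counseling), the ten two- and
three-mechanism combination strategies plus the comprehensive plan,
and the three real-event case parameterisations (China/Shijiazhuang,
UK March, UK December).

Need levels map to clipped-normal means: low 0.2, medium 0.5,
high 0.8, all with sd 0.15.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import (
    InterventionConfig,
    ModelParams,
    NeedsSpec,
    SimulationConfig,
)
from .engine import run, summarize

__all__ = [
    "ScenarioPreset",
    "scenario_library",
    "get_preset",
    "combination_study",
    "needs_sweep",
    "COMBINATIONS",
    "SWEEP_SCENARIOS",
    "NEED_LEVELS",
]

NEED_LEVELS = {"low": 0.2, "medium": 0.5, "high": 0.8}

# combination number -> (supply, review/guidance, official, counseling)
COMBINATIONS: dict[str, tuple[bool, bool, bool, bool]] = {
    "none": (False, False, False, False),
    "combo_1": (True, True, False, False),    # supply + information
    "combo_2": (True, False, True, False),    # supply + official
    "combo_3": (True, False, False, True),    # supply + psychology
    "combo_4": (False, True, True, False),    # information + official
    "combo_5": (False, True, False, True),    # information + psychology
    "combo_6": (False, False, True, True),    # official + psychology
    "combo_7": (True, True, True, False),     # supply + information + official
    "combo_8": (True, True, False, True),     # supply + information + psychology
    "combo_9": (True, False, True, True),     # supply + official + psychology
    "combo_10": (False, True, True, True),    # information + official + psychology
    "comprehensive": (True, True, True, True),
}

SWEEP_SCENARIOS = ("none", "no_supply", "comprehensive")


@dataclass
class ScenarioPreset:
    name: str
    description: str
    config: SimulationConfig


def _needs(s_level: str, m_level: str) -> NeedsSpec:
    return NeedsSpec(m0_mean=NEED_LEVELS[m_level], s0_mean=NEED_LEVELS[s_level])


def _mechanisms(name: str) -> InterventionConfig:
    supply, info, official, psych = COMBINATIONS[name]
    return InterventionConfig(
        supply_enabled=supply,
        review_guidance_enabled=info,
        official_enabled=official,
        counseling_enabled=psych,
    )


def scenario_library() -> list[ScenarioPreset]:
    """All named presets; names are unique."""
    presets: list[ScenarioPreset] = []

    def add(name: str, description: str, config: SimulationConfig) -> None:
        presets.append(ScenarioPreset(name, description, config))

    # --- need-level grid, no intervention -----------------------------
    grid = [("high", "high"), ("high", "low"), ("low", "high"),
            ("low", "low"), ("medium", "medium")]
    for s, m in grid:
        add(f"no_intervention_{s}S_{m}M",
            f"No intervention; {s} safety need, {m} material need",
            SimulationConfig(needs=_needs(s, m), horizon=30))

    # --- supply monitoring ---------------------------------------------
    for q_move in (1.0, 2.0):
        for s, m in [("high", "high"), ("low", "high"), ("medium", "medium")]:
            add(f"supply_qmove{q_move:g}_{s}S_{m}M",
                f"Supply monitoring only, Q_move={q_move:g}; "
                f"{s} safety, {m} material need",
                SimulationConfig(
                    needs=_needs(s, m),
                    interventions=InterventionConfig(supply_enabled=True,
                                                     q_move=q_move),
                    horizon=30))

    # --- information review & guidance ---------------------------------
    for t_exam in (1, 2):
        for s, m in [("high", "high"), ("low", "high"), ("medium", "medium")]:
            add(f"review_texam{t_exam}_{s}S_{m}M",
                f"Information review & guidance only, t_exam={t_exam}; "
                f"{s} safety, {m} material need",
                SimulationConfig(
                    needs=_needs(s, m),
                    interventions=InterventionConfig(
                        review_guidance_enabled=True, t_exam=t_exam),
                    horizon=30))

    # --- official response ---------------------------------------------
    official_variants = [
        ("official", InterventionConfig(official_enabled=True)),
        ("official_low_trust",
         InterventionConfig(official_enabled=True, tr_gov=0.5)),
        ("official_delayed",
         InterventionConfig(official_enabled=True, t_timely_g=3)),
    ]
    for stem, iv in official_variants:
        for s, m in [("high", "high"), ("low", "high"), ("medium", "medium")]:
            add(f"{stem}_{s}S_{m}M",
                f"{stem.replace('_', ' ').capitalize()} only; "
                f"{s} safety, {m} material need",
                SimulationConfig(needs=_needs(s, m), interventions=replace(iv),
                                 horizon=30))

    # --- psychological counseling ---------------------------------------
    for s, m in [("high", "high"), ("low", "high"), ("medium", "medium")]:
        add(f"counseling_{s}S_{m}M",
            f"Psychological counseling only; {s} safety, {m} material need",
            SimulationConfig(
                needs=_needs(s, m),
                interventions=InterventionConfig(counseling_enabled=True),
                horizon=30))

    # --- combination strategies (low safety / high material regime) -----
    for name in COMBINATIONS:
        label = {"none": "no_intervention", "comprehensive": "comprehensive"}
        add(label.get(name, name),
            f"Combination strategy '{name}' in the low-safety/"
            "high-material regime",
            SimulationConfig(needs=_needs("low", "high"),
                             interventions=_mechanisms(name), horizon=30))

    # --- case studies ----------------------------------------------------
    case_model = ModelParams(d_sd=0.6, d_a=0.5, lambda1=0.1, lambda2=0.1)
    with warnings.catch_warnings():
        # the China case deliberately uses a response strength of 10
        warnings.simplefilter("ignore", UserWarning)
        china_interventions = InterventionConfig(
            supply_enabled=True, review_guidance_enabled=True,
            official_enabled=True, counseling_enabled=True,
            q_move=1.0, gov_strength=10.0, str_pr=1.0,
            t_timely_g=2, t_timely_p=1, tr_gov=1.0, tr_ol=0.8)
    add("china_case",
        "Shijiazhuang (China, Jan 2021) event: strong, trusted and timely "
        "official response, counseling, guidance and supply monitoring",
        SimulationConfig(
            model=replace(case_model),
            needs=NeedsSpec(m0_mean=0.5, s0_mean=0.0),
            interventions=china_interventions,
            horizon=20))
    add("uk_march",
        "UK March 2020 event: lower-trust official response, counseling "
        "and supply monitoring, no information guidance",
        SimulationConfig(
            model=replace(case_model),
            needs=NeedsSpec(m0_mean=0.6, s0_mean=0.3),
            interventions=InterventionConfig(
                supply_enabled=True, review_guidance_enabled=False,
                official_enabled=True, counseling_enabled=True,
                q_move=1.0, gov_strength=1.0, str_pr=1.0,
                t_timely_g=1, t_timely_p=1, tr_gov=0.5, tr_ol=0.8),
            horizon=30))
    add("uk_december",
        "UK December 2020 event: high needs, weakened supply transfer "
        "(Q_move=0.5), weaker and later counseling, guidance on",
        SimulationConfig(
            model=replace(case_model),
            needs=NeedsSpec(m0_mean=0.8, s0_mean=0.6),
            interventions=InterventionConfig(
                supply_enabled=True, review_guidance_enabled=True,
                official_enabled=True, counseling_enabled=True,
                q_move=0.5, gov_strength=1.0, str_pr=0.5,
                t_timely_g=1, t_timely_p=2, tr_gov=0.5, tr_ol=0.8),
            horizon=30))

    names = [p.name for p in presets]
    assert len(names) == len(set(names)), "preset names must be unique"
    return presets


def get_preset(name: str) -> ScenarioPreset:
    for preset in scenario_library():
        if preset.name == name:
            return preset
    available = ", ".join(p.name for p in scenario_library())
    raise KeyError(f"unknown preset {name!r}; available: {available}")


def combination_study(replicates: int = 30, seed: int = 0,
                      horizon: int = 30) -> pd.DataFrame:
    """Replicated comparison of the 12 strategies (10 combinations,
    comprehensive plan and no intervention) in the low-safety/
    high-material regime.

    Aggregation: mean over replicates for peaks and final counts,
    median for the time-to-peak and stop times, fraction for stopped.
    """
    records = []
    for name in COMBINATIONS:
        config = SimulationConfig(
            needs=_needs("low", "high"),
            interventions=_mechanisms(name),
            horizon=horizon, seed=seed)
        summaries = [summarize(run(config.replace(seed=seed + r)))
                     for r in range(replicates)]
        t_stops = [s.t_stop for s in summaries if s.t_stop is not None]
        records.append({
            "plan": name,
            "supply": COMBINATIONS[name][0],
            "information": COMBINATIONS[name][1],
            "official": COMBINATIONS[name][2],
            "psychology": COMBINATIONS[name][3],
            "mean_max_buyers": float(np.mean([s.max_buyers for s in summaries])),
            "median_t_max": float(np.median([s.t_max for s in summaries])),
            "stopped_fraction": float(np.mean([s.stopped for s in summaries])),
            "median_t_stop": float(np.median(t_stops)) if t_stops else np.nan,
            "mean_final_buyers": float(np.mean([s.final_buyers for s in summaries])),
            "mean_replenishments": float(np.mean([s.n_replenishments
                                                  for s in summaries])),
        })
    return pd.DataFrame.from_records(records)


def _sweep_interventions(scenario: str) -> InterventionConfig:
    if scenario == "none":
        return InterventionConfig()
    if scenario == "no_supply":
        # combined intervention excluding supply monitoring
        return InterventionConfig(review_guidance_enabled=True,
                                  official_enabled=True,
                                  counseling_enabled=True)
    if scenario == "comprehensive":
        return InterventionConfig(supply_enabled=True,
                                  review_guidance_enabled=True,
                                  official_enabled=True,
                                  counseling_enabled=True)
    raise ValueError(f"unknown sweep scenario {scenario!r}; "
                     f"choose from {SWEEP_SCENARIOS}")


def needs_sweep(n_runs: int = 100, scenario: str = "comprehensive",
                seed: int = 0, horizon: int = 100) -> pd.DataFrame:
    """Random-needs sweep: per run, draw the initial material- and
    safety-need means uniformly on [0, 1], simulate to the horizon and
    record the final buyer count.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    iv = _sweep_interventions(scenario)
    rng = np.random.default_rng(seed)
    records = []
    for k in range(n_runs):
        s_mean, m_mean = rng.uniform(0.0, 1.0, 2)
        config = SimulationConfig(
            needs=NeedsSpec(m0_mean=float(m_mean), s0_mean=float(s_mean)),
            interventions=replace(iv),
            horizon=horizon, seed=seed + 1 + k)
        series = run(config)
        records.append({
            "run": k,
            "scenario": scenario,
            "s0_mean": float(s_mean),
            "m0_mean": float(m_mean),
            "final_buyers": int(series.buyer_count[-1]),
        })
    return pd.DataFrame.from_records(records)
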
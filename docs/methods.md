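# Methods

## Model

The simulator is a discrete-time, synchronous multi-agent model of
panic-buying contagion. A population of `N` agents occupies a fixed
Barabási–Albert network; behaviour evolves through coupled per-agent
recursions for material need `M`, safety need `S`, panic emotion `E`,
attitude `A` and a binary buying state, plus one global stock variable
`Q`. The model assumes:

- the network is static over a run (no growth, birth or death);
- safety need is pinned to its initial value (`S(t) = S0`), reflecting
  that safety information arrives through official channels and is not
  updated by the contagion itself;
- the buying state is memoryless: it is recomputed from the attitude
  every tick, so agents can revert to non-buying (there is no
  forgetting or satiation mechanism — an agent whose attitude stays
  above threshold keeps buying every tick);
- `α + β = 1` with `α > β` (material need dominates safety need in the
  Maslow ordering); both are population-wide constants.

### Tick pipeline

Tick 1 is the initial state: `M0`, `S0`, `Con` are drawn from clipped
normals, emotion and attitude are computed with zero herd pressure and
no interventions, and `Q = 1`. Every later tick runs one synchronous
pass:

1. deplete `Q` by `NI(t−1)/N` (floored at 0);
2. if supply monitoring is on and `Q < d_SD`, add `Q_move` (one event);
3. draw a uniformly random purchase order over last tick's buyers;
4. buyers compute their perceived stock `Q_i = Q(t−1) − order_i/N`
   (floored at 0) and self-experience `μ(d_SD − Q_i)`; non-buyers
   receive the delivered neighbour-post influence;
5. update `M` (buyers: self-experience; non-buyers: influence; both
   minus `λ₁·I_gov` when the official response is active), clamp to
   `[0,1]`;
6. herd pressure `F = (NI_i(t−1)/N_i)·Con(i)`;
7. update `E = α·M + β·S + F − λ₂·PR`, clamp to `[0,1]`;
8. weights `θ₁ = |1−E|`, `θ₂ = |E|`; attitude
   `A = θ₁(α·M + β(1−S)) + θ₂·E`;
9. buying states `A ≥ d_A` and the buyer count.

All `t−1` subscripts in the update rules refer to the previous tick's
recorded values, making the pipeline order-independent within a tick.

### Posts and their delayed influence

Every buyer publishes one post per tick bought (a post probability
below 1 is exposed in the configuration). A post carries its
publisher's current attitude; the influence vector computed from the
posts of tick `s` is delivered to need updates at tick `s + 1 + t_exam`
— one intrinsic tick of social latency, plus the review delay when
review and guidance are active. Under review, a post is classed as a
rumor when its buying tendency contradicts actual scarcity
(`(A_j − d_A)(d_SD − Q) < 0`, evaluated with the global stock at
publication time; the zero product counts as truth), and its
contribution is multiplied by `−γ` (rumors) or `+γ` (truth). An agent
with no posting buying neighbours receives zero influence (the 0/0
case of the mean is defined as 0).

### Delayed persistent effects

The disturbance starts at tick 1. A mechanism with delay `d` first
acts at tick `2 + d` (the first update that can use a reaction to the
tick-1 state) and persists every tick thereafter: the official
response subtracts `λ₁·Gov·TR_gov` from every agent's material need,
counseling subtracts `λ₂·Str_PR·TR_ol` from every emotion. The
alternative onset reading (`1 + d`) is available via
`effect_onset="event_plus_delay"`. Persistence (rather than a one-shot
correction) is the reading consistent with the sustained post-peak
decay of buyer counts in the published single-mechanism trajectories.

One printed form of the counseling-adjusted emotion update omits the
`PR(t)` factor after `λ₂`; since `PR(t)` is defined and named in the
surrounding description, the implemented update is `−λ₂·PR(t)`.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `N` | population size | 1000 | agents |
| `m_attach` | edges per new node in the BA growth | 3 | edges |
| `leader_fraction` | share of top-degree nodes made opinion leaders | 0.05 | — |
| `α`, `β` | material vs. safety weight | 0.6 / 0.4 | — |
| `μ` | self-experience gain | 0.2 | — |
| `d_SD` | supply–demand threshold | 0.65 | stock units |
| `d_A` | panic-buying attitude threshold | 0.6 | — |
| `γ` | authenticity factor of reviewed posts | 1.0 | — |
| `λ₁`, `λ₂` | official / counseling influence gains | 0.2 / 0.2 | — |
| `Q_move` | stock units per replenishment | 1.0 | stock units |
| `Gov`, `Str_PR` | response / counseling strength | 1.0 / 1.0 | — |
| `t_exam`, `t_timelyG`, `t_timelyP` | review / response / counseling delays | 1 / 1 / 1 | ticks |
| `TR_gov`, `TR_ol`, `TR_ordinary` | trust weights | 1.0 / 1.0 / 1.0 | — |

`m_attach = 3` is not fixed by the source study; it is the standard BA
density giving mean degree ≈ 6 at `N = 1000`. `Gov` values above 1
(used by the China case, `Gov = 10`) are accepted with a warning since
they exceed the nominal `(0,1)` range. Need distributions are normals
clipped to `[0,1]`; the low/medium/high study levels use means
0.2/0.5/0.8 with sd 0.15, and conformity uses `N(0.5, 0.15)`.

## Randomness and reproducibility

One master seed spawns three independent sub-streams: network growth,
initial draws, and the per-tick stream (purchase orders and post
draws). Toggling an intervention therefore never perturbs unrelated
randomness, which is what makes the disabled-mechanism /
zeroed-parameter equivalence exact. Replicate `r` runs with seed
`base + r` and regenerates both the network and the initial draws.
Identical configuration and seed give byte-identical CSV output.

## What the generator emulates — and what it does not

The synthetic population emulates the study conditions themselves:
clipped-normal needs and conformity, a scale-free contact structure
with degree-ranked opinion leaders, and a single homogeneous stock.
It does not emulate features of real purchase data: heterogeneous
per-agent `α/β`, household stocking capacity, price signals, media
cycles, or the decay of attention (forgetting). Passing tests
therefore demonstrate internal correctness of the dynamics and
reproducibility of the study grid, not predictive validity for real
panic-buying incidents.

## Numerical conventions

- `M`, `E` are clamped to `[0,1]` after their updates and `Q` is
  floored at 0; attitudes stay in `[0,1]` automatically once `E` does.
- Degree ties at the opinion-leader cutoff break by ascending node id.
- Purchase ranks are 1-indexed and drawn fresh each tick.
- "Stopped" requires a zero buyer count sustained to the end of the
  horizon; a transient zero does not count. Aggregation across
  replicates uses means for peaks, medians for stop times
  (never-stopping runs enter as horizon + 1), modes for event counts
  and fractions for stop indicators.
- Horizons: 30 ticks for single-mechanism and combination studies,
  20 for the China case, 100 for the random-needs sweep (where the
  final buyer count is read at tick 100).

## Known limitations

Two structural properties of the printed update rules dominate the
strong-need regimes and are worth understanding before comparing
against previously reported single-run trajectories:

1. **Emotion saturation.** Herd pressure enters the emotion sum with
   weight up to `Con(i)`, so in high-need regimes `E` clamps at 1 for
   most agents, which forces `A = 1` regardless of material need. Once
   a large majority buys, the supply channel (which only acts on `M`)
   cannot unlock the population; under supply monitoring alone the
   stock is then re-topped every tick rather than a handful of times.
2. **Explosive influence.** The neighbour-influence term adds the full
   mean attitude excess of buying neighbours to every non-buyer's need
   every tick, so medium-need outbreaks grow by roughly a factor of two
   per tick and reach near-saturation within four ticks. Reported
   trajectories in which a medium-need outbreak peaks at around a
   hundred buyers, or in which an official response caps the peak well
   below saturation, are not reachable from these update rules; the
   corresponding headline checks in `tests/test_acceptance.py` document
   this by failing at their stated tolerances while the structural
   property checks all pass.

There is also a genuine tension between two reported behaviours of the
official response: as a single mechanism it reportedly drives a
high-need outbreak to zero, while in supply-free combinations the same
mechanism reportedly leaves 700+ buyers indefinitely. Under any single
reading of the persistent response effect, only one of the two can
hold; this implementation follows the persistent reading, under which
official-containing combinations eventually collapse.

The forgetting mechanism (decay of attention after an outbreak) is
explicitly out of scope, as are price dynamics, per-agent targeting of
counseling, and any fitting to observed purchase data.
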
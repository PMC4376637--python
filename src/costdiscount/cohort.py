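"""Synthetic stimulus design and agent simulation.

The stimulus designer reproduces the discriminative two-block design: offer
pairs are kept only when, for at least two of nine simulated agents per model
family, a deterministic hyperbolic, linear and concave (sigmoidal) decider
disagree about the preferred option; trivial pairs (tiny cost difference,
huge magnitude difference) are excluded and pairs with two high costs are
rationed.  Agents then choose by softmax sampling, yielding trial tables with
known ground truth for the fitting pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import ChoiceDataset, StimulusSet
from .models import ChoiceParams, choice_probability, discounted_value, get_model
from .staircase import StaircaseConfig, StaircaseState, pest_update

__all__ = [
    "Agent",
    "default_agent_grids",
    "design_exp1_stimuli",
    "simulate_cohort",
    "simulate_exp2_session",
]


@dataclass(frozen=True)
class Agent:
    """A simulated decider: a generating model plus choice parameters."""

    model: str
    params: Mapping[str, float]
    beta: float
    alpha: float = 1.0
    subject: str = "agent"

    def __post_init__(self) -> None:
        spec = get_model(self.model)
        for par in spec.params:
            if par not in self.params:
                raise ValueError(f"agent for {self.model!r} is missing parameter {par!r}")
            lo, hi = spec.bounds[par]
            if not lo <= float(self.params[par]) <= hi:
                raise ValueError(
                    f"agent parameter {par}={self.params[par]} outside native bounds [{lo}, {hi}]"
                )
        if not self.beta > 0:
            raise ValueError("agent beta must be > 0")

    def choice_params(self) -> ChoiceParams:
        return ChoiceParams(values=dict(self.params), beta=self.beta, alpha=self.alpha)


def default_agent_grids() -> dict[str, list[dict[str, float]]]:
    """Nine shallow-to-steep parameter sets per design family.

    The concave family is represented by the sigmoidal model (three log-spaced
    slopes crossed with three turning points).
    """
    return {
        "hyperbolic": [{"k": float(k)} for k in np.geomspace(0.5, 30.0, 9)],
        "linear": [{"k": float(k)} for k in np.geomspace(5.0, 75.0, 9)],
        "sigmoidal": [
            {"k": float(k), "p": p}
            for k in np.geomspace(3.0, 30.0, 3)
            for p in (0.3, 0.5, 0.7)
        ],
    }


def _family_preferences(m1, c1, m2, c2, grids) -> np.ndarray:
    """Deterministic preferred option per (family, agent, pair): 1, 2 or 0 (tie)."""
    families = sorted(grids)
    n_agents = len(grids[families[0]])
    prefs = np.zeros((len(families), n_agents, len(m1)), dtype=np.int8)
    for fi, fam in enumerate(families):
        if len(grids[fam]) != n_agents:
            raise ValueError("every family must have the same number of agents")
        for ai, params in enumerate(grids[fam]):
            v1 = discounted_value(fam, m1, c1, params)
            v2 = discounted_value(fam, m2, c2, params)
            prefs[fi, ai] = np.where(v1 > v2, 1, np.where(v2 > v1, 2, 0))
    return prefs


def discriminative_mask(
    m1, c1, m2, c2, grids: Mapping[str, Sequence[Mapping[str, float]]], min_agents: int = 2
) -> np.ndarray:
    """True where a pair separates at least two model families for >= ``min_agents`` agents.

    For each agent index the three family deciders are compared; the pair
    counts for that agent when two families with strict preferences disagree.
    """
    prefs = _family_preferences(
        np.asarray(m1, float), np.asarray(c1, float), np.asarray(m2, float), np.asarray(c2, float), grids
    )
    n_fam = prefs.shape[0]
    disagree = np.zeros(prefs.shape[1:], dtype=bool)  # (agents, pairs)
    for a in range(n_fam):
        for b in range(a + 1, n_fam):
            both = (prefs[a] != 0) & (prefs[b] != 0)
            disagree |= both & (prefs[a] != prefs[b])
    return disagree.sum(axis=0) >= min_agents


def design_exp1_stimuli(
    n_per_block: int = 100,
    agent_grids: Mapping[str, Sequence[Mapping[str, float]]] | None = None,
    seed: int = 0,
    n_blocks: int = 2,
    cost_type: str = "effort",
    magnitude_max: int = 75,
    cost_grid_step: float = 0.05,
    trivial_cost_gap: float = 0.1,
    trivial_magnitude_gap: float = 40.0,
    high_cost_threshold: float = 0.4,
    high_cost_fraction: float = 0.15,
    min_agents: int = 2,
    max_draws: int = 2_000_000,
) -> StimulusSet:
    """Draw a discriminative two-block stimulus set.

    Candidate pairs are sampled over integer magnitudes in [0, ``magnitude_max``]
    and gridded costs in [0, 1] and retained when they (a) are not trivial
    (cost gap < ``trivial_cost_gap`` paired with magnitude gap >
    ``trivial_magnitude_gap``), (b) pass :func:`discriminative_mask`, (c) do
    not exceed the quota of pairs with both costs above
    ``high_cost_threshold``, and (d) do not duplicate a retained pair.
    Raises ``RuntimeError`` naming the binding constraint when ``max_draws``
    candidates do not yield enough pairs.
    """
    grids = dict(agent_grids) if agent_grids is not None else default_agent_grids()
    rng = np.random.default_rng(seed)
    n_total = n_per_block * n_blocks
    high_quota = int(np.floor(high_cost_fraction * n_total))
    n_cost_levels = int(round(1.0 / cost_grid_step)) + 1

    kept: list[tuple[float, float, float, float]] = []
    seen: set[tuple[float, float, float, float]] = set()
    n_high = 0
    drawn = 0
    rejected = {"trivial": 0, "not_discriminative": 0, "high_cost_quota": 0, "duplicate": 0}
    batch = 4096
    while len(kept) < n_total and drawn < max_draws:
        m = rng.integers(0, magnitude_max + 1, size=(batch, 2)).astype(float)
        c = rng.integers(0, n_cost_levels, size=(batch, 2)) * cost_grid_step
        drawn += batch
        trivial = (np.abs(c[:, 0] - c[:, 1]) < trivial_cost_gap) & (
            np.abs(m[:, 0] - m[:, 1]) > trivial_magnitude_gap
        )
        rejected["trivial"] += int(trivial.sum())
        ok = ~trivial
        disc = np.zeros(batch, dtype=bool)
        disc[ok] = discriminative_mask(m[ok, 0], c[ok, 0], m[ok, 1], c[ok, 1], grids, min_agents)
        rejected["not_discriminative"] += int(ok.sum() - disc.sum())
        for i in np.flatnonzero(disc):
            if len(kept) >= n_total:
                break
            pair = (m[i, 0], round(c[i, 0], 6), m[i, 1], round(c[i, 1], 6))
            if pair in seen:
                rejected["duplicate"] += 1
                continue
            is_high = pair[1] > high_cost_threshold and pair[3] > high_cost_threshold
            if is_high and n_high >= high_quota:
                rejected["high_cost_quota"] += 1
                continue
            seen.add(pair)
            kept.append(pair)
            n_high += int(is_high)
    if len(kept) < n_total:
        binding = max(rejected, key=rejected.get)
        raise RuntimeError(
            f"could only assemble {len(kept)}/{n_total} stimulus pairs after {drawn} draws; "
            f"binding constraint: {binding} (rejections: {rejected})"
        )
    arr = np.array(kept, dtype=float)
    block = np.repeat(np.arange(1, n_blocks + 1), n_per_block)
    return StimulusSet(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], block, cost_type=cost_type)


def simulate_cohort(
    agents: Sequence[Agent],
    stimuli: StimulusSet,
    seed: int = 0,
    realized_fraction: float = 0.3,
) -> list[ChoiceDataset]:
    """Sample one choice dataset per agent on a shared stimulus set.

    Option 1 is chosen with its softmax probability under the agent's model.
    Realised-cost flags hit ``realized_fraction`` exactly (drawn without
    replacement, then shuffled) and never influence the simulated choices.
    """
    if len(stimuli) == 0:
        raise ValueError("stimulus set is empty")
    streams = np.random.SeedSequence(seed).spawn(len(agents))
    n = len(stimuli)
    n_realized = int(round(realized_fraction * n))
    datasets = []
    for idx, (agent, ss) in enumerate(zip(agents, streams)):
        rng = np.random.default_rng(ss)
        v1 = discounted_value(agent.model, stimuli.m1, stimuli.c1, agent.params, agent.alpha)
        v2 = discounted_value(agent.model, stimuli.m2, stimuli.c2, agent.params, agent.alpha)
        p1 = choice_probability(agent.beta, v1, v2)
        chosen = np.where(rng.random(n) < p1, 1, 2)
        realized = np.zeros(n, dtype=bool)
        realized[:n_realized] = True
        rng.shuffle(realized)
        subject = agent.subject if agent.subject != "agent" else f"s{idx + 1:02d}"
        datasets.append(
            ChoiceDataset(
                subject=subject,
                cost_type=stimuli.cost_type,
                m1=stimuli.m1,
                c1=stimuli.c1,
                m2=stimuli.m2,
                c2=stimuli.c2,
                chosen=chosen,
                realized=realized,
                block=stimuli.block,
                trial=np.arange(1, n + 1),
                default_option=None,
            )
        )
    return datasets


def simulate_exp2_session(
    agent: Agent,
    config: StaircaseConfig | None = None,
    seed: int = 0,
) -> tuple[ChoiceDataset, dict]:
    """Run an agent through the interleaved-staircase session.

    Per block, each of the six cost levels is offered ``trials_per_level``
    times in randomised order; the costly option's magnitude follows its own
    PEST staircase while the default option costs nothing.  Each staircase
    owns an independent random stream, so perturbing the choices at one level
    can never alter another level's offer sequence.

    Returns the trial table (option 1 = default) and per-(block, level)
    traces with the offered magnitudes, acceptances and re-initialisation
    trial indices.
    """
    config = config or StaircaseConfig()
    root = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(root.spawn(1)[0])
    # two independent streams per (block, level): one for the agent's choices,
    # one for re-initialisation jitter, so each staircase is self-contained
    level_streams = root.spawn(2 * len(config.blocks) * len(config.effort_levels))

    rows = {k: [] for k in ("m1", "c1", "m2", "c2", "chosen", "block", "trial")}
    traces: dict = {}
    realized_all = []
    trial_counter = 0
    stream_i = 0
    for bi, blk in enumerate(config.blocks, start=1):
        states = {}
        rngs = {}
        jitter_rngs = {}
        for level in config.effort_levels:
            states[level] = StaircaseState(
                effort=level,
                magnitude=blk.initial_magnitude,
                step=blk.initial_step,
                initial_magnitude=blk.initial_magnitude,
                initial_step=blk.initial_step,
                jitter=blk.jitter,
            )
            rngs[level] = np.random.default_rng(level_streams[stream_i])
            jitter_rngs[level] = np.random.default_rng(level_streams[stream_i + 1])
            traces[(bi, level)] = {
                "offered": [],
                "accepted": [],
                "reinit_at": [],
                "jitter_seed": level_streams[stream_i + 1].entropy,
                "jitter_key": level_streams[stream_i + 1].spawn_key,
            }
            stream_i += 2
        order = np.repeat(np.array(config.effort_levels), config.trials_per_level)
        order_rng.shuffle(order)
        n_block = len(order)
        realized = np.zeros(n_block, dtype=bool)
        realized[: int(round(config.realized_fraction * n_block))] = True
        order_rng.shuffle(realized)
        realized_all.append(realized)
        for t, level in enumerate(order):
            level = float(level)
            state = states[level]
            offer_m = state.magnitude
            v_default = discounted_value(agent.model, blk.default_magnitude, 0.0, agent.params, agent.alpha)
            v_var = discounted_value(agent.model, offer_m, level, agent.params, agent.alpha)
            p_accept = choice_probability(agent.beta, v_var, v_default)
            accepted = bool(rngs[level].random() < p_accept)
            trial_counter += 1
            rows["m1"].append(blk.default_magnitude)
            rows["c1"].append(0.0)
            rows["m2"].append(offer_m)
            rows["c2"].append(level)
            rows["chosen"].append(2 if accepted else 1)
            rows["block"].append(bi)
            rows["trial"].append(trial_counter)
            tr = traces[(bi, level)]
            tr["offered"].append(offer_m)
            tr["accepted"].append(accepted)
            new_state = pest_update(state, accepted, jitter_rngs[level])
            if new_state.n_reinit > state.n_reinit:
                tr["reinit_at"].append(len(tr["offered"]) - 1)
            states[level] = new_state
        traces[(bi, "final_states")] = states
    # costs of the variable option exceed 1 never; magnitudes may exceed 75 by
    # staircase design, so bypass the Experiment-1 stimulus bounds here.
    dataset = ChoiceDataset(
        subject=agent.subject,
        cost_type="effort",
        m1=rows["m1"],
        c1=rows["c1"],
        m2=rows["m2"],
        c2=rows["c2"],
        chosen=rows["chosen"],
        realized=np.concatenate(realized_all),
        block=rows["block"],
        trial=rows["trial"],
        default_option=1,
    )
    return dataset, traces
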
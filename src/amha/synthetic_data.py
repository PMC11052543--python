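"""Synthetic longitudinal panels and networks with known ground truth.

Everything downstream — filtering, descriptives, calibration, simulation —
is testable offline against the generator's bookkeeping: the true rates,
the full per-person trajectory log and the exact transition log with
neighbour context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .calibration import AMHaParameters, SocialRate
from .data_model import (STATE_ORDER, CutoffPolicy, SocialNetwork, StatePanel,
                         TransitionTable)
from .network_sim import (_graph_to_csr, _neighbor_counts, _step_probs,
                          _synchronous_step)


def default_true_parameters() -> AMHaParameters:
    """Plausible per-4-year rates used as the default generative truth.

    Spontaneous rates sit in the 0.02-0.30 band and social rates in the
    0.01-0.05 per-neighbour band; social terms exist for moderate uptake,
    escalation under heavy contacts, and abstinence pulls from abstaining
    contacts.
    """
    alpha = {("A", "M"): 0.12, ("A", "H"): 0.01,
             ("M", "A"): 0.11, ("M", "H"): 0.08,
             ("H", "A"): 0.02, ("H", "M"): 0.25}
    beta = {
        ("A", "M"): {"M": SocialRate(0.02), "H": SocialRate(0.03)},
        ("M", "H"): {"H": SocialRate(0.04)},
        ("M", "A"): {"A": SocialRate(0.02)},
        ("H", "A"): {"A": SocialRate(0.01)},
    }
    return AMHaParameters(alpha=alpha, beta=beta, reference_period_years=4.0)


@dataclass
class ScenarioConfig:
    """Everything needed to generate one synthetic study."""

    n_persons: int = 2000
    n_waves: int = 5
    interval_years: float = 4.0
    mean_degree: float = 3.0
    max_degree: int = 10
    initial_fractions: tuple[float, float, float] = (0.30, 0.50, 0.20)
    assortativity_strength: float = 0.0
    clustering_targets: dict = field(default_factory=lambda: {"A": 1.4, "H": 1.5})
    params: AMHaParameters = field(default_factory=default_true_parameters)
    seed: int | None = None
    start_year: float = 1985.0
    female_fraction: float = 0.5
    age_range: tuple[float, float] = (25.0, 70.0)
    policy: CutoffPolicy = field(default_factory=CutoffPolicy)

    def __post_init__(self) -> None:
        frac = np.asarray(self.initial_fractions, dtype=float)
        if frac.min() < 0 or abs(frac.sum() - 1.0) > 1e-9:
            raise ValueError("initial fractions must be non-negative and sum to 1")
        if self.mean_degree <= 0 or self.mean_degree >= self.n_persons:
            raise ValueError("mean degree unachievable for this population size")
        if self.n_waves < 1 or self.interval_years <= 0:
            raise ValueError("need at least one wave and a positive interval")


@dataclass
class GroundTruth:
    """The generator's bookkeeping: the oracle for every downstream module."""

    params: AMHaParameters
    trajectories: pd.DataFrame        # person_id, wave, state
    transition_log: TransitionTable   # realized transitions with context
    config: ScenarioConfig

    def n_transitions(self) -> int:
        return len(self.transition_log)

    def to_json(self, path) -> None:
        payload = {
            "params": self.params.to_dict(),
            "config": {
                "n_persons": self.config.n_persons,
                "n_waves": self.config.n_waves,
                "interval_years": self.config.interval_years,
                "mean_degree": self.config.mean_degree,
                "initial_fractions": list(self.config.initial_fractions),
                "assortativity_strength": self.config.assortativity_strength,
                "seed": self.config.seed,
            },
            "n_transitions": self.n_transitions(),
            "trajectories": self.trajectories.to_dict(orient="list"),
            "transition_log": self.transition_log.df.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                         default=str))


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------

def generate_network(config: ScenarioConfig,
                     rng: np.random.Generator | None = None) -> SocialNetwork:
    """Configuration-model graph with a linearly decreasing degree distribution.

    Degrees are drawn from a triangular distribution over ``0..K`` with
    weights ``K+1-k``, whose mean is ``K/3``; ``K`` is chosen from the mean
    degree target (and capped at ``max_degree``).  Parallel edges and
    self-loops from the pairing are discarded, which at these densities
    changes the mean degree only marginally.
    """
    rng = rng or np.random.default_rng(config.seed)
    K = max(1, min(int(round(3 * config.mean_degree)), config.max_degree))
    weights = np.arange(K + 1, 0, -1, dtype=float)
    weights /= weights.sum()
    degrees = rng.choice(np.arange(K + 1), size=config.n_persons, p=weights)
    if degrees.sum() % 2 == 1:
        degrees[rng.integers(config.n_persons)] += 1
    g = nx.configuration_model(degrees.tolist(),
                               seed=int(rng.integers(2**31)))
    g = nx.Graph(g)          # collapse parallel edges
    g.remove_edges_from(nx.selfloop_edges(g))
    relations = ("family", "spouse", "friend")
    simple = nx.Graph()
    simple.add_nodes_from(range(config.n_persons))
    for u, v in g.edges():
        simple.add_edge(int(u), int(v),
                        relation=relations[rng.integers(len(relations))])
    return SocialNetwork(simple)


# ---------------------------------------------------------------------------
# initial state seeding with optional assortativity
# ---------------------------------------------------------------------------

def _clustering(states: np.ndarray, edges: np.ndarray, which: int) -> float:
    n = states.shape[0]
    n_x = int((states == which).sum())
    if n_x < 2 or edges.shape[0] == 0:
        return np.nan
    obs = int(((states[edges[:, 0]] == which)
               & (states[edges[:, 1]] == which)).sum())
    exp = edges.shape[0] * n_x * (n_x - 1) / (n * (n - 1))
    return obs / exp if exp > 0 else np.nan


def seed_states(network: SocialNetwork, config: ScenarioConfig,
                rng: np.random.Generator | None = None) -> dict:
    """Assign initial states with the configured marginals and clustering.

    With assortativity strength ``s`` the A and H clustering targets are
    interpolated between 1 (random mixing) and the configured targets, and
    greedy label swaps on the fixed graph push the realized clustering
    toward them (stopping within 0.1 or at the swap budget).
    """
    rng = rng or np.random.default_rng(config.seed)
    nodes = list(network.graph.nodes)
    n = len(nodes)
    counts = np.floor(np.asarray(config.initial_fractions) * n).astype(int)
    while counts.sum() < n:
        counts[int(rng.integers(3))] += 1
    states = np.repeat(np.arange(3), counts)
    rng.shuffle(states)
    s = config.assortativity_strength
    if s > 0 and network.n_edges > 0:
        edges = np.array(list(network.graph.edges()))
        index = {v: i for i, v in enumerate(nodes)}
        edges = np.vectorize(index.get)(edges)
        targets = {STATE_ORDER.index(k): 1.0 + s * (v - 1.0)
                   for k, v in config.clustering_targets.items()}

        def errors(st):
            out = {}
            for which, tgt in targets.items():
                c = _clustering(st, edges, which)
                if not np.isnan(c):
                    out[which] = c - tgt
            return out

        def done(err):
            return all(abs(e) < 0.08 for e in err.values())

        def objective(err):
            return sum(e ** 2 for e in err.values())

        err = errors(states)
        best = objective(err)
        budget = 50 * n
        for _ in range(budget):
            if done(err):
                break
            i, j = rng.integers(n, size=2)
            if states[i] == states[j]:
                continue
            states[i], states[j] = states[j], states[i]
            cand_err = errors(states)
            cand = objective(cand_err)
            if cand < best:
                best, err = cand, cand_err
            else:
                states[i], states[j] = states[j], states[i]
    return {v: STATE_ORDER[states[i]] for i, v in enumerate(nodes)}


# ---------------------------------------------------------------------------
# panel evolution
# ---------------------------------------------------------------------------

def evolve_panel(network: SocialNetwork, initial_states: dict,
                 config: ScenarioConfig,
                 rng: np.random.Generator | None = None
                 ) -> tuple[StatePanel, GroundTruth]:
    """Evolve states wave-to-wave under the true rates and emit a panel.

    The generative law is exactly the simulator's synchronous step with
    ``dt`` equal to the inter-wave interval.  Drinks per week are sampled
    within the state's band for the person's sex (A: 0; M: uniform up to
    the threshold; H: geometric above it) so that re-classification
    reproduces the generated states exactly.
    """
    rng = rng or np.random.default_rng(config.seed)
    params = config.params
    adj, nodes = _graph_to_csr(network)
    n = len(nodes)
    state_arr = np.array([STATE_ORDER.index(initial_states[v]) for v in nodes],
                         dtype=np.intp)
    dest, alpha, beta = params.as_arrays()
    scale = config.interval_years / params.reference_period_years

    traj = np.empty((config.n_waves, n), dtype=np.intp)
    traj[0] = state_arr
    log_frames = []
    for w in range(config.n_waves - 1):
        counts = _neighbor_counts(adj, traj[w])
        nxt = _synchronous_step(traj[w], adj, dest, alpha, beta, scale, rng)
        traj[w + 1] = nxt
        log_frames.append(pd.DataFrame({
            "person_id": nodes, "wave": w,
            "from_state": [STATE_ORDER[c] for c in traj[w]],
            "to_state": [STATE_ORDER[c] for c in nxt],
            "n_A": counts[:, 0].astype(int),
            "n_M": counts[:, 1].astype(int),
            "n_H": counts[:, 2].astype(int),
            "interval_years": config.interval_years,
        }))

    sexes = np.where(rng.random(n) < config.female_fraction, "female", "male")
    age0 = rng.uniform(*config.age_range, size=n)
    thresholds = np.where(sexes == "female", config.policy.female_threshold,
                          config.policy.male_threshold)

    frames = []
    for w in range(config.n_waves):
        drinks = np.zeros(n)
        is_m = traj[w] == 1
        is_h = traj[w] == 2
        # moderate: 1..threshold inclusive; heavy: strictly above threshold
        drinks[is_m] = np.ceil(rng.uniform(0, 1, is_m.sum())
                               * thresholds[is_m])
        drinks[is_h] = thresholds[is_h] + rng.geometric(
            0.25, size=int(is_h.sum()))
        frames.append(pd.DataFrame({
            "person_id": nodes, "wave": w,
            "midpoint_year": config.start_year + w * config.interval_years,
            "sex": sexes, "age": np.round(age0 + w * config.interval_years, 1),
            "drinks_per_week": drinks,
        }))
    panel = StatePanel(pd.concat(frames, ignore_index=True)).classify(
        config.policy)

    trajectories = pd.DataFrame({
        "person_id": np.tile(nodes, config.n_waves),
        "wave": np.repeat(np.arange(config.n_waves), n),
        "state": [STATE_ORDER[c] for c in traj.ravel()],
    })
    if log_frames:
        log_df = pd.concat(log_frames, ignore_index=True)
    else:
        log_df = pd.DataFrame(columns=["person_id", "wave", "from_state",
                                       "to_state", "n_A", "n_M", "n_H",
                                       "interval_years"])
    truth = GroundTruth(params=params, trajectories=trajectories,
                        transition_log=TransitionTable(log_df), config=config)
    return panel, truth


@dataclass
class Scenario:
    """A complete synthetic study: inputs plus their ground truth."""

    network: SocialNetwork
    initial_states: dict
    panel: StatePanel
    truth: GroundTruth
    config: ScenarioConfig


def generate_scenario(config: ScenarioConfig | None = None,
                      seed: int | None = None) -> Scenario:
    """Network, initial states and evolved panel from one seeded config."""
    config = config or ScenarioConfig()
    if seed is not None:
        config.seed = seed
    rng = np.random.default_rng(config.seed)
    network = generate_network(config, rng)
    states = seed_states(network, config, rng)
    panel, truth = evolve_panel(network, states, config, rng)
    return Scenario(network=network, initial_states=states, panel=panel,
                    truth=truth, config=config)
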
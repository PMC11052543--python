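"""Discrete-time stochastic three-state dynamics on a static network.

At every step each node leaves its state with probability
``(alpha + sum_Z beta^Z N_Z) / reference_period * dt`` per destination,
where ``N_Z`` counts neighbours currently in state ``Z``; the stay
probability is the complement.  Updates are synchronous by default, with
neighbour counts frozen at the step start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .calibration import AMHaParameters
from .data_model import (STATE_ORDER, NeighborContext, SocialNetwork,
                         StatePanel, state_code)

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Knobs of one stochastic run batch."""

    params: AMHaParameters
    timestep_years: float = 1.0
    horizon_years: float = 30.0
    replicates: int = 1
    seed: int | None = None
    scheme: str = "synchronous"

    def __post_init__(self) -> None:
        if self.timestep_years <= 0 or self.horizon_years < 0:
            raise ValueError("timestep and horizon must be positive")
        if self.scheme not in ("synchronous", "asynchronous"):
            raise ValueError(f"unknown update scheme: {self.scheme}")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon_years / self.timestep_years))


def step_probabilities(node_state, context: NeighborContext,
                       params: AMHaParameters, dt: float) -> dict[str, float]:
    """Exact per-step destination probabilities for a single node.

    Returns a mapping destination state -> probability, including the stay
    probability as the complement of the two leave probabilities.  Raises
    when the leave probabilities exceed one (the timestep is too large).
    """
    x = str(node_state)
    per_year = dt / params.reference_period_years
    probs = {}
    for y in STATE_ORDER:
        if y == x:
            continue
        counts = {z: context.count(z) for z in STATE_ORDER}
        probs[y] = params.transition_rate(x, y, counts) * per_year
    leave = sum(probs.values())
    if leave > 1.0 + 1e-12:
        raise ValueError(
            f"total leave probability {leave:.3f} exceeds 1 for state {x}; "
            "use a smaller timestep")
    probs[x] = 1.0 - leave
    return probs


# ---------------------------------------------------------------------------
# vectorised stepping kernel (shared with the synthetic generator)
# ---------------------------------------------------------------------------

def _graph_to_csr(network) -> tuple[sp.csr_matrix, list]:
    if isinstance(network, SocialNetwork):
        g = network.graph
    elif isinstance(network, nx.Graph):
        g = network
    else:
        raise TypeError("network must be a SocialNetwork or networkx.Graph")
    nodes = list(g.nodes)
    adj = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr",
                                   dtype=np.float64)
    return sp.csr_matrix(adj), nodes


def _states_to_array(initial_states, nodes: Sequence) -> np.ndarray:
    if isinstance(initial_states, Mapping):
        missing = [n for n in nodes if n not in initial_states]
        if missing:
            raise ValueError(f"{len(missing)} nodes have unknown initial "
                             f"states (e.g. {missing[:3]})")
        arr = np.array([state_code(initial_states[n]) for n in nodes],
                       dtype=np.intp)
    else:
        arr = np.asarray(
            [state_code(s) if isinstance(s, str) else int(s)
             for s in initial_states], dtype=np.intp)
        if arr.shape[0] != len(nodes):
            raise ValueError("initial state vector length mismatch")
    if arr.min() < 0 or arr.max() > 2:
        raise ValueError("states must be A, M or H")
    return arr


def _neighbor_counts(adj: sp.csr_matrix, states: np.ndarray) -> np.ndarray:
    onehot = np.zeros((states.shape[0], 3))
    onehot[np.arange(states.shape[0]), states] = 1.0
    return adj @ onehot


def _step_probs(states, counts, dest, alpha, beta, scale) -> np.ndarray:
    """Leave probabilities, shape (n, 2), destinations given by dest[states]."""
    a = alpha[states]                       # (n, 2)
    b = beta[states]                        # (n, 2, 3)
    rates = a + np.einsum("nij,nj->ni", b, counts)
    return rates * scale


def _synchronous_step(states, adj, dest, alpha, beta, scale, rng,
                      check: bool = True) -> np.ndarray:
    counts = _neighbor_counts(adj, states)
    probs = _step_probs(states, counts, dest, alpha, beta, scale)
    total = probs.sum(axis=1)
    if check and total.max() > 1.0 + 1e-12:
        raise ValueError(
            f"per-step leave probability {total.max():.3f} exceeds 1; "
            "use a smaller timestep")
    u = rng.random(states.shape[0])
    d = dest[states]                        # (n, 2)
    nxt = np.where(u < probs[:, 0], d[:, 0],
                   np.where(u < total, d[:, 1], states))
    return nxt.astype(np.intp)


def _asynchronous_step(states, neighbors, dest, alpha, beta, scale, rng
                       ) -> np.ndarray:
    states = states.copy()
    order = rng.permutation(states.shape[0])
    for i in order:
        c = np.zeros(3)
        for j in neighbors[i]:
            c[states[j]] += 1
        x = states[i]
        rates = alpha[x] + beta[x] @ c
        probs = rates * scale
        total = probs.sum()
        if total > 1.0 + 1e-12:
            raise ValueError("per-step leave probability exceeds 1; "
                             "use a smaller timestep")
        u = rng.random()
        if u < probs[0]:
            states[i] = dest[x, 0]
        elif u < total:
            states[i] = dest[x, 1]
    return states


# ---------------------------------------------------------------------------
# simulation driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Per-step state fractions per replicate plus summaries."""

    times: np.ndarray                      # years from start, len T
    fractions: np.ndarray                  # (replicates, T, 3)
    final_states: np.ndarray               # (replicates, n_nodes) int8
    nodes: list
    config: SimulationConfig

    @property
    def mean_fractions(self) -> np.ndarray:
        return self.fractions.mean(axis=0)

    def ci_fractions(self, lo: float = 2.5, hi: float = 97.5
                     ) -> tuple[np.ndarray, np.ndarray]:
        return (np.percentile(self.fractions, lo, axis=0),
                np.percentile(self.fractions, hi, axis=0))

    def final_fraction(self, state) -> np.ndarray:
        """Final fraction of the given state, one value per replicate."""
        return self.fractions[:, -1, state_code(state)]

    def to_frame(self) -> pd.DataFrame:
        mean = self.mean_fractions
        lo, hi = self.ci_fractions()
        out = {"time": self.times}
        for i, s in enumerate(STATE_ORDER):
            out[s] = mean[:, i]
            out[f"{s}_lo"] = lo[:, i]
            out[f"{s}_hi"] = hi[:, i]
        return pd.DataFrame(out)

    def summary(self) -> dict:
        mean = self.mean_fractions
        lo, hi = self.ci_fractions()
        return {
            "replicates": int(self.fractions.shape[0]),
            "n_nodes": len(self.nodes),
            "final": {s: {"mean": float(mean[-1, i]),
                          "ci": [float(lo[-1, i]), float(hi[-1, i])]}
                      for i, s in enumerate(STATE_ORDER)},
        }


def simulate(network, initial_states, config: SimulationConfig
             ) -> SimulationResult:
    """Run the stochastic dynamics; seeded runs are bit-reproducible.

    ``initial_states`` is a node->state mapping or a state sequence aligned
    with the graph's node order.  A guard verifies that no node's total
    leave probability can exceed one at the initial configuration.
    """
    adj, nodes = _graph_to_csr(network)
    s0 = _states_to_array(initial_states, nodes)
    params = config.params
    dest, alpha, beta = params.as_arrays()
    scale = config.timestep_years / params.reference_period_years
    max_deg = int(adj.sum(axis=1).max()) if adj.nnz else 0
    worst = params.max_total_rate({s: max_deg for s in STATE_ORDER}) * scale
    if worst > 1.0 + 1e-12:
        raise ValueError(
            f"worst-case per-step leave probability {worst:.3f} exceeds 1 at "
            f"max degree {max_deg}; use a smaller timestep")

    n_steps = config.n_steps
    times = np.arange(n_steps + 1) * config.timestep_years
    seeds = np.random.SeedSequence(config.seed).spawn(config.replicates)
    fractions = np.empty((config.replicates, n_steps + 1, 3))
    finals = np.empty((config.replicates, len(nodes)), dtype=np.int8)
    neighbors = None
    if config.scheme == "asynchronous":
        g = network.graph if isinstance(network, SocialNetwork) else network
        index = {n: i for i, n in enumerate(nodes)}
        neighbors = [[index[m] for m in g.neighbors(n)] for n in nodes]
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        states = s0.copy()
        fractions[r, 0] = np.bincount(states, minlength=3) / len(nodes)
        for t in range(n_steps):
            if config.scheme == "synchronous":
                states = _synchronous_step(states, adj, dest, alpha, beta,
                                           scale, rng)
            else:
                states = _asynchronous_step(states, neighbors, dest, alpha,
                                            beta, scale, rng)
            fractions[r, t + 1] = np.bincount(states, minlength=3) / len(nodes)
        finals[r] = states
    return SimulationResult(times=times, fractions=fractions,
                            final_states=finals, nodes=nodes, config=config)


# ---------------------------------------------------------------------------
# forecasting from an observed wave
# ---------------------------------------------------------------------------

@dataclass
class ForecastResult:
    """Simulation anchored at an observed wave plus an observed-vs-simulated table."""

    simulation: SimulationResult
    start_wave: int
    start_year: float
    comparison: pd.DataFrame
    n_dropped: int = 0

    def calendar_frame(self) -> pd.DataFrame:
        df = self.simulation.to_frame()
        df.insert(0, "year", self.start_year + df["time"])
        return df


def forecast(panel: StatePanel, network: SocialNetwork,
             params: AMHaParameters, wave: int, horizon_years: float,
             timestep_years: float = 1.0, replicates: int = 33,
             seed: int | None = None) -> ForecastResult:
    """Simulate forward from one wave's observed states on a static network.

    Nodes without an observed state at the anchor wave are dropped (the
    count is logged).  The comparison table lists state fractions at any
    later observed waves alongside the simulated mean at the nearest
    simulated time, restricted to the simulated node set.
    """
    states = panel.wave_states(wave)
    g = network.graph
    known_nodes = [n for n in g.nodes if n in states]
    n_dropped = g.number_of_nodes() - len(known_nodes)
    if not known_nodes:
        raise ValueError("no network nodes with observed states at that wave")
    if n_dropped:
        logger.info("forecast: dropped %d state-unknown nodes", n_dropped)
    sub = SocialNetwork(g.subgraph(known_nodes).copy())
    waves = panel.waves.set_index("wave")
    start_year = float(waves.loc[wave, "midpoint_year"])
    config = SimulationConfig(params=params, timestep_years=timestep_years,
                              horizon_years=horizon_years,
                              replicates=replicates, seed=seed)
    if horizon_years == 0:
        frac = np.zeros((1, 1, 3))
        arr = _states_to_array(states, known_nodes)
        frac[0, 0] = np.bincount(arr, minlength=3) / len(known_nodes)
        sim = SimulationResult(times=np.array([0.0]), fractions=frac,
                               final_states=arr[None, :].astype(np.int8),
                               nodes=known_nodes, config=config)
    else:
        sim = simulate(sub, states, config)
    node_set = set(known_nodes)
    rows = []
    for w in waves.index:
        if w <= wave:
            continue
        obs = {n: s for n, s in panel.wave_states(int(w)).items()
               if n in node_set}
        if not obs:
            continue
        year = float(waves.loc[w, "midpoint_year"])
        t = year - start_year
        if t > sim.times[-1] + 1e-9:
            continue
        ti = int(np.argmin(np.abs(sim.times - t)))
        arr = np.array([state_code(s) for s in obs.values()])
        obs_frac = np.bincount(arr, minlength=3) / len(arr)
        row = {"wave": int(w), "year": year, "n_observed": len(arr)}
        for i, s in enumerate(STATE_ORDER):
            row[f"observed_{s}"] = float(obs_frac[i])
            row[f"simulated_{s}"] = float(sim.mean_fractions[ti, i])
        rows.append(row)
    comparison = pd.DataFrame(rows)
    return ForecastResult(simulation=sim, start_wave=int(wave),
                          start_year=start_year, comparison=comparison,
                          n_dropped=n_dropped)
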
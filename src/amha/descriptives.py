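"""Validation statistics for the three-state panel and network.

Stability/transition matrices, wave-to-wave state correlation, cutoff
sweeps, spatial correlation and clustering of states on the network,
chi-squared adjacency tests, degree distributions and per-wave summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .data_model import (STATE_ORDER, CutoffPolicy, SocialNetwork, StatePanel,
                         TransitionTable, classify_series)
from .calibration import _as_df


# ---------------------------------------------------------------------------
# transition matrix and stability
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    """Row-stochastic 3x3 matrix of observed wave-to-wave transitions.

    ``matrix[i, j]`` is the fraction of state-``i`` person-waves observed in
    state ``j`` at the next wave; ``n_obs[i]`` the at-risk count per row.
    Rows with no observations are NaN.
    """

    matrix: np.ndarray
    n_obs: np.ndarray
    states: tuple = STATE_ORDER

    def stay_probability(self, state) -> float:
        i = STATE_ORDER.index(str(state))
        return float(self.matrix[i, i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.states),
                            columns=list(self.states))


def transition_matrix(transitions) -> TransitionMatrix:
    """Empirical transition matrix ``P[X][Y] = #(X->Y) / #(X->.)``."""
    df = _as_df(transitions)
    if df.empty:
        raise ValueError("no transitions")
    mat = np.full((3, 3), np.nan)
    n_obs = np.zeros(3, dtype=int)
    counts = df.groupby(["from_state", "to_state"]).size()
    for i, x in enumerate(STATE_ORDER):
        row = np.array([counts.get((x, y), 0) for y in STATE_ORDER], dtype=float)
        n = row.sum()
        n_obs[i] = int(n)
        if n > 0:
            mat[i] = row / n
    return TransitionMatrix(matrix=mat, n_obs=n_obs)


def annualize_stability(stay_probability: float, interval_years: float,
                        method: str = "geometric",
                        matrix: TransitionMatrix | None = None,
                        state: str | None = None) -> float:
    """Convert a per-interval stay probability to a yearly one.

    ``geometric`` takes the interval-th root of the stay probability.
    ``matrix_root`` takes the diagonal of the interval-th root of the full
    transition matrix (requires ``matrix`` and ``state``); if no real
    stochastic root exists, NaN is returned.  Neither convention is a
    perfect inverse of the aggregation — both are provided deliberately.
    """
    if interval_years <= 0:
        raise ValueError("interval_years must be positive")
    if method == "geometric":
        if not (0 < stay_probability <= 1):
            raise ValueError("stay probability must be in (0, 1]")
        return float(stay_probability ** (1.0 / interval_years))
    if method == "matrix_root":
        if matrix is None or state is None:
            raise ValueError("matrix_root needs the full matrix and a state")
        root = _real_matrix_root(matrix.matrix, interval_years)
        if root is None:
            return float("nan")
        return float(root[STATE_ORDER.index(str(state)),
                          STATE_ORDER.index(str(state))])
    raise ValueError(f"unknown annualization method: {method}")


def _real_matrix_root(P: np.ndarray, interval: float,
                      tol: float = 1e-8) -> np.ndarray | None:
    if np.isnan(P).any():
        return None
    R = scipy.linalg.fractional_matrix_power(P, 1.0 / interval)
    if np.iscomplexobj(R):
        if np.abs(R.imag).max() > tol:
            return None
        R = R.real
    if R.min() < -tol or np.abs(R.sum(axis=1) - 1).max() > 1e-6:
        return None  # no usable stochastic root
    return np.clip(R, 0.0, None)


# ---------------------------------------------------------------------------
# wave-to-wave state correlation
# ---------------------------------------------------------------------------

def state_correlation_by_wave(panel: StatePanel) -> pd.DataFrame:
    """Pearson r between ordinal states at consecutive waves, per wave pair.

    States are encoded A=0, M=1, H=2; the last row (wave = -1) carries the
    unweighted mean across wave pairs.
    """
    if not panel.has_states:
        raise ValueError("panel has no states; call classify() first")
    code = {s: i for i, s in enumerate(STATE_ORDER)}
    wide = (panel.df.assign(c=panel.df["state"].map(code))
            .pivot(index="person_id", columns="wave", values="c"))
    waves = sorted(wide.columns)
    rows = []
    for w0, w1 in zip(waves[:-1], waves[1:]):
        both = wide[[w0, w1]].dropna()
        n = len(both)
        if n < 3 or both[w0].nunique() < 2 or both[w1].nunique() < 2:
            r = float("nan")
        else:
            r = float(np.corrcoef(both[w0], both[w1])[0, 1])
        rows.append({"wave": w0, "next_wave": w1, "r": r, "n": n})
    out = pd.DataFrame(rows)
    mean_r = float(out["r"].mean())
    out = pd.concat([out, pd.DataFrame([{"wave": -1, "next_wave": -1,
                                         "r": mean_r, "n": int(out["n"].sum())}])],
                    ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# spatial correlation / clustering
# ---------------------------------------------------------------------------

@dataclass
class SpatialCorrelationMatrix:
    """Observed-over-expected edge counts between states, on fixed edges.

    The null permutes the observed state labels over the state-known nodes
    with the graph held fixed; expectations are computed analytically.
    Cells involving a state absent at the wave are NaN.
    """

    C: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    n_nodes: int
    n_edges: int
    states: tuple = STATE_ORDER

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=list(self.states),
                            columns=list(self.states))


def spatial_correlation(states: Mapping, network: SocialNetwork
                        ) -> SpatialCorrelationMatrix:
    """Spatial correlation ``C[X][Y]`` for one wave's state assignment.

    ``states`` maps node -> state; only edges between state-known nodes
    count.  For distinct states the expected count is
    ``m * 2 n_X n_Y / (n (n-1))`` and for equal states
    ``m * n_X (n_X - 1) / (n (n-1))`` with ``m`` edges among ``n``
    state-known nodes — the exact mean over label permutations.
    """
    known = {node: str(s) for node, s in states.items() if pd.notna(s)}
    nodes = [v for v in network.graph.nodes if v in known]
    n = len(nodes)
    counts = np.zeros(3)
    for v in nodes:
        counts[STATE_ORDER.index(known[v])] += 1
    observed = np.zeros((3, 3))
    m = 0
    for u, v in network.graph.edges():
        if u in known and v in known:
            i, j = STATE_ORDER.index(known[u]), STATE_ORDER.index(known[v])
            observed[i, j] += 1
            if i != j:
                observed[j, i] += 1
            m += 1
    expected = np.zeros((3, 3))
    if n >= 2:
        denom = n * (n - 1)
        for i in range(3):
            for j in range(3):
                if i == j:
                    expected[i, j] = m * counts[i] * (counts[i] - 1) / denom
                else:
                    expected[i, j] = m * 2 * counts[i] * counts[j] / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        C = observed / expected
    for i in range(3):
        for j in range(3):
            if counts[i] == 0 or counts[j] == 0 or expected[i, j] == 0:
                C[i, j] = np.nan  # absent state: undefined, not zero
    return SpatialCorrelationMatrix(C=C, observed=observed, expected=expected,
                                    n_nodes=n, n_edges=m)


def spatial_correlation_by_wave(panel: StatePanel, network: SocialNetwork
                                ) -> dict[int, SpatialCorrelationMatrix]:
    return {int(w): spatial_correlation(panel.wave_states(int(w)), network)
            for w in panel.waves["wave"]}


def mean_spatial_correlation(panel: StatePanel, network: SocialNetwork
                             ) -> pd.DataFrame:
    """Unweighted mean of per-wave spatial-correlation matrices."""
    mats = [m.C for m in spatial_correlation_by_wave(panel, network).values()]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.stack(mats), axis=0)
    return pd.DataFrame(mean, index=list(STATE_ORDER), columns=list(STATE_ORDER))


# ---------------------------------------------------------------------------
# chi-squared adjacency test
# ---------------------------------------------------------------------------

@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame
    expected: np.ndarray
    n_pairs: int
    warning: str | None = None


def chisq_state_adjacency(states: Mapping, network: SocialNetwork,
                          ego_state) -> ChiSquareResult:
    """Pearson chi-squared independence test of ego state vs neighbour state.

    The contingency table is 2x3: (ego in ``ego_state`` / not) by neighbour
    state, counting ordered ego-neighbour pairs over edges whose endpoints
    both have known states; df = 2.  Expected cells below 5 attach a warning.
    """
    ego_state = str(ego_state)
    known = {node: str(s) for node, s in states.items() if pd.notna(s)}
    table = np.zeros((2, 3))
    for u, v in network.graph.edges():
        if u not in known or v not in known:
            continue
        for ego, nbr in ((u, v), (v, u)):
            row = 0 if known[ego] == ego_state else 1
            table[row, STATE_ORDER.index(known[nbr])] += 1
    n_pairs = int(table.sum())
    if n_pairs == 0 or table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("degenerate contingency table for chi-squared test")
    chi2, p, dof, expected = scipy.stats.chi2_contingency(table,
                                                          correction=False)
    warning = None
    if expected.min() < 5:
        warning = "expected cell count below 5; chi-squared approximation weak"
    frame = pd.DataFrame(table, index=[ego_state, f"not {ego_state}"],
                         columns=list(STATE_ORDER))
    return ChiSquareResult(statistic=float(chi2), df=int(dof),
                           p_value=float(p), table=frame, expected=expected,
                           n_pairs=n_pairs, warning=warning)


# ---------------------------------------------------------------------------
# cutoff sweep
# ---------------------------------------------------------------------------

@dataclass
class StabilityCurve:
    """Annualized stay probabilities as a function of the female cutoff.

    ``combined`` is the probability of staying in one's own state among
    person-waves starting in the moderate or heavy state (so it responds to
    where the moderate/heavy boundary is drawn).
    """

    cutoffs: np.ndarray
    per_state: pd.DataFrame       # columns A, M, H indexed by cutoff
    combined: np.ndarray
    interval_years: float

    def to_frame(self) -> pd.DataFrame:
        out = self.per_state.copy()
        out["MH_combined"] = self.combined
        out.index.name = "female_cutoff"
        return out.reset_index()

    def argmax_combined(self) -> float:
        return float(self.cutoffs[int(np.nanargmax(self.combined))])

    def plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        for s in STATE_ORDER:
            ax.plot(self.cutoffs, self.per_state[s], label=s)
        ax.plot(self.cutoffs, self.combined, "k--", label="M+H combined")
        ax.set_xlabel("female weekly-drinks cutoff (male = 2x)")
        ax.set_ylabel("annualized stay probability")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def stability_cutoff_sweep(panel: StatePanel,
                           cutoff_grid: Sequence[float]) -> StabilityCurve:
    """Re-classify the panel at each cutoff and recompute stay probabilities.

    The male threshold is held at twice the female one.  Stay probabilities
    pool all consecutive wave pairs and are annualized geometrically with
    the mean inter-wave interval.
    """
    cutoffs = np.asarray(sorted(cutoff_grid), dtype=float)
    if cutoffs.size == 0 or np.any(np.diff(cutoffs) <= 0):
        raise ValueError("cutoff grid must be non-empty and strictly increasing")
    waves = panel.waves
    mean_dt = float(waves["interval_years"].dropna().mean())
    per_state_rows, combined = [], []
    for c in cutoffs:
        policy = CutoffPolicy.from_female_threshold(float(c))
        codes = classify_series(panel.df["drinks_per_week"], panel.df["sex"],
                                policy)
        wide = (panel.df.assign(s=codes)
                .pivot(index="person_id", columns="wave", values="s"))
        cols = sorted(wide.columns)
        stay = {s: [0, 0] for s in STATE_ORDER}   # [stayed, at-risk]
        mh_stay, mh_n = 0, 0
        for w0, w1 in zip(cols[:-1], cols[1:]):
            both = wide[[w0, w1]].dropna()
            for s in STATE_ORDER:
                at = both[both[w0] == s]
                stay[s][0] += int((at[w1] == s).sum())
                stay[s][1] += len(at)
            mh = both[both[w0].isin(["M", "H"])]
            mh_stay += int((mh[w0] == mh[w1]).sum())
            mh_n += len(mh)
        row = {}
        for s in STATE_ORDER:
            stayed, n = stay[s]
            row[s] = (annualize_stability(stayed / n, mean_dt)
                      if n > 0 and stayed > 0 else np.nan)
        per_state_rows.append(row)
        combined.append(annualize_stability(mh_stay / mh_n, mean_dt)
                        if mh_n > 0 and mh_stay > 0 else np.nan)
    per_state = pd.DataFrame(per_state_rows, index=cutoffs)
    return StabilityCurve(cutoffs=cutoffs, per_state=per_state,
                          combined=np.asarray(combined), interval_years=mean_dt)


# ---------------------------------------------------------------------------
# degree distribution and wave summaries
# ---------------------------------------------------------------------------

def degree_distribution(network: SocialNetwork,
                        restrict_to=None) -> pd.Series:
    """Counts of nodes per degree, optionally within a node subset.

    When restricted, degrees are recomputed inside the induced subgraph.
    """
    g = network.graph
    if restrict_to is not None:
        g = g.subgraph(set(restrict_to))
    degrees = pd.Series(dict(g.degree()), dtype=int)
    if degrees.empty:
        return pd.Series(dtype=int)
    return degrees.value_counts().sort_index()


def wave_summary(panel: StatePanel, network: SocialNetwork) -> pd.DataFrame:
    """Per-wave descriptives: egos, age, drinks/day and contact composition.

    Contacts count only neighbours with known state at the wave; the
    abstaining/heavy contact columns report means with the percentage of
    all state-known contacts in parentheses-style companion columns.
    """
    if not panel.has_states:
        raise ValueError("panel has no states; call classify() first")
    rows = []
    for w in panel.waves["wave"]:
        w = int(w)
        sub = panel.df[(panel.df["wave"] == w) & panel.df["state"].notna()]
        states = dict(zip(sub["person_id"], sub["state"]))
        contacts = np.zeros(3)
        total_contacts = 0
        per_ego_counts = []
        for ego in sub["person_id"]:
            c = np.zeros(3)
            if ego in network.graph:
                for nbr in network.graph.neighbors(ego):
                    s = states.get(nbr)
                    if s is not None:
                        c[STATE_ORDER.index(s)] += 1
            per_ego_counts.append(c)
        if per_ego_counts:
            arr = np.vstack(per_ego_counts)
            contacts = arr.mean(axis=0)
            total_contacts = arr.sum()
        mean_contacts = float(contacts.sum())
        rows.append({
            "wave": w,
            "midpoint_year": float(sub["midpoint_year"].iloc[0]) if len(sub) else np.nan,
            "egos": int(len(sub)),
            "mean_age": float(sub["age"].mean()) if len(sub) else np.nan,
            "mean_drinks_per_day": float(sub["drinks_per_week"].mean() / 7.0)
                                   if len(sub) else np.nan,
            "mean_contacts": mean_contacts,
            "mean_contacts_abstain": float(contacts[0]),
            "pct_contacts_abstain": float(100 * contacts[0] / mean_contacts)
                                    if mean_contacts > 0 else 0.0,
            "mean_contacts_heavy": float(contacts[2]),
            "pct_contacts_heavy": float(100 * contacts[2] / mean_contacts)
                                  if mean_contacts > 0 else 0.0,
        })
    return pd.DataFrame(rows)
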
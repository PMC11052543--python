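"""Domain types, state classification, filtering, transition extraction and I/O.

The observational unit is a person-wave: one person's self-reported drinking
at one examination wave.  Drinking is classified into three states —
abstaining (``A``), moderate (``M``) and heavy (``H``) — using sex-specific
weekly-drinks thresholds.  The social context is an undirected network over
person ids, optionally labelled with a relationship type.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: canonical state order; the ordinal scale A=0, M=1, H=2 is used for
#: correlations and cutoff sweeps only, never for the dynamics.
STATE_ORDER = ("A", "M", "H")

#: relationship labels recognised on edges.
RELATION_LABELS = ("family", "spouse", "friend", "coworker", "neighbour", "other")

#: relationship labels removed by the study filters.
EXCLUDED_RELATIONS = ("coworker", "neighbour")


class DrinkingState(str, enum.Enum):
    """One of the three drinking states."""

    A = "A"
    M = "M"
    H = "H"

    @property
    def ordinal(self) -> int:
        return STATE_ORDER.index(self.value)

    def __lt__(self, other: "DrinkingState") -> bool:  # ordering for sweeps only
        if not isinstance(other, DrinkingState):
            return NotImplemented
        return self.ordinal < other.ordinal

    def __str__(self) -> str:
        return self.value


def state_code(state) -> int:
    """Ordinal code of a state given as enum or single-letter string."""
    return STATE_ORDER.index(str(state))


@dataclass(frozen=True)
class CutoffPolicy:
    """Weekly-drinks thresholds separating moderate from heavy drinking.

    The defaults follow the NIAAA convention of 7 drinks/week for women and
    14 for men.  Policies produced by a cutoff sweep constrain the male
    threshold to twice the female one.
    """

    female_threshold: float = 7.0
    male_threshold: float = 14.0

    def __post_init__(self) -> None:
        if self.female_threshold <= 0 or self.male_threshold <= 0:
            raise ValueError("cutoff thresholds must be positive")

    @classmethod
    def from_female_threshold(cls, female_threshold: float) -> "CutoffPolicy":
        """Sweep constructor: male threshold fixed at twice the female one."""
        return cls(female_threshold=female_threshold,
                   male_threshold=2.0 * female_threshold)

    def threshold(self, sex: str) -> float:
        sex = _normalize_sex(sex)
        return self.female_threshold if sex == "female" else self.male_threshold


def _normalize_sex(sex) -> str | None:
    if sex is None or (isinstance(sex, float) and np.isnan(sex)):
        return None
    s = str(sex).strip().lower()
    if s in ("f", "female", "woman", "w"):
        return "female"
    if s in ("m", "male", "man"):
        return "male"
    raise ValueError(f"unrecognised sex label: {sex!r}")


def classify_state(drinks_per_week, sex, policy: CutoffPolicy | None = None):
    """Classify weekly drink count into a :class:`DrinkingState`.

    Zero drinks is abstinent for either sex; counts up to and including the
    sex-specific threshold are moderate; anything strictly above is heavy.
    Returns ``None`` when drinks or sex is missing (the record is flagged and
    excluded downstream rather than imputed).
    """
    policy = policy or CutoffPolicy()
    sex = _normalize_sex(sex)
    if sex is None or drinks_per_week is None:
        return None
    d = float(drinks_per_week)
    if np.isnan(d):
        return None
    if d < 0:
        raise ValueError("drinks_per_week must be non-negative")
    if d == 0:
        return DrinkingState.A
    if d <= policy.threshold(sex):
        return DrinkingState.M
    return DrinkingState.H


def classify_series(drinks: pd.Series, sex: pd.Series,
                    policy: CutoffPolicy | None = None) -> pd.Series:
    """Vectorised :func:`classify_state` over aligned pandas Series."""
    policy = policy or CutoffPolicy()
    sexes = sex.map(lambda s: _normalize_sex(s) if pd.notna(s) else None)
    d = pd.to_numeric(drinks, errors="coerce")
    if (d.dropna() < 0).any():
        raise ValueError("drinks_per_week must be non-negative")
    thr = sexes.map({"female": policy.female_threshold,
                     "male": policy.male_threshold})
    out = pd.Series(pd.NA, index=drinks.index, dtype="object")
    known = d.notna() & thr.notna()
    out[known & (d == 0)] = "A"
    out[known & (d > 0) & (d <= thr)] = "M"
    out[known & (d > thr)] = "H"
    return out


@dataclass(frozen=True)
class PersonWave:
    """One person's observation at one wave."""

    person_id: object
    wave: int
    midpoint_year: float
    sex: str | None
    age: float
    drinks_per_week: float | None
    state: DrinkingState | None = None


@dataclass
class NeighborContext:
    """Counts of an ego's state-known network neighbours in each state."""

    n_A: int
    n_M: int
    n_H: int

    @property
    def degree(self) -> int:
        """Degree among state-known neighbours."""
        return self.n_A + self.n_M + self.n_H

    def count(self, state) -> int:
        return (self.n_A, self.n_M, self.n_H)[state_code(state)]


@dataclass(frozen=True)
class TransitionRecord:
    """One ego observed at two consecutive waves, with its social context.

    The neighbour context is evaluated at the origin wave.
    """

    person_id: object
    wave_pair: tuple[int, int]
    from_state: DrinkingState
    to_state: DrinkingState
    context: NeighborContext
    interval_years: float


PANEL_COLUMNS = ("person_id", "wave", "midpoint_year", "sex", "age",
                 "drinks_per_week")


class StatePanel:
    """Longitudinal person-wave panel backed by a :class:`pandas.DataFrame`.

    Columns: ``person_id, wave, midpoint_year, sex, age, drinks_per_week`` and,
    once :meth:`classify` has run, a derived ``state`` column with values in
    ``{"A","M","H"}`` or missing.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel is missing columns: {missing}")
        df["wave"] = df["wave"].astype(int)
        if validate:
            dup = df.duplicated(subset=["person_id", "wave"])
            if dup.any():
                raise ValueError("duplicate (person_id, wave) records")
            if (pd.to_numeric(df["age"], errors="coerce").dropna() < 0).any():
                raise ValueError("age must be non-negative")
            d = pd.to_numeric(df["drinks_per_week"], errors="coerce").dropna()
            if (d < 0).any():
                raise ValueError("drinks_per_week must be non-negative")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "StatePanel":
        return StatePanel(self.df, validate=False)

    # -- classification ----------------------------------------------------

    def classify(self, policy: CutoffPolicy | None = None) -> "StatePanel":
        """Return a panel with the derived ``state`` column (re)computed."""
        out = self.copy()
        out.df["state"] = classify_series(out.df["drinks_per_week"],
                                          out.df["sex"], policy)
        return out

    @property
    def has_states(self) -> bool:
        return "state" in self.df.columns

    # -- wave metadata -----------------------------------------------------

    @property
    def waves(self) -> pd.DataFrame:
        """Ordered wave metadata: midpoint year and interval to the next wave."""
        w = (self.df.groupby("wave")["midpoint_year"].first()
             .sort_index().rename("midpoint_year").to_frame())
        w["interval_years"] = w["midpoint_year"].shift(-1) - w["midpoint_year"]
        if (w["interval_years"].dropna() <= 0).any():
            raise ValueError("wave midpoints must be strictly increasing")
        return w.reset_index()

    def wave_states(self, wave: int) -> dict:
        """Mapping person_id -> state string for one wave (known states only)."""
        if not self.has_states:
            raise ValueError("panel has no states; call classify() first")
        sub = self.df[(self.df["wave"] == wave) & self.df["state"].notna()]
        return dict(zip(sub["person_id"], sub["state"]))

    def state_fractions(self, wave: int) -> dict:
        states = pd.Series(list(self.wave_states(wave).values()))
        frac = states.value_counts(normalize=True)
        return {s: float(frac.get(s, 0.0)) for s in STATE_ORDER}

    # -- record view -------------------------------------------------------

    def records(self) -> Iterator[PersonWave]:
        has_state = self.has_states
        for row in self.df.itertuples(index=False):
            state = getattr(row, "state", None) if has_state else None
            yield PersonWave(
                person_id=row.person_id, wave=int(row.wave),
                midpoint_year=float(row.midpoint_year),
                sex=row.sex if pd.notna(row.sex) else None,
                age=float(row.age),
                drinks_per_week=(float(row.drinks_per_week)
                                 if pd.notna(row.drinks_per_week) else None),
                state=DrinkingState(state) if pd.notna(state) and state else None,
            )

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "StatePanel":
        return cls(pd.read_csv(path))

    def to_csv(self, path, sidecar: Mapping | None = None) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False)
        _write_sidecar(path, sidecar, kind="panel", n_records=len(self.df))


class SocialNetwork:
    """Undirected simple graph over person ids with optional relation labels."""

    def __init__(self, graph: nx.Graph | None = None):
        g = nx.Graph()
        if graph is not None:
            g.add_nodes_from(graph.nodes(data=True))
            for u, v, data in graph.edges(data=True):
                if u == v:
                    continue  # self-loops carry no social information
                g.add_edge(u, v, **data)
        self.graph = g

    @classmethod
    def from_edges(cls, edges: Iterable[tuple]) -> "SocialNetwork":
        """Build from ``(u, v)`` or ``(u, v, relation)`` tuples."""
        g = nx.Graph()
        for e in edges:
            if len(e) == 2:
                g.add_edge(e[0], e[1])
            else:
                g.add_edge(e[0], e[1], relation=e[2])
        return cls(g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "SocialNetwork":
        return SocialNetwork(self.graph)

    def relations(self) -> set:
        return {d.get("relation") for _, _, d in self.graph.edges(data=True)}

    def drop_relations(self, labels: Sequence[str]) -> tuple["SocialNetwork", int]:
        """Remove edges whose relation label is in ``labels``; keep nodes."""
        labels = set(labels)
        out = self.copy()
        to_drop = [(u, v) for u, v, d in out.graph.edges(data=True)
                   if d.get("relation") in labels]
        out.graph.remove_edges_from(to_drop)
        return out, len(to_drop)

    def subgraph(self, nodes: Iterable) -> "SocialNetwork":
        return SocialNetwork(self.graph.subgraph(set(nodes)).copy())

    def adjacency(self, nodes: Sequence) -> sp.csr_matrix:
        """CSR adjacency over the given node ordering (absent nodes isolated)."""
        index = {n: i for i, n in enumerate(nodes)}
        rows, cols = [], []
        for u, v in self.graph.edges():
            iu, iv = index.get(u), index.get(v)
            if iu is None or iv is None:
                continue
            rows += [iu, iv]
            cols += [iv, iu]
        n = len(nodes)
        data = np.ones(len(rows), dtype=np.float64)
        return sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_edgelist_csv(cls, path) -> "SocialNetwork":
        df = pd.read_csv(path)
        g = nx.Graph()
        has_rel = "relation" in df.columns
        for row in df.itertuples(index=False):
            attrs = {}
            if has_rel and pd.notna(row.relation):
                attrs["relation"] = row.relation
            g.add_edge(row.source, row.target, **attrs)
        return cls(g)

    def to_edgelist_csv(self, path, sidecar: Mapping | None = None) -> None:
        path = Path(path)
        rows = [{"source": u, "target": v, "relation": d.get("relation", "")}
                for u, v, d in self.graph.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "relation"]).to_csv(
            path, index=False)
        _write_sidecar(path, sidecar, kind="network",
                       n_nodes=self.n_nodes, n_edges=self.n_edges)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    @classmethod
    def from_graphml(cls, path) -> "SocialNetwork":
        return cls(nx.read_graphml(path))


def _write_sidecar(path: Path, sidecar: Mapping | None, **counts) -> None:
    meta = {"counts": counts, "filters": dict(sidecar or {})}
    side = path.with_suffix(path.suffix + ".meta.json")
    side.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# study filters
# ---------------------------------------------------------------------------

@dataclass
class FilterLog:
    """Bookkeeping of what the study filters removed."""

    persons_removed: int = 0
    records_removed: int = 0
    relation_edges_removed: int = 0
    incident_edges_removed: int = 0
    nodes_removed: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class FilteredData:
    """Result of :func:`apply_study_filters`; unpacks as ``panel, network``."""

    panel: StatePanel
    network: SocialNetwork
    log: FilterLog = field(default_factory=FilterLog)

    def __iter__(self):
        return iter((self.panel, self.network))


def apply_study_filters(panel: StatePanel, network: SocialNetwork,
                        min_age: float = 21.0,
                        excluded_relations: Sequence[str] = EXCLUDED_RELATIONS,
                        policy: CutoffPolicy | None = None) -> FilteredData:
    """Restrict to adults with known drinking data; drop excluded edge types.

    Keeps person-waves with age strictly above ``min_age`` and a classifiable
    drinking state, removes coworker/neighbour edges, and drops edges incident
    to persons excluded everywhere.  Raises if any filter empties the data.
    """
    p = panel if panel.has_states else panel.classify(policy)
    df = p.df
    keep = (pd.to_numeric(df["age"], errors="coerce") > min_age) & df["state"].notna()
    kept = df[keep]
    if kept.empty:
        raise ValueError("study filters removed every record "
                         "(age/known-drinking filter emptied the panel)")
    log = FilterLog(
        records_removed=int((~keep).sum()),
        persons_removed=int(df["person_id"].nunique()
                            - kept["person_id"].nunique()),
    )
    out_panel = StatePanel(kept, validate=False)
    out_panel.df["state"] = kept["state"].values

    net, n_rel = network.drop_relations(excluded_relations)
    log.relation_edges_removed = n_rel
    kept_persons = set(kept["person_id"])
    before_edges = net.n_edges
    before_nodes = net.n_nodes
    net = net.subgraph(n for n in net.graph.nodes if n in kept_persons)
    log.incident_edges_removed = before_edges - net.n_edges
    log.nodes_removed = before_nodes - net.n_nodes
    if net.n_nodes == 0:
        raise ValueError("study filters removed every network node "
                         "(restriction to known-drinking adults emptied it)")
    logger.info("study filters: %s", log.as_dict())
    return FilteredData(out_panel, net, log)


# ---------------------------------------------------------------------------
# transition extraction
# ---------------------------------------------------------------------------

TRANSITION_COLUMNS = ("person_id", "wave", "from_state", "to_state",
                      "n_A", "n_M", "n_H", "interval_years")


class TransitionTable:
    """Collection of ego transitions with neighbour context, as a DataFrame.

    Columns: ``person_id, wave`` (origin wave), ``from_state, to_state``,
    neighbour counts ``n_A, n_M, n_H`` at the origin wave, ``interval_years``.
    """

    def __init__(self, df: pd.DataFrame, n_skipped: int = 0):
        missing = [c for c in TRANSITION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"transition table missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        self.n_skipped = n_skipped

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: Iterable[TransitionRecord]) -> "TransitionTable":
        rows = [{
            "person_id": r.person_id, "wave": r.wave_pair[0],
            "from_state": str(r.from_state), "to_state": str(r.to_state),
            "n_A": r.context.n_A, "n_M": r.context.n_M, "n_H": r.context.n_H,
            "interval_years": r.interval_years,
        } for r in records]
        return cls(pd.DataFrame(rows, columns=TRANSITION_COLUMNS))

    def records(self) -> list[TransitionRecord]:
        return [TransitionRecord(
            person_id=row.person_id,
            wave_pair=(int(row.wave), int(row.wave) + 1),
            from_state=DrinkingState(row.from_state),
            to_state=DrinkingState(row.to_state),
            context=NeighborContext(int(row.n_A), int(row.n_M), int(row.n_H)),
            interval_years=float(row.interval_years),
        ) for row in self.df.itertuples(index=False)]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TransitionTable":
        return cls(pd.read_csv(path))


def extract_transitions(panel: StatePanel,
                        network: SocialNetwork) -> TransitionTable:
    """One record per ego per consecutive wave pair with both states observed.

    Neighbour counts include only neighbours whose state is observed at the
    origin wave; persons missing either wave are skipped (counted in
    ``n_skipped``).
    """
    if not panel.has_states:
        raise ValueError("panel has no states; call classify() first")
    waves = panel.waves
    if len(waves) < 2:
        raise ValueError("need at least two waves to extract transitions")

    persons = pd.Index(sorted(set(panel.df["person_id"])
                              | set(network.graph.nodes)))
    adj = network.adjacency(list(persons))
    code_map = {s: i for i, s in enumerate(STATE_ORDER)}

    wide = (panel.df.assign(code=panel.df["state"].map(code_map))
            .pivot(index="person_id", columns="wave", values="code")
            .reindex(persons))

    frames = []
    n_skipped = 0
    wave_ids = list(waves["wave"])
    intervals = list(waves["interval_years"])
    for i in range(len(wave_ids) - 1):
        w0, w1, dt = wave_ids[i], wave_ids[i + 1], intervals[i]
        s0 = wide[w0].to_numpy(dtype=float) if w0 in wide else np.full(len(persons), np.nan)
        s1 = wide[w1].to_numpy(dtype=float) if w1 in wide else np.full(len(persons), np.nan)
        known0 = ~np.isnan(s0)
        onehot = np.zeros((len(persons), 3))
        idx = np.flatnonzero(known0)
        onehot[idx, s0[idx].astype(int)] = 1.0
        counts = adj @ onehot  # state-known neighbour counts at origin wave
        both = known0 & ~np.isnan(s1)
        n_skipped += int((known0 & np.isnan(s1)).sum()
                         + (~known0 & ~np.isnan(s1)).sum())
        if not both.any():
            continue
        sel = np.flatnonzero(both)
        frames.append(pd.DataFrame({
            "person_id": persons[sel],
            "wave": w0,
            "from_state": [STATE_ORDER[int(c)] for c in s0[sel]],
            "to_state": [STATE_ORDER[int(c)] for c in s1[sel]],
            "n_A": counts[sel, 0].astype(int),
            "n_M": counts[sel, 1].astype(int),
            "n_H": counts[sel, 2].astype(int),
            "interval_years": float(dt),
        }))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=TRANSITION_COLUMNS)
    logger.info("extracted %d transitions (%d person-waves skipped)",
                len(df), n_skipped)
    return TransitionTable(df, n_skipped=n_skipped)
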
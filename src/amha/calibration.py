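"""Estimation of spontaneous and social transition rates from panel data.

For every ordered state pair ``X -> Y`` the transition fraction among
at-risk egos is regressed on the number of neighbours in an influencing
state ``Z`` with a weighted least squares fit (weights = at-risk counts).
The intercept is the spontaneous rate ``alpha[X->Y]``; the slope is the
social rate per neighbour ``beta[X->Y][Z]``, retained only when positive
and significant.  Rates are expressed per reference period (default 4
years) and rescaled linearly by the simulators.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .data_model import STATE_ORDER, TransitionTable

#: the six ordered transitions of the three-state model.
TRANSITIONS: tuple[tuple[str, str], ...] = (
    ("A", "M"), ("A", "H"), ("M", "A"), ("M", "H"), ("H", "A"), ("H", "M"))

#: cross-state social terms tested by default, as (from, to, influencer):
#: heavy neighbours pulling abstainers into drinking, and abstaining
#: neighbours pulling heavy drinkers toward moderation.
DEFAULT_CROSS_TERMS: tuple[tuple[str, str, str], ...] = (
    ("A", "M", "H"), ("H", "M", "A"))


@dataclass
class SocialRate:
    """One social rate with its inference metadata."""

    value: float
    se: float | None = None
    p_value: float | None = None
    significant: bool = True

    def as_dict(self) -> dict:
        return {"value": self.value, "se": self.se, "p_value": self.p_value,
                "significant": self.significant}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SocialRate":
        return cls(value=float(d["value"]), se=d.get("se"),
                   p_value=d.get("p_value"),
                   significant=bool(d.get("significant", True)))


@dataclass
class AMHaParameters:
    """Full set of spontaneous (alpha) and social (beta) transition rates.

    ``alpha[(X, Y)]`` is the per-reference-period spontaneous rate;
    ``beta[(X, Y)][Z]`` the additional per-period rate per neighbour in
    state ``Z``.  Non-significant social rates are stored with value 0 so
    that metadata survives filtering.
    """

    alpha: dict = field(default_factory=dict)
    beta: dict = field(default_factory=dict)
    reference_period_years: float = 4.0

    def __post_init__(self) -> None:
        for (x, y), a in self.alpha.items():
            if a < 0:
                raise ValueError(f"alpha[{x}->{y}] must be non-negative")
        for (x, y), by_z in self.beta.items():
            for z, rate in by_z.items():
                if rate.value < 0:
                    raise ValueError(f"beta[{x}->{y}][{z}] must be non-negative")
                if z == x:
                    raise ValueError("same-state reinforcement terms "
                                     f"(beta[{x}->{y}][{z}]) are not modelled")

    # -- accessors ---------------------------------------------------------

    def get_alpha(self, x: str, y: str) -> float:
        return float(self.alpha.get((x, y), 0.0))

    def get_beta(self, x: str, y: str, z: str) -> float:
        entry = self.beta.get((x, y), {}).get(z)
        if entry is None or not entry.significant:
            return 0.0
        return float(entry.value)

    def set_beta(self, x: str, y: str, z: str, value: float, **meta) -> None:
        self.beta.setdefault((x, y), {})[z] = SocialRate(value=value, **meta)

    def transition_rate(self, x: str, y: str, counts: Mapping[str, float]) -> float:
        """Per-period rate of ``x -> y`` given neighbour counts by state."""
        r = self.get_alpha(x, y)
        for z in STATE_ORDER:
            r += self.get_beta(x, y, z) * float(counts.get(z, 0))
        return r

    def copy(self) -> "AMHaParameters":
        return copy.deepcopy(self)

    # -- array form for the simulators -------------------------------------

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """``(dest, alpha, beta)`` arrays indexed by origin-state ordinal.

        ``dest[i]`` lists the two destination ordinals for origin ``i``;
        ``alpha[i, j]`` and ``beta[i, j, z]`` are the per-period rates of the
        transition to ``dest[i, j]``.
        """
        dest = np.zeros((3, 2), dtype=np.intp)
        alpha = np.zeros((3, 2))
        beta = np.zeros((3, 2, 3))
        for i, x in enumerate(STATE_ORDER):
            dests = [j for j in range(3) if j != i]
            dest[i] = dests
            for j, yd in enumerate(dests):
                y = STATE_ORDER[yd]
                alpha[i, j] = self.get_alpha(x, y)
                for zc, z in enumerate(STATE_ORDER):
                    beta[i, j, zc] = self.get_beta(x, y, z)
        return dest, alpha, beta

    def max_total_rate(self, max_counts: Mapping[str, float]) -> float:
        """Largest total per-period leave rate at the given neighbour counts."""
        worst = 0.0
        for x in STATE_ORDER:
            total = sum(self.transition_rate(x, y, max_counts)
                        for y in STATE_ORDER if y != x)
            worst = max(worst, total)
        return worst

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        trans = {}
        for x, y in TRANSITIONS:
            key = f"{x}->{y}"
            entry = {"alpha": self.get_alpha(x, y), "beta": {}}
            for z, rate in sorted(self.beta.get((x, y), {}).items()):
                entry["beta"][z] = rate.as_dict()
            trans[key] = entry
        return {"reference_period_years": self.reference_period_years,
                "transitions": trans}

    @classmethod
    def from_dict(cls, d: Mapping) -> "AMHaParameters":
        alpha, beta = {}, {}
        for key, entry in d.get("transitions", {}).items():
            x, y = key.split("->")
            alpha[(x, y)] = float(entry.get("alpha", 0.0))
            for z, rd in entry.get("beta", {}).items():
                beta.setdefault((x, y), {})[z] = SocialRate.from_dict(rd)
        return cls(alpha=alpha, beta=beta,
                   reference_period_years=float(
                       d.get("reference_period_years", 4.0)))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "AMHaParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def describe(self) -> str:
        """Plain-text rate table (per reference period)."""
        lines = [f"rates per {self.reference_period_years:g} years"]
        for x, y in TRANSITIONS:
            parts = [f"{x}->{y}: alpha={self.get_alpha(x, y):.4f}"]
            for z in STATE_ORDER:
                b = self.get_beta(x, y, z)
                if b > 0:
                    parts.append(f"beta^{z}={b:.4f}")
            lines.append("  " + "  ".join(parts))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# regression machinery
# ---------------------------------------------------------------------------

def _as_df(transitions) -> pd.DataFrame:
    if isinstance(transitions, TransitionTable):
        return transitions.df
    if isinstance(transitions, pd.DataFrame):
        return transitions
    return TransitionTable.from_records(list(transitions)).df


@dataclass
class RegressionFit:
    """WLS fit of the ``X -> Y`` transition fraction on neighbour count in Z."""

    from_state: str
    to_state: str
    influencer: str
    points: pd.DataFrame          # columns k, fraction, n
    intercept: float
    slope: float | None
    intercept_se: float | None = None
    slope_se: float | None = None
    intercept_p: float | None = None
    slope_p: float | None = None
    nobs: int = 0

    def predict(self, k) -> np.ndarray:
        s = 0.0 if self.slope is None else self.slope
        return self.intercept + s * np.asarray(k, dtype=float)

    def as_row(self) -> dict:
        return {"from_state": self.from_state, "to_state": self.to_state,
                "influencer": self.influencer, "intercept": self.intercept,
                "slope": self.slope, "intercept_se": self.intercept_se,
                "slope_se": self.slope_se, "intercept_p": self.intercept_p,
                "slope_p": self.slope_p, "nobs": self.nobs}


def aggregate_by_neighbor_count(transitions, from_state: str, to_state: str,
                                influencing_state: str) -> pd.DataFrame:
    """Per neighbour-count ``k``: fraction transitioning and number at risk.

    At-risk means origin state ``from_state``; the fraction is the share of
    those whose destination is ``to_state``.  Counts with no at-risk egos
    yield no point.
    """
    df = _as_df(transitions)
    sub = df[df["from_state"] == from_state]
    if sub.empty:
        return pd.DataFrame(columns=["k", "fraction", "n"])
    k = sub[f"n_{influencing_state}"]
    hit = (sub["to_state"] == to_state)
    g = pd.DataFrame({"k": k, "hit": hit}).groupby("k")["hit"].agg(
        fraction="mean", n="size").reset_index()
    g["n"] = g["n"].astype(int)
    return g[["k", "fraction", "n"]]


def fit_wls(points: pd.DataFrame, from_state: str = "?", to_state: str = "?",
            influencer: str = "?") -> RegressionFit:
    """Weighted least squares of transition fraction on neighbour count.

    Weights are the at-risk counts, so that with a flat truth the fit
    collapses to the pooled binomial estimate.  Standard errors use the
    known binomial variance of each aggregated fraction in a sandwich
    covariance (each point's variance is p(1-p)/n at the fitted value),
    giving z-based p-values; the aggregated points are averages of many
    egos, so the small number of distinct counts does not limit the
    effective degrees of freedom.  With a single distinct count only the
    intercept (the weighted fraction) is defined.
    """
    if len(points) == 0:
        raise ValueError("no aggregated points to fit")
    k = points["k"].to_numpy(dtype=float)
    y = points["fraction"].to_numpy(dtype=float)
    w = points["n"].to_numpy(dtype=float)
    nobs = int(points["n"].sum())
    if len(np.unique(k)) < 2:
        inter = float(np.average(y, weights=w))
        return RegressionFit(from_state, to_state, influencer, points.copy(),
                             intercept=inter, slope=None, nobs=nobs)
    res = sm.WLS(y, sm.add_constant(k), weights=w).fit()
    se = _binomial_sandwich_se(k, w, res.params, res.fittedvalues)
    if se is None:
        pv = [None, None]
        se = [None, None]
    else:
        zstat = np.abs(res.params) / np.maximum(se, 1e-300)
        pv = 2 * scipy.stats.norm.sf(zstat)
    return RegressionFit(
        from_state, to_state, influencer, points.copy(),
        intercept=float(res.params[0]), slope=float(res.params[1]),
        intercept_se=_maybe(se[0]), slope_se=_maybe(se[1]),
        intercept_p=_maybe(pv[0]), slope_p=_maybe(pv[1]), nobs=nobs)


def _binomial_sandwich_se(k, w, params, fitted):
    """Sandwich covariance with per-point binomial variance p(1-p)/n."""
    X = np.column_stack([np.ones_like(k), k])
    p = np.clip(np.asarray(fitted, dtype=float), 1e-8, 1 - 1e-8)
    V = p * (1 - p) / w
    XtWX = X.T @ (w[:, None] * X)
    try:
        bread = np.linalg.inv(XtWX)
    except np.linalg.LinAlgError:
        return None
    meat = X.T @ ((w ** 2 * V)[:, None] * X)
    cov = bread @ meat @ bread
    return np.sqrt(np.maximum(np.diag(cov), 0.0))


def _maybe(x):
    return None if x is None or not np.isfinite(x) else float(x)


@dataclass
class LogisticComparison:
    """Linear vs logistic fit of the same transition, compared per count."""

    wls: RegressionFit
    table: pd.DataFrame           # k, n, fraction, p_linear, p_logistic
    max_divergence: float
    logit_intercept: float
    logit_slope: float

    @property
    def nonlinear(self) -> bool:
        return self.max_divergence >= 0.02


def fit_logistic_check(transitions, from_state: str, to_state: str,
                       influencing_state: str) -> LogisticComparison:
    """Compare the WLS linear fit against a grouped logistic regression.

    Reports per-count predicted probabilities from both fits and their
    maximum absolute divergence over the observed counts.
    """
    points = aggregate_by_neighbor_count(transitions, from_state, to_state,
                                         influencing_state)
    wls = fit_wls(points, from_state, to_state, influencing_state)
    k = points["k"].to_numpy(dtype=float)
    y = points["fraction"].to_numpy(dtype=float)
    n = points["n"].to_numpy(dtype=float)
    if len(np.unique(k)) < 2 or np.all(y == y[0]):
        p_lin = wls.predict(k)
        table = points.assign(p_linear=p_lin, p_logistic=p_lin)
        return LogisticComparison(wls, table, 0.0,
                                  logit_intercept=float("nan"),
                                  logit_slope=0.0)
    glm = sm.GLM(y, sm.add_constant(k), family=sm.families.Binomial(),
                 var_weights=n).fit()
    p_log = np.asarray(glm.predict(sm.add_constant(k)), dtype=float)
    p_lin = wls.predict(k)
    table = points.assign(p_linear=p_lin, p_logistic=p_log)
    return LogisticComparison(
        wls, table, max_divergence=float(np.max(np.abs(p_lin - p_log))),
        logit_intercept=float(glm.params[0]), logit_slope=float(glm.params[1]))


# ---------------------------------------------------------------------------
# full calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Calibrated parameters together with every regression fit."""

    params: AMHaParameters
    fits: list[RegressionFit]
    significance_level: float

    def fits_frame(self) -> pd.DataFrame:
        return pd.DataFrame([f.as_row() for f in self.fits])


def calibrate(transitions, significance_level: float = 0.05,
              cross_terms: Iterable[tuple[str, str, str]] = DEFAULT_CROSS_TERMS,
              reference_period_years: float = 4.0) -> CalibrationResult:
    """Fit all six transitions and return filtered :class:`AMHaParameters`.

    For each transition the primary influencer is the destination state;
    ``cross_terms`` adds further ``(from, to, influencer)`` fits.  A social
    rate is retained iff its slope is positive with p at or below the
    significance level; otherwise it is stored as 0 with its metadata.
    Negative intercepts are clipped at 0 (rates are probabilities).
    """
    df = _as_df(transitions)
    if df.empty:
        raise ValueError("no transitions to calibrate on")
    cross = [tuple(t) for t in cross_terms]
    alpha, beta, fits = {}, {}, []
    for x, y in TRANSITIONS:
        influencers = [y] + [z for (fx, ty, z) in cross
                             if (fx, ty) == (x, y) and z != y]
        influencers = [z for z in influencers if z != x]
        at_risk = df[df["from_state"] == x]
        if at_risk.empty:
            raise ValueError(f"no at-risk observations for transition {x}->{y}")
        for pos, z in enumerate(influencers):
            points = aggregate_by_neighbor_count(df, x, y, z)
            fit = fit_wls(points, x, y, z)
            fits.append(fit)
            if pos == 0:  # primary fit carries the spontaneous rate
                alpha[(x, y)] = max(0.0, float(fit.intercept))
            slope = fit.slope
            significant = (slope is not None and slope > 0
                           and fit.slope_p is not None
                           and fit.slope_p <= significance_level)
            beta.setdefault((x, y), {})[z] = SocialRate(
                value=float(slope) if significant else 0.0,
                se=fit.slope_se, p_value=fit.slope_p, significant=significant)
    params = AMHaParameters(alpha=alpha, beta=beta,
                            reference_period_years=reference_period_years)
    return CalibrationResult(params=params, fits=fits,
                             significance_level=significance_level)


# ---------------------------------------------------------------------------
# per-wave trend diagnostics
# ---------------------------------------------------------------------------

@dataclass
class TrendResult:
    """Per-wave rate estimates and a weighted linear time-trend test."""

    per_wave: pd.DataFrame   # transition, influencer, wave, alpha, beta, SEs
    trends: pd.DataFrame     # transition, parameter, slope, slope_p, n_waves


def per_wave_trend(transitions,
                   cross_terms: Iterable[tuple[str, str, str]] = ()) -> TrendResult:
    """Fit every transition separately per wave pair and test for a trend.

    Requires at least three wave pairs.  The trend test regresses the
    per-wave estimates on the wave index, weighting by inverse squared
    standard error, and reports the slope p-value; a non-significant trend
    supports pooling waves.
    """
    df = _as_df(transitions)
    wave_ids = sorted(df["wave"].unique())
    if len(wave_ids) < 3:
        raise ValueError("per-wave trend needs at least three wave pairs")
    rows = []
    terms = [(x, y, y) for x, y in TRANSITIONS] + [tuple(t) for t in cross_terms]
    for x, y, z in terms:
        for w in wave_ids:
            sub = df[df["wave"] == w]
            points = aggregate_by_neighbor_count(sub, x, y, z)
            if points.empty:
                continue
            fit = fit_wls(points, x, y, z)
            rows.append({"transition": f"{x}->{y}", "influencer": z, "wave": w,
                         "alpha": fit.intercept, "alpha_se": fit.intercept_se,
                         "beta": fit.slope, "beta_se": fit.slope_se,
                         "nobs": fit.nobs})
    per_wave = pd.DataFrame(rows)
    trends = []
    for (trans, z), grp in per_wave.groupby(["transition", "influencer"]):
        for param, se_col in (("alpha", "alpha_se"), ("beta", "beta_se")):
            vals = grp[[param, se_col, "wave"]].dropna()
            if len(vals) < 3:
                continue
            w = 1.0 / np.maximum(vals[se_col].to_numpy(dtype=float), 1e-12) ** 2
            res = sm.WLS(vals[param].to_numpy(dtype=float),
                         sm.add_constant(vals["wave"].to_numpy(dtype=float)),
                         weights=w).fit()
            trends.append({"transition": trans, "influencer": z,
                           "parameter": param,
                           "slope": float(res.params[1]),
                           "slope_p": _maybe(res.pvalues[1]),
                           "n_waves": int(len(vals))})
    return TrendResult(per_wave=per_wave, trends=pd.DataFrame(trends))
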
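"""Well-mixed three-state dynamics as a system of ordinary differential equations.

Each of the six flows between states has a spontaneous part and social
parts proportional to the influencing subpopulation.  With the default
``per_capita`` convention the social terms multiply population fractions,
so trajectories are invariant to the total population size; ``per_count``
multiplies absolute counts, matching a complete-graph stochastic run with
the same per-neighbour rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .calibration import AMHaParameters, TRANSITIONS
from .data_model import STATE_ORDER


@dataclass
class PopulationState:
    """Population composition at one time point (counts or fractions)."""

    A: float
    M: float
    H: float
    time: float = 0.0

    @property
    def total(self) -> float:
        return self.A + self.M + self.H

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.M, self.H], dtype=float)

    @classmethod
    def from_array(cls, y, time: float = 0.0) -> "PopulationState":
        return cls(A=float(y[0]), M=float(y[1]), H=float(y[2]), time=time)

    def fractions(self) -> np.ndarray:
        return self.as_array() / self.total


def _flow_rates(y: np.ndarray, params: AMHaParameters,
                convention: str) -> np.ndarray:
    """Per-year flow for each of the six ordered transitions."""
    n = y.sum()
    social = y / n if convention == "per_capita" else y
    per_year = 1.0 / params.reference_period_years
    flows = np.zeros(len(TRANSITIONS))
    for t, (x, yd) in enumerate(TRANSITIONS):
        rate = params.get_alpha(x, yd)
        for zc, z in enumerate(STATE_ORDER):
            rate += params.get_beta(x, yd, z) * social[zc]
        flows[t] = y[STATE_ORDER.index(x)] * rate * per_year
    return flows


def amha_derivatives(state: PopulationState | np.ndarray,
                     params: AMHaParameters,
                     convention: str = "per_capita") -> np.ndarray:
    """Time derivatives (per year) of the three subpopulations.

    Flow balance over all six transitions, including the direct A<->H
    channels; the components sum to zero by construction.
    """
    if convention not in ("per_capita", "per_count"):
        raise ValueError(f"unknown density convention: {convention}")
    y = state.as_array() if isinstance(state, PopulationState) else \
        np.asarray(state, dtype=float)
    if np.any(y < 0):
        raise ValueError("population components must be non-negative")
    flows = _flow_rates(y, params, convention)
    dy = np.zeros(3)
    for t, (x, yd) in enumerate(TRANSITIONS):
        dy[STATE_ORDER.index(x)] -= flows[t]
        dy[STATE_ORDER.index(yd)] += flows[t]
    return dy


@dataclass
class Trajectory:
    """ODE solution sampled at requested output times."""

    times: np.ndarray
    values: np.ndarray            # shape (len(times), 3), state counts
    total: float

    def fractions(self) -> np.ndarray:
        return self.values / self.total

    def to_frame(self) -> pd.DataFrame:
        frac = self.fractions()
        return pd.DataFrame({"time": self.times,
                             "A": frac[:, 0], "M": frac[:, 1],
                             "H": frac[:, 2]})

    def final_state(self) -> PopulationState:
        return PopulationState.from_array(self.values[-1],
                                          time=float(self.times[-1]))


def integrate(initial: PopulationState, params: AMHaParameters,
              horizon_years: float, step: float | None = None,
              convention: str = "per_capita",
              rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the system over ``horizon_years``.

    Adaptive RK45 by default; passing ``step`` switches to a fixed-step
    classic RK4 for bit-reproducibility.  Conservation of the total is
    enforced to 1e-6 of the population and tiny negative excursions are
    projected back to zero.
    """
    if horizon_years <= 0:
        raise ValueError("horizon_years must be positive")
    y0 = initial.as_array()
    total = y0.sum()
    if step is not None:
        times, values = _rk4(y0, params, horizon_years, step, convention)
    else:
        times = np.linspace(0.0, horizon_years, max(2, int(horizon_years) + 1))
        sol = solve_ivp(lambda t, y: amha_derivatives(np.clip(y, 0, None),
                                                      params, convention),
                        (0.0, horizon_years), y0, t_eval=times,
                        rtol=rtol, atol=atol * max(total, 1.0), method="RK45")
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        values = sol.y.T
    if np.min(values) < -1e-6 * total:
        raise RuntimeError("negative component beyond tolerance; "
                           "reduce the step size")
    values = np.clip(values, 0.0, None)
    drift = np.abs(values.sum(axis=1) - total).max()
    if drift > 1e-6 * total:
        raise RuntimeError(f"conservation violated by {drift:g}")
    return Trajectory(times=np.asarray(times), values=values, total=total)


def _rk4(y0, params, horizon, step, convention):
    n_steps = int(np.ceil(horizon / step))
    times = [0.0]
    values = [y0.copy()]
    y = y0.copy()
    t = 0.0
    f = lambda y: amha_derivatives(np.clip(y, 0, None), params, convention)
    for _ in range(n_steps):
        h = min(step, horizon - t)
        k1 = f(y)
        k2 = f(y + h / 2 * k1)
        k3 = f(y + h / 2 * k2)
        k4 = f(y + h * k3)
        y = np.clip(y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, None)
        t += h
        times.append(t)
        values.append(y.copy())
    return np.array(times), np.vstack(values)


def steady_state(params: AMHaParameters, initial: PopulationState,
                 convention: str = "per_capita", tol: float = 1e-8,
                 max_years: float = 5000.0,
                 chunk_years: float = 50.0) -> tuple[PopulationState, bool]:
    """Integrate until the dynamics settle; returns ``(state, converged)``.

    Convergence means the largest derivative falls below ``tol`` times the
    population per year before the horizon cap; otherwise the flag is False.
    """
    y = initial.as_array()
    total = y.sum()
    t = 0.0
    while t < max_years:
        traj = integrate(PopulationState.from_array(y), params,
                         chunk_years, convention=convention)
        y = traj.values[-1]
        t += chunk_years
        if np.abs(amha_derivatives(y, params, convention)).max() < tol * total:
            return PopulationState.from_array(y, time=t), True
    return PopulationState.from_array(y, time=t), False
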
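import numpy as np
import pandas as pd
import pytest

import amha
from amha import (AMHaParameters, aggregate_by_neighbor_count, calibrate,
                  fit_logistic_check, fit_wls, per_wave_trend)
from amha.calibration import (DEFAULT_CROSS_TERMS, SocialRate, TRANSITIONS,
                              RegressionFit)
from amha.data_model import TransitionTable


def make_transitions(rows):
    """Rows of (from, to, n_A, n_M, n_H[, wave])."""
    recs = []
    for i, r in enumerate(rows):
        wave = r[5] if len(r) > 5 else 0
        recs.append({"person_id": i, "wave": wave, "from_state": r[0],
                     "to_state": r[1], "n_A": r[2], "n_M": r[3], "n_H": r[4],
                     "interval_years": 4.0})
    return TransitionTable(pd.DataFrame(recs))


def simulate_transitions(rng, n, alpha, beta, k_dist, from_state="M",
                         to_state="H", influencer="H", wave=0):
    """Binomial oracle data: each ego transitions w.p. alpha + beta*k."""
    ks = rng.choice(len(k_dist), size=n, p=k_dist)
    p = alpha + beta * ks
    hits = rng.random(n) < p
    others = [s for s in "AMH" if s != from_state]
    rows = []
    for k, hit in zip(ks, hits):
        to = to_state if hit else from_state
        counts = {"A": 0, "M": 0, "H": 0}
        counts[influencer] = int(k)
        rows.append((from_state, to, counts["A"], counts["M"], counts["H"],
                     wave))
    return make_transitions(rows)


class TestAggregate:
    def test_simple_fraction(self):
        rows = [("M", "H", 0, 0, 0)] * 2 + [("M", "M", 0, 0, 0)] * 8
        pts = aggregate_by_neighbor_count(make_transitions(rows), "M", "H", "H")
        assert len(pts) == 1
        assert pts["fraction"].iloc[0] == pytest.approx(0.2)
        assert pts["n"].iloc[0] == 10

    def test_no_at_risk_no_point(self):
        rows = [("M", "M", 0, 0, 1)]
        pts = aggregate_by_neighbor_count(make_transitions(rows), "M", "H", "H")
        assert list(pts["k"]) == [1]
        pts_a = aggregate_by_neighbor_count(make_transitions(rows), "A", "M", "H")
        assert pts_a.empty

    def test_binomial_oracle_bounds(self, rng):
        alpha, beta = 0.05, 0.03
        table = simulate_transitions(rng, 40000, alpha, beta,
                                     [0.4, 0.3, 0.2, 0.1])
        pts = aggregate_by_neighbor_count(table, "M", "H", "H")
        for row in pts.itertuples(index=False):
            p = alpha + beta * row.k
            se = np.sqrt(p * (1 - p) / row.n)
            assert abs(row.fraction - p) < 3.5 * se


class TestFitWLS:
    def test_exact_line_equal_weights(self):
        pts = pd.DataFrame({"k": [0, 1, 2], "fraction": [0.1, 0.3, 0.5],
                            "n": [100, 100, 100]})
        fit = fit_wls(pts)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)
        assert fit.slope == pytest.approx(0.2, abs=1e-12)

    def test_equal_weights_match_ols_closed_form(self, rng):
        k = np.arange(6, dtype=float)
        y = rng.random(6)
        pts = pd.DataFrame({"k": k, "fraction": y, "n": [50] * 6})
        fit = fit_wls(pts)
        # closed-form OLS oracle
        slope = np.cov(k, y, bias=True)[0, 1] / np.var(k)
        intercept = y.mean() - slope * k.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)

    def test_single_k_intercept_only(self):
        pts = pd.DataFrame({"k": [2, 2], "fraction": [0.2, 0.4],
                            "n": [30, 10]})
        fit = fit_wls(pts)
        assert fit.slope is None
        assert fit.intercept == pytest.approx(0.25)  # weighted mean

    def test_weighted_flat_collapses_to_pooled_mle(self):
        pts = pd.DataFrame({"k": [0, 1], "fraction": [0.1, 0.1],
                            "n": [10, 1000]})
        fit = fit_wls(pts)
        assert fit.intercept == pytest.approx(0.1)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery_within_3se(self, rng):
        alpha, beta = 0.081, 0.05
        hits = 0
        reps = 40
        for _ in range(reps):
            table = simulate_transitions(rng, 12000, alpha, beta,
                                         [0.35, 0.3, 0.2, 0.1, 0.05])
            pts = aggregate_by_neighbor_count(table, "M", "H", "H")
            fit = fit_wls(pts)
            ok = (abs(fit.intercept - alpha) < 3 * fit.intercept_se
                  and abs(fit.slope - beta) < 3 * fit.slope_se)
            hits += ok
        assert hits / reps >= 0.9

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            fit_wls(pd.DataFrame(columns=["k", "fraction", "n"]))


class TestLogisticCheck:
    def test_all_k_zero_reduces_to_base_rate(self):
        rows = [("M", "H", 0, 0, 0)] * 3 + [("M", "M", 0, 0, 0)] * 7
        cmp = fit_logistic_check(make_transitions(rows), "M", "H", "H")
        assert cmp.max_divergence == pytest.approx(0.0, abs=1e-9)
        assert cmp.wls.intercept == pytest.approx(0.3)

    def test_low_rate_linear_range(self, rng):
        table = simulate_transitions(rng, 60000, 0.05, 0.03,
                                     [0.35, 0.3, 0.2, 0.1, 0.05])
        cmp = fit_logistic_check(table, "M", "H", "H")
        assert cmp.max_divergence < 0.02
        assert not cmp.nonlinear

    def test_high_rate_flags_nonlinearity(self, rng):
        # fractions approach saturation: logistic bends away from the line
        table = simulate_transitions(rng, 50000, 0.10, 0.112,
                                     [0.3, 0.15, 0.15, 0.1, 0.1, 0.1, 0.05,
                                      0.05])
        cmp = fit_logistic_check(table, "M", "H", "H")
        assert cmp.max_divergence > 0.02
        assert cmp.nonlinear


class TestCalibrate:
    def test_intercept_only_data(self):
        rows = [("M", "H", 0, 0, 0)] * 10 + [("M", "M", 0, 0, 0)] * 90
        rows += [(s, s, 0, 0, 0) for s in "AH" for _ in range(10)]
        result = calibrate(make_transitions(rows))
        assert result.params.get_alpha("M", "H") == pytest.approx(0.1)
        for x, y in TRANSITIONS:
            for z in "AMH":
                assert result.params.get_beta(x, y, z) == 0.0

    def test_missing_origin_state_errors(self):
        rows = [("M", "M", 0, 0, 0)] * 5
        with pytest.raises(ValueError, match="at-risk"):
            calibrate(make_transitions(rows))

    def test_detects_planted_social_term(self, rng):
        sc = amha.generate_scenario(amha.ScenarioConfig(
            n_persons=8000, n_waves=7, seed=77,
            params=_single_beta_params()))
        result = calibrate(sc.truth.transition_log)
        assert result.params.get_beta("M", "H", "H") > 0
        fit = [f for f in result.fits
               if (f.from_state, f.to_state, f.influencer) == ("M", "H", "H")][0]
        assert abs(fit.slope - 0.05) < 3 * fit.slope_se

    def test_cross_terms_follow_config(self, small_scenario):
        result = calibrate(small_scenario.truth.transition_log,
                           cross_terms=[("A", "H", "M")])
        combos = {(f.from_state, f.to_state, f.influencer)
                  for f in result.fits}
        assert ("A", "H", "M") in combos
        assert ("A", "M", "H") not in combos

    def test_negative_slope_never_retained(self, small_scenario):
        result = calibrate(small_scenario.truth.transition_log)
        for (x, y), by_z in result.params.beta.items():
            for z, rate in by_z.items():
                assert rate.value >= 0

    def test_default_cross_terms(self):
        assert ("A", "M", "H") in DEFAULT_CROSS_TERMS
        assert ("H", "M", "A") in DEFAULT_CROSS_TERMS


def _single_beta_params():
    alpha = {("A", "M"): 0.12, ("A", "H"): 0.01, ("M", "A"): 0.11,
             ("M", "H"): 0.08, ("H", "A"): 0.02, ("H", "M"): 0.25}
    beta = {("M", "H"): {"H": SocialRate(0.05)}}
    return AMHaParameters(alpha=alpha, beta=beta)


class TestPerWaveTrend:
    def test_single_wave_pair_errors(self):
        rows = [("M", "H", 0, 0, 0, 0)] * 5
        with pytest.raises(ValueError, match="three wave pairs"):
            per_wave_trend(make_transitions(rows))

    def test_homogeneous_data_no_trend(self, rng):
        frames = []
        for w in range(4):
            frames.append(simulate_transitions(
                rng, 4000, 0.08, 0.04, [0.4, 0.3, 0.2, 0.1], wave=w).df)
        for s in "AH":  # give other origins some mass
            for w in range(4):
                frames.append(make_transitions(
                    [(s, s, 0, 0, 0, w)] * 50).df)
        table = TransitionTable(pd.concat(frames, ignore_index=True))
        result = per_wave_trend(table)
        row = result.trends[
            (result.trends["transition"] == "M->H")
            & (result.trends["parameter"] == "alpha")]
        assert row["slope_p"].iloc[0] > 0.05

    def test_doubling_alpha_detected(self, rng):
        frames = []
        alphas = [0.05, 0.0833, 0.1167, 0.15]  # tripling across waves
        for w, a in enumerate(alphas):
            frames.append(simulate_transitions(
                rng, 6000, a, 0.0, [0.5, 0.3, 0.2], wave=w).df)
        table = TransitionTable(pd.concat(frames, ignore_index=True))
        result = per_wave_trend(table)
        row = result.trends[
            (result.trends["transition"] == "M->H")
            & (result.trends["parameter"] == "alpha")]
        assert row["slope_p"].iloc[0] < 0.05
        assert row["slope"].iloc[0] > 0


class TestParameters:
    def test_json_roundtrip(self, tmp_path, simple_params):
        path = tmp_path / "params.json"
        simple_params.to_json(path)
        back = AMHaParameters.from_json(path)
        assert back.to_dict() == simple_params.to_dict()

    def test_nonsignificant_beta_reads_as_zero(self):
        p = AMHaParameters(alpha={("M", "H"): 0.1},
                           beta={("M", "H"): {"H": SocialRate(
                               0.0, p_value=0.3, significant=False)}})
        assert p.get_beta("M", "H", "H") == 0.0

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            AMHaParameters(alpha={("M", "H"): -0.1})

    def test_same_state_reinforcement_rejected(self):
        with pytest.raises(ValueError, match="reinforcement"):
            AMHaParameters(beta={("M", "H"): {"M": SocialRate(0.1)}})

    def test_max_total_rate(self, simple_params):
        worst = simple_params.max_total_rate({"A": 5, "M": 5, "H": 5})
        # M is the busiest state: 0.08+0.06 + (0.02+0.04)*5
        assert worst == pytest.approx(0.44)

    def test_transition_rate(self, simple_params):
        r = simple_params.transition_rate("M", "H", {"H": 2})
        assert r == pytest.approx(0.06 + 0.08)

    def test_describe_mentions_all_transitions(self, simple_params):
        text = simple_params.describe()
        for x, y in TRANSITIONS:
            assert f"{x}->{y}" in text
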
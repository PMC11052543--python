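import itertools

import numpy as np
import pandas as pd
import pytest

import amha
from amha import (SocialNetwork, annualize_stability, chisq_state_adjacency,
                  degree_distribution, extract_transitions,
                  spatial_correlation, stability_cutoff_sweep,
                  state_correlation_by_wave, transition_matrix, wave_summary)
from amha.data_model import STATE_ORDER, TransitionTable
from amha.descriptives import TransitionMatrix, mean_spatial_correlation

from conftest import make_panel


def table_from(rows):
    """TransitionTable from (from_state, to_state) pairs, zero context."""
    df = pd.DataFrame([{"person_id": i, "wave": 0, "from_state": f,
                        "to_state": t, "n_A": 0, "n_M": 0, "n_H": 0,
                        "interval_years": 4.0}
                       for i, (f, t) in enumerate(rows)])
    return TransitionTable(df)


class TestTransitionMatrix:
    def test_two_observations(self):
        tm = transition_matrix(table_from([("A", "A"), ("A", "M")]))
        assert np.allclose(tm.matrix[0], [0.5, 0.5, 0.0])

    def test_all_self_transitions_identity(self):
        tm = transition_matrix(table_from([(s, s) for s in STATE_ORDER] * 2))
        assert np.allclose(tm.matrix, np.eye(3))

    def test_rows_sum_to_one(self, small_scenario):
        tm = transition_matrix(small_scenario.truth.transition_log)
        assert np.allclose(np.nansum(tm.matrix, axis=1), 1.0, atol=1e-12)
        assert np.nanmin(tm.matrix) >= 0 and np.nanmax(tm.matrix) <= 1

    def test_matches_generator_chain_on_isolated_nodes(self):
        # no edges -> pure Markov chain with the spontaneous rates; the
        # empirical matrix must approach the true per-interval chain.
        cfg = amha.ScenarioConfig(n_persons=5000, n_waves=3, mean_degree=0.2,
                                  seed=9)
        sc = amha.generate_scenario(cfg)
        log = sc.truth.transition_log.df
        iso = log[(log.n_A + log.n_M + log.n_H) == 0]
        tm = transition_matrix(TransitionTable(iso))
        p = sc.config.params
        expected = np.eye(3)
        for (x, y), a in p.alpha.items():
            i, j = STATE_ORDER.index(x), STATE_ORDER.index(y)
            expected[i, j] = a
            expected[i, i] -= a
        assert np.nanmax(np.abs(tm.matrix - expected)) < 0.02


class TestAnnualize:
    def test_perfect_stability(self):
        assert annualize_stability(1.0, 4) == 1.0

    def test_geometric_root(self):
        # 0.75 ** 0.25 computed directly
        assert annualize_stability(0.75, 4) == pytest.approx(0.9306048591)

    def test_identity_matrix_root(self):
        tm = TransitionMatrix(matrix=np.eye(3), n_obs=np.ones(3, int))
        val = annualize_stability(0.9, 4, method="matrix_root", matrix=tm,
                                  state="A")
        assert val == pytest.approx(1.0)

    def test_matrix_root_consistent_with_chain(self):
        # a genuine 1-year chain raised to the 4th power must root back.
        q = np.array([[0.9, 0.08, 0.02], [0.05, 0.9, 0.05], [0.02, 0.18, 0.8]])
        tm = TransitionMatrix(matrix=np.linalg.matrix_power(q, 4),
                              n_obs=np.ones(3, int))
        for i, s in enumerate(STATE_ORDER):
            val = annualize_stability(0.5, 4, method="matrix_root", matrix=tm,
                                      state=s)
            assert val == pytest.approx(q[i, i], abs=1e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            annualize_stability(0.5, 0)
        with pytest.raises(ValueError):
            annualize_stability(0.0, 4)
        with pytest.raises(ValueError):
            annualize_stability(0.5, 4, method="nope")


class TestStateCorrelation:
    def test_identical_states_r_one(self):
        panel = make_panel([(i, w, 2000 + 4 * w, "male", 40, d)
                            for i, d in enumerate([0, 5, 20, 0, 5])
                            for w in (0, 1)]).classify()
        out = state_correlation_by_wave(panel)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_shuffled_states_near_zero(self, rng):
        n = 2000
        rows = []
        for i in range(n):
            rows.append((i, 0, 2000, "male", 40, float(rng.integers(0, 30))))
            rows.append((i, 1, 2004, "male", 44, float(rng.integers(0, 30))))
        out = state_correlation_by_wave(make_panel(rows).classify())
        assert abs(out["r"].iloc[0]) < 3 / np.sqrt(n)

    def test_matches_bruteforce_on_trajectories(self, small_scenario):
        out = state_correlation_by_wave(small_scenario.panel)
        # independent oracle: correlation from the generator's trajectory log
        traj = small_scenario.truth.trajectories
        code = {s: i for i, s in enumerate(STATE_ORDER)}
        wide = traj.assign(c=traj["state"].map(code)).pivot(
            index="person_id", columns="wave", values="c")
        r0 = np.corrcoef(wide[0], wide[1])[0, 1]
        assert out["r"].iloc[0] == pytest.approx(r0, abs=1e-12)
        assert out["r"].iloc[-1] == pytest.approx(
            out["r"].iloc[:-1].mean())


def brute_force_spatial(states_list, edges):
    """Mean observed edge counts per state pair over all label permutations."""
    labels = list(states_list)
    n = len(labels)
    totals = np.zeros((3, 3))
    count = 0
    for perm in set(itertools.permutations(labels)):
        obs = np.zeros((3, 3))
        for u, v in edges:
            i = STATE_ORDER.index(perm[u])
            j = STATE_ORDER.index(perm[v])
            obs[i, j] += 1
            if i != j:
                obs[j, i] += 1
        totals += obs
        count += 1
    return totals / count


class TestSpatialCorrelation:
    def test_uniform_states_clustering_one(self):
        net = SocialNetwork.from_edges([(0, 1), (1, 2), (2, 0)])
        out = spatial_correlation({0: "M", 1: "M", 2: "M"}, net)
        assert out.C[1, 1] == pytest.approx(1.0)

    def test_four_cycle_hand_value(self):
        # A-A-H-H around a 4-cycle: one A-A edge observed, expected 2/3.
        net = SocialNetwork.from_edges([(0, 1), (1, 2), (2, 3), (3, 0)])
        out = spatial_correlation({0: "A", 1: "A", 2: "H", 3: "H"}, net)
        assert out.C[0, 0] == pytest.approx(1.5)
        assert out.expected[0, 0] == pytest.approx(2 / 3)

    def test_analytic_equals_exhaustive_enumeration(self, rng):
        # fixture set of graphs with <= 8 nodes vs the brute-force oracle
        for trial in range(6):
            n = int(rng.integers(4, 9))
            edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                     if rng.random() < 0.45]
            if not edges:
                continue
            states = [STATE_ORDER[k] for k in rng.integers(0, 3, n)]
            net = SocialNetwork.from_edges(edges)
            net.graph.add_nodes_from(range(n))
            out = spatial_correlation(dict(enumerate(states)), net)
            oracle = brute_force_spatial(states, edges)
            assert np.allclose(out.expected, oracle, atol=1e-9)

    def test_observed_and_expected_sum_to_m(self, small_scenario):
        states = small_scenario.panel.wave_states(0)
        out = spatial_correlation(states, small_scenario.network)
        # off-diagonal cells hold both orientations; halve them in the total
        half = (out.observed.sum() + np.trace(out.observed)) / 2
        assert half == pytest.approx(out.n_edges)
        half_e = (out.expected.sum() + np.trace(out.expected)) / 2
        assert half_e == pytest.approx(out.n_edges, rel=1e-9)

    def test_permutation_null_centers_on_one(self, rng):
        n, reps = 60, 2000
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.08]
        net = SocialNetwork.from_edges(edges)
        net.graph.add_nodes_from(range(n))
        base = [STATE_ORDER[k] for k in rng.integers(0, 3, n)]
        vals = []
        for _ in range(reps):
            perm = rng.permutation(base)
            out = spatial_correlation(dict(enumerate(perm)), net)
            vals.append(out.C[0, 0])
        vals = np.asarray(vals)
        se = vals.std() / np.sqrt(reps)
        assert abs(vals.mean() - 1.0) < 2 * se + 1e-3

    def test_absent_state_is_missing(self):
        net = SocialNetwork.from_edges([(0, 1)])
        out = spatial_correlation({0: "A", 1: "A"}, net)
        assert np.isnan(out.C[2, 2]) and np.isnan(out.C[0, 2])

    def test_mean_over_waves(self, small_scenario):
        mean = mean_spatial_correlation(small_scenario.panel,
                                        small_scenario.network)
        assert mean.shape == (3, 3)
        assert np.isfinite(mean.values).all()


class TestChiSquared:
    def test_identical_rows_zero(self):
        # two triangles with identical ego/neighbour composition
        net = SocialNetwork.from_edges([(0, 1), (2, 3), (4, 5), (6, 7)])
        states = {0: "H", 1: "A", 2: "H", 3: "M", 4: "M", 5: "A", 6: "M",
                  7: "M"}
        res = chisq_state_adjacency(states, net, "H")
        # oracle: direct textbook formula
        table = res.table.values
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - exp) ** 2 / exp).sum()
        assert res.statistic == pytest.approx(chi2, abs=1e-9)

    def test_df_is_two(self, small_scenario):
        states = small_scenario.panel.wave_states(0)
        res = chisq_state_adjacency(states, small_scenario.network, "H")
        assert res.df == 2

    def test_matches_textbook_formula(self, small_scenario):
        states = small_scenario.panel.wave_states(1)
        res = chisq_state_adjacency(states, small_scenario.network, "A")
        table = res.table.values
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - exp) ** 2 / exp).sum()
        assert res.statistic == pytest.approx(chi2, abs=1e-9)

    def test_small_expected_warns(self):
        net = SocialNetwork.from_edges([(0, 1), (2, 3)])
        res = chisq_state_adjacency({0: "A", 1: "M", 2: "M", 3: "H"}, net, "A")
        assert res.warning is not None


class TestCutoffSweep:
    def test_grid_of_one(self, small_scenario):
        curve = stability_cutoff_sweep(small_scenario.panel, [7.0])
        assert len(curve.cutoffs) == 1

    def test_cutoff_above_max_drinks(self):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(300):
            for w in (0, 1):
                rows.append((i, w, 2000 + 4 * w, "male", 40,
                             float(rng.integers(0, 10))))
        curve = stability_cutoff_sweep(make_panel(rows), [50.0])
        # H never occurs: combined equals the M row
        assert np.isnan(curve.per_state["H"].iloc[0])
        assert curve.combined[0] == pytest.approx(curve.per_state["M"].iloc[0])

    def test_recovers_generative_threshold(self, rng):
        # states generated with a true boundary at 7: moderate drinks are
        # uniform on 1..7, heavy drinks 8 and above, both resampled per wave,
        # and true state transitions are rare.  Any other cutoff splits a
        # band and churns, so the combined stay probability peaks at 7.
        n = 4000
        chain = {"A": [0.96, 0.03, 0.01], "M": [0.03, 0.94, 0.03],
                 "H": [0.02, 0.04, 0.94]}
        rows = []
        for i in range(n):
            state = ["A", "M", "H"][int(rng.integers(0, 3))]
            for w in (0, 1):
                if state == "A":
                    drinks = 0.0
                elif state == "M":
                    drinks = float(rng.integers(1, 8))
                else:
                    drinks = 8.0 + float(rng.geometric(0.15) - 1)
                rows.append((i, w, 2000 + 4 * w, "female", 40, drinks))
                state = ["A", "M", "H"][
                    int(rng.choice(3, p=chain[state]))]
        curve = stability_cutoff_sweep(make_panel(rows), [3, 5, 7, 9, 11, 14])
        assert curve.argmax_combined() == 7.0

    def test_plot_writes_file(self, tmp_path, small_scenario):
        curve = stability_cutoff_sweep(small_scenario.panel, [5, 7, 9])
        out = tmp_path / "curve.png"
        curve.plot(out)
        assert out.stat().st_size > 0

    def test_bad_grid_rejected(self, small_scenario):
        with pytest.raises(ValueError):
            stability_cutoff_sweep(small_scenario.panel, [])
        with pytest.raises(ValueError):
            stability_cutoff_sweep(small_scenario.panel, [7, 7])


class TestDegreeDistribution:
    def test_star_graph(self):
        net = SocialNetwork.from_edges([(0, 1), (0, 2), (0, 3)])
        hist = degree_distribution(net)
        assert hist.to_dict() == {1: 3, 3: 1}

    def test_empty_graph(self):
        net = SocialNetwork.from_edges([])
        assert degree_distribution(net).empty

    def test_generator_mean_degree(self, small_scenario):
        hist = degree_distribution(small_scenario.network)
        mean = (hist.index * hist).sum() / hist.sum()
        target = small_scenario.config.mean_degree
        assert abs(mean - target) / target < 0.10


class TestWaveSummary:
    def test_unit_conversion(self, path_network):
        panel = make_panel([("a", 0, 2000, "male", 40, 7.0)]).classify()
        net = SocialNetwork.from_edges([])
        out = wave_summary(panel, net)
        assert out["mean_drinks_per_day"].iloc[0] == pytest.approx(1.0)

    def test_no_edges_zero_contacts(self):
        panel = make_panel([("a", 0, 2000, "male", 40, 7.0),
                            ("b", 0, 2000, "male", 40, 0.0)]).classify()
        out = wave_summary(panel, SocialNetwork.from_edges([]))
        assert out["mean_contacts"].iloc[0] == 0.0

    def test_matches_generator_marginals(self, small_scenario):
        out = wave_summary(small_scenario.panel, small_scenario.network)
        cfg = small_scenario.config
        assert (out["egos"] == cfg.n_persons).all()
        # wave-0 abstainer contact share ~ configured abstainer fraction
        assert out["pct_contacts_abstain"].iloc[0] == pytest.approx(
            100 * cfg.initial_fractions[0], abs=6)
        assert abs(out["mean_contacts"].iloc[0] - cfg.mean_degree) \
            / cfg.mean_degree < 0.10
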
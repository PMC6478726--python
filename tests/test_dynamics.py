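import numpy as np
import pytest

from mobsir.dynamics import (
    I,
    R,
    S,
    HealthStateVector,
    InvalidStateError,
    SimulationConfig,
    run_to_absorbing,
    seed_epidemic,
    update_states_cooperative,
    update_states_single,
)
from mobsir.geometry import ConfigurationError, contact_pairs, initialize_particles
from mobsir.observables import outbreak_fractions

from conftest import make_contacts, make_dual_states, make_single_states


class TestSeeding:
    def test_single_seed_counts(self, rng):
        states = seed_epidemic(HealthStateVector.all_susceptible(5, "single"), "single", rng)
        assert states.counts() == {"S": 4, "I": 1, "R": 0}

    def test_cooperative_seed_is_doubly_infected(self, rng):
        states = seed_epidemic(
            HealthStateVector.all_susceptible(8, "cooperative"), "cooperative", rng
        )
        assert states.counts()["AB"] == 1 and states.counts()["S"] == 7

    def test_deterministic_given_seed(self):
        base = HealthStateVector.all_susceptible(100, "single")
        a = seed_epidemic(base, "single", 42)
        b = seed_epidemic(base, "single", 42)
        assert np.array_equal(a.a, b.a)

    def test_rejects_non_susceptible_input(self, rng):
        states = HealthStateVector.all_susceptible(5, "single")
        states.a[0] = R
        with pytest.raises(InvalidStateError):
            seed_epidemic(states, "single", rng)


class TestSingleUpdate:
    def test_zero_probability_only_recovers(self, rng):
        states = make_single_states([I, S, S, R])
        contacts = make_contacts([(0, 1), (0, 2)], 4)
        out = update_states_single(states, contacts, 0.0, rng)
        assert out.counts() == {"S": 2, "I": 0, "R": 2}

    def test_certain_transmission_on_star(self, rng):
        states = make_single_states([I, S, S, S])
        contacts = make_contacts([(0, 1), (0, 2), (0, 3)], 4)
        out = update_states_single(states, contacts, 1.0, rng)
        assert out.a[0] == R and np.all(out.a[1:] == I)

    def test_multi_neighbor_acquisition_probability(self):
        # susceptible with 3 infected contacts at p = 0.5: P(infect) = 1 - 0.5^3
        states = make_single_states([I, I, I, S])
        contacts = make_contacts([(0, 3), (1, 3), (2, 3)], 4)
        rng = np.random.default_rng(8)
        trials = 10_000
        hits = sum(
            update_states_single(states, contacts, 0.5, rng).a[3] == I
            for _ in range(trials)
        )
        p_expect = 1 - 0.5**3
        se = np.sqrt(p_expect * (1 - p_expect) / trials)
        assert abs(hits / trials - p_expect) < 3 * se

    def test_invalid_probability_rejected(self, rng):
        states = make_single_states([I, S])
        contacts = make_contacts([(0, 1)], 2)
        with pytest.raises(ConfigurationError):
            update_states_single(states, contacts, 1.5, rng)


class TestCooperativeUpdate:
    def test_secondary_infection_of_recovered_other(self, rng):
        # neighbor recovered from A meets a B-infectious particle at q = 1
        states = make_dual_states([S, R], [I, S])
        contacts = make_contacts([(0, 1)], 2)
        out = update_states_cooperative(states, contacts, 0.0, 1.0, rng)
        assert out.a[1] == R and out.b[1] == I  # neighbor is now aB

    def test_same_pathogen_immunity(self, rng):
        # neighbor recovered from B cannot be reinfected with B
        states = make_dual_states([S, S], [I, R])
        contacts = make_contacts([(0, 1)], 2)
        out = update_states_cooperative(states, contacts, 1.0, 1.0, rng)
        assert out.b[1] == R and out.a[1] == S

    def test_doubly_infected_transmits_both(self, rng):
        states = make_dual_states([I, S], [I, S])
        contacts = make_contacts([(0, 1)], 2)
        out = update_states_cooperative(states, contacts, 1.0, 1.0, rng)
        assert out.a[1] == I and out.b[1] == I  # naive target became AB

    def test_currently_infected_target_counts_as_secondary(self, rng):
        # A-infected target acquires B at rate q (becomes AB)
        states = make_dual_states([S, I], [I, S])
        contacts = make_contacts([(0, 1)], 2)
        out = update_states_cooperative(states, contacts, 0.0, 1.0, rng)
        assert out.a[1] == R and out.b[1] == I


class TestRunToAbsorbing:
    def test_zero_transmission_absorbs_immediately(self):
        cfg = SimulationConfig(n=64, box_size=100.0, radius=20.0, p=0.0, seed=4)
        res = run_to_absorbing(cfg)
        assert res.absorbed and res.steps == 1
        assert outbreak_fractions(res.final_states)["rho"] == pytest.approx(1 / 64)

    def test_static_certain_spread_matches_component_oracle(self):
        # at p = 1, v = 0 the epidemic is a BFS flood: it reaches exactly
        # the seed's connected component, one graph layer per step
        import networkx as nx

        cfg = SimulationConfig(
            n=512, box_size=320.0, radius=30.0, velocity=0.0, p=1.0, seed=12
        )
        res = run_to_absorbing(cfg)
        oracle_rng = np.random.default_rng(cfg.seed)  # replays the run's draws
        ens = initialize_particles(cfg.n, cfg.box_size, oracle_rng)
        g = nx.Graph()
        g.add_nodes_from(range(cfg.n))
        g.add_edges_from(map(tuple, contact_pairs(ens, cfg.radius).pairs))
        seed_idx = int(oracle_rng.integers(cfg.n))
        component = nx.node_connected_component(g, seed_idx)
        rho = outbreak_fractions(res.final_states)["rho"]
        assert rho == pytest.approx(len(component) / cfg.n)
        ecc = max(
            nx.single_source_shortest_path_length(g, seed_idx).values()
        )
        assert res.steps == ecc + 1
        assert rho > 0.9  # supercritical geometry: giant component

    def test_supercritical_static_consumes_rng_identically_with_census(self):
        cfg = SimulationConfig(n=200, box_size=250.0, radius=30.0, velocity=10.0,
                               p=0.6, seed=3)
        with_census = run_to_absorbing(cfg, record_census=True)
        without = run_to_absorbing(cfg)
        assert with_census.counts.equals(without.counts)

    def test_static_equals_ballistic_at_zero_velocity(self):
        a = run_to_absorbing(
            SimulationConfig(n=128, box_size=160.0, radius=25.0, p=0.7,
                             motion="static", seed=9)
        )
        b = run_to_absorbing(
            SimulationConfig(n=128, box_size=160.0, radius=25.0, p=0.7,
                             velocity=0.0, motion="ballistic", seed=9)
        )
        assert a.counts.equals(b.counts)

    def test_guaranteed_termination_at_full_transmission(self):
        cfg = SimulationConfig(n=256, box_size=200.0, radius=30.0, p=1.0, q=1.0,
                               mode="cooperative", motion="annealed", seed=5)
        res = run_to_absorbing(cfg)
        assert res.absorbed and res.steps <= cfg.n

    def test_max_steps_flags_non_absorbed(self):
        cfg = SimulationConfig(n=512, box_size=320.0, radius=30.0, p=1.0,
                               velocity=0.0, seed=12, max_steps=2)
        res = run_to_absorbing(cfg)
        assert not res.absorbed
        assert res.final_states.num_infected() > 0


class TestStateInvariants:
    @pytest.mark.parametrize("mode,q", [("single", 0.0), ("cooperative", 0.8)])
    @pytest.mark.parametrize("seed", [1, 22])
    def test_conservation_monotonicity_and_one_step_infectious(self, mode, q, seed):
        cfg = SimulationConfig(n=256, box_size=250.0, radius=25.0, velocity=12.0,
                               p=0.5, q=q, mode=mode, seed=seed)
        res = run_to_absorbing(cfg, record_snapshots=True)
        counts = res.counts.drop(columns="step")
        assert (counts.sum(axis=1) == cfg.n).all()
        prev = None
        for states, _ in res.snapshots:
            if prev is not None:
                for arr_prev, arr in ((prev.a, states.a),) + (
                    ((prev.b, states.b),) if mode == "cooperative" else ()
                ):
                    # compartments only move forward S -> I -> R
                    assert np.all(arr >= arr_prev)
                    # infectious for exactly one update
                    assert np.all(arr[arr_prev == I] == R)
                    # never-infected count cannot grow
                    assert (arr == S).sum() <= (arr_prev == S).sum()
            prev = states

    def test_cooperative_q_equals_p_marginal_matches_single(self):
        # with q = p the A-marginal of the two-pathogen process is the
        # plain SIR process in distribution (two-sample KS over seeds)
        from scipy.stats import ks_2samp

        single, coop = [], []
        for s in range(120):
            c1 = SimulationConfig(n=128, box_size=226.0, radius=30.0, p=0.25,
                                  mode="single", motion="annealed", seed=3000 + s)
            single.append(
                outbreak_fractions(
                    run_to_absorbing(c1).final_states, require_absorbing=False
                )["rho"]
            )
            c2 = SimulationConfig(n=128, box_size=226.0, radius=30.0, p=0.25,
                                  q=0.25, mode="cooperative", motion="annealed",
                                  seed=7000 + s, seed_state="A")
            coop.append(
                outbreak_fractions(
                    run_to_absorbing(c2).final_states, require_absorbing=False
                )["rho_a"]
            )
        assert ks_2samp(single, coop).pvalue > 0.01


class TestRunExport:
    def test_columnar_export_round_trip(self, tmp_path):
        import pandas as pd

        cfg = SimulationConfig(n=64, box_size=100.0, radius=20.0, p=0.8, seed=2)
        res = run_to_absorbing(cfg, record_census=True)
        path = tmp_path / "run.csv"
        res.to_csv(path)
        table = pd.read_csv(path)
        assert {"step", "S", "I", "R", "IS", "IR"} <= set(table.columns)
        assert len(table) == len(res.counts)
        summary = res.summary()
        assert summary["absorbed"] == res.absorbed
        assert 0 <= summary["rho"] <= 1
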
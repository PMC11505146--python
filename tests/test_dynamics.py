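import numpy as np
import pytest

from cotnet import build_network, enumerate_organizations
from cotnet.dynamics import (mass_action_simulate, persistent_set,
                             theorem_check)
from cotnet.network import NetworkError
from cotnet.synth import GeneratorConfig, random_network


@pytest.fixture()
def inflow_outflow_net():
    return build_network(["A"], [("in", {}, {"A": 1}),
                                 ("out", {"A": 1}, {})])


class TestSimulate:
    def test_zero_state_stays_zero(self):
        net = build_network(["A", "B"], [("r", {"A": 1}, {"B": 1})])
        traj = mass_action_simulate(net, {"r": 1.0}, {"A": 0, "B": 0})
        assert np.allclose(traj.concentrations, 0.0)

    def test_inflow_outflow_settles_at_ratio(self, inflow_outflow_net):
        # dc/dt = k_in - k_out c has closed form 1 + (c0 - 1) e^{-t}
        traj = mass_action_simulate(inflow_outflow_net,
                                    {"in": 1.0, "out": 1.0}, {"A": 0.0},
                                    t_end=30.0)
        expected = 1 + (0 - 1) * np.exp(-traj.times)
        assert np.allclose(traj.species_row("A"), expected, atol=1e-6)

    def test_unimolecular_decay_closed_form(self):
        net = build_network(["A", "B"], [("r", {"A": 1}, {"B": 1})])
        traj = mass_action_simulate(net, {"r": 0.7}, {"A": 1.0, "B": 0.0},
                                    t_end=20.0)
        assert np.allclose(traj.species_row("A"),
                           np.exp(-0.7 * traj.times), atol=1e-6)
        assert traj.species_row("B")[-1] == pytest.approx(1.0, abs=1e-6)

    def test_csv_export(self, inflow_outflow_net):
        traj = mass_action_simulate(inflow_outflow_net,
                                    {"in": 1.0, "out": 1.0}, {"A": 0.5})
        csv = traj.to_csv()
        assert csv.splitlines()[0] == "time,A"

    def test_bad_rates(self, inflow_outflow_net):
        with pytest.raises(NetworkError):
            mass_action_simulate(inflow_outflow_net, {"in": -1.0}, {"A": 0})


class TestPersistentSet:
    def test_all_zero_trajectory(self):
        net = build_network(["A", "B"], [("r", {"A": 1}, {"B": 1})])
        traj = mass_action_simulate(net, {"r": 1.0}, {"A": 0, "B": 0})
        species, reactions = persistent_set(traj)
        assert species == frozenset() and reactions == frozenset()

    def test_decay_leaves_product_only(self):
        net = build_network(["A", "B"], [("r", {"A": 1}, {"B": 1})])
        traj = mass_action_simulate(net, {"r": 1.0}, {"A": 1, "B": 0},
                                    t_end=100.0)
        species, reactions = persistent_set(traj, rate_constants={"r": 1.0})
        assert species == {"B"}
        assert reactions == frozenset()  # B supports no reaction
        # ... and that pair is the empty organization
        assert reactions in enumerate_organizations(net)

    def test_inflow_outflow_pair_is_org(self, inflow_outflow_net):
        rates = {"in": 1.0, "out": 1.0}
        traj = mass_action_simulate(inflow_outflow_net, rates, {"A": 0.2},
                                    t_end=100.0)
        species, reactions = persistent_set(traj, rate_constants=rates)
        assert species == {"A"}
        assert reactions == {"in", "out"}
        assert reactions in enumerate_organizations(inflow_outflow_net)

    def test_monotone_in_threshold(self, inflow_outflow_net):
        rates = {"in": 1e-3, "out": 1.0}
        traj = mass_action_simulate(inflow_outflow_net, rates, {"A": 1.0},
                                    t_end=200.0)
        loose, _ = persistent_set(traj, threshold=1e-6)
        tight, _ = persistent_set(traj, threshold=1e-2)
        assert tight <= loose

    def test_empty_trajectory_rejected(self, inflow_outflow_net):
        from cotnet.dynamics import Trajectory
        traj = Trajectory(inflow_outflow_net, np.array([]),
                          np.zeros((1, 0)))
        with pytest.raises(NetworkError):
            persistent_set(traj)


class TestTheorem:
    def test_zero_initial_no_inflows(self):
        net = build_network(["A", "B"], [("r", {"A": 1}, {"B": 1})])
        assert theorem_check(net, {"r": 1.0}, {"A": 0, "B": 0})

    def test_tyson_generic_rates(self, tyson, tyson_orgs):
        rng = np.random.default_rng(7)
        rates = {r.id: float(rng.uniform(0.5, 1.5))
                 for r in tyson.reactions}
        init = {s.id: float(rng.uniform(0.2, 1.0))
                for s in tyson.reactive_species}
        assert theorem_check(tyson, rates, init,
                             organizations=tyson_orgs)

    @pytest.mark.parametrize("seed", range(12))
    def test_random_networks(self, seed):
        cfg = GeneratorConfig(n_species=4, n_reactions=6, p_inflow=0.3,
                              p_outflow=0.2, seed=seed, conservative=True,
                              degradation=True)
        net = random_network(cfg)
        rng = np.random.default_rng(seed + 1000)
        rates = {r.id: float(rng.uniform(0.2, 2.0)) for r in net.reactions}
        init = {s.id: float(rng.uniform(0.1, 1.0))
                for s in net.reactive_species}
        assert theorem_check(net, rates, init)
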
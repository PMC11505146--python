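import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cotnet import (FluxVector, NetworkError, active_reactions, build_network,
                    is_feasible_flux)
from cotnet.synth import GeneratorConfig, random_network

# Stoichiometric matrix printed for the Tyson model (rows C2, CP, pM, M, Y,
# YP; columns Reaction1..Reaction9).
TYSON_N = np.array([
    [1, -1, 1, 0, 0, 0, 0, 0, 0],
    [0, 1, -1, -1, 0, 0, 0, 0, 0],
    [0, 0, 0, 1, 1, 0, 0, 0, -1],
    [-1, 0, 0, 0, -1, 0, 0, 0, 1],
    [0, 0, 0, -1, 0, 1, -1, 0, 0],
    [1, 0, 0, 0, 0, 0, 0, -1, 0],
])


class TestBuildNetwork:
    def test_tyson_matrix(self, tyson):
        assert tyson.N.shape == (6, 9)
        assert np.array_equal(tyson.N, TYSON_N)

    def test_mpf_destruction_column(self, tyson):
        col = tyson.N[:, tyson.column("Reaction1")]
        assert np.count_nonzero(col) == 3
        assert col[tyson.row("C2")] == 1
        assert col[tyson.row("M")] == -1
        assert col[tyson.row("YP")] == 1

    def test_identity_reaction_zero_column(self):
        net = build_network(["A"], [("r", {"A": 1}, {"A": 1})])
        assert np.array_equal(net.N, np.zeros((1, 1), dtype=int))

    def test_boundary_species_have_no_row(self, tyson):
        assert tyson.m == 6
        assert tyson.species_by_id["EmptySet"].is_boundary
        assert tyson.species_by_id["EmptySet"].index is None

    def test_inflow_outflow_flags(self, tyson):
        assert tyson.inflow_reactions == {"Reaction6"}
        assert tyson.reactions_by_id["Reaction7"].is_outflow
        assert tyson.reactions_by_id["Reaction8"].is_outflow
        assert not tyson.reactions_by_id["Reaction1"].is_outflow

    def test_duplicate_species_id(self):
        with pytest.raises(NetworkError, match="duplicate species"):
            build_network(["A", "A"], [("r", {"A": 1}, {})])

    def test_duplicate_reaction_id(self):
        with pytest.raises(NetworkError, match="duplicate reaction"):
            build_network(["A"], [("r", {"A": 1}, {}),
                                  ("r", {}, {"A": 1})])

    def test_undeclared_species(self):
        with pytest.raises(NetworkError, match="undeclared"):
            build_network(["A"], [("r", {"B": 1}, {"A": 1})])

    def test_empty_reaction_rejected(self):
        with pytest.raises(NetworkError, match="empty"):
            build_network(["A"], [("r", {}, {})])

    def test_column_sums_match_direct_count(self, tyson):
        for j, r in enumerate(tyson.reactions):
            total = 0
            for sid, c in r.products.items():
                if not tyson.species_by_id[sid].is_boundary:
                    total += c
            for sid, c in r.reactants.items():
                if not tyson.species_by_id[sid].is_boundary:
                    total -= c
            assert tyson.N[:, j].sum() == total


class TestActiveReactions:
    def test_cp_y_with_inflow(self, tyson):
        got = active_reactions(tyson, {"CP", "Y"}, {"Reaction6"})
        assert got == {"Reaction6", "Reaction3", "Reaction4", "Reaction7"}

    def test_cp_y_without_inflow(self, tyson):
        got = active_reactions(tyson, {"CP", "Y"})
        assert got == {"Reaction3", "Reaction4", "Reaction7"}

    def test_empty_set(self, tyson):
        assert active_reactions(tyson, set()) == set()

    def test_non_inflow_in_inflow_subset(self, tyson):
        with pytest.raises(NetworkError, match="not inflow"):
            active_reactions(tyson, {"Y"}, {"Reaction7"})

    def test_boundary_species_rejected(self, tyson):
        with pytest.raises(NetworkError):
            active_reactions(tyson, {"EmptySet"})

    @given(seed=st.integers(0, 200), extra=st.integers(0, 5))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_species(self, seed, extra):
        net = random_network(GeneratorConfig(n_species=6, n_reactions=8,
                                             seed=seed))
        rng = np.random.default_rng(seed)
        ids = [s.id for s in net.reactive_species]
        small = set(rng.choice(ids, size=2, replace=False))
        big = small | set(rng.choice(ids, size=min(extra, len(ids)),
                                     replace=False))
        assert active_reactions(net, small) <= active_reactions(net, big)


class TestFluxFeasibility:
    def test_with_inflow_vector(self, tyson):
        v = FluxVector.from_values(tyson, [0, 0, 1, 1, 0, 1, 1, 0, 0])
        R = {"Reaction3", "Reaction4", "Reaction6", "Reaction7"}
        assert is_feasible_flux(tyson, v, R)

    def test_without_inflow_vector(self, tyson):
        w = FluxVector.from_values(tyson, [0, 0, 1, 1, 0, 0, 1, 0, 0])
        assert is_feasible_flux(tyson, w,
                                {"Reaction3", "Reaction4", "Reaction7"})

    def test_zero_vector_nonempty_set(self, tyson):
        z = FluxVector.from_values(tyson, [0.0] * 9)
        assert not is_feasible_flux(tyson, z, {"Reaction3"})
        assert is_feasible_flux(tyson, z, set())

    def test_length_mismatch(self, tyson):
        with pytest.raises(NetworkError, match="length"):
            FluxVector.from_values(tyson, [1.0] * 5)

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, tyson, scale):
        values = [0, 0, 1, 1, 0, 1, 1, 0, 0]
        v = FluxVector.from_values(tyson, [x * scale for x in values])
        R = {"Reaction3", "Reaction4", "Reaction6", "Reaction7"}
        assert is_feasible_flux(tyson, v, R)
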
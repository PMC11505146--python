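from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cotnet import (AnalysisOptions, NetworkError, brute_force_organizations,
                    build_network, closure, enumerate_organizations,
                    is_closed, is_valid_compartmentalization)
from cotnet.synth import GeneratorConfig, random_network

TYSON_ORG_SETS = [
    frozenset(),
    frozenset({"Reaction6", "Reaction7"}),
    frozenset({"Reaction2", "Reaction3"}),
    frozenset({"Reaction2", "Reaction3", "Reaction6", "Reaction7"}),
    frozenset({f"Reaction{i}" for i in range(1, 10)}),
]


class TestIsClosed:
    def test_c2_cp_closed(self, tyson):
        assert is_closed(tyson, {"C2", "CP"}, {"Reaction2", "Reaction3"})

    def test_c2_cp_y_not_closed(self, tyson):
        S = {"C2", "CP", "Y"}
        R = {"Reaction2", "Reaction3", "Reaction4", "Reaction6", "Reaction7"}
        assert not is_closed(tyson, S, R)  # Reaction4 produces pM

    def test_empty_closed(self, tyson):
        assert is_closed(tyson, set(), set())


class TestClosure:
    def test_cascade_to_full(self, tyson):
        got = closure(tyson, {"C2", "CP", "Y"}, {"Reaction6"})
        assert got == {"C2", "CP", "pM", "M", "Y", "YP"}

    def test_empty_fixpoint(self, tyson):
        assert closure(tyson, set()) == set()

    def test_single_species(self, tyson):
        # C2 activates only its phosphorylation, CP only the reversion
        assert closure(tyson, {"C2"}) == {"C2", "CP"}

    def test_idempotent_and_monotone(self, tyson):
        first = closure(tyson, {"Y"})
        assert closure(tyson, first) == first
        assert first <= closure(tyson, {"Y", "C2"})


class TestEnumerateTyson:
    def test_exactly_five_organizations(self, tyson_orgs):
        assert sorted(tyson_orgs.reaction_sets(), key=sorted) == \
            sorted(TYSON_ORG_SETS, key=sorted)

    def test_empty_org_present(self, tyson_orgs):
        assert frozenset() in tyson_orgs.reaction_sets()

    def test_o3_compartments(self, tyson_orgs):
        o3 = next(o for o in tyson_orgs
                  if o.reactions == TYSON_ORG_SETS[3])
        assert o3.compartments == (frozenset({"C2", "CP"}), frozenset({"Y"}))

    def test_full_is_single_compartment(self, tyson_orgs):
        o4 = next(o for o in tyson_orgs if len(o.reactions) == 9)
        assert o4.k == 1

    def test_not_incomplete(self, tyson_orgs):
        assert not tyson_orgs.incomplete


class TestEnumerateEdgeCases:
    def test_single_irreversible_reaction(self):
        net = build_network(["A", "B"], [("r", {"A": 1}, {"B": 1})])
        res = enumerate_organizations(net)
        assert res.reaction_sets() == {frozenset()}

    def test_empty_network(self):
        net = build_network(["A"], [("r", {"A": 1}, {"A": 1})])
        res = enumerate_organizations(net)
        # the identity reaction is self-maintaining on its own
        assert frozenset() in res.reaction_sets()

    def test_timeout_flags_incomplete(self, markevich):
        res = enumerate_organizations(markevich,
                                      AnalysisOptions(timeout=1e-4))
        assert res.incomplete

    def test_result_independent_of_reaction_order(self, tyson):
        reversed_net = build_network(
            [(s.id, s.name, s.is_boundary) for s in tyson.species],
            [(r.id, dict(r.reactants), dict(r.products))
             for r in reversed(tyson.reactions)])
        res = enumerate_organizations(reversed_net)
        assert res.reaction_sets() == set(TYSON_ORG_SETS)


class TestBruteForce:
    def test_tyson_agrees(self, tyson, tyson_orgs):
        bf = brute_force_organizations(tyson)
        assert bf.reaction_sets() == tyson_orgs.reaction_sets()
        assert bf.compartment_map() == tyson_orgs.compartment_map()

    def test_empty_network(self):
        net = build_network(["A", "B"], [("r", {"A": 1}, {"B": 1})])
        assert brute_force_organizations(net).reaction_sets() == {frozenset()}

    def test_guard(self):
        net = random_network(GeneratorConfig(n_species=11, n_reactions=4))
        with pytest.raises(NetworkError, match="guard"):
            brute_force_organizations(net)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_random(self, seed):
        cfg = GeneratorConfig(n_species=3 + seed % 4, n_reactions=4 + seed % 5,
                              p_inflow=0.25, p_outflow=0.25, seed=seed)
        net = random_network(cfg)
        a = enumerate_organizations(net)
        b = brute_force_organizations(net)
        assert a.reaction_sets() == b.reaction_sets()
        assert a.compartment_map() == b.compartment_map()


class TestOrganizationInvariants:
    def test_revalidation_exact(self, tyson, tyson_orgs):
        for org in tyson_orgs:
            # witness feasible on exactly the org's reactions, checked in
            # exact rational arithmetic
            for j, r in enumerate(tyson.reactions):
                positive = org.flux_witness.exact[j] > 0
                assert positive == (r.id in org.reactions)
            rows = [tyson.row(s) for s in sorted(org.species)]
            for i in rows:
                total = sum(Fraction(int(tyson.N[i, j])) *
                            org.flux_witness.exact[j]
                            for j in range(tyson.n))
                assert total >= 0
            # blocks form a valid compartmentalization
            assert is_valid_compartmentalization(
                tyson, org.compartments, org.reactions)
            # blocks are pairwise disjoint and cover the species
            seen = set()
            for b in org.compartments:
                assert not (b & seen)
                seen |= b
            assert seen == org.species

    def test_disjoint_union_is_organization(self, tyson_orgs):
        by_set = {o.reactions: o for o in tyson_orgs}
        o1 = by_set[frozenset({"Reaction6", "Reaction7"})]
        o2 = by_set[frozenset({"Reaction2", "Reaction3"})]
        assert not (o1.species & o2.species)
        assert (o1.reactions | o2.reactions) in tyson_orgs

    @given(seed=st.integers(0, 5_000))
    @settings(max_examples=15, deadline=None)
    def test_disjoint_union_random(self, seed):
        net = random_network(GeneratorConfig(n_species=6, n_reactions=7,
                                             p_inflow=0.3, p_outflow=0.3,
                                             seed=seed))
        res = enumerate_organizations(
            net, AnalysisOptions(k_max=8))
        orgs = list(res)
        for a in orgs:
            for b in orgs:
                if a.species & b.species or a.reactions >= b.reactions:
                    continue
                assert (a.reactions | b.reactions) in res
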
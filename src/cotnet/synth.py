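"""Synthetic reaction-network generators for testing.

``random_network`` samples small unstructured networks (the oracle
equivalence and theorem property tests run over these); ``planted_network``
builds networks with a known organizational structure: disjoint
self-maintaining cycles plus bridge reactions whose supports span cycles,
so a k-compartment organization exists by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .network import ReactionNetwork, build_network

__all__ = ["GeneratorConfig", "random_network", "planted_network"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for :func:`random_network` (deterministic by seed)."""

    n_species: int = 5
    n_reactions: int = 8
    max_stoich: int = 2
    p_inflow: float = 0.15
    p_outflow: float = 0.15
    seed: int = 0
    #: never let a non-inflow reaction increase the total molecule count
    #: (keeps mass-action trajectories bounded; used by the dynamics tests)
    conservative: bool = False
    #: append a first-order degradation reaction for every species, so all
    #: trajectories decay exponentially or settle at positive steady states
    #: (makes finite-window persistence detection reliable)
    degradation: bool = False

    def __post_init__(self):
        if self.n_species <= 0 or self.n_reactions <= 0:
            raise ValueError("n_species and n_reactions must be positive")
        if self.max_stoich <= 0:
            raise ValueError("max_stoich must be positive")


def _sample_side(rng: np.random.Generator, species: list[str],
                 max_stoich: int) -> dict[str, int]:
    n_terms = int(rng.integers(1, 3))  # one or two distinct species
    chosen = rng.choice(len(species), size=min(n_terms, len(species)),
                        replace=False)
    return {species[int(i)]: int(rng.integers(1, max_stoich + 1))
            for i in chosen}


def random_network(config: GeneratorConfig) -> ReactionNetwork:
    """Sample a random reaction network; identical config => identical
    network."""
    rng = np.random.default_rng(config.seed)
    species = [f"S{i}" for i in range(config.n_species)]
    reactions = []
    for j in range(config.n_reactions):
        u = rng.random()
        if u < config.p_inflow:
            reactants: dict[str, int] = {}
        else:
            reactants = _sample_side(rng, species, config.max_stoich)
        u = rng.random()
        if u < config.p_outflow and reactants:
            products: dict[str, int] = {}
        else:
            products = _sample_side(rng, species, config.max_stoich)
        if not reactants and not products:
            products = {species[0]: 1}
        if config.conservative:
            budget = sum(reactants.values()) if reactants else 1
            trimmed: dict[str, int] = {}
            for sid in sorted(products):
                take = min(products[sid], budget - sum(trimmed.values()))
                if take > 0:
                    trimmed[sid] = take
            products = trimmed
            if not reactants and not products:
                products = {species[0]: 1}
        reactions.append((f"R{j}", reactants, products))
    if config.degradation:
        for i, sid in enumerate(species):
            reactions.append((f"D{i}", {sid: 1}, {}))
    return build_network(species, reactions)


def planted_network(k_blocks: int, bridge_reactions: int | None = None,
                    seed: int = 0) -> ReactionNetwork:
    """Build ``k_blocks`` disjoint two-species interconversion cycles plus
    bridge reactions spanning pairs of blocks.

    Each cycle ``A_i <-> B_i`` is a closed, self-maintaining
    single-compartment organization; each bridge consumes one species from
    each of two blocks and produces a fresh species outside all blocks, so
    merging bridged blocks into one compartment destroys closedness.  With
    bridges on every pair (the default), the union of all cycles is an
    organization requiring exactly ``k_blocks`` compartments.
    """
    if k_blocks < 1:
        raise ValueError("k_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    species: list[str] = []
    reactions = []
    for i in range(k_blocks):
        a, b = f"A{i}", f"B{i}"
        species += [a, b]
        reactions.append((f"cyc{i}_f", {a: 1}, {b: 1}))
        reactions.append((f"cyc{i}_r", {b: 1}, {a: 1}))
    pairs = list(itertools.combinations(range(k_blocks), 2))
    if bridge_reactions is None:
        chosen = pairs
    else:
        idx = list(rng.permutation(len(pairs)))[:bridge_reactions] \
            if pairs else []
        chosen = [pairs[int(i)] for i in sorted(idx)]
    for b_id, (i, j) in enumerate(chosen):
        waste = f"X{b_id}"
        species.append(waste)
        reactions.append((f"bridge{b_id}", {f"A{i}": 1, f"A{j}": 1},
                          {waste: 1}))
    return build_network(species, reactions)
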
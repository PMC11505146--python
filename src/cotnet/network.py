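"""Reaction-network primitives: species, reactions, stoichiometry, fluxes.

A :class:`ReactionNetwork` holds an ordered species list, an ordered list of
irreversible reactions, and the integer stoichiometric matrix ``N`` whose
rows are the *reactive* (non-boundary) species and whose columns are the
reactions.  Boundary species (constant pools such as ``EmptySet``) take part
in reaction equations but have no row in ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "FluxVector",
    "NetworkError",
    "build_network",
    "active_reactions",
    "is_feasible_flux",
]

#: ids/names treated as the universal "empty set" pool when flagging
#: boundary species.
DEFAULT_BOUNDARY_NAMES = frozenset({"emptyset", "ø", "empty"})


class NetworkError(ValueError):
    """Raised for structurally invalid network definitions."""


@dataclass(frozen=True)
class Species:
    """A chemical species.

    ``index`` is the row of the species in the stoichiometric matrix, or
    ``None`` for boundary species (which have no row).
    """

    id: str
    name: str = ""
    is_boundary: bool = False
    index: Optional[int] = None


@dataclass(frozen=True)
class Reaction:
    """An irreversible reaction with integer stoichiometric counts.

    ``reactants``/``products`` are multisets mapping species id -> count.
    ``is_inflow`` / ``is_outflow`` are derived from the boundary-stripped
    multisets and never user-set.
    """

    id: str
    label: str = ""
    reactants: Mapping[str, int] = field(default_factory=dict)
    products: Mapping[str, int] = field(default_factory=dict)
    is_inflow: bool = False
    is_outflow: bool = False

    def __post_init__(self):
        for side in (self.reactants, self.products):
            for sid, count in side.items():
                if not isinstance(count, int) or count <= 0:
                    raise NetworkError(
                        f"reaction {self.id!r}: stoichiometric count for "
                        f"{sid!r} must be a positive integer, got {count!r}"
                    )
        if not self.reactants and not self.products:
            raise NetworkError(
                f"reaction {self.id!r} has empty reactants and products"
            )


class ReactionNetwork:
    """Species + irreversible reactions + stoichiometric matrix.

    Use :func:`build_network` to construct instances; the constructor
    assumes pre-validated input.
    """

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction],
                 N: np.ndarray):
        self.species: tuple[Species, ...] = tuple(species)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.N = N
        self.species_by_id = {s.id: s for s in self.species}
        self.reactions_by_id = {r.id: r for r in self.reactions}
        self.reactive_species: tuple[Species, ...] = tuple(
            s for s in self.species if not s.is_boundary
        )
        self._col = {r.id: j for j, r in enumerate(self.reactions)}

    # -- basic geometry ------------------------------------------------
    @property
    def m(self) -> int:
        """Number of reactive species (rows of N)."""
        return len(self.reactive_species)

    @property
    def n(self) -> int:
        """Number of reactions (columns of N)."""
        return len(self.reactions)

    def column(self, reaction_id: str) -> int:
        return self._col[reaction_id]

    def row(self, species_id: str) -> int:
        idx = self.species_by_id[species_id].index
        if idx is None:
            raise NetworkError(f"{species_id!r} is a boundary species (no row)")
        return idx

    # -- reaction classification ---------------------------------------
    def support(self, reaction_id: str) -> frozenset[str]:
        """Reactive reactant species of a reaction (its support)."""
        r = self.reactions_by_id[reaction_id]
        return frozenset(
            sid for sid in r.reactants if not self.species_by_id[sid].is_boundary
        )

    def reactive_products(self, reaction_id: str) -> frozenset[str]:
        r = self.reactions_by_id[reaction_id]
        return frozenset(
            sid for sid in r.products if not self.species_by_id[sid].is_boundary
        )

    def reaction_species(self, reaction_id: str) -> frozenset[str]:
        return self.support(reaction_id) | self.reactive_products(reaction_id)

    @property
    def inflow_reactions(self) -> frozenset[str]:
        return frozenset(r.id for r in self.reactions if r.is_inflow)

    def species_of(self, reaction_ids: Iterable[str]) -> frozenset[str]:
        """Reactive species touched by any of the given reactions."""
        out: set[str] = set()
        for rid in reaction_ids:
            out |= self.reaction_species(rid)
        return frozenset(out)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<ReactionNetwork m={self.m} n={self.n}>"

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        return (
            self.species == other.species
            and self.reactions == other.reactions
            and np.array_equal(self.N, other.N)
        )

    def __hash__(self):
        return hash((self.species, self.reactions))


@dataclass(frozen=True)
class FluxVector:
    """Nonnegative per-reaction rates; ``support`` holds ids with v > 0.

    ``exact`` optionally carries the rates as exact rationals (used when a
    witness was certified with rational arithmetic).
    """

    v: tuple[float, ...]
    support: frozenset[str]
    exact: Optional[tuple[Fraction, ...]] = None

    @classmethod
    def from_values(cls, net: ReactionNetwork, values, tol: float = 1e-9,
                    exact=None) -> "FluxVector":
        vals = tuple(float(x) for x in values)
        if len(vals) != net.n:
            raise NetworkError(
                f"flux length {len(vals)} != number of reactions {net.n}"
            )
        if any(x < -tol for x in vals):
            raise NetworkError("flux vector has negative entries")
        supp = frozenset(
            net.reactions[j].id for j, x in enumerate(vals) if x > tol
        )
        return cls(v=vals, support=supp,
                   exact=tuple(exact) if exact is not None else None)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.v, dtype=float)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_network(species_list: Sequence[Species | tuple | str],
                  reaction_list: Sequence[Reaction | tuple],
                  boundary_names: frozenset[str] = DEFAULT_BOUNDARY_NAMES,
                  ) -> ReactionNetwork:
    """Build a validated :class:`ReactionNetwork`.

    ``species_list`` entries may be :class:`Species`, plain id strings, or
    ``(id, name, is_boundary)`` tuples.  ``reaction_list`` entries may be
    :class:`Reaction` or ``(id, reactants, products)`` tuples.  The
    stoichiometric matrix entry for reactive species *s* and reaction *j*
    is ``products_j[s] - reactants_j[s]``.  Inflow/outflow flags are
    derived from the boundary-stripped multisets.
    """
    species: list[Species] = []
    for entry in species_list:
        if isinstance(entry, Species):
            species.append(entry)
        elif isinstance(entry, str):
            species.append(Species(id=entry))
        else:
            species.append(Species(*entry))

    seen: set[str] = set()
    for s in species:
        if s.id in seen:
            raise NetworkError(f"duplicate species id {s.id!r}")
        seen.add(s.id)

    # apply the boundary name list and assign row indices
    normalized: list[Species] = []
    idx = 0
    for s in species:
        boundary = s.is_boundary or s.id.lower() in boundary_names \
            or s.name.lower() in boundary_names
        if boundary:
            normalized.append(Species(s.id, s.name, True, None))
        else:
            normalized.append(Species(s.id, s.name, False, idx))
            idx += 1
    species = normalized
    by_id = {s.id: s for s in species}

    reactions: list[Reaction] = []
    seen_r: set[str] = set()
    for entry in reaction_list:
        if isinstance(entry, Reaction):
            rid, label = entry.id, entry.label
            reactants, products = dict(entry.reactants), dict(entry.products)
        else:
            rid, reactants, products = entry[0], dict(entry[1]), dict(entry[2])
            label = entry[3] if len(entry) > 3 else ""
        if rid in seen_r:
            raise NetworkError(f"duplicate reaction id {rid!r}")
        seen_r.add(rid)
        for sid in list(reactants) + list(products):
            if sid not in by_id:
                raise NetworkError(
                    f"reaction {rid!r} references undeclared species {sid!r}"
                )
        stripped_reactants = {
            sid: c for sid, c in reactants.items() if not by_id[sid].is_boundary
        }
        stripped_products = {
            sid: c for sid, c in products.items() if not by_id[sid].is_boundary
        }
        reactions.append(Reaction(
            id=rid, label=label, reactants=reactants, products=products,
            is_inflow=not stripped_reactants,
            is_outflow=not stripped_products,
        ))

    m = sum(1 for s in species if not s.is_boundary)
    N = np.zeros((m, len(reactions)), dtype=int)
    for j, r in enumerate(reactions):
        for sid, c in r.products.items():
            s = by_id[sid]
            if not s.is_boundary:
                N[s.index, j] += c
        for sid, c in r.reactants.items():
            s = by_id[sid]
            if not s.is_boundary:
                N[s.index, j] -= c
    return ReactionNetwork(species, reactions, N)


# ---------------------------------------------------------------------------
# active reactions and flux feasibility
# ---------------------------------------------------------------------------

def active_reactions(net: ReactionNetwork, S: Iterable[str],
                     inflow_subset: Iterable[str] = ()) -> frozenset[str]:
    """Reactions active on the species set ``S``.

    Every non-inflow reaction whose support is a subset of ``S`` is active;
    inflow reactions are optional and only those in ``inflow_subset`` are
    included.
    """
    S = frozenset(S)
    for sid in S:
        sp = net.species_by_id.get(sid)
        if sp is None or sp.is_boundary:
            raise NetworkError(f"{sid!r} is not a reactive species")
    inflow_subset = frozenset(inflow_subset)
    inflows = net.inflow_reactions
    bad = inflow_subset - inflows
    if bad:
        raise NetworkError(f"not inflow reactions: {sorted(bad)}")
    active = {
        r.id for r in net.reactions
        if not r.is_inflow and net.support(r.id) <= S
    }
    return frozenset(active) | inflow_subset


def mandatory_reactions(net: ReactionNetwork, S: Iterable[str]) -> frozenset[str]:
    """Non-inflow reactions whose support lies inside ``S``."""
    S = frozenset(S)
    return frozenset(
        r.id for r in net.reactions
        if not r.is_inflow and net.support(r.id) <= S
    )


def is_feasible_flux(net: ReactionNetwork, v: FluxVector,
                     R: Iterable[str], tol: float = 1e-9) -> bool:
    """True iff ``v_j > 0`` exactly for the reactions in ``R``."""
    if len(v.v) != net.n:
        raise NetworkError(
            f"flux length {len(v.v)} != number of reactions {net.n}"
        )
    R = frozenset(R)
    for j, r in enumerate(net.reactions):
        positive = v.v[j] > tol
        if positive != (r.id in R):
            return False
    return True
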
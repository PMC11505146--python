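"""Compartmentalization of reaction sets.

A reaction set ``R`` with species ``S`` (the species its reactions touch)
is organization-shaped when ``S`` can be split into pairwise disjoint
*blocks* such that

* every reaction of ``R`` finds its whole support inside one block (it is
  active there); reaction products may land in any block of ``S``;
* no reaction outside ``R`` finds its whole support inside one block
  (nothing extra is activated);
* a global flux with support exactly ``R`` has nonnegative net production
  for every species of ``S``.

Because each reaction's support must sit inside a single block, the species
co-occurring in a support of ``R`` form indivisible units (*support
components*); minimizing the number of blocks reduces to coloring these
units so that no outside reaction ever sees its whole support in one color
class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .maintenance import self_maintenance_witness
from .network import NetworkError, ReactionNetwork, mandatory_reactions

__all__ = [
    "Compartmentalization",
    "is_valid_compartmentalization",
    "minimal_compartmentalization",
    "compartment_stats",
]


@dataclass(frozen=True)
class Compartmentalization:
    """An ordered list of pairwise-disjoint species blocks."""

    blocks: tuple[frozenset[str], ...]

    @property
    def k(self) -> int:
        return len(self.blocks)

    def sorted_blocks(self) -> list[list[str]]:
        return [sorted(b) for b in self.blocks]


def _canonical(blocks: Iterable[frozenset[str]]) -> Compartmentalization:
    ordered = sorted((frozenset(b) for b in blocks if b),
                     key=lambda b: sorted(b))
    return Compartmentalization(tuple(ordered))


# ---------------------------------------------------------------------------
# literal validity check
# ---------------------------------------------------------------------------

def is_valid_compartmentalization(net: ReactionNetwork,
                                  blocks: Sequence[Iterable[str]],
                                  R: Iterable[str]) -> bool:
    """Check the block conditions for ``R`` against the given blocks.

    True iff the blocks are pairwise disjoint and cover the species of
    ``R``, each block activates only reactions of ``R`` and every non-inflow
    reaction of ``R`` is activated by some block, all products stay within
    the union, and a global self-maintenance flux exists.  Overlapping
    blocks yield ``False``, not an error.
    """
    R = frozenset(R)
    blocks = [frozenset(b) for b in blocks]
    union: set[str] = set()
    for b in blocks:
        if b & union:
            return False
        union |= b
    species = net.species_of(R)
    if not species <= union:
        return False

    covered: set[str] = set()
    for b in blocks:
        mand = mandatory_reactions(net, b)
        if not mand <= R:
            return False  # block activates a reaction outside R
        covered |= mand
    for rid in R:
        r = net.reactions_by_id[rid]
        if not net.reactive_products(rid) <= union:
            return False  # produces outside the organization
        if r.is_inflow:
            covered.add(rid)  # inflows are optional, usable anywhere
    if not R <= covered:
        return False  # some reaction of R is active in no block
    return self_maintenance_witness(net, R) is not None


# ---------------------------------------------------------------------------
# minimal compartmentalization
# ---------------------------------------------------------------------------

def _support_components(net: ReactionNetwork, R: frozenset[str],
                        species: frozenset[str],
                        ) -> tuple[list[frozenset[str]], dict[str, int]]:
    """Partition species(R) into units joined by support co-occurrence."""
    parent: dict[str, str] = {sid: sid for sid in species}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for rid in R:
        supp = sorted(net.support(rid))
        for a, b in zip(supp, supp[1:]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

    groups: dict[str, set[str]] = {}
    for sid in species:
        groups.setdefault(find(sid), set()).add(sid)
    comps = sorted((frozenset(g) for g in groups.values()),
                   key=lambda c: sorted(c))
    comp_of = {sid: i for i, c in enumerate(comps) for sid in c}
    return comps, comp_of


def _forbidden_sets(net: ReactionNetwork, R: frozenset[str],
                    species: frozenset[str], comp_of: dict[str, int]
                    ) -> Optional[list[frozenset[int]]]:
    """Component sets that may never share a block.

    Each non-inflow reaction outside ``R`` whose support lies inside the
    organization's species would be activated by any block containing all
    the components its support touches.  Returns ``None`` when some such
    reaction fits inside a single component (no valid split exists).
    """
    constraints: set[frozenset[int]] = set()
    for r in net.reactions:
        if r.id in R or r.is_inflow:
            continue
        supp = net.support(r.id)
        if supp and supp <= species:
            touched = frozenset(comp_of[sid] for sid in supp)
            if len(touched) == 1:
                return None
            constraints.add(touched)
    # a superset constraint is implied by any subset constraint
    out = [c for c in constraints
           if not any(o < c for o in constraints)]
    return out


def _min_coloring(n_items: int, constraints: list[frozenset[int]],
                  k_max: int) -> Optional[list[int]]:
    """Color items 0..n-1 so no constraint set is monochromatic.

    Returns a coloring using the minimum number of colors (<= k_max), or
    ``None``.  Backtracking with symmetry breaking; only constrained items
    participate, so instances are tiny.
    """
    if not constraints:
        return [0] * n_items
    involved = sorted(set(itertools.chain.from_iterable(constraints)))
    by_item: dict[int, list[frozenset[int]]] = {i: [] for i in involved}
    for c in constraints:
        for i in c:
            by_item[i].append(c)

    for k in range(2, k_max + 1):
        colors: dict[int, int] = {}

        def ok(item: int) -> bool:
            for c in by_item[item]:
                if all(j in colors for j in c) and \
                        len({colors[j] for j in c}) == 1:
                    return False
            return True

        def assign(pos: int, used: int) -> bool:
            if pos == len(involved):
                return True
            item = involved[pos]
            for color in range(min(used + 1, k)):
                colors[item] = color
                if ok(item) and assign(pos + 1, max(used, color + 1)):
                    return True
                del colors[item]
            return False

        if assign(0, 0):
            full = [0] * n_items
            for i in involved:
                full[i] = colors[i]
            return full
    return None


def minimal_compartmentalization(net: ReactionNetwork, R: Iterable[str],
                                 k_max: int = 4,
                                 ) -> Optional[Compartmentalization]:
    """A compartmentalization of ``R`` with the fewest blocks, or ``None``.

    The number of blocks is unique; block contents of equal-k solutions are
    canonicalized (unconstrained components join the first block, blocks
    ordered lexicographically).  Self-maintenance is *not* checked here —
    only the activation/closedness structure.
    """
    R = frozenset(R)
    species = net.species_of(R)
    if not species:
        return Compartmentalization(())  # empty organization: zero blocks
    comps, comp_of = _support_components(net, R, species)
    constraints = _forbidden_sets(net, R, species, comp_of)
    if constraints is None:
        return None
    coloring = _min_coloring(len(comps), constraints, k_max)
    if coloring is None:
        return None
    blocks: dict[int, set[str]] = {}
    for i, c in enumerate(comps):
        blocks.setdefault(coloring[i], set()).update(c)
    return _canonical(frozenset(b) for b in blocks.values())


def compartment_stats(organizations) -> tuple[float, int]:
    """``(fraction of orgs with k >= 2, max k over orgs)``."""
    orgs = list(organizations)
    if not orgs:
        raise NetworkError("empty organization set")
    ks = [len(o.compartments) for o in orgs]
    multi = sum(1 for k in ks if k >= 2)
    return multi / len(orgs), max(ks)
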
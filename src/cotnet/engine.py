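"""Organization enumeration: closedness, closure, and the search engine.

An *organization* is identified by its set of active reactions ``R``: its
species are those touched by ``R``, and ``R`` qualifies when

* the species split into at most ``k_max`` disjoint blocks such that every
  reaction of ``R`` has its support inside one block and no other reaction
  does (see :mod:`cotnet.compartments`), and
* a flux strictly positive exactly on ``R`` has nonnegative net production
  for every touched species (see :mod:`cotnet.maintenance`).

The engine generates candidates completely rather than heuristically.  Key
observation: for any organization ``R``, let ``X`` be the set of reactions
outside ``R`` whose support lies inside the organization's species (these
are exactly the reactions the block split must de-activate; each has a
support of at least two species).  Then the organization's support-species
set is an ordinary closed set of the network *with the reactions of X
removed*.  Enumerating, for every subset ``X`` of multi-species-support
("bridge") reactions, all closed sets of the reduced network in lectic
order (NextClosure) therefore reaches every organization; optional inflow
choices are layered on top, and every candidate is validated independently
(block coloring + exactly certified LP), so generation order cannot affect
soundness.  A literal brute-force oracle backstops completeness at small
scale.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from .compartments import minimal_compartmentalization
from .config import DEFAULT_OPTIONS, AnalysisOptions
from .maintenance import exact_feasible, self_maintenance_witness
from .network import (FluxVector, NetworkError, ReactionNetwork,
                      mandatory_reactions)

logger = logging.getLogger(__name__)

__all__ = [
    "Organization",
    "EnumerationResult",
    "is_closed",
    "closure",
    "enumerate_organizations",
    "brute_force_organizations",
]


@dataclass(frozen=True)
class Organization:
    """A closed, self-maintaining subnetwork keyed by its reaction set."""

    reactions: frozenset[str]
    species: frozenset[str]
    compartments: tuple[frozenset[str], ...]
    flux_witness: FluxVector

    def __eq__(self, other):
        if not isinstance(other, Organization):
            return NotImplemented
        return self.reactions == other.reactions

    def __hash__(self):
        return hash(self.reactions)

    @property
    def k(self) -> int:
        return len(self.compartments)

    def to_json(self) -> dict:
        return {
            "reactions": sorted(self.reactions),
            "species": sorted(self.species),
            "compartments": [sorted(b) for b in self.compartments],
            "flux_witness": list(self.flux_witness.v),
        }


class EnumerationResult:
    """Set of organizations plus completeness/timing metadata."""

    def __init__(self, organizations: Iterable[Organization],
                 incomplete: bool = False, runtime_ms: float = 0.0):
        orgs = {o.reactions: o for o in organizations}
        self.organizations: tuple[Organization, ...] = tuple(
            sorted(orgs.values(), key=lambda o: (len(o.reactions),
                                                 sorted(o.reactions)))
        )
        self.incomplete = incomplete
        self.runtime_ms = runtime_ms

    def __iter__(self) -> Iterator[Organization]:
        return iter(self.organizations)

    def __len__(self) -> int:
        return len(self.organizations)

    def __contains__(self, item) -> bool:
        if isinstance(item, Organization):
            item = item.reactions
        key = frozenset(item)
        return any(o.reactions == key for o in self.organizations)

    def reaction_sets(self) -> set[frozenset[str]]:
        return {o.reactions for o in self.organizations}

    def compartment_map(self) -> dict[frozenset[str], int]:
        return {o.reactions: o.k for o in self.organizations}

    def to_json(self) -> dict:
        return {
            "organizations": [o.to_json() for o in self.organizations],
            "incomplete": self.incomplete,
            "runtime_ms": self.runtime_ms,
        }


# ---------------------------------------------------------------------------
# closedness and closure (single species set)
# ---------------------------------------------------------------------------

def is_closed(net: ReactionNetwork, S: Iterable[str],
              R: Iterable[str]) -> bool:
    """True iff ``R`` produces nothing outside ``S`` and contains every
    non-inflow reaction active on ``S``."""
    S, R = frozenset(S), frozenset(R)
    for rid in R:
        if not net.reactive_products(rid) <= S:
            return False
    return mandatory_reactions(net, S) <= R


def closure(net: ReactionNetwork, S: Iterable[str],
            inflow_subset: Iterable[str] = ()) -> frozenset[str]:
    """Smallest closed superset of ``S`` (selected inflows always fire).

    Monotone and idempotent; the fixpoint of repeatedly adding the products
    of active reactions.
    """
    current = {net.species_by_id[s].id for s in S}
    for sid in current:
        if net.species_by_id[sid].is_boundary:
            raise NetworkError(f"{sid!r} is a boundary species")
    inflow_subset = frozenset(inflow_subset)
    bad = inflow_subset - net.inflow_reactions
    if bad:
        raise NetworkError(f"not inflow reactions: {sorted(bad)}")
    while True:
        new: set[str] = set()
        for r in net.reactions:
            if r.id in inflow_subset or (
                    not r.is_inflow and net.support(r.id) <= current):
                new |= net.reactive_products(r.id) - current
        if not new:
            return frozenset(current)
        current |= new


# ---------------------------------------------------------------------------
# candidate validation
# ---------------------------------------------------------------------------

def _validate(net: ReactionNetwork, R: frozenset[str],
              options: AnalysisOptions) -> Optional[Organization]:
    comp = minimal_compartmentalization(net, R, k_max=options.k_max)
    if comp is None:
        return None
    witness = self_maintenance_witness(net, R, tol=options.tol)
    if witness is None:
        return None
    return Organization(reactions=R, species=net.species_of(R),
                        compartments=comp.blocks, flux_witness=witness)


# ---------------------------------------------------------------------------
# bitmask closure machinery
# ---------------------------------------------------------------------------

class _BitView:
    """Bitmask view of the network over its support universe."""

    def __init__(self, net: ReactionNetwork):
        self.net = net
        universe: set[str] = set()
        for r in net.reactions:
            universe |= net.support(r.id)
        self.universe = sorted(universe)
        self.bit = {s: 1 << i for i, s in enumerate(self.universe)}
        self.p = len(self.universe)
        # (reaction id, support mask, product mask within the universe)
        self.rules: list[tuple[str, int, int]] = []
        for r in net.reactions:
            if r.is_inflow:
                continue
            supp = net.support(r.id)
            smask = 0
            for s in supp:
                smask |= self.bit[s]
            pmask = 0
            for s in net.reactive_products(r.id):
                if s in self.bit:
                    pmask |= self.bit[s]
            self.rules.append((r.id, smask, pmask))
        self.bridges = [(rid, sm, pm) for rid, sm, pm in self.rules
                        if bin(sm).count("1") >= 2]

    def mask_of(self, species: Iterable[str]) -> int:
        m = 0
        for s in species:
            if s in self.bit:
                m |= self.bit[s]
        return m

    def species_from(self, mask: int) -> frozenset[str]:
        return frozenset(s for s in self.universe if mask & self.bit[s])


def _close_mask(mask: int, rules: list[tuple[str, int, int]]) -> int:
    changed = True
    while changed:
        changed = False
        for _, sm, pm in rules:
            if (sm & mask) == sm and (pm | mask) != mask:
                mask |= pm
                changed = True
    return mask


def _closed_masks(p: int, rules: list[tuple[str, int, int]]
                  ) -> Iterator[int]:
    """All closed masks in lectic order (NextClosure)."""
    A = _close_mask(0, rules)
    yield A
    while True:
        found = False
        for i in reversed(range(p)):
            v = 1 << i
            if A & v:
                A &= ~v
            else:
                B = _close_mask(A | v, rules)
                # B must add no element below position i
                if (B & ~A) & (v - 1) == 0:
                    A = B
                    yield A
                    found = True
                    break
        if not found:
            return


# ---------------------------------------------------------------------------
# main enumeration
# ---------------------------------------------------------------------------

def enumerate_organizations(net: ReactionNetwork,
                            options: AnalysisOptions = DEFAULT_OPTIONS,
                            ) -> EnumerationResult:
    """Enumerate all organizations of ``net`` (up to ``options.k_max``
    compartments).

    Returns an :class:`EnumerationResult`; if the timeout or a cap was hit
    the result is flagged ``incomplete`` and holds whatever was found.
    """
    t0 = time.perf_counter()
    deadline = t0 + options.timeout
    incomplete = False

    view = _BitView(net)
    inflows = sorted(net.inflow_reactions)
    inflow_pmask = {f: view.mask_of(net.reactive_products(f))
                    for f in inflows}

    n_bridges = len(view.bridges)
    bridge_subset_cap = 1 << 16
    n_subsets = 1 << n_bridges
    if n_subsets > bridge_subset_cap:
        logger.warning("too many bridge reactions (%d); exploring %d "
                       "exclusion subsets only", n_bridges, bridge_subset_cap)
        n_subsets = bridge_subset_cap
        incomplete = True

    candidates: set[frozenset[str]] = set()
    n_closed = 0
    stop = False
    for xmask in range(n_subsets):
        if stop:
            break
        excluded_ids = {view.bridges[i][0] for i in range(n_bridges)
                        if xmask >> i & 1}
        excl_supports = [view.bridges[i][1] for i in range(n_bridges)
                         if xmask >> i & 1]
        rules = [rule for rule in view.rules if rule[0] not in excluded_ids]
        for Y in _closed_masks(view.p, rules):
            n_closed += 1
            if n_closed > options.max_closed_sets or \
                    time.perf_counter() > deadline:
                incomplete = True
                stop = True
                logger.warning("closed-set enumeration stopped early "
                               "(%d closed sets)", n_closed)
                break
            # canonical pairs only: every excluded bridge must actually be
            # blocked, i.e. its support lies inside Y
            if any((sm & Y) != sm for sm in excl_supports):
                continue
            base = frozenset(rid for rid, sm, _ in rules if (sm & Y) == sm)
            applicable = [f for f in inflows if (inflow_pmask[f] & Y)
                          == inflow_pmask[f]]
            for r in range(len(applicable) + 1):
                for combo in itertools.combinations(applicable, r):
                    candidates.add(base | frozenset(combo))
            if len(candidates) > options.max_organizations:
                incomplete = True
                stop = True
                break

    found: dict[frozenset[str], Organization] = {}
    for R in sorted(candidates, key=lambda R: (len(R), sorted(R))):
        if time.perf_counter() > deadline:
            incomplete = True
            break
        org = _validate(net, R, options)
        if org is not None:
            found[R] = org

    runtime_ms = (time.perf_counter() - t0) * 1e3
    return EnumerationResult(found.values(), incomplete=incomplete,
                             runtime_ms=runtime_ms)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _partitions(items: list[str], max_blocks: int
                ) -> Iterator[list[list[str]]]:
    """All set partitions of ``items`` into at most ``max_blocks`` blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest, max_blocks):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        if len(part) < max_blocks:
            yield part + [[first]]


def brute_force_organizations(net: ReactionNetwork, k_max: int = 4,
                              ) -> EnumerationResult:
    """Literal-definition oracle: exhaust species subsets, set partitions
    and inflow choices, checking activation, global closedness and an
    exact-rational self-maintenance LP for each combination.

    Guarded to small networks (<= 10 reactive species, <= 12 reactions).
    Intentionally shares no search logic with
    :func:`enumerate_organizations`.
    """
    t0 = time.perf_counter()
    if net.m > 10 or net.n > 12:
        raise NetworkError(
            f"brute-force guard exceeded (m={net.m}, n={net.n})")
    species_ids = sorted(s.id for s in net.reactive_species)
    inflows = sorted(net.inflow_reactions)

    mandatory_cache: dict[frozenset[str], frozenset[str]] = {}

    def mand(block: frozenset[str]) -> frozenset[str]:
        if block not in mandatory_cache:
            mandatory_cache[block] = mandatory_reactions(net, block)
        return mandatory_cache[block]

    lp_cache: dict[frozenset[str], bool] = {}

    def maintains(R: frozenset[str]) -> bool:
        if R not in lp_cache:
            lp_cache[R] = _exact_self_maintaining(net, R)
        return lp_cache[R]

    best: dict[frozenset[str], tuple[int, tuple[frozenset[str], ...]]] = {}

    for size in range(len(species_ids) + 1):
        for subset in itertools.combinations(species_ids, size):
            S = frozenset(subset)
            for part in _partitions(list(subset), k_max):
                blocks = [frozenset(b) for b in part]
                activated = frozenset().union(*(mand(b) for b in blocks)) \
                    if blocks else frozenset()
                for icount in range(len(inflows) + 1):
                    for icombo in itertools.combinations(inflows, icount):
                        if any(not net.reactive_products(f) <= S
                               for f in icombo):
                            continue
                        R = activated | frozenset(icombo)
                        if any(not net.reactive_products(rid) <= S
                               for rid in R):
                            continue  # not closed as a whole
                        if not maintains(R):
                            continue
                        if net.species_of(R) != S:
                            continue  # count blocks only at the exact species
                        k = len(blocks)
                        blocks_canon = tuple(sorted(blocks,
                                                    key=lambda b: sorted(b)))
                        if R not in best or k < best[R][0]:
                            best[R] = (k, blocks_canon)

    orgs = []
    for R, (k, blocks) in best.items():
        witness = self_maintenance_witness(net, R, float_screen=False)
        assert witness is not None
        orgs.append(Organization(reactions=R, species=net.species_of(R),
                                 compartments=blocks, flux_witness=witness))
    runtime_ms = (time.perf_counter() - t0) * 1e3
    return EnumerationResult(orgs, incomplete=False, runtime_ms=runtime_ms)


def _exact_self_maintaining(net: ReactionNetwork, R: frozenset[str]) -> bool:
    """Exact-rational feasibility of the self-maintenance LP (oracle path)."""
    from fractions import Fraction

    if not R:
        return True
    cols = [net.column(rid) for rid in sorted(R)]
    rows = [net.row(sid) for sid in sorted(net.species_of(R))]
    A = [[Fraction(int(net.N[i, j])) for j in cols] for i in rows]
    b = [-sum(row) for row in A]
    return exact_feasible(A, b) is not None
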
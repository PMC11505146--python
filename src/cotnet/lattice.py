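"""Hasse lattice of organizations and per-model summary parameters."""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .config import DEFAULT_OPTIONS, AnalysisOptions
from .engine import EnumerationResult, Organization, enumerate_organizations
from .network import NetworkError, ReactionNetwork

__all__ = [
    "OrganizationLattice",
    "ModelParameters",
    "build_lattice",
    "height",
    "width",
    "persistence",
    "compute_parameters",
    "to_dot",
]


@dataclass
class OrganizationLattice:
    """Organizations partially ordered by reaction-set inclusion.

    ``hasse_edges`` is the transitive reduction of the inclusion order
    (pairs of reaction sets, lower first); ``layers`` maps each reaction
    set to its level index (0 = bottom).
    """

    organizations: tuple[Organization, ...]
    hasse_edges: tuple[tuple[frozenset[str], frozenset[str]], ...]
    layers: dict[frozenset[str], int] = field(default_factory=dict)

    def by_reactions(self, R: Iterable[str]) -> Organization:
        key = frozenset(R)
        for o in self.organizations:
            if o.reactions == key:
                return o
        raise KeyError(sorted(key))

    def sub_organizations(self, org: Organization) -> list[Organization]:
        return [o for o in self.organizations
                if o.reactions < org.reactions]


def build_lattice(organizations: Iterable[Organization],
                  layering: str = "depth") -> OrganizationLattice:
    """Build the Hasse diagram of the inclusion order on reaction sets.

    Layers are assigned by longest-chain depth from the bottom
    (``layering="depth"``, default) or by raw reaction count
    (``layering="count"``).
    """
    orgs = list(organizations)
    keys = [o.reactions for o in orgs]
    if len(set(keys)) != len(keys):
        raise NetworkError("duplicate reaction sets among organizations")

    G = nx.DiGraph()
    G.add_nodes_from(keys)
    for a in keys:
        for b in keys:
            if a < b:
                G.add_edge(a, b)
    H = nx.transitive_reduction(G) if G.number_of_edges() else G

    if layering == "count":
        sizes = sorted({len(k) for k in keys})
        level = {s: i for i, s in enumerate(sizes)}
        layers = {k: level[len(k)] for k in keys}
    elif layering == "depth":
        layers = {}
        for k in nx.topological_sort(H):
            preds = list(H.predecessors(k))
            layers[k] = 1 + max((layers[p] for p in preds), default=-1)
    else:
        raise ValueError(f"unknown layering mode {layering!r}")

    edges = tuple(sorted(H.edges(),
                         key=lambda e: (sorted(e[0]), sorted(e[1]))))
    orgs_sorted = tuple(sorted(orgs, key=lambda o: (len(o.reactions),
                                                    sorted(o.reactions))))
    return OrganizationLattice(orgs_sorted, edges, layers)


def height(lattice: OrganizationLattice) -> int:
    """Number of layers (nodes in the longest chain)."""
    if not lattice.organizations:
        return 0
    return max(lattice.layers.values()) + 1


def width(lattice: OrganizationLattice) -> int:
    """Maximum number of organizations in a single layer."""
    if not lattice.organizations:
        return 0
    counts: dict[int, int] = {}
    for lvl in lattice.layers.values():
        counts[lvl] = counts.get(lvl, 0) + 1
    return max(counts.values())


def persistence(net: ReactionNetwork,
                organizations: Iterable[Organization]) -> float:
    """Reactions of the largest organization divided by total reactions.

    For a network with zero reactions the value is 1 by convention.
    """
    orgs = list(organizations)
    if not orgs:
        raise NetworkError("organization set is empty (must contain at "
                           "least the empty organization)")
    if net.n == 0:
        return 1.0
    return max(len(o.reactions) for o in orgs) / net.n


@dataclass
class ModelParameters:
    """Per-model summary record."""

    n_species: int
    n_reactions: int
    n_organizations: int
    height: int
    width: int
    persistence: float
    fraction_multi_compartment: float
    max_compartments: int
    runtime_ms: float
    incomplete: bool
    largest_organizations: list[list[str]] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "n_species": self.n_species,
            "n_reactions": self.n_reactions,
            "n_organizations": self.n_organizations,
            "height": self.height,
            "width": self.width,
            "persistence": self.persistence,
            "fraction_multi_compartment": self.fraction_multi_compartment,
            "max_compartments": self.max_compartments,
            "runtime_ms": self.runtime_ms,
            "incomplete": self.incomplete,
            "largest_organizations": self.largest_organizations,
        }


def compute_parameters(net: ReactionNetwork,
                       options: AnalysisOptions = DEFAULT_OPTIONS,
                       result: Optional[EnumerationResult] = None,
                       ) -> ModelParameters:
    """Enumerate organizations (unless supplied) and summarize the model."""
    from .compartments import compartment_stats

    t0 = time.perf_counter()
    if result is None:
        result = enumerate_organizations(net, options)
    if len(result) == 0:
        # only possible when enumeration was cut off before finding even
        # the empty organization
        return ModelParameters(
            n_species=net.m, n_reactions=net.n, n_organizations=0,
            height=0, width=0, persistence=0.0,
            fraction_multi_compartment=0.0, max_compartments=0,
            runtime_ms=result.runtime_ms, incomplete=True)
    lattice = build_lattice(result, layering=options.layering)
    frac_multi, max_k = compartment_stats(result)
    max_size = max(len(o.reactions) for o in result)
    largest = [sorted(o.reactions) for o in result
               if len(o.reactions) == max_size]
    runtime_ms = result.runtime_ms or (time.perf_counter() - t0) * 1e3
    return ModelParameters(
        n_species=net.m,
        n_reactions=net.n,
        n_organizations=len(result),
        height=height(lattice),
        width=width(lattice),
        persistence=persistence(net, result),
        fraction_multi_compartment=frac_multi,
        max_compartments=max_k,
        runtime_ms=runtime_ms,
        incomplete=result.incomplete,
        largest_organizations=largest,
    )


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------

def _esc(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;")
            .replace(">", "&gt;"))


def to_dot(lattice: OrganizationLattice) -> str:
    """Graphviz DOT rendering of the lattice.

    Node labels show reactions / species / compartment blocks (separated by
    ``|``); single-compartment organizations are boxes, multi-compartment
    ones ellipses; reactions absent from every sub-organization are
    highlighted in green.
    """
    lines = ["digraph organizations {", "  rankdir=BT;",
             '  node [fontsize=10];']
    names: dict[frozenset[str], str] = {}
    if not lattice.organizations:
        lines.append('  o0 [shape=box, label="(empty)"];')
    for i, org in enumerate(lattice.organizations):
        names[org.reactions] = f"o{i}"
        inherited: set[str] = set()
        for sub in lattice.sub_organizations(org):
            inherited |= sub.reactions
        parts = []
        for rid in sorted(org.reactions):
            if rid in inherited:
                parts.append(_esc(rid))
            else:
                parts.append(f'<FONT COLOR="green">{_esc(rid)}</FONT>')
        rline = ",".join(parts) if parts else "&#8709;"
        sline = _esc(",".join(sorted(org.species))) or "&#8709;"
        cline = _esc("|".join(",".join(sorted(b))
                              for b in org.compartments)) or "&#8709;"
        shape = "box" if org.k <= 1 else "ellipse"
        label = f"<{rline}<BR/>{sline}<BR/>{cline}>"
        lines.append(f"  o{i} [shape={shape}, label={label}];")
    for lower, upper in lattice.hasse_edges:
        lines.append(f"  {names[lower]} -> {names[upper]};")
    lines.append("}")
    return "\n".join(lines) + "\n"
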
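"""Model input/output: SBML, a plain-text reaction dialect, and fixtures.

SBML Level 2/3 documents are read with the standard-library XML parser
(namespace-agnostic element matching), which covers the stoichiometric
content needed here: species with boundary/constant flags, reactions with
integer stoichiometries, and reversibility.  Kinetic laws, rules, events
and modifiers are ignored — organizations are purely stoichiometric.

The text dialect is one reaction per line::

    R1: 2 A + B -> C        # optional comment
    R2: 0 -> A              # "0" (or empty side) denotes the empty set

Reversible SBML reactions are split into two irreversible reactions
(``<id>`` and ``<id>_rev``); all counts downstream use the post-split list.
"""

from __future__ import annotations

import re
import warnings
import xml.etree.ElementTree as ET
from typing import Sequence

from .network import (DEFAULT_BOUNDARY_NAMES, NetworkError, Reaction,
                      ReactionNetwork, Species, build_network)

__all__ = [
    "read_sbml",
    "read_sbml_string",
    "write_sbml",
    "read_reaction_text",
    "write_reaction_text",
    "tyson_fixture",
    "markevich_fixture",
]


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _find_all(elem, name):
    return [c for c in elem.iter() if _local(c.tag) == name]


def _children(elem, name):
    return [c for c in elem if _local(c.tag) == name]


def _bool(value, default=False) -> bool:
    if value is None:
        return default
    return value.strip().lower() in ("true", "1")


def _stoich(ref, rid: str) -> int:
    raw = ref.get("stoichiometry")
    if raw is None:
        return 1
    value = float(raw)
    if abs(value - round(value)) > 1e-9:
        raise NetworkError(
            f"reaction {rid!r}: fractional stoichiometry {value} is not "
            "supported (scale the model to integer counts)")
    return int(round(value))


def read_sbml_string(text: str,
                     boundary_names=DEFAULT_BOUNDARY_NAMES) -> ReactionNetwork:
    """Parse an SBML document from a string; see :func:`read_sbml`."""
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise NetworkError(f"unparseable SBML: {exc}") from exc
    models = _find_all(root, "model")
    if not models:
        raise NetworkError("no <model> element found")
    model = models[0]

    species_entries: list[Species] = []
    for lst in _find_all(model, "listOfSpecies"):
        for sp in _children(lst, "species"):
            sid = sp.get("id") or sp.get("name")
            if sid is None:
                raise NetworkError("species without id")
            boundary = _bool(sp.get("boundaryCondition")) or \
                _bool(sp.get("constant"))
            species_entries.append(
                Species(id=sid, name=sp.get("name", "") or "",
                        is_boundary=boundary))

    reactions: list[tuple] = []
    for lst in _find_all(model, "listOfReactions"):
        for rx in _children(lst, "reaction"):
            rid = rx.get("id") or rx.get("name")
            if rid is None:
                raise NetworkError("reaction without id")
            reversible = _bool(rx.get("reversible"), default=True)
            reactants: dict[str, int] = {}
            products: dict[str, int] = {}
            for side_name, store in (("listOfReactants", reactants),
                                     ("listOfProducts", products)):
                for side in _children(rx, side_name):
                    for ref in _children(side, "speciesReference"):
                        sid = ref.get("species")
                        store[sid] = store.get(sid, 0) + _stoich(ref, rid)
            label = rx.get("name", "") or ""
            reactions.append((rid, reactants, products, label))
            if reversible:
                reactions.append((f"{rid}_rev", dict(products),
                                  dict(reactants), f"{label} (reverse)"))

    if not reactions:
        warnings.warn("SBML model has zero reactions; returning an empty "
                      "network", stacklevel=2)
    return build_network(species_entries, reactions,
                         boundary_names=boundary_names)


def read_sbml(path, boundary_names=DEFAULT_BOUNDARY_NAMES) -> ReactionNetwork:
    """Read an SBML L2/L3 file into a :class:`ReactionNetwork`.

    Species and reactions keep document order; reversible reactions are
    split into forward/reverse irreversible pairs.
    """
    with open(path, encoding="utf-8") as fh:
        return read_sbml_string(fh.read(), boundary_names=boundary_names)


_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"


def write_sbml(net: ReactionNetwork, model_id: str = "model") -> str:
    """Serialize a network as a minimal SBML Level 3 document."""
    ET.register_namespace("", _SBML_NS)
    root = ET.Element(f"{{{_SBML_NS}}}sbml",
                      attrib={"level": "3", "version": "1"})
    model = ET.SubElement(root, f"{{{_SBML_NS}}}model",
                          attrib={"id": model_id})
    comps = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{_SBML_NS}}}compartment",
                  attrib={"id": "default", "constant": "true"})
    lspecies = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for s in net.species:
        attrib = {
            "id": s.id, "compartment": "default",
            "hasOnlySubstanceUnits": "true",
            "boundaryCondition": "true" if s.is_boundary else "false",
            "constant": "true" if s.is_boundary else "false",
        }
        if s.name:
            attrib["name"] = s.name
        ET.SubElement(lspecies, f"{{{_SBML_NS}}}species", attrib=attrib)
    lreactions = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for r in net.reactions:
        attrib = {"id": r.id, "reversible": "false", "fast": "false"}
        if r.label:
            attrib["name"] = r.label
        rx = ET.SubElement(lreactions, f"{{{_SBML_NS}}}reaction",
                           attrib=attrib)
        for side_name, side in (("listOfReactants", r.reactants),
                                ("listOfProducts", r.products)):
            if not side:
                continue
            lst = ET.SubElement(rx, f"{{{_SBML_NS}}}{side_name}")
            for sid in sorted(side):
                ET.SubElement(lst, f"{{{_SBML_NS}}}speciesReference",
                              attrib={"species": sid,
                                      "stoichiometry": str(side[sid]),
                                      "constant": "true"})
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# plain-text reaction dialect
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+)\s*)?([A-Za-z_][\w.\-]*)$")


def _parse_side(text: str, lineno: int) -> dict[str, int]:
    text = text.strip()
    if text in ("", "0", "Ø"):
        return {}
    out: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise NetworkError(
                f"line {lineno}: malformed term {term!r}")
        count = int(m.group(1)) if m.group(1) else 1
        sid = m.group(2)
        out[sid] = out.get(sid, 0) + count
    return out


def read_reaction_text(text: str,
                       boundary_names=DEFAULT_BOUNDARY_NAMES
                       ) -> ReactionNetwork:
    """Parse the plain-text reaction dialect into a network.

    Species are declared implicitly, ordered by first appearance; ids
    matching the boundary name list become boundary species.
    """
    species_order: list[str] = []
    seen: set[str] = set()
    reactions: list[tuple] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line or "->" not in line:
            raise NetworkError(f"line {lineno}: expected 'id: lhs -> rhs', "
                               f"got {raw!r}")
        rid, rest = line.split(":", 1)
        rid = rid.strip()
        lhs, rhs = rest.split("->", 1)
        reactants = _parse_side(lhs, lineno)
        products = _parse_side(rhs, lineno)
        if not reactants and not products:
            raise NetworkError(f"line {lineno}: both sides empty")
        for sid in list(reactants) + list(products):
            if sid not in seen:
                seen.add(sid)
                species_order.append(sid)
        reactions.append((rid, reactants, products))
    return build_network(species_order, reactions,
                         boundary_names=boundary_names)


def _format_side(side: dict[str, int]) -> str:
    if not side:
        return "0"
    return " + ".join(
        f"{count} {sid}" if count != 1 else sid
        for sid, count in sorted(side.items()))


def write_reaction_text(net: ReactionNetwork) -> str:
    """Serialize a network to the canonical text dialect."""
    lines = []
    for r in net.reactions:
        lines.append(f"{r.id}: {_format_side(dict(r.reactants))} -> "
                     f"{_format_side(dict(r.products))}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# built-in fixtures
# ---------------------------------------------------------------------------

def tyson_fixture() -> ReactionNetwork:
    """The six-variable cell-cycle network of Tyson (1991).

    Nine irreversible reactions over six reactive species plus the
    ``EmptySet`` pool; reaction ids follow the BioModels SBML numbering
    (``Reaction1`` … ``Reaction9``), labels carry the original paper
    numbering (R1 … R9).
    """
    species: Sequence = [
        ("C2", "cdc2", False),
        ("CP", "cdc2-P", False),
        ("pM", "preMPF (P-cyclin-cdc2-P)", False),
        ("M", "active MPF (P-cyclin-cdc2)", False),
        ("Y", "cyclin", False),
        ("YP", "cyclin-P", False),
        ("EmptySet", "EmptySet", True),
    ]
    reactions = [
        ("Reaction1", {"M": 1}, {"C2": 1, "YP": 1},
         "R6: destruction of active MPF releasing phosphorylated cyclin"),
        ("Reaction2", {"C2": 1}, {"CP": 1},
         "R8: phosphorylation of cdc2"),
        ("Reaction3", {"CP": 1}, {"C2": 1},
         "R9: reversion of cdc2 phosphorylation"),
        ("Reaction4", {"CP": 1, "Y": 1}, {"pM": 1},
         "R3: cdc2-P combines with cyclin to preMPF"),
        ("Reaction5", {"M": 1}, {"pM": 1},
         "R5: opposition of MPF activation by a protein kinase"),
        ("Reaction6", {"EmptySet": 1}, {"Y": 1},
         "R1: de novo synthesis of cyclin"),
        ("Reaction7", {"Y": 1}, {"EmptySet": 1},
         "R2: cyclin instability"),
        ("Reaction8", {"YP": 1}, {"EmptySet": 1},
         "R7: rapid proteolysis of phosphorylated cyclin"),
        ("Reaction9", {"pM": 1}, {"M": 1},
         "R4: dephosphorylation of cdc2 to form active MPF"),
    ]
    return build_network(species, reactions)


def markevich_fixture() -> ReactionNetwork:
    """A 16-species, 27-reaction elementary-step MAPK double
    phosphorylation/dephosphorylation cycle (Markevich et al., 2004,
    random elementary mechanism).

    MAPK ``M`` is phosphorylated by ``MAPKK`` on two sites (Y and T, in
    random order, distributively) and dephosphorylated by ``MKP3``;
    catalytic conversions are elementary (binding equilibrium plus an
    irreversible catalytic step), dephosphorylation goes through product
    complexes that release reversibly.  The network is reconstructed from
    the published mechanism; see the package README for details.
    """
    from .markevich import build as _build

    return _build()
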
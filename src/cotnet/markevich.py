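"""Reconstructed random elementary MAPK double (de)phosphorylation cycle.

Dual phosphorylation/dephosphorylation of MAPK (Markevich et al., 2004):
MAPK ``M`` is phosphorylated distributively by ``MAPKK`` on its Y and T
sites in random order and dephosphorylated by ``MKP3``; every catalytic
conversion is resolved into elementary steps (reversible substrate
binding plus an irreversible catalytic step), and the phosphatase works
through product complexes (``*_dep``) before release.  16 species, 27
irreversible reactions, no inflows or outflows (the network conserves the
MAPK, MAPKK and MKP3 moieties).

The original BioModels file is not redistributable here, so the network is
reconstructed from the published mechanism.  Its organizational structure
contains the published chain — the empty organization, the two-complex
MKP3/M equilibrium (4 species, one compartment), the two-compartment
kinase/phosphatase cycling subsystem and the full network — see the test
suite and the project notes for the detailed comparison.
"""

from __future__ import annotations

from .network import ReactionNetwork, build_network

SPECIES = [
    "M", "MpY", "MpT", "Mpp", "MAPKK", "MKP3",
    "M_MAPKK", "MpY_MAPKK", "MpT_MAPKK",
    "Mpp_MKP3", "MpY_MKP3_dep", "MpT_MKP3_dep",
    "MpY_MKP3", "MpT_MKP3", "M_MKP3_Y", "M_MKP3_T",
]

REACTIONS = [
    # --- phosphorylation by MAPKK (random order, distributive) ---
    ("v1", {"M": 1, "MAPKK": 1}, {"M_MAPKK": 1}, "M + MAPKK binding"),
    ("v2", {"M_MAPKK": 1}, {"M": 1, "MAPKK": 1}, "M_MAPKK dissociation"),
    ("v3", {"M_MAPKK": 1}, {"MpY": 1, "MAPKK": 1}, "phosphorylation of Y"),
    ("v4", {"M_MAPKK": 1}, {"MpT": 1, "MAPKK": 1}, "phosphorylation of T"),
    ("v5", {"MpY": 1, "MAPKK": 1}, {"MpY_MAPKK": 1}, "MpY + MAPKK binding"),
    ("v6", {"MpY_MAPKK": 1}, {"MpY": 1, "MAPKK": 1},
     "MpY_MAPKK dissociation"),
    ("v7", {"MpY_MAPKK": 1}, {"Mpp": 1, "MAPKK": 1}, "phosphorylation of T"),
    ("v8", {"MpT": 1, "MAPKK": 1}, {"MpT_MAPKK": 1}, "MpT + MAPKK binding"),
    ("v9", {"MpT_MAPKK": 1}, {"MpT": 1, "MAPKK": 1},
     "MpT_MAPKK dissociation"),
    ("v10", {"MpT_MAPKK": 1}, {"Mpp": 1, "MAPKK": 1},
     "phosphorylation of Y"),
    # --- first dephosphorylation round (random site choice) ---
    ("v11", {"Mpp": 1, "MKP3": 1}, {"Mpp_MKP3": 1}, "Mpp + MKP3 binding"),
    ("v12", {"Mpp_MKP3": 1}, {"Mpp": 1, "MKP3": 1},
     "Mpp_MKP3 dissociation"),
    ("v13", {"Mpp_MKP3": 1}, {"MpY_MKP3_dep": 1},
     "dephosphorylation of T (product complex)"),
    ("v14", {"Mpp_MKP3": 1}, {"MpT_MKP3_dep": 1},
     "dephosphorylation of Y (product complex)"),
    ("v15", {"MpY_MKP3_dep": 1}, {"MpY": 1, "MKP3": 1}, "MpY release"),
    ("v16", {"MpT_MKP3_dep": 1}, {"MpT": 1, "MKP3": 1}, "MpT release"),
    ("v17", {"MpT": 1, "MKP3": 1}, {"MpT_MKP3_dep": 1},
     "MpT rebinding to the product complex"),
    # --- second dephosphorylation round ---
    ("v18", {"MpY": 1, "MKP3": 1}, {"MpY_MKP3": 1}, "MpY + MKP3 binding"),
    ("v19", {"MpY_MKP3": 1}, {"MpY": 1, "MKP3": 1},
     "MpY_MKP3 dissociation"),
    ("v20", {"MpY_MKP3": 1}, {"M_MKP3_Y": 1}, "dephosphorylation of Y"),
    ("v21", {"MpT": 1, "MKP3": 1}, {"MpT_MKP3": 1}, "MpT + MKP3 binding"),
    ("v22", {"MpT_MKP3": 1}, {"MpT": 1, "MKP3": 1},
     "MpT_MKP3 dissociation"),
    ("v23", {"MpT_MKP3": 1}, {"M_MKP3_T": 1}, "dephosphorylation of T"),
    # --- unphosphorylated MAPK / MKP3 equilibria ---
    ("v24", {"M_MKP3_Y": 1}, {"M": 1, "MKP3": 1}, "M release (Y pocket)"),
    ("v25", {"M": 1, "MKP3": 1}, {"M_MKP3_Y": 1}, "M rebinding (Y pocket)"),
    ("v26", {"M_MKP3_T": 1}, {"M": 1, "MKP3": 1}, "M release (T pocket)"),
    ("v27", {"M": 1, "MKP3": 1}, {"M_MKP3_T": 1}, "M rebinding (T pocket)"),
]


def build() -> ReactionNetwork:
    return build_network(SPECIES, REACTIONS)
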
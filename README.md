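# cotnet

Chemical-organization analysis of reaction networks: enumerate all
(possibly compartmentalized) **organizations** — closed, self-maintaining
subnetworks — of an SBML or plain-text reaction network, arrange them in a
Hasse lattice, and compute per-model complexity parameters (organization
count, lattice height/width, persistence, compartmentalization
statistics).

An organization is identified by its set of active reactions `R`:

* the species touched by `R` can be split into at most `k_max` disjoint
  blocks such that every reaction of `R` finds its whole support (reactant
  set) inside one block and no reaction outside `R` does — inflow
  reactions (empty support) are optional;
* a flux vector strictly positive exactly on `R` exists with nonnegative
  net production for every touched species, decided by LP and certified in
  exact rational arithmetic.

The enumeration is complete, not heuristic: all closed species sets are
generated in lectic order (NextClosure) for every subset of excludable
"bridge" reactions (multi-species supports), candidates are validated
independently, and a literal brute-force oracle
(`brute_force_organizations`) backstops completeness on small networks.

## Command line

```sh
# single model: organizations, parameters, lattice
cotnet analyze model.xml --json report.json --dot lattice.dot
cotnet analyze model.txt --timeout 60 --k-max 4

# a directory of models -> one CSV row per model
cotnet batch models/ --csv summary.csv
```

Inputs may be SBML Level 2/3 files or the plain-text dialect
(`R1: 2 A + B -> C`, `0` for the empty set). Reversible SBML reactions are
split into irreversible pairs; species with `boundaryCondition`/`constant`
set (or named `EmptySet`) are treated as unconstrained pools.

## Library

```python
from cotnet import tyson_fixture, enumerate_organizations, compute_parameters

net = tyson_fixture()            # 6 reactive species, 9 reactions
orgs = enumerate_organizations(net)
print(len(orgs))                 # 5
print(compute_parameters(net, result=orgs))
```

Key modules: `network` (stoichiometry, active reactions, fluxes), `io`
(SBML + text dialect + fixtures), `maintenance` (LP with an exact rational
simplex), `compartments` (minimal compartmentalization via component
coloring), `engine` (enumeration + brute-force oracle), `lattice` (Hasse
diagram, metrics, DOT export), `dynamics` (mass-action simulation and
trajectory persistence), `synth` (random and planted test networks),
`cli`.

## Bundled networks

* **Tyson (1991) cell-cycle model** (`tyson_fixture`): the six-variable
  network, reproduced exactly; its five organizations, lattice (height 4,
  width 2), persistence 1, multi-compartment fraction 1/5 and the
  two-compartment minimal compartmentalization `{C2,CP} | {Y}` all match
  the published analysis.
* **Markevich (2004) elementary MAPK cycle** (`markevich_fixture`): a
  16-species / 27-reaction reconstruction of the random elementary dual
  phosphorylation/dephosphorylation mechanism (the BioModels original is
  not redistributable here). Its lattice contains the published chain —
  empty set ⊂ four-species single-compartment equilibrium ⊂ a unique
  two-compartment intermediate that contains MpY and MKP3 but not the
  MpY·MKP3 complex ⊂ full network — with height 4, persistence 1 and a
  compartment maximum of 2. It additionally contains other valid
  distributed organizations, so the published totals (4 organizations,
  width 1, fraction 1/4) are not met; for mass-conserving networks those
  totals are incompatible with the printed organization definitions
  (any two-compartment organization sitting above a pure equilibrium
  module forces further enumerable suborganizations).

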
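"""Mass-action simulation and trajectory persistence extraction.

Property-level validation of the structure/dynamics link: the subnetwork
that keeps strictly positive concentrations and fluxes along a trajectory
of ``dc/dt = N v(c)`` is an organization of the underlying network.
"Non-vanishing" is operationalized with a tail window, an absolute
threshold, and a decay-trend filter (slowly vanishing species, e.g.
algebraic decay, are classified as vanishing when the tail still shrinks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .config import DEFAULT_OPTIONS, AnalysisOptions
from .engine import EnumerationResult, enumerate_organizations
from .network import NetworkError, ReactionNetwork, mandatory_reactions

__all__ = ["Trajectory", "mass_action_simulate", "persistent_set",
           "theorem_check"]


@dataclass
class Trajectory:
    """Times plus per-species concentration rows (species order = rows of
    the stoichiometric matrix)."""

    net: ReactionNetwork
    times: np.ndarray
    concentrations: np.ndarray  # shape (m, len(times))

    def species_row(self, sid: str) -> np.ndarray:
        return self.concentrations[self.net.row(sid)]

    def to_csv(self) -> str:
        header = "time," + ",".join(s.id for s in self.net.reactive_species)
        lines = [header]
        for i, t in enumerate(self.times):
            vals = ",".join(f"{c:.10g}" for c in self.concentrations[:, i])
            lines.append(f"{t:.10g},{vals}")
        return "\n".join(lines) + "\n"


def _rate_vector(net: ReactionNetwork, k: np.ndarray, c: np.ndarray
                 ) -> np.ndarray:
    v = k.copy()
    for j, r in enumerate(net.reactions):
        for sid, count in r.reactants.items():
            sp = net.species_by_id[sid]
            if sp.is_boundary:
                continue  # boundary pools have unit activity
            v[j] *= max(c[sp.index], 0.0) ** count
    return v


def mass_action_simulate(net: ReactionNetwork,
                         rate_constants: Mapping[str, float] | Iterable[float],
                         initial: Mapping[str, float] | Iterable[float],
                         t_end: float = 50.0,
                         n_points: int = 200,
                         log_times: bool = False) -> Trajectory:
    """Integrate ``dc/dt = N v(c)`` with mass-action fluxes
    ``v_j = k_j * prod(c_reactants)``.

    ``rate_constants``/``initial`` may be mappings (reaction/species id ->
    value) or sequences in network order.  Deterministic for fixed inputs.
    """
    if isinstance(rate_constants, Mapping):
        k = np.array([float(rate_constants.get(r.id, 0.0))
                      for r in net.reactions])
    else:
        k = np.asarray(list(rate_constants), dtype=float)
        if k.shape != (net.n,):
            raise NetworkError(f"expected {net.n} rate constants")
    if isinstance(initial, Mapping):
        c0 = np.array([float(initial.get(s.id, 0.0))
                       for s in net.reactive_species])
    else:
        c0 = np.asarray(list(initial), dtype=float)
        if c0.shape != (net.m,):
            raise NetworkError(f"expected {net.m} initial concentrations")
    if (k < 0).any() or (c0 < 0).any():
        raise NetworkError("rates and initial concentrations must be >= 0")

    N = net.N.astype(float)

    def rhs(_t, c):
        return N @ _rate_vector(net, k, c)

    if log_times:
        times = np.concatenate(
            [[0.0], np.geomspace(t_end * 1e-4, t_end, n_points - 1)])
    else:
        times = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), c0, t_eval=times, method="LSODA",
                    rtol=1e-8, atol=1e-12)
    if not sol.success:
        raise NetworkError(f"integration failed: {sol.message}")
    conc = np.clip(sol.y, 0.0, None)
    return Trajectory(net=net, times=sol.t, concentrations=conc)


def persistent_set(trajectory: Trajectory,
                   tail_fraction: float = 0.2,
                   threshold: float = 1e-6,
                   rate_constants: Optional[Mapping[str, float]] = None,
                   decay_ratio: float = 0.5,
                   ) -> tuple[frozenset[str], frozenset[str]]:
    """Extract the persistent (species, reactions) pair from a trajectory.

    A species persists when its minimum over the tail window stays above
    ``threshold`` and the tail is not still decaying (the tail minimum must
    exceed ``decay_ratio`` times the minimum over the preceding window).
    Persistent reactions are the non-inflow reactions supported by the
    persistent species plus the inflows, excluding reactions with a zero
    rate constant.
    """
    if not 0 < tail_fraction <= 1:
        raise NetworkError("tail_fraction must be in (0, 1]")
    if threshold <= 0:
        raise NetworkError("threshold must be positive")
    times = trajectory.times
    if len(times) == 0:
        raise NetworkError("empty trajectory")
    net = trajectory.net
    # index-based windows: with log-spaced sampling the tail window is the
    # last decade(s), which makes the decay filter catch algebraic decay
    n = len(times)
    w = max(1, int(round(tail_fraction * n)))
    tail = slice(n - w, n)
    prev = slice(max(0, n - 2 * w), n - w)

    species: set[str] = set()
    for s in net.reactive_species:
        row = trajectory.concentrations[s.index]
        tail_min = row[tail].min()
        if tail_min <= threshold:
            continue
        if prev.stop > prev.start:
            prev_min = row[prev].min()
            if prev_min > 0 and tail_min < decay_ratio * prev_min:
                continue  # still decaying towards zero
        species.add(s.id)

    def rate_of(rid: str) -> float:
        if rate_constants is None:
            return 1.0
        return float(rate_constants.get(rid, 0.0))

    reactions = {
        rid for rid in mandatory_reactions(net, species) if rate_of(rid) > 0
    }
    reactions |= {rid for rid in net.inflow_reactions if rate_of(rid) > 0}
    return frozenset(species), frozenset(reactions)


def theorem_check(net: ReactionNetwork,
                  rate_constants: Mapping[str, float] | Iterable[float],
                  initial: Mapping[str, float] | Iterable[float],
                  options: AnalysisOptions = DEFAULT_OPTIONS,
                  t_end: float = 1e4,
                  n_points: int = 400,
                  organizations: Optional[EnumerationResult] = None,
                  ) -> bool:
    """True iff the persistent subnetwork of the simulation is one of the
    network's organizations."""
    traj = mass_action_simulate(net, rate_constants, initial,
                                t_end=t_end, n_points=n_points,
                                log_times=True)
    if isinstance(rate_constants, Mapping):
        rates = rate_constants
    else:
        rates = {r.id: k for r, k in zip(net.reactions, rate_constants)}
    _, reactions = persistent_set(traj, rate_constants=rates)
    if organizations is None:
        organizations = enumerate_organizations(net, options)
    return reactions in organizations
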
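"""Shared analysis options."""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class AnalysisOptions:
    """Options shared by the enumeration engine and the metrics layer.

    Attributes
    ----------
    tol:
        Numeric tolerance below which a value is treated as zero.  Shared
        between flux-support checks and the floating-point LP screen.
    k_max:
        Maximum number of compartments considered when deciding whether a
        reaction set is an organization.
    timeout:
        Wall-clock budget (seconds) for a single enumeration.  When
        exceeded, the partial result is returned with ``incomplete=True``.
    max_closed_sets:
        Cap on the number of closed species sets explored; exceeding it
        also flags the result incomplete.
    max_organizations:
        Cap on the number of organizations collected.
    layering:
        ``"depth"`` assigns lattice layers by longest-chain depth from the
        bottom; ``"count"`` layers by raw reaction count.
    """

    tol: float = 1e-9
    k_max: int = 4
    timeout: float = 600.0
    max_closed_sets: int = 200_000
    max_organizations: int = 100_000
    layering: str = "depth"

    def with_(self, **kwargs) -> "AnalysisOptions":
        return replace(self, **kwargs)


DEFAULT_OPTIONS = AnalysisOptions()
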
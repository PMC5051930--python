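"""Core record types for encounter-sharing collaboration analysis.

The data model mirrors the event structure of an electronic-health-record
extract: each patient *encounter* has a binary outcome (e.g. a top-box
patient-satisfaction score) and baseline covariates such as triage acuity;
each *provider event* records one action a provider performed during an
encounter ("provider P performed activity A during encounter E").  From
these, providers are linked through the encounters they share.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return an unordered provider pair in canonical (sorted) order."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class EncounterRecord:
    """One patient encounter.

    ``outcome`` is 1 (positive), 0 (negative) or ``None`` when the outcome
    was never observed (e.g. no satisfaction survey returned).  Encounters
    with a missing outcome stay in the bipartite structure but are excluded
    from every outcome-weighted computation.
    """

    encounter_id: str
    outcome: int | None
    covariates: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome is not None and self.outcome not in (0, 1):
            raise ValueError(
                f"outcome for {self.encounter_id!r} must be 0, 1 or missing; "
                f"got {self.outcome!r}"
            )


@dataclass(frozen=True)
class ProviderEvent:
    """One action instance: a hyperedge (provider, activity, encounter).

    Rows may repeat — each repetition is a distinct action instance and
    contributes to the involvement edge's ``action_count``.
    """

    provider_id: str
    encounter_id: str
    activity_category: str = ""
    action_type: str = ""


@dataclass(frozen=True)
class ProviderRecord:
    """A provider with a coarse professional category and free-text position."""

    provider_id: str
    category: str = "other"
    position: str = ""


@dataclass
class CollaborationEdge:
    """An undirected provider pair scored over their shared encounters.

    ``shared_count`` is |A ∩ B| over the analysis encounters, ``sei`` the
    Jaccard shared-encounter index, ``spoi`` the shared positive-outcome
    index, and ``spor = spoi / sei`` their ratio (1 = outcome-neutral).
    ``p_value`` is filled by the permutation test.
    """

    provider_a: str
    provider_b: str
    shared_count: int
    sei: float
    spoi: float
    spor: float
    p_value: float | None = None

    def __post_init__(self) -> None:
        self.provider_a, self.provider_b = canonical_pair(
            self.provider_a, self.provider_b
        )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.provider_a, self.provider_b)


@dataclass
class EncounterValidation:
    """Row-level accounting for an encounter table read.

    Nothing is silently mutated: every dropped or flagged row is counted.
    """

    n_rows: int = 0
    n_kept: int = 0
    dropped_missing_id: int = 0
    dropped_bad_outcome: int = 0
    missing_outcome: int = 0
    missing_covariates: int = 0


@dataclass
class EventValidation:
    """Row-level accounting for a provider-event table read."""

    n_rows: int = 0
    n_kept: int = 0
    dropped_unknown_encounter: int = 0
    dropped_missing_field: int = 0
    activity_counts: dict[str, int] = field(default_factory=dict)
    action_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class NetworkSummary:
    """Whole-network descriptive statistics for a collaboration network.

    ``diameter`` and ``mean_path_length`` are computed on the largest
    connected component since thresholded projections need not be connected.
    """

    n_nodes: int
    n_edges: int
    density: float
    mean_degree: float
    diameter: int
    mean_clustering: float
    mean_path_length: float


@dataclass
class DistributionStats:
    """Edge-weight distribution summary for one shared-encounter threshold."""

    threshold: int
    n_providers: int
    n_edges: int
    mean: float
    sd: float
    p5: float
    p10: float
    p90: float
    p95: float
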
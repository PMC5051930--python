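"""Permutation null model for collaboration-edge significance.

An edge's SPOR is compared against its distribution under outcome
exchangeability: the risk-adjusted outcomes r are randomly permuted across
encounters while the provider–encounter topology is held fixed, the SPOR
is recomputed for every edge, and the procedure is repeated B times
(B = 1,000 by default).  Because SEI depends only on topology, the edge
set is identical in every permuted network; only SPOI (hence SPOR) moves.

The per-edge p-value is the fraction of permutations whose SPOR strictly
exceeds the observed SPOR.  Small p (≤ 0.05) marks a high-scoring
collaboration — positive outcomes concentrate in the pair's shared
encounters more than chance allows — and large p (≥ 0.95) a low-scoring
one.  No multiplicity correction is applied across edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .network import BipartiteNetwork, _r_values, encounter_sets, project
from .risk import RiskAdjustedOutcome
from .types import canonical_pair

HIGH_CUT = 0.05
LOW_CUT = 0.95


@dataclass(frozen=True)
class PermutationResult:
    """Permutation outcome for one edge."""

    edge: tuple[str, str]
    observed_spor: float
    exceed_count: int
    n_permutations: int
    p_value: float


@dataclass
class NullDistribution:
    """Per-edge null SPOR samples on fixed topology.

    ``samples[b, k]`` is the SPOR of edge ``edges[k]`` in permuted network
    b; ``observed[k]`` is the SPOR in the real network.
    """

    edges: list[tuple[str, str]]
    observed: np.ndarray
    samples: np.ndarray
    network: nx.Graph = field(repr=False, default=None)


def permute_outcomes(
    r: Mapping[str, float] | Mapping[str, RiskAdjustedOutcome],
    rng: np.random.Generator,
) -> dict[str, float]:
    """Uniformly permute the risk-adjusted outcomes across encounters.

    The multiset of values is preserved exactly; only the assignment of
    values to encounter IDs changes.
    """
    rv = _r_values(r)
    if not rv:
        raise ValueError("r must be non-empty")
    keys = sorted(rv)
    values = np.array([rv[k] for k in keys])
    return dict(zip(keys, values[rng.permutation(len(keys))]))


def _edge_matrices(
    edges: Sequence[tuple[str, str]],
    sets: Mapping[str, frozenset[str]],
    index: Mapping[str, int],
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Sparse (edge × encounter) indicators for intersections and unions."""
    rows_i, cols_i, rows_u, cols_u = [], [], [], []
    for k, (a, b) in enumerate(edges):
        inter = sets[a] & sets[b]
        union = sets[a] | sets[b]
        cols_i.extend(index[e] for e in sorted(inter))
        rows_i.extend([k] * len(inter))
        cols_u.extend(index[e] for e in sorted(union))
        rows_u.extend([k] * len(union))
    shape = (len(edges), len(index))
    m_inter = sp.csr_matrix(
        (np.ones(len(rows_i)), (rows_i, cols_i)), shape=shape
    )
    m_union = sp.csr_matrix(
        (np.ones(len(rows_u)), (rows_u, cols_u)), shape=shape
    )
    return m_inter, m_union


def null_distribution(
    bipartite: BipartiteNetwork,
    r: Mapping[str, float] | Mapping[str, RiskAdjustedOutcome],
    min_shared: int = 6,
    n_permutations: int = 1000,
    seed: int = 0,
    network: nx.Graph | None = None,
) -> NullDistribution:
    """Null SPOR samples for every edge of the observed network.

    The observed network is projected once (or supplied via ``network``)
    and its topology reused for all permutations.  Each permutation b draws
    its shuffle from an independent substream spawned from ``seed``, so
    results are reproducible and independent of execution order.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rv = _r_values(r)
    if network is None:
        network = project(bipartite, rv, min_shared=min_shared)
    if network.number_of_edges() == 0:
        raise ValueError("observed network has no edges at this threshold")

    sets = encounter_sets(bipartite, rv.keys())
    enc_ids = sorted(rv)
    index = {e: i for i, e in enumerate(enc_ids)}
    r_vec = np.array([rv[e] for e in enc_ids])

    edges = sorted(canonical_pair(u, v) for u, v in network.edges())
    m_inter, m_union = _edge_matrices(edges, sets, index)
    sei_vec = np.array([network.edges[e]["sei"] for e in edges])
    observed = np.array([network.edges[e]["spor"] for e in edges])

    samples = np.empty((n_permutations, len(edges)))
    children = np.random.SeedSequence(seed).spawn(n_permutations)
    for b, child in enumerate(children):
        perm = np.random.default_rng(child).permutation(len(r_vec))
        shuffled = r_vec[perm]
        samples[b] = (m_inter @ shuffled) / (m_union @ shuffled) / sei_vec
    return NullDistribution(edges=edges, observed=observed, samples=samples, network=network)


def edge_pvalue(
    observed: float,
    null_samples: Sequence[float] | np.ndarray,
    edge: tuple[str, str] = ("", ""),
    smoothed: bool = False,
) -> PermutationResult:
    """p-value as the fraction of null SPORs strictly exceeding observed.

    Ties count as *not* exceeding.  With ``smoothed=True`` the
    (k + 1) / (B + 1) estimator is used instead, which never returns 0.
    """
    null = np.asarray(null_samples, dtype=float)
    if null.size == 0:
        raise ValueError("null_samples must be non-empty")
    k = int((null > observed).sum())
    b = null.size
    p = (k + 1) / (b + 1) if smoothed else k / b
    return PermutationResult(
        edge=tuple(edge),
        observed_spor=float(observed),
        exceed_count=k,
        n_permutations=b,
        p_value=float(p),
    )


def evaluate_edges(
    null: NullDistribution, smoothed: bool = False
) -> list[PermutationResult]:
    """Per-edge permutation results for a computed null distribution."""
    exceed = (null.samples > null.observed).sum(axis=0).astype(int)
    b = null.samples.shape[0]
    results = []
    for k, edge in enumerate(null.edges):
        p = (exceed[k] + 1) / (b + 1) if smoothed else exceed[k] / b
        results.append(
            PermutationResult(
                edge=edge,
                observed_spor=float(null.observed[k]),
                exceed_count=int(exceed[k]),
                n_permutations=b,
                p_value=float(p),
            )
        )
    return results


def classify_edges(
    results: Iterable[PermutationResult],
    high_cut: float = HIGH_CUT,
    low_cut: float = LOW_CUT,
) -> dict[tuple[str, str], str]:
    """Label each edge high (p ≤ high_cut), low (p ≥ low_cut) or neither.

    Both cuts are inclusive.
    """
    labels = {}
    for res in results:
        if res.p_value <= high_cut:
            labels[res.edge] = "high"
        elif res.p_value >= low_cut:
            labels[res.edge] = "low"
        else:
            labels[res.edge] = "neither"
    return labels


def annotate_network(
    network: nx.Graph,
    results: Iterable[PermutationResult],
    labels: Mapping[tuple[str, str], str] | None = None,
) -> nx.Graph:
    """Attach p-values (and labels, if given) to the network's edges in place."""
    for res in results:
        data = network.edges[res.edge]
        data["p_value"] = res.p_value
        data["exceed_count"] = res.exceed_count
        data["n_permutations"] = res.n_permutations
        if labels is not None:
            data["label"] = labels[res.edge]
    return network


# ---------------------------------------------------------------------------
# provider scoring groups


@dataclass(frozen=True)
class ScoringGroupMember:
    provider_id: str
    flagged_edges: int
    degree: int
    flagged_fraction: float
    positive_encounters: int
    total_encounters: int


@dataclass
class ScoringGroupReport:
    """Providers whose flagged-edge share meets the scoring-group rule.

    A provider joins the group for ``direction`` when at least
    ``min_fraction`` of its collaborations carry that label and it has at
    least ``min_flagged`` flagged edges (multiple flagged collaborations,
    not one lucky edge).  The group-level summary is the degree-weighted
    average flagged fraction, i.e. Σ flagged / Σ degree over members.
    """

    direction: str
    min_fraction: float
    min_flagged: int
    members: list[ScoringGroupMember]

    @property
    def weighted_average_fraction(self) -> float:
        total_degree = sum(m.degree for m in self.members)
        if total_degree == 0:
            return float("nan")
        return sum(m.flagged_edges for m in self.members) / total_degree


def scoring_groups(
    network: nx.Graph,
    labels: Mapping[tuple[str, str], str],
    direction: str,
    bipartite: BipartiteNetwork | None = None,
    min_fraction: float = 0.05,
    min_flagged: int = 2,
) -> ScoringGroupReport:
    """Providers concentrated in high- (or low-) scoring collaborations.

    ``direction`` is ``"high"`` or ``"low"``.  "Total collaborative
    interactions" is the provider's degree in the thresholded network.
    Encounter totals and positive-outcome counts come from ``bipartite``
    when supplied (0 otherwise).  A provider can belong to both the high
    and the low group — the two calls are independent.
    """
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    flagged: dict[str, int] = {}
    for (a, b), label in labels.items():
        if label != direction:
            continue
        flagged[a] = flagged.get(a, 0) + 1
        flagged[b] = flagged.get(b, 0) + 1
    members = []
    for pid in sorted(network.nodes):
        degree = network.degree[pid]
        count = flagged.get(pid, 0)
        if degree == 0 or count < min_flagged:
            continue
        fraction = count / degree
        if fraction < min_fraction:
            continue
        total = positive = 0
        if bipartite is not None:
            for eid in bipartite.involvement.get(pid, ()):
                enc = bipartite.encounters[eid]
                if enc.outcome is not None:
                    total += 1
                    positive += enc.outcome
        members.append(
            ScoringGroupMember(
                provider_id=pid,
                flagged_edges=count,
                degree=int(degree),
                flagged_fraction=fraction,
                positive_encounters=positive,
                total_encounters=total,
            )
        )
    return ScoringGroupReport(
        direction=direction,
        min_fraction=min_fraction,
        min_flagged=min_flagged,
        members=members,
    )
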
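"""Collaboration networks weighted by shared risk-adjusted outcomes.

Providers and encounters form a bipartite (affiliation) network: an
involvement edge links provider j to encounter i when j performed at least
one action during i.  Projecting onto providers links every pair that
shares encounters.  Each retained pair (those sharing at least
``min_shared`` encounters) is scored by three quantities over the analysis
encounters — those with a computable risk-adjusted outcome r:

* SEI (shared encounter index), the Jaccard index of the pair's encounter
  sets:  SEI = |A ∩ B| / |A ∪ B|;
* SPOI (shared positive-outcome index), the share of risk-adjusted outcome
  mass concentrated in the shared encounters:
  SPOI = Σ_{A∩B} r / Σ_{A∪B} r;
* SPOR = SPOI / SEI, the concentration of positive outcomes in the shared
  encounters relative to what the pair's sharing frequency alone predicts.

SPOR = 1 is neutral: under exchangeable outcomes E[SPOI] equals SEI
exactly, and a pair that collaborates exclusively (A = B) has SPOR = 1 for
any outcomes whatsoever.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .risk import RiskAdjustedOutcome
from .types import (
    DistributionStats,
    EncounterRecord,
    NetworkSummary,
    ProviderEvent,
    canonical_pair,
)

logger = logging.getLogger(__name__)


@dataclass
class BipartiteNetwork:
    """Provider–encounter affiliation network.

    ``involvement`` maps provider → {encounter → action_count}: at most one
    involvement edge per (provider, encounter), aggregating repeated action
    rows.  ``encounters`` keeps the full encounter records (including those
    with missing outcomes, so the structure stays inspectable).
    """

    involvement: dict[str, dict[str, int]] = field(default_factory=dict)
    encounters: dict[str, EncounterRecord] = field(default_factory=dict)

    @property
    def n_providers(self) -> int:
        return len(self.involvement)

    @property
    def n_encounters(self) -> int:
        return len(self.encounters)

    def to_networkx(self) -> nx.Graph:
        """Bipartite view as a networkx graph (bipartite attribute 0/1).

        Provider and encounter identifiers may collide, so nodes are
        namespaced as ``provider:<id>`` and ``encounter:<id>``.
        """
        graph = nx.Graph()
        for eid, enc in self.encounters.items():
            graph.add_node(f"encounter:{eid}", bipartite=1, outcome=enc.outcome)
        for pid, encs in self.involvement.items():
            graph.add_node(f"provider:{pid}", bipartite=0)
            for eid, count in encs.items():
                graph.add_edge(f"provider:{pid}", f"encounter:{eid}", action_count=count)
        return graph


def build_bipartite(
    events: Iterable[ProviderEvent], encounters: Iterable[EncounterRecord]
) -> BipartiteNetwork:
    """Aggregate validated events into the bipartite affiliation network."""
    enc_map = {e.encounter_id: e for e in encounters}
    involvement: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for ev in events:
        if ev.encounter_id not in enc_map:
            raise ValueError(
                f"event references unknown encounter {ev.encounter_id!r}; "
                "run events through read_events/validation first"
            )
        involvement[ev.provider_id][ev.encounter_id] += 1
    return BipartiteNetwork(
        involvement={p: dict(e) for p, e in involvement.items()},
        encounters=enc_map,
    )


def encounter_sets(
    network: BipartiteNetwork, analysis_encounters: Iterable[str]
) -> dict[str, frozenset[str]]:
    """Per-provider encounter sets A_j restricted to analysis encounters.

    ``analysis_encounters`` is the set of encounter IDs with a computable
    risk-adjusted outcome; restricting both SEI and SPOI to this universe
    keeps the two indices on the same footing (otherwise SPOR would not be
    centred at 1).  Providers whose restricted set is empty are omitted.
    """
    allowed = set(analysis_encounters)
    out: dict[str, frozenset[str]] = {}
    for pid, encs in network.involvement.items():
        restricted = frozenset(e for e in encs if e in allowed)
        if restricted:
            out[pid] = restricted
    return out


def sei(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Shared encounter index: Jaccard index |A∩B| / |A∪B|.

    Pairs with an empty intersection are never scored; passing one is a
    contract violation.
    """
    inter = len(a & b)
    if inter == 0:
        raise ValueError("sei undefined for disjoint encounter sets")
    return inter / len(a | b)


def spoi(
    a: frozenset[str] | set[str],
    b: frozenset[str] | set[str],
    r: Mapping[str, float],
) -> float:
    """Shared positive-outcome index: Σ_{A∩B} r / Σ_{A∪B} r.

    Sums run in sorted encounter order so that identical sets produce
    bit-identical sums (and A = B gives exactly 1.0).
    """
    inter = a & b
    if not inter:
        raise ValueError("spoi undefined for disjoint encounter sets")
    num = sum(r[e] for e in sorted(inter))
    den = sum(r[e] for e in sorted(a | b))
    if den <= 0.0:
        raise ZeroDivisionError("zero risk-adjusted outcome mass over the union")
    return num / den


def spor(sei_val: float, spoi_val: float) -> float:
    """Shared positive outcome ratio SPOR = SPOI / SEI (1 = neutral)."""
    if sei_val <= 0.0:
        raise ValueError("sei must be positive")
    return spoi_val / sei_val


def _r_values(r: Mapping[str, float] | Mapping[str, RiskAdjustedOutcome]) -> dict[str, float]:
    """Accept either plain r floats or RiskAdjustedOutcome records."""
    out: dict[str, float] = {}
    for k, v in r.items():
        out[k] = v.r if isinstance(v, RiskAdjustedOutcome) else float(v)
    return out


def shared_counts(
    sets: Mapping[str, frozenset[str]]
) -> Counter[tuple[str, str]]:
    """Count shared encounters for every co-incident provider pair.

    Uses an inverted encounter → providers index, so only pairs that
    actually share at least one encounter are ever enumerated.
    """
    by_encounter: dict[str, list[str]] = defaultdict(list)
    for pid, encs in sets.items():
        for e in encs:
            by_encounter[e].append(pid)
    counts: Counter[tuple[str, str]] = Counter()
    for providers in by_encounter.values():
        providers.sort()
        for pair in combinations(providers, 2):
            counts[pair] += 1
    return counts


def project(
    bipartite: BipartiteNetwork,
    r: Mapping[str, float] | Mapping[str, RiskAdjustedOutcome],
    min_shared: int = 6,
) -> nx.Graph:
    """Project the affiliation network onto providers at a sharing threshold.

    Returns an undirected graph whose nodes are providers with at least one
    surviving edge and whose edges carry ``shared_count``, ``sei``,
    ``spoi`` and ``spor``.  Pairs sharing fewer than ``min_shared``
    encounters (over the analysis encounters) are excluded; isolated
    providers are dropped from the node set.
    """
    if min_shared < 2:
        raise ValueError("min_shared must be >= 2")
    rv = _r_values(r)
    sets = encounter_sets(bipartite, rv.keys())
    graph = nx.Graph(min_shared=int(min_shared), isolated_providers_dropped=True)
    n_zero_mass = 0
    for (pa, pb), count in shared_counts(sets).items():
        if count < min_shared:
            continue
        a, b = sets[pa], sets[pb]
        try:
            spoi_val = spoi(a, b, rv)
        except ZeroDivisionError:
            n_zero_mass += 1
            continue
        sei_val = sei(a, b)
        graph.add_edge(
            pa,
            pb,
            shared_count=int(count),
            sei=float(sei_val),
            spoi=float(spoi_val),
            spor=float(spor(sei_val, spoi_val)),
        )
    if n_zero_mass:
        logger.warning("dropped %d edge(s) with zero outcome mass over the union", n_zero_mass)
    if graph.number_of_edges() == 0:
        logger.warning("no provider pair shares >= %d encounters; network is empty", min_shared)
    return graph


def summarize(network: nx.Graph) -> NetworkSummary:
    """Descriptive statistics of a collaboration network.

    Diameter and mean shortest-path length are computed on the largest
    connected component; clustering is averaged over all nodes.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot summarise an empty network")
    n = network.number_of_nodes()
    m = network.number_of_edges()
    giant = network.subgraph(max(nx.connected_components(network), key=len))
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        density=float(nx.density(network)),
        mean_degree=2.0 * m / n,
        diameter=int(nx.diameter(giant)) if giant.number_of_nodes() > 1 else 0,
        mean_clustering=float(nx.average_clustering(network)),
        mean_path_length=(
            float(nx.average_shortest_path_length(giant))
            if giant.number_of_nodes() > 1
            else 0.0
        ),
    )


def distribution_stats(network: nx.Graph, threshold: int) -> DistributionStats:
    """SPOR distribution summary for one thresholded network.

    Percentiles use linear interpolation between order statistics.  An
    empty network yields zero counts and NaN statistics.
    """
    spors = np.array([d["spor"] for _, _, d in network.edges(data=True)])
    if spors.size == 0:
        nan = float("nan")
        return DistributionStats(threshold, 0, 0, nan, nan, nan, nan, nan, nan)
    p5, p10, p90, p95 = np.percentile(spors, [5, 10, 90, 95])
    return DistributionStats(
        threshold=threshold,
        n_providers=network.number_of_nodes(),
        n_edges=network.number_of_edges(),
        mean=float(spors.mean()),
        sd=float(spors.std(ddof=1)) if spors.size > 1 else 0.0,
        p5=float(p5),
        p10=float(p10),
        p90=float(p90),
        p95=float(p95),
    )


def threshold_sweep(
    bipartite: BipartiteNetwork,
    r: Mapping[str, float] | Mapping[str, RiskAdjustedOutcome],
    thresholds: Sequence[int] = (2, 4, 6, 8, 10),
) -> list[DistributionStats]:
    """SPOR distribution statistics across a sweep of sharing thresholds.

    Low thresholds admit nascent relationships whose SPOR is volatile (one
    lucky encounter moves the ratio a lot); raising the threshold stabilises
    the distribution.  The sweep is how an operating threshold is chosen.
    """
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if any(t < 2 for t in thresholds):
        raise ValueError("every threshold must be >= 2")
    return [
        distribution_stats(project(bipartite, r, min_shared=t), t)
        for t in thresholds
    ]
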
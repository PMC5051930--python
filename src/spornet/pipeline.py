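"""End-to-end analysis pipeline.

Stages: load or generate tables → fit the logistic risk model →
risk-adjust outcomes → build the bipartite network → threshold-sweep
report → project at the analysis threshold → permutation test →
high/low edge classification → provider scoring groups.  Every run writes
its resolved configuration next to its outputs, and a fixed master seed
reproduces every output byte-identically.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as sio
from . import network as snet
from . import permutation as sperm
from . import risk as srisk
from . import synthetic as ssyn
from .types import canonical_pair

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the cause."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Either ``encounters_path``/``events_path`` point at CSV tables, or
    ``generator`` supplies a synthetic configuration.  The defaults match
    the framework's standard operating settings: sweep thresholds 2–10,
    analysis threshold 6 shared encounters, B = 1,000 permutations, high
    and low cuts at p ≤ 0.05 / p ≥ 0.95, and a 5% scoring-group rule.
    """

    out_dir: str = "spornet-run"
    encounters_path: str | None = None
    events_path: str | None = None
    generator: ssyn.GeneratorConfig | None = None
    covariates: tuple[srisk.CovariateSpec, ...] = (
        srisk.CovariateSpec("acuity", kind="categorical"),
    )
    thresholds: tuple[int, ...] = (2, 4, 6, 8, 10)
    analysis_threshold: int = 6
    n_permutations: int = 1000
    high_cut: float = 0.05
    low_cut: float = 0.95
    min_fraction: float = 0.05
    min_flagged: int = 2
    smoothed_pvalues: bool = False
    seed: int = 0

    def resolved(self) -> dict:
        doc = dataclasses.asdict(self)
        return doc


@dataclass
class PipelineResult:
    config: RunConfig
    out_dir: Path
    n_encounters: int = 0
    n_events: int = 0
    network_edges: int = 0
    network_nodes: int = 0
    n_high: int = 0
    n_low: int = 0
    summary: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _derive_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def _write_edge_results(path: Path, network, results, labels) -> None:
    cols = (
        "provider_a", "provider_b", "shared_count", "sei", "spoi", "spor",
        "exceed_count", "n_permutations", "p_value", "label",
    )
    by_edge = {res.edge: res for res in results}
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for edge in sorted(by_edge):
            data = network.edges[edge]
            res = by_edge[edge]
            w.writerow([
                edge[0], edge[1], data["shared_count"], data["sei"],
                data["spoi"], data["spor"], res.exceed_count,
                res.n_permutations, res.p_value, labels[edge],
            ])


def _write_scoring(path: Path, report: sperm.ScoringGroupReport) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([
            "provider_id", "flagged_edges", "degree", "flagged_fraction",
            "positive_encounters", "total_encounters",
        ])
        for m in report.members:
            w.writerow([
                m.provider_id, m.flagged_edges, m.degree, m.flagged_fraction,
                m.positive_encounters, m.total_encounters,
            ])


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full evaluation pipeline and write the output bundle.

    Outputs in ``config.out_dir``: ``resolved_config.json``,
    ``validation.json``, ``risk_model.json``, ``sweep.csv``,
    ``network.csv``/``network.graphml``, ``edge_results.csv``,
    ``scoring_high.csv``/``scoring_low.csv`` and ``summary.json``.  A
    failing stage leaves an ``INCOMPLETE`` marker naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")
    result = PipelineResult(config=config, out_dir=out)
    gen_seed, perm_seed = _derive_seeds(config.seed, 2)

    try:
        sio.write_json(config.resolved(), out / "resolved_config.json")

        # -- load or generate -----------------------------------------
        @_stage("load")
        def load():
            if config.generator is not None:
                gen = dataclasses.replace(config.generator, seed=gen_seed)
                data = ssyn.generate(gen)
                ssyn.write_tables(data, out / "input")
                return data.encounters, data.events, {"source": "generator"}
            if config.encounters_path is None or config.events_path is None:
                raise ValueError("need either generator or encounters/events paths")
            encounters, enc_rep = sio.read_encounters(config.encounters_path)
            events, ev_rep = sio.read_events(
                config.events_path, (e.encounter_id for e in encounters)
            )
            return encounters, events, {
                "source": "files",
                "encounters": dataclasses.asdict(enc_rep),
                "events": dataclasses.asdict(ev_rep),
            }

        encounters, events, validation = load()
        sio.write_json(validation, out / "validation.json")
        result.n_encounters = len(encounters)
        result.n_events = len(events)
        logger.info("loaded %d encounters, %d events", len(encounters), len(events))

        # -- risk model ------------------------------------------------
        @_stage("risk_model")
        def fit():
            model = srisk.fit_risk_model(encounters, config.covariates)
            model.to_json(out / "risk_model.json")
            return model

        model = fit()

        @_stage("risk_adjust")
        def adjust():
            return srisk.risk_adjusted_outcomes(encounters, model)

        r = adjust()
        logger.info("risk-adjusted %d encounters", len(r))

        # -- networks --------------------------------------------------
        @_stage("bipartite")
        def bip():
            return snet.build_bipartite(events, encounters)

        bipartite = bip()

        @_stage("threshold_sweep")
        def sweep():
            stats = snet.threshold_sweep(bipartite, r, config.thresholds)
            sio.write_sweep(stats, out / "sweep.csv")
            return stats

        sweep()

        @_stage("project")
        def proj():
            return snet.project(bipartite, r, min_shared=config.analysis_threshold)

        network = proj()
        result.network_nodes = network.number_of_nodes()
        result.network_edges = network.number_of_edges()
        logger.info(
            "collaboration network at threshold %d: %d providers, %d edges",
            config.analysis_threshold, result.network_nodes, result.network_edges,
        )

        if network.number_of_edges() == 0:
            logger.warning("empty collaboration network; skipping permutation stage")
            sio.write_network(network, out / "network.csv", format="csv")
            sio.write_json(
                {"network": None, "note": "empty network at analysis threshold"},
                out / "summary.json",
            )
            marker.unlink()
            return result

        # -- permutation test ------------------------------------------
        @_stage("permutation")
        def permute():
            null = sperm.null_distribution(
                bipartite, r,
                min_shared=config.analysis_threshold,
                n_permutations=config.n_permutations,
                seed=perm_seed,
                network=network,
            )
            results = sperm.evaluate_edges(null, smoothed=config.smoothed_pvalues)
            labels = sperm.classify_edges(results, config.high_cut, config.low_cut)
            sperm.annotate_network(network, results, labels)
            return results, labels

        results, labels = permute()
        result.n_high = sum(1 for v in labels.values() if v == "high")
        result.n_low = sum(1 for v in labels.values() if v == "low")
        logger.info("flagged %d high and %d low edges", result.n_high, result.n_low)

        # -- reports ---------------------------------------------------
        @_stage("report")
        def report():
            sio.write_network(network, out / "network.csv", format="csv")
            sio.write_network(network, out / "network.graphml", format="graphml")
            _write_edge_results(out / "edge_results.csv", network, results, labels)
            groups = {}
            for direction in ("high", "low"):
                grp = sperm.scoring_groups(
                    network, labels, direction, bipartite,
                    min_fraction=config.min_fraction,
                    min_flagged=config.min_flagged,
                )
                _write_scoring(out / f"scoring_{direction}.csv", grp)
                groups[direction] = grp
            summary = snet.summarize(network)
            doc = {
                "network": dataclasses.asdict(summary),
                "n_high": result.n_high,
                "n_low": result.n_low,
                "high_fraction": result.n_high / result.network_edges,
                "low_fraction": result.n_low / result.network_edges,
                "scoring_groups": {
                    d: {
                        "n_members": len(g.members),
                        "weighted_average_fraction": g.weighted_average_fraction,
                    }
                    for d, g in groups.items()
                },
            }
            sio.write_json(doc, out / "summary.json")
            return doc

        result.summary = report()
        marker.unlink()
        return result
    except PipelineError as exc:
        marker.write_text(f"{exc}\n")
        raise
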
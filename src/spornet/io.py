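"""Flat-file input/output: encounter and event tables, network export.

Tables are RFC-4180 CSV with a header row (UTF-8).  Column names are
configurable through a schema mapping because EHR export schemas vary;
the defaults expect ``encounter_id``/``outcome`` (+ covariate columns) for
encounters and ``provider_id``/``encounter_id``/``activity_category``/
``action_type`` for events.  Networks are written as an edge CSV (bit-exact
round trip) or GraphML.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .types import (
    CollaborationEdge,
    DistributionStats,
    EncounterRecord,
    EncounterValidation,
    EventValidation,
    ProviderEvent,
    canonical_pair,
)

#: strings treated as missing values (case-insensitive, after stripping)
NA_TOKENS = frozenset({"", "na", "n/a", "nan", "null", "none", "."})

EDGE_COLUMNS = (
    "provider_a",
    "provider_b",
    "shared_count",
    "sei",
    "spoi",
    "spor",
    "p_value",
)


def _is_na(value: str) -> bool:
    return value.strip().lower() in NA_TOKENS


def _parse_covariate(value: str) -> Any:
    """Parse a covariate cell: numeric if possible, else the stripped string."""
    s = value.strip()
    if _is_na(s):
        return None
    try:
        x = float(s)
    except ValueError:
        return s
    return int(x) if x.is_integer() else x


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_encounters(
    path: str | Path,
    schema: Mapping[str, Any] | None = None,
) -> tuple[list[EncounterRecord], EncounterValidation]:
    """Read and validate an encounter table.

    Parameters
    ----------
    path
        CSV file with one row per encounter.
    schema
        Optional mapping with keys ``encounter_id`` and ``outcome`` giving
        the actual column names, and ``covariates`` mapping covariate names
        to columns.  When ``covariates`` is absent, every remaining column
        is taken as a covariate under its own name.

    Returns
    -------
    (records, report)
        Validated records and a :class:`EncounterValidation` accounting for
        every dropped or flagged row.  Rows without an encounter ID or with
        an outcome that is neither 0, 1 nor a missing-value token are
        dropped and counted.  A duplicated encounter ID is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = dict(schema or {})
    id_col = schema.get("encounter_id", "encounter_id")
    outcome_col = schema.get("outcome", "outcome")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, [id_col, outcome_col], path)
    cov_map: dict[str, str] = schema.get("covariates") or {
        c: c for c in df.columns if c not in (id_col, outcome_col)
    }
    _require_columns(df, cov_map.values(), path)

    report = EncounterValidation(n_rows=len(df))
    records: list[EncounterRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        eid = str(row_d[id_col]).strip()
        if _is_na(eid):
            report.dropped_missing_id += 1
            continue
        if eid in seen:
            raise ValueError(f"{path}: duplicate encounter_id {eid!r}")
        raw = str(row_d[outcome_col]).strip()
        outcome: int | None
        if _is_na(raw):
            outcome = None
            report.missing_outcome += 1
        else:
            try:
                val = float(raw)
            except ValueError:
                report.dropped_bad_outcome += 1
                continue
            if val not in (0.0, 1.0):
                report.dropped_bad_outcome += 1
                continue
            outcome = int(val)
        covariates = {name: _parse_covariate(str(row_d[col])) for name, col in cov_map.items()}
        if any(v is None for v in covariates.values()):
            report.missing_covariates += 1
        seen.add(eid)
        records.append(EncounterRecord(eid, outcome, covariates))
        report.n_kept += 1
    return records, report


def read_events(
    path: str | Path,
    known_encounters: Iterable[str],
    schema: Mapping[str, str] | None = None,
) -> tuple[list[ProviderEvent], EventValidation]:
    """Read a provider-event table, dropping events on unknown encounters.

    Repeated (provider, encounter, activity, action) rows are retained:
    each row is one action instance.  An empty table is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = dict(schema or {})
    pid_col = schema.get("provider_id", "provider_id")
    eid_col = schema.get("encounter_id", "encounter_id")
    act_col = schema.get("activity_category", "activity_category")
    typ_col = schema.get("action_type", "action_type")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, [pid_col, eid_col], path)
    if len(df) == 0:
        raise ValueError(f"{path}: event table is empty")
    known = set(known_encounters)

    report = EventValidation(n_rows=len(df))
    activity: Counter[str] = Counter()
    action: Counter[str] = Counter()
    events: list[ProviderEvent] = []
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        pid = str(row_d[pid_col]).strip()
        eid = str(row_d[eid_col]).strip()
        if _is_na(pid) or _is_na(eid):
            report.dropped_missing_field += 1
            continue
        if eid not in known:
            report.dropped_unknown_encounter += 1
            continue
        cat = str(row_d.get(act_col, "")).strip()
        typ = str(row_d.get(typ_col, "")).strip()
        activity[cat] += 1
        action[typ] += 1
        events.append(ProviderEvent(pid, eid, cat, typ))
        report.n_kept += 1
    report.activity_counts = dict(activity)
    report.action_counts = dict(action)
    return events, report


# ---------------------------------------------------------------------------
# network export / import


def _fmt(value: Any) -> str:
    if value is None:
        return ""
    return str(value)


def write_network(
    network: nx.Graph, path: str | Path, format: str = "csv"
) -> None:
    """Write a collaboration network to disk.

    ``format="csv"`` writes one edge per row (canonically ordered pairs,
    sorted) with columns ``provider_a, provider_b, shared_count, sei, spoi,
    spor, p_value``; floats are written with ``str()`` so the CSV round
    trip is bit-exact.  ``format="graphml"`` writes GraphML with node and
    edge attributes (``None`` attributes are omitted — GraphML has no null).
    """
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(EDGE_COLUMNS)
            rows = []
            for u, v, data in network.edges(data=True):
                a, b = canonical_pair(u, v)
                rows.append(
                    (
                        a,
                        b,
                        _fmt(data.get("shared_count")),
                        _fmt(data.get("sei")),
                        _fmt(data.get("spoi")),
                        _fmt(data.get("spor")),
                        _fmt(data.get("p_value")),
                    )
                )
            writer.writerows(sorted(rows))
    elif format == "graphml":
        clean = nx.Graph(**{k: v for k, v in network.graph.items() if v is not None})
        for n, data in network.nodes(data=True):
            clean.add_node(n, **{k: v for k, v in data.items() if v is not None})
        for u, v, data in network.edges(data=True):
            clean.add_edge(u, v, **{k: v for k, v in data.items() if v is not None})
        nx.write_graphml(clean, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_csv(path: str | Path) -> nx.Graph:
    """Read an edge CSV written by :func:`write_network` back into a graph."""
    graph = nx.Graph()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            p_raw = row.get("p_value", "")
            graph.add_edge(
                row["provider_a"],
                row["provider_b"],
                shared_count=int(row["shared_count"]),
                sei=float(row["sei"]),
                spoi=float(row["spoi"]),
                spor=float(row["spor"]),
                p_value=float(p_raw) if p_raw != "" else None,
            )
    return graph


def edges_from_network(network: nx.Graph) -> list[CollaborationEdge]:
    """Materialise a network's edges as :class:`CollaborationEdge` records."""
    out = [
        CollaborationEdge(
            u,
            v,
            shared_count=data["shared_count"],
            sei=data["sei"],
            spoi=data["spoi"],
            spor=data["spor"],
            p_value=data.get("p_value"),
        )
        for u, v, data in network.edges(data=True)
    ]
    return sorted(out, key=lambda e: e.pair)


def write_sweep(stats: Sequence[DistributionStats], path: str | Path) -> None:
    """Write a threshold-sweep report (one row per threshold)."""
    cols = ("threshold", "n_providers", "n_edges", "mean", "sd", "p5", "p10", "p90", "p95")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for s in stats:
            writer.writerow([_fmt(getattr(s, c)) for c in cols])


def write_json(obj: Any, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
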
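"""Ingestion, normalization, network export and pipeline configuration.

Abundance tables arrive as TSV/CSV (optionally gzipped) with samples in
rows or taxa in rows; counts are normalized to per-sample relative
abundances.  Learned networks are exported to GraphML (full attributes:
direction, sign, confidence, node statistics), SIF (adjacency only, for
Cytoscape import) or a flat TSV edge list.  Every report embeds the
resolved configuration hash and seed so that runs can be audited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .graph_core import EdgeAnnotation, PartiallyDirectedGraph
from .pc_stable import DataError, DataTable

logger = logging.getLogger(__name__)

_TAXON_MARKERS = ("__", ";", "|", "bacteria", "archaea", "k__", "unclassified")

EXPORT_FORMATS = ("graphml", "sif", "tsv")


@dataclass
class PipelineConfig:
    """Resolved knobs for a full pipeline run.

    alpha — significance level of the conditional-independence tests;
    bootstrap_B — replicates for edge confidence and effect p-values;
    permutation_N — rounds of the network-significance permutation test;
    effect_summary — how CPDAG parent-set ambiguity is summarized;
    sensitivity_step — percent of samples perturbed per scan increment.
    """

    alpha: float = 0.05
    bootstrap_B: int = 200
    permutation_N: int = 1000
    effect_summary: str = "min_abs"
    sensitivity_step: float = 1.0
    max_cond_size: Optional[int] = None
    seed: int = 0
    input_path: Optional[str] = None
    output_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.bootstrap_B < 2 or self.permutation_N < 10:
            raise ValueError("bootstrap_B >= 2 and permutation_N >= 10 required")
        if self.sensitivity_step <= 0:
            raise ValueError("sensitivity_step must be positive")
        if self.effect_summary not in ("min_abs", "mean"):
            raise ValueError("effect_summary must be 'min_abs' or 'mean'")
        logger.info("resolved config: %s (hash %s)", self.as_dict(), self.hash())

    def as_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: "str | Path") -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def _looks_like_taxa(labels) -> bool:
    hits = sum(
        any(marker in str(lbl).lower() for marker in _TAXON_MARKERS) for lbl in labels
    )
    return hits >= max(1, len(labels) // 2)


def read_abundance_table(
    path: "str | Path", orientation: str = "auto"
) -> DataTable:
    """Read a TSV/CSV abundance matrix into a samples x taxa table.

    ``orientation`` is ``samples_in_rows``, ``taxa_in_rows`` or ``auto``.
    Auto-detection looks for taxonomy-style markers (";", "__", ...) in the
    headers and falls back to treating the longer axis as samples.  Gzip is
    handled transparently by the file suffix.
    """
    if orientation not in ("auto", "samples_in_rows", "taxa_in_rows"):
        raise DataError(f"unknown orientation {orientation!r}")
    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    sep = "," if stem.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise DataError(f"empty table: {path}")

    if orientation == "auto":
        if _looks_like_taxa(df.index) and not _looks_like_taxa(df.columns):
            orientation = "taxa_in_rows"
        elif _looks_like_taxa(df.columns) and not _looks_like_taxa(df.index):
            orientation = "samples_in_rows"
        else:
            orientation = (
                "samples_in_rows" if df.shape[0] >= df.shape[1] else "taxa_in_rows"
            )
        logger.info("orientation auto-detected as %s for %s", orientation, path.name)
    if orientation == "taxa_in_rows":
        df = df.T

    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = [
            (str(r), str(c))
            for r, c in zip(*np.where(numeric.isna().to_numpy()))
        ]
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataError(
            f"non-numeric cell at sample {df.index[r]!r}, taxon {df.columns[c]!r} "
            f"({len(bad)} offending cells in total)"
        )
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise DataError(f"duplicate taxa names: {dup}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise DataError(f"duplicate sample ids: {dup}")
    return DataTable.from_dataframe(numeric)


def to_relative_abundance(counts: DataTable) -> DataTable:
    """Normalize each sample (row) by its total so that rows sum to 1.

    Input already normalized (every row sum within 1e-8 of 1) passes
    through unchanged with an info log; negative entries or an all-zero
    sample are errors.
    """
    values = counts.values
    if (values < 0).any():
        raise DataError("negative entries are not valid abundances")
    sums = values.sum(axis=1)
    zero = np.where(sums == 0)[0]
    if zero.size:
        raise DataError(f"sample {counts.sample_ids[zero[0]]!r} has zero total count")
    if np.allclose(sums, 1.0, atol=1e-8):
        logger.info("table already row-normalized; returning unchanged")
        return DataTable(
            values.copy(), list(counts.variable_names), list(counts.sample_ids)
        )
    return DataTable(
        values / sums[:, None], list(counts.variable_names), list(counts.sample_ids)
    )


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def _edge_records(g: PartiallyDirectedGraph):
    ann = g.annotations
    for a, b in sorted(g.directed_edges):
        e = ann.get(frozenset((a, b)), EdgeAnnotation())
        yield a, b, "directed", e.sign, e.confidence
    for pair in sorted(g.undirected_edges, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        e = ann.get(pair, EdgeAnnotation())
        yield a, b, "undirected", e.sign, e.confidence


def export_network(
    g: PartiallyDirectedGraph,
    path: "str | Path",
    fmt: Optional[str] = None,
    node_stats: Optional[Dict[str, Dict]] = None,
    config_hash: str = "",
    seed: Optional[int] = None,
) -> Path:
    """Write a network to GraphML, SIF or a TSV edge list.

    GraphML carries every attribute (edge direction / sign / confidence,
    per-node statistics such as mean abundance, influence and phylum) and
    round-trips losslessly through :func:`import_network`.  SIF carries
    adjacency only; TSV carries the flat edge list.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt not in EXPORT_FORMATS:
        raise DataError(
            f"unknown format {fmt!r}; supported formats: {', '.join(EXPORT_FORMATS)}"
        )
    node_stats = node_stats or {}

    if fmt == "graphml":
        gx = nx.DiGraph()
        gx.graph["node_order"] = "|".join(g.nodes)
        gx.graph["config_hash"] = config_hash
        gx.graph["seed"] = -1 if seed is None else int(seed)
        for v in g.nodes:
            attrs = {k: val for k, val in node_stats.get(v, {}).items()}
            gx.add_node(v, **attrs)
        for a, b, direction, sign, conf in _edge_records(g):
            gx.add_edge(a, b, direction=direction, sign=sign, confidence=conf)
        nx.write_graphml(gx, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for a, b, direction, _, _ in _edge_records(g):
                rel = "causes" if direction == "directed" else "assoc"
                fh.write(f"{a}\t{rel}\t{b}\n")
    else:  # tsv
        with open(path, "w") as fh:
            fh.write(f"# config_hash={config_hash} seed={seed}\n")
            fh.write("source\ttarget\tdirection\tsign\tconfidence\n")
            for a, b, direction, sign, conf in _edge_records(g):
                fh.write(f"{a}\t{b}\t{direction}\t{sign}\t{conf}\n")
    return path


def import_network(path: "str | Path") -> Tuple[PartiallyDirectedGraph, Dict[str, Dict]]:
    """Read back a GraphML file written by :func:`export_network`."""
    gx = nx.read_graphml(Path(path))
    order = gx.graph.get("node_order", "")
    nodes = order.split("|") if order else list(gx.nodes)
    directed, undirected, ann = [], [], {}
    for a, b, attrs in gx.edges(data=True):
        pair = frozenset((a, b))
        ann[pair] = EdgeAnnotation(
            sign=int(attrs.get("sign", 0)),
            confidence=float(attrs.get("confidence", 1.0)),
        )
        if attrs.get("direction", "directed") == "directed":
            directed.append((a, b))
        else:
            undirected.append(pair)
    node_stats = {v: dict(gx.nodes[v]) for v in gx.nodes}
    return (
        PartiallyDirectedGraph(nodes, directed, undirected, ann),
        node_stats,
    )


def write_table(frame: pd.DataFrame, path: "str | Path", config_hash: str = "", seed: Optional[int] = None) -> Path:
    """TSV report writer that stamps the config hash and seed as a comment."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        frame.to_csv(fh, sep="\t", index=False)
    return path
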
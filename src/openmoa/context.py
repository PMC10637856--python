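"""Context-specific restriction of the reference network by expression.

A generic reference network covers every curated interaction; in a given
cell line only the expressed genes can participate. This module removes
gene nodes whose abundance (TPM) falls strictly below a threshold in *any*
of the supplied expression datasets - a gene must clear the bar in every
dataset to stay. Drug nodes are not genes and always survive. Genes absent
from a dataset are treated as unexpressed (TPM 0) in that dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .ingest import ReferenceNetwork, SchemaError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionTable:
    """Gene -> TPM map for one expression dataset."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.values.items() if not v >= 0.0}
        if bad:
            raise ValueError(f"negative or non-numeric TPM value(s): {bad}")

    def tpm(self, gene_id: str) -> float:
        """TPM for a gene; absence means unmeasured, treated as 0."""
        return self.values.get(gene_id, 0.0)

    def __len__(self) -> int:
        return len(self.values)


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a ``gene<TAB>tpm`` table (header required)."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    missing = [c for c in ("gene", "tpm") if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: expression table is missing column(s) {', '.join(missing)}")
    values: dict[str, float] = {}
    for row in frame.itertuples(index=False):
        values[str(row.gene)] = float(row.tpm)
    return ExpressionTable(values)


def filter_by_expression(
    network: ReferenceNetwork,
    tables: Iterable[ExpressionTable | Mapping[str, float]],
    tpm_threshold: float = 1.0,
) -> ReferenceNetwork:
    """Remove low-expression gene nodes and all their incident edges.

    A gene node is removed iff in any table its TPM is strictly below
    ``tpm_threshold`` (absence counts as 0). The comparison is strict, so a
    gene at exactly the threshold is kept. Drug nodes always survive. The
    TF set is implicitly intersected with the surviving nodes, and PPI
    symmetry is preserved because both directions share the same endpoints.

    Raises
    ------
    ValueError
        If no table is given, any table is empty (it would delete every
        gene), or the threshold is not positive.
    """
    if not tpm_threshold > 0:
        raise ValueError(f"tpm_threshold must be positive, got {tpm_threshold}")
    tables = [t if isinstance(t, ExpressionTable) else ExpressionTable(dict(t)) for t in tables]
    if not tables:
        raise ValueError("at least one expression table is required")
    for i, table in enumerate(tables):
        if len(table) == 0:
            raise ValueError(f"expression table {i} is empty; it would remove every gene")

    keep: set[str] = set()
    for node in network.nodes():
        if network.node_kind(node) == "drug":
            keep.add(node)
        elif all(t.tpm(node) >= tpm_threshold for t in tables):
            keep.add(node)

    filtered = ReferenceNetwork()
    for node in network.nodes():
        if node in keep:
            data = network.graph.nodes[node]
            filtered.add_node(node, kind=data["kind"], is_tf=data["is_tf"])
    for u, v, k in network.edges():
        if u in keep and v in keep:
            filtered.add_edge(u, v, k)
    logger.info(
        "context filter (TPM >= %g in all %d datasets): %d -> %d nodes, %d -> %d edges",
        tpm_threshold,
        len(tables),
        network.number_of_nodes(),
        filtered.number_of_nodes(),
        network.number_of_edges(),
        filtered.number_of_edges(),
    )
    return filtered
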
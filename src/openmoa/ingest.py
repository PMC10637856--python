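"""Ingestion of typed interaction tables into a directed reference network.

The reference network merges three interaction sources into one directed
multigraph over a shared identifier space:

* drug -> target-gene edges (directed, as curated),
* protein-protein interactions (undirected evidence, stored as a pair of
  directed edges),
* transcription-factor -> gene regulatory links (directed).

PPI rows carry STRING-style integer evidence channels (``combined_score``,
``experimental``, ``experimental_transferred``) and are filtered before the
network is assembled: only interactions whose combined score strictly
exceeds a threshold (default 700) and which have direct or
homology-transferred experimental evidence are retained.

Parallel edges of *different* types between the same ordered node pair are
deliberately kept distinct: the mechanism-path search must be able to tell a
regulatory edge from a PPI edge joining the same two proteins, because only
the former may terminate a path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

DRUG_TARGET = "drug_target"
PPI = "ppi"
REGULATORY = "regulatory"
EDGE_TYPES = (DRUG_TARGET, PPI, REGULATORY)

#: Required header columns for each source-table kind.
TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    DRUG_TARGET: ("drug", "gene"),
    REGULATORY: ("tf", "gene"),
    PPI: (
        "protein1",
        "protein2",
        "combined_score",
        "experimental",
        "experimental_transferred",
    ),
}


class SchemaError(ValueError):
    """An input table does not match its documented header schema."""


@dataclass(frozen=True)
class InteractionRecord:
    """One typed, possibly scored edge read from a source table.

    Score fields are populated for PPI records only; drug-target and
    regulatory records carry ``None`` in all three.
    """

    source_id: str
    target_id: str
    edge_type: str
    combined_score: int | None = None
    experimental_score: int | None = None
    experimental_transferred_score: int | None = None


def read_interaction_table(path: str | Path, source_kind: str) -> list[InteractionRecord]:
    """Read one interaction source table into records.

    Parameters
    ----------
    path
        Tab-separated file with a header row matching the schema for
        ``source_kind`` (see :data:`TABLE_SCHEMAS`).
    source_kind
        One of ``"drug_target"``, ``"ppi"``, ``"regulatory"``.

    Returns
    -------
    list of InteractionRecord
        One record per well-formed data row. Self-loop rows and rows with
        missing or unparseable mandatory fields are dropped with a logged
        count.

    Raises
    ------
    SchemaError
        If the header is missing a mandatory column.
    """
    if source_kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown source kind {source_kind!r}; expected one of {EDGE_TYPES}")
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty %s table, no interactions read", path, source_kind)
        return []
    missing = [c for c in TABLE_SCHEMAS[source_kind] if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: {source_kind} table is missing column(s) {', '.join(missing)}"
        )

    id_cols = TABLE_SCHEMAS[source_kind][:2]
    records: list[InteractionRecord] = []
    n_self = 0
    n_bad = 0
    for _, row in frame.iterrows():
        src, tgt = row[id_cols[0]], row[id_cols[1]]
        if pd.isna(src) or pd.isna(tgt) or not str(src).strip() or not str(tgt).strip():
            n_bad += 1
            continue
        src, tgt = str(src).strip(), str(tgt).strip()
        if src == tgt:
            n_self += 1
            continue
        if source_kind == PPI:
            try:
                scores = {
                    "combined_score": int(row["combined_score"]),
                    "experimental_score": int(row["experimental"]),
                    "experimental_transferred_score": int(row["experimental_transferred"]),
                }
            except (TypeError, ValueError):
                n_bad += 1
                continue
            records.append(InteractionRecord(src, tgt, PPI, **scores))
        else:
            records.append(InteractionRecord(src, tgt, source_kind))
    if n_self:
        logger.info("%s: dropped %d self-loop row(s)", path, n_self)
    if n_bad:
        logger.warning("%s: dropped %d row(s) with missing/invalid mandatory fields", path, n_bad)
    logger.info("%s: read %d %s record(s)", path, len(records), source_kind)
    return records


def filter_ppi_records(
    records: Sequence[InteractionRecord],
    min_combined: int = 700,
    require_experimental: bool = True,
) -> list[InteractionRecord]:
    """Keep high-confidence PPI records with experimental support.

    A record survives iff ``combined_score > min_combined`` (strict) and,
    when ``require_experimental`` is set, at least one of the experimental
    or experimental-transferred channels is positive. Input order is
    preserved; the operation is idempotent.
    """
    kept: list[InteractionRecord] = []
    for rec in records:
        if rec.edge_type != PPI:
            raise ValueError(f"filter_ppi_records got a {rec.edge_type!r} record")
        if (
            rec.combined_score is None
            or rec.experimental_score is None
            or rec.experimental_transferred_score is None
        ):
            raise ValueError(
                f"PPI record {rec.source_id}->{rec.target_id} lacks a score column"
            )
        if rec.combined_score <= min_combined:
            continue
        if require_experimental and not (
            rec.experimental_score > 0 or rec.experimental_transferred_score > 0
        ):
            continue
        kept.append(rec)
    return kept


class ReferenceNetwork:
    """Directed typed multigraph of drug and gene nodes.

    Nodes carry ``kind`` (``"drug"`` or ``"gene"``) and an ``is_tf`` flag.
    Edges are keyed by their type, so at most one edge of each type exists
    per ordered node pair while parallel edges of different types coexist.
    """

    def __init__(self) -> None:
        self.graph = nx.MultiDiGraph()

    # -- construction ---------------------------------------------------

    def add_node(self, node_id: str, kind: str = "gene", is_tf: bool = False) -> None:
        if node_id in self.graph:
            prev = self.graph.nodes[node_id]
            if prev["kind"] != kind:
                raise ValueError(
                    f"node {node_id!r} registered as both {prev['kind']!r} and {kind!r}"
                )
            prev["is_tf"] = prev["is_tf"] or is_tf
        else:
            self.graph.add_node(node_id, kind=kind, is_tf=is_tf)

    def add_edge(self, source_id: str, target_id: str, edge_type: str) -> None:
        if edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {edge_type!r}")
        for nid in (source_id, target_id):
            if nid not in self.graph:
                self.add_node(nid)
        # the edge type is the multigraph key, so re-insertion deduplicates
        self.graph.add_edge(source_id, target_id, key=edge_type)

    # -- queries --------------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.graph

    @property
    def tf_set(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("is_tf")}

    def node_kind(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["kind"]

    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, str]]:
        """All directed edges as (source, target, edge_type) triples."""
        return [(u, v, k) for u, v, k in self.graph.edges(keys=True)]

    def has_edge(self, source_id: str, target_id: str, edge_type: str) -> bool:
        return self.graph.has_edge(source_id, target_id, edge_type)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceNetwork):
            return NotImplemented
        return dict(self.graph.nodes(data=True)) == dict(other.graph.nodes(data=True)) and set(
            self.edges()
        ) == set(other.edges())

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"ReferenceNetwork({self.number_of_nodes()} nodes, "
            f"{self.number_of_edges()} edges, {len(self.tf_set)} TFs)"
        )

    # -- serialization --------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the merged typed edge list (source, target, edge_type)."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("source\ttarget\tedge_type\n")
            for u, v, k in sorted(self.edges()):
                fh.write(f"{u}\t{v}\t{k}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceNetwork":
        """Rebuild a network from a typed edge list written by :meth:`to_tsv`.

        Node kinds and the TF flag are recovered from edge roles: a node is
        a drug iff it sources a drug-target edge, and a TF iff it sources a
        regulatory edge.
        """
        frame = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in ("source", "target", "edge_type") if c not in frame.columns]
        if missing:
            raise SchemaError(f"{path}: edge list is missing column(s) {', '.join(missing)}")
        net = cls()
        drugs = set(frame.loc[frame["edge_type"] == DRUG_TARGET, "source"])
        tfs = set(frame.loc[frame["edge_type"] == REGULATORY, "source"])
        for d in sorted(drugs):
            net.add_node(d, kind="drug")
        for t in sorted(tfs):
            net.add_node(t, kind="gene", is_tf=True)
        for row in frame.itertuples(index=False):
            net.add_edge(row.source, row.target, row.edge_type)
        return net


def build_reference_network(
    drug_records: Iterable[InteractionRecord],
    ppi_records: Iterable[InteractionRecord],
    regulatory_records: Iterable[InteractionRecord],
) -> ReferenceNetwork:
    """Merge source-filtered records into one directed reference network.

    Drug-target and regulatory edges keep their curated direction; every
    PPI record is inserted in both directions. Duplicate (source, target,
    type) triples collapse. The TF set is the set of regulatory-edge
    sources; a node is a drug iff it sources a drug-target edge.

    Raises
    ------
    ValueError
        If one identifier is used both as a drug and as a TF (regulatory
        source) - a namespace collision rather than a biological statement.
    """
    drug_records = list(drug_records)
    ppi_records = list(ppi_records)
    regulatory_records = list(regulatory_records)
    for recs, kind in (
        (drug_records, DRUG_TARGET),
        (ppi_records, PPI),
        (regulatory_records, REGULATORY),
    ):
        for rec in recs:
            if rec.edge_type != kind:
                raise ValueError(
                    f"expected only {kind!r} records, got {rec.edge_type!r} "
                    f"({rec.source_id}->{rec.target_id})"
                )

    drug_ids = {r.source_id for r in drug_records}
    tf_ids = {r.source_id for r in regulatory_records}
    clash = drug_ids & tf_ids
    if clash:
        raise ValueError(
            "identifier(s) appear both as drug and as regulatory source: "
            + ", ".join(sorted(clash))
        )

    net = ReferenceNetwork()
    for d in sorted(drug_ids):
        net.add_node(d, kind="drug")
    for t in sorted(tf_ids):
        net.add_node(t, kind="gene", is_tf=True)
    for rec in drug_records:
        net.add_edge(rec.source_id, rec.target_id, DRUG_TARGET)
    for rec in ppi_records:
        net.add_edge(rec.source_id, rec.target_id, PPI)
        net.add_edge(rec.target_id, rec.source_id, PPI)
    for rec in regulatory_records:
        net.add_edge(rec.source_id, rec.target_id, REGULATORY)
    logger.info(
        "reference network: %d nodes, %d edges (%d drugs, %d TFs)",
        net.number_of_nodes(),
        net.number_of_edges(),
        len(drug_ids),
        len(tf_ids),
    )
    return net
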
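"""Centric-subnetwork extraction and best mechanism-path queries.

Once every edge carries a confidence score, two summaries matter to a
practitioner: the *centric subnetwork* - the subgraph induced by the top
fraction (default 1%) of positively scored edges, with ties at the cutoff
kept - and the single most probable step-by-step mechanism path between the
starting node and a chosen endpoint. The path aggregate is the product of
edge confidences (a sum of logs), consistent with treating edges as
independent events; ties are broken lexicographically on the node sequence
for reproducibility.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .ingest import ReferenceNetwork
from .pathweight import (
    Edge,
    WeightedEdge,
    constrained_shortest_paths,
)

logger = logging.getLogger(__name__)


@dataclass
class CentricSubnetwork:
    """Top-confidence edges, the percentile cutoff, and the fraction used."""

    edges: list[WeightedEdge]
    cutoff_confidence: float
    fraction: float


def extract_centric_subnetwork(
    weighted: Sequence[WeightedEdge], fraction: float = 0.01
) -> CentricSubnetwork:
    """Extract all edges in the top ``fraction`` of positive confidences.

    Only edges with confidence > 0 are eligible. The cutoff is the
    confidence at rank ``ceil(fraction * n_eligible)`` of the descending
    sort; every edge at or above the cutoff is included, so boundary ties
    can push the output past the nominal count. Output is independent of
    input order.

    Raises
    ------
    ValueError
        If no weighted edges are given or none has positive confidence.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not weighted:
        raise ValueError("no weighted edges to extract from")
    eligible = [w for w in weighted if w.confidence > 0.0]
    if not eligible:
        raise ValueError("no edges with positive confidence; nothing to extract")
    ranked = sorted(eligible, key=lambda w: (-w.confidence, w.key))
    rank = math.ceil(fraction * len(eligible))
    cutoff = ranked[rank - 1].confidence
    kept = [w for w in ranked if w.confidence >= cutoff]
    logger.info(
        "centric subnetwork: fraction %g of %d scored edges -> cutoff %.6g, %d edge(s)",
        fraction,
        len(eligible),
        cutoff,
        len(kept),
    )
    return CentricSubnetwork(kept, cutoff, fraction)


@dataclass
class MoaPath:
    """An ordered mechanism path with its aggregate confidence."""

    edges: list[WeightedEdge]

    @property
    def length(self) -> int:
        return len(self.edges)

    @property
    def node_sequence(self) -> list[str]:
        return [self.edges[0].source_id, *(e.target_id for e in self.edges)]

    @property
    def log10_path_confidence(self) -> float:
        total = 0.0
        for e in self.edges:
            if e.confidence <= 0.0:
                return -math.inf
            total += math.log10(e.confidence)
        return total

    def to_dict(self) -> dict:
        log_conf = self.log10_path_confidence
        return {
            "nodes": self.node_sequence,
            "edges": [
                {
                    "source": e.source_id,
                    "target": e.target_id,
                    "edge_type": e.edge_type,
                    "confidence": e.confidence,
                    "log10_pscore": e.log10_pscore,
                }
                for e in self.edges
            ],
            "length": self.length,
            "log10_path_confidence": log_conf,
            "path_confidence": 0.0 if math.isinf(log_conf) else 10.0**log_conf,
        }


def best_moa_path(
    network: ReferenceNetwork,
    weighted: Sequence[WeightedEdge],
    start_id: str,
    endpoint_id: str,
    max_len: int = 8,
) -> MoaPath | None:
    """Most confident constrained shortest path between two nodes.

    Among all constrained shortest paths (identical semantics to the
    scoring engine) the path maximizing the sum of log10 edge confidences
    is returned; an edge with confidence 0 contributes -inf, ranking its
    path below any fully scored one. Equal-score ties resolve to the
    lexicographically smallest node sequence (then edge-type sequence).
    Returns ``None`` with a logged explanation when no admissible path
    exists.
    """
    lut: dict[Edge, WeightedEdge] = {w.key: w for w in weighted}
    action = constrained_shortest_paths(network, start_id, endpoint_id, max_len=max_len)
    if action is None:
        logger.info(
            "no constrained path from %s to %s within %d edges", start_id, endpoint_id, max_len
        )
        return None

    def edge_conf(e: Edge) -> float:
        w = lut.get(e)
        return w.confidence if w is not None else 0.0

    def path_score(path: tuple[Edge, ...]) -> float:
        total = 0.0
        for e in path:
            c = edge_conf(e)
            if c <= 0.0:
                return -math.inf
            total += math.log10(c)
        return total

    def sort_key(path: tuple[Edge, ...]):
        nodes = (path[0][0], *(e[1] for e in path))
        types = tuple(e[2] for e in path)
        return (-path_score(path), nodes, types)

    best = min(action.paths, key=sort_key)
    edges = [
        lut.get(e) or WeightedEdge(*e, log10_pscore=0.0, confidence=0.0, n_actions=0)
        for e in best
    ]
    return MoaPath(edges)


# -- export helpers -----------------------------------------------------


def write_subnetwork_tsv(edges: Iterable[WeightedEdge], path: str | Path) -> None:
    from .pathweight import write_weighted_edges

    write_weighted_edges(edges, path)


def write_sif(edges: Iterable[WeightedEdge], path: str | Path) -> None:
    """SIF export (``source<TAB>edge_type<TAB>target``) for network viewers."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for e in edges:
            fh.write(f"{e.source_id}\t{e.edge_type}\t{e.target_id}\n")


def write_graphml(edges: Iterable[WeightedEdge], path: str | Path) -> None:
    """GraphML export carrying confidence and penalty attributes."""
    g = nx.MultiDiGraph()
    for e in edges:
        g.add_edge(
            e.source_id,
            e.target_id,
            key=e.edge_type,
            edge_type=e.edge_type,
            confidence=e.confidence,
            log10_pscore=e.log10_pscore,
            n_actions=e.n_actions,
        )
    nx.write_graphml(g, path)


def write_path_json(moa_path: MoaPath | None, path: str | Path, status: str = "ok") -> None:
    payload = (
        {"status": status, **moa_path.to_dict()}
        if moa_path is not None
        else {"status": "no constrained path found"}
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
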
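"""Constrained shortest-path enumeration and edge confidence scoring.

This is the core engine. For a perturbed starting node (a drug-binding
target or a modulated gene) and each signature endpoint, it enumerates
*all* minimum-length directed paths whose final edge is a regulatory edge
leaving a transcription factor - expression changes are assumed to be
TF-mediated, so a path may only reach an endpoint through a TF->gene edge.
Minimality is over constrained paths: a shorter path that violates the
TF-last-edge rule does not count.

Scoring treats every edge as an independent event. One endpoint defines a
*drug action*: the set of its m constrained shortest paths. If the
endpoint's penalty score (its signature FDR, ``PScore(ep)``) is the
probability that the endpoint was not perturbed, and at least one of the m
paths must be active if it was, each distinct edge of the action receives
the m-th root::

    PScore(se) = PScore(ep) ** (1/m)

An edge shared by several actions (a *common edge*) multiplies the
penalties it collected::

    PScore(ce) = PScore(se_1) * ... * PScore(se_n)

and the reported confidence is ``1 - PScore``. With thousands of actions
the product underflows double precision, so all accumulation is done in
log10 space; the log field of a weighted edge is authoritative and the
linear confidence is derived from it.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ingest import REGULATORY, ReferenceNetwork, SchemaError
from .signature import FDR_FLOOR, SignatureEntry

logger = logging.getLogger(__name__)

#: (source, target, edge_type)
Edge = tuple[str, str, str]

_LN10 = math.log(10.0)


@dataclass
class ActionPathSet:
    """All constrained shortest paths from the start to one endpoint.

    ``paths`` holds edge sequences of identical length; ``m`` (their count)
    is the denominator of the even penalty split. Every path's final edge
    is a regulatory edge whose source is a TF, and every path is simple.
    """

    start_id: str
    endpoint_id: str
    paths: list[tuple[Edge, ...]]
    endpoint_fdr: float = math.nan

    @property
    def m(self) -> int:
        return len(self.paths)

    @property
    def length(self) -> int:
        return len(self.paths[0]) if self.paths else 0


@dataclass(frozen=True)
class WeightedEdge:
    """A network edge with its accumulated penalty and derived confidence."""

    source_id: str
    target_id: str
    edge_type: str
    log10_pscore: float
    confidence: float
    n_actions: int

    @property
    def key(self) -> Edge:
        return (self.source_id, self.target_id, self.edge_type)


def confidence_from_log10(log10_pscore: float) -> float:
    """1 - 10**log10_pscore, computed stably and clamped to [0, 1]."""
    return min(1.0, max(0.0, -math.expm1(log10_pscore * _LN10)))


def constrained_shortest_paths(
    network: ReferenceNetwork,
    start_id: str,
    endpoint_id: str,
    max_len: int = 8,
    endpoint_fdr: float = math.nan,
) -> ActionPathSet | None:
    """Enumerate all constrained shortest paths between two nodes.

    A path is admissible iff its final edge is a regulatory edge leaving a
    TF; all other hops may use any edge type, including both directions of
    a PPI pair. Returns ``None`` when no admissible path of length at most
    ``max_len`` exists. Parallel edges of different types expand into
    distinct paths, so ``m`` counts edge sequences, not node sequences.

    Raises
    ------
    KeyError
        If either node is not in the network (the message names it).
    """
    g = network.graph
    for nid in (start_id, endpoint_id):
        if nid not in g:
            raise KeyError(f"unknown node {nid!r}")
    if start_id == endpoint_id:
        raise ValueError("start and endpoint must differ")
    tf_set = network.tf_set

    def allowed(u: str, v: str) -> bool:
        if v != endpoint_id:
            return True
        return u in tf_set and g.has_edge(u, v, REGULATORY)

    # layered BFS recording the shortest-path predecessor DAG; the whole
    # level on which the endpoint appears is finished so every predecessor
    # at that depth is collected
    dist: dict[str, int] = {start_id: 0}
    preds: dict[str, list[str]] = {}
    frontier = [start_id]
    depth = 0
    while frontier and endpoint_id not in dist and depth < max_len:
        nxt: list[str] = []
        for u in frontier:
            for v in g.successors(u):
                if not allowed(u, v):
                    continue
                if v not in dist:
                    dist[v] = depth + 1
                    preds[v] = [u]
                    nxt.append(v)
                elif dist[v] == depth + 1:
                    preds[v].append(u)
        frontier = nxt
        depth += 1
    if endpoint_id not in dist:
        logger.debug(
            "no constrained path %s -> %s within %d edges", start_id, endpoint_id, max_len
        )
        return None

    node_paths: list[list[str]] = []

    def backtrack(v: str, suffix: list[str]) -> None:
        if v == start_id:
            node_paths.append([start_id, *suffix])
            return
        for u in preds[v]:
            backtrack(u, [v, *suffix])

    backtrack(endpoint_id, [])

    paths: list[tuple[Edge, ...]] = []
    for np_ in node_paths:
        hop_options: list[list[Edge]] = []
        last_idx = len(np_) - 2
        for i, (a, b) in enumerate(zip(np_, np_[1:])):
            keys = [REGULATORY] if i == last_idx else sorted(g[a][b].keys())
            hop_options.append([(a, b, k) for k in keys])
        for combo in itertools.product(*hop_options):
            paths.append(tuple(combo))
    paths.sort()
    return ActionPathSet(start_id, endpoint_id, paths, endpoint_fdr)


def assign_action_pscores(action: ActionPathSet) -> dict[Edge, float]:
    """Per-action penalty: every distinct edge gets ``fdr ** (1/m)``.

    The root is taken once per action no matter how many of the m paths
    contain the edge; the exponent is evaluated in log space.
    """
    if action.m == 0:
        raise ValueError("action has no paths (m = 0)")
    fdr = action.endpoint_fdr
    if not 0.0 < fdr <= 1.0:
        raise ValueError(f"endpoint FDR must be in (0, 1], got {fdr!r}")
    per_edge = 10.0 ** (math.log10(fdr) / action.m)
    return {e: per_edge for e in set(itertools.chain.from_iterable(action.paths))}


def accumulate_edge_pscores(
    network: ReferenceNetwork, actions: Sequence[ActionPathSet]
) -> list[WeightedEdge]:
    """Multiply per-action penalties across actions for every network edge.

    Returns one weighted edge per network edge, sorted by (source, target,
    type). Edges touched by no action keep ``log10_pscore = 0`` and
    confidence 0. Per-edge contributions are sorted before summation so the
    result is bitwise independent of action order.
    """
    contribs: dict[Edge, list[float]] = defaultdict(list)
    for action in actions:
        if action.m == 0:
            raise ValueError("action has no paths (m = 0)")
        fdr = max(action.endpoint_fdr, FDR_FLOOR)
        c = math.log10(fdr) / action.m
        for e in set(itertools.chain.from_iterable(action.paths)):
            contribs[e].append(c)
    out: list[WeightedEdge] = []
    for e in sorted(network.edges()):
        cs = contribs.get(e)
        if cs:
            log10_pscore = math.fsum(sorted(cs))
            n_actions = len(cs)
        else:
            log10_pscore = 0.0
            n_actions = 0
        out.append(
            WeightedEdge(
                *e,
                log10_pscore=log10_pscore,
                confidence=confidence_from_log10(log10_pscore),
                n_actions=n_actions,
            )
        )
    return out


def score_perturbation(
    network: ReferenceNetwork,
    start_id: str,
    endpoints: Sequence[SignatureEntry],
    max_len: int = 8,
) -> list[WeightedEdge]:
    """Score every network edge against one perturbation.

    Runs the constrained shortest-path search from ``start_id`` toward each
    endpoint (one action per reachable endpoint), splits each endpoint's
    penalty over its action, and accumulates per-edge products. Endpoints
    equal to the start are skipped with a warning; FDRs of exactly 0 are
    floored at :data:`~openmoa.signature.FDR_FLOOR` to keep logs finite.
    """
    if start_id not in network:
        raise KeyError(f"unknown start node {start_id!r}")
    actions: list[ActionPathSet] = []
    n_considered = 0
    for entry in endpoints:
        if entry.gene_id == start_id:
            logger.warning("skipping endpoint identical to start node %r", start_id)
            continue
        n_considered += 1
        action = constrained_shortest_paths(
            network,
            start_id,
            entry.gene_id,
            max_len=max_len,
            endpoint_fdr=max(entry.fdr, FDR_FLOOR),
        )
        if action is not None:
            actions.append(action)
    weighted = accumulate_edge_pscores(network, actions)
    n_scored = sum(1 for w in weighted if w.n_actions > 0)
    logger.info(
        "scored perturbation at %s: %d/%d endpoints reachable, %d edges with confidence > 0",
        start_id,
        len(actions),
        n_considered,
        n_scored,
    )
    return weighted


# -- serialization ------------------------------------------------------


def write_weighted_edges(weighted: Iterable[WeightedEdge], path: str | Path) -> None:
    """Write the weighted edge table with 12 significant digits."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\tedge_type\tlog10_pscore\tconfidence\tn_actions\n")
        for w in weighted:
            fh.write(
                f"{w.source_id}\t{w.target_id}\t{w.edge_type}\t"
                f"{w.log10_pscore:.12g}\t{w.confidence:.12g}\t{w.n_actions}\n"
            )


def read_weighted_edges(path: str | Path) -> list[WeightedEdge]:
    frame = pd.read_csv(path, sep="\t", dtype={0: str, 1: str, 2: str})
    expected = ("source", "target", "edge_type", "log10_pscore", "confidence", "n_actions")
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: weighted edge table is missing column(s) {', '.join(missing)}")
    return [
        WeightedEdge(
            str(row.source),
            str(row.target),
            str(row.edge_type),
            float(row.log10_pscore),
            float(row.confidence),
            int(row.n_actions),
        )
        for row in frame.itertuples(index=False)
    ]
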
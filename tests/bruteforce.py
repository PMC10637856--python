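"""Independent brute-force oracles and random fixture generators.

Everything here deliberately avoids the library's search and accumulation
code paths: paths are enumerated by exhaustive DFS over all simple typed
paths, penalties are multiplied as plain floats (no log space), and the BH
adjustment is the textbook step-up written out directly. These serve as
ground truth for equivalence tests on small graphs.
"""

from __future__ import annotations

import math

import numpy as np

from openmoa import InteractionRecord, SignatureEntry, build_reference_network
from openmoa.ingest import DRUG_TARGET, PPI, REGULATORY


# -- path enumeration ---------------------------------------------------


def brute_constrained_shortest_paths(network, start, end, max_len=8):
    """All minimum-length simple typed paths ending in a TF regulatory edge."""
    g = network.graph
    tfs = network.tf_set
    results = []

    def extend(node, visited, edges):
        if node == end:
            last = edges[-1]
            if last[2] == REGULATORY and last[0] in tfs:
                results.append(tuple(edges))
            return
        if len(edges) >= max_len:
            return
        for _, v, k in g.out_edges(node, keys=True):
            if v in visited:
                continue
            extend(v, visited | {v}, edges + [(node, v, k)])

    for _, v, k in sorted(g.out_edges(start, keys=True)):
        if v == start:
            continue
        extend(v, {start, v}, [(start, v, k)])
    if not results:
        return None
    shortest = min(len(p) for p in results)
    return sorted(p for p in results if len(p) == shortest)


def csp_via_tf_append(network, start, end, max_len=8):
    """Alternative formulation: search to each TF regulator, then append
    the final regulatory edge. Must agree with the direct constrained
    search exactly."""
    g = network.graph
    tfs = network.tf_set
    regulators = sorted(
        {u for u, v, k in g.in_edges(end, keys=True) if k == REGULATORY and u in tfs}
    )
    if not regulators:
        return None

    # layered BFS (graph without `end`) recording all shortest node paths
    def all_shortest_node_paths(target):
        if target == start:
            return 0, [[start]]
        dist = {start: 0}
        preds: dict[str, list[str]] = {}
        frontier = [start]
        depth = 0
        while frontier and target not in dist and depth < max_len - 1:
            nxt = []
            for u in frontier:
                for v in g.successors(u):
                    if v == end:
                        continue
                    if v not in dist:
                        dist[v] = depth + 1
                        preds[v] = [u]
                        nxt.append(v)
                    elif dist[v] == depth + 1:
                        preds[v].append(u)
            frontier = nxt
            depth += 1
        if target not in dist:
            return None, []
        paths = []

        def back(v, suffix):
            if v == start:
                paths.append([start] + suffix)
                return
            for u in preds[v]:
                back(u, [v] + suffix)

        back(target, [])
        return dist[target], paths

    per_tf = {}
    best = None
    for tf in regulators:
        d, node_paths = all_shortest_node_paths(tf)
        if d is None:
            continue
        per_tf[tf] = node_paths
        if best is None or d + 1 < best:
            best = d + 1
    if best is None or best > max_len:
        return None
    out = []
    for tf, node_paths in per_tf.items():
        for np_ in node_paths:
            if len(np_) != best:  # only globally minimal totals
                continue
            hop_options = []
            for a, b in zip(np_, np_[1:]):
                hop_options.append([(a, b, k) for k in sorted(g[a][b].keys())])
            hop_options.append([(tf, end, REGULATORY)])
            import itertools

            for combo in itertools.product(*hop_options):
                out.append(tuple(combo))
    return sorted(out) if out else None


# -- scoring ------------------------------------------------------------


def brute_score(network, start, endpoints, max_len=8):
    """Straight-line reimplementation: explicit products, no log space.

    Returns {edge: (pscore, confidence, n_actions)} for every network edge.
    """
    table = {e: [1.0, 0] for e in network.edges()}
    for entry in endpoints:
        if entry.gene_id == start:
            continue
        paths = brute_constrained_shortest_paths(network, start, entry.gene_id, max_len)
        if not paths:
            continue
        m = len(paths)
        per = max(entry.fdr, 1e-300) ** (1.0 / m)
        union = set()
        for p in paths:
            union.update(p)
        for e in union:
            table[e][0] *= per
            table[e][1] += 1
    return {e: (ps, 1.0 - ps, n) for e, (ps, n) in table.items()}


def brute_centric(conf_by_edge, fraction):
    """{edge} in the top-fraction of positive confidences, ties included."""
    eligible = [(c, e) for e, c in conf_by_edge.items() if c > 0.0]
    if not eligible:
        return None
    confs = sorted((c for c, _ in eligible), reverse=True)
    cutoff = confs[math.ceil(fraction * len(confs)) - 1]
    return {e for c, e in eligible if c >= cutoff}


def brute_best_path(network, conf_by_edge, start, end, max_len=8):
    """Argmax of the edge-confidence product over all constrained shortest
    paths, ties broken on the lexicographically smallest node then type
    sequence."""
    paths = brute_constrained_shortest_paths(network, start, end, max_len)
    if paths is None:
        return None

    def product(path):
        prod = 1.0
        for e in path:
            prod *= conf_by_edge.get(e, 0.0)
        return prod

    def key(path):
        nodes = (path[0][0],) + tuple(e[1] for e in path)
        types = tuple(e[2] for e in path)
        return (-product(path), nodes, types)

    return min(paths, key=key)


# -- statistics ---------------------------------------------------------


def bh_naive(pvals):
    """Textbook Benjamini-Hochberg step-up, aligned to input order."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def normal_two_tailed_quadrature(z):
    """2 * integral of the standard normal density from |z| to infinity."""
    from scipy import integrate

    density = lambda t: math.exp(-0.5 * t * t) / math.sqrt(2.0 * math.pi)
    tail, _ = integrate.quad(density, abs(z), np.inf)
    return min(1.0, 2.0 * tail)


# -- random typed fixtures ----------------------------------------------


def random_typed_network(rng):
    """Small random typed digraph (<= 12 nodes) built through the public
    record/merge route, so PPI symmetry and node kinds hold."""
    n_drugs = int(rng.integers(0, 2))
    n_prots = int(rng.integers(2, 5))
    n_tfs = int(rng.integers(1, 4))
    n_genes = int(rng.integers(2, 5))
    drugs = [f"D{i}" for i in range(n_drugs)]
    prots = [f"P{i}" for i in range(n_prots)]
    tfs = [f"T{i}" for i in range(n_tfs)]
    genes = [f"G{i}" for i in range(n_genes)]

    drug_recs = []
    for d in drugs:
        if rng.random() < 0.8:
            t = str(rng.choice(np.array(prots + tfs)))
            drug_recs.append(InteractionRecord(d, t, DRUG_TARGET))
    ppi_nodes = prots + tfs
    ppi_recs = []
    for i, a in enumerate(ppi_nodes):
        for b in ppi_nodes[i + 1 :]:
            if rng.random() < 0.35:
                ppi_recs.append(
                    InteractionRecord(
                        a,
                        b,
                        PPI,
                        combined_score=int(rng.integers(701, 1000)),
                        experimental_score=int(rng.integers(1, 400)),
                        experimental_transferred_score=0,
                    )
                )
    reg_recs = []
    reg_targets = prots + tfs + genes
    for tf in tfs:
        for tgt in reg_targets:
            if tgt == tf:
                continue
            if rng.random() < 0.3:
                reg_recs.append(InteractionRecord(tf, tgt, REGULATORY))
    return build_reference_network(drug_recs, ppi_recs, reg_recs)


def random_scoring_case(rng):
    """(network, start, endpoints) or None if the draw has no usable start."""
    net = random_typed_network(rng)
    non_drug = sorted(n for n in net.nodes() if net.node_kind(n) == "gene")
    if len(non_drug) < 2:
        return None
    start = str(rng.choice(np.array(non_drug)))
    candidates = [n for n in non_drug if n != start]
    k = int(rng.integers(1, min(4, len(candidates)) + 1))
    chosen = rng.choice(np.array(candidates), size=k, replace=False)
    endpoints = [
        SignatureEntry(str(g), 0.0, 0.0, float(rng.uniform(1e-4, 0.9))) for g in chosen
    ]
    return net, start, endpoints
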
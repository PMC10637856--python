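"""Perturbation-signature statistics.

A perturbation signature assigns each gene a Z-score summarizing its
expression change after treatment (CMap level-5 style). Scores are
converted to two-tailed normal p-values, p = 2*(1 - Phi(|z|)), and then to
Benjamini-Hochberg false-discovery rates. The FDR of an endpoint gene is
its *penalty score*: the probability-like weight that its expression did
not actually change, which the path-scoring engine distributes over the
shortest paths reaching it.

FDRs are always computed on the full signature *before* the genes are
mapped onto network nodes; subsetting first and adjusting after would
understate the multiplicity of the original screen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ingest import ReferenceNetwork, SchemaError

logger = logging.getLogger(__name__)

#: Floor applied to FDR values before any log/root arithmetic so that
#: log-space accumulation stays finite even for astronomically significant
#: endpoints (two-tailed p underflows to 0 around |z| ~ 39).
FDR_FLOOR = 1e-300


@dataclass(frozen=True)
class SignatureEntry:
    """One signature gene with its Z-score, two-tailed p, and BH FDR."""

    gene_id: str
    z: float
    p: float
    fdr: float


def z_to_pvalue(z: float) -> float:
    """Two-tailed normal p-value for a Z-score, clamped to [0, 1].

    Even in ``z`` and strictly decreasing in ``|z|``; ``z = 0`` gives 1.
    """
    if not math.isfinite(z):
        raise ValueError(f"Z-score must be finite, got {z!r}")
    return float(min(1.0, max(0.0, 2.0 * stats.norm.sf(abs(z)))))


def adjust_fdr_bh(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, aligned to input order.

    Output is elementwise >= input and capped at 1; an empty input yields
    an empty output.
    """
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return np.empty(0, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def build_signature(gene_ids: Sequence[str], z_scores: Sequence[float]) -> list[SignatureEntry]:
    """Compute p and FDR for a full signature of (gene, Z) pairs."""
    if len(gene_ids) != len(z_scores):
        raise ValueError("gene_ids and z_scores differ in length")
    pvals = [z_to_pvalue(z) for z in z_scores]
    fdrs = adjust_fdr_bh(pvals)
    return [
        SignatureEntry(str(g), float(z), p, float(f))
        for g, z, p, f in zip(gene_ids, z_scores, pvals, fdrs)
    ]


def read_signature_table(path: str | Path) -> list[SignatureEntry]:
    """Read a ``gene<TAB>z`` table, computing p and FDR over all rows.

    If the table already carries ``p`` and ``fdr`` columns (a previously
    scored signature written by :func:`write_signature_table`), those values
    are used verbatim instead of being recomputed.
    """
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    missing = [c for c in ("gene", "z") if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: signature table is missing column(s) {', '.join(missing)}")
    genes = [str(g) for g in frame["gene"]]
    zs = [float(z) for z in frame["z"]]
    if "p" in frame.columns and "fdr" in frame.columns:
        return [
            SignatureEntry(g, z, float(p), float(f))
            for g, z, p, f in zip(genes, zs, frame["p"], frame["fdr"])
        ]
    return build_signature(genes, zs)


def write_signature_table(entries: Iterable[SignatureEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tz\tp\tfdr\n")
        for e in entries:
            fh.write(f"{e.gene_id}\t{e.z:.12g}\t{e.p:.12g}\t{e.fdr:.12g}\n")


def map_signature(
    network: ReferenceNetwork, entries: Sequence[SignatureEntry]
) -> list[SignatureEntry]:
    """Keep only signature entries whose gene is a network node.

    The FDRs carried by the entries must already have been computed on the
    full signature; mapping never re-adjusts them.
    """
    mapped = [e for e in entries if e.gene_id in network]
    logger.info(
        "signature mapping: %d/%d genes on network nodes (%d unmapped)",
        len(mapped),
        len(entries),
        len(entries) - len(mapped),
    )
    return mapped


def filter_by_fdr(entries: Sequence[SignatureEntry], max_fdr: float) -> list[SignatureEntry]:
    """Optional endpoint selection: keep entries with FDR <= ``max_fdr``."""
    if not 0.0 < max_fdr <= 1.0:
        raise ValueError(f"max_fdr must be in (0, 1], got {max_fdr}")
    kept = [e for e in entries if e.fdr <= max_fdr]
    logger.info("FDR filter (<= %g): kept %d/%d entries", max_fdr, len(kept), len(entries))
    return kept
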
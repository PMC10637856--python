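"""Seeded synthetic fixtures with a planted mechanism path.

Real runs of this pipeline consume curated releases of drug-target, PPI,
regulatory, expression, and perturbation-signature resources, none of which
can ship with a package. This module generates small tables in exactly the
same schemas, with a known ground truth planted inside, so every stage is
testable end to end.

The planted structure is a single mechanism chain::

    drug -> P1 -> ... -> TF -> gene        (drug_target, ppi..., regulatory)

whose downstream genes (the planted TF's regulon) are the only truly
differentially expressed genes in the signature. The background is
Erdos-Renyi per edge type - the simplest null that still produces multiple
equal-length shortest paths. Two sampling rules protect the ground truth:
background edges never connect two planted-chain nodes directly (no
shortcuts around the chain), and no background TF regulates a planted
downstream gene (the planted TF is its genes' only regulator). Equal-length
alternative routes through background nodes are allowed and expected.

Background signature Z-scores are standard normal. Planted downstream genes
receive |Z| values chosen so that their BH FDR lands exactly on the
requested scale: gene at DE rank i gets two-tailed p = scale * i / n, which
the step-up procedure maps back to ``fdr = scale``.

A fraction of generated PPI rows deliberately fails the evidence filters
(low combined score, or no experimental support) so ingestion filtering is
exercised on every fixture.
"""

from __future__ import annotations

import json
import logging
import tempfile
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .context import read_expression_table, filter_by_expression
from .ingest import (
    DRUG_TARGET,
    PPI,
    REGULATORY,
    build_reference_network,
    filter_ppi_records,
    read_interaction_table,
)
from .pathweight import score_perturbation
from .signature import filter_by_fdr, map_signature, read_signature_table
from .subnet import extract_centric_subnetwork

logger = logging.getLogger(__name__)

#: Fraction of background PPI rows emitted with failing evidence scores.
LOW_EVIDENCE_RATE = 0.15


@dataclass(frozen=True)
class SynthesisSpec:
    """Parameters of one synthetic study condition.

    ``planted_path_length`` counts edges of the drug -> ... -> gene chain
    (minimum 2: drug -> TF -> gene). ``de_fraction`` sets how many genes
    are differentially expressed (all within the planted TF's regulon, at
    least one when positive); 0 plants no expression change at all.
    ``de_fdr_scale`` is the BH FDR the planted genes land on.
    """

    n_drugs: int = 3
    n_proteins: int = 20
    n_tfs: int = 5
    n_genes: int = 40
    ppi_density: float = 0.08
    regulatory_density: float = 0.05
    planted_path_length: int = 4
    de_fraction: float = 0.05
    de_fdr_scale: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_path_length < 2:
            raise ValueError("planted_path_length must be >= 2 (drug -> TF -> gene)")
        if self.n_tfs < 1:
            raise ValueError("need at least one TF: the planted path ends in a regulatory edge")
        if self.n_drugs < 1 or self.n_genes < 1:
            raise ValueError("need at least one drug and one gene")
        if self.n_proteins < self.planted_path_length - 2:
            raise ValueError(
                f"planted chain needs {self.planted_path_length - 2} proteins, "
                f"only {self.n_proteins} available"
            )
        for name in ("ppi_density", "regulatory_density"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not 0.0 <= self.de_fraction < 1.0:
            raise ValueError(f"de_fraction must be in [0, 1), got {self.de_fraction}")
        if not 0.0 < self.de_fdr_scale < 1.0:
            raise ValueError(f"de_fdr_scale must be in (0, 1), got {self.de_fdr_scale}")

    @property
    def n_de(self) -> int:
        if self.de_fraction == 0.0:
            return 0
        return max(1, round(self.de_fraction * self.n_genes))


FIXTURE_FILES = {
    "drug_target": "drug_target.tsv",
    "ppi": "ppi.tsv",
    "regulatory": "regulatory.tsv",
    "expression_a": "expression_a.tsv",
    "expression_b": "expression_b.tsv",
    "signature": "signature.tsv",
    "manifest": "manifest.json",
}


def generate_fixture(spec: SynthesisSpec, out_dir: str | Path) -> dict:
    """Write one fixture (five TSVs plus a JSON manifest) and return the manifest.

    The same spec and seed always produce byte-identical files. The
    manifest records the planted path, the spec, per-file row counts, and
    the start node for downstream scoring.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    probe = out_dir / ".write_probe"
    try:
        probe.touch()
        probe.unlink()
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"output directory {out_dir} is not writable") from exc

    rng = np.random.default_rng(spec.seed)
    drugs = [f"DRUG{i:02d}" for i in range(1, spec.n_drugs + 1)]
    prots = [f"P{i:03d}" for i in range(1, spec.n_proteins + 1)]
    tfs = [f"TF{i:02d}" for i in range(1, spec.n_tfs + 1)]
    genes = [f"G{i:03d}" for i in range(1, spec.n_genes + 1)]

    # planted chain: drug, L-2 proteins, the planted TF, the planted gene
    chain_prots = prots[: spec.planted_path_length - 2]
    p_drug, p_tf, p_gene = drugs[0], tfs[0], genes[0]
    planted_nodes = [p_drug, *chain_prots, p_tf, p_gene]
    planted_edges: list[tuple[str, str, str]] = [
        (p_drug, planted_nodes[1], DRUG_TARGET),
        *[(a, b, PPI) for a, b in zip(planted_nodes[1:-1], planted_nodes[2:-1])],
        (p_tf, p_gene, REGULATORY),
    ]
    start = planted_nodes[1]
    guard = set(chain_prots) | {p_tf}  # no background edge may join two of these

    de_genes = genes[: spec.n_de]

    # -- drug-target rows
    dt_rows: list[tuple[str, str]] = [(p_drug, start)]
    for d in drugs[1:]:
        n_targets = 1 + int(rng.integers(0, 2))
        for t in rng.choice(np.array(prots + tfs), size=n_targets, replace=False):
            dt_rows.append((d, str(t)))

    # -- PPI rows
    ppi_nodes = prots + tfs
    planted_pairs = {frozenset((a, b)) for a, b, k in planted_edges if k == PPI}
    ppi_rows: list[tuple[str, str, int, int, int]] = []
    for a, b, _ in (e for e in planted_edges if e[2] == PPI):
        ppi_rows.append(
            (
                a,
                b,
                int(rng.integers(850, 1000)),
                int(rng.integers(100, 400)),
                int(rng.integers(0, 100)),
            )
        )
    for i, a in enumerate(ppi_nodes):
        for b in ppi_nodes[i + 1 :]:
            if frozenset((a, b)) in planted_pairs:
                continue
            if a in guard and b in guard:
                continue  # keep the planted chain shortcut-free
            if rng.random() >= spec.ppi_density:
                continue
            if rng.random() < LOW_EVIDENCE_RATE:
                # row that ingestion filtering must reject
                if rng.random() < 0.5:
                    row = (a, b, int(rng.integers(150, 701)), int(rng.integers(1, 300)), 0)
                else:
                    row = (a, b, int(rng.integers(701, 1000)), 0, 0)
            else:
                row = (
                    a,
                    b,
                    int(rng.integers(701, 1000)),
                    int(rng.integers(1, 400)),
                    int(rng.integers(0, 200)),
                )
            ppi_rows.append(row)

    # -- regulatory rows: planted regulon first, then background
    reg_rows: list[tuple[str, str]] = [(p_tf, p_gene)]
    for g in de_genes:
        if g != p_gene:
            reg_rows.append((p_tf, g))
    reserved = set(de_genes) | {p_gene}
    for tf in tfs:
        for g in genes:
            if g in reserved:
                continue
            if rng.random() < spec.regulatory_density:
                reg_rows.append((tf, g))

    # -- expression tables: lognormal TPM, planted machinery forced expressed
    expr_nodes = ppi_nodes + genes
    forced = set(planted_nodes[1:]) | set(de_genes)
    expr_tables: dict[str, list[tuple[str, float]]] = {}
    for name in ("expression_a", "expression_b"):
        tpm = np.round(rng.lognormal(mean=2.0, sigma=1.5, size=len(expr_nodes)), 3)
        rows = []
        for node, v in zip(expr_nodes, tpm):
            if node in forced:
                v = max(v, 5.0)
            rows.append((node, float(v)))
        expr_tables[name] = rows

    # -- signature: all gene-tier nodes plus unmapped decoys
    decoys = [f"DECOY{i:02d}" for i in range(1, 6)]
    sig_genes = genes + decoys
    z = rng.normal(0.0, 1.0, size=len(sig_genes))
    signs = rng.choice([-1.0, 1.0], size=len(de_genes))
    for rank, g in enumerate(de_genes, start=1):
        p_target = spec.de_fdr_scale * rank / len(sig_genes)
        z[sig_genes.index(g)] = signs[rank - 1] * stats.norm.isf(p_target / 2.0)
    sig_rows = [(g, float(v)) for g, v in zip(sig_genes, z)]

    # -- write files
    def write(name: str, header: str, rows: Sequence[tuple]) -> None:
        with open(out_dir / FIXTURE_FILES[name], "w", encoding="utf-8", newline="\n") as fh:
            fh.write(header + "\n")
            for row in rows:
                fh.write("\t".join(_fmt(x) for x in row) + "\n")

    def _fmt(x) -> str:
        return f"{x:.12g}" if isinstance(x, float) else str(x)

    write("drug_target", "drug\tgene", dt_rows)
    write(
        "ppi",
        "protein1\tprotein2\tcombined_score\texperimental\texperimental_transferred",
        ppi_rows,
    )
    write("regulatory", "tf\tgene", reg_rows)
    write("expression_a", "gene\ttpm", expr_tables["expression_a"])
    write("expression_b", "gene\ttpm", expr_tables["expression_b"])
    write("signature", "gene\tz", sig_rows)

    manifest = {
        "spec": asdict(spec),
        "seed": spec.seed,
        "planted_path": planted_nodes,
        "planted_edges": [list(e) for e in planted_edges],
        # edges checkable downstream of the start node (the drug->target
        # edge can never lie on a path that begins at the target)
        "mechanism_edges": [list(e) for e in planted_edges[1:]],
        "start": start,
        "de_genes": de_genes,
        "counts": {
            "drugs": len(drugs),
            "proteins": len(prots),
            "tfs": len(tfs),
            "genes": len(genes),
            "drug_target_rows": len(dt_rows),
            "ppi_rows": len(ppi_rows),
            "regulatory_rows": len(reg_rows),
            "signature_rows": len(sig_rows),
        },
        "files": {k: v for k, v in FIXTURE_FILES.items() if k != "manifest"},
    }
    with open(out_dir / FIXTURE_FILES["manifest"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info(
        "fixture written to %s (%d ppi rows, %d regulatory rows, %d DE genes)",
        out_dir,
        len(ppi_rows),
        len(reg_rows),
        len(de_genes),
    )
    return manifest


def default_recovery_max_fdr(spec: SynthesisSpec) -> float:
    """Endpoint FDR cutoff for recovery runs.

    Two orders of magnitude above the planted DE scale (capped at 0.05):
    planted genes pass with a wide margin while null genes essentially
    never do.
    """
    return min(100.0 * spec.de_fdr_scale, 0.05)


def run_fixture_pipeline(
    fixture_dir: str | Path,
    manifest: dict,
    fraction: float = 0.05,
    max_fdr: float | None = None,
    max_len: int = 8,
):
    """Run ingest -> context -> signature -> scoring -> subnetwork on a fixture.

    Returns ``(network, weighted, subnetwork_or_None)``; the subnetwork is
    ``None`` when no edge was scored (e.g. no endpoint passed the FDR
    cutoff).
    """
    fixture_dir = Path(fixture_dir)
    files = manifest["files"]
    drug = read_interaction_table(fixture_dir / files["drug_target"], DRUG_TARGET)
    ppi = filter_ppi_records(read_interaction_table(fixture_dir / files["ppi"], PPI))
    reg = read_interaction_table(fixture_dir / files["regulatory"], REGULATORY)
    net = build_reference_network(drug, ppi, reg)
    tables = [
        read_expression_table(fixture_dir / files["expression_a"]),
        read_expression_table(fixture_dir / files["expression_b"]),
    ]
    net = filter_by_expression(net, tables, tpm_threshold=1.0)
    entries = read_signature_table(fixture_dir / files["signature"])
    entries = map_signature(net, entries)
    if max_fdr is not None:
        entries = filter_by_fdr(entries, max_fdr)
    weighted = score_perturbation(net, manifest["start"], entries, max_len=max_len)
    if not any(w.n_actions > 0 for w in weighted):
        return net, weighted, None
    return net, weighted, extract_centric_subnetwork(weighted, fraction)


def planted_path_recovery_rate(
    spec: SynthesisSpec,
    n_replicates: int,
    fraction: float = 0.05,
    max_fdr: float | None = None,
) -> float:
    """Fraction of seeded replicates recovering every planted mechanism edge.

    Each replicate regenerates the fixture with seed ``spec.seed + i``,
    runs the full pipeline from the planted drug target, and checks that
    every planted edge downstream of the start lies in the top-``fraction``
    centric subnetwork. ``max_fdr`` defaults to
    :func:`default_recovery_max_fdr`; replicates with no scored edge count
    as failures.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if max_fdr is None:
        max_fdr = default_recovery_max_fdr(spec)
    hits = 0
    for i in range(n_replicates):
        rep_spec = replace(spec, seed=spec.seed + i)
        with tempfile.TemporaryDirectory() as tmp:
            manifest = generate_fixture(rep_spec, tmp)
            _, _, sub = run_fixture_pipeline(
                tmp, manifest, fraction=fraction, max_fdr=max_fdr
            )
        if sub is None:
            continue
        kept = {w.key for w in sub.edges}
        if all(tuple(e) in kept for e in manifest["mechanism_edges"]):
            hits += 1
    rate = hits / n_replicates
    logger.info(
        "planted-path recovery: %d/%d replicates at fraction %g", hits, n_replicates, fraction
    )
    return rate
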
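"""End-to-end driver: configuration, stage composition, and run reports.

The driver adds no computation of its own - it calls the stage functions in
order (ingest -> context -> signature -> scoring -> subnetwork -> optional
path query), materializes every intermediate table to disk so any stage can
be inspected or re-run, and writes a JSON report with the counts observed
at each stage. Floating-point outputs use 12 significant digits so that
identical inputs produce byte-identical output files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .context import filter_by_expression, read_expression_table
from .ingest import (
    DRUG_TARGET,
    PPI,
    REGULATORY,
    build_reference_network,
    filter_ppi_records,
    read_interaction_table,
)
from .pathweight import score_perturbation, write_weighted_edges
from .signature import (
    filter_by_fdr,
    map_signature,
    read_signature_table,
    write_signature_table,
)
from .subnet import (
    best_moa_path,
    extract_centric_subnetwork,
    write_graphml,
    write_path_json,
    write_sif,
    write_subnetwork_tsv,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One reproducible run: input paths plus the thresholds of the method.

    Defaults reproduce the canonical settings: PPI combined score > 700,
    expression TPM >= 1.0, top 1% of confidences for the centric
    subnetwork.
    """

    drug_targets: str = ""
    ppi: str = ""
    regulatory: str = ""
    expression: list[str] = field(default_factory=list)
    signature: str = ""
    start_id: str = ""
    end_id: str | None = None
    min_combined: int = 700
    require_experimental: bool = True
    tpm_threshold: float = 1.0
    max_fdr: float | None = None
    max_len: int = 8
    fraction: float = 0.01
    seed: int = 0
    out_dir: str = "openmoa_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.start_id:
            raise ValueError("config is missing start_id")
        missing = []
        for name in ("drug_targets", "ppi", "regulatory", "signature"):
            p = getattr(self, name)
            if not p:
                missing.append(name)
            elif not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if missing:
            raise ValueError(f"config is missing input path(s): {', '.join(missing)}")
        if not self.expression:
            raise ValueError("config needs at least one expression table")
        for p in self.expression:
            if not Path(p).exists():
                raise FileNotFoundError(f"expression file not found: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    report: dict = {
        "version": __version__,
        "parameters": {
            "min_combined": config.min_combined,
            "require_experimental": config.require_experimental,
            "tpm_threshold": config.tpm_threshold,
            "max_fdr": config.max_fdr,
            "max_len": config.max_len,
            "fraction": config.fraction,
            "start_id": config.start_id,
            "end_id": config.end_id,
            "seed": config.seed,
        },
        "stages": {},
    }

    def stage(name: str):
        logger.info("[%s] starting", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    with stage("ingest"):
        drug = read_interaction_table(config.drug_targets, DRUG_TARGET)
        ppi_raw = read_interaction_table(config.ppi, PPI)
        ppi = filter_ppi_records(
            ppi_raw,
            min_combined=config.min_combined,
            require_experimental=config.require_experimental,
        )
        reg = read_interaction_table(config.regulatory, REGULATORY)
        network = build_reference_network(drug, ppi, reg)
        network.to_tsv(out_dir / "network.tsv")
        report["stages"]["ingest"] = {
            "drug_records": len(drug),
            "ppi_records_raw": len(ppi_raw),
            "ppi_records_filtered": len(ppi),
            "regulatory_records": len(reg),
            "nodes": network.number_of_nodes(),
            "edges": network.number_of_edges(),
        }

    with stage("context"):
        tables = [read_expression_table(p) for p in config.expression]
        network = filter_by_expression(network, tables, tpm_threshold=config.tpm_threshold)
        network.to_tsv(out_dir / "context_network.tsv")
        report["stages"]["context"] = {
            "expression_tables": len(tables),
            "nodes": network.number_of_nodes(),
            "edges": network.number_of_edges(),
        }

    with stage("signature"):
        entries = read_signature_table(config.signature)
        write_signature_table(entries, out_dir / "signature_scored.tsv")
        mapped = map_signature(network, entries)
        if config.max_fdr is not None:
            mapped = filter_by_fdr(mapped, config.max_fdr)
        report["stages"]["signature"] = {
            "entries": len(entries),
            "mapped": len(mapped),
        }

    with stage("score"):
        weighted = score_perturbation(
            network, config.start_id, mapped, max_len=config.max_len
        )
        write_weighted_edges(weighted, out_dir / "weighted.tsv")
        n_scored = sum(1 for w in weighted if w.n_actions > 0)
        report["stages"]["score"] = {
            "edges": len(weighted),
            "scored_edges": n_scored,
        }

    with stage("subnet"):
        if n_scored == 0:
            logger.warning("no edge was scored; centric subnetwork is empty")
            write_subnetwork_tsv([], out_dir / "subnetwork.tsv")
            write_sif([], out_dir / "subnetwork.sif")
            report["stages"]["subnet"] = {"edges": 0, "cutoff_confidence": None}
        else:
            sub = extract_centric_subnetwork(weighted, fraction=config.fraction)
            write_subnetwork_tsv(sub.edges, out_dir / "subnetwork.tsv")
            write_sif(sub.edges, out_dir / "subnetwork.sif")
            write_graphml(sub.edges, out_dir / "subnetwork.graphml")
            report["stages"]["subnet"] = {
                "edges": len(sub.edges),
                "cutoff_confidence": sub.cutoff_confidence,
            }

    if config.end_id:
        with stage("path"):
            moa = best_moa_path(
                network, weighted, config.start_id, config.end_id, max_len=config.max_len
            )
            write_path_json(moa, out_dir / "moa_path.json")
            report["stages"]["path"] = (
                {"found": False}
                if moa is None
                else {
                    "found": True,
                    "length": moa.length,
                    "log10_path_confidence": moa.log10_path_confidence,
                    "nodes": moa.node_sequence,
                }
            )

    report["wall_time_s"] = round(time.monotonic() - t0, 3)
    with open(out_dir / "report.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
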
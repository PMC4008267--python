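"""End-to-end orchestration: simulate/load -> DE -> candidates -> network.

``run_pipeline`` executes the whole analysis under one configuration and
writes every stage's output plus a JSON run manifest (config snapshot,
per-stage counts, SHA-256 checksums of all written files, recovery metrics
when planted truth is available).  Identical configuration and seed yield
identical checksums.

By default correlation scoring is restricted to candidate pairs whose miRNA
was called differentially expressed -- the screen's logic is "which of the
responding miRNAs drive which transcripts" -- with ``all_mirnas=True`` to
score every candidate instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import __version__
from .diffexp import DECriteria, DifferentialExpression
from .errors import ConfigurationError
from .expression import ExpressionMatrix
from .network import TargetCorrelationModel, build_network, export_network, recovery
from .simulate import PlantedTruth, SimulationConfig, SyntheticBundle, simulate_bundle, write_bundle
from .targets import (
    CandidatePair,
    consensus,
    predict_builtin,
    read_mirna_fasta,
    read_tool_table,
    read_utr_fasta,
)

__all__ = ["PipelineConfig", "InputPaths", "run_pipeline"]

log = logging.getLogger("mirtarnet.pipeline")


@dataclass(frozen=True)
class InputPaths:
    """File-based inputs for a run on real (non-simulated) data."""

    mirna_matrix: str
    mrna_matrix: str
    metadata: str
    mirna_fasta: str | None = None
    utr_fasta: str | None = None
    tool_tables: tuple[tuple[str, str], ...] = ()  # (tool_name, path)
    truth: str | None = None


@dataclass(frozen=True)
class PipelineConfig:
    """One run's full configuration.

    Exactly one of ``simulation`` / ``inputs`` supplies the data.
    ``de_scope`` is a timepoint label, ``"last"`` (default; resolves to the
    final timepoint of the design) or ``"pooled"``.
    """

    simulation: SimulationConfig | None = None
    inputs: InputPaths | None = None
    mirna_criteria: DECriteria = field(default_factory=DECriteria)
    mrna_criteria: DECriteria = field(default_factory=DECriteria)
    de_scope: str = "last"
    min_tools: int = 3
    use_builtin_predictor: bool = True
    min_site_type: str = "7mer-A1"
    r_min: float = 0.5
    correlation_mode: str = "ratio"
    all_mirnas: bool = False
    keep_unclassified: bool = False
    tf_list: tuple[str, ...] = ()
    export_formats: tuple[str, ...] = ("SIF", "GraphML")

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of simulation settings or input paths must be given"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = asdict(config)
    for key in ("mirna_criteria", "mrna_criteria"):
        snap[key] = asdict(getattr(config, key))
    return snap


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the run manifest (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    t0 = time.monotonic()
    stage = "inputs"
    try:
        # ---- stage 1: data ------------------------------------------------
        truth: PlantedTruth | set | None = None
        if config.simulation is not None:
            bundle = simulate_bundle(config.simulation)
            inp = outdir / "inputs"
            written.update(
                {f"inputs/{k}": p for k, p in write_bundle(bundle, inp).items()}
            )
            mirna_matrix, mrna_matrix = bundle.mirna_matrix, bundle.mrna_matrix
            tool_tables = bundle.prediction_tables
            mirnas, utrs = bundle.mirnas, bundle.utrs
            truth = bundle.truth
        else:
            paths = config.inputs
            mirna_matrix = ExpressionMatrix.read(paths.mirna_matrix, paths.metadata)
            mrna_matrix = ExpressionMatrix.read(paths.mrna_matrix, paths.metadata)
            tool_tables = {
                name: read_tool_table(path, name) for name, path in paths.tool_tables
            }
            mirnas = read_mirna_fasta(paths.mirna_fasta) if paths.mirna_fasta else []
            utrs = read_utr_fasta(paths.utr_fasta) if paths.utr_fasta else []
            if paths.truth:
                import pandas as pd

                tdf = pd.read_csv(paths.truth, sep="\t")
                truth = {
                    (str(r.mirna_id), str(r.gene_id)) for r in tdf.itertuples()
                }
        log.info("stage data: %d miRNAs x %d genes", len(mirna_matrix.feature_ids),
                 len(mrna_matrix.feature_ids))

        scope = config.de_scope
        if scope == "last":
            scope = mirna_matrix.timepoints[-1]

        # ---- stage 2: differential expression -----------------------------
        stage = "diffexp"
        de_mir = DifferentialExpression(mirna_matrix, config.mirna_criteria).fit(scope)
        de_gene = DifferentialExpression(mrna_matrix, config.mrna_criteria).fit(scope)
        written["de_mirna"] = outdir / "de_mirna.tsv"
        written["de_mrna"] = outdir / "de_mrna.tsv"
        de_mir.write(written["de_mirna"])
        de_gene.write(written["de_mrna"])
        log.info("stage diffexp (%s): %d/%d miRNAs, %d/%d mRNAs significant",
                 scope, de_mir.n_significant, len(de_mir.frame),
                 de_gene.n_significant, len(de_gene.frame))

        # ---- stage 3: candidate pairs -------------------------------------
        stage = "targets"
        pair_lists: list[Sequence[CandidatePair]] = [
            tool_tables[name] for name in sorted(tool_tables)
        ]
        if config.use_builtin_predictor and mirnas and utrs:
            pair_lists.append(predict_builtin(mirnas, utrs, config.min_site_type))
        candidates = consensus(pair_lists, config.min_tools)
        written["candidates"] = outdir / "candidates.tsv"
        with open(written["candidates"], "w") as fh:
            fh.write("mirna_id\tgene_id\tconsensus_count\ttools\n")
            for c in candidates:
                fh.write(
                    f"{c.mirna_id}\t{c.gene_id}\t{c.consensus_count}"
                    f"\t{','.join(sorted(c.tools))}\n"
                )
        log.info("stage targets: %d consensus candidates (min_tools=%d, %d tools)",
                 len(candidates), config.min_tools, len(pair_lists))

        # ---- stage 4: correlation scoring ---------------------------------
        stage = "network"
        if config.all_mirnas:
            scored_candidates = candidates
        else:
            de_set = set(de_mir.significant_features)
            scored_candidates = [c for c in candidates if c.mirna_id in de_set]
        model = TargetCorrelationModel(
            scored_candidates, mirna_matrix, mrna_matrix, config.correlation_mode
        )
        results = model.fit(r_min=config.r_min)
        written["edges"] = outdir / "edges.tsv"
        results.write(written["edges"])

        net = results.build_network(
            de_mir, de_gene, config.tf_list, config.keep_unclassified
        )
        for fmt in config.export_formats:
            for key, p in export_network(net, outdir, fmt).items():
                written[f"net:{fmt}:{key}"] = p
        n_hc = len(results.high_confidence)
        log.info("stage network: %d edges scored, %d high-confidence", len(results.edges), n_hc)

        # ---- stage 5: recovery --------------------------------------------
        stage = "recovery"
        report = None
        if truth is not None:
            report = recovery(truth, results.edges, high_conf_only=True)
            written["recovery"] = outdir / "recovery.json"
            with open(written["recovery"], "w") as fh:
                json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
            log.info("stage recovery: precision=%.3f recall=%.3f", report.precision,
                     report.recall)
    except Exception as exc:
        from .errors import MirtarnetError

        raise MirtarnetError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config": _config_snapshot(config),
        "de_scope_resolved": scope,
        "counts": {
            "mirnas_tested": len(de_mir.frame),
            "mrnas_tested": len(de_gene.frame),
            "mirnas_significant": de_mir.n_significant,
            "mrnas_significant": de_gene.n_significant,
            "consensus_candidates": len(candidates),
            "candidates_scored": len(scored_candidates),
            "edges_scored": len(results.edges),
            "edges_negative": sum(e.sign == "negative" for e in results.edges),
            "edges_positive": sum(e.sign == "positive" for e in results.edges),
            "high_confidence_edges": n_hc,
            "network_nodes": net.number_of_nodes(),
            "network_edges": net.number_of_edges(),
        },
        "recovery": report.as_dict() if report is not None else None,
        "checksums": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(written.values())
        },
        "elapsed_s": round(time.monotonic() - t0, 3),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
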
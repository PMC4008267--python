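"""Synthetic paired miRNA/mRNA time courses with planted repressive edges.

Emulates the design of a two-condition (control vs UVB), four-timepoint
(d1, d4, d7, d9), replicated log2-intensity screen in which a minority of
miRNAs respond monotonically to the treatment and each responding miRNA
represses a disjoint set of planted target genes:

* a regulated miRNA i has control mean c_i everywhere and UVB mean
  ``c_i + s_i * effect_size * g(t)`` with ``g`` a linear ramp over the
  timepoint index (0, 1/3, 2/3, 1) and ``s_i = +/-1``;
* each planted target j of miRNA i has its UVB mean shifted by
  ``-beta * (miRNA UVB shift)`` at every timepoint;
* unregulated features have zero condition effect;
* i.i.d. Gaussian noise (sd ``noise_sd``) is added to every sample value.

On top of the matrices the generator emits (a) per-tool prediction tables
that include each true edge with probability ``tool_sensitivity`` and each
non-edge with probability ``tool_fp_rate``, independently per tool, and
(b) mature miRNA sequences (21 nt RNA) and 3'UTRs (600 nt DNA) in which
every true edge gets one embedded canonical 8mer seed-match site, while
rejection sampling keeps 7mer-m8/8mer sites of the planted miRNAs out of
all non-target UTRs.

Everything is a pure function of the configuration, including its seed:
the same :class:`SimulationConfig` always yields a byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError
from .expression import ExpressionMatrix
from .targets import CandidatePair, MatureMiRNA, UTRRecord, reverse_complement_dna

__all__ = [
    "SimulationConfig",
    "TruthEdge",
    "PlantedTruth",
    "SyntheticBundle",
    "simulate_expression",
    "simulate_prediction_tables",
    "emit_sequences",
    "simulate_bundle",
    "write_bundle",
]

_RNA = np.array(list("ACGU"))
_DNA = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of the synthetic screen.

    Defaults describe the reference scenario used throughout the tests:
    40 miRNAs of which 20 respond to UVB, 5 planted targets each among 400
    genes, triplicates at four timepoints, a 2.0 log2-unit maximal miRNA
    effect, unit repression strength, and 0.25 sd measurement noise; ten
    simulated prediction tools at 70% sensitivity / 1% false-positive rate.
    """

    n_mirnas: int = 40
    n_genes: int = 400
    n_regulated_mirnas: int = 20
    targets_per_mirna: int = 5
    timepoints: tuple[str, ...] = ("d1", "d4", "d7", "d9")
    n_replicates: int = 3
    effect_size: float = 2.0
    repression_strength: float = 1.0
    noise_sd: float = 0.25
    n_tools: int = 10
    tool_sensitivity: float = 0.7
    tool_fp_rate: float = 0.01
    utr_length: int = 600
    mirna_length: int = 21
    baseline_range: tuple[float, float] = (6.0, 12.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regulated_mirnas > self.n_mirnas:
            raise ConfigurationError("n_regulated_mirnas exceeds n_mirnas")
        if self.n_regulated_mirnas * self.targets_per_mirna > self.n_genes:
            raise ConfigurationError("more planted targets than genes")
        for name in ("tool_sensitivity", "tool_fp_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if min(self.n_mirnas, self.n_genes, self.n_replicates, self.n_tools) < 0:
            raise ConfigurationError("counts must be non-negative")
        if len(self.timepoints) < 1:
            raise ConfigurationError("need at least one timepoint")
        if self.mirna_length < 8:
            raise ConfigurationError("miRNA length must be >= 8")
        if self.utr_length < 8:
            raise ConfigurationError("UTR length must be >= 8 (site embedding)")

    @property
    def mirna_ids(self) -> list[str]:
        return [f"miR-{i + 1:03d}" for i in range(self.n_mirnas)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"GENE{j + 1:04d}" for j in range(self.n_genes)]


@dataclass(frozen=True)
class TruthEdge:
    mirna_id: str
    gene_id: str
    beta: float
    direction: str  # trajectory of the miRNA under UVB: "up" | "down"


@dataclass(frozen=True)
class PlantedTruth:
    """The simulator's ground-truth repressive edge list."""

    edges: tuple[TruthEdge, ...]

    def __post_init__(self) -> None:
        pairs = [(e.mirna_id, e.gene_id) for e in self.edges]
        if len(pairs) != len(set(pairs)):
            raise ConfigurationError("duplicate planted pairs")

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(e.mirna_id, e.gene_id) for e in self.edges}

    @property
    def mirna_ids(self) -> set[str]:
        return {e.mirna_id for e in self.edges}


@dataclass
class SyntheticBundle:
    """Everything one simulated study produces."""

    config: SimulationConfig
    mirna_matrix: ExpressionMatrix
    mrna_matrix: ExpressionMatrix
    truth: PlantedTruth
    prediction_tables: dict[str, list[CandidatePair]]
    mirnas: list[MatureMiRNA]
    utrs: list[UTRRecord]
    site_positions: dict[tuple[str, str], int]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng([config.rng_seed, stream])


def _sample_columns(config: SimulationConfig) -> tuple[list[str], pd.DataFrame]:
    rows = []
    for cond in ("control", "UVB"):
        for tp in config.timepoints:
            for rep in range(1, config.n_replicates + 1):
                rows.append({"sample_id": f"{cond}_{tp}_r{rep}",
                             "condition": cond, "timepoint": tp, "replicate": rep})
    meta = pd.DataFrame(rows).set_index("sample_id")
    return list(meta.index), meta


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, PlantedTruth]:
    """Simulate the paired miRNA and mRNA matrices and the planted edge list."""
    rng = _rng(config, 0)
    mirna_ids, gene_ids = config.mirna_ids, config.gene_ids
    n_reg = config.n_regulated_mirnas
    signs = rng.choice([-1.0, 1.0], size=n_reg)
    gene_perm = rng.permutation(config.n_genes)
    lo, hi = config.baseline_range
    base_mir = rng.uniform(lo, hi, config.n_mirnas)
    base_gene = rng.uniform(lo, hi, config.n_genes)

    n_tp = len(config.timepoints)
    ramp = (
        np.linspace(0.0, 1.0, n_tp) if n_tp > 1 else np.array([1.0])
    )  # g(t): minimal monotone shape, g(last) = 1

    # UVB shift per feature per timepoint (log2 units)
    shift_mir = np.zeros((config.n_mirnas, n_tp))
    shift_gene = np.zeros((config.n_genes, n_tp))
    edges = []
    for i in range(n_reg):
        shift_mir[i] = signs[i] * config.effect_size * ramp
        targets = gene_perm[i * config.targets_per_mirna : (i + 1) * config.targets_per_mirna]
        for j in targets:
            shift_gene[j] = -config.repression_strength * shift_mir[i]
            edges.append(
                TruthEdge(
                    mirna_id=mirna_ids[i],
                    gene_id=gene_ids[j],
                    beta=config.repression_strength,
                    direction="up" if signs[i] > 0 else "down",
                )
            )
    truth = PlantedTruth(tuple(edges))

    sample_ids, meta = _sample_columns(config)
    n_samples = len(sample_ids)

    def build(base: np.ndarray, shift: np.ndarray) -> np.ndarray:
        vals = np.empty((base.size, n_samples))
        col = 0
        for cond in ("control", "UVB"):
            for t in range(n_tp):
                mean = base if cond == "control" else base + shift[:, t]
                for _ in range(config.n_replicates):
                    vals[:, col] = mean
                    col += 1
        return vals

    mir_vals = build(base_mir, shift_mir)
    gene_vals = build(base_gene, shift_gene)
    mir_vals = mir_vals + rng.normal(0.0, config.noise_sd, mir_vals.shape)
    gene_vals = gene_vals + rng.normal(0.0, config.noise_sd, gene_vals.shape)

    mirna_matrix = ExpressionMatrix(
        pd.DataFrame(mir_vals, index=mirna_ids, columns=sample_ids), meta
    )
    mrna_matrix = ExpressionMatrix(
        pd.DataFrame(gene_vals, index=gene_ids, columns=sample_ids), meta.copy()
    )
    return mirna_matrix, mrna_matrix, truth


def simulate_prediction_tables(
    truth: PlantedTruth, config: SimulationConfig
) -> dict[str, list[CandidatePair]]:
    """Per-tool candidate tables: true edges at ``tool_sensitivity``, non-edges
    at ``tool_fp_rate``, independently per tool and pair."""
    rng = _rng(config, 1)
    mirna_ids, gene_ids = config.mirna_ids, config.gene_ids
    mirna_set, gene_set = set(mirna_ids), set(gene_ids)
    for m, g in truth.pairs:
        if m not in mirna_set or g not in gene_set:
            raise ConfigurationError(f"truth edge ({m}, {g}) outside the simulated features")
    true_list = sorted(truth.pairs)
    tables: dict[str, list[CandidatePair]] = {}
    for t in range(config.n_tools):
        name = f"tool{t + 1:02d}"
        tools = frozenset({name})
        hits: list[tuple[str, str]] = []
        keep_true = rng.random(len(true_list)) < config.tool_sensitivity
        hits.extend(p for p, k in zip(true_list, keep_true) if k)
        fp_draw = rng.random((config.n_mirnas, config.n_genes)) < config.tool_fp_rate
        for i, j in zip(*np.nonzero(fp_draw)):
            pair = (mirna_ids[i], gene_ids[j])
            if pair not in truth.pairs:
                hits.append(pair)
        tables[name] = [CandidatePair(m, g, tools) for m, g in sorted(set(hits))]
    return tables


def _random_seq(rng: np.random.Generator, alphabet: np.ndarray, length: int) -> str:
    return "".join(rng.choice(alphabet, size=length))


def emit_sequences(
    truth: PlantedTruth,
    config: SimulationConfig,
    max_retries: int = 200,
) -> tuple[list[MatureMiRNA], list[UTRRecord], dict[tuple[str, str], int]]:
    """Mature miRNA sequences and UTRs with one embedded 8mer site per true edge.

    Rejection sampling enforces (a) pairwise-distinct miRNA seeds and (b) no
    7mer-m8 or 8mer site of any planted miRNA in UTRs that are not its target.
    """
    rng = _rng(config, 2)
    mirna_ids, gene_ids = config.mirna_ids, config.gene_ids

    mirnas: list[MatureMiRNA] = []
    seen_seeds: set[str] = set()
    for mid in mirna_ids:
        for _ in range(max_retries):
            seq = _random_seq(rng, _RNA, config.mirna_length)
            if seq[1:8] not in seen_seeds:
                seen_seeds.add(seq[1:8])
                mirnas.append(MatureMiRNA(mid, seq))
                break
        else:
            raise GenerationError(f"could not draw a distinct seed for {mid}")
    by_id = {m.id: m for m in mirnas}

    # core7(m) = reverse complement (DNA) of miRNA nt 2-8; its presence in a
    # UTR is exactly a 7mer-m8-or-better site for m
    core7 = {
        mid: reverse_complement_dna(by_id[mid].seed7.replace("U", "T"))
        for mid in truth.mirna_ids
    }
    target_mirna: dict[str, str] = {}
    for e in truth.edges:
        if e.gene_id in target_mirna:
            raise ConfigurationError(
                f"gene {e.gene_id} planted as target of two miRNAs; one site per UTR is supported"
            )
        target_mirna[e.gene_id] = e.mirna_id

    utrs: list[UTRRecord] = []
    positions: dict[tuple[str, str], int] = {}
    for gid in gene_ids:
        owner = target_mirna.get(gid)
        for _ in range(max_retries):
            seq = _random_seq(rng, _DNA, config.utr_length)
            pos = -1
            if owner is not None:
                pos = int(rng.integers(0, config.utr_length - 8 + 1))
                site = core7[owner] + "A"  # 8mer site
                seq = seq[:pos] + site + seq[pos + 8 :]
            ok = all(
                core7[mid] not in seq
                for mid in core7
                if mid != owner
            )
            if ok:
                utrs.append(UTRRecord(gid, seq))
                if owner is not None:
                    positions[(owner, gid)] = pos
                break
        else:
            raise GenerationError(f"rejection sampling exhausted for UTR of {gid}")
    return mirnas, utrs, positions


def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Run all three generators under one configuration."""
    mirna_matrix, mrna_matrix, truth = simulate_expression(config)
    tables = simulate_prediction_tables(truth, config)
    mirnas, utrs, positions = emit_sequences(truth, config)
    return SyntheticBundle(
        config=config,
        mirna_matrix=mirna_matrix,
        mrna_matrix=mrna_matrix,
        truth=truth,
        prediction_tables=tables,
        mirnas=mirnas,
        utrs=utrs,
        site_positions=positions,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["mirna_matrix"] = outdir / "mirna_matrix.tsv"
    paths["mrna_matrix"] = outdir / "mrna_matrix.tsv"
    paths["samples"] = outdir / "samples.tsv"
    bundle.mirna_matrix.write(paths["mirna_matrix"], paths["samples"])
    bundle.mrna_matrix.write(paths["mrna_matrix"])

    paths["truth"] = outdir / "truth_edges.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("mirna_id\tgene_id\tbeta\tdirection\n")
        for e in sorted(bundle.truth.edges, key=lambda e: (e.mirna_id, e.gene_id)):
            fh.write(f"{e.mirna_id}\t{e.gene_id}\t{e.beta:.6g}\t{e.direction}\n")

    tool_dir = outdir / "tools"
    tool_dir.mkdir(exist_ok=True)
    for name in sorted(bundle.prediction_tables):
        p = tool_dir / f"{name}.tsv"
        with open(p, "w") as fh:
            fh.write("mirna_id\tgene_id\n")
            for pair in bundle.prediction_tables[name]:
                fh.write(f"{pair.mirna_id}\t{pair.gene_id}\n")
        paths[f"tool:{name}"] = p

    paths["mirna_fasta"] = outdir / "mirnas.fasta"
    with open(paths["mirna_fasta"], "w") as fh:
        for m in bundle.mirnas:
            fh.write(f">{m.id}\n{m.sequence}\n")
    paths["utr_fasta"] = outdir / "utrs.fasta"
    with open(paths["utr_fasta"], "w") as fh:
        for u in bundle.utrs:
            fh.write(f">{u.gene_id}\n{u.sequence}\n")
    return paths
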
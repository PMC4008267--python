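"""Correlation scoring of candidate pairs and the signed bipartite network.

High-confidence target calling follows the expression-based rationale: a
miRNA that represses a transcript should move opposite to it, so a candidate
(miRNA, gene) pair is scored by the Pearson correlation of their expression
profiles across the time course and flagged high-confidence only when the
correlation is negative (r <= -r_min).  Positive edges are kept and labelled
-- they are informative (indirect regulation, shared upstream drivers) -- but
never high-confidence.

Two profile modes are provided because either is a defensible reading of
"expression profiles":

* ``ratio`` (default): per-(timepoint, replicate) log2(UVB/control) values,
  n = timepoints x replicates.  Removes baseline differences between
  features; a flat, unresponsive gene has zero variance here and its edges
  are classified ``none``.
* ``intensity``: all log2 sample intensities, n = 2 x timepoints x
  replicates.

No p-value is attached to r: with a handful of paired observations the
threshold on |r| is the decision rule, and it is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .diffexp import DifferentialExpressionResults
from .errors import ConsistencyError
from .expression import ExpressionMatrix
from .targets import CandidatePair

__all__ = [
    "InteractionEdge",
    "RecoveryReport",
    "pearson_r",
    "score_pairs",
    "TargetCorrelationModel",
    "TargetNetworkResults",
    "build_network",
    "export_network",
    "recovery",
    "EDGE_COLORS",
]

EDGE_COLORS = {"positive": "red", "negative": "green", "none": "grey"}
NODE_ROLES = ("mirna", "target", "transcription_factor")


@dataclass(frozen=True)
class InteractionEdge:
    """A scored candidate pair.

    ``r`` is NaN when the correlation is undefined (zero variance); the sign
    is then ``none``.  ``high_confidence`` is true exactly when the sign is
    negative.
    """

    mirna_id: str
    gene_id: str
    r: float
    n: int
    sign: str  # "positive" | "negative" | "none"
    high_confidence: bool
    consensus_count: int

    def __post_init__(self) -> None:
        if not np.isnan(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")
        if self.high_confidence and self.sign != "negative":
            raise ValueError("high_confidence edge must have negative sign")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Sample Pearson correlation and the number of paired observations.

    Returns ``(nan, n)`` when either vector has zero variance (the
    undefined-correlation signal); raises on length mismatch or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), n)
    # two-pass definitional formula; a result within a few ulp of +/-1 is
    # rounded to exactly +/-1 (the residual is roundoff of the dot products,
    # below the resolution of the statistic itself)
    dx, dy = x - x.mean(), y - y.mean()
    r = float(np.dot(dx, dy) / np.sqrt(np.dot(dx, dx) * np.dot(dy, dy)))
    if abs(r) > 1.0 - 4 * np.finfo(float).eps:
        r = float(np.sign(r))
    return (r, n)


def _profiles(
    matrix: ExpressionMatrix, mode: str
) -> pd.DataFrame:
    if mode == "ratio":
        return matrix.log_ratios()
    if mode == "intensity":
        ordered = [
            s
            for cond in ("control", "UVB")
            for s in matrix.samples(cond)
        ]
        return matrix.values[ordered]
    raise ValueError(f"unknown correlation mode {mode!r}; expected 'ratio' or 'intensity'")


def score_pairs(
    candidates: Sequence[CandidatePair],
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    mode: str = "ratio",
    r_min: float = 0.5,
) -> list[InteractionEdge]:
    """Score each candidate pair by Pearson correlation of paired profiles.

    Sign classification: ``negative`` if r <= -r_min, ``positive`` if
    r >= +r_min, else ``none`` (including undefined r).
    """
    if not 0 < r_min <= 1:
        raise ValueError(f"r_min must be in (0, 1], got {r_min}")
    mir_prof = _profiles(mirna_matrix, mode)
    gene_prof = _profiles(mrna_matrix, mode)
    if mode == "ratio" and list(mir_prof.columns) != list(gene_prof.columns):
        raise ConsistencyError("miRNA and mRNA matrices have different designs")
    edges: list[InteractionEdge] = []
    for cand in candidates:
        if cand.mirna_id not in mir_prof.index:
            raise LookupError(f"miRNA {cand.mirna_id!r} absent from the miRNA matrix")
        if cand.gene_id not in gene_prof.index:
            raise LookupError(f"gene {cand.gene_id!r} absent from the mRNA matrix")
        r, n = pearson_r(
            mir_prof.loc[cand.mirna_id].to_numpy(),
            gene_prof.loc[cand.gene_id].to_numpy(),
        )
        if np.isnan(r):
            sign = "none"
        elif r <= -r_min:
            sign = "negative"
        elif r >= r_min:
            sign = "positive"
        else:
            sign = "none"
        edges.append(
            InteractionEdge(
                mirna_id=cand.mirna_id,
                gene_id=cand.gene_id,
                r=r,
                n=n,
                sign=sign,
                high_confidence=(sign == "negative"),
                consensus_count=cand.consensus_count,
            )
        )
    return edges


class TargetCorrelationModel:
    """Model object: candidate pairs plus the paired expression matrices.

    ``fit(r_min=...)`` scores every candidate and returns a
    :class:`TargetNetworkResults` carrying the classified edges.
    """

    def __init__(
        self,
        candidates: Sequence[CandidatePair],
        mirna_matrix: ExpressionMatrix,
        mrna_matrix: ExpressionMatrix,
        mode: str = "ratio",
    ):
        if mode not in ("ratio", "intensity"):
            raise ValueError(f"unknown correlation mode {mode!r}")
        self.candidates = list(candidates)
        self.mirna_matrix = mirna_matrix
        self.mrna_matrix = mrna_matrix
        self.mode = mode

    def fit(self, r_min: float = 0.5) -> "TargetNetworkResults":
        edges = score_pairs(
            self.candidates, self.mirna_matrix, self.mrna_matrix, self.mode, r_min
        )
        return TargetNetworkResults(edges, mode=self.mode, r_min=r_min)


class TargetNetworkResults:
    """Scored interaction edges with sign classes and high-confidence flags."""

    def __init__(self, edges: Sequence[InteractionEdge], mode: str, r_min: float):
        self.edges = list(edges)
        self.mode = mode
        self.r_min = r_min

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mirna_id": e.mirna_id,
                    "gene_id": e.gene_id,
                    "r": e.r,
                    "n": e.n,
                    "sign": e.sign,
                    "high_confidence": e.high_confidence,
                    "consensus_count": e.consensus_count,
                }
                for e in self.edges
            ],
            columns=[
                "mirna_id",
                "gene_id",
                "r",
                "n",
                "sign",
                "high_confidence",
                "consensus_count",
            ],
        )

    @property
    def high_confidence(self) -> list[InteractionEdge]:
        return [e for e in self.edges if e.high_confidence]

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def build_network(
        self,
        de_mirnas: DifferentialExpressionResults | pd.DataFrame,
        de_mrnas: DifferentialExpressionResults | pd.DataFrame,
        tf_list: Iterable[str] | None = None,
        keep_unclassified: bool = False,
    ) -> nx.Graph:
        return build_network(self.edges, de_mirnas, de_mrnas, tf_list, keep_unclassified)

    def recovery(self, truth, high_conf_only: bool = True) -> "RecoveryReport":
        return recovery(truth, self.edges, high_conf_only)

    def summary(self) -> str:
        counts = {s: 0 for s in ("negative", "positive", "none")}
        for e in self.edges:
            counts[e.sign] += 1
        rs = [e.r for e in self.edges if not np.isnan(e.r)]
        lines = [
            "miRNA-target correlation network",
            "=" * 32,
            f"mode: {self.mode}   |r| threshold: {self.r_min}",
            f"candidate pairs scored: {len(self.edges)}",
            f"negative (high-confidence): {counts['negative']}",
            f"positive: {counts['positive']}   unclassified: {counts['none']}",
        ]
        if rs:
            lines.append(f"mean r over defined pairs: {np.mean(rs):+.3f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<TargetNetworkResults: {len(self.edges)} edges,"
            f" {len(self.high_confidence)} high-confidence>"
        )


def _de_frame(de) -> pd.DataFrame:
    return de.frame if isinstance(de, DifferentialExpressionResults) else de


def build_network(
    edges: Sequence[InteractionEdge],
    de_mirnas: DifferentialExpressionResults | pd.DataFrame,
    de_mrnas: DifferentialExpressionResults | pd.DataFrame,
    tf_list: Iterable[str] | None = None,
    keep_unclassified: bool = False,
) -> nx.Graph:
    """Assemble the signed bipartite miRNA-target graph.

    Nodes carry ``role`` (mirna / target / transcription_factor), the DE
    ``de_direction`` and linear ``fold``; edges carry r, n, sign, the vote
    count and the display color (red=positive, green=negative).  Edges with
    sign ``none`` are dropped unless ``keep_unclassified``.
    """
    mir_de = _de_frame(de_mirnas)
    gene_de = _de_frame(de_mrnas)
    tfs = set(tf_list or ())
    kept = [e for e in edges if keep_unclassified or e.sign != "none"]
    g = nx.Graph()
    for e in kept:
        if e.mirna_id not in mir_de.index:
            raise ConsistencyError(f"edge miRNA {e.mirna_id!r} absent from miRNA DE table")
        if e.gene_id not in gene_de.index:
            raise ConsistencyError(f"edge gene {e.gene_id!r} absent from mRNA DE table")
    mirna_ids = sorted({e.mirna_id for e in kept})
    gene_ids = sorted({e.gene_id for e in kept})
    for mid in mirna_ids:
        row = mir_de.loc[mid]
        g.add_node(
            mid,
            role="mirna",
            de_direction=str(row["direction"]),
            fold=float(row["fold"]),
            bipartite=0,
        )
    for gid in gene_ids:
        row = gene_de.loc[gid]
        g.add_node(
            gid,
            role="transcription_factor" if gid in tfs else "target",
            de_direction=str(row["direction"]),
            fold=float(row["fold"]),
            bipartite=1,
        )
    for e in sorted(kept, key=lambda e: (e.mirna_id, e.gene_id)):
        g.add_edge(
            e.mirna_id,
            e.gene_id,
            r=float(e.r),
            n=int(e.n),
            sign=e.sign,
            high_confidence=bool(e.high_confidence),
            consensus_count=int(e.consensus_count),
            color=EDGE_COLORS[e.sign],
        )
    _assert_structure(g)
    return g


def _assert_structure(g: nx.Graph) -> None:
    """Structural invariants checked on every constructed network."""
    for u, v, data in g.edges(data=True):
        roles = {g.nodes[u]["role"], g.nodes[v]["role"]}
        if "mirna" not in roles or roles == {"mirna"}:
            raise ConsistencyError(f"edge ({u}, {v}) is not miRNA <-> gene")
        if not np.isnan(data["r"]) and abs(data["r"]) > 1 + 1e-12:
            raise ConsistencyError(f"edge ({u}, {v}) has |r| > 1")
        if data["high_confidence"] and data["sign"] != "negative":
            raise ConsistencyError(f"edge ({u}, {v}) high-confidence but not negative")


def export_network(
    net: nx.Graph,
    outdir: str | Path,
    fmt: str = "SIF",
    basename: str = "network",
) -> dict[str, Path]:
    """Write the network plus node/edge attribute tables; byte-stable output.

    ``fmt`` is ``SIF`` or ``GraphML``.  SIF lines are
    ``<mirna>\\t<sign>\\t<gene>`` sorted by (mirna, gene); the companion
    attribute TSVs are written for both formats.  Returns the written paths.
    """
    fmt_l = fmt.lower()
    if fmt_l not in ("sif", "graphml"):
        raise ValueError(f"unknown format {fmt!r}; expected 'SIF' or 'GraphML'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edge_rows = sorted(
        ((u, v) if net.nodes[u]["role"] == "mirna" else (v, u) for u, v in net.edges),
        key=lambda p: p,
    )
    paths: dict[str, Path] = {}

    if fmt_l == "sif":
        sif = outdir / f"{basename}.sif"
        with open(sif, "w") as fh:
            for m, t in edge_rows:
                fh.write(f"{m}\t{net.edges[m, t]['sign']}\t{t}\n")
        paths["network"] = sif
    else:
        gml = outdir / f"{basename}.graphml"
        # rebuild in sorted order so serialization is deterministic
        ordered = nx.Graph()
        for nid in sorted(net.nodes):
            ordered.add_node(nid, **net.nodes[nid])
        for m, t in edge_rows:
            ordered.add_edge(m, t, **net.edges[m, t])
        nx.write_graphml(ordered, gml)
        paths["network"] = gml

    nodes_tsv = outdir / f"{basename}.nodes.tsv"
    with open(nodes_tsv, "w") as fh:
        fh.write("id\trole\tde_direction\tfold\n")
        for nid in sorted(net.nodes):
            nd = net.nodes[nid]
            fh.write(f"{nid}\t{nd['role']}\t{nd['de_direction']}\t{nd['fold']:.6g}\n")
    paths["nodes"] = nodes_tsv

    edges_tsv = outdir / f"{basename}.edges.tsv"
    with open(edges_tsv, "w") as fh:
        fh.write("mirna_id\tgene_id\tr\tn\tsign\tconsensus_count\tcolor\n")
        for m, t in edge_rows:
            ed = net.edges[m, t]
            fh.write(
                f"{m}\t{t}\t{ed['r']:.6f}\t{ed['n']}\t{ed['sign']}"
                f"\t{ed['consensus_count']}\t{ed['color']}\n"
            )
    paths["edges"] = edges_tsv
    return paths


@dataclass(frozen=True)
class RecoveryReport:
    """Set comparison of inferred (miRNA, gene) pairs against planted truth.

    ``precision_defined`` / ``recall_defined`` flag whether the corresponding
    denominator was nonzero; an undefined ratio with zero errors is reported
    as 1.0 with the flag cleared.
    """

    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True
    recall_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "precision_defined": self.precision_defined,
            "recall_defined": self.recall_defined,
        }


def recovery(truth, edges: Sequence[InteractionEdge], high_conf_only: bool = True) -> RecoveryReport:
    """Score inferred edges against the simulator's planted edge list.

    ``truth`` is a :class:`~mirtarnet.simulate.PlantedTruth` or any object
    with a ``pairs`` attribute (a set of (mirna_id, gene_id) tuples) or an
    iterable of such tuples.
    """
    if hasattr(truth, "pairs"):
        true_pairs = set(truth.pairs)
    else:
        true_pairs = {(m, g) for m, g in truth}
    inferred = {
        (e.mirna_id, e.gene_id)
        for e in edges
        if (e.high_confidence if high_conf_only else True)
    }
    tp = len(inferred & true_pairs)
    fp = len(inferred - true_pairs)
    fn = len(true_pairs - inferred)
    precision_defined = (tp + fp) > 0
    recall_defined = (tp + fn) > 0
    precision = tp / (tp + fp) if precision_defined else 1.0
    recall = tp / (tp + fn) if recall_defined else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return RecoveryReport(tp, fp, fn, precision, recall, f1, precision_defined, recall_defined)
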
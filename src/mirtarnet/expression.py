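"""Expression matrices for paired two-condition time-course designs.

The container is a thin, validated wrapper over two pandas DataFrames:
``values`` (features x samples, log2 intensities) and per-sample
``metadata`` with columns ``condition`` (``control`` or ``UVB``),
``timepoint`` and ``replicate``.  All internal arithmetic stays on the
log2 scale; linear fold changes appear only at reporting boundaries, so
the conventional 1.5-fold cutoff becomes a +/- log2(1.5) threshold.

``log_ratios`` pairs replicate k of the treated condition with replicate
k of the control at the same timepoint and returns per-feature
log2(UVB/control) profiles ordered by (timepoint, replicate) -- the
quantity the downstream correlation scoring operates on by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, ParseError

__all__ = [
    "CONDITIONS",
    "ExpressionMatrix",
    "FoldChange",
    "read_matrix",
    "log_ratios",
    "fold_change",
    "ddct_fold",
]

CONDITIONS = ("control", "UVB")
METADATA_COLUMNS = ("condition", "timepoint", "replicate")


@dataclass
class ExpressionMatrix:
    """Validated feature-by-sample log2 expression matrix with sample annotations."""

    values: pd.DataFrame
    metadata: pd.DataFrame
    timepoints: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        v, m = self.values, self.metadata
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ParseError(f"duplicate feature id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id: {dup!r}")
        missing_meta = [s for s in v.columns if s not in m.index]
        if missing_meta:
            raise ParseError(f"metadata missing for sample(s): {missing_meta}")
        extra = [s for s in m.index if s not in v.columns]
        if extra:
            raise ParseError(f"metadata lists unknown sample(s): {extra}")
        for col in METADATA_COLUMNS:
            if col not in m.columns:
                raise ParseError(f"metadata lacks required column {col!r}")
        bad_cond = sorted(set(m["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ParseError(
                f"unknown condition label(s) {bad_cond}; expected one of {CONDITIONS}"
            )
        if v.isna().any().any():
            col = v.columns[v.isna().any()][0]
            raise ParseError(f"missing values are not supported (found in sample {col!r})")
        # timepoint order = order of first appearance in the metadata
        self.timepoints = tuple(dict.fromkeys(m["timepoint"]))
        for cond in CONDITIONS:
            for tp in self.timepoints:
                if self.samples(cond, tp).empty:
                    raise DesignError(f"design cell ({cond}, {tp}) has no samples")

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples(self, condition: str, timepoint: str | None = None) -> pd.Index:
        """Sample ids for a condition (optionally one timepoint), sorted by
        (timepoint order, replicate)."""
        m = self.metadata
        mask = m["condition"] == condition
        if timepoint is not None:
            mask &= m["timepoint"] == timepoint
        sub = m[mask]
        order = {tp: i for i, tp in enumerate(getattr(self, "timepoints", ()))} or None
        if order:
            sub = sub.sort_values(
                ["timepoint", "replicate"],
                key=lambda s: s.map(order) if s.name == "timepoint" else s,
                kind="stable",
            )
        else:
            sub = sub.sort_values(["timepoint", "replicate"], kind="stable")
        return sub.index

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.metadata)

    # -- IO --------------------------------------------------------------
    @classmethod
    def read(cls, path: str | Path, metadata_path: str | Path) -> "ExpressionMatrix":
        """Read a TSV matrix (first column ``feature_id``) and its sample table."""
        values = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype={"replicate": int})
        meta.index = meta.index.astype(str)
        values.columns = values.columns.astype(str)
        return cls(values, meta)

    def write(self, path: str | Path, metadata_path: str | Path | None = None) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")
        if metadata_path is not None:
            meta = self.metadata.copy()
            meta.index.name = "sample_id"
            meta.to_csv(metadata_path, sep="\t")

    # -- derived quantities ----------------------------------------------
    def log_ratios(self) -> pd.DataFrame:
        """Per-feature log2(UVB/control), replicate-paired within each timepoint.

        Returns a features x (timepoint, replicate) DataFrame; column order is
        (timepoint order, replicate).  Requires a paired design: the same
        replicate labels in both conditions at every timepoint.
        """
        cols: dict[tuple[str, object], pd.Series] = {}
        for tp in self.timepoints:
            uvb = self.samples("UVB", tp)
            ctl = self.samples("control", tp)
            reps_u = list(self.metadata.loc[uvb, "replicate"])
            reps_c = list(self.metadata.loc[ctl, "replicate"])
            if reps_u != reps_c:
                raise DesignError(
                    f"unpaired design at timepoint {tp!r}: UVB replicates {reps_u}"
                    f" vs control replicates {reps_c}"
                )
            for su, sc, rep in zip(uvb, ctl, reps_u):
                cols[(tp, rep)] = self.values[su] - self.values[sc]
        out = pd.DataFrame(cols)
        out.columns = pd.MultiIndex.from_tuples(out.columns, names=["timepoint", "replicate"])
        return out


def read_matrix(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Functional alias for :meth:`ExpressionMatrix.read`."""
    return ExpressionMatrix.read(path, metadata_path)


def log_ratios(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Functional alias for :meth:`ExpressionMatrix.log_ratios`."""
    return matrix.log_ratios()


@dataclass(frozen=True)
class FoldChange:
    """A linear fold (>= 1) with a direction flag and the signed log2 mean."""

    fold: float
    direction: str  # "up" | "down" | "none"
    log2_mean: float


def fold_change(profile, timepoint: str | None = None) -> FoldChange:
    """Linear fold change of a log2-ratio profile.

    ``profile`` is a Series indexed by (timepoint, replicate) as produced by
    :meth:`ExpressionMatrix.log_ratios`, or any 1-D collection of log2 ratios.
    With ``timepoint`` given, only that timepoint's entries are used; the
    default pools the whole profile.
    """
    s = pd.Series(profile) if not isinstance(profile, pd.Series) else profile
    if timepoint is not None:
        if not isinstance(s.index, pd.MultiIndex):
            raise ValueError("timepoint selection needs a (timepoint, replicate) index")
        s = s.xs(timepoint, level="timepoint")
    if len(s) == 0:
        raise ValueError("empty profile selection")
    mean = float(s.mean())
    direction = "up" if mean > 0 else ("down" if mean < 0 else "none")
    return FoldChange(fold=2.0 ** abs(mean), direction=direction, log2_mean=mean)


def ddct_fold(dct_treated: float, dct_control: float) -> float:
    """Relative quantification by the ddCt transform: ``2**-(dCt_t - dCt_c)``.

    Inputs are delta-Ct values (target Ct minus endogenous-control Ct) for the
    treated and control samples; the result is the linear expression ratio.
    """
    if not (math.isfinite(dct_treated) and math.isfinite(dct_control)):
        raise ValueError(f"ddCt inputs must be finite, got {dct_treated}, {dct_control}")
    return 2.0 ** -(dct_treated - dct_control)
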
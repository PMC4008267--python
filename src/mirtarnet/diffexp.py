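"""Differential-expression calling: Welch t, Benjamini-Hochberg, conjunctive rule.

A feature is called differentially expressed when BOTH conditions hold:
its linear fold change (``2**|mean log2 UVB - mean log2 control|``) reaches
the fold cutoff (default 1.5), AND its BH-adjusted two-sided Welch-t p-value
falls below alpha (default 0.05).  ``use_adjusted=False`` switches the second
condition to the raw p-value.

The Welch (unequal-variance) t-test is used rather than a pooled-variance or
moderated-variance test: with triplicate microarray groups it is the robust
default, and empirical-Bayes variance shrinkage is deliberately out of scope
here.  Degenerate features (zero variance in both groups and equal means,
which arise in noise-free simulations) are reported as t=0, p=1 by the
matrix-level caller; the scalar :func:`welch_t` raises on them instead so the
degeneracy is never silent in direct use.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError
from .expression import ExpressionMatrix

__all__ = [
    "DECriteria",
    "TTestResult",
    "welch_t",
    "bh_adjust",
    "DifferentialExpression",
    "DifferentialExpressionResults",
    "call_de",
]


@dataclass(frozen=True)
class DECriteria:
    """Thresholds of the conjunctive DE rule."""

    fold_cutoff: float = 1.5
    alpha: float = 0.05
    use_adjusted: bool = True

    def __post_init__(self) -> None:
        if self.fold_cutoff < 1:
            raise ValueError(f"fold_cutoff must be >= 1, got {self.fold_cutoff}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


class TTestResult(NamedTuple):
    t_stat: float
    df: float
    p_raw: float


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Two-sided Welch t-test with Welch-Satterthwaite degrees of freedom.

    Groups of size < 2, or zero variance in both groups with equal means,
    raise :class:`DegenerateDataError`.  Zero variance in both groups with
    *unequal* means yields t = +/-inf, p = 0 (an infinitely confident call).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError(f"need n >= 2 per group, got {a.size} and {b.size}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            raise DegenerateDataError("zero variance in both groups and equal means")
        return TTestResult(float(np.sign(diff) * np.inf), float("nan"), 0.0)
    sa, sb = va / a.size, vb / b.size
    se = np.sqrt(sa + sb)
    t = diff / se
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Equivalent to the definition ``q_(i) = min_{j >= i} min(1, p_(j) * m / j)``
    on the ascending order statistics, mapped back to the original positions.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        bad = p[(~np.isfinite(p)) | (p < 0) | (p > 1)][0]
        raise ValueError(f"p-values must lie in [0, 1], got {bad}")
    return multipletests(p, method="fdr_bh")[1]


class DifferentialExpression:
    """Model object: an expression matrix plus the DE decision rule.

    Parameters
    ----------
    matrix :
        Log2 expression matrix with control/UVB sample annotations.
    criteria :
        Fold-change and significance thresholds; defaults are a 1.5-fold
        cutoff with BH-adjusted p < 0.05.

    ``fit`` runs the per-feature Welch t-test (UVB vs control) at the chosen
    scope and returns a :class:`DifferentialExpressionResults`.
    """

    def __init__(self, matrix: ExpressionMatrix, criteria: DECriteria | None = None):
        if len(matrix.feature_ids) == 0:
            raise ValueError("empty expression matrix")
        self.matrix = matrix
        self.criteria = criteria or DECriteria()

    def fit(self, scope: str = "pooled") -> "DifferentialExpressionResults":
        """Test every feature; ``scope`` is a timepoint label or ``"pooled"``."""
        m = self.matrix
        tp = None if scope == "pooled" else scope
        if tp is not None and tp not in m.timepoints:
            raise ValueError(f"unknown timepoint {tp!r}; have {m.timepoints}")
        uvb = m.samples("UVB", tp)
        ctl = m.samples("control", tp)
        if len(uvb) < 2 or len(ctl) < 2:
            raise DegenerateDataError(
                f"need >= 2 replicates per condition at scope {scope!r}"
            )
        a = m.values[list(uvb)].to_numpy(dtype=float)
        b = m.values[list(ctl)].to_numpy(dtype=float)
        na, nb = a.shape[1], b.shape[1]
        ma, mb = a.mean(axis=1), b.mean(axis=1)
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        log2fc = ma - mb

        sa, sb = va / na, vb / nb
        degenerate = (va == 0) & (vb == 0)
        flat = degenerate & (log2fc == 0)
        exact = degenerate & (log2fc != 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(sa + sb)
            df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        p = np.empty_like(t)
        regular = ~degenerate
        p[regular] = 2.0 * stats.t.sf(np.abs(t[regular]), df[regular])
        # zero variance, equal means: no evidence of change at all
        t[flat], df[flat], p[flat] = 0.0, np.nan, 1.0
        # zero variance, unequal means: noise-free shift
        t[exact] = np.sign(log2fc[exact]) * np.inf
        df[exact], p[exact] = np.nan, 0.0

        p_adj = bh_adjust(p)
        fold = 2.0 ** np.abs(log2fc)
        direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
        p_sel = p_adj if self.criteria.use_adjusted else p
        significant = (fold >= self.criteria.fold_cutoff) & (p_sel < self.criteria.alpha)

        frame = pd.DataFrame(
            {
                "log2fc": log2fc,
                "fold": fold,
                "t_stat": t,
                "df": df,
                "p_raw": p,
                "p_adj": p_adj,
                "direction": direction,
                "significant": significant,
            },
            index=m.feature_ids.copy(),
        )
        frame.index.name = "feature_id"
        return DifferentialExpressionResults(frame, self.criteria, scope, (na, nb))


class DifferentialExpressionResults:
    """Per-feature DE table plus the criteria that produced it."""

    def __init__(
        self,
        frame: pd.DataFrame,
        criteria: DECriteria,
        scope: str,
        group_sizes: tuple[int, int],
    ):
        self.frame = frame
        self.criteria = criteria
        self.scope = scope
        self.group_sizes = group_sizes

    @property
    def significant_features(self) -> pd.Index:
        return self.frame.index[self.frame["significant"]]

    @property
    def n_significant(self) -> int:
        return int(self.frame["significant"].sum())

    def direction_of(self, feature_id: str) -> str:
        return str(self.frame.at[feature_id, "direction"])

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t")

    def summary(self) -> str:
        c = self.criteria
        n = len(self.frame)
        up = int((self.frame["significant"] & (self.frame["direction"] == "up")).sum())
        down = self.n_significant - up
        p_kind = "adjusted" if c.use_adjusted else "raw"
        lines = [
            "Differential expression (Welch t, Benjamini-Hochberg)",
            "=" * 53,
            f"scope: {self.scope}   groups: UVB n={self.group_sizes[0]},"
            f" control n={self.group_sizes[1]}",
            f"rule: fold >= {c.fold_cutoff} AND {p_kind} p < {c.alpha}",
            f"features tested: {n}",
            f"significant: {self.n_significant} ({up} up, {down} down)",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DifferentialExpressionResults: {self.n_significant}/{len(self.frame)}"
            f" significant at scope {self.scope!r}>"
        )


def call_de(
    matrix: ExpressionMatrix,
    criteria: DECriteria | None = None,
    scope: str = "pooled",
) -> DifferentialExpressionResults:
    """Convenience wrapper: build the model and fit in one call."""
    return DifferentialExpression(matrix, criteria).fit(scope)
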
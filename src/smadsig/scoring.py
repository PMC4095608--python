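"""Weighted signature scoring, median dichotomization, meta-gene indices,
the IQR outlier rule, and rank correlation.

Two score modes are provided: ``weighted_sum`` (per-sample sum of weight x
expression over present signature genes, matching the R-based survival
analyses) and ``weighted_mean`` (the sum divided by the number of present
genes, matching the meta-analysis tool's averaged gene-set expression).
Signature genes missing from a cohort are dropped from scoring and recorded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, GeneSignature

__all__ = [
    "ScoreVector",
    "signature_score",
    "dichotomize_median",
    "MetaIndexDef",
    "fit_meta_index",
    "apply_meta_index",
    "remove_outliers",
    "correlate_after_outliers",
    "META_DIFF_GENES",
]

# Curated luminal-differentiation gene list for the metaDiff index.
META_DIFF_GENES = (
    "FOXA1", "CITED1", "GATA3", "ESR1", "PGR", "WNT4",
    "KRT19", "MUC1", "ELF5", "KIT", "CYP24A1",
)


@dataclass
class ScoreVector:
    """Per-sample scores plus the gene coverage bookkeeping."""

    scores: pd.Series
    genes_used: int
    genes_missing: list[str] = field(default_factory=list)


def signature_score(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    mode: str = "weighted_sum",
) -> ScoreVector:
    """Weighted expression score of a signature for every sample."""
    if mode not in ("weighted_sum", "weighted_mean"):
        raise ValueError(f"unknown score mode {mode!r}")
    weights = signature.weights
    present = [g for g in weights.index if g in matrix.values.index]
    missing = [g for g in weights.index if g not in matrix.values.index]
    if not present:
        raise ValueError("no signature gene is present in the expression matrix")
    w = weights.loc[present].to_numpy(dtype=float)
    scores = matrix.values.loc[present].to_numpy().T @ w
    if mode == "weighted_mean":
        scores = scores / len(present)
    return ScoreVector(
        scores=pd.Series(scores, index=matrix.sample_ids),
        genes_used=len(present),
        genes_missing=missing,
    )


def dichotomize_median(scores: ScoreVector | pd.Series) -> pd.Series:
    """Label samples High iff score > median, Low otherwise (median ties Low)."""
    s = scores.scores if isinstance(scores, ScoreVector) else pd.Series(scores)
    if len(s) < 2:
        raise ValueError("need >= 2 samples to dichotomize")
    med = float(np.median(s.to_numpy()))
    labels = pd.Series(np.where(s.to_numpy() > med, "High", "Low"), index=s.index)
    if (labels == "Low").all():
        warnings.warn("all scores <= median (degenerate grouping): every sample Low")
    return labels


@dataclass
class MetaIndexDef:
    """Definition (and, after fitting, the learned gene list) of a meta-gene index.

    Methods: ``top_fraction_median`` (median expression of the top
    ``fraction`` of genes most positively correlated with the anchor, e.g. a
    proliferation index anchored on PCNA), ``top_k_weighted_sum``
    (correlation-weighted sum of the top ``k`` anchor-correlated genes, e.g.
    an ephrin index anchored on EFNA1), and ``curated_median`` (median of a
    fixed list, e.g. an 11-gene luminal-differentiation index).
    """

    name: str
    method: str
    anchor_gene: str | None = None
    curated_genes: tuple[str, ...] | None = None
    fraction: float = 0.01
    k: int = 30
    genes_: tuple[str, ...] | None = None
    weights_: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.method not in ("top_fraction_median", "top_k_weighted_sum", "curated_median"):
            raise ValueError(f"unknown meta-index method {self.method!r}")
        if self.method == "curated_median":
            if not self.curated_genes:
                raise ValueError("curated_median requires curated_genes")
        elif self.anchor_gene is None:
            raise ValueError(f"{self.method} requires an anchor gene")

    @property
    def fitted(self) -> bool:
        return self.genes_ is not None


def fit_meta_index(reference: ExpressionMatrix, definition: MetaIndexDef) -> MetaIndexDef:
    """Learn the index gene list (and weights) from a reference panel.

    Anchor methods rank all other genes by Pearson correlation with the
    anchor across reference samples; ``top_fraction_median`` keeps the top
    ``ceil(fraction * n_genes)`` genes, ``top_k_weighted_sum`` the top ``k``
    with their correlation coefficients as weights.  ``curated_median``
    passes its list through unchanged.
    """
    if definition.method == "curated_median":
        return replace(definition, genes_=tuple(definition.curated_genes), weights_=None)
    anchor = definition.anchor_gene
    if anchor not in reference.values.index:
        raise ValueError(f"anchor gene {anchor!r} absent from the reference panel")
    values = reference.values
    anchor_expr = values.loc[anchor]
    candidates = values.drop(index=anchor)
    cors = candidates.T.corrwith(anchor_expr)
    cors = cors.sort_values(ascending=False)
    if definition.method == "top_fraction_median":
        n_top = math.ceil(definition.fraction * len(values))
        top = cors.index[:n_top]
        return replace(definition, genes_=tuple(top), weights_=None)
    if definition.k > len(values):
        raise ValueError(f"k={definition.k} exceeds the panel's {len(values)} genes")
    top = cors.index[: definition.k]
    return replace(
        definition,
        genes_=tuple(top),
        weights_=tuple(float(cors[g]) for g in top),
    )


def apply_meta_index(matrix: ExpressionMatrix, definition: MetaIndexDef) -> ScoreVector:
    """Evaluate a fitted meta-gene index on an expression matrix.

    Requires at least half the index genes to be present.  Median methods
    take the per-sample median over present genes; the weighted method the
    per-sample sum of weight x expression.
    """
    if not definition.fitted:
        raise ValueError(f"meta-index {definition.name!r} is not fitted")
    genes = list(definition.genes_)
    present = [g for g in genes if g in matrix.values.index]
    missing = [g for g in genes if g not in matrix.values.index]
    if len(present) * 2 < len(genes):
        raise ValueError(
            f"meta-index {definition.name!r}: only {len(present)}/{len(genes)} genes "
            f"present (missing: {missing})"
        )
    sub = matrix.values.loc[present]
    if definition.method == "top_k_weighted_sum":
        w = np.array([definition.weights_[genes.index(g)] for g in present])
        scores = sub.to_numpy().T @ w
    else:
        scores = np.median(sub.to_numpy(), axis=0)
    return ScoreVector(
        scores=pd.Series(scores, index=matrix.sample_ids),
        genes_used=len(present),
        genes_missing=missing,
    )


def remove_outliers(x) -> tuple[np.ndarray, np.ndarray]:
    """Drop points outside ``[m - 1.5*IQR, m + 1.5*IQR]`` (m = median).

    Quartiles use linear interpolation (type-7); the rule is applied once,
    never iterated, and the interval is closed.  Returns (retained values,
    removed indices).  Vectors shorter than 4 pass through with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        warnings.warn("fewer than 4 points: outlier rule skipped")
        return x.copy(), np.array([], dtype=int)
    q1, q3 = np.quantile(x, [0.25, 0.75])  # type-7 (linear) interpolation
    iqr = q3 - q1
    m = float(np.median(x))
    lo, hi = m - 1.5 * iqr, m + 1.5 * iqr
    keep = (x >= lo) & (x <= hi)
    return x[keep], np.flatnonzero(~keep)


def outlier_interval(x) -> tuple[float, float]:
    """The closed retention interval of the IQR outlier rule."""
    x = np.asarray(x, dtype=float)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    m = float(np.median(x))
    return m - 1.5 * (q3 - q1), m + 1.5 * (q3 - q1)


def correlate_after_outliers(x: ScoreVector | pd.Series, y: ScoreVector | pd.Series):
    """Spearman correlation of two score vectors after outlier removal.

    The IQR rule is applied to each variable independently; only samples
    surviving in both are correlated.  Returns (rho, p, n_used, n_removed);
    ties get average ranks and the two-sided p uses the t approximation.
    """
    xs = x.scores if isinstance(x, ScoreVector) else pd.Series(x)
    ys = y.scores if isinstance(y, ScoreVector) else pd.Series(y)
    common = xs.index.intersection(ys.index)
    xs, ys = xs.loc[common], ys.loc[common]
    _, removed_x = remove_outliers(xs.to_numpy())
    _, removed_y = remove_outliers(ys.to_numpy())
    removed = set(removed_x) | set(removed_y)
    keep = [i for i in range(len(common)) if i not in removed]
    if len(keep) < 5:
        raise ValueError(f"only {len(keep)} pairs survive outlier removal (need >= 5)")
    rho, p = stats.spearmanr(xs.iloc[keep], ys.iloc[keep])
    return float(rho), float(p), len(keep), len(removed)
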
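"""Deriving the directionally weighted tumor-suppressor signature.

The cascade: occupancy-defined target genes are tested for differential in
vitro expression across the four conditions (M3 +/- TGF-beta, M4 +/- TGF-beta),
genes uniquely regulated in the tumor-suppressor-competent M3 line are
selected, an in vivo filter (control vs receptor-blocked tumors) assigns the
definitive direction of regulation, and surviving genes receive a +/-1 weight
equal to their in vivo direction.  Genes whose in vitro and in vivo
directions disagree are kept and flagged discordant; the weight always
follows the in vivo direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, GeneSignature, SignatureEntry

__all__ = [
    "anova_four_condition",
    "pairwise_regulation",
    "hierarchical_cluster",
    "ClusterAssignment",
    "select_unique_m3",
    "select_common",
    "in_vivo_filter",
    "derive_signature",
    "DerivedSignatures",
]

# A "DiffResult" is a DataFrame indexed by gene id with columns
# effect, statistic, p, q, direction (and a boolean significance flag).


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def anova_four_condition(
    matrix: ExpressionMatrix,
    groups: pd.Series | dict,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA per gene across the four in vitro conditions.

    ``groups`` maps sample id -> condition label (exactly 4 labels, >= 2
    replicates each).  Genes with BH q < ``fdr`` are flagged heterogeneous.
    Genes that are constant everywhere get F = 0 and p = 1.
    """
    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 4:
        raise ValueError(f"expected 4 condition labels, got {labels}")
    blocks = []
    for label in labels:
        samples = groups.index[groups == label]
        if len(samples) < 2:
            raise ValueError(f"condition {label!r} has < 2 replicates")
        blocks.append(matrix.values[list(samples)].to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        fstat, pval = stats.f_oneway(*blocks, axis=1)
    degenerate = np.isnan(fstat)
    fstat = np.where(degenerate, 0.0, fstat)
    pval = np.where(degenerate, 1.0, pval)
    q = _bh(pval)
    return pd.DataFrame(
        {
            "effect": np.nan,
            "statistic": fstat,
            "p": pval,
            "q": q,
            "direction": 0,
            "heterogeneous": q < fdr,
        },
        index=matrix.gene_ids,
    )


def pairwise_regulation(
    matrix: ExpressionMatrix,
    treated_samples: Iterable[str],
    control_samples: Iterable[str],
    p_cut: float = 0.001,
    fold_cut: float = 1.5,
) -> pd.DataFrame:
    """Two-sample t-test per gene with a fold-change gate.

    A gene's direction is nonzero iff p < ``p_cut`` and the anti-logged fold
    change ``2**|effect|`` is >= ``fold_cut``; the sign of the mean log2
    difference (treated - control) gives the direction.
    """
    treated = matrix.values[list(treated_samples)].to_numpy()
    control = matrix.values[list(control_samples)].to_numpy()
    if treated.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("each group needs >= 2 replicates")
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = stats.ttest_ind(treated, control, axis=1, equal_var=True)
    degenerate = np.isnan(tstat)
    tstat = np.where(degenerate, 0.0, tstat)
    pval = np.where(degenerate, 1.0, pval)
    effect = treated.mean(axis=1) - control.mean(axis=1)
    fold = 2.0 ** np.abs(effect)
    significant = (pval < p_cut) & (fold >= fold_cut)
    direction = np.where(significant, np.sign(effect).astype(int), 0)
    return pd.DataFrame(
        {
            "effect": effect,
            "statistic": tstat,
            "p": pval,
            "q": _bh(pval),
            "direction": direction,
        },
        index=matrix.gene_ids,
    )


@dataclass
class ClusterAssignment:
    """Flat cluster labels plus the agglomerative linkage record."""

    labels: pd.Series  # gene id -> cluster label (1..k)
    linkage: np.ndarray

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hierarchical_cluster(
    matrix: ExpressionMatrix, k: int = 5, axis: str = "genes"
) -> ClusterAssignment:
    """Euclidean average-linkage clustering of genes (or sample groups).

    The dendrogram is cut into ``k`` flat clusters.  ``k`` defaults to 5,
    the number of visually distinct expression-pattern clusters in the
    four-condition design.
    """
    data = matrix.values.to_numpy()
    index = matrix.gene_ids
    if axis == "samples":
        data = data.T
        index = matrix.sample_ids
    elif axis != "genes":
        raise ValueError("axis must be 'genes' or 'samples'")
    if data.shape[0] < 2:
        raise ValueError("need >= 2 observations to cluster")
    if k > data.shape[0]:
        raise ValueError(f"k={k} exceeds the number of observations ({data.shape[0]})")
    if not np.isfinite(data).all():
        raise ValueError("non-finite values cannot be clustered")
    Z = hierarchy.linkage(data, method="average", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(pd.Series(labels, index=index), Z)


def select_unique_m3(m3_result: pd.DataFrame, m4_result: pd.DataFrame) -> set[str]:
    """Genes regulated in the M3 comparison but not in the M4 comparison."""
    m3_dir = m3_result["direction"]
    m4_dir = m4_result["direction"].reindex(m3_result.index).fillna(0)
    return set(m3_result.index[(m3_dir != 0) & (m4_dir == 0)])


def select_common(m3_result: pd.DataFrame, m4_result: pd.DataFrame) -> set[str]:
    """Genes regulated in both comparisons (the 'generic' response pool)."""
    common_index = m3_result.index.intersection(m4_result.index)
    m3_dir = m3_result.loc[common_index, "direction"]
    m4_dir = m4_result.loc[common_index, "direction"]
    return set(common_index[(m3_dir != 0) & (m4_dir != 0)])


def in_vivo_filter(
    tumor_matrix: ExpressionMatrix,
    control_samples: Iterable[str],
    blocked_samples: Iterable[str],
    fdr: float = 0.2,
) -> pd.DataFrame:
    """Direction of in vivo regulation from control vs receptor-blocked tumors.

    Two-sample t per gene with BH adjustment; for genes with q < ``fdr`` the
    direction is the sign of (control mean - blocked mean): the control
    tumors are the high-signal condition, the dominant-negative-receptor
    tumors the low-signal condition.  Other genes have direction 0 and a
    False ``passed`` flag.
    """
    control = tumor_matrix.values[list(control_samples)].to_numpy()
    blocked = tumor_matrix.values[list(blocked_samples)].to_numpy()
    if control.shape[1] < 2 or blocked.shape[1] < 2:
        raise ValueError("each genotype group needs >= 2 tumors")
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pval = stats.ttest_ind(control, blocked, axis=1, equal_var=True)
    degenerate = np.isnan(tstat)
    tstat = np.where(degenerate, 0.0, tstat)
    pval = np.where(degenerate, 1.0, pval)
    effect = control.mean(axis=1) - blocked.mean(axis=1)
    q = _bh(pval)
    passed = q < fdr
    direction = np.where(passed, np.sign(effect).astype(int), 0)
    return pd.DataFrame(
        {
            "effect": effect,
            "statistic": tstat,
            "p": pval,
            "q": q,
            "direction": direction,
            "passed": passed,
        },
        index=tumor_matrix.gene_ids,
    )


@dataclass
class DerivedSignatures:
    """The tumor-suppressor signature, its 'generic' counterpart, and the
    gene counts surviving each filter stage."""

    tstss: GeneSignature
    generic: GeneSignature
    counts: dict


def _build_signature(genes, invitro: pd.DataFrame, invivo: pd.DataFrame) -> GeneSignature:
    entries = []
    for gene in sorted(genes):
        vivo_dir = int(invivo.loc[gene, "direction"])
        vitro_dir = int(invitro.loc[gene, "direction"]) if gene in invitro.index else 0
        concordance = (
            "concordant" if vitro_dir == vivo_dir and vitro_dir != 0 else "discordant"
        )
        entries.append(
            SignatureEntry(
                gene_id=gene,
                weight=vivo_dir,
                in_vitro_direction=vitro_dir,
                in_vivo_direction=vivo_dir,
                concordance=concordance,
            )
        )
    return GeneSignature(entries)


def derive_signature(
    chip_targets: set[str],
    unique_m3: set[str],
    invitro: pd.DataFrame,
    invivo: pd.DataFrame,
    common: set[str] | None = None,
) -> DerivedSignatures:
    """Assemble the weighted signature from the three filters.

    Signature genes are ``chip_targets & unique_m3 & {in vivo q < fdr}``;
    each weight equals the in vivo direction, and concordance records the
    agreement of the in vitro and in vivo directions.  The complementary
    'generic' signature applies the identical in vivo filter to ``common``
    (genes regulated in both cell lines).  An empty result warns rather than
    raising.
    """
    passed_invivo = set(invivo.index[invivo["passed"]])
    core_genes = chip_targets & unique_m3 & passed_invivo
    if not core_genes:
        import warnings

        warnings.warn("no genes survived all filters: empty signature")
    tstss = _build_signature(core_genes, invitro, invivo)
    generic_genes = (chip_targets & (common or set())) & passed_invivo
    generic = _build_signature(generic_genes, invitro, invivo)
    counts = {
        "chip_targets": len(chip_targets),
        "unique_m3": len(unique_m3),
        "common": len(common or set()),
        "passed_invivo": len(passed_invivo),
        "tstss": len(tstss),
        "generic": len(generic),
    }
    return DerivedSignatures(tstss=tstss, generic=generic, counts=counts)
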
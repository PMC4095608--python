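"""Calling TGF-beta-dependent Smad3 binding regions (SBRs) from two-condition
tiling-probe data, plus positional annotation and characterization.

The caller tests, at every probe, the paired treated-minus-vehicle intensity
differences of all probes within +/- ``bandwidth_bp`` (one difference per
probe per replicate) with a one-sided Wilcoxon signed-rank test, adjusts the
per-probe p-values by Benjamini-Hochberg, and merges significant probes into
runs of at least ``min_run_bp`` bases allowing gaps up to ``max_gap_bp``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AnalysisConfig, GenomicInterval, TssRecord

__all__ = [
    "ProbePanel",
    "SbrCall",
    "RegionAnnotation",
    "quantile_normalize",
    "normalize_panel",
    "call_sbrs",
    "annotate_regions",
    "occupancy_overlap",
    "tss_relative_density",
]


@dataclass
class ProbePanel:
    """Tiling probes on one chromosome with replicate intensities per condition.

    ``vehicle`` and ``treated`` are (replicates x probes) arrays; probe
    positions are strictly increasing.
    """

    chrom: str
    probe_positions: np.ndarray
    vehicle: np.ndarray
    treated: np.ndarray

    def __post_init__(self) -> None:
        self.probe_positions = np.asarray(self.probe_positions, dtype=int)
        self.vehicle = np.atleast_2d(np.asarray(self.vehicle, dtype=float))
        self.treated = np.atleast_2d(np.asarray(self.treated, dtype=float))
        if np.any(np.diff(self.probe_positions) <= 0):
            raise ValueError("probe positions must be strictly increasing")
        n = len(self.probe_positions)
        if self.vehicle.shape[1] != n or self.treated.shape[1] != n:
            raise ValueError("intensity matrices must share the probe dimension")
        if self.vehicle.shape[0] < 2 or self.treated.shape[0] < 2:
            raise ValueError("need >= 2 replicates per condition")

    @property
    def n_probes(self) -> int:
        return len(self.probe_positions)


@dataclass
class SbrCall:
    """A called Smad3 binding region."""

    interval: GenomicInterval
    midpoint: int
    statistic: float
    qvalue: float
    occupancy: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return f"SBR_{self.interval.chrom}_{self.interval.start}"


def quantile_normalize(arrays: np.ndarray) -> np.ndarray:
    """Quantile-normalize arrays (rows) to a common distribution.

    Every output row has, as its sorted value vector, the per-rank mean of
    the input rows; tied entries receive the mean of their rank-means.  A
    single array is returned unchanged with a warning.
    """
    arrays = np.atleast_2d(np.asarray(arrays, dtype=float))
    n_arrays, n_values = arrays.shape
    if n_arrays == 1:
        warnings.warn("quantile normalization of a single array is the identity")
        return arrays.copy()
    rank_means = np.mean(np.sort(arrays, axis=1), axis=0)
    out = np.empty_like(arrays)
    grid = np.arange(1, n_values + 1, dtype=float)
    for i in range(n_arrays):
        ranks = stats.rankdata(arrays[i], method="average")
        out[i] = np.interp(ranks, grid, rank_means)
    return out


def normalize_panel(panel: ProbePanel) -> ProbePanel:
    """Quantile-normalize all arrays of one comparison group (both conditions)."""
    nv = panel.vehicle.shape[0]
    stacked = np.vstack([panel.vehicle, panel.treated])
    normed = quantile_normalize(stacked)
    return ProbePanel(panel.chrom, panel.probe_positions.copy(), normed[:nv], normed[nv:])


@lru_cache(maxsize=64)
def _signed_rank_sf(m: int) -> np.ndarray:
    """Exact null survival function of the signed-rank statistic W+ for m
    untied pairs: entry w is P(W+ >= w), w = 0..m(m+1)/2."""
    max_w = m * (m + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for rank in range(1, m + 1):
        shifted = np.zeros_like(counts)
        shifted[rank:] = counts[: max_w + 1 - rank]
        counts = counts + shifted
    pmf = counts / 2.0**m
    return np.cumsum(pmf[::-1])[::-1]


def signed_rank_p(diffs: np.ndarray, alternative: str = "greater") -> float:
    """One-sided Wilcoxon signed-rank p-value for paired differences.

    Exact when the nonzero |differences| are untied and m <= 40; otherwise a
    normal approximation with tie correction and continuity correction.
    Zero differences are dropped (standard convention).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 1.0
    if alternative == "less":
        d = -d
    elif alternative != "greater":
        raise ValueError("alternative must be 'greater' or 'less'")
    absd = np.abs(d)
    ranks = stats.rankdata(absd, method="average")
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < m
    if not has_ties and m <= 40:
        return float(_signed_rank_sf(m)[int(round(w_plus))])
    mean = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))


def window_pvalues(panel: ProbePanel, config: AnalysisConfig | None = None):
    """Per-probe one-sided window p-values (NaN where the window has < 5 probes).

    At each probe, the window gathers treated-minus-vehicle differences for
    every (probe, replicate) pair within +/- ``bandwidth_bp``; replicates are
    paired by index.
    """
    config = config or AnalysisConfig()
    pos = panel.probe_positions
    reps = min(panel.vehicle.shape[0], panel.treated.shape[0])
    diffs = panel.treated[:reps] - panel.vehicle[:reps]  # (reps, probes)
    bw = config.bandwidth_bp
    pvals = np.full(panel.n_probes, np.nan)
    lo = np.searchsorted(pos, pos - bw, side="left")
    hi = np.searchsorted(pos, pos + bw, side="right")
    for i in range(panel.n_probes):
        if hi[i] - lo[i] < 5:
            continue
        pvals[i] = signed_rank_p(diffs[:, lo[i] : hi[i]].ravel())
    return pvals


def call_sbrs(panel: ProbePanel, config: AnalysisConfig | None = None) -> list[SbrCall]:
    """Call binding regions from a (normalized) probe panel.

    Probes whose BH-adjusted window p-value is <= ``chip_fdr`` are merged
    into runs: consecutive significant probes at most ``max_gap_bp`` apart,
    reported only if the run spans >= ``min_run_bp`` bases.  Each call
    carries the mean treated-minus-vehicle difference over its probes as the
    statistic and the minimum q-value in the run.
    """
    config = config or AnalysisConfig()
    pvals = window_pvalues(panel, config)
    tested = ~np.isnan(pvals)
    qvals = np.full_like(pvals, np.nan)
    if tested.sum() == 0:
        return []
    qvals[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    significant = np.zeros(panel.n_probes, dtype=bool)
    significant[tested] = qvals[tested] <= config.chip_fdr
    if not significant.any():
        return []
    pos = panel.probe_positions
    reps = min(panel.vehicle.shape[0], panel.treated.shape[0])
    probe_diff = (panel.treated[:reps] - panel.vehicle[:reps]).mean(axis=0)
    sig_idx = np.flatnonzero(significant)
    runs = np.split(sig_idx, np.flatnonzero(np.diff(pos[sig_idx]) > config.max_gap_bp) + 1)
    calls = []
    for run in runs:
        start, end = int(pos[run[0]]), int(pos[run[-1]]) + 1
        if end - start < config.min_run_bp:
            continue
        interval = GenomicInterval(panel.chrom, start, end)
        calls.append(
            SbrCall(
                interval=interval,
                midpoint=interval.midpoint,
                statistic=float(probe_diff[run].mean()),
                qvalue=float(np.nanmin(qvals[run])),
            )
        )
    return calls


@dataclass
class RegionAnnotation:
    """Gene assignment of one binding-region call."""

    call: SbrCall
    gene: str | None  # nearest-TSS gene within the distance cap, else None
    distance: int | None
    genes_within: list[str] = field(default_factory=list)  # all genes in range


def annotate_regions(
    calls, tss_records, config: AnalysisConfig | None = None
) -> list[RegionAnnotation]:
    """Assign each call the gene with the smallest |TSS - midpoint|.

    Assignment requires the minimum distance to be <= ``tss_max_distance_bp``
    (10 kb by default); all genes within the cap are also reported.
    Equidistant TSS tie-break: lexicographically smallest gene id is primary,
    all tied genes appear in ``genes_within``.
    """
    config = config or AnalysisConfig()
    tss_by_chrom: dict[str, list[TssRecord]] = {}
    for rec in tss_records:
        tss_by_chrom.setdefault(rec.interval.chrom, []).append(rec)
    if not tss_records:
        warnings.warn("empty TSS table: all calls unassigned")
    annotations = []
    for call in calls:
        candidates = tss_by_chrom.get(call.interval.chrom, [])
        in_range = [
            (abs(rec.position - call.midpoint), rec.gene_id)
            for rec in candidates
            if abs(rec.position - call.midpoint) <= config.tss_max_distance_bp
        ]
        if not in_range:
            annotations.append(RegionAnnotation(call, None, None, []))
            continue
        in_range.sort()
        best_dist = in_range[0][0]
        tied = sorted(g for d, g in in_range if d == best_dist)
        annotations.append(
            RegionAnnotation(call, tied[0], best_dist, [g for _, g in in_range])
        )
    return annotations


def occupancy_overlap(per_line_genes: dict) -> dict[frozenset, int]:
    """Exact-subset gene counts across cell lines (petal-plot counts).

    For every non-empty subset of lines, the number of genes occupied in
    exactly those lines.  The counts partition the union of all gene sets.
    """
    if len(per_line_genes) < 2:
        raise ValueError("need >= 2 cell lines")
    union = set().union(*per_line_genes.values())
    counts: dict[frozenset, int] = {}
    for gene in union:
        subset = frozenset(line for line, genes in per_line_genes.items() if gene in genes)
        counts[subset] = counts.get(subset, 0) + 1
    return counts


def common_to_all_fraction(counts: dict[frozenset, int]) -> float:
    """Share of the union occupied in every line, from exact-subset counts."""
    union = sum(counts.values())
    if union == 0:
        raise ValueError("empty occupancy table")
    all_lines = frozenset().union(*counts.keys())
    return counts.get(all_lines, 0) / union


def validation_discordance_summary(
    n_positive: int,
    n_positive_confirmed: int,
    n_negative: int,
    n_negative_with_binding: int,
) -> dict:
    """Concordance bookkeeping for array calls validated by an independent assay.

    Array-positive regions not confirmed are false positives; array-negative
    regions where the assay finds binding are false negatives.  Reports the
    share of discordant calls that are false negatives and the overall
    discordance rate among the validated regions.
    """
    if not 0 <= n_positive_confirmed <= n_positive:
        raise ValueError("confirmed count must be within the positive count")
    if not 0 <= n_negative_with_binding <= n_negative:
        raise ValueError("binding count must be within the negative count")
    false_positives = n_positive - n_positive_confirmed
    false_negatives = n_negative_with_binding
    discordant = false_positives + false_negatives
    total = n_positive + n_negative
    return {
        "false_positives": false_positives,
        "false_negatives": false_negatives,
        "discordant": discordant,
        "false_negative_fraction": false_negatives / discordant if discordant else 0.0,
        "discordance_rate": discordant / total if total else 0.0,
    }


@dataclass
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    distances: np.ndarray

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def tss_relative_density(
    annotations,
    tss_records,
    window: tuple[int, int] = (-7500, 2500),
    grid_points: int = 1001,
) -> DensityEstimate:
    """Gaussian-kernel density of signed midpoint-to-TSS distances.

    Distances are strand-aware (negative = upstream of the assigned gene's
    TSS) and restricted to ``window``; the density is renormalized to
    integrate to 1 over the window.  Requires annotated calls with a gene
    assignment; raises if fewer than 2 distances remain.
    """
    distances = signed_tss_distances(annotations, tss_records)
    return density_from_distances(distances, window, grid_points)


def density_from_distances(distances, window=(-7500, 2500), grid_points=1001):
    """KDE over precomputed signed distances (normal-reference bandwidth)."""
    d = np.asarray(distances, dtype=float)
    d = d[(d >= window[0]) & (d <= window[1])]
    return _density_from_distances(d, window, grid_points)


def _density_from_distances(d, window, grid_points) -> DensityEstimate:
    if d.size < 2:
        raise ValueError("need >= 2 distances for a density estimate")
    grid = np.linspace(window[0], window[1], grid_points)
    if np.ptp(d) == 0:
        # all mass at one point: a narrow Gaussian at the common value
        kde_vals = stats.norm.pdf(grid, loc=d[0], scale=max(1.0, abs(d[0]) * 1e-3))
    else:
        kde = stats.gaussian_kde(d)  # Scott's (normal-reference) bandwidth
        kde_vals = kde(grid)
    area = np.trapezoid(kde_vals, grid)
    return DensityEstimate(grid, kde_vals / area, d)


def signed_tss_distances(annotations, tss_records) -> np.ndarray:
    """Signed distance of each assigned call to its gene's TSS.

    Negative = upstream relative to the gene's strand: for a + strand gene
    the distance is midpoint - TSS, for a - strand gene TSS - midpoint.
    """
    tss_map = {rec.gene_id: rec for rec in tss_records}
    out = []
    for ann in annotations:
        if ann.gene is None:
            continue
        rec = tss_map[ann.gene]
        raw = ann.call.midpoint - rec.position
        out.append(raw if rec.strand == "+" else -raw)
    return np.asarray(out, dtype=float)
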
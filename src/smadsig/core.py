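"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere (BED convention), both in memory
and on disk.  Interval midpoints are ``floor((start + end) / 2)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TssRecord",
    "ExpressionMatrix",
    "SurvivalCohort",
    "SignatureEntry",
    "GeneSignature",
    "AnalysisConfig",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not isinstance(self.start, (int, np.integer)) or not isinstance(
            self.end, (int, np.integer)
        ):
            raise TypeError(
                f"interval coordinates must be integers, got "
                f"({self.start!r}, {self.end!r})"
            )
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: a 1-bp anchor interval plus strand."""

    gene_id: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.interval.end != self.interval.start + 1:
            raise ValueError(
                f"TSS anchor for {self.gene_id} must be a 1-bp interval, got "
                f"{self.interval.start}-{self.interval.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be '+' or '-', got {self.strand!r}")

    @property
    def position(self) -> int:
        return self.interval.start


class ExpressionMatrix:
    """log2 expression values, genes x samples, with sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.  All values
        must be finite; gene and sample ids must be unique.
    sample_annotations
        Optional DataFrame indexed by sample id (e.g. columns ``cell_line``,
        ``treatment``, ``genotype``, ``cohort``).  Only samples present in
        ``values`` are kept.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        sample_annotations: pd.DataFrame | None = None,
    ) -> None:
        values = pd.DataFrame(values)
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if values.columns.duplicated().any():
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            bad = values.index[~np.isfinite(arr).all(axis=1)].tolist()[:5]
            raise ValueError(f"non-finite expression values (genes {bad} ...)")
        self.values = values.astype(float)
        if sample_annotations is not None:
            sample_annotations = pd.DataFrame(sample_annotations)
            sample_annotations = sample_annotations.loc[
                [s for s in self.sample_ids if s in sample_annotations.index]
            ]
        self.sample_annotations = sample_annotations

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def restrict_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[keep], self.sample_annotations)

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids whose annotation matches every ``column=value`` pair."""
        if self.sample_annotations is None:
            raise ValueError("matrix has no sample annotations")
        mask = pd.Series(True, index=self.sample_annotations.index)
        for col, val in conditions.items():
            mask &= self.sample_annotations[col] == val
        return list(self.sample_annotations.index[mask])

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.sample_annotations)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


ER_STATES = ("ER+", "ER-", "unknown")


class SurvivalCohort:
    """Per-sample time-to-event data with ER stratum and clinical covariates.

    ``data`` is indexed by sample id with at least columns ``time`` (months,
    >= 0), ``event`` (0/1) and ``er_status`` (one of ``ER+``, ``ER-``,
    ``unknown``); any further columns are clinical covariates.  ``expression``
    optionally links samples to columns of an :class:`ExpressionMatrix`.
    """

    def __init__(
        self, data: pd.DataFrame, expression: ExpressionMatrix | None = None
    ) -> None:
        data = pd.DataFrame(data).copy()
        for col in ("time", "event"):
            if col not in data.columns:
                raise ValueError(f"survival table lacks required column {col!r}")
        if data.index.duplicated().any():
            raise ValueError("duplicate sample ids in survival table")
        if (data["time"] < 0).any():
            bad = data.index[data["time"] < 0].tolist()
            raise ValueError(f"negative survival time for samples {bad}")
        if not data["event"].isin([0, 1]).all():
            bad = data.index[~data["event"].isin([0, 1])].tolist()
            raise ValueError(f"event flag not in {{0,1}} for samples {bad}")
        if "er_status" not in data.columns:
            data["er_status"] = "unknown"
        data["er_status"] = data["er_status"].fillna("unknown")
        bad = ~data["er_status"].isin(ER_STATES)
        if bad.any():
            raise ValueError(
                f"unrecognized er_status values: {sorted(data.loc[bad, 'er_status'].unique())}"
            )
        data["event"] = data["event"].astype(int)
        data["time"] = data["time"].astype(float)
        self.data = data
        self.expression = expression

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def samples_missing_expression(self) -> list[str]:
        if self.expression is None:
            return list(self.data.index)
        have = set(self.expression.sample_ids)
        return [s for s in self.data.index if s not in have]

    def subset(self, samples) -> "SurvivalCohort":
        return SurvivalCohort(self.data.loc[list(samples)], self.expression)

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SurvivalCohort({len(self)} samples, {self.n_events} events)"


@dataclass(frozen=True)
class SignatureEntry:
    gene_id: str
    weight: int
    in_vitro_direction: int = 0
    in_vivo_direction: int | None = None
    concordance: str | None = None

    def __post_init__(self) -> None:
        if self.weight not in (-1, 1):
            raise ValueError(
                f"signature weight for {self.gene_id} must be -1 or +1, got {self.weight!r}"
            )
        if self.in_vitro_direction not in (-1, 0, 1):
            raise ValueError("in_vitro_direction must be in {-1, 0, +1}")
        if self.in_vivo_direction is not None and self.in_vivo_direction not in (-1, 1):
            raise ValueError("in_vivo_direction must be -1 or +1")


class GeneSignature:
    """An ordered list of (gene, +/-1 weight) entries with provenance labels.

    The canonical weighting follows the in vivo direction of regulation; a
    gene is *concordant* when its in vitro and in vivo directions agree (and
    the in vitro direction is nonzero), *discordant* otherwise.
    """

    def __init__(self, entries) -> None:
        entries = list(entries)
        seen = set()
        for e in entries:
            if e.gene_id in seen:
                raise ValueError(f"duplicate gene in signature: {e.gene_id}")
            seen.add(e.gene_id)
        self.entries = entries

    @classmethod
    def from_weights(cls, weights: Mapping[str, int]) -> "GeneSignature":
        return cls(SignatureEntry(g, int(w)) for g, w in weights.items())

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    @property
    def weights(self) -> pd.Series:
        return pd.Series(
            [e.weight for e in self.entries], index=self.gene_ids, dtype=int
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneSignature) and self.entries == other.entries

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneSignature({len(self)} genes)"


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the pipeline, with defaults used throughout.

    ``chip_fdr``
        BH false-discovery rate for calling occupied probes (0.15).
    ``window_bp`` / ``bandwidth_bp``
        Sliding-window size for the tiling statistic; probes within
        +/- ``bandwidth_bp`` of a center probe form its window (200 / 100).
    ``min_run_bp`` / ``max_gap_bp``
        Minimum run of significant probes and maximum intra-run gap when
        merging probes into binding regions (200 / 100).
    ``invitro_anova_fdr``
        FDR for the four-condition in vitro ANOVA (0.05).
    ``invitro_p`` / ``invitro_fold``
        Per-comparison significance and fold-change gates for pairwise in
        vitro regulation calls (0.001 / 1.5, fold on the anti-logged scale).
    ``invivo_fdr``
        FDR for the control-vs-receptor-blocked tumor filter (0.2).
    ``tss_max_distance_bp``
        Maximum |TSS - region midpoint| for gene assignment (10 kb).
    """

    chip_fdr: float = 0.15
    window_bp: int = 200
    bandwidth_bp: int = 100
    min_run_bp: int = 200
    max_gap_bp: int = 100
    invitro_anova_fdr: float = 0.05
    invitro_p: float = 0.001
    invitro_fold: float = 1.5
    invivo_fdr: float = 0.2
    tss_max_distance_bp: int = 10_000
    seed: int = 0
    score_mode: str = "weighted_sum"

    def __post_init__(self) -> None:
        for name in ("chip_fdr", "invitro_anova_fdr", "invitro_p", "invivo_fdr"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("window_bp", "bandwidth_bp", "min_run_bp", "max_gap_bp",
                     "tss_max_distance_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.invitro_fold < 1:
            raise ValueError("invitro_fold must be >= 1 (anti-logged scale)")
        if self.score_mode not in ("weighted_sum", "weighted_mean"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        return cls(**dict(d))
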
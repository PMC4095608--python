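"""Synthetic data generators with planted ground truth.

Every generator is a pure function of its parameters and a seed, and its
defaults mirror the study design the pipeline targets: tiling probes at
35-bp spacing with quadruplicate/duplicate ChIP replicates, a four-condition
(two cell lines x +/- TGF-beta) expression design with three biological
replicates, six tumors per genotype for the in vivo comparison, a 36-tissue
normal reference panel, and survival cohorts whose hazard depends on a
planted signature score with an ER-restricted effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ExpressionMatrix, GeneSignature, GenomicInterval, SurvivalCohort
from .motifs import IUPAC
from .peaks import ProbePanel
from .scoring import signature_score

__all__ = [
    "PlantedTruth",
    "simulate_tiling_experiment",
    "simulate_expression_design",
    "simulate_tumor_expression",
    "simulate_reference_panel",
    "simulate_cohort_expression",
    "simulate_survival_cohort",
    "simulate_promoter_sequences",
]

GENE_CLASSES = ("unique_M3", "common_M3_M4", "null")
CONDITIONS = ("M3_vehicle", "M3_tgfb", "M4_vehicle", "M4_tgfb")


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators, consumed by recovery tests."""

    sbr_intervals: list = field(default_factory=list)  # (GenomicInterval, log2 shift)
    gene_classes: dict = field(default_factory=dict)  # gene -> class label
    in_vitro_direction: dict = field(default_factory=dict)  # gene -> -1/+1
    invivo_direction: dict = field(default_factory=dict)  # gene -> -1/+1
    concordance: dict = field(default_factory=dict)  # gene -> concordant/discordant
    cohort_beta: float | None = None  # log hazard ratio per unit signature score
    er_effect_only: bool | None = None
    motif_plants: dict = field(default_factory=dict)  # region id -> [(motif, offset)]

    def genes_of_class(self, label: str) -> set[str]:
        return {g for g, c in self.gene_classes.items() if c == label}


def simulate_tiling_experiment(
    n_probes: int,
    probe_spacing_bp: int = 35,
    replicates_per_condition: int = 4,
    planted=(),
    noise_sd: float = 0.3,
    baseline: float = 8.0,
    chrom: str = "chr1",
    origin: int = 0,
    seed: int = 0,
) -> tuple[ProbePanel, PlantedTruth]:
    """Two-condition tiling-probe intensities with planted enriched intervals.

    Vehicle intensities are i.i.d. Normal(baseline, noise_sd) per probe and
    replicate; treated intensities add each planted interval's log2 shift at
    the probes it covers.  Deterministic under a fixed seed.
    """
    if probe_spacing_bp <= 0:
        raise ValueError("probe spacing must be positive")
    if replicates_per_condition < 2:
        raise ValueError("need >= 2 replicates per condition")
    positions = origin + probe_spacing_bp * np.arange(n_probes)
    span = GenomicInterval(chrom, int(positions[0]), int(positions[-1]) + 1)
    shift = np.zeros(n_probes)
    planted = list(planted)
    for interval, s in planted:
        if s < 0:
            raise ValueError("planted shifts must be >= 0")
        if interval.chrom != chrom or interval.start < span.start or interval.end > span.end:
            raise ValueError(
                f"planted interval {interval} outside the probe span "
                f"{span.chrom}:{span.start}-{span.end}"
            )
        covered = (positions >= interval.start) & (positions < interval.end)
        shift[covered] += s
    rng = np.random.default_rng(seed)
    vehicle = rng.normal(baseline, noise_sd, size=(replicates_per_condition, n_probes))
    treated = rng.normal(
        baseline + shift, noise_sd, size=(replicates_per_condition, n_probes)
    )
    panel = ProbePanel(chrom, positions, vehicle, treated)
    return panel, PlantedTruth(sbr_intervals=planted)


def _assign_directions(rng, genes, discordant_fraction):
    vitro = {g: int(rng.choice([-1, 1])) for g in genes}
    flip = {g: rng.random() < discordant_fraction for g in genes}
    vivo = {g: -vitro[g] if flip[g] else vitro[g] for g in genes}
    conc = {g: "discordant" if flip[g] else "concordant" for g in genes}
    return vitro, vivo, conc


def simulate_expression_design(
    n_genes: int = 1000,
    n_replicates: int = 3,
    class_fractions: dict | None = None,
    effect_log2: float = 2.0,
    noise_sd: float = 0.15,
    discordant_fraction: float = 0.25,
    baseline: float = 7.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Four-condition (M3/M4 x +/- TGF-beta) in vitro expression design.

    ``unique_M3`` genes shift (by their in vitro direction x ``effect_log2``)
    only in the M3 treated condition; ``common_M3_M4`` genes shift in both
    treated conditions; the remainder are null.  About a quarter of regulated
    genes are planted with an opposite in vivo direction (discordant), the
    share of direction flips seen between culture and tumors.
    """
    fractions = dict(class_fractions or {"unique_M3": 0.05, "common_M3_M4": 0.05})
    unknown = set(fractions) - {"unique_M3", "common_M3_M4"}
    if unknown:
        raise ValueError(f"unknown gene classes: {sorted(unknown)}")
    total = sum(fractions.values())
    if total > 1:
        raise ValueError("class fractions must sum to <= 1")
    positive = [f for f in fractions.values() if f > 0]
    if positive and n_genes * min(positive) < 1:
        raise ValueError("n_genes too small for the smallest class fraction")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_unique = int(round(fractions.get("unique_M3", 0) * n_genes))
    n_common = int(round(fractions.get("common_M3_M4", 0) * n_genes))
    classes = {}
    for i, g in enumerate(genes):
        if i < n_unique:
            classes[g] = "unique_M3"
        elif i < n_unique + n_common:
            classes[g] = "common_M3_M4"
        else:
            classes[g] = "null"
    regulated = [g for g in genes if classes[g] != "null"]
    vitro, vivo, conc = _assign_directions(rng, regulated, discordant_fraction)

    samples, annot = [], []
    for cond in CONDITIONS:
        cell_line, treatment = cond.split("_")
        for r in range(1, n_replicates + 1):
            samples.append(f"{cond}_{r}")
            annot.append({"cell_line": cell_line, "treatment": treatment})
    mean = np.full((n_genes, len(samples)), baseline)
    for gi, g in enumerate(genes):
        if classes[g] == "null":
            continue
        delta = vitro[g] * effect_log2
        for si, s in enumerate(samples):
            if s.startswith("M3_tgfb") or (
                classes[g] == "common_M3_M4" and s.startswith("M4_tgfb")
            ):
                mean[gi, si] += delta
    values = mean + rng.normal(0.0, noise_sd, size=mean.shape)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.DataFrame(annot, index=samples),
    )
    truth = PlantedTruth(
        gene_classes=classes,
        in_vitro_direction=vitro,
        invivo_direction=vivo,
        concordance=conc,
    )
    return matrix, truth


def simulate_tumor_expression(
    truth: PlantedTruth,
    n_tumors_per_genotype: int = 6,
    effect_log2: float = 1.5,
    noise_sd: float = 0.5,
    baseline: float = 7.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Control vs receptor-blocked tumor expression honoring the planted
    in vivo directions.

    For each regulated gene, (control mean - blocked mean) equals the
    planted in vivo direction times ``effect_log2``; discordant genes
    thereby flip sign relative to their in vitro regulation.
    """
    if not truth.invivo_direction:
        raise ValueError("truth carries no in vivo directions")
    if n_tumors_per_genotype < 2:
        raise ValueError("need >= 2 tumors per genotype")
    rng = np.random.default_rng(seed)
    genes = sorted(truth.gene_classes) if truth.gene_classes else sorted(truth.invivo_direction)
    samples = [f"CON_{i}" for i in range(1, n_tumors_per_genotype + 1)] + [
        f"DNR_{i}" for i in range(1, n_tumors_per_genotype + 1)
    ]
    annot = pd.DataFrame(
        {"genotype": ["control"] * n_tumors_per_genotype + ["blocked"] * n_tumors_per_genotype},
        index=samples,
    )
    mean = np.full((len(genes), len(samples)), baseline)
    for gi, g in enumerate(genes):
        direction = truth.invivo_direction.get(g)
        if direction is None:
            continue
        mean[gi, :n_tumors_per_genotype] += direction * effect_log2 / 2.0
        mean[gi, n_tumors_per_genotype:] -= direction * effect_log2 / 2.0
    values = mean + rng.normal(0.0, noise_sd, size=mean.shape)
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), annot)


def simulate_reference_panel(
    n_genes: int = 200,
    n_tissues: int = 36,
    anchor_gene: str = "PCNA",
    rho_profile: dict | None = None,
    baseline: float = 7.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Multi-tissue reference panel with controlled anchor-gene correlations.

    Genes named in ``rho_profile`` target the given Pearson correlation with
    the anchor (|rho| < 1 strictly); all other genes are independent noise.
    """
    rho_profile = dict(rho_profile or {})
    for g, rho in rho_profile.items():
        if abs(rho) >= 1:
            raise ValueError(f"|rho| must be < 1, got {rho} for {g}")
    if anchor_gene in rho_profile:
        raise ValueError("the anchor gene cannot appear in rho_profile")
    rng = np.random.default_rng(seed)
    named = list(rho_profile)
    n_filler = n_genes - 1 - len(named)
    if n_filler < 0:
        raise ValueError("n_genes too small for the rho profile")
    genes = [anchor_gene] + named + [f"R{i:05d}" for i in range(n_filler)]
    anchor_z = rng.standard_normal(n_tissues)
    values = np.empty((len(genes), n_tissues))
    values[0] = anchor_z
    for gi, g in enumerate(genes[1:], start=1):
        rho = rho_profile.get(g, 0.0)
        noise = rng.standard_normal(n_tissues)
        values[gi] = rho * anchor_z + np.sqrt(1.0 - rho**2) * noise
    tissues = [f"tissue_{i:02d}" for i in range(1, n_tissues + 1)]
    return ExpressionMatrix(pd.DataFrame(values + baseline, index=genes, columns=tissues))


def simulate_cohort_expression(
    genes,
    n_samples: int,
    baseline: float = 8.0,
    noise_sd: float = 1.0,
    prefix: str = "P",
    seed: int = 0,
) -> ExpressionMatrix:
    """I.i.d. Gaussian log2 expression for a patient cohort (helper for
    survival simulations)."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    samples = [f"{prefix}{i:04d}" for i in range(1, n_samples + 1)]
    values = rng.normal(baseline, noise_sd, size=(len(genes), n_samples))
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def simulate_survival_cohort(
    expression: ExpressionMatrix,
    signature: GeneSignature,
    beta: float,
    er_fraction: float = 0.7,
    er_effect_only: bool = True,
    baseline_hazard: float = 0.01,
    censor_rate: float = 0.008,
    covariate_spec: dict | None = None,
    score_mode: str = "weighted_sum",
    seed: int = 0,
) -> SurvivalCohort:
    """Survival cohort whose hazard depends on the planted signature score.

    Event times are exponential with hazard ``baseline_hazard * exp(beta *
    centered score)`` in the affected stratum (ER+ when ``er_effect_only``,
    everyone otherwise) and ``baseline_hazard`` elsewhere; censoring is an
    independent exponential with rate ``censor_rate``.
    """
    if censor_rate <= 0:
        raise ValueError("censor_rate must be positive")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    missing = [g for g in signature.gene_ids if g not in expression.values.index]
    if missing:
        raise ValueError(f"signature gene(s) absent from expression: {missing}")
    rng = np.random.default_rng(seed)
    n = len(expression.sample_ids)
    score = signature_score(expression, signature, mode=score_mode).scores.to_numpy()
    score = score - score.mean()
    er = np.where(rng.random(n) < er_fraction, "ER+", "ER-")
    affected = (er == "ER+") if er_effect_only else np.ones(n, dtype=bool)
    hazard = np.where(affected, baseline_hazard * np.exp(beta * score), baseline_hazard)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(1.0 / censor_rate, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    data = pd.DataFrame(
        {"time": time, "event": event, "er_status": er}, index=expression.sample_ids
    )
    for name, spec in (covariate_spec or {}).items():
        kind = spec[0]
        if kind == "normal":
            data[name] = rng.normal(spec[1], spec[2], size=n)
        elif kind == "binary":
            data[name] = rng.binomial(1, spec[1], size=n)
        else:
            raise ValueError(f"unknown covariate kind {kind!r}")
    cohort = SurvivalCohort(data, expression)
    return cohort


def _concrete_instance(rng, consensus: str) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in consensus.upper())


def simulate_promoter_sequences(
    n_regions: int,
    length_bp: int = 2000,
    motif_plant_spec: dict | None = None,
    bin_bp: int = 100,
    seed: int = 0,
) -> tuple[list[SeqRecord], PlantedTruth]:
    """Random promoter sequences with motifs planted into chosen bins.

    ``motif_plant_spec`` maps an IUPAC consensus to ``(bin indices, plant
    probability)``; bins index ``bin_bp`` windows from the sequence start.
    Background is i.i.d. uniform ACGT; planted instances are concrete
    resolutions of the consensus, inserted without overlapping each other.
    """
    if length_bp % 2:
        raise ValueError("length_bp must be even (sequences center on a midpoint)")
    spec = dict(motif_plant_spec or {})
    n_bins = length_bp // bin_bp
    for consensus, (bins, prob) in spec.items():
        if len(consensus) > bin_bp:
            raise ValueError(f"motif {consensus} longer than a {bin_bp}-bp bin")
        if not 0 <= prob <= 1:
            raise ValueError("plant probability must be in [0, 1]")
        for b in bins:
            if not 0 <= b < n_bins:
                raise ValueError(f"bin {b} outside the sequence ({n_bins} bins)")
    rng = np.random.default_rng(seed)
    records = []
    plants: dict[str, list] = {}
    for i in range(n_regions):
        seq = rng.choice(list("ACGT"), size=length_bp)
        occupied: list[tuple[int, int]] = []
        region_id = f"region_{i:04d}"
        plants[region_id] = []
        for consensus, (bins, prob) in spec.items():
            w = len(consensus)
            for b in bins:
                if rng.random() >= prob:
                    continue
                for _attempt in range(50):
                    offset = int(rng.integers(b * bin_bp, (b + 1) * bin_bp - w + 1))
                    if all(offset + w <= s or offset >= e for s, e in occupied):
                        break
                else:  # pragma: no cover - pathological density
                    continue
                instance = _concrete_instance(rng, consensus)
                seq[offset : offset + w] = list(instance)
                occupied.append((offset, offset + w))
                plants[region_id].append((consensus, offset))
        records.append(SeqRecord(Seq("".join(seq)), id=region_id, description=""))
    return records, PlantedTruth(motif_plants=plants)
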
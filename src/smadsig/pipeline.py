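"""End-to-end orchestration of the synthetic demonstration pipeline.

``run_pipeline`` wires the stages together on generated data: simulate the
tiling and expression experiments, call binding regions, derive the weighted
signature, score a patient cohort, run the survival analysis, and validate
the signature by weight-vector permutation.  Every run emits one manifest
recording the configuration, seed, file digests and per-stage row counts;
identical config + seed reproduces byte-identical outputs (timestamps are
deliberately absent).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io
from .core import AnalysisConfig, GeneSignature, GenomicInterval, SignatureEntry, TssRecord
from .peaks import annotate_regions, call_sbrs, normalize_panel
from .permutation import exhaustive_weight_scan
from .scoring import dichotomize_median, signature_score
from .signature import (
    anova_four_condition,
    derive_signature,
    in_vivo_filter,
    pairwise_regulation,
    select_common,
    select_unique_m3,
)
from .simulate import (
    simulate_cohort_expression,
    simulate_expression_design,
    simulate_survival_cohort,
    simulate_tiling_experiment,
    simulate_tumor_expression,
)
from .survival import cox_fit, logrank_test

STAGES = ("simulate", "callpeaks", "derive", "score", "survival", "permute")

__all__ = ["STAGES", "RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    version: str
    stages: list = field(default_factory=list)
    row_counts: dict = field(default_factory=dict)
    file_digests: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: AnalysisConfig,
    stages=STAGES,
    outdir="smadsig_run",
    n_genes: int = 120,
    gene_spacing_bp: int = 3000,
    cohort_size: int = 300,
    cohort_beta: float = np.log(1.85),
    permute_k_max: int = 12,
) -> RunManifest:
    """Run the synthetic demonstration pipeline.

    ``stages`` must be a prefix of the dependency order ``STAGES``.  The
    demo plants binding regions at the promoters of the regulated genes,
    derives the signature through the full filter cascade, and evaluates it
    on a simulated cohort whose hazard follows the planted truth.
    """
    stages = list(stages)
    if stages != list(STAGES[: len(stages)]):
        expected = STAGES[: len(stages)]
        raise ValueError(
            f"stages must form a prefix of {STAGES}; got {stages} "
            f"(missing upstream stage(s) of {stages[-1]!r}: expected {list(expected)})"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed, version=__version__)
    seed = config.seed
    ctx: dict = {}

    def emit(path: Path):
        manifest.outputs.append(str(path.name))
        manifest.file_digests[path.name] = _sha256(path)

    for stage in stages:
        manifest.stages.append(stage)
        if stage == "simulate":
            invitro, truth = simulate_expression_design(
                n_genes=n_genes,
                class_fractions={"unique_M3": 0.1, "common_M3_M4": 0.1},
                seed=seed,
            )
            tumors = simulate_tumor_expression(truth, seed=seed + 1)
            regulated = sorted(g for g, c in truth.gene_classes.items() if c != "null")
            rng = np.random.default_rng(seed + 2)
            nulls = sorted(truth.genes_of_class("null"))
            decoys = sorted(rng.choice(nulls, size=min(10, len(nulls)), replace=False))
            chip_genes = regulated + decoys
            genes = sorted(truth.gene_classes)
            tss = [
                TssRecord(
                    g,
                    GenomicInterval("chr1", 500 + i * gene_spacing_bp, 501 + i * gene_spacing_bp, "+"),
                    "+",
                )
                for i, g in enumerate(genes)
            ]
            tss_pos = {t.gene_id: t.position for t in tss}
            planted = [
                (GenomicInterval("chr1", tss_pos[g] - 200, tss_pos[g] + 200), 2.0)
                for g in chip_genes
            ]
            n_probes = (len(genes) * gene_spacing_bp) // 35
            panel, _ = simulate_tiling_experiment(
                n_probes=n_probes, planted=planted, seed=seed + 3
            )
            ctx.update(invitro=invitro, truth=truth, tumors=tumors, panel=panel, tss=tss)
            io.write_expression_table(
                invitro, outdir / "invitro_expression.tsv", outdir / "invitro_annotations.tsv"
            )
            io.write_expression_table(
                tumors, outdir / "tumor_expression.tsv", outdir / "tumor_annotations.tsv"
            )
            io.write_tss_table(tss, outdir / "tss.tsv")
            for name in (
                "invitro_expression.tsv", "invitro_annotations.tsv",
                "tumor_expression.tsv", "tumor_annotations.tsv", "tss.tsv",
            ):
                emit(outdir / name)
            manifest.row_counts["simulate_genes"] = n_genes
            manifest.row_counts["simulate_planted_regions"] = len(planted)
        elif stage == "callpeaks":
            _require(ctx, "panel", stage)
            calls = call_sbrs(normalize_panel(ctx["panel"]), config)
            annotations = annotate_regions(calls, ctx["tss"], config)
            ctx["chip_targets"] = {a.gene for a in annotations if a.gene is not None}
            io.write_regions_bed(calls, outdir / "sbr_calls.bed")
            emit(outdir / "sbr_calls.bed")
            manifest.row_counts["sbr_calls"] = len(calls)
            manifest.row_counts["chip_target_genes"] = len(ctx["chip_targets"])
        elif stage == "derive":
            _require(ctx, "invitro", stage)
            invitro, tumors = ctx["invitro"], ctx["tumors"]
            ann = invitro.sample_annotations
            groups = ann["cell_line"] + "_" + ann["treatment"]
            anova = anova_four_condition(invitro, groups, fdr=config.invitro_anova_fdr)
            flagged = invitro.restrict_genes(anova.index[anova["heterogeneous"]])
            m3 = pairwise_regulation(
                flagged,
                flagged.samples_where(cell_line="M3", treatment="tgfb"),
                flagged.samples_where(cell_line="M3", treatment="vehicle"),
                p_cut=config.invitro_p,
                fold_cut=config.invitro_fold,
            )
            m4 = pairwise_regulation(
                flagged,
                flagged.samples_where(cell_line="M4", treatment="tgfb"),
                flagged.samples_where(cell_line="M4", treatment="vehicle"),
                p_cut=config.invitro_p,
                fold_cut=config.invitro_fold,
            )
            unique_m3 = select_unique_m3(m3, m4)
            common = select_common(m3, m4)
            invivo = in_vivo_filter(
                tumors,
                tumors.samples_where(genotype="control"),
                tumors.samples_where(genotype="blocked"),
                fdr=config.invivo_fdr,
            )
            derived = derive_signature(
                ctx.get("chip_targets", set(invitro.gene_ids)),
                unique_m3, m3, invivo, common=common,
            )
            ctx["signature"] = derived.tstss
            io.write_signature_file(derived.tstss, outdir / "signature.tsv")
            io.write_signature_file(derived.generic, outdir / "generic_signature.tsv")
            emit(outdir / "signature.tsv")
            emit(outdir / "generic_signature.tsv")
            manifest.row_counts.update(
                {f"derive_{k}": v for k, v in derived.counts.items()}
            )
        elif stage == "score":
            _require(ctx, "signature", stage)
            if len(ctx["signature"]) == 0:
                raise RuntimeError("derived signature is empty; cannot score")
            cohort_expr = simulate_cohort_expression(
                ctx["invitro"].gene_ids, cohort_size, seed=seed + 4
            )
            scores = signature_score(cohort_expr, ctx["signature"], mode=config.score_mode)
            ctx.update(cohort_expr=cohort_expr, scores=scores)
            scores.scores.rename("score").to_frame().to_csv(
                outdir / "scores.tsv", sep="\t", index_label="sample"
            )
            emit(outdir / "scores.tsv")
            manifest.row_counts["scored_samples"] = len(scores.scores)
            manifest.row_counts["score_genes_used"] = scores.genes_used
        elif stage == "survival":
            _require(ctx, "scores", stage)
            truth_sig = _truth_signature(ctx["truth"])
            cohort = simulate_survival_cohort(
                ctx["cohort_expr"], truth_sig, beta=cohort_beta,
                er_effect_only=True, seed=seed + 5,
            )
            ctx["cohort"] = cohort
            labels = dichotomize_median(ctx["scores"])
            lr = logrank_test(cohort.data["time"], cohort.data["event"], labels.to_numpy())
            high = (labels == "High").astype(float)
            cox = cox_fit(
                cohort.data["time"], cohort.data["event"],
                high.rename("signature_high").to_frame(),
            )
            io.write_survival_table(cohort, outdir / "survival.tsv")
            result = {
                "logrank_chi_square": lr.chi_square,
                "logrank_p": lr.p,
                "cox_hazard_ratio": cox.hazard_ratio("signature_high"),
                "cox_ci": list(cox.ci("signature_high")),
                "n": cox.n,
                "n_events": cox.n_events,
            }
            (outdir / "survival_results.json").write_text(
                json.dumps(result, indent=2, sort_keys=True)
            )
            emit(outdir / "survival.tsv")
            emit(outdir / "survival_results.json")
            manifest.row_counts["cohort_samples"] = len(cohort)
            manifest.row_counts["cohort_events"] = cohort.n_events
        elif stage == "permute":
            _require(ctx, "cohort", stage)
            sig = ctx["signature"]
            genes = sig.gene_ids[:permute_k_max]
            weights = [e.weight for e in sig.entries[:permute_k_max]]
            scan = exhaustive_weight_scan(
                ctx["cohort_expr"], genes, ctx["cohort"],
                reference_weights=weights, score_mode=config.score_mode,
            )
            summary = {
                "n_vectors": scan.n_vectors,
                "reference_statistic": scan.reference_statistic,
                "percentile": scan.percentile,
                "k": len(genes),
            }
            (outdir / "permutation_summary.json").write_text(
                json.dumps(summary, indent=2, sort_keys=True)
            )
            np.savetxt(outdir / "permutation_statistics.tsv", scan.statistics, fmt="%.6g")
            emit(outdir / "permutation_summary.json")
            emit(outdir / "permutation_statistics.tsv")
            manifest.row_counts["permutation_vectors"] = scan.n_vectors
        else:  # pragma: no cover
            raise ValueError(f"unknown stage {stage!r}")

    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _require(ctx: dict, key: str, stage: str) -> None:
    if key not in ctx:
        raise RuntimeError(f"stage {stage!r} is missing upstream output {key!r}")


def _truth_signature(truth) -> GeneSignature:
    entries = [
        SignatureEntry(
            g,
            truth.invivo_direction[g],
            truth.in_vitro_direction.get(g, 0),
            truth.invivo_direction[g],
            truth.concordance.get(g),
        )
        for g in sorted(truth.genes_of_class("unique_M3"))
    ]
    return GeneSignature(entries)
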
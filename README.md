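# smadsig

Derivation and survival validation of a directionally weighted TGF-β/Smad3
tumor-suppressor gene signature (TSTSS) from differential transcription-factor
occupancy and expression data.

## The scientific problem

TGF-β plays a dual role in breast cancer: it suppresses early tumors but can
promote progression later, and both arms can be active in a patient at the
time of surgery. A gene signature that captures *only* the tumor-suppressive
arm makes it possible to ask whether that arm is still active in a clinical
cohort — high signature expression should then predict good outcome,
specifically in ER+ disease. `smadsig` implements the full computational
pipeline for building and validating such a signature, for computational
biologists who want to run, stress-test, or adapt the strategy on their own
(or synthetic) data:

1. **Occupancy calling** (`smadsig.peaks`) — TGF-β-induced Smad3 binding
   regions (SBRs) are called from two-condition tiling-probe intensities: a
   one-sided Wilcoxon signed-rank statistic over sliding 200-bp windows
   (bandwidth 100 bp) on treated−vehicle paired differences, BH-adjusted at
   FDR 0.15, merged into runs ≥ 200 bases with gaps ≤ 100 bases, and
   annotated to the gene with the nearest TSS within ±10 kb.
2. **Motif characterization** (`smadsig.motifs`) — IUPAC consensus scanning
   (the canonical Smad element GTCT / AGAC), positional 100-bp bin fractions
   around peak midpoints ±1000 bp with equidistant bins combined, two-way
   (group × distance) ANOVA against control promoters, and one-sided Fisher
   co-occurrence tests with Bonferroni correction.
3. **Signature derivation** (`smadsig.signature`) — the filter cascade:
   four-condition ANOVA (FDR < 0.05) over Smad3 target genes in the
   M3/M4 ± TGF-β in vitro design, pairwise regulation calls (p < 0.001 and
   fold ≥ 1.5×), selection of genes regulated *uniquely* in the
   tumor-suppressor-competent M3 line, and an in vivo filter (control vs
   dominant-negative-receptor tumors, FDR < 0.2) that assigns each surviving
   gene a weight w ∈ {−1, +1} equal to its **in vivo** direction of
   regulation — genes regulated in opposite directions in vitro and in vivo
   are kept and flagged *discordant*.
4. **Scoring and outcome analysis** (`smadsig.scoring`, `smadsig.survival`) —
   per-sample weighted score `s_j = Σ_i w_i x_ij` (or its mean), median
   dichotomization (High iff score > median), Kaplan–Meier curves, the
   two-group log-rank test, and Cox proportional-hazards fits (Efron ties,
   Wald CIs). Meta-gene indices (proliferation anchored on PCNA, ephrin
   anchored on EFNA1, an 11-gene luminal-differentiation median) and Spearman
   correlation after a once-applied IQR outlier rule
   ([m − 1.5·IQR, m + 1.5·IQR]) connect the signature to underlying biology.
5. **Permutation validation** (`smadsig.permutation`) — exhaustive
   enumeration of all 2^k binary weight vectors (4,194,304 at k = 22) in
   Gray-code order with exact incremental score updates, and 10,000 random
   gene subsets with random ±1 weights, each scored by the dichotomized
   log-rank chi-square; the in-vivo-weighted signature is ranked against the
   resulting distribution.

Every input class has a synthetic generator with planted ground truth
(`smadsig.simulate`), so the whole pipeline is exercisable end-to-end with
parameter-recovery guarantees and no external downloads.

## Worked example

The `run` subcommand executes the synthetic demonstration pipeline
(simulate → callpeaks → derive → score → survival → permute):

```bash
smadsig run --seed 1 --outdir demo
```

With seed 1 this plants 34 binding regions at the promoters of regulated
genes among 120 genes, calls all 34 back from the tiling signal, derives a
12-gene weighted signature through the full cascade (`demo/signature.tsv`):

```
gene    weight  in_vitro_direction  in_vivo_direction  concordance
G00000  -1      -1                  -1                 concordant
G00004  1       -1                  1                  discordant
...
```

and evaluates it on a 300-patient simulated cohort whose hazard follows the
planted truth (`demo/survival_results.json`):

```json
{
  "logrank_chi_square": 31.71,
  "logrank_p": 1.79e-08,
  "cox_hazard_ratio": 2.44,
  "cox_ci": [1.77, 3.36],
  "n": 300,
  "n_events": 161
}
```

Low signature expression roughly doubles the hazard of an event, and the
exhaustive 2^12-vector scan (`demo/permutation_summary.json`) ranks the
derived weighting above 98.6% of all alternative weightings
(`"percentile": 0.9856`) — the signature's direction assignments, not just
its gene list, carry the prognostic information. Each run writes a
`manifest.json` with config, seed and file digests; identical seeds
reproduce byte-identical outputs.

The same stages are available as individual subcommands (`simulate`,
`callpeaks`, `motif`, `derive`, `score`, `metaindex`, `survival`, `permute`)
over TSV/BED/FASTA files, and as plain library functions.

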
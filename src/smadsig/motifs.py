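"""Consensus-motif scanning in binding regions, positional bin enrichment
around peak midpoints, and transcription-factor co-occurrence testing.

Motifs are IUPAC consensus strings (the canonical Smad binding element is
GTCT, scanned together with its reverse complement AGAC).  Position weight
matrices are out of scope; user-supplied consensus motifs stand in for
matrix-library scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "MotifModel",
    "RegionMotifMatrix",
    "scan_motif",
    "bin_motif_fractions",
    "bin_enrichment_anova",
    "cooccurrence_test",
    "dedupe_motif_sites",
    "DEFAULT_MOTIFS",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(consensus: str) -> str:
    return consensus.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifModel:
    """A named IUPAC consensus motif."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("consensus must be non-empty")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC symbols in consensus: {sorted(bad)}")
        object.__setattr__(self, "consensus", self.consensus.upper())

    @property
    def family(self) -> str:
        return self.name.split(".")[0]

    def __len__(self) -> int:
        return len(self.consensus)


DEFAULT_MOTIFS = (
    MotifModel("SMAD", "GTCT"),
    MotifModel("AP1", "TGASTCA"),
)


def _matches_at(seq: str, pattern: str, offset: int) -> bool:
    for j, code in enumerate(pattern):
        base = seq[offset + j]
        if base == "N" or base not in IUPAC[code]:
            return False  # N in the sequence never matches
    return True


def scan_motif(sequence: str, motif: MotifModel) -> list[tuple[int, str]]:
    """All matches of the consensus (strand +) and of its reverse complement
    (strand -) in ``sequence``; 0-based start offsets."""
    seq = sequence.upper()
    hits: list[tuple[int, str]] = []
    for pattern, strand in ((motif.consensus, "+"), (reverse_complement(motif.consensus), "-")):
        w = len(pattern)
        for offset in range(len(seq) - w + 1):
            if _matches_at(seq, pattern, offset):
                hits.append((offset, strand))
    hits.sort()
    return hits


def bin_motif_fractions(
    sequences, motif: MotifModel, bin_bp: int = 100
) -> np.ndarray:
    """Fraction of regions with >= 1 motif hit per combined distance class.

    Each sequence must be 2000 bp, centered on a peak midpoint (+/- 1000 bp),
    and is divided into ``bin_bp`` bins.  Bins equidistant from the midpoint
    are combined, giving distance classes 0-100, 100-200, ..., 900-1000 bp;
    a region counts for a class if either member bin contains a hit start.
    """
    sequences = list(sequences)
    half = 1000
    n_classes = half // bin_bp
    counts = np.zeros(n_classes)
    for idx, seq in enumerate(sequences):
        s = str(getattr(seq, "seq", seq))
        if len(s) != 2 * half:
            name = getattr(seq, "id", f"region {idx}")
            raise ValueError(f"{name}: sequence must be {2 * half} bp, got {len(s)}")
        hit_classes = set()
        for offset, _strand in scan_motif(s, motif):
            dist = offset - half  # signed offset of the hit start from midpoint
            cls = (abs(dist) if dist >= 0 else abs(dist) - 1) // bin_bp
            # a hit starting at -1 lies in the first upstream bin (class 0)
            if cls < n_classes:
                hit_classes.add(cls)
        for cls in hit_classes:
            counts[cls] += 1
    return counts / max(len(sequences), 1)


def bin_enrichment_anova(peak_fractions, control_fractions) -> pd.DataFrame:
    """Two-way (group x distance) ANOVA on the per-bin fraction table.

    Additive model with one observation per cell; returns F and p for the
    group factor (peaks vs controls) and the distance factor.
    """
    peak_fractions = np.asarray(peak_fractions, dtype=float)
    control_fractions = np.asarray(control_fractions, dtype=float)
    if peak_fractions.shape != control_fractions.shape:
        raise ValueError("groups must share the same distance classes")
    if peak_fractions.size < 2:
        raise ValueError("need >= 2 distance classes")
    n = peak_fractions.size
    df = pd.DataFrame(
        {
            "fraction": np.concatenate([peak_fractions, control_fractions]),
            "group": ["peak"] * n + ["control"] * n,
            "distance": [str(i) for i in range(n)] * 2,
        }
    )
    fit = smf.ols("fraction ~ C(group) + C(distance)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    out = table.loc[["C(group)", "C(distance)"], ["F", "PR(>F)"]].copy()
    out.index = ["group", "distance"]
    out = out.rename(columns={"PR(>F)": "p"})
    # a perfectly additive table has zero residual variance; report the
    # factors with zero sum-of-squares as null rather than 0/0 noise
    ms_resid = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
    if ms_resid < 1e-12:
        for factor, label in (("C(group)", "group"), ("C(distance)", "distance")):
            if table.loc[factor, "sum_sq"] < 1e-12:
                out.loc[label, ["F", "p"]] = (0.0, 1.0)
    return out


class RegionMotifMatrix:
    """Boolean region x motif presence with a peak/control group label."""

    def __init__(self, presence: pd.DataFrame, groups: pd.Series) -> None:
        presence = pd.DataFrame(presence).astype(bool)
        groups = pd.Series(groups).reindex(presence.index)
        if groups.isna().any():
            raise ValueError("every region needs a group label")
        bad = set(groups.unique()) - {"peak", "control"}
        if bad:
            raise ValueError(f"group labels must be 'peak'/'control', got {sorted(bad)}")
        self.presence = presence
        self.groups = groups

    @classmethod
    def from_sequences(cls, peak_seqs, control_seqs, motifs) -> "RegionMotifMatrix":
        rows, labels, index = [], [], []
        for label, seqs in (("peak", peak_seqs), ("control", control_seqs)):
            for i, seq in enumerate(seqs):
                s = str(getattr(seq, "seq", seq))
                rows.append({m.name: bool(scan_motif(s, m)) for m in motifs})
                labels.append(label)
                index.append(getattr(seq, "id", f"{label}_{i}"))
        presence = pd.DataFrame(rows, index=index)
        return cls(presence, pd.Series(labels, index=index))

    @property
    def motif_names(self) -> list[str]:
        return list(self.presence.columns)


def rank_motifs_by_enrichment(matrix: RegionMotifMatrix) -> pd.Series:
    """One-sided Fisher p (enrichment in peaks) per single motif, ascending."""
    pvals = {}
    peaks = matrix.groups == "peak"
    for name in matrix.motif_names:
        present = matrix.presence[name]
        table = [
            [int((present & peaks).sum()), int((~present & peaks).sum())],
            [int((present & ~peaks).sum()), int((~present & ~peaks).sum())],
        ]
        pvals[name] = stats.fisher_exact(table, alternative="greater")[1]
    return pd.Series(pvals).sort_values()


def default_pairs(matrix: RegionMotifMatrix, smad_name: str = "SMAD", n_top: int = 6):
    """All pairs among the SMAD motif and the ``n_top`` most enriched others."""
    ranking = rank_motifs_by_enrichment(matrix)
    others = [m for m in ranking.index if m != smad_name][:n_top]
    chosen = ([smad_name] if smad_name in matrix.motif_names else []) + others
    return [(a, b) for i, a in enumerate(chosen) for b in chosen[i + 1 :]]


def cooccurrence_test(matrix: RegionMotifMatrix, pairs=None) -> pd.DataFrame:
    """Fisher's exact co-occurrence test per motif pair, peaks vs controls.

    For each pair, a 2x2 table of group x both-sites-present is tested
    one-sided for enrichment in peaks; Bonferroni adjustment multiplies by
    the number of pairs (capped at 1).
    """
    if (matrix.groups == "peak").sum() == 0 or (matrix.groups == "control").sum() == 0:
        raise ValueError("both groups must be non-empty")
    if pairs is None:
        pairs = default_pairs(matrix)
    pairs = list(pairs)
    rows = []
    peaks = matrix.groups == "peak"
    for a, b in pairs:
        for name in (a, b):
            if name not in matrix.presence.columns:
                raise ValueError(f"motif {name!r} absent from the region matrix")
        both = matrix.presence[a] & matrix.presence[b]
        table = np.array(
            [
                [int((both & peaks).sum()), int((~both & peaks).sum())],
                [int((both & ~peaks).sum()), int((~both & ~peaks).sum())],
            ]
        )
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "motif_a": a,
                "motif_b": b,
                "peaks_both": table[0, 0],
                "controls_both": table[1, 0],
                "p": p,
                "p_bonferroni": min(1.0, p * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def dedupe_motif_sites(sites) -> list[tuple[str, int, int]]:
    """Collapse redundant TF sites: same family and overlapping offsets merge.

    ``sites`` holds (motif name, offset, length) triples; the motif family is
    the name up to the first dot (AP1.01 and AP1.02 are both AP1), and any
    SMAD-family variant (SMAD, SMAD2/3/4, SMAD.generic) collapses to SMAD,
    so a generic SMAD site overlapping a SMAD3 site counts once.  Returns
    merged (family, start, end) sites sorted by family then position.
    """
    by_family: dict[str, list[tuple[int, int]]] = {}
    for name, offset, length in sites:
        family = str(name).split(".")[0]
        if family.startswith("SMAD"):
            family = "SMAD"
        by_family.setdefault(family, []).append((int(offset), int(offset) + int(length)))
    merged = []
    for family, intervals in by_family.items():
        intervals.sort()
        current_start, current_end = intervals[0]
        for start, end in intervals[1:]:
            if start < current_end:  # overlapping (not merely adjacent)
                current_end = max(current_end, end)
            else:
                merged.append((family, current_start, current_end))
                current_start, current_end = start, end
        merged.append((family, current_start, current_end))
    return sorted(merged)
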
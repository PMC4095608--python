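"""Peak calling: quantile normalization, the windowed signed-rank statistic,
region merging, TSS annotation, occupancy overlap, and positional density."""

import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

from smadsig.core import AnalysisConfig, GenomicInterval, TssRecord
from smadsig.peaks import (
    ProbePanel,
    SbrCall,
    annotate_regions,
    call_sbrs,
    common_to_all_fraction,
    density_from_distances,
    normalize_panel,
    occupancy_overlap,
    quantile_normalize,
    signed_rank_p,
    tss_relative_density,
    validation_discordance_summary,
)
from smadsig.simulate import simulate_tiling_experiment


class TestQuantileNormalize:
    def test_two_array_rank_means(self):
        out = quantile_normalize(np.array([[1.0, 2, 3], [4.0, 5, 6]]))
        np.testing.assert_allclose(out, [[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])

    def test_identical_arrays_unchanged(self):
        arr = np.array([[3.0, 1, 2], [3.0, 1, 2]])
        np.testing.assert_allclose(quantile_normalize(arr), arr)

    def test_ties_get_mean_of_rank_means(self):
        # rank means over sorted rows: (1, 1.5, 2.5); the tied entries in the
        # first row share average rank 1.5 -> (1 + 1.5)/2 = 1.25
        out = quantile_normalize(np.array([[1.0, 1, 2], [1.0, 2, 3]]))
        np.testing.assert_allclose(out[0], [1.25, 1.25, 2.5])

    def test_single_array_identity_with_warning(self):
        with pytest.warns(UserWarning, match="identity"):
            out = quantile_normalize(np.array([[5.0, 1.0, 3.0]]))
        np.testing.assert_allclose(out, [[5.0, 1.0, 3.0]])

    def test_output_columns_share_sorted_values(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(4, 50))
        out = quantile_normalize(arr)
        ref = np.sort(out[0])
        for row in out[1:]:
            np.testing.assert_allclose(np.sort(row), ref)

    def test_monotone_in_each_array(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(size=(3, 40))
        out = quantile_normalize(arr)
        for x, y in zip(arr, out):
            order = np.argsort(x)
            assert np.all(np.diff(y[order]) >= 0)

    def test_matches_limma_reference(self, tmp_path):
        """Cross-check against limma::normalizeBetweenArrays (quantile)."""
        rng = np.random.default_rng(7)
        arr = rng.normal(8, 1, size=(4, 25))
        ours = quantile_normalize(arr)
        np.savetxt(tmp_path / "x.tsv", arr.T, delimiter="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.table("x.tsv", sep="\\t"))
            y <- normalizeBetweenArrays(x, method="quantile")
            write.table(y, "y.tsv", sep="\\t", row.names=FALSE, col.names=FALSE)
            """
        )
        (tmp_path / "qn.R").write_text(script)
        subprocess.run(["Rscript", "qn.R"], cwd=tmp_path, check=True, capture_output=True)
        theirs = np.loadtxt(tmp_path / "y.tsv", delimiter="\t").T
        np.testing.assert_allclose(ours, theirs, atol=1e-8)


class TestSignedRank:
    @pytest.mark.parametrize("m", [5, 8, 12, 20])
    def test_matches_scipy_exact(self, m):
        rng = np.random.default_rng(m)
        for _ in range(5):
            d = rng.normal(0.3, 1.0, size=m)
            ours = signed_rank_p(d)
            theirs = stats.wilcoxon(d, alternative="greater", method="exact").pvalue
            assert ours == pytest.approx(theirs, rel=1e-12)

    def test_all_zero_differences(self):
        assert signed_rank_p(np.zeros(10)) == 1.0


def _planted_panel(seed, start=5000, end=5400, shift=2.0, n_probes=300):
    return simulate_tiling_experiment(
        n_probes, planted=[(GenomicInterval("chr1", start, end), shift)], seed=seed
    )[0]


class TestCallSbrs:
    def test_identical_conditions_yield_zero_calls(self):
        rng = np.random.default_rng(2)
        intensities = rng.normal(8, 0.3, size=(4, 200))
        panel = ProbePanel("chr1", np.arange(200) * 35, intensities, intensities.copy())
        assert call_sbrs(panel) == []

    def test_planted_region_recovered_as_single_overlapping_call(self):
        plant = GenomicInterval("chr1", 5000, 5400)
        calls = call_sbrs(normalize_panel(_planted_panel(seed=4)))
        assert len(calls) == 1
        assert calls[0].interval.overlaps(plant)
        assert calls[0].qvalue <= 0.15

    def test_short_plant_below_minimum_run_not_called(self):
        # a 120-bp plant cannot produce the 200-base minimum run
        panel = _planted_panel(seed=4, end=5120)
        assert call_sbrs(normalize_panel(panel)) == []

    def test_shift_invariance_under_common_constant(self):
        panel = _planted_panel(seed=9)
        shifted = ProbePanel(
            panel.chrom, panel.probe_positions, panel.vehicle + 3.5, panel.treated + 3.5
        )
        a = call_sbrs(normalize_panel(panel))
        b = call_sbrs(normalize_panel(shifted))
        assert [(c.interval.start, c.interval.end) for c in a] == [
            (c.interval.start, c.interval.end) for c in b
        ]

    def test_calls_never_overlap_and_satisfy_min_run(self):
        config = AnalysisConfig()
        for seed in range(6):
            panel = simulate_tiling_experiment(
                400,
                planted=[
                    (GenomicInterval("chr1", 3000, 3400), 2.0),
                    (GenomicInterval("chr1", 9000, 9500), 2.0),
                ],
                seed=seed,
            )[0]
            calls = call_sbrs(normalize_panel(panel), config)
            for c in calls:
                assert c.interval.length >= config.min_run_bp
            for c1, c2 in zip(calls, calls[1:]):
                assert c1.interval.end <= c2.interval.start


class TestAnnotate:
    def _tss(self, gene, pos, strand="+"):
        return TssRecord(gene, GenomicInterval("chr1", pos, pos + 1, strand), strand)

    def _call(self, midpoint):
        return SbrCall(
            GenomicInterval("chr1", midpoint - 100, midpoint + 100), midpoint, 1.0, 0.05
        )

    def test_nearest_tss_wins(self):
        anns = annotate_regions(
            [self._call(5000)], [self._tss("A", 4200), self._tss("B", 5900)]
        )
        assert anns[0].gene == "A" and anns[0].distance == 800

    def test_beyond_10kb_unassigned(self):
        anns = annotate_regions([self._call(50_000)], [self._tss("A", 65_000)])
        assert anns[0].gene is None

    def test_equidistant_tie_reports_both_lexicographic_primary(self):
        anns = annotate_regions(
            [self._call(5000)], [self._tss("Z", 4500), self._tss("B", 5500)]
        )
        assert anns[0].gene == "B"
        assert set(anns[0].genes_within) == {"B", "Z"}

    def test_assignment_minimizes_distance_exhaustively(self):
        rng = np.random.default_rng(3)
        tss = [self._tss(f"g{i}", int(p)) for i, p in enumerate(rng.integers(0, 60_000, 25))]
        calls = [self._call(int(m)) for m in rng.integers(200, 60_000, 15)]
        for ann in annotate_regions(calls, tss):
            dists = {t.gene_id: abs(t.position - ann.call.midpoint) for t in tss}
            if ann.gene is None:
                assert min(dists.values()) > 10_000
            else:
                assert dists[ann.gene] == min(dists.values())

    def test_empty_tss_table_warns_all_unassigned(self):
        with pytest.warns(UserWarning, match="empty TSS"):
            anns = annotate_regions([self._call(5000)], [])
        assert anns[0].gene is None


class TestOccupancyOverlap:
    def test_two_line_counts(self):
        counts = occupancy_overlap({"A": {"g1", "g2"}, "B": {"g2"}})
        assert counts[frozenset({"A"})] == 1
        assert counts[frozenset({"A", "B"})] == 1
        assert frozenset({"B"}) not in counts

    def test_four_identical_sets(self):
        genes = {f"g{i}" for i in range(10)}
        counts = occupancy_overlap({line: set(genes) for line in "ABCD"})
        assert counts == {frozenset("ABCD"): 10}

    def test_counts_partition_union(self):
        rng = np.random.default_rng(8)
        sets = {
            line: {f"g{i}" for i in rng.choice(40, size=15, replace=False)}
            for line in "ABCD"
        }
        counts = occupancy_overlap(sets)
        assert sum(counts.values()) == len(set().union(*sets.values()))

    def test_common_fraction(self):
        counts = {frozenset("AB"): 3, frozenset("A"): 5, frozenset("B"): 2}
        assert common_to_all_fraction(counts) == pytest.approx(0.3)


class TestValidationSummary:
    def test_counts(self):
        s = validation_discordance_summary(67, 65, 33, 11)
        assert s["false_positives"] == 2
        assert s["false_negatives"] == 11
        assert s["discordant"] == 13

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            validation_discordance_summary(5, 6, 3, 0)


class TestDensity:
    def test_midpoints_at_tss_mode_at_zero(self):
        tss = [TssRecord(f"g{i}", GenomicInterval("chr1", p, p + 1, "+"), "+")
               for i, p in enumerate(range(1000, 9000, 500))]
        calls = [SbrCall(GenomicInterval("chr1", p - 50, p + 50), p, 1.0, 0.01)
                 for p in range(1000, 9000, 500)]
        anns = annotate_regions(calls, tss)
        est = tss_relative_density(anns, tss)
        assert abs(est.grid[np.argmax(est.density)]) < 200
        assert est.integral() == pytest.approx(1.0, abs=1e-6)

    def test_uniform_distances_give_flat_density(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(-7500, 2500, size=4000)
        est = density_from_distances(d)
        inner = (est.grid > -6500) & (est.grid < 1500)
        flat = 1.0 / 10_000
        assert np.all(np.abs(est.density[inner] - flat) < 0.35 * flat)

    def test_strand_awareness(self):
        # a midpoint 500 bp left of a minus-strand TSS is downstream (+500)
        tss = [TssRecord("g", GenomicInterval("chr1", 5000, 5001, "-"), "-"),
               TssRecord("h", GenomicInterval("chr1", 40000, 40001, "+"), "+")]
        call = SbrCall(GenomicInterval("chr1", 4400, 4600), 4500, 1.0, 0.01)
        anns = annotate_regions([call], tss)
        from smadsig.peaks import signed_tss_distances

        assert signed_tss_distances(anns, tss).tolist() == [500.0]

    def test_too_few_distances_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            density_from_distances([100.0])
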
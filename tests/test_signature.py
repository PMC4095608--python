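"""The filter cascade: four-condition ANOVA, pairwise regulation calls,
clustering, unique-in-M3 selection, the in vivo filter, and assembly of the
weighted signature."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from smadsig.core import ExpressionMatrix
from smadsig.signature import (
    anova_four_condition,
    derive_signature,
    hierarchical_cluster,
    in_vivo_filter,
    pairwise_regulation,
    select_common,
    select_unique_m3,
)
from smadsig.simulate import simulate_expression_design, simulate_tumor_expression


def _bh_bruteforce(p):
    """Literal step-up definition: q_i = min_{j: p_j >= p_i} min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBenjaminiHochberg:
    def test_hand_step_up_example(self):
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=8)
    )
    @settings(deadline=None, derandomize=True, max_examples=80)
    def test_matches_bruteforce_definition(self, pvals):
        q = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(q, _bh_bruteforce(pvals), rtol=1e-10)
        assert np.all(q >= np.asarray(pvals) - 1e-12)


def _four_condition_matrix(rows, reps=3):
    samples = [f"{c}_{r}" for c in ("M3v", "M3t", "M4v", "M4t") for r in range(reps)]
    df = pd.DataFrame(rows, columns=samples)
    groups = pd.Series([s.rsplit("_", 1)[0] for s in samples], index=samples)
    return ExpressionMatrix(df), groups


class TestAnova:
    def test_constant_gene_not_flagged(self):
        matrix, groups = _four_condition_matrix(np.full((1, 12), 5.0))
        matrix.values.index = ["flat"]
        res = anova_four_condition(matrix, groups)
        assert res.loc["flat", "statistic"] == 0.0
        assert res.loc["flat", "p"] == 1.0
        assert not res.loc["flat", "heterogeneous"]

    def test_planted_shift_flagged(self):
        rng = np.random.default_rng(0)
        base = rng.normal(7, 0.1, size=(20, 12))
        base[0, 3:6] += 2.0  # unique shift in one condition
        matrix, groups = _four_condition_matrix(base)
        matrix.values.index = [f"g{i}" for i in range(20)]
        res = anova_four_condition(matrix, groups)
        assert res.iloc[0]["q"] < 0.05 and res.iloc[0]["heterogeneous"]

    def test_wrong_group_count_rejected(self):
        matrix, groups = _four_condition_matrix(np.zeros((2, 12)))
        matrix.values.index = ["a", "b"]
        with pytest.raises(ValueError, match="4 condition"):
            anova_four_condition(matrix, groups.str[:2])


class TestPairwiseRegulation:
    def _matrix(self, treated, control):
        values = np.column_stack([treated, control])
        samples = [f"t{i}" for i in range(treated.shape[1])] + [
            f"c{i}" for i in range(control.shape[1])
        ]
        df = pd.DataFrame(values, columns=samples,
                          index=[f"g{i}" for i in range(values.shape[0])])
        return ExpressionMatrix(df), samples[: treated.shape[1]], samples[treated.shape[1]:]

    def test_identical_groups_all_zero_direction(self):
        rng = np.random.default_rng(1)
        block = rng.normal(7, 0.2, size=(10, 3))
        m, t, c = self._matrix(block, block + rng.normal(0, 1e-6, block.shape))
        res = pairwise_regulation(m, t, c)
        assert (res["direction"] == 0).all()

    def test_planted_upshift_called_positive(self):
        rng = np.random.default_rng(2)
        control = rng.normal(7, 0.1, size=(1, 3))
        treated = control + 1.0  # fold 2.0 > 1.5
        m, t, c = self._matrix(treated, control)
        res = pairwise_regulation(m, t, c)
        assert res.iloc[0]["direction"] == 1

    def test_fold_gate_blocks_small_shift(self):
        # +0.4 log2 (fold 1.32) with tiny noise: p < 0.001 but below 1.5x
        rng = np.random.default_rng(3)
        control = rng.normal(7, 0.005, size=(1, 3))
        treated = control + 0.4
        m, t, c = self._matrix(treated, control)
        res = pairwise_regulation(m, t, c)
        assert res.iloc[0]["p"] < 0.001
        assert res.iloc[0]["direction"] == 0

    def test_single_replicate_rejected(self):
        m, t, c = self._matrix(np.zeros((2, 1)), np.zeros((2, 3)))
        with pytest.raises(ValueError, match="replicates"):
            pairwise_regulation(m, t, c)


class TestHierarchicalCluster:
    def test_identical_profiles_merge_at_zero(self):
        df = pd.DataFrame([[1.0, 2, 3], [1.0, 2, 3], [9.0, 9, 9]],
                          index=["a", "b", "c"], columns=["s1", "s2", "s3"])
        result = hierarchical_cluster(ExpressionMatrix(df), k=2)
        assert result.merge_heights[0] == 0.0
        assert result.labels["a"] == result.labels["b"] != result.labels["c"]

    def test_two_separated_blocks_recovered(self):
        rng = np.random.default_rng(4)
        block1 = rng.normal(0, 0.1, size=(6, 5))
        block2 = rng.normal(10, 0.1, size=(6, 5))
        df = pd.DataFrame(np.vstack([block1, block2]),
                          index=[f"g{i}" for i in range(12)],
                          columns=[f"s{j}" for j in range(5)])
        labels = hierarchical_cluster(ExpressionMatrix(df), k=2).labels
        # brute-force best bipartition is exactly the two planted blocks
        assert len(set(labels.iloc[:6])) == 1
        assert len(set(labels.iloc[6:])) == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(15, 4)),
                          index=[f"g{i}" for i in range(15)],
                          columns=list("wxyz"))
        heights = hierarchical_cluster(ExpressionMatrix(df), k=3).merge_heights
        assert np.all(np.diff(heights) >= -1e-12)

    def test_k_too_large_rejected(self):
        df = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("xyz"))
        with pytest.raises(ValueError, match="k="):
            hierarchical_cluster(ExpressionMatrix(df), k=4)


class TestSelection:
    def _diff(self, directions):
        return pd.DataFrame(
            {"direction": pd.Series(directions)},
            index=list(directions),
        )

    def test_unique_m3_rules(self):
        m3 = self._diff({"a": 1, "b": 1, "c": 0, "d": -1})
        m4 = self._diff({"a": 0, "b": 1, "c": 0, "d": 0})
        assert select_unique_m3(m3, m4) == {"a", "d"}
        assert select_common(m3, m4) == {"b"}

    def test_unique_and_common_disjoint(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(30)]
        m3 = self._diff({g: int(rng.choice([-1, 0, 1])) for g in genes})
        m4 = self._diff({g: int(rng.choice([-1, 0, 1])) for g in genes})
        assert select_unique_m3(m3, m4) & select_common(m3, m4) == set()


class TestInVivoFilter:
    def test_direction_sign_convention(self):
        # higher in control tumors => upregulated by the intact pathway (+1)
        rng = np.random.default_rng(7)
        control = rng.normal(8, 0.2, size=(1, 6))
        blocked = control - 1.5
        df = pd.DataFrame(np.column_stack([control, blocked]),
                          index=["g"],
                          columns=[f"c{i}" for i in range(6)] + [f"b{i}" for i in range(6)])
        res = in_vivo_filter(ExpressionMatrix(df),
                             [f"c{i}" for i in range(6)], [f"b{i}" for i in range(6)])
        assert res.loc["g", "direction"] == 1 and res.loc["g", "passed"]

    def test_sign_accuracy_on_planted_design(self):
        _, truth = simulate_expression_design(seed=21)
        tumors = simulate_tumor_expression(truth, seed=22)
        res = in_vivo_filter(
            tumors,
            tumors.samples_where(genotype="control"),
            tumors.samples_where(genotype="blocked"),
        )
        surviving = [g for g in res.index if res.loc[g, "passed"]
                     and g in truth.invivo_direction]
        correct = [g for g in surviving
                   if res.loc[g, "direction"] == truth.invivo_direction[g]]
        assert len(surviving) > 0
        assert len(correct) / len(surviving) >= 0.9

    def test_single_tumor_rejected(self):
        df = pd.DataFrame(np.zeros((2, 3)), index=["a", "b"], columns=["c1", "b1", "b2"])
        with pytest.raises(ValueError, match="tumors"):
            in_vivo_filter(ExpressionMatrix(df), ["c1"], ["b1", "b2"])


class TestDeriveSignature:
    def _inputs(self):
        invitro = pd.DataFrame({"direction": [1, 1, 1]}, index=["up", "flip", "gated"])
        invivo = pd.DataFrame(
            {
                "direction": [1, -1, 0],
                "passed": [True, True, False],
                "q": [0.05, 0.1, 0.35],
            },
            index=["up", "flip", "gated"],
        )
        return invitro, invivo

    def test_concordant_gene_weighted_by_invivo(self):
        invitro, invivo = self._inputs()
        derived = derive_signature({"up", "flip", "gated"}, {"up", "flip", "gated"},
                                   invitro, invivo)
        entry = {e.gene_id: e for e in derived.tstss.entries}["up"]
        assert entry.weight == 1 and entry.concordance == "concordant"

    def test_discordant_gene_included_with_invivo_weight(self):
        # in vitro up, in vivo down: kept, weight follows the in vivo direction
        invitro, invivo = self._inputs()
        derived = derive_signature({"up", "flip", "gated"}, {"up", "flip", "gated"},
                                   invitro, invivo)
        entry = {e.gene_id: e for e in derived.tstss.entries}["flip"]
        assert entry.weight == -1 and entry.concordance == "discordant"

    def test_invivo_gate_excludes(self):
        invitro, invivo = self._inputs()
        derived = derive_signature({"up", "flip", "gated"}, {"up", "flip", "gated"},
                                   invitro, invivo)
        assert "gated" not in derived.tstss.gene_ids

    def test_empty_result_warns(self):
        invitro, invivo = self._inputs()
        with pytest.warns(UserWarning, match="empty signature"):
            derived = derive_signature(set(), set(), invitro, invivo)
        assert len(derived.tstss) == 0
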
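"""Gene territories, state categories, expression groups and crosstabs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from senechip.calling import PeakRegion
from senechip.chipnorm import HIGHER_IN_A, HIGHER_IN_B, DifferentialRegion
from senechip.core import GenomeTable, GeneModel
from senechip.integrate import (
    GeneMarkState,
    assign_diff_regions_to_tss_bins,
    assign_states,
    classify_bivalent_transition,
    classify_state,
    crosstab_states_by_group,
    fold_change_filter,
    gene_territory,
    load_qpcr_table,
    partition_expression_groups,
)

from conftest import iv


class TestGeneTerritory:
    def test_plus_strand(self, genome):
        g = GeneModel("g", iv("chrT", 1000, 4000, "+"))
        assert gene_territory(g, genome) == iv("chrT", 500, 4000)

    def test_minus_strand(self, genome):
        g = GeneModel("g", iv("chrT", 1000, 4000, "-"))
        assert gene_territory(g, genome) == iv("chrT", 1000, 4500)

    def test_clipped_at_origin(self, genome):
        g = GeneModel("g", iv("chrT", 200, 1200, "+"))
        assert gene_territory(g, genome).start == 0


class TestClassifyState:
    @pytest.mark.parametrize(
        "a,b,mark,expected",
        [
            (True, True, "K4", "K4-K4"),
            (True, False, "K27", "K27-None"),
            (False, True, "K4", "None-K4"),
            (False, False, "K4", "None-None"),
        ],
    )
    def test_mapping(self, a, b, mark, expected):
        assert classify_state(a, b, mark) == expected

    def test_exhausts_four_categories(self):
        cats = {classify_state(a, b, "K4") for a in (True, False) for b in (True, False)}
        assert cats == {"K4-K4", "K4-None", "None-K4", "None-None"}


class TestBivalentTransition:
    def _state(self, mark, a, b):
        return GeneMarkState("g", mark, a, b, classify_state(a, b, mark))

    @pytest.mark.parametrize(
        "k4_b,k27_b,expected",
        [
            (False, False, "lost_both"),
            (True, False, "retained_K4"),
            (False, True, "retained_K27"),
            (True, True, "retained_both"),
        ],
    )
    def test_four_transitions(self, k4_b, k27_b, expected):
        result = classify_bivalent_transition(
            self._state("K4", True, k4_b), self._state("K27", True, k27_b)
        )
        assert result == expected

    def test_requires_bivalency_at_first_condition(self):
        with pytest.raises(ValueError):
            classify_bivalent_transition(
                self._state("K4", False, True), self._state("K27", True, True)
            )


class TestPartitionExpressionGroups:
    def test_ten_records_in_rank_order(self):
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "expr_a": np.full(10, 8.0),
                "expr_b": 8.0 * 2.0 ** np.arange(-3.0, 7.0),
            }
        )
        out = partition_expression_groups(df)
        assert list(out["group"]) == list("AABBCCDDEE")
        assert list(out["gene_id"]) == [f"g{i}" for i in range(10)]  # already ranked

    def test_4090_records_split_into_818s(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i:04d}" for i in range(4090)],
                "expr_a": rng.random(4090) * 100,
                "expr_b": rng.random(4090) * 100,
            }
        )
        out = partition_expression_groups(df)
        assert out["group"].value_counts().tolist() == [818] * 5
        # group A holds the most condition-A-skewed genes
        assert out[out.group == "A"].log_ratio.max() <= out[out.group == "E"].log_ratio.min()

    def test_ties_broken_by_gene_id_and_order_invariant(self):
        df = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(10)], "expr_a": 3.0, "expr_b": 3.0}
        )
        out1 = partition_expression_groups(df)
        out2 = partition_expression_groups(df.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(out1.reset_index(drop=True), out2.reset_index(drop=True))
        assert list(out1["gene_id"]) == sorted(df["gene_id"])

    def test_too_few_records_rejected(self):
        df = pd.DataFrame({"gene_id": ["a"], "expr_a": [1.0], "expr_b": [1.0]})
        with pytest.raises(ValueError):
            partition_expression_groups(df)


class TestCrosstab:
    def _records(self, n=10):
        return partition_expression_groups(
            pd.DataFrame(
                {
                    "gene_id": [f"g{i}" for i in range(n)],
                    "expr_a": np.ones(n),
                    "expr_b": np.linspace(1, 100, n),
                }
            )
        )

    def test_degenerate_single_category(self):
        states = [GeneMarkState(f"g{i}", "K4", True, True, "K4-K4") for i in range(10)]
        counts, props = crosstab_states_by_group(states, self._records(), "K4")
        assert (counts["K4-K4"] == 2).all()
        assert (props["K4-K4"] == 1.0).all()
        assert counts.sum().sum() == 10

    def test_row_sums_reproduce_group_sizes(self):
        rng = np.random.default_rng(2)
        cats = [(bool(a), bool(b)) for a, b in rng.integers(0, 2, (10, 2))]
        states = [
            GeneMarkState(f"g{i}", "K4", a, b, classify_state(a, b, "K4"))
            for i, (a, b) in enumerate(cats)
        ]
        counts, _ = crosstab_states_by_group(states, self._records(), "K4")
        assert counts.sum(axis=1).tolist() == [2] * 5
        assert (counts.values >= 0).all() and counts.shape == (5, 4)

    def test_unmatched_gene_reported(self):
        states = [GeneMarkState("missing", "K4", True, True, "K4-K4")]
        with pytest.raises(ValueError, match="missing"):
            crosstab_states_by_group(states, self._records(), "K4")


class TestAssignStates:
    def test_presence_and_diff_support(self, genome):
        genes = [GeneModel("g1", iv("chrT", 1000, 4000, "+"))]
        peak = PeakRegion(iv("chrT", 900, 1200), 3, 1e-9)
        diff = [DifferentialRegion(iv("chrT", 900, 1100), HIGHER_IN_A, 2.0, 1)]
        states = assign_states(genes, [peak], [], "K4", genome, diff)
        s = states[0]
        assert (s.present_a, s.present_b, s.category) == (True, False, "K4-None")
        assert s.diff_supported
        wrong_dir = [DifferentialRegion(iv("chrT", 900, 1100), HIGHER_IN_B, -2.0, 1)]
        assert not assign_states(genes, [peak], [], "K4", genome, wrong_dir)[0].diff_supported


class TestTssBins:
    def _genes(self):
        return [
            GeneModel("gp", iv("chrT", 1000, 4000, "+")),
            GeneModel("gm", iv("chrU", 2000, 5001, "-")),  # TSS 5000
        ]

    def _region(self, chrom, mid):
        return DifferentialRegion(iv(chrom, mid - 100, mid + 100), HIGHER_IN_A, 1.0, 1)

    @pytest.mark.parametrize(
        "chrom,mid,expected_bin",
        [
            ("chrT", 1250, 2),   # 250 bp downstream on + strand
            ("chrU", 4900, 1),   # 100 bp downstream on - strand
            ("chrT", 999, -1),   # 1 bp upstream
            ("chrT", 1000, 1),   # bin +1 covers [TSS, TSS+200)
        ],
    )
    def test_strand_aware_bin_index(self, chrom, mid, expected_bin):
        hist = assign_diff_regions_to_tss_bins([self._region(chrom, mid)], self._genes())
        assert hist.counts == {expected_bin: 1}

    def test_far_regions_unassigned(self):
        hist = assign_diff_regions_to_tss_bins([self._region("chrT", 25_000)], self._genes())
        assert hist.counts == {} and hist.unassigned == 1


class TestFoldChangeFilter:
    def test_qpcr_worked_examples(self):
        table = load_qpcr_table()
        surg = table[table["set"] == "SURG"]["fold"]
        sdrg = table[table["set"] == "SDRG"]["fold"]
        assert fold_change_filter(surg, 15) == 8
        assert fold_change_filter(sdrg, 24) == 6
        assert surg.max() == 90148

    def test_threshold_inclusive_and_empty(self):
        assert fold_change_filter([15.0, 14.999], 15) == 1
        assert fold_change_filter([], 15) == 0

    def test_non_positive_fold_rejected(self):
        with pytest.raises(ValueError):
            fold_change_filter([10.0, 0.0], 2)
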
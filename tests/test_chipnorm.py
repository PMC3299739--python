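"""Two-stage differential detection: filtering, normalization, labeling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from senechip.chipnorm import (
    HIGHER_IN_A,
    HIGHER_IN_B,
    DiffConfig,
    call_differential_bins,
    differential_regions,
    merge_directional,
    quantile_normalize,
    stage1_filter,
)
from senechip.windows import WindowGrid

from conftest import make_track


class TestStage1Filter:
    def test_double_zero_bins_removed(self, genome):
        grid = WindowGrid(genome, 200)
        a = make_track(grid, chrT=[0, 30, 2], chrU=np.full(50, 2.0))
        b = make_track(grid, chrT=[0, 1, 2], chrU=np.full(50, 2.0))
        kept = stage1_filter(a, b, None, None)
        assert not kept["chrT"][0]

    def test_enriched_bin_retained(self, genome):
        grid = WindowGrid(genome, 200)
        base = np.full(150, 2.0)
        a_vec = base.copy()
        a_vec[5] = 30  # far above the background rate of ~2
        a = make_track(grid, chrT=a_vec, chrU=np.full(50, 2.0))
        b = make_track(grid, chrT=base, chrU=np.full(50, 2.0))
        kept = stage1_filter(a, b, None, None)
        assert kept["chrT"][5] and not kept["chrT"][6]

    def test_biased_bins_removed_when_both_inputs_high(self, genome):
        grid = WindowGrid(genome, 200)
        a_vec = np.full(150, 2.0)
        a_vec[3] = 50
        a = make_track(grid, chrT=a_vec, chrU=np.full(50, 2.0))
        b = make_track(grid, chrT=a_vec, chrU=np.full(50, 2.0))
        in_vec = np.full(150, 1.0)
        in_vec[3] = 10  # 10x the input mean in both inputs
        ia = make_track(grid, chrT=in_vec, chrU=np.ones(50))
        ib = make_track(grid, chrT=in_vec, chrU=np.ones(50))
        assert stage1_filter(a, b, ia, ib)["chrT"][3] == False  # noqa: E712
        assert stage1_filter(a, b, ia, ib, DiffConfig(use_bias_filter=False))["chrT"][3]
        one_sided = make_track(grid, chrT=np.ones(150), chrU=np.ones(50))
        assert stage1_filter(a, b, ia, one_sided)["chrT"][3]


class TestQuantileNormalize:
    def test_identical_inputs_unchanged(self):
        a = np.array([3.0, 1.0, 7.0])
        na, nb = quantile_normalize(a, a)
        np.testing.assert_allclose(na, a)
        np.testing.assert_allclose(nb, a)

    def test_worked_example(self):
        na, nb = quantile_normalize(np.array([1.0, 2, 3]), np.array([2.0, 4, 6]))
        np.testing.assert_allclose(na, [1.5, 3.0, 4.5])
        np.testing.assert_allclose(nb, [1.5, 3.0, 4.5])

    def test_ties_averaged_over_tied_ranks(self):
        na, _ = quantile_normalize(np.array([1.0, 1.0, 2.0]), np.array([1.0, 2.0, 3.0]))
        # reference [1, 1.5, 2.5]; the two tied values share mean(1, 1.5)
        np.testing.assert_allclose(na, [1.25, 1.25, 2.5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.ones(3), np.ones(4))

    @given(st.data())
    @settings(derandomize=True, max_examples=60)
    def test_rank_equivariance_and_common_distribution(self, data):
        n = data.draw(st.integers(2, 40))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        a, b = rng.random(n) * 10, rng.random(n) * 10  # ties have probability 0
        na, nb = quantile_normalize(a, b)
        np.testing.assert_allclose(np.sort(na), np.sort(nb))  # identical EDFs
        perm = rng.permutation(n)
        pa, pb = quantile_normalize(a[perm], b[perm])
        np.testing.assert_allclose(pa, na[perm])
        np.testing.assert_allclose(pb, nb[perm])


class TestCallDifferentialBins:
    def test_pseudocounted_ratio_rule(self):
        labels, fold = call_differential_bins(np.array([10.0]), np.array([4.0]))
        assert labels[0] == 1  # 11/5 = 2.2 >= 2
        assert fold[0] == pytest.approx(np.log2(11 / 5))

    def test_equal_values_unlabeled(self):
        labels, _ = call_differential_bins(np.array([5.0, 0.0]), np.array([5.0, 0.0]))
        assert list(labels) == [0, 0]

    def test_swapping_inputs_flips_labels(self):
        rng = np.random.default_rng(0)
        a, b = rng.poisson(8, 50).astype(float), rng.poisson(8, 50).astype(float)
        la, _ = call_differential_bins(a, b)
        lb, _ = call_differential_bins(b, a)
        np.testing.assert_array_equal(la, -lb)

    def test_monotone_in_tau(self):
        rng = np.random.default_rng(1)
        a, b = rng.poisson(10, 400).astype(float), rng.poisson(10, 400).astype(float)
        loose, _ = call_differential_bins(a, b, DiffConfig(tau=2.0))
        tight, _ = call_differential_bins(a, b, DiffConfig(tau=2.5))
        assert np.all((tight == 0) | (tight == loose))
        assert (tight != 0).sum() <= (loose != 0).sum()


class TestMergeDirectional:
    def _grid(self, genome):
        return WindowGrid(genome, 200)

    def _labels(self, grid, chrT):
        labels = {c: np.zeros(grid.n_windows(c), dtype=np.int8) for c in grid.genome}
        labels["chrT"][: len(chrT)] = chrT
        folds = {c: labels[c].astype(float) * 0.5 for c in grid.genome}
        return labels, folds

    def test_same_direction_run_merges(self, genome):
        grid = self._grid(genome)
        labels, folds = self._labels(grid, [0] * 10 + [1, 1, 1])
        regions = merge_directional(labels, grid, folds)
        assert len(regions) == 1
        r = regions[0]
        assert (r.interval.start, r.interval.end, r.n_bins) == (2000, 2600, 3)
        assert r.direction == HIGHER_IN_A

    def test_opposite_directions_never_merge(self, genome):
        grid = self._grid(genome)
        labels, folds = self._labels(grid, [1, -1])
        regions = merge_directional(labels, grid, folds)
        assert [r.direction for r in regions] == [HIGHER_IN_A, HIGHER_IN_B]

    def test_no_labels_gives_empty_output(self, genome):
        grid = self._grid(genome)
        labels, folds = self._labels(grid, [])
        assert merge_directional(labels, grid, folds) == []

    def test_gap_does_not_bridge_opposite_direction(self, genome):
        grid = self._grid(genome)
        labels, folds = self._labels(grid, [1, -1, 1])
        regions = merge_directional(labels, grid, folds, merge_gap=1)
        assert len(regions) == 3


class TestFullProcedure:
    def test_antisymmetric_under_condition_swap(self, genome):
        grid = WindowGrid(genome, 200)
        rng = np.random.default_rng(3)
        a = make_track(grid, chrT=rng.poisson(12, 150).astype(float), chrU=rng.poisson(12, 50).astype(float))
        b = make_track(grid, chrT=rng.poisson(12, 150).astype(float), chrU=rng.poisson(12, 50).astype(float))
        fwd, _ = differential_regions(a, b)
        rev, _ = differential_regions(b, a)
        assert len(fwd) == len(rev)
        flip = {HIGHER_IN_A: HIGHER_IN_B, HIGHER_IN_B: HIGHER_IN_A}
        for rf, rr in zip(fwd, rev):
            assert rf.interval == rr.interval
            assert rr.direction == flip[rf.direction]
            assert rf.mean_log2_fold == pytest.approx(-rr.mean_log2_fold)

    def test_null_false_labels_rare_at_depth(self):
        """With no planted differential and counts deep enough that 2-fold
        Poisson ratio noise is negligible, under 1% of retained bins are
        labeled differential."""
        from senechip.simulate import SimConfig, simulate_experiment
        from senechip.windows import count_windows, deduplicate, extend_reads, scale_to_total

        cfg = SimConfig(
            seed=0,
            background_rate=0.05,
            k4_proportions={"both": 0.625, "none": 0.375, "a_only": 0.0, "b_only": 0.0},
            k27_proportions={"none": 0.94, "both": 0.06, "a_only": 0.0, "b_only": 0.0},
        )
        res = simulate_experiment(cfg)
        grid = WindowGrid(res.genome, 200)

        def track(lib):
            return count_windows(
                extend_reads(deduplicate(res.reads[lib]), res.genome), grid
            )

        ta, tb = track("K4_ip_a"), track("K4_ip_b")
        ia = scale_to_total(track("input_a"), ta.library_total)
        ib = scale_to_total(track("input_b"), tb.library_total)
        _, table = differential_regions(ta, tb, ia, ib)
        retained = sum(int(m.sum()) for m in table.retained.values())
        labeled = sum(int((l != 0).sum()) for l in table.labels.values())
        assert retained > 500
        assert labeled / retained < 0.01


def test_config_invariants():
    with pytest.raises(ValueError):
        DiffConfig(tau=0.5)
    with pytest.raises(ValueError):
        DiffConfig(pseudocount=0.0)
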
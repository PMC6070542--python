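"""Network construction: symmetrization, thresholding, sparsity, cost."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connrep import (
    ConnectomeScan,
    apply_mask,
    cost_normalize,
    group_threshold_mask,
    sparsity,
    symmetrize,
    threshold_sweep,
)
from connrep.construction import EdgeMask, total_cost

from conftest import random_weight_matrix


def scans_with_edge(values, n=4, i=0, j=1):
    """One scan per value, with P_ij set to that value."""
    scans = []
    for k, v in enumerate(values):
        m = np.zeros((n, n))
        m[i, j] = m[j, i] = v
        scans.append(ConnectomeScan(f"{k:02d}", "1", m))
    return scans


class TestSymmetrize:
    def test_consistent_directed_inputs_pass_through(self):
        # seed-at-i and seed-at-j estimates that already agree: the average
        # reproduces the input (diagonal zeroed)
        rng = np.random.default_rng(0)
        fw = rng.random((5, 5))
        fw = 0.5 * (fw + fw.T)
        out = symmetrize(fw, fw.T)
        expected = fw.copy()
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(out, expected)

    def test_averages_forward_and_backward(self):
        fw = np.zeros((3, 3))
        bw = np.zeros((3, 3))
        fw[0, 1] = 0.2
        bw[1, 0] = 0.4
        out = symmetrize(fw, bw)
        assert out[0, 1] == pytest.approx(0.3)
        assert out[1, 0] == pytest.approx(0.3)

    def test_zero_inputs_and_shape_mismatch(self):
        assert np.all(symmetrize(np.zeros((4, 4)), np.zeros((4, 4))) == 0.0)
        with pytest.raises(ValueError, match="shape"):
            symmetrize(np.zeros((3, 3)), np.zeros((4, 4)))


class TestGroupThreshold:
    def test_zero_variance_edge_removed_below_threshold(self):
        scans = scans_with_edge([0.05, 0.05, 0.05])
        mask = group_threshold_mask(scans, 0.0575, "common")
        assert not mask.mask[0, 1]
        mask = group_threshold_mask(scans, 0.04, "common")
        assert mask.mask[0, 1]

    def test_mean_plus_two_sd_rule_hand_computed(self):
        # mean 0.025, sample sd 0.0129099, mean + 2 sd = 0.0508198 >= 0.05
        scans = scans_with_edge([0.01, 0.02, 0.03, 0.04])
        vals = np.array([0.01, 0.02, 0.03, 0.04])
        assert vals.mean() + 2 * vals.std(ddof=1) == pytest.approx(0.0508198, abs=1e-6)
        mask = group_threshold_mask(scans, 0.05, "common")
        assert mask.mask[0, 1]
        # a hair above the statistic removes it
        mask = group_threshold_mask(scans, 0.0509, "common")
        assert not mask.mask[0, 1]

    def test_tie_retains_edge(self):
        scans = scans_with_edge([0.05, 0.05])
        mask = group_threshold_mask(scans, 0.05, "common")
        assert mask.mask[0, 1]

    def test_separate_returns_one_mask_per_session(self, small_cohort):
        result = group_threshold_mask(small_cohort.all_scans(), 0.02, "separate")
        assert set(result) == {"1", "2"}
        for ses, mask in result.items():
            assert mask.session_scope == ses
            assert mask.strategy == "separate"

    def test_fewer_than_two_scans_errors(self):
        (scan,) = scans_with_edge([0.05])
        with pytest.raises(ValueError, match="2 scans"):
            group_threshold_mask([scan], 0.05, "common")

    def test_common_masks_shared_hence_equal_sparsity(self, small_cohort):
        mask = group_threshold_mask(small_cohort.all_scans(), 0.02, "common")
        # one pooled mask applies to every scan: sparsity trivially identical
        assert mask.session_scope == "pooled"
        assert sparsity(mask) == sparsity(mask)

    def test_raising_threshold_never_adds_edges(self, small_cohort):
        scans = small_cohort.all_scans()
        prev = None
        for t in threshold_sweep(0.01, 0.10, 0.01):
            mask = group_threshold_mask(scans, float(t), "common").mask
            if prev is not None:
                assert np.all(mask <= prev)  # edges only disappear
            prev = mask

    def test_separate_close_to_common_with_small_session_noise(self, default_cohort):
        scans = default_cohort.all_scans()
        com = group_threshold_mask(scans, 0.0575, "common")
        sep = group_threshold_mask(scans, 0.0575, "separate")
        for mask in sep.values():
            assert abs(sparsity(mask) - sparsity(com)) < 0.05


class TestThresholdSweep:
    def test_study_design_yields_37_thresholds(self):
        ths = threshold_sweep(0.01, 0.10, 0.0025)
        assert len(ths) == 37
        assert ths[0] == pytest.approx(0.01)
        assert ths[-1] == pytest.approx(0.10)

    def test_degenerate_and_plain_ranges(self):
        assert list(threshold_sweep(0.01, 0.01, 0.0025)) == [0.01]
        assert len(threshold_sweep(0.0, 0.3, 0.01)) == 31
        with pytest.raises(ValueError, match="step"):
            threshold_sweep(0.0, 0.1, 0.0)


class TestSparsity:
    def test_full_78_node_mask_denominator(self):
        m = ~np.eye(78, dtype=bool)
        assert sparsity(m) == 1.0
        assert 78 * 77 // 2 == 3003

    def test_empty_and_half_full(self):
        assert sparsity(np.zeros((10, 10), dtype=bool)) == 0.0
        m = np.zeros((4, 4), dtype=bool)
        for i, j in [(0, 1), (0, 2), (2, 3)]:
            m[i, j] = m[j, i] = True
        assert sparsity(m) == 0.5


class TestApplyMaskAndCost:
    def test_full_and_empty_masks(self, small_cohort):
        scan = small_cohort.all_scans()[0]
        n = scan.n_nodes
        full = EdgeMask(~np.eye(n, dtype=bool), 0.01, "common")
        empty = EdgeMask(np.zeros((n, n), dtype=bool), 0.01, "common")
        assert np.array_equal(apply_mask(scan, full).matrix, scan.matrix)
        assert np.all(apply_mask(scan, empty).matrix == 0.0)

    def test_single_retained_edge_symmetric(self, small_cohort):
        scan = small_cohort.all_scans()[0]
        n = scan.n_nodes
        m = np.zeros((n, n), dtype=bool)
        m[0, 1] = m[1, 0] = True
        out = apply_mask(scan, EdgeMask(m, 0.01, "common"))
        assert np.count_nonzero(out.matrix) == 2
        assert out.matrix[0, 1] == out.matrix[1, 0]

    def test_apply_mask_idempotent(self, small_cohort):
        scan = small_cohort.all_scans()[0]
        mask = group_threshold_mask(small_cohort.all_scans(), 0.02, "common")
        once = apply_mask(scan, mask)
        twice = apply_mask(once, mask)
        assert np.array_equal(once.matrix, twice.matrix)

    def test_cost_normalize_examples(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.4
        out = cost_normalize(m)
        assert out[0, 1] == pytest.approx(1.0)
        m[0, 2] = m[2, 0] = 0.1
        m[0, 1] = m[1, 0] = 0.3
        out = cost_normalize(m)
        assert out[0, 2] == pytest.approx(0.25)
        assert out[0, 1] == pytest.approx(0.75)

    def test_cost_normalize_all_zero_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            cost_normalize(np.zeros((4, 4)))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_cost_normalize_unit_cost_and_idempotence_at_unit_cost(self, seed):
        rng = np.random.default_rng(seed)
        W = random_weight_matrix(rng, 8)
        if total_cost(W) == 0.0:
            return
        out = cost_normalize(W)
        assert total_cost(out) == pytest.approx(1.0, abs=1e-12)
        again = cost_normalize(out)
        assert np.allclose(out, again, rtol=1e-12)
        assert np.all((W == 0) == (out == 0))
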
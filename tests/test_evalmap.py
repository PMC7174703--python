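"""Detection matching, recall/precision, SWC and density export."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytomap3d.evalmap import (UndefinedMetricError, density_grid,
                               match_detections, parse_swc, per_block_report,
                               recall_precision, to_swc)


def brute_force_best_matching(a, m, max_dist):
    """All one-to-one assignments; max cardinality, then min total distance."""
    a, m = np.asarray(a, float), np.asarray(m, float)
    best = (0, 0.0)
    n = min(len(a), len(m))
    best_pairs = []
    for k in range(n, -1, -1):
        found = None
        for a_idx in itertools.permutations(range(len(a)), k):
            for m_idx in itertools.combinations(range(len(m)), k):
                d = [np.linalg.norm(a[i] - m[j]) for i, j in zip(a_idx, m_idx)]
                if all(x <= max_dist for x in d):
                    if found is None or sum(d) < found[0]:
                        found = (sum(d), list(zip(a_idx, m_idx)))
        if found:
            return k, found[1]
    return 0, []


class TestMatching:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).uniform(0, 100, (12, 3))
        matches = match_detections(pts, pts, 5.0)
        assert len(matches) == 12
        assert all(d == 0.0 for _, _, d in matches)

    def test_shifted_beyond_max_dist(self):
        pts = np.random.default_rng(0).uniform(0, 100, (8, 3))
        assert match_detections(pts + 50.0, pts, 10.0) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_equals_brute_force_small_sets(self, seed):
        # well-separated truth + small jitter: greedy must find the unique
        # optimal assignment
        rng = np.random.default_rng(seed)
        m = rng.uniform(0, 200, (5, 3))
        while np.min(np.linalg.norm(m[:, None] - m[None], axis=2)
                     + np.eye(5) * 1e9) < 45.0:
            m = rng.uniform(0, 200, (5, 3))
        a = m + rng.normal(0, 1.5, m.shape)
        k_bf, pairs_bf = brute_force_best_matching(a, m, 10.0)
        matches = match_detections(a, m, 10.0)
        assert len(matches) == k_bf
        assert sorted((i, j) for i, j, _ in matches) == sorted(pairs_bf)

    def test_ambiguous_pair_resolved_optimally(self):
        # one auto point near two manual points: ascending-distance greedy
        # picks the globally cheapest assignment
        m = [(0.0, 0.0, 0.0), (6.0, 0.0, 0.0), (50.0, 0.0, 0.0)]
        a = [(1.0, 0.0, 0.0), (7.0, 0.0, 0.0), (49.0, 0.0, 0.0)]
        k_bf, pairs_bf = brute_force_best_matching(a, m, 10.0)
        matches = match_detections(a, m, 10.0)
        assert len(matches) == k_bf == 3
        assert sorted((i, j) for i, j, _ in matches) == sorted(pairs_bf)

    def test_monotone_in_max_dist(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 100, (15, 3))
        m = rng.uniform(0, 100, (12, 3))
        counts = [len(match_detections(a, m, d)) for d in (2.0, 5.0, 10.0, 25.0)]
        assert counts == sorted(counts)


class TestRecallPrecision:
    def test_identical_sets_100_100(self):
        pts = np.random.default_rng(1).uniform(0, 100, (10, 3))
        assert recall_precision(pts, pts, 10.0) == (100.0, 100.0)

    def test_nine_of_ten(self):
        pts = np.random.default_rng(1).uniform(0, 200, (10, 3))
        rec, prec = recall_precision(pts[:9], pts, 10.0)
        assert (rec, prec) == (90.0, 100.0)

    def test_empty_sets_raise(self):
        pts = np.ones((3, 3))
        with pytest.raises(UndefinedMetricError):
            recall_precision(pts, np.empty((0, 3)), 10.0)
        with pytest.raises(UndefinedMetricError):
            recall_precision(np.empty((0, 3)), pts, 10.0)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 100, (14, 3))
        m = rng.uniform(0, 100, (11, 3))
        r1, p1 = recall_precision(a, m, 15.0)
        r2, p2 = recall_precision(m, a, 15.0)
        assert (r1, p1) == (p2, r2)


class TestPerBlockReport:
    def test_five_perfect_blocks(self):
        pts = np.random.default_rng(3).uniform(0, 100, (20, 3))
        rep = per_block_report([(pts, pts)] * 5, 10.0)
        assert rep.mean_recall == 100.0 and rep.mean_precision == 100.0
        assert rep.sem_recall == 0.0

    def test_hand_computed_sem(self):
        # recalls (80, 90, 100) -> mean 90, SEM = SD/sqrt(3) = 5.7735
        rng = np.random.default_rng(4)
        blocks = []
        for n_missed in (2, 1, 0):
            m = rng.uniform(0, 500, (10, 3))
            a = m[n_missed:]
            blocks.append((a, m))
        rep = per_block_report(blocks, 10.0)
        assert np.isclose(rep.mean_recall, 90.0)
        assert np.isclose(rep.sem_recall, 5.7735, atol=1e-3)

    def test_single_block_sem_unavailable(self):
        pts = np.ones((4, 3))
        rep = per_block_report([(pts, pts)], 10.0)
        assert rep.sem_recall is None and rep.sem_precision is None

    def test_empty_manual_block_excluded(self):
        pts = np.ones((4, 3))
        with pytest.warns(UserWarning):
            rep = per_block_report([(pts, pts), (pts, np.empty((0, 3)))], 10.0)
        assert rep.excluded_blocks == [1]
        assert len(rep.blocks) == 1


class TestSwc:
    def test_node_per_cell_parent_minus_one(self):
        pts = np.random.default_rng(5).uniform(0, 100, (7, 3))
        rows = parse_swc(to_swc(pts))
        assert rows.shape == (7, 7)
        assert (rows[:, 1] == 1).all()
        assert (rows[:, 6] == -1).all()

    def test_empty_input_header_only(self):
        text = to_swc([])
        assert all(line.startswith("#") for line in text.strip().splitlines())

    def test_round_trip_coordinates(self):
        pts = np.random.default_rng(6).uniform(0, 300, (20, 3))
        rows = parse_swc(to_swc(pts))
        assert np.allclose(rows[:, 2:5], np.round(pts, 3), atol=5e-4)


class TestDensityGrid:
    def test_single_cell_bin(self):
        grid = density_grid([(25.0, 5.0, 5.0)], 20.0, extent_um=(40.0, 20.0, 20.0))
        assert grid.data[1, 0, 0] == 1 and grid.data.sum() == 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 200), st.integers(0, 10_000))
    def test_count_conservation_property(self, n, seed):
        pts = np.random.default_rng(seed).uniform(0, 400, (n, 3))
        grid = density_grid(pts, 20.0, extent_um=(400.0, 400.0, 400.0))
        assert int(grid.data.sum()) == n

    def test_uniform_counts_poisson(self):
        # chi-square sanity on 10^4 uniform points in 10^3 bins of 20 μm
        n = 10_000
        pts = np.random.default_rng(8).uniform(0, 200, (n, 3))
        grid = density_grid(pts, 20.0, extent_um=(200.0, 200.0, 200.0))
        counts = grid.data.ravel()
        lam = n / counts.size
        chi2 = ((counts - lam) ** 2 / lam).sum()
        # dof = 999; 4 sigma two-sided band
        dof = counts.size - 1
        assert abs(chi2 - dof) < 4 * np.sqrt(2 * dof)

    def test_outside_cells_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            grid = density_grid([(500.0, 5.0, 5.0)], 20.0, extent_um=(100.0,) * 3)
        assert grid.data.sum() == 1
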
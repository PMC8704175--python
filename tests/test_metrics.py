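from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from segeval.geometry import EmptyMaskError, GridMismatchError, Mask3D
from segeval.metrics import (
    directed_distance_percentile,
    dsc,
    evaluate_cohort,
    evaluate_pair,
    hausdorff,
    hd95,
    mann_whitney,
    round_half_up,
    summarize_values,
    t_test,
)
from segeval import tables
from .conftest import random_mask


def brute_force_directed_percentile(a_pts, b_pts, q):
    d = np.linalg.norm(a_pts[:, None, :] - b_pts[None, :, :], axis=2)
    return float(np.percentile(d.min(axis=1), q))


class TestDSC:
    def test_identical_masks_give_one(self, rng):
        m = random_mask(rng)
        assert dsc(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((1, 2, 2), np.uint8)
        b = np.zeros((1, 2, 2), np.uint8)
        a[0, 0, 0] = 1
        b[0, 1, 1] = 1
        assert dsc(Mask3D(a, (1, 1, 1)), Mask3D(b, (1, 1, 1))) == 0.0

    def test_half_overlap(self):
        a = np.zeros((1, 2, 4), np.uint8)
        b = np.zeros((1, 2, 4), np.uint8)
        a[0, 0, :] = 1  # |A| = 4
        b[0, :, :2] = 1  # |B| = 4, intersection 2
        assert dsc(Mask3D(a, (1, 1, 1)), Mask3D(b, (1, 1, 1))) == 0.5

    def test_grid_mismatch_and_double_empty_errors(self, rng):
        m = random_mask(rng)
        with pytest.raises(GridMismatchError):
            dsc(m, Mask3D(m.voxels, (9.0, 1.0, 1.0)))
        empty = Mask3D(np.zeros_like(m.voxels), m.spacing)
        with pytest.raises(EmptyMaskError):
            dsc(empty, empty)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_bounds(self, seed):
        r = np.random.default_rng(seed)
        a, b = random_mask(r), random_mask(r)
        v = dsc(a, b)
        assert 0.0 <= v <= 1.0
        assert v == dsc(b, a)

    def test_axis_permutation_invariance(self, rng):
        a, b = random_mask(rng, spacing=(1, 1, 1)), random_mask(rng, spacing=(1, 1, 1))
        base = dsc(a, b)
        for perm in [(1, 0, 2), (2, 1, 0)]:
            ap = Mask3D(a.voxels.transpose(perm), (1, 1, 1))
            bp = Mask3D(b.voxels.transpose(perm), (1, 1, 1))
            assert dsc(ap, bp) == base


class TestDirectedPercentile:
    def test_single_points_ten_mm_apart(self):
        assert directed_distance_percentile([(0, 0, 0)], [(0, 0, 10)], 100) == 10.0

    def test_identical_point_sets_give_zero(self, rng):
        pts = rng.random((20, 3))
        assert directed_distance_percentile(pts, pts, 95) == 0.0

    def test_matches_brute_force_on_random_clouds(self, rng):
        a = rng.random((200, 3)) * 50
        b = rng.random((200, 3)) * 50
        for q in (50, 95, 100):
            got = directed_distance_percentile(a, b, q)
            assert got == pytest.approx(brute_force_directed_percentile(a, b, q))

    def test_bad_percentile_rejected(self):
        with pytest.raises(ValueError):
            directed_distance_percentile([(0, 0, 0)], [(0, 0, 0)], 0)


class TestHD95:
    def test_identical_masks_zero(self, rng):
        m = random_mask(rng)
        assert hd95(m, m) == 0.0

    def test_two_voxels_eight_mm_apart(self):
        a = np.zeros((1, 1, 3), np.uint8)
        b = np.zeros((1, 1, 3), np.uint8)
        a[0, 0, 0] = 1
        b[0, 0, 2] = 1
        assert hd95(Mask3D(a, (1, 1, 4)), Mask3D(b, (1, 1, 4))) == 8.0

    def test_symmetry_and_upper_bound_by_hd(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        v = hd95(a, b)
        assert v == hd95(b, a)
        assert v <= hausdorff(a, b)

    def test_isotropic_spacing_scales_distances_not_dsc(self, rng):
        a, b = random_mask(rng, spacing=(1, 1, 1)), random_mask(rng, spacing=(1, 1, 1))
        a2 = Mask3D(a.voxels, (2, 2, 2))
        b2 = Mask3D(b.voxels, (2, 2, 2))
        assert hd95(a2, b2) == pytest.approx(2 * hd95(a, b))
        assert dsc(a2, b2) == dsc(a, b)

    @pytest.mark.parametrize("point_set", ["surface", "full"])
    def test_matches_brute_force_oracle(self, rng, point_set):
        from segeval.geometry import extract_surface_points

        for _ in range(10):
            a, b = random_mask(rng, p=0.35), random_mask(rng, p=0.35)
            if point_set == "surface":
                pa, pb = extract_surface_points(a), extract_surface_points(b)
            else:
                pa, pb = a.foreground_points_mm(), b.foreground_points_mm()
            expected = max(
                brute_force_directed_percentile(pa, pb, 95),
                brute_force_directed_percentile(pb, pa, 95),
            )
            assert hd95(a, b, point_set=point_set) == pytest.approx(expected)


class TestCohort:
    def test_single_pair_mean_is_value_sd_zero(self, rng):
        m = random_mask(rng)
        _, summary = evaluate_cohort([(m, m)])
        assert summary.n == 1
        assert summary.mean_dsc == 1.0
        assert summary.sd_dsc == 0.0

    def test_reference_cohort_group_means(self):
        df = tables.load_validation_metrics()
        g1 = df[df.group == "clinician_scoring"]
        g2 = df[df.group == "turing_test"]
        s1 = summarize_values(g1.dsc, g1.hd95_mm).rounded()
        s2 = summarize_values(g2.dsc, g2.hd95_mm).rounded()
        assert (s1.mean_dsc, s1.sd_dsc) == (0.91, 0.02)
        assert (s2.mean_dsc, s2.sd_dsc) == (0.89, 0.02)
        assert s1.mean_hd95 == 8.59

    def test_rounding_is_half_up(self):
        assert round_half_up(2.675) == 2.68
        assert round_half_up(0.905, 2) == 0.91
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(8.585, 2) == 8.59


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert mann_whitney(x, x)["p_two_sided"] == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_constant_samples_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = mann_whitney([2, 2, 2], [2, 2])
        assert out["p_two_sided"] == 1.0

    def test_small_samples_match_exact_enumeration_oracle(self, rng):
        for trial in range(20):
            x = rng.integers(0, 6, 4).astype(float)
            y = rng.integers(0, 6, 4).astype(float)
            if np.unique(np.concatenate([x, y])).size == 1:
                continue
            got = mann_whitney(x, y)
            # independent oracle: explicit loop over all C(8,4) labelings
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            center = len(x) * len(y) / 2
            off = len(x) * (len(x) + 1) / 2
            u_obs = ranks[: len(x)].sum() - off
            hits = total = 0
            for c in combinations(range(8), 4):
                u = ranks[list(c)].sum() - off
                total += 1
                if abs(u - center) >= abs(u_obs - center) - 1e-9:
                    hits += 1
            assert got["method"] == "exact"
            assert got["p_two_sided"] == pytest.approx(hits / total)

    def test_large_sample_matches_scipy_asymptotic(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.3, 1, 25)
        got = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert got["p_two_sided"] == pytest.approx(float(ref.pvalue))
        assert got["U"] == min(float(ref.statistic), 30 * 25 - float(ref.statistic))


def test_t_test_matches_scipy(rng):
    x, y = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
    got = t_test(x, y)
    ref = stats.ttest_ind(x, y)
    assert got["p_two_sided"] == pytest.approx(float(ref.pvalue))


def test_evaluate_pair_reports_consistent_fields(rng):
    a, b = random_mask(rng), random_mask(rng)
    m = evaluate_pair(a, b, patient_id="p")
    assert m.hd95_mm <= m.hd_mm
    assert m.hd95_mm == max(m.directed_95_a_to_b_mm, m.directed_95_b_to_a_mm)
    assert 0 <= m.dsc <= 1
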
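"""Evaluation metrics against brute-force oracles and hand-counted cases."""
import numpy as np
import pytest

from hepaseg.grids import Mask
from hepaseg.metrics import (asd, confusion_counts, dice_score,
                             extract_surface, major_axis_length,
                             precision_recall, rvd, stratify_cases)


def brute_force_asd(a, b, spacing):
    sa = extract_surface(a, spacing).points_mm
    sb = extract_surface(b, spacing).points_mm
    d_ab = sum(np.sqrt(((p - sb) ** 2).sum(axis=1)).min() for p in sa)
    d_ba = sum(np.sqrt(((p - sa) ** 2).sum(axis=1)).min() for p in sb)
    return (d_ab + d_ba) / (len(sa) + len(sb))


class TestDice:
    def test_identical_nonempty(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        assert dice_score(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dice_score(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, :2] = a[0, 1, :2] = a[0, 2, :2] = a[0, 3, :2] = True  # 8
        b[0, 0, :2] = b[0, 1, :2] = b[1, 0, :2] = b[1, 1, :2] = True  # 8, 4 shared
        assert dice_score(a, b) == 0.5

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice_score(z, z) == 1.0

    def test_matches_confusion_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random((8, 8, 8)) < 0.3
            b = rng.random((8, 8, 8)) < 0.3
            c = confusion_counts(a, b)
            expected = 1.0 if a.sum() + b.sum() == 0 else \
                2 * c.tp / (2 * c.tp + c.fp + c.fn)
            assert dice_score(a, b) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_score(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestSurface:
    def test_single_voxel(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        s = extract_surface(m, (1, 1, 1))
        assert len(s.indices) == 1

    def test_solid_cube_surface_count(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        assert len(extract_surface(m, (1, 1, 1)).indices) == 26

    def test_thin_slab_all_surface(self):
        m = np.zeros((5, 5, 1), bool)
        m[:, :, 0] = True
        assert len(extract_surface(m, (1, 1, 1)).indices) == 25

    def test_border_counts_as_outside(self):
        m = np.ones((3, 3, 3), bool)
        assert len(extract_surface(m, (1, 1, 1)).indices) == 26  # all but center

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            extract_surface(np.zeros((3, 3, 3), bool), (1, 1, 1))


class TestASD:
    def test_identical_zero(self):
        m = np.zeros((6, 6, 6), bool)
        m[2:4, 2:4, 2:4] = True
        assert asd(m, m, (1, 1, 1)) == 0.0

    def test_two_points_three_apart(self):
        a = np.zeros((8, 4, 4), bool)
        b = np.zeros((8, 4, 4), bool)
        a[1, 1, 1] = True
        b[4, 1, 1] = True
        assert asd(a, b, (1, 1, 1)) == pytest.approx(3.0, abs=1e-12)
        assert asd(a, b, (0.5, 1, 1)) == pytest.approx(1.5, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.random((10, 10, 10)) < 0.2
        b = rng.random((10, 10, 10)) < 0.2
        a[0, 0, 0] = b[5, 5, 5] = True
        sp = (0.7, 0.7, 2.5)
        assert asd(a, b, sp) == pytest.approx(asd(b, a, sp), abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        spacing = (0.7, 0.7, 2.5)
        for _ in range(50):
            a = rng.random((16, 16, 16)) < 0.2
            b = rng.random((16, 16, 16)) < 0.2
            if not a.any():
                a[tuple(rng.integers(0, 16, 3))] = True
            if not b.any():
                b[tuple(rng.integers(0, 16, 3))] = True
            assert asd(a, b, spacing) == pytest.approx(
                brute_force_asd(a, b, spacing), abs=1e-9)

    def test_empty_raises(self):
        m = np.zeros((4, 4, 4), bool)
        n = m.copy()
        n[1, 1, 1] = True
        with pytest.raises(ValueError):
            asd(m, n, (1, 1, 1))


class TestRVDPrecisionRecall:
    def test_rvd_cases(self):
        a = np.zeros((10, 10, 10), bool)
        a.flat[:100] = True
        b = np.zeros((10, 10, 10), bool)
        b.flat[:102] = True
        assert rvd(a, b) == pytest.approx(0.02)
        assert rvd(a, a) == 0.0
        assert rvd(a, np.zeros_like(a)) == -1.0
        with pytest.raises(ValueError):
            rvd(np.zeros_like(a), b)

    def test_precision_recall_counts(self):
        # TP=4, FP=4, FN=12
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a.flat[:8] = True
        b.flat[4:20] = True
        prec, rec = precision_recall(a, b)
        assert prec == 0.5 and rec == 0.25

    def test_subset_case(self):
        b = np.zeros((4, 4, 4), bool)
        b[1:3, 1:3, 1:3] = True
        a = b.copy()
        a[2, 2, 2] = False
        prec, rec = precision_recall(a, b)
        assert prec == 1.0
        assert rec == pytest.approx(a.sum() / b.sum())

    def test_precision_recall_duality(self):
        rng = np.random.default_rng(2)
        a = rng.random((6, 6, 6)) < 0.4
        b = rng.random((6, 6, 6)) < 0.4
        assert precision_recall(a, b)[0] == precision_recall(b, a)[1]


class TestMajorAxis:
    def test_single_voxel_zero(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        assert major_axis_length(m, (1, 1, 1)) == [0.0]

    def test_rod_endpoint_distance(self):
        m = np.zeros((3, 3, 13), bool)
        m[1, 1, 1:12] = True
        (length,) = major_axis_length(m, (1, 1, 1))
        assert length == pytest.approx(10.0)

    def test_two_components_sorted_by_label(self):
        m = np.zeros((20, 5, 5), bool)
        m[1:4, 1, 1] = True      # length 2
        m[10:16, 1, 1] = True    # length 5
        lengths = major_axis_length(m, (1, 1, 1))
        assert sorted(lengths) == pytest.approx([2.0, 5.0])

    def test_empty_mask_empty_list(self):
        assert major_axis_length(np.zeros((3, 3, 3), bool), (1, 1, 1)) == []

    def test_spacing_scales_lengths(self):
        m = np.zeros((3, 3, 6), bool)
        m[1, 1, 1:5] = True
        (length,) = major_axis_length(m, (1, 1, 2.5))
        assert length == pytest.approx(3 * 2.5)


class TestStratification:
    def test_all_high(self):
        out = stratify_cases([{"dice": 1.0, "lengths": [5.0]}] * 3)
        assert out["low"]["n_cases"] == 0
        assert np.isnan(out["low"]["mean_major_axis_mm"])

    def test_boundary_goes_high(self):
        out = stratify_cases([{"dice": 0.59, "lengths": [1.0]},
                              {"dice": 0.60, "lengths": [2.0]}])
        assert out["high"]["n_cases"] == 1
        assert out["low"]["n_cases"] == 1
        assert out["high"]["mean_major_axis_mm"] == 2.0

    def test_group_means(self):
        cases = [{"dice": 0.3, "lengths": [10.0, 20.0]},
                 {"dice": 0.9, "lengths": [40.0]}]
        out = stratify_cases(cases)
        assert out["low"]["mean_major_axis_mm"] == 15.0
        assert out["high"]["mean_major_axis_mm"] == 40.0


def test_axis_permutation_invariance():
    rng = np.random.default_rng(3)
    a = rng.random((8, 10, 6)) < 0.25
    b = rng.random((8, 10, 6)) < 0.25
    a[0, 0, 0] = b[1, 1, 1] = True
    spacing = (0.7, 1.1, 2.0)
    perm = (2, 0, 1)
    ap, bp = a.transpose(perm), b.transpose(perm)
    sp = tuple(spacing[i] for i in perm)
    assert dice_score(ap, bp) == dice_score(a, b)
    assert asd(ap, bp, sp) == pytest.approx(asd(a, b, spacing), abs=1e-12)
    assert sorted(major_axis_length(ap, sp)) == pytest.approx(
        sorted(major_axis_length(a, spacing)), abs=1e-9)


def test_mask_container_carries_spacing():
    g = np.zeros((4, 4, 4), np.uint8)
    g[1:3, 1:3, 1:3] = 1
    m = Mask(g, (2.0, 1.0, 1.0))
    s = extract_surface(m)
    assert s.spacing == (2.0, 1.0, 1.0)
    assert s.points_mm[:, 0].max() <= 2.0 * 3
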
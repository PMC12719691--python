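"""Metric unit tests against brute-force voxel/distance oracles."""

import numpy as np
import pytest

from dvaseg import (
    BinaryMask,
    EmptySurfaceError,
    GridMismatchError,
    MetricConfig,
    QualityMatrix,
    cohort_score,
    extract_surface,
    per_slice_cohort_score,
    scan_quality,
    surface_dsc,
    volumetric_dsc,
)
from conftest import random_mask_pair


def brute_dsc(a, b):
    na, nb = a.labels.sum(), b.labels.sum()
    return 2.0 * np.logical_and(a.labels, b.labels).sum() / (na + nb)


def brute_surface(mask):
    """Face-neighbour surface voxels by explicit enumeration."""
    pts = []
    arr = mask.labels
    for idx in np.argwhere(arr):
        z, y, x = idx
        for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)]:
            nz, ny, nx = z + dz, y + dy, x + dx
            if (not (0 <= nz < arr.shape[0] and 0 <= ny < arr.shape[1]
                     and 0 <= nx < arr.shape[2]) or not arr[nz, ny, nx]):
                pts.append(idx * np.asarray(mask.spacing))
                break
    return np.array(pts)


def brute_surface_dsc(a, b, tau):
    sa, sb = brute_surface(a), brute_surface(b)
    hits = 0
    for p in sa:
        if np.sqrt(((sb - p) ** 2).sum(axis=1)).min() <= tau:
            hits += 1
    for q in sb:
        if np.sqrt(((sa - q) ** 2).sum(axis=1)).min() <= tau:
            hits += 1
    return hits / (len(sa) + len(sb))


def square_mask(shape, z, y0, y1, x0, x1, spacing=(1.0, 1.0, 1.0)):
    arr = np.zeros(shape, dtype=np.uint8)
    arr[z, y0:y1, x0:x1] = 1
    return BinaryMask(arr, spacing)


class TestVolumetricDsc:
    def test_worked_examples(self):
        full = square_mask((1, 10, 10), 0, 0, 10, 0, 10)
        assert volumetric_dsc(full, full) == 1.0
        a = square_mask((1, 12, 20), 0, 1, 11, 0, 10)
        b = square_mask((1, 12, 20), 0, 1, 11, 10, 20)
        assert volumetric_dsc(a, b) == 0.0
        # 10x10 squares overlapping in a 5x10 strip: |A|=|B|=100, |A^B|=50
        c = square_mask((1, 12, 20), 0, 1, 11, 5, 15)
        assert volumetric_dsc(a, c) == pytest.approx(0.5)

    def test_empty_conventions(self):
        empty = BinaryMask(np.zeros((2, 3, 3), np.uint8), (1, 1, 1))
        one = square_mask((2, 3, 3), 0, 0, 2, 0, 2)
        assert volumetric_dsc(empty, empty) == 1.0
        assert volumetric_dsc(empty, empty,
                              MetricConfig(empty_pair_value=0.3)) == 0.3
        assert volumetric_dsc(empty, one) == 0.0

    def test_shape_mismatch_raises(self):
        a = square_mask((1, 4, 4), 0, 0, 2, 0, 2)
        b = square_mask((2, 4, 4), 0, 0, 2, 0, 2)
        with pytest.raises(GridMismatchError):
            volumetric_dsc(a, b)


class TestSurfaceExtraction:
    def test_single_voxel_is_its_own_surface(self):
        m = square_mask((3, 3, 3), 1, 1, 2, 1, 2, spacing=(2.0, 1.0, 0.5))
        surf = extract_surface(m)
        assert surf.shape == (1, 3)
        np.testing.assert_allclose(surf[0], [2.0, 1.0, 0.5])

    def test_cube_surface_excludes_centre(self):
        arr = np.zeros((5, 5, 5), np.uint8)
        arr[1:4, 1:4, 1:4] = 1
        surf = extract_surface(BinaryMask(arr, (1, 1, 1)))
        assert len(surf) == 26
        assert not any((p == [2, 2, 2]).all() for p in surf)

    def test_thin_sheet_is_all_surface(self):
        m = square_mask((1, 6, 6), 0, 1, 5, 1, 5)
        assert len(extract_surface(m)) == 16

    def test_empty_mask_raises(self):
        with pytest.raises(EmptySurfaceError):
            extract_surface(BinaryMask(np.zeros((2, 2, 2), np.uint8), (1, 1, 1)))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, _ = random_mask_pair(rng)
        if a.is_empty():
            return
        got = extract_surface(a)
        expect = brute_surface(a)
        assert sorted(map(tuple, got)) == sorted(map(tuple, expect))


class TestSurfaceDsc:
    def test_identity_and_offset_examples(self):
        a = square_mask((1, 10, 10), 0, 1, 9, 1, 9)
        assert surface_dsc(a, a, MetricConfig(tolerance_mm=0.0)) == 1.0
        # 8x8 squares offset by one 1 mm voxel: every surface point is
        # within 1 mm of the other surface
        b = square_mask((1, 10, 10), 0, 1, 9, 2, 10)
        assert surface_dsc(a, b, MetricConfig(tolerance_mm=1.0)) == 1.0
        assert surface_dsc(a, b, MetricConfig(tolerance_mm=0.0)) < 1.0

    def test_empty_conventions(self):
        empty = BinaryMask(np.zeros((2, 4, 4), np.uint8), (1, 1, 1))
        one = square_mask((2, 4, 4), 0, 0, 2, 0, 2)
        assert surface_dsc(empty, empty) == 1.0
        assert surface_dsc(empty, one) == 0.0

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(4)
        a, b = random_mask_pair(rng)
        if a.is_empty() or b.is_empty():
            pytest.skip("degenerate draw")
        vals = [surface_dsc(a, b, MetricConfig(tolerance_mm=t))
                for t in (0.0, 0.5, 1.0, 2.0, 5.0, 50.0)]
        assert vals == sorted(vals)
        assert vals[-1] == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b = random_mask_pair(rng)
        tau = float(rng.uniform(0.0, 3.0))
        cfg = MetricConfig(tolerance_mm=tau)
        if a.is_empty() or b.is_empty():
            return
        assert surface_dsc(a, b, cfg) == brute_surface_dsc(a, b, tau)
        assert surface_dsc(b, a, cfg) == surface_dsc(a, b, cfg)


class TestScanQuality:
    def test_mean_of_components(self):
        a = square_mask((1, 12, 20), 0, 1, 11, 0, 10)
        c = square_mask((1, 12, 20), 0, 1, 11, 5, 15)
        cfg = MetricConfig(tolerance_mm=5.0)
        expect = 0.5 * (volumetric_dsc(a, c, cfg) + surface_dsc(a, c, cfg))
        assert scan_quality(a, c, cfg) == pytest.approx(expect)
        assert scan_quality(a, a, cfg) == 1.0

    def test_disjoint_far_masks_score_zero(self):
        a = square_mask((1, 4, 40), 0, 0, 4, 0, 4)
        b = square_mask((1, 4, 40), 0, 0, 4, 36, 40)
        assert scan_quality(a, b, MetricConfig(tolerance_mm=1.0)) == 0.0


class TestCohortScore:
    def test_mean_of_row_maxima(self):
        q = QualityMatrix([[0.8, 0.6], [0.5, 0.7], [0.9, 0.9]])
        assert cohort_score(q) == pytest.approx(0.8)

    def test_single_variant_reduces_to_mean(self):
        rng = np.random.default_rng(0)
        col = rng.random((7, 1))
        assert cohort_score(QualityMatrix(col)) == pytest.approx(col.mean())

    @pytest.mark.parametrize("seed", range(25))
    def test_monotone_under_added_variants(self, seed):
        rng = np.random.default_rng(seed)
        n, k = rng.integers(1, 8), rng.integers(1, 5)
        scores = rng.random((n, k))
        extra = rng.random((n, 1))
        before = cohort_score(QualityMatrix(scores))
        after = cohort_score(QualityMatrix(np.hstack([scores, extra])))
        assert after >= before - 1e-12
        # direct recomputation oracle
        assert after == pytest.approx(
            float(np.mean(np.max(np.hstack([scores, extra]), axis=1))))

    def test_rejects_invalid_matrices(self):
        with pytest.raises(ValueError):
            QualityMatrix(np.empty((0, 2)))
        with pytest.raises(ValueError):
            QualityMatrix([[0.5, 1.2]])


def test_per_slice_score_at_least_per_scan_for_identical_masks():
    """With a single variant equal to the reference both modes give 1."""
    m = square_mask((3, 8, 8), 1, 2, 6, 2, 6)
    assert per_slice_cohort_score([[m]], [m]) == 1.0
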
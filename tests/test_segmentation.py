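"""Threshold, 3x3 morphology, component extraction and Feret metrology."""

import numpy as np
import pytest

from hccwave import (
    BinaryImage,
    CTSlice,
    MRAConfig,
    ROIMask,
    SegmentationConfig,
    TissueIntensityModel,
    binarize,
    dilate3x3,
    erode3x3,
    extract_lesions,
    max_feret_diameter,
    morphological_open,
    run_pipeline,
)
from hccwave.phantom import PhantomSpec, generate_phantom
from hccwave.segmentation import EmptyMaskError

PITCH = 0.8


def bimg(mask):
    return BinaryImage(mask=np.asarray(mask, dtype=bool), pixel_pitch=PITCH)


def brute_erode(mask):
    """Direct neighbourhood scan; out-of-bounds neighbours count as 0."""
    m = np.asarray(mask, dtype=bool)
    out = np.zeros_like(m)
    rows, cols = m.shape
    for r in range(rows):
        for c in range(cols):
            ok = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < rows and 0 <= cc < cols and m[rr, cc]):
                        ok = False
            out[r, c] = ok
    return out


def brute_dilate(mask):
    m = np.asarray(mask, dtype=bool)
    out = np.zeros_like(m)
    rows, cols = m.shape
    for r in range(rows):
        for c in range(cols):
            hit = False
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and m[rr, cc]:
                        hit = True
            out[r, c] = hit
    return out


def brute_feret(pixels, pitch):
    """All-pairs caliper over every given pixel, plus one-pitch end correction."""
    pts = np.asarray(pixels, dtype=float)
    best = 0.0
    for i in range(len(pts)):
        for j in range(i, len(pts)):
            d = np.hypot(*(pts[i] - pts[j]))
            best = max(best, d)
    return (best + 1.0) * pitch / 10.0


def disk_mask(shape, center, radius_px):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


class TestBinarize:
    def test_uniform_below_threshold(self):
        assert not binarize(np.full((4, 4), 60.0), 65.0, PITCH).mask.any()

    def test_uniform_above_threshold(self):
        assert binarize(np.full((4, 4), 90.0), 65.0, PITCH).mask.all()

    def test_strict_inequality_elementwise(self):
        img = np.array([[64, 65, 66], [90, 55, 70], [65, 66, 64]], dtype=float)
        expected = np.array([[0, 0, 1], [1, 0, 1], [0, 1, 0]], dtype=bool)
        np.testing.assert_array_equal(binarize(img, 65.0, PITCH).mask, expected)

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), np.nan, PITCH)


class TestMorphology:
    def test_erode_single_pixel_vanishes(self):
        m = np.zeros((7, 7), dtype=bool)
        m[3, 3] = True
        assert not erode3x3(bimg(m)).mask.any()

    def test_erode_solid_block_keeps_centre(self):
        m = np.zeros((9, 9), dtype=bool)
        m[2:7, 2:7] = True
        expected = np.zeros_like(m)
        expected[3:6, 3:6] = True
        np.testing.assert_array_equal(erode3x3(bimg(m)).mask, expected)

    def test_erode_all_ones_shrinks_at_border(self):
        m = np.ones((6, 8), dtype=bool)
        out = erode3x3(bimg(m)).mask
        assert out[1:-1, 1:-1].all()
        assert not out[0].any() and not out[-1].any()
        assert not out[:, 0].any() and not out[:, -1].any()

    def test_dilate_single_pixel_grows_to_block(self):
        m = np.zeros((7, 7), dtype=bool)
        m[3, 3] = True
        expected = np.zeros_like(m)
        expected[2:5, 2:5] = True
        np.testing.assert_array_equal(dilate3x3(bimg(m)).mask, expected)

    def test_dilate_empty_stays_empty(self):
        assert not dilate3x3(bimg(np.zeros((5, 5)))).mask.any()

    def test_opening_restores_solid_block(self):
        m = np.zeros((9, 9), dtype=bool)
        m[2:7, 2:7] = True
        np.testing.assert_array_equal(morphological_open(bimg(m)).mask, m)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_neighbourhood_scan(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((12, 15)) < 0.45
        np.testing.assert_array_equal(erode3x3(bimg(m)).mask, brute_erode(m))
        np.testing.assert_array_equal(dilate3x3(bimg(m)).mask, brute_dilate(m))

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_erosion_dilation_duality(self, seed):
        """dilate(b) == NOT erode(NOT b) under the reflect boundary rule."""
        rng = np.random.default_rng(seed)
        b = bimg(rng.random((20, 20)) < 0.4)
        lhs = dilate3x3(b, "reflect").mask
        rhs = ~erode3x3(bimg(~b.mask), "reflect").mask
        np.testing.assert_array_equal(lhs, rhs)

    def test_opening_removes_isolated_pixels(self):
        rng = np.random.default_rng(9)
        m = np.zeros((30, 30), dtype=bool)
        idx = rng.choice(900, size=12, replace=False)
        m[np.unravel_index(idx, m.shape)] = True
        # keep only truly isolated specks
        from scipy import ndimage

        lab, n = ndimage.label(m, structure=np.ones((3, 3)))
        sizes = ndimage.sum_labels(m, lab, range(1, n + 1))
        m[np.isin(lab, np.nonzero(sizes > 1)[0] + 1)] = False
        assert not morphological_open(bimg(m)).mask.any()

    def test_opening_preserves_large_disk(self):
        m = disk_mask((40, 40), (19.5, 19.5), 12.5)
        opened = morphological_open(bimg(m)).mask
        change = abs(int(opened.sum()) - int(m.sum())) / m.sum()
        assert opened.sum() > 0
        assert change < 0.15

    @pytest.mark.parametrize("seed", [6, 7])
    def test_opening_idempotent_and_antiextensive(self, seed):
        rng = np.random.default_rng(seed)
        b = bimg(rng.random((25, 25)) < 0.5)
        once = morphological_open(b)
        twice = morphological_open(once)
        np.testing.assert_array_equal(once.mask, twice.mask)
        assert not (once.mask & ~b.mask).any()  # open(b) subset of b


class TestExtractLesions:
    def test_two_blobs_give_two_measurements(self, full_roi):
        m = np.zeros((20, 20), dtype=bool)
        m[2:4, 2:7] = True  # 10 px
        m[10:12, 10:15] = True  # 10 px
        out = extract_lesions(bimg(m), full_roi((20, 20)))
        assert len(out) == 2
        assert all(l.pixel_count == 10 for l in out)

    def test_blob_outside_roi_excluded(self):
        m = np.zeros((20, 20), dtype=bool)
        m[2:5, 2:5] = True
        roi = np.zeros((20, 20), dtype=bool)
        roi[10:, 10:] = True
        assert extract_lesions(bimg(m), ROIMask(mask=roi)) == []

    def test_diagonal_chain_is_single_component(self, full_roi):
        m = np.zeros((10, 10), dtype=bool)
        for i in range(5):
            m[i, i] = True
        out = extract_lesions(bimg(m), full_roi((10, 10)))
        assert len(out) == 1
        assert out[0].pixel_count == 5

    def test_min_pixels_filter(self, full_roi):
        m = np.zeros((10, 10), dtype=bool)
        m[1, 1:4] = True  # 3 px < default min of 4
        assert extract_lesions(bimg(m), full_roi((10, 10))) == []
        assert len(extract_lesions(bimg(m), full_roi((10, 10)), min_pixels=3)) == 1

    def test_empty_roi_raises(self):
        m = np.ones((5, 5), dtype=bool)
        with pytest.raises(EmptyMaskError):
            extract_lesions(bimg(m), ROIMask(mask=np.zeros((5, 5), dtype=bool)))

    def test_area_and_invariants(self, full_roi):
        m = np.zeros((30, 30), dtype=bool)
        m[5:10, 5:10] = True  # 25 px
        (les,) = extract_lesions(bimg(m), full_roi((30, 30)))
        assert les.area_cm2 == pytest.approx(25 * (PITCH / 10) ** 2)
        assert les.max_diameter_cm >= PITCH / 10
        assert les.area_cm2 <= les.max_diameter_cm**2 + 1e-12


class TestMaxFeretDiameter:
    def test_single_pixel_has_one_pitch_diameter(self):
        assert max_feret_diameter(np.array([[3, 4]]), PITCH) == pytest.approx(0.08)

    def test_horizontal_run(self):
        pts = np.array([[0, c] for c in range(100)])
        assert max_feret_diameter(pts, PITCH) == pytest.approx(8.0)

    def test_rasterized_disk_recovers_true_diameter(self):
        # 5.0 cm diameter at 0.8 mm pitch -> radius 31.25 px
        m = disk_mask((80, 80), (39.5, 39.5), 31.25)
        pts = np.argwhere(m)
        d = max_feret_diameter(pts, PITCH)
        assert d == pytest.approx(5.0, abs=0.16)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.unique(rng.integers(0, 40, size=(60, 2)), axis=0)
        assert max_feret_diameter(pts, PITCH) == pytest.approx(
            brute_feret(pts, PITCH), abs=1e-12
        )

    def test_collinear_points(self):
        pts = np.array([[i, 2 * i] for i in range(10)])
        assert max_feret_diameter(pts, PITCH) == pytest.approx(
            brute_feret(pts, PITCH), abs=1e-12
        )

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            max_feret_diameter(np.empty((0, 2)), PITCH)


class TestRunPipeline:
    def test_near_noiseless_disk_measured_accurately(self, full_roi):
        spec = PhantomSpec(
            tissue=TissueIntensityModel(55, 0.5, 90, 0.5),
            lesions=((127.5, 255.5, 4.0),),
            seed=1,
        )
        inst = generate_phantom(spec)
        out = run_pipeline(inst.slice, full_roi(spec.field_shape))
        assert len(out) == 1
        assert out[0].max_diameter_cm == pytest.approx(4.0, abs=0.32)

    def test_phantom_without_lesion_yields_empty_list(self, full_roi):
        spec = PhantomSpec(seed=2)
        inst = generate_phantom(spec)
        assert run_pipeline(inst.slice, full_roi(spec.field_shape)) == []

    def test_contrast_monotonicity(self, full_roi):
        """More enhancement never shrinks the detected lesion (noiseless)."""
        counts = []
        for mu_c in (70.0, 80.0, 90.0, 105.0):
            spec = PhantomSpec(
                tissue=TissueIntensityModel(55, 0.5, mu_c, 0.5),
                lesions=((127.5, 255.5, 3.0),),
                seed=3,
            )
            inst = generate_phantom(spec)
            out = run_pipeline(inst.slice, full_roi(spec.field_shape))
            counts.append(out[0].pixel_count if out else 0)
        assert counts == sorted(counts)

    def test_deterministic(self, full_roi):
        spec = PhantomSpec(lesions=((127.5, 255.5, 2.0),), seed=4)
        inst = generate_phantom(spec)
        a = run_pipeline(inst.slice, full_roi(spec.field_shape))
        b = run_pipeline(inst.slice, full_roi(spec.field_shape))
        assert [l.max_diameter_cm for l in a] == [l.max_diameter_cm for l in b]

    def test_threshold_multiplier_zero_admits_more_pixels(self, full_roi):
        spec = PhantomSpec(lesions=((127.5, 255.5, 3.0),), seed=5)
        inst = generate_phantom(spec)
        default = run_pipeline(inst.slice, full_roi(spec.field_shape))
        literal = run_pipeline(
            inst.slice,
            full_roi(spec.field_shape),
            seg=SegmentationConfig(threshold_sd_multiplier=0.0),
        )
        assert sum(l.pixel_count for l in literal) >= sum(
            l.pixel_count for l in default
        )
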
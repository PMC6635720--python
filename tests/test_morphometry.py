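"""Unit tests for the geometric feature extractors."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from scipy.spatial.distance import cdist
from skimage.draw import disk as draw_disk, line as draw_line

from cmlcells.morphometry import (
    DegenerateShapeError,
    MorphometryConfig,
    SplitResult,
    avg_cytoplasm_b,
    bottleneck_pair,
    boundary_pixels,
    count_lobes,
    extract_features,
    hausdorff_distance,
    min_convex_thickness,
    nucleus_area,
    ordered_contour,
    perimeter_smaller_part,
    pixel_perimeter,
    resolve_split,
    validate_split,
)

from conftest import random_blob, record_from_truth


def _disk_mask(shape, center, r):
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, r, shape=shape)
    m[rr, cc] = True
    return m


def _dumbbell(neck_width=10):
    """Two radius-40 disks bridged by a narrow neck."""
    m = np.zeros((110, 230), dtype=bool)
    m |= _disk_mask(m.shape, (55, 55), 40)
    m |= _disk_mask(m.shape, (55, 175), 40)
    half = neck_width // 2
    m[55 - half : 55 + half, 55:175] = True
    return m


class TestLobesAndArea:
    def test_single_disk_one_lobe(self):
        assert count_lobes(_disk_mask((60, 60), (30, 30), 20)) == 1

    def test_three_disjoint_disks(self):
        m = np.zeros((60, 180), dtype=bool)
        for c in (30, 90, 150):
            m |= _disk_mask(m.shape, (30, c), 20)
        assert count_lobes(m) == 3

    def test_empty_mask_errors(self):
        with pytest.raises(DegenerateShapeError):
            count_lobes(np.zeros((10, 10), dtype=bool))

    def test_filled_square_area(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2:7, 2:7] = True
        assert nucleus_area(m) == 25

    def test_disk_area_near_pi_r2(self):
        m = _disk_mask((120, 120), (60, 60), 50)
        assert abs(nucleus_area(m) - np.pi * 50**2) / (np.pi * 50**2) < 0.02

    def test_area_additive_over_parts(self):
        a = _disk_mask((60, 160), (30, 40), 18)
        b = _disk_mask((60, 160), (30, 120), 23)
        assert nucleus_area(a | b) == nucleus_area(a) + nucleus_area(b)


class TestCytoplasmColor:
    def test_neutral_gray_near_zero(self):
        img = np.full((40, 40, 3), 128, dtype=np.uint8)
        m = np.ones((40, 40), dtype=bool)
        assert abs(avg_cytoplasm_b(img, m)) < 1.0

    def test_blue_is_negative(self):
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        img[..., 2] = 255
        assert avg_cytoplasm_b(img, np.ones((40, 40), bool)) < 0

    def test_matches_independent_srgb_to_lab_conversion(self):
        img = np.full((8, 8, 3), (200, 180, 140), dtype=np.uint8)
        got = avg_cytoplasm_b(img, np.ones((8, 8), bool))
        # independent conversion: sRGB -> linear -> XYZ (D65) -> L*a*b*
        rgb = np.array([200, 180, 140]) / 255.0
        lin = np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
        M = np.array(
            [
                [0.4124564, 0.3575761, 0.1804375],
                [0.2126729, 0.7151522, 0.0721750],
                [0.0193339, 0.1191920, 0.9503041],
            ]
        )
        X, Y, Z = M @ lin
        xn, yn, zn = 0.95047, 1.0, 1.08883

        def f(t):
            return t ** (1 / 3) if t > (6 / 29) ** 3 else t / (3 * (6 / 29) ** 2) + 4 / 29

        b_star = 200 * (f(Y / yn) - f(Z / zn))
        assert got == pytest.approx(b_star, abs=0.3)

    def test_empty_cytoplasm_errors(self):
        img = np.zeros((16, 16, 3), dtype=np.uint8)
        with pytest.raises(DegenerateShapeError):
            avg_cytoplasm_b(img, np.zeros((16, 16), bool))


class TestBottleneck:
    def test_dumbbell_pair_spans_neck(self):
        res = bottleneck_pair(_dumbbell(neck_width=10))
        assert res.split_performed
        assert 9 <= res.t1 <= 12
        # both endpoints sit on opposite sides of the neck
        assert {res.point_a[0] < 55, res.point_b[0] < 55} == {True, False}

    def test_disk_is_pinch_free(self):
        res = bottleneck_pair(_disk_mask((100, 100), (50, 50), 40))
        assert not res.split_performed
        assert res.t1 is None

    def test_background_crossing_pair_rejected(self):
        # C-shaped ring with a narrow opening: the closest far-contour pair
        # spans the opening (background) and must be rejected in favor of a
        # pair crossing the solid limb
        yy, xx = np.mgrid[0:110, 0:110] - 55.0
        rho = np.hypot(yy, xx)
        ang = np.degrees(np.arctan2(yy, xx))
        mask = (rho >= 28) & (rho <= 46) & ~(np.abs(ang) < 6)
        res = bottleneck_pair(mask)
        assert res.split_performed
        rr, cc = draw_line(*res.point_a, *res.point_b)
        assert mask[rr, cc].all()  # accepted segment stays on foreground
        # the rejected tip-to-tip chord is shorter than the accepted pair
        assert res.t1 > 11

    def test_thin_mask_degenerate(self):
        m = np.zeros((20, 20), dtype=bool)
        m[10, 2:18] = True
        with pytest.raises(DegenerateShapeError):
            bottleneck_pair(m)


class TestValidateSplit:
    def _rect(self, area):
        m = np.zeros((400, 400), dtype=bool)
        rows = 200
        m[:rows, : area // rows] = True
        assert m.sum() == area
        return m

    def test_accept_case(self):
        # 76000 = 4.0 x 19000 > 3.8x and total 95000 > 74000
        assert validate_split(self._rect(76000), self._rect(19000))

    def test_ratio_failure(self):
        assert not validate_split(self._rect(40000), self._rect(30000))

    def test_total_area_failure(self):
        assert not validate_split(self._rect(50000), self._rect(10000))

    def test_inverted_comparator(self):
        cfg = MorphometryConfig(split_comparator="inverted")
        assert validate_split(self._rect(40000), self._rect(38000), cfg)

    def test_rejected_split_retries_and_terminates(self):
        # small dumbbell: total area far below 74000 so every split is
        # rejected; the retry loop must terminate without a split
        res = resolve_split(_dumbbell())
        assert not res.split_performed


class TestConvexThickness:
    def test_rectangle_min_side(self):
        m = np.zeros((80, 80), dtype=bool)
        m[20:50, 10:60] = True  # 30 x 50
        assert min_convex_thickness(m) == pytest.approx(30.0, abs=0.01)

    def test_disk_diameter(self):
        m = _disk_mask((140, 140), (70, 70), 50)
        assert min_convex_thickness(m) == pytest.approx(100, rel=0.02)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(8)
        blob = random_blob(rng, size=80)
        base = min_convex_thickness(blob)
        for angle in (17, 49, 81):
            rot = ndi.rotate(blob.astype(np.uint8), angle, order=0, reshape=True) > 0
            assert min_convex_thickness(rot) == pytest.approx(base, rel=0.04)

    def test_matches_projection_sweep(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            blob = random_blob(rng, size=72)
            if blob is None:
                continue
            got = min_convex_thickness(blob)
            pts = boundary_pixels(blob).astype(float)
            corners = np.concatenate(
                [pts + d for d in ([0.5, 0.5], [0.5, -0.5], [-0.5, 0.5], [-0.5, -0.5])]
            )
            thetas = np.deg2rad(np.arange(0, 180, 0.1))
            dirs = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
            proj = corners @ dirs.T
            ref = (proj.max(axis=0) - proj.min(axis=0)).min()
            assert got == pytest.approx(ref, rel=0.005)

    def test_tiny_mask_degenerate(self):
        m = np.zeros((10, 10), dtype=bool)
        m[4, 4] = True
        with pytest.raises(DegenerateShapeError):
            min_convex_thickness(m)


class TestHausdorff:
    def test_identity_zero(self):
        pts = np.array([[0, 0], [3, 1], [5, 5]])
        assert hausdorff_distance(pts, pts) == 0.0

    def test_single_pair_euclidean(self):
        assert hausdorff_distance(np.array([[0, 0]]), np.array([[3, 4]])) == 5.0

    def test_matches_brute_force_and_symmetry(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            u = rng.uniform(0, 50, size=(50, 2))
            v = rng.uniform(0, 50, size=(40, 2))
            d = cdist(u, v)
            ref = max(d.min(axis=1).max(), d.min(axis=0).max())
            assert hausdorff_distance(u, v) == pytest.approx(ref)
            assert hausdorff_distance(u, v) == hausdorff_distance(v, u)

    def test_directed_mode(self):
        u = np.array([[0.0, 0.0]])
        v = np.array([[0.0, 0.0], [0.0, 10.0]])
        assert hausdorff_distance(u, v, mode="directed") == 0.0
        assert hausdorff_distance(v, u, mode="directed") == 10.0

    def test_empty_errors(self):
        with pytest.raises(DegenerateShapeError):
            hausdorff_distance(np.empty((0, 2)), np.array([[1, 1]]))


class TestPerimeter:
    def test_square_border_count(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True  # 10x10: 4*10 - 4 border pixels
        assert pixel_perimeter(m) == 36

    def test_disk_matches_naive_border_count(self):
        m = _disk_mask((200, 200), (100, 100), 80)
        # independent oracle: scan every pixel for a background 4-neighbor
        count = 0
        for r, c in zip(*np.nonzero(m)):
            if not (m[r - 1, c] and m[r + 1, c] and m[r, c - 1] and m[r, c + 1]):
                count += 1
        assert pixel_perimeter(m) == count
        # staircase counting biases a circle toward 4*sqrt(2)*r, about 10%
        # below the true circumference
        assert abs(pixel_perimeter(m) - 2 * np.pi * 80) / (2 * np.pi * 80) < 0.12

    def test_no_split_returns_zero(self):
        assert perimeter_smaller_part(SplitResult(False)) == 0.0


class TestOrderedContour:
    def test_walks_every_border_pixel_once(self):
        m = _disk_mask((50, 50), (25, 25), 15)
        contour = ordered_contour(m)
        border = {tuple(p) for p in boundary_pixels(m)}
        assert {tuple(p) for p in contour} == border
        assert len(contour) == len(border)
        steps = np.abs(np.diff(np.vstack([contour, contour[:1]]), axis=0)).max(axis=1)
        assert (steps == 1).all()  # consecutive pixels are 8-adjacent


class TestGeometryInvariants:
    def test_t2_dominates_t1_and_segment_stays_inside(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 25:
            blob = random_blob(rng)
            if blob is None:
                continue
            try:
                res = bottleneck_pair(blob)
                t2 = min_convex_thickness(blob)
            except DegenerateShapeError:
                continue
            checked += 1
            if res.t1 is not None:
                assert res.t1 <= t2 + 1e-9
                rr, cc = draw_line(*res.point_a, *res.point_b)
                assert blob[rr, cc].all()

    def test_convex_shapes_have_unit_ratio(self):
        for r in (15, 28, 41):
            m = _disk_mask((120, 120), (60, 60), r)
            assert not bottleneck_pair(m).split_performed


class TestExtractFeatures:
    def test_round_myeloblast_fixture(self, mb_scene):
        fv = extract_features(record_from_truth(mb_scene), mb_scene.image)
        assert fv.num == 1
        assert fv.t1_over_t2 > 0.92

    def test_band_fixture(self, band_scene):
        fv = extract_features(record_from_truth(band_scene), band_scene.image)
        assert 0.1 < fv.t1_over_t2 < 0.53
        assert fv.p1 > 0

    def test_trilobed_fixture(self, trilobe_scene):
        fv = extract_features(record_from_truth(trilobe_scene), trilobe_scene.image)
        assert fv.num == 3
        assert "multi-lobed" in fv.flags

    def test_missing_cytoplasm_flagged(self, mb_scene):
        rec = record_from_truth(mb_scene)
        rec.nucleus_mask = rec.cell_mask.copy()
        rec.cytoplasm_mask = np.zeros_like(rec.cell_mask)
        fv = extract_features(rec, mb_scene.image)
        assert fv.acoc is None
        assert "missing-acoc" in fv.flags
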
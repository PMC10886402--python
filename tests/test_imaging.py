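"""Annotation parsing, rasterization vs brute force, preprocess, augment."""

import json

import numpy as np
import pytest

from maefnet import imaging
from maefnet.imaging import (AugmentationSpec, PolygonAnnotation,
                             PreprocessSpec, augment, polygons_to_mask,
                             preprocess, read_labelme)

# --------------------------------------------------------------------------
# brute-force point-in-polygon oracle (crossing number + on-boundary test)


def _on_segment(px, py, ax, ay, bx, by, tol=1e-12):
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if abs(cross) > tol * max(1.0, abs(bx - ax) + abs(by - ay)):
        return False
    dot = (px - ax) * (bx - ax) + (py - ay) * (by - ay)
    sq = (bx - ax) ** 2 + (by - ay) ** 2
    return -tol <= dot <= sq + tol


def point_in_polygon(px, py, verts):
    """Even-odd rule with boundary counted as inside."""
    n = len(verts)
    inside = False
    for i in range(n):
        ax, ay = verts[i]
        bx, by = verts[(i + 1) % n]
        if _on_segment(px, py, ax, ay, bx, by):
            return True
        if (ay > py) != (by > py):
            x_at = ax + (py - ay) * (bx - ax) / (by - ay)
            if px < x_at:
                inside = not inside
    return inside


def brute_force_mask(verts, height, width):
    mask = np.zeros((height, width), np.uint8)
    for r in range(height):
        for c in range(width):
            mask[r, c] = point_in_polygon(c + 0.5, r + 0.5, verts)
    return mask


def _random_simple_polygon(rng, lo, hi, n_verts):
    """Star-shaped (hence simple) polygon with random radii around a center;
    resamples until shapely's strict validity check passes (near-collinear
    vertex triples can otherwise degenerate)."""
    import shapely

    while True:
        cx, cy = rng.uniform(lo + 2, hi - 2, size=2)
        angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_verts))
        if np.min(np.diff(angles, append=angles[0] + 2 * np.pi)) < 0.05:
            continue
        rmax = rng.uniform(1.0, min(cx - lo, cy - lo, hi - cx, hi - cy))
        radii = rmax * rng.uniform(0.4, 1.0, size=n_verts)
        pts = [(cx + r * np.cos(a), cy + r * np.sin(a))
               for a, r in zip(angles, radii)]
        if shapely.Polygon(pts).is_valid:
            return pts


def test_rasterization_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    for trial in range(30):
        h, w = rng.integers(8, 33, size=2)
        verts = _random_simple_polygon(rng, 0, min(h, w), rng.integers(3, 9))
        poly = PolygonAnnotation("muscle", tuple(verts))
        got = polygons_to_mask([poly], int(h), int(w))
        expected = brute_force_mask(verts, int(h), int(w))
        np.testing.assert_array_equal(got, expected,
                                      err_msg=f"trial {trial}")


def test_rasterization_union_of_disjoint_squares():
    a = PolygonAnnotation("a", ((1.0, 1.0), (5.0, 1.0), (5.0, 5.0), (1.0, 5.0)))
    b = PolygonAnnotation("b", ((8.0, 8.0), (12.0, 8.0), (12.0, 12.0),
                                (8.0, 12.0)))
    both = polygons_to_mask([a, b], 16, 16)
    sep = polygons_to_mask([a], 16, 16) + polygons_to_mask([b], 16, 16)
    np.testing.assert_array_equal(both, sep)
    assert both.sum() == 2 * 16  # 4x4 pixel centers strictly inside each


def test_rasterization_empty_and_out_of_bounds():
    assert polygons_to_mask([], 8, 8).sum() == 0
    outside = PolygonAnnotation("x", ((100.0, 100.0), (110.0, 100.0),
                                      (110.0, 110.0)))
    with pytest.warns(UserWarning):
        mask = polygons_to_mask([outside], 8, 8)
    assert mask.sum() == 0


def _write_labelme(path, shapes, h=32, w=40):
    payload = {"shapes": shapes, "imageHeight": h, "imageWidth": w}
    path.write_text(json.dumps(payload))
    return path


def test_read_labelme_round_trip(tmp_path):
    f = _write_labelme(tmp_path / "a.json", [
        {"label": "breast",
         "points": [[2.0, 3.0], [10.0, 3.0], [10.0, 12.0], [2.0, 12.0]]}])
    polys, (h, w) = read_labelme(f)
    assert (h, w) == (32, 40)
    assert len(polys) == 1 and polys[0].label == "breast"
    assert polys[0].points[0] == (2.0, 3.0)


def test_read_labelme_empty_and_errors(tmp_path):
    f = _write_labelme(tmp_path / "empty.json", [])
    polys, _ = read_labelme(f)
    assert polys == []
    (tmp_path / "missing.json").write_text(json.dumps({"shapes": []}))
    with pytest.raises(ValueError, match="imageHeight"):
        read_labelme(tmp_path / "missing.json")
    f2 = _write_labelme(tmp_path / "degenerate.json",
                        [{"label": "x", "points": [[0, 0], [5, 5]]}])
    with pytest.raises(ValueError, match="at least 3"):
        read_labelme(f2)


def test_self_intersecting_polygon_rejected():
    with pytest.raises(ValueError, match="self-intersecting"):
        PolygonAnnotation("bow", ((0.0, 0.0), (4.0, 4.0), (4.0, 0.0),
                                  (0.0, 4.0)))


# --------------------------------------------------------------------------
# preprocessing


def test_preprocess_scales_to_512():
    img = np.random.default_rng(0).integers(
        0, 255, size=(1536, 1536)).astype(np.uint8)
    out = preprocess(img, PreprocessSpec(output_side=512))
    assert out.shape == (512, 512) and out.dtype == np.uint8


def test_preprocess_identity_when_full_frame():
    img = np.arange(64 * 64, dtype=np.uint8).reshape(64, 64)
    out = preprocess(img, PreprocessSpec(crop_box=(0, 0, 64, 64),
                                         output_side=64))
    np.testing.assert_array_equal(out, img)


def test_preprocess_mask_stays_binary():
    mask = np.zeros((100, 100), np.uint8)
    mask[20:70, 30:80] = 1
    out = preprocess(mask, PreprocessSpec(output_side=64, is_mask=True))
    assert set(np.unique(out)) <= {0, 1}
    assert out.shape == (64, 64)


def test_preprocess_bad_crop_rejected():
    img = np.zeros((32, 32), np.uint8)
    with pytest.raises(ValueError):
        preprocess(img, PreprocessSpec(crop_box=(0, 0, 64, 64)))


# --------------------------------------------------------------------------
# augmentation


def _sample_pair(seed=0, side=48):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 255, size=(side, side)).astype(np.uint8)
    mask = np.zeros((side, side), np.uint8)
    mask[10:30, 14:34] = 1
    return img, mask


def test_augment_all_probabilities_zero_is_identity():
    img, mask = _sample_pair()
    spec = AugmentationSpec(rotation_p=0, vertical_flip_p=0,
                            horizontal_flip_p=0, perspective_p=0, elastic_p=0)
    out_img, out_mask = augment(img, mask, spec)
    np.testing.assert_array_equal(out_img, img)
    np.testing.assert_array_equal(out_mask, mask)


def test_vertical_flip_is_involution_and_preserves_area():
    img, mask = _sample_pair()
    spec = AugmentationSpec(rotation_p=0, vertical_flip_p=1.0,
                            horizontal_flip_p=0, perspective_p=0, elastic_p=0)
    once_img, once_mask = augment(img, mask, spec)
    assert once_mask.sum() == mask.sum()
    twice_img, twice_mask = augment(once_img, once_mask, spec)
    np.testing.assert_array_equal(twice_img, img)
    np.testing.assert_array_equal(twice_mask, mask)


def test_horizontal_flip_preserves_foreground_count():
    img, mask = _sample_pair(seed=2)
    spec = AugmentationSpec(rotation_p=0, vertical_flip_p=0,
                            horizontal_flip_p=1.0, perspective_p=0,
                            elastic_p=0)
    _, out_mask = augment(img, mask, spec)
    assert out_mask.sum() == mask.sum()


def test_augment_keeps_mask_binary_under_all_ops():
    img, mask = _sample_pair(seed=3)
    spec = AugmentationSpec(rotation_p=1.0, vertical_flip_p=1.0,
                            horizontal_flip_p=1.0, perspective_p=1.0,
                            elastic_p=1.0, seed=5)
    out_img, out_mask = augment(img, mask, spec)
    assert set(np.unique(out_mask)) <= {0, 1}
    assert out_img.shape == img.shape and out_img.dtype == img.dtype


def test_augment_seeded_rng_reproducible():
    img, mask = _sample_pair(seed=4)
    spec = AugmentationSpec(seed=11)
    a_img, a_mask = augment(img, mask, spec)
    b_img, b_mask = augment(img, mask, spec)
    np.testing.assert_array_equal(a_img, b_img)
    np.testing.assert_array_equal(a_mask, b_mask)


def test_augment_dimension_mismatch():
    img, mask = _sample_pair()
    with pytest.raises(ValueError):
        augment(img, mask[:-1], AugmentationSpec())


def test_mask_png_round_trip(tmp_path):
    _, mask = _sample_pair(seed=6)
    imaging.write_mask(tmp_path / "m.png", mask)
    back = imaging.read_mask(tmp_path / "m.png")
    np.testing.assert_array_equal(back, mask)
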
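"""Landmark schema, validation, and annotation/image round trips."""

import json

import numpy as np
import pytest

from mammometry.io import (
    AnnotationParseError,
    FormatError,
    ValidationError,
    read_annotation,
    read_image,
    write_annotation,
    write_image,
)
from mammometry.model import (
    FOOTPRINT_ROLES,
    ROLE_ORDER,
    AffineTransform2D,
    ImageRecord,
    LandmarkRole,
    LandmarkSet,
    SchemaError,
    Side,
    footprint_ordinal,
    role_side,
    validate_landmark_set,
)

from conftest import random_valid_set


class TestSchema:
    def test_exactly_30_distinct_roles(self):
        assert len(ROLE_ORDER) == 30
        assert len(set(ROLE_ORDER)) == 30

    def test_footprint_roles_carry_side_and_ordinal(self):
        for side in Side:
            ordinals = [footprint_ordinal(r) for r in FOOTPRINT_ROLES[side]]
            assert ordinals == list(range(1, 14))
            assert all(role_side(r) is side for r in FOOTPRINT_ROLES[side])
        assert role_side(LandmarkRole.STERNAL_NOTCH) is None

    def test_missing_role_rejected_by_name(self, symmetric_set):
        pts = [p for r, p in symmetric_set.points.items() if r is not LandmarkRole.NIPPLE_L]
        with pytest.raises(SchemaError, match="NIPPLE_L"):
            LandmarkSet(pts)

    def test_duplicate_role_rejected(self, symmetric_set):
        pts = list(symmetric_set.points.values())
        pts.append(pts[-1])
        with pytest.raises(SchemaError, match="duplicate"):
            LandmarkSet(pts)


def _segments_intersect(p1, p2, p3, p4):
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return np.sign(v)
    return (orient(p1, p2, p3) != orient(p1, p2, p4)
            and orient(p3, p4, p1) != orient(p3, p4, p2))


def brute_force_simple(vertices):
    """O(n^2) non-adjacent segment intersection check."""
    n = len(vertices)
    segs = [(vertices[i], vertices[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            if _segments_intersect(*segs[i], *segs[j]):
                return False
    return True


def ray_cast_inside(point, vertices):
    """Point-in-polygon by ray casting (crossing number)."""
    x, y = point
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if xi > x:
                inside = not inside
    return inside


class TestValidation:
    def test_generator_output_is_valid(self, symmetric_torso):
        assert validate_landmark_set(symmetric_torso.truth) == []

    def test_bow_tie_footprint_flagged_and_matches_brute_force(self, symmetric_set):
        coords = symmetric_set.as_array().copy()
        i2, i5 = 6, 9  # swap two left-footprint vertices to force a crossing
        coords[[i2, i5]] = coords[[i5, i2]]
        broken = symmetric_set.replace_coordinates(coords)
        fp = broken.footprint(Side.LEFT)
        assert not brute_force_simple(fp)
        assert any("self-intersection: FOOTPRINT_L" in v for v in validate_landmark_set(broken))

    def test_simple_check_agrees_with_brute_force_on_random_13gons(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            lset = random_valid_set(rng)
            coords = lset.as_array().copy()
            if rng.random() < 0.5:  # randomly corrupt half of them
                i, j = rng.choice(np.arange(4, 17), 2, replace=False)
                coords[[i, j]] = coords[[j, i]]
            cand = lset.replace_coordinates(coords)
            cand.image_width = cand.image_height = None
            fp = cand.footprint(Side.LEFT)
            flagged = any("self-intersection: FOOTPRINT_L" in v
                          for v in validate_landmark_set(cand))
            assert flagged == (not brute_force_simple(fp))

    def test_nipple_outside_footprint_flagged_and_matches_ray_cast(self, symmetric_set):
        coords = symmetric_set.as_array().copy()
        idx = list(ROLE_ORDER).index(LandmarkRole.NIPPLE_R)
        coords[idx] = [10.0, 10.0]
        broken = symmetric_set.replace_coordinates(coords)
        assert not ray_cast_inside(coords[idx], broken.footprint(Side.RIGHT))
        assert any("nipple outside footprint: R" in v for v in validate_landmark_set(broken))

    def test_validation_is_pure(self, symmetric_set):
        assert validate_landmark_set(symmetric_set) == validate_landmark_set(symmetric_set)

    def test_out_of_bounds_coordinate_flagged(self, symmetric_set):
        symmetric_set.image_width, symmetric_set.image_height = 100, 100
        assert any("out of image bounds" in v for v in validate_landmark_set(symmetric_set))


class TestAnnotationIO:
    def test_round_trip_lossless_on_random_sets(self, tmp_path):
        rng = np.random.default_rng(0)
        for i in range(10):
            lset = random_valid_set(rng)
            path = tmp_path / f"ann_{i}.json"
            write_annotation(lset, path)
            back = read_annotation(path)
            np.testing.assert_allclose(back.as_array(), lset.as_array(), atol=1e-6)

    def test_writes_are_byte_identical(self, tmp_path, symmetric_set):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_annotation(symmetric_set, p1)
        write_annotation(symmetric_set, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_role_in_file_names_it(self, tmp_path, symmetric_set):
        path = tmp_path / "a.json"
        write_annotation(symmetric_set, path)
        doc = json.loads(path.read_text())
        doc["points"] = [p for p in doc["points"] if p["role"] != "NIPPLE_L"]
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="NIPPLE_L"):
            read_annotation(path)

    def test_malformed_json_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(AnnotationParseError):
            read_annotation(path)

    def test_invalid_set_never_written(self, tmp_path, symmetric_set):
        coords = symmetric_set.as_array().copy()
        coords[[6, 9]] = coords[[9, 6]]  # bow-tie
        broken = symmetric_set.replace_coordinates(coords)
        path = tmp_path / "x.json"
        with pytest.raises(ValidationError):
            write_annotation(broken, path)
        assert not path.exists()

    def test_unknown_keys_preserved_in_metadata(self, tmp_path, symmetric_set):
        path = tmp_path / "a.json"
        write_annotation(symmetric_set, path)
        doc = json.loads(path.read_text())
        doc["operator"] = "tester"
        path.write_text(json.dumps(doc))
        assert read_annotation(path).metadata["operator"] == "tester"


class TestImageIO:
    def test_8bit_png_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        rec = ImageRecord(rng.integers(0, 256, (40, 30), dtype=np.uint8), 8)
        path = tmp_path / "img.png"
        write_image(rec, path)
        back = read_image(path)
        assert back.bit_depth == 8
        np.testing.assert_array_equal(back.pixels, rec.pixels)

    def test_16bit_png_preserves_depth(self, tmp_path):
        rng = np.random.default_rng(2)
        rec = ImageRecord(rng.integers(0, 65536, (20, 20), dtype=np.uint16), 16)
        path = tmp_path / "img16.png"
        write_image(rec, path)
        back = read_image(path)
        assert back.bit_depth == 16
        np.testing.assert_array_equal(back.pixels, rec.pixels)

    def test_jpeg_reads_as_8bit(self, tmp_path):
        rec = ImageRecord(np.full((16, 16), 128, dtype=np.uint8), 8)
        path = tmp_path / "img.jpg"
        write_image(rec, path)
        assert read_image(path).bit_depth == 8

    def test_unsupported_format_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            read_image(tmp_path / "x.bmp")


class TestAffine:
    def test_inverse_round_trip(self):
        t = AffineTransform2D(np.array([[1.5, 0.2, 3.0], [-0.1, 2.0, -7.0]]))
        pts = np.random.default_rng(0).uniform(-50, 50, (20, 2))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="invertible"):
            AffineTransform2D(np.array([[1.0, 2.0, 0.0], [2.0, 4.0, 0.0]]))
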
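"""Landmark parsing, signed ANB angle and threshold-band classification."""

import math

import numpy as np
import pandas as pd
import pytest

from fedceph.labeling import (
    KIM,
    STEINER,
    DegenerateGeometryError,
    LandmarkParseError,
    Point2D,
    SkeletalClass,
    ThresholdStandard,
    classify_skeletal,
    compute_anb_angle,
    parse_landmark_file,
)
from fedceph.manifest import DatasetManifest, label_manifest

from oracles import signed_angle_oracle


class TestParseLandmarkFile:
    def test_direct_parse(self):
        lms = parse_landmark_file("10,20\n30,40\n50,60", expected_n=3)
        assert [(p.x, p.y) for p in lms.points] == [(10, 20), (30, 40), (50, 60)]
        assert (lms.a.x, lms.n.x, lms.b.x) == (10, 30, 50)

    def test_nineteen_line_layout_maps_a_n_b(self):
        lines = [f"{i},{i * 2}" for i in range(1, 20)]
        lms = parse_landmark_file("\n".join(lines), expected_n=19)
        assert (lms.a.x, lms.a.y) == (5, 10)  # 5th line
        assert (lms.n.x, lms.n.y) == (2, 4)  # 2nd line
        assert (lms.b.x, lms.b.y) == (6, 12)  # 6th line

    def test_trailing_lines_ignored(self):
        text = "\n".join(f"{i},{i}" for i in range(1, 20)) + "\nnot-a-point\n"
        assert parse_landmark_file(text, expected_n=19).n_points == 19

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(LandmarkParseError) as err:
            parse_landmark_file("10,20\nabc,40\n1,1", expected_n=3)
        assert err.value.line == 2

    def test_truncated_file(self):
        with pytest.raises(LandmarkParseError, match="found only 2"):
            parse_landmark_file("1,2\n3,4", expected_n=3)

    def test_whitespace_separator_tolerated(self):
        lms = parse_landmark_file("1 2\n3\t4\n5, 6", expected_n=3)
        assert (lms.b.x, lms.b.y) == (5, 6)


class TestComputeAnbAngle:
    def test_collinear_rays_zero(self):
        assert compute_anb_angle(
            Point2D(1, 0), Point2D(0, 0), Point2D(2, 0), "up"
        ) == pytest.approx(0.0)

    def test_orthogonal_ccw_positive(self):
        assert compute_anb_angle(
            Point2D(0, 1), Point2D(0, 0), Point2D(1, 0), "up"
        ) == pytest.approx(90.0)

    def test_atan2_value(self):
        assert compute_anb_angle(
            Point2D(3, 4), Point2D(0, 0), Point2D(5, 0), "up"
        ) == pytest.approx(53.130102, abs=1e-6)

    def test_degenerate_geometry(self):
        with pytest.raises(DegenerateGeometryError):
            compute_anb_angle(Point2D(0, 0), Point2D(0, 0), Point2D(1, 0))

    def test_matches_arccos_cross_oracle_and_symmetries(self, rng):
        """Invariant under rotation/scaling; negates under reflection."""
        for _ in range(1000):
            pts = rng.normal(0, 10, (3, 2))
            a, n, b = pts
            if np.allclose(a, n) or np.allclose(b, n):
                continue
            ang = compute_anb_angle(Point2D(*a), Point2D(*n), Point2D(*b), "up")
            assert ang == pytest.approx(signed_angle_oracle(a, n, b), abs=1e-9)
            theta = rng.uniform(0, 2 * math.pi)
            scale = rng.uniform(0.1, 10)
            rot = np.array(
                [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
            )
            ra, rn, rb = (scale * (rot @ p) for p in (a, n, b))
            ang_t = compute_anb_angle(Point2D(*ra), Point2D(*rn), Point2D(*rb), "up")
            assert ang_t == pytest.approx(ang, abs=1e-8)
            # reflection about the y axis
            fa, fn, fb = (np.array([-p[0], p[1]]) for p in (a, n, b))
            ang_f = compute_anb_angle(Point2D(*fa), Point2D(*fn), Point2D(*fb), "up")
            assert ang_f == pytest.approx(-ang, abs=1e-8)

    def test_y_axis_down_equals_flipped_up(self, rng):
        for _ in range(100):
            a, n, b = rng.normal(0, 5, (3, 2))
            if np.allclose(a, n) or np.allclose(b, n):
                continue
            down = compute_anb_angle(Point2D(*a), Point2D(*n), Point2D(*b), "down")
            up = compute_anb_angle(
                Point2D(a[0], -a[1]), Point2D(n[0], -n[1]), Point2D(b[0], -b[1]), "up"
            )
            assert down == up


class TestClassifySkeletal:
    @pytest.mark.parametrize(
        "angle,standard,expected",
        [
            (5.6, KIM, SkeletalClass.II),  # the Dicle worked example
            (3.2, STEINER, SkeletalClass.I),  # inclusive lower boundary
            (5.7, STEINER, SkeletalClass.I),  # inclusive upper boundary
            (-2.0, KIM, SkeletalClass.III),
            (5.8, STEINER, SkeletalClass.II),
            (0.0, KIM, SkeletalClass.I),
            (4.0, KIM, SkeletalClass.I),
            (4.0001, KIM, SkeletalClass.II),
        ],
    )
    def test_band_rules(self, angle, standard, expected):
        assert classify_skeletal(angle, standard) is expected

    @pytest.mark.parametrize("standard", [KIM, STEINER])
    def test_exhaustive_and_exclusive(self, standard):
        grid = np.concatenate(
            [
                np.arange(-20, 20, 0.05),
                [standard.class1_low, standard.class1_high],
            ]
        )
        for angle in grid:
            cls = classify_skeletal(float(angle), standard)
            in_band = standard.class1_low <= angle <= standard.class1_high
            above = angle > standard.class1_high
            below = angle < standard.class1_low
            assert [in_band, above, below].count(True) == 1
            assert cls is (
                SkeletalClass.I if in_band else SkeletalClass.II if above else SkeletalClass.III
            )

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            ThresholdStandard("bad", 5.0, 3.0)

    def test_class_code_bijection(self):
        for cls in SkeletalClass:
            assert SkeletalClass.from_index(cls.index) is cls
            assert SkeletalClass.from_label(cls.label) is cls
        assert [c.value for c in SkeletalClass] == [1, 2, 3]
        assert [c.index for c in SkeletalClass] == [0, 1, 2]


def _inline_manifest(angles_per_client: dict[str, list[float]]) -> DatasetManifest:
    rows = []
    for cid, angles in angles_per_client.items():
        for k, angle in enumerate(angles):
            # N at origin, B straight down (pixel frame), A rotated by angle
            t = math.radians(angle)
            rows.append(
                {
                    "image_path": f"{cid}_{k}.png",
                    "landmark_path": "",
                    "client_id": cid,
                    "ax": 10 * math.sin(t) + 50,
                    "ay": 10 * math.cos(t) + 50,
                    "nx": 50.0,
                    "ny": 50.0,
                    "bx": 50.0,
                    "by": 70.0,
                }
            )
    standards = {cid: KIM for cid in angles_per_client}
    return DatasetManifest(records=pd.DataFrame(rows), standards=standards)


class TestLabelManifest:
    def test_counts_one_per_class(self):
        manifest = _inline_manifest({"c": [1.0, 5.0, -1.0]})
        labeled, report, errors = label_manifest(manifest)
        assert not errors
        assert report["overall"]["counts"] == {"I": 1, "II": 1, "III": 1}
        assert list(labeled.records["class"]) == ["I", "II", "III"]

    def test_empty_manifest(self):
        manifest = DatasetManifest(
            records=pd.DataFrame(columns=["image_path", "landmark_path", "client_id"]),
            standards={},
        )
        labeled, report, errors = label_manifest(manifest)
        assert report["overall"]["total"] == 0 and not errors

    def test_table_proportions_full_precision(self):
        """Class mix 399/284/180 reports full-precision proportions that
        round to the 0.46/0.33/0.21 ratio row."""
        angles = [2.0] * 399 + [6.0] * 284 + [-2.0] * 180
        manifest = _inline_manifest({"dicle": angles})
        _, report, _ = label_manifest(manifest)
        props = report["per_client"]["dicle"]["proportions"]
        total = 399 + 284 + 180
        assert props["I"] == pytest.approx(399 / total, abs=1e-12)
        assert props["II"] == pytest.approx(284 / total, abs=1e-12)
        assert props["III"] == pytest.approx(180 / total, abs=1e-12)
        assert [round(props[k], 2) for k in ("I", "II", "III")] == [0.46, 0.33, 0.21]
        assert sum(report["per_client"]["dicle"]["counts"].values()) == total

    def test_relabeling_idempotent(self):
        manifest = _inline_manifest({"c": [1.0, 5.0, -1.0, 3.3]})
        once, _, _ = label_manifest(manifest)
        twice, _, _ = label_manifest(once)
        assert list(once.records["class"]) == list(twice.records["class"])

    def test_bad_record_collected_not_fatal(self):
        manifest = _inline_manifest({"c": [1.0, 5.0]})
        manifest.records.loc[1, ["ax", "ay"]] = [50.0, 50.0]  # A == N: degenerate
        _, report, errors = label_manifest(manifest)
        assert len(errors) == 1 and report["overall"]["total"] == 1
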
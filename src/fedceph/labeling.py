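"""ANB-angle computation and skeletal-class labeling for lateral cephalograms.

The sagittal jaw relationship is classified from the ANB angle: the angle at
nasion (N) between the rays towards A-point (subspinale, maxilla) and B-point
(supramentale, mandible).  A positive angle means the maxilla lies anterior to
the mandible.  Two threshold conventions are supported:

* Steiner analysis: Class I for ANB in [3.2, 5.7] degrees, Class II above,
  Class III below.
* The Kim convention: Class I for ANB in [0, 4] degrees, Class II above,
  Class III below.

Landmark annotation files contain one ``x,y`` line per landmark.  In the
19-landmark layout used by the ISBI challenge export, A, N and B are the 5th,
2nd and 6th landmarks (1-based); a 3-landmark file is read in A, N, B order.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Literal, Sequence

__all__ = [
    "Point2D",
    "LandmarkSet",
    "ThresholdStandard",
    "SkeletalClass",
    "KIM",
    "STEINER",
    "STANDARDS",
    "A_LINE",
    "N_LINE",
    "B_LINE",
    "LandmarkParseError",
    "DegenerateGeometryError",
    "parse_landmark_file",
    "compute_anb_angle",
    "classify_skeletal",
]

# 1-based landmark positions of A-point, nasion and B-point in the
# 19-landmark annotation layout.
A_LINE, N_LINE, B_LINE = 5, 2, 6


class LandmarkParseError(ValueError):
    """Raised for a malformed or truncated landmark annotation file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message)


class DegenerateGeometryError(ValueError):
    """Raised when the ANB angle is undefined (A or B coincides with N)."""


@dataclass(frozen=True)
class Point2D:
    """A planar point in pixel coordinates."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite point coordinates ({self.x}, {self.y})")


@dataclass(frozen=True)
class LandmarkSet:
    """An ordered set of landmark points for one radiograph.

    Either the full 19-landmark layout (A/N/B at 1-based positions 5/2/6) or
    the compact 3-point layout in fixed A, N, B order.
    """

    points: tuple[Point2D, ...]

    def __post_init__(self) -> None:
        if len(self.points) not in (3, 19):
            raise ValueError(
                f"expected 3 or 19 landmarks, got {len(self.points)}"
            )

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def a(self) -> Point2D:
        return self.points[0] if self.n_points == 3 else self.points[A_LINE - 1]

    @property
    def n(self) -> Point2D:
        return self.points[1] if self.n_points == 3 else self.points[N_LINE - 1]

    @property
    def b(self) -> Point2D:
        return self.points[2] if self.n_points == 3 else self.points[B_LINE - 1]


@dataclass(frozen=True)
class ThresholdStandard:
    """A named ANB-angle band rule.

    The closed band ``[class1_low, class1_high]`` is Class I; angles strictly
    above the band are Class II and strictly below are Class III.
    """

    name: str
    class1_low: float
    class1_high: float

    def __post_init__(self) -> None:
        if not self.class1_low < self.class1_high:
            raise ValueError(
                f"invalid band for {self.name!r}: "
                f"low {self.class1_low} must be < high {self.class1_high}"
            )


KIM = ThresholdStandard("kim", 0.0, 4.0)
STEINER = ThresholdStandard("steiner", 3.2, 5.7)
STANDARDS: dict[str, ThresholdStandard] = {"kim": KIM, "steiner": STEINER}


class SkeletalClass(Enum):
    """Sagittal skeletal class with stable integer codes 1/2/3.

    ``index`` gives the 0-based model-target index (I=0, II=1, III=2).
    """

    I = 1
    II = 2
    III = 3

    @property
    def index(self) -> int:
        return self.value - 1

    @property
    def label(self) -> str:
        return self.name

    @classmethod
    def from_index(cls, index: int) -> "SkeletalClass":
        return cls(index + 1)

    @classmethod
    def from_label(cls, label: str) -> "SkeletalClass":
        return cls[label.strip().upper()]


_COORD_SPLIT = re.compile(r"[,\s;]+")


def parse_landmark_file(text: str, expected_n: int = 19) -> LandmarkSet:
    """Parse a landmark annotation into the first ``expected_n`` points.

    Each line holds one point as ``x,y`` (whitespace separators tolerated).
    Lines beyond ``expected_n`` are ignored: some dataset exports append
    extra metadata lines after the landmark block.

    Raises
    ------
    LandmarkParseError
        With the offending 1-based line number if one of the first
        ``expected_n`` non-empty lines is malformed, or if fewer than
        ``expected_n`` parseable lines exist.
    """
    points: list[Point2D] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if len(points) >= expected_n:
            break
        fields = [f for f in _COORD_SPLIT.split(line) if f]
        if len(fields) < 2:
            raise LandmarkParseError(
                f"line {lineno}: expected 'x,y', got {raw!r}", line=lineno
            )
        try:
            x, y = float(fields[0]), float(fields[1])
        except ValueError as exc:
            raise LandmarkParseError(
                f"line {lineno}: non-numeric coordinate in {raw!r}", line=lineno
            ) from exc
        points.append(Point2D(x, y))
    if len(points) < expected_n:
        raise LandmarkParseError(
            f"expected {expected_n} landmarks, found only {len(points)}"
        )
    return LandmarkSet(tuple(points))


def compute_anb_angle(
    a: Point2D,
    n: Point2D,
    b: Point2D,
    y_axis: Literal["down", "up"] = "down",
) -> float:
    """Signed ANB angle in degrees, in the interval (-180, 180].

    The angle is measured from the ray N->B to the ray N->A,
    counter-clockwise positive in an x-right / y-up frame.  With
    ``y_axis="down"`` (the image pixel convention, default) the y components
    are negated first, so that for a facing-right lateral cephalogram a
    maxilla anterior to the mandible yields a positive angle and a protruded
    mandible (Class III) yields a negative one.  The magnitude equals the
    unsigned angle at N.
    """
    if y_axis not in ("down", "up"):
        raise ValueError(f"y_axis must be 'down' or 'up', got {y_axis!r}")
    ax, ay = a.x - n.x, a.y - n.y
    bx, by = b.x - n.x, b.y - n.y
    if y_axis == "down":
        ay, by = -ay, -by
    if (ax == 0.0 and ay == 0.0) or (bx == 0.0 and by == 0.0):
        raise DegenerateGeometryError(
            "A or B coincides with N; the ANB angle is undefined"
        )
    angle = math.degrees(math.atan2(bx * ay - by * ax, ax * bx + ay * by))
    if angle <= -180.0:
        angle += 360.0
    return angle


def classify_skeletal(angle: float, standard: ThresholdStandard) -> SkeletalClass:
    """Map a finite ANB angle to a skeletal class under ``standard``.

    Class I on the closed band, Class II strictly above, Class III strictly
    below.  Total on finite angles: exactly one class for every input.
    """
    if not math.isfinite(angle):
        raise ValueError(f"angle must be finite, got {angle}")
    if angle > standard.class1_high:
        return SkeletalClass.II
    if angle < standard.class1_low:
        return SkeletalClass.III
    return SkeletalClass.I


def classify_many(
    angles: Iterable[float], standard: ThresholdStandard
) -> list[SkeletalClass]:
    return [classify_skeletal(a, standard) for a in angles]
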
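"""Synthetic two-client cephalogram-like datasets.

Generates stylized lateral-cephalogram images with exactly controlled ANB
angles, so that every other module is exercisable without the real
radiographs.  Generation is angle-first: a class is chosen, an angle is
sampled uniformly from that class's band under the client's threshold
standard, and the A/N/B landmark geometry is solved to realize the angle
exactly — making the labeler's correctness a construction invariant.  The
rendered image draws a cranial contour, a maxillary ridge through A and a
mandibular contour through B whose anterior offset varies monotonically with
the angle, so the class is visually learnable by a small CNN.

The default configuration mirrors the two-clinic benchmark this package
simulates: client "dicle" with 856 images, class ratios 0.46/0.33/0.21 and
the Kim labeling band; client "isbi" with 400 images, ratios 0.2/0.22/0.58
and the Steiner band.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import ellipse_perimeter, line_aa

from .labeling import (
    A_LINE,
    B_LINE,
    KIM,
    N_LINE,
    STANDARDS,
    STEINER,
    Point2D,
    SkeletalClass,
    ThresholdStandard,
    classify_skeletal,
    compute_anb_angle,
)
from .manifest import DatasetManifest, write_manifest

__all__ = [
    "ClientProfile",
    "SynthConfig",
    "SynthRecord",
    "apportion",
    "sample_angle",
    "place_landmarks",
    "render_image",
    "generate_records",
    "generate_dataset",
    "records_to_arrays",
    "split_records",
]

#: margin (degrees) kept from each class-band boundary so landmark jitter
#: can never push a record across a class boundary
BAND_MARGIN = 0.1


@dataclass(frozen=True)
class ClientProfile:
    client_id: str
    n_images: int
    class_ratios: tuple[float, float, float]
    standard: ThresholdStandard

    def __post_init__(self) -> None:
        if abs(sum(self.class_ratios) - 1.0) > 1e-9:
            raise ValueError(f"class ratios must sum to 1, got {self.class_ratios}")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic two-client dataset."""

    clients: tuple[ClientProfile, ...] = (
        ClientProfile("dicle", 856, (0.46, 0.33, 0.21), KIM),
        ClientProfile("isbi", 400, (0.2, 0.22, 0.58), STEINER),
    )
    image_size: int = 64
    # landmark placement noise: ~0.5 px at 64 px crop scale, the accuracy of
    # careful expert annotation; keeps angle-coded contour noise well below
    # the 4-degree class-band width so classes stay visually separable
    angle_jitter: float = 0.5
    angle_range_clip: float = 15.0  # max |ANB| sampled, degrees
    render_noise: float = 0.05
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.clients:
            if self.angle_range_clip <= max(abs(c.standard.class1_low), abs(c.standard.class1_high)):
                raise ValueError(
                    f"angle clip {self.angle_range_clip} must exceed the outer "
                    f"thresholds of standard {c.standard.name!r}"
                )

    def scaled(self, factor: float) -> "SynthConfig":
        """Same ratios/standards with client sizes scaled down."""
        clients = tuple(
            ClientProfile(c.client_id, max(3, int(round(c.n_images * factor))),
                          c.class_ratios, c.standard)
            for c in self.clients
        )
        return SynthConfig(
            clients=clients,
            image_size=self.image_size,
            angle_jitter=self.angle_jitter,
            angle_range_clip=self.angle_range_clip,
            render_noise=self.render_noise,
            test_fraction=self.test_fraction,
            seed=self.seed,
        )

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)


@dataclass
class SynthRecord:
    client_id: str
    skeletal_class: SkeletalClass
    angle: float
    a: Point2D
    n: Point2D
    b: Point2D
    split: str = "train"
    image: np.ndarray | None = None
    image_path: str | None = None
    landmark_path: str | None = None


def apportion(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of ``n`` items by ``ratios``.

    Deterministic and exact: counts sum to ``n`` and match the ratios to
    within one item; ties broken by class order.
    """
    quotas = [n * r for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def sample_angle(
    cls: SkeletalClass,
    standard: ThresholdStandard,
    clip: float,
    rng: np.random.Generator,
    margin: float = BAND_MARGIN,
) -> float:
    """Uniform draw from the class's ANB band, clipped and margin-shrunk."""
    lo, hi = standard.class1_low, standard.class1_high
    if cls is SkeletalClass.I:
        a, b = lo + margin, hi - margin
    elif cls is SkeletalClass.II:
        a, b = hi + margin, clip
    else:
        a, b = -clip, lo - margin
    if not a < b:
        raise ValueError(
            f"empty band for class {cls.label} under {standard.name!r} with clip {clip}"
        )
    return float(rng.uniform(a, b))


def _solve_a(n: Point2D, b: Point2D, angle_deg: float, reach: float) -> Point2D:
    """Place A so the signed ANB angle (pixel frame, y down) is exact."""
    # work in the y-up frame where the sign convention is defined
    nx, ny = n.x, -n.y
    bx, by = b.x, -b.y
    ux, uy = bx - nx, by - ny
    norm = float(np.hypot(ux, uy))
    ux, uy = ux / norm, uy / norm
    t = np.deg2rad(angle_deg)
    # rotate the unit N->B direction counter-clockwise by the target angle
    dx = ux * np.cos(t) - uy * np.sin(t)
    dy = ux * np.sin(t) + uy * np.cos(t)
    ax, ay = nx + reach * dx, ny + reach * dy
    return Point2D(ax, -ay)


def place_landmarks(
    angle_deg: float,
    image_size: int,
    jitter: float,
    rng: np.random.Generator,
    clip: float = 15.0,
) -> tuple[Point2D, Point2D, Point2D]:
    """Solve A/N/B positions realizing ``angle_deg`` exactly (y-down frame).

    N is anchored in the upper-anterior region, B below it with an anterior
    offset that decreases as the angle grows (a protruded mandible for
    negative angles); jitter perturbs N and B, then A is re-solved so the
    recomputed angle matches the request to within 1e-9 degrees.  Raises
    after 100 failed in-bounds attempts.
    """
    s = float(image_size)
    for _ in range(100):
        n = Point2D(
            0.58 * s + jitter * rng.normal(),
            0.28 * s + jitter * rng.normal(),
        )
        # anterior offset of the mandible: ~1 px per degree at 64 px, so the
        # class signal stays legible to a small CNN above the jitter noise
        b = Point2D(
            n.x + 0.02 * s - (angle_deg / clip) * 0.22 * s + jitter * rng.normal(),
            n.y + 0.50 * s + jitter * rng.normal(),
        )
        a = _solve_a(n, b, angle_deg, reach=0.30 * s)
        pts = (a, n, b)
        if all(2.0 <= p.x <= s - 3.0 and 2.0 <= p.y <= s - 3.0 for p in pts):
            return pts
    raise RuntimeError(
        f"could not place landmarks inside a {image_size}px image for angle {angle_deg}"
    )


def _draw_line(canvas: np.ndarray, p0: tuple[float, float], p1: tuple[float, float],
               intensity: float) -> None:
    h, w = canvas.shape
    r0, c0 = int(round(p0[1])), int(round(p0[0]))
    r1, c1 = int(round(p1[1])), int(round(p1[0]))
    rr, cc, val = line_aa(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    canvas[rr[keep], cc[keep]] = np.maximum(
        canvas[rr[keep], cc[keep]], intensity * val[keep]
    )


def render_image(
    a: Point2D,
    n: Point2D,
    b: Point2D,
    image_size: int,
    noise: float,
    rng: np.random.Generator,
    contours: bool = True,
) -> np.ndarray:
    """Render a stylized cephalogram crop as a uint8 grayscale image.

    Draws a cranial contour (elliptical arc), a maxillary ridge through A and
    a mandibular contour through B; additive Gaussian background noise.
    Deterministic for a fixed generator state.  With ``contours=False`` and
    zero noise the image is blank (debug path).
    """
    s = image_size
    canvas = np.zeros((s, s), dtype=np.float64)
    if noise > 0:
        canvas += np.abs(rng.normal(0.0, noise, (s, s)))
    if contours:
        # cranial vault: elliptical arc around the upper posterior region
        rr, cc = ellipse_perimeter(
            int(0.40 * s), int(0.42 * s), int(0.33 * s), int(0.36 * s)
        )
        keep = (rr >= 0) & (rr < s) & (cc >= 0) & (cc < s) & (rr < 0.55 * s)
        canvas[rr[keep], cc[keep]] = np.maximum(canvas[rr[keep], cc[keep]], 0.55)
        # maxillary ridge: line through N and A, extended beyond A
        ext = (a.x + 0.35 * (a.x - n.x), a.y + 0.35 * (a.y - n.y))
        _draw_line(canvas, (n.x, n.y), (a.x, a.y), 0.85)
        _draw_line(canvas, (a.x, a.y), ext, 0.85)
        # mandibular contour: gonion-to-B-to-chin polyline through B
        post = (b.x - 0.22 * s, b.y - 0.10 * s)
        chin = (b.x + 0.06 * s, b.y + 0.06 * s)
        _draw_line(canvas, post, (b.x, b.y), 0.95)
        _draw_line(canvas, (b.x, b.y), chin, 0.95)
    return (np.clip(canvas, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def split_records(
    records: list[SynthRecord], test_fraction: float, rng: np.random.Generator
) -> None:
    """Stratified train/test split per client, within 1 sample per class."""
    by_group: dict[tuple[str, SkeletalClass], list[SynthRecord]] = {}
    for r in records:
        by_group.setdefault((r.client_id, r.skeletal_class), []).append(r)
    for group in by_group.values():
        n_test = int(round(test_fraction * len(group)))
        order = rng.permutation(len(group))
        for i in order[:n_test]:
            group[i].split = "test"
        for i in order[n_test:]:
            group[i].split = "train"


def generate_records(
    cfg: SynthConfig, render: bool = True
) -> list[SynthRecord]:
    """Generate all records in memory (images optional).

    Class counts per client follow the deterministic largest-remainder
    apportionment of the configured ratios; every record's realized angle
    classifies back to its intended class under the client's standard.
    """
    ss = np.random.SeedSequence([int(cfg.seed), 0xCE9])
    records: list[SynthRecord] = []
    client_seeds = ss.spawn(len(cfg.clients) + 1)
    for profile, child in zip(cfg.clients, client_seeds[:-1]):
        rng = np.random.default_rng(child)
        counts = apportion(profile.n_images, profile.class_ratios)
        for cls, count in zip(SkeletalClass, counts):
            for _ in range(count):
                angle = sample_angle(
                    cls, profile.standard, cfg.angle_range_clip, rng
                )
                a, n, b = place_landmarks(
                    angle, cfg.image_size, cfg.angle_jitter, rng,
                    clip=cfg.angle_range_clip,
                )
                realized = compute_anb_angle(a, n, b, y_axis="down")
                assert classify_skeletal(realized, profile.standard) is cls
                img = (
                    render_image(a, n, b, cfg.image_size, cfg.render_noise, rng)
                    if render
                    else None
                )
                records.append(
                    SynthRecord(
                        client_id=profile.client_id,
                        skeletal_class=cls,
                        angle=realized,
                        a=a,
                        n=n,
                        b=b,
                        image=img,
                    )
                )
    split_records(records, cfg.test_fraction, np.random.default_rng(client_seeds[-1]))
    return records


def _filler_points(
    a: Point2D, n: Point2D, b: Point2D, image_size: int, rng: np.random.Generator
) -> list[Point2D]:
    """16 meaningless filler landmarks kept at least 5 px from A/N/B."""
    fillers = []
    while len(fillers) < 16:
        p = Point2D(
            float(rng.uniform(1, image_size - 1)), float(rng.uniform(1, image_size - 1))
        )
        if all(np.hypot(p.x - q.x, p.y - q.y) > 5.0 for q in (a, n, b)):
            fillers.append(p)
    return fillers


def generate_dataset(cfg: SynthConfig, out_dir: str | Path) -> DatasetManifest:
    """Write images, 19-slot landmark files and a manifest CSV to disk.

    Landmark files use the 19-line layout with A/N/B at lines 5/2/6 and
    filler points elsewhere, so the full annotation-parsing path is
    exercised.  The manifest ships unlabeled (no class column values are
    needed downstream of labeling); the config is serialized alongside for
    provenance.
    """
    import pandas as pd

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "landmarks").mkdir(parents=True, exist_ok=True)
    records = generate_records(cfg, render=True)
    filler_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0xF111]))
    rows = []
    for i, rec in enumerate(records):
        stem = f"{rec.client_id}_{i:05d}"
        img_path = out / "images" / f"{stem}.png"
        lm_path = out / "landmarks" / f"{stem}.txt"
        Image.fromarray(rec.image, mode="L").save(img_path)
        slots: list[Point2D | None] = [None] * 19
        slots[A_LINE - 1], slots[N_LINE - 1], slots[B_LINE - 1] = rec.a, rec.n, rec.b
        fillers = iter(_filler_points(rec.a, rec.n, rec.b, cfg.image_size, filler_rng))
        lines = [
            f"{p.x:.4f},{p.y:.4f}" if p is not None else None for p in slots
        ]
        lines = [ln if ln is not None else
                 (lambda q: f"{q.x:.4f},{q.y:.4f}")(next(fillers)) for ln in lines]
        lm_path.write_text("\n".join(lines) + "\n")
        rec.image_path = str(img_path.relative_to(out))
        rec.landmark_path = str(lm_path.relative_to(out))
        rows.append(
            {
                "image_path": rec.image_path,
                "landmark_path": rec.landmark_path,
                "client_id": rec.client_id,
                "class": rec.skeletal_class.label,
                "split": rec.split,
            }
        )
    df = pd.DataFrame(rows)
    standards = {c.client_id: c.standard for c in cfg.clients}
    manifest = DatasetManifest(records=df, standards=standards, root=out)
    write_manifest(manifest, out / "manifest.csv")
    (out / "synth_config.json").write_text(cfg.to_json())
    return manifest


def records_to_arrays(
    records: list[SynthRecord], split: str | None = None, client_id: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack rendered records into (N,1,H,W) float images in [0,1] + targets."""
    sel = [
        r
        for r in records
        if (split is None or r.split == split)
        and (client_id is None or r.client_id == client_id)
    ]
    if not sel:
        return np.zeros((0, 1, 1, 1)), np.zeros(0, dtype=np.intp)
    x = np.stack([r.image for r in sel]).astype(np.float64) / 255.0
    y = np.array([r.skeletal_class.index for r in sel], dtype=np.intp)
    return x[:, None, :, :], y
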
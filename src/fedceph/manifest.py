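"""Dataset manifests: CSV listings of images, landmark files and labels.

A manifest row references an image, the landmark annotation that locates
A/N/B (either a file path or inline ``ax..by`` columns), the client the
record belongs to, and — once labeled — the skeletal class.  Each client is
bound to a labeling threshold standard (e.g. one clinic labels under the
Steiner band, another under the Kim band), mirroring the multi-institution
setting this package simulates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .labeling import (
    STANDARDS,
    LandmarkParseError,
    Point2D,
    SkeletalClass,
    ThresholdStandard,
    classify_skeletal,
    compute_anb_angle,
    parse_landmark_file,
)

__all__ = [
    "DatasetManifest",
    "LabelingError",
    "read_manifest",
    "write_manifest",
    "label_manifest",
]

MANIFEST_COLUMNS = ["image_path", "landmark_path", "client_id", "class"]
_INLINE = ["ax", "ay", "nx", "ny", "bx", "by"]


@dataclass
class LabelingError:
    """A per-record labeling failure, collected without aborting the run."""

    index: int
    image_path: str
    reason: str


@dataclass
class DatasetManifest:
    """A table of dataset records plus the per-client threshold standards."""

    records: pd.DataFrame
    standards: dict[str, ThresholdStandard]
    root: Path | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ("image_path", "client_id") if c not in self.records.columns]
        if missing:
            raise ValueError(f"manifest missing required columns: {missing}")
        for cid in self.records["client_id"].unique():
            if str(cid) not in self.standards:
                raise ValueError(f"no threshold standard configured for client {cid!r}")

    def __len__(self) -> int:
        return len(self.records)

    def client_ids(self) -> list[str]:
        return [str(c) for c in self.records["client_id"].unique()]

    def standard_for(self, client_id: str) -> ThresholdStandard:
        return self.standards[str(client_id)]

    def resolve_points(self, row: pd.Series) -> tuple[Point2D, Point2D, Point2D]:
        """A/N/B points for one record, from inline columns or landmark file."""
        if all(c in row.index and pd.notna(row.get(c)) for c in _INLINE):
            return (
                Point2D(float(row["ax"]), float(row["ay"])),
                Point2D(float(row["nx"]), float(row["ny"])),
                Point2D(float(row["bx"]), float(row["by"])),
            )
        lp = row.get("landmark_path")
        if lp is None or (isinstance(lp, float) and pd.isna(lp)) or str(lp) == "":
            raise LandmarkParseError("record has neither inline points nor a landmark file")
        path = Path(lp)
        if self.root is not None and not path.is_absolute():
            path = self.root / path
        text = path.read_text()
        n_lines = len([ln for ln in text.splitlines() if ln.strip()])
        lms = parse_landmark_file(text, expected_n=19 if n_lines >= 19 else 3)
        return lms.a, lms.n, lms.b


def read_manifest(
    csv_path: str | Path,
    standards: dict[str, ThresholdStandard] | None = None,
) -> DatasetManifest:
    """Read a manifest CSV; standards default to a ``standards.json`` sidecar.

    The sidecar maps client ids to either a named standard ("kim",
    "steiner") or an explicit ``{"name":..., "class1_low":..., "class1_high":...}``.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, dtype={"client_id": str})
    if standards is None:
        sidecar = csv_path.with_name("standards.json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no standards given and no sidecar at {sidecar}"
            )
        raw = json.loads(sidecar.read_text())
        standards = {}
        for cid, val in raw.items():
            if isinstance(val, str):
                standards[cid] = STANDARDS[val]
            else:
                standards[cid] = ThresholdStandard(
                    val["name"], float(val["class1_low"]), float(val["class1_high"])
                )
    return DatasetManifest(records=df, standards=standards, root=csv_path.parent)


def write_manifest(manifest: DatasetManifest, csv_path: str | Path) -> None:
    """Write the manifest CSV and a ``standards.json`` sidecar next to it."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in MANIFEST_COLUMNS if c in manifest.records.columns]
    cols += [c for c in manifest.records.columns if c not in cols]
    manifest.records.to_csv(csv_path, index=False, columns=cols)
    sidecar = {
        cid: {"name": s.name, "class1_low": s.class1_low, "class1_high": s.class1_high}
        for cid, s in manifest.standards.items()
    }
    csv_path.with_name("standards.json").write_text(json.dumps(sidecar, indent=2))


def _count_table(labels: pd.Series) -> dict:
    counts = {c.label: int((labels == c.label).sum()) for c in SkeletalClass}
    total = int(labels.notna().sum())
    props = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return {"counts": counts, "proportions": props, "total": total}


def label_manifest(
    manifest: DatasetManifest, y_axis: str = "down"
) -> tuple[DatasetManifest, dict, list[LabelingError]]:
    """Assign a skeletal class to every record via its ANB angle.

    Returns the labeled manifest (class stored as the roman label, plus a
    ``anb_angle`` column), a report with per-client and overall class counts
    and full-precision proportions, and the list of per-record errors
    (unresolvable landmarks do not abort the run).
    """
    df = manifest.records.copy()
    errors: list[LabelingError] = []
    labels: list[str | None] = []
    angles: list[float | None] = []
    for idx, row in df.iterrows():
        try:
            a, n, b = manifest.resolve_points(row)
            angle = compute_anb_angle(a, n, b, y_axis=y_axis)
            cls = classify_skeletal(angle, manifest.standard_for(row["client_id"]))
            labels.append(cls.label)
            angles.append(angle)
        except (ValueError, OSError) as exc:
            errors.append(LabelingError(int(idx), str(row["image_path"]), str(exc)))
            labels.append(None)
            angles.append(None)
    df["class"] = labels
    df["anb_angle"] = angles
    labeled = DatasetManifest(records=df, standards=manifest.standards, root=manifest.root)
    report = {"overall": _count_table(df["class"]), "per_client": {}}
    for cid in labeled.client_ids():
        report["per_client"][cid] = _count_table(
            df.loc[df["client_id"].astype(str) == cid, "class"]
        )
    report["n_errors"] = len(errors)
    return labeled, report, errors
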
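"""Contour annotation data model and cohort file I/O.

A cohort is a flat collection of hand-drawn closed hippocampal outlines
(:class:`ContourReading`), each tagged with provenance: the subject it came
from, the side (left/right hippocampus), the diagnostic group, the reader who
drew it, and a repeat index (readers trace each structure more than once).

Coordinates live in a y-up Cartesian millimetre frame.  Contours are closed by
convention — the last point connects back to the first, which is *not*
duplicated — and are normalized to counter-clockwise orientation on load.

Two on-disk formats are supported: a hierarchical JSON document and a long CSV
with one row per contour point.  Both are versioned with ``schema_version``
and round-trip exactly (floats are written with full precision).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
SIDES = ("left", "right")
GROUPS = ("control", "subject")

#: CSV column order, one row per contour point.
CSV_COLUMNS = (
    "subject_id",
    "side",
    "group",
    "reader_id",
    "repeat_index",
    "point_index",
    "x_mm",
    "y_mm",
    "is_fiducial",
    "pixel_spacing_mm",
)


class SchemaError(ValueError):
    """Raised when an annotation file or record violates the cohort schema."""


def signed_area(points: np.ndarray) -> float:
    """Signed area of a closed polygon (positive = counter-clockwise, y-up)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def is_simple_polygon(points: np.ndarray) -> bool:
    """True if the implicitly-closed polyline bounds a simple polygon."""
    if len(points) < 3:
        return False
    poly = Polygon(points)
    return poly.is_valid and poly.area > 0


@dataclass
class ContourReading:
    """One hand-drawn closed contour with fiducial markers and provenance.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    side : {"left", "right"}
        Hippocampal side; left and right are modelled separately downstream.
    group : {"control", "subject"}
        Diagnostic group: ``control`` = healthy aging, ``subject`` = early AD.
    reader_id : str
        Opaque identifier of the human reader who drew the contour.
    repeat_index : int
        0-based index of the reader's repeated tracing of this structure.
    points : (n, 2) array
        Ordered contour vertices in millimetres, y-up, first point not
        repeated at the end.  Normalized to CCW by :meth:`validate`.
    fiducial_indices : tuple of int
        Strictly increasing indices into ``points`` marking the anatomical
        fiducials that anchor point correspondence.
    pixel_spacing_mm : float
        Isotropic pixel spacing of the source image (1.0 if points are
        already in mm).
    """

    subject_id: str
    side: str
    group: str
    reader_id: str
    repeat_index: int
    points: np.ndarray
    fiducial_indices: tuple
    pixel_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.fiducial_indices = tuple(int(i) for i in self.fiducial_indices)

    # -- validation -------------------------------------------------------

    def validate(self, check_simple: bool = True) -> "ContourReading":
        """Enforce the reading invariants in place, returning self.

        Flips clockwise contours to counter-clockwise (remapping fiducial
        indices accordingly, keeping the start point fixed) and raises
        :class:`SchemaError` on any violation that cannot be repaired.
        """
        rid = self.record_id()
        if self.side not in SIDES:
            raise SchemaError(f"{rid}: side must be one of {SIDES}, got {self.side!r}")
        if self.group not in GROUPS:
            raise SchemaError(f"{rid}: group must be one of {GROUPS}, got {self.group!r}")
        if self.repeat_index < 0:
            raise SchemaError(f"{rid}: repeat_index must be >= 0")
        if self.pixel_spacing_mm <= 0:
            raise SchemaError(f"{rid}: pixel_spacing_mm must be positive")
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise SchemaError(f"{rid}: points must be an (n, 2) array")
        n = len(self.points)
        if n < 4:
            raise SchemaError(f"{rid}: need at least 4 contour points, got {n}")
        if not np.all(np.isfinite(self.points)):
            raise SchemaError(f"{rid}: non-finite coordinates")
        k = len(self.fiducial_indices)
        if k < 1:
            raise SchemaError(f"{rid}: at least one fiducial is required")
        fid = np.asarray(self.fiducial_indices)
        if np.any(fid < 0) or np.any(fid >= n):
            raise SchemaError(
                f"{rid}: fiducial index out of range (n={n}, fiducials={self.fiducial_indices})"
            )
        if np.any(np.diff(fid) <= 0):
            raise SchemaError(f"{rid}: fiducial_indices must be strictly increasing")

        if signed_area(self.points) < 0:
            # clockwise in the y-up frame: reverse traversal, keep the start
            # point in place, and remap fiducials onto the reversed order.
            logger.info("%s: clockwise contour normalized to CCW", rid)
            self.points = self.points[[0] + list(range(n - 1, 0, -1))]
            self.fiducial_indices = tuple(sorted((n - i) % n for i in fid))
        if check_simple and not is_simple_polygon(self.points):
            raise SchemaError(f"{rid}: contour is not a simple polygon")
        return self

    def record_id(self) -> str:
        return (
            f"reading({self.subject_id}/{self.side}/{self.reader_id}"
            f"/rep{self.repeat_index})"
        )

    def sort_key(self):
        return (self.subject_id, self.side, self.reader_id, self.repeat_index)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ContourReading):
            return NotImplemented
        return (
            self.sort_key() == other.sort_key()
            and self.group == other.group
            and self.fiducial_indices == other.fiducial_indices
            and self.pixel_spacing_mm == other.pixel_spacing_mm
            and self.points.shape == other.points.shape
            and np.array_equal(self.points, other.points)
        )


@dataclass
class Cohort:
    """A set of contour readings plus free-form metadata."""

    readings: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def validate(self) -> "Cohort":
        groups: dict = {}
        for r in self.readings:
            r.validate()
            prev = groups.setdefault(r.subject_id, r.group)
            if prev != r.group:
                raise SchemaError(
                    f"subject {r.subject_id!r} carries inconsistent group labels "
                    f"({prev!r} vs {r.group!r})"
                )
        self.readings.sort(key=ContourReading.sort_key)
        return self

    def __len__(self) -> int:
        return len(self.readings)

    def __iter__(self) -> Iterator[ContourReading]:
        return iter(self.readings)

    def subjects(self) -> list:
        return sorted({r.subject_id for r in self.readings})

    def filter(self, side: str | None = None) -> "Cohort":
        """Sub-cohort restricted to one side (readings shared, not copied)."""
        keep = [r for r in self.readings if side is None or r.side == side]
        return Cohort(readings=keep, metadata=dict(self.metadata))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.metadata == other.metadata and self.readings == other.readings


# -- format detection -----------------------------------------------------


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("json", "csv"):
            raise ValueError(f"unknown cohort format {format!r}")
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv"):
        return suffix
    raise ValueError(f"cannot infer cohort format from {path.name!r}; pass format=")


# -- JSON -----------------------------------------------------------------


def _reading_to_dict(r: ContourReading) -> dict:
    return {
        "subject_id": r.subject_id,
        "side": r.side,
        "group": r.group,
        "reader_id": r.reader_id,
        "repeat_index": r.repeat_index,
        "pixel_spacing_mm": r.pixel_spacing_mm,
        "fiducial_indices": list(r.fiducial_indices),
        "points": [[float(x), float(y)] for x, y in r.points],
    }


def _reading_from_dict(d: dict, where: str) -> ContourReading:
    required = {
        "subject_id",
        "side",
        "group",
        "reader_id",
        "repeat_index",
        "points",
        "fiducial_indices",
    }
    missing = required - d.keys()
    if missing:
        raise SchemaError(f"{where}: missing fields {sorted(missing)}")
    return ContourReading(
        subject_id=str(d["subject_id"]),
        side=str(d["side"]),
        group=str(d["group"]),
        reader_id=str(d["reader_id"]),
        repeat_index=int(d["repeat_index"]),
        points=np.asarray(d["points"], dtype=float),
        fiducial_indices=tuple(d["fiducial_indices"]),
        pixel_spacing_mm=float(d.get("pixel_spacing_mm", 1.0)),
    )


def read_cohort(path, format: str | None = None) -> Cohort:
    """Read a cohort annotation file (JSON or CSV) and validate it.

    All :class:`ContourReading` invariants are enforced; clockwise contours
    are flipped to CCW with a logged note.  Readings are returned sorted by
    (subject_id, side, reader_id, repeat_index).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        with open(path) as fh:
            doc = json.load(fh)
        if not isinstance(doc, dict) or "readings" not in doc:
            raise SchemaError(f"{path.name}: not a cohort document (no 'readings')")
        version = doc.get("schema_version")
        if version is not None and int(version) > SCHEMA_VERSION:
            raise SchemaError(f"{path.name}: unsupported schema_version {version}")
        readings = [
            _reading_from_dict(d, f"{path.name} readings[{i}]")
            for i, d in enumerate(doc["readings"])
        ]
        cohort = Cohort(readings=readings, metadata=dict(doc.get("metadata", {})))
    else:
        cohort = _read_csv(path)
    return cohort.validate()


def write_cohort(cohort: Cohort, path, format: str | None = None) -> None:
    """Write a cohort to ``path`` in JSON or CSV; round-trips exactly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    cohort.validate()
    if fmt == "json":
        doc = {
            "schema_version": SCHEMA_VERSION,
            "metadata": cohort.metadata,
            "readings": [_reading_to_dict(r) for r in cohort.readings],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    else:
        _write_csv(cohort, path)


# -- CSV ------------------------------------------------------------------


def _write_csv(cohort: Cohort, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(
            f"# hippomorph-cohort schema_version={SCHEMA_VERSION} "
            f"metadata={json.dumps(cohort.metadata)}\n"
        )
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in cohort.readings:
            fidset = set(r.fiducial_indices)
            for i, (x, y) in enumerate(r.points):
                writer.writerow(
                    [
                        r.subject_id,
                        r.side,
                        r.group,
                        r.reader_id,
                        r.repeat_index,
                        i,
                        repr(float(x)),
                        repr(float(y)),
                        int(i in fidset),
                        repr(float(r.pixel_spacing_mm)),
                    ]
                )


def _read_csv(path: Path) -> Cohort:
    metadata: dict = {}
    with open(path, newline="") as fh:
        first = fh.readline()
        if first.startswith("#"):
            marker = "metadata="
            if marker in first:
                metadata = json.loads(first.split(marker, 1)[1])
        else:
            fh.seek(0)
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) < set(CSV_COLUMNS):
            raise SchemaError(
                f"{path.name}: CSV header must contain columns {CSV_COLUMNS}"
            )
        rows: dict = {}
        for lineno, row in enumerate(reader, start=2):
            try:
                key = (
                    row["subject_id"],
                    row["side"],
                    row["group"],
                    row["reader_id"],
                    int(row["repeat_index"]),
                    float(row["pixel_spacing_mm"]),
                )
                point = (
                    int(row["point_index"]),
                    float(row["x_mm"]),
                    float(row["y_mm"]),
                    bool(int(row["is_fiducial"])),
                )
            except (KeyError, ValueError) as exc:
                raise SchemaError(f"{path.name} line {lineno}: {exc}") from exc
            rows.setdefault(key, []).append(point)
    readings = []
    for key, pts in rows.items():
        subject_id, side, group, reader_id, repeat_index, spacing = key
        pts.sort(key=lambda p: p[0])
        indices = [p[0] for p in pts]
        if indices != list(range(len(pts))):
            raise SchemaError(
                f"{path.name}: reading({subject_id}/{side}/{reader_id}/rep{repeat_index})"
                " has non-contiguous point_index values"
            )
        readings.append(
            ContourReading(
                subject_id=subject_id,
                side=side,
                group=group,
                reader_id=reader_id,
                repeat_index=repeat_index,
                points=np.array([[p[1], p[2]] for p in pts]),
                fiducial_indices=tuple(i for i, p in enumerate(pts) if p[3]),
                pixel_spacing_mm=spacing,
            )
        )
    return Cohort(readings=readings, metadata=metadata)


def from_pixel_coordinates(
    points_px: np.ndarray, pixel_spacing_mm: float, image_height_px: float
) -> np.ndarray:
    """Convert image-frame pixel coordinates (y-down) to mm in the y-up frame."""
    pts = np.asarray(points_px, dtype=float).copy()
    pts[:, 1] = image_height_px - pts[:, 1]
    return pts * float(pixel_spacing_mm)
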
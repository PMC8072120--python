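"""Data model and on-disk formats.

All coordinate conventions live here: pixel coordinates are 0-based, x
rightward, y downward, continuous (sub-pixel allowed), with a pixel's center
at integer coordinates.  Vein and boundary polylines are stored
distal→proximal; the lobe contour is a closed polyline stored starting from
the left rim endpoint.  Annotations natively live on the histological image
(where anatomy is selected) and are transported to fresh-image coordinates by
the registration module; ``frame_of_reference`` records which space they are
in.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from ._geometry import as_points, point_polyline_distance
from .errors import InputError, ValidationError

__all__ = [
    "POLLINATION_TYPES",
    "PetalImage",
    "SpecimenRecord",
    "SpecimenTable",
    "AnatomicalAnnotation",
    "ControlPointSet",
    "load_image",
    "save_image",
    "read_annotation",
    "write_annotation",
    "load_specimen_table",
]

POLLINATION_TYPES = frozenset(
    {"hummingbird", "bee", "bat", "moth", "to_be_determined"}
)

MIN_IMAGE_SIDE = 32


@dataclass
class PetalImage:
    """An 8-bit RGB scan of a flattened ventral petal.

    ``kind`` distinguishes the fresh scan (petal on a dark cloth) from the
    backlit histological scan of the same, fixed petal.
    """

    pixels: np.ndarray  # H x W x 3 uint8
    kind: str  # "fresh" | "histological"
    resolution: float  # dots per inch
    specimen_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError("pixels must be an H x W x 3 array")
        if px.shape[0] < MIN_IMAGE_SIDE or px.shape[1] < MIN_IMAGE_SIDE:
            raise ValidationError(
                f"image must be at least {MIN_IMAGE_SIDE} px on each side"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.kind not in ("fresh", "histological"):
            raise ValidationError(f"unknown image kind {self.kind!r}")
        if not self.resolution > 0:
            raise ValidationError("resolution (dpi) must be positive")

    @property
    def shape(self):
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class SpecimenRecord:
    species: str
    specimen_id: str
    pollination_type: str
    accession: str = ""

    def __post_init__(self):
        if self.pollination_type not in POLLINATION_TYPES:
            raise ValidationError(
                f"unknown pollination_type {self.pollination_type!r} "
                f"(expected one of {sorted(POLLINATION_TYPES)})"
            )


@dataclass
class SpecimenTable:
    """A cohort of specimen records with per-species bookkeeping."""

    records: list[SpecimenRecord]

    @property
    def total(self) -> int:
        return len(self.records)

    def species_counts(self) -> pd.Series:
        s = pd.Series([r.species for r in self.records], dtype=object)
        return s.value_counts().sort_index()

    def pollination_by_species(self) -> dict[str, str]:
        return {r.species: r.pollination_type for r in self.records}


_POLYLINE_FIELDS = (
    "lobe_contour",
    "midvein",
    "sidevein_left",
    "sidevein_right",
    "tube_boundary_left",
    "tube_boundary_right",
)

RIM_TOL = 2.0  # px: rim endpoints must sit on the contour
MIDVEIN_TOL = 5.0  # px: midvein distal end must reach the contour


@dataclass
class AnatomicalAnnotation:
    """Manually curated petal anatomy in image pixel coordinates.

    ``lobe_contour`` is the full closed petal outline; ``rim_endpoints`` are
    the two points where the lobe meets the tube (the lobe–tube connected
    rim), splitting the outline into a distal lobe arc and a proximal tube
    outline.
    """

    specimen_id: str
    frame_of_reference: str  # "histological" | "fresh"
    lobe_contour: np.ndarray
    midvein: np.ndarray
    sidevein_left: np.ndarray
    sidevein_right: np.ndarray
    tube_boundary_left: np.ndarray
    tube_boundary_right: np.ndarray
    rim_endpoints: np.ndarray  # (2, 2)

    def __post_init__(self):
        if self.frame_of_reference not in ("histological", "fresh"):
            raise ValidationError(
                f"unknown frame_of_reference {self.frame_of_reference!r}"
            )
        for name in _POLYLINE_FIELDS:
            pts = as_points(getattr(self, name))
            if len(pts) < 2:
                raise ValidationError(f"{name} needs at least 2 vertices")
            setattr(self, name, pts)
        rim = as_points(self.rim_endpoints)
        if rim.shape != (2, 2):
            raise ValidationError("rim_endpoints must be exactly two points")
        for i, p in enumerate(rim):
            d = point_polyline_distance(p, self.lobe_contour, closed=True)
            if d > RIM_TOL:
                raise ValidationError(
                    f"rim_endpoints[{i}] lies {d:.2f} px from lobe_contour "
                    f"(tolerance {RIM_TOL} px)"
                )
        self.rim_endpoints = rim
        d = point_polyline_distance(
            self.midvein[0], self.lobe_contour, closed=True
        )
        d_last = point_polyline_distance(
            self.midvein[-1], self.lobe_contour, closed=True
        )
        if min(d, d_last) > MIDVEIN_TOL:
            raise ValidationError(
                f"midvein distal endpoint lies {min(d, d_last):.2f} px from "
                f"lobe_contour (tolerance {MIDVEIN_TOL} px)"
            )

    def polylines(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in _POLYLINE_FIELDS}

    def with_frame(self, frame_of_reference: str) -> "AnatomicalAnnotation":
        return replace(self, frame_of_reference=frame_of_reference)


@dataclass
class ControlPointSet:
    """Paired landmarks visible in both scans (serration tips, cut traces)."""

    pairs: list[tuple[tuple[float, float], tuple[float, float]]]

    def __post_init__(self):
        if len(self.pairs) < 3:
            raise ValidationError("need at least 3 control point pairs")
        src = self.hist
        if len(np.unique(np.round(src, 9), axis=0)) != len(src):
            raise ValidationError("duplicated source (histological) control points")

    @property
    def hist(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=float)

    @property
    def fresh(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=float)

    def __len__(self):
        return len(self.pairs)


# ---------------------------------------------------------------------------
# images


def load_image(path, kind: str, dpi: float = 600.0) -> PetalImage:
    """Read a PNG/TIFF scan as an 8-bit RGB :class:`PetalImage`.

    Grayscale inputs are promoted to 3 channels by replication; an alpha
    channel is dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise InputError(f"zero-area image: {path}")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 3:
        pass
    else:
        raise InputError(f"unsupported channel layout {arr.shape} in {path}")
    if arr.dtype != np.uint8:
        raise InputError(f"expected an 8-bit image, got dtype {arr.dtype}")
    return PetalImage(
        pixels=arr, kind=kind, resolution=dpi, specimen_id=path.stem
    )


def save_image(image: PetalImage | np.ndarray, path) -> None:
    arr = image.pixels if isinstance(image, PetalImage) else np.asarray(image)
    Image.fromarray(arr).save(Path(path))


# ---------------------------------------------------------------------------
# annotations (JSON)


def _pts_out(a: np.ndarray):
    return [[float(x), float(y)] for x, y in np.asarray(a, dtype=float)]


def annotation_to_dict(
    ann: AnatomicalAnnotation, control_points: ControlPointSet | None = None
) -> dict:
    doc = {
        "specimen_id": ann.specimen_id,
        "frame_of_reference": ann.frame_of_reference,
        **{name: _pts_out(getattr(ann, name)) for name in _POLYLINE_FIELDS},
        "rim_endpoints": _pts_out(ann.rim_endpoints),
    }
    if control_points is not None:
        doc["control_points"] = [
            {"hist": [float(h[0]), float(h[1])],
             "fresh": [float(f[0]), float(f[1])]}
            for h, f in control_points.pairs
        ]
    return doc


def write_annotation(
    ann: AnatomicalAnnotation,
    path,
    control_points: ControlPointSet | None = None,
) -> None:
    doc = annotation_to_dict(ann, control_points)
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def annotation_from_dict(doc: dict):
    missing = [
        k
        for k in ("specimen_id", "frame_of_reference", "rim_endpoints")
        + _POLYLINE_FIELDS
        if k not in doc
    ]
    if missing:
        raise ValidationError(
            "annotation document missing required field(s): "
            + ", ".join(missing)
        )
    ann = AnatomicalAnnotation(
        specimen_id=doc["specimen_id"],
        frame_of_reference=doc["frame_of_reference"],
        rim_endpoints=np.asarray(doc["rim_endpoints"], dtype=float),
        **{
            name: np.asarray(doc[name], dtype=float)
            for name in _POLYLINE_FIELDS
        },
    )
    cps = None
    if doc.get("control_points"):
        cps = ControlPointSet(
            pairs=[
                (tuple(map(float, d["hist"])), tuple(map(float, d["fresh"])))
                for d in doc["control_points"]
            ]
        )
    return ann, cps


def read_annotation(path):
    """Read an annotation JSON file.

    Returns ``(AnatomicalAnnotation, ControlPointSet | None)``; all
    invariants are validated and a violation raises
    :class:`~petalign.errors.ValidationError` naming the failing field.
    """
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"cannot read annotation {path}: {exc}") from exc
    return annotation_from_dict(doc)


# ---------------------------------------------------------------------------
# specimen tables (CSV)


def load_specimen_table(path) -> SpecimenTable:
    """Read a specimen CSV into a :class:`SpecimenTable`.

    Accepts either one row per specimen (``specimen_id`` column) or one row
    per species with a ``count`` column, in which case specimen ids are
    synthesized as ``<species>#<i>``.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read specimen table {path}: {exc}") from exc
    if df.empty and "species" not in df.columns:
        return SpecimenTable(records=[])
    cols = set(df.columns)
    if "species" not in cols or "pollination_type" not in cols:
        raise ValidationError(
            "specimen table needs 'species' and 'pollination_type' columns"
        )
    if not ({"specimen_id", "count"} & cols):
        raise ValidationError(
            "specimen table needs a 'specimen_id' or 'count' column"
        )
    records: list[SpecimenRecord] = []
    for _, row in df.iterrows():
        ptype = str(row["pollination_type"]).strip().lower().replace(" ", "_")
        acc = str(row["accession"]) if "accession" in cols and pd.notna(row.get("accession")) else ""
        if "specimen_id" in cols and pd.notna(row.get("specimen_id")):
            records.append(
                SpecimenRecord(
                    species=row["species"],
                    specimen_id=str(row["specimen_id"]),
                    pollination_type=ptype,
                    accession=acc,
                )
            )
        else:
            n = int(row["count"])
            records.extend(
                SpecimenRecord(
                    species=row["species"],
                    specimen_id=f"{row['species']}#{i + 1}",
                    pollination_type=ptype,
                    accession=acc,
                )
                for i in range(n)
            )
    seen = set()
    for r in records:
        key = (r.species, r.specimen_id)
        if key in seen:
            raise ValidationError(f"duplicate specimen {key}")
        seen.add(key)
    return SpecimenTable(records=records)
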
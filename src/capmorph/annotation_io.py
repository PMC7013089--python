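"""Canonical annotation format for traced capillary cross-sections.

A capillary profile on a transmission electron micrograph is described by
hand-traced closed contours for three compartment boundaries (blood/EC
transition = lumen, abluminal EC surface, outer basement-membrane boundary),
optional pericyte and endothelial-nucleus polygons, optional intraluminal
projection polylines, and annotator-scored categorical observations
(peg-socket counts, basement-membrane disruption).

Coordinates are image-pixel coordinates (x rightward, y downward, 0-based,
vertices at pixel centers); the physical scale is carried per contour as
nanometres per pixel.  The JSON document is the canonical interchange format;
ImageJ ROI archives are supported as an import convenience only.
"""

from __future__ import annotations

import io
import json
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

FORMAT_VERSION = "1.0"

#: Tolerance (pixels) used when checking nesting of hand-traced boundaries.
#: Traced transitions may touch; half a pixel absorbs tracing jitter.
CONTAINMENT_TOL_PX = 0.5

#: The 14 study groups: four training studies plus the claudication study.
#: "pre"/"post" refer to before/after endurance exercise training.
GROUP_LABELS = (
    "endurance_pre",
    "endurance_post",
    "ar_pre",
    "ar_post",
    "nr_pre",
    "nr_post",
    "normotensive_pre",
    "normotensive_post",
    "hypertensive_pre",
    "hypertensive_post",
    "diabetic_pre",
    "diabetic_post",
    "ic_control",
    "ic_pad",
)

#: Untrained groups of participants without a disease diagnosis; pooled as
#: the healthy reference for cross-study comparisons (n = 42 subjects).
HEALTHY_POOL_GROUPS = (
    "endurance_pre",
    "ar_pre",
    "nr_pre",
    "normotensive_pre",
    "ic_control",
)


class AnnotationError(Exception):
    """Base class for annotation I/O problems."""


class AnnotationParseError(AnnotationError):
    """Raised when a document cannot be parsed into annotations."""


class AnnotationValidationError(AnnotationError):
    """Raised when annotations violate structural invariants.

    ``violations`` is a list of ``(annotation_id, rule, message)`` tuples; no
    annotation is silently dropped.
    """

    def __init__(self, violations: list[tuple[str, str, str]]):
        self.violations = violations
        lines = [f"{aid}: [{rule}] {msg}" for aid, rule, msg in violations]
        super().__init__(
            "annotation validation failed:\n" + "\n".join(lines)
        )


@dataclass
class Contour:
    """An ordered 2-D point list with physical scale.

    Closed contours are polygons (the wrap segment is implicit, the first
    point is not repeated); open contours are polylines (used for
    intraluminal projections).
    """

    points: np.ndarray
    closed: bool = True
    scale_nm_per_px: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")

    # -- geometry helpers ---------------------------------------------------

    def polygon(self) -> Polygon:
        if not self.closed:
            raise ValueError("open polyline has no polygon interior")
        return Polygon(self.points)

    def check(self) -> list[str]:
        """Return a list of invariant-violation messages (empty if valid)."""
        problems = []
        n = len(self.points)
        if self.closed and n < 3:
            problems.append(f"closed contour needs >= 3 points, got {n}")
        if not self.closed and n < 2:
            problems.append(f"polyline needs >= 2 points, got {n}")
        if not np.isfinite(self.points).all():
            problems.append("contour has non-finite coordinates")
        if not (self.scale_nm_per_px > 0):
            problems.append(f"scale_nm_per_px must be > 0, got {self.scale_nm_per_px}")
        if self.closed and n >= 3 and np.isfinite(self.points).all():
            if not Polygon(self.points).is_valid:
                problems.append("closed contour is self-intersecting")
        return problems

    def to_dict(self) -> dict:
        return {
            "points": [[float(x), float(y)] for x, y in self.points],
            "closed": bool(self.closed),
            "scale_nm_per_px": float(self.scale_nm_per_px),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Contour":
        return cls(
            points=np.asarray(d["points"], dtype=float),
            closed=bool(d["closed"]),
            scale_nm_per_px=float(d["scale_nm_per_px"]),
        )

    def __eq__(self, other) -> bool:  # value semantics for round-trip tests
        if not isinstance(other, Contour):
            return NotImplemented
        return (
            self.closed == other.closed
            and self.scale_nm_per_px == other.scale_nm_per_px
            and self.points.shape == other.points.shape
            and np.array_equal(self.points, other.points)
        )


@dataclass
class CapillaryAnnotation:
    """One capillary profile's complete trace set, flags, and provenance."""

    micrograph_id: str
    subject_id: str
    biopsy_id: str
    group: str
    rater_id: str
    lumen: Contour
    ec_abluminal: Contour
    bm_outer: Contour
    pericytes: list[Contour] = field(default_factory=list)
    nuclei: list[Contour] = field(default_factory=list)
    projections: list[Contour] = field(default_factory=list)
    ec_sockets_n: int = 0
    ec_sockets_empty_n: int = 0
    pc_sockets_n: int = 0
    pc_sockets_empty_n: int = 0
    bm_disrupted: bool = False

    # -- validation ---------------------------------------------------------

    def check(self, tol_px: float = CONTAINMENT_TOL_PX) -> list[tuple[str, str]]:
        """Return ``(rule, message)`` tuples for every violated invariant."""
        problems: list[tuple[str, str]] = []

        named = [("lumen", self.lumen), ("ec_abluminal", self.ec_abluminal),
                 ("bm_outer", self.bm_outer)]
        named += [(f"pericyte[{i}]", c) for i, c in enumerate(self.pericytes)]
        named += [(f"nucleus[{i}]", c) for i, c in enumerate(self.nuclei)]
        named += [(f"projection[{i}]", c) for i, c in enumerate(self.projections)]

        for role, contour in named:
            if role.startswith("projection"):
                if contour.closed:
                    problems.append(("contour.open", f"{role} must be an open polyline"))
            elif not contour.closed:
                problems.append(("contour.closed", f"{role} must be a closed contour"))
            for msg in contour.check():
                problems.append(("contour.valid", f"{role}: {msg}"))
        if problems:
            return problems  # geometry checks below assume valid contours

        scales = {c.scale_nm_per_px for _, c in named}
        if len(scales) > 1:
            problems.append(("scale.consistent",
                             f"contours carry different scales: {sorted(scales)}"))

        if self.group not in GROUP_LABELS:
            problems.append(("group.known", f"unknown study group {self.group!r}"))

        if self.ec_sockets_empty_n > self.ec_sockets_n:
            problems.append(("sockets.ec_empty_le_total",
                             f"{self.ec_sockets_empty_n} empty > {self.ec_sockets_n} EC sockets"))
        if self.pc_sockets_empty_n > self.pc_sockets_n:
            problems.append(("sockets.pc_empty_le_total",
                             f"{self.pc_sockets_empty_n} empty > {self.pc_sockets_n} PC sockets"))
        for name in ("ec_sockets_n", "ec_sockets_empty_n",
                     "pc_sockets_n", "pc_sockets_empty_n"):
            if getattr(self, name) < 0:
                problems.append(("sockets.nonnegative", f"{name} is negative"))

        lum = self.lumen.polygon()
        ec = self.ec_abluminal.polygon()
        bm = self.bm_outer.polygon()
        ec_tol = ec.buffer(tol_px)
        bm_tol = bm.buffer(tol_px)
        area_eps = 1e-6

        if lum.difference(ec_tol).area > area_eps:
            problems.append(("containment.lumen_in_ec",
                             "lumen is not contained in the abluminal EC contour"))
        if ec.difference(bm_tol).area > area_eps:
            problems.append(("containment.ec_in_bm",
                             "abluminal EC contour is not contained in the outer BM contour"))
        lum_shrunk = lum.buffer(-tol_px)
        for i, pc in enumerate(self.pericytes):
            poly = pc.polygon()
            if poly.difference(bm_tol).area > area_eps:
                problems.append(("pericyte.in_bm",
                                 f"pericyte[{i}] is not contained in the outer BM contour"))
            if poly.intersection(lum_shrunk).area > area_eps:
                problems.append(("pericyte.disjoint_lumen",
                                 f"pericyte[{i}] overlaps the lumen"))
        for i, nuc in enumerate(self.nuclei):
            if nuc.polygon().difference(ec_tol).area > area_eps:
                problems.append(("nucleus.in_ec",
                                 f"nucleus[{i}] is not contained in the abluminal EC contour"))
        return problems

    @property
    def scale_nm_per_px(self) -> float:
        return self.lumen.scale_nm_per_px

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "micrograph_id": self.micrograph_id,
            "subject_id": self.subject_id,
            "biopsy_id": self.biopsy_id,
            "group": self.group,
            "rater_id": self.rater_id,
            "lumen": self.lumen.to_dict(),
            "ec_abluminal": self.ec_abluminal.to_dict(),
            "bm_outer": self.bm_outer.to_dict(),
            "pericytes": [c.to_dict() for c in self.pericytes],
            "nuclei": [c.to_dict() for c in self.nuclei],
            "projections": [c.to_dict() for c in self.projections],
            "ec_sockets_n": int(self.ec_sockets_n),
            "ec_sockets_empty_n": int(self.ec_sockets_empty_n),
            "pc_sockets_n": int(self.pc_sockets_n),
            "pc_sockets_empty_n": int(self.pc_sockets_empty_n),
            "bm_disrupted": bool(self.bm_disrupted),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CapillaryAnnotation":
        try:
            return cls(
                micrograph_id=str(d["micrograph_id"]),
                subject_id=str(d["subject_id"]),
                biopsy_id=str(d["biopsy_id"]),
                group=str(d["group"]),
                rater_id=str(d["rater_id"]),
                lumen=Contour.from_dict(d["lumen"]),
                ec_abluminal=Contour.from_dict(d["ec_abluminal"]),
                bm_outer=Contour.from_dict(d["bm_outer"]),
                pericytes=[Contour.from_dict(c) for c in d.get("pericytes", [])],
                nuclei=[Contour.from_dict(c) for c in d.get("nuclei", [])],
                projections=[Contour.from_dict(c) for c in d.get("projections", [])],
                ec_sockets_n=int(d.get("ec_sockets_n", 0)),
                ec_sockets_empty_n=int(d.get("ec_sockets_empty_n", 0)),
                pc_sockets_n=int(d.get("pc_sockets_n", 0)),
                pc_sockets_empty_n=int(d.get("pc_sockets_empty_n", 0)),
                bm_disrupted=bool(d.get("bm_disrupted", False)),
            )
        except KeyError as exc:
            raise AnnotationParseError(
                f"annotation {d.get('micrograph_id', '<unknown>')!r}: "
                f"missing field {exc.args[0]!r}"
            ) from exc


def validate_annotations(
    annotations: Iterable[CapillaryAnnotation],
    tol_px: float = CONTAINMENT_TOL_PX,
) -> None:
    """Check every annotation; raise one error listing all violations."""
    violations: list[tuple[str, str, str]] = []
    for ann in annotations:
        for rule, msg in ann.check(tol_px=tol_px):
            violations.append((ann.micrograph_id, rule, msg))
    if violations:
        raise AnnotationValidationError(violations)


# ---------------------------------------------------------------------------
# JSON document I/O
# ---------------------------------------------------------------------------

def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    return obj


def annotations_to_json(annotations: Sequence[CapillaryAnnotation]) -> str:
    """Render annotations as canonical JSON (sorted keys, 6-digit floats)."""
    doc = {
        "format_version": FORMAT_VERSION,
        "annotations": [_round_floats(a.to_dict()) for a in annotations],
    }
    return json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n"


def save_annotation_file(
    annotations: Sequence[CapillaryAnnotation],
    path: str | Path,
    validate: bool = True,
) -> None:
    if validate:
        validate_annotations(annotations)
    Path(path).write_text(annotations_to_json(annotations), encoding="utf-8")


def load_annotation_file(
    path: str | Path, validate: bool = True
) -> list[CapillaryAnnotation]:
    """Read and validate an annotation JSON document.

    All invariant violations are collected and reported together in a single
    :class:`AnnotationValidationError`.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(doc, dict) or "annotations" not in doc:
        raise AnnotationParseError(f"{path}: missing top-level 'annotations' array")
    annotations = []
    for i, record in enumerate(doc["annotations"]):
        try:
            annotations.append(CapillaryAnnotation.from_dict(record))
        except (AnnotationParseError, TypeError, ValueError) as exc:
            raise AnnotationParseError(f"{path}: record {i}: {exc}") from exc
    if validate:
        validate_annotations(annotations)
    return annotations


# ---------------------------------------------------------------------------
# ImageJ ROI import (convenience adapter; the JSON schema is canonical)
# ---------------------------------------------------------------------------

_ROI_TYPES = {0: "polygon", 4: "freeline", 5: "polyline", 7: "freehand", 8: "traced"}
_CLOSED_ROI_TYPES = {"polygon", "freehand", "traced"}


def read_imagej_roi(data: bytes) -> tuple[str, np.ndarray, bool]:
    """Decode a single ImageJ ``.roi`` blob to (kind, (n,2) points, closed).

    Supports the vertex-list ROI kinds produced by digital-pen tracing
    (polygon, freehand, traced, polyline, freeline).  Point, oval, rectangle
    and line ROIs carry no usable vertex list and are rejected.
    """
    if data[:4] != b"Iout":
        raise AnnotationParseError("not an ImageJ ROI (missing 'Iout' magic)")
    roi_type = data[6]
    kind = _ROI_TYPES.get(roi_type)
    if kind is None:
        raise AnnotationParseError(
            f"unsupported ImageJ ROI type code {roi_type} "
            "(only polygon/freehand/traced/polyline/freeline are supported)"
        )
    top, left = struct.unpack(">hh", data[8:12])
    (n,) = struct.unpack(">H", data[16:18])
    if n < 2:
        raise AnnotationParseError("ROI has fewer than 2 vertices")
    off = 64
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=off).astype(float) + left
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=off + 2 * n).astype(float) + top
    points = np.column_stack([xs, ys])
    return kind, points, kind in _CLOSED_ROI_TYPES


def write_imagej_roi(points: np.ndarray, closed: bool = True) -> bytes:
    """Encode a vertex list as an ImageJ ``.roi`` blob (integer coordinates)."""
    pts = np.asarray(points)
    ipts = np.rint(pts).astype(int)
    left, top = ipts[:, 0].min(), ipts[:, 1].min()
    right, bottom = ipts[:, 0].max(), ipts[:, 1].max()
    n = len(ipts)
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)  # header version
    header[6] = 0 if closed else 5  # polygon / polyline
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">H", header, 16, n)
    xs = (ipts[:, 0] - left).astype(">i2").tobytes()
    ys = (ipts[:, 1] - top).astype(">i2").tobytes()
    return bytes(header) + xs + ys


#: Roles a ROI name may be mapped to by :func:`import_imagej_rois`.
ROI_ROLES = ("lumen", "ec_abluminal", "bm_outer", "pericyte", "nucleus", "projection")
_MANDATORY_ROLES = ("lumen", "ec_abluminal", "bm_outer")


def import_imagej_rois(
    roi_archive: str | Path | io.BytesIO,
    role_map: Mapping[str, str],
    scale_nm_per_px: float,
    micrograph_id: str = "roi_import",
    subject_id: str = "unknown",
    biopsy_id: str = "unknown",
    group: str = GROUP_LABELS[0],
    rater_id: str = "A",
    validate: bool = True,
) -> tuple[CapillaryAnnotation, list[str]]:
    """Build one annotation from a ``.zip`` archive of ImageJ ``.roi`` files.

    ``role_map`` maps ROI names (without the ``.roi`` suffix) to roles in
    :data:`ROI_ROLES`.  Returns the annotation and the list of archive entries
    whose names were not mapped (reported, never silently dropped).
    """
    contours: dict[str, list[Contour]] = {role: [] for role in ROI_ROLES}
    unmapped: list[str] = []
    with zipfile.ZipFile(roi_archive) as zf:
        for entry in sorted(zf.namelist()):
            name = entry[:-4] if entry.endswith(".roi") else entry
            role = role_map.get(name)
            if role is None:
                unmapped.append(name)
                continue
            if role not in ROI_ROLES:
                raise AnnotationParseError(f"unknown role {role!r} for ROI {name!r}")
            kind, points, closed = read_imagej_roi(zf.read(entry))
            if role == "projection" and closed:
                closed = False  # projections are polylines even if traced closed
            contours[role].append(
                Contour(points=points, closed=closed, scale_nm_per_px=scale_nm_per_px)
            )
    missing = [r for r in _MANDATORY_ROLES if not contours[r]]
    if missing:
        raise AnnotationParseError(
            f"ROI archive is missing mandatory role(s): {', '.join(missing)}"
        )
    for role in _MANDATORY_ROLES:
        if len(contours[role]) > 1:
            raise AnnotationParseError(f"multiple ROIs mapped to role {role!r}")
    ann = CapillaryAnnotation(
        micrograph_id=micrograph_id,
        subject_id=subject_id,
        biopsy_id=biopsy_id,
        group=group,
        rater_id=rater_id,
        lumen=contours["lumen"][0],
        ec_abluminal=contours["ec_abluminal"][0],
        bm_outer=contours["bm_outer"][0],
        pericytes=contours["pericyte"],
        nuclei=contours["nucleus"],
        projections=contours["projection"],
    )
    if validate:
        validate_annotations([ann])
    return ann, unmapped


# ---------------------------------------------------------------------------
# Tabular outputs
# ---------------------------------------------------------------------------

#: profiles.csv columns.  Units: *_nm in nanometres, *_pct in percent,
#: pc_coverage as a fraction of the abluminal EC perimeter in [0, 1].
PROFILE_COLUMNS = [
    "micrograph_id", "subject_id", "biopsy_id", "group", "rater_id",
    "lumen_radius_nm", "ec_thickness_nm", "bm_thickness_nm",
    "pc_coverage", "nucleus_area_density_pct", "luminal_enlargement_pct",
    "min_feret_nm", "max_feret_nm", "aspect_ratio",
    "excluded", "exclusion_reason", "mode",
    "ec_sockets_n", "ec_sockets_empty_n", "pc_sockets_n", "pc_sockets_empty_n",
    "bm_disrupted",
]

#: subjects.csv columns.  Index means are over included profiles only;
#: pct_capillaries_* frequencies are percentages of included profiles.
SUBJECT_COLUMNS = [
    "subject_id", "biopsy_id", "group", "age_years",
    "n_profiles_annotated", "n_profiles_included",
    "lumen_radius_nm", "ec_thickness_nm", "bm_thickness_nm",
    "pc_coverage", "nucleus_area_density_pct", "luminal_enlargement_pct",
    "pct_capillaries_with_ec_sockets", "pct_capillaries_with_empty_ec_sockets",
    "pct_capillaries_with_pc_sockets", "pct_capillaries_with_empty_pc_sockets",
    "pct_capillaries_bm_disrupted",
]


def _write_table(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    out = df.reindex(columns=columns) if len(df) else pd.DataFrame(columns=columns)
    out.to_csv(path, index=False, encoding="utf-8", float_format="%.6g")


def write_profile_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write per-profile metric rows to ``profiles.csv``."""
    _write_table(records, PROFILE_COLUMNS, path)


def write_subject_table(summaries: pd.DataFrame, path: str | Path) -> None:
    """Write per-subject summaries to ``subjects.csv``."""
    _write_table(summaries, SUBJECT_COLUMNS, path)
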
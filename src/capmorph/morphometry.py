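"""Per-profile geometric indices of capillary cross-sections.

All indices derive from areas A and boundary lengths C of the traced
compartment boundaries (lumen, abluminal EC surface, outer BM boundary):

* lumen radius            R = 2 A_lumen / C_lumen
* EC layer thickness      ring area over mean bounding perimeter
* BM layer thickness      ring area (pericyte bodies excluded) over mean
                          bounding perimeter
* pericyte coverage       fraction of the abluminal EC arc length whose
                          radial projection from the lumen centroid meets a
                          pericyte profile
* EC nucleus area density traced nucleus area as % of the EC ring area
* luminal enlargement     summed intraluminal projection length as % of the
                          luminal perimeter

Two thickness conventions are provided.  ``consistent`` (the default)
estimates each layer as its ring area divided by the mean of the two bounding
perimeters; it recovers the true thickness on annular fixtures.  ``as_printed``
evaluates the literal historical formulas, which use the full enclosed area of
the outer boundary instead of the ring area; it is retained so the divergence
between the two conventions can be quantified rather than hidden.

Profiles with a max/min Feret (caliper) diameter ratio above the cutoff
(default 1.2) are flagged as obliquely sectioned and excluded from downstream
aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .annotation_io import CapillaryAnnotation, Contour, PROFILE_COLUMNS

Mode = Literal["consistent", "as_printed"]

#: Max/min Feret ratio above which a profile counts as obliquely sectioned.
ASPECT_RATIO_CUTOFF = 1.2


class GeometryError(ValueError):
    """Raised when a contour configuration admits no meaningful index."""


@dataclass
class MorphometryConfig:
    mode: Mode = "consistent"
    aspect_ratio_cutoff: float = ASPECT_RATIO_CUTOFF

    def __post_init__(self) -> None:
        if self.mode not in ("consistent", "as_printed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.aspect_ratio_cutoff > 1:
            raise ValueError("aspect_ratio_cutoff must be > 1")


@dataclass
class CapillaryMetrics:
    """The per-profile index vector plus exclusion bookkeeping."""

    lumen_radius_nm: float
    ec_thickness_nm: float
    bm_thickness_nm: float
    pc_coverage: float
    nucleus_area_density_pct: float
    luminal_enlargement_pct: float
    min_feret_nm: float
    max_feret_nm: float
    aspect_ratio: float
    excluded: bool
    exclusion_reason: Literal["none", "oblique_section", "invalid_geometry"]
    mode: Mode


# ---------------------------------------------------------------------------
# Elementary polygon measures
# ---------------------------------------------------------------------------

def _shoelace_px(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(x @ np.roll(y, -1) - y @ np.roll(x, -1))


def polygon_area(contour: Contour) -> float:
    """Absolute enclosed area in nm² (shoelace; orientation-independent)."""
    if not contour.closed:
        raise GeometryError("area requires a closed contour")
    if len(contour.points) < 3:
        raise GeometryError("area requires >= 3 points")
    return abs(_shoelace_px(contour.points)) * contour.scale_nm_per_px**2


def polygon_perimeter(contour: Contour) -> float:
    """Boundary length in nm (closed contours include the wrap segment)."""
    pts = contour.points
    if len(pts) < 2:
        raise GeometryError("perimeter requires >= 2 points")
    seg = np.diff(pts, axis=0)
    length = float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if contour.closed:
        length += float(np.hypot(*(pts[0] - pts[-1])))
    return length * contour.scale_nm_per_px


def polygon_centroid_px(points: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon, in pixel coordinates."""
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-12:
        return points.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def feret_diameters(contour: Contour) -> tuple[float, float, float]:
    """(min Feret, max Feret, max/min ratio) of a closed contour, in nm.

    Caliper diameters of the convex hull: the maximum Feret is the hull
    diameter; the minimum Feret is attained perpendicular to a hull edge.
    """
    if not contour.closed:
        raise GeometryError("Feret diameters require a closed contour")
    pts = contour.points
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise GeometryError(f"degenerate contour: {exc}") from exc
    hp = pts[hull.vertices]
    # max Feret: diameter of the hull vertex set (Gram-matrix distance trick)
    sq = (hp**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (hp @ hp.T)
    dmax = float(np.sqrt(max(d2.max(), 0.0)))
    # min Feret: minimal projection width over hull edge normals
    edges = np.roll(hp, -1, axis=0) - hp
    norms = np.hypot(edges[:, 0], edges[:, 1])
    ok = norms > 0
    normals = np.column_stack([-edges[ok, 1], edges[ok, 0]]) / norms[ok, None]
    proj = hp @ normals.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    dmin = float(widths.min())
    if dmin <= 0:
        raise GeometryError("degenerate (collinear) contour")
    s = contour.scale_nm_per_px
    return dmin * s, dmax * s, dmax / dmin


# ---------------------------------------------------------------------------
# Compartment indices
# ---------------------------------------------------------------------------

def lumen_radius(ann: CapillaryAnnotation) -> float:
    """Lumen radius R = 2 A_lumen / C_lumen, in nm."""
    c = polygon_perimeter(ann.lumen)
    if c <= 0:
        raise GeometryError("lumen has zero perimeter")
    return 2.0 * polygon_area(ann.lumen) / c


def ec_thickness(ann: CapillaryAnnotation, mode: Mode = "consistent") -> float:
    """Mean EC layer thickness in nm.

    consistent: 2 (A_EC:BM − A_lumen) / (C_EC:BM + C_lumen) — the EC ring
    area over the mean of its two bounding perimeters.
    as_printed: 2 (A_EC:BM − ΣA_PC) / (C_EC:BM + C_lumen) — the literal
    historical formula with the full enclosed abluminal area.
    """
    a_ec = polygon_area(ann.ec_abluminal)
    c_ec = polygon_perimeter(ann.ec_abluminal)
    c_lum = polygon_perimeter(ann.lumen)
    if mode == "as_printed":
        a_pc = sum(polygon_area(p) for p in ann.pericytes)
        return 2.0 * (a_ec - a_pc) / (c_ec + c_lum)
    a_lum = polygon_area(ann.lumen)
    num = a_ec - a_lum
    if num <= 0:
        raise GeometryError("non-nested contours: EC ring area is not positive")
    return 2.0 * num / (c_ec + c_lum)


def bm_thickness(ann: CapillaryAnnotation, mode: Mode = "consistent") -> float:
    """Mean BM layer thickness in nm.

    consistent: 2 (A_BM:Endo − A_EC:BM − ΣA_PC) / (C_BM:Endo + C_EC:BM) — the
    BM ring area with embedded pericyte bodies excluded, over the mean of its
    two bounding perimeters.
    as_printed: 2 (A_BM:Endo − A_EC:BM − A_lumen) / (C_BM:Endo + C_EC:BM +
    C_lumen) — the literal historical formula (can go negative because it
    subtracts the lumen area a second time).
    """
    a_bm = polygon_area(ann.bm_outer)
    c_bm = polygon_perimeter(ann.bm_outer)
    a_ec = polygon_area(ann.ec_abluminal)
    c_ec = polygon_perimeter(ann.ec_abluminal)
    if mode == "as_printed":
        a_lum = polygon_area(ann.lumen)
        c_lum = polygon_perimeter(ann.lumen)
        return 2.0 * (a_bm - a_ec - a_lum) / (c_bm + c_ec + c_lum)
    a_pc = sum(polygon_area(p) for p in ann.pericytes)
    num = a_bm - a_ec - a_pc
    if num <= 0:
        raise GeometryError("non-nested contours: BM ring area is not positive")
    return 2.0 * num / (c_bm + c_ec)


# -- pericyte coverage -------------------------------------------------------

_TWO_PI = 2.0 * np.pi


def _angular_interval(points: np.ndarray, center: np.ndarray) -> tuple[float, float]:
    """Angular interval (start, end) subtended by a polygon seen from center.

    Traverses the polygon accumulating signed angle increments, so arcs wider
    than 180° are handled; an accumulated swing of 2π or more means the
    polygon surrounds the center (full coverage).
    """
    rel = points - center
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    d = np.diff(np.append(ang, ang[0]))
    d = (d + np.pi) % _TWO_PI - np.pi
    cum = np.concatenate([[0.0], np.cumsum(d)])
    lo, hi = float(cum.min()), float(cum.max())
    if hi - lo >= _TWO_PI:
        return 0.0, _TWO_PI
    return ang[0] + lo, ang[0] + hi


def _merge_circular(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of angular intervals, normalized into [0, 2π) segments."""
    segs: list[tuple[float, float]] = []
    for a, b in intervals:
        if b - a >= _TWO_PI:
            return [(0.0, _TWO_PI)]
        width = (b - a) % _TWO_PI
        a = a % _TWO_PI
        b = a + width
        if b <= _TWO_PI:
            segs.append((a, b))
        else:
            segs.append((a, _TWO_PI))
            segs.append((0.0, b - _TWO_PI))
    segs.sort()
    merged = [list(segs[0])]
    for a, b in segs[1:]:
        if a <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    # wrap-around join
    if len(merged) > 1 and merged[0][0] <= 1e-12 and merged[-1][1] >= _TWO_PI - 1e-12:
        merged[0][0] = merged[-1][0] - _TWO_PI
        merged.pop()
    return [tuple(m) for m in merged]


def pc_coverage(ann: CapillaryAnnotation) -> float:
    """Fraction of the abluminal EC arc length subtended by pericytes.

    Each pericyte footprint is projected radially from the lumen centroid
    onto the abluminal EC contour; overlapping footprints are merged before
    the covered arc length is summed.
    """
    if not ann.pericytes:
        return 0.0
    center = polygon_centroid_px(ann.lumen.points)
    segs = _merge_circular(
        [_angular_interval(p.points, center) for p in ann.pericytes]
    )
    if segs == [(0.0, _TWO_PI)]:
        return 1.0
    pts = ann.ec_abluminal.points
    rel = pts - center
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    nxt = np.roll(pts, -1, axis=0)
    seg_len = np.hypot(*(nxt - pts).T)
    d_ang = (np.roll(ang, -1) - ang + np.pi) % _TWO_PI - np.pi
    # each edge spans the angular interval [a, b]; its covered arc length is
    # proportional to the angular overlap with the pericyte union
    a = np.where(d_ang > 0, ang, ang + d_ang)
    b = a + np.abs(d_ang)
    width = np.maximum(b - a, 1e-12)
    overlap = np.zeros_like(a)
    for sa, sb in segs:
        for shift in (-_TWO_PI, 0.0, _TWO_PI):
            overlap += np.clip(
                np.minimum(b, sb + shift) - np.maximum(a, sa + shift), 0.0, None
            )
    covered = float((seg_len * np.minimum(overlap / width, 1.0)).sum())
    total = float(seg_len.sum())
    frac = covered / total
    return min(max(frac, 0.0), 1.0)


def nucleus_area_density(ann: CapillaryAnnotation) -> float:
    """Summed EC nucleus area as a percentage of the EC ring area."""
    if not ann.nuclei:
        return 0.0
    a_nuc = sum(polygon_area(n) for n in ann.nuclei)
    a_ring = polygon_area(ann.ec_abluminal) - polygon_area(ann.lumen)
    if a_ring <= 0:
        raise GeometryError("non-nested contours: EC ring area is not positive")
    density = 100.0 * a_nuc / a_ring
    if density > 100.0:
        raise GeometryError("nucleus area exceeds the EC ring area")
    return density


def luminal_enlargement(ann: CapillaryAnnotation) -> float:
    """Summed intraluminal projection length as % of the luminal perimeter.

    The source definition ((C_lumen + ΣL_proj) / C_lumen) is a ratio >= 1;
    the excess percentage 100 ΣL_proj / C_lumen is reported, matching the
    magnitude of published group values (~10-17 % of luminal EC surface).
    """
    if not ann.projections:
        return 0.0
    c_lum = polygon_perimeter(ann.lumen)
    if c_lum <= 0:
        raise GeometryError("lumen has zero perimeter")
    total = sum(polygon_perimeter(p) for p in ann.projections)
    return 100.0 * total / c_lum


# ---------------------------------------------------------------------------
# Profile-level aggregation
# ---------------------------------------------------------------------------

def compute_profile_metrics(
    ann: CapillaryAnnotation, config: MorphometryConfig | None = None
) -> CapillaryMetrics:
    """Compute every index for one profile; flag rather than fail.

    Obliquely sectioned profiles (aspect ratio above the cutoff, measured on
    the abluminal EC contour) keep their metric values but are flagged
    ``oblique_section``; geometry errors flag ``invalid_geometry`` with NaN
    metrics.
    """
    cfg = config or MorphometryConfig()
    try:
        fmin, fmax, ratio = feret_diameters(ann.ec_abluminal)
        metrics = CapillaryMetrics(
            lumen_radius_nm=lumen_radius(ann),
            ec_thickness_nm=ec_thickness(ann, cfg.mode),
            bm_thickness_nm=bm_thickness(ann, cfg.mode),
            pc_coverage=pc_coverage(ann),
            nucleus_area_density_pct=nucleus_area_density(ann),
            luminal_enlargement_pct=luminal_enlargement(ann),
            min_feret_nm=fmin,
            max_feret_nm=fmax,
            aspect_ratio=ratio,
            excluded=False,
            exclusion_reason="none",
            mode=cfg.mode,
        )
    except GeometryError:
        nan = float("nan")
        return CapillaryMetrics(
            lumen_radius_nm=nan, ec_thickness_nm=nan, bm_thickness_nm=nan,
            pc_coverage=nan, nucleus_area_density_pct=nan,
            luminal_enlargement_pct=nan, min_feret_nm=nan, max_feret_nm=nan,
            aspect_ratio=nan, excluded=True,
            exclusion_reason="invalid_geometry", mode=cfg.mode,
        )
    if metrics.aspect_ratio > cfg.aspect_ratio_cutoff:
        metrics.excluded = True
        metrics.exclusion_reason = "oblique_section"
    return metrics


def profile_table(
    annotations: Iterable[CapillaryAnnotation],
    config: MorphometryConfig | None = None,
) -> pd.DataFrame:
    """Measure a set of annotations into a per-profile record table."""
    cfg = config or MorphometryConfig()
    rows = []
    for ann in annotations:
        m = compute_profile_metrics(ann, cfg)
        rows.append({
            "micrograph_id": ann.micrograph_id,
            "subject_id": ann.subject_id,
            "biopsy_id": ann.biopsy_id,
            "group": ann.group,
            "rater_id": ann.rater_id,
            "lumen_radius_nm": m.lumen_radius_nm,
            "ec_thickness_nm": m.ec_thickness_nm,
            "bm_thickness_nm": m.bm_thickness_nm,
            "pc_coverage": m.pc_coverage,
            "nucleus_area_density_pct": m.nucleus_area_density_pct,
            "luminal_enlargement_pct": m.luminal_enlargement_pct,
            "min_feret_nm": m.min_feret_nm,
            "max_feret_nm": m.max_feret_nm,
            "aspect_ratio": m.aspect_ratio,
            "excluded": m.excluded,
            "exclusion_reason": m.exclusion_reason,
            "mode": m.mode,
            "ec_sockets_n": ann.ec_sockets_n,
            "ec_sockets_empty_n": ann.ec_sockets_empty_n,
            "pc_sockets_n": ann.pc_sockets_n,
            "pc_sockets_empty_n": ann.pc_sockets_empty_n,
            "bm_disrupted": float(ann.bm_disrupted),
        })
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    dup = df.duplicated(subset=["micrograph_id", "rater_id"])
    if dup.any():
        raise ValueError(
            "duplicate (micrograph_id, rater_id) rows: "
            + ", ".join(df.loc[dup, "micrograph_id"].unique()[:5])
        )
    return df
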
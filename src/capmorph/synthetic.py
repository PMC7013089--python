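"""Synthetic study cohorts with known ground truth.

The original biopsy micrographs are not publicly deposited, so every pipeline
stage is exercised on generated cohorts instead: 14 study groups (four
endurance-training studies plus a claudication study), 6-14 subjects per
group, ~40 capillary profiles per biopsy, with group-level means taken from
the published group table where printed and from documented placeholder
values where only figures exist.

Each capillary profile is built as three nested ellipses (lumen, abluminal EC
surface, outer BM boundary) with a shared low-amplitude harmonic boundary
perturbation, discretized at >= 256 vertices; pericytes are angular-arc
polygons embedded in the BM ring, the EC nucleus is a sector polygon inside
the EC ring, and intraluminal projections are radial polylines whose summed
length fixes the surface-enlargement index exactly.  A configurable fraction
of profiles is drawn elongated (aspect ratio > 1.2) to exercise the
oblique-section exclusion filter.

Two-rater measurement noise is multiplicative lognormal on the derived
indices, not on vertices: each rater's copy of an annotation carries a
per-profile calibration factor on the nm-per-pixel scale (all length indices
scale with it; dimensionless indices are invariant) plus independent factors
on the projection lengths and the nucleus area.  BM thickness inherits the
calibration factor but is taken from a single rater downstream, matching the
measurement protocol.

Every generated annotation maps to exactly one truth record, enabling
parameter-recovery tests; generation is deterministic given the master seed
(hierarchical seeding: cohort -> subject -> biopsy -> rater).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    GROUP_LABELS,
    CapillaryAnnotation,
    Contour,
    save_annotation_file,
)

_TWO_PI = 2.0 * np.pi

#: Radial band of the BM ring occupied by pericyte bodies (fractions of the
#: EC-to-BM radial span).
PC_BAND = (0.25, 0.75)

#: Physical floors for capillary geometry draws (nm); draws are clipped, the
#: resulting mean shift is far below one Monte-Carlo SEM at study group sizes.
FLOORS = {"lumen_radius_nm": 300.0, "ec_thickness_nm": 40.0, "bm_thickness_nm": 40.0}


@dataclass
class GroupPhenotype:
    """Generating distribution for one study group."""

    label: str
    n_subjects: int
    n_capillaries: int = 40
    # index means and between-subject SDs (printed group SDs where available)
    lumen_radius_nm: float = 1500.0
    lumen_radius_sd: float = 300.0
    ec_thickness_nm: float = 400.0
    ec_thickness_sd: float = 100.0
    bm_thickness_nm: float = 400.0
    bm_thickness_sd: float = 80.0
    pc_coverage: float = 0.25
    pc_coverage_sd: float = 0.07
    nucleus_area_density_pct: float = 16.0
    nucleus_area_density_sd: float = 5.0
    luminal_enlargement_pct: float = 14.0
    luminal_enlargement_sd: float = 3.0
    disrupted_bm_p: float = 0.25
    disrupted_bm_sd: float = 0.08
    p_ec_socket: float = 0.40
    p_ec_socket_sd: float = 0.08
    p_empty_ec_socket: float = 0.12  # unconditional per-capillary probability
    p_empty_ec_socket_sd: float = 0.06
    p_pc_socket: float = 0.15
    p_pc_socket_sd: float = 0.06
    p_empty_pc_socket: float = 0.08
    p_empty_pc_socket_sd: float = 0.04
    nucleus_presence_p: float = 0.6
    # elongation mixture for the oblique-section filter
    oblique_fraction: float = 0.15
    elongation_included: tuple[float, float] = (1.0, 1.15)
    elongation_oblique: tuple[float, float] = (1.25, 1.6)
    age_range: tuple[float, float] = (25.0, 65.0)
    # geometry discretization
    n_vertices: int = 256
    harmonic_amplitude: float = 0.01
    scale_nm_per_px: float = 4.0
    # fraction of the printed variance assigned to the subject level
    between_subject_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("disrupted_bm_p", "p_ec_socket", "p_empty_ec_socket",
                     "p_pc_socket", "p_empty_pc_socket", "nucleus_presence_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_subjects < 1 or self.n_capillaries < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.between_subject_fraction <= 1.0:
            raise ValueError("between_subject_fraction must be in [0, 1]")


#: Subject cohorts: groups listed together share subjects (pre/post biopsies
#: of the same individuals); claudication controls and patients are distinct.
SUBJECT_COHORTS = (
    ("endur", ("endurance_pre", "endurance_post")),
    ("ar", ("ar_pre", "ar_post")),
    ("nr", ("nr_pre", "nr_post")),
    ("normo", ("normotensive_pre", "normotensive_post")),
    ("hyper", ("hypertensive_pre", "hypertensive_post")),
    ("diab", ("diabetic_pre", "diabetic_post")),
    ("icctl", ("ic_control",)),
    ("icpad", ("ic_pad",)),
)

#: Training effects reported for EC and BM thickness (post/pre ratios);
#: groups not listed are unchanged by training.
_EC_TRAINING_FACTOR = {"endurance_post": 1.173, "ar_post": 1.272,
                       "nr_post": 1.092, "diabetic_post": 1.135}
_BM_TRAINING_FACTOR = {"endurance_post": 0.863, "ar_post": 0.759,
                       "hypertensive_post": 0.869}
#: BM thickening factors in the untrained patient groups relative to healthy.
_BM_PATHOLOGY_FACTOR = {"diabetic_pre": 1.385, "diabetic_post": 1.385 * 0.9,
                        "ic_pad": 1.455}
#: Peg-socket placeholder frequencies; patient-group empty-EC-socket
#: frequencies and the claudication socket excesses follow reported values.
_EMPTY_EC_SOCKET = {
    "hypertensive_pre": 0.206, "hypertensive_post": 0.206,
    "diabetic_pre": 0.271, "diabetic_post": 0.271,
    "ic_pad": 0.300,
}
_EC_SOCKET = {"ic_pad": 0.40 * 1.213}
_PC_SOCKET = {"ic_pad": 0.15 * 1.466}

_AGE_RANGES = {
    "endur": (23.0, 38.0), "ar": (25.0, 48.0), "nr": (25.0, 48.0),
    "normo": (42.0, 66.0), "hyper": (45.0, 70.0), "diab": (48.0, 70.0),
    "icctl": (52.0, 75.0), "icpad": (52.0, 75.0),
}


def reference_group_table() -> pd.DataFrame:
    """The packaged published group table (means ± SD per study group)."""
    with importlib.resources.files("capmorph.data").joinpath(
        "published_group_table.csv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def default_study_config() -> dict[str, GroupPhenotype]:
    """Generating phenotypes for the 14 study groups.

    Printed values parameterize the nucleus-density, enlargement and
    BM-disruption distributions and the group sizes; geometric absolutes
    (radius, layer thicknesses) are documented placeholders with the printed
    pathology/training ratios applied on top.
    """
    ref = reference_group_table().set_index("group")
    cohort_of = {g: c for c, gs in SUBJECT_COHORTS for g in gs}
    config: dict[str, GroupPhenotype] = {}
    for label in GROUP_LABELS:
        row = ref.loc[label]
        config[label] = GroupPhenotype(
            label=label,
            n_subjects=int(row["n_subjects"]),
            ec_thickness_nm=400.0 * _EC_TRAINING_FACTOR.get(label, 1.0),
            ec_thickness_sd=100.0 * _EC_TRAINING_FACTOR.get(label, 1.0),
            bm_thickness_nm=400.0 * _BM_TRAINING_FACTOR.get(label, 1.0)
            * _BM_PATHOLOGY_FACTOR.get(label, 1.0),
            bm_thickness_sd=80.0 * _BM_PATHOLOGY_FACTOR.get(label, 1.0),
            nucleus_area_density_pct=float(row["nucleus_area_density_mean"]),
            nucleus_area_density_sd=float(row["nucleus_area_density_sd"]),
            luminal_enlargement_pct=float(row["luminal_enlargement_mean"]),
            luminal_enlargement_sd=float(row["luminal_enlargement_sd"]),
            disrupted_bm_p=float(row["disrupted_bm_mean"]) / 100.0,
            disrupted_bm_sd=float(row["disrupted_bm_sd"]) / 100.0,
            p_ec_socket=_EC_SOCKET.get(label, 0.40),
            p_empty_ec_socket=_EMPTY_EC_SOCKET.get(label, 0.12),
            p_pc_socket=_PC_SOCKET.get(label, 0.15),
            age_range=_AGE_RANGES[cohort_of[label]],
        )
    return config


# ---------------------------------------------------------------------------
# Geometry construction
# ---------------------------------------------------------------------------

def _cum_lengths(points: np.ndarray) -> np.ndarray:
    seg = np.roll(points, -1, axis=0) - points
    return np.hypot(seg[:, 0], seg[:, 1])


def _arc_indices(seg_len: np.ndarray, start: int, target_len: float) -> int:
    """Number of consecutive edges from ``start`` closest to ``target_len``."""
    n = len(seg_len)
    rolled = np.roll(seg_len, -start)
    cum = np.cumsum(rolled)
    k = int(np.searchsorted(cum, target_len) + 1)
    k = min(max(k, 1), n - 1)
    if k >= 2 and abs(cum[k - 2] - target_len) < abs(cum[k - 1] - target_len):
        k -= 1
    return k


def _band_polygon(inner: np.ndarray, outer: np.ndarray,
                  idx: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Polygon between two nested contours over vertex indices ``idx``."""
    a = inner[idx] + lo * (outer[idx] - inner[idx])
    b = inner[idx] + hi * (outer[idx] - inner[idx])
    return np.vstack([a, b[::-1]])


def _shoelace(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(float(x @ np.roll(y, -1) - y @ np.roll(x, -1)))


@dataclass
class CapillaryTruth:
    """Per-capillary generating parameters."""

    micrograph_id: str
    lumen_radius_nm: float
    ec_thickness_nm: float
    bm_thickness_nm: float
    elongation: float
    oblique: bool
    pc_coverage: float
    nucleus_area_density_pct: float
    luminal_enlargement_pct: float
    bm_disrupted: bool
    ec_sockets_n: int
    ec_sockets_empty_n: int
    pc_sockets_n: int
    pc_sockets_empty_n: int


def build_capillary_annotation(
    *,
    micrograph_id: str,
    subject_id: str,
    biopsy_id: str,
    group: str,
    rater_id: str,
    lumen_radius_nm: float,
    ec_thickness_nm: float,
    bm_thickness_nm: float,
    elongation: float,
    pc_coverage: float,
    nucleus_area_density_pct: float,
    luminal_enlargement_pct: float,
    flags: dict,
    rng: np.random.Generator,
    n_vertices: int = 256,
    harmonic_amplitude: float = 0.01,
    scale_nm_per_px: float = 4.0,
) -> tuple[CapillaryAnnotation, dict]:
    """Build one annotated profile realizing the given index values.

    Returns the annotation and a dict of the values actually realized by the
    discretized geometry (arc quantization makes pericyte coverage and
    nucleus density match their targets only to within one vertex spacing).
    """
    n = int(n_vertices)
    t = np.linspace(0.0, _TWO_PI, n, endpoint=False)
    # shared harmonic wobble so layer thicknesses stay near their targets
    eps = np.zeros(n)
    if harmonic_amplitude > 0:
        for k in (3, 4, 5):
            eps += (harmonic_amplitude * rng.uniform(0.4, 1.0)
                    * np.cos(k * t + rng.uniform(0, _TWO_PI)))
    e = float(elongation)
    # the BM thickness target is the pericyte-free (material) thickness; the
    # geometric ring is widened so that excluding the embedded pericyte band
    # (radial fraction PC_BAND, arc fraction = coverage) recovers the target
    cov = min(max(pc_coverage, 0.0), 0.85)
    band_frac = PC_BAND[1] - PC_BAND[0]
    t_bm_geom = bm_thickness_nm / (1.0 - band_frac * cov)
    phi = rng.uniform(0, _TWO_PI)  # random section orientation
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    center_px = rng.uniform(400.0, 600.0, size=2)

    def ring(radius: float) -> np.ndarray:
        # similar ellipses: an oblique section stretches every boundary by
        # the same factor, so all three contours share the elongation
        pts = np.column_stack([radius * np.sqrt(e) * np.cos(t),
                               radius / np.sqrt(e) * np.sin(t)])
        pts *= (1.0 + eps)[:, None]
        return (pts @ rot.T) / scale_nm_per_px + center_px

    lum = ring(lumen_radius_nm)
    ecb = ring(lumen_radius_nm + ec_thickness_nm)
    bmb = ring(lumen_radius_nm + ec_thickness_nm + t_bm_geom)

    def contour(points: np.ndarray, closed: bool = True) -> Contour:
        return Contour(points=points, closed=closed,
                       scale_nm_per_px=scale_nm_per_px)

    # pericytes: 1-2 disjoint arcs embedded in the BM ring, covering the
    # requested fraction of the abluminal EC arc length
    ec_seg = _cum_lengths(ecb)
    c_ec = float(ec_seg.sum())
    pericytes: list[Contour] = []
    realized_cov = 0.0
    if cov > 0.01:
        if cov > 0.12 and rng.random() < 0.5:
            split = rng.uniform(0.35, 0.65)
            fracs = [cov * split, cov * (1.0 - split)]
        else:
            fracs = [cov]
        start = int(rng.integers(n))
        used = 0
        for frac in fracs:
            k = _arc_indices(ec_seg, start, frac * c_ec)
            if used + k + 4 > n:
                break
            idx = (start + np.arange(k + 1)) % n
            pericytes.append(contour(_band_polygon(ecb, bmb, idx, *PC_BAND)))
            realized_cov += float(ec_seg[idx[:-1]].sum()) / c_ec
            gap = int(rng.integers(3, max(4, n // 8)))
            start = (start + k + gap) % n
            used += k + gap

    # EC nucleus: sector polygon(s) inside the EC ring hitting the target
    # area fraction of the ring
    nuclei: list[Contour] = []
    realized_density = 0.0
    a_ring_px = _shoelace(ecb) - _shoelace(lum)
    target_pct = min(max(nucleus_area_density_pct, 0.0), 95.0)
    if target_pct > 0.5 and a_ring_px > 0:
        remaining_px = target_pct / 100.0 * a_ring_px
        start = int(rng.integers(n))
        for _ in range(2):  # at most two nucleus profiles
            if remaining_px <= 0.005 * a_ring_px:
                break
            per_edge = 0.7 * a_ring_px / n  # coarse area of one band edge
            k = int(np.clip(round(remaining_px / per_edge), 2, n - 4))
            idx = (start + np.arange(k + 1)) % n
            poly = _band_polygon(lum, ecb, idx, 0.15, 0.85)
            area = _shoelace(poly)
            # refine the span until the polygon area brackets the target
            while area < remaining_px and k < n - 4:
                k += 1
                idx = (start + np.arange(k + 1)) % n
                poly = _band_polygon(lum, ecb, idx, 0.15, 0.85)
                area = _shoelace(poly)
            while area > remaining_px and k > 2:
                k -= 1
                idx = (start + np.arange(k + 1)) % n
                candidate = _band_polygon(lum, ecb, idx, 0.15, 0.85)
                if _shoelace(candidate) < remaining_px:
                    # keep whichever side of the target is closer
                    if (area - remaining_px) < (remaining_px - _shoelace(candidate)):
                        break
                poly, area = candidate, _shoelace(candidate)
            nuclei.append(contour(poly))
            realized_density += 100.0 * area / a_ring_px
            remaining_px -= area
            start = (start + k + max(2, n // 16)) % n

    # intraluminal projections: radial polylines with exact total length
    projections: list[Contour] = []
    realized_enl = 0.0
    c_lum_px = float(_cum_lengths(lum).sum())
    enl = max(luminal_enlargement_pct, 0.0)
    if enl > 0:
        total_px = enl / 100.0 * c_lum_px
        max_piece = 0.7 * (lumen_radius_nm / scale_nm_per_px)
        pieces = max(1, int(np.ceil(total_px / max(max_piece, 1.0))),
                     int(round(total_px * scale_nm_per_px / 1000.0)))
        piece = total_px / pieces
        centroid = lum.mean(axis=0)
        for _ in range(pieces):
            i = int(rng.integers(n))
            p0 = lum[i]
            u = centroid - p0
            u = u / np.hypot(*u)
            projections.append(contour(np.vstack([p0, p0 + u * piece]),
                                       closed=False))
        realized_enl = 100.0 * piece * pieces / c_lum_px

    ann = CapillaryAnnotation(
        micrograph_id=micrograph_id, subject_id=subject_id,
        biopsy_id=biopsy_id, group=group, rater_id=rater_id,
        lumen=contour(lum), ec_abluminal=contour(ecb), bm_outer=contour(bmb),
        pericytes=pericytes, nuclei=nuclei, projections=projections,
        **flags,
    )
    realized = {
        "pc_coverage": realized_cov,
        "nucleus_area_density_pct": realized_density,
        "luminal_enlargement_pct": realized_enl,
    }
    return ann, realized


# ---------------------------------------------------------------------------
# Distribution sampling
# ---------------------------------------------------------------------------

def _gamma_draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Positive draw with the requested mean and SD (gamma-shaped)."""
    if mean <= 0:
        return 0.0
    if sd <= 0:
        return mean
    shape = (mean / sd) ** 2
    return float(rng.gamma(shape, sd**2 / mean))


#: Ceiling for one capillary's generated nucleus area density (percent of the
#: EC ring area).  Kept well below 100 so that multiplicative rater noise can
#: never push a reading past the whole EC ring, which would invalidate the
#: profile's geometry.
NUCLEUS_DENSITY_CAP = 80.0


def _capped_gamma_mean(target: float, sd: float, cap: float) -> float:
    """Gamma mean whose cap-censored expectation equals ``target``.

    Draws above ``cap`` are clipped by the geometry, which would bias the
    realized mean low; the pre-clip mean is inflated by fixed-point iteration
    so that E[min(X, cap)] hits the target.
    """
    from scipy.stats import gamma as _gamma

    if sd <= 0 or target <= 0 or target >= cap:
        return target
    m = target
    for _ in range(12):
        k = (m / sd) ** 2
        theta = sd**2 / m
        censored = (m * _gamma.cdf(cap, k + 1, scale=theta)
                    + cap * _gamma.sf(cap, k, scale=theta))
        if censored <= 0:
            break
        m_new = min(m * target / censored, cap * 3.0)
        if abs(m_new - m) < 1e-6 * target:
            m = m_new
            break
        m = m_new
    return m


def _subject_means(phenotype: GroupPhenotype, z: dict[str, float]) -> dict[str, float]:
    """Subject-level index means from shared standard-normal subject effects."""
    f = np.sqrt(phenotype.between_subject_fraction)
    p = phenotype

    def norm(mean, sd, key, lo=None, hi=None):
        v = mean + z[key] * f * sd
        if lo is not None:
            v = max(v, lo)
        if hi is not None:
            v = min(v, hi)
        return v

    means = {
        "lumen_radius_nm": norm(p.lumen_radius_nm, p.lumen_radius_sd,
                                "lumen_radius_nm", lo=FLOORS["lumen_radius_nm"]),
        "ec_thickness_nm": norm(p.ec_thickness_nm, p.ec_thickness_sd,
                                "ec_thickness_nm", lo=FLOORS["ec_thickness_nm"]),
        "bm_thickness_nm": norm(p.bm_thickness_nm, p.bm_thickness_sd,
                                "bm_thickness_nm", lo=FLOORS["bm_thickness_nm"]),
        "pc_coverage": norm(p.pc_coverage, p.pc_coverage_sd,
                            "pc_coverage", lo=0.02, hi=0.85),
        "nucleus_area_density_pct": norm(p.nucleus_area_density_pct,
                                         p.nucleus_area_density_sd,
                                         "nucleus_area_density_pct", lo=0.5),
        "luminal_enlargement_pct": norm(p.luminal_enlargement_pct,
                                        p.luminal_enlargement_sd,
                                        "luminal_enlargement_pct", lo=0.0),
        "disrupted_bm_p": norm(p.disrupted_bm_p, p.disrupted_bm_sd,
                               "disrupted_bm_p", lo=0.0, hi=1.0),
        "p_ec_socket": norm(p.p_ec_socket, p.p_ec_socket_sd,
                            "p_ec_socket", lo=0.0, hi=1.0),
        "p_empty_ec_socket": norm(p.p_empty_ec_socket, p.p_empty_ec_socket_sd,
                                  "p_empty_ec_socket", lo=0.0, hi=1.0),
        "p_pc_socket": norm(p.p_pc_socket, p.p_pc_socket_sd,
                            "p_pc_socket", lo=0.0, hi=1.0),
        "p_empty_pc_socket": norm(p.p_empty_pc_socket, p.p_empty_pc_socket_sd,
                                  "p_empty_pc_socket", lo=0.0, hi=1.0),
    }
    # conditional nucleus-density gamma given a nucleus is present: the
    # within-subject variance is chosen so that averaging over a biopsy's
    # profiles reproduces the printed group SD, and the mean is corrected for
    # the geometric density ceiling
    pres = p.nucleus_presence_p
    m_nuc = means["nucleus_area_density_pct"] / pres if pres > 0 else 0.0
    var_total = ((1.0 - p.between_subject_fraction)
                 * p.nucleus_area_density_sd**2)
    # presence/absence sampling already contributes m² p(1-p) of variance;
    # if that alone exceeds the requested within-subject variance, the
    # conditional density is held at its mean
    var_g = (var_total - m_nuc**2 * pres * (1.0 - pres)) / pres if pres > 0 else 0.0
    sd_nuc = float(np.sqrt(max(var_g, 0.0)))
    means["nucleus_gamma_sd"] = sd_nuc
    means["nucleus_gamma_mean"] = _capped_gamma_mean(
        m_nuc, sd_nuc, NUCLEUS_DENSITY_CAP)
    return means


def _socket_counts(rng, p_any: float, p_empty: float) -> tuple[int, int]:
    """Socket presence + truncated-geometric count (mean ~1.5 when present)."""
    if rng.random() >= p_any:
        return 0, 0
    count = 1 + int(rng.geometric(1.0 / 1.5) - 1)
    count = min(count, 6)
    p_empty_cond = min(p_empty / p_any, 1.0) if p_any > 0 else 0.0
    if rng.random() < p_empty_cond:
        empty = int(rng.integers(1, count + 1))
    else:
        empty = 0
    return count, empty


def sample_capillary(
    phenotype: GroupPhenotype,
    rng: np.random.Generator,
    subject_means: dict[str, float] | None = None,
    micrograph_id: str = "cap_0",
    subject_id: str = "subject_0",
    biopsy_id: str = "biopsy_0",
    rater_id: str = "truth",
) -> tuple[CapillaryAnnotation, CapillaryTruth]:
    """Draw one capillary profile from a phenotype (or given subject means)."""
    p = phenotype
    means = subject_means or _subject_means(p, {k: 0.0 for k in (
        "lumen_radius_nm", "ec_thickness_nm", "bm_thickness_nm", "pc_coverage",
        "nucleus_area_density_pct", "luminal_enlargement_pct", "disrupted_bm_p",
        "p_ec_socket", "p_empty_ec_socket", "p_pc_socket", "p_empty_pc_socket",
    )})
    # 50/50 split of the published group variance between the subject level
    # and the capillary level
    w = np.sqrt(1.0 - p.between_subject_fraction)

    oblique = rng.random() < p.oblique_fraction
    elong = float(rng.uniform(*(p.elongation_oblique if oblique
                                else p.elongation_included)))
    r0 = max(_gamma_draw(rng, means["lumen_radius_nm"], w * p.lumen_radius_sd),
             FLOORS["lumen_radius_nm"])
    t_ec = max(_gamma_draw(rng, means["ec_thickness_nm"], w * p.ec_thickness_sd),
               FLOORS["ec_thickness_nm"])
    t_bm = max(_gamma_draw(rng, means["bm_thickness_nm"], w * p.bm_thickness_sd),
               FLOORS["bm_thickness_nm"])
    cov = float(np.clip(
        rng.normal(means["pc_coverage"],
                   np.sqrt(1.0 - p.between_subject_fraction) * p.pc_coverage_sd)
        if p.pc_coverage_sd > 0 else means["pc_coverage"], 0.0, 0.85))
    # nucleus: presence/absence model keeps the per-capillary density
    # distribution positive while matching the subject mean
    if (rng.random() < p.nucleus_presence_p
            and means["nucleus_area_density_pct"] > 0):
        nuc = min(_gamma_draw(rng, means["nucleus_gamma_mean"],
                              means["nucleus_gamma_sd"]),
                  NUCLEUS_DENSITY_CAP)
    else:
        nuc = 0.0
    enl = _gamma_draw(rng, means["luminal_enlargement_pct"],
                      w * p.luminal_enlargement_sd)

    disrupted = bool(rng.random() < means["disrupted_bm_p"])
    ec_n, ec_empty = _socket_counts(rng, means["p_ec_socket"],
                                    means["p_empty_ec_socket"])
    pc_n, pc_empty = _socket_counts(rng, means["p_pc_socket"],
                                    means["p_empty_pc_socket"])
    flags = {
        "ec_sockets_n": ec_n, "ec_sockets_empty_n": ec_empty,
        "pc_sockets_n": pc_n, "pc_sockets_empty_n": pc_empty,
        "bm_disrupted": disrupted,
    }
    ann, realized = build_capillary_annotation(
        micrograph_id=micrograph_id, subject_id=subject_id,
        biopsy_id=biopsy_id, group=p.label, rater_id=rater_id,
        lumen_radius_nm=r0, ec_thickness_nm=t_ec, bm_thickness_nm=t_bm,
        elongation=elong, pc_coverage=cov, nucleus_area_density_pct=nuc,
        luminal_enlargement_pct=enl, flags=flags, rng=rng,
        n_vertices=p.n_vertices, harmonic_amplitude=p.harmonic_amplitude,
        scale_nm_per_px=p.scale_nm_per_px,
    )
    truth = CapillaryTruth(
        micrograph_id=micrograph_id,
        lumen_radius_nm=r0, ec_thickness_nm=t_ec, bm_thickness_nm=t_bm,
        elongation=elong, oblique=elong > 1.2,
        pc_coverage=realized["pc_coverage"],
        nucleus_area_density_pct=realized["nucleus_area_density_pct"],
        luminal_enlargement_pct=realized["luminal_enlargement_pct"],
        bm_disrupted=disrupted,
        ec_sockets_n=ec_n, ec_sockets_empty_n=ec_empty,
        pc_sockets_n=pc_n, pc_sockets_empty_n=pc_empty,
    )
    return ann, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class RaterNoise:
    """Per-rater multiplicative lognormal noise on the dual-measured indices.

    ``sigma_calibration`` scales each rater's nm-per-pixel calibration (lumen
    radius and both layer thicknesses inherit it; dimensionless indices do
    not); ``sigma_enlargement`` and ``sigma_nucleus`` act on the projection
    lengths and nucleus areas.

    With ``repeat_until_accepted`` (the default), reading pairs whose
    mean-relative deviation exceeds ``repeat_tolerance`` are redrawn, matching
    the measurement protocol in which discordant readings were repeated: the
    recorded data contain only reconciled pairs.  The conditioning is on the
    reading *difference* only, so the merged means stay unbiased.
    """

    sigma_calibration: float = 0.05
    sigma_enlargement: float = 0.05
    sigma_nucleus: float = 0.05
    repeat_until_accepted: bool = True
    repeat_tolerance: float = 0.10

    def _pair(self, rng: np.random.Generator, sigma: float) -> tuple[float, float]:
        """One (rater1, rater2) lognormal factor pair, repeated to tolerance."""
        if sigma <= 0:
            return 1.0, 1.0
        threshold = 2.0 * np.arctanh(self.repeat_tolerance / 2.0)
        for _ in range(100):
            n1, n2 = rng.normal(0.0, sigma, size=2)
            if not self.repeat_until_accepted or abs(n1 - n2) <= threshold:
                return float(np.exp(n1)), float(np.exp(n2))
        return 1.0, 1.0


@dataclass
class CohortConfig:
    groups: dict[str, GroupPhenotype] = field(default_factory=default_study_config)
    rater_ids: tuple[str, str] = ("A", "B")
    rater_noise: RaterNoise = field(default_factory=RaterNoise)

    def __post_init__(self) -> None:
        labels = list(self.groups)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels in cohort config")


@dataclass
class Cohort:
    annotations: dict[str, list[CapillaryAnnotation]]  # per rater
    truth_capillaries: pd.DataFrame
    truth_subjects: pd.DataFrame
    truth_groups: pd.DataFrame
    ages: dict[str, float]  # biopsy_id -> age
    master_seed: int
    manifest: dict


def _scaled_contour(c: Contour, scale_factor: float) -> Contour:
    return Contour(points=c.points.copy(), closed=c.closed,
                   scale_nm_per_px=c.scale_nm_per_px * scale_factor)


def _rater_copy(
    ann: CapillaryAnnotation, rater_id: str, f: float, e: float, nu: float,
) -> CapillaryAnnotation:
    """A rater's reading of one profile (noise on indices, not on tracing).

    ``f`` multiplies the calibration (all nm-dimensioned indices), ``e`` the
    projection lengths (surface enlargement), ``nu`` the nucleus areas
    (nucleus density).
    """
    s_nu = float(np.sqrt(nu))

    def proj(c: Contour) -> Contour:
        pts = c.points[0] + (c.points - c.points[0]) * e
        return Contour(points=pts, closed=False,
                       scale_nm_per_px=c.scale_nm_per_px * f)

    def nuc(c: Contour) -> Contour:
        # nucleus polygons are radial band sectors (inner arc + reversed
        # outer arc); scaling the band width about its midline multiplies the
        # area by ``nu`` while keeping the sector inside the EC ring
        pts = c.points
        m = len(pts) // 2
        if len(pts) == 2 * m:
            inner, outer = pts[:m], pts[m:][::-1]
            mid = 0.5 * (inner + outer)
            inner2 = mid + (inner - mid) * nu
            outer2 = mid + (outer - mid) * nu
            pts = np.vstack([inner2, outer2[::-1]])
        else:  # not a band polygon: isotropic scaling about the centroid
            centroid = pts.mean(axis=0)
            pts = centroid + (pts - centroid) * s_nu
        return Contour(points=pts, closed=True,
                       scale_nm_per_px=c.scale_nm_per_px * f)

    return replace(
        ann,
        rater_id=rater_id,
        lumen=_scaled_contour(ann.lumen, f),
        ec_abluminal=_scaled_contour(ann.ec_abluminal, f),
        bm_outer=_scaled_contour(ann.bm_outer, f),
        pericytes=[_scaled_contour(c, f) for c in ann.pericytes],
        nuclei=[nuc(c) for c in ann.nuclei],
        projections=[proj(c) for c in ann.projections],
    )


_Z_KEYS = (
    "lumen_radius_nm", "ec_thickness_nm", "bm_thickness_nm", "pc_coverage",
    "nucleus_area_density_pct", "luminal_enlargement_pct", "disrupted_bm_p",
    "p_ec_socket", "p_empty_ec_socket", "p_pc_socket", "p_empty_pc_socket",
)


def generate_cohort(
    config: CohortConfig | None = None, master_seed: int = 0
) -> Cohort:
    """Generate the full multi-study cohort with per-rater annotation sets.

    Deterministic given ``master_seed``; subjects are seeded independently of
    group-list order, so removing a group does not change another group's
    draws.  Subjects shared between pre- and post-training groups carry the
    same subject effects in both biopsies.
    """
    cfg = config or CohortConfig()
    if master_seed < 0 or master_seed >= 2**31:
        raise ValueError("master_seed must be in [0, 2^31)")
    annotations: dict[str, list[CapillaryAnnotation]] = {
        r: [] for r in cfg.rater_ids
    }
    truth_caps: list[dict] = []
    truth_subj: list[dict] = []
    ages: dict[str, float] = {}

    cohort_index = {name: i for i, (name, _) in enumerate(SUBJECT_COHORTS)}
    group_cohort = {g: name for name, gs in SUBJECT_COHORTS for g in gs}
    group_pos = {g: gi for _, gs in SUBJECT_COHORTS for gi, g in enumerate(gs)}

    for label, phenotype in cfg.groups.items():
        if label not in group_cohort:
            raise ValueError(f"unknown study group {label!r}")
        cname = group_cohort[label]
        ci = cohort_index[cname]
        for si in range(phenotype.n_subjects):
            subject_id = f"{cname}_{si:02d}"
            biopsy_id = f"{subject_id}_{label}"
            # subject effects shared across the pre/post biopsies
            subj_rng = np.random.default_rng(
                np.random.SeedSequence([master_seed, 1, ci, si]))
            z = {k: float(subj_rng.standard_normal()) for k in _Z_KEYS}
            age = float(subj_rng.uniform(*phenotype.age_range))
            ages[biopsy_id] = age
            means = _subject_means(phenotype, z)
            truth_subj.append({
                "subject_id": subject_id, "biopsy_id": biopsy_id,
                "group": label, "age_years": age, **means,
            })
            bio_rng = np.random.default_rng(np.random.SeedSequence(
                [master_seed, 2, ci, si, group_pos[label]]))
            rater_rng = np.random.default_rng(np.random.SeedSequence(
                [master_seed, 3, ci, si, group_pos[label]]))
            for ki in range(phenotype.n_capillaries):
                mid = f"{biopsy_id}_cap{ki:03d}"
                ann, truth = sample_capillary(
                    phenotype, bio_rng, subject_means=means,
                    micrograph_id=mid, subject_id=subject_id,
                    biopsy_id=biopsy_id,
                )
                truth_caps.append({"biopsy_id": biopsy_id, "group": label,
                                   **truth.__dict__})
                noise = cfg.rater_noise
                fs = noise._pair(rater_rng, noise.sigma_calibration)
                es = noise._pair(rater_rng, noise.sigma_enlargement)
                nus = noise._pair(rater_rng, noise.sigma_nucleus)
                for rater, f, e_, nu in zip(cfg.rater_ids, fs, es, nus):
                    annotations[rater].append(
                        _rater_copy(ann, rater, f, e_, nu))

    truth_groups = pd.DataFrame([
        {"group": p.label, "n_subjects": p.n_subjects,
         "n_capillaries": p.n_capillaries,
         "lumen_radius_nm": p.lumen_radius_nm,
         "ec_thickness_nm": p.ec_thickness_nm,
         "bm_thickness_nm": p.bm_thickness_nm,
         "pc_coverage": p.pc_coverage,
         "nucleus_area_density_pct": p.nucleus_area_density_pct,
         "luminal_enlargement_pct": p.luminal_enlargement_pct,
         "pct_capillaries_bm_disrupted": 100.0 * p.disrupted_bm_p,
         "pct_capillaries_with_ec_sockets": 100.0 * p.p_ec_socket,
         "pct_capillaries_with_empty_ec_sockets": 100.0 * p.p_empty_ec_socket,
         "pct_capillaries_with_pc_sockets": 100.0 * p.p_pc_socket,
         "pct_capillaries_with_empty_pc_sockets": 100.0 * p.p_empty_pc_socket}
        for p in cfg.groups.values()
    ])
    n_caps = sum(len(v) for v in annotations.values()) // max(len(cfg.rater_ids), 1)
    manifest = {
        "master_seed": master_seed,
        "n_groups": len(cfg.groups),
        "n_biopsies": int(sum(p.n_subjects for p in cfg.groups.values())),
        "n_capillaries": int(n_caps),
        "raters": list(cfg.rater_ids),
        "format_version": "1.0",
    }
    return Cohort(
        annotations=annotations,
        truth_capillaries=pd.DataFrame(truth_caps),
        truth_subjects=pd.DataFrame(truth_subj),
        truth_groups=truth_groups,
        ages=ages,
        master_seed=master_seed,
        manifest=manifest,
    )


def save_cohort(cohort: Cohort, outdir: str | Path, validate: bool = False) -> dict:
    """Write per-rater annotation files, the truth archive, and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for rater, anns in cohort.annotations.items():
        p = outdir / f"annotations_rater_{rater}.json"
        save_annotation_file(anns, p, validate=validate)
        paths[f"annotations_{rater}"] = str(p)
    truth = {
        "subjects": cohort.truth_subjects.to_dict(orient="records"),
        "groups": cohort.truth_groups.to_dict(orient="records"),
        "capillaries": cohort.truth_capillaries.to_dict(orient="records"),
        "ages": cohort.ages,
    }
    tp = outdir / "truth.json"
    tp.write_text(json.dumps(truth, sort_keys=True, default=float) + "\n",
                  encoding="utf-8")
    paths["truth"] = str(tp)
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(cohort.manifest, sort_keys=True, indent=2) + "\n",
                  encoding="utf-8")
    paths["manifest"] = str(mp)
    return paths


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

#: Subject-summary columns compared against generating group means.
RECOVERY_INDICES = (
    "lumen_radius_nm", "ec_thickness_nm", "bm_thickness_nm", "pc_coverage",
    "nucleus_area_density_pct", "luminal_enlargement_pct",
    "pct_capillaries_bm_disrupted", "pct_capillaries_with_ec_sockets",
    "pct_capillaries_with_empty_ec_sockets", "pct_capillaries_with_pc_sockets",
    "pct_capillaries_with_empty_pc_sockets",
)


def recovery_report(
    truth_groups: pd.DataFrame, subject_table: pd.DataFrame
) -> pd.DataFrame:
    """Generating vs pipeline-recovered group means with Monte-Carlo SEs.

    One row per (group, index): the generating group mean, the mean of the
    recovered subject means, the Monte-Carlo SEM (subject-level SD over
    sqrt(n)), and the z-score of the discrepancy.
    """
    rows = []
    tg = truth_groups.set_index("group")
    for group, grp in subject_table.groupby("group"):
        if group not in tg.index:
            raise ValueError(f"group {group!r} missing from truth table")
        for index in RECOVERY_INDICES:
            gen = float(tg.loc[group, index])
            vals = grp[index].dropna().to_numpy(dtype=float)
            rec = float(vals.mean())
            sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            z = (rec - gen) / sem if sem and np.isfinite(sem) and sem > 0 else np.nan
            rows.append({"group": group, "parameter": index,
                         "generating_value": gen, "recovered_value": rec,
                         "mc_sem": sem, "n_subjects": len(vals), "z": z})
    return pd.DataFrame(rows)
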
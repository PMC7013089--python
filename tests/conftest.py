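import numpy as np
import pytest

from capmorph.annotation_io import CapillaryAnnotation, Contour


def regular_polygon(radius: float, n: int = 512, center=(0.0, 0.0),
                    phase: float = 0.0) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False) + phase
    return np.column_stack([center[0] + radius * np.cos(t),
                            center[1] + radius * np.sin(t)])


def circle_contour(radius: float, n: int = 512, center=(0.0, 0.0),
                   scale: float = 1.0, phase: float = 0.0) -> Contour:
    return Contour(points=regular_polygon(radius, n, center, phase),
                   closed=True, scale_nm_per_px=scale)


def ellipse_contour(a: float, b: float, n: int = 512, center=(0.0, 0.0),
                    scale: float = 1.0) -> Contour:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return Contour(points=np.column_stack([center[0] + a * np.cos(t),
                                           center[1] + b * np.sin(t)]),
                   closed=True, scale_nm_per_px=scale)


def annulus_annotation(r0=2000.0, r1=2500.0, r2=2800.0, n=512, scale=1.0,
                       center=(3000.0, 3000.0), pericytes=(), nuclei=(),
                       projections=(), **flags) -> CapillaryAnnotation:
    """Concentric-circle profile: lumen r0, abluminal EC r1, outer BM r2."""
    return CapillaryAnnotation(
        micrograph_id=flags.pop("micrograph_id", "fixture"),
        subject_id=flags.pop("subject_id", "subj"),
        biopsy_id=flags.pop("biopsy_id", "bio"),
        group=flags.pop("group", "endurance_pre"),
        rater_id=flags.pop("rater_id", "A"),
        lumen=circle_contour(r0, n, center, scale),
        ec_abluminal=circle_contour(r1, n, center, scale),
        bm_outer=circle_contour(r2, n, center, scale),
        pericytes=list(pericytes),
        nuclei=list(nuclei),
        projections=list(projections),
        **flags,
    )


def arc_band(r_in: float, r_out: float, theta0: float, theta1: float,
             n: int = 64, center=(3000.0, 3000.0), scale: float = 1.0) -> Contour:
    """Annular-sector polygon between radii over [theta0, theta1] (radians)."""
    t = np.linspace(theta0, theta1, n)
    inner = np.column_stack([center[0] + r_in * np.cos(t),
                             center[1] + r_in * np.sin(t)])
    outer = np.column_stack([center[0] + r_out * np.cos(t[::-1]),
                             center[1] + r_out * np.sin(t[::-1])])
    return Contour(points=np.vstack([inner, outer]), closed=True,
                   scale_nm_per_px=scale)


def square_contour(side: float, center=(0.0, 0.0), scale: float = 1.0,
                   reverse: bool = False) -> Contour:
    h = side / 2.0
    pts = np.array([[-h, -h], [h, -h], [h, h], [-h, h]], dtype=float) + center
    if reverse:
        pts = pts[::-1]
    return Contour(points=pts, closed=True, scale_nm_per_px=scale)


@pytest.fixture
def annulus():
    return annulus_annotation()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_annotation(rng: np.random.Generator, micrograph_id: str = "m0",
                      n: int = 64) -> CapillaryAnnotation:
    """A small random but valid annotation for round-trip tests."""
    from capmorph.synthetic import GroupPhenotype, sample_capillary

    phen = GroupPhenotype(
        label="endurance_pre", n_subjects=1, n_capillaries=1, n_vertices=n,
    )
    ann, _ = sample_capillary(phen, rng, micrograph_id=micrograph_id)
    ann.ec_sockets_n = int(rng.integers(0, 4))
    ann.ec_sockets_empty_n = int(rng.integers(0, ann.ec_sockets_n + 1))
    ann.pc_sockets_n = int(rng.integers(0, 3))
    ann.pc_sockets_empty_n = int(rng.integers(0, ann.pc_sockets_n + 1))
    ann.bm_disrupted = bool(rng.random() < 0.3)
    return ann
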
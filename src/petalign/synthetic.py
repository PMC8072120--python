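"""Fully ground-truthed synthetic petal specimens.

Emulates the two acquisition products the real workflow consumes — a fresh
ventral-petal scan on a dark cloth and a backlit "histological" twin of the
same petal — together with every annotation the pipeline needs (contour,
vein tracks, tube boundaries, rim endpoints, paired control points) and the
generative truth (patterning modes, amplitudes, the hist↔fresh transform).

A petal is a serrated half-ellipse lobe atop a tapering tube.  Pigment is
laid down in the four patterning modes at controllable amplitude: distal and
proximal linear gradients anchored at the respective petal end, a darkened
corridor around the vein tracks (vascular mode), and off-vein blobs (random
mode).  The histological twin is the fresh geometry under a recorded random
projective perturbation, rendered pale-on-bright with visible veins.

Shapes deliberately vary between species (aspect, serration, tube taper):
the method's claim is alignment across shapes, and naive un-warped pixel
comparison must fail on these cohorts (a documented negative control).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw

from .errors import ConfigError, InputError
from .io import (
    AnatomicalAnnotation,
    ControlPointSet,
    PetalImage,
    save_image,
    write_annotation,
)
from .modes import ModeCall
from .registration import PlanarTransform, apply_matrix

__all__ = [
    "SpecimenParams",
    "SyntheticSpecimen",
    "SpeciesConfig",
    "CohortConfig",
    "Cohort",
    "generate_specimen",
    "generate_cohort",
    "four_mode_cohort",
    "gradient_cohort",
]


@dataclass
class SpecimenParams:
    """Geometry, coloring and pattern amplitudes for one synthetic petal.

    Amplitudes are fractions of the pigment contrast vector (≈0.5 gray units
    of luminance at amplitude 1.0).  ``vein_amp`` and ``spot_amp`` are
    mutually exclusive, as are nonzero ``distal_amp``/``proximal_amp`` for a
    clean single-mode truth label (both may be nonzero in quantitative
    cohorts; the truth label then follows the larger one).
    """

    lobe_rx: float = 90.0
    lobe_ry: float = 115.0
    serration_n: int = 8  # even, so the apex stays unperturbed
    serration_depth: float = 3.0
    tube_len: float = 120.0
    taper: float = 0.75
    margin: float = 42.0
    distal_amp: float = 0.0
    proximal_amp: float = 0.0
    vein_amp: float = 0.0
    spot_amp: float = 0.0
    n_spots: int = 22
    vein_halfwidth: float = 5.0
    gradient_extent: float = 0.45  # fraction of petal length a gradient spans
    base_color: tuple = (235, 225, 215)
    pigment_color: tuple = (120, 150, 110)  # subtracted at amplitude 1
    background: int = 10
    hist_background: int = 245
    noise_sd: float = 2.0
    dpi: float = 600.0

    def __post_init__(self):
        if self.vein_amp > 0 and self.spot_amp > 0:
            raise ConfigError(
                "vein_amp and spot_amp are mutually exclusive "
                "(vascular vs random mode)"
            )
        if self.serration_n % 2:
            raise ConfigError("serration_n must be even")
        for a in ("distal_amp", "proximal_amp", "vein_amp", "spot_amp"):
            if not 0 <= getattr(self, a) <= 1:
                raise ConfigError(f"{a} must lie in [0, 1]")

    def truth_modes(self) -> ModeCall:
        if self.vein_amp > 0:
            variegated = "vascular"
        elif self.spot_amp > 0:
            variegated = "random"
        else:
            variegated = "none"
        if self.distal_amp == self.proximal_amp == 0:
            gradient = "none"
        elif self.distal_amp >= self.proximal_amp:
            gradient = "distal"
        else:
            gradient = "proximal"
        return ModeCall(variegated, gradient)


@dataclass
class SyntheticSpecimen:
    specimen_id: str
    species: str
    fresh_image: PetalImage
    hist_image: PetalImage
    truth_annotation_fresh: AnatomicalAnnotation
    truth_annotation_hist: AnatomicalAnnotation
    control_points: ControlPointSet
    truth_modes: ModeCall
    amplitudes: dict
    params: SpecimenParams
    transform_hist_to_fresh: PlanarTransform
    seed: int


def _lobe_point(params: SpecimenParams, theta, cx, y_rim):
    """Serrated lobe boundary point(s) at ellipse angle theta (π=left rim)."""
    theta = np.asarray(theta, dtype=float)
    eps = (
        params.serration_depth
        / min(params.lobe_rx, params.lobe_ry)
        * np.maximum(0.0, np.sin(params.serration_n * theta))
    )
    x = cx + (1 + eps) * params.lobe_rx * np.cos(theta)
    y = y_rim - (1 + eps) * params.lobe_ry * np.sin(theta)
    return np.column_stack([x, y])


def _build_geometry(params: SpecimenParams):
    """Fresh-frame anatomy polylines and key landmarks."""
    p = params
    cx = p.margin + p.lobe_rx * (1 + p.serration_depth / p.lobe_rx)
    y_rim = p.margin + p.lobe_ry + p.serration_depth
    y_base = y_rim + p.tube_len
    y_apex = y_rim - p.lobe_ry

    theta = np.linspace(np.pi, 0.0, 361)
    arc = _lobe_point(p, theta, cx, y_rim)
    left_rim = np.array([cx - p.lobe_rx, y_rim])
    right_rim = np.array([cx + p.lobe_rx, y_rim])
    bl = np.array([cx - p.lobe_rx * p.taper, y_base])
    br = np.array([cx + p.lobe_rx * p.taper, y_base])

    def _line(a, b, n=31):
        t = np.linspace(0.0, 1.0, n)[:, None]
        return a + t * (b - a)

    # closed outline, stored from the left rim: lobe arc (via apex) to the
    # right rim, down the right tube edge, across the base, back up the left
    contour = np.vstack(
        [arc, _line(right_rim, br)[1:], _line(br, bl)[1:], _line(bl, left_rim)[1:-1]]
    )

    midvein = _line(np.array([cx, y_apex]), np.array([cx, y_base]), 41)
    sl_top = np.array([cx - p.lobe_rx / 2, y_rim - p.lobe_ry * np.sqrt(3) / 2])
    sr_top = np.array([cx + p.lobe_rx / 2, y_rim - p.lobe_ry * np.sqrt(3) / 2])
    sl_bot = np.array([cx - p.lobe_rx * p.taper / 2, y_base])
    sr_bot = np.array([cx + p.lobe_rx * p.taper / 2, y_base])
    sidevein_left = _line(sl_top, sl_bot, 31)
    sidevein_right = _line(sr_top, sr_bot, 31)
    tube_left = _line(left_rim, bl, 21)
    tube_right = _line(right_rim, br, 21)

    width = int(np.ceil(2 * cx))
    height = int(np.ceil(y_base + p.margin))
    return {
        "contour": contour,
        "midvein": midvein,
        "sidevein_left": sidevein_left,
        "sidevein_right": sidevein_right,
        "tube_boundary_left": tube_left,
        "tube_boundary_right": tube_right,
        "rim_endpoints": np.vstack([left_rim, right_rim]),
        "y_apex": y_apex,
        "y_base": y_base,
        "canvas": (height, width),
        "serration_tips": _lobe_point(
            p,
            np.pi / (2 * p.serration_n)
            + 2 * np.pi * np.arange(p.serration_n // 2) / p.serration_n,
            cx,
            y_rim,
        ),
        "tube_corners": np.vstack([bl, br]),
    }


def _polyline_mask(shape, polylines) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    for poly in polylines:
        pts = np.round(poly).astype(int)
        for a, b in zip(pts[:-1], pts[1:]):
            rr, cc = draw.line(a[1], a[0], b[1], b[0])
            keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            m[rr[keep], cc[keep]] = True
    return m


def _pigment_field(params, geom, silhouette, vein_dist, rng):
    """Pigment intensity in [0, 1] per pixel, summed over active modes."""
    h, w = silhouette.shape
    yy = np.arange(h, dtype=float)[:, None]
    t = np.clip(
        (yy - geom["y_apex"]) / (geom["y_base"] - geom["y_apex"]), 0.0, 1.0
    )
    t = np.broadcast_to(t, (h, w))
    ext = params.gradient_extent
    P = np.zeros((h, w))
    if params.distal_amp > 0:
        P += params.distal_amp * np.clip(1.0 - t / ext, 0.0, 1.0)
    if params.proximal_amp > 0:
        P += params.proximal_amp * np.clip((t - (1 - ext)) / ext, 0.0, 1.0)
    if params.vein_amp > 0:
        P += params.vein_amp * np.clip(
            params.vein_halfwidth + 1.0 - vein_dist, 0.0, 1.0
        )
    if params.spot_amp > 0:
        edge_dist = ndi.distance_transform_edt(silhouette)
        ok = (
            silhouette
            & (vein_dist > params.vein_halfwidth + 8)
            & (t > 0.18)
            & (t < 0.82)
            & (edge_dist > 10)
        )
        cand = np.argwhere(ok)
        if len(cand) == 0:
            raise InputError("no room to place random-mode spots")
        picks = cand[rng.choice(len(cand), min(params.n_spots, len(cand)), replace=False)]
        spot = np.zeros((h, w))
        yy2, xx2 = np.mgrid[0:h, 0:w]
        for r, c in picks:
            rad = rng.uniform(4.0, 9.0)
            d2 = (yy2 - r) ** 2 + (xx2 - c) ** 2
            spot = np.maximum(spot, np.exp(-d2 / (2 * (rad / 1.6) ** 2)))
        P += params.spot_amp * spot
    return np.clip(P, 0.0, 0.95) * silhouette


def _random_projective(rng, center, canvas) -> np.ndarray:
    """A mild random projective map (fresh → hist), fixed about ``center``."""
    phi = np.deg2rad(rng.uniform(-8, 8))
    s = rng.uniform(0.95, 1.05)
    shear = rng.uniform(-0.04, 0.04)
    tx, ty = rng.uniform(-8, 8, size=2)
    c, si = np.cos(phi), np.sin(phi)
    A = np.array(
        [
            [s * c, -s * si + shear, tx],
            [s * si, s * c, ty],
            [0, 0, 1.0],
        ]
    )
    persp = rng.uniform(-4e-5, 4e-5, size=2)
    A[2, 0], A[2, 1] = persp
    T0 = np.array([[1, 0, -center[0]], [0, 1, -center[1]], [0, 0, 1.0]])
    T1 = np.array([[1, 0, center[0]], [0, 1, center[1]], [0, 0, 1.0]])
    return T1 @ A @ T0


def generate_specimen(
    params: SpecimenParams | None = None,
    seed: int = 0,
    specimen_id: str = "synthetic",
    species: str = "synthetic",
) -> SyntheticSpecimen:
    """Render one fully ground-truthed specimen (deterministic in ``seed``)."""
    params = params or SpecimenParams()
    rng = np.random.default_rng(seed)
    geom = _build_geometry(params)
    h, w = geom["canvas"]

    # fresh image ----------------------------------------------------------
    rr, cc = draw.polygon(
        geom["contour"][:, 1], geom["contour"][:, 0], shape=(h, w)
    )
    silhouette = np.zeros((h, w), dtype=bool)
    silhouette[rr, cc] = True
    vein_lines = _polyline_mask(
        (h, w), [geom["midvein"], geom["sidevein_left"], geom["sidevein_right"]]
    )
    vein_dist = ndi.distance_transform_edt(~vein_lines)
    P = _pigment_field(params, geom, silhouette, vein_dist, rng)

    img = np.full((h, w, 3), float(params.background))
    base = np.array(params.base_color, dtype=float)
    pigc = np.array(params.pigment_color, dtype=float)
    img[silhouette] = base[None, :] - P[silhouette, None] * pigc[None, :]
    img += rng.normal(0.0, params.noise_sd, size=img.shape)
    fresh_px = np.clip(np.round(img), 0, 255).astype(np.uint8)

    # histological twin ----------------------------------------------------
    M = _random_projective(rng, center=(w / 2, h / 2), canvas=(h, w))
    tf_hist = {
        name: apply_matrix(M, geom[name])
        for name in (
            "contour",
            "midvein",
            "sidevein_left",
            "sidevein_right",
            "tube_boundary_left",
            "tube_boundary_right",
        )
    }
    rim_hist = apply_matrix(M, geom["rim_endpoints"])
    rr, cc = draw.polygon(
        tf_hist["contour"][:, 1], tf_hist["contour"][:, 0], shape=(h, w)
    )
    sil_h = np.zeros((h, w), dtype=bool)
    sil_h[rr, cc] = True
    vein_h = _polyline_mask(
        (h, w),
        [tf_hist["midvein"], tf_hist["sidevein_left"], tf_hist["sidevein_right"]],
    )
    vd_h = ndi.distance_transform_edt(~vein_h)
    # fixed tissue absorbs a good part of the backlight; veins absorb more
    imgh = np.full((h, w, 3), float(params.hist_background))
    imgh[sil_h] = np.array([186.0, 181.0, 172.0])
    vein_shade = np.clip(3.5 - vd_h, 0.0, 1.0) * sil_h
    imgh -= 60.0 * vein_shade[:, :, None]
    imgh += rng.normal(0.0, params.noise_sd, size=imgh.shape)
    hist_px = np.clip(np.round(imgh), 0, 255).astype(np.uint8)

    # annotations and control points ---------------------------------------
    ann_fresh = AnatomicalAnnotation(
        specimen_id=specimen_id,
        frame_of_reference="fresh",
        lobe_contour=geom["contour"],
        midvein=geom["midvein"],
        sidevein_left=geom["sidevein_left"],
        sidevein_right=geom["sidevein_right"],
        tube_boundary_left=geom["tube_boundary_left"],
        tube_boundary_right=geom["tube_boundary_right"],
        rim_endpoints=geom["rim_endpoints"],
    )
    ann_hist = AnatomicalAnnotation(
        specimen_id=specimen_id,
        frame_of_reference="histological",
        lobe_contour=tf_hist["contour"],
        midvein=tf_hist["midvein"],
        sidevein_left=tf_hist["sidevein_left"],
        sidevein_right=tf_hist["sidevein_right"],
        tube_boundary_left=tf_hist["tube_boundary_left"],
        tube_boundary_right=tf_hist["tube_boundary_right"],
        rim_endpoints=rim_hist,
    )
    landmarks = np.vstack(
        [geom["serration_tips"], geom["rim_endpoints"], geom["tube_corners"]]
    )
    landmarks_h = apply_matrix(M, landmarks)
    cps = ControlPointSet(
        pairs=[
            (tuple(hpt), tuple(fpt))
            for hpt, fpt in zip(landmarks_h, landmarks)
        ]
    )

    return SyntheticSpecimen(
        specimen_id=specimen_id,
        species=species,
        fresh_image=PetalImage(fresh_px, "fresh", params.dpi, specimen_id),
        hist_image=PetalImage(hist_px, "histological", params.dpi, specimen_id),
        truth_annotation_fresh=ann_fresh,
        truth_annotation_hist=ann_hist,
        control_points=cps,
        truth_modes=params.truth_modes(),
        amplitudes={
            "gradient_amp": params.distal_amp - params.proximal_amp,
            "distal_amp": params.distal_amp,
            "proximal_amp": params.proximal_amp,
            "vein_amp": params.vein_amp,
            "spot_amp": params.spot_amp,
        },
        params=params,
        transform_hist_to_fresh=PlanarTransform(
            model="projective", matrix=np.linalg.inv(M), rms_residual=0.0
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class SpeciesConfig:
    name: str
    pollination_type: str = "to_be_determined"
    distal_amp: tuple = (0.0, 0.0)  # (mean, sd); sampled per specimen, >= 0
    proximal_amp: tuple = (0.0, 0.0)
    vein_amp: tuple = (0.0, 0.0)
    spot_amp: tuple = (0.0, 0.0)


@dataclass
class CohortConfig:
    species: list  # list[SpeciesConfig]
    specimens_per_species: int = 10
    master_seed: int = 0
    shape_jitter: float = 0.03  # fractional within-species shape variation
    noise_sd: float = 2.0

    def __post_init__(self):
        if not self.species:
            raise ConfigError("cohort needs at least one species")
        if self.specimens_per_species < 1:
            raise ConfigError("need at least one specimen per species")


@dataclass
class Cohort:
    specimens: list
    manifest: pd.DataFrame


def _sample_amp(rng, mean_sd) -> float:
    mean, sd = mean_sd
    if mean <= 0:
        return 0.0
    return float(np.clip(rng.normal(mean, sd), 0.02, 0.9))


def generate_cohort(config: CohortConfig, out_dir=None) -> Cohort:
    """Generate a reproducible multi-species cohort.

    All randomness flows from ``master_seed`` through per-species and
    per-specimen spawned seed sequences, so any specimen can be regenerated
    in isolation.  With ``out_dir`` set, images (PNG), annotation JSONs
    (histological frame, with control points) and a manifest CSV are
    written.
    """
    root = np.random.SeedSequence(config.master_seed)
    species_seqs = root.spawn(len(config.species))
    specimens = []
    rows = []
    for sp, seq in zip(config.species, species_seqs):
        sp_rng = np.random.default_rng(seq)
        # species-level base shape: the point of the method is alignment
        # across shapes, so shapes differ strongly between species
        base = dict(
            lobe_rx=sp_rng.uniform(72, 104),
            aspect=sp_rng.uniform(1.05, 1.45),
            serration_depth=sp_rng.uniform(2.0, 4.0),
            tube_len=sp_rng.uniform(100, 140),
            taper=sp_rng.uniform(0.65, 0.85),
        )
        child_seqs = seq.spawn(config.specimens_per_species)
        for i, cseq in enumerate(child_seqs):
            rng = np.random.default_rng(cseq)
            j = 1 + config.shape_jitter * rng.standard_normal(4)
            params = SpecimenParams(
                lobe_rx=base["lobe_rx"] * j[0],
                lobe_ry=base["lobe_rx"] * base["aspect"] * j[1],
                serration_depth=base["serration_depth"],
                tube_len=base["tube_len"] * j[2],
                taper=float(np.clip(base["taper"] * j[3], 0.55, 0.9)),
                distal_amp=_sample_amp(rng, sp.distal_amp),
                proximal_amp=_sample_amp(rng, sp.proximal_amp),
                vein_amp=_sample_amp(rng, sp.vein_amp),
                spot_amp=_sample_amp(rng, sp.spot_amp),
                noise_sd=config.noise_sd,
            )
            sid = f"{sp.name}-{i + 1:03d}"
            seed = int(rng.integers(0, 2**31 - 1))
            spec = generate_specimen(
                params, seed=seed, specimen_id=sid, species=sp.name
            )
            specimens.append(spec)
            rows.append(
                {
                    "specimen_id": sid,
                    "species": sp.name,
                    "pollination_type": sp.pollination_type,
                    "variegated": spec.truth_modes.variegated,
                    "gradient": spec.truth_modes.gradient,
                    **spec.amplitudes,
                    "seed": seed,
                }
            )
    manifest = pd.DataFrame(rows)
    cohort = Cohort(specimens=specimens, manifest=manifest)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for spec in cohort.specimens:
        d = out_dir / spec.specimen_id
        d.mkdir(exist_ok=True)
        save_image(spec.fresh_image, d / "fresh.png")
        save_image(spec.hist_image, d / "hist.png")
        write_annotation(
            spec.truth_annotation_hist,
            d / "annotation.json",
            control_points=spec.control_points,
        )
    cohort.manifest.to_csv(out_dir / "manifest.csv", index=False)


def four_mode_cohort(
    specimens_per_species: int = 10, master_seed: int = 0
) -> CohortConfig:
    """Four species, one pure strong-amplitude patterning mode each.

    Pollinator labels follow the qualitative association observed in
    Ligeriinae (hummingbird ↔ vascular/distal, bee ↔ random/proximal), which
    also makes the cohort usable for association statistics.
    """
    return CohortConfig(
        species=[
            SpeciesConfig("vascular-sp", "hummingbird", vein_amp=(0.55, 0.05)),
            SpeciesConfig("random-sp", "bee", spot_amp=(0.6, 0.05)),
            SpeciesConfig("distal-sp", "hummingbird", distal_amp=(0.6, 0.06)),
            SpeciesConfig("proximal-sp", "bee", proximal_amp=(0.6, 0.06)),
        ],
        specimens_per_species=specimens_per_species,
        master_seed=master_seed,
    )


def gradient_cohort(
    n_species: int = 6,
    specimens_per_species: int = 10,
    master_seed: int = 0,
) -> CohortConfig:
    """Cohort whose specimens carry independent distal and proximal gradients.

    Every species shares the same amplitude distributions (variation is
    per-specimen), so PC scores can be tested for recovery of the two
    generative amplitudes; species still differ in shape.
    """
    half = n_species // 2
    return CohortConfig(
        species=[
            SpeciesConfig(
                f"grad-sp{i + 1}",
                "hummingbird" if i < half else "bee",
                distal_amp=(0.4, 0.15),
                proximal_amp=(0.35, 0.13),
            )
            for i in range(n_species)
        ],
        specimens_per_species=specimens_per_species,
        master_seed=master_seed,
    )
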
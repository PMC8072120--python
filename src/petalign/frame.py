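"""Canonical homologous-ROI frame, 161-point correspondence, and warping.

The frame is a half-circle (lobe) of radius R sitting on a rectangle (distal
third of the tube) of height H, rasterized to a (R+H) x 2R image with the
lobe apex on the top row and the proximal cut on the bottom row.  161
labelled destination points are laid out on the frame — along the
semicircular arc, the midvein center line, two side-vein lines and the two
tube boundaries — and matched index-wise against 161 source points resampled
from the mapped anatomy of each specimen.  The petal image is then pulled
into the frame by a piecewise affine warp over the Delaunay triangulation of
the destination points, which interpolates every correspondence exactly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import Delaunay
from skimage import transform as sktf

from ._geometry import as_points, resample_polyline
from .errors import ConfigError, InputError
from .io import AnatomicalAnnotation, PetalImage
from .segmentation import split_lobe_contour

__all__ = [
    "TOTAL_POINTS",
    "FrameConfig",
    "ROIFrame",
    "PointCorrespondence",
    "HomologousROI",
    "build_frame",
    "resample_sources",
    "warp_to_roi",
    "roi_rms_difference",
]

TOTAL_POINTS = 161

GROUPS = (
    "contour_arc",
    "midvein",
    "sidevein_left",
    "sidevein_right",
    "tube_boundary_left",
    "tube_boundary_right",
)

#: Default allocation of the 161 points across anatomy groups.  Only the
#: total is canonical; the split is configurable and recorded in metadata.
DEFAULT_COUNTS = (61, 26, 22, 22, 15, 15)


@dataclass
class FrameConfig:
    radius_px: int = 128  # lobe half-circle radius R
    tube_height_px: int = 64  # rectangle height H
    group_counts: tuple = DEFAULT_COUNTS
    sidevein_frac: float = 0.5  # side-vein abscissa at x = R ± frac*R


@dataclass
class ROIFrame:
    radius_px: int
    tube_height_px: int
    destination_points: np.ndarray  # (161, 2)
    groups: np.ndarray  # (161,) str labels
    group_counts: dict

    @property
    def width(self) -> int:
        return 2 * self.radius_px

    @property
    def height(self) -> int:
        return self.radius_px + self.tube_height_px

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def points_of(self, group: str) -> np.ndarray:
        return self.destination_points[self.groups == group]

    def frame_mask(self) -> np.ndarray:
        """Boolean raster of the frame interior (semicircle ∪ rectangle)."""
        R, H = self.radius_px, self.tube_height_px
        yy, xx = np.mgrid[0 : R + H, 0 : 2 * R]
        lobe = (yy <= R) & ((xx - R) ** 2 + (R - yy) ** 2 <= R**2)
        tube = yy >= R
        return lobe | tube

    def vein_corridor(self, half_width: float = 6.0) -> np.ndarray:
        """Pixels within ``half_width`` of the three destination vein lines."""
        mask = np.zeros(self.shape, dtype=bool)
        yy, xx = np.mgrid[0 : self.height, 0 : self.width]
        for g in ("midvein", "sidevein_left", "sidevein_right"):
            pts = self.points_of(g)
            x0 = pts[0, 0]
            y_top = pts[:, 1].min()
            near = (np.abs(xx - x0) <= half_width) & (yy >= y_top - half_width)
            mask |= near
        return mask & self.frame_mask()


def build_frame(config: FrameConfig | None = None) -> ROIFrame:
    """Place the 161 destination points deterministically on the frame.

    Contour-arc points are uniform in angle over the semicircle (180°→0°,
    i.e. left rim → apex → right rim); the midvein runs down the vertical
    center line from the apex; each side-vein line drops from its
    intersection with the semicircle to the bottom edge; tube boundaries are
    the rectangle's vertical sides.
    """
    config = config or FrameConfig()
    R, H = config.radius_px, config.tube_height_px
    if R < 16 or H < 8:
        raise ConfigError("need radius_px >= 16 and tube_height_px >= 8")
    counts = tuple(int(c) for c in config.group_counts)
    if len(counts) != 6 or any(c < 2 for c in counts):
        raise ConfigError("group_counts must be six integers >= 2")
    if sum(counts) != TOTAL_POINTS:
        raise ConfigError(
            f"group_counts must sum to {TOTAL_POINTS}, got {sum(counts)}"
        )
    s = float(config.sidevein_frac)
    if not 0.0 < s < 1.0:
        raise ConfigError("sidevein_frac must be in (0, 1)")
    n_arc, n_mid, n_sl, n_sr, n_tl, n_tr = counts

    theta = np.linspace(np.pi, 0.0, n_arc)
    arc = np.column_stack([R + R * np.cos(theta), R - R * np.sin(theta)])

    mid = np.column_stack(
        [np.full(n_mid, float(R)), np.linspace(0.0, float(R + H), n_mid)]
    )

    y_side_top = R - R * np.sqrt(1.0 - s * s)
    side_l = np.column_stack(
        [np.full(n_sl, R - s * R), np.linspace(y_side_top, float(R + H), n_sl)]
    )
    side_r = np.column_stack(
        [np.full(n_sr, R + s * R), np.linspace(y_side_top, float(R + H), n_sr)]
    )

    tube_l = np.column_stack(
        [np.zeros(n_tl), np.linspace(float(R), float(R + H), n_tl)]
    )
    tube_r = np.column_stack(
        [np.full(n_tr, float(2 * R)), np.linspace(float(R), float(R + H), n_tr)]
    )

    dest = np.vstack([arc, mid, side_l, side_r, tube_l, tube_r])
    groups = np.concatenate(
        [np.full(c, g) for g, c in zip(GROUPS, counts)]
    )
    return ROIFrame(
        radius_px=R,
        tube_height_px=H,
        destination_points=dest,
        groups=groups,
        group_counts=dict(zip(GROUPS, counts)),
    )


@dataclass
class PointCorrespondence:
    source_points: np.ndarray  # (161, 2) in fresh-image coords
    destination_points: np.ndarray  # (161, 2) in frame coords
    groups: np.ndarray

    def __post_init__(self):
        self.source_points = as_points(self.source_points)
        self.destination_points = as_points(self.destination_points)
        if len(self.source_points) != len(self.destination_points):
            raise InputError("source/destination point counts differ")
        if len(self.groups) != len(self.source_points):
            raise InputError("group labels must align with points")


@dataclass
class HomologousROI:
    """A petal warped into the canonical frame."""

    pixels: np.ndarray  # (R+H) x 2R x 3 uint8, zero outside validity
    validity_mask: np.ndarray  # bool, inside-frame and inside-warp support
    specimen_id: str = ""

    @property
    def shape(self):
        return self.pixels.shape[:2]


def _orient_distal_first(poly: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Flip an open polyline so its first vertex is nearest ``anchor``."""
    d0 = np.linalg.norm(poly[0] - anchor)
    d1 = np.linalg.norm(poly[-1] - anchor)
    return poly[::-1].copy() if d1 < d0 else poly


def resample_sources(
    annotation: AnatomicalAnnotation, frame: ROIFrame
) -> PointCorrespondence:
    """Arrange the 161 source points on the mapped anatomy.

    The lobe arc (rim → apex → rim) is resampled by uniform arc length and
    anchored at the rim endpoints (the semicircle's diameter ends); each vein
    and boundary line is resampled between its distal and proximal ends.
    Stored vertex order of the veins is normalized distal-first, so reversed
    input polylines give identical sources.
    """
    if annotation.frame_of_reference != "fresh":
        raise InputError(
            "resample_sources expects an annotation in fresh coordinates "
            "(register and map it first)"
        )
    counts = frame.group_counts
    arc = split_lobe_contour(annotation.lobe_contour, annotation.rim_endpoints)
    src_arc = resample_polyline(arc, counts["contour_arc"])
    left_rim, right_rim = src_arc[0], src_arc[-1]
    apex = src_arc[(counts["contour_arc"] - 1) // 2]

    veins = {
        "midvein": annotation.midvein,
        "sidevein_left": annotation.sidevein_left,
        "sidevein_right": annotation.sidevein_right,
        "tube_boundary_left": annotation.tube_boundary_left,
        "tube_boundary_right": annotation.tube_boundary_right,
    }
    # annotators may have labelled left/right in the mirrored sense; fix
    # against the arc orientation (left = start of the normalized arc)
    dl = np.linalg.norm(
        _orient_distal_first(veins["sidevein_left"], apex)[0] - left_rim
    )
    dr = np.linalg.norm(
        _orient_distal_first(veins["sidevein_left"], apex)[0] - right_rim
    )
    if dr < dl:
        warnings.warn("left/right labels mirrored relative to contour; swapping")
        veins["sidevein_left"], veins["sidevein_right"] = (
            veins["sidevein_right"],
            veins["sidevein_left"],
        )
        veins["tube_boundary_left"], veins["tube_boundary_right"] = (
            veins["tube_boundary_right"],
            veins["tube_boundary_left"],
        )

    anchors = {
        "midvein": apex,
        "sidevein_left": apex,
        "sidevein_right": apex,
        "tube_boundary_left": left_rim,
        "tube_boundary_right": right_rim,
    }
    pieces = [src_arc]
    for name in GROUPS[1:]:
        poly = _orient_distal_first(as_points(veins[name]), anchors[name])
        pieces.append(resample_polyline(poly, counts[name]))
    source = np.vstack(pieces)
    return PointCorrespondence(
        source_points=source,
        destination_points=frame.destination_points,
        groups=frame.groups,
    )


def _dedupe(dest: np.ndarray, src: np.ndarray):
    """Merge coincident destination points, averaging their sources.

    The frame construction places a few destinations exactly on top of each
    other (midvein top = apex, side-vein tops on the arc, tube-boundary tops
    at the rims); their sources coincide for a consistent annotation.
    """
    key = np.round(dest, 6)
    _, idx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(idx)  # keep first-occurrence order
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(len(order))
    d_out = dest[np.sort(idx)]
    s_out = np.zeros_like(d_out)
    counts = np.zeros(len(d_out))
    for i, g in enumerate(inv):
        s_out[rank[g]] += src[i]
        counts[rank[g]] += 1
    return d_out, s_out / counts[:, None]


def warp_to_roi(
    image: PetalImage | np.ndarray,
    corr: PointCorrespondence,
    frame: ROIFrame,
    method: str = "piecewise",
) -> HomologousROI:
    """Warp the fresh petal image into the canonical frame.

    ``method="piecewise"`` (default) fits one affine map per Delaunay
    triangle of the destination points, interpolating all correspondences
    exactly; ``method="global_affine"`` is a least-squares single-affine
    fallback for comparison.  Inverse mapping with bilinear interpolation;
    pixels outside the validity mask are zero.
    """
    px = image.pixels if isinstance(image, PetalImage) else np.asarray(image)
    sid = image.specimen_id if isinstance(image, PetalImage) else ""
    h_img, w_img = px.shape[:2]
    src = corr.source_points
    if (
        src[:, 0].min() < -0.5
        or src[:, 1].min() < -0.5
        or src[:, 0].max() > w_img - 0.5
        or src[:, 1].max() > h_img - 0.5
    ):
        raise InputError("source points fall outside the image")
    dest, src_u = _dedupe(corr.destination_points, src)

    tri = Delaunay(dest)
    d_areas = _tri_areas(dest, tri.simplices)
    if np.any(d_areas < 1e-9):
        t = int(np.argmin(d_areas))
        raise InputError(
            f"destination triangle {t} {tri.simplices[t].tolist()} is degenerate"
        )

    yy, xx = np.mgrid[0 : frame.height, 0 : frame.width]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    simp = tri.find_simplex(grid)
    valid = simp >= 0

    if method == "piecewise":
        s_areas = _tri_areas(src_u, tri.simplices)
        bad_simplices = s_areas < 1e-6
        if bad_simplices.any():
            warnings.warn(
                f"{int(bad_simplices.sum())} source triangle(s) collapsed to "
                "zero area; excluded from the validity mask"
            )
            valid &= ~np.isin(simp, np.nonzero(bad_simplices)[0])
        # barycentric piecewise-affine map frame -> image: exact at vertices
        s = np.where(simp >= 0, simp, 0)
        T = tri.transform[s]  # (N, 3, 2): rows 0:2 the inverse matrix, row 2 the offset
        b = np.einsum("nij,nj->ni", T[:, :2, :], grid - T[:, 2, :])
        lam = np.column_stack([b, 1.0 - b.sum(axis=1)])  # (N, 3)
        verts = tri.simplices[s]  # (N, 3)
        mapped = np.einsum("nk,nkj->nj", lam, src_u[verts])
    elif method == "global_affine":
        tf = sktf.estimate_transform("affine", dest, src_u)
        mapped = tf(grid)
    else:
        raise InputError(f"unknown warp method {method!r}")

    inside = (
        (mapped[:, 0] >= -0.5)
        & (mapped[:, 0] <= w_img - 0.5)
        & (mapped[:, 1] >= -0.5)
        & (mapped[:, 1] <= h_img - 0.5)
    )
    valid &= inside
    valid = valid.reshape(frame.shape) & frame.frame_mask()

    # sampling coordinates are clipped into the image domain: pixels the
    # validity bound keeps (within half a pixel of the border) then sample
    # the border row/column instead of the constant pad
    samp_x = np.clip(mapped[:, 0], 0.0, w_img - 1.0)
    samp_y = np.clip(mapped[:, 1], 0.0, h_img - 1.0)
    out = np.stack(
        [
            ndi.map_coordinates(
                px[:, :, c].astype(float),
                [samp_y, samp_x],  # (row, col)
                order=1,
                mode="constant",
                cval=0.0,
            ).reshape(frame.shape)
            for c in range(3)
        ],
        axis=2,
    )
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    out[~valid] = 0
    return HomologousROI(pixels=out, validity_mask=valid, specimen_id=sid)


def correspondence_residuals(corr: PointCorrespondence) -> np.ndarray:
    """Per-point error (px) of the piecewise-affine map at the landmarks.

    Builds the same deduplicated Delaunay/barycentric map the warp uses and
    evaluates it at every destination point; the piecewise-affine property
    makes these residuals zero up to floating point (coincident destinations
    are checked against their averaged source).
    """
    dest, src_u = _dedupe(corr.destination_points, corr.source_points)
    tri = Delaunay(dest)
    simp = tri.find_simplex(dest, tol=1e-9)
    if np.any(simp < 0):
        raise InputError("a destination point falls outside its own hull")
    T = tri.transform[simp]
    b = np.einsum("nij,nj->ni", T[:, :2, :], dest - T[:, 2, :])
    lam = np.column_stack([b, 1.0 - b.sum(axis=1)])
    mapped = np.einsum("nk,nkj->nj", lam, src_u[tri.simplices[simp]])
    return np.linalg.norm(mapped - src_u, axis=1)


def _tri_areas(pts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a, b, c = pts[simplices[:, 0]], pts[simplices[:, 1]], pts[simplices[:, 2]]
    return 0.5 * np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )


def roi_rms_difference(
    a: HomologousROI, b: HomologousROI, erode: int = 2
) -> float:
    """Normalized RMS grayscale difference over the common validity mask.

    The mask intersection is eroded by ``erode`` px to discount the
    contour-adjacent ring where rasterization aliasing of serrated edges
    dominates.  Gray values are on [0, 1].
    """
    from scipy import ndimage as ndi

    from ._geometry import luma

    mask = a.validity_mask & b.validity_mask
    if erode > 0:
        mask = ndi.binary_erosion(mask, iterations=erode)
    if not mask.any():
        raise InputError("validity masks do not overlap")
    ga = luma(a.pixels)[mask] / 255.0
    gb = luma(b.pixels)[mask] / 255.0
    return float(np.sqrt(np.mean((ga - gb) ** 2)))


def unaligned_rms_difference(
    image_a,
    image_b,
    shape: tuple[int, int] = (192, 256),
    petal_area: float = 20_000.0,
    threshold: float = 0.2,
) -> float:
    """Negative control: gray RMS without any landmark alignment.

    Petals are only centered on their centroid and isotropically scaled to a
    common area — the naive ROI normalization the homologous warp replaces.
    The RMS is taken over the union of the two petal masks, so silhouette
    mismatch between shapes contributes fully.  Gray values on [0, 1].
    """
    from ._geometry import luma as _luma

    def _normalize(img):
        px = img.pixels if isinstance(img, PetalImage) else np.asarray(img)
        g = _luma(px) / 255.0
        mask = g > threshold
        if not mask.any():
            raise InputError("no foreground above threshold")
        scale = np.sqrt(petal_area / mask.sum())
        cy, cx = ndi.center_of_mass(mask)
        oy, ox = np.mgrid[0 : shape[0], 0 : shape[1]]
        sy = (oy - shape[0] / 2) / scale + cy
        sx = (ox - shape[1] / 2) / scale + cx
        gg = ndi.map_coordinates(g, [sy, sx], order=1, cval=0.0)
        mm = ndi.map_coordinates(mask.astype(float), [sy, sx], order=1, cval=0.0) > 0.5
        return gg, mm

    ga, ma = _normalize(image_a)
    gb, mb = _normalize(image_b)
    union = ma | mb
    if not union.any():
        raise InputError("petals do not overlap the comparison raster")
    return float(np.sqrt(np.mean((ga[union] - gb[union]) ** 2)))
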
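"""Petal/background separation and contour extraction.

Both acquisition set-ups produce a petal on a (nearly) uniform field — a
dark cloth for the fresh scan, a bright backlight for the histological scan —
so a two-component Gaussian mixture in RGB separates petal from background.
The foreground component is picked by mean luminance (brighter for fresh,
darker for backlit scans).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from ._geometry import (
    as_points,
    luma,
    point_polyline_distance,
    resample_polyline,
    split_closed_polyline,
)
from .errors import InputError, SegmentationError
from .io import PetalImage

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "PetalSegmenter",
    "segment_petal",
    "split_lobe_contour",
]


@dataclass
class SegmentationConfig:
    n_components: int = 2
    close_radius: int = 3  # px; bridges scan noise, preserves serrations
    contour_points: int = 400
    max_pixels: int = 50_000  # GMM is fitted on a subsample this big
    seed: int = 0
    foreground: str = "bright"  # "bright" (fresh) | "dark" (backlit)
    min_mean_separation: float = 2.0  # gray levels between component lumas


@dataclass
class SegmentationResult:
    foreground_mask: np.ndarray  # H x W bool
    contour: np.ndarray  # closed polyline, (x, y)
    component_means: np.ndarray  # n_components x 3 RGB means
    config_used: SegmentationConfig
    clipped: bool = False  # petal touches all four image borders


class PetalSegmenter(BaseEstimator):
    """Gaussian-mixture petal segmenter with sklearn estimator semantics.

    ``fit`` learns the color mixture from a pixel subsample of one image;
    ``predict`` labels pixels of an image as foreground.  ``segment`` runs
    the full fit → label → morphology → contour pipeline.
    """

    def __init__(
        self,
        n_components: int = 2,
        close_radius: int = 3,
        contour_points: int = 400,
        max_pixels: int = 50_000,
        seed: int = 0,
        foreground: str = "bright",
        min_mean_separation: float = 2.0,
    ):
        self.n_components = n_components
        self.close_radius = close_radius
        self.contour_points = contour_points
        self.max_pixels = max_pixels
        self.seed = seed
        self.foreground = foreground
        self.min_mean_separation = min_mean_separation

    # -- estimator API ------------------------------------------------------

    def fit(self, image, y=None):
        px = _pixels(image).reshape(-1, 3).astype(float)
        if self.n_components < 2:
            raise InputError("need n_components >= 2")
        if self.foreground not in ("bright", "dark"):
            raise InputError("foreground must be 'bright' or 'dark'")
        rng = np.random.default_rng(self.seed)
        if len(px) > self.max_pixels:
            px = px[rng.choice(len(px), self.max_pixels, replace=False)]
        if float(px.std(axis=0).max()) < 1e-6:
            raise SegmentationError("no contrast: image is a single color")
        gmm = GaussianMixture(
            n_components=self.n_components,
            covariance_type="full",
            random_state=self.seed,
            n_init=1,
        )
        gmm.fit(px)
        lumas = luma(gmm.means_)
        if np.ptp(lumas) < self.min_mean_separation:
            raise SegmentationError(
                "no contrast: mixture components are indistinguishable"
            )
        self.gmm_ = gmm
        self.component_lumas_ = lumas
        self.foreground_label_ = (
            int(np.argmax(lumas))
            if self.foreground == "bright"
            else int(np.argmin(lumas))
        )
        return self

    def predict(self, image) -> np.ndarray:
        """Raw (pre-morphology) boolean foreground mask."""
        px = _pixels(image)
        labels = self.gmm_.predict(px.reshape(-1, 3).astype(float))
        return (labels == self.foreground_label_).reshape(px.shape[:2])

    # -- full pipeline ------------------------------------------------------

    def segment(self, image) -> SegmentationResult:
        self.fit(image)
        raw = self.predict(image)
        mask = postprocess_mask(raw, self.close_radius)
        if not mask.any():
            raise SegmentationError("no foreground pixels after post-processing")
        clipped = bool(
            mask[0].any() and mask[-1].any()
            and mask[:, 0].any() and mask[:, -1].any()
        )
        if clipped:
            warnings.warn(
                "foreground touches all four image borders; petal likely clipped",
                stacklevel=2,
            )
        contour = trace_contour(mask, self.contour_points)
        return SegmentationResult(
            foreground_mask=mask,
            contour=contour,
            component_means=self.gmm_.means_.copy(),
            config_used=SegmentationConfig(**self.get_params()),
            clipped=clipped,
        )


def _pixels(image) -> np.ndarray:
    if isinstance(image, PetalImage):
        return image.pixels
    a = np.asarray(image)
    if a.ndim != 3 or a.shape[2] != 3:
        raise InputError("expected an H x W x 3 image")
    return a


def postprocess_mask(mask: np.ndarray, close_radius: int = 3) -> np.ndarray:
    """Morphological closing, hole filling, largest-component retention.

    Idempotent: applying it to its own output returns the same mask.
    """
    m = np.asarray(mask, dtype=bool)
    if close_radius > 0:
        m = morphology.closing(m, morphology.disk(close_radius)).astype(bool)
    m = ndi.binary_fill_holes(m)
    labels, n = ndi.label(m)
    if n > 1:
        sizes = ndi.sum_labels(m, labels, index=np.arange(1, n + 1))
        m = labels == (1 + int(np.argmax(sizes)))
    return m


def trace_contour(mask: np.ndarray, n_points: int = 400) -> np.ndarray:
    """Closed (x, y) polyline around the mask, uniform in arc length.

    Deterministic: the contour is oriented with positive shoelace area in
    image coordinates and starts at the vertex nearest the top-left corner.
    """
    padded = np.pad(np.asarray(mask, float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise SegmentationError("empty mask: no contour to trace")
    rc = max(contours, key=len)
    xy = np.column_stack([rc[:, 1], rc[:, 0]]) - 1.0  # (row, col) -> (x, y)
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    from ._geometry import signed_area

    if signed_area(xy) < 0:
        xy = xy[::-1]
    start = int(np.argmin(np.hypot(xy[:, 0], xy[:, 1])))
    xy = np.roll(xy, -start, axis=0)
    return resample_polyline(xy, n_points, closed=True)


def segment_petal(
    image, config: SegmentationConfig | None = None
) -> SegmentationResult:
    """Separate petal from field and trace its contour (functional surface)."""
    config = config or SegmentationConfig()
    seg = PetalSegmenter(
        n_components=config.n_components,
        close_radius=config.close_radius,
        contour_points=config.contour_points,
        max_pixels=config.max_pixels,
        seed=config.seed,
        foreground=config.foreground,
        min_mean_separation=config.min_mean_separation,
    )
    return seg.segment(image)


def split_lobe_contour(contour, rim_endpoints) -> np.ndarray:
    """Cut the closed petal outline at the rim chord; return the lobe arc.

    The returned open arc is the contour piece on the distal side of the
    lobe–tube rim (the arc whose points lie farther from the proximal image
    edge on average, i.e. smaller mean y), ordered left-rim → apex →
    right-rim regardless of the order the rim endpoints were given in.
    """
    c = as_points(contour)
    rim = as_points(rim_endpoints)
    if np.allclose(rim[0], rim[1]):
        raise InputError("rim endpoints coincide")
    for i, p in enumerate(rim):
        d = point_polyline_distance(p, c, closed=True)
        if d > 2.0 + 1e-9:
            raise InputError(
                f"rim endpoint {i} lies {d:.2f} px from the contour"
            )
    arc_a, arc_b = split_closed_polyline(c, rim[0], rim[1])
    # distal side: farther from the proximal (bottom) image edge
    arc = arc_a if arc_a[:, 1].mean() < arc_b[:, 1].mean() else arc_b
    return _normalize_arc_orientation(arc)


def _normalize_arc_orientation(arc: np.ndarray) -> np.ndarray:
    """Order the lobe arc so its start is the left rim endpoint.

    Convention: rotating the chord direction (start→end) by +90° in image
    coordinates must point away from the arc (toward the proximal side).
    """
    chord = arc[-1] - arc[0]
    normal = np.array([-chord[1], chord[0]])  # +90° rotation, y down
    mid = 0.5 * (arc[0] + arc[-1])
    toward_arc = arc.mean(axis=0) - mid
    if float(normal @ toward_arc) > 0:
        return arc[::-1].copy()
    return arc
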
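"""Qualitative patterning-mode calling on homologous ROIs.

Four modes describe where nectar-guide pigment sits in the canonical frame:
the *variegated* family (pigment initiating at the petal center) splits into
``vascular`` (pigment overlays the vein lines) and ``random`` (pigment
ignores them); the *gradient* family (pigment initiating at a petal end)
splits into ``distal`` (from the lobe tip) and ``proximal`` (from the tube).
Within each family the labels are mutually exclusive by construction, and
``none`` records the absence of that family.

The geometric operationalization below (score field, Otsu threshold,
border-anchored components, corridor enrichment) is this package's explicit
translation of the visual/developmental mode definitions; every threshold
lives in :class:`ModeConfig` so sensitivity analyses are scriptable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator

from ._geometry import luma
from .errors import InputError
from .frame import HomologousROI, ROIFrame

__all__ = [
    "ModeConfig",
    "ModeCall",
    "pigment_score",
    "pigment_mask",
    "classify_specimen",
    "aggregate_species",
    "ModeClassifier",
]


@dataclass
class ModeConfig:
    min_contrast: float = 0.08  # gray units; floor under the Otsu threshold
    min_fraction: float = 0.005  # pigment below this areal fraction = none
    delta_min: float = 0.04  # gray units; |profile delta| to call a gradient
    corridor_px: float = 6.0  # vein corridor half-width on the frame
    enrich_min: float = 1.5  # corridor enrichment ratio for "vascular"
    gradient_min_area: int = 50  # px; minimum area of a gradient component
    anchor_frac: float = 0.2  # border contact fraction to count as anchored
    dark_guides: bool = True  # guides darker than ground color; False inverts


@dataclass
class ModeCall:
    variegated: str  # "vascular" | "random" | "none"
    gradient: str  # "distal" | "proximal" | "none"
    vein_enrichment: float = 0.0
    gradient_delta: float = 0.0
    pigment_fraction: float = 0.0

    def __post_init__(self):
        if self.variegated not in ("vascular", "random", "none"):
            raise InputError(f"bad variegated label {self.variegated!r}")
        if self.gradient not in ("distal", "proximal", "none"):
            raise InputError(f"bad gradient label {self.gradient!r}")


def pigment_score(
    roi: HomologousROI, config: ModeConfig | None = None
) -> np.ndarray:
    """Signed pigment contrast field: ground-color gray minus pixel gray.

    The petal ground color is the median gray over valid pixels, so the
    score is positive where the petal is darker than its ground color and
    the field is invariant under global brightness shifts.  Zero outside the
    validity mask.
    """
    config = config or ModeConfig()
    if not roi.validity_mask.any():
        raise InputError("ROI has an empty validity mask")
    gray = luma(roi.pixels) / 255.0
    ground = float(np.median(gray[roi.validity_mask]))
    score = np.where(roi.validity_mask, ground - gray, 0.0)
    return score if config.dark_guides else -score


def pigment_mask(
    field: np.ndarray,
    config: ModeConfig | None = None,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Threshold the score field into a pigment mask.

    The threshold is the larger of the Otsu threshold of the positive scores
    and ``min_contrast``.  ``has_pigment`` is False when the masked fraction
    falls below ``min_fraction`` or no score exceeds ``min_contrast``.
    """
    config = config or ModeConfig()
    f = np.asarray(field, dtype=float)
    if not np.isfinite(f).all():
        raise InputError("score field contains non-finite values")
    valid = np.ones(f.shape, bool) if valid is None else np.asarray(valid, bool)
    pos = f[valid & (f > 0)]
    if pos.size == 0 or float(f[valid].max()) <= config.min_contrast:
        return np.zeros(f.shape, dtype=bool), False
    if np.ptp(pos) < 1e-12:  # single positive level: Otsu is the midpoint
        thr = float(pos[0]) / 2.0
    else:
        thr = float(threshold_otsu(pos))
    thr = max(thr, config.min_contrast)
    mask = valid & (f > thr)
    frac = mask.sum() / max(valid.sum(), 1)
    return mask, bool(frac >= config.min_fraction)


def _border_bands(frame: ROIFrame, width: int = 3):
    """Pixel bands along the distal semicircular arc and the proximal edge."""
    R, H = frame.radius_px, frame.tube_height_px
    fm = frame.frame_mask()
    yy, xx = np.mgrid[0 : frame.height, 0 : frame.width]
    r = np.sqrt((xx - R) ** 2 + (R - yy) ** 2)
    distal = fm & (yy <= R) & (r >= R - width)
    proximal = fm & (yy >= R + H - width)
    return distal, proximal


def classify_specimen(
    roi: HomologousROI,
    frame: ROIFrame,
    config: ModeConfig | None = None,
) -> ModeCall:
    """Call the variegated and gradient modes for one specimen.

    Pigment components anchored broadly on the distal arc or the proximal
    edge are gradient evidence; the remaining (interior) components are
    variegated evidence.  The gradient label comes from the longitudinal
    profile of the score field restricted to gradient evidence (apex third
    vs proximal third); the variegated label from the vein-corridor
    enrichment of the interior pigment.
    """
    config = config or ModeConfig()
    if roi.shape != frame.shape:
        raise InputError("ROI raster does not match the frame")
    field = pigment_score(roi, config)
    mask, has_pigment = pigment_mask(field, config, valid=roi.validity_mask)
    frac = float(mask.sum() / max(roi.validity_mask.sum(), 1))
    if not has_pigment:
        return ModeCall("none", "none", 0.0, 0.0, frac)

    distal_band, proximal_band = _border_bands(frame)
    labels, n = ndi.label(mask)
    gradient_evidence = np.zeros(mask.shape, bool)
    interior = np.zeros(mask.shape, bool)
    for i in range(1, n + 1):
        comp = labels == i
        anchored = False
        if comp.sum() >= config.gradient_min_area:
            for band in (distal_band, proximal_band):
                # contact measured along the border: fraction of the band's
                # columns (distal) / width covered by this component
                contact = comp & band
                band_cols = np.unique(np.nonzero(band)[1])
                cols = np.unique(np.nonzero(contact)[1])
                if len(cols) >= config.anchor_frac * len(band_cols):
                    anchored = True
        if anchored:
            gradient_evidence |= comp
        else:
            interior |= comp

    # gradient family: longitudinal profile over anchored evidence
    gradient_delta = 0.0
    gradient = "none"
    if gradient_evidence.any():
        h = frame.height
        t = np.arange(h) / (h - 1)
        evid = np.where(gradient_evidence, field, 0.0)
        denom = roi.validity_mask.sum(axis=1).clip(min=1)
        profile = evid.sum(axis=1) / denom
        top = profile[t < 1 / 3].mean()
        bottom = profile[t > 2 / 3].mean()
        gradient_delta = float(top - bottom)
        if gradient_delta > config.delta_min:
            gradient = "distal"
        elif gradient_delta < -config.delta_min:
            gradient = "proximal"

    # variegated family: corridor enrichment of interior pigment
    variegated = "none"
    enrichment = 0.0
    if interior.any() and interior.sum() / max(roi.validity_mask.sum(), 1) >= config.min_fraction:
        corridor = frame.vein_corridor(config.corridor_px) & roi.validity_mask
        corridor_area_frac = corridor.sum() / max(roi.validity_mask.sum(), 1)
        pigment_in = (interior & corridor).sum() / max(interior.sum(), 1)
        enrichment = float(pigment_in / max(corridor_area_frac, 1e-12))
        variegated = "vascular" if enrichment >= config.enrich_min else "random"

    return ModeCall(variegated, gradient, enrichment, gradient_delta, frac)


def aggregate_species(calls: list[ModeCall]) -> ModeCall:
    """Majority-vote aggregation of specimen calls to one species label pair.

    Per family the majority among non-none labels wins; ``none`` wins only
    if at least half of the specimens are none.  Ties break toward the label
    with the larger mean supporting score (distance of the enrichment from
    its threshold, |gradient delta|).
    """
    if not calls:
        raise InputError("cannot aggregate an empty list of calls")
    cfg = ModeConfig()

    def vote(labels, supports):
        n = len(labels)
        non_none = [(l, s) for l, s in zip(labels, supports) if l != "none"]
        if n - len(non_none) >= n / 2 or not non_none:
            return "none"
        cand = {}
        for l, s in non_none:
            cand.setdefault(l, []).append(s)
        best = max(
            cand.items(), key=lambda kv: (len(kv[1]), float(np.mean(kv[1])))
        )
        return best[0]

    variegated = vote(
        [c.variegated for c in calls],
        [abs(c.vein_enrichment - cfg.enrich_min) for c in calls],
    )
    gradient = vote(
        [c.gradient for c in calls],
        [abs(c.gradient_delta) for c in calls],
    )
    return ModeCall(
        variegated,
        gradient,
        float(np.mean([c.vein_enrichment for c in calls])),
        float(np.mean([c.gradient_delta for c in calls])),
        float(np.mean([c.pigment_fraction for c in calls])),
    )


class ModeClassifier(BaseEstimator):
    """sklearn-style wrapper: ``predict`` maps ROIs to :class:`ModeCall`s."""

    def __init__(
        self,
        min_contrast: float = 0.08,
        min_fraction: float = 0.005,
        delta_min: float = 0.04,
        corridor_px: float = 6.0,
        enrich_min: float = 1.5,
        gradient_min_area: int = 50,
        anchor_frac: float = 0.2,
        dark_guides: bool = True,
    ):
        self.min_contrast = min_contrast
        self.min_fraction = min_fraction
        self.delta_min = delta_min
        self.corridor_px = corridor_px
        self.enrich_min = enrich_min
        self.gradient_min_area = gradient_min_area
        self.anchor_frac = anchor_frac
        self.dark_guides = dark_guides

    def _config(self) -> ModeConfig:
        return ModeConfig(**self.get_params())

    def fit(self, X=None, y=None):
        return self  # stateless; present for pipeline compatibility

    def predict(self, rois, frame: ROIFrame) -> list[ModeCall]:
        cfg = self._config()
        return [classify_specimen(r, frame, cfg) for r in rois]
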
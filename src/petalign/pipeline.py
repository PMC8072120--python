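"""End-to-end orchestration: raw scans + annotation → homologous ROI.

The per-specimen chain mirrors the four extraction steps: (1) anatomy on the
histological image (contour from GMM segmentation, veins from the manual
annotation), (2) control-point registration of the two scans, (3) mapping
the anatomy into fresh coordinates, (4) the 161-point piecewise-affine warp
into the canonical frame.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from ._geometry import project_point_to_polyline
from .frame import (
    HomologousROI,
    ROIFrame,
    build_frame,
    resample_sources,
    warp_to_roi,
)
from .io import AnatomicalAnnotation, ControlPointSet, PetalImage
from .registration import estimate_transform, map_annotation
from .segmentation import SegmentationConfig, segment_petal

__all__ = ["process_specimen", "process_cohort"]


def process_specimen(
    fresh_image: PetalImage,
    annotation_hist: AnatomicalAnnotation,
    control_points: ControlPointSet,
    frame: ROIFrame | None = None,
    hist_image: PetalImage | None = None,
    seg_config: SegmentationConfig | None = None,
    transform_model: str = "projective",
    warp_method: str = "piecewise",
) -> HomologousROI:
    """Extract the homologous ROI of one specimen.

    When ``hist_image`` is given, the lobe contour is re-derived from its
    GMM segmentation (backlit scan: foreground is the darker component) and
    the annotation's rim endpoints are re-projected onto the segmented
    contour; the manually tracked veins are kept as annotated.
    """
    frame = frame or build_frame()
    ann = annotation_hist
    if hist_image is not None:
        cfg = seg_config or SegmentationConfig(foreground="dark")
        seg = segment_petal(hist_image, cfg)
        rims = np.vstack(
            [
                project_point_to_polyline(p, seg.contour, closed=True)[1]
                for p in ann.rim_endpoints
            ]
        )
        ann = replace(ann, lobe_contour=seg.contour, rim_endpoints=rims)
    t = estimate_transform(control_points, model=transform_model)
    ann_fresh = map_annotation(ann, t)
    corr = resample_sources(ann_fresh, frame)
    return warp_to_roi(fresh_image, corr, frame, method=warp_method)


def process_cohort(
    cohort,
    frame: ROIFrame | None = None,
    use_hist_segmentation: bool = True,
    **kwargs,
):
    """Run :func:`process_specimen` over a synthetic cohort.

    Returns ``(rois, frame)`` with ROIs in manifest order.
    """
    frame = frame or build_frame()
    rois = []
    for spec in cohort.specimens:
        rois.append(
            process_specimen(
                spec.fresh_image,
                spec.truth_annotation_hist,
                spec.control_points,
                frame=frame,
                hist_image=spec.hist_image if use_hist_segmentation else None,
                **kwargs,
            )
        )
    return rois, frame
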
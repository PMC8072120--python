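"""Control-point registration between histological and fresh scans.

Both scans are flatbed images of the same physical petal, so a planar
transform relates them; a projective model (the default) subsumes the
placement, scale and shear differences the two passes can introduce.
Estimation is least squares over paired landmarks (Hartley-normalized DLT
for the projective model, as implemented in scikit-image).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import transform as sktf

from ._geometry import as_points
from .errors import EstimationError, InputError
from .io import AnatomicalAnnotation, ControlPointSet

__all__ = [
    "PlanarTransform",
    "estimate_transform",
    "map_annotation",
    "apply_matrix",
]

_MIN_PAIRS = {"similarity": 2, "affine": 3, "projective": 4}


@dataclass
class PlanarTransform:
    model: str  # "similarity" | "affine" | "projective"
    matrix: np.ndarray  # 3x3 homogeneous, maps hist -> fresh
    rms_residual: float = float("nan")

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise InputError("matrix must be 3x3 homogeneous")
        if not np.isfinite(m).all() or abs(np.linalg.det(m)) < 1e-12:
            raise EstimationError("transform matrix is singular")
        self.matrix = m

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_matrix(self.matrix, points)

    def inverse(self) -> "PlanarTransform":
        return replace(self, matrix=np.linalg.inv(self.matrix))

    def compose(self, other: "PlanarTransform") -> "PlanarTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return PlanarTransform(
            model="projective", matrix=self.matrix @ other.matrix
        )


def apply_matrix(matrix: np.ndarray, points) -> np.ndarray:
    p = as_points(points)
    h = np.column_stack([p, np.ones(len(p))]) @ np.asarray(matrix).T
    w = h[:, 2:3]
    if np.any(np.abs(w) < 1e-12):
        raise EstimationError("point maps to infinity under transform")
    return h[:, :2] / w


def _collinear(pts: np.ndarray) -> bool:
    c = pts - pts.mean(axis=0)
    return np.linalg.matrix_rank(c, tol=1e-8) < 2


def estimate_transform(
    cps: ControlPointSet | tuple[np.ndarray, np.ndarray],
    model: str = "projective",
) -> PlanarTransform:
    """Least-squares planar transform mapping histological → fresh points.

    With the minimum pair count the fit interpolates exactly.  Raises
    :class:`EstimationError` on too few or collinear source points.
    """
    if model not in _MIN_PAIRS:
        raise InputError(f"unknown model {model!r}")
    if isinstance(cps, ControlPointSet):
        src, dst = cps.hist, cps.fresh
    else:
        src, dst = as_points(cps[0]), as_points(cps[1])
    need = _MIN_PAIRS[model]
    if len(src) < need:
        raise EstimationError(
            f"{model} transform needs at least {need} point pairs, got {len(src)}"
        )
    if model in ("affine", "projective") and _collinear(src):
        raise EstimationError(
            f"{model} transform needs non-collinear source points"
        )
    tf = sktf.estimate_transform(model, src, dst)
    matrix = np.asarray(tf.params, dtype=float)
    if not np.isfinite(matrix).all():
        raise EstimationError("degenerate point configuration")
    resid = apply_matrix(matrix, src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return PlanarTransform(model=model, matrix=matrix, rms_residual=rms)


def map_annotation(
    annotation: AnatomicalAnnotation, t: PlanarTransform
) -> AnatomicalAnnotation:
    """Transport an annotation from histological into fresh coordinates.

    Every polyline vertex and rim endpoint is transformed; vertex counts and
    ordering are preserved; ``frame_of_reference`` becomes ``"fresh"``.
    """
    if annotation.frame_of_reference != "histological":
        raise InputError(
            "map_annotation expects an annotation in histological coordinates"
        )
    kwargs = {
        name: t(poly) for name, poly in annotation.polylines().items()
    }
    return AnatomicalAnnotation(
        specimen_id=annotation.specimen_id,
        frame_of_reference="fresh",
        rim_endpoints=t(annotation.rim_endpoints),
        **kwargs,
    )
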
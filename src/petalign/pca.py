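"""Pixel-level PCA of homologous ROIs ("eigen-petal" analysis).

Each warped ROI is converted to grayscale, restricted to the pixels valid in
every specimen, and flattened row-major into a vector; the specimen × pixel
matrix is decomposed by mean-centered SVD.  Per-specimen component scores
are the quantitative pattern traits; inverse reconstruction from the mean
plus a scaled loading ("virtual ROI") visualizes what a component encodes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._geometry import luma
from .errors import InputError
from .frame import HomologousROI

__all__ = [
    "roi_to_gray_vector",
    "common_validity_mask",
    "PatternPCA",
    "fit_pca",
    "virtual_roi",
    "deviation_map",
]


def common_validity_mask(rois: list[HomologousROI]) -> np.ndarray:
    """Intersection of the validity masks of a ROI stack."""
    if not rois:
        raise InputError("empty ROI list")
    mask = rois[0].validity_mask.copy()
    for r in rois[1:]:
        if r.validity_mask.shape != mask.shape:
            raise InputError("ROI rasters have inconsistent shapes")
        mask &= r.validity_mask
    return mask


def roi_to_gray_vector(
    roi: HomologousROI, common_mask: np.ndarray
) -> np.ndarray:
    """Flatten a ROI to a gray vector on [0, 1] over the common mask.

    Gray is BT.601 luma; pixels are taken row-major.  The mask must be a
    subset of the ROI's own validity mask.
    """
    mask = np.asarray(common_mask, dtype=bool)
    if mask.shape != roi.shape:
        raise InputError(
            f"mask shape {mask.shape} does not match ROI raster {roi.shape}"
        )
    if np.any(mask & ~roi.validity_mask):
        raise InputError("common mask includes pixels invalid in this ROI")
    return luma(roi.pixels)[mask] / 255.0


class PatternPCA(BaseEstimator, TransformerMixin):
    """Mean-centered SVD of a specimen × pixel gray matrix.

    Components are ordered by explained variance and carry a deterministic
    sign convention: each loading is oriented so that its element of largest
    magnitude is positive (component signs are otherwise arbitrary, and all
    downstream statistics are sign-invariant).

    Attributes (after ``fit``)
    --------------------------
    mean_ : (P,) pixel-wise mean gray vector
    components_ : (K, P) orthonormal loadings
    explained_variance_ratio_ : (K,) non-increasing fractions
    scores_ : (N, K) raw per-specimen scores (mean specimen scores to 0)
    standardized_scores_ : (N, K) scores scaled to sample SD 1
    score_sd_ : (K,) sample SD of the raw scores (σ_k)
    common_mask_ : frame mask the vectors were taken over (set by
        :func:`fit_pca` / ``fit_rois``), used to fold vectors back to rasters
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InputError("expected a 2-D specimen x pixel matrix")
        n, p = X.shape
        if n < 3:
            raise InputError("need at least 3 specimens for PCA")
        if p < 2:
            raise InputError("need at least 2 pixels for PCA")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        # mean-centering leaves rank <= n-1; keep that many components so
        # zero-variance components stay queryable (with ratio 0)
        k = min(n - 1, p)
        if self.n_components is not None:
            k = min(k, int(self.n_components))
        u, s, vt = u[:, :k], s[:k], vt[:k]
        # numerically-zero singular values are exactly zero variance
        tol = max(n, p) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
        s = np.where(s > max(tol, 1e-12), s, 0.0)
        # sign convention: largest-|.| element of each loading positive
        flip = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
        flip[flip == 0] = 1.0
        vt = vt * flip[:, None]
        u = u * flip[None, :]
        self.components_ = vt
        self.singular_values_ = s
        total_var = float(np.sum(Xc**2))
        self.explained_variance_ratio_ = (
            s**2 / total_var if total_var > 0 else np.zeros_like(s)
        )
        self.explained_variance_ = s**2 / max(n - 1, 1)
        self.scores_ = u * s
        sd = self.scores_.std(axis=0, ddof=1)
        self.score_sd_ = sd
        with np.errstate(divide="ignore", invalid="ignore"):
            self.standardized_scores_ = np.where(
                sd > 0, self.scores_ / sd, 0.0
            )
        self.n_samples_ = n
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def inverse_transform(self, scores):
        check_is_fitted(self, "components_")
        return self.mean_ + np.asarray(scores, dtype=float) @ self.components_

    @property
    def n_components_(self) -> int:
        return len(self.singular_values_)

    # -- ROI conveniences ---------------------------------------------------

    def fit_rois(self, rois: list[HomologousROI]):
        mask = common_validity_mask(rois)
        X = np.stack([roi_to_gray_vector(r, mask) for r in rois])
        self.fit(X)
        self.common_mask_ = mask
        return self

    def fold(self, vector: np.ndarray) -> np.ndarray:
        """Place a pixel vector back into the frame raster (background 0)."""
        check_is_fitted(self, "common_mask_")
        out = np.zeros(self.common_mask_.shape, dtype=float)
        out[self.common_mask_] = vector
        return out


def fit_pca(stack, rois: bool = False) -> PatternPCA:
    """Fit a :class:`PatternPCA` on a specimen × pixel matrix or ROI list."""
    model = PatternPCA()
    if rois:
        return model.fit_rois(stack)
    return model.fit(stack)


def _check_k(model: PatternPCA, k: int) -> int:
    if not 1 <= k <= model.n_components_:
        raise InputError(
            f"component index {k} out of range 1..{model.n_components_}"
        )
    return k - 1


def virtual_roi(
    model: PatternPCA, k: int, s: float, clip: bool = True
) -> np.ndarray:
    """Inverse-PCA reconstruction: mean + s·σ_k·loading_k, folded to the frame.

    ``k`` is 1-based; ``s`` is the score offset in SD units.  Values are
    clipped to [0, 1] unless ``clip=False``.
    """
    i = _check_k(model, k)
    vec = model.mean_ + s * model.score_sd_[i] * model.components_[i]
    if clip:
        vec = np.clip(vec, 0.0, 1.0)
    return model.fold(vec)


def amplitude_recovery_r(
    scores: np.ndarray, amplitudes: np.ndarray, n_components: int = 2
) -> np.ndarray:
    """Axis-matched correlation between PC scores and generative amplitudes.

    PCA recovers the span of the generative pattern fields but, when those
    fields are not orthogonal, only up to a rotation within that span.  Axis
    matching therefore takes, for each amplitude, the best linear
    recombination of the top ``n_components`` scores (the multiple
    correlation coefficient).  Returns one |r| per amplitude column.
    """
    S = np.asarray(scores, dtype=float)[:, :n_components]
    A = np.atleast_2d(np.asarray(amplitudes, dtype=float).T).T
    X = np.column_stack([np.ones(len(S)), S])
    out = []
    for j in range(A.shape[1]):
        coef, _, _, _ = np.linalg.lstsq(X, A[:, j], rcond=None)
        pred = X @ coef
        out.append(abs(float(np.corrcoef(pred, A[:, j])[0, 1])))
    return np.array(out)


def deviation_map(model: PatternPCA, k: int) -> np.ndarray:
    """|virtual(+2 SD) − virtual(−2 SD)| before clipping = 4σ_k·|loading_k|.

    Highlights where on the frame a component moves gray levels; non-negative
    everywhere, all-zero for a zero-variance component.
    """
    i = _check_k(model, k)
    return model.fold(4.0 * model.score_sd_[i] * np.abs(model.components_[i]))
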
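"""Association statistics between guide patterns and pollination types.

Covers the three analyses downstream of the homologous ROI: cross-tabulation
of qualitative modes against pollination types with a Pearson χ² test of
independence; the LOD score of a quantitative PC trait

    LOD = (n/2) · log10( Σᵢ (yᵢ − ȳ)² / Σᵢ (yᵢ − ŷ_{p(i)})² )

(ȳ the grand mean, ŷ_{p(i)} the mean of specimen i's pollination type) with
a label-shuffling permutation test; and forward–backward stepwise OLS of a
coded pollination response on PC scores.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError

__all__ = [
    "cross_tabulate",
    "chi2_independence",
    "lod_score",
    "permutation_test",
    "LODResult",
    "stepwise_select",
    "StepwiseResult",
]

_FAMILY_COLUMNS = {
    "variegated": ("random", "vascular"),
    "gradient": ("distal", "proximal"),
}


def cross_tabulate(
    species_modes: pd.DataFrame,
    pollination_types: dict[str, str] | pd.Series,
    family: str,
) -> pd.DataFrame:
    """Count species per (pollination type, mode) cell for one mode family.

    ``species_modes`` has columns ``species`` and the family column
    (``variegated`` or ``gradient``).  Species with pollination type
    ``to_be_determined`` are excluded.  Columns are the family's two modes
    plus ``none``.
    """
    if family not in _FAMILY_COLUMNS:
        raise InputError("family must be 'variegated' or 'gradient'")
    ptypes = dict(pollination_types)
    df = species_modes[["species", family]].copy()
    df["pollination_type"] = df["species"].map(ptypes)
    df = df.dropna(subset=["pollination_type"])
    df = df[df["pollination_type"] != "to_be_determined"]
    if df.empty:
        raise InputError("no species overlap between modes and pollination types")
    cols = list(_FAMILY_COLUMNS[family]) + ["none"]
    bad = set(df[family]) - set(cols)
    if bad:
        raise InputError(f"unknown {family} mode label(s): {sorted(bad)}")
    table = pd.crosstab(df["pollination_type"], df[family])
    table = table.reindex(columns=cols, fill_value=0)
    table.index.name = "pollination_type"
    return table


def chi2_independence(table: pd.DataFrame | np.ndarray):
    """Pearson χ² test of independence, no continuity correction.

    Zero-marginal rows/columns are dropped with a warning before computing
    degrees of freedom.  Returns ``(statistic, df, p)``.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise InputError("contingency table must be 2-D")
    if np.any(arr < 0) or arr.sum() <= 0:
        raise InputError("table needs non-negative counts and a positive total")
    rows = arr.sum(axis=1) > 0
    cols = arr.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        warnings.warn("dropping zero-marginal rows/columns before the test")
        arr = arr[rows][:, cols]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise InputError("need at least 2 non-empty rows and columns")
    res = sps.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _check_groups(y, groups):
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 1 or len(y) != len(groups):
        raise InputError("y and groups must be equal-length 1-D sequences")
    if len(y) < 2:
        raise InputError("need at least 2 specimens")
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise InputError("need at least 2 pollination-type groups")
    return y, groups, uniq


def lod_score(y, groups) -> float:
    """(n/2)·log10 of total over within-group sum of squares of the trait."""
    y, groups, uniq = _check_groups(y, groups)
    n = len(y)
    sst = float(np.sum((y - y.mean()) ** 2))
    group_means = {g: y[groups == g].mean() for g in uniq}
    ssw = float(sum(np.sum((y[groups == g] - group_means[g]) ** 2) for g in uniq))
    if ssw <= 0:
        raise InputError(
            "within-group sum of squares is zero (degenerate separation; "
            "LOD is infinite)"
        )
    return (n / 2.0) * np.log10(sst / ssw)


@dataclass
class LODResult:
    n: int
    lod: float
    y_bar: float
    group_means: dict
    p_value: float
    null_lods: np.ndarray
    n_perm: int
    seed: int | None
    floored: bool  # True when no null LOD reached the observed one

    def __str__(self):
        p = (
            f"p < {1.0 / (self.n_perm + 1):.2e}"
            if self.floored
            else f"p = {self.p_value:.4g}"
        )
        return f"LOD = {self.lod:.4f} ({p}, n = {self.n}, {self.n_perm} shuffles)"


def permutation_test(
    y, groups, n_perm: int = 10_000, seed: int | None = None
) -> LODResult:
    """Label-shuffling null distribution of the LOD score.

    The trait/pollination-type pairing is shuffled ``n_perm`` times; the
    p-value is the add-one estimator ``(1 + #{null ≥ observed}) / (n_perm +
    1)``, which cannot reach zero — when no null value reaches the observed
    LOD the result is flagged ``floored`` (p below the test's resolution).
    """
    y, groups, uniq = _check_groups(y, groups)
    observed = lod_score(y, groups)
    rng = np.random.default_rng(seed)
    n = len(y)

    # vectorized within-group SS over all shuffles: permuting y against
    # fixed labels is equivalent to shuffling the pairing
    codes = np.searchsorted(uniq, groups)
    counts = np.bincount(codes)
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    yp = y[perm]  # (n_perm, n)
    sums = np.zeros((n_perm, len(uniq)))
    sqs = np.zeros((n_perm, len(uniq)))
    for g in range(len(uniq)):
        sel = yp[:, codes == g]
        sums[:, g] = sel.sum(axis=1)
        sqs[:, g] = (sel**2).sum(axis=1)
    ssw = (sqs - sums**2 / counts).sum(axis=1)
    sst = float(np.sum((y - y.mean()) ** 2))
    ssw = np.clip(ssw, 1e-300, None)
    null = (n / 2.0) * np.log10(sst / ssw)

    b = int(np.sum(null >= observed - 1e-12))
    p = (1.0 + b) / (n_perm + 1.0)
    return LODResult(
        n=n,
        lod=observed,
        y_bar=float(y.mean()),
        group_means={str(g): float(y[groups == g].mean()) for g in uniq},
        p_value=p,
        null_lods=null,
        n_perm=n_perm,
        seed=seed,
        floored=(b == 0),
    )


@dataclass
class StepwiseResult:
    selected: list  # ordered predictor names in the final model
    status: dict  # predictor -> "in" | "out"
    coefficients: dict  # predictor -> B (final model)
    standard_errors: dict
    t_statistics: dict
    t_pvalues: dict
    r_squared: float
    f_statistic: float
    f_pvalue: float
    p_enter: float
    p_remove: float
    response_coding: dict


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS fit; returns (coef, rss, rank)."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef) ** 2))
    return coef, rss, rank


def stepwise_select(
    X: pd.DataFrame,
    y,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    response_coding: dict | None = None,
) -> StepwiseResult:
    """Forward–backward stepwise OLS of a coded response on candidate PCs.

    ``y`` may be numeric or categorical; categorical responses are coded via
    ``response_coding`` (default ``{"bee": 0, "hummingbird": 1}``, other
    categories excluded — mirroring the quantitative association analysis,
    which is restricted to the two well-replicated pollination types).
    Predictors enter while their partial-F p-value < ``p_enter`` and are
    removed when it rises ≥ ``p_remove``.
    """
    import statsmodels.api as sm

    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"PC{i + 1}" for i in range(X.shape[1])]
    y = np.asarray(y)
    coding = response_coding or {"bee": 0.0, "hummingbird": 1.0}
    if y.dtype.kind in "OUS":
        keep = np.isin(y, list(coding))
        X, y = X.loc[keep].reset_index(drop=True), y[keep]
        y = np.array([coding[v] for v in y], dtype=float)
    else:
        y = y.astype(float)
    n = len(y)
    if n < 4:
        raise InputError("need at least 4 specimens for stepwise regression")
    if np.ptp(y) == 0:
        raise InputError("constant response")
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)

    current: list[str] = []

    def design(sel):
        cols = [np.ones(n)] + [Xv[:, names.index(c)] for c in sel]
        return np.column_stack(cols)

    def partial_f_p(sel_small, sel_big):
        _, rss0, _ = _ols(design(sel_small), y)
        _, rss1, rank1 = _ols(design(sel_big), y)
        df_num = len(sel_big) - len(sel_small)
        df_den = n - rank1
        if df_den <= 0 or rss1 <= 1e-30:
            return 0.0
        f = ((rss0 - rss1) / df_num) / (rss1 / df_den)
        return float(sps.f.sf(max(f, 0.0), df_num, df_den))

    sst = float(np.sum((y - y.mean()) ** 2))
    changed = True
    while changed:
        changed = False
        # forward step: best candidate by partial-F p-value (skipped once the
        # fit is numerically perfect — residual is then rounding noise and
        # every additional predictor would spuriously "improve" it)
        _, rss_cur, _ = _ols(design(current), y)
        best_p, best_c = None, None
        for c in names if rss_cur > 1e-10 * sst else []:
            if c in current:
                continue
            cand = design(current + [c])
            if np.linalg.matrix_rank(cand) <= len(current) + 1:
                continue  # collinear with what is already in
            p = partial_f_p(current, current + [c])
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is not None and best_p < p_enter:
            current.append(best_c)
            changed = True
        # backward step: drop anything whose partial-F p rose above p_remove
        for c in list(current):
            p = partial_f_p([x for x in current if x != c], current)
            if p >= p_remove:
                current.remove(c)
                changed = True

    if current:
        model = sm.OLS(y, sm.add_constant(pd.DataFrame(
            {c: Xv[:, names.index(c)] for c in current}
        ), has_constant="add")).fit()
        coeffs = {c: float(model.params[c]) for c in current}
        ses = {c: float(model.bse[c]) for c in current}
        ts = {c: float(model.tvalues[c]) for c in current}
        tps = {c: float(model.pvalues[c]) for c in current}
        r2 = float(model.rsquared)
        fstat, fp = float(model.fvalue), float(model.f_pvalue)
    else:
        coeffs, ses, ts, tps = {}, {}, {}, {}
        r2, fstat, fp = 0.0, float("nan"), float("nan")
    return StepwiseResult(
        selected=list(current),
        status={c: ("in" if c in current else "out") for c in names},
        coefficients=coeffs,
        standard_errors=ses,
        t_statistics=ts,
        t_pvalues=tps,
        r_squared=r2,
        f_statistic=fstat,
        f_pvalue=fp,
        p_enter=p_enter,
        p_remove=p_remove,
        response_coding=coding,
    )


def exhaustive_permutation_p(y, groups) -> float:
    """Exact permutation p of the LOD by enumerating label assignments.

    Feasible only for small n; used as an independent check of the
    Monte-Carlo permutation test.
    """
    y, groups, uniq = _check_groups(y, groups)
    observed = lod_score(y, groups)
    n = len(y)
    idx = np.arange(n)
    count = 0
    total = 0
    for perm in itertools.permutations(idx):
        total += 1
        if lod_score(y[list(perm)], groups) >= observed - 1e-12:
            count += 1
    return count / total
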
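"""Trait preparation: covariate residualization and ordinalization.

The quantitative trait enters the liability model as an ordinal variable:
the observed volume is first residualized by ordinary least squares on a
processing-site indicator (Helsinki vs the rest, reflecting the different
image-processing pipeline), sex, age and intracranial volume, then cut
into K classes of roughly equal size on the pooled residual distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import N_BV_CATEGORIES
from .exceptions import CollinearityError, DegenerateBinningError

__all__ = ["OrdinalSpec", "residualize", "quantile_bin", "build_design",
           "prepare"]

DEFAULT_COVARIATES = ("site", "sex", "age", "icv")


@dataclass(frozen=True)
class OrdinalSpec:
    """K ordinal classes defined by K-1 strictly increasing cutpoints."""

    k: int
    cutpoints: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        cuts = np.asarray(self.cutpoints, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "cutpoints", cuts)
        object.__setattr__(self, "counts", counts)
        if cuts.size != self.k - 1:
            raise ValueError("need k-1 cutpoints")
        if np.any(np.diff(cuts) <= 0):
            raise ValueError("cutpoints must be strictly increasing")

    def assign(self, values):
        """Category 1..k per value; ties at a cutpoint go to the lower class."""
        return np.searchsorted(self.cutpoints, np.asarray(values, dtype=float),
                               side="left") + 1

    def to_dict(self):
        return {"k": self.k, "cutpoints": self.cutpoints.tolist(),
                "counts": self.counts.tolist()}

    @classmethod
    def from_dict(cls, d):
        return cls(k=int(d["k"]), cutpoints=np.asarray(d["cutpoints"]),
                   counts=np.asarray(d["counts"]))


def _find_dependent_columns(X, names, tol=1e-10):
    """Columns that add no rank when appended left to right."""
    dependent = []
    rank = 0
    kept = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.column_stack([kept, X[:, j]])
        r = np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(X).max()))
        if r > rank:
            kept = cand
            rank = r
        else:
            dependent.append(names[j])
    return dependent


def residualize(values, covariates):
    """OLS residuals of ``values`` on a covariate design (plus intercept).

    Returns ``(residuals, coefficients)`` where coefficients is a Series
    indexed by column name (including ``intercept``).  Residuals are
    orthogonal to every covariate column and have mean zero.
    """
    y = np.asarray(values, dtype=float)
    X = pd.DataFrame(covariates) if covariates is not None else pd.DataFrame(
        index=range(y.size)
    )
    if y.ndim != 1 or len(X) != y.size:
        raise ValueError("values and covariates must align row-wise")
    names = ["intercept"] + [str(c) for c in X.columns]
    mat = np.column_stack([np.ones(y.size)] + [
        np.asarray(X[c], dtype=float) for c in X.columns
    ])
    if np.isnan(mat).any() or np.isnan(y).any():
        bad = [n for n, col in zip(names, mat.T) if np.isnan(col).any()]
        raise ValueError(f"missing values in design columns {bad} or response")
    if y.size < mat.shape[1] + 1:
        raise ValueError(
            f"need at least p+2 = {mat.shape[1] + 1} rows, got {y.size}"
        )
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise CollinearityError(_find_dependent_columns(mat, names))
    beta, *_ = np.linalg.lstsq(mat, y, rcond=None)
    resid = y - mat @ beta
    return resid, pd.Series(beta, index=names)


def quantile_bin(residuals, k=N_BV_CATEGORIES):
    """Cut values into ``k`` classes at left-continuous empirical quantiles.

    Cutpoint j is the ceil(j*n/k)-th order statistic; ties are resolved by
    sending every value equal to a cutpoint to the lower class, so class
    sizes are equal up to ties (deterministic, order-independent).
    Returns ``(categories, OrdinalSpec)``.
    """
    x = np.asarray(residuals, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(x).size < k:
        raise DegenerateBinningError(
            f"only {np.unique(x).size} distinct values for k={k} classes"
        )
    srt = np.sort(x)
    n = x.size
    idx = np.ceil(np.arange(1, k) * n / k).astype(int) - 1
    cuts = srt[idx]
    if np.any(np.diff(cuts) <= 0):
        # mass points straddling several quantiles: collapse duplicates by
        # nudging upward through the order statistics
        cuts = np.array(sorted(set(cuts)))
        extra = np.setdiff1d(np.unique(srt), cuts)
        while cuts.size < k - 1 and extra.size:
            cand = extra[np.argmin(np.abs(extra - np.median(x)))]
            cuts = np.sort(np.append(cuts, cand))
            extra = np.setdiff1d(extra, [cand])
        if cuts.size < k - 1:
            raise DegenerateBinningError("could not place k-1 distinct cutpoints")
    cats = np.searchsorted(cuts, x, side="left") + 1
    counts = np.bincount(cats, minlength=k + 1)[1:]
    return cats, OrdinalSpec(k=k, cutpoints=cuts, counts=counts)


def build_design(df, covariates=DEFAULT_COVARIATES, site_reference="Helsinki"):
    """Numeric design table from long-format columns.

    ``site`` becomes a single 0/1 indicator for ``site_reference`` (the
    site whose processing pipeline differed); ``sex`` becomes an
    is-male indicator; other covariates pass through as numeric.
    """
    out = {}
    for c in covariates:
        if c == "site":
            out["site_helsinki"] = (
                df["site"].astype(str) == site_reference
            ).astype(float).to_numpy()
        elif c == "sex":
            out["sex_male"] = (
                df["sex"].astype(str).str.upper().str[0] == "M"
            ).astype(float).to_numpy()
        else:
            out[c] = pd.to_numeric(df[c]).to_numpy(dtype=float)
    return pd.DataFrame(out, index=df.index)


def prepare(df, k=N_BV_CATEGORIES, covariates=DEFAULT_COVARIATES,
            site_reference="Helsinki"):
    """Residualize the trait on covariates and ordinalize into k classes.

    All individuals (affected and unaffected) enter the regression and the
    pooled binning jointly.  Returns ``(DataFrame with bv_cat, OrdinalSpec,
    coefficients)``.
    """
    df = pd.DataFrame(df).copy()
    design = build_design(df, covariates, site_reference) if covariates else None
    resid, coef = residualize(df["bv"].to_numpy(dtype=float), design)
    cats, spec = quantile_bin(resid, k=k)
    df["bv_cat"] = cats
    return df, spec, coef
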
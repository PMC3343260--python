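"""Liability-threshold machinery and constrained polychoric estimation.

The disease trait is an unobserved standard-normal liability dichotomized at
the threshold implied by population prevalence; the quantitative trait is an
ordinalized latent normal.  Each twin pair contributes the exact probability
of its observed ordinal cell under a 4-variate normal over
(Sz1, BV1, Sz2, BV2) — full-information maximum likelihood, so pairs with a
missing member (singletons) or a missing ordinal category marginalize
naturally.

``fit_structure`` estimates the five free polychoric correlations of the
twin design (one cross-trait within-member correlation shared by everyone,
within-trait and cross-trait cross-member correlations per zygosity) with
the disease-side twin correlations *fixed* at their population values — the
ascertainment correction: nothing about the disease margin is learned from
the selected sample.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import ndtri

from . import _mvnorm
from .constants import PREVALENCE, R_SZ_DZ, R_SZ_MZ
from .exceptions import ConvergenceError

__all__ = [
    "ThresholdSet",
    "CorrelationStructure",
    "FitResult",
    "threshold_from_prevalence",
    "bvn_rect",
    "mvn_rect",
    "pair_table_loglik",
    "fit_structure",
]

#: chi-square(1) critical value at 95%, the profile-likelihood cutoff
LRT_CRIT_95 = 3.841458820694124

# integration order inside the likelihood: the ordinal-trait slabs are
# conditioned on, the (half-infinite) disease dimensions are integrated
# exactly; see _mvnorm.mvn_rect_batch
_INT_ORDER = np.array([1, 3, 0, 2])  # (BV1, BV2, Sz1, Sz2)
_DEFAULT_POINTS = 512


def threshold_from_prevalence(p):
    """Liability z-threshold with upper-tail mass ``p`` (affected fraction)."""
    p = float(p)
    if not 0.0 < p < 1.0:
        raise ValueError(f"prevalence must lie strictly in (0, 1), got {p}")
    return float(-ndtri(p))


def bvn_rect(r, lower, upper):
    """Standard bivariate normal rectangle probability, |error| <= 1e-10.

    Closed form via Owen's T function; +-inf bounds allowed.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    return _mvnorm.bvn_rect_prob(r, lower, upper)


def mvn_rect(corr, lower, upper, n_points=131072):
    """Rectangle probability under a zero-mean MVN with correlation ``corr``.

    Deterministic quasi–Monte-Carlo (fixed scrambled-Sobol rule) with the
    two widest dimensions integrated in closed form; absolute error at the
    default rule is ~1e-8.  Supports dimensions 1, 2 and 4.
    """
    return _mvnorm.mvn_rect_prob(corr, lower, upper, n_points=n_points)


@dataclass(frozen=True)
class ThresholdSet:
    """Liability thresholds: one fixed disease threshold, K-1 ordinal cuts.

    ``bv_thresholds`` are shared across members, zygosities and affection
    groups (the equality constraint of the analysis).
    """

    sz_threshold: float
    bv_thresholds: np.ndarray

    def __post_init__(self):
        cuts = np.asarray(self.bv_thresholds, dtype=float)
        object.__setattr__(self, "bv_thresholds", cuts)
        if cuts.size and np.any(np.diff(cuts) <= 0):
            raise ValueError("bv_thresholds must be strictly increasing")

    @property
    def n_categories(self):
        return self.bv_thresholds.size + 1

    def sz_bounds(self, affected):
        t = self.sz_threshold
        return (t, np.inf) if affected else (-np.inf, t)

    def bv_bounds(self, category):
        """Bounds of ordinal category 1..K; None/NaN marginalizes."""
        if category is None or (isinstance(category, float) and np.isnan(category)):
            return (-np.inf, np.inf)
        j = int(category)
        if not 1 <= j <= self.n_categories:
            raise ValueError(f"category {j} outside 1..{self.n_categories}")
        cuts = self.bv_thresholds
        lo = cuts[j - 2] if j > 1 else -np.inf
        hi = cuts[j - 1] if j < self.n_categories else np.inf
        return (lo, hi)


@dataclass
class CorrelationStructure:
    """The five estimated polychoric twin correlations plus the fixed pair.

    ``r_within`` is the cross-trait within-member correlation, constrained
    equal for every individual; cross-member correlations come per
    zygosity.  The disease-side twin correlations are fixed constants, not
    estimates.
    """

    r_within: float
    r_bv_mz: float
    r_bv_dz: float
    r_cross_mz: float
    r_cross_dz: float
    r_sz_mz: float = R_SZ_MZ
    r_sz_dz: float = R_SZ_DZ
    ci: dict = field(default_factory=dict)

    _FREE = ("r_within", "r_bv_mz", "r_bv_dz", "r_cross_mz", "r_cross_dz")

    def matrix(self, zygosity):
        """Implied 4x4 correlation over (Sz1, BV1, Sz2, BV2)."""
        zyg = str(zygosity).upper()
        if zyg == "MZ":
            r_sz, r_bv, r_x = self.r_sz_mz, self.r_bv_mz, self.r_cross_mz
        elif zyg == "DZ":
            r_sz, r_bv, r_x = self.r_sz_dz, self.r_bv_dz, self.r_cross_dz
        else:
            raise ValueError(f"unknown zygosity {zygosity!r}")
        rw = self.r_within
        return np.array(
            [
                [1.0, rw, r_sz, r_x],
                [rw, 1.0, r_x, r_bv],
                [r_sz, r_x, 1.0, rw],
                [r_x, r_bv, rw, 1.0],
            ]
        )

    def validate(self):
        for name in self._FREE:
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [-1, 1]")
        for zyg in ("MZ", "DZ"):
            if np.linalg.eigvalsh(self.matrix(zyg))[0] < -1e-10:
                raise ValueError(f"{zyg} correlation matrix not PSD")


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    loglik: float
    params: dict
    converged: bool
    model: str
    n_pairs: int = 0
    n_singles: int = 0
    ci: dict = field(default_factory=dict)
    boundary: list = field(default_factory=list)
    message: str = ""
    n_iter: int = 0


# ---------------------------------------------------------------------------
# pair-table aggregation


@dataclass
class _CellTable:
    """Observed ordinal cells with counts, one instance per dataset."""

    pair_cells: dict  # zygosity -> (keys ndarray (m,4), counts ndarray)
    single_cells: dict  # zygosity -> (keys ndarray (m,2), counts ndarray)
    n_pairs: int
    n_singles: int
    n_categories: int


_MISSING_CAT = 0  # internal code for a marginalized ordinal category


def _cat_code(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return _MISSING_CAT
    return int(v)


def aggregate_cells(data, n_categories=None):
    """Collapse long-format twin data into ordinal-cell counts.

    Member order within a pair is irrelevant to the model (the implied
    matrix is exchangeable), so cells are canonicalized by sorting the two
    (affected, category) member tuples — mirrored cells pool.
    """
    df = pd.DataFrame(data)
    required = {"pair_id", "zygosity", "affected", "bv_cat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"data lack columns {sorted(missing)}")
    cats = pd.to_numeric(df["bv_cat"], errors="coerce")
    if n_categories is None:
        if cats.notna().sum() == 0:
            raise ValueError("no ordinal categories present in data")
        n_categories = int(cats.max())

    pair_counter = {"MZ": Counter(), "DZ": Counter()}
    single_counter = {"MZ": Counter(), "DZ": Counter()}
    n_pairs = n_singles = 0
    cols = df[["pair_id", "zygosity", "affected"]].copy()
    cols["cat"] = cats
    for pid, grp in cols.groupby("pair_id", sort=False):
        zyg = str(grp["zygosity"].iloc[0]).upper()
        if grp["zygosity"].nunique() > 1:
            raise ValueError(f"pair {pid!r} mixes zygosities")
        if len(grp) > 2:
            raise ValueError(f"pair {pid!r} has more than two members")
        members = [
            (int(a), _cat_code(c)) for a, c in zip(grp["affected"], grp["cat"])
        ]
        if len(members) == 2:
            m1, m2 = sorted(members)
            pair_counter[zyg][(m1[0], m1[1], m2[0], m2[1])] += 1
            n_pairs += 1
        else:
            single_counter[zyg][members[0]] += 1
            n_singles += 1

    def _pack(counter, width):
        out = {}
        for zyg, ctr in counter.items():
            if ctr:
                keys = np.array(sorted(ctr), dtype=int).reshape(-1, width)
                counts = np.array([ctr[tuple(k)] for k in keys], dtype=float)
            else:
                keys = np.empty((0, width), dtype=int)
                counts = np.empty(0)
            out[zyg] = (keys, counts)
        return out

    return _CellTable(
        pair_cells=_pack(pair_counter, 4),
        single_cells=_pack(single_counter, 2),
        n_pairs=n_pairs,
        n_singles=n_singles,
        n_categories=n_categories,
    )


def _cell_bounds(keys, thresholds):
    """(m, 4) lower/upper bound arrays for cells (a1, c1, a2, c2)."""
    m = keys.shape[0]
    lower = np.empty((m, 4))
    upper = np.empty((m, 4))
    t = thresholds.sz_threshold
    cuts = np.concatenate(([-np.inf], thresholds.bv_thresholds, [np.inf]))
    for j, col in enumerate((0, 2)):  # Sz dims 0 and 2
        aff = keys[:, 2 * j].astype(bool)
        lower[:, col] = np.where(aff, t, -np.inf)
        upper[:, col] = np.where(aff, np.inf, t)
    for j, col in enumerate((1, 3)):  # BV dims 1 and 3
        cat = keys[:, 2 * j + 1]
        present = cat != _MISSING_CAT
        lower[:, col] = np.where(present, cuts[np.maximum(cat - 1, 0)], -np.inf)
        upper[:, col] = np.where(present, cuts[np.minimum(cat, cuts.size - 1)], np.inf)
    return lower, upper


def _loglik_from_mats(mats, thresholds, cells, n_points=_DEFAULT_POINTS):
    """FIML log-likelihood given per-zygosity 4x4 implied correlations.

    Returns -inf (boundary, not an exception) when a populated cell has
    non-positive probability or an implied matrix is not PSD.
    """
    total = 0.0
    for zyg, (keys, counts) in cells.pair_cells.items():
        if counts.size == 0:
            continue
        R = mats[zyg][np.ix_(_INT_ORDER, _INT_ORDER)]
        try:
            chol = np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            return -np.inf
        lower, upper = _cell_bounds(keys, thresholds)
        probs = _mvnorm.mvn_rect_batch(
            chol, lower[:, _INT_ORDER], upper[:, _INT_ORDER], n_points=n_points
        )
        if np.any(probs <= 0.0):
            return -np.inf
        total += float(counts @ np.log(probs))
    for zyg, (keys, counts) in cells.single_cells.items():
        if counts.size == 0:
            continue
        r_within = float(mats[zyg][0, 1])
        for (aff, cat), n in zip(keys, counts):
            lo_s, hi_s = thresholds.sz_bounds(bool(aff))
            lo_b, hi_b = thresholds.bv_bounds(None if cat == _MISSING_CAT else cat)
            if np.isinf(lo_b) and np.isinf(hi_b):
                p = _mvnorm._phi(hi_s) - _mvnorm._phi(lo_s)
            else:
                p = _mvnorm.bvn_rect_prob(r_within, (lo_s, lo_b), (hi_s, hi_b))
            if p <= 0.0:
                return -np.inf
            total += float(n) * np.log(p)
    return total


def pair_table_loglik(structure, thresholds, data, n_points=_DEFAULT_POINTS):
    """Log-likelihood of categorized twin data under a correlation structure.

    ``data`` may be a long-format DataFrame or a pre-aggregated cell table.
    """
    cells = data if isinstance(data, _CellTable) else aggregate_cells(
        data, n_categories=thresholds.n_categories
    )
    mats = {z: structure.matrix(z) for z in ("MZ", "DZ")}
    return _loglik_from_mats(mats, thresholds, cells, n_points=n_points)


# ---------------------------------------------------------------------------
# estimation


def _threshold_params_from_cuts(cuts):
    cuts = np.asarray(cuts, dtype=float)
    return np.concatenate(([cuts[0]], np.log(np.diff(cuts)))) if cuts.size else cuts


def _cuts_from_threshold_params(tp):
    tp = np.asarray(tp, dtype=float)
    if tp.size == 0:
        return tp
    return tp[0] + np.concatenate(([0.0], np.cumsum(np.exp(tp[1:]))))


def start_thresholds(data, n_categories):
    """Ordinal cutpoints from pooled category frequencies (moment start)."""
    cats = pd.to_numeric(pd.DataFrame(data)["bv_cat"], errors="coerce").dropna()
    counts = np.array(
        [np.sum(cats == j) for j in range(1, n_categories + 1)], dtype=float
    )
    if np.any(counts == 0):
        counts += 0.5  # continuity correction for empty classes
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return ndtri(cum)


def _moment_start_correlations(df):
    """Crude product-moment starting values on numeric scores."""
    wide = df.pivot_table(
        index="pair_id", columns="member", values=["affected", "bv_cat"],
        aggfunc="first",
    )
    zyg = df.groupby("pair_id")["zygosity"].first().astype(str).str.upper()

    def _corr(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            return 0.0
        return float(np.clip(np.corrcoef(x[ok], y[ok])[0, 1] * 1.2, -0.9, 0.9))

    aff = {m: wide.get(("affected", m)) for m in (1, 2)}
    cat = {m: wide.get(("bv_cat", m)) for m in (1, 2)}
    for m in (1, 2):
        if aff[m] is None:
            aff[m] = pd.Series(np.nan, index=wide.index)
        if cat[m] is None:
            cat[m] = pd.Series(np.nan, index=wide.index)
    r_within = _corr(
        pd.concat([aff[1], aff[2]]), pd.concat([cat[1], cat[2]])
    )
    out = {"r_within": r_within}
    for z in ("MZ", "DZ"):
        mask = (zyg == z).reindex(wide.index, fill_value=False)
        out[f"r_bv_{z.lower()}"] = _corr(cat[1][mask], cat[2][mask])
        out[f"r_cross_{z.lower()}"] = _corr(
            pd.concat([aff[1][mask], aff[2][mask]]),
            pd.concat([cat[2][mask], cat[1][mask]]),
        )
    return out


def _minimize_multistart(nll, starts, bounds=None, maxiter=300):
    best = None
    for x0 in starts:
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def profile_interval(nll, theta_hat, index, nll_min, crit=LRT_CRIT_95,
                     step=0.05, max_expand=60, xtol=1e-4, maxiter=120):
    """Profile-likelihood interval for parameter ``index`` of ``nll``.

    Re-optimizes the remaining parameters at each fixed value (warm
    started), expands outward until -2*dlnL crosses ``crit``, then solves
    the crossing by Brent's method.  Returns (lo, hi); an endpoint is
    +-inf if no crossing is found within the expansion range.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    free = [i for i in range(theta_hat.size) if i != index]
    warm = {"x": theta_hat[free]}

    def prof(v):
        def reduced(x):
            full = np.empty(theta_hat.size)
            full[free] = x
            full[index] = v
            return nll(full)

        if free:
            res = minimize(
                reduced, warm["x"], method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-10},
            )
            warm["x"] = res.x
            return res.fun
        return reduced(np.empty(0))

    def g(v):
        return 2.0 * (prof(v) - nll_min) - crit

    out = []
    for direction in (-1.0, 1.0):
        lo_v = theta_hat[index]
        found = None
        h = step
        for _ in range(max_expand):
            v = lo_v + direction * h
            gv = g(v)
            if np.isfinite(gv) and gv > 0:
                found = (v, lo_v) if direction < 0 else (lo_v, v)
                break
            if np.isfinite(gv):
                lo_v = v
                h = step
            else:
                h *= 0.5
                if h < 1e-6:
                    break
        if found is None:
            out.append(-np.inf if direction < 0 else np.inf)
        else:
            out.append(float(brentq(g, found[0], found[1], xtol=xtol)))
    return tuple(out)


def fit_structure(data, prevalence=PREVALENCE, n_categories=None,
                  fix_sz_mz=R_SZ_MZ, fix_sz_dz=R_SZ_DZ, ci=False,
                  n_points=_DEFAULT_POINTS, maxiter=300):
    """Constrained ML estimation of the polychoric twin-correlation structure.

    Five correlations are free (on an atanh scale); the disease-side twin
    correlations and threshold are fixed (ascertainment correction).
    Ordinal thresholds are estimated jointly, parameterized as first cut
    plus log-increments to enforce ordering.

    ``ci`` may be ``True`` (profile-likelihood intervals for all five
    correlations) or an iterable of correlation names to profile.

    Returns ``(CorrelationStructure, ThresholdSet, FitResult)``.
    """
    df = pd.DataFrame(data)
    zygs = set(df["zygosity"].astype(str).str.upper())
    if not {"MZ", "DZ"} <= zygs:
        raise ValueError("data must contain both MZ and DZ pairs")
    cells = aggregate_cells(df, n_categories=n_categories)
    k = cells.n_categories
    sz_t = threshold_from_prevalence(prevalence)

    cuts0 = start_thresholds(df, k)
    tp0 = _threshold_params_from_cuts(cuts0)
    n_thresh = tp0.size

    corr_names = list(CorrelationStructure._FREE)

    def unpack(theta):
        rs = np.tanh(theta[:5])
        cuts = _cuts_from_threshold_params(theta[5:])
        struct = CorrelationStructure(
            *rs, r_sz_mz=fix_sz_mz, r_sz_dz=fix_sz_dz
        )
        thr = ThresholdSet(sz_threshold=sz_t, bv_thresholds=cuts)
        return struct, thr

    def nll(theta):
        struct, thr = unpack(theta)
        mats = {z: struct.matrix(z) for z in ("MZ", "DZ")}
        ll = _loglik_from_mats(mats, thr, cells, n_points=n_points)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    moments = _moment_start_correlations(df)
    z_moment = np.arctanh(np.clip(
        [moments[n] for n in corr_names], -0.95, 0.95
    ))
    starts = [
        np.concatenate((np.zeros(5), tp0)),
        np.concatenate((z_moment, tp0)),
    ]
    zb = [(-5.0, 5.0)] * 5 + [(-4.0, 4.0)] + [(-8.0, 3.0)] * (n_thresh - 1)
    best = _minimize_multistart(nll, starts, bounds=zb, maxiter=maxiter)
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("polychoric fit failed from every start", best)

    struct, thr = unpack(best.x)
    boundary = [
        n for n in corr_names if abs(getattr(struct, n)) > 0.995
    ]
    result = FitResult(
        loglik=-float(best.fun),
        params={
            **{n: float(getattr(struct, n)) for n in corr_names},
            "bv_thresholds": thr.bv_thresholds.tolist(),
            "r_sz_mz": fix_sz_mz,
            "r_sz_dz": fix_sz_dz,
            "sz_threshold": sz_t,
        },
        converged=bool(best.success),
        model="polychoric",
        n_pairs=cells.n_pairs,
        n_singles=cells.n_singles,
        boundary=boundary,
        message=str(best.message),
        n_iter=int(best.nit),
    )
    if ci:
        wanted = corr_names if ci is True else [n for n in corr_names
                                                if n in set(ci)]
        for name in wanted:
            i = corr_names.index(name)
            lo, hi = profile_interval(nll, best.x, i, float(best.fun))
            interval = (float(np.tanh(lo)), float(np.tanh(hi)))
            struct.ci[name] = interval
            result.ci[name] = interval
    return struct, thr, result
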
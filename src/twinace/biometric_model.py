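"""Bivariate Cholesky ACE model with a fixed disease side.

The disease-side paths are held at the square roots of external population
variance components (the ascertainment correction); the six trait-side
paths are estimated by FIML on the ordinal pair table, subject to unit
trait variance (the specific unique-environment path is eliminated by the
constraint).  The fitted triangle is then re-expressed as the
correlated-factors solution — per-trait variance proportions h2/c2/e2 and
factor correlations r_g, r_c, r_e — and the phenotypic correlation is
decomposed into its A/C/E parts:

    r_ph = sqrt(h2_sz) r_g sqrt(h2_bv)
         + sqrt(c2_sz) r_c sqrt(c2_bv)
         + sqrt(e2_sz) r_e sqrt(e2_bv)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .constants import PREVALENCE, SZ_C2, SZ_E2, SZ_H2
from .exceptions import ConvergenceError
from .liability_core import (
    FitResult,
    ThresholdSet,
    _DEFAULT_POINTS,
    _loglik_from_mats,
    _moment_start_correlations,
    aggregate_cells,
    profile_interval,
    start_thresholds,
    threshold_from_prevalence,
)
from .twin_sim import PathCoefficients, implied_cov

__all__ = [
    "StandardizedSolution",
    "fit_ace",
    "fit_submodel",
    "standardize",
    "decompose_rph",
    "variance_explained",
]

_PATH_NAMES = ("a_pc", "c_pc", "e_pc", "a_s", "c_s")
_COMPONENT_TO_PATH = {
    "A_common": "a_pc",
    "C_common": "c_pc",
    "E_common": "e_pc",
    "A_specific": "a_s",
    "C_specific": "c_s",
}
_BOUNDARY_TOL = 1e-4
_DEGENERATE_TOL = 1e-10

#: printed alongside every likelihood-ratio test against a variance
#: component: the null value lies on the boundary of the parameter space,
#: so the nominal chi-square reference is conservative (the asymptotic
#: distribution is a chi-bar-square mixture).
LRT_BOUNDARY_CAVEAT = (
    "variance components are tested on the boundary of the parameter "
    "space; the nominal chi-square p-value is conservative"
)


@dataclass
class StandardizedSolution:
    """Correlated-factors solution of a fitted bivariate Cholesky model.

    ``r_c`` (or ``r_g``/``r_e``) is ``None`` when the matching trait-side
    variance component is zero — the factor correlation is then undefined
    and its contribution to r_ph is zero.
    """

    h2_bv: float
    c2_bv: float
    e2_bv: float
    r_g: float | None
    r_c: float | None
    r_e: float | None
    r_ph: float
    r_ph_a: float
    r_ph_c: float
    r_ph_e: float
    h2_sz: float = SZ_H2
    c2_sz: float = SZ_C2
    e2_sz: float = SZ_E2
    ci: dict = field(default_factory=dict)
    boundary: list = field(default_factory=list)

    def validate(self, tol=1e-8):
        if abs(self.h2_bv + self.c2_bv + self.e2_bv - 1.0) > tol:
            raise ValueError("trait variance components do not sum to 1")
        if abs(self.r_ph - (self.r_ph_a + self.r_ph_c + self.r_ph_e)) > tol:
            raise ValueError("r_ph decomposition does not add up")
        return self


def _as_sz_dict(fixed_sz):
    if fixed_sz is None:
        return {"h2": SZ_H2, "c2": SZ_C2, "e2": SZ_E2}
    if isinstance(fixed_sz, dict):
        d = dict(fixed_sz)
    else:
        h2, c2, e2 = fixed_sz
        d = {"h2": float(h2), "c2": float(c2), "e2": float(e2)}
    if abs(d["h2"] + d["c2"] + d["e2"] - 1.0) > 1e-6:
        raise ValueError("fixed disease components must sum to 1")
    return d


def _paths_from_free(values, free_names, sz):
    """PathCoefficients from the free trait paths, or None when the
    unit-variance constraint leaves no room for the specific E path."""
    p = dict.fromkeys(_PATH_NAMES, 0.0)
    p.update(zip(free_names, values))
    e_s2 = 1.0 - sum(v * v for v in p.values())
    if e_s2 <= _DEGENERATE_TOL:
        return None, -e_s2
    return PathCoefficients(
        a_c=float(np.sqrt(sz["h2"])), c_c=float(np.sqrt(sz["c2"])),
        e_c=float(np.sqrt(sz["e2"])),
        a_pc=p["a_pc"], c_pc=p["c_pc"], e_pc=p["e_pc"],
        a_s=p["a_s"], c_s=p["c_s"], e_s=float(np.sqrt(e_s2)),
    ), 0.0


def _falconer_start(df, sz):
    """Moment-based starting paths (Falconer-style transforms).

    Crude product-moment twin correlations give h2 = 2(rMZ - rDZ),
    c2 = 2 rDZ - rMZ; the cross-trait cross-twin correlations split the
    within-person correlation into A/C/E channels the same way.
    """
    m = _moment_start_correlations(df)
    h2 = np.clip(2.0 * (m["r_bv_mz"] - m["r_bv_dz"]), 0.05, 0.9)
    c2 = np.clip(2.0 * m["r_bv_dz"] - m["r_bv_mz"], 0.02, 0.9)
    if h2 + c2 > 0.95:
        scale = 0.95 / (h2 + c2)
        h2, c2 = h2 * scale, c2 * scale
    a_c, c_c, e_c = np.sqrt(sz["h2"]), np.sqrt(sz["c2"]), np.sqrt(sz["e2"])
    cov_a = 2.0 * (m["r_cross_mz"] - m["r_cross_dz"])
    cov_c = 2.0 * m["r_cross_dz"] - m["r_cross_mz"]
    a_pc = np.clip(cov_a / a_c, -0.9 * np.sqrt(h2), 0.9 * np.sqrt(h2))
    c_pc = np.clip(cov_c / c_c, -0.9 * np.sqrt(c2), 0.9 * np.sqrt(c2)) \
        if c_c > 0 else 0.0
    e_pc = np.clip(
        (m["r_within"] - a_c * a_pc - c_c * c_pc) / e_c, -0.25, 0.25
    ) if e_c > 0 else 0.0
    a_s = np.sqrt(max(h2 - a_pc**2, 1e-4))
    c_s = np.sqrt(max(c2 - c_pc**2, 1e-4))
    start = {"a_pc": a_pc, "c_pc": c_pc, "e_pc": e_pc, "a_s": a_s, "c_s": c_s}
    ss = sum(v * v for v in start.values())
    if ss > 0.95:
        start = {k: v * np.sqrt(0.95 / ss) for k, v in start.items()}
    return start


def fit_ace(data, prevalence=PREVALENCE, fixed_sz=None, drop=frozenset(),
            n_categories=None, ci=False, n_points=_DEFAULT_POINTS,
            maxiter=300):
    """FIML fit of the bivariate Cholesky ACE model on ordinal pair data.

    Disease-side paths are fixed at the square roots of ``fixed_sz``
    (default: the population values .81/.11/.08) and the disease threshold
    at the prevalence quantile.  The five free trait-side paths (minus any
    in ``drop``) and the ordinal thresholds are estimated jointly; the
    specific unique-environment path is recovered from the unit-variance
    constraint, with a penalty steering the optimizer away from an
    imaginary root.  ``ci=True`` adds profile-likelihood intervals for the
    free paths.
    """
    sz = _as_sz_dict(fixed_sz)
    drop = set(drop)
    if "E_specific" in drop:
        raise ValueError("the specific unique-environment path is never "
                         "droppable (it absorbs measurement error)")
    unknown = drop - set(_COMPONENT_TO_PATH)
    if unknown:
        raise ValueError(f"unknown components {sorted(unknown)}")
    dropped_paths = {_COMPONENT_TO_PATH[c] for c in drop}
    free_names = [p for p in _PATH_NAMES if p not in dropped_paths]

    df = pd.DataFrame(data)
    zygs = set(df["zygosity"].astype(str).str.upper())
    if not {"MZ", "DZ"} <= zygs:
        raise ValueError("data must contain both MZ and DZ pairs")
    cells = aggregate_cells(df, n_categories=n_categories)
    sz_t = threshold_from_prevalence(prevalence)
    cuts0 = start_thresholds(df, cells.n_categories)

    from .liability_core import (_cuts_from_threshold_params,
                                 _threshold_params_from_cuts)
    tp0 = _threshold_params_from_cuts(cuts0)
    n_free = len(free_names)

    def unpack(theta):
        paths, viol = _paths_from_free(theta[:n_free], free_names, sz)
        cuts = _cuts_from_threshold_params(theta[n_free:])
        return paths, viol, cuts

    def nll(theta):
        paths, viol, cuts = unpack(theta)
        if paths is None:
            return 1e10 * (1.0 + viol)
        thr = ThresholdSet(sz_threshold=sz_t, bv_thresholds=cuts)
        mats = {z: implied_cov(paths, z) for z in ("MZ", "DZ")}
        ll = _loglik_from_mats(mats, thr, cells, n_points=n_points)
        if not np.isfinite(ll):
            return 1e10
        return -ll

    neutral = {"a_pc": 0.1, "c_pc": 0.1, "e_pc": 0.1, "a_s": 0.6, "c_s": 0.3}
    falconer = _falconer_start(df, sz)
    starts = [
        np.concatenate(([falconer[n] for n in free_names], tp0)),
        np.concatenate(([neutral[n] for n in free_names], tp0)),
    ]
    bounds = [(-0.999, 0.999)] * n_free + [(-4.0, 4.0)] + \
        [(-8.0, 3.0)] * (tp0.size - 1)
    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-10,
                                "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("ACE fit failed from every start", best)

    paths, _, cuts = unpack(best.x)
    if paths is None:
        raise ConvergenceError("ACE fit ended at an inadmissible point", best)
    boundary = []
    if paths.c2_bv < _BOUNDARY_TOL and "c_pc" in free_names:
        boundary.append("c2_bv")
    if paths.h2_bv < _BOUNDARY_TOL and "a_pc" in free_names:
        boundary.append("h2_bv")

    model = _model_label(drop)
    result = FitResult(
        loglik=-float(best.fun),
        params={
            "paths": {n: float(getattr(paths, n))
                      for n in ("a_c", "c_c", "e_c", "a_pc", "c_pc", "e_pc",
                                "a_s", "c_s", "e_s")},
            "bv_thresholds": cuts.tolist(),
            "sz_threshold": sz_t,
            "fixed_sz": sz,
            "dropped": sorted(drop),
        },
        converged=bool(best.success),
        model=model,
        n_pairs=cells.n_pairs,
        n_singles=cells.n_singles,
        boundary=boundary,
        message=str(best.message),
        n_iter=int(best.nit),
    )
    if ci:
        wanted = free_names if ci is True else [n for n in free_names
                                                if n in set(ci)]
        for name in wanted:
            i = free_names.index(name)
            lo, hi = profile_interval(nll, best.x, i, float(best.fun))
            result.ci[name] = (float(lo), float(hi))
    return result


def _model_label(drop):
    has_a = not {"A_common", "A_specific"} <= drop
    has_c = not {"C_common", "C_specific"} <= drop
    if has_a and has_c:
        return "ACE" if not drop else "ACE-" + "".join(sorted(drop))
    if has_a:
        return "AE"
    if has_c:
        return "CE"
    return "E"


def _paths_from_result(fit):
    return PathCoefficients(**fit.params["paths"])


def standardize(fit):
    """Correlated-factors solution of a converged Cholesky fit.

    Variance proportions are sums of squared paths per component; each
    factor correlation is the cross covariance over the geometric mean of
    the component variances, undefined (``None``) when the trait-side
    component is zero — its r_ph contribution is then exactly zero.
    """
    if not fit.converged:
        raise ConvergenceError("cannot standardize a non-converged fit", fit)
    p = _paths_from_result(fit)
    h2, c2, e2 = p.h2_bv, p.c2_bv, p.e2_bv

    def factor_corr(cross, comp_sz_path, comp_bv):
        if comp_bv <= _DEGENERATE_TOL or comp_sz_path <= 0.0:
            return None
        return float(cross / np.sqrt(comp_bv))

    r_g = factor_corr(p.a_pc, p.a_c, h2)
    r_c = factor_corr(p.c_pc, p.c_c, c2)
    r_e = factor_corr(p.e_pc, p.e_c, e2)
    r_ph_a = p.a_c * p.a_pc
    r_ph_c = p.c_c * p.c_pc
    r_ph_e = p.e_c * p.e_pc
    sol = StandardizedSolution(
        h2_bv=float(h2), c2_bv=float(c2), e2_bv=float(e2),
        r_g=r_g, r_c=r_c, r_e=r_e,
        r_ph=float(r_ph_a + r_ph_c + r_ph_e),
        r_ph_a=float(r_ph_a), r_ph_c=float(r_ph_c), r_ph_e=float(r_ph_e),
        h2_sz=float(p.h2_sz), c2_sz=float(p.c2_sz), e2_sz=float(p.e2_sz),
        boundary=list(fit.boundary),
    )
    return sol.validate()


def decompose_rph(sol):
    """Fractions of the phenotypic correlation carried by each channel.

    Fractions sum to one but are *not* clamped to [0, 1]: when the parts
    have opposite signs an individual share may be negative or exceed one.
    """
    if sol.r_ph == 0.0:
        raise ValueError("r_ph is zero; proportions are undefined")
    return {
        "genetic": sol.r_ph_a / sol.r_ph,
        "common_env": sol.r_ph_c / sol.r_ph,
        "unique_env": sol.r_ph_e / sol.r_ph,
    }


def variance_explained(r_ph):
    """Percent of trait variance associated with the other trait: 100 r^2."""
    if abs(r_ph) > 1.0:
        raise ValueError(f"|r_ph| must be <= 1, got {r_ph}")
    return 100.0 * r_ph * r_ph


def fit_submodel(data, drop, full=None, **kwargs):
    """Refit with the named components fixed at zero and test against ACE.

    Returns ``(FitResult, lrt)`` where ``lrt`` holds -2*dlnL, its degrees
    of freedom (number of dropped paths), the nominal chi-square p-value
    and the boundary caveat.  ``full`` lets a previously fitted full model
    be reused.
    """
    drop = set(drop)
    if full is None:
        full = fit_ace(data, **kwargs)
    reduced = fit_ace(data, drop=drop, **kwargs) if drop else full
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    df_lrt = len(drop)
    pval = float(chi2.sf(stat, df_lrt)) if df_lrt else 1.0
    lrt = {
        "minus2_delta_loglik": float(stat),
        "df": df_lrt,
        "p_value": pval,
        "caveat": LRT_BOUNDARY_CAVEAT if df_lrt else "",
    }
    return reduced, lrt
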
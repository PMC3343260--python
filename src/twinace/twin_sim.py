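"""Synthetic twin cohorts with the covariance structure the analysis assumes.

A bivariate Cholesky ACE model generates latent liabilities for the disease
(Sz) and the quantitative trait (a brain volume, BV) for both members of a
twin pair.  Additive-genetic factors correlate 1 across MZ and 0.5 across
DZ co-twins, common-environmental factors correlate 1 in both, unique-
environmental factors are individual.  Disease status is the liability
dichotomized at the threshold implied by population prevalence.

Ascertainment schemes reproduce how clinical twin samples are actually
assembled: keeping pairs through an affected proband plus control pairs, or
filling the exact per-site cell counts of the consortium's sampling frame
(concordant, discordant and healthy-control pairs, with singletons where
patient and co-twin counts disagree).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import N_BV_CATEGORIES, PREVALENCE, SZ_C2, SZ_E2, SZ_H2
from .exceptions import ExhaustionError, InvariantViolationError
from .liability_core import threshold_from_prevalence

__all__ = [
    "PathCoefficients",
    "SimulationConfig",
    "TwinRecord",
    "implied_cov",
    "simulate_pairs",
    "ascertain",
    "table1_frame",
    "frame_totals",
    "cerebrum_paths",
    "write_twin_csv",
    "read_twin_csv",
]

_TOL = 1e-8
SITES = ("Helsinki", "Jena", "London", "Utrecht")


@dataclass(frozen=True)
class PathCoefficients:
    """The nine paths of the bivariate Cholesky ACE model.

    ``a_c, c_c, e_c`` load the first-trait (disease) factors on disease
    liability; ``a_pc, c_pc, e_pc`` load those same factors on the second
    trait (the cross paths written a', c', e' in the correlated-factors
    picture); ``a_s, c_s, e_s`` are trait-specific.  Both liabilities are
    standardized: the squared paths on each trait sum to one.
    """

    a_c: float
    c_c: float
    e_c: float
    a_pc: float
    c_pc: float
    e_pc: float
    a_s: float
    c_s: float
    e_s: float

    def validate(self, tol=_TOL):
        sz = self.a_c**2 + self.c_c**2 + self.e_c**2
        bv = (self.a_pc**2 + self.c_pc**2 + self.e_pc**2
              + self.a_s**2 + self.c_s**2 + self.e_s**2)
        if abs(sz - 1.0) > tol:
            raise InvariantViolationError(
                f"disease liability variance {sz:.10f} != 1"
            )
        if abs(bv - 1.0) > tol:
            raise InvariantViolationError(
                f"trait variance {bv:.10f} != 1"
            )
        return self

    # standardized (correlated-factors) summaries ------------------------
    @property
    def h2_sz(self):
        return self.a_c**2

    @property
    def c2_sz(self):
        return self.c_c**2

    @property
    def e2_sz(self):
        return self.e_c**2

    @property
    def h2_bv(self):
        return self.a_pc**2 + self.a_s**2

    @property
    def c2_bv(self):
        return self.c_pc**2 + self.c_s**2

    @property
    def e2_bv(self):
        return self.e_pc**2 + self.e_s**2

    @property
    def r_ph(self):
        """Within-person cross-trait (phenotypic liability) correlation."""
        return self.a_c * self.a_pc + self.c_c * self.c_pc + self.e_c * self.e_pc

    @classmethod
    def from_components(cls, h2_bv, c2_bv, e2_bv, r_g=0.0, r_c=0.0, r_e=0.0,
                        h2_sz=SZ_H2, c2_sz=SZ_C2, e2_sz=SZ_E2):
        """Build paths from variance proportions and factor correlations.

        With the disease entered first in the Cholesky order, the cross
        path of each component is ``r * sqrt(comp_bv)`` and the specific
        path ``sqrt(comp_bv * (1 - r^2))``; a zero component forces both
        its paths to zero regardless of the (then meaningless) correlation.
        """
        for name, v in (("h2_bv", h2_bv), ("c2_bv", c2_bv), ("e2_bv", e2_bv),
                        ("h2_sz", h2_sz), ("c2_sz", c2_sz), ("e2_sz", e2_sz)):
            if v < -_TOL or v > 1 + _TOL:
                raise InvariantViolationError(f"{name}={v} outside [0, 1]")
        for name, pair in (("bv", (h2_bv, c2_bv, e2_bv)),
                           ("sz", (h2_sz, c2_sz, e2_sz))):
            if abs(sum(pair) - 1.0) > 1e-6:
                raise InvariantViolationError(
                    f"{name} components sum to {sum(pair)}, not 1"
                )
        for name, r in (("r_g", r_g), ("r_c", r_c), ("r_e", r_e)):
            if abs(r) > 1 + _TOL:
                raise InvariantViolationError(f"{name}={r} outside [-1, 1]")

        def split(comp, r):
            if comp <= 0.0:
                return 0.0, 0.0
            cross = r * np.sqrt(comp)
            spec = np.sqrt(max(comp - cross**2, 0.0))
            return float(cross), float(spec)

        a_pc, a_s = split(h2_bv, r_g)
        c_pc, c_s = split(c2_bv, r_c)
        e_pc, e_s = split(e2_bv, r_e)
        return cls(
            a_c=float(np.sqrt(h2_sz)), c_c=float(np.sqrt(c2_sz)),
            e_c=float(np.sqrt(e2_sz)),
            a_pc=a_pc, c_pc=c_pc, e_pc=e_pc, a_s=a_s, c_s=c_s, e_s=e_s,
        ).validate(tol=1e-6)


def cerebrum_paths():
    """Generating truth for the headline trait (total cerebral volume).

    h2 = .76, c2 = 0, e2 = .24 with genetic correlation -.21; the
    unique-environmental correlation is solved so the within-person
    cross-trait correlation is exactly -.22.
    """
    h2_bv, c2_bv, e2_bv = 0.76, 0.0, 0.24
    r_g = -0.21
    r_ph = -0.22
    r_e = (r_ph - np.sqrt(SZ_H2) * r_g * np.sqrt(h2_bv)) / (
        np.sqrt(SZ_E2) * np.sqrt(e2_bv)
    )
    return PathCoefficients.from_components(
        h2_bv, c2_bv, e2_bv, r_g=r_g, r_c=0.0, r_e=float(r_e)
    )


def implied_cov(paths, zygosity):
    """Model-implied 4x4 covariance over (Sz1, BV1, Sz2, BV2).

    Genetic factors share alpha = 1 (MZ) or 0.5 (DZ) across co-twins;
    common-environment shares fully, unique environment not at all.
    """
    if not isinstance(paths, PathCoefficients):
        paths = PathCoefficients(*paths)
    paths.validate()
    zyg = str(zygosity).upper()
    if zyg == "MZ":
        alpha = 1.0
    elif zyg == "DZ":
        alpha = 0.5
    else:
        raise ValueError(f"unknown zygosity {zygosity!r}; expected MZ or DZ")
    p = paths
    within = p.a_c * p.a_pc + p.c_c * p.c_pc + p.e_c * p.e_pc
    sz_x = alpha * p.a_c**2 + p.c_c**2
    bv_x = alpha * (p.a_pc**2 + p.a_s**2) + (p.c_pc**2 + p.c_s**2)
    cross = alpha * p.a_c * p.a_pc + p.c_c * p.c_pc
    return np.array(
        [
            [1.0, within, sz_x, cross],
            [within, 1.0, cross, bv_x],
            [sz_x, cross, 1.0, within],
            [cross, bv_x, within, 1.0],
        ]
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort."""

    n_mz_pairs: int
    n_dz_pairs: int
    prevalence: float = PREVALENCE
    n_bv_categories: int = N_BV_CATEGORIES
    seed: int = 0
    ascertainment_scheme: str = "population"
    #: optional linear confounding of the *observed* trait by covariates,
    #: e.g. {"helsinki": 0.3, "age": -0.01}; empty means the observed value
    #: is the latent liability itself
    covariate_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise InvariantViolationError(
                f"prevalence must lie in (0, 1), got {self.prevalence}"
            )
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise InvariantViolationError("pair counts must be >= 0")
        if self.n_bv_categories < 2:
            raise InvariantViolationError("need at least 2 ordinal classes")
        if self.ascertainment_scheme not in (
            "population", "proband_plus_controls", "table1_frame"
        ):
            raise InvariantViolationError(
                f"unknown ascertainment scheme {self.ascertainment_scheme!r}"
            )


@dataclass
class TwinRecord:
    """One individual; the canonical collection is a long-format DataFrame."""

    pair_id: str
    zygosity: str
    member: int
    affected: int
    bv_continuous: float
    bv_category: int | None
    site: str
    sex: str
    age: float
    icv: float

    @classmethod
    def from_row(cls, row):
        cat = row.get("bv_cat")
        return cls(
            pair_id=row["pair_id"], zygosity=row["zygosity"],
            member=int(row["member"]), affected=int(row["affected"]),
            bv_continuous=float(row["bv"]),
            bv_category=None if pd.isna(cat) else int(cat),
            site=row["site"], sex=row["sex"],
            age=float(row["age"]), icv=float(row["icv"]),
        )


#: CSV column order of the long twin format
CSV_COLUMNS = ["pair_id", "zygosity", "member", "affected", "bv", "bv_cat",
               "site", "sex", "age", "icv"]

# Table-1 site totals drive the site mix of simulated cohorts
_SITE_WEIGHTS = np.array([186, 38, 132, 328]) / 684.0


def _simulate_zygosity(paths, zyg, n_pairs, prefix, rng, config, threshold):
    if n_pairs == 0:
        return pd.DataFrame(columns=CSV_COLUMNS + ["liab_sz", "liab_bv", "group"])
    cov = implied_cov(paths, zyg)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_pairs, 4)) @ chol.T  # (Sz1, BV1, Sz2, BV2)

    site = rng.choice(SITES, size=n_pairs, p=_SITE_WEIGHTS)
    sex = rng.choice(["F", "M"], size=n_pairs)
    age = np.clip(rng.normal(38.0, 11.3, size=n_pairs), 18.0, 70.0)
    icv = rng.normal(1450.0, 120.0, size=(n_pairs, 2))

    rows = []
    eff = config.covariate_effects
    for member in (1, 2):
        liab_sz = z[:, 0 if member == 1 else 2]
        liab_bv = z[:, 1 if member == 1 else 3]
        bv = liab_bv.copy()
        if eff:
            bv = bv + eff.get("helsinki", 0.0) * (site == "Helsinki")
            bv = bv + eff.get("sex_male", 0.0) * (sex == "M")
            bv = bv + eff.get("age", 0.0) * age
            bv = bv + eff.get("icv", 0.0) * icv[:, member - 1]
        rows.append(pd.DataFrame({
            "pair_id": [f"{prefix}{i:06d}" for i in range(n_pairs)],
            "zygosity": zyg,
            "member": member,
            "affected": (liab_sz > threshold).astype(int),
            "bv": bv,
            "bv_cat": np.nan,
            "site": site,
            "sex": sex,
            "age": age,
            "icv": icv[:, member - 1],
            "liab_sz": liab_sz,
            "liab_bv": liab_bv,
        }))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["pair_id", "member"], ignore_index=True)


def simulate_pairs(paths, config):
    """Draw a population cohort of twin pairs under the generating model.

    Latent (Sz, BV) liabilities per pair come from the zygosity-appropriate
    4-variate normal of ``implied_cov``; disease status is the liability
    exceeding the prevalence threshold.  Deterministic given
    ``config.seed`` (one numpy default_rng / PCG64 generator per call).
    Latent truth columns (``liab_sz``, ``liab_bv``) are retained for
    recovery tests; writers drop them.
    """
    rng = np.random.default_rng(config.seed)
    threshold = threshold_from_prevalence(config.prevalence)
    mz = _simulate_zygosity(paths, "MZ", config.n_mz_pairs, "mz", rng,
                            config, threshold)
    dz = _simulate_zygosity(paths, "DZ", config.n_dz_pairs, "dz", rng,
                            config, threshold)
    parts = [d for d in (mz, dz) if len(d)]
    if not parts:
        return mz
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# ascertainment


def table1_frame():
    """Per-site individual counts of the consortium sampling frame.

    Rows are (zygosity, group) cells, columns sites.  ``concordant`` and
    ``control`` rows count individuals (an odd count implies a singleton);
    the discordant rows count patients and co-twins separately — where the
    two disagree, the surplus individuals enter as singletons from
    discordant pairs.
    """
    data = {
        ("MZ", "concordant"):        [13, 0, 38, 0],
        ("MZ", "discordant_patient"): [14, 11, 14, 13],
        ("MZ", "discordant_cotwin"): [15, 11, 17, 13],
        ("MZ", "control"):           [48, 16, 53, 134],
        ("DZ", "concordant"):        [0, 0, 0, 0],
        ("DZ", "discordant_patient"): [23, 0, 3, 13],
        ("DZ", "discordant_cotwin"): [23, 0, 3, 13],
        ("DZ", "control"):           [50, 0, 4, 142],
    }
    frame = pd.DataFrame.from_dict(data, orient="index", columns=list(SITES))
    frame.index = pd.MultiIndex.from_tuples(frame.index,
                                            names=["zygosity", "group"])
    return frame


def frame_totals(frame):
    """Headline totals of an ascertainment frame."""
    by_zyg = frame.sum(axis=1).groupby("zygosity").sum()
    affected = frame.xs("concordant", level="group").sum().sum() + \
        frame.xs("discordant_patient", level="group").sum().sum()
    return {
        "total": int(frame.sum().sum()),
        "mz": int(by_zyg.get("MZ", 0)),
        "dz": int(by_zyg.get("DZ", 0)),
        "affected": int(affected),
    }


def _classify_pairs(df):
    """Pair-level view: pair_id, zygosity, n_affected, member ids."""
    grp = df.groupby("pair_id", sort=False)
    info = grp.agg(
        zygosity=("zygosity", "first"),
        n_affected=("affected", "sum"),
        n_members=("member", "count"),
    ).reset_index()
    return info


def _take(pool, n, cell):
    if len(pool) < n:
        raise ExhaustionError(cell, needed=n, available=len(pool))
    taken = pool[:n]
    del pool[:n]
    return taken


def _fill_from_frame(df, frame, rng):
    info = _classify_pairs(df)
    pools = {}
    for zyg in ("MZ", "DZ"):
        sub = info[(info["zygosity"] == zyg) & (info["n_members"] == 2)]
        for grp_name, mask in (
            ("concordant", sub["n_affected"] == 2),
            ("discordant", sub["n_affected"] == 1),
            ("control", sub["n_affected"] == 0),
        ):
            ids = sub.loc[mask, "pair_id"].tolist()
            rng.shuffle(ids)
            pools[(zyg, grp_name)] = ids

    by_pair = {pid: g for pid, g in df.groupby("pair_id", sort=False)}
    pieces = []

    def emit(pair_ids, site, group, keep="both"):
        for pid in pair_ids:
            g = by_pair[pid].copy()
            if keep == "affected":
                g = g[g["affected"] == 1]
            elif keep == "unaffected":
                g = g[g["affected"] == 0]
            g["site"] = site
            g["group"] = group
            pieces.append(g)

    for zyg in ("MZ", "DZ"):
        for si, site in enumerate(frame.columns):
            conc = int(frame.loc[(zyg, "concordant"), site])
            pairs, single = divmod(conc, 2)
            emit(_take(pools[(zyg, "concordant")], pairs,
                       (zyg, "concordant", site)), site, "concordant")
            if single:
                emit(_take(pools[(zyg, "concordant")], 1,
                           (zyg, "concordant", site)), site, "concordant",
                     keep="affected")
                # keep exactly one affected member of that pair
                pieces[-1] = pieces[-1].iloc[:1]

            pt = int(frame.loc[(zyg, "discordant_patient"), site])
            co = int(frame.loc[(zyg, "discordant_cotwin"), site])
            full = min(pt, co)
            emit(_take(pools[(zyg, "discordant")], full,
                       (zyg, "discordant", site)), site, "discordant")
            emit(_take(pools[(zyg, "discordant")], pt - full,
                       (zyg, "discordant", site)), site, "discordant",
                 keep="affected")
            emit(_take(pools[(zyg, "discordant")], co - full,
                       (zyg, "discordant", site)), site, "discordant",
                 keep="unaffected")

            hc = int(frame.loc[(zyg, "control"), site])
            pairs, single = divmod(hc, 2)
            emit(_take(pools[(zyg, "control")], pairs,
                       (zyg, "control", site)), site, "control")
            if single:
                emit(_take(pools[(zyg, "control")], 1,
                           (zyg, "control", site)), site, "control")
                pieces[-1] = pieces[-1].iloc[:1]

    out = pd.concat(pieces, ignore_index=True)
    return out


def ascertain(records, scheme, seed=None, frame=None, n_control_pairs=None,
              control_ratio=None):
    """Select twin pairs the way a clinical twin study is assembled.

    ``population`` returns the records unchanged.  ``proband_plus_controls``
    keeps every pair containing an affected member plus control pairs —
    ``n_control_pairs`` explicit, or ``control_ratio`` control pairs per
    case pair (default: the case:control pair ratio of the bundled
    sampling frame, ~1.9).  ``table1_frame`` fills the per-site cell counts
    of ``frame`` (default: the bundled frame) by consuming randomly-ordered
    pairs of the right kind; selection never splits a pair except where the
    frame itself implies singletons.
    """
    df = pd.DataFrame(records)
    rng = np.random.default_rng(seed)
    if scheme == "population":
        return df.copy()
    if scheme == "proband_plus_controls":
        info = _classify_pairs(df)
        case_ids = info.loc[info["n_affected"] > 0, "pair_id"]
        control_ids = info.loc[
            (info["n_affected"] == 0) & (info["n_members"] == 2), "pair_id"
        ].tolist()
        if n_control_pairs is None:
            if control_ratio is None:
                control_ratio = _default_control_ratio()
            n_control_pairs = int(round(control_ratio * len(case_ids)))
        n_control_pairs = min(n_control_pairs, len(control_ids))
        rng.shuffle(control_ids)
        keep = set(case_ids) | set(control_ids[:n_control_pairs])
        return df[df["pair_id"].isin(keep)].reset_index(drop=True)
    if scheme == "table1_frame":
        if frame is None:
            frame = table1_frame()
        return _fill_from_frame(df, frame, rng)
    raise ValueError(f"unknown ascertainment scheme {scheme!r}")


def _default_control_ratio():
    frame = table1_frame()
    case_pairs = 0.0
    control_pairs = 0.0
    for zyg in ("MZ", "DZ"):
        case_pairs += frame.loc[(zyg, "concordant")].sum() / 2.0
        case_pairs += frame.loc[(zyg, "discordant_patient")].sum()
        control_pairs += frame.loc[(zyg, "control")].sum() / 2.0
    return control_pairs / case_pairs


# ---------------------------------------------------------------------------
# long-format CSV round trip


def write_twin_csv(df, path, params=None):
    """Write the long twin format; a JSON sidecar records provenance."""
    path = Path(path)
    out = pd.DataFrame(df).reindex(columns=CSV_COLUMNS)
    out.to_csv(path, index=False, na_rep="")
    if params is not None:
        if isinstance(params, SimulationConfig):
            params = asdict(params)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(params, indent=2, sort_keys=True, default=str) + "\n"
        )
    return path


def read_twin_csv(path):
    """Read the long twin format; returns (DataFrame, sidecar params or None)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"pair_id": str, "zygosity": str,
                                  "site": str, "sex": str})
    sidecar = path.with_suffix(path.suffix + ".json")
    params = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return df, params
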
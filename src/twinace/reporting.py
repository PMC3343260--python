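"""Pipeline orchestration and publication-shaped tables.

``run_pipeline`` chains simulate -> prep -> polychoric -> fit under one
config and emits a sample-description table, a correlation table, a
model-fit table and a machine-readable JSON carrying every estimate plus
full provenance (config hash, seed, version).  Reruns with the same config
and seed reproduce every output byte-identically: all randomness flows
from the single seed and every integration rule is fixed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biometric_model import decompose_rph, fit_ace, fit_submodel, standardize
from .constants import N_BV_CATEGORIES, PREVALENCE, SZ_C2, SZ_E2, SZ_H2
from .exceptions import IncompleteResultsError
from .liability_core import fit_structure
from .preprocess import DEFAULT_COVARIATES, prepare
from .twin_sim import (
    PathCoefficients,
    SimulationConfig,
    ascertain,
    cerebrum_paths,
    simulate_pairs,
    write_twin_csv,
)

__all__ = ["PipelineConfig", "run_pipeline", "format_table", "demo_config"]

log = logging.getLogger("twinace")


@dataclass
class PipelineConfig:
    """One reproducible analysis run.

    Either ``input_path`` points at an existing long-format twin CSV, or
    ``simulation`` describes a cohort to generate: pair counts, generating
    variance components / factor correlations, and an ascertainment
    scheme.  CLI flags override config-file values (flag > file > default).
    """

    seed: int = 0
    prevalence: float = PREVALENCE
    k: int = N_BV_CATEGORIES
    fixed_sz: dict = field(default_factory=lambda: {
        "h2": SZ_H2, "c2": SZ_C2, "e2": SZ_E2,
    })
    models: list = field(default_factory=lambda: ["ACE", "AE"])
    out_dir: str = "twinace_out"
    log_level: str = "INFO"
    ci: bool = False
    covariates: tuple = DEFAULT_COVARIATES
    input_path: str | None = None
    simulation: dict | None = None

    @classmethod
    def from_file(cls, path):
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
            else json.loads(text)
        return cls(**data)

    def to_dict(self):
        d = asdict(self)
        d["covariates"] = list(self.covariates)
        return d

    def digest(self):
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def demo_config(out_dir="twinace_out", seed=1):
    """The bundled demonstration: consortium sampling frame filled from a
    cohort generated under the cerebrum truth."""
    return PipelineConfig(
        seed=seed,
        out_dir=out_dir,
        simulation={
            "n_mz_pairs": 40000,
            "n_dz_pairs": 25000,
            "components": None,  # None -> cerebrum generating model
            "scheme": "table1_frame",
        },
    )


def _paths_from_sim_block(sim):
    comp = sim.get("components")
    if comp is None:
        return cerebrum_paths()
    if isinstance(comp, dict):
        return PathCoefficients.from_components(
            comp["h2_bv"], comp["c2_bv"], comp["e2_bv"],
            r_g=comp.get("r_g", 0.0), r_c=comp.get("r_c", 0.0),
            r_e=comp.get("r_e", 0.0),
        )
    return PathCoefficients(*comp).validate()


def _sample_description(df):
    """Table-1-shaped counts: individuals, mean age and sex mix per cell."""
    df = df.copy()
    if "group" not in df.columns:
        n_aff = df.groupby("pair_id")["affected"].transform("sum")
        df["group"] = np.where(
            n_aff == 2, "concordant",
            np.where(n_aff == 1, "discordant", "control"),
        )
    rows = []
    for (zyg, grp, site), g in df.groupby(["zygosity", "group", "site"]):
        rows.append({
            "zygosity": zyg, "group": grp, "site": site,
            "n": len(g),
            "n_affected": int(g["affected"].sum()),
            "mean_age": round(float(g["age"].mean()), 2)
            if "age" in g else float("nan"),
            "n_female": int((g["sex"] == "F").sum()) if "sex" in g else 0,
            "n_male": int((g["sex"] == "M").sum()) if "sex" in g else 0,
        })
    return pd.DataFrame(rows).sort_values(
        ["zygosity", "group", "site"], ignore_index=True
    )


def _num(x):
    if x is None:
        return None
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(config):
    """Execute the full analysis; returns the report bundle as a dict.

    Any stage failure aborts with the stage name; outputs written before
    the failure stay on disk.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out_dir / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.info(
        "fixed constants: sz h2=%.2f c2=%.2f e2=%.2f; r_sz mz=%.2f dz=%.3f; "
        "prevalence=%g", config.fixed_sz["h2"], config.fixed_sz["c2"],
        config.fixed_sz["e2"],
        config.fixed_sz["h2"] + config.fixed_sz["c2"],
        0.5 * config.fixed_sz["h2"] + config.fixed_sz["c2"],
        config.prevalence,
    )
    from . import __version__
    bundle = {"provenance": {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
    }}
    stage = "load"
    try:
        if config.simulation is not None:
            stage = "simulate"
            sim = dict(config.simulation)
            paths = _paths_from_sim_block(sim)
            sim_cfg = SimulationConfig(
                n_mz_pairs=int(sim.get("n_mz_pairs", 5000)),
                n_dz_pairs=int(sim.get("n_dz_pairs", 5000)),
                prevalence=config.prevalence,
                n_bv_categories=config.k,
                seed=config.seed,
                ascertainment_scheme=sim.get("scheme", "population"),
                covariate_effects=sim.get("covariate_effects", {}) or {},
            )
            df = simulate_pairs(paths, sim_cfg)
            if sim_cfg.ascertainment_scheme != "population":
                df = ascertain(df, sim_cfg.ascertainment_scheme,
                               seed=config.seed + 1)
            write_twin_csv(df, out_dir / "data.csv", params=sim_cfg)
        else:
            stage = "load"
            from .twin_sim import read_twin_csv
            if config.input_path is None:
                raise ValueError("config needs input_path or simulation")
            df, _ = read_twin_csv(config.input_path)

        stage = "sample_description"
        sample = _sample_description(df)
        sample.to_csv(out_dir / "table1_sample.csv", index=False)
        bundle["sample"] = sample.to_dict(orient="records")

        stage = "prep"
        covs = tuple(config.covariates) if config.covariates else ()
        df, spec, coef = prepare(df, k=config.k, covariates=covs)
        (out_dir / "ordinal_spec.json").write_text(
            json.dumps(spec.to_dict(), indent=2) + "\n"
        )

        stage = "polychoric"
        struct, thr, corr_fit = fit_structure(
            df, prevalence=config.prevalence, n_categories=config.k,
            ci=config.ci,
        )
        bundle["polychoric"] = {
            "estimates": {n: _num(getattr(struct, n))
                          for n in struct._FREE},
            "fixed": {"r_sz_mz": struct.r_sz_mz, "r_sz_dz": struct.r_sz_dz},
            "ci": _jsonable(struct.ci),
            "loglik": corr_fit.loglik,
            "converged": corr_fit.converged,
            "bv_thresholds": thr.bv_thresholds.tolist(),
        }
        format_table(bundle["polychoric"], "table2").to_csv(
            out_dir / "table2_correlations.csv", index=False
        )

        stage = "fit"
        bundle["models"] = {}
        full = None
        for model in config.models:
            name = str(model).upper()
            if name == "ACE":
                fit = fit_ace(df, prevalence=config.prevalence,
                              fixed_sz=config.fixed_sz, ci=config.ci)
                full = fit
                lrt = None
            elif name == "AE":
                fit, lrt = fit_submodel(
                    df, {"C_common", "C_specific"}, full=full,
                    prevalence=config.prevalence, fixed_sz=config.fixed_sz,
                    ci=config.ci,
                )
            else:
                raise ValueError(f"unknown model {model!r}")
            sol = standardize(fit)
            entry = {
                "loglik": fit.loglik,
                "converged": fit.converged,
                "paths": fit.params["paths"],
                "ci": _jsonable(fit.ci),
                "boundary": fit.boundary,
                "standardized": {
                    k: _num(getattr(sol, k))
                    for k in ("h2_bv", "c2_bv", "e2_bv", "r_g", "r_c", "r_e",
                              "r_ph", "r_ph_a", "r_ph_c", "r_ph_e")
                },
            }
            if sol.r_ph != 0.0:
                entry["rph_decomposition"] = _jsonable(decompose_rph(sol))
            if lrt is not None:
                entry["lrt_vs_full"] = _jsonable(lrt)
            bundle["models"][name] = entry
        if "ACE" in bundle["models"]:
            format_table(bundle["models"]["ACE"], "table3").to_csv(
                out_dir / "table3_model.csv", index=False
            )

        stage = "write"
        (out_dir / "results.json").write_text(
            json.dumps(_jsonable(bundle), indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        log.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
    return bundle


# ---------------------------------------------------------------------------
# formatting


def _fmt(x, decimals=2):
    """Paper-style number: 2 decimals, no leading zero, no signed zero."""
    if x is None:
        return "NA"
    v = round(float(x), decimals)
    if v == 0.0:
        v = 0.0  # normalize -0.0
    s = f"{v:.{decimals}f}"
    return s.replace("-0.", "-.").removeprefix("0")


def _fmt_ci(ci):
    if not ci or ci[0] is None or ci[1] is None:
        return ""
    return f"({_fmt(ci[0])} to {_fmt(ci[1])})"


def _excludes_zero(ci):
    return bool(ci) and ci[0] is not None and ci[1] is not None and (
        (ci[0] > 0 and ci[1] > 0) or (ci[0] < 0 and ci[1] < 0)
    )


def format_table(results, style):
    """Render a results block in the journal layout of the matching table.

    ``table1``: sample description; ``table2``: the five estimated
    polychoric correlations (fixed disease-side correlations footnoted);
    ``table3``: standardized variance components and factor correlations,
    a ``*`` marking estimates whose 95% CI excludes zero.
    """
    if style == "table1":
        df = pd.DataFrame(results)
        need = {"zygosity", "group", "site", "n"}
        if not need <= set(df.columns):
            raise IncompleteResultsError(
                f"table1 needs columns {sorted(need)}"
            )
        return df
    if style == "table2":
        try:
            est = results["estimates"]
            ci = results.get("ci", {})
            row = {}
            for name in ("r_within", "r_bv_mz", "r_bv_dz",
                         "r_cross_mz", "r_cross_dz"):
                mark = "*" if _excludes_zero(ci.get(name)) else ""
                row[name] = f"{_fmt(est[name])}{mark} {_fmt_ci(ci.get(name))}".strip()
            row["r_sz_mz_fixed"] = _fmt(results["fixed"]["r_sz_mz"])
            row["r_sz_dz_fixed"] = f'{results["fixed"]["r_sz_dz"]:.3f}'.removeprefix("0")
        except KeyError as exc:
            raise IncompleteResultsError(f"table2 missing field {exc}") from exc
        return pd.DataFrame([row])
    if style == "table3":
        try:
            std = results["standardized"]
            ci = results.get("ci", {})
            row = {}
            for name in ("h2_bv", "c2_bv", "e2_bv", "r_g", "r_c", "r_e",
                         "r_ph"):
                mark = "*" if _excludes_zero(ci.get(name)) else ""
                row[name] = f"{_fmt(std[name])}{mark} {_fmt_ci(ci.get(name))}".strip()
        except KeyError as exc:
            raise IncompleteResultsError(f"table3 missing field {exc}") from exc
        return pd.DataFrame([row])
    raise ValueError(f"unknown table style {style!r}")
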
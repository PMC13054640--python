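"""End-to-end orchestration: classify -> metrics -> stability -> models -> SEM.

A run is driven by one YAML/dict config naming the input tables (monthly
climate or a precomputed SPEI extract, biomass, composition), the
classification thresholds, the SPEI scale (fixed or screened), and the
output directory.  All tabular I/O is tidy CSV; a JSON manifest records
row counts in and out of every stage with itemized exclusions, so the
accounting inputs = outputs + exclusions can be audited.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, lmm, sem, spei, stability

__all__ = ["RunConfig", "load_config", "validate_config", "run_pipeline"]

DEFAULTS = {
    "thresholds": {"extreme": 1.28, "normal": 0.67},
    "spei": {"scale": 9, "target_month": 8, "screen_scales": None, "quadratic": True},
    "models": {"select": False, "alpha": 0.05, "strength_model": False},
    "sem": {"enabled": True},
    "sensitivity": {"unit": None},
    "seed": 0,
}


class RunConfig(dict):
    """Validated pipeline configuration (a dict with defaults filled in)."""


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _merge_defaults(raw, Path(path).parent)


def _merge_defaults(raw: dict, base: Path | None = None) -> RunConfig:
    cfg = RunConfig()
    for key, val in DEFAULTS.items():
        if isinstance(val, dict):
            cfg[key] = {**val, **raw.get(key, {})}
        else:
            cfg[key] = raw.get(key, val)
    cfg["inputs"] = dict(raw.get("inputs", {}))
    cfg["output_dir"] = raw.get("output_dir", "results")
    if base is not None:
        for k, v in cfg["inputs"].items():
            p = Path(v)
            cfg["inputs"][k] = str(p if p.is_absolute() else base / p)
        out = Path(cfg["output_dir"])
        cfg["output_dir"] = str(out if out.is_absolute() else base / out)
    return cfg


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of problems; empty means the config is runnable."""
    problems = []
    th = cfg["thresholds"]
    if not (th["extreme"] > th["normal"] > 0):
        problems.append("thresholds must satisfy extreme > normal > 0")
    inputs = cfg.get("inputs", {})
    if "biomass" not in inputs or "composition" not in inputs:
        problems.append("inputs must name biomass and composition files")
    if "climate" not in inputs and "spei" not in inputs:
        problems.append("inputs must name either climate or a precomputed spei file")
    for key, path in inputs.items():
        if not Path(path).exists():
            problems.append(f"input {key!r}: file not found: {path}")
    return problems


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, write: bool = True) -> dict:
    """Execute the full analysis; returns {tables, fits, manifest}.

    Stage order: SPEI (computed from climate or loaded precomputed) ->
    event catalog -> composition cleaning and community properties ->
    stability and LRR tables -> resistance/resilience and LRR mixed models
    (with Tukey-adjusted cell contrasts) -> multigroup path model ->
    optional leave-one-out sensitivity.  A stage failure retains the
    outputs produced so far and records the failure point in the manifest.
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(cfg["output_dir"])
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(cfg), "stages": {}, "failure": None}
    tables: dict[str, pd.DataFrame] = {}
    fits: dict = {}

    def _stage(name):
        manifest["stages"][name] = {"t_start": time.time()}
        return manifest["stages"][name]

    def _done(st, **counts):
        st["seconds"] = round(time.time() - st.pop("t_start"), 3)
        st.update(counts)

    try:
        st = _stage("spei")
        if "spei" in cfg["inputs"]:
            spei_df = spei.read_precomputed_spei(
                cfg["inputs"]["spei"], scale=cfg["spei"]["scale"],
                month=cfg["spei"]["target_month"],
            )
        else:
            climate = pd.read_csv(cfg["inputs"]["climate"]).rename(
                columns={"precip_mm": "precip", "pet_mm": "pet"}
            )
            spei_df = spei.compute_spei(
                climate, cfg["spei"]["scale"], target_month=cfg["spei"]["target_month"]
            )
        tables["spei"] = spei_df
        _done(st, rows_out=len(spei_df))

        st = _stage("event_catalog")
        catalog = stability.classify_years(
            spei_df, extreme=cfg["thresholds"]["extreme"], normal=cfg["thresholds"]["normal"]
        )
        tables["event_catalog"] = catalog
        _done(st, rows_in=len(spei_df), rows_out=len(catalog),
              excluded_missing_spei=int(len(spei_df) - len(catalog)))

        st = _stage("community_properties")
        comp = pd.read_csv(cfg["inputs"]["composition"])
        clean, excluded = community.clean_composition(comp)
        props = community.community_properties(clean)
        tables["community_properties"] = props
        _done(st, rows_in=len(comp), rows_out=len(clean),
              excluded_plot_years=len(excluded))

        st = _stage("stability_table")
        biomass = pd.read_csv(cfg["inputs"]["biomass"]).rename(
            columns={"biomass_g_m2": "biomass"}
        )
        stab, excl = stability.build_stability_table(biomass, catalog, props)
        stab["experiment_uid"] = stab["site"].astype(str) + ":" + stab["experiment"].astype(str)
        stab["plot_uid"] = stab["experiment_uid"] + ":" + stab["plot"].astype(str)
        stab["year"] = stab["event_year"]
        tables["stability"] = stab
        _done(st, rows_out=len(stab), exclusions=excl)

        st = _stage("lrr_table")
        lrr, excl_lrr = stability.build_lrr_table(biomass, catalog, props)
        lrr["experiment_uid"] = lrr["site"].astype(str) + ":" + lrr["experiment"].astype(str)
        lrr["plot_uid"] = lrr["experiment_uid"] + ":" + lrr["plot"].astype(str)
        lrr["year"] = lrr["event_year"]
        tables["lrr"] = lrr
        _done(st, rows_out=len(lrr), exclusions=excl_lrr)

        st = _stage("stability_models")
        res = lmm.fit_stability_models(
            stab, select=cfg["models"]["select"], alpha=cfg["models"]["alpha"]
        )
        fits["stability_models"] = res
        tidy = []
        for (resp, etype), fit in res["fits"].items():
            t = fit.tidy()
            t.insert(0, "model", f"{resp}_{etype}")
            tidy.append(t)
        tables["stability_coefficients"] = (
            pd.concat(tidy, ignore_index=True) if tidy else pd.DataFrame()
        )
        _done(st, models=len(res["fits"]), flags=res["flags"])

        st = _stage("lrr_models")
        lres = lmm.fit_lrr_models(lrr, strength_model=cfg["models"]["strength_model"])
        fits["lrr_models"] = lres
        cells = []
        for metric, tbl in lres["cells"].items():
            t = tbl.copy()
            t.insert(0, "metric", metric)
            cells.append(t)
        tables["lrr_cells"] = pd.concat(cells, ignore_index=True) if cells else pd.DataFrame()
        contrasts = []
        for metric, tbl in lres["contrasts"].items():
            t = tbl.copy()
            t.insert(0, "metric", metric)
            contrasts.append(t)
        tables["lrr_contrasts"] = (
            pd.concat(contrasts, ignore_index=True) if contrasts else pd.DataFrame()
        )
        _done(st, metrics=len(lres["cells"]), flags=lres["flags"])

        if cfg["sem"]["enabled"]:
            st = _stage("path_model")
            sem_data = _sem_frame(stab)
            if len(sem_data) >= 30:
                diagram = sem.default_diagram()
                pf = sem.fit_path_model(diagram, sem_data, vc_factors=["experiment_uid", "plot_uid"])
                fits["path_model"] = pf
                tables["sem_edges"] = pf.edges
                tables["sem_claims"] = pf.claims
                tables["sem_effects"] = sem.standardized_effects(pf)
                _done(st, rows_in=len(sem_data), fishers_c=pf.fishers_c,
                      df=pf.df, p=pf.p_value, flags=pf.flags)
            else:
                _done(st, rows_in=len(sem_data), skipped="too few complete rows")

        if cfg["sensitivity"]["unit"]:
            st = _stage("sensitivity")
            unit = cfg["sensitivity"]["unit"]
            df = lmm._prepare_stability(stab, "resistance")
            df["event_type"] = (df["event_type"] == "extreme_wet").astype(int)
            sens = lmm.sensitivity_leave_one_out(
                "y ~ richness + dominance + evenness + event_type + treatment",
                df, unit={"site": "site", "event_year": "year"}[unit],
            )
            tables["sensitivity"] = sens
            _done(st, refits=sens["omitted"].nunique() - 1)
    except Exception as exc:  # noqa: BLE001 - partial outputs retained
        manifest["failure"] = f"{type(exc).__name__}: {exc}"

    if write:
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    if manifest["failure"]:
        raise RuntimeError(
            f"pipeline failed at a stage ({manifest['failure']}); partial outputs "
            f"written to {outdir}" if write else manifest["failure"]
        )
    return {"tables": tables, "fits": fits, "manifest": manifest}


def _sem_frame(stab: pd.DataFrame) -> pd.DataFrame:
    df = stab.copy()
    df["nutrients"] = (df["treatment"] == "nutrient").astype(float)
    df["event_strength"] = df["spei_strength"]
    df = df.rename(
        columns={
            "prior_richness": "richness",
            "prior_dominance": "dominance",
            "prior_evenness": "evenness",
        }
    )
    df["resistance"] = np.log(df["resistance"])
    df["resilience"] = np.log(df["resilience"])
    keep = ["nutrients", "richness", "dominance", "evenness", "event_strength",
            "resistance", "resilience", "event_type", "experiment_uid", "plot_uid"]
    return df[keep].replace([np.inf, -np.inf], np.nan).dropna().reset_index(drop=True)
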
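"""Synthetic multi-site grassland data with known ground truth.

Emulates the structure the analysis assumes: several sites, each with
nested experiments holding paired control/nutrient-addition plots observed
over decades; monthly precipitation and PET series from which a k-month
SPEI drives interannual biomass variation; plot communities with a
persistent dominant species, fewer species and higher dominance under
nutrient addition; and event-year biomass excursions whose magnitude and
recovery follow linear models in the (z-scored) prior-year community
properties, so the stability pipeline has exact generating coefficients to
recover.

The event-year machinery works backwards from the stability statistics:
ln(resistance) and ln(resilience) are drawn from the generating linear
models and event-year / following-year biomass are then solved from
    Omega = Ybar_n / |Y_e - Ybar_n|,   Delta = |Y_e - Ybar_n| / |Y_e+1 - Ybar_n|
which makes the mapping from generator coefficients to fitted standardized
coefficients the identity (up to sampling noise).  Default effect sizes
mirror the magnitudes and signs reported for mesic-grassland stability
(richness buffers dry events, dominance buffers wet events, evenness aids
recovery in unfertilized plots, nutrients reduce richness and raise
dominance).

One RNG stream per stage, all derived from the master seed, so stages can
be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .community import clean_composition, community_properties
from .spei import compute_spei
from .stability import classify_years

__all__ = ["GeneratorConfig", "SyntheticBundle", "generate_climate",
           "generate_communities", "generate_biomass", "generate_all"]


def _default_resistance_effects() -> dict:
    return {
        "dry": {"intercept": 1.67, "richness": 0.12, "dominance": -0.01,
                "evenness": 0.03, "nutrient": -0.19},
        "wet": {"intercept": 1.43, "richness": 0.02, "dominance": 0.06,
                "evenness": 0.006, "nutrient": -0.184},
    }


def _default_resilience_effects() -> dict:
    return {
        "dry": {"intercept": 0.87, "richness": -0.18, "dominance": -0.07,
                "evenness": 0.36, "nutrient": -0.53,
                "dominance_x_nutrient": 0.09, "evenness_x_nutrient": -0.42},
        "wet": {"intercept": 0.126, "richness": -0.08, "dominance": 0.05,
                "evenness": 0.04, "nutrient": 0.15,
                "dominance_x_nutrient": -0.25, "evenness_x_nutrient": -0.09},
    }


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic generator.

    Sizes default to desk scale (3 sites x 2 experiments x 30 paired plots
    x 40 years, ~7k plot-years).  ``resistance_effects`` /
    ``resilience_effects`` are the generating coefficient tables per event
    type on z-scored prior-year predictors (binary nutrient left 0/1);
    community effects are on the raw scales (species counts, Dirichlet
    weights).
    """

    seed: int = 0
    n_sites: int = 3
    n_experiments_per_site: int = 2
    n_plots: int = 30  # per experiment; even, half control / half nutrient
    years: int = 40
    start_year: int = 1980

    # climate
    precip_base: float = 75.0  # mm/month annual-mean level
    precip_seasonality: float = 0.5
    precip_shape: float = 4.0  # gamma shape; sd = mean / sqrt(shape)
    pet_base: float = 80.0
    pet_seasonality: float = 0.6
    pet_noise: float = 3.0
    spei_driver_scale: int = 9
    target_month: int = 8

    # community
    site_pool_size: int = 24
    presence_prob: float = 0.55
    nutrient_richness_effect: float = -1.2  # expected species-count change
    dominance_concentration: float = 6.0  # dominant's Dirichlet weight
    nutrient_dominance_boost: float = 0.12  # relative weight increase
    dominant_weight_jitter: float = 0.30  # lognormal sd across plots
    evenness_heterogeneity: float = 0.50  # lognormal sd of subordinate conc.
    nonplant_rate: float = 0.3

    # biomass
    ln_baseline: float = 5.86  # ~350 g m^-2
    sd_site: float = 0.15
    sd_experiment: float = 0.10
    sd_plot: float = 0.20
    sd_year: float = 0.05
    sd_resid: float = 0.10
    beta_spei: float = 0.15  # ln-biomass response per unit SPEI

    # stability ground truth (z-scored predictors; see class docstring)
    resistance_effects: dict = field(default_factory=_default_resistance_effects)
    resilience_effects: dict = field(default_factory=_default_resilience_effects)
    sd_ln_resistance: float = 0.50
    sd_ln_resilience: float = 0.60
    sd_event_site_year: float = 0.15  # shared event-level intercept
    sd_event_plot: float = 0.10  # persistent plot-level stability intercept

    def null(self) -> "GeneratorConfig":
        """Copy with every stability effect (except intercepts) zeroed."""
        import copy

        cfg = copy.deepcopy(self)
        for table in (cfg.resistance_effects, cfg.resilience_effects):
            for etype in table:
                for term in table[etype]:
                    if term != "intercept":
                        table[etype][term] = 0.0
        return cfg


@dataclass
class SyntheticBundle:
    """Everything a pipeline run needs, plus the generating truth."""

    climate: pd.DataFrame
    composition: pd.DataFrame
    biomass: pd.DataFrame
    spei: pd.DataFrame  # driver-scale August SPEI per site-year
    catalog: pd.DataFrame  # realized event classification
    truth: dict


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def generate_climate(cfg: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Monthly precipitation (seasonal gamma) and PET (seasonal sinusoid).

    August SPEI at the driver scale is standard normal over the series by
    construction of the SPEI transform, so ~1 in 10 Augusts falls beyond
    +/-1.28 in each tail.
    """
    rng = _rng(cfg.seed, 1) if rng is None else rng
    rows = []
    months = np.arange(1, 13)
    for s in range(cfg.n_sites):
        site = f"site{s + 1}"
        site_wetness = float(np.exp(rng.normal(0.0, 0.08)))
        p_mean = cfg.precip_base * site_wetness * (
            1.0 + cfg.precip_seasonality * np.cos(2 * np.pi * (months - 6) / 12.0)
        )
        pet_mean = cfg.pet_base * (
            1.0 + cfg.pet_seasonality * np.cos(2 * np.pi * (months - 7) / 12.0)
        )
        for year in range(cfg.start_year, cfg.start_year + cfg.years):
            precip = rng.gamma(cfg.precip_shape, p_mean / cfg.precip_shape)
            pet = np.maximum(0.0, pet_mean + rng.normal(0.0, cfg.pet_noise, 12))
            for m in months:
                rows.append((site, year, int(m), float(precip[m - 1]), float(pet[m - 1])))
    return pd.DataFrame(rows, columns=["site", "year", "month", "precip", "pet"])


_NONPLANT = ["litter", "fungi"]


def generate_communities(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Plot x year x species percent-cover table with a persistent dominant.

    Each plot carries one dominant species (high Dirichlet weight, always
    present) and draws subordinates from the site pool each year; nutrient
    plots draw fewer species in expectation and give the dominant extra
    weight.  Occasional litter/fungi rows exercise composition cleaning.
    """
    rng = _rng(cfg.seed, 2) if rng is None else rng
    rows = []
    dominants = {}
    p_ctrl = cfg.presence_prob
    p_nut = p_ctrl + cfg.nutrient_richness_effect / (cfg.site_pool_size - 1)
    for s in range(cfg.n_sites):
        site = f"site{s + 1}"
        pool = [f"sp{s + 1:02d}_{i:02d}" for i in range(cfg.site_pool_size)]
        dom_candidates = pool[:4]
        for e in range(cfg.n_experiments_per_site):
            exp = f"exp{e + 1}"
            for p in range(cfg.n_plots):
                plot = f"plot{p + 1:02d}"
                treatment = "control" if p % 2 == 0 else "nutrient"
                dom = dom_candidates[rng.integers(0, len(dom_candidates))]
                dominants[(site, exp, plot)] = dom
                w_dom = cfg.dominance_concentration * float(
                    np.exp(rng.normal(0.0, cfg.dominant_weight_jitter))
                )
                if treatment == "nutrient":
                    w_dom *= 1.0 + cfg.nutrient_dominance_boost
                c_sub = float(np.exp(rng.normal(0.0, cfg.evenness_heterogeneity)))
                subs = [sp for sp in pool if sp != dom]
                p_pres = p_ctrl if treatment == "control" else p_nut
                for year in range(cfg.start_year, cfg.start_year + cfg.years):
                    present = [sp for sp in subs if rng.random() < p_pres]
                    species = [dom] + present
                    weights = np.r_[w_dom, np.full(len(present), c_sub)]
                    rel = rng.dirichlet(weights)
                    total_cover = rng.uniform(60.0, 110.0)
                    for sp, r in zip(species, rel):
                        rows.append((site, exp, plot, year, treatment, sp, r * total_cover))
                    if rng.random() < cfg.nonplant_rate:
                        lbl = _NONPLANT[rng.integers(0, len(_NONPLANT))]
                        rows.append((site, exp, plot, year, treatment, lbl,
                                     float(rng.uniform(3.0, 20.0))))
    comp = pd.DataFrame(
        rows,
        columns=["site", "experiment", "plot", "year", "treatment", "species", "abundance"],
    )
    truth = {
        "dominants": dominants,
        "expected_richness": {
            "control": 1 + (cfg.site_pool_size - 1) * p_ctrl,
            "nutrient": 1 + (cfg.site_pool_size - 1) * p_nut,
        },
    }
    return comp, truth


def _zscore_within(values: pd.Series) -> tuple[pd.Series, float, float]:
    mu, sd = float(values.mean()), float(values.std(ddof=1))
    if not np.isfinite(sd) or sd == 0:
        return values * 0.0, mu, 1.0
    return (values - mu) / sd, mu, sd


def generate_biomass(
    cfg: GeneratorConfig,
    climate: pd.DataFrame,
    composition: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Biomass per plot-year with event excursions tied to community properties.

    Returns (biomass table, driver-scale August SPEI, event catalog, truth).
    Baseline ln biomass carries site/experiment/plot and crossed year
    intercepts plus a linear response to the driver-scale SPEI.  In extreme
    years, ln(resistance) is drawn from the generating model and event-year
    biomass solved from it; the following year (when not itself extreme) is
    likewise solved from the drawn ln(resilience).
    """
    rng = _rng(cfg.seed, 3) if rng is None else rng
    spei = compute_spei(climate, cfg.spei_driver_scale, target_month=cfg.target_month)
    catalog = classify_years(spei)
    cat = catalog.set_index(["site", "year"])

    clean, _ = clean_composition(composition)
    props = community_properties(clean)
    props_idx = props.set_index(["site", "experiment", "plot", "year"])

    plots = composition[["site", "experiment", "plot", "treatment"]].drop_duplicates()
    years = np.arange(cfg.start_year, cfg.start_year + cfg.years)

    site_eff = {s: rng.normal(0, cfg.sd_site) for s in sorted(plots["site"].unique())}
    exp_eff = {
        k: rng.normal(0, cfg.sd_experiment)
        for k in sorted(map(tuple, plots[["site", "experiment"]].drop_duplicates().to_numpy()))
    }
    plot_eff = {
        k: rng.normal(0, cfg.sd_plot)
        for k in sorted(map(tuple, plots[["site", "experiment", "plot"]].to_numpy()))
    }
    year_eff = {int(y): rng.normal(0, cfg.sd_year) for y in years}
    stab_plot_eff = {k: rng.normal(0, cfg.sd_event_plot) for k in plot_eff}

    spei_idx = spei.set_index(["site", "year"])["spei"]

    ln_b = {}
    for r in plots.itertuples(index=False):
        base = (
            cfg.ln_baseline
            + site_eff[r.site]
            + exp_eff[(r.site, r.experiment)]
            + plot_eff[(r.site, r.experiment, r.plot)]
        )
        for y in years:
            sv = spei_idx.get((r.site, int(y)), np.nan)
            sv = 0.0 if not np.isfinite(sv) else sv
            ln_b[(r.site, r.experiment, r.plot, int(y))] = (
                base + year_eff[int(y)] + cfg.beta_spei * sv + rng.normal(0, cfg.sd_resid)
            )

    biomass = pd.DataFrame(
        [(s, e, p, y, v) for (s, e, p, y), v in ln_b.items()],
        columns=["site", "experiment", "plot", "year", "ln_biomass"],
    )
    biomass = biomass.merge(plots, on=["site", "experiment", "plot"])
    biomass["biomass"] = np.exp(biomass["ln_biomass"])

    cls = biomass.merge(catalog[["site", "year", "class"]], on=["site", "year"], how="left")

    # z-scales for prior-year predictors, per event type over event rows
    events = cls[cls["class"].isin(["extreme_dry", "extreme_wet"])].copy()
    events["prior_year"] = events["year"] - 1
    pri = events.merge(
        props.rename(columns={"year": "prior_year"}),
        on=["site", "experiment", "plot", "prior_year"],
        how="left",
        suffixes=("", "_p"),
    )
    # resilience is only defined when the following year is non-extreme and
    # observed; its predictor scaling is computed over that subset, matching
    # the model data it will be estimated from
    def _next_ok(row) -> bool:
        try:
            nc = cat.loc[(row["site"], int(row["year"]) + 1), "class"]
        except KeyError:
            return False
        return nc in ("normal", "other") and int(row["year"]) + 1 <= int(years[-1])

    pri["next_ok"] = np.array([_next_ok(r) for _, r in pri.iterrows()], dtype=bool)
    zscales: dict[str, dict[str, dict[str, tuple[float, float]]]] = {}
    for response, frame in (("resistance", pri), ("resilience", pri[pri["next_ok"]])):
        zscales[response] = {}
        for etype, sub in frame.groupby("class"):
            key = "dry" if etype == "extreme_dry" else "wet"
            zscales[response][key] = {}
            for term in ("richness", "dominance", "evenness"):
                _, mu, sd = _zscore_within(sub[term].dropna())
                zscales[response][key][term] = (mu, sd)

    ev_year_eff = {
        k: rng.normal(0, cfg.sd_event_site_year)
        for k in sorted(map(tuple, events[["site", "year"]].drop_duplicates().to_numpy()))
    }

    bio_map = biomass.set_index(["site", "experiment", "plot", "year"])["biomass"].to_dict()
    normal_years: dict[tuple, list[int]] = {}
    for _, r in cls[cls["class"] == "normal"].iterrows():
        normal_years.setdefault((r["site"], r["experiment"], r["plot"]), []).append(int(r["year"]))

    # first pass: draw ln(resistance)/ln(resilience) for every event row;
    # the draws are fixed, the biomass values are solved afterwards
    drawn = {"resistance": [], "resilience": []}
    records = []
    for _, r in events.sort_values(["site", "experiment", "plot", "year"]).iterrows():
        pk = (r["site"], r["experiment"], r["plot"])
        if pk not in normal_years:
            continue
        etype = "dry" if r["class"] == "extreme_dry" else "wet"

        def _z(response: str) -> dict[str, float]:
            zz = {}
            for term in ("richness", "dominance", "evenness"):
                mu, sd = zscales[response][etype][term]
                try:
                    val = props_idx.loc[pk + (int(r["year"]) - 1,), term]
                    zz[term] = (float(val) - mu) / sd
                except KeyError:
                    zz[term] = 0.0
            return zz

        z = _z("resistance")
        nut = 1.0 if r["treatment"] == "nutrient" else 0.0
        shared = ev_year_eff[(r["site"], int(r["year"]))] + stab_plot_eff[pk]

        eff = cfg.resistance_effects[etype]
        ln_omega = (
            eff["intercept"]
            + eff["richness"] * z["richness"]
            + eff["dominance"] * z["dominance"]
            + eff["evenness"] * z["evenness"]
            + eff["nutrient"] * nut
            + shared
            + rng.normal(0, cfg.sd_ln_resistance)
        )
        ln_omega = max(ln_omega, 0.05)
        drawn["resistance"].append(
            {"site": r["site"], "experiment": r["experiment"], "plot": r["plot"],
             "event_year": int(r["year"]), "event_type": f"extreme_{etype}",
             "ln_resistance": ln_omega}
        )

        next_year = int(r["year"]) + 1
        try:
            next_class = cat.loc[(r["site"], next_year), "class"]
        except KeyError:
            next_class = None
        next_key = pk + (next_year,)
        ln_delta = None
        if next_class in ("normal", "other") and next_key in bio_map:
            effR = cfg.resilience_effects[etype]
            zr = _z("resilience")
            ln_delta = (
                effR["intercept"]
                + effR["richness"] * zr["richness"]
                + effR["dominance"] * zr["dominance"]
                + effR["evenness"] * zr["evenness"]
                + effR["nutrient"] * nut
                + effR["dominance_x_nutrient"] * zr["dominance"] * nut
                + effR["evenness_x_nutrient"] * zr["evenness"] * nut
                + shared
                + rng.normal(0, cfg.sd_ln_resilience)
            )
            drawn["resilience"].append(
                {"site": r["site"], "experiment": r["experiment"], "plot": r["plot"],
                 "event_year": int(r["year"]), "event_type": f"extreme_{etype}",
                 "ln_resilience": ln_delta}
            )
        records.append((pk, int(r["year"]), etype, ln_omega, ln_delta))

    # second pass: solve biomass values to self-consistency.  Recovery years
    # that are classified normal feed back into the plot's normal-year mean,
    # so the excursions are recomputed against the updated mean until the
    # baseline the draws are anchored to equals the mean an analyst would
    # compute from the emitted data.
    prev: dict | None = None
    for _ in range(60):
        ybar_it = {
            pk: float(np.mean([bio_map[pk + (y,)] for y in yrs]))
            for pk, yrs in normal_years.items()
        }
        if prev is not None and all(
            abs(ybar_it[pk] - prev[pk]) <= 1e-10 * max(1.0, abs(prev[pk])) for pk in ybar_it
        ):
            break
        prev = ybar_it
        for pk, year, etype, ln_omega, ln_delta in records:
            yn = ybar_it[pk]
            dev = yn * np.exp(-ln_omega)
            sign = -1.0 if etype == "dry" else 1.0
            bio_map[pk + (year,)] = yn + sign * dev
            if ln_delta is not None:
                dev_next = dev * np.exp(-ln_delta)
                if etype == "dry":
                    # keep the recovery-year biomass positive
                    dev_next = min(dev_next, 0.95 * yn)
                bio_map[pk + (year + 1,)] = yn + sign * dev_next

    biomass["biomass"] = [
        bio_map[(s, e, p, int(y))]
        for s, e, p, y in biomass[["site", "experiment", "plot", "year"]].itertuples(index=False)
    ]
    biomass = biomass.drop(columns="ln_biomass")

    truth = {
        "resistance_effects": cfg.resistance_effects,
        "resilience_effects": cfg.resilience_effects,
        "zscales": zscales,
        "drawn": {k: pd.DataFrame(v) for k, v in drawn.items()},
        "n_events": int(len(events)),
    }
    return biomass, spei, catalog, truth


def generate_all(cfg: GeneratorConfig) -> SyntheticBundle:
    """Run all stages with per-stage RNG streams derived from the seed."""
    climate = generate_climate(cfg, _rng(cfg.seed, 1))
    composition, ctruth = generate_communities(cfg, _rng(cfg.seed, 2))
    biomass, spei, catalog, btruth = generate_biomass(
        cfg, climate, composition, _rng(cfg.seed, 3)
    )
    truth = {"config": asdict(cfg), **ctruth, **btruth}
    return SyntheticBundle(climate, composition, biomass, spei, catalog, truth)
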
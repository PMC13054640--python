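"""Replicate studies that validate the pipeline against generator truth.

These run the full chain — climate, SPEI, community metrics, stability
statistics, mixed models — on freshly generated synthetic studies and
measure: recovery of the generating coefficients (within +-2 SE), the
per-term false-positive rate under a null generator, recovery of the
generating SPEI timescale, and the type-I rate of the path model's global
Fisher's C test.  Both the acceptance script and the acceptance tests call
these with fixed seeds.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import community, lmm, sem, stability, synth
from .spei import compute_spei, select_timescale

__all__ = [
    "replicate_config",
    "fit_headline_models",
    "recovery_study",
    "null_calibration_study",
    "timescale_study",
    "fishers_c_calibration",
]

#: the four headline generating effects checked in recovery studies:
#: (response, event type, model term)
HEADLINE_TERMS = (
    ("resistance", "extreme_dry", "richness"),
    ("resistance", "extreme_wet", "dominance"),
    ("resilience", "extreme_dry", "evenness"),
    ("resilience", "extreme_wet", "dominance:treatment"),
)


def replicate_config(seed: int, **overrides) -> synth.GeneratorConfig:
    """Reduced-size study conditions used for replicate validation runs."""
    defaults = dict(n_sites=3, n_experiments_per_site=2, n_plots=12, years=45)
    defaults.update(overrides)
    return synth.GeneratorConfig(seed=int(seed), **defaults)


def _truth_of(cfg: synth.GeneratorConfig, response: str, etype: str, term: str) -> float:
    table = cfg.resistance_effects if response == "resistance" else cfg.resilience_effects
    eff = table["dry" if etype == "extreme_dry" else "wet"]
    key = {
        "richness": "richness", "dominance": "dominance", "evenness": "evenness",
        "treatment": "nutrient",
        "dominance:treatment": "dominance_x_nutrient",
        "evenness:treatment": "evenness_x_nutrient",
    }[term]
    return float(eff[key])


def fit_headline_models(bundle: synth.SyntheticBundle) -> dict:
    """Per-event-type resistance/resilience fits on one synthetic study.

    Fits the model structures the generator draws from: resistance without
    treatment interactions, resilience with the dominance/evenness by
    treatment interactions; standardized predictors within each subset.
    """
    clean, _ = community.clean_composition(bundle.composition)
    props = community.community_properties(clean)
    stab, _ = stability.build_stability_table(bundle.biomass, bundle.catalog, props)
    stab["experiment_uid"] = stab["site"] + ":" + stab["experiment"]
    stab["plot_uid"] = stab["experiment_uid"] + ":" + stab["plot"]
    stab["year"] = stab["event_year"]
    fits = {}
    for response in ("resistance", "resilience"):
        df = lmm._prepare_stability(stab, response)
        formula = "y ~ richness + dominance + evenness + treatment"
        if response == "resilience":
            formula += " + dominance:treatment + evenness:treatment"
        for etype in ("extreme_dry", "extreme_wet"):
            sub = df[df["event_type"] == etype]
            if len(sub) < 20 or sub["treatment"].nunique() < 2:
                continue
            sub, _ = lmm.standardize_predictors(sub, ["richness", "dominance", "evenness"])
            try:
                fits[(response, etype)] = lmm.fit_lmm(formula, sub, reml=True)
            except RuntimeError:
                continue
    return fits


def recovery_study(n_replicates: int, base_seed: int) -> pd.DataFrame:
    """Whether each headline generating effect lies within +-2 SE, per replicate."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_replicates):
            cfg = replicate_config(_sub_seed(base_seed, i))
            fits = fit_headline_models(synth.generate_all(cfg))
            for response, etype, term in HEADLINE_TERMS:
                fit = fits.get((response, etype))
                if fit is None:
                    continue
                truth = _truth_of(cfg, response, etype, term)
                est, se = float(fit.params[term]), float(fit.bse[term])
                rows.append(
                    {"replicate": i, "response": response, "event_type": etype,
                     "term": term, "truth": truth, "estimate": est, "se": se,
                     "covered": abs(est - truth) <= 2 * se}
                )
    return pd.DataFrame(rows)


def null_calibration_study(n_replicates: int, base_seed: int) -> pd.DataFrame:
    """Per-term Wald rejections at alpha = 0.05 under the all-zero generator."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_replicates):
            cfg = replicate_config(_sub_seed(base_seed, i)).null()
            fits = fit_headline_models(synth.generate_all(cfg))
            for (response, etype), fit in fits.items():
                for term in fit.params.index:
                    if term == "Intercept":
                        continue
                    rows.append(
                        {"replicate": i, "response": response, "event_type": etype,
                         "term": term, "p": float(fit.pvalues[term]),
                         "rejected": bool(fit.pvalues[term] < 0.05)}
                    )
    return pd.DataFrame(rows)


def timescale_study(n_replicates: int, base_seed: int) -> list[int | None]:
    """Selected SPEI timescale per replicate (the generator drives month 9)."""
    wins = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_replicates):
            cfg = replicate_config(_sub_seed(base_seed, i))
            bundle = synth.generate_all(cfg)
            control = bundle.biomass[bundle.biomass["treatment"] == "control"]
            by_scale = {
                k: compute_spei(bundle.climate, k, target_month=cfg.target_month)
                for k in (3, 6, 9, 12)
            }
            best, _ = select_timescale(control, by_scale)
            wins.append(best)
    return wins


def fishers_c_calibration(n_replicates: int, base_seed: int, n: int = 180) -> float:
    """Rejection rate of Fisher's C at alpha = 0.05 on data drawn from the
    default diagram (claims true by construction)."""
    diagram = sem.default_diagram(group=None)
    rej = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_replicates):
            data = sem.simulate_default_diagram(
                n, np.random.default_rng(_sub_seed(base_seed, i))
            )
            pf = sem.fit_path_model(diagram, data)
            rej += pf.p_value < 0.05
    return rej / n_replicates


def _sub_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(base_seed), index]).generate_state(1)[0] % (2**31))
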
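"""Stability metrics: event classification, resistance, resilience, LRRs.

Site-years are classified from August SPEI-9: extreme wet at SPEI >= 1.28,
extreme dry at SPEI <= -1.28 (1-in-10-year tails of a standard normal),
normal strictly inside (-0.67, 0.67) (the central 50%), everything else
"other".  Per plot and extreme event:

    resistance  Omega = Ybar_n / |Y_e - Ybar_n|
    resilience  Delta = |Y_e - Ybar_n| / |Y_e+1 - Ybar_n|

with Ybar_n the plot's mean biomass over its normal-classified years, Y_e
event-year biomass and Y_e+1 the following year's.  Resilience is dropped
when the following year is itself extreme.  Log response ratios are
ln(Y_e / Ybar_n) for biomass and for each community property.  Model tables
carry community properties from the year before the event.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "EXTREME_THRESHOLD",
    "NORMAL_CUTOFF",
    "classify_years",
    "normal_mean_biomass",
    "resistance",
    "resilience",
    "log_response_ratio",
    "build_stability_table",
    "build_lrr_table",
]

#: 1-in-10-year tail of the standard normal (z at cumulative 0.90)
EXTREME_THRESHOLD = 1.28
#: bound of the central 50% of the standard normal (z at cumulative 0.75)
NORMAL_CUTOFF = 0.67

_PLOT_KEY = ["site", "experiment", "plot"]


def classify_years(
    spei: pd.DataFrame,
    extreme: float = EXTREME_THRESHOLD,
    normal: float = NORMAL_CUTOFF,
) -> pd.DataFrame:
    """Exhaustive site-year classification from (August) SPEI values.

    Boundary conventions: |SPEI| equal to ``extreme`` is extreme; |SPEI|
    equal to ``normal`` is "other" (the normal band is open).  Missing SPEI
    leaves the year unclassified (dropped here, excluded downstream).
    """
    if not (extreme > normal > 0):
        raise ValueError("thresholds must satisfy extreme > normal > 0")
    df = spei.dropna(subset=["spei"]).copy()
    s = df["spei"].to_numpy(dtype=float)
    cls = np.where(
        s >= extreme,
        "extreme_wet",
        np.where(s <= -extreme, "extreme_dry", np.where(np.abs(s) < normal, "normal", "other")),
    )
    df["class"] = cls
    return df[["site", "year", "spei", "class"]].reset_index(drop=True)


def normal_mean_biomass(biomass: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Ybar_n per plot: mean biomass over that plot's normal-classified years.

    Plots with no normal year are excluded (reported via the returned
    frame simply not containing them; callers count the difference).
    """
    merged = biomass.merge(catalog[["site", "year", "class"]], on=["site", "year"], how="inner")
    normal = merged[merged["class"] == "normal"]
    return (
        normal.groupby(_PLOT_KEY, as_index=False)["biomass"]
        .mean()
        .rename(columns={"biomass": "y_normal_mean"})
    )


#: deviations below this fraction of the baseline are numerically zero
_REL_TOL = 1e-9


def resistance(y_normal_mean: float, y_event: float) -> float:
    """Omega = Ybar_n / |Y_e - Ybar_n|; NaN (undefined) when Y_e == Ybar_n.

    Deviations below ``_REL_TOL`` of the baseline count as zero: they are
    smaller than the float precision of the baseline mean itself.
    """
    dev = abs(y_event - y_normal_mean)
    if y_normal_mean <= 0 or dev <= _REL_TOL * y_normal_mean:
        return np.nan
    return y_normal_mean / dev


def resilience(
    y_normal_mean: float, y_event: float, y_after: float, next_year_class: str
) -> float:
    """Delta = |Y_e - Ybar_n| / |Y_e+1 - Ybar_n|.

    Missing (NaN) when the following year is itself extreme, when Y_e+1 is
    missing, or when either deviation is zero (undefined / complete
    recovery, flagged upstream by exclusion counts).
    """
    if next_year_class in ("extreme_dry", "extreme_wet"):
        return np.nan
    if y_after is None or not np.isfinite(y_after):
        return np.nan
    num = abs(y_event - y_normal_mean)
    den = abs(y_after - y_normal_mean)
    floor = _REL_TOL * abs(y_normal_mean)
    if num <= floor or den <= floor:
        return np.nan
    return num / den


def log_response_ratio(y_event: float, y_normal_mean: float) -> float:
    """ln(Y_e / Ybar_n); NaN for nonpositive inputs (excluded with a flag)."""
    if y_event <= 0 or y_normal_mean <= 0:
        return np.nan
    return float(np.log(y_event / y_normal_mean))


def build_stability_table(
    biomass: pd.DataFrame,
    catalog: pd.DataFrame,
    properties: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per plot x extreme event rows with Omega, Delta and prior-year predictors.

    ``biomass`` columns: site, experiment, plot, year, treatment, biomass.
    ``catalog``: classify_years output.  ``properties`` (optional):
    community_properties output, used to attach richness/dominance/evenness
    from the year before each event; event rows lacking the prior year are
    excluded.

    Returns (table, exclusion counts by reason).
    """
    excl = {
        "no_normal_years": 0,
        "undefined_resistance": 0,
        "missing_prior_year_properties": 0,
    }
    cat = catalog.set_index(["site", "year"])
    ybar = normal_mean_biomass(biomass, catalog)
    n_plots = len(biomass[_PLOT_KEY].drop_duplicates())
    excl["no_normal_years"] = n_plots - len(ybar)

    bio = biomass.merge(catalog[["site", "year", "spei", "class"]], on=["site", "year"], how="inner")
    bio = bio.merge(ybar, on=_PLOT_KEY, how="inner")
    bio_idx = bio.set_index(_PLOT_KEY + ["year"])["biomass"]

    events = bio[bio["class"].isin(["extreme_dry", "extreme_wet"])].rename(
        columns={"class": "event_type"}
    )
    rows = []
    for r in events.itertuples(index=False):
        omega = resistance(r.y_normal_mean, r.biomass)
        if not np.isfinite(omega):
            excl["undefined_resistance"] += 1
        next_key = (r.site, r.experiment, r.plot, r.year + 1)
        y_after = bio_idx.get(next_key, np.nan)
        try:
            next_class = cat.loc[(r.site, r.year + 1), "class"]
        except KeyError:
            next_class = "unclassified"
        delta = resilience(r.y_normal_mean, r.biomass, y_after, next_class)
        rows.append(
            {
                "site": r.site,
                "experiment": r.experiment,
                "plot": r.plot,
                "treatment": r.treatment,
                "event_year": r.year,
                "event_type": r.event_type,
                "spei_strength": abs(r.spei),
                "y_normal_mean": r.y_normal_mean,
                "y_event": r.biomass,
                "y_after": y_after,
                "resistance": omega,
                "resilience": delta,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table, excl

    if properties is not None:
        prior = properties.rename(
            columns={
                "richness": "prior_richness",
                "dominance": "prior_dominance",
                "evenness": "prior_evenness",
            }
        )[_PLOT_KEY + ["year", "prior_richness", "prior_dominance", "prior_evenness"]]
        prior = prior.assign(event_year=prior["year"] + 1).drop(columns="year")
        before = len(table)
        table = table.merge(prior, on=_PLOT_KEY + ["event_year"], how="inner")
        excl["missing_prior_year_properties"] = before - len(table)
    return table.reset_index(drop=True), excl


def build_lrr_table(
    biomass: pd.DataFrame,
    catalog: pd.DataFrame,
    properties: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Log response ratios per plot x event for biomass and community metrics.

    For each metric the normal-year baseline is that plot's mean over
    normal-classified years (the same normal-year set as for biomass).
    Rows with nonpositive event or baseline values are excluded and counted.
    """
    excl = {"nonpositive_values": 0}
    frames = [("biomass", biomass.rename(columns={"biomass": "value"}))]
    if properties is not None:
        for metric in ("richness", "dominance", "evenness"):
            frames.append(
                (metric, properties.rename(columns={metric: "value"})[
                    _PLOT_KEY + ["year", "treatment", "value"]
                ])
            )
    out = []
    for metric, df in frames:
        merged = df.merge(
            catalog[["site", "year", "spei", "class"]], on=["site", "year"], how="inner"
        )
        base = (
            merged[merged["class"] == "normal"]
            .groupby(_PLOT_KEY, as_index=False)["value"]
            .mean()
            .rename(columns={"value": "baseline"})
        )
        ev = merged[merged["class"].isin(["extreme_dry", "extreme_wet"])].merge(
            base, on=_PLOT_KEY, how="inner"
        )
        lrr = np.where(
            (ev["value"] > 0) & (ev["baseline"] > 0),
            np.log(ev["value"] / ev["baseline"]),
            np.nan,
        )
        excl["nonpositive_values"] += int(np.isnan(lrr).sum())
        out.append(
            pd.DataFrame(
                {
                    "site": ev["site"],
                    "experiment": ev["experiment"],
                    "plot": ev["plot"],
                    "treatment": ev["treatment"],
                    "event_year": ev["year"],
                    "event_type": ev["class"],
                    "spei_strength": ev["spei"].abs(),
                    "metric": metric,
                    "lrr": lrr,
                }
            )
        )
    table = pd.concat(out, ignore_index=True).dropna(subset=["lrr"]).reset_index(drop=True)
    return table, excl
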
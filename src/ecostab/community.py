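"""Plant community properties: richness, Evar evenness, long-term dominance.

Operates on tidy composition tables (site, experiment, plot, year,
treatment, species, abundance) where abundance is percent cover or biomass.
Cleaning removes non-plant records (litter, fungi, ...) and renormalizes
relative abundance within each plot-year; richness counts species with
positive abundance; evenness is Smith & Wilson's Evar (variance of log
abundances mapped to [0, 1] by an arctangent, independent of richness); the
long-term dominant is the species that tops relative abundance in the most
years of a plot's record, and dominance is that species' relative abundance
each year (0 when absent).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_NONPLANT_LABELS",
    "clean_composition",
    "richness",
    "evar_evenness",
    "identify_long_term_dominant",
    "dominance_series",
    "community_properties",
]

DEFAULT_NONPLANT_LABELS = (
    "litter",
    "miscellaneous litter",
    "fungi",
    "bare ground",
    "rock",
    "moss-unknown",
)

_PLOT_KEY = ["site", "experiment", "plot"]
_PLOT_YEAR_KEY = _PLOT_KEY + ["year"]


def clean_composition(
    raw: pd.DataFrame, nonplant_labels=DEFAULT_NONPLANT_LABELS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop non-plant and zero rows; recompute within-plot-year rel_abundance.

    Matching of ``nonplant_labels`` against species names is
    case-insensitive on the stripped name.  Plot-years whose total plant
    abundance is zero are excluded and reported.

    Returns (clean table with a ``rel_abundance`` column, excluded-plot-year
    table with a ``reason`` column).
    """
    labels = {str(lb).strip().lower() for lb in nonplant_labels}
    df = raw.copy()
    if (df["abundance"] < 0).any():
        raise ValueError("negative abundance values in composition table")
    name = df["species"].astype(str).str.strip().str.lower()
    df = df[~name.isin(labels)]
    df = df[df["abundance"] > 0]
    totals = df.groupby(_PLOT_YEAR_KEY)["abundance"].transform("sum")
    df = df.assign(rel_abundance=df["abundance"] / totals)

    all_py = raw[_PLOT_YEAR_KEY].drop_duplicates()
    kept_py = df[_PLOT_YEAR_KEY].drop_duplicates()
    excluded = all_py.merge(kept_py, on=_PLOT_YEAR_KEY, how="left", indicator=True)
    excluded = excluded[excluded["_merge"] == "left_only"].drop(columns="_merge")
    excluded["reason"] = "no plant abundance after cleaning"
    return df.reset_index(drop=True), excluded.reset_index(drop=True)


def richness(abundances) -> int:
    """Number of species with positive abundance."""
    x = np.asarray(abundances, dtype=float)
    return int(np.sum(x > 0))


def evar_evenness(abundances) -> float:
    """Smith & Wilson's Evar on the S present (positive) abundances.

    Evar = 1 - (2/pi) * arctan(Var_S[ln x]), with the population
    (divide-by-S) variance of natural-log abundances.  Scale-invariant;
    1 when all species are equal; a single-species community returns 1 by
    convention (zero log-variance).
    """
    x = np.asarray(abundances, dtype=float)
    x = x[x > 0]
    if len(x) == 0:
        raise ValueError("no positive abundances")
    ln = np.log(x)
    var = float(np.mean((ln - ln.mean()) ** 2))
    return 1.0 - (2.0 / np.pi) * np.arctan(var)


def identify_long_term_dominant(plot_history: pd.DataFrame) -> str:
    """Species topping relative abundance in the most years of the record.

    Ties in a single year (identical max rel_abundance) credit every tied
    species with a top year.  Ties across the record break by higher mean
    rel_abundance over all years, then lexicographic species name.
    """
    top_years: dict[str, int] = {}
    for _, yr in plot_history.groupby("year"):
        mx = yr["rel_abundance"].max()
        for sp in yr.loc[yr["rel_abundance"] == mx, "species"]:
            top_years[sp] = top_years.get(sp, 0) + 1
    mean_ab = plot_history.groupby("species")["rel_abundance"].sum() / plot_history[
        "year"
    ].nunique()
    return min(
        top_years,
        key=lambda sp: (-top_years[sp], -float(mean_ab.get(sp, 0.0)), sp),
    )


def dominance_series(plot_history: pd.DataFrame, dominant: str) -> pd.Series:
    """The dominant's rel_abundance per year (0 in years it is absent)."""
    per_year = (
        plot_history[plot_history["species"] == dominant]
        .groupby("year")["rel_abundance"]
        .sum()
    )
    years = sorted(plot_history["year"].unique())
    return per_year.reindex(years, fill_value=0.0).rename("dominance")


def community_properties(clean: pd.DataFrame) -> pd.DataFrame:
    """Per plot-year richness, Evar evenness, dominant identity and dominance.

    The long-term dominant is identified once per plot over all available
    years; its yearly relative abundance is the dominance value even in
    years another species ranks higher.
    """
    rows = []
    for key, plot in clean.groupby(_PLOT_KEY, sort=True):
        dom = identify_long_term_dominant(plot)
        dom_by_year = dominance_series(plot, dom)
        for year, yr in plot.groupby("year"):
            ab = yr["rel_abundance"].to_numpy()
            rows.append(
                {
                    "site": key[0],
                    "experiment": key[1],
                    "plot": key[2],
                    "year": year,
                    "treatment": yr["treatment"].iloc[0],
                    "richness": richness(ab),
                    "evenness": evar_evenness(ab),
                    "dominant_species": dom,
                    "dominance": float(dom_by_year.loc[year]),
                }
            )
    return pd.DataFrame(rows)
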
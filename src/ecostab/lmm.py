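"""Linear mixed models for stability responses.

Wraps statsmodels' MixedLM behind the random-intercept structure used
throughout the analysis — plot nested in experiment nested in site, with a
crossed year intercept — implemented as variance components over a single
spanning group.  Adds the surrounding inferential machinery: standardized
coefficients, AICc, Nakagawa marginal/conditional R^2, variance inflation
factors, a likelihood-ratio ladder for dropping interaction terms,
Tukey-adjusted pairwise cell contrasts for the log-response-ratio models,
and leave-one-out sensitivity refits.

Term-level p-values are Wald (normal) tests; coefficients and standard
errors are the reproduction contract, degrees-of-freedom approximations
are not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .spei import aicc

__all__ = [
    "FitResult",
    "standardize_predictors",
    "fit_lmm",
    "vif",
    "select_model_loglik",
    "fit_stability_models",
    "fit_lrr_models",
    "pairwise_tukey",
    "sensitivity_leave_one_out",
    "DEFAULT_VC",
    "DEFAULT_LADDER",
]

#: random-intercept factors: plot in experiment in site, crossed with year
DEFAULT_VC = ["site", "experiment_uid", "plot_uid", "year"]

#: interaction-drop order for the selection ladder (first listed, first tried)
DEFAULT_LADDER = [
    "richness:event_type",
    "dominance:event_type",
    "evenness:event_type",
    "richness:treatment",
    "dominance:treatment",
    "evenness:treatment",
]


@dataclass
class FitResult:
    """A fitted mixed (or degenerate-to-OLS) model, tidied.

    ``params``/``bse``/``pvalues`` are indexed by fixed-effect term.
    ``vcomp`` maps random factor -> intercept variance (data scale);
    ``scale`` is the residual variance.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    n: int
    k_params: int
    aicc: float
    marginal_r2: float
    conditional_r2: float
    vcomp: dict[str, float]
    scale: float
    converged: bool
    reml: bool
    formula: str
    flags: list[str] = field(default_factory=list)
    model_result: object | None = None
    fe_cov: np.ndarray | None = None  # fixed-effect covariance (term order)

    def tidy(self) -> pd.DataFrame:
        z = self.params / self.bse
        return pd.DataFrame(
            {
                "term": self.params.index,
                "beta": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "stat": z.to_numpy(),
                "p": self.pvalues.to_numpy(),
            }
        )


def standardize_predictors(
    table: pd.DataFrame, terms: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score the named numeric columns; return the table and (mean, sd) map.

    Binary 0/1 indicators are left to the caller (pass only continuous
    terms).  A constant column raises, naming the term.
    """
    out = table.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for term in terms:
        x = out[term].to_numpy(dtype=float)
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"predictor {term!r} is constant; cannot standardize")
        out[term] = (x - mu) / sd
        scaling[term] = (mu, sd)
    return out, scaling


def unstandardize(values, term: str, scaling: dict[str, tuple[float, float]]):
    """Inverse of :func:`standardize_predictors` for one column."""
    mu, sd = scaling[term]
    return np.asarray(values, dtype=float) * sd + mu


def _merge_flags(fit: "FitResult", flags: list[str]) -> "FitResult":
    fit.flags = flags + fit.flags
    return fit


def _fe_cov_gls(
    X, data: pd.DataFrame, factors: list[str], vcomp: dict[str, float], scale: float
) -> np.ndarray:
    """(X' V^-1 X)^-1 with V = scale*I + sum_f vcomp_f Z_f Z_f' (Woodbury)."""
    X = np.asarray(X, dtype=float)
    blocks, variances = [], []
    for f in factors:
        v = float(vcomp.get(f, 0.0))
        if v <= 1e-10 * scale:
            continue
        codes, levels = pd.factorize(data[f])
        Z = np.zeros((len(data), len(levels)))
        Z[np.arange(len(data)), codes] = 1.0
        blocks.append(Z)
        variances.append(np.full(len(levels), v))
    xtx = X.T @ X / scale
    if not blocks:
        return np.linalg.inv(xtx)
    Z = np.hstack(blocks)
    d = np.concatenate(variances)
    A = Z.T @ Z / scale + np.diag(1.0 / d)
    B = X.T @ Z / scale
    return np.linalg.inv(xtx - B @ np.linalg.solve(A, B.T))


def fit_lmm(
    formula: str,
    data: pd.DataFrame,
    vc_factors: list[str] | None = None,
    reml: bool = True,
) -> FitResult:
    """Fit a Gaussian linear mixed model with random-intercept components.

    Parameters
    ----------
    formula
        Patsy fixed-effects formula (response on the left).
    data
        Model frame; rows with missing values in modeled columns must be
        dropped by the caller.
    vc_factors
        Columns giving one random intercept each; factors with < 2 levels
        are dropped with a flag rather than raising.  An empty list (or all
        factors degenerate) falls back to OLS with a flag.
    reml
        Restricted maximum likelihood (reporting) vs ML (model comparison).
    """
    vc_factors = list(DEFAULT_VC if vc_factors is None else vc_factors)
    flags: list[str] = []
    kept, partitions = [], []
    for f in vc_factors:
        if data[f].nunique() < 2:
            flags.append(f"random factor {f!r} has < 2 levels; dropped")
            continue
        part = tuple(pd.factorize(data[f])[0])
        if part in partitions:
            # aliased grouping (e.g. one experiment per site): the two
            # variance components are not separately identified
            flags.append(f"random factor {f!r} aliases an earlier factor; dropped")
            continue
        partitions.append(part)
        kept.append(f)

    if not kept:
        res = smf.ols(formula, data=data).fit()
        flags.append("no usable random factors; ordinary least squares fit")
        n, k = int(res.nobs), len(res.params) + 1
        var_f = float(np.var(res.fittedvalues, ddof=0))
        denom = var_f + float(res.scale)
        return FitResult(
            res.params, res.bse, res.pvalues, float(res.llf), n, k,
            aicc(float(res.llf), k, n), var_f / denom, var_f / denom,
            {}, float(res.scale), True, reml, formula, flags, res,
            fe_cov=np.asarray(res.cov_params()),
        )

    vcf = {f: f"0 + C({f})" for f in kept}
    md = smf.mixedlm(
        formula, data, groups=np.ones(len(data)), re_formula="0", vc_formula=vcf
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        # lbfgs and bfgs each occasionally stop at a spurious optimum on
        # variance boundaries; fit with both and keep the better likelihood
        res = None
        for method in ("lbfgs", "bfgs"):
            try:
                cand = md.fit(reml=reml, method=method, maxiter=200)
            except Exception:  # noqa: BLE001
                continue
            if res is None or float(cand.llf) > float(res.llf):
                res = cand
        if res is None:
            try:
                res = md.fit(reml=reml, method="powell", maxiter=500)
            except Exception:
                # singular random-effects design (e.g. too few levels per
                # event subset): drop the factor with fewest levels and
                # refit, flagging the reduction
                reduced = sorted(kept, key=lambda f: data[f].nunique())[1:]
                flags.append(
                    "singular random-effects fit; refit without factor "
                    f"{sorted(kept, key=lambda f: data[f].nunique())[0]!r}"
                )
                return _merge_flags(fit_lmm(formula, data, reduced, reml), flags)
        if not reml:
            # the zero-variance model is nested in the mixed model, so the
            # ML log-likelihood can never fall below the OLS one: a lower
            # value exposes an optimizer failure
            ols_llf = float(smf.ols(formula, data=data).fit().llf)
            if float(res.llf) < ols_llf - 1e-6:
                try:
                    res2 = md.fit(reml=False, method="powell", maxiter=1000)
                    if float(res2.llf) > float(res.llf):
                        res = res2
                except Exception:  # noqa: BLE001
                    pass
            if float(res.llf) < ols_llf - 1e-6:
                flags.append(
                    "ML optimum below the zero-variance likelihood; "
                    "falling back to the zero-variance fit"
                )
                return _merge_flags(fit_lmm(formula, data, [], reml), flags)
        for w in caught:
            if "boundary" in str(w.message).lower():
                flags.append("variance component on boundary (possibly zero)")
            elif "positive definite" in str(w.message).lower():
                flags.append("Hessian not positive definite at optimum")
    if not getattr(res, "converged", True):
        converged = False
        flags.append("optimizer did not report convergence")

    fe = res.fe_params
    # fixed-effect covariance conditional on the estimated variance
    # components (GLS formula via Woodbury); statsmodels' joint observed
    # information is undefined at variance boundaries, this never is
    vcomp_map = dict(zip(md.exog_vc.names, res.vcomp))
    fe_cov = _fe_cov_gls(md.exog, data, kept, vcomp_map, float(res.scale))
    bse = pd.Series(np.sqrt(np.diag(fe_cov)), index=fe.index)
    pvals = pd.Series(
        2 * stats.norm.sf(np.abs(fe.to_numpy() / bse.to_numpy())), index=fe.index
    )
    vcomp = {name: float(v) for name, v in vcomp_map.items()}
    scale = float(res.scale)

    exog = md.exog
    var_f = float(np.var(exog @ fe.to_numpy(), ddof=0))
    total = var_f + sum(vcomp.values()) + scale
    marg = var_f / total
    cond = (var_f + sum(vcomp.values())) / total

    n = len(data)
    k = len(fe) + len(vcomp) + 1
    return FitResult(
        fe, bse, pvals, float(res.llf), n, k, aicc(float(res.llf), k, n),
        marg, cond, vcomp, scale, converged, reml, formula, flags, res,
        fe_cov=fe_cov,
    )


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2_j).

    Perfect collinearity yields ``inf`` for the involved columns.
    """
    X = design.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 terms for VIF")
    out = {}
    for j, name in enumerate(design.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def _drop_term(formula: str, term: str) -> str:
    rhs_terms = [t.strip() for t in formula.split("~")[1].split("+")]
    kept = [t for t in rhs_terms if t.replace(" ", "") != term.replace(" ", "")]
    return formula.split("~")[0].strip() + " ~ " + " + ".join(kept)


def select_model_loglik(
    full_formula: str,
    droppable_interactions: list[str],
    data: pd.DataFrame,
    vc_factors: list[str] | None = None,
    alpha: float = 0.05,
) -> tuple[str, pd.DataFrame]:
    """Likelihood-ratio ladder over interaction terms (ML fits).

    Walks ``droppable_interactions`` in order; each term is dropped from the
    current formula when the likelihood-ratio test against the reduced model
    is non-significant at ``alpha``, and retained otherwise.  Returns the
    final formula and the ladder table (term, LR statistic, df, p, action).
    """
    current = full_formula
    rows = []
    for term in droppable_interactions:
        if term.replace(" ", "") not in current.replace(" ", ""):
            continue
        reduced = _drop_term(current, term)
        try:
            fit_full = fit_lmm(current, data, vc_factors, reml=False)
            fit_red = fit_lmm(reduced, data, vc_factors, reml=False)
        except RuntimeError as exc:
            rows.append({"term": term, "lr": np.nan, "df": np.nan, "p": np.nan,
                         "action": f"skipped ({exc})"})
            continue
        lr = max(0.0, 2.0 * (fit_full.llf - fit_red.llf))
        df = max(1, len(fit_full.params) - len(fit_red.params))
        p = float(stats.chi2.sf(lr, df))
        if p < alpha:
            action = "retained"
        else:
            action = "dropped"
            current = reduced
        rows.append({"term": term, "lr": lr, "df": df, "p": p, "action": action})
    return current, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stability (resistance / resilience) models


def _prepare_stability(stability: pd.DataFrame, response: str) -> pd.DataFrame:
    df = stability.copy()
    if response == "resistance":
        df = df[np.isfinite(df["resistance"]) & (df["resistance"] > 0)]
        df["y"] = np.log(df["resistance"])
    else:
        df = df[np.isfinite(df["resilience"]) & (df["resilience"] > 0)]
        df["y"] = np.log(df["resilience"])
    df = df.rename(
        columns={
            "prior_richness": "richness",
            "prior_dominance": "dominance",
            "prior_evenness": "evenness",
        }
    )
    df["treatment"] = (df["treatment"] == "nutrient").astype(int)
    df = df.dropna(subset=["y", "richness", "dominance", "evenness"])
    return df


def fit_stability_models(
    stability: pd.DataFrame,
    select: bool = True,
    ladder: list[str] | None = None,
    alpha: float = 0.05,
    vc_factors: list[str] | None = None,
) -> dict:
    """Resistance/resilience models: combined selection, then per event type.

    For each response the combined-events model
    ``ln(response) ~ richness + dominance + evenness + event_type + treatment
    + property:event_type + property:treatment`` is reduced by the
    likelihood-ratio ladder (when ``select``), then refit by REML separately
    for extreme dry and extreme wet events with the event-type terms removed.
    Continuous predictors are z-scored so coefficients are standardized.

    Returns a dict with the selected formulas, ladder tables and a
    ``fits`` mapping ``(response, event_type) -> FitResult`` (missing cells
    are flagged, not raised).
    """
    ladder = list(DEFAULT_LADDER if ladder is None else ladder)
    out: dict = {"ladders": {}, "selected": {}, "fits": {}, "flags": []}
    base = "y ~ richness + dominance + evenness + event_type + treatment"
    full = base + " + " + " + ".join(ladder)
    for response in ("resistance", "resilience"):
        df = _prepare_stability(stability, response)
        df["event_type"] = (df["event_type"] == "extreme_wet").astype(int)
        if select and df["event_type"].nunique() > 1:
            scaled, _ = standardize_predictors(df, ["richness", "dominance", "evenness"])
            selected, ladder_tbl = select_model_loglik(full, ladder, scaled, vc_factors, alpha)
        else:
            selected, ladder_tbl = full, pd.DataFrame()
            if select:
                out["flags"].append(f"{response}: single event type; ladder skipped")
        out["ladders"][response] = ladder_tbl
        out["selected"][response] = selected
        per_type = _strip_event_terms(selected)
        for etype, code in (("dry", 0), ("wet", 1)):
            sub = df[df["event_type"] == code]
            if len(sub) < 10 or sub["treatment"].nunique() < 2:
                out["flags"].append(f"{response}/{etype}: insufficient rows; model absent")
                continue
            # standardize within the fitted subset so coefficients are on
            # that event type's predictor scale
            sub, _ = standardize_predictors(sub, ["richness", "dominance", "evenness"])
            try:
                out["fits"][(response, etype)] = fit_lmm(per_type, sub, vc_factors, reml=True)
            except RuntimeError as exc:
                out["flags"].append(f"{response}/{etype}: fit failed ({exc})")
    return out


def _strip_event_terms(formula: str) -> str:
    rhs = [t.strip() for t in formula.split("~")[1].split("+")]
    kept = [t for t in rhs if "event_type" not in t]
    return "y ~ " + " + ".join(kept)


# ---------------------------------------------------------------------------
# log-response-ratio models and Tukey-adjusted cell contrasts


def pairwise_tukey(fit: FitResult, cell_terms: list[str]) -> pd.DataFrame:
    """All pairwise contrasts among cell-mean coefficients, Tukey-adjusted.

    ``cell_terms`` name coefficients of a cell-means parametrization.  The
    familywise adjustment uses the studentized-range distribution on the
    Wald statistic (q = sqrt(2)|t|, k cells, residual df).
    """
    idx = [list(fit.params.index).index(t) for t in cell_terms]
    cov = np.asarray(fit.fe_cov)[np.ix_(idx, idx)]
    est = fit.params.loc[cell_terms].to_numpy()
    k = len(cell_terms)
    df_resid = max(fit.n - fit.k_params, 2)
    rows = []
    for i, j in combinations(range(k), 2):
        diff = est[i] - est[j]
        se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
        t = diff / se if se > 0 else np.inf
        p = float(stats.studentized_range.sf(np.sqrt(2.0) * abs(t), k, df_resid))
        rows.append(
            {"contrast": f"{cell_terms[i]} - {cell_terms[j]}", "estimate": diff,
             "se": se, "t": t, "p_tukey": min(1.0, p)}
        )
    return pd.DataFrame(rows)


def fit_lrr_models(
    lrr: pd.DataFrame,
    vc_factors: list[str] | None = None,
    strength_model: bool = False,
) -> dict:
    """Per-metric LRR models: event type x treatment cells with Tukey contrasts.

    For each metric (biomass, richness, dominance, evenness) fits a
    cell-means mixed model ``lrr ~ 0 + C(cell)`` where ``cell`` crosses
    event type with treatment, plus the usual random intercepts; reports
    marginal means per cell with SEs and all 6 pairwise contrasts with a
    familywise Tukey-style adjustment.  When ``strength_model`` is set, an
    additional model with the three-way |SPEI| strength x event type x
    treatment interaction is fit per metric.
    """
    out: dict = {"fits": {}, "cells": {}, "contrasts": {}, "strength": {}, "flags": []}
    for metric, sub in lrr.groupby("metric"):
        sub = sub.dropna(subset=["lrr"]).copy()
        sub["cell"] = sub["event_type"].str.replace("extreme_", "") + ":" + sub["treatment"]
        cells = sorted(sub["cell"].unique())
        if len(cells) < 2:
            out["flags"].append(f"{metric}: fewer than 2 populated cells; skipped")
            continue
        fit = fit_lmm("lrr ~ 0 + C(cell)", sub, vc_factors, reml=True)
        term_of = {c: f"C(cell)[{c}]" for c in cells}
        cell_tbl = pd.DataFrame(
            {
                "cell": cells,
                "estimate": [fit.params[term_of[c]] for c in cells],
                "se": [fit.bse[term_of[c]] for c in cells],
            }
        )
        cell_tbl["p_vs_zero"] = 2 * stats.norm.sf(
            np.abs(cell_tbl["estimate"] / cell_tbl["se"])
        )
        out["fits"][metric] = fit
        out["cells"][metric] = cell_tbl
        out["contrasts"][metric] = pairwise_tukey(fit, [term_of[c] for c in cells])
        if len(cells) < 4:
            out["flags"].append(f"{metric}: {4 - len(cells)} empty cell(s); contrasts partial")
        if strength_model:
            sub["treat01"] = (sub["treatment"] == "nutrient").astype(int)
            sub["is_wet"] = (sub["event_type"] == "extreme_wet").astype(int)
            out["strength"][metric] = fit_lmm(
                "lrr ~ spei_strength * is_wet * treat01", sub, vc_factors, reml=True
            )
    return out


def sensitivity_leave_one_out(
    formula: str,
    data: pd.DataFrame,
    unit: str,
    vc_factors: list[str] | None = None,
    reml: bool = True,
) -> pd.DataFrame:
    """Refit the model once per omitted level of ``unit`` (site or event year).

    Returns a long table (omitted, term, beta, se, converged); a base-fit
    row is included with ``omitted = '<none>'``.  Failed refits are recorded
    and do not abort the sweep.
    """
    levels = sorted(data[unit].unique())
    if len(levels) < 3:
        raise ValueError(f"need >= 3 levels of {unit!r} for leave-one-out")
    rows = []

    def _one(label: str, sub: pd.DataFrame) -> None:
        try:
            fit = fit_lmm(formula, sub, vc_factors, reml=reml)
        except RuntimeError as exc:
            rows.append({"omitted": label, "term": "<failed>", "beta": np.nan,
                         "se": np.nan, "converged": False, "note": str(exc)})
            return
        for term in fit.params.index:
            rows.append({"omitted": label, "term": term, "beta": fit.params[term],
                         "se": fit.bse[term], "converged": fit.converged, "note": ""})

    _one("<none>", data)
    for lev in levels:
        _one(str(lev), data[data[unit] != lev])
    return pd.DataFrame(rows)
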
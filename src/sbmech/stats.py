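"""Descriptive statistics, collinearity screening, and the linear
mixed-model workflow with horse-level random intercepts.

The modeling stage is a workflow, not a new estimator: Gaussian linear mixed
models are fitted by REML via statsmodels' MixedLM, with Wald-z p-values for
fixed effects. Model building follows the conventional two-step screen:
candidates entering at p < 0.20 univariably, then backward elimination until
every retained term has p < 0.05, with ties in p broken by covariate name
order so selection is deterministic. Covariate pairs correlated beyond
|rho| > 0.60 are flagged so at most one of each pair is offered to a model
(the better-fitting one by AIC/BIC).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

SITES = ("dorsal", "palmar", "sesamoid")
LAYERS = ("superficial", "deep", "total")


@dataclass
class ModelSpec:
    outcome: str
    fixed_effects: list[str]
    group: str = "horse_id"
    stratify_by: str | None = None

    def formula(self) -> str:
        rhs = " + ".join(self.fixed_effects) if self.fixed_effects else "1"
        return f"{self.outcome} ~ {rhs}"


@dataclass
class FitResult:
    params: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper
    pvalues: pd.Series
    group_variance: float
    residual_variance: float
    aic: float
    bic: float
    converged: bool
    n_obs: int

    def __post_init__(self) -> None:
        lo, hi = self.conf_int["lower"], self.conf_int["upper"]
        common = self.params.index.intersection(self.conf_int.index)
        ok = np.isfinite(lo[common]) & np.isfinite(hi[common])  # NaN CI: degenerate fit
        inside = (lo[common][ok] <= self.params[common][ok]) & (self.params[common][ok] <= hi[common][ok])
        if not inside.all():
            raise ValueError("confidence bounds do not bracket the estimates")


@dataclass
class SelectionResult:
    spec: ModelSpec
    fit: FitResult
    univariable_p: dict[str, float]
    entered: list[str]
    retained: list[str]
    interactions_retained: list[str] = field(default_factory=list)
    stratified_fits: dict[str, FitResult] | None = None
    notice: str | None = None


def cov_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100 x sd / mean (%)."""
    if mean == 0:
        raise ZeroDivisionError("CoV undefined for zero mean")
    return 100.0 * sd / mean


def descriptives(
    table: pd.DataFrame,
    outcome: str,
    by: tuple[str, ...] = ("site", "layer"),
) -> pd.DataFrame:
    """Mean, sample sd (n-1) and CoV (%) of ``outcome`` per cell of ``by``.

    Cells with zero mean get NaN CoV and a warning flag column.
    """
    rows = []
    for keys, grp in table.groupby(list(by), observed=True, sort=True):
        vals = grp[outcome].dropna().to_numpy(dtype=float)
        mean = float(vals.mean()) if vals.size else np.nan
        sd = float(vals.std(ddof=1)) if vals.size >= 2 else np.nan
        flagged = mean == 0
        cov = np.nan if flagged or np.isnan(sd) else cov_percent(mean, sd)
        if flagged:
            logger.warning("CoV undefined (zero mean) in cell %s", keys)
        rec = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        rec.update(n=vals.size, mean=mean, sd=sd, cov_pct=cov, cov_undefined=flagged)
        rows.append(rec)
    return pd.DataFrame(rows)


def collinearity_screen(
    table: pd.DataFrame,
    covariates: list[str],
    threshold: float = 0.60,
) -> list[tuple[str, str, float]]:
    """Pairs of numeric covariates with |Pearson rho| > threshold.

    Zero-variance covariates are excluded with a warning. Callers should
    retain at most one member of each flagged pair (the lower-AIC/BIC one).
    """
    usable = []
    for c in covariates:
        v = table[c].to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            logger.warning("covariate %r has zero variance: excluded from screen", c)
            continue
        usable.append(c)
    flagged = []
    for i, a in enumerate(usable):
        for b in usable[i:]:
            rho = float(table[a].corr(table[b]))
            if abs(rho) > threshold:
                flagged.append((a, b, rho))
    return flagged


def _check_design(table: pd.DataFrame, spec: ModelSpec) -> None:
    import patsy

    y, x = patsy.dmatrices(spec.formula(), table, return_type="dataframe")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # name the aliased columns: those whose removal restores full rank
        aliased = []
        for j, name in enumerate(x.columns):
            sub = np.delete(x.to_numpy(), j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                aliased.append(name)
        raise ValueError(f"singular design; aliased terms: {aliased}")


def fit_mixed(spec: ModelSpec, table: pd.DataFrame, reml: bool = True) -> FitResult:
    """Gaussian linear mixed model with a random intercept per group."""
    if table[spec.group].nunique() < 2:
        raise ValueError("need >= 2 groups for a random-intercept model")
    _check_design(table, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(spec.formula(), table, groups=table[spec.group])
        res = model.fit(reml=reml)
    fe = res.fe_params
    ci = res.conf_int().loc[fe.index]
    ci.columns = ["lower", "upper"]
    k = len(fe) + 2  # fixed effects + two variance components
    llf = float(res.llf)
    n = int(res.nobs)
    return FitResult(
        params=fe,
        conf_int=ci,
        pvalues=res.pvalues.loc[fe.index],
        group_variance=float(np.squeeze(res.cov_re)),
        residual_variance=float(res.scale),
        aic=-2 * llf + 2 * k,
        bic=-2 * llf + k * np.log(n),
        converged=bool(res.converged),
        n_obs=n,
    )


def _term_pvalue(fit: FitResult, term: str) -> float:
    """p-value for a model term: the smallest Wald p among its design
    columns (a categorical term is kept if any level is significant)."""
    cols = [
        c for c in fit.pvalues.index
        if c == term or c.startswith(f"{term}[") or c.split("[")[0] == term
    ]
    if not cols:
        return float("nan")
    return float(fit.pvalues[cols].min())


def select_model(
    outcome: str,
    candidates: list[str],
    table: pd.DataFrame,
    group: str = "horse_id",
    entry_p: float = 0.20,
    stay_p: float = 0.05,
    forced: tuple[str, ...] = (),
    interactions: tuple[tuple[str, str], ...] = (),
    reml: bool = True,
) -> SelectionResult:
    """Univariable screen at p < entry_p, then backward elimination at
    p < stay_p, then testing of the supplied two-way interactions among
    retained main effects; a retained site-by-covariate interaction triggers
    site-stratified refits. Deterministic: p ties break by name order.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    uni_p: dict[str, float] = {}
    for cand in sorted(candidates):
        spec = ModelSpec(outcome, list(forced) + [cand], group=group)
        try:
            fit = fit_mixed(spec, table, reml=reml)
            uni_p[cand] = _term_pvalue(fit, cand)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("univariable fit failed for %r: %s", cand, exc)
            uni_p[cand] = float("nan")
    entered = [c for c in sorted(candidates) if np.isfinite(uni_p[c]) and uni_p[c] < entry_p]

    if not entered:
        spec = ModelSpec(outcome, list(forced), group=group)
        fit = fit_mixed(spec, table, reml=reml)
        return SelectionResult(
            spec, fit, uni_p, entered=[], retained=[],
            notice="no candidate passed the univariable screen; "
                   "intercept-only (plus forced terms) model returned",
        )

    retained = list(entered)
    while True:
        spec = ModelSpec(outcome, list(forced) + retained, group=group)
        fit = fit_mixed(spec, table, reml=reml)
        pvals = {t: _term_pvalue(fit, t) for t in retained}
        worst = max(retained, key=lambda t: (pvals[t], t))
        if pvals[worst] < stay_p or len(retained) == 0:
            break
        retained.remove(worst)
        if not retained:
            spec = ModelSpec(outcome, list(forced), group=group)
            fit = fit_mixed(spec, table, reml=reml)
            break

    kept_inter: list[str] = []
    for a, b in interactions:
        if a in retained and b in retained:
            term = f"{a}:{b}"
            trial = ModelSpec(outcome, list(forced) + retained + kept_inter + [term], group=group)
            try:
                tfit = fit_mixed(trial, table, reml=reml)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if _term_pvalue(tfit, term) < stay_p:
                kept_inter.append(term)
    if kept_inter:
        spec = ModelSpec(outcome, list(forced) + retained + kept_inter, group=group)
        fit = fit_mixed(spec, table, reml=reml)

    stratified = None
    if any("site" in t for t in kept_inter) and "site" in table.columns:
        stratified = {}
        strat_terms = [t for t in retained if "site" not in t]
        for site, sub in table.groupby("site", observed=True):
            if sub[group].nunique() < 2:
                continue
            sspec = ModelSpec(outcome, list(forced) + strat_terms, group=group)
            try:
                stratified[str(site)] = fit_mixed(sspec, sub, reml=reml)
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("stratified fit failed for site %s: %s", site, exc)

    return SelectionResult(
        spec, fit, uni_p, entered=entered, retained=retained,
        interactions_retained=kept_inter, stratified_fits=stratified,
    )


def expected_observations(n_horses: int, n_sites: int, n_layers: int, n_cycles: int) -> int:
    """Design bookkeeping: rows = horses x sites x layers x cycles."""
    return n_horses * n_sites * n_layers * n_cycles
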
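"""Linear models predicting a sequence's information density from metadata.

Ordinary least squares with treatment (dummy) coding: the intercept is the
response mean at the reference levels (tool / antler / Geissenkloesterle /
almost complete), and each factor coefficient is a shift against that
reference. Models are built stepwise — adding one theoretically motivated
term at a time and comparing by AIC — and effect sizes are reported as
semipartial R^2 (the drop in R^2 when a term is removed from the full
model), with a one-sided bootstrap lower confidence bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

#: Reference level per factor predictor, used for treatment coding.
DEFAULT_REFERENCES: dict[str, str] = {
    "object_type": "tool",
    "material": "antler",
    "site": "Geissenkloesterle",
    "preservation": "almost_complete",
}

#: Predictors treated as continuous (no dummy coding).
CONTINUOUS_TERMS = ("volume", "max_date")


@dataclass(frozen=True)
class ModelFit:
    """A fitted OLS model plus the summaries the model ladder reports."""

    terms: tuple[str, ...]
    formula: str
    coefficients: pd.DataFrame  # estimate, std_err, t, p per parameter
    aic: float
    f_stat: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n_params: int
    r_squared: float
    residuals: np.ndarray
    fitted: np.ndarray
    result: object = field(repr=False, compare=False, default=None)

    @property
    def label(self) -> str:
        return " + ".join(("Intercept",) + self.terms)


def _term_expr(term: str, references: Mapping[str, str]) -> str:
    """Render one model term, dummy-coding factors with their reference level."""
    def atom(name: str) -> str:
        if name in references:
            return f'C({name}, Treatment(reference="{references[name]}"))'
        return name

    if "*" in term:
        a, b = (t.strip() for t in term.split("*", 1))
        return f"{atom(a)} * {atom(b)}"
    return atom(term.strip())


def build_formula(
    response: str, terms: Sequence[str], references: Mapping[str, str] | None = None
) -> str:
    """Patsy formula for ``response ~ terms`` with treatment-coded factors."""
    references = DEFAULT_REFERENCES if references is None else references
    if not terms:
        return f"{response} ~ 1"
    return f"{response} ~ " + " + ".join(_term_expr(t, references) for t in terms)


def fit_entropy_rate_model(
    data: pd.DataFrame,
    terms: Sequence[str] = (),
    response: str = "entropy_rate",
    references: Mapping[str, str] | None = None,
) -> ModelFit:
    """OLS fit of ``response`` on the given terms with treatment coding.

    Rows with missing values in the response or any used predictor are
    dropped listwise. Rank-deficient design matrices are rejected with the
    collinear columns named.
    """
    formula = build_formula(response, terms, references)
    res = smf.ols(formula, data=data).fit()
    exog = res.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name columns whose removal restores full rank
        names = res.model.exog_names
        collinear = []
        for j in range(exog.shape[1]):
            keep = [c for c in range(exog.shape[1]) if c != j]
            if np.linalg.matrix_rank(exog[:, keep]) == rank:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")
    if len(data) < exog.shape[1] + 2:
        raise ValueError("need at least 2 more rows than parameters")
    coef = pd.DataFrame(
        {
            "estimate": res.params,
            "std_err": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
            "ci_low": res.conf_int()[0],
            "ci_high": res.conf_int()[1],
        }
    )
    return ModelFit(
        terms=tuple(terms),
        formula=formula,
        coefficients=coef,
        aic=float(res.aic),
        f_stat=float(res.fvalue) if terms else float("nan"),
        f_pvalue=float(res.f_pvalue) if terms else float("nan"),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        n_params=exog.shape[1],
        r_squared=float(res.rsquared),
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        result=res,
    )


def stepwise_aic_selection(
    data: pd.DataFrame,
    base_terms: Sequence[str] = ("volume", "max_date", "object_type"),
    alternative_terms: Sequence[str] = ("site", "preservation", "material"),
    interaction_terms: Sequence[str] = (
        "volume*preservation",
        "volume*object_type",
        "max_date*object_type",
    ),
    response: str = "entropy_rate",
    references: Mapping[str, str] | None = None,
) -> tuple[list[ModelFit], ModelFit]:
    """Build the stepwise model ladder and select the AIC-best model.

    The ladder starts from the intercept-only model, adds the base terms
    cumulatively in their theoretically motivated order, then tries each
    alternative term and each interaction on top of the full base. Lower
    AIC indicates the preferable model; the full ladder is returned so
    the comparison is inspectable, with the minimum-AIC fit singled out.
    """
    ladder: list[ModelFit] = [fit_entropy_rate_model(data, (), response, references)]
    acc: list[str] = []
    for term in base_terms:
        acc.append(term)
        ladder.append(fit_entropy_rate_model(data, tuple(acc), response, references))
    for extra in tuple(alternative_terms) + tuple(interaction_terms):
        if "*" in extra:
            parts = {t.strip() for t in extra.split("*")}
            terms = tuple(t for t in acc if t not in parts) + (extra,)
        else:
            terms = tuple(acc) + (extra,)
        ladder.append(fit_entropy_rate_model(data, terms, response, references))
    best = min(ladder, key=lambda m: m.aic)
    return ladder, best


def ladder_table(ladder: Sequence[ModelFit]) -> pd.DataFrame:
    """Model-comparison table: specification, df, F, p, AIC per rung."""
    return pd.DataFrame(
        {
            "model": [m.label for m in ladder],
            "df": [m.n_params for m in ladder],
            "resid_df": [m.df_resid for m in ladder],
            "F": [m.f_stat for m in ladder],
            "p": [m.f_pvalue for m in ladder],
            "AIC": [m.aic for m in ladder],
            "r_squared": [m.r_squared for m in ladder],
        }
    )


@dataclass(frozen=True)
class SemipartialR2:
    """Semipartial R^2 of one term with a one-sided bootstrap lower bound."""

    term: str
    delta_r2: float
    ci_lower: float
    ci_upper: float = 1.0
    n_boot: int = 0


def semipartial_r2(
    data: pd.DataFrame,
    full_terms: Sequence[str],
    dropped_term: str,
    n_boot: int = 1000,
    seed: int = 0,
    response: str = "entropy_rate",
    references: Mapping[str, str] | None = None,
) -> SemipartialR2:
    """Effect size of one term: R^2(full) - R^2(full without the term).

    The uncertainty is a one-sided 95% interval [lower, 1], with the lower
    bound the 5th percentile of the statistic over ``n_boot`` nonparametric
    bootstrap resamples of the rows.
    """
    if dropped_term not in full_terms:
        raise ValueError(f"{dropped_term!r} not in full model terms {full_terms}")
    reduced = tuple(t for t in full_terms if t != dropped_term)

    def delta(d: pd.DataFrame) -> float:
        full = fit_entropy_rate_model(d, full_terms, response, references)
        red = fit_entropy_rate_model(d, reduced, response, references)
        return full.r_squared - red.r_squared

    point = delta(data)
    rng = np.random.default_rng(seed)
    boots = []
    n = len(data)
    for _ in range(n_boot):
        sample = data.iloc[rng.integers(0, n, size=n)]
        try:
            boots.append(delta(sample))
        except ValueError:
            continue  # resample lost a factor level; skip it
    lower = float(np.quantile(boots, 0.05)) if boots else float("nan")
    return SemipartialR2(dropped_term, float(point), lower, 1.0, len(boots))


@dataclass(frozen=True)
class DiagnosticsReport:
    """Residual diagnostics: flags, never hard failures."""

    shapiro_stat: float
    shapiro_p: float
    normality_ok: bool
    bp_stat: float
    bp_p: float
    homoscedastic: bool
    resid_fitted_corr: float
    degenerate_residuals: bool

    def flags(self) -> list[str]:
        out = []
        if self.degenerate_residuals:
            out.append("degenerate-residuals")
        if not self.normality_ok:
            out.append("non-normal-residuals")
        if not self.homoscedastic:
            out.append("heteroscedastic")
        return out


def model_diagnostics(fit: ModelFit, alpha: float = 0.05) -> DiagnosticsReport:
    """Check the linear-model assumptions on a fitted model's residuals.

    Shapiro-Wilk for normality, Breusch-Pagan for homoscedasticity, and
    the residual-vs-fitted correlation as a linearity summary. A residual
    variance of (numerically) zero marks the fit degenerate, in which case
    the tests are undefined and skipped.
    """
    resid = fit.residuals
    degenerate = bool(np.var(resid) < 1e-12)
    if degenerate:
        return DiagnosticsReport(
            float("nan"), float("nan"), True,
            float("nan"), float("nan"), True,
            float("nan"), True,
        )
    sh_stat, sh_p = stats.shapiro(resid)
    exog = fit.result.model.exog if fit.result is not None else np.column_stack(
        [np.ones_like(fit.fitted), fit.fitted]
    )
    if exog.shape[1] < 2:
        # intercept-only model: no regressors to drive the variance, the
        # Breusch-Pagan statistic is undefined
        bp_stat, bp_p = float("nan"), 1.0
    else:
        bp_stat, bp_p, _, _ = het_breuschpagan(resid, exog)
    corr = float(np.corrcoef(resid, fit.fitted)[0, 1]) if np.var(fit.fitted) > 0 else 0.0
    return DiagnosticsReport(
        shapiro_stat=float(sh_stat),
        shapiro_p=float(sh_p),
        normality_ok=bool(sh_p > alpha),
        bp_stat=float(bp_stat),
        bp_p=float(bp_p),
        homoscedastic=bool(bp_p > alpha),
        resid_fitted_corr=corr,
        degenerate_residuals=False,
    )
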
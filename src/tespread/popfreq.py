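"""Associations between genic H3K9me3 and nearest-TE population frequency.

TEs under stronger purifying selection segregate at lower frequencies, so if
heterochromatin spreading from a TE into its neighbouring gene is
deleterious, genes with higher H3K9me3 should have rarer nearest TEs.  This
module provides the statistics used to test that prediction and its
confounders: group contrasts by observed/not-observed status, plain and
partial Spearman correlations, the stage-enrichment-count association,
family-aware ANOVA on log density (with a mixed-model variant), and
quadratic logistic models of TE presence with backward AIC selection.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TEFrequency:
    te_id: str
    n_present: int
    n_absent: int
    n_no_call: int

    @property
    def n_called(self) -> int:
        return self.n_present + self.n_absent

    @property
    def frequency(self) -> float:
        return self.n_present / self.n_called

    @property
    def observed(self) -> bool:
        return self.frequency > 0


def te_population_frequency(calls: Sequence[str], te_id: str = "") -> TEFrequency:
    """Population frequency of a TE from per-genome present/absent/no_call calls.

    The denominator excludes no-calls.  A TE present in no called genome —
    seen only in the reference — has frequency 0 and observed = False.
    """
    counts = pd.Series(list(calls)).value_counts()
    f = TEFrequency(
        te_id=te_id,
        n_present=int(counts.get("present", 0)),
        n_absent=int(counts.get("absent", 0)),
        n_no_call=int(counts.get("no_call", 0)),
    )
    if f.n_called == 0:
        raise ValueError(f"TE {te_id}: all genomes are no-calls")
    return f


def group_compare(values_a: Sequence[float], values_b: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney U contrast of two groups, with medians."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("group_compare requires non-empty groups")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "p": float(res.pvalue),
        "U": float(res.statistic),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": a.size,
        "n_b": b.size,
    }


def spearman_suite(
    x: Sequence[float], y: Sequence[float], covariate: Sequence[float] | None = None
) -> tuple[float, float]:
    """Spearman rho and p, optionally partialling out a covariate.

    The partial correlation uses the pairwise-rho formula on rank-transformed
    data, r_xy.z = (rho_xy - rho_xz rho_yz) / sqrt((1-rho_xz^2)(1-rho_yz^2)),
    with the p-value from a t approximation on n-3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    for v in (x, y):
        if np.unique(v).size < 2:
            raise ValueError("zero variance in a ranked vector")
    if covariate is None:
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    z = np.asarray(covariate, dtype=float)
    if np.unique(z).size < 2:
        raise ValueError("zero variance in the covariate")
    rxy = stats.spearmanr(x, y).statistic
    rxz = stats.spearmanr(x, z).statistic
    ryz = stats.spearmanr(y, z).statistic
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0:
        raise ValueError("covariate perfectly rank-correlated with x or y")
    r = (rxy - rxz * ryz) / denom
    n = x.size
    df = n - 3
    r = float(np.clip(r, -1, 1))
    if abs(r) == 1:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    return r, float(2 * stats.t.sf(abs(t), df))


def stage_count_association(
    records: pd.DataFrame,
    count_col: str = "stage_enrichment_count",
    freq_col: str = "nearest_te_frequency",
    exclude_genes: Sequence[str] = (),
) -> dict:
    """Spearman association between stage-enrichment count and nearest-TE
    frequency.  Genes in ``exclude_genes`` are dropped (robustness variant).
    Returns {"rho": ..., "p": ..., "n": ...}; rho/p are NaN when either
    vector is constant."""
    df = records.drop(index=[g for g in exclude_genes if g in records.index], errors="ignore")
    df = df[[count_col, freq_col]].dropna()
    if df.empty or df[count_col].nunique() < 2 or df[freq_col].nunique() < 2:
        return {"rho": float("nan"), "p": float("nan"), "n": len(df)}
    rho, p = spearman_suite(df[count_col], df[freq_col])
    return {"rho": rho, "p": p, "n": len(df)}


@dataclass
class ModelReport:
    family: str
    terms: list[str]
    coefficients: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    aic_trail: list[tuple[str, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    anova: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "terms": self.terms,
            "coefficients": self.coefficients,
            "pvalues": self.pvalues,
            "aic_trail": self.aic_trail,
            "warnings": self.warnings,
        }


def anova_te_family(
    records: pd.DataFrame,
    density_col: str = "h3k9_density",
    observed_col: str = "nearest_te_observed",
    family_col: str = "nearest_te_family",
    frequency_col: str = "nearest_te_frequency",
) -> ModelReport:
    """Two-way ANOVA: log density ~ observed/not + TE family + interaction.

    Restricted to genes with positive density (the zero-inflated tail defeats
    any transform), with the density log-transformed.  When only one family
    is present the family and interaction terms are dropped and the model
    reduces to a one-way comparison.  A companion mixed model treats family
    as a random intercept and reports the sign of the TE-frequency
    coefficient.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = records[[density_col, observed_col, family_col]].dropna()
    df = df[df[density_col] > 0].copy()
    df["log_density"] = np.log(df[density_col])
    df["observed"] = df[observed_col].astype(bool)
    df["family"] = df[family_col].astype(str)
    report = ModelReport(family="anova", terms=[])
    n_fam = df["family"].nunique()
    if df["observed"].nunique() < 2:
        raise ValueError("both observed states must be present")
    # interaction needs >= 2 families with both observed states represented
    both_states = (
        df.groupby("family")["observed"].nunique().ge(2).sum() if n_fam > 1 else 0
    )
    if n_fam < 2:
        formula = "log_density ~ C(observed)"
        report.warnings.append("single TE family: family and interaction terms dropped")
    elif both_states < 2:
        formula = "log_density ~ C(observed) + C(family)"
        report.warnings.append("interaction term dropped: too few families with both states")
    else:
        formula = "log_density ~ C(observed) + C(family) + C(observed):C(family)"
    fit = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report.anova = anova_lm(fit, typ=2)
    report.terms = [t for t in report.anova.index if t != "Residual"]
    report.pvalues = {
        t: float(report.anova.loc[t, "PR(>F)"]) for t in report.terms
    }
    report.coefficients = {k: float(v) for k, v in fit.params.items()}
    # mixed-model companion: frequency slope with family as random intercept
    if frequency_col in records.columns and n_fam >= 2:
        mdf = records[[density_col, frequency_col, family_col]].dropna()
        mdf = mdf[mdf[density_col] > 0].copy()
        mdf["log_density"] = np.log(mdf[density_col])
        mdf["frequency"] = mdf[frequency_col].astype(float)
        mdf["family"] = mdf[family_col].astype(str)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mixed = smf.mixedlm(
                    "log_density ~ frequency", data=mdf, groups=mdf["family"]
                ).fit(reml=True)
            report.coefficients["mixed_frequency"] = float(mixed.params["frequency"])
            report.pvalues["mixed_frequency"] = float(mixed.pvalues["frequency"])
        except Exception as exc:  # singular fits on tiny data
            report.warnings.append(f"mixed model failed: {exc}")
    return report


def _fit_logit(df: pd.DataFrame, response: str, terms: Sequence[str]):
    import statsmodels.api as sm

    X = sm.add_constant(df[list(terms)], has_constant="add") if terms else pd.DataFrame(
        {"const": np.ones(len(df))}, index=df.index
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(df[response].astype(float), X).fit(disp=0, maxiter=200)


def logistic_frequency_model(
    records: pd.DataFrame,
    response_col: str = "observed",
    predictors: Sequence[str] = ("h3k9_density", "recomb_rate"),
) -> ModelReport:
    """Quadratic logistic model of TE presence with backward AIC selection.

    The full model is logit p ~ x + x^2 for each predictor (density or
    stage count, and recombination rate).  Backward elimination removes one
    term at a time while the AIC improves; a quadratic term shields its
    linear parent (hierarchy), so x can only leave after x^2.  Terms that are
    eliminated simply do not appear in the retained set.
    """
    df = records.copy()
    y = df[response_col].astype(int)
    if y.nunique() < 2:
        raise ValueError("logistic model needs both response classes present")
    terms = []
    for p in predictors:
        q = f"{p}_sq"
        df[q] = df[p].astype(float) ** 2
        terms.extend([p, q])
    df = df[[response_col] + terms].dropna()
    report = ModelReport(family="logistic", terms=[])
    current = list(terms)
    fit = _fit_logit(df, response_col, current)
    report.aic_trail.append(("full", float(fit.aic)))
    improved = True
    while improved and current:
        improved = False
        best_aic = fit.aic
        best_drop = None
        for t in current:
            if not t.endswith("_sq") and f"{t}_sq" in current:
                continue  # hierarchy: quadratic must leave first
            trial = _fit_logit(df, response_col, [u for u in current if u != t])
            if trial.aic < best_aic - 1e-9:
                best_aic, best_drop = trial.aic, t
        if best_drop is not None:
            current.remove(best_drop)
            fit = _fit_logit(df, response_col, current)
            report.aic_trail.append((f"-{best_drop}", float(fit.aic)))
            improved = True
    report.terms = list(current)
    report.coefficients = {k: float(v) for k, v in fit.params.items()}
    report.pvalues = {k: float(v) for k, v in fit.pvalues.items()}
    if not fit.mle_retvals.get("converged", True) or np.abs(fit.params).max() > 50:
        report.warnings.append(
            "possible complete separation: coefficients unreliable"
        )
    return report
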
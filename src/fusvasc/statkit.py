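"""Statistical layer for the quantification tables.

Benjamini-Hochberg FDR control and MRI percent-signal-change are implemented
from their definitions; the standard hypothesis tests (paired t, one-way
ANOVA, Mann-Whitney U, Kolmogorov-Smirnov, Pearson correlation) and the
factorial general linear model are delegated to scipy / statsmodels behind a
uniform result interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "TestResult",
    "GlmResult",
    "bh_adjust",
    "percent_signal_change",
    "compare_groups",
    "fit_glm",
    "pearson_corr",
]


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class GlmResult:
    terms: pd.DataFrame  # index: term; columns: F, p_value, df
    r_squared: float
    adj_r_squared: float
    design: str

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1:
            raise ValueError("R^2 must lie in [0, 1]")
        if self.adj_r_squared > self.r_squared + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed R^2")


def bh_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up procedure.

    Returns per-hypothesis rejection decisions (original order) and the
    data-driven significance threshold — the largest p-value declared
    significant (NaN when nothing is rejected).  The threshold is an output
    of the procedure on the supplied p-value set, recomputed every time.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), float("nan")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) / m) * q
    if not below.any():
        return np.zeros(m, dtype=bool), float("nan")
    k = int(np.max(np.nonzero(below)[0]))
    threshold = ranked[k]
    return p <= threshold, float(threshold)


def percent_signal_change(
    roi_treated_mean: float, roi_contralateral_mean: float
) -> float:
    """Percent signal change of a treated ROI against the untreated
    contralateral side: (treated - contralateral) / contralateral * 100."""
    if roi_contralateral_mean <= 0:
        raise ValueError("contralateral mean must be positive")
    return (
        (roi_treated_mean - roi_contralateral_mean)
        / roi_contralateral_mean
        * 100.0
    )


def compare_groups(samples, design: str) -> TestResult | list[TestResult]:
    """Dispatch a group comparison to the named standard test.

    ``paired`` — within-animal paired-samples t-test on two equal-length
    samples; ``independent-factorial`` — one-way (univariate) ANOVA across
    two or more independent samples; ``distributional`` — Mann-Whitney U
    (central tendency) and Kolmogorov-Smirnov (overall distribution),
    returned as a pair.
    """
    groups = [np.asarray(s, dtype=float) for s in samples]
    sizes = tuple(len(g) for g in groups)
    if design == "paired":
        if len(groups) != 2:
            raise ValueError("paired design needs exactly two samples")
        if sizes[0] != sizes[1]:
            raise ValueError("paired samples must have equal lengths")
        if sizes[0] < 2:
            raise ValueError("need at least two pairs")
        if np.array_equal(groups[0], groups[1]):
            return TestResult("paired_t", 0.0, 1.0, sizes)
        stat, p = stats.ttest_rel(groups[0], groups[1])
        return TestResult("paired_t", float(stat), float(p), sizes)
    if design == "independent-factorial":
        if len(groups) < 2 or any(s < 2 for s in sizes):
            raise ValueError("ANOVA needs >= 2 groups of >= 2 observations")
        stat, p = stats.f_oneway(*groups)
        return TestResult("anova_f", float(stat), float(p), sizes)
    if design == "distributional":
        if len(groups) != 2 or any(s < 2 for s in sizes):
            raise ValueError("distributional design needs two samples")
        u, pu = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        ks, pk = stats.ks_2samp(groups[0], groups[1])
        return [
            TestResult("mannwhitney_u", float(u), float(pu), sizes),
            TestResult("kolmogorov_smirnov", float(ks), float(pk), sizes),
        ]
    raise ValueError(f"unknown design {design!r}")


def fit_glm(
    table: pd.DataFrame,
    response: str,
    factors: tuple[str, ...] = ("tissue", "drug", "n_treatments"),
    covariates: tuple[str, ...] = (),
) -> GlmResult:
    """Factorial general linear model on a quantification table.

    Ordinary least squares with treatment-coded categorical factors, all
    two-way interactions and the full interaction, plus optional numeric
    covariates; per-term F statistics use Type II sums of squares.
    """
    missing = [c for c in (response, *factors, *covariates) if c not in table]
    if missing:
        raise ValueError(f"columns missing from table: {missing}")
    rhs = " * ".join(f"C({f})" for f in factors)
    if covariates:
        rhs = rhs + " + " + " + ".join(covariates)
    formula = f"{response} ~ {rhs}"
    model = smf.ols(formula, data=table)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        _, r = np.linalg.qr(model.exog)
        aliased = [
            model.exog_names[j]
            for j in range(model.exog.shape[1])
            if abs(r[j, j]) < 1e-8
        ]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    fit = model.fit()
    table_anova = anova_lm(fit, typ=2)
    terms = table_anova.rename(
        columns={"F": "F", "PR(>F)": "p_value", "df": "df"}
    )[["F", "p_value", "df"]]
    return GlmResult(
        terms=terms,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(min(fit.rsquared, fit.rsquared_adj)),
        design=formula,
    )


def pearson_corr(x, y) -> TestResult:
    """Pearson product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return TestResult("pearson_r", float(r), float(p), (int(x.size),))
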
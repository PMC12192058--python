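"""Statistical battery for vascular-density tables and cohort covariates.

Wraps the standard tests used to analyse cross-modality vascular density
data and physiological covariates: Pearson correlation matrices, ordinary
least squares with interactions, one-way ANOVA / ANCOVA / two-way
repeated-measures ANOVA with Tukey HSD post hoc, the two-sample
Kolmogorov–Smirnov and pooled-variance t tests, and the two-way
random-effects absolute-agreement single-measure intraclass correlation
ICC(2,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DensityTable",
    "correlation_matrix",
    "fit_linear_model",
    "anova_suite",
    "ks_two_sample",
    "t_two_sample",
    "icc_two_way",
]

MODALITIES = ("SRUS", "uCT")
SEGMENTS = ("cranial", "central", "caudal")
ROIS = ("total", "cortex", "medulla")


@dataclass
class DensityTable:
    """Long-format vascular density records.

    One row per (animal, modality, segment, roi); density is a fraction in
    [0, 1].
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"animal", "modality", "segment", "roi", "density"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"density table needs columns {sorted(need)}")
        dens = self.records["density"]
        if ((dens < 0) | (dens > 1)).any():
            raise ValueError("densities must lie in [0, 1]")
        dup = self.records.duplicated(subset=["animal", "modality", "segment", "roi"])
        if dup.any():
            raise ValueError("at most one record per (animal, modality, segment, roi)")

    def to_csv(self, path: str) -> None:
        self.records.to_csv(path, index=False)


def correlation_matrix(table: pd.DataFrame, columns: list[str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p for the numeric columns.

    Constant columns give undefined correlations, reported as NaN.
    Returns (r matrix, p matrix) as DataFrames.
    """
    if columns is None:
        columns = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    k = len(columns)
    r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    p = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[columns[i], columns[j]]].dropna()
            if len(sub) < 3:
                raise ValueError(
                    f"need >= 3 complete cases for ({columns[i]}, {columns[j]})"
                )
            a, b = sub.iloc[:, 0].to_numpy(float), sub.iloc[:, 1].to_numpy(float)
            if np.std(a) == 0 or np.std(b) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = sps.pearsonr(a, b)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    return r, p


def fit_linear_model(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    interactions: list[tuple[str, str]] | None = None,
):
    """Ordinary least squares with optional pairwise interactions.

    Returns the fitted statsmodels results object (coefficients, overall F
    vs the intercept-only model, R², adjusted R², per-term p values).
    """
    import statsmodels.formula.api as smf

    terms = list(predictors)
    for a, b in interactions or []:
        terms.append(f"{a}:{b}")
    formula = f"{outcome} ~ " + " + ".join(terms)
    n, p = len(table), len(terms)
    if n <= p + 1:
        raise ValueError("need more observations than model parameters")
    model = smf.ols(formula, data=table)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix; drop collinear predictors")
    return model.fit()


def anova_suite(
    table: pd.DataFrame,
    design: str,
    outcome: str = "density",
    group: str | None = None,
    covariate: str | None = None,
    subject: str = "animal",
    within: list[str] | None = None,
) -> dict:
    """One-way ANOVA, ANCOVA, or two-way repeated-measures ANOVA.

    ``design`` is one of ``oneway``, ``ancova``, ``twoway_repeated``.
    Tukey HSD pairwise comparisons are attached for the between-group
    designs.  Repeated-measures designs drop subjects with incomplete
    blocks (listwise, with a warning).
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import AnovaRM, anova_lm
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    out: dict = {"design": design}
    if design == "oneway":
        if group is None:
            raise ValueError("oneway design needs a group column")
        groups = [g[outcome].to_numpy(float) for _, g in table.groupby(group)]
        if len(groups) < 2:
            raise ValueError("need >= 2 groups")
        f, p = sps.f_oneway(*groups)
        out["F"], out["p"] = float(f), float(p)
        out["tukey"] = pairwise_tukeyhsd(
            table[outcome].to_numpy(float), table[group].astype(str).to_numpy()
        )
    elif design == "ancova":
        if group is None or covariate is None:
            raise ValueError("ancova needs group and covariate columns")
        model = smf.ols(f"{outcome} ~ C({group}) * {covariate}", data=table).fit()
        out["table"] = anova_lm(model, typ=2)
        out["tukey"] = pairwise_tukeyhsd(
            table[outcome].to_numpy(float), table[group].astype(str).to_numpy()
        )
    elif design == "twoway_repeated":
        within = within or ["modality", "roi"]
        counts = table.groupby(subject).size()
        full = counts.max()
        bad = counts[counts < full].index
        if len(bad):
            warnings.warn(f"dropping {len(bad)} subjects with incomplete blocks")
            table = table[~table[subject].isin(bad)]
        res = AnovaRM(table, depvar=outcome, subject=subject, within=within).fit()
        out["table"] = res.anova_table
    else:
        raise ValueError(f"unknown design {design!r}")
    return out


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov–Smirnov statistic D and asymptotic p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def t_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test: (t, df = n1+n2-2, two-sided p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), len(a) + len(b) - 2, float(res.pvalue)


def icc_two_way(
    table: pd.DataFrame,
    rater_col: str = "rater",
    item_col: str = "item",
    value_col: str = "value",
) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""
    import pingouin as pg

    piv = table.pivot(index=item_col, columns=rater_col, values=value_col)
    if piv.isna().any().any():
        raise ValueError("ICC requires a complete rater x item table")
    if piv.shape[0] < 2 or piv.shape[1] < 2:
        raise ValueError("ICC needs >= 2 raters and >= 2 items")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(
            data=table, targets=item_col, raters=rater_col, ratings=value_col
        )
    # two-way random, absolute agreement, single measure; label differs by version
    sel = res["Type"].isin(["ICC(A,1)", "ICC2"])
    return float(res.loc[sel, "ICC"].iloc[0])
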
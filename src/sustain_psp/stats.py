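"""Descriptive and inferential statistics linking subtypes, stages, syndromes
and clinical scores.

Conventions: two-sample t-tests are Welch (unequal variance) with
Satterthwaite degrees of freedom; chi-square is Pearson without continuity
correction; every p-value is reported with both an uncorrected flag and a
Bonferroni-corrected flag for a stated family size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class StatResult:
    name: str
    statistic: float
    df: float
    p_value: float
    family_size: int = 1
    group_summaries: list = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant_uncorrected(self) -> bool:
        return self.p_value < 0.05

    @property
    def corrected_threshold(self) -> float:
        return 0.05 / self.family_size

    @property
    def significant_corrected(self) -> bool:
        return self.p_value < self.corrected_threshold


def welch_t(mean_a=None, sd_a=None, n_a=None, mean_b=None, sd_b=None,
            n_b=None, a=None, b=None, name: str = "welch_t",
            family_size: int = 1) -> StatResult:
    """Welch unequal-variance t-test from summary statistics or raw vectors.

    Sign convention: ``t = (first - second) / se``.
    """
    if a is not None or b is not None:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        mean_a, sd_a, n_a = a.mean(), a.std(ddof=1), a.size
        mean_b, sd_b, n_b = b.mean(), b.std(ddof=1), b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0 or (sd_a == 0 and sd_b == 0):
        raise ValueError("invalid standard deviations")
    res = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                   equal_var=False)
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return StatResult(
        name, float(res.statistic), float(df), float(res.pvalue),
        family_size=family_size,
        group_summaries=[(mean_a, sd_a, n_a), (mean_b, sd_b, n_b)])


def chi_square(counts, family_size: int = 1, name: str = "chi_square"):
    """Pearson chi-square (no continuity correction) with pairwise post-hoc
    row comparisons, Bonferroni-corrected over the number of row pairs.

    Returns ``(StatResult, post_hoc_table)``.
    """
    table = np.asarray(counts, dtype=float)
    res = sps.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq <= 0):
        raise ValueError("all expected counts must be positive")
    overall = StatResult(name, float(res.statistic), float(res.dof),
                         float(res.pvalue), family_size=family_size)
    pairs = list(combinations(range(table.shape[0]), 2))
    rows = []
    for i, j in pairs:
        sub = table[[i, j]]
        # A degenerate 2xk sub-table (empty column) is compared on its
        # populated columns only.
        sub = sub[:, sub.sum(axis=0) > 0]
        r = sps.chi2_contingency(sub, correction=False)
        p_adj = min(1.0, float(r.pvalue) * len(pairs))
        rows.append({"row_a": i, "row_b": j, "chi2": float(r.statistic),
                     "df": float(r.dof), "p": float(r.pvalue),
                     "p_bonferroni": p_adj})
    return overall, pd.DataFrame(rows)


def prorate_score(item_scores, items_expected: int) -> float:
    """Adjusted assessment total when at least 80% of items were completed:
    mean of completed items times the expected item count; otherwise NaN."""
    items = np.asarray(item_scores, dtype=float)
    completed = items[np.isfinite(items)]
    if items_expected <= 0:
        raise ValueError("items_expected must be positive")
    if completed.size / items_expected >= 0.8:
        return float(completed.mean() * items_expected)
    return float("nan")


def clinical_score_lm(data: pd.DataFrame, score: str,
                      family_size: int = 10) -> pd.DataFrame:
    """OLS of ``score ~ subtype + stage + age + sex`` on subtypable scans.

    ``subtype`` must be coded numerically with the cortical subtype = 1 so
    that negative subtype coefficients mean the other (subcortical) subtype
    scores worse on scales where higher is worse. Returns a per-term
    coefficient table with direction labels.
    """
    cols = [score, "subtype", "stage", "age", "sex"]
    df = data[cols].dropna()
    if "subtypable" in data.columns:
        df = df[data.loc[df.index, "subtypable"]]
    if len(df) < 20:
        raise ValueError(f"{score}: fewer than 20 complete cases")
    model = smf.ols(f"{score} ~ subtype + stage + age + C(sex)", data=df)
    try:
        res = model.fit()
    except Exception as exc:  # pragma: no cover
        raise ValueError(f"{score}: model fit failed ({exc})") from exc
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(f"{score}: rank-deficient design (collinear terms)")
    out = pd.DataFrame({
        "term": res.params.index,
        "coef": res.params.to_numpy(),
        "t": res.tvalues.to_numpy(),
        "p": res.pvalues.to_numpy(),
    })
    out["significant_uncorrected"] = out["p"] < 0.05
    out["significant_corrected"] = out["p"] < 0.05 / family_size
    out["n"] = len(df)
    return out


def subtype_covariate_logit(data: pd.DataFrame,
                            outcome: str = "subtype") -> pd.DataFrame:
    """Logistic regression of subtype on stage and the regressed covariates.

    The stage term is the headline check: a clean subtype model shows no
    residual dependence of subtype on stage. Categorical levels with fewer
    than 3 observations are collapsed into the reference with a warning.
    """
    import warnings

    df = data.dropna(subset=[outcome]).copy()
    y = df[outcome].astype(int)
    if y.nunique() < 2:
        raise ValueError("subtype outcome is constant (degenerate)")
    terms = ["stage", "tiv_mm3", "age"]
    X = df[terms].astype(float).copy()
    X["tiv_mm3"] = X["tiv_mm3"] / 1e5   # scale for optimizer conditioning
    for cat in ["sex", "field_strength", "manufacturer", "cohort"]:
        if cat not in df.columns:
            continue
        values = df[cat].astype(str)
        counts = values.value_counts()
        ref = counts.index[0]
        small = [l for l in counts.index if counts[l] < 3 and l != ref]
        if small:
            warnings.warn(f"{cat}: collapsing sparse level(s) {small} "
                          f"into reference '{ref}'", stacklevel=2)
            values = values.where(~values.isin(small), ref)
        for lev in sorted(set(values) - {ref}):
            X[f"{cat}[{lev}]"] = (values == lev).astype(float)
    X = sm.add_constant(X)
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    return pd.DataFrame({
        "term": res.params.index,
        "coef": res.params.to_numpy(),
        "z": res.tvalues.to_numpy(),
        "p": res.pvalues.to_numpy(),
    })


def stage_anova(data: pd.DataFrame, stage: str = "expected_stage",
                syndrome: str = "syndrome", subtype: str = "subtype"):
    """Additive two-factor ANOVA ``stage ~ syndrome + subtype`` with Tukey
    HSD pairwise syndrome comparisons.

    Returns ``(anova_table, tukey_frame)``. Unbalanced cells are handled by
    least squares; a single-observation cell only triggers a warning.
    """
    import warnings

    df = data[[stage, syndrome, subtype]].dropna().copy()
    for factor in (syndrome, subtype):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor} needs >= 2 levels")
    cell_n = df.groupby([syndrome, subtype], observed=True)[stage].count()
    if (cell_n < 2).any():
        warnings.warn("single-observation cell(s) in the syndrome x subtype "
                      "layout; estimates rely on unbalanced least squares",
                      stacklevel=2)
    res = smf.ols(f"{stage} ~ C({syndrome}) + C({subtype})", data=df).fit()
    table = anova_lm(res, typ=2)
    tk = pairwise_tukeyhsd(df[stage].to_numpy(),
                           df[syndrome].astype(str).to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:],
                         columns=tk.summary().data[0])
    return table, tukey


def demographics_table(data: pd.DataFrame, group_col: str,
                       continuous: list[str], categorical: list[str],
                       family_size: int = 44) -> pd.DataFrame:
    """Pairwise group comparisons: Welch t for continuous rows, chi-square
    for categorical rows, with the stated correction family."""
    groups = sorted(data[group_col].dropna().unique())
    rows = []
    for g1, g2 in combinations(groups, 2):
        d1, d2 = data[data[group_col] == g1], data[data[group_col] == g2]
        for var in continuous:
            a, b = d1[var].dropna(), d2[var].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            r = welch_t(a=a, b=b, name=var, family_size=family_size)
            rows.append({
                "variable": var, "group_a": g1, "group_b": g2,
                "statistic": r.statistic, "df": r.df, "p": r.p_value,
                "mean_a": a.mean(), "sd_a": a.std(ddof=1), "n_a": len(a),
                "mean_b": b.mean(), "sd_b": b.std(ddof=1), "n_b": len(b),
                "significant_uncorrected": r.significant_uncorrected,
                "significant_corrected": r.significant_corrected,
            })
        for var in categorical:
            tab = pd.crosstab(data[group_col], data[var])
            tab = tab.loc[[g1, g2]]
            tab = tab.loc[:, tab.sum(axis=0) > 0]
            if tab.shape[1] < 2:
                continue
            r, _ = chi_square(tab.to_numpy(), family_size=family_size,
                              name=var)
            rows.append({
                "variable": var, "group_a": g1, "group_b": g2,
                "statistic": r.statistic, "df": r.df, "p": r.p_value,
                "significant_uncorrected": r.significant_uncorrected,
                "significant_corrected": r.significant_corrected,
            })
    return pd.DataFrame(rows)
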
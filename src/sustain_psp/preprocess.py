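"""From raw volume tables to the sign-flipped z-score biomarker panel.

Pipeline order is fixed: combine hemispheres -> covariate-adjust against
controls -> select biomarkers by effect size -> z-score against controls.
Re-running on identical input is bit-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

ROI_PREFIX = "roi_"

#: Covariates of the adjustment model. Continuous terms enter as-is;
#: categorical terms are treatment-coded with the most frequent control
#: level as reference.
CONTINUOUS_COVARIATES = ["age", "tiv_mm3"]
CATEGORICAL_COVARIATES = ["sex", "field_strength", "manufacturer"]


def roi_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(ROI_PREFIX)]


# ---------------------------------------------------------------------------
# Hemisphere combining
# ---------------------------------------------------------------------------

def _combine_names(names):
    """Map a list of labels to (combined label -> members) respecting the
    `_L`/`_R` suffix convention; raises on orphan hemisphere labels."""
    out, orphans = {}, []
    nameset = set(names)
    for n in names:
        if n.endswith("_L") or n.endswith("_R"):
            stem, side = n[:-2], n[-1]
            partner = f"{stem}_{'R' if side == 'L' else 'L'}"
            if partner not in nameset:
                orphans.append((n, partner))
                continue
            out.setdefault(stem, []).append(n)
        else:
            out[n] = [n]
    if orphans:
        missing = ", ".join(p for _, p in sorted(orphans))
        raise ValueError(f"hemisphere label(s) without partner: expected {missing}")
    return out


def combine_hemispheres(volumes):
    """Sum left/right labelled volumes into combined regions.

    Accepts a mapping ``{label: volume}`` or a DataFrame whose ROI columns are
    prefixed ``roi_``; unpaired (midline) labels pass through unchanged.
    """
    if isinstance(volumes, pd.DataFrame):
        rois = roi_columns(volumes)
        mapping = _combine_names([c[len(ROI_PREFIX):] for c in rois])
        other = volumes[[c for c in volumes.columns if c not in rois]]
        combined = {
            ROI_PREFIX + stem: volumes[[ROI_PREFIX + m for m in members]].sum(axis=1)
            for stem, members in mapping.items()
        }
        return pd.concat([other, pd.DataFrame(combined, index=volumes.index)],
                         axis=1)
    mapping = _combine_names(list(volumes))
    return {stem: float(sum(volumes[m] for m in members))
            for stem, members in mapping.items()}


# ---------------------------------------------------------------------------
# Covariate adjustment
# ---------------------------------------------------------------------------

@dataclass
class CovariateAdjuster:
    """Per-ROI linear model fit on controls, propagated to patients.

    ``adjusted = observed - (predicted - mean control prediction)``, so
    adjusted volumes stay on the control-mean scale.
    """

    coefficients: pd.DataFrame        # design columns x ROIs
    standard_errors: pd.DataFrame
    design_terms: list                # [(name, kind, levels?, reference?)]
    control_mean: pd.Series           # mean adjusted control volume per ROI
    control_sd: pd.Series
    mean_control_prediction: pd.Series
    dropped_covariates: list = field(default_factory=list)

    @property
    def rois(self) -> list[str]:
        return list(self.coefficients.columns)


def _build_design(df: pd.DataFrame, design_terms) -> pd.DataFrame:
    cols = {"const": np.ones(len(df))}
    for term in design_terms:
        if term["kind"] == "continuous":
            cols[term["name"]] = df[term["name"]].to_numpy(dtype=float)
        else:
            values = df[term["name"]].astype(str)
            known = set(term["levels"]) | {term["reference"]}
            unseen = sorted(set(values) - known)
            if unseen:
                warnings.warn(
                    f"{term['name']}: unseen level(s) {unseen} mapped to "
                    f"reference '{term['reference']}'", stacklevel=2)
                values = values.where(values.isin(known), term["reference"])
            for lev in term["levels"]:
                cols[f"{term['name']}[{lev}]"] = (values == str(lev)).to_numpy(float)
    return pd.DataFrame(cols, index=df.index)


def fit_covariate_adjuster(controls: pd.DataFrame,
                           rois: list[str] | None = None) -> CovariateAdjuster:
    """Ordinary least squares of each ROI volume on the scan covariates,
    fit on the control population only."""
    if rois is None:
        rois = roi_columns(controls)
    if not rois:
        raise ValueError("no ROI columns found")
    design_terms, dropped = [], []
    for name in CONTINUOUS_COVARIATES:
        design_terms.append({"name": name, "kind": "continuous"})
    for name in CATEGORICAL_COVARIATES:
        levels = controls[name].astype(str).value_counts()
        if len(levels) < 2:
            dropped.append(name)
            logger.warning("covariate %s has a single level; dropped", name)
            continue
        reference = levels.index[0]  # most frequent control level
        design_terms.append({
            "name": name, "kind": "categorical",
            "levels": sorted(str(l) for l in levels.index if str(l) != reference),
            "reference": reference,
        })
    D = _build_design(controls, design_terms)
    n, p = D.shape
    if n < p + 2:
        raise ValueError(f"insufficient controls: {n} rows for {p} coefficients")
    if np.linalg.matrix_rank(D.to_numpy()) < p:
        raise ValueError("rank-deficient covariate design on controls")

    coefs, ses, preds = {}, {}, {}
    Y = controls[rois]
    for roi in rois:
        res = sm.OLS(Y[roi].to_numpy(dtype=float), D.to_numpy()).fit()
        coefs[roi] = res.params
        ses[roi] = res.bse
        preds[roi] = res.fittedvalues
    coefficients = pd.DataFrame(coefs, index=D.columns)
    standard_errors = pd.DataFrame(ses, index=D.columns)
    mean_pred = pd.Series({r: float(np.mean(preds[r])) for r in rois})

    adjuster = CovariateAdjuster(
        coefficients=coefficients, standard_errors=standard_errors,
        design_terms=design_terms, control_mean=pd.Series(dtype=float),
        control_sd=pd.Series(dtype=float),
        mean_control_prediction=mean_pred, dropped_covariates=dropped)
    adjusted_controls = apply_adjuster(adjuster, controls, rois=rois)
    adjuster.control_mean = adjusted_controls[rois].mean()
    adjuster.control_sd = adjusted_controls[rois].std(ddof=1)
    if (adjuster.control_sd <= 0).any():
        raise ValueError("control adjusted-volume SD must be positive")
    return adjuster


def apply_adjuster(adjuster: CovariateAdjuster, scans: pd.DataFrame,
                   rois: list[str] | None = None) -> pd.DataFrame:
    """Covariate-adjust scan volumes with a control-fit model.

    Applied identically to controls and patients. Not idempotent: re-applying
    subtracts the covariate prediction again.
    """
    if rois is None:
        rois = adjuster.rois
    D = _build_design(scans, adjuster.design_terms).to_numpy()
    out = scans.copy()
    pred = D @ adjuster.coefficients.loc[:, rois].to_numpy()
    out[rois] = (scans[rois].to_numpy(dtype=float) - pred
                 + adjuster.mean_control_prediction[rois].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Effect size and selection
# ---------------------------------------------------------------------------

def cohens_d(group_a, group_b) -> float:
    """Standardized mean difference ``(mean_a - mean_b) / pooled SD``."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
           / (a.size + b.size - 2))
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def select_biomarkers(adjusted: pd.DataFrame, threshold: float = 0.6,
                      rois: list[str] | None = None):
    """Keep ROIs whose control-minus-patient effect size is >= threshold.

    Cohen's d is computed on covariate-adjusted baseline volumes as controls
    minus patients, so atrophy gives d > 0. Returns ``(selected, table)``
    with the selected list ordered by descending d.
    """
    if rois is None:
        rois = roi_columns(adjusted)
    base = adjusted[adjusted["visit"] == 0]
    ctrl = base[base["group"] == "control"]
    pat = base[base["group"] == "patient"]
    if ctrl.empty or pat.empty:
        raise ValueError("both controls and patients required at baseline")
    d = {roi: cohens_d(ctrl[roi], pat[roi]) for roi in rois}
    table = (pd.DataFrame({"roi": list(d), "cohens_d": list(d.values())})
             .sort_values("cohens_d", ascending=False, kind="stable")
             .reset_index(drop=True))
    table["selected"] = table["cohens_d"] >= threshold
    selected = table.loc[table["selected"], "roi"].tolist()
    if not selected:
        raise ValueError(
            f"no ROI reaches Cohen's d >= {threshold}; review the threshold")
    return selected, table


# ---------------------------------------------------------------------------
# z-scoring
# ---------------------------------------------------------------------------

@dataclass
class ZScorePanel:
    """Sign-flipped z-scores (higher = more atrophy) for every scan."""

    zscores: pd.DataFrame          # scans x biomarkers
    meta: pd.DataFrame             # scan identifiers and covariates
    biomarkers: list[str]
    cohens_d: pd.Series
    control_mean: pd.Series
    control_sd: pd.Series

    def matrix(self, mask=None) -> np.ndarray:
        Z = self.zscores if mask is None else self.zscores[mask]
        return Z.to_numpy(dtype=float)

    def baseline_patients(self) -> pd.Series:
        return (self.meta["group"] == "patient") & (self.meta["visit"] == 0)


def compute_zscores(adjusted: pd.DataFrame, adjuster: CovariateAdjuster,
                    selected: list[str],
                    d_table: pd.DataFrame | None = None) -> ZScorePanel:
    """``x = -(v_adj - mu_control) / sigma_control`` for every scan.

    Follow-up scans are scored with the baseline-fit adjuster statistics
    (no refit). Scans missing any selected ROI are excluded with a logged
    reason.
    """
    mu = adjuster.control_mean[selected]
    sd = adjuster.control_sd[selected]
    if (sd <= 0).any():
        raise ValueError("control SD must be positive for all selected ROIs")
    complete = adjusted[selected].notna().all(axis=1)
    if (~complete).any():
        n_bad = int((~complete).sum())
        logger.warning("excluding %d scans with missing selected ROI volumes",
                       n_bad)
    rows = adjusted[complete]
    x = -(rows[selected].to_numpy(dtype=float) - mu.to_numpy()) / sd.to_numpy()
    names = [c[len(ROI_PREFIX):] for c in selected]
    meta_cols = [c for c in rows.columns if c not in set(roi_columns(rows))]
    d = None
    if d_table is not None:
        d = (d_table.set_index("roi")["cohens_d"]
             .reindex(selected).rename(index=dict(zip(selected, names))))
    return ZScorePanel(
        zscores=pd.DataFrame(x, columns=names, index=rows.index),
        meta=rows[meta_cols].copy(),
        biomarkers=names,
        cohens_d=d if d is not None else pd.Series(dtype=float),
        control_mean=mu.rename(index=dict(zip(selected, names))),
        control_sd=sd.rename(index=dict(zip(selected, names))),
    )


def preprocess_cohort(cohort: pd.DataFrame, d_threshold: float = 0.6):
    """combine -> adjust -> select -> z-score; returns (panel, adjuster, d table)."""
    combined = combine_hemispheres(cohort)
    controls = combined[(combined["group"] == "control")
                        & (combined["visit"] == 0)]
    adjuster = fit_covariate_adjuster(controls)
    adjusted = apply_adjuster(adjuster, combined)
    selected, d_table = select_biomarkers(adjusted, threshold=d_threshold)
    panel = compute_zscores(adjusted, adjuster, selected, d_table)
    return panel, adjuster, d_table


def residual_age_association(adjusted: pd.DataFrame,
                             rois: list[str] | None = None) -> pd.DataFrame:
    """Slope t-statistics of adjusted volume on age, to confirm age effects
    were regressed out (one row per ROI)."""
    if rois is None:
        rois = roi_columns(adjusted)
    D = np.column_stack([np.ones(len(adjusted)),
                         adjusted["age"].to_numpy(dtype=float)])
    rows = []
    for roi in rois:
        res = sm.OLS(adjusted[roi].to_numpy(dtype=float), D).fit()
        rows.append({"roi": roi, "slope": res.params[1],
                     "t": res.tvalues[1], "p": res.pvalues[1]})
    return pd.DataFrame(rows)
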
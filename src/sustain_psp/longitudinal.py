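"""Longitudinal consistency of frozen-model assignments.

A fitted model is frozen at baseline and applied to follow-up scans; if the
model captures real trajectories, subjects should keep their subtype and
move to the same or a later stage. Metrics follow the published definitions:
subtype stability counts same-subtype pairs and stage-0-to-subtype
transitions as consistent (a pair that stays "normal appearing" is not),
and stage progression classifies pairs by maximum-likelihood stage while
rates use the continuous expected stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

NORMAL = "normal_appearing"


def build_visit_pairs(assignments: pd.DataFrame,
                      cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per consecutive visit pair of each patient subject."""
    days = cohort.set_index(["subject_id", "visit"])["days_since_baseline"]
    pat = assignments.merge(
        days.rename("days").reset_index(), on=["subject_id", "visit"],
        how="left").sort_values(["subject_id", "visit"], kind="stable")
    rows = []
    for sid, g in pat.groupby("subject_id", sort=True):
        g = g.reset_index(drop=True)
        for i in range(len(g) - 1):
            a, b = g.loc[i], g.loc[i + 1]
            dt = (b["days"] - a["days"]) / 365.25
            if dt <= 0:
                raise ValueError(
                    f"{sid}: non-positive gap between visits "
                    f"{a['visit']} and {b['visit']}")
            rows.append({
                "subject_id": sid,
                "earlier_scan": a["scan_id"], "later_scan": b["scan_id"],
                "dt_years": dt,
                "earlier_subtype": int(a["ml_subtype"]),
                "later_subtype": int(b["ml_subtype"]),
                "earlier_stage": int(a["ml_stage"]),
                "later_stage": int(b["ml_stage"]),
                "earlier_expected_stage": float(a["expected_stage"]),
                "later_expected_stage": float(b["expected_stage"]),
                "earlier_subtypable": bool(a["subtypable"]),
                "later_subtypable": bool(b["subtypable"]),
            })
    return pd.DataFrame(rows)


def _category(subtypable, subtype):
    return f"subtype_{subtype}" if subtypable else NORMAL


def subtype_stability(pairs: pd.DataFrame, n_subtypes: int = 2):
    """Proportion of longitudinally consistent pairs plus the transition matrix.

    Consistent: same subtype at both scans (both subtypable), or the earlier
    scan not subtypable at stage 0 and the later scan subtypable.
    """
    if pairs.empty:
        raise ValueError("no visit pairs provided")
    cats = [NORMAL] + [f"subtype_{c}" for c in range(n_subtypes)]
    trans = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    consistent = 0
    for _, p in pairs.iterrows():
        ce = _category(p["earlier_subtypable"], p["earlier_subtype"])
        cl = _category(p["later_subtypable"], p["later_subtype"])
        trans.loc[ce, cl] += 1
        same_subtype = (p["earlier_subtypable"] and p["later_subtypable"]
                        and p["earlier_subtype"] == p["later_subtype"])
        from_zero = (not p["earlier_subtypable"] and p["earlier_stage"] == 0
                     and p["later_subtypable"])
        if same_subtype or from_zero:
            consistent += 1
    return consistent / len(pairs), trans


def stage_progression(pairs: pd.DataFrame, by: str | None = None,
                      groups: pd.Series | None = None):
    """Proportions (progressed, unchanged, regressed) by maximum-likelihood
    stage; optionally broken down by a per-pair grouping series."""
    if pairs.empty:
        raise ValueError("no visit pairs provided")

    def props(df):
        delta = df["later_stage"] - df["earlier_stage"]
        n = len(df)
        return pd.Series({
            "progressed": float((delta > 0).sum() / n),
            "unchanged": float((delta == 0).sum() / n),
            "regressed": float((delta < 0).sum() / n),
            "n": n,
        })

    overall = props(pairs)
    if groups is None:
        return overall
    breakdown = (pairs.assign(_g=groups.to_numpy())
                 .groupby("_g").apply(props, include_groups=False))
    breakdown.index.name = by or "group"
    return overall, breakdown


def progression_rate(pairs: pd.DataFrame, groups: pd.Series,
                     compare: tuple[str, str] | None = None):
    """Per-group mean progression rate in stages/year, with a Welch t
    comparison between two named groups.

    The rate of a pair is the change in expected stage over the gap; pairs
    are averaged within subject before averaging within group.
    """
    if pairs.empty:
        raise ValueError("no visit pairs provided")
    if (pairs["dt_years"] <= 0).any():
        raise ValueError("non-positive visit gap")
    df = pairs.assign(
        rate=(pairs["later_expected_stage"] - pairs["earlier_expected_stage"])
        / pairs["dt_years"],
        group=groups.to_numpy(),
    )
    per_subject = (df.groupby(["group", "subject_id"])["rate"].mean()
                   .reset_index())
    summary = (per_subject.groupby("group")["rate"]
               .agg(["mean", "std", "count"]))
    result = {"per_group": summary}
    if compare is not None:
        g1, g2 = compare
        a = per_subject.loc[per_subject["group"] == g1, "rate"].to_numpy()
        b = per_subject.loc[per_subject["group"] == g2, "rate"].to_numpy()
        t = sps.ttest_ind(a, b, equal_var=False)
        se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        diff = a.mean() - b.mean()
        tcrit = sps.t.ppf(0.975, t.df)
        result["comparison"] = {
            "groups": (g1, g2), "t": float(t.statistic), "df": float(t.df),
            "p": float(t.pvalue), "difference": float(diff),
            "ci95": (float(diff - tcrit * se), float(diff + tcrit * se)),
        }
    return result
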
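"""End-to-end study orchestration: generate, preprocess, fit, assign,
validate, and score recovery against the latent truth.

This is the programmatic equivalent of running the numbered analysis
scripts in order, used by the recovery experiments and the acceptance
script so that every replicate exercises the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import assign as assign_mod
from . import longitudinal as longit
from .model import SuStaInFit, event_grid_from_data, fit_mixture_path
from .preprocess import preprocess_cohort
from .synthetic import SynthConfig, generate_cohort


@dataclass
class StudyResult:
    config: SynthConfig
    cohort: pd.DataFrame
    truth: pd.DataFrame
    panel: object
    d_table: pd.DataFrame
    grid: object
    fits: list
    assignments: pd.DataFrame
    pairs: pd.DataFrame
    metrics: dict

    @property
    def fit(self) -> SuStaInFit:
        return self.fits[-1]


def _subtype_label_map(merged: pd.DataFrame) -> dict:
    """Match fitted subtype labels to true ones by majority vote among
    subtypable baseline scans."""
    sub = merged[(merged["visit"] == 0) & merged["subtypable"]]
    maps = {}
    for s in sorted(sub["true_subtype"].unique()):
        votes = sub.loc[sub["true_subtype"] == s, "ml_subtype"]
        maps[int(s)] = int(votes.mode().iloc[0]) if len(votes) else int(s)
    return maps


def recovery_metrics(assignments: pd.DataFrame, truth: pd.DataFrame,
                     cohort: pd.DataFrame, true_E: int) -> dict:
    """Stage/subtype recovery and longitudinal consistency of one study."""
    merged = assignments.merge(truth, on=["subject_id", "visit"])
    base = merged[merged["visit"] == 0]
    out = {
        "stage_spearman": float(spearmanr(
            base["expected_stage"], base["true_stage"]).statistic),
    }
    label_map = _subtype_label_map(merged)
    sub = base[base["subtypable"]]
    mid = sub[(sub["true_stage"] >= 0.2 * true_E)
              & (sub["true_stage"] <= 0.8 * true_E)]
    if len(mid):
        out["mid_stage_subtype_accuracy"] = float(
            (mid["ml_subtype"] == mid["true_subtype"].map(label_map)).mean())
    patients = set(truth["subject_id"])
    pairs = longit.build_visit_pairs(
        assignments[assignments["subject_id"].isin(patients)], cohort)
    out["n_pairs"] = int(len(pairs))
    if len(pairs):
        stability, transitions = longit.subtype_stability(pairs)
        progression = longit.stage_progression(pairs)
        out["subtype_stability"] = float(stability)
        out["transitions"] = transitions
        out["progressed"] = float(progression["progressed"])
        out["unchanged"] = float(progression["unchanged"])
        out["progressed_or_same"] = float(
            progression["progressed"] + progression["unchanged"])
        syn = cohort[cohort["visit"] == 0].set_index("subject_id")["syndrome"]
        groups = pairs["subject_id"].map(syn)
        if {"RS", "subcortical"} <= set(groups.unique()):
            rates = longit.progression_rate(pairs, groups,
                                            compare=("RS", "subcortical"))
            per = rates["per_group"]
            out["rate_rs"] = float(per.loc["RS", "mean"])
            out["rate_subcortical"] = float(per.loc["subcortical", "mean"])
            out["rate_comparison"] = rates["comparison"]
    out["pairs"] = pairs
    return out


def run_study(config: SynthConfig, n_subtypes: int = 2,
              fit_seed: int = 0, d_threshold: float = 0.6,
              **fit_kwargs) -> StudyResult:
    """Generate a cohort from ``config`` and push it through the whole
    pipeline: preprocess, grid, hierarchical mixture fit, frozen-model
    assignment of every scan, and longitudinal validation."""
    cohort, truth = generate_cohort(config)
    panel, adjuster, d_table = preprocess_cohort(cohort,
                                                 d_threshold=d_threshold)
    X = panel.matrix(panel.baseline_patients())
    grid = event_grid_from_data(X, panel.biomarkers)
    fits = fit_mixture_path(X, grid, n_subtypes, seed=fit_seed, **fit_kwargs)
    assignments = assign_mod.assign_cohort(panel, fits[-1])
    metrics = recovery_metrics(assignments, truth, cohort,
                               true_E=config.event_grid.n_events)
    pairs = metrics.pop("pairs")
    metrics.pop("transitions", None)
    return StudyResult(config, cohort, truth, panel, d_table, grid, fits,
                       assignments, pairs, metrics)
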
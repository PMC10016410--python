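"""Per-scan posterior over (subtype, stage) under a frozen fitted model.

Every scan — baseline or follow-up — gets a posterior matrix, maximum
likelihood labels, a probability-weighted expected stage, and a subtypable
flag. Scans whose maximum-likelihood stage is 0 (no measurable atrophy) or
the end stage (every event passed) carry no subtype information and are
flagged not subtypable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import (SuStaInFit, _as_matrix, _check_finite,
                    _stage_loglik_matrix, trajectory_matrix)
from .preprocess import ZScorePanel


@dataclass
class Assignment:
    scan_id: str
    posterior: np.ndarray        # C x (E + 1), sums to 1
    ml_subtype: int
    ml_stage: int
    subtype_probability: float
    expected_stage: float
    subtypable: bool


def _log_posterior_cube(X: np.ndarray, fit: SuStaInFit) -> np.ndarray:
    """Unnormalized log P(c, k | x_j) for all scans; shape (n, C, E+1)."""
    grid = fit.grid
    cube = np.empty((X.shape[0], fit.n_subtypes, grid.n_stages))
    for c, (f, s) in enumerate(zip(fit.fractions, fit.sequences)):
        G = trajectory_matrix(grid, s.order)
        cube[:, c, :] = (np.log(f) - np.log(grid.n_stages)
                         + _stage_loglik_matrix(X, G, grid.sigma))
    return cube


def posterior(x, fit: SuStaInFit) -> np.ndarray:
    """P(c, k | x), normalized over all subtype-stage pairs; shape C x (E+1)."""
    X = _as_matrix(x)
    _check_finite(X, fit.grid)
    cube = _log_posterior_cube(X, fit)[0]
    if not np.all(np.isfinite(cube)):
        raise ValueError("non-finite likelihood in posterior computation")
    return np.exp(cube - logsumexp(cube))


def _labels_from_posterior(post: np.ndarray, n_events: int,
                           joint: bool = False):
    subtype_mass = post.sum(axis=1)
    if joint:
        ml_subtype, ml_stage = np.unravel_index(int(post.argmax()),
                                                post.shape)
        ml_subtype, ml_stage = int(ml_subtype), int(ml_stage)
    else:
        ml_subtype = int(subtype_mass.argmax())      # ties: lowest index
        ml_stage = int(post[ml_subtype].argmax())
    expected_stage = float((post * np.arange(n_events + 1)[None, :]).sum())
    subtypable = ml_stage not in (0, n_events)
    return ml_subtype, ml_stage, float(subtype_mass[ml_subtype]), \
        expected_stage, subtypable


def assign(x, fit: SuStaInFit, scan_id: str = "",
           joint: bool = False) -> Assignment:
    """Maximum-likelihood subtype and stage for one scan.

    By default the subtype maximizes the stage-summed posterior mass and the
    stage then maximizes the posterior within that subtype; ``joint=True``
    takes the argmax over (subtype, stage) pairs instead. The expected stage
    averages over every stage of every subtype.
    """
    post = posterior(x, fit)
    ml_subtype, ml_stage, prob, expected, subtypable = \
        _labels_from_posterior(post, fit.grid.n_events, joint=joint)
    return Assignment(scan_id, post, ml_subtype, ml_stage, prob,
                      expected, subtypable)


def assign_cohort(panel: ZScorePanel, fit: SuStaInFit) -> pd.DataFrame:
    """Assignment table for every scan in a z-score panel (frozen model)."""
    if list(panel.biomarkers) != list(fit.grid.biomarkers):
        raise ValueError("panel biomarkers do not match the fitted grid")
    meta = panel.meta.reset_index(drop=True)
    X = panel.matrix()
    rows = []
    if X.shape[0]:
        cube = _log_posterior_cube(X, fit)
        if not np.all(np.isfinite(cube)):
            raise ValueError("non-finite likelihood during assignment")
        post = np.exp(cube - logsumexp(cube, axis=(1, 2), keepdims=True))
        for j in range(X.shape[0]):
            ml_subtype, ml_stage, prob, expected, subtypable = \
                _labels_from_posterior(post[j], fit.grid.n_events)
            rows.append({
                "scan_id": f"{meta.loc[j, 'subject_id']}_v{meta.loc[j, 'visit']}",
                "subject_id": meta.loc[j, "subject_id"],
                "visit": meta.loc[j, "visit"],
                "ml_subtype": ml_subtype,
                "ml_stage": ml_stage,
                "expected_stage": expected,
                "subtype_probability": prob,
                "subtypable": subtypable,
            })
    out = pd.DataFrame(rows, columns=[
        "scan_id", "subject_id", "visit", "ml_subtype", "ml_stage",
        "expected_stage", "subtype_probability", "subtypable"])
    n_ns = int((~out["subtypable"]).sum()) if len(out) else 0
    out.attrs["n_not_subtypable"] = n_ns
    return out
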
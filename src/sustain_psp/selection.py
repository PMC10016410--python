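"""Choosing the number of subtypes by cross-validated information criterion.

CVIC(C) is minus twice the summed out-of-sample log-likelihood over folds.
The parsimony rule: accept an extra subtype only if CVIC improves by more
than a margin, or if it is within the margin *and* the mean per-fold test
log-likelihood strictly improves; otherwise keep the smaller model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import EventGrid, dataset_loglik, fit_mixture_path


@dataclass
class CvicTable:
    fold_logliks: pd.DataFrame   # folds x candidate C, out-of-sample loglik
    table: pd.DataFrame          # per C: cvic, mean_fold_loglik, total

    def cvic(self, C: int) -> float:
        return float(self.table.set_index("n_subtypes").loc[C, "cvic"])


def make_folds(subject_ids, n_folds: int, seed: int | None = None):
    """Subject-level fold assignment, a pure function of (id order, seed)."""
    ids = pd.unique(pd.Series(subject_ids))
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    fold_of = {ids[j]: int(i % n_folds) for i, j in enumerate(perm)}
    sizes = np.bincount(list(fold_of.values()), minlength=n_folds)
    if sizes.min() < 5:
        raise ValueError(f"smallest fold has {sizes.min()} subjects (< 5)")
    return fold_of


def crossval_cvic(X, subject_ids, grid: EventGrid, candidates,
                  n_folds: int = 10, seed: int | None = None,
                  **fit_kwargs) -> CvicTable:
    """Paired k-fold CVIC for consecutive subtype counts.

    For every fold a hierarchical mixture path is fit on the training
    subjects and evaluated on the held-out subjects; folds are identical
    across candidate C so comparisons are paired.
    """
    X = np.asarray(X, dtype=float)
    candidates = sorted(int(c) for c in candidates)
    if candidates != list(range(1, len(candidates) + 1)):
        raise ValueError("candidates must be consecutive counts from 1")
    fold_of = make_folds(subject_ids, n_folds, seed)
    folds = np.array([fold_of[s] for s in subject_ids])
    rng = np.random.default_rng(seed)
    fold_ll = np.zeros((n_folds, len(candidates)))
    for k in range(n_folds):
        train, test = folds != k, folds == k
        fits = fit_mixture_path(X[train], grid, max(candidates),
                                seed=int(rng.integers(2**31 - 1)),
                                **fit_kwargs)
        for ci, C in enumerate(candidates):
            fold_ll[k, ci] = dataset_loglik(X[test], fits[C - 1])
    fold_df = pd.DataFrame(fold_ll, columns=candidates)
    fold_df.index.name = "fold"
    table = pd.DataFrame({
        "n_subtypes": candidates,
        "cvic": -2.0 * fold_ll.sum(axis=0),
        "mean_fold_loglik": fold_ll.mean(axis=0),
        "total_test_loglik": fold_ll.sum(axis=0),
    })
    return CvicTable(fold_logliks=fold_df, table=table)


def select_subtype_count(cvic: CvicTable, cvic_margin: float = 6.0):
    """Most parsimonious supported model; returns ``(C, rationale)``."""
    t = cvic.table.sort_values("n_subtypes").reset_index(drop=True)
    if t.empty:
        raise ValueError("empty CVIC table")
    chosen = int(t.loc[0, "n_subtypes"])
    rationale = "single candidate" if len(t) == 1 else "base model"
    for i in range(1, len(t)):
        C = int(t.loc[i, "n_subtypes"])
        improvement = t.loc[i - 1, "cvic"] - t.loc[i, "cvic"]
        mean_gain = t.loc[i, "mean_fold_loglik"] - t.loc[i - 1, "mean_fold_loglik"]
        if improvement > cvic_margin:
            chosen, rationale = C, (
                f"C={C}: CVIC improved by {improvement:.2f} (> margin {cvic_margin})")
        elif improvement >= -cvic_margin and mean_gain > 0:
            chosen, rationale = C, (
                f"C={C}: CVIC within margin and mean fold log-likelihood "
                f"improved by {mean_gain:.3f}")
        else:
            rationale = (f"stopped at C={chosen}: C={C} gives CVIC change "
                         f"{improvement:.2f} with mean fold gain {mean_gain:.3f}")
            break
    return chosen, rationale
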
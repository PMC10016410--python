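"""Choose the number of atrophy subtypes by cross-validated CVIC.

Ten-fold subject-level cross-validation: each fold fits the hierarchical
mixture on training patients and scores held-out patients;
CVIC(C) = -2 x summed out-of-sample log-likelihood. The most parsimonious
supported model wins (margin 6 on the deviance scale, or a mean per-fold
log-likelihood improvement).

Usage: python analysis/03_select_subtypes.py [--zscores results/zscores.csv]
       [--max-subtypes 2] [--folds 10] [--seed 1] [--out results/]
"""

import argparse
from pathlib import Path

import pandas as pd

from sustain_psp.model import event_grid_from_data
from sustain_psp.preprocess import ROI_PREFIX
from sustain_psp.selection import crossval_cvic, select_subtype_count


def load_panel(path):
    zs = pd.read_csv(path)
    meta_cols = ["subject_id", "visit", "group", "syndrome",
                 "days_since_baseline"]
    biomarkers = [c for c in zs.columns
                  if c not in meta_cols and zs[c].dtype.kind == "f"
                  and c not in ("age", "tiv_mm3", "field_strength",
                                "psprs_total", "psprs_history",
                                "psprs_mentation", "psprs_bulbar",
                                "psprs_ocular", "psprs_limb", "psprs_gait",
                                "updrs", "seadl", "mmse")]
    return zs, biomarkers


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--zscores", type=Path, default=Path("results/zscores.csv"))
    ap.add_argument("--max-subtypes", type=int, default=2)
    ap.add_argument("--folds", type=int, default=10)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-starts", type=int, default=4,
                    help="greedy restarts per cross-validation fit")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    zs, biomarkers = load_panel(args.zscores)
    base = zs[(zs["group"] == "patient") & (zs["visit"] == 0)]
    X = base[biomarkers].to_numpy()
    grid = event_grid_from_data(X, biomarkers)
    print(f"{X.shape[0]} baseline patients, {len(biomarkers)} biomarkers, "
          f"{grid.n_events} model stages")

    cv = crossval_cvic(X, base["subject_id"].to_numpy(), grid,
                       list(range(1, args.max_subtypes + 1)),
                       n_folds=args.folds, seed=args.seed,
                       n_starts=args.n_starts, split_starts=2)
    chosen, why = select_subtype_count(cv)
    args.out.mkdir(parents=True, exist_ok=True)
    cv.table.to_csv(args.out / "cvic.csv", index=False)
    print(cv.table.to_string(index=False))
    print(f"selected {chosen} subtype(s): {why}")
    print(f"wrote {args.out}/cvic.csv")


if __name__ == "__main__":
    main()
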
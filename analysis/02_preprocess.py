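"""Build the z-score biomarker panel from the raw cohort table.

Combines hemispheric volumes, fits the covariate adjuster (age, sex, TIV,
field strength, manufacturer) on controls and propagates it to patients,
selects regions with Cohen's d >= 0.6 (controls minus patients on adjusted
baseline volumes), and writes sign-flipped z-scores for every scan.

Usage: python analysis/02_preprocess.py [--cohort results/cohort.csv]
       [--out results/] [--d-threshold 0.6]
"""

import argparse
from pathlib import Path

import pandas as pd

from sustain_psp.preprocess import preprocess_cohort, residual_age_association


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--d-threshold", type=float, default=0.6)
    args = ap.parse_args()

    cohort = pd.read_csv(args.cohort)
    panel, adjuster, d_table = preprocess_cohort(
        cohort, d_threshold=args.d_threshold)

    args.out.mkdir(parents=True, exist_ok=True)
    d_table.to_csv(args.out / "biomarker_selection.csv", index=False)
    zs = pd.concat([panel.meta.reset_index(drop=True),
                    panel.zscores.reset_index(drop=True)], axis=1)
    zs.to_csv(args.out / "zscores.csv", index=False)

    kept = d_table["selected"].sum()
    print(f"selected {kept}/{len(d_table)} regions at d >= {args.d_threshold} "
          f"(strongest: {d_table.iloc[0]['roi']} "
          f"d = {d_table.iloc[0]['cohens_d']:.2f})")
    from sustain_psp.preprocess import apply_adjuster, combine_hemispheres
    adjusted = apply_adjuster(adjuster, combine_hemispheres(cohort))
    base = adjusted[adjusted["visit"] == 0]
    for grp in ("control", "patient"):
        resid = residual_age_association(base[base["group"] == grp])
        n_assoc = int((resid["t"].abs() >= 2).sum())
        print(f"residual age association in {grp}s: {n_assoc}/{len(resid)} "
              f"regions with |t| >= 2 (median |t| = "
              f"{resid['t'].abs().median():.2f})")
    print(f"wrote {args.out}/zscores.csv ({len(zs)} scans x {kept} biomarkers)")


if __name__ == "__main__":
    main()
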
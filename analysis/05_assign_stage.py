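"""Assign every scan — baseline and follow-up — a subtype and stage under
the frozen baseline-fit model.

Each scan gets the full posterior over (subtype, stage), maximum-likelihood
labels, the probability-weighted expected stage, and the subtypable flag
(stage 0 and the end stage carry no subtype information).

Usage: python analysis/05_assign_stage.py [--model results/model.json]
       [--zscores results/zscores.csv] [--out results/]
"""

import argparse
import importlib.util
from pathlib import Path

import pandas as pd

from sustain_psp.assign import assign_cohort
from sustain_psp.model import SuStaInFit
from sustain_psp.preprocess import ZScorePanel

_spec = importlib.util.spec_from_file_location(
    "select_subtypes", Path(__file__).parent / "03_select_subtypes.py")
_sel = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_sel)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--model", type=Path, default=Path("results/model.json"))
    ap.add_argument("--zscores", type=Path, default=Path("results/zscores.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    fit = SuStaInFit.from_json(args.model.read_text())
    zs, biomarkers = _sel.load_panel(args.zscores)
    panel = ZScorePanel(
        zscores=zs[fit.grid.biomarkers], meta=zs.drop(columns=biomarkers),
        biomarkers=list(fit.grid.biomarkers),
        cohens_d=pd.Series(dtype=float),
        control_mean=pd.Series(dtype=float),
        control_sd=pd.Series(dtype=float))
    table = assign_cohort(panel, fit)

    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "assignments.csv", index=False)
    pat = table[panel.meta["group"].to_numpy() == "patient"]
    n_ns = (~pat["subtypable"]).sum()
    print(f"assigned {len(table)} scans ({len(pat)} patient scans); "
          f"{n_ns} patient scans not subtypable "
          f"({100 * n_ns / max(len(pat), 1):.1f}%)")
    shares = pat.loc[pat["subtypable"], "ml_subtype"].value_counts(
        normalize=True).sort_index()
    print("subtypable patient scans by subtype:",
          {int(k): f"{100 * v:.1f}%" for k, v in shares.items()})
    print(f"wrote {args.out}/assignments.csv")


if __name__ == "__main__":
    main()
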
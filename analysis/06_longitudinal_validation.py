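"""Validate the frozen model on follow-up scans.

If the cross-sectionally fitted trajectories are real, subjects should stay
in their subtype and move to the same or a later stage at follow-up.
Reports subtype stability (same subtype, or stage 0 into a subtype), the
transition matrix, stage-progression proportions, and per-syndrome
progression rates with a Welch t comparison of Richardson-syndrome versus
subcortical-variant cases.

Usage: python analysis/06_longitudinal_validation.py
       [--assignments results/assignments.csv]
       [--cohort results/cohort.csv] [--out results/]
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from sustain_psp.longitudinal import (build_visit_pairs, progression_rate,
                                      stage_progression, subtype_stability)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--assignments", type=Path,
                    default=Path("results/assignments.csv"))
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    assignments = pd.read_csv(args.assignments)
    cohort = pd.read_csv(args.cohort)
    patients = set(cohort.loc[cohort["group"] == "patient", "subject_id"])
    pairs = build_visit_pairs(
        assignments[assignments["subject_id"].isin(patients)], cohort)

    stability, transitions = subtype_stability(pairs)
    progression = stage_progression(pairs)
    syn = cohort[cohort["visit"] == 0].set_index("subject_id")["syndrome"]
    rates = progression_rate(pairs, pairs["subject_id"].map(syn),
                             compare=("RS", "subcortical"))

    n_cons = int(round(stability * len(pairs)))
    print(f"subtype stability: {100 * stability:.1f}% "
          f"({n_cons}/{len(pairs)} visit pairs consistent)")
    same_or_later = progression["progressed"] + progression["unchanged"]
    print(f"stage progression: {100 * progression['progressed']:.1f}% later, "
          f"{100 * progression['unchanged']:.1f}% same "
          f"(same-or-later {100 * same_or_later:.1f}%)")
    print(rates["per_group"].round(3).to_string())
    cmp = rates["comparison"]
    print(f"RS vs subcortical rate difference "
          f"{cmp['difference']:.2f} stages/year "
          f"(t = {cmp['t']:.2f}, p = {cmp['p']:.3f}, "
          f"95% CI {cmp['ci95'][0]:.2f} to {cmp['ci95'][1]:.2f})")

    args.out.mkdir(parents=True, exist_ok=True)
    transitions.to_csv(args.out / "subtype_transitions.csv")
    out = {
        "n_pairs": int(len(pairs)),
        "subtype_stability": stability,
        "stage_progression": {k: float(v) for k, v in progression.items()},
        "rates_by_syndrome": {
            g: {"mean": float(r["mean"]), "sd": float(r["std"]),
                "n": int(r["count"])}
            for g, r in rates["per_group"].iterrows()},
        "rate_comparison": {k: v for k, v in cmp.items() if k != "groups"},
    }
    (args.out / "validation.json").write_text(json.dumps(out, indent=2))
    print(f"wrote {args.out}/validation.json and subtype_transitions.csv")


if __name__ == "__main__":
    main()
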
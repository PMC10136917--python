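#!/usr/bin/env python
"""Score the cohort: totals, severity bands, band tallies, Cronbach's alpha.

Reads results/cohort.csv (or any table with D1..D9/A1..A7 columns), writes
results/scored.csv and results/severity_tally.csv, and prints the
per-instrument reliability.
"""

import argparse
from pathlib import Path

import pandas as pd

from tinnet.instruments import (
    GAD7,
    PHQ9,
    cronbach_alpha,
    severity_band,
    severity_tally,
    total_score,
    validate_responses,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--input", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    raw = pd.read_csv(args.input)
    responses, report = validate_responses(
        raw, (PHQ9, GAD7), subject_id_column="subject"
    )
    print(
        f"validated {report.n_kept}/{report.n_input} subjects "
        f"({report.n_rejected} rejected)"
    )

    scored = pd.DataFrame(index=responses.subjects)
    tallies = []
    for ins in (PHQ9, GAD7):
        totals = total_score(responses, ins)
        scored[f"{ins.name}_total"] = totals
        scored[f"{ins.name}_band"] = [severity_band(int(s), ins) for s in totals]
        alpha = cronbach_alpha(responses, ins)
        print(f"{ins.name}: mean total {totals.mean():.2f}, alpha = {alpha:.2f}")
        tallies.append(severity_tally(responses, ins).to_frame().assign(
            instrument=ins.name
        ))
    scored.to_csv(args.out / "scored.csv", index_label="subject")
    pd.concat(tallies).to_csv(args.out / "severity_tally.csv", index=False)
    print(f"wrote {args.out/'scored.csv'} and {args.out/'severity_tally.csv'}")


if __name__ == "__main__":
    main()
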
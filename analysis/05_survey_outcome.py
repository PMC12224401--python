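#!/usr/bin/env python
"""Survey processing: exclusions, non-daily FV outcome, bivariate table.

Drops records with missing required items, derives weekly fruit/vegetable
days (summed, capped at 7) and the non-daily indicator, and compares
daily vs non-daily consumers on demographics and neighbourhood exposures
(chi-square / Mann-Whitney).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from foodenv.survey import (
    apply_exclusions,
    bivariate_table,
    derive_outcome_frame,
    prevalence_pct,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/simulation"))
    ap.add_argument("--metrics", type=Path, default=Path("results/metrics/metrics.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/survey"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    participants = pd.read_csv(args.sim / "participants.csv")
    analytic, log = apply_exclusions(participants)
    with open(args.out / "exclusion_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    analytic = derive_outcome_frame(analytic)
    analytic.to_csv(args.out / "analytic.csv", index=False)

    metrics = pd.read_csv(args.metrics)
    table4 = bivariate_table(analytic, metrics)
    table4.to_csv(args.out / "table4_bivariate.csv", index=False)

    print(f"{log['n_input']} records, {log['n_excluded']} excluded "
          f"-> {log['n_analytic']} analytic")
    print(f"non-daily FV prevalence: {prevalence_pct(analytic):.1f}%")
    gender_p = table4.loc[(table4["variable"] == "gender")
                          & (table4["test"] != ""), "p_value"].iloc[0]
    print(f"gender vs outcome chi-square p = {gender_p:.2g}")


if __name__ == "__main__":
    main()
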
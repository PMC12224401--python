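#!/usr/bin/env python
"""Classify acquired establishments into outlet categories and health groups.

Name-first, provider-type-fallback classification with the shipped
Spanish-language term inventory; reports the classification yield, the
category mix over classified establishments, and writes the unclassified
review queue.
"""

import argparse
from pathlib import Path

import pandas as pd

from foodenv.classify import (
    TermInventory,
    classification_summary,
    classify_frame,
    review_queue,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="in_dir", type=Path, default=Path("results/acquisition"))
    ap.add_argument("--out", type=Path, default=Path("results/classification"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    acquired = pd.read_csv(args.in_dir / "establishments_acquired.csv")
    inventory = TermInventory.default()
    classified = classify_frame(acquired, inventory)
    classified.to_csv(args.out / "establishments_classified.csv", index=False)
    summary = classification_summary(classified["category"])
    summary.to_csv(args.out / "classification_summary.csv", index=False)
    review_queue(classified, inventory).to_csv(args.out / "review_queue.csv", index=False)

    n_total = int(summary.loc[summary["label"] == "total", "count"].iloc[0])
    n_cls = int(summary.loc[summary["label"] == "classified", "count"].iloc[0])
    print(f"classified {n_cls} of {n_total} establishments "
          f"({100 * n_cls / n_total:.1f}%); {n_total - n_cls} to review queue")
    cats = summary[summary["kind"] == "category"].sort_values("count", ascending=False)
    for _, r in cats.head(3).iterrows():
        print(f"  {r['label']}: {r['count']} ({r['proportion_pct']:.1f}% of classified)")


if __name__ == "__main__":
    main()
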
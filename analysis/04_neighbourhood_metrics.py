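#!/usr/bin/env python
"""Neighbourhood metrics: densities, population density, SEI, tables 1-3.

Assigns classified establishments to neighbourhoods (point-in-polygon),
computes per-km² densities by category and health group, the composite
social environment index, and the quartile-stratified descriptive tables.
"""

import argparse
from pathlib import Path

import pandas as pd

from foodenv.geo import assign_points, build_metrics, read_neighbourhoods_geojson
from foodenv.pipeline import render_report


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/simulation"))
    ap.add_argument("--classified", type=Path,
                    default=Path("results/classification/establishments_classified.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/metrics"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    nb = read_neighbourhoods_geojson(args.sim / "neighbourhoods.geojson")
    classified = pd.read_csv(args.classified)
    assignment = assign_points(classified, nb)
    metrics = build_metrics(nb, classified, assignment)
    metrics.to_csv(args.out / "metrics.csv", index=False)
    written = render_report({"neighbourhoods": nb, "metrics": metrics}, args.out)

    print(f"assigned {int(assignment.notna().sum())} establishments "
          f"({int(assignment.isna().sum())} outside all polygons)")
    print(f"median total density {metrics['density_total'].median():.1f}/km2; "
          f"median popdens {metrics['popdens'].median():.0f}/km2")
    t3 = pd.read_csv(args.out / "table3_density_by_quartile.csv")
    sei = t3[t3["stratifier"] == "sei"]
    q1 = sei.loc[sei["quartile"] == "Q1", "density_total_median"].iloc[0]
    q4 = sei.loc[sei["quartile"] == "Q4", "density_total_median"].iloc[0]
    print(f"social gradient: median total density {q4:.1f} in SEI Q4 vs {q1:.1f} in Q1")
    print("wrote:", ", ".join(written))


if __name__ == "__main__":
    main()
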
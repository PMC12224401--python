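#!/usr/bin/env python
"""Generate the study-scale synthetic region.

Three cities tiled into 2,442 quarter-km² neighbourhoods with log-normal
population density, four census dimension scores, ~48,000 food
establishments whose intensity rises with population and social
environment, and ~1,290 survey respondents nested in a subset of
neighbourhoods.  Writes neighbourhoods (GeoJSON), the establishment
registry and the respondent file under results/simulation/.
"""

import argparse
from pathlib import Path

from foodenv.config import CityConfig
from foodenv.geo import write_neighbourhoods_geojson
from foodenv.synthetic import (
    generate_establishments,
    generate_neighbourhoods,
    generate_participants,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/simulation"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = CityConfig(seed=args.seed)
    nb = generate_neighbourhoods(cfg)
    est = generate_establishments(nb, cfg)
    part = generate_participants(nb, cfg, establishments=est)

    write_neighbourhoods_geojson(nb, args.out / "neighbourhoods.geojson")
    est.to_csv(args.out / "establishments_registry.csv", index=False)
    part.to_csv(args.out / "participants.csv", index=False)
    cfg.to_yaml(args.out / "config.yaml")

    by_city = est.groupby("city").size()
    print(f"{len(nb)} neighbourhoods in {nb['city'].nunique()} cities")
    print(f"{len(est)} establishments ({', '.join(f'{c}: {n}' for c, n in by_city.items())})")
    print(f"{len(part)} survey respondents in "
          f"{part['neighbourhood_id'].nunique()} neighbourhoods")


if __name__ == "__main__":
    main()
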
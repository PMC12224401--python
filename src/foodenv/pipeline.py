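"""End-to-end pipeline orchestration and report rendering.

Stage order: simulate → query → deduplicate → classify → metrics →
survey outcome → models → report.  Every stage writes its output under the
run directory, and a reproducibility manifest records the config snapshot,
seed, per-stage record counts and the conservation identities linking them
(registry = assigned + unassigned; classified + unclassified = total;
input = analytic + excluded).  Identical config + seed reproduce every
output byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import TermInventory, classification_summary, classify_frame, review_queue
from .config import CATEGORIES, CityConfig
from .geo import (
    build_metrics,
    assign_points,
    quartile_table,
    write_neighbourhoods_geojson,
)
from .models import exposure_or_table, prepare_analytic, save_fits_json
from .query import (
    MockProvider,
    deduplicate,
    grids_from_neighbourhoods,
    records_to_frame,
    run_query,
)
from .survey import apply_exclusions, bivariate_table, derive_outcome_frame
from .synthetic import (
    UNINFORMATIVE_LABELS,
    generate_establishments,
    generate_neighbourhoods,
    generate_participants,
)

logger = logging.getLogger(__name__)

EXPOSURES = ["density_total"] + [f"density_{c}" for c in CATEGORIES]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: CityConfig,
    out_dir,
    inventory: TermInventory | None = None,
    grid_spacing_km: float = 1.0,
    min_model_participants: int = 50,
) -> dict:
    """Run every stage on a synthetic city; returns the manifest dict.

    With too few analytic participants (or fewer than 2 survey
    neighbourhoods) the model stage is skipped with an explicit notice in
    the manifest rather than failing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory = inventory or TermInventory.default()
    manifest: dict = {
        "software_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "counts": {},
    }
    counts = manifest["counts"]

    def stage(name):
        manifest["stages"].append(name)
        logger.info("pipeline stage: %s", name)

    try:
        stage("simulate")
        config.validate()
        config.to_yaml(out / "config.yaml")
        nb = generate_neighbourhoods(config)
        registry = generate_establishments(nb, config)
        participants = generate_participants(nb, config, establishments=registry)
        write_neighbourhoods_geojson(nb, out / "neighbourhoods.geojson")
        registry.to_csv(out / "establishments_registry.csv", index=False)
        participants.to_csv(out / "participants.csv", index=False)
        counts["generated_neighbourhoods"] = len(nb)
        counts["generated_establishments"] = len(registry)
        counts["generated_participants"] = len(participants)

        stage("query")
        provider = MockProvider(registry)
        grids = grids_from_neighbourhoods(nb, spacing=grid_spacing_km)
        terms = inventory.all_terms() + UNINFORMATIVE_LABELS
        raw = run_query(provider, grids, terms)
        counts["retrieved_raw"] = len(raw)

        stage("deduplicate")
        unique = deduplicate(raw)
        acquired = records_to_frame(unique)
        acquired.to_csv(out / "establishments_acquired.csv", index=False)
        counts["deduplicated"] = len(unique)

        stage("classify")
        classified = classify_frame(acquired, inventory)
        classified.to_csv(out / "establishments_classified.csv", index=False)
        summary = classification_summary(classified["category"])
        summary.to_csv(out / "classification_summary.csv", index=False)
        review_queue(classified, inventory).to_csv(out / "review_queue.csv", index=False)
        counts["classified"] = int(
            summary.loc[summary["label"] == "classified", "count"].iloc[0]
        )
        counts["unclassified"] = int(
            summary.loc[summary["label"] == "unclassified", "count"].iloc[0]
        )

        stage("metrics")
        assignment = assign_points(classified, nb)
        counts["assigned"] = int(assignment.notna().sum())
        counts["unassigned"] = int(assignment.isna().sum())
        metrics = build_metrics(nb, classified, assignment)
        metrics.to_csv(out / "metrics.csv", index=False)

        stage("outcome")
        analytic_raw, excl_log = apply_exclusions(participants)
        counts["excluded"] = excl_log["n_excluded"]
        counts["analytic"] = excl_log["n_analytic"]
        with open(out / "exclusion_log.json", "w") as fh:
            json.dump(excl_log, fh, indent=1)
        analytic = None
        table4 = None
        if len(analytic_raw):
            analytic = derive_outcome_frame(analytic_raw)
            analytic.to_csv(out / "analytic.csv", index=False)
            table4 = bivariate_table(analytic, metrics)

        stage("models")
        or_table = None
        fits = {}
        if analytic is None or len(analytic) < min_model_participants:
            manifest["model_stage"] = (
                f"skipped: {0 if analytic is None else len(analytic)} analytic "
                f"participants (< {min_model_participants})"
            )
            counts["modelled"] = 0
        elif analytic["neighbourhood_id"].nunique() < 2:
            manifest["model_stage"] = "skipped: fewer than 2 neighbourhoods"
            counts["modelled"] = 0
        else:
            merged = prepare_analytic(analytic, metrics)
            or_table, fits = exposure_or_table(merged, EXPOSURES)
            save_fits_json(fits, out / "model_fits.json")
            counts["modelled"] = len(merged)

        stage("report")
        render_report(
            {
                "neighbourhoods": nb,
                "metrics": metrics,
                "classified": classified,
                "summary": summary,
                "table4": table4,
                "table5": or_table,
            },
            out,
        )

        manifest["conservation"] = {
            "classified_plus_unclassified_equals_dedup":
                counts["classified"] + counts["unclassified"] == counts["deduplicated"],
            "assigned_plus_unassigned_equals_dedup":
                counts["assigned"] + counts["unassigned"] == counts["deduplicated"],
            "analytic_plus_excluded_equals_input":
                counts["analytic"] + counts["excluded"]
                == counts["generated_participants"],
        }
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    except StageError:
        raise
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "?"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise StageError(manifest["failed_stage"], exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def render_report(outputs: dict, out_dir) -> list[str]:
    """Write CSV analogues of the five descriptive/model tables.

    Partial inputs produce a partial report: each table is emitted only
    when its inputs are present, and the list of written files is returned.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    nb = outputs.get("neighbourhoods")
    metrics = outputs.get("metrics")
    if nb is not None and metrics is not None:
        # Table 1: census characteristics, overall and by city
        rows = []
        frames = [("Overall", metrics)] + [
            (city, sub) for city, sub in metrics.groupby("city", sort=True)
        ]
        for label, sub in frames:
            rows.append({
                "city": label,
                "n_neighbourhoods": len(sub),
                "popdens_median": sub["popdens"].median(),
                "popdens_p25": sub["popdens"].quantile(0.25),
                "popdens_p75": sub["popdens"].quantile(0.75),
                "sei_median": sub["sei"].median(),
                "sei_p25": sub["sei"].quantile(0.25),
                "sei_p75": sub["sei"].quantile(0.75),
            })
        pd.DataFrame(rows).to_csv(out / "table1_census.csv", index=False)
        written.append("table1_census.csv")

        # Table 2: density distribution by city
        dens_cols = [c for c in metrics.columns if c.startswith("density_")]
        rows = []
        for label, sub in frames:
            row = {"city": label, "n_neighbourhoods": len(sub)}
            for c in dens_cols:
                row[f"{c}_median"] = sub[c].median()
                row[f"{c}_p25"] = sub[c].quantile(0.25)
                row[f"{c}_p75"] = sub[c].quantile(0.75)
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "table2_density_by_city.csv", index=False)
        written.append("table2_density_by_city.csv")

        # Table 3: densities by popdens and SEI quartiles
        t3 = []
        for strat in ("popdens", "sei"):
            t = quartile_table(metrics, strat)
            t.insert(0, "stratifier", strat)
            t3.append(t)
        pd.concat(t3, ignore_index=True).to_csv(
            out / "table3_density_by_quartile.csv", index=False
        )
        written.append("table3_density_by_quartile.csv")

    if outputs.get("summary") is not None:
        outputs["summary"].to_csv(out / "classification_summary.csv", index=False)
        written.append("classification_summary.csv")
    if outputs.get("table4") is not None:
        outputs["table4"].to_csv(out / "table4_bivariate.csv", index=False)
        written.append("table4_bivariate.csv")
    if outputs.get("table5") is not None:
        outputs["table5"].to_csv(out / "table5_or.csv", index=False)
        written.append("table5_or.csv")
    missing = [t for t in ("table4", "table5") if outputs.get(t) is None]
    if missing:
        logger.warning("render_report: missing inputs for %s", missing)
    return written
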
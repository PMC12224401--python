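"""Neighbourhood-level spatial measures.

Implements the area-based metrics of the community food environment:

* point-in-polygon assignment of establishments to neighbourhoods
  (deterministic tie-break on shared boundaries: smallest neighbourhood id);
* establishment densities per km² — total (classified + unclassified) and
  per outlet category / health group (classified only);
* population density;
* the composite social environment index (SEI): census dimension variables
  (sanitation, housing, employment, education) z-scored across the pooled
  analysis set and averaged with equal weight, higher = more favourable;
* quartile-stratified descriptive tables of densities.

Neighbourhood tables carry their geometry either as a shapely ``geometry``
column or as cell bounds ``x0, y0, x1, y1``; coordinates are planar km or
lon/lat, declared by a CRS flag (``DataFrame.attrs["crs"]``).
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping, shape
from shapely.strtree import STRtree

from .config import CATEGORIES, GROUP_ORDER, HEALTH_GROUPS
from .classify import UNCLASSIFIED

logger = logging.getLogger(__name__)

DENSITY_COLUMNS = (
    ["density_total"]
    + [f"density_{c}" for c in CATEGORIES]
    + [f"density_{g}" for g in GROUP_ORDER]
)


class CRSMismatchError(ValueError):
    pass


def ensure_geometry(neighbourhoods: pd.DataFrame) -> pd.DataFrame:
    """Attach a shapely ``geometry`` column (from cell bounds if absent)."""
    if "geometry" in neighbourhoods.columns:
        return neighbourhoods
    df = neighbourhoods.copy()
    df["geometry"] = [
        box(r.x0, r.y0, r.x1, r.y1) for r in df.itertuples(index=False)
    ]
    return df


# -- GeoJSON I/O -------------------------------------------------------------

def write_neighbourhoods_geojson(neighbourhoods: pd.DataFrame, path) -> None:
    df = ensure_geometry(neighbourhoods)
    props_cols = [c for c in df.columns if c not in ("geometry",)]
    features = []
    for _, row in df.iterrows():
        props = {}
        for c in props_cols:
            v = row[c]
            props[c] = float(v) if isinstance(v, (np.floating, np.integer)) else v
        features.append({
            "type": "Feature",
            "geometry": mapping(row["geometry"]),
            "properties": props,
        })
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "x_crs": neighbourhoods.attrs.get("crs", "planar_km"),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_neighbourhoods_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        doc = json.load(fh)
    rows = []
    geoms = []
    for feat in doc["features"]:
        rows.append(feat["properties"])
        geoms.append(shape(feat["geometry"]))
    df = pd.DataFrame(rows)
    df["geometry"] = geoms
    df.attrs["crs"] = doc.get("x_crs", "planar_km")
    return df


# -- spatial join ------------------------------------------------------------

def assign_points(
    establishments: pd.DataFrame,
    neighbourhoods: pd.DataFrame,
    crs: str | None = None,
) -> pd.Series:
    """Assign each establishment point to the neighbourhood containing it.

    Returns a Series of neighbourhood ids aligned with the establishment
    index (NaN for points outside every polygon, counted and logged).
    Points on a shared boundary go to the lexicographically smallest
    neighbourhood id.  Raises :class:`CRSMismatchError` when the declared
    CRS flags of the two tables disagree.
    """
    est_crs = crs or establishments.attrs.get("crs")
    nb_crs = crs or neighbourhoods.attrs.get("crs")
    if est_crs is not None and nb_crs is not None and est_crs != nb_crs:
        raise CRSMismatchError(f"CRS mismatch: {est_crs!r} vs {nb_crs!r}")

    nb = ensure_geometry(neighbourhoods).reset_index(drop=True)
    ids = nb["id"].to_numpy(object)
    tree = STRtree(nb["geometry"].tolist())
    pts = shapely.points(
        establishments["x"].to_numpy(float), establishments["y"].to_numpy(float)
    )
    pi, gi = tree.query(pts, predicate="intersects")
    best: dict[int, str] = {}
    for p, g in zip(pi, gi):
        nid = ids[g]
        if p not in best or nid < best[p]:
            best[p] = nid
    out = pd.Series(
        [best.get(i, np.nan) for i in range(len(establishments))],
        index=establishments.index,
        name="neighbourhood_id",
        dtype=object,
    )
    n_unassigned = int(out.isna().sum())
    if n_unassigned:
        logger.info("assign_points: %d points outside all polygons", n_unassigned)
    return out


# -- densities ---------------------------------------------------------------

def compute_density(
    neighbourhoods: pd.DataFrame,
    classified: pd.DataFrame,
    assignment: pd.Series | None = None,
) -> pd.DataFrame:
    """Establishment densities (count / km²) per neighbourhood.

    ``classified`` needs a ``category`` column; unclassified establishments
    count toward ``density_total`` only, never toward category or
    health-group densities.  ``assignment`` defaults to the establishments'
    own ``neighbourhood_id`` column.  Neighbourhoods with no establishments
    get all-zero densities.
    """
    if (neighbourhoods["area_km2"] <= 0).any():
        raise ValueError("all neighbourhood areas must be positive")
    nb_ids = neighbourhoods["id"]
    assigned = assignment if assignment is not None else classified["neighbourhood_id"]
    est = pd.DataFrame({
        "neighbourhood_id": assigned.to_numpy(object),
        "category": classified["category"].to_numpy(object),
    }).dropna(subset=["neighbourhood_id"])

    total = est.groupby("neighbourhood_id").size()
    out = pd.DataFrame({"id": nb_ids.to_numpy(object)})
    area = neighbourhoods["area_km2"].to_numpy(float)
    out["density_total"] = nb_ids.map(total).fillna(0).to_numpy(float) / area

    cls = est[est["category"] != UNCLASSIFIED]
    by_cat = cls.groupby(["neighbourhood_id", "category"]).size().unstack(fill_value=0)
    for cat in CATEGORIES:
        cnt = by_cat[cat] if cat in by_cat.columns else pd.Series(dtype=float)
        out[f"density_{cat}"] = nb_ids.map(cnt).fillna(0).to_numpy(float) / area
    for grp in GROUP_ORDER:
        cats = [c for c, g in HEALTH_GROUPS.items() if g == grp]
        out[f"density_{grp}"] = sum(out[f"density_{c}"] for c in cats)
    return out


def social_environment_index(
    neighbourhoods: pd.DataFrame,
    directions: dict[str, int] | None = None,
) -> pd.Series:
    """Composite SEI: equal-weight mean of z-scored dimension variables.

    z-scores are pooled across every neighbourhood in the analysis set (all
    cities on one common scale), population SD convention (ddof=0).
    ``directions`` maps a dimension column to ±1; deprivation-coded
    variables (higher = worse) must be declared as -1 so that higher SEI
    always means a more favourable social environment.
    """
    dims = [c for c in neighbourhoods.columns if c.startswith("dim_")]
    if not dims:
        raise ValueError("no dim_* columns found")
    if len(neighbourhoods) < 2:
        raise ValueError("SEI needs >= 2 neighbourhoods for dispersion")
    directions = directions or {}
    zs = []
    for c in dims:
        col = neighbourhoods[c].to_numpy(float)
        sd = col.std()
        if sd == 0:
            raise ValueError(f"zero-variance dimension: {c}")
        z = (col - col.mean()) / sd
        zs.append(directions.get(c, 1) * z)
    sei = np.mean(zs, axis=0)
    return pd.Series(sei, index=neighbourhoods.index, name="sei")


def build_metrics(
    neighbourhoods: pd.DataFrame,
    classified: pd.DataFrame,
    assignment: pd.Series | None = None,
    directions: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Full per-neighbourhood metrics table: popdens, SEI, densities."""
    dens = compute_density(neighbourhoods, classified, assignment)
    out = dens.copy()
    out.insert(1, "city", neighbourhoods["city"].to_numpy(object))
    out.insert(2, "area_km2", neighbourhoods["area_km2"].to_numpy(float))
    out.insert(
        3, "popdens",
        neighbourhoods["population"].to_numpy(float)
        / neighbourhoods["area_km2"].to_numpy(float),
    )
    out.insert(4, "sei", social_environment_index(neighbourhoods, directions).to_numpy())
    return out


def quartile_table(
    metrics: pd.DataFrame,
    stratifier: str,
    value_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Mean and median of each density by quartile of a stratifier.

    Quartile cut points use linear-interpolation quantiles (numpy default,
    type 7).  Heavy ties that collapse a cut point are tolerated: bins are
    merged with a logged warning and the remaining (unequal) bins reported.
    """
    if len(metrics) < 4:
        raise ValueError("quartile_table needs >= 4 neighbourhoods")
    if value_columns is None:
        value_columns = [c for c in DENSITY_COLUMNS if c in metrics.columns]
    s = metrics[stratifier].to_numpy(float)
    if np.allclose(s, s[0]):
        raise ValueError(f"stratifier {stratifier!r} is constant; no quartiles")
    try:
        q = pd.qcut(s, 4, labels=["Q1", "Q2", "Q3", "Q4"])
    except ValueError:
        logger.warning(
            "quartile_table: ties collapse %s quartile edges; using unequal bins",
            stratifier,
        )
        q = pd.qcut(s, 4, duplicates="drop")
        q = q.rename_categories([f"Q{i + 1}" for i in range(len(q.categories))])
    rows = []
    grouped = pd.DataFrame({"quartile": q}).join(metrics[value_columns].reset_index(drop=True))
    for lab, sub in grouped.groupby("quartile", observed=True):
        row = {"quartile": str(lab), "n_neighbourhoods": len(sub)}
        for c in value_columns:
            row[f"{c}_mean"] = sub[c].mean()
            row[f"{c}_median"] = sub[c].median()
        rows.append(row)
    return pd.DataFrame(rows)
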
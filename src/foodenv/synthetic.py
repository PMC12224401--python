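"""Synthetic multi-city study region generator.

The study's real inputs — a commercial point-of-interest extraction, census
microgeography and a national health survey — are private.  This module
generates structurally faithful stand-ins with known ground truth so every
downstream stage (query, classification, metrics, models) is testable and
parameter recovery can be checked:

* **Neighbourhoods** — square cells tiling per-city bounding boxes on a
  planar km grid, with log-normal population density and four census
  dimension scores (sanitation, housing, employment, education) correlated
  with log density.
* **Establishments** — per-neighbourhood counts from a negative-binomial
  model whose log-intensity is linear in population and the social
  environment index (SEI), each with a composed Spanish name, provider-style
  type labels with configurable noise, and a configurable residue of
  deliberately ambiguous records.
* **Participants** — survey respondents nested in a subset of
  neighbourhoods, whose non-daily fruit/vegetable outcome is drawn from a
  random-intercept logistic model; weekly day counts are back-filled
  consistently with the binary outcome.

All draws flow from ``CityConfig.seed`` through a single
``numpy.random.Generator``; identical config + seed reproduce every output
exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import CATEGORIES, CityConfig, ParameterError

PLANAR_CRS = "planar_km"
#: gap between city bounding boxes on the shared planar grid (km)
_CITY_GAP_KM = 50.0

#: Display naming terms per category; each contains a name-inventory term
#: after normalization, so a name composed from it is classifiable by name.
NAMING_TERMS: dict[str, list[str]] = {
    "fruit_vegetable_store": ["Verdulería", "Frutería"],
    "fresh_food_retail": ["Carnicería", "Pescadería", "Panadería", "Pastelería"],
    "small_food_retail": ["Almacén", "Abarrotes", "Bodega", "Minimercado"],
    "supermarket": ["Supermercado", "Hipermercado"],
    "ready_for_consumption": [
        "Restaurante", "Cafetería", "Pizzería", "Fuente de Soda",
        "Cocinería", "Sanguchería",
    ],
    "convenience_store": ["Minimarket", "OK Market", "Spid", "Big John"],
    "fast_food_chain": [
        "McDonald's", "Burger King", "KFC", "Doggis", "Juan Maestro", "Telepizza",
    ],
    "candy_ice_cream": ["Heladería", "Confitería", "Chocolatería", "Dulcería"],
}

#: Provider ("Google-style") type labels consistent with each category.
PROVIDER_LABELS: dict[str, list[str]] = {
    "fruit_vegetable_store": ["greengrocer"],
    "fresh_food_retail": ["bakery", "butcher_shop", "fish_market"],
    "small_food_retail": ["grocery_store"],
    "supermarket": ["supermarket"],
    "ready_for_consumption": ["restaurant", "cafe", "meal_takeaway"],
    "convenience_store": ["convenience_store"],
    "fast_food_chain": ["fast_food_restaurant"],
    "candy_ice_cream": ["ice_cream_shop", "candy_store"],
}

#: Labels carrying no category information.
UNINFORMATIVE_LABELS: list[str] = ["food", "store", "establishment", "point_of_interest"]

#: Proper nouns for composing establishment names.  None contains an
#: inventory term, so a noun-only name is unclassifiable by name.
PROPER_NOUNS: list[str] = [
    "El Sol", "La Estrella", "Los Andes", "Don Pedro", "Doña Rosa", "San Martín",
    "Santa Clara", "Las Flores", "El Trébol", "La Esquina", "Don Jacinto",
    "Los Aromos", "Villa Alegre", "El Roble", "La Cumbre", "Portal Norte",
    "Plaza Sur", "El Faro", "La Palmera", "Los Castaños", "Doña Elvira",
    "San Benito", "El Volcán", "La Araucana", "Los Alerces", "Cerro Verde",
    "El Cóndor", "La Bahía", "Tres Montes", "Nueva Aurora", "El Manantial",
    "La Ribera", "Los Copihues", "Valle Hermoso", "El Lucero", "Doña Carmen",
]

#: First tokens for deliberately ambiguous names ("Donde Marta" style).
AMBIGUOUS_LEADS: list[str] = ["Donde", "Casa", "Rincón", "Local", "Quiosco", "Paradero"]
AMBIGUOUS_TAILS: list[str] = [
    "Marta", "Juanito", "Lola", "Pepe", "Clarita", "Manuel", "Tía Ana",
    "El Flaco", "La Negra", "Don Lalo",
]


def _allocate_counts(total: int, weights: tuple[float, ...]) -> list[int]:
    """Largest-remainder split of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    exact = total * w / w.sum()
    base = np.floor(exact).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:rem]] += 1
    return base.tolist()


def generate_neighbourhoods(config: CityConfig) -> pd.DataFrame:
    """Generate square-cell neighbourhoods tiling per-city bounding boxes.

    Returns a DataFrame (attrs ``crs="planar_km"``) with columns ``id``,
    ``city``, ``x0, y0, x1, y1`` (cell bounds, km), ``area_km2``,
    ``popdens``, ``population`` and ``dim_1..dim_k`` census dimension
    scores.  Dimension scores are correlated with log population density at
    ``sei_popdens_correlation`` and carry arbitrary per-dimension affine
    scales (z-scoring downstream absorbs them).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = _allocate_counts(config.n_neighbourhoods, config.city_weights)
    cell = config.cell_size_km
    mu, sigma = config.popdens_lognormal_params

    rows = []
    x_offset = 0.0
    for city, n_c in zip(config.city_labels, counts):
        nx = int(np.ceil(np.sqrt(n_c))) if n_c else 0
        code = city[:3].upper()
        for i in range(n_c):
            r, c = divmod(i, nx)
            x0 = x_offset + c * cell
            y0 = r * cell
            rows.append((f"{code}-{i:05d}", city, x0, y0, x0 + cell, y0 + cell))
        if n_c:
            x_offset += nx * cell + _CITY_GAP_KM
    df = pd.DataFrame(rows, columns=["id", "city", "x0", "y0", "x1", "y1"])
    df["area_km2"] = (df["x1"] - df["x0"]) * (df["y1"] - df["y0"])

    n = len(df)
    log_popdens = rng.normal(mu, sigma, size=n)
    df["popdens"] = np.exp(log_popdens)
    df["population"] = df["popdens"] * df["area_km2"]

    # dimension scores: corr * z(log popdens) + sqrt(1-corr^2) * noise, then
    # an arbitrary affine per dimension so raw scales differ
    z = (log_popdens - mu) / sigma
    r = config.sei_popdens_correlation
    scales = [10.0, 2.0, 5.0, 1.0, 7.0, 3.0]
    offsets = [50.0, 3.0, 20.0, 0.0, 10.0, 5.0]
    for k in range(config.sei_dimension_count):
        noise = rng.normal(size=n)
        raw = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * noise
        sc = scales[k % len(scales)]
        off = offsets[k % len(offsets)]
        df[f"dim_{k + 1}"] = off + sc * raw
    df.attrs["crs"] = PLANAR_CRS
    return df


def _internal_sei(neighbourhoods: pd.DataFrame) -> np.ndarray:
    """Mean of z-scored (ddof=0) dimension columns; generator-internal."""
    dims = [c for c in neighbourhoods.columns if c.startswith("dim_")]
    z = np.column_stack([
        (neighbourhoods[c] - neighbourhoods[c].mean()) / neighbourhoods[c].std(ddof=0)
        for c in dims
    ])
    return z.mean(axis=1)


def generate_establishments(
    neighbourhoods: pd.DataFrame, config: CityConfig
) -> pd.DataFrame:
    """Generate the establishment registry for a set of neighbourhoods.

    Per-neighbourhood counts are negative-binomial with mean proportional to
    ``population * exp(density_sei_gradient * SEI)``, normalized so the
    expected total equals ``establishments_per_capita`` times the total
    population.  Each establishment receives planar coordinates uniform in
    its cell, a composed name, provider primary/secondary labels (noisy at
    ``label_noise``) and a true category; an ``ambiguous_name_fraction``
    share carries neither an inventory term nor an informative label.
    """
    if neighbourhoods.empty:
        raise ParameterError("neighbourhoods must be non-empty")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    sei = _internal_sei(neighbourhoods)
    pop = neighbourhoods["population"].to_numpy(float)
    weight = pop * np.exp(config.density_sei_gradient * sei)
    total_expected = config.establishments_per_capita * pop.sum()
    if total_expected <= 0 or weight.sum() <= 0:
        mu_j = np.zeros(len(neighbourhoods))
    else:
        mu_j = total_expected * weight / weight.sum()

    size = config.nb_dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        p = size / (size + mu_j)
    counts = np.where(mu_j > 0, rng.negative_binomial(size, np.clip(p, 1e-12, 1.0)), 0)

    n_est = int(counts.sum())
    if n_est == 0:
        return pd.DataFrame(columns=[
            "provider_id", "name", "address", "x", "y", "primary_type",
            "secondary_types", "true_category", "neighbourhood_id", "city",
        ])

    idx = np.repeat(np.arange(len(neighbourhoods)), counts)
    nb = neighbourhoods.iloc[idx].reset_index(drop=True)
    x = rng.uniform(nb["x0"].to_numpy(), nb["x1"].to_numpy())
    y = rng.uniform(nb["y0"].to_numpy(), nb["y1"].to_numpy())

    cat_idx = rng.choice(len(CATEGORIES), size=n_est, p=np.asarray(config.category_mix))
    cats = np.asarray(CATEGORIES, dtype=object)[cat_idx]
    ambiguous = rng.random(n_est) < config.ambiguous_name_fraction
    fallback = (~ambiguous) & (rng.random(n_est) < config.fallback_name_fraction)
    noisy = rng.random(n_est) < config.label_noise

    names, primaries, secondaries = [], [], []
    n_cat = len(CATEGORIES)
    for i in range(n_est):
        cat = cats[i]
        if ambiguous[i]:
            lead = AMBIGUOUS_LEADS[rng.integers(len(AMBIGUOUS_LEADS))]
            tail = AMBIGUOUS_TAILS[rng.integers(len(AMBIGUOUS_TAILS))]
            names.append(f"{lead} {tail}")
            primaries.append(UNINFORMATIVE_LABELS[rng.integers(len(UNINFORMATIVE_LABELS))])
            secondaries.append("")
            continue
        noun = PROPER_NOUNS[rng.integers(len(PROPER_NOUNS))]
        if fallback[i]:
            names.append(noun)
        else:
            terms = NAMING_TERMS[cat]
            names.append(f"{terms[rng.integers(len(terms))]} {noun}")
        if noisy[i]:
            other = CATEGORIES[(cat_idx[i] + 1 + rng.integers(n_cat - 1)) % n_cat]
            labels = PROVIDER_LABELS[other]
        else:
            labels = PROVIDER_LABELS[cat]
        primaries.append(labels[rng.integers(len(labels))])
        extra = UNINFORMATIVE_LABELS[rng.integers(len(UNINFORMATIVE_LABELS))]
        secondaries.append(extra)

    streets = rng.integers(1, 9999, size=n_est)
    df = pd.DataFrame({
        "provider_id": [f"POI{i:07d}" for i in range(n_est)],
        "name": names,
        "address": [f"{nm.split()[-1]} {num}, {city}"
                    for nm, num, city in zip(names, streets, nb["city"])],
        "x": x,
        "y": y,
        "primary_type": primaries,
        "secondary_types": secondaries,
        "true_category": cats,
        "neighbourhood_id": nb["id"].to_numpy(),
        "city": nb["city"].to_numpy(),
    })
    df.attrs["crs"] = PLANAR_CRS
    return df


# admissible (fruit, veg) pairs by binary outcome: capped sum < 7 iff non-daily
_NON_DAILY_PAIRS = [(f, v) for f in range(8) for v in range(8) if f + v <= 6]
_DAILY_PAIRS = [(f, v) for f in range(8) for v in range(8) if f + v >= 7]


def generate_participants(
    neighbourhoods: pd.DataFrame,
    config: CityConfig,
    establishments: pd.DataFrame | None = None,
    metrics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Generate survey respondents nested in a subset of neighbourhoods.

    The binary non-daily outcome is drawn from
    ``logit(p) = intercept + beta_exposure * z(exposure) + covariates + u_j``
    with ``u_j ~ Normal(0, sigma_u^2)`` per neighbourhood; weekly fruit and
    vegetable day counts are then back-filled uniformly over the pairs
    consistent with the outcome (daily => capped sum of 7; non-daily =>
    sum <= 6).  A ``missingness_rate`` share of records get one required
    item blanked, feeding the exclusion stage.

    Exposure densities are taken from ``metrics`` (column
    ``config.outcome_exposure``) or computed internally as total count/area
    from ``establishments``; with neither, the exposure is zero for all.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    truth = config.outcome_model
    n = config.n_participants
    if n == 0:
        return pd.DataFrame(columns=[
            "id", "neighbourhood_id", "age", "gender", "education",
            "fruit_days", "veg_days",
        ])

    nb = neighbourhoods.reset_index(drop=True)
    if metrics is not None:
        expo_map = metrics.set_index("id")[config.outcome_exposure]
        exposure_all = nb["id"].map(expo_map).to_numpy(float)
    elif establishments is not None and len(establishments):
        counts = establishments["neighbourhood_id"].value_counts()
        exposure_all = (
            nb["id"].map(counts).fillna(0.0).to_numpy(float)
            / nb["area_km2"].to_numpy(float)
        )
    else:
        exposure_all = np.zeros(len(nb))

    k = min(config.n_survey_neighbourhoods, len(nb))
    chosen = rng.choice(len(nb), size=k, replace=False)
    assign = rng.integers(0, k, size=n)          # uniform over chosen cells
    nb_idx = chosen[assign]
    u_j = rng.normal(0.0, truth.sigma_u, size=k)

    age = 20.0 + 70.0 * rng.beta(1.2, 1.6, size=n)
    male = rng.random(n) >= config.female_share
    edu_levels = np.array(["<primary", "primary", "secondary", "university"], dtype=object)
    edu = edu_levels[rng.choice(4, size=n, p=np.asarray(config.education_mix))]
    low_edu = np.isin(edu, ["<primary", "primary"]).astype(float)

    exposure = exposure_all[nb_idx]
    sd_e = exposure.std(ddof=0)
    z_expo = (exposure - exposure.mean()) / sd_e if sd_e > 0 else np.zeros(n)
    z_age = (age - age.mean()) / age.std(ddof=0)

    lin = (
        truth.intercept
        + truth.beta_exposure * z_expo
        + truth.beta_age * z_age
        + truth.beta_male * male.astype(float)
        + truth.beta_education * low_edu
        + u_j[assign]
    )
    non_daily = rng.random(n) < expit(lin)

    pair_nd = np.asarray(_NON_DAILY_PAIRS)
    pair_d = np.asarray(_DAILY_PAIRS)
    fruit = np.empty(n, dtype=float)
    veg = np.empty(n, dtype=float)
    pick_nd = rng.integers(0, len(pair_nd), size=n)
    pick_d = rng.integers(0, len(pair_d), size=n)
    fruit[non_daily] = pair_nd[pick_nd[non_daily], 0]
    veg[non_daily] = pair_nd[pick_nd[non_daily], 1]
    fruit[~non_daily] = pair_d[pick_d[~non_daily], 0]
    veg[~non_daily] = pair_d[pick_d[~non_daily], 1]

    df = pd.DataFrame({
        "id": [f"P{i:05d}" for i in range(n)],
        "neighbourhood_id": nb["id"].to_numpy()[nb_idx],
        "age": np.round(age, 1),
        "gender": np.where(male, "male", "female"),
        "education": edu,
        "fruit_days": fruit,
        "veg_days": veg,
    })

    miss = rng.random(n) < config.missingness_rate
    fields = np.array(["age", "gender", "education", "fruit_days", "veg_days"])
    which = rng.integers(0, len(fields), size=n)
    for i in np.flatnonzero(miss):
        df.loc[i, fields[which[i]]] = np.nan
    return df
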
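"""Grid-covering term-query acquisition against an abstract POI provider.

The acquisition procedure mirrors commercial points-of-interest extraction:
a regular lattice of query points covers each city's bounding box, and for
every (term, point) pair the provider is asked for establishments within a
search radius whose name or type labels match the term.  When the search
radius is at least ``spacing / sqrt(2)`` the union of the query discs covers
the plane between lattice points, so any establishment matched by at least
one term is retrieved at least once.  The raw concatenated result list is
then cleaned and de-duplicated (by provider id, or by normalized name plus
proximity when ids are absent).

Only a mock provider backed by a registry table ships here; a live adapter
for a commercial service would implement the same ``search`` contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .classify import normalize_text

logger = logging.getLogger(__name__)

PLANAR_CRS = "planar_km"
LONLAT_CRS = "lonlat"

_EARTH_RADIUS_KM = 6371.0088


def _haversine_km(x1, y1, x2, y2):
    """Great-circle distance (km) between (lon, lat) degree pairs."""
    lam1, phi1, lam2, phi2 = map(np.radians, (x1, y1, x2, y2))
    d = (
        np.sin((phi2 - phi1) / 2) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2
    )
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(d))


def pair_distance_km(x1, y1, x2, y2, crs: str = PLANAR_CRS):
    if crs == LONLAT_CRS:
        return _haversine_km(x1, y1, x2, y2)
    return math.hypot(x2 - x1, y2 - y1)


@dataclass(frozen=True)
class GridSpec:
    """Query lattice over one bounding box.

    ``search_radius >= spacing / sqrt(2)`` guarantees that the radius-discs
    around the lattice points cover the whole box (half-diagonal of a grid
    cell), which is what makes retrieval completeness provable.
    """

    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    spacing: float
    search_radius: float
    crs: str = PLANAR_CRS

    def __post_init__(self):
        xmin, ymin, xmax, ymax = self.bounds
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if xmax < xmin or ymax < ymin:
            raise ValueError("degenerate bounds: max < min")
        if self.search_radius < self.spacing / math.sqrt(2) - 1e-12:
            raise ValueError(
                "search_radius must be >= spacing/sqrt(2) for disc coverage"
            )


@dataclass(frozen=True)
class ProviderRecord:
    """One establishment as returned by a POI provider."""

    provider_id: str
    name: str
    address: str
    x: float
    y: float
    primary_type: str
    secondary_types: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.secondary_types) > 7:
            raise ValueError("at most 7 secondary type labels")


class POIProvider(Protocol):
    """Contract for a points-of-interest search backend.

    ``search`` must be idempotent and deterministic for a fixed underlying
    registry: same (term, x, y, radius) -> same record list.
    """

    def search(self, term: str, x: float, y: float, radius: float) -> list[ProviderRecord]:
        ...


def _axis_points(lo: float, hi: float, spacing: float) -> np.ndarray:
    if hi - lo < 1e-12:
        return np.array([lo])
    pts = np.arange(lo, hi - 1e-9, spacing)
    return np.append(pts, hi)


def make_grid(spec: GridSpec) -> list[tuple[float, float]]:
    """Ordered (row-major, y outer) lattice of query points covering bounds.

    Edges are always included, so a spacing larger than the box extent still
    emits corner and far-edge points and coverage is preserved.  A
    degenerate (zero-extent) box collapses to a single point with a warning.
    """
    xmin, ymin, xmax, ymax = spec.bounds
    if xmax - xmin < 1e-12 and ymax - ymin < 1e-12:
        logger.warning("make_grid: degenerate bounding box, emitting one point")
    xs = _axis_points(xmin, xmax, spec.spacing)
    ys = _axis_points(ymin, ymax, spec.spacing)
    return [(float(x), float(y)) for y in ys for x in xs]


class MockProvider:
    """Deterministic POI provider backed by an in-memory registry table.

    The registry is the synthetic establishment file (columns
    ``provider_id, name, address, x, y, primary_type, secondary_types``).
    A term matches a record when it occurs word-bounded in the normalized
    name or equals one of the normalized type labels.
    """

    def __init__(self, registry: pd.DataFrame, crs: str = PLANAR_CRS):
        self.crs = crs
        self._records: list[ProviderRecord] = []
        self._token_index: dict[str, set[int]] = {}
        self._norm_names: list[str] = []
        xs, ys = [], []
        for i, row in enumerate(registry.itertuples(index=False)):
            sec = getattr(row, "secondary_types", "")
            if sec is None or (isinstance(sec, float) and pd.isna(sec)):
                sec = ""
            if isinstance(sec, str):
                sec_t = tuple(t for t in sec.split(";") if t)
            else:
                sec_t = tuple(sec)
            rec = ProviderRecord(
                provider_id=str(row.provider_id),
                name=str(row.name),
                address=str(getattr(row, "address", "")),
                x=float(row.x),
                y=float(row.y),
                primary_type=str(row.primary_type),
                secondary_types=sec_t,
            )
            self._records.append(rec)
            xs.append(rec.x)
            ys.append(rec.y)
            norm = normalize_text(rec.name)
            self._norm_names.append(norm)
            tokens = set(norm.split())
            tokens.add(normalize_text(rec.primary_type))
            tokens.update(normalize_text(t) for t in sec_t)
            for tok in tokens:
                if tok:
                    self._token_index.setdefault(tok, set()).add(i)
        self._tree = (
            cKDTree(np.column_stack([xs, ys])) if self._records else None
        )

    def __len__(self) -> int:
        return len(self._records)

    @property
    def records(self) -> list[ProviderRecord]:
        return list(self._records)

    def vocabulary(self) -> list[str]:
        """All indexed tokens; a term list that spans the registry."""
        return sorted(self._token_index)

    def _candidates(self, term: str) -> set[int]:
        toks = normalize_text(term).split()
        if not toks:
            return set()
        cand = self._token_index.get(toks[0], set())
        if len(toks) == 1:
            return cand
        # multi-word term: verify word-bounded phrase in the normalized name
        phrase = " ".join(toks)
        return {
            i for i in cand
            if f" {phrase} " in f" {self._norm_names[i]} "
        }

    def search(self, term: str, x: float, y: float, radius: float) -> list[ProviderRecord]:
        if self._tree is None:
            return []
        if self.crs == LONLAT_CRS:
            # conservative prefilter in degrees, exact haversine check after
            deg = radius / 111.0 / max(math.cos(math.radians(y)), 1e-6)
            near = self._tree.query_ball_point([x, y], r=max(deg, radius / 111.0))
            near = [
                i for i in near
                if _haversine_km(x, y, self._records[i].x, self._records[i].y) <= radius
            ]
        else:
            near = self._tree.query_ball_point([x, y], r=radius)
        cand = self._candidates(term)
        hits = sorted(i for i in near if i in cand)
        return [self._records[i] for i in hits]


class LiveProviderStub:
    """Placeholder documenting the live commercial-service adapter contract.

    A real adapter would implement :class:`POIProvider` on top of a paid web
    service (authentication, paging, quota handling).  It is intentionally
    unimplemented here: the analysis pipeline runs against a registry-backed
    :class:`MockProvider`.
    """

    def search(self, term: str, x: float, y: float, radius: float) -> list[ProviderRecord]:
        raise NotImplementedError("live provider adapter is not implemented")


def run_query(
    provider: POIProvider,
    grid: GridSpec | Iterable[GridSpec],
    terms: Sequence[str],
) -> list[ProviderRecord]:
    """Exhaustive term x grid-point product query.

    Returns the raw concatenated record list (duplicates expected: the same
    establishment is returned from every disc containing it and for every
    term it matches).  A provider failure at a point is retried once, then
    skipped with a logged warning; a term with no hits anywhere is normal.
    """
    if not terms:
        raise ValueError("term list must be non-empty")
    specs = [grid] if isinstance(grid, GridSpec) else list(grid)
    raw: list[ProviderRecord] = []
    term_hits: dict[str, int] = {t: 0 for t in terms}
    n_failures = 0
    for spec in specs:
        for (x, y) in make_grid(spec):
            for term in terms:
                try:
                    recs = provider.search(term, x, y, spec.search_radius)
                except Exception:
                    try:
                        recs = provider.search(term, x, y, spec.search_radius)
                    except Exception as exc:  # retry failed: skip point/term
                        n_failures += 1
                        logger.warning(
                            "provider failed twice at (%g, %g) term %r: %s",
                            x, y, term, exc,
                        )
                        continue
                term_hits[term] += len(recs)
                raw.extend(recs)
    logger.info(
        "run_query: %d raw records, %d empty terms, %d skipped failures",
        len(raw), sum(1 for v in term_hits.values() if v == 0), n_failures,
    )
    return raw


def deduplicate(
    raw: Sequence[ProviderRecord],
    epsilon_km: float = 0.025,
    crs: str = PLANAR_CRS,
) -> list[ProviderRecord]:
    """Collapse the raw query result to one record per establishment.

    Records sharing a provider id are merged (first occurrence wins).
    Records without a provider id are merged when their normalized names are
    equal and they lie within ``epsilon_km`` of an already-kept record
    (default 25 m) — two branches of one chain further apart stay distinct.
    Idempotent: deduplicating an already-unique list is the identity.
    """
    kept: list[ProviderRecord] = []
    seen_ids: set[str] = set()
    by_name: dict[str, list[ProviderRecord]] = {}
    n_merged = 0
    for rec in raw:
        if rec.provider_id:
            if rec.provider_id in seen_ids:
                n_merged += 1
                continue
            seen_ids.add(rec.provider_id)
            kept.append(rec)
            continue
        norm = normalize_text(rec.name)
        matched = False
        for prev in by_name.get(norm, ()):
            if pair_distance_km(rec.x, rec.y, prev.x, prev.y, crs) <= epsilon_km:
                matched = True
                break
        if matched:
            n_merged += 1
            continue
        by_name.setdefault(norm, []).append(rec)
        kept.append(rec)
    if n_merged:
        logger.info("deduplicate: merged %d duplicate records", n_merged)
    return kept


def records_to_frame(records: Sequence[ProviderRecord]) -> pd.DataFrame:
    """Tabulate provider records for the classifier."""
    return pd.DataFrame({
        "provider_id": [r.provider_id for r in records],
        "name": [r.name for r in records],
        "address": [r.address for r in records],
        "x": [r.x for r in records],
        "y": [r.y for r in records],
        "primary_type": [r.primary_type for r in records],
        "secondary_types": [";".join(r.secondary_types) for r in records],
    })


def grids_from_neighbourhoods(
    neighbourhoods: pd.DataFrame,
    spacing: float = 1.0,
    search_radius: float | None = None,
    crs: str = PLANAR_CRS,
) -> list[GridSpec]:
    """One covering GridSpec per city from the neighbourhood cell bounds."""
    if search_radius is None:
        search_radius = spacing / math.sqrt(2) * 1.001
    specs = []
    for _, sub in neighbourhoods.groupby("city", sort=True):
        bounds = (
            float(sub["x0"].min()), float(sub["y0"].min()),
            float(sub["x1"].max()), float(sub["y1"].max()),
        )
        specs.append(GridSpec(bounds=bounds, spacing=spacing,
                              search_radius=search_radius, crs=crs))
    return specs
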
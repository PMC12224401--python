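"""Rule-based classification of food establishments.

Each establishment is assigned one of eight outlet categories (fruit and
vegetable store, fresh food retail, small food retail, supermarket,
ready-for-consumption, convenience store, fast-food chain, candy/ice-cream
shop) via a name-first hierarchy:

1. the normalized establishment *name* is scanned for terms from a
   qualitative inventory of Latin-American food-retail terminology
   (word-boundary matches only; the highest-priority hit wins, ties broken
   by longest term then lexicographically);
2. if no name term matches, the provider-assigned *type labels* (primary
   first, then secondaries in order) are looked up against the inventory's
   provider-type entries;
3. otherwise the establishment is left ``unclassified`` — it still counts
   toward total density but is excluded from category-stratified outputs.

Categories map onto three health groups (most healthy / mixed / less
healthy) reflecting the predominance of fresh versus ultra-processed food
in each outlet type.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass
from difflib import get_close_matches
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .config import CATEGORIES, GROUP_ORDER, HEALTH_GROUPS

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"

_PUNCT_RE = re.compile(r"[^\w\s]", flags=re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Lowercase, fold accents, strip punctuation, collapse whitespace.

    "Almacén  El-Sol" -> "almacen el sol".  Applied to names, inventory
    terms and provider labels alike, so inventories may carry accents.
    """
    if text is None:
        return ""
    text = unicodedata.normalize("NFKD", str(text))
    text = "".join(c for c in text if not unicodedata.combining(c))
    text = text.lower()
    text = _PUNCT_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


class UnclassifiedCategoryError(ValueError):
    """Raised when a health group is requested for an unclassified record."""


def health_group(category: str) -> str:
    """Map an outlet category to its health group (fixed partition)."""
    if category == UNCLASSIFIED:
        raise UnclassifiedCategoryError(
            "unclassified establishments have no health group; exclude them "
            "from stratified outputs"
        )
    try:
        return HEALTH_GROUPS[category]
    except KeyError:
        raise ValueError(f"unknown category: {category!r}") from None


@dataclass(frozen=True)
class TermEntry:
    term: str          # normalized
    category: str
    match_kind: str    # name | provider_type | both
    priority: int      # smaller = higher precedence


class TermInventory:
    """Ordered inventory of search terms / synonyms mapped to categories.

    Drives both the acquisition queries and the classifier.  Terms are
    normalized on load; matching is word-boundary, never substring, so
    "mercado" does not fire inside "supermercado".
    """

    def __init__(self, entries: Iterable[TermEntry]):
        self.entries: list[TermEntry] = []
        seen: dict[str, set[str]] = {"name": set(), "provider_type": set()}
        for e in entries:
            if e.category not in CATEGORIES:
                raise ValueError(f"unknown category in inventory: {e.category!r}")
            if e.match_kind not in ("name", "provider_type", "both"):
                raise ValueError(f"bad match_kind: {e.match_kind!r}")
            term = normalize_text(e.term)
            if not term:
                raise ValueError("empty term in inventory")
            kinds = ("name", "provider_type") if e.match_kind == "both" else (e.match_kind,)
            for k in kinds:
                if term in seen[k]:
                    raise ValueError(f"duplicate {k} term: {term!r}")
                seen[k].add(term)
            self.entries.append(TermEntry(term, e.category, e.match_kind, int(e.priority)))
        if not self.entries:
            raise ValueError("inventory is empty")

        name_entries = [e for e in self.entries if e.match_kind in ("name", "both")]
        # precedence: priority asc, longer term first, then lexicographic
        name_entries.sort(key=lambda e: (e.priority, -len(e.term), e.term))
        self._name_entries = name_entries
        self._name_regexes = [
            re.compile(r"(?<!\w)" + re.escape(e.term) + r"(?!\w)") for e in name_entries
        ]
        self._provider_map = {
            e.term: e for e in self.entries if e.match_kind in ("provider_type", "both")
        }

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def name_terms(self) -> list[str]:
        return [e.term for e in self._name_entries]

    @property
    def provider_terms(self) -> list[str]:
        return sorted(self._provider_map)

    def all_terms(self) -> list[str]:
        """Deduplicated union of name and provider-type terms (query list)."""
        out: list[str] = []
        for t in self.name_terms + self.provider_terms:
            if t not in out:
                out.append(t)
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TermInventory":
        required = {"term", "category", "match_kind", "priority"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"inventory missing columns: {sorted(missing)}")
        return cls(
            TermEntry(r.term, r.category, r.match_kind, int(r.priority))
            for r in df.itertuples(index=False)
        )

    @classmethod
    def from_csv(cls, path) -> "TermInventory":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def default(cls) -> "TermInventory":
        """The shipped Spanish-language inventory (~60 terms, replaceable)."""
        with resources.files("foodenv.data").joinpath("term_inventory.csv").open("rb") as fh:
            return cls.from_frame(pd.read_csv(fh))


def classify(
    name: str,
    primary_type: str | None,
    secondary_types: Sequence[str] | None,
    inventory: TermInventory,
) -> tuple[str, str, str]:
    """Classify one establishment.

    Returns ``(category, match_stage, matched_term)`` where match_stage is
    ``"name"``, ``"provider_type"`` or ``"none"``.  An empty name with no
    informative labels yields ``unclassified`` (not an error).
    """
    norm_name = normalize_text(name)
    if norm_name:
        for entry, rx in zip(inventory._name_entries, inventory._name_regexes):
            if rx.search(norm_name):
                return entry.category, "name", entry.term
    labels = [primary_type] if primary_type else []
    if secondary_types:
        labels.extend(t for t in secondary_types if t)
    for label in labels:
        entry = inventory._provider_map.get(normalize_text(label))
        if entry is not None:
            return entry.category, "provider_type", entry.term
    return UNCLASSIFIED, "none", ""


def _split_secondary(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    if isinstance(value, (list, tuple)):
        return list(value)
    return [t for t in str(value).split(";") if t]


def classify_frame(
    establishments: pd.DataFrame,
    inventory: TermInventory | None = None,
) -> pd.DataFrame:
    """Classify every row of an establishment table.

    Expects columns ``name``, ``primary_type`` and optionally
    ``secondary_types`` (semicolon-joined).  Returns a copy with
    ``category``, ``match_stage`` and ``matched_term`` columns appended.
    Row order never influences any single row's category.
    """
    inventory = inventory or TermInventory.default()
    df = establishments.copy()
    sec = df["secondary_types"] if "secondary_types" in df.columns else None
    cats, stages, terms = [], [], []
    for i, (nm, pt) in enumerate(zip(df["name"], df.get("primary_type", [None] * len(df)))):
        sec_i = _split_secondary(sec.iloc[i]) if sec is not None else []
        c, s, t = classify(nm, None if pd.isna(pt) else pt, sec_i, inventory)
        cats.append(c)
        stages.append(s)
        terms.append(t)
    df["category"] = cats
    df["match_stage"] = stages
    df["matched_term"] = terms
    return df


def classification_summary(categories: pd.Series | Sequence[str]) -> pd.DataFrame:
    """Counts and proportions per category and health group.

    Proportions are computed over *classified* establishments only; the
    unclassified residue is reported as a separate row with no proportion.
    Category counts plus unclassified always sum to the input size.
    """
    s = pd.Series(list(categories), dtype="object")
    if s.empty:
        logger.warning("classification_summary: empty input")
        return pd.DataFrame(columns=["label", "kind", "count", "proportion_pct"])
    n_total = len(s)
    n_unclassified = int((s == UNCLASSIFIED).sum())
    n_classified = n_total - n_unclassified
    rows = []
    for cat in CATEGORIES:
        cnt = int((s == cat).sum())
        prop = 100.0 * cnt / n_classified if n_classified else float("nan")
        rows.append({"label": cat, "kind": "category", "count": cnt,
                     "proportion_pct": prop})
    for grp in GROUP_ORDER:
        cnt = int(s.isin([c for c, g in HEALTH_GROUPS.items() if g == grp]).sum())
        prop = 100.0 * cnt / n_classified if n_classified else float("nan")
        rows.append({"label": grp, "kind": "health_group", "count": cnt,
                     "proportion_pct": prop})
    rows.append({"label": UNCLASSIFIED, "kind": "residue", "count": n_unclassified,
                 "proportion_pct": float("nan")})
    rows.append({"label": "classified", "kind": "total", "count": n_classified,
                 "proportion_pct": 100.0 * n_classified / n_total})
    rows.append({"label": "total", "kind": "total", "count": n_total,
                 "proportion_pct": float("nan")})
    if n_classified == 0:
        logger.warning("classification_summary: no classifiable establishments; "
                       "category proportions undefined")
    return pd.DataFrame(rows)


def review_queue(classified: pd.DataFrame, inventory: TermInventory | None = None) -> pd.DataFrame:
    """Unclassified records with their nearest-miss inventory terms.

    Surrogate for a manual review pass: each residual record is emitted with
    the inventory terms closest (difflib ratio) to its name tokens so a
    curator can extend the inventory.
    """
    inventory = inventory or TermInventory.default()
    residue = classified[classified["category"] == UNCLASSIFIED].copy()
    terms = inventory.name_terms
    near = []
    for nm in residue["name"]:
        tokens = normalize_text(nm).split()
        hits: list[str] = []
        for tok in tokens:
            hits.extend(get_close_matches(tok, terms, n=1, cutoff=0.75))
        near.append(";".join(dict.fromkeys(hits)))
    residue["nearest_terms"] = near
    return residue
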
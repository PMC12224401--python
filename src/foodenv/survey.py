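"""Individual survey processing: exclusions, dietary outcome, bivariate tables.

The dietary outcome follows the surveillance-survey convention: weekly fruit
days and vegetable days (each 0–7) are summed and capped at 7; respondents
with a capped total below 7 are "non-daily" fruit/vegetable consumers, a
proxy for lower dietary quality.  Note the capping semantics: someone eating
fruit 4 days and vegetables 3 days counts as a daily consumer even if the
days never coincide — the rule is applied verbatim, not reinterpreted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_FIELDS = ("age", "gender", "education", "fruit_days", "veg_days")

#: 4-level education order and the binary recode (completed secondary or
#: above vs not) used in models.
EDUCATION_LEVELS = ("<primary", "primary", "secondary", "university")
LOW_EDUCATION = ("<primary", "primary")


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop records missing any required variable; log counts per field.

    Retained records are returned unaltered (pure row selection).  The log
    reports, per field, how many records had that field missing (a record
    missing several fields appears under each), plus totals.
    """
    miss = pd.DataFrame(index=records.index)
    for f in REQUIRED_FIELDS:
        if f in records.columns:
            col = records[f]
            m = col.isna()
            if col.dtype == object:
                m |= col.astype(str).str.strip().eq("")
            miss[f] = m
        else:
            miss[f] = True
    any_missing = miss.any(axis=1)
    analytic = records.loc[~any_missing]
    log = {f: int(miss[f].sum()) for f in REQUIRED_FIELDS}
    log["n_input"] = len(records)
    log["n_excluded"] = int(any_missing.sum())
    log["n_analytic"] = len(analytic)
    if len(analytic) == 0 and len(records) > 0:
        logger.warning("apply_exclusions: ALL %d records excluded", len(records))
    return analytic, log


def derive_outcome(fruit_days, veg_days) -> tuple[int, bool]:
    """Weekly FV days (summed, capped at 7) and the non-daily flag.

    ``non_daily`` is True when the capped total is below 7.  Inputs outside
    0..7 raise.
    """
    f, v = float(fruit_days), float(veg_days)
    if not (0 <= f <= 7 and float(f).is_integer()):
        raise ValueError(f"fruit_days out of range 0..7: {fruit_days!r}")
    if not (0 <= v <= 7 and float(v).is_integer()):
        raise ValueError(f"veg_days out of range 0..7: {veg_days!r}")
    fv = min(int(f) + int(v), 7)
    return fv, fv < 7


def derive_outcome_frame(participants: pd.DataFrame) -> pd.DataFrame:
    """Vectorized outcome derivation; adds ``fv_days`` and ``non_daily``."""
    f = participants["fruit_days"].to_numpy(float)
    v = participants["veg_days"].to_numpy(float)
    ok = (
        np.isfinite(f) & np.isfinite(v)
        & (f >= 0) & (f <= 7) & (v >= 0) & (v <= 7)
        & (f == np.floor(f)) & (v == np.floor(v))
    )
    if not ok.all():
        bad = participants.index[~ok][:5].tolist()
        raise ValueError(f"fruit/veg days out of range 0..7 at rows {bad}")
    df = participants.copy()
    df["fv_days"] = np.minimum(f + v, 7).astype(int)
    df["non_daily"] = (df["fv_days"] < 7).astype(int)
    return df


def _fmt_median_iqr(x: pd.Series) -> str:
    if len(x) == 0:
        return "—"
    return f"{x.median():.1f} ({x.quantile(0.25):.1f}–{x.quantile(0.75):.1f})"


def bivariate_table(
    participants: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
    continuous_extra: list[str] | None = None,
) -> pd.DataFrame:
    """Daily vs non-daily comparison table.

    Categorical rows (gender, 4-level education) are compared with an
    uncorrected chi-square test; continuous rows (age and, when ``metrics``
    is joined by neighbourhood id, population density, SEI and every density
    column) with the Mann–Whitney U test (asymptotic, tie-corrected).
    Medians with IQRs are reported for continuous variables, counts with
    column percentages for categorical ones.  Degenerate strata (an empty
    group) are reported with the statistic flagged as not testable.
    """
    if participants.empty:
        raise ValueError("analytic set is empty")
    df = participants.copy()
    if "non_daily" not in df.columns:
        df = derive_outcome_frame(df)
    if metrics is not None:
        mcols = ["id"] + [
            c for c in metrics.columns
            if c == "popdens" or c == "sei" or c.startswith("density_")
        ]
        df = df.merge(
            metrics[mcols], left_on="neighbourhood_id", right_on="id",
            how="left", suffixes=("", "_nb"),
        )
    daily = df[df["non_daily"] == 0]
    nondaily = df[df["non_daily"] == 1]

    rows: list[dict] = []

    def add_categorical(var: str, levels) -> None:
        present = [lv for lv in levels if (df[var] == lv).any()]
        tab = np.array([
            [(daily[var] == lv).sum(), (nondaily[var] == lv).sum()]
            for lv in present
        ])
        p = np.nan
        test = "chi-square"
        if tab.shape[0] >= 2 and (tab.sum(axis=0) > 0).all():
            p = stats.chi2_contingency(tab, correction=False)[1]
        else:
            test = "chi-square (not testable)"
        for i, lv in enumerate(present):
            n_d, n_nd = int(tab[i, 0]), int(tab[i, 1])
            n_tot = n_d + n_nd
            rows.append({
                "variable": var, "level": str(lv),
                "total": f"{n_tot} ({100 * n_tot / len(df):.1f})",
                "daily": f"{n_d} ({100 * n_d / max(len(daily), 1):.1f})",
                "non_daily": f"{n_nd} ({100 * n_nd / max(len(nondaily), 1):.1f})",
                "p_value": p if i == 0 else np.nan,
                "test": test if i == 0 else "",
            })

    def add_continuous(var: str) -> None:
        x, y = daily[var].dropna(), nondaily[var].dropna()
        p = np.nan
        test = "mann-whitney"
        if len(x) >= 1 and len(y) >= 1 and not (x.nunique() == 1 and y.nunique() == 1
                                                and x.iloc[0] == y.iloc[0]):
            try:
                p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic")[1]
            except ValueError:
                test = "mann-whitney (degenerate)"
        else:
            test = "mann-whitney (degenerate)"
        rows.append({
            "variable": var, "level": "median (IQR)",
            "total": _fmt_median_iqr(df[var].dropna()),
            "daily": _fmt_median_iqr(x),
            "non_daily": _fmt_median_iqr(y),
            "p_value": p, "test": test,
        })

    rows.append({
        "variable": "n", "level": "",
        "total": str(len(df)),
        "daily": f"{len(daily)} ({100 * len(daily) / len(df):.1f})",
        "non_daily": f"{len(nondaily)} ({100 * len(nondaily) / len(df):.1f})",
        "p_value": np.nan, "test": "",
    })
    add_categorical("gender", ["female", "male"])
    add_continuous("age")
    add_categorical("education", list(EDUCATION_LEVELS))
    for extra in (continuous_extra or []):
        add_continuous(extra)
    if metrics is not None:
        for c in ["popdens", "sei"] + [c for c in df.columns if c.startswith("density_")]:
            if c in df.columns:
                add_continuous(c)
    return pd.DataFrame(rows)


def prevalence_pct(participants: pd.DataFrame) -> float:
    """Non-daily prevalence in percent over the analytic set."""
    df = participants if "non_daily" in participants.columns else derive_outcome_frame(participants)
    return 100.0 * df["non_daily"].mean()
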
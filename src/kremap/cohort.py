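"""Analytic cohort construction: exclusions, staging, category collapsing.

Registry records arrive with separate pathologic and clinical AJCC stage
fields.  Stage is resolved hierarchically — pathology first, clinical when
pathology is absent — and dichotomized into a late-stage indicator
(stage III/IV vs 0/I/II).  Records whose resolved stage is unknown stay in
the cohort for incidence analyses but enter neither the late-stage
numerator nor denominator.
"""

from __future__ import annotations

import logging
from typing import Mapping, Union

import pandas as pd

__all__ = [
    "STAGE_LEVELS",
    "apply_exclusions",
    "resolve_stage",
    "late_stage_indicator",
    "add_derived_columns",
    "collapse_categories",
    "summarize_cohort",
    "render_summary",
    "late_stage_from_stage_counts",
]

logger = logging.getLogger(__name__)

STAGE_LEVELS = ("0", "I", "II", "III", "IV", "unknown", "missing")
_ABSENT = {"unknown", "missing"}
_LATE = {"III", "IV"}
_EARLY = {"0", "I", "II"}

#: Default raw -> collapsed category mappings.  Raw values already at the
#: collapsed level map to themselves; anything unmapped falls back to the
#: variable's Unknown level.
DEFAULT_MAPPINGS: dict[str, dict[str, str]] = {
    "payer": {
        "Private": "Private",
        "Private insurance": "Private",
        "Medicaid": "Medicaid",
        "Medicare": "Medicare",
        "Uninsured": "Uninsured/Self-Pay",
        "Self-Pay": "Uninsured/Self-Pay",
        "Uninsured/Self-Pay": "Uninsured/Self-Pay",
        "Other": "Other",
        "Other insurance": "Other",
        "Unknown": "Unknown",
    },
    "race_eth": {
        "NH-White": "NH-White",
        "Non-Hispanic White": "NH-White",
        "NH-Black": "NH-Black",
        "Non-Hispanic Black": "NH-Black",
        "NH-Other/Unknown": "NH-Other/Unknown",
        "Hispanic": "Hispanic",
        "Hispanic (any race)": "Hispanic",
    },
    "ruca": {
        "Metropolitan": "Metropolitan",
        "Micropolitan": "Micropolitan",
        "Small Town": "Small Town",
        "Rural": "Rural",
    },
}

_UNKNOWN_LEVEL = {"payer": "Unknown", "race_eth": "NH-Other/Unknown", "ruca": "Unknown"}


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop records with no residential location at the block-group level.

    Returns the included table and the number excluded.
    """
    if len(records) == 0:
        return records.copy(), 0
    bg = records["block_group_id"]
    keep = bg.notna() & (bg.astype(str).str.strip() != "")
    included = records.loc[keep].copy()
    return included, int((~keep).sum())


def resolve_stage(
    path_stage: Union[str, pd.Series], clin_stage: Union[str, pd.Series]
) -> Union[str, pd.Series]:
    """Hierarchical stage: pathology first, clinical if pathology absent.

    When both are absent the resolved stage is ``unknown``.
    """
    if isinstance(path_stage, str) and isinstance(clin_stage, str):
        if path_stage not in _ABSENT:
            return path_stage
        if clin_stage not in _ABSENT:
            return clin_stage
        return "unknown"
    path_stage = pd.Series(path_stage)
    clin_stage = pd.Series(clin_stage)
    out = path_stage.where(~path_stage.isin(_ABSENT), clin_stage)
    return out.where(~out.isin(_ABSENT), "unknown")


def late_stage_indicator(resolved_stage: Union[str, pd.Series]):
    """1 for stage III/IV, 0 for stage 0/I/II, NA for unknown."""
    if isinstance(resolved_stage, str):
        if resolved_stage in _LATE:
            return 1
        if resolved_stage in _EARLY:
            return 0
        return pd.NA
    s = pd.Series(resolved_stage)
    out = pd.Series(pd.NA, index=s.index, dtype="Int64")
    out[s.isin(_LATE)] = 1
    out[s.isin(_EARLY)] = 0
    return out


def add_derived_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Attach ``resolved_stage`` and ``late_stage`` columns."""
    out = table.copy()
    out["resolved_stage"] = resolve_stage(out["path_stage"], out["clin_stage"])
    out["late_stage"] = late_stage_indicator(out["resolved_stage"])
    return out


def collapse_categories(
    table: pd.DataFrame, mappings: Mapping[str, Mapping[str, str]] = DEFAULT_MAPPINGS
) -> pd.DataFrame:
    """Collapse raw demographic categories to the reporting levels.

    Payer collapses to six levels, race/ethnicity to four, RUCA to four;
    the comorbidity count becomes {0, 1, 2+, Unknown}.  Unmapped raw
    values land in the variable's Unknown level.
    """
    out = table.copy()
    for col, mapping in mappings.items():
        if col in out.columns:
            out[col] = (
                out[col].astype(str).map(mapping).fillna(_UNKNOWN_LEVEL.get(col, "Unknown"))
            )
    if "comorbidity_count" in out.columns:
        cc = pd.to_numeric(out["comorbidity_count"], errors="coerce")
        cat = pd.Series("Unknown", index=out.index, dtype=object)
        cat[cc == 0] = "0"
        cat[cc == 1] = "1"
        cat[cc >= 2] = "2+"
        out["comorbidity_cat"] = cat
    return out


_SUMMARY_VARS = ["sex", "race_eth", "comorbidity_cat", "payer", "ruca", "resolved_stage"]


def summarize_cohort(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-site characteristic table: n, counts and percentages per level.

    Percentages are of the site n, to one decimal.  Sites with zero
    records are omitted with a logged notice.
    """
    if "late_stage" not in table.columns:
        table = add_derived_columns(table)
    if "comorbidity_cat" not in table.columns:
        table = collapse_categories(table)
    summaries: dict[str, pd.DataFrame] = {}
    for site in ("breast", "colorectal", "lung"):
        sub = table[table["site"] == site]
        n = len(sub)
        if n == 0:
            logger.info("site %s has no records; omitted from summary", site)
            continue
        rows = [("n", "", n, 100.0)]
        if "age" in sub.columns:
            age = pd.to_numeric(sub["age"], errors="coerce")
            if age.notna().any():
                rows.append(("age_mean", "", round(float(age.mean()), 1),
                             round(float(age.std()), 1)))
        for var in _SUMMARY_VARS:
            if var not in sub.columns:
                continue
            counts = sub[var].value_counts(dropna=False)
            for level, count in counts.items():
                rows.append((var, str(level), int(count), round(100.0 * count / n, 1)))
        late = sub["late_stage"]
        for label, mask in (("Yes", late == 1), ("No", late == 0)):
            count = int(mask.sum())
            rows.append(("late_stage", label, count, round(100.0 * count / n, 1)))
        n_missing = int(late.isna().sum())
        if n_missing:
            rows.append(("late_stage", "Unknown", n_missing, round(100.0 * n_missing / n, 1)))
        summaries[site] = pd.DataFrame(rows, columns=["variable", "level", "count", "pct"])
    return summaries


def render_summary(summaries: dict[str, pd.DataFrame]) -> str:
    """Plain-text rendering of :func:`summarize_cohort` output."""
    parts = []
    for site, df in summaries.items():
        parts.append(f"== {site} ==")
        for _, row in df.iterrows():
            label = f"{row.variable} {row.level}".strip()
            parts.append(f"  {label:<32s} {row['count']:>10} ({row.pct})")
    return "\n".join(parts)


def late_stage_from_stage_counts(stage_counts: Mapping[str, int]) -> dict[str, float]:
    """Late-stage arithmetic on an aggregated stage-at-diagnosis table.

    Applies the stage-III/IV rule to printed per-stage counts — the form
    in which published cohort tables report staging — and returns the
    late/early counts and the late-stage percentage (of all staged plus
    unstaged records, one decimal).
    """
    n_late = n_early = n_unknown = 0
    for stage, count in stage_counts.items():
        ind = late_stage_indicator(str(stage))
        if ind is pd.NA:
            n_unknown += count
        elif ind == 1:
            n_late += count
        else:
            n_early += count
    n = n_late + n_early + n_unknown
    return {
        "n": n,
        "n_late": n_late,
        "n_early": n_early,
        "n_unknown": n_unknown,
        "pct_late": round(100.0 * n_late / n, 1) if n else float("nan"),
    }
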
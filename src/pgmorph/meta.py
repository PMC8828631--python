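"""Log response-ratio meta-analysis of stress effects on PG attributes.

A *case* is one article × species × stress-type × treatment-level group of
chloroplasts.  Within each article × stress group one level is the control:
an author-designated control wins; otherwise the lowest treatment intensity
is taken as the non-stress reference.  The effect size of an attribute for
a case is the log response ratio

    ES = ln(X̄_stress / X̄_control),

with means taken across all chloroplast cross-sections in each arm.  Per
stress type the cases are summarised by the unweighted mean ES, its
standard error, and the fraction of cases whose ES is negative.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .attributes import SEVEN_ATTRIBUTES

logger = logging.getLogger(__name__)

#: Columns expected in a case-metadata table.
CASE_COLUMNS = ("case_id", "article_id", "species", "stress_type", "level",
                "is_control")

POOLED_LABEL = "all stress"


# ---------------------------------------------------------------------------
# control designation
# ---------------------------------------------------------------------------

def assign_control(cases: pd.DataFrame) -> pd.DataFrame:
    """Designate the control case within each article × stress group.

    An author-flagged ``is_control`` takes precedence; otherwise the lowest
    ``level`` (coerced to numeric when possible) becomes the control.
    Groups with a single level and no flag are dropped with a logged
    warning; equal lowest levels without a flag are an error.
    """
    missing = [c for c in ("case_id", "article_id", "stress_type", "level")
               if c not in cases.columns]
    if missing:
        raise ValueError(f"case table missing columns: {missing}")
    out = cases.copy()
    if "is_control" not in out.columns:
        out["is_control"] = False
    out["is_control"] = (out["is_control"].astype("boolean")
                         .fillna(False).astype(bool))

    keep_idx: list = []
    for (article, stress), group in out.groupby(["article_id", "stress_type"],
                                                sort=False):
        if group["is_control"].sum() > 1:
            raise ValueError(
                f"multiple controls flagged in {article}/{stress}")
        if group["is_control"].any():
            keep_idx.extend(group.index)
            continue
        if len(group) < 2:
            logger.warning(
                "dropping %s/%s: single level and no designated control",
                article, stress)
            continue
        levels = pd.to_numeric(group["level"], errors="coerce")
        if levels.isna().any():
            raise ValueError(
                f"non-numeric levels without a control flag in "
                f"{article}/{stress}: {group['level'].tolist()}")
        lowest = levels.min()
        at_lowest = group.index[levels == lowest]
        if len(at_lowest) > 1:
            raise ValueError(
                f"ambiguous equal-lowest levels in {article}/{stress}: "
                f"cases {group.loc[at_lowest, 'case_id'].tolist()}")
        out.loc[at_lowest[0], "is_control"] = True
        keep_idx.extend(group.index)
    return out.loc[keep_idx].reset_index(drop=True)


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def effect_size(mean_stress: float, mean_control: float) -> float:
    """ln(mean_stress / mean_control); NaN (with a logged reason) when a
    mean is non-positive or non-finite — zero-PG arms occur legitimately."""
    if not (np.isfinite(mean_stress) and np.isfinite(mean_control)):
        logger.info("ES undefined: non-finite mean")
        return math.nan
    if mean_stress <= 0 or mean_control <= 0:
        logger.info("ES undefined: non-positive mean (stress=%g, control=%g)",
                    mean_stress, mean_control)
        return math.nan
    return math.log(mean_stress / mean_control)


def case_effect_sizes(attributes: pd.DataFrame, cases: pd.DataFrame, *,
                      attribute_names: tuple[str, ...] = SEVEN_ATTRIBUTES,
                      ) -> pd.DataFrame:
    """One ES per stress case × attribute.

    ``attributes`` holds one row per chloroplast with a ``case_id`` column;
    ``cases`` is the metadata table with controls already designated (see
    :func:`assign_control`).  Arm means are taken over non-null chloroplast
    values.  An attribute entirely null in either arm yields a null ES.
    """
    if "case_id" not in attributes.columns:
        raise ValueError("attribute table needs a case_id column")
    if not cases["is_control"].any():
        raise ValueError("no control designated; run assign_control first")

    records = []
    for (article, stress), group in cases.groupby(
            ["article_id", "stress_type"], sort=False):
        controls = group[group["is_control"]]
        if len(controls) != 1:
            raise ValueError(
                f"expected exactly one control in {article}/{stress}")
        control = controls.iloc[0]
        ctrl_values = attributes[attributes["case_id"] == control["case_id"]]
        for _, case in group[~group["is_control"]].iterrows():
            stress_values = attributes[
                attributes["case_id"] == case["case_id"]]
            for attr in attribute_names:
                xs = stress_values[attr].dropna()
                xc = ctrl_values[attr].dropna()
                mean_s = float(xs.mean()) if len(xs) else math.nan
                mean_c = float(xc.mean()) if len(xc) else math.nan
                records.append({
                    "case_id": case["case_id"],
                    "article_id": article,
                    "stress_type": stress,
                    "attribute": attr,
                    "es": effect_size(mean_s, mean_c),
                    "mean_stress": mean_s, "mean_control": mean_c,
                    "n_stress": int(len(xs)), "n_control": int(len(xc)),
                })
    return pd.DataFrame(records, columns=[
        "case_id", "article_id", "stress_type", "attribute", "es",
        "mean_stress", "mean_control", "n_stress", "n_control"])


# ---------------------------------------------------------------------------
# per-stress summaries
# ---------------------------------------------------------------------------

def _summarise(group: pd.DataFrame, stress: str) -> dict:
    es = group["es"]
    valid = es[np.isfinite(es)]
    n = len(valid)
    mean = float(valid.mean()) if n else math.nan
    se = float(valid.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return {
        "stress_type": stress,
        "attribute": group["attribute"].iloc[0],
        "mean_es": mean, "se": se, "n_cases": n,
        "fraction_negative": float((valid < 0).mean()) if n else math.nan,
        "n_null_es": int(len(es) - n),
    }


def stress_summary(records: pd.DataFrame, *,
                   min_studies: int = 10) -> pd.DataFrame:
    """Mean ± SE effect size and direction split per stress type × attribute.

    Stress types reported in strictly more than ``min_studies`` cases get
    their own rows; every case also contributes to a pooled row labelled
    ``"all stress"``.  Null ES values are excluded from the statistics and
    counted in ``n_null_es``; ``fraction_negative`` is the share of valid
    ES below zero.  A single-case group gets SE 0 by convention.
    """
    rows = []
    for attr, by_attr in records.groupby("attribute", sort=False):
        rows.append(_summarise(by_attr, POOLED_LABEL))
        for stress, group in by_attr.groupby("stress_type", sort=True):
            if group["case_id"].nunique() > min_studies:
                rows.append(_summarise(group, stress))
    return pd.DataFrame(rows, columns=[
        "stress_type", "attribute", "mean_es", "se", "n_cases",
        "fraction_negative", "n_null_es"])


# ---------------------------------------------------------------------------
# supplementary-style workbook I/O
# ---------------------------------------------------------------------------

def read_supplementary_workbook(
        path: str | Path, *,
        data_sheet: str | int = 0,
        cases_sheet: str | int = 1,
        column_map: dict[str, str] | None = None,
        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a two-sheet XLSX workbook of per-chloroplast data + case metadata.

    The first sheet holds one row per chloroplast (a ``case_id`` column plus
    attribute columns); the second the case metadata.  ``column_map`` renames
    workbook columns to the canonical names (e.g. ``{"Number of PGs":
    "npg"}``) and is applied to both sheets.
    """
    data = pd.read_excel(path, sheet_name=data_sheet)
    cases = pd.read_excel(path, sheet_name=cases_sheet)
    if column_map:
        data = data.rename(columns=column_map)
        cases = cases.rename(columns=column_map)
    if "case_id" not in data.columns or "case_id" not in cases.columns:
        raise ValueError("both sheets need a case_id column "
                         "(use column_map to rename)")
    return data, cases


def write_supplementary_workbook(data: pd.DataFrame, cases: pd.DataFrame,
                                 path: str | Path) -> Path:
    """Write the two-sheet workbook layout read back by
    :func:`read_supplementary_workbook`."""
    path = Path(path)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        data.to_excel(writer, sheet_name="chloroplasts", index=False)
        cases.to_excel(writer, sheet_name="cases", index=False)
    return path
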
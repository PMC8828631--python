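"""Derived per-chloroplast PG attributes.

Seven attributes summarise plastoglobule morphology in a chloroplast
cross-section:

* ``npg`` — number of PGs;
* ``pct_pg`` — percentage of the starch-corrected chloroplast area
  (CA − starch) occupied by PGs; scale-free, so computable without a
  physical pixel size;
* ``diam_nm`` — mean circular-equivalent PG diameter (ØPG), nm;
* ``ned`` — normalised electrodensity,
  (reference grey − PG grey) / reference grey × 100, with the vacuole as
  the bright reference; also scale-free;
* ``pct_core`` / ``pct_coat`` — percentages of (CA − starch) occupied by
  the PG cores and coats under a shell model in which each PG cross-section
  is a central neutral-lipid disk surrounded by an annular amphipathic
  lipid/protein coat of fixed thickness (3 nm by default);
* ``core_coat_ratio`` — %Core / %Coat, computed from summed areas.

The core/coat partition is exact: for a PG of diameter Ø and coat
thickness t, core = π·max(Ø/2 − t, 0)² and coat = π·(Ø/2)² − core, so the
two parts always sum to the PG disk area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphometry import NM2_PER_UM2, ChloroplastRecord

#: Canonical order of the seven PG attributes.
SEVEN_ATTRIBUTES = ("npg", "pct_pg", "diam_nm", "ned",
                    "pct_core", "pct_coat", "core_coat_ratio")


@dataclass(frozen=True)
class CoatModel:
    """Fixed-thickness coat model; default 3 nm."""

    coat_thickness: float = 3.0

    def __post_init__(self) -> None:
        if self.coat_thickness <= 0:
            raise ValueError("coat_thickness must be positive")


def diameter_from_area(area: float, *, units: str = "nm2") -> float:
    """Circular-equivalent diameter in nm of a PG cross-section area.

    ``units`` is ``"nm2"`` or ``"um2"``.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    if units == "um2":
        area = area * NM2_PER_UM2
    elif units != "nm2":
        raise ValueError("units must be 'nm2' or 'um2'")
    return 2.0 * math.sqrt(area / math.pi)


def percent_pg(pg_total_area: float, ca: float, starch_area: float) -> float:
    """%PG = 100 · PG total area / (CA − starch area).

    All three areas must share one unit; the unit cancels, so pixel areas
    are as valid as nm² (scale-free mode).
    """
    if starch_area < 0:
        raise ValueError("starch area must be non-negative")
    if ca <= starch_area:
        raise ValueError("starch exceeds chloroplast")
    return 100.0 * pg_total_area / (ca - starch_area)


def normalized_electrodensity(reference_grey: float, pg_grey: float) -> float:
    """nED = (reference grey − PG grey) / reference grey × 100.

    Positive for PGs darker (more osmiophilic) than the reference; may be
    negative if a PG is brighter than the vacuole.
    """
    if reference_grey == 0:
        raise ValueError("reference grey must be non-zero")
    return 100.0 * (reference_grey - pg_grey) / reference_grey


def core_coat_partition(diameter: float,
                        model: CoatModel = CoatModel(),
                        ) -> tuple[float, float]:
    """Split a PG cross-section into core and coat areas (nm²).

    The core radius is clamped at zero for diameters below twice the coat
    thickness, so tiny disks are all coat; core + coat equals the disk area
    exactly in every case.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    r = diameter / 2.0
    r_core = max(r - model.coat_thickness, 0.0)
    core = math.pi * r_core ** 2
    coat = math.pi * r ** 2 - core
    return core, coat


def percent_core_coat(record: ChloroplastRecord,
                      model: CoatModel = CoatModel(),
                      ) -> tuple[float | None, float | None, float | None]:
    """(%Core, %Coat, ratio) for one chloroplast.

    Core and coat areas are summed over all PGs and normalised by
    (CA − starch), like %PG.  The ratio is %Core/%Coat of the summed areas
    (not a mean of per-PG ratios).  Returns nulls in scale-free mode; a
    chloroplast with no PGs gets (0, 0, null).
    """
    if not record.scale.known:
        return None, None, None
    assert record.pg_areas_um2 is not None and record.ca_um2 is not None
    if record.npg == 0:
        return 0.0, 0.0, None
    core_sum = coat_sum = 0.0
    for area_um2 in record.pg_areas_um2:
        d = diameter_from_area(area_um2, units="um2")
        core, coat = core_coat_partition(d, model)
        core_sum += core
        coat_sum += coat
    denom = (record.ca_um2 - record.starch_area_um2) * NM2_PER_UM2
    pct_core = 100.0 * core_sum / denom
    pct_coat = 100.0 * coat_sum / denom
    ratio = core_sum / coat_sum if coat_sum > 0 else None
    return pct_core, pct_coat, ratio


def attribute_set(record: ChloroplastRecord,
                  model: CoatModel = CoatModel()) -> dict[str, float | None]:
    """The seven attributes for one chloroplast as a plain dict."""
    pg_px_total = sum(record.pg_px)
    pct = percent_pg(pg_px_total, record.ca_px, record.starch_px)

    if record.vacuole_grey is not None and record.npg > 0:
        # area-weighted mean grey over all PG pixels of the chloroplast
        mean_pg_grey = (sum(a * g for a, g in
                            zip(record.pg_px, record.pg_greys))
                        / pg_px_total)
        ned = normalized_electrodensity(record.vacuole_grey, mean_pg_grey)
    else:
        ned = None

    if record.scale.known and record.npg > 0:
        assert record.pg_areas_um2 is not None
        diam = float(np.mean([diameter_from_area(a, units="um2")
                              for a in record.pg_areas_um2]))
    else:
        diam = None
    pct_core, pct_coat, ratio = percent_core_coat(record, model)
    return {
        "npg": record.npg, "pct_pg": pct, "diam_nm": diam, "ned": ned,
        "pct_core": pct_core, "pct_coat": pct_coat, "core_coat_ratio": ratio,
    }


def attribute_table(records: list[ChloroplastRecord],
                    model: CoatModel = CoatModel()) -> pd.DataFrame:
    """One row of the seven attributes per chloroplast.

    Scale-free records carry only ``npg``, ``pct_pg`` and ``ned``; the
    diameter and core/coat columns are NaN for them.
    """
    rows = []
    for rec in records:
        row = {"image_id": rec.image_id,
               "chloroplast_id": rec.chloroplast_id,
               "case_id": rec.case_id,
               "n_clusters": rec.n_clusters,
               "scale_known": rec.scale.known}
        row.update(attribute_set(rec, model))
        rows.append(row)
    df = pd.DataFrame(rows, columns=[
        "image_id", "chloroplast_id", "case_id", "n_clusters", "scale_known",
        *SEVEN_ATTRIBUTES])
    return df.astype({a: float for a in SEVEN_ATTRIBUTES})


def pg_diameter_table(records: list[ChloroplastRecord]) -> pd.DataFrame:
    """Long-format per-PG diameters (nm), for distribution summaries."""
    rows = [
        {"image_id": rec.image_id, "chloroplast_id": rec.chloroplast_id,
         "case_id": rec.case_id, "pg_index": k,
         "diam_nm": diameter_from_area(a, units="um2")}
        for rec in records if rec.pg_areas_um2
        for k, a in enumerate(rec.pg_areas_um2)
    ]
    return pd.DataFrame(rows, columns=["image_id", "chloroplast_id",
                                       "case_id", "pg_index", "diam_nm"])
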
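"""Tukey-fence outlier screening and distribution summaries.

Morphometric PG attributes are strongly right-skewed (a few chloroplasts
carry over a hundred PGs, a few PGs exceed 1000 nm), so quality control
uses Tukey's boxplot rule: a value is atypical when it lies more than
1.5·IQR above the third quartile or below the first.  Values are flagged,
never silently removed — dropping is an explicit opt-in, mirroring the
manual reconsideration step such values get in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class OutlierReport:
    """Fences and flags for one attribute within one group."""

    attribute: str
    group: str | None
    fences: tuple[float, float]
    flagged_ids: list
    n_values: int

    @property
    def flagged_fraction(self) -> float:
        return len(self.flagged_ids) / self.n_values if self.n_values else 0.0


@dataclass
class DistributionSummary:
    """Boxplot-style summary: median, mean, central 95% interval, quartiles."""

    n: int
    median: float
    mean: float
    central_95: tuple[float, float]   # 2.5th and 97.5th percentiles
    q1: float
    q3: float
    whisker_low: float    # smallest value inside the Tukey fences
    whisker_high: float


def _quartiles(values: np.ndarray, method: str) -> tuple[float, float]:
    if method == "linear":
        q1, q3 = np.percentile(values, [25, 75])
    elif method == "hinges":
        # Tukey's hinges: medians of the lower/upper halves, the median
        # itself included in both halves when n is odd
        v = np.sort(values)
        n = len(v)
        half = (n + 1) // 2
        q1 = float(np.median(v[:half]))
        q3 = float(np.median(v[n - half:]))
    else:
        raise ValueError("method must be 'linear' or 'hinges'")
    return float(q1), float(q3)


def tukey_fences(values, *, k: float = 1.5,
                 method: str = "linear") -> tuple[float, float]:
    """(lower, upper) Tukey fences: Q1 − k·IQR and Q3 + k·IQR.

    Quartiles use linear interpolation of order statistics by default;
    ``method='hinges'`` switches to Tukey's original hinges.  Requires at
    least four finite values.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 4:
        raise ValueError("too few for fences")
    q1, q3 = _quartiles(values, method)
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def flag_outliers(table: pd.DataFrame, attributes: list[str], *,
                  group: str | None = None,
                  id_column: str | None = None,
                  method: str = "linear") -> list[OutlierReport]:
    """Tukey-flag each attribute, within each level of ``group`` if given.

    Returns one report per attribute × group.  Nothing is removed; apply
    :func:`drop_flagged` to act on the flags.
    """
    for attr in attributes:
        if attr not in table.columns:
            raise KeyError(f"unknown attribute: {attr}")
    if group is not None and group not in table.columns:
        raise KeyError(f"unknown grouping column: {group}")

    groups = ([(None, table)] if group is None
              else list(table.groupby(group, sort=True)))
    reports = []
    for gname, sub in groups:
        for attr in attributes:
            values = sub[attr].to_numpy(dtype=float)
            finite = np.isfinite(values)
            lo, hi = tukey_fences(values[finite], method=method)
            flagged = finite & ((values < lo) | (values > hi))
            ids = (sub.loc[flagged, id_column].tolist() if id_column
                   else sub.index[flagged].tolist())
            reports.append(OutlierReport(
                attribute=attr,
                group=None if gname is None else str(gname),
                fences=(lo, hi), flagged_ids=ids,
                n_values=int(finite.sum())))
    return reports


def drop_flagged(table: pd.DataFrame,
                 reports: list[OutlierReport]) -> pd.DataFrame:
    """Mask flagged cells (by table index) to NaN; returns a copy."""
    out = table.copy()
    for rep in reports:
        out.loc[out.index.isin(rep.flagged_ids), rep.attribute] = np.nan
    return out


def reports_to_frame(reports: list[OutlierReport]) -> pd.DataFrame:
    return pd.DataFrame([{
        "attribute": r.attribute, "group": r.group,
        "fence_low": r.fences[0], "fence_high": r.fences[1],
        "n_values": r.n_values, "n_flagged": len(r.flagged_ids),
        "flagged_fraction": r.flagged_fraction,
    } for r in reports])


def summarize_distribution(values) -> DistributionSummary:
    """Median, mean, central 95% interval and boxplot statistics."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise ValueError("no finite values")
    p2_5, q1, q3, p97_5 = np.percentile(values, [2.5, 25, 75, 97.5])
    iqr = q3 - q1
    inside = values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]
    return DistributionSummary(
        n=len(values),
        median=float(np.median(values)),
        mean=float(values.mean()),
        central_95=(float(p2_5), float(p97_5)),
        q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()))
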
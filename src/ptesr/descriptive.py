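"""Descriptive hydrochemistry: means, CVs, rankings, exceedance rates.

All statistics are computed on the *working* values (below-detection cells
substituted at MDL/2).  The coefficient of variation uses the sample
(n−1 denominator) standard deviation; exceedance is strict (value > limit),
so a sample sitting exactly at a drinking limit is compliant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ConcentrationTable, substitute_censored

__all__ = ["summarize", "exceedance", "rank"]


def summarize(
    table: ConcentrationTable,
    water_type: str | None = "surface",
) -> pd.DataFrame:
    """Per-analyte summary statistics.

    Returns a DataFrame indexed by analyte with columns ``mean``, ``sd``,
    ``min``, ``max``, ``cv_percent``, ``exceed_count``, ``exceed_percent``.
    ``cv_percent`` is NaN (undefined marker) when the mean is zero;
    exceedance columns are NaN for analytes without a configured limit.

    By default only surface-water samples enter the summary; pass
    ``water_type=None`` to include every sample.
    """
    sub = substitute_censored(table.subset(water_type))
    if sub.n < 2:
        raise ValueError("need at least 2 samples for summary statistics")
    x = sub.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    out = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "min": x.min(axis=0),
            "max": x.max(axis=0),
        }
    )
    out["cv_percent"] = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    counts, pcts = [], []
    for spec in sub.analytes:
        if spec.drinking_limit is None:
            counts.append(np.nan)
            pcts.append(np.nan)
        else:
            c, p = exceedance(sub, spec.name, spec.drinking_limit)
            counts.append(c)
            pcts.append(p)
    out["exceed_count"] = counts
    out["exceed_percent"] = pcts
    out.index.name = "analyte"
    return out


def exceedance(
    table: ConcentrationTable, analyte: str, limit: float
) -> tuple[int, float]:
    """Count and percent of samples strictly above ``limit`` for one analyte.

    The percent is exact (100·count/n); round only at display time.
    """
    if limit <= 0:
        raise ValueError("limit must be positive")
    if analyte not in table.values.columns:
        raise KeyError(f"analyte {analyte!r} not in table")
    working = substitute_censored(table)
    col = working.values[analyte].to_numpy()
    count = int((col > limit).sum())
    return count, 100.0 * count / working.n


def rank(summary: pd.DataFrame, key: str = "mean") -> list[str]:
    """Analytes in descending order of ``key`` (``mean`` or ``cv_percent``).

    Ties break lexicographically by analyte name so the ordering is
    deterministic; NaN keys sort last.
    """
    if key not in ("mean", "cv_percent"):
        raise ValueError("key must be 'mean' or 'cv_percent'")
    if summary.empty:
        raise ValueError("summary is empty")
    df = summary.reset_index()
    name_col = df.columns[0]
    df["_nan"] = df[key].isna()
    df = df.sort_values(["_nan", key, name_col], ascending=[True, False, True])
    return df[name_col].tolist()
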
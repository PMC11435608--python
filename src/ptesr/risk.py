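"""Deterministic oral-ingestion health risk assessment (USEPA model).

Chain of quantities, per sample, analyte and population group:

    CDI = (C_w · 10⁻³ · IR · EF · ED) / (BW · AT)      chronic daily intake
    HQ  = CDI / RfD                                     hazard quotient
    HI  = Σ_j HQ_j                                      hazard index
    CR  = CDI · SF                                      cancer risk
    CCR = Σ CR                                          cumulative cancer risk

with C_w the water concentration in μg/L (the 10⁻³ converts to mg/L since
RfD and SF are per mg), IR the ingestion rate (L/day), EF the exposure
frequency (days/year), ED the exposure duration (years), BW body weight
(kg) and AT the averaging time in days: ED·365 for non-carcinogenic
effects, LE·365 (LE = life expectancy, years) for carcinogenic effects.

Risk levels: HI ≤ 1 → level I (acceptable), HI > 1 → level II.  CR bands
are half-open at the lower edge: <10⁻⁶ I, [10⁻⁶, 10⁻⁵) II, [10⁻⁵, 10⁻⁴)
III, [10⁻⁴, 10⁻³) IV, ≥10⁻³ V.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .data import ConcentrationTable, substitute_censored
from .defaults import EXPOSURE_DEFAULTS, RFD_MG_PER_KG_DAY, SF_KG_DAY_PER_MG

__all__ = [
    "ExposureParams",
    "ToxicityTable",
    "RiskAssessment",
    "cdi",
    "hazard_quotient",
    "hazard_index",
    "cancer_risk",
    "cumulative_cancer_risk",
    "classify_hi",
    "classify_cr",
    "assess",
    "hi_sensitivity",
    "default_exposure",
    "default_toxicity",
]

_UG_TO_MG = 1e-3
_DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class ExposureParams:
    """Ingestion exposure parameters for one population group.

    IR: ingestion rate, L/day; EF: exposure frequency, days/year;
    ED: exposure duration, years; BW: body weight, kg;
    LE: life expectancy, years.
    """

    group: str
    IR: float
    EF: float
    ED: float
    BW: float
    LE: float

    def __post_init__(self) -> None:
        for name in ("IR", "EF", "ED", "BW", "LE"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.group}: {name} must be positive")
        if self.EF > 365:
            raise ValueError(f"{self.group}: EF cannot exceed 365 days/year")
        if self.ED > self.LE:
            raise ValueError(f"{self.group}: ED cannot exceed life expectancy")


@dataclass(frozen=True)
class ToxicityTable:
    """Reference doses (mg/(kg·d)) and slope factors (kg·d/mg) per analyte."""

    rfd: dict
    sf: dict

    def __post_init__(self) -> None:
        for name, v in self.rfd.items():
            if v <= 0:
                raise ValueError(f"RfD for {name} must be positive")
        for name, v in self.sf.items():
            if v <= 0:
                raise ValueError(f"SF for {name} must be positive")


def default_exposure() -> dict[str, ExposureParams]:
    return {
        g: ExposureParams(group=g, **vals) for g, vals in EXPOSURE_DEFAULTS.items()
    }


def default_toxicity() -> ToxicityTable:
    return ToxicityTable(rfd=dict(RFD_MG_PER_KG_DAY), sf=dict(SF_KG_DAY_PER_MG))


# ---------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------


def cdi(c_w, params: ExposureParams, horizon: str = "noncarcinogenic"):
    """Chronic daily intake, mg/(kg·d), from a concentration in μg/L.

    ``horizon`` selects the averaging time: ``"noncarcinogenic"`` uses
    AT = ED·365 days (so ED cancels when EF = 365), ``"carcinogenic"``
    uses AT = LE·365 days.
    """
    c_w = np.asarray(c_w, dtype=float)
    if (c_w < 0).any():
        raise ValueError("concentration must be non-negative")
    if horizon == "noncarcinogenic":
        at_days = params.ED * _DAYS_PER_YEAR
    elif horizon == "carcinogenic":
        at_days = params.LE * _DAYS_PER_YEAR
    else:
        raise ValueError("horizon must be 'noncarcinogenic' or 'carcinogenic'")
    if params.BW <= 0 or at_days <= 0:
        raise ValueError("body weight and averaging time must be positive")
    out = (c_w * _UG_TO_MG * params.IR * params.EF * params.ED) / (
        params.BW * at_days
    )
    return float(out) if out.ndim == 0 else out


def hazard_quotient(cdi_value, rfd: float):
    """HQ = CDI / RfD."""
    if rfd <= 0:
        raise ValueError("RfD must be positive")
    return np.asarray(cdi_value, dtype=float) / rfd if np.ndim(cdi_value) else cdi_value / rfd


def hazard_index(hq_values) -> float:
    """HI = Σ HQ.  An empty set sums to 0 with a warning."""
    hq = np.atleast_1d(np.asarray(hq_values, dtype=float))
    if hq.size == 0:
        warnings.warn("hazard index of an empty HQ set is 0", stacklevel=2)
        return 0.0
    return float(hq.sum())


def cancer_risk(cdi_value, sf: float):
    """CR = CDI · SF."""
    if sf <= 0:
        raise ValueError("slope factor must be positive")
    return np.asarray(cdi_value, dtype=float) * sf if np.ndim(cdi_value) else cdi_value * sf


def cumulative_cancer_risk(cr_values) -> float:
    """CCR = Σ CR over carcinogens."""
    cr = np.atleast_1d(np.asarray(cr_values, dtype=float))
    return float(cr.sum()) if cr.size else 0.0


def classify_hi(hi: float) -> str:
    """Two-level non-carcinogenic classification: HI ≤ 1 → I, HI > 1 → II."""
    if hi < 0:
        raise ValueError("HI must be non-negative")
    return "I" if hi <= 1.0 else "II"


_CR_EDGES = (1e-6, 1e-5, 1e-4, 1e-3)
_CR_LEVELS = ("I", "II", "III", "IV", "V")


def classify_cr(cr: float) -> str:
    """Five-level carcinogenic classification, half-open at lower edges.

    <10⁻⁶ → I; [10⁻⁶, 10⁻⁵) → II; [10⁻⁵, 10⁻⁴) → III;
    [10⁻⁴, 10⁻³) → IV; ≥10⁻³ → V.
    """
    if cr < 0:
        raise ValueError("CR must be non-negative")
    idx = int(np.searchsorted(_CR_EDGES, cr, side="right"))
    return _CR_LEVELS[idx]


# ---------------------------------------------------------------------
# full assessment
# ---------------------------------------------------------------------


@dataclass
class RiskAssessment:
    """Per (sample, group) risk table plus summaries.

    ``hq``/``cr`` are DataFrames with a (group, sample_id) MultiIndex and
    analyte columns; ``hi``/``ccr``/``hi_level``/``cr_level`` are Series on
    the same index.  ``concentrations`` keeps the working values used so
    sensitivity analyses can correlate against them.
    """

    hq: pd.DataFrame
    hi: pd.Series
    cr: pd.DataFrame
    ccr: pd.Series
    hi_level: pd.Series
    cr_level: pd.Series
    concentrations: pd.DataFrame

    @property
    def groups(self) -> list[str]:
        return list(self.hq.index.get_level_values("group").unique())

    def to_frame(self) -> pd.DataFrame:
        """Flat table, one row per (sample, group), for CSV export."""
        out = pd.concat(
            [
                self.hq.add_prefix("hq_"),
                self.hi.rename("hi"),
                self.cr.add_prefix("cr_"),
                self.ccr.rename("ccr"),
                self.hi_level.rename("hi_level"),
                self.cr_level.rename("cr_level"),
            ],
            axis=1,
        )
        return out.reset_index()

    def summary(self) -> dict:
        """Per-group headline fractions (percent, full precision).

        ``pct_hi_acceptable``: percent of samples at HI level I (HI ≤ 1).
        ``cr_level_counts`` / ``cr_level_percent``: distribution over the
        five CR bands.
        """
        out: dict = {}
        for g in self.groups:
            hi_g = self.hi.xs(g, level="group")
            n = len(hi_g)
            levels = self.cr_level.xs(g, level="group")
            counts = {lv: int((levels == lv).sum()) for lv in _CR_LEVELS}
            out[g] = {
                "n": n,
                "hi_below_count": int((hi_g <= 1.0).sum()),
                "pct_hi_acceptable": 100.0 * float((hi_g <= 1.0).sum()) / n,
                "cr_level_counts": counts,
                "cr_level_percent": {
                    lv: 100.0 * c / n for lv, c in counts.items()
                },
            }
        return out


def assess(
    table: ConcentrationTable,
    exposure: dict[str, ExposureParams] | None = None,
    tox: ToxicityTable | None = None,
    water_type: str | None = "surface",
) -> RiskAssessment:
    """Full deterministic risk table for every sample and population group.

    Only analytes with a configured RfD enter HQ/HI; only those with a
    slope factor enter CR/CCR.  Working (censor-substituted) values are
    used.  By default only surface-water samples are assessed.
    """
    exposure = exposure or default_exposure()
    tox = tox or default_toxicity()
    working = substitute_censored(table.subset(water_type))
    conc = working.values
    rfd_analytes = [a for a in working.analyte_names if a in tox.rfd]
    sf_analytes = [a for a in working.analyte_names if a in tox.sf]

    hq_parts, cr_parts = [], []
    for g, params in exposure.items():
        cdi_nc = pd.DataFrame(
            {a: cdi(conc[a].to_numpy(), params, "noncarcinogenic") for a in rfd_analytes},
            index=conc.index,
        )
        hq_g = pd.DataFrame(
            {a: hazard_quotient(cdi_nc[a].to_numpy(), tox.rfd[a]) for a in rfd_analytes},
            index=conc.index,
        )
        cr_g = pd.DataFrame(
            {
                a: cancer_risk(
                    cdi(conc[a].to_numpy(), params, "carcinogenic"), tox.sf[a]
                )
                for a in sf_analytes
            },
            index=conc.index,
        )
        for df in (hq_g, cr_g):
            df.index = pd.MultiIndex.from_product(
                [[g], conc.index], names=["group", "sample_id"]
            )
        hq_parts.append(hq_g)
        cr_parts.append(cr_g)

    hq = pd.concat(hq_parts)
    cr = pd.concat(cr_parts)
    hi = hq.sum(axis=1).rename("hi")
    ccr = cr.sum(axis=1).rename("ccr")
    hi_level = hi.map(classify_hi).rename("hi_level")
    cr_level = ccr.map(classify_cr).rename("cr_level")
    return RiskAssessment(
        hq=hq, hi=hi, cr=cr, ccr=ccr, hi_level=hi_level, cr_level=cr_level,
        concentrations=conc,
    )


def hi_sensitivity(
    risk: RiskAssessment, group: str, mode: str = "contribution"
) -> pd.DataFrame:
    """Rank analytes by their leverage on the hazard index for one group.

    ``mode="contribution"`` scores each analyte by mean(HQ_j)/mean(HI) — the
    shares sum to 1.  ``mode="spearman"`` scores by the Spearman rank
    correlation between the analyte's concentration and HI across samples.
    Returns a DataFrame (index analyte, columns ``score``, ``mode``) sorted
    descending with lexicographic tie-break; degenerate inputs (constant
    HI) yield NaN scores.
    """
    hq_g = risk.hq.xs(group, level="group")
    hi_g = risk.hi.xs(group, level="group")
    if len(hi_g) < 2:
        raise ValueError("sensitivity needs at least 2 samples")
    if mode == "contribution":
        mean_hi = float(hi_g.mean())
        if mean_hi == 0:
            scores = pd.Series(np.nan, index=hq_g.columns)
        else:
            scores = hq_g.mean(axis=0) / mean_hi
    elif mode == "spearman":
        scores = {}
        hi_arr = hi_g.to_numpy()
        degenerate = np.allclose(hi_arr, hi_arr[0])
        for a in hq_g.columns:
            col = risk.concentrations.loc[hi_g.index, a].to_numpy()
            if degenerate or np.allclose(col, col[0]):
                scores[a] = np.nan
            else:
                scores[a] = float(spearmanr(col, hi_arr).statistic)
        scores = pd.Series(scores)
    else:
        raise ValueError("mode must be 'contribution' or 'spearman'")
    out = pd.DataFrame({"score": scores})
    out["mode"] = mode
    out.index.name = "analyte"
    out["_nan"] = out["score"].isna()
    out = (
        out.reset_index()
        .sort_values(["_nan", "score", "analyte"], ascending=[True, False, True])
        .drop(columns="_nan")
        .set_index("analyte")
    )
    return out
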
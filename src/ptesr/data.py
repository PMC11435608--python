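"""Data model and I/O for sample-by-analyte concentration tables.

Concentrations are held in μg/L throughout.  A table couples three aligned
pieces of state: the recorded values (censored cells carry the analyte's MDL
as the recorded bound), a boolean censoring mask, and per-sample metadata
(water type, river).  ``substitute_censored`` produces the *working* table in
which every below-detection cell is replaced by MDL/2 — the conventional
receptor-modelling substitute — while the censoring flags are preserved so
the uncertainty model can still apply its below-detection branch.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .defaults import DRINKING_LIMITS_UG_L, ERROR_FRACTION, MDL_UG_L, PTE_PANEL

WATER_TYPES = ("surface", "ground", "mine")
_CENSOR_MARKERS = ("<MDL", "<mdl", "")

__all__ = [
    "AnalyteSpec",
    "ConcentrationTable",
    "default_analytes",
    "load_analyte_config",
    "dump_analyte_config",
    "read_concentrations",
    "substitute_censored",
    "write_table",
]


@dataclass(frozen=True)
class AnalyteSpec:
    """One analyte's measurement/QC configuration.

    Parameters
    ----------
    name : str
        Analyte identifier (element symbol, e.g. ``"Fe"``).
    mdl : float
        Method detection limit, μg/L, strictly positive.
    error_fraction : float
        Relative measurement error in (0, 1), used above the MDL.
    drinking_limit : float, optional
        Regulatory drinking-water limit, μg/L, strictly positive.
    """

    name: str
    mdl: float
    error_fraction: float
    drinking_limit: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("analyte name must be non-empty")
        if not np.isfinite(self.mdl) or self.mdl <= 0:
            raise ValueError(f"{self.name}: mdl must be > 0, got {self.mdl}")
        if not (0.0 < self.error_fraction < 1.0):
            raise ValueError(
                f"{self.name}: error_fraction must lie in (0, 1), "
                f"got {self.error_fraction}"
            )
        if self.drinking_limit is not None and self.drinking_limit <= 0:
            raise ValueError(
                f"{self.name}: drinking_limit must be > 0, got {self.drinking_limit}"
            )


def default_analytes(names: tuple[str, ...] = PTE_PANEL) -> list[AnalyteSpec]:
    """Panel of :class:`AnalyteSpec` built from the bundled placeholder config."""
    return [
        AnalyteSpec(
            name=n,
            mdl=MDL_UG_L[n],
            error_fraction=ERROR_FRACTION[n],
            drinking_limit=DRINKING_LIMITS_UG_L.get(n),
        )
        for n in names
    ]


@dataclass
class ConcentrationTable:
    """Samples × analytes concentration matrix with metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        n × m recorded concentrations, μg/L; index is the sample id,
        columns are analyte names.  Censored cells hold the analyte MDL.
    censored : pandas.DataFrame
        Boolean mask, aligned with ``values``.
    meta : pandas.DataFrame
        Per-sample metadata with at least a ``water_type`` column; may
        carry ``river`` and coordinate columns (pass-through).
    analytes : list of AnalyteSpec
        Ordered, one entry per column of ``values``.
    """

    values: pd.DataFrame
    censored: pd.DataFrame
    meta: pd.DataFrame
    analytes: list[AnalyteSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        if [a.name for a in self.analytes] != cols:
            raise ValueError("analyte specs must match value columns in order")
        if list(self.censored.columns) != cols or not self.censored.index.equals(
            self.values.index
        ):
            raise ValueError("censored mask misaligned with values")
        if not self.meta.index.equals(self.values.index):
            raise ValueError("metadata misaligned with values")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        bad = self.values < 0
        if bad.any().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"negative concentration at sample {self.values.index[i]!r}, "
                f"analyte {cols[j]!r}"
            )
        wt = self.meta["water_type"]
        unknown = set(wt) - set(WATER_TYPES)
        if unknown:
            raise ValueError(f"unknown water_type values: {sorted(unknown)}")

    # -- basic views --------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def analyte_names(self) -> list[str]:
        return list(self.values.columns)

    def analyte(self, name: str) -> AnalyteSpec:
        for spec in self.analytes:
            if spec.name == name:
                return spec
        raise KeyError(f"analyte {name!r} not in table")

    def matrix(self) -> np.ndarray:
        """Dense n × m float array of the recorded values."""
        return self.values.to_numpy(dtype=float, copy=True)

    def subset(self, water_type: str | None = None) -> "ConcentrationTable":
        """Restrict to one water type (``None`` keeps everything)."""
        if water_type is None:
            return self
        if water_type not in WATER_TYPES:
            raise ValueError(f"water_type must be one of {WATER_TYPES}")
        keep = self.meta["water_type"] == water_type
        return ConcentrationTable(
            values=self.values.loc[keep].copy(),
            censored=self.censored.loc[keep].copy(),
            meta=self.meta.loc[keep].copy(),
            analytes=list(self.analytes),
        )


def substitute_censored(table: ConcentrationTable) -> ConcentrationTable:
    """Replace every censored cell's working value by MDL/2.

    Idempotent; uncensored cells are never touched and the censoring flags
    are preserved for the uncertainty construction.
    """
    values = table.values.copy()
    for spec in table.analytes:
        mask = table.censored[spec.name]
        if mask.any():
            values.loc[mask, spec.name] = spec.mdl / 2.0
    return ConcentrationTable(
        values=values,
        censored=table.censored.copy(),
        meta=table.meta.copy(),
        analytes=list(table.analytes),
    )


# ---------------------------------------------------------------------
# analyte config files (YAML)
# ---------------------------------------------------------------------

def load_analyte_config(path) -> list[AnalyteSpec]:
    """Read analyte specs from a YAML file.

    Layout: a mapping ``analytes:`` of name → {mdl, error_fraction,
    drinking_limit (optional)}, or a top-level list of such records with a
    ``name`` key.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict) and "analytes" in raw:
        raw = raw["analytes"]
    specs: list[AnalyteSpec] = []
    if isinstance(raw, dict):
        items = [{"name": k, **v} for k, v in raw.items()]
    else:
        items = list(raw)
    for rec in items:
        specs.append(
            AnalyteSpec(
                name=str(rec["name"]),
                mdl=float(rec["mdl"]),
                error_fraction=float(rec["error_fraction"]),
                drinking_limit=(
                    float(rec["drinking_limit"])
                    if rec.get("drinking_limit") is not None
                    else None
                ),
            )
        )
    return specs


def dump_analyte_config(specs: list[AnalyteSpec], path) -> None:
    """Write analyte specs as YAML (editable starting point for users)."""
    payload = {
        "analytes": {
            s.name: {
                "mdl": s.mdl,
                "error_fraction": s.error_fraction,
                **(
                    {"drinking_limit": s.drinking_limit}
                    if s.drinking_limit is not None
                    else {}
                ),
            }
            for s in specs
        }
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------

_META_COLS = ("sample_id", "water_type", "river")


def read_concentrations(path, analytes: list[AnalyteSpec]) -> ConcentrationTable:
    """Read a wide CSV (one row per sample) into a validated table.

    The CSV must carry ``sample_id`` and ``water_type`` columns, an optional
    ``river`` column (any further non-analyte columns are kept as metadata),
    and one column per configured analyte.  Cells that are blank or read
    ``<MDL`` are flagged censored and recorded at the analyte's MDL.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns or "water_type" not in df.columns:
        raise ValueError("CSV must have 'sample_id' and 'water_type' columns")
    by_name = {a.name: a for a in analytes}
    analyte_cols = [c for c in df.columns if c not in _META_COLS]
    meta_extra = [c for c in analyte_cols if c not in by_name]
    # columns that are neither metadata nor configured analytes: reject if
    # they look numeric-ish analyte data, keep known extras like coordinates
    known_extra = {"lat", "lon", "latitude", "longitude", "x", "y"}
    bad = [c for c in meta_extra if c.lower() not in known_extra]
    if bad:
        raise ValueError(f"unknown analyte column(s): {bad}")
    analyte_cols = [c for c in analyte_cols if c in by_name]

    ids = df["sample_id"].tolist()
    if len(set(ids)) != len(ids):
        dup = next(x for x in ids if ids.count(x) > 1)
        raise ValueError(f"duplicate sample id: {dup!r}")

    n = len(df)
    values = pd.DataFrame(index=pd.Index(ids, name="sample_id"),
                          columns=analyte_cols, dtype=float)
    censored = pd.DataFrame(False, index=values.index, columns=analyte_cols)
    for col in analyte_cols:
        spec = by_name[col]
        for row_pos, raw in enumerate(df[col].tolist()):
            raw = raw.strip()
            if raw in _CENSOR_MARKERS:
                values.iloc[row_pos, values.columns.get_loc(col)] = spec.mdl
                censored.iloc[row_pos, censored.columns.get_loc(col)] = True
                continue
            try:
                val = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric value {raw!r} at sample {ids[row_pos]!r}, "
                    f"analyte {col!r}"
                ) from exc
            if val < 0:
                raise ValueError(
                    f"negative concentration at sample {ids[row_pos]!r}, "
                    f"analyte {col!r}: {val}"
                )
            values.iloc[row_pos, values.columns.get_loc(col)] = val

    meta_cols = [c for c in df.columns if c in _META_COLS or c in meta_extra]
    meta = df[meta_cols].copy()
    meta.index = values.index
    meta = meta.drop(columns=["sample_id"])
    specs = [by_name[c] for c in analyte_cols]
    return ConcentrationTable(values=values, censored=censored, meta=meta,
                              analytes=specs)


def write_table(obj, path) -> None:
    """Write a :class:`ConcentrationTable` or DataFrame to CSV.

    Numeric cells are written with ``repr`` round-trip precision; censored
    cells of a concentration table are written as ``<MDL`` so the flags
    survive a read/write cycle.
    """
    if isinstance(obj, ConcentrationTable):
        out = obj.values.map(lambda v: format(v, ".17g"))
        out = out.mask(obj.censored, "<MDL")
        out = pd.concat([obj.meta, out], axis=1)
        out.insert(0, "sample_id", obj.values.index)
        out.to_csv(path, index=False)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, float_format="%.17g")
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def table_to_csv_string(table: ConcentrationTable) -> str:
    """Render a table to the CSV text ``read_concentrations`` accepts."""
    buf = io.StringIO()
    write_table(table, buf)
    return buf.getvalue()
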
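"""End-to-end orchestration: describe → PMF → risk on one input table.

``run_all`` executes the three analysis stages in order, writes every
artifact (summary CSV, G/F/residual CSVs, PMF diagnostics JSON, risk CSV,
risk summary JSON) into an output directory, and returns a ``RunReport``
whose JSON/Markdown renderings make the run reproducible and traceable
(seed, config digest, stage timings).
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import ConcentrationTable, substitute_censored
from .descriptive import rank, summarize
from .pmf import PMFConfig, build_uncertainty, fit_pmf
from .risk import ExposureParams, ToxicityTable, assess, hi_sensitivity

__all__ = ["RunReport", "run_all", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    """Structured record of one pipeline run."""

    input_digest: dict
    summary_file: str
    pmf: dict
    risk_summary: dict
    rankings: dict
    sensitivity: dict
    artifacts: list[str] = field(default_factory=list)
    version: str = __version__
    seed: int | None = None
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=_jsonify)

    def to_markdown(self) -> str:
        lines = [
            "# PTE source apportionment & risk report",
            "",
            f"- tool version: {self.version}",
            f"- seed: {self.seed}",
            f"- generated: {self.timestamp}",
            f"- input: n={self.input_digest['n']} samples × "
            f"m={self.input_digest['m']} analytes, "
            f"{self.input_digest['censored_fraction']:.2%} censored",
            "",
            "## PMF",
            f"- factors: {self.pmf['p']}, Q = {self.pmf['Q']:.4g}, "
            f"Q/Q_exp = {self.pmf['q_ratio']:.3g}, "
            f"converged = {self.pmf['converged']}",
            "- factor shares (% of reconstructed mass): "
            + ", ".join(f"{v:.1f}" for v in self.pmf["factor_percent"]),
            "",
            "## Risk summary",
        ]
        for g, s in self.risk_summary.items():
            lines.append(
                f"- {g}: HI ≤ 1 for {s['pct_hi_acceptable']:.2f}% of samples; "
                "CR levels "
                + ", ".join(
                    f"{lv}: {pct:.1f}%"
                    for lv, pct in s["cr_level_percent"].items()
                    if s["cr_level_counts"][lv]
                )
            )
        lines.append("")
        lines.append("## Artifacts")
        lines.extend(f"- {a}" for a in self.artifacts)
        return "\n".join(lines) + "\n"


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _digest(table: ConcentrationTable) -> dict:
    h = hashlib.sha256(
        pd.util.hash_pandas_object(table.values).to_numpy().tobytes()
    ).hexdigest()[:16]
    return {
        "n": table.n,
        "m": table.m,
        "censored_fraction": float(table.censored.to_numpy().mean()),
        "values_sha256_16": h,
    }


def run_all(
    table: ConcentrationTable,
    out_dir,
    p: int = 4,
    seed: int | None = None,
    n_starts: int = 20,
    exposure: dict[str, ExposureParams] | None = None,
    tox: ToxicityTable | None = None,
    water_type: str | None = "surface",
) -> RunReport:
    """Run describe → PMF → risk, writing all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def _save(df: pd.DataFrame, name: str) -> str:
        path = out / name
        df.to_csv(path, float_format="%.12g")
        artifacts.append(name)
        return name

    # stage 1: descriptive
    try:
        summary = summarize(table, water_type=water_type)
        summary_file = _save(summary, "summary.csv")
        rankings = {
            "by_mean": rank(summary, "mean"),
            "by_cv": rank(summary, "cv_percent"),
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("describe", exc) from exc

    # stage 2: PMF on the working surface-water matrix
    try:
        working = substitute_censored(table.subset(water_type))
        X = working.matrix()
        U = build_uncertainty(working)
        sol = fit_pmf(
            X, U, PMFConfig(p=p, n_starts=n_starts, seed=seed),
            analyte_names=working.analyte_names,
        )
        cols = working.analyte_names
        _save(pd.DataFrame(sol.G, index=working.values.index,
                           columns=[f"factor{k + 1}" for k in range(p)]), "G.csv")
        _save(pd.DataFrame(sol.F, columns=cols,
                           index=[f"factor{k + 1}" for k in range(p)]), "F.csv")
        _save(pd.DataFrame(sol.E, index=working.values.index, columns=cols),
              "residuals.csv")
        pmf_diag = {
            "p": p,
            "Q": sol.Q,
            "q_expected": sol.q_expected,
            "q_ratio": sol.Q / sol.q_expected if sol.q_expected > 0 else None,
            "converged": sol.converged,
            "n_iter": sol.n_iter,
            "best_start": sol.start_index,
            "factor_percent": sol.factor_percent.tolist(),
        }
        (out / "pmf_diagnostics.json").write_text(
            json.dumps(pmf_diag, indent=2, default=_jsonify)
        )
        artifacts.append("pmf_diagnostics.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError("pmf", exc) from exc

    # stage 3: health risk
    try:
        risk = assess(table, exposure=exposure, tox=tox, water_type=water_type)
        _save(risk.to_frame().set_index("group"), "risk.csv")
        risk_summary = risk.summary()
        (out / "risk_summary.json").write_text(
            json.dumps(risk_summary, indent=2, default=_jsonify)
        )
        artifacts.append("risk_summary.json")
        sens = {
            g: hi_sensitivity(risk, g)["score"].to_dict() for g in risk.groups
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("risk", exc) from exc

    report = RunReport(
        input_digest=_digest(table),
        summary_file=summary_file,
        pmf=pmf_diag,
        risk_summary=risk_summary,
        rankings=rankings,
        sensitivity=sens,
        artifacts=artifacts,
        seed=seed,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    (out / "report.json").write_text(report.to_json())
    (out / "report.md").write_text(report.to_markdown())
    return report
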
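"""Synthetic concentration tables with known source structure.

The generator emulates the shape of a small plateau coal-mining river
survey: ~34 surface-water samples (plus a few groundwater and mine-water
samples), a 17-element PTE panel, and a handful of distinct pollution
sources.  Samples are mixtures X = G·F of p non-negative sources: per-factor
contributions G are gamma-distributed (shape 2, unit mean — right-skewed,
as source activity tends to be), and profiles F are block-sparse so each
factor has a distinct dominant-analyte signature (the identifiability
condition PMF needs).  Multiplicative Gaussian noise with coefficient
``noise_cv`` mirrors the error-fraction structure of the measurement
uncertainty model, and per-analyte detection limits are set at a low
quantile of the simulated values so a realistic fraction of cells is
left-censored.

The ground truth (G, F, noise, censoring mask) is retained so factor
recovery and statistics can be tested without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AnalyteSpec, ConcentrationTable
from .defaults import DRINKING_LIMITS_UG_L, PTE_PANEL

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "make_worked_fixtures"]

# typical concentration scale per analyte, μg/L — reproduces the familiar
# Fe > Al > Zn > Mn > … ordering of mean levels in mining-impacted rivers
_ANALYTE_SCALE: dict[str, float] = {
    "Fe": 300.0, "Al": 150.0, "Zn": 60.0, "Mn": 40.0, "Ba": 35.0,
    "B": 20.0, "Ni": 6.0, "Li": 5.0, "Cd": 1.5, "Mo": 1.2,
    "Cu": 1.0, "Co": 0.6, "Hg": 0.3, "Se": 0.25, "As": 0.2,
    "Pb": 0.15, "Sb": 0.1,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration (defaults are the reference study design)."""

    n_surface: int = 34
    n_ground: int = 5
    n_mine: int = 2
    analytes: tuple[str, ...] = PTE_PANEL
    p: int = 4
    gamma_shape: float = 2.0
    profile_sparsity: float = 0.5
    noise_cv: float = 0.10
    mdl_quantile: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        n = self.n_surface + self.n_ground + self.n_mine
        m = len(self.analytes)
        if not (1 <= self.p <= min(n, m) - 1):
            raise ValueError("p must satisfy 1 <= p <= min(n, m) - 1")
        if not (0.0 <= self.profile_sparsity < 1.0):
            raise ValueError("profile_sparsity must lie in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not (0.0 <= self.mdl_quantile < 1.0):
            raise ValueError("mdl_quantile must lie in [0, 1)")

    @property
    def n(self) -> int:
        return self.n_surface + self.n_ground + self.n_mine

    @property
    def m(self) -> int:
        return len(self.analytes)


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated table."""

    G_true: np.ndarray
    F_true: np.ndarray
    noise: np.ndarray  # multiplicative factors (1 + ε) actually applied
    censor_mask: np.ndarray
    mdl: dict[str, float]
    spec: SyntheticSpec = field(repr=False, default=None)


def generate(spec: SyntheticSpec) -> tuple[ConcentrationTable, SyntheticTruth]:
    """Draw one synthetic concentration table plus its ground truth.

    Deterministic for a fixed ``spec.seed``.  With ``noise_cv=0`` and
    ``mdl_quantile=0`` the observed matrix equals G_true·F_true exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, p = spec.n, spec.m, spec.p
    names = list(spec.analytes)
    scales = np.array([_ANALYTE_SCALE.get(a, 1.0) for a in names])

    # contributions: gamma, unit mean per factor, mild factor-size spread
    factor_weight = 0.8 + 0.4 * rng.random(p)
    G = rng.gamma(spec.gamma_shape, 1.0 / spec.gamma_shape, size=(n, p))
    G *= factor_weight[None, :]

    # block-sparse profiles: analytes assigned round-robin to a dominant
    # factor; each factor row then has profile_sparsity of its entries
    # near zero, giving every source a distinct signature
    F = np.zeros((p, m))
    dominant = rng.permutation(m) % p
    n_near_zero = int(round(spec.profile_sparsity * m))
    for k in range(p):
        own = np.flatnonzero(dominant == k)
        others = np.flatnonzero(dominant != k)
        zeroed = rng.choice(others, size=min(n_near_zero, others.size),
                            replace=False)
        for j in range(m):
            base = scales[j] / p
            if j in own:
                F[k, j] = base * rng.uniform(1.5, 3.0)
            elif j in zeroed:
                F[k, j] = base * rng.uniform(0.0, 0.05)
            else:
                F[k, j] = base * rng.uniform(0.1, 0.5)

    signal = G @ F
    eps = spec.noise_cv * rng.standard_normal(size=(n, m))
    X = np.maximum(signal * (1.0 + eps), 0.0)

    # detection limits at a low quantile of each analyte's simulated values
    mdl = {}
    censored = np.zeros_like(X, dtype=bool)
    for j, a in enumerate(names):
        if spec.mdl_quantile > 0:
            q = float(np.quantile(X[:, j], spec.mdl_quantile))
            mdl_j = max(q, 1e-9)
        else:
            mdl_j = max(float(X[:, j].min()) / 10.0, 1e-9)
        mdl[a] = mdl_j
        censored[:, j] = X[:, j] < mdl_j

    ef = spec.noise_cv if spec.noise_cv > 0 else 0.05
    specs = [
        AnalyteSpec(
            name=a,
            mdl=mdl[a],
            error_fraction=min(ef, 0.99),
            drinking_limit=DRINKING_LIMITS_UG_L.get(a),
        )
        for a in names
    ]

    ids = (
        [f"SW{i + 1:02d}" for i in range(spec.n_surface)]
        + [f"GW{i + 1:02d}" for i in range(spec.n_ground)]
        + [f"MW{i + 1:02d}" for i in range(spec.n_mine)]
    )
    water = (
        ["surface"] * spec.n_surface
        + ["ground"] * spec.n_ground
        + ["mine"] * spec.n_mine
    )
    index = pd.Index(ids, name="sample_id")
    recorded = X.copy()
    for j, a in enumerate(names):
        recorded[censored[:, j], j] = mdl[a]  # censored cells carry the bound
    values = pd.DataFrame(recorded, index=index, columns=names)
    mask = pd.DataFrame(censored, index=index, columns=names)
    meta = pd.DataFrame({"water_type": water, "river": "synthetic"}, index=index)

    table = ConcentrationTable(values=values, censored=mask, meta=meta, analytes=specs)
    truth = SyntheticTruth(
        G_true=G, F_true=F, noise=1.0 + eps, censor_mask=censored, mdl=mdl,
        spec=spec,
    )
    return table, truth


# ---------------------------------------------------------------------
# engineered worked fixture
# ---------------------------------------------------------------------


def make_worked_fixtures() -> dict:
    """Deterministic 34-sample surface-water fixture with known headline counts.

    The table is *synthetic*, engineered so that under the bundled limits,
    toxicity constants and exposure defaults the pipeline reports exactly:

    - 27/34 samples above the Fe and Al drinking limits (79.41%),
    - 1/34 above the Mn and Zn limits (2.94%),
    - 2/34 with a children's hazard index above 1 (HI ≤ 1 for 94.12%),
    - 25/34 at carcinogenic risk level III and 9/34 at level II for every
      population group (73.5% / 26.5%).

    Returns a dict with keys ``table``, ``analytes`` and the sample counts.
    """
    names = list(PTE_PANEL)
    n = 34
    base = {
        "Fe": 100.0, "Mn": 20.0, "Cu": 2.0, "Zn": 50.0, "Al": 50.0,
        "Hg": 0.05, "As": 0.3, "Se": 0.5, "Cd": 0.5, "Pb": 0.5,
        "Li": 2.0, "B": 20.0, "Ba": 50.0, "Sb": 0.1, "Ni": 5.0,
        "Co": 0.5, "Mo": 1.0,
    }
    X = pd.DataFrame(
        {a: np.full(n, base[a]) for a in names},
        index=pd.Index([f"SW{i + 1:02d}" for i in range(n)], name="sample_id"),
    )
    # 27 samples exceed Fe (limit 300) and Al (limit 200)
    X.iloc[:27, X.columns.get_loc("Fe")] = 400.0
    X.iloc[:27, X.columns.get_loc("Al")] = 250.0
    # exactly one sample exceeds Mn (limit 100) and Zn (limit 1000)
    X.iloc[33, X.columns.get_loc("Mn")] = 150.0
    X.iloc[33, X.columns.get_loc("Zn")] = 1200.0
    # 25 samples at As high enough for CR level III in all groups,
    # 9 at level II
    X.iloc[:25, X.columns.get_loc("As")] = 2.0
    # two samples pushed over HI = 1 for children via Cd
    X.iloc[:2, X.columns.get_loc("Cd")] = 4.0

    specs = [
        AnalyteSpec(
            name=a,
            mdl=min(base[a] / 10.0, 1.0),
            error_fraction=0.1,
            drinking_limit=DRINKING_LIMITS_UG_L.get(a),
        )
        for a in names
    ]
    mask = pd.DataFrame(False, index=X.index, columns=X.columns)
    meta = pd.DataFrame(
        {"water_type": "surface", "river": "worked"}, index=X.index
    )
    table = ConcentrationTable(values=X, censored=mask, meta=meta, analytes=specs)
    return {
        "table": table,
        "analytes": specs,
        "n": n,
        "fe_al_exceed": 27,
        "mn_zn_exceed": 1,
        "hi_above_1": 2,
        "cr_level_iii": 25,
    }
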
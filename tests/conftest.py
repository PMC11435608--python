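import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ptesr.data import AnalyteSpec, ConcentrationTable
from ptesr.synthetic import make_worked_fixtures

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def worked():
    """Engineered 34-sample fixture with known exceedance/risk counts."""
    return make_worked_fixtures()


@pytest.fixture
def small_table():
    """Tiny 4-sample, 3-analyte table with one censored cell."""
    specs = [
        AnalyteSpec("Fe", mdl=10.0, error_fraction=0.1, drinking_limit=300.0),
        AnalyteSpec("Mn", mdl=1.0, error_fraction=0.2, drinking_limit=100.0),
        AnalyteSpec("Hg", mdl=0.04, error_fraction=0.15, drinking_limit=1.0),
    ]
    ids = pd.Index(["s1", "s2", "s3", "s4"], name="sample_id")
    values = pd.DataFrame(
        {"Fe": [120.0, 350.0, 80.0, 400.0],
         "Mn": [5.0, 20.0, 2.0, 150.0],
         "Hg": [0.04, 0.5, 0.2, 0.3]},
        index=ids,
    )
    censored = pd.DataFrame(False, index=ids, columns=values.columns)
    censored.loc["s1", "Hg"] = True
    meta = pd.DataFrame(
        {"water_type": ["surface", "surface", "ground", "surface"],
         "river": ["A", "A", "B", "B"]},
        index=ids,
    )
    return ConcentrationTable(values=values, censored=censored, meta=meta,
                              analytes=specs)


@pytest.fixture(scope="session")
def rank1_case():
    """Fixed 4×3 matrix + uncertainties for the rank-1 oracle comparison."""
    X = np.array([[1.0, 2.0, 0.5],
                  [2.0, 3.5, 1.2],
                  [0.3, 0.9, 0.2],
                  [1.5, 2.2, 0.8]])
    U = np.array([[0.2, 0.3, 0.1],
                  [0.3, 0.4, 0.2],
                  [0.1, 0.2, 0.1],
                  [0.2, 0.3, 0.15]])
    return X, U


def rank1_grid_q(X, U, n_grid=600):
    """Independent brute-force oracle: dense grid over the rank-1 cone.

    The unit profile direction f (3-vector, positive octant) is scanned on
    an angular grid; for each f the optimal non-negative contribution g has
    the closed form g_i = max(0, Σ_j w_ij x_ij f_j / Σ_j w_ij f_j²) with
    w = 1/u².  Returns the minimal Q over the grid.
    """
    thetas = np.linspace(0.0, np.pi / 2, n_grid)
    phis = np.linspace(0.0, np.pi / 2, n_grid)
    w = 1.0 / U**2
    best = np.inf
    for t in thetas:
        st, ct = np.sin(t), np.cos(t)
        for p in phis:
            f = np.array([st * np.cos(p), st * np.sin(p), ct])
            num = (w * X * f[None, :]).sum(axis=1)
            den = (w * f[None, :] ** 2).sum(axis=1)
            g = np.maximum(num / den, 0.0)
            q = (((X - np.outer(g, f)) / U) ** 2).sum()
            if q < best:
                best = q
    return best
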
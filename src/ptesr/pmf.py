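"""Uncertainty-weighted positive matrix factorization (PMF).

A receptor model decomposing a non-negative samples × analytes concentration
matrix ``X`` into ``p`` source contributions ``G`` (n × p) and source
profiles ``F`` (p × m),

    X = G · F + E,

by minimizing the uncertainty-weighted least-squares objective

    Q = Σ_ij (E_ij / u_ij)²,

where ``u_ij`` is the per-cell measurement uncertainty.  The optimizer is
alternating non-negative weighted least squares: with ``F`` fixed each row
of ``G`` solves an independent weighted NNLS problem, and symmetrically for
the columns of ``F``; each block update is an exact minimizer, so Q is
monotone non-increasing along every run.  Multi-start over random
non-negative initializations guards against local minima, and the lowest-Q
start wins.

Uncertainties follow the EPA-style two-branch rule:

    u_ij = (5/6)·MDL_j                          if x_ij ≤ MDL_j,
    u_ij = sqrt((EF_j·x_ij)² + (0.5·MDL_j)²)    otherwise,

with MDL the method detection limit and EF the per-analyte error fraction.

``WeightedPMF`` is a scikit-learn style estimator (``fit`` / ``transform`` /
``get_params``) so it can sit in sklearn pipelines; ``fit_pmf`` is the
functional wrapper.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data import ConcentrationTable, substitute_censored

__all__ = [
    "build_uncertainty",
    "WeightedPMF",
    "PMFConfig",
    "PMFSolution",
    "fit_pmf",
    "factor_summaries",
    "match_factors",
    "scan_p",
]


def build_uncertainty(table: ConcentrationTable) -> np.ndarray:
    """Per-cell uncertainty matrix u (n × m, μg/L) from the two-branch rule.

    Cells at or below the analyte's MDL — including all censored cells,
    whose working value is MDL/2 — get u = (5/6)·MDL; cells above it get
    u = sqrt((EF·x)² + (0.5·MDL)²).  Every entry is strictly positive.
    """
    working = substitute_censored(table)
    x = working.matrix()
    u = np.empty_like(x)
    for j, spec in enumerate(working.analytes):
        below = x[:, j] <= spec.mdl
        u[below, j] = (5.0 / 6.0) * spec.mdl
        above = ~below
        u[above, j] = np.sqrt(
            (spec.error_fraction * x[above, j]) ** 2 + (0.5 * spec.mdl) ** 2
        )
    return u


# ---------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------


class WeightedPMF(TransformerMixin, BaseEstimator):
    """Uncertainty-weighted PMF as a scikit-learn estimator.

    Parameters
    ----------
    n_components : int
        Number of sources p; must satisfy ``p <= min(n, m) - 1``.
    n_starts : int, default 20
        Random non-negative initializations; the lowest-Q run is kept.
    max_iter : int, default 5000
        Iteration cap per run (one iteration = full G then F update).
    rel_tol : float, default 1e-9
        Convergence: relative Q decrease below this for ``patience``
        consecutive iterations.
    patience : int, default 20
        Consecutive small-decrease iterations required to declare
        convergence.
    robust : bool, default False
        EPA-style robust mode: scaled residuals with \\|e/u\\| > 4 are
        down-weighted by inflating the effective uncertainty.
    random_state : int or None
        Seed; fits are bit-reproducible for a fixed seed.

    Attributes
    ----------
    contributions_ : ndarray (n, p)
        Fitted G with columns scaled to mean 1 (scale absorbed into F).
    components_ : ndarray (p, m)
        Fitted profiles F.
    residual_ : ndarray (n, m)
        E = X − G·F.
    q_ : float
        Objective at the best start.
    q_expected_ : float
        nm − p(n+m), the theoretical expectation of Q for a correctly
        specified model.
    converged_ : bool
    n_iter_ : int
        Iterations used by the winning start.
    best_start_ : int
        Index of the winning random start.
    factor_percent_ : ndarray (p,)
        Share of total reconstructed mass per factor (sums to 100).
    profile_percent_ : ndarray (p, m)
        Per-analyte percentage split across factors (columns sum to 100).
    """

    ROBUST_CUTOFF = 4.0
    # absolute convergence floor per cell: a mean squared scaled residual
    # this small is numerically exact (noiseless data never satisfies the
    # relative criterion because Q decays geometrically toward zero)
    ABS_TOL_PER_CELL = 1e-12

    def __init__(
        self,
        n_components: int = 4,
        n_starts: int = 20,
        max_iter: int = 5000,
        rel_tol: float = 1e-9,
        patience: int = 20,
        robust: bool = False,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.rel_tol = rel_tol
        self.patience = patience
        self.robust = robust
        self.random_state = random_state

    # -- internals ----------------------------------------------------

    @staticmethod
    def _q_value(X, U, G, F):
        return float((((X - G @ F) / U) ** 2).sum())

    def _effective_u(self, X, U, G, F):
        if not self.robust:
            return U
        scaled = np.abs(X - G @ F) / U
        infl = np.sqrt(np.maximum(scaled / self.ROBUST_CUTOFF, 1.0))
        return U * infl

    @staticmethod
    def _update_G(X, U, G, F):
        # row i of G: min_{g>=0} || diag(1/u_i) (F^T g - x_i) ||^2
        for i in range(X.shape[0]):
            w = 1.0 / U[i, :]
            A = (F * w[None, :]).T
            b = X[i, :] * w
            G[i, :], _ = nnls(A, b)
        return G

    @staticmethod
    def _update_F(X, U, G, F):
        for j in range(X.shape[1]):
            w = 1.0 / U[:, j]
            A = G * w[:, None]
            b = X[:, j] * w
            F[:, j], _ = nnls(A, b)
        return F

    def _run_once(self, X, U, rng):
        n, m = X.shape
        p = self.n_components
        col_scale = X.mean(axis=0)
        col_scale[col_scale <= 0] = col_scale[col_scale > 0].min() if (col_scale > 0).any() else 1.0
        G = rng.uniform(0.0, 1.0, size=(n, p))
        # scale F so E[G F] matches column magnitudes of X
        F = rng.uniform(0.0, 1.0, size=(p, m)) * (4.0 * col_scale / p)[None, :]
        q_prev = self._q_value(X, U, G, F)
        trajectory = [q_prev]
        small = 0
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            Ueff = self._effective_u(X, U, G, F)
            G = self._update_G(X, Ueff, G, F)
            F = self._update_F(X, Ueff, G, F)
            q = self._q_value(X, Ueff, G, F)
            trajectory.append(q)
            rel = (q_prev - q) / q_prev if q_prev > 0 else 0.0
            q_prev = q
            if q <= self.ABS_TOL_PER_CELL * X.size:
                converged = True
                break
            if abs(rel) < self.rel_tol:
                small += 1
                if small >= self.patience:
                    converged = True
                    break
            else:
                small = 0
        return G, F, q_prev, converged, it, trajectory

    # -- API ----------------------------------------------------------

    def fit(self, X, y=None, *, uncertainty=None):
        """Fit PMF to ``X`` (n × m, non-negative) with uncertainties ``u``.

        ``uncertainty`` defaults to all-ones (unweighted least squares).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, m = X.shape
        if uncertainty is None:
            U = np.ones_like(X)
        else:
            U = np.asarray(uncertainty, dtype=float)
        if U.shape != X.shape:
            raise ValueError(f"uncertainty shape {U.shape} != X shape {X.shape}")
        if not np.isfinite(X).all() or not np.isfinite(U).all():
            raise ValueError("X and uncertainty must be finite")
        if (X < 0).any():
            raise ValueError("X must be non-negative")
        if (U <= 0).any():
            raise ValueError("uncertainties must be strictly positive")
        p = self.n_components
        if not (1 <= p <= min(n, m) - 1):
            raise ValueError(
                f"n_components={p} out of bounds for shape {X.shape} "
                f"(need 1 <= p <= min(n, m) - 1 = {min(n, m) - 1})"
            )
        if self.n_starts < 1 or self.max_iter < 1:
            raise ValueError("n_starts and max_iter must be >= 1")

        root = np.random.SeedSequence(self.random_state)
        children = root.spawn(self.n_starts)
        best = None
        for s in range(self.n_starts):
            rng = np.random.default_rng(children[s])
            G, F, q, conv, it, traj = self._run_once(X, U, rng)
            if best is None or q < best[2]:
                best = (G, F, q, conv, it, s, traj)
        G, F, q, conv, it, s, traj = best

        # normalize G columns to mean 1, absorbing the scale into F
        scale = G.mean(axis=0)
        pos = scale > 0
        G[:, pos] /= scale[pos][None, :]
        F[pos, :] *= scale[pos][:, None]

        self.contributions_ = G
        self.components_ = F
        self.residual_ = X - G @ F
        self.q_ = self._q_value(X, U, G, F)
        self.q_expected_ = float(n * m - p * (n + m))
        self.converged_ = bool(conv)
        self.n_iter_ = int(it)
        self.best_start_ = int(s)
        self.q_trajectory_ = np.asarray(traj)
        self.factor_percent_, self.profile_percent_ = factor_summaries(G, F)
        if not conv:
            warnings.warn(
                "PMF did not converge in any start; best solution returned "
                "with converged_=False",
                RuntimeWarning,
                stacklevel=2,
            )
        return self

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).contributions_

    def transform(self, X, *, uncertainty=None):
        """Project new samples on the fitted profiles (weighted NNLS per row)."""
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        U = (
            np.ones_like(X)
            if uncertainty is None
            else np.asarray(uncertainty, dtype=float)
        )
        G = np.zeros((X.shape[0], self.n_components))
        return self._update_G(X, U, G, self.components_.copy())

    def inverse_transform(self, G):
        check_is_fitted(self, "components_")
        return np.asarray(G) @ self.components_


# ---------------------------------------------------------------------
# functional wrapper and dataclasses
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class PMFConfig:
    """Run configuration for :func:`fit_pmf`."""

    p: int
    n_starts: int = 20
    max_iter: int = 5000
    rel_tol: float = 1e-9
    seed: int | None = None
    robust: bool = False


@dataclass
class PMFSolution:
    """Result bundle for one PMF fit."""

    G: np.ndarray
    F: np.ndarray
    E: np.ndarray
    Q: float
    q_expected: float
    converged: bool
    start_index: int
    n_iter: int
    factor_percent: np.ndarray
    profile_percent: np.ndarray
    analyte_names: list[str] = field(default_factory=list)


def fit_pmf(X, U, config: PMFConfig, analyte_names: list[str] | None = None) -> PMFSolution:
    """Fit uncertainty-weighted PMF; thin wrapper around :class:`WeightedPMF`."""
    est = WeightedPMF(
        n_components=config.p,
        n_starts=config.n_starts,
        max_iter=config.max_iter,
        rel_tol=config.rel_tol,
        robust=config.robust,
        random_state=config.seed,
    )
    est.fit(X, uncertainty=U)
    return PMFSolution(
        G=est.contributions_,
        F=est.components_,
        E=est.residual_,
        Q=est.q_,
        q_expected=est.q_expected_,
        converged=est.converged_,
        start_index=est.best_start_,
        n_iter=est.n_iter_,
        factor_percent=est.factor_percent_,
        profile_percent=est.profile_percent_,
        analyte_names=list(analyte_names) if analyte_names else [],
    )


def factor_summaries(G: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Factor mass shares and per-analyte profile splits, both in percent.

    ``factor_percent[k]`` is 100·Σ_ij G_ik F_kj / Σ_ijk G_ik F_kj — each
    factor's share of the total reconstructed mass.  ``profile_percent[k, j]``
    is 100·F_kj / Σ_k F_kj, the split of analyte j across factors; columns
    with an all-zero profile yield NaN.
    """
    G = np.asarray(G, dtype=float)
    F = np.asarray(F, dtype=float)
    mass = G.sum(axis=0) * F.sum(axis=1)  # Σ_ij G_ik F_kj, separable
    total = mass.sum()
    if total <= 0:
        raise ValueError("all-zero reconstruction; factor shares undefined")
    factor_percent = 100.0 * mass / total
    colsum = F.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        profile_percent = np.where(colsum > 0, 100.0 * F / colsum[None, :], np.nan)
    return factor_percent, profile_percent


def match_factors(
    F_hat: np.ndarray, F_true: np.ndarray
) -> tuple[tuple[int, ...], float]:
    """Align recovered profiles with generating ones by exhaustive permutation.

    Rows are compared after unit-norm scaling (cosine similarity, scale
    invariant).  Returns ``(perm, mean_cosine)`` where ``F_hat[perm[k]]``
    is the recovered row matched to ``F_true[k]`` and ``mean_cosine`` is
    the mean over rows under that optimal assignment.  Exhaustive search is
    limited to p ≤ 8; use a linear-assignment heuristic beyond that.
    """
    F_hat = np.asarray(F_hat, dtype=float)
    F_true = np.asarray(F_true, dtype=float)
    if F_hat.shape != F_true.shape:
        raise ValueError("profile matrices must have the same shape")
    p = F_hat.shape[0]
    if p > 8:
        raise ValueError("exhaustive matching limited to p <= 8 factors")

    def _unit(M):
        norms = np.linalg.norm(M, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return M / norms

    A = _unit(F_hat)
    B = _unit(F_true)
    C = B @ A.T  # C[k, l] = cos(F_true[k], F_hat[l])
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(p)):
        score = float(np.mean([C[k, perm[k]] for k in range(p)]))
        if score > best_score:
            best_perm, best_score = perm, score
    return best_perm, best_score


def scan_p(X, U, p_values, n_starts: int = 10, seed: int | None = None, **kw) -> dict[int, dict]:
    """Q/q_expected diagnostics across candidate factor counts.

    Helper for choosing p: returns ``{p: {"Q": ..., "q_expected": ...,
    "ratio": ..., "converged": ...}}``.  Ratios near 1 indicate a factor
    count consistent with the stated uncertainties.
    """
    out: dict[int, dict] = {}
    for p in p_values:
        sol = fit_pmf(X, U, PMFConfig(p=p, n_starts=n_starts, seed=seed, **kw))
        out[p] = {
            "Q": sol.Q,
            "q_expected": sol.q_expected,
            "ratio": sol.Q / sol.q_expected if sol.q_expected > 0 else float("nan"),
            "converged": sol.converged,
        }
    return out
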
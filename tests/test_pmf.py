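import numpy as np
import pytest
from sklearn.base import clone
from sklearn.decomposition import NMF

from ptesr.data import substitute_censored
from ptesr.pmf import (
    PMFConfig,
    WeightedPMF,
    build_uncertainty,
    factor_summaries,
    fit_pmf,
    match_factors,
    scan_p,
)
from ptesr.synthetic import SyntheticSpec, generate


class TestBuildUncertainty:
    def test_below_mdl_branch(self, small_table):
        # Hg at s1 is censored (working value MDL/2) -> (5/6)*MDL
        u = build_uncertainty(small_table)
        j = small_table.analyte_names.index("Hg")
        assert u[0, j] == pytest.approx((5.0 / 6.0) * 0.04, rel=1e-12)

    def test_above_mdl_branch_direct_substitution(self, small_table):
        # Fe at s1: x=120, MDL=10, EF=0.1 -> sqrt(12^2 + 5^2) = 13
        u = build_uncertainty(small_table)
        assert u[0, 0] == pytest.approx(np.sqrt(12.0**2 + 5.0**2), rel=1e-12)

    def test_x_exactly_at_mdl_uses_below_branch(self):
        import pandas as pd

        from ptesr.data import AnalyteSpec, ConcentrationTable

        ids = pd.Index(["a", "b"], name="sample_id")
        t = ConcentrationTable(
            values=pd.DataFrame({"Fe": [10.0, 20.0]}, index=ids),
            censored=pd.DataFrame(False, index=ids, columns=["Fe"]),
            meta=pd.DataFrame({"water_type": "surface"}, index=ids),
            analytes=[AnalyteSpec("Fe", mdl=10.0, error_fraction=0.1)],
        )
        u = build_uncertainty(t)
        assert u[0, 0] == pytest.approx((5.0 / 6.0) * 10.0, rel=1e-12)

    def test_all_entries_positive(self, worked):
        u = build_uncertainty(worked["table"])
        assert (u > 0).all()


class TestFitBasics:
    def test_noiseless_data_reaches_zero_q(self):
        rng = np.random.default_rng(0)
        G0 = rng.uniform(0, 1, (10, 2))
        F0 = rng.uniform(0, 1, (2, 6))
        X = G0 @ F0
        sol = fit_pmf(X, np.ones_like(X), PMFConfig(p=2, n_starts=20, seed=1))
        assert sol.Q <= 1e-6
        assert sol.converged

    def test_deterministic_given_seed(self, rank1_case):
        X, U = rank1_case
        cfg = PMFConfig(p=1, n_starts=3, seed=42)
        a = fit_pmf(X, U, cfg)
        b = fit_pmf(X, U, cfg)
        assert a.Q == b.Q
        np.testing.assert_array_equal(a.G, b.G)
        np.testing.assert_array_equal(a.F, b.F)

    def test_solution_invariants(self, rank1_case):
        X, U = rank1_case
        sol = fit_pmf(X, U, PMFConfig(p=2, n_starts=5, seed=0))
        assert (sol.G >= 0).all() and (sol.F >= 0).all()
        np.testing.assert_allclose(sol.E, X - sol.G @ sol.F, atol=1e-12)
        q_recomputed = (((X - sol.G @ sol.F) / U) ** 2).sum()
        assert sol.Q == pytest.approx(q_recomputed, rel=1e-8)
        assert sol.q_expected == X.size - 2 * sum(X.shape)
        # G columns renormalized to mean 1
        np.testing.assert_allclose(sol.G.mean(axis=0), 1.0, rtol=1e-9)
        assert sol.factor_percent.sum() == pytest.approx(100.0, abs=1e-6)

    def test_monotone_q_trajectory(self, rank1_case):
        X, U = rank1_case
        est = WeightedPMF(n_components=2, n_starts=3, random_state=0).fit(
            X, uncertainty=U
        )
        traj = est.q_trajectory_
        assert (np.diff(traj) <= 1e-9 * traj[:-1] + 1e-12).all()

    def test_q_invariant_under_permutation_and_scaling(self, rank1_case):
        X, U = rank1_case
        sol = fit_pmf(X, U, PMFConfig(p=2, n_starts=3, seed=1))

        def q(G, F):
            return (((X - G @ F) / U) ** 2).sum()

        perm = [1, 0]
        assert q(sol.G[:, perm], sol.F[perm, :]) == pytest.approx(sol.Q, rel=1e-10)
        d = np.array([3.0, 0.25])
        assert q(sol.G * d[None, :], sol.F / d[:, None]) == pytest.approx(
            sol.Q, rel=1e-10
        )

    @pytest.mark.parametrize("p", [0, 3, 10])
    def test_p_out_of_bounds_rejected(self, rank1_case, p):
        X, U = rank1_case  # min(n,m)-1 = 2
        with pytest.raises(ValueError):
            fit_pmf(X, U, PMFConfig(p=p, n_starts=1))

    def test_nonfinite_input_rejected(self, rank1_case):
        X, U = rank1_case
        bad = X.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_pmf(bad, U, PMFConfig(p=1))

    def test_unweighted_fit_not_worse_than_sklearn_nmf(self):
        # with unit uncertainties Q is the plain squared Frobenius error,
        # so sklearn's NMF provides an independent ceiling
        rng = np.random.default_rng(5)
        X = rng.gamma(2.0, 1.0, size=(15, 8))
        sol = fit_pmf(X, np.ones_like(X), PMFConfig(p=3, n_starts=10, seed=5))
        ref = NMF(n_components=3, init="nndsvda", max_iter=2000, tol=1e-10,
                  random_state=0).fit(X)
        q_ref = np.linalg.norm(X - ref.transform(X) @ ref.components_) ** 2
        assert sol.Q <= q_ref * 1.01


class TestRobustMode:
    def test_outlier_distorts_robust_fit_less(self):
        # one wild cell: the robust fit should track the clean structure
        # more closely than the plain fit on the uncontaminated cells
        rng = np.random.default_rng(8)
        g0 = rng.uniform(0.5, 1.5, 10)
        f0 = rng.uniform(0.5, 1.5, 6)
        X = np.outer(g0, f0)  # rank 1, so a wild cell cannot be absorbed
        Xc = X.copy()
        Xc[0, 0] *= 30.0
        U = 0.1 * X + 0.01
        clean_mask = np.ones_like(X, dtype=bool)
        clean_mask[0, 0] = False

        def clean_error(sol):
            E = Xc - sol.G @ sol.F
            return np.abs(E[clean_mask] / U[clean_mask]).mean()

        plain = fit_pmf(Xc, U, PMFConfig(p=1, n_starts=5, seed=8))
        robust = fit_pmf(Xc, U, PMFConfig(p=1, n_starts=5, seed=8, robust=True))
        assert clean_error(robust) < 0.5 * clean_error(plain)

    def test_robust_matches_plain_without_outliers(self):
        rng = np.random.default_rng(4)
        G0 = rng.uniform(0.5, 1.5, (10, 2))
        F0 = rng.uniform(0.5, 1.5, (2, 5))
        X = G0 @ F0  # exactly factorizable: no residual exceeds the cutoff
        plain = fit_pmf(X, np.ones_like(X), PMFConfig(p=2, n_starts=5, seed=4))
        robust = fit_pmf(X, np.ones_like(X),
                         PMFConfig(p=2, n_starts=5, seed=4, robust=True))
        assert robust.Q == pytest.approx(plain.Q, abs=1e-8)


class TestEstimatorAPI:
    def test_get_params_and_clone(self):
        est = WeightedPMF(n_components=3, n_starts=7, random_state=9)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_transform_recovers_training_contributions(self):
        rng = np.random.default_rng(2)
        G0 = rng.uniform(0.1, 1, (12, 2))
        F0 = rng.uniform(0.1, 1, (2, 5))
        X = G0 @ F0
        est = WeightedPMF(n_components=2, n_starts=10, random_state=3).fit(X)
        G = est.transform(X)
        np.testing.assert_allclose(G @ est.components_, X, atol=1e-5)

    def test_inverse_transform_shape(self):
        X = np.random.default_rng(1).uniform(0.1, 1, (8, 4))
        est = WeightedPMF(n_components=2, n_starts=3, random_state=0).fit(X)
        assert est.inverse_transform(est.contributions_).shape == X.shape


class TestFactorSummaries:
    def test_single_factor_all_100(self):
        G = np.array([[1.0], [2.0]])
        F = np.array([[3.0, 4.0]])
        fp, pp = factor_summaries(G, F)
        np.testing.assert_allclose(fp, [100.0])
        np.testing.assert_allclose(pp, [[100.0, 100.0]])

    def test_identical_factors_split_evenly(self):
        G = np.tile(np.array([[1.0], [2.0]]), (1, 2))
        F = np.tile(np.array([[3.0, 4.0]]), (2, 1))
        fp, pp = factor_summaries(G, F)
        np.testing.assert_allclose(fp, [50.0, 50.0])
        np.testing.assert_allclose(pp.sum(axis=0), [100.0, 100.0])

    def test_hand_computed_2x2x2(self):
        G = np.array([[1.0, 0.0], [1.0, 2.0]])
        F = np.array([[1.0, 1.0], [0.0, 3.0]])
        # mass_k = (sum_i G_ik)(sum_j F_kj): factor1 = 2*2=4, factor2 = 2*3=6
        fp, pp = factor_summaries(G, F)
        np.testing.assert_allclose(fp, [40.0, 60.0])
        np.testing.assert_allclose(pp, [[100.0, 25.0], [0.0, 75.0]])

    def test_zero_reconstruction_rejected(self):
        with pytest.raises(ValueError):
            factor_summaries(np.zeros((2, 2)), np.zeros((2, 3)))


class TestMatchFactors:
    def test_swapped_rows_recovered(self):
        F = np.array([[1.0, 0.0, 2.0], [0.0, 3.0, 1.0]])
        perm, cos = match_factors(F[[1, 0], :], F)
        assert perm == (1, 0)
        assert cos == pytest.approx(1.0)

    def test_scale_invariance(self):
        F = np.array([[1.0, 2.0], [3.0, 0.5], [0.1, 4.0]])
        perm, cos = match_factors(3.0 * F, F)
        assert perm == (0, 1, 2)
        assert cos == pytest.approx(1.0)

    def test_orthogonal_rows_beat_all_other_permutations(self):
        F = np.eye(4)
        shuffled = F[[2, 0, 3, 1], :]
        perm, cos = match_factors(shuffled, F)
        assert cos == pytest.approx(1.0)
        # brute force: every non-optimal permutation scores strictly lower
        import itertools

        for other in itertools.permutations(range(4)):
            if other == perm:
                continue
            score = np.mean([shuffled[other[k]] @ F[k] for k in range(4)])
            assert score < cos

    def test_p_above_8_rejected(self):
        F = np.eye(9)
        with pytest.raises(ValueError):
            match_factors(F, F)


class TestModelAdequacy:
    def test_q_ratio_near_one_when_uncertainty_matches_noise(self):
        # matched conditions: negligible detection limits so u ≈ EF·x equals
        # the generator's multiplicative noise scale
        spec = SyntheticSpec(n_ground=0, n_mine=0, seed=11, mdl_quantile=0.0)
        table, _ = generate(spec)
        w = substitute_censored(table)
        sol = fit_pmf(w.matrix(), build_uncertainty(w),
                      PMFConfig(p=4, n_starts=5, seed=11))
        assert 0.5 <= sol.Q / sol.q_expected <= 2.0

    def test_scan_p_reports_decreasing_q(self, worked):
        w = substitute_censored(worked["table"])
        X = w.matrix()
        U = build_uncertainty(w)
        diag = scan_p(X, U, [1, 2], n_starts=2, seed=0)
        assert diag[2]["Q"] <= diag[1]["Q"]
        assert set(diag[1]) == {"Q", "q_expected", "ratio", "converged"}
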
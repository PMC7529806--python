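import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from sklearn.linear_model import Lasso

from vpeca import model as md
from vpeca.io import MotifHitMatrix, SampleDesign
from vpeca.landscape import CandidateMap
from vpeca.model import (
    FEATURE_COLUMNS,
    estimate_selection_status,
    fit_accessibility,
    compute_priors,
    step3_objective,
    stratified_folds,
    tf_feature,
    classify_res,
)


def _features(p0, agg=None, n_snps=1):
    n = len(p0)
    agg = np.zeros((n, 5)) if agg is None else np.asarray(agg)
    df = pd.DataFrame(agg, columns=FEATURE_COLUMNS,
                      index=[f"re{i}" for i in range(n)])
    df.insert(0, "n_snps", n_snps)
    df["p0"] = p0
    return df


def naive_selection_loop(features, tol=1e-6, max_iter=100, clip=1e-6):
    """Straight-line reference implementation of the mu/P iteration."""
    X = np.column_stack([np.ones(len(features)), features[FEATURE_COLUMNS].to_numpy()])
    P = features["p0"].to_numpy(dtype=float).copy()
    mu = np.zeros(X.shape[1])
    for _ in range(max_iter):
        Pc = np.clip(P, clip, 1 - clip)
        z = np.log(Pc / (1 - Pc))
        mu_new = np.linalg.lstsq(X, z, rcond=None)[0]
        P = 1 / (1 + np.exp(-(X @ mu_new)))
        if np.max(np.abs(mu_new - mu)) < tol:
            return mu_new, P
        mu = mu_new
    return mu, P


class TestSelectionStatus:
    def test_degenerate_prior_yields_no_selection(self):
        feats = _features(np.zeros(10))
        fit = estimate_selection_status(feats)
        assert (fit.S == 0).all()
        assert (fit.P_sel < 0.5).all()

    def test_two_group_synthetic_matches_naive_reference(self):
        rng = np.random.default_rng(11)
        n = 60
        high = rng.random(n) < 0.3
        agg = np.where(high[:, None], rng.uniform(2, 4, (n, 5)), rng.uniform(0, 0.5, (n, 5)))
        p0 = np.where(high, 0.99, 0.01)
        feats = _features(p0, agg)
        fit = estimate_selection_status(feats)
        mu_ref, P_ref = naive_selection_loop(feats)
        np.testing.assert_allclose(fit.mu, mu_ref, atol=1e-8)
        np.testing.assert_allclose(fit.P_sel.to_numpy(), P_ref, atol=1e-8)
        assert fit.converged
        assert set(fit.S[fit.S == 1].index) == set(feats.index[high])

    def test_threshold_is_strictly_greater(self):
        # identical features with p0 = 0.95 converge to P exactly 0.95,
        # which must NOT be selected (strict inequality)
        fit = estimate_selection_status(_features([0.95] * 5))
        np.testing.assert_allclose(fit.P_sel.to_numpy(), 0.95, rtol=1e-6)
        assert (fit.P_sel <= 0.95).all()
        assert (fit.S == 0).all()

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        agg = rng.uniform(0, 3, (20, 5))
        p0 = rng.uniform(0.01, 0.99, 20)
        feats = _features(p0, agg)
        fit1 = estimate_selection_status(feats)
        fit2 = estimate_selection_status(feats.iloc[::-1])
        np.testing.assert_allclose(fit1.mu, fit2.mu, atol=1e-10)
        pd.testing.assert_series_equal(fit1.P_sel.sort_index(), fit2.P_sel.sort_index())

    def test_snp_free_res_excluded_but_reported(self):
        feats = _features([0.9, 0.9, 0.1], agg=np.ones((3, 5)))
        feats.loc["re2", "n_snps"] = 0
        fit = estimate_selection_status(feats)
        assert fit.P_sel["re2"] == 0.0 and fit.S["re2"] == 0

    def test_too_few_res_rejected(self):
        with pytest.raises(ValueError):
            estimate_selection_status(_features([0.5]))


def _acc_design(n_rep=5):
    rows = []
    for pop, tag in (("adaptive", "A"), ("wildtype", "W")):
        for i in range(1, n_rep + 1):
            for t in ("0h", "6h", "1d", "3d", "5d"):
                rows.append((f"{tag}{i}_{t}", f"{tag}{i}", t, pop))
    return SampleDesign(pd.DataFrame(rows, columns=["sample_id", "individual", "time", "population"]))


class TestAccessibility:
    def test_unselected_re_reduces_to_group_mean(self):
        design = _acc_design()
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.uniform(1, 3, (3, 50)),
                            index=["a", "b", "c"], columns=design.sample_ids)
        acc = fit_accessibility(vals, design, pd.Series(0, index=["a", "b", "c"]))
        assert (acc.omega.to_numpy() == 0).all()
        assert (acc.omega_p.to_numpy() == 1).all()
        for t in acc.eta.index:
            cols = design.samples_at(t)["sample_id"]
            np.testing.assert_allclose(acc.eta.loc[t], vals[cols].mean(axis=1))

    def test_noiseless_exact_recovery(self):
        design = _acc_design()
        delta = design.delta
        vals = pd.DataFrame([2.0 + 1.0 * delta], index=["a"], columns=design.sample_ids)
        acc = fit_accessibility(vals, design, pd.Series(1, index=["a"]))
        np.testing.assert_allclose(acc.eta["a"], 2.0, atol=1e-12)
        np.testing.assert_allclose(acc.omega["a"], 1.0, atol=1e-12)
        assert (acc.omega_p["a"] < 1e-10).all()

    def test_matches_normal_equations_oracle(self):
        design = _acc_design()
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(
            2.0 + 1.0 * design.delta + rng.normal(0, 0.1, (4, 50)),
            index=list("abcd"), columns=design.sample_ids,
        )
        acc = fit_accessibility(vals, design, pd.Series(1, index=list("abcd")))
        rss = np.zeros(4)
        for t in acc.eta.index:
            sub = design.samples_at(t)
            X = np.column_stack([np.ones(len(sub)), (sub["population"] == "adaptive").astype(float)])
            beta = np.linalg.solve(X.T @ X, X.T @ vals[sub["sample_id"]].to_numpy().T)
            np.testing.assert_allclose(acc.eta.loc[t].to_numpy(), beta[0], atol=1e-10)
            np.testing.assert_allclose(acc.omega.loc[t].to_numpy(), beta[1], atol=1e-10)
            resid = vals[sub["sample_id"]].to_numpy().T - X @ beta
            rss += (resid**2).sum(axis=0)
        np.testing.assert_allclose(acc.sigma2_o.to_numpy(), rss / (50 - 10), atol=1e-12)

    def test_missing_population_flags_omega_untested(self):
        design = _acc_design(n_rep=2)
        keep = ~((design.table["time"] == "6h") & (design.table["population"] == "adaptive"))
        design = SampleDesign(design.table[keep])
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.uniform(1, 2, (2, keep.sum())),
                            index=["a", "b"], columns=design.sample_ids)
        acc = fit_accessibility(vals, design, pd.Series(1, index=["a", "b"]))
        assert (acc.omega.loc["6h"] == 0).all()
        assert (acc.omega_p.loc["6h"] == 1).all()


class TestPriors:
    def _cmap(self, genes, res):
        return CandidateMap({g: (0, 1) for g in genes},
                            {g: list(res) for g in genes},
                            {g: res[0] for g in genes})

    def test_identical_profiles_give_unit_correlation(self):
        ctx = [f"c{i}" for i in range(10)]
        prof = np.arange(10, dtype=float)
        pe = pd.DataFrame([prof], index=["G1"], columns=ctx)
        po = pd.DataFrame([prof], index=["R1"], columns=ctx)
        beta0, gamma0, flat = compute_priors(pe, po, self._cmap(["G1"], ["R1"]), tfs=[])
        assert beta0.loc["R1", "G1"] == pytest.approx(1.0)

    def test_constant_row_flagged_zero(self):
        ctx = [f"c{i}" for i in range(5)]
        pe = pd.DataFrame([np.arange(5.0)], index=["G1"], columns=ctx)
        po = pd.DataFrame([np.ones(5)], index=["R1"], columns=ctx)
        beta0, _, flat = compute_priors(pe, po, self._cmap(["G1"], ["R1"]), tfs=[])
        assert beta0.loc["R1", "G1"] == 0.0
        assert "R1" in flat

    def test_too_few_contexts_rejected(self):
        ctx = ["c0", "c1"]
        pe = pd.DataFrame([[1.0, 2.0]], index=["G1"], columns=ctx)
        po = pd.DataFrame([[1.0, 2.0]], index=["R1"], columns=ctx)
        with pytest.raises(ValueError):
            compute_priors(pe, po, self._cmap(["G1"], ["R1"]), tfs=[])

    def test_independent_noise_priors_are_small(self):
        rng = np.random.default_rng(9)
        ctx = [f"c{i}" for i in range(200)]
        pe = pd.DataFrame(rng.normal(size=(20, 200)),
                          index=[f"G{i}" for i in range(20)], columns=ctx)
        po = pd.DataFrame(rng.normal(size=(30, 200)),
                          index=[f"R{i}" for i in range(30)], columns=ctx)
        cmap = self._cmap([f"G{i}" for i in range(20)], [f"R{i}" for i in range(30)])
        beta0, _, _ = compute_priors(pe, po, cmap, tfs=[])
        # null Pearson over 200 contexts: |r| < 0.25 is a ~3.5 sigma event
        assert (np.abs(beta0.to_numpy()) < 0.25).mean() > 0.99


class TestTfFeature:
    def test_empty_motif_set_gives_zero(self):
        B = MotifHitMatrix(pd.DataFrame(0.0, index=["r1"], columns=["T1", "T2"]))
        tf_expr = pd.DataFrame(np.ones((2, 4)), index=["T1", "T2"])
        gamma = pd.Series([1.0, 1.0], index=["T1", "T2"])
        np.testing.assert_allclose(tf_feature(B, tf_expr, gamma, "r1"), 0.0)

    def test_single_tf_arithmetic(self):
        B = MotifHitMatrix(pd.DataFrame([[2.0]], index=["r1"], columns=["T1"]))
        tf_expr = pd.DataFrame([[3.0, 3.0]], index=["T1"])
        gamma = pd.Series([1.0], index=["T1"])
        np.testing.assert_allclose(tf_feature(B, tf_expr, gamma, "r1"), 6.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        tfs = [f"T{m}" for m in range(6)]
        B = MotifHitMatrix(pd.DataFrame(rng.uniform(0, 2, (3, 6)),
                                        index=["r0", "r1", "r2"], columns=tfs))
        tf_expr = pd.DataFrame(rng.uniform(0, 5, (6, 8)), index=tfs)
        gamma = pd.Series(rng.normal(size=6), index=tfs)
        got = tf_feature(B, tf_expr, gamma, "r1")
        expected = np.zeros(8)
        for s in range(8):
            for m, tf in enumerate(tfs):
                expected[s] += gamma[tf] * B.B.loc["r1", tf] * tf_expr.loc[tf].iloc[s]
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestLassoSolver:
    def test_soft_threshold_closed_form_on_orthonormal_design(self):
        rng = np.random.default_rng(21)
        n, p = 40, 5
        # columns orthogonal to each other and to the ones vector, scaled
        # to sd exactly 1, so standardisation is the identity
        G = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        Q, _ = np.linalg.qr(G)
        X = Q[:, 1 : p + 1] * np.sqrt(n)
        beta = np.array([2.0, -1.5, 0.0, 0.0, 0.6])
        y = X @ beta + rng.normal(0, 0.3, n)
        groups = np.repeat(np.arange(5), 8)
        folds = stratified_folds(groups, 5, 0)
        coef, icept, lam = md._lasso_cv(X, y, folds, seed=0)
        # closed form for sklearn's (1/2n)||.||^2 + lam||.||_1 at X'X = nI
        xty = X.T @ (y - y.mean()) / n
        expect = np.sign(xty) * np.maximum(np.abs(xty) - lam, 0.0)
        sd = X.std(axis=0)
        np.testing.assert_allclose(coef * sd, expect, atol=1e-6)

    def test_matches_split_variable_qp_oracle(self):
        rng = np.random.default_rng(13)
        n, p = 30, 6
        X = rng.normal(size=(n, p))
        y = X @ np.array([1.5, 0, -2.0, 0, 0.8, 0]) + rng.normal(0, 0.5, n)
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        lam = 0.1
        skl = Lasso(alpha=lam, max_iter=100000, tol=1e-12).fit(Xs, y)

        def obj(z):
            b = z[:p] - z[p:]
            r = yc - Xs @ b
            return (r @ r) / (2 * n) + lam * z.sum()

        res = optimize.minimize(obj, np.zeros(2 * p), bounds=[(0, None)] * 2 * p,
                                method="L-BFGS-B", options={"maxiter": 20000, "ftol": 1e-16})
        oracle = res.x[:p] - res.x[p:]
        np.testing.assert_allclose(skl.coef_, oracle, atol=1e-4)


class TestStep3Objective:
    def _instance(self, seed=0, n_re=3, n_tf=4, n=20, mask=None):
        rng = np.random.default_rng(seed)
        tg = rng.normal(5, 2, n)
        O = rng.uniform(1, 3, (n_re, n))
        B = rng.uniform(0, 2, (n_re, n_tf))
        TF = rng.uniform(0, 4, (n_tf, n))
        delta = (np.arange(n) < n // 2).astype(float)
        S = np.ones(n_re)
        dS = np.outer(S, delta)
        alpha_mask = np.array([True, False, True])[:n_re] if mask is None else mask
        beta0 = rng.normal(size=n_re)
        gamma0 = rng.normal(size=n_tf)
        theta = rng.normal(size=1 + n_re + n_tf + int(alpha_mask.sum()))
        args = (tg, O, B, TF, dS, alpha_mask, beta0, gamma0, 1.0)
        return theta, args

    def test_gradient_matches_central_differences(self):
        for seed in range(10):
            theta, args = self._instance(seed)
            _, g = step3_objective(theta, *args)
            num = np.empty_like(theta)
            h = 1e-6
            for j in range(len(theta)):
                up, dn = theta.copy(), theta.copy()
                up[j] += h
                dn[j] -= h
                num[j] = (step3_objective(up, *args)[0] - step3_objective(dn, *args)[0]) / (2 * h)
            denom = np.maximum(np.abs(g), 1.0)
            assert np.max(np.abs(g - num) / denom) < 1e-5

    def test_reduces_to_ols_without_priors(self):
        # prior_scale = 0, gamma fixed, no free alpha: the optimum over
        # (b0, beta) is ordinary least squares on the composite features
        theta, args = self._instance(3, mask=np.zeros(3, dtype=bool))
        tg, O, B, TF, dS, alpha_mask, beta0, gamma0, _ = args
        gamma = np.array([0.5, 1.0, -0.3, 0.2])
        F = (B * gamma[None, :]) @ TF
        feats = O * F
        X = np.column_stack([np.ones(len(tg)), feats.T])
        ols = np.linalg.lstsq(X, tg, rcond=None)[0]
        theta_star = np.concatenate([[ols[0]], ols[1:], gamma])
        _, g = step3_objective(theta_star, tg, O, B, TF, dS, alpha_mask,
                               np.zeros(3), np.zeros(4), 0.0)
        np.testing.assert_allclose(g[:4], 0.0, atol=1e-8)


class TestClassification:
    def _selection(self, p):
        P = pd.Series(p)
        return md.SelectionFit(np.zeros(6), P, (P > 0.95).astype(int), 1, True, 0.95)

    def _fit(self, gene, beta, alpha):
        idx = list(beta)
        z = pd.DataFrame(0.0, index=idx, columns=["s"])
        return md.ExpressionFit(gene, 0.0, pd.Series(beta), pd.Series({"T": 1.0}),
                                pd.Series(alpha), 1.0, 0.1, 0.1, z,
                                pd.Series(0.0, index=idx), pd.Series({"T": 0.0}), "ok")

    def test_threshold_rule_for_asre(self):
        selection = self._selection({"r1": 0.99, "r2": 0.80, "r3": 0.2})
        fits = {
            "g1": self._fit("g1", {"r1": 1.2, "r2": 0.7}, {"r1": 0.5, "r2": 0.0}),
            "g2": self._fit("g2", {"r3": 0.0}, {"r3": 0.0}),
        }
        cls = classify_res(fits, selection)
        assert cls.re_class["r1"] == "ASRE"   # P>0.95, alpha!=0, beta!=0
        assert cls.re_class["r2"] == "ARE"    # active but P below threshold
        assert cls.re_class["r3"] == "inactive"
        assert set(cls.gene_res["g1"]["ASRE"]) == {"r1"}

    def test_asre_subset_of_are_and_idempotent(self, default_study, default_result):
        cls = default_result.classes
        assert set(cls.asre) <= set(cls.are)
        again = classify_res(default_result.fits, default_result.selection,
                             default_result.accessibility)
        pd.testing.assert_series_equal(again.re_class, cls.re_class)

    def test_selection_indicator_matches_strict_threshold(self, default_result):
        selfit = default_result.selection
        expected = (selfit.P_sel > 0.95).astype(int)
        pd.testing.assert_series_equal(selfit.S, expected, check_names=False)
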
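"""The statistical core: selection status, accessibility, and expression models.

Three conditionally independent pieces are estimated in sequence.

1. *Selection status.*  Each RE's latent selection indicator S_k follows a
   logistic model on LD-weighted aggregated selection scores.  Starting
   from the prior p0_k = 1 - mean combined p-value of the RE's SNPs, the
   coefficients mu and the probabilities P(S_k = 1) are updated by
   iterated least squares on the logit scale until mu stabilises; S_k = 1
   where the converged probability strictly exceeds 0.95.

2. *Accessibility.*  Openness obeys O_{ijk} = eta_{jk} + omega_{jk}
   delta_i S_k + eps, eps ~ N(0, sigma_ok^2).  Per (RE, time) the
   intercept and population shift are ordinary least squares; the error
   variance is indexed by RE only, so residuals pool across time points
   and the t-test on omega uses the pooled degrees of freedom.

3. *Expression.*  TG = b0 + sum_k beta_k Z_k (sum_m gamma_m B_km TF_m) + eps
   with plug-in activity Z_k = O_k + alpha_k delta S_k.  Per gene: step 1
   is an L1 fit of beta at gamma = gamma0 (cross-validated penalty);
   step 2 an L1 fit of gamma at the step-1 beta; step 3 a quasi-Newton
   refinement of (b0, beta, gamma, alpha) on the survivors with linear
   correlation-prior rewards and ridge terms on beta and gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.linear_model import Lasso, LassoCV

from .io import MotifHitMatrix, OpennessMatrix, SampleDesign
from .landscape import CandidateMap

NONZERO_TOL = 1e-8
LOGIT_CLIP = 1e-6

FEATURE_COLUMNS = ["agg_fst", "agg_ihs", "agg_xpehh", "agg_pbs", "agg_y"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Selection status
# ---------------------------------------------------------------------------

@dataclass
class SelectionFit:
    mu: np.ndarray  # intercept, 4 score terms, dDAF term
    P_sel: pd.Series  # per RE, 0 for SNP-free REs
    S: pd.Series  # binary, strict threshold
    n_iter: int
    converged: bool
    threshold: float


def estimate_selection_status(
    features: pd.DataFrame,
    threshold: float = 0.95,
    tol: float = 1e-6,
    max_iter: int = 100,
    clip: float = LOGIT_CLIP,
) -> SelectionFit:
    """Iterated least squares for the logistic selection-status model.

    ``features`` is the output of
    :func:`vpeca.selection.aggregate_re_features`.  REs without SNPs are
    excluded from the regression and reported with P = 0, S = 0.
    """
    has_snps = features["n_snps"] > 0
    sub = features[has_snps]
    if len(sub) < 2:
        raise ValueError("need at least 2 REs with SNPs to fit the selection model")
    X = np.column_stack([np.ones(len(sub)), sub[FEATURE_COLUMNS].to_numpy(dtype=float)])
    if not np.isfinite(X).all():
        raise ValueError("non-finite selection features")
    P = sub["p0"].to_numpy(dtype=float)

    mu = np.zeros(X.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        z = np.log(np.clip(P, clip, 1 - clip) / (1 - np.clip(P, clip, 1 - clip)))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn("rank-deficient selection design; ridge fallback (1e-8)")
            mu_new = np.linalg.solve(X.T @ X + 1e-8 * np.eye(X.shape[1]), X.T @ z)
        else:
            mu_new, *_ = np.linalg.lstsq(X, z, rcond=None)
        P = _sigmoid(X @ mu_new)
        if np.max(np.abs(mu_new - mu)) < tol:
            mu = mu_new
            converged = True
            break
        mu = mu_new
    if not converged:
        warnings.warn("selection-status loop did not converge; returning last fit")

    P_full = pd.Series(0.0, index=features.index)
    P_full[sub.index] = P
    S = (P_full > threshold).astype(int)
    return SelectionFit(mu, P_full, S, n_iter, converged, threshold)


# ---------------------------------------------------------------------------
# Accessibility
# ---------------------------------------------------------------------------

@dataclass
class AccessibilityFit:
    eta: pd.DataFrame  # time x RE baseline openness
    omega: pd.DataFrame  # time x RE population shift (0 where S = 0)
    omega_p: pd.DataFrame  # two-sided t-test p on omega (1 where untested)
    sigma2_o: pd.Series  # per-RE pooled residual variance
    df: pd.Series  # pooled residual degrees of freedom
    omega_flag: pd.DataFrame  # p < alpha and S = 1

    def flag_by_re(self) -> pd.Series:
        return self.omega_flag.any(axis=0)


def fit_accessibility(
    openness: OpennessMatrix | pd.DataFrame,
    design: SampleDesign,
    S: pd.Series,
    alpha: float = 0.05,
) -> AccessibilityFit:
    """Least-squares fit of the per-(RE, time) accessibility model.

    For selected REs, openness at each time regresses on the population
    indicator; for unselected REs omega is fixed at 0 and eta is the
    within-time mean.  The error variance pools residuals across the five
    time points within an RE (the model's variance is RE-indexed), and the
    omega t-test uses those pooled degrees of freedom.  Time points
    missing one population leave omega undefined (NaN, flagged untested).
    """
    values = openness.values if isinstance(openness, OpennessMatrix) else openness
    values = values[design.sample_ids]
    res = values.index
    s = S.reindex(res).fillna(0).to_numpy(dtype=int)
    times = [t for t in design.table["time"].unique()]

    eta = pd.DataFrame(index=times, columns=res, dtype=float)
    omega = pd.DataFrame(0.0, index=times, columns=res)
    tstat = pd.DataFrame(np.nan, index=times, columns=res)
    rss = np.zeros(len(res))
    dfree = np.zeros(len(res))
    se_factor = pd.Series(np.nan, index=times, dtype=float)

    for t in times:
        cols = design.samples_at(t)["sample_id"].tolist()
        d = (design.samples_at(t)["population"].to_numpy() == "adaptive").astype(float)
        O = values[cols].to_numpy(dtype=float)  # REs x samples at this time
        n = len(cols)
        n_a, n_w = d.sum(), n - d.sum()
        mean_o = O.mean(axis=1)
        if n_a > 0 and n_w > 0:
            dc = d - d.mean()
            slope = (O @ dc) / (dc @ dc)
            se_factor[t] = np.sqrt(1.0 / n_a + 1.0 / n_w)
        else:
            slope = np.full(len(res), np.nan)
        use_slope = (s == 1) & np.isfinite(slope)
        w = np.where(use_slope, slope, 0.0)
        icept = mean_o - w * d.mean()
        resid = O - icept[:, None] - np.outer(w, d)
        rss += (resid**2).sum(axis=1)
        dfree += np.where(use_slope, n - 2, n - 1)
        eta.loc[t] = icept
        omega.loc[t] = np.where(use_slope, slope, 0.0)
        tstat.loc[t] = np.where(use_slope, slope, np.nan)  # scaled below

    sigma2 = pd.Series(np.where(dfree > 0, rss / np.maximum(dfree, 1), np.nan), index=res)
    pvals = pd.DataFrame(1.0, index=times, columns=res)
    for t in times:
        tested = (tstat.loc[t].notna() & sigma2.notna()).to_numpy()
        if tested.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                tv = tstat.loc[t].to_numpy()[tested] / (np.sqrt(sigma2.to_numpy()[tested]) * se_factor[t])
            tv = np.where(np.isnan(tv), 0.0, tv)  # omega = 0 with zero variance
            pvals.loc[t, tested] = 2 * stats.t.sf(np.abs(tv), dfree[tested])
    flag = (pvals < alpha) & (pd.DataFrame(np.broadcast_to(s == 1, pvals.shape), index=times, columns=res))
    return AccessibilityFit(eta, omega, pvals, sigma2, pd.Series(dfree, index=res), flag)


# ---------------------------------------------------------------------------
# Cross-context priors
# ---------------------------------------------------------------------------

def _row_corr(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between every row of ``a`` and every row of ``b``."""
    n = a.shape[1]
    az = a.to_numpy(dtype=float)
    bz = b.to_numpy(dtype=float)
    a_sd = az.std(axis=1)
    b_sd = bz.std(axis=1)
    flat = [*a.index[a_sd == 0], *b.index[b_sd == 0]]
    az = (az - az.mean(axis=1, keepdims=True)) / np.where(a_sd == 0, 1, a_sd)[:, None]
    bz = (bz - bz.mean(axis=1, keepdims=True)) / np.where(b_sd == 0, 1, b_sd)[:, None]
    corr = az @ bz.T / n
    corr[a_sd == 0, :] = 0.0
    corr[:, b_sd == 0] = 0.0
    return pd.DataFrame(corr, index=a.index, columns=b.index), flat


def compute_priors(
    panel_expression: pd.DataFrame,
    panel_openness: pd.DataFrame,
    cmap: CandidateMap,
    tfs: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Cross-context correlation priors beta0 (RE x gene) and gamma0 (TF x gene).

    Correlations are Pearson, across the shared context columns of the
    panel matrices (>= 3 contexts required).  Constant rows yield a prior
    of 0 and are reported in the flagged-id list.
    """
    contexts = [c for c in panel_openness.columns if c in set(panel_expression.columns)]
    if len(contexts) < 3:
        raise ValueError("need at least 3 shared panel contexts for priors")
    genes = [g for g in cmap.genes() if g in panel_expression.index]
    expr = panel_expression.loc[genes, contexts]
    beta0, flat_b = _row_corr(panel_openness[contexts], expr)
    tf_rows = [m for m in tfs if m in panel_expression.index]
    gamma0, flat_g = _row_corr(panel_expression.loc[tf_rows, contexts], expr)
    return beta0, gamma0, sorted(set(flat_b) | set(flat_g))


# ---------------------------------------------------------------------------
# Expression model
# ---------------------------------------------------------------------------

def tf_feature(
    B: MotifHitMatrix,
    tf_expr: pd.DataFrame,
    gamma: pd.Series,
    re_id: str,
) -> np.ndarray:
    """Motif-weighted TF activity at one RE: sum_m gamma_m B[k,m] TF_m per sample."""
    tfs = [m for m in B.tfs if m in gamma.index and m in tf_expr.index]
    if not tfs:
        return np.zeros(tf_expr.shape[1])
    wvec = gamma[tfs].to_numpy() * B.B.loc[re_id, tfs].to_numpy()
    return wvec @ tf_expr.loc[tfs].to_numpy(dtype=float)


def stratified_folds(groups, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic K-fold assignment spreading every replicate group over folds."""
    rng = np.random.default_rng(seed)
    groups = np.asarray(groups)
    fold_of = np.empty(len(groups), dtype=int)
    for g in pd.unique(groups):
        idx = np.nonzero(groups == g)[0]
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % n_folds
    out = []
    all_idx = np.arange(len(groups))
    for f in range(n_folds):
        test = all_idx[fold_of == f]
        if len(test):
            out.append((all_idx[fold_of != f], test))
    return out


def _lasso_cv(X: np.ndarray, y: np.ndarray, folds, seed: int,
              rule: str = "1se") -> tuple[np.ndarray, float, float]:
    """Cross-validated L1 fit on standardised predictors.

    The penalty is chosen over a 40-point path by 5-fold CV; ``rule``
    is ``"1se"`` (largest penalty within one standard error of the CV
    minimum — the parsimonious standard choice) or ``"min"``.  Returns
    coefficients on the original scale, the intercept, and the chosen
    penalty.  Zero-variance columns get coefficient 0.
    """
    sd = X.std(axis=0)
    usable = sd > 0
    if not usable.any():
        return np.zeros(X.shape[1]), float(y.mean()), np.inf
    Xs = (X[:, usable] - X[:, usable].mean(axis=0)) / sd[usable]
    model = LassoCV(cv=folds, alphas=40, max_iter=5000, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, y)
    alpha = float(model.alpha_)
    if rule == "1se":
        mse = model.mse_path_.mean(axis=1)
        se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
        i_min = int(np.argmin(mse))
        ok = np.nonzero(mse <= mse[i_min] + se[i_min])[0]
        alpha = float(model.alphas_[ok.min()])  # alphas_ is decreasing
        refit = Lasso(alpha=alpha, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refit.fit(Xs, y)
        coefs = refit.coef_
    else:
        coefs = model.coef_
    coef = np.zeros(X.shape[1])
    coef[usable] = coefs / sd[usable]
    intercept = float(y.mean() - coef @ X.mean(axis=0))
    return coef, intercept, alpha


@dataclass
class ExpressionFit:
    """Per-gene expression model: supports, effects and plug-in activity."""

    gene: str
    b0: float
    beta: pd.Series  # over I_l; zero off the step-1 support
    gamma: pd.Series  # over candidate TFs; zero off the step-2 support
    alpha: pd.Series  # over I_l; zero where S_k = 0 or off support
    sigma2: float
    lambda_beta: float
    lambda_gamma: float
    Z: pd.DataFrame  # activity O + alpha * delta * S, REs x samples
    beta0: pd.Series
    gamma0: pd.Series
    status: str  # ok | empty | no_tf | fallback

    @property
    def active_res(self) -> list[str]:
        return self.beta.index[self.beta.abs() > NONZERO_TOL].tolist()

    @property
    def active_tfs(self) -> list[str]:
        return self.gamma.index[self.gamma.abs() > NONZERO_TOL].tolist()


def _step3_pack(theta, n_re, n_tf):
    b0 = theta[0]
    beta = theta[1 : 1 + n_re]
    gamma = theta[1 + n_re : 1 + n_re + n_tf]
    alpha_free = theta[1 + n_re + n_tf :]
    return b0, beta, gamma, alpha_free


def step3_objective(
    theta: np.ndarray,
    tg: np.ndarray,
    O: np.ndarray,  # n_re x n_samples
    Bsub: np.ndarray,  # n_re x n_tf
    TF: np.ndarray,  # n_tf x n_samples
    dS: np.ndarray,  # n_re x n_samples: delta_i * S_k
    alpha_mask: np.ndarray,  # bool per RE: alpha is a free parameter
    beta0: np.ndarray,
    gamma0: np.ndarray,
    prior_scale: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Joint objective and analytic gradient for the step-3 refinement.

    0.5 * ||TG - b0 - sum_k beta_k (O_k + alpha_k dS_k) f_k(gamma)||^2
    - s * (beta0.beta + gamma0.gamma) + s/2 * (||beta||^2 + ||gamma||^2),
    with f_k(gamma) = sum_m gamma_m B_km TF_m and alpha fixed at 0 for
    unselected REs.
    """
    n_re, n_tf = Bsub.shape
    b0, beta, gamma, alpha_free = _step3_pack(theta, n_re, n_tf)
    alpha = np.zeros(n_re)
    alpha[alpha_mask] = alpha_free
    F = (Bsub * gamma[None, :]) @ TF  # n_re x n_samples
    Zm = O + alpha[:, None] * dS
    pred = b0 + beta @ (Zm * F)
    r = tg - pred
    s = prior_scale
    obj = 0.5 * float(r @ r) - s * float(beta0 @ beta + gamma0 @ gamma) \
        + 0.5 * s * float(beta @ beta + gamma @ gamma)

    g_b0 = -float(r.sum())
    g_beta = -(Zm * F) @ r - s * beta0 + s * beta
    g_alpha = -(beta[:, None] * dS * F) @ r
    # dpred_s/dgamma_m = sum_k beta_k Z_ks B_km TF_ms
    W = beta[:, None] * Zm  # n_re x n_samples
    g_gamma = -np.einsum("km,ks,ms->m", Bsub, W * r[None, :], TF, optimize=True) - s * gamma0 + s * gamma
    grad = np.concatenate([[g_b0], g_beta, g_gamma, g_alpha[alpha_mask]])
    return obj, grad


def fit_expression_gene(
    gene: str,
    tg: np.ndarray,
    candidates: list[str],
    openness: pd.DataFrame,
    B: MotifHitMatrix,
    tf_expr: pd.DataFrame,
    S: pd.Series,
    delta: np.ndarray,
    beta0: pd.Series | None = None,
    gamma0: pd.Series | None = None,
    folds: int = 5,
    seed: int = 0,
    prior_scale: float = 1.0,
    groups=None,
) -> ExpressionFit:
    """Three-stage estimation of one gene's regulatory model.

    ``groups`` are per-sample condition labels (population, time) for the
    stratified, seed-deterministic CV folds.  Priors default to a neutral
    gamma0 of ones and beta0 of zeros when not supplied.
    """
    candidates = list(candidates)
    n = len(tg)
    if n < folds:
        raise ValueError("fewer samples than CV folds")
    if not candidates:
        raise ValueError(f"gene {gene}: empty candidate RE set")
    if groups is None:
        groups = np.zeros(n, dtype=int)
    fold_splits = stratified_folds(groups, folds, seed)

    tf_all = [m for m in B.tfs if m in tf_expr.index]
    g0 = pd.Series(1.0, index=tf_all) if gamma0 is None else gamma0.reindex(tf_all).fillna(0.0)
    b0_prior = pd.Series(0.0, index=candidates) if beta0 is None else beta0.reindex(candidates).fillna(0.0)
    s_k = S.reindex(candidates).fillna(0).to_numpy(dtype=float)

    O = openness.loc[candidates].to_numpy(dtype=float)
    TFmat = tf_expr.loc[tf_all].to_numpy(dtype=float)
    Ball = B.B.loc[candidates, tf_all].to_numpy(dtype=float)

    def empty(status: str) -> ExpressionFit:
        zb = pd.Series(0.0, index=candidates)
        zg = pd.Series(0.0, index=tf_all)
        return ExpressionFit(gene, float(np.mean(tg)), zb, zg, zb.copy(),
                             float(np.var(tg)), np.inf, np.inf,
                             openness.loc[candidates].copy(), b0_prior, g0, status)

    # --- step 1: L1 in beta at gamma = gamma0, alpha = 0 -------------------
    F0 = (Ball * g0.to_numpy()[None, :]) @ TFmat  # n_re x n_samples
    X1 = (O * F0).T
    coef1, icept1, lam_beta = _lasso_cv(X1, tg, fold_splits, seed)
    surv_re = [k for k, c in zip(candidates, coef1) if abs(c) > NONZERO_TOL]
    if not surv_re:
        return empty("empty")

    re_idx = [candidates.index(k) for k in surv_re]
    Bsub = Ball[re_idx]
    tf_cand = [m for j, m in enumerate(tf_all) if (Bsub[:, j] > 0).any()]
    if not tf_cand:
        return empty("no_tf")
    tf_j = [tf_all.index(m) for m in tf_cand]

    # --- step 2: L1 in gamma at the step-1 beta, alpha = 0 -----------------
    beta1 = coef1[re_idx]
    # predictor for TF m: sum_k beta_k O_k B_km TF_m
    X2 = np.einsum("ks,km,ms->sm", beta1[:, None] * O[re_idx], Bsub[:, tf_j], TFmat[tf_j], optimize=True)
    coef2, icept2, lam_gamma = _lasso_cv(X2, tg, fold_splits, seed + 1)
    surv_tf = [m for m, c in zip(tf_cand, coef2) if abs(c) > NONZERO_TOL]
    if not surv_tf:
        return empty("no_tf")
    tf_j2 = [tf_all.index(m) for m in surv_tf]
    gamma2 = coef2[[tf_cand.index(m) for m in surv_tf]]

    # --- step 3: quasi-Newton joint refinement on the survivors ------------
    dS = np.outer(s_k[re_idx], delta)  # free alpha only where S_k = 1
    alpha_mask = s_k[re_idx] == 1
    theta0 = np.concatenate([[icept2], beta1, gamma2, np.zeros(int(alpha_mask.sum()))])
    args = (
        tg, O[re_idx], Bsub[:, [tf_cand.index(m) for m in surv_tf]], TFmat[tf_j2],
        dS, alpha_mask,
        b0_prior[surv_re].to_numpy(), g0[surv_tf].to_numpy(),
        prior_scale,
    )
    res = optimize.minimize(step3_objective, theta0, args=args, jac=True, method="L-BFGS-B",
                            options={"maxiter": 500})
    status = "ok"
    if not res.success:
        theta = theta0
        status = "fallback"
    else:
        theta = res.x
    b0_hat, beta_hat, gamma_hat, alpha_free = _step3_pack(theta, len(surv_re), len(surv_tf))

    beta_full = pd.Series(0.0, index=candidates)
    beta_full[surv_re] = beta_hat
    gamma_full = pd.Series(0.0, index=tf_all)
    gamma_full[surv_tf] = gamma_hat
    alpha_full = pd.Series(0.0, index=candidates)
    alpha_full[np.array(surv_re)[alpha_mask]] = alpha_free

    Z = openness.loc[candidates].copy()
    Z += np.outer(alpha_full.to_numpy() * s_k, delta)
    Fhat = (B.B.loc[candidates, tf_all].to_numpy() * gamma_full.to_numpy()[None, :]) @ TFmat
    resid = tg - b0_hat - beta_full.to_numpy() @ (Z.to_numpy() * Fhat)
    return ExpressionFit(
        gene, float(b0_hat), beta_full, gamma_full, alpha_full,
        float(resid @ resid / n), lam_beta, lam_gamma, Z, b0_prior, g0, status,
    )


def fit_all_genes(
    expr: pd.DataFrame,
    cmap: CandidateMap,
    openness: pd.DataFrame,
    B: MotifHitMatrix,
    design: SampleDesign,
    S: pd.Series,
    beta0: pd.DataFrame | None = None,
    gamma0: pd.DataFrame | None = None,
    folds: int = 5,
    seed: int = 0,
    prior_scale: float = 1.0,
) -> dict[str, ExpressionFit]:
    """Run the per-gene expression model for every mapped gene."""
    tf_ids = [m for m in B.tfs if m in expr.index]
    tf_expr = expr.loc[tf_ids]
    delta = design.delta
    groups = (design.table["population"] + ":" + design.table["time"]).to_numpy()
    fits: dict[str, ExpressionFit] = {}
    for i, gene in enumerate(cmap.genes()):
        if gene not in expr.index:
            continue
        cand = [k for k in cmap.candidates[gene] if k in openness.index]
        if not cand:
            continue
        fits[gene] = fit_expression_gene(
            gene, expr.loc[gene].to_numpy(dtype=float), cand, openness, B, tf_expr,
            S, delta,
            beta0=beta0[gene] if beta0 is not None and gene in beta0.columns else None,
            gamma0=gamma0[gene] if gamma0 is not None and gene in gamma0.columns else None,
            folds=folds, seed=seed + i, prior_scale=prior_scale, groups=groups,
        )
    return fits


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class ReClassification:
    """ARE / ASRE / inactive status per RE plus per-gene RE lists."""

    re_class: pd.Series  # ARE | ASRE | inactive
    gene_res: dict[str, dict[str, list[str]]]  # gene -> {"ARE": [...], "ASRE": [...]}
    omega_flag: pd.Series  # RE-level differential-accessibility flag

    @property
    def are(self) -> list[str]:
        return self.re_class.index[self.re_class.isin(["ARE", "ASRE"])].tolist()

    @property
    def asre(self) -> list[str]:
        return self.re_class.index[self.re_class == "ASRE"].tolist()


def classify_res(
    fits: dict[str, ExpressionFit],
    selection: SelectionFit,
    accessibility: AccessibilityFit | None = None,
    tol: float = NONZERO_TOL,
) -> ReClassification:
    """Label REs: ARE if beta != 0 in any gene model; ASRE additionally
    requires P(S=1) > 0.95 and alpha != 0 in a model where that beta is
    nonzero.  Idempotent; ASRE is a subset of ARE by construction."""
    res = selection.P_sel.index
    is_are = pd.Series(False, index=res)
    has_alpha = pd.Series(False, index=res)
    gene_res: dict[str, dict[str, list[str]]] = {}
    for gene, fit in fits.items():
        active = fit.beta.abs() > tol
        for k in fit.beta.index[active]:
            if k in is_are.index:
                is_are[k] = True
                if abs(fit.alpha.get(k, 0.0)) > tol:
                    has_alpha[k] = True
    sel = selection.P_sel > selection.threshold
    is_asre = is_are & has_alpha & sel.reindex(res).fillna(False)
    cls = pd.Series("inactive", index=res)
    cls[is_are] = "ARE"
    cls[is_asre] = "ASRE"
    for gene, fit in fits.items():
        active = [k for k in fit.beta.index[fit.beta.abs() > tol] if k in cls.index]
        gene_res[gene] = {
            "ARE": [k for k in active if cls[k] in ("ARE", "ASRE")],
            "ASRE": [k for k in active if cls[k] == "ASRE"],
        }
    oflag = accessibility.flag_by_re().reindex(res).fillna(False) if accessibility is not None \
        else pd.Series(False, index=res)
    return ReClassification(cls, gene_res, oflag)
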
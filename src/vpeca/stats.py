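"""Supporting statistics: enrichment tests, ME scores, differential analysis.

The differential fit is a per-entity ordinary-least-squares linear model

    y ~ 1 + Population + Time + individual

with individuals nested inside populations (one reference individual per
population is dropped to keep the design full rank).  t-tests on a
contrast are followed by Benjamini-Hochberg correction across entities.
Unlike moderated-variance pipelines, variances are per-entity OLS
estimates; with few replicates this costs some power but keeps the test
exact under normality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import SampleDesign, TIME_LEVELS
from .selection import bh_fdr


def hypergeom_enrichment(x: int, M: int, K: int, N: int) -> tuple[float, float]:
    """Over-representation of a K-element gold set in an N-element query.

    Returns the upper tail P(X >= x) for X ~ Hypergeometric(M, K, N) and
    the fold enrichment x / (K N / M).
    """
    if not (0 <= K <= M and 0 <= N <= M):
        raise ValueError("need K, N <= M and all counts non-negative")
    if not 0 <= x <= min(K, N):
        raise ValueError(f"overlap {x} impossible for (M={M}, K={K}, N={N})")
    p_upper = float(sps.hypergeom.sf(x - 1, M, K, N))
    expected = K * N / M
    fold = x / expected if expected > 0 else float("nan")
    return p_upper, fold


def me_score(p: float, fold_change: float, floor: float = 1e-300) -> float:
    """Motif enrichment score sqrt(-log10(p) * fold_change)."""
    if fold_change < 0:
        raise ValueError("fold change must be >= 0")
    if p > 1 or p < 0:
        raise ValueError("p outside [0, 1]")
    if p == 0:
        warnings.warn(f"p = 0 floored at {floor:g}")
        p = floor
    return float(np.sqrt(-np.log10(p) * fold_change))


EXPRESSION_LEVEL_BREAKS = (6.0, 12.0, 30.0, 120.0)  # levels I..V


def expression_level(fpkm) -> np.ndarray:
    """Bin FPKM into the five reporting levels (I..V as 1..5)."""
    return np.digitize(np.asarray(fpkm, dtype=float), EXPRESSION_LEVEL_BREAKS) + 1


def me_level(me, n_levels: int = 7, breaks=None) -> np.ndarray:
    """Bin ME scores into equal-width levels over [0, max observed]."""
    me = np.asarray(me, dtype=float)
    if breaks is None:
        top = me.max() if me.size else 1.0
        top = top if top > 0 else 1.0
        breaks = np.linspace(0, top, n_levels + 1)[1:-1]
    return np.digitize(me, breaks) + 1


def dynamic_tf_filter(
    tf_expr: pd.DataFrame,
    me: pd.DataFrame,
    min_max_fpkm: float = 12.0,
    min_max_me: float = 2.0,
    me_breaks=None,
) -> tuple[list[str], list[str]]:
    """Select expressed, motif-enriched TFs and the dynamic subset.

    ``tf_expr`` and ``me`` are per-TF x per-time-point means.  The long
    list requires max FPKM >= 12 and max ME score >= 2 across time; the
    short list keeps long-list TFs whose expression level or ME level
    changes between time points.
    """
    common = tf_expr.index.intersection(me.index)
    expr = tf_expr.loc[common]
    mescore = me.loc[common]
    long_mask = (expr.max(axis=1) >= min_max_fpkm) & (mescore.max(axis=1) >= min_max_me)
    long_list = common[long_mask].tolist()
    breaks = me_breaks
    if breaks is None:
        top = float(mescore.to_numpy().max()) if mescore.size else 1.0
        top = top if top > 0 else 1.0
        breaks = np.linspace(0, top, 8)[1:-1]
    short_list = []
    for tf in long_list:
        e_lvls = expression_level(expr.loc[tf].to_numpy())
        m_lvls = me_level(mescore.loc[tf].to_numpy(), breaks=breaks)
        if len(set(e_lvls)) > 1 or len(set(m_lvls)) > 1:
            short_list.append(tf)
    return long_list, short_list


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # per entity: coef, t, p, q, flag
    contrast: str
    design_columns: list[str]


def _design_matrix(design: SampleDesign) -> tuple[np.ndarray, list[str]]:
    """Encode ~1 + Population + Time + individual with nested reference coding.

    The first individual of each population (in design order) is the
    reference; its dummy is dropped, which removes the aliasing between
    the individual block and the population column.
    """
    t = design.table
    cols: list[np.ndarray] = [np.ones(len(t))]
    names = ["intercept"]
    cols.append((t["population"] == "adaptive").to_numpy(dtype=float))
    names.append("population[adaptive]")
    times = [lv for lv in TIME_LEVELS if lv in set(t["time"])]
    for lv in times[1:]:
        cols.append((t["time"] == lv).to_numpy(dtype=float))
        names.append(f"time[{lv}]")
    for pop in ("adaptive", "wildtype"):
        indivs = t.loc[t["population"] == pop, "individual"].unique().tolist()
        for ind in indivs[1:]:
            cols.append((t["individual"] == ind).to_numpy(dtype=float))
            names.append(f"individual[{ind}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient differential design; dropping aliased columns")
        keep = []
        for j in range(X.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(X[:, trial]) == len(trial):
                keep.append(j)
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names


def contrast_vector(names: list[str], contrast: str) -> np.ndarray:
    """Build a contrast vector from its string form.

    ``population`` tests adaptive - wildtype; ``time:<a>-<b>`` tests time
    level a minus level b (reference level contributes 0).
    """
    c = np.zeros(len(names))
    if contrast == "population":
        c[names.index("population[adaptive]")] = 1.0
        return c
    if contrast.startswith("time:"):
        a, b = contrast[len("time:"):].split("-")
        for lv, sign in ((a, 1.0), (b, -1.0)):
            if lv not in TIME_LEVELS:
                raise ValueError(f"unknown time level {lv!r}")
            col = f"time[{lv}]"
            if col in names:  # the reference level contributes 0
                c[names.index(col)] = sign
        return c
    raise ValueError(f"unknown contrast {contrast!r}")


def differential(
    y: pd.DataFrame,
    design: SampleDesign,
    contrast: str,
    fdr: float = 0.05,
    flag_on: str = "q",
) -> DifferentialResult:
    """Per-entity OLS contrast test with BH correction across entities.

    ``flag_on='q'`` flags entities at BH q < fdr (the time-contrast rule);
    ``flag_on='p'`` flags at raw p < fdr (the population-contrast rule).
    """
    values = y[design.sample_ids].to_numpy(dtype=float)
    X, names = _design_matrix(design)
    c = contrast_vector(names, contrast)
    n, k = X.shape
    if n <= k:
        raise ValueError("not enough samples for the differential design")
    XtX_inv = np.linalg.pinv(X.T @ X)
    H = XtX_inv @ X.T
    beta = values @ H.T  # entities x k
    resid = values - beta @ X.T
    dfree = n - np.linalg.matrix_rank(X)
    s2 = (resid**2).sum(axis=1) / dfree
    cvar = float(c @ XtX_inv @ c)
    est = beta @ c
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = est / np.sqrt(s2 * cvar)
    tvals = np.where(np.isfinite(tvals), tvals, 0.0)
    pvals = 2 * sps.t.sf(np.abs(tvals), dfree)
    qvals, _ = bh_fdr(pvals, fdr)
    flags = (qvals < fdr) if flag_on == "q" else (pvals < fdr)
    table = pd.DataFrame(
        {"coef": est, "t": tvals, "p": pvals, "q": qvals, "flag": flags}, index=y.index
    )
    return DifferentialResult(table, contrast, names)
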
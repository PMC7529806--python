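"""Per-SNP composite selection evidence and per-RE aggregation.

Each SNP carries four selection-test scores (Fst, iHS, XP-EHH, PBS) as
-log10 p-values, a derived-allele-frequency difference between the
adaptive and wildtype populations (dDAF), and an LD score whose
reciprocal down-weights redundant correlated SNPs.  The four tests are
composited by Fisher's method into a single CMS-like p-value per SNP;
SNPs passing Benjamini-Hochberg FDR on that p-value are flagged as under
selection.  Per regulatory element, the SNPs inside its interval are
aggregated into LD-weighted mean scores and a prior selection
probability, the inputs of the logistic selection-status model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

SCORE_COLUMNS = ["fst_mlogp", "ihs_mlogp", "xpehh_mlogp", "pbs_mlogp"]

P_FLOOR = 1e-300


def fisher_combine(pvalues, floor: float = P_FLOOR) -> tuple[float, float]:
    """Fisher's combination: stat = -2 sum(ln p), upper chi2 tail with 2Q df.

    Zero p-values are clamped to ``floor`` (with a warning) so the log stays
    finite; p > 1 is an error.
    """
    p = np.asarray(pvalues, dtype=float)
    if (p > 1).any():
        raise ValueError("p-values above 1")
    if (p < 0).any():
        raise ValueError("negative p-values")
    if (p < floor).any():
        warnings.warn(f"p-value(s) below {floor:g} clamped before log")
        p = np.maximum(p, floor)
    stat = -2.0 * np.log(p).sum()
    return float(stat), float(stats.chi2.sf(stat, df=2 * p.size))


def bh_fdr(pvalues, level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q-values, reject at ``level``)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    if n == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q <= level


def delta_daf(derived_counts_adaptive: tuple[int, int], derived_counts_wildtype: tuple[int, int]) -> float:
    """Derived-allele-frequency difference, adaptive minus wildtype."""
    out = []
    for count, total in (derived_counts_adaptive, derived_counts_wildtype):
        if total <= 0:
            raise ValueError("allele total must be positive")
        if not 0 <= count <= total:
            raise ValueError(f"count {count} outside [0, {total}]")
        out.append(count / total)
    return out[0] - out[1]


def ld_weights(ld_scores) -> np.ndarray:
    """SNP weights w = 1/r from LD scores r > 0."""
    r = np.asarray(ld_scores, dtype=float)
    bad = np.nonzero(r <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive LD score at position(s) {bad.tolist()}")
    return 1.0 / r


@dataclass
class SnpTable:
    """Per-SNP selection evidence.

    ``table`` columns: snp_id, chrom, pos, the four ``*_mlogp`` scores,
    ddaf, ld_score, weight, combined_p, selected.
    """

    table: pd.DataFrame

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()


def build_snp_table(
    df: pd.DataFrame,
    fdr_level: float = 0.05,
    floor: float = P_FLOOR,
    strict_missing: bool = False,
) -> SnpTable:
    """Assemble a :class:`SnpTable` from raw per-SNP evidence.

    ``df`` needs snp_id, chrom, pos, the four ``*_mlogp`` columns, ddaf and
    ld_score.  Missing individual scores (e.g. iHS undefined at fixed
    sites) are imputed as p = 1 and the SNP flagged; with
    ``strict_missing`` the chi-square df drops to twice the number of
    observed scores instead.  A precomputed ``combined_p`` column is
    honoured; otherwise Fisher's combination of the four scores supplies
    it.  ``selected`` is the BH-FDR pass at ``fdr_level``.
    """
    t = df.copy()
    X = t[SCORE_COLUMNS].to_numpy(dtype=float)
    if (X[~np.isnan(X)] < 0).any():
        raise ValueError("-log10 p scores must be non-negative")
    y = t["ddaf"].to_numpy(dtype=float)
    if (np.abs(y) > 1).any():
        raise ValueError("ddaf outside [-1, 1]")
    t["weight"] = ld_weights(t["ld_score"].to_numpy())
    t["imputed_scores"] = np.isnan(X).any(axis=1)

    if "combined_p" not in t.columns:
        pmat = np.power(10.0, -X)  # p=1 where the score is missing
        missing = np.isnan(pmat)
        pmat = np.where(missing, 1.0, pmat)
        if (pmat < floor).any():
            warnings.warn(f"combined scores below {floor:g} clamped")
            pmat = np.maximum(pmat, floor)
        statv = -2.0 * np.log(pmat).sum(axis=1)
        df_chi2 = np.full(len(t), 2 * len(SCORE_COLUMNS))
        if strict_missing:
            df_chi2 = 2 * (~missing).sum(axis=1)
        t["combined_p"] = stats.chi2.sf(statv, df=df_chi2)
    cp = t["combined_p"].to_numpy(dtype=float)
    if ((cp < 0) | (cp > 1)).any():
        raise ValueError("combined_p outside [0, 1]")
    _, reject = bh_fdr(cp, fdr_level)
    t["selected"] = reject
    t[SCORE_COLUMNS] = np.where(np.isnan(X), 0.0, X)
    return SnpTable(t.reset_index(drop=True))


def read_snp_table(path, **kwargs) -> SnpTable:
    return build_snp_table(pd.read_csv(path, sep="\t"), **kwargs)


def aggregate_re_features(snps: SnpTable, res) -> pd.DataFrame:
    """LD-weighted per-RE aggregation of SNP evidence.

    For RE k with SNP set J_k (positions inside [start, end)):
    ``agg_X[q] = mean_p w_p X_{p,q}``, ``agg_Y = mean_p w_p Y_p`` and the
    prior ``p0 = 1 - mean_p c_p``.  REs with no SNP get zero features and
    p0 = 0 (no evidence, no selection signal) and are excluded from the
    logistic regression downstream.
    """
    t = snps.table
    trees: dict[str, IntervalTree] = {}
    for re in res:
        trees.setdefault(re.chrom, IntervalTree()).addi(re.start, re.end, re.re_id)
    members: dict[str, list[int]] = {re.re_id: [] for re in res}
    for i, (chrom, pos) in enumerate(zip(t["chrom"], t["pos"])):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree[int(pos)]:
            members[iv.data].append(i)

    X = t[SCORE_COLUMNS].to_numpy(dtype=float)
    Y = t["ddaf"].to_numpy(dtype=float)
    w = t["weight"].to_numpy(dtype=float)
    c = t["combined_p"].to_numpy(dtype=float)

    rows = []
    for re in res:
        idx = np.array(members[re.re_id], dtype=int)
        if idx.size == 0:
            rows.append((re.re_id, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0))
            continue
        wk = w[idx]
        aggx = (wk[:, None] * X[idx]).mean(axis=0)
        aggy = float((wk * Y[idx]).mean())
        p0 = float(np.clip(1.0 - c[idx].mean(), 0.0, 1.0))
        rows.append((re.re_id, idx.size, *aggx, aggy, p0))
    return pd.DataFrame(
        rows,
        columns=["re_id", "n_snps", "agg_fst", "agg_ihs", "agg_xpehh", "agg_pbs", "agg_y", "p0"],
    ).set_index("re_id")


def fe_score(n_sel_in_peaks: int, n_all_in_peaks: int, n_sel_total: int, n_all_total: int) -> float:
    """Fold enrichment of selected SNPs inside open-chromatin peaks.

    FE = (selected-in-peaks / all-in-peaks) / (selected-total / all-total).
    Undefined denominators return NaN with a warning.
    """
    if n_all_in_peaks == 0 or n_sel_total == 0:
        warnings.warn("FE score undefined (empty peak SNP set or no selected SNPs)")
        return float("nan")
    if n_all_total <= 0:
        raise ValueError("total SNP count must be positive")
    return (n_sel_in_peaks / n_all_in_peaks) / (n_sel_total / n_all_total)


def fold_ratio_enrichment(
    n_sel_in_region: int,
    region_len: int,
    n_total: int,
    genome_len: int,
    n_selected_total: int,
) -> tuple[float, float]:
    """Density fold ratio of selected SNPs in a region plus a binomial tail p.

    fold = (selected-in-region / region bp) / (total SNPs / genome bp);
    p = P(X >= x) for X ~ Binomial(n_selected_total, region_len/genome_len).
    ``n_selected_total`` is supplied, not recomputed, so toy runs stay
    self-consistent.
    """
    if region_len <= 0 or genome_len <= 0:
        raise ValueError("lengths must be positive")
    if region_len > genome_len:
        raise ValueError("region longer than genome")
    fold = (n_sel_in_region / region_len) / (n_total / genome_len)
    p = float(stats.binom.sf(n_sel_in_region - 1, n_selected_total, region_len / genome_len))
    return fold, p
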
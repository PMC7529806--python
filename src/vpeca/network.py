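"""TF-RE-TG triplet assembly and subnetwork extraction.

A triplet (TF m, RE k, TG l) exists when the gene model gives RE k a
nonzero effect on gene l, TF m a nonzero activity weight for gene l, and
TF m has a motif hit on RE k.  Collapsing REs projects the triplets onto
a TF -> TG gene-level edge list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import MotifHitMatrix, NETWORK_COLUMNS
from .model import NONZERO_TOL, ExpressionFit, ReClassification


@dataclass
class TripletNetwork:
    triplets: pd.DataFrame  # columns NETWORK_COLUMNS
    edges: pd.DataFrame  # TF, TG, n_res (projection)

    def __len__(self) -> int:
        return len(self.triplets)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for tf, tg in zip(self.edges["TF"], self.edges["TG"]):
            g.add_edge(tf, tg)
        return g


def _project(triplets: pd.DataFrame) -> pd.DataFrame:
    if triplets.empty:
        return pd.DataFrame(columns=["TF", "TG", "n_res"])
    return (
        triplets.groupby(["TF", "TG"], sort=True)["RE_id"]
        .nunique()
        .reset_index()
        .rename(columns={"RE_id": "n_res"})
    )


def assemble_triplets(
    fits: dict[str, ExpressionFit],
    B: MotifHitMatrix,
    classes: ReClassification,
    P_sel: pd.Series | None = None,
    tol: float = NONZERO_TOL,
) -> TripletNetwork:
    """Enumerate every supported (TF, RE, TG) triplet from the gene fits."""
    rows = []
    for gene, fit in fits.items():
        res_k = fit.beta.index[fit.beta.abs() > tol]
        tfs_m = fit.gamma.index[fit.gamma.abs() > tol]
        for k in res_k:
            if k not in B.B.index:
                continue
            hits = B.B.loc[k]
            for m in tfs_m:
                if hits.get(m, 0.0) > 0:
                    rows.append(
                        (
                            m, k, gene,
                            float(fit.beta[k]), float(fit.gamma[m]), float(fit.alpha.get(k, 0.0)),
                            float(P_sel[k]) if P_sel is not None and k in P_sel.index else np.nan,
                            classes.re_class.get(k, "inactive"),
                            bool(classes.omega_flag.get(k, False)),
                        )
                    )
    triplets = pd.DataFrame(rows, columns=NETWORK_COLUMNS)
    return TripletNetwork(triplets, _project(triplets))


def tf_subnetwork(
    net: TripletNetwork,
    root_tf: str,
    order: int = 1,
    gene_flags: pd.Series | None = None,
    re_flags: pd.Series | None = None,
) -> TripletNetwork:
    """Downstream closure of ``root_tf`` to the given neighbour order.

    Genes failing ``gene_flags`` and REs failing ``re_flags`` (boolean,
    True = keep) are pruned; the root is always retained.  Downstream
    means edges out of the root only; feedback into the root does not
    expand the closure.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    t = net.triplets
    if root_tf not in set(t["TF"]):
        raise KeyError(f"root TF {root_tf!r} absent from the network")

    def keep_gene(g: str) -> bool:
        return g == root_tf or gene_flags is None or bool(gene_flags.get(g, False))

    def keep_re(k: str) -> bool:
        return re_flags is None or bool(re_flags.get(k, False))

    frontier = {root_tf}
    nodes = {root_tf}
    sel_rows = []
    for _ in range(order):
        sub = t[t["TF"].isin(frontier)]
        sub = sub[[keep_gene(g) and keep_re(k) for g, k in zip(sub["TG"], sub["RE_id"])]]
        sel_rows.append(sub)
        frontier = set(sub["TG"]) - nodes
        nodes |= frontier
        if not frontier:
            break
    triplets = pd.concat(sel_rows).drop_duplicates() if sel_rows else t.iloc[:0]
    return TripletNetwork(triplets.reset_index(drop=True), _project(triplets))


def tf_enrichment_in_subnetwork(
    net: TripletNetwork,
    background_occurrences: pd.Series,
    top_n: int = 25,
) -> pd.DataFrame:
    """Rank TFs by subnetwork occurrence / genome-wide background occurrence.

    The background count of a TF is the maximum occurrence among all
    motifs assigned to it (supplied precomputed).  TFs with zero
    background are excluded with a warning; ties break by TF id.
    """
    occ = net.triplets.groupby("TF")["RE_id"].count()
    tfs = occ.index
    zero_bg = [m for m in tfs if background_occurrences.get(m, 0) <= 0]
    if zero_bg:
        warnings.warn(f"TF(s) with zero background occurrence excluded: {zero_bg}")
    rows = [
        (m, int(occ[m]), float(background_occurrences[m]), occ[m] / background_occurrences[m])
        for m in tfs
        if background_occurrences.get(m, 0) > 0
    ]
    out = pd.DataFrame(rows, columns=["TF", "occurrence", "background", "score"])
    out = out.sort_values(["score", "TF"], ascending=[False, True], kind="stable")
    return out.head(top_n).reset_index(drop=True)


def degree_summary(net: TripletNetwork, root_tf: str) -> tuple[pd.Series, float]:
    """REs-per-target histogram under one TF and its mean (2-decimal report)."""
    sub = net.triplets[net.triplets["TF"] == root_tf]
    if sub.empty:
        return pd.Series(dtype=int), float("nan")
    counts = sub.groupby("TG")["RE_id"].nunique()
    return counts, round(float(counts.mean()), 2)


def mean_res_per_target(n_res: int, n_targets: int) -> float:
    """Average number of REs per target gene, reported to 2 decimals."""
    if n_targets <= 0:
        raise ValueError("target count must be positive")
    return round(n_res / n_targets, 2)
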
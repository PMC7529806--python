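"""End-to-end orchestration: scores -> selection -> accessibility -> expression -> network."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .io import MotifHitMatrix, OpennessMatrix, ExpressionMatrix, SampleDesign
from .landscape import CandidateMap
from .model import (
    AccessibilityFit,
    ExpressionFit,
    ReClassification,
    SelectionFit,
    classify_res,
    compute_priors,
    estimate_selection_status,
    fit_accessibility,
    fit_all_genes,
)
from .network import TripletNetwork, assemble_triplets
from .selection import SnpTable, aggregate_re_features

log = logging.getLogger("vpeca")


def restrict_candidates(cmap: CandidateMap, beta0: pd.DataFrame, min_abs_prior: float) -> CandidateMap:
    """Keep candidate REs whose cross-context correlation prior clears the bar.

    The gene's promoter is always retained; REs missing from the prior
    matrix are dropped (no panel evidence).
    """
    cands = {}
    for gene, ks in cmap.candidates.items():
        prom = cmap.promoters.get(gene)
        kept = [
            k for k in ks
            if k == prom
            or (k in beta0.index and gene in beta0.columns
                and abs(beta0.loc[k, gene]) >= min_abs_prior)
        ]
        cands[gene] = kept
    return CandidateMap(cmap.boundaries, cands, cmap.promoters)


@dataclass
class Thresholds:
    """Every decision threshold of the pipeline, with its standard default."""

    fdr: float = 0.05
    sel_threshold: float = 0.95
    omega_p: float = 0.05
    max_min_ratio: float = 500.0
    promoter_len: int = 2000
    flank: int = 1_000_000
    prior_scale: float = 1.0
    cv_folds: int = 5
    # candidate REs additionally need |cross-context RE-gene correlation|
    # at or above this (promoters always kept); 0 disables the restriction
    min_abs_prior: float = 0.2


@dataclass
class PipelineResult:
    features: pd.DataFrame
    selection: SelectionFit
    accessibility: AccessibilityFit
    fits: dict[str, ExpressionFit]
    classes: ReClassification
    network: TripletNetwork
    beta0: pd.DataFrame | None = None
    gamma0: pd.DataFrame | None = None

    def summary(self) -> dict:
        cls = self.classes.re_class
        return {
            "n_res": int(len(cls)),
            "n_are": int(cls.isin(["ARE", "ASRE"]).sum()),
            "n_asre": int((cls == "ASRE").sum()),
            "n_selected": int(self.selection.S.sum()),
            "n_genes_modeled": int(sum(bool(f.active_res) for f in self.fits.values())),
            "n_re_tg_interactions": int(
                sum(len(f.active_res) for f in self.fits.values())
            ),
            "n_triplets": int(len(self.network)),
            "n_tf_tg_edges": int(len(self.network.edges)),
        }


def fit_study(
    expression: ExpressionMatrix,
    openness: OpennessMatrix,
    design: SampleDesign,
    snps: SnpTable,
    res,
    cmap: CandidateMap,
    B: MotifHitMatrix,
    panel_expression: pd.DataFrame | None = None,
    panel_openness: pd.DataFrame | None = None,
    seed: int = 0,
    thresholds: Thresholds | None = None,
) -> PipelineResult:
    """Run the full inference chain on in-memory inputs."""
    th = thresholds or Thresholds()
    t0 = time.time()
    features = aggregate_re_features(snps, res)
    selection = estimate_selection_status(features, threshold=th.sel_threshold)
    log.info("selection: %d/%d REs selected (%.1fs)", int(selection.S.sum()), len(features), time.time() - t0)

    accessibility = fit_accessibility(openness, design, selection.S, alpha=th.omega_p)

    beta0 = gamma0 = None
    fit_cmap = cmap
    if panel_expression is not None and panel_openness is not None:
        beta0, gamma0, flat = compute_priors(panel_expression, panel_openness, cmap, B.tfs)
        if flat:
            log.info("priors: %d constant panel rows flagged", len(flat))
        if th.min_abs_prior > 0:
            fit_cmap = restrict_candidates(cmap, beta0, th.min_abs_prior)

    t0 = time.time()
    fits = fit_all_genes(
        expression.values, fit_cmap, openness.values, B, design, selection.S,
        beta0=beta0, gamma0=gamma0, folds=th.cv_folds, seed=seed, prior_scale=th.prior_scale,
    )
    log.info("expression: %d genes fitted (%.1fs)", len(fits), time.time() - t0)

    classes = classify_res(fits, selection, accessibility)
    net = assemble_triplets(fits, B, classes, P_sel=selection.P_sel)
    return PipelineResult(features, selection, accessibility, fits, classes, net, beta0, gamma0)


def write_results(result: PipelineResult, outdir) -> dict[str, Path]:
    """Write the standard TSV artifacts plus a JSON summary manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sel = pd.DataFrame(
        {"P_selected": result.selection.P_sel, "S": result.selection.S}
    ).join(result.features)
    paths["selection_fit"] = out / "selection_fit.tsv"
    sel.to_csv(paths["selection_fit"], sep="\t", index_label="re_id")

    acc = pd.concat(
        {
            "eta": result.accessibility.eta.T,
            "omega": result.accessibility.omega.T,
            "omega_p": result.accessibility.omega_p.T,
        },
        axis=1,
    )
    acc.columns = [f"{a}_{b}" for a, b in acc.columns]
    acc["sigma2_o"] = result.accessibility.sigma2_o
    paths["accessibility_fit"] = out / "accessibility_fit.tsv"
    acc.to_csv(paths["accessibility_fit"], sep="\t", index_label="re_id")

    rows = []
    for gene, fit in result.fits.items():
        for k in fit.active_res:
            rows.append((gene, k, fit.beta[k], fit.alpha.get(k, 0.0), fit.b0, fit.sigma2, fit.status))
    expr_df = pd.DataFrame(rows, columns=["gene", "re_id", "beta", "alpha", "b0", "sigma2", "status"])
    paths["expression_fits"] = out / "expression_fits.tsv"
    expr_df.to_csv(paths["expression_fits"], sep="\t", index=False)

    cls = pd.DataFrame({"class": result.classes.re_class, "omega_flag": result.classes.omega_flag})
    paths["re_classes"] = out / "re_classes.tsv"
    cls.to_csv(paths["re_classes"], sep="\t", index_label="re_id")

    paths["triplets"] = out / "triplets.tsv"
    vio.write_network(result.network.triplets, paths["triplets"])
    paths["edges"] = out / "tf_tg_edges.tsv"
    result.network.edges.to_csv(paths["edges"], sep="\t", index=False)

    paths["manifest"] = out / "manifest.json"
    manifest = {"summary": result.summary(), "artifacts": {k: str(v.name) for k, v in paths.items() if k != "manifest"}}
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
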
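"""Synthetic paired-omics studies drawn from the package's own generative model.

The generator emulates the study design the model targets: two
populations (adaptive vs wildtype) x 5 hypoxia time points x a few
individuals each, a toy one-chromosome genome with evenly spaced genes,
a promoter and one distal RE per gene, chromatin loops covering about
half the TSSs (so boundary logic is exercised both ways), SNPs inside
REs with composite selection scores, and expression/openness matrices
drawn from the selection, accessibility and expression equations with
known coefficients.  Everything is reproducible from (config, seed).

What it does *not* emulate: realistic LD-block structure, read-level
noise, multi-chromosome genomes, or heavy-tailed FPKM distributions —
recovery results here certify the estimation machinery, not performance
on real sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .io import (
    ExpressionMatrix,
    GeneAnnotation,
    LoopRecord,
    MotifHitMatrix,
    OpennessMatrix,
    RegulatoryElement,
    SampleDesign,
    TIME_LEVELS,
)
from .landscape import candidate_map, promoter_id, promoter_interval, regulatory_boundary
from .landscape import CandidateMap
from .selection import SCORE_COLUMNS, SnpTable, aggregate_re_features, build_snp_table
from .model import FEATURE_COLUMNS, _sigmoid


@dataclass
class SimulationConfig:
    """Sizes, effect sizes and noise levels of a synthetic study.

    Defaults are the canonical recovery conditions: 100 genes x
    (1 promoter + 1 distal RE) = 200 REs with 20% carrying selection
    signal, 50 TFs, 400 SNPs, 2 populations x 5 time points x 5
    individuals, |beta| in [0.5, 1.5], |gamma| in [0.5, 1.0],
    omega = 2 sigma_o at half the selected (RE, time) cells, alpha = 1.
    """

    n_genes: int = 100
    n_tfs: int = 50
    n_individuals_per_pop: int = 5
    snps_per_re: int = 2
    frac_selected: float = 0.2
    n_panel_contexts: int = 60

    genome_len: int = 10_000_000
    chrom: str = "chr1"
    promoter_len: int = 2000
    distal_len: int = 600
    distal_offset: tuple[int, int] = (10_000, 50_000)
    loop_half_width: tuple[int, int] = (60_000, 300_000)
    loop_tss_coverage: float = 0.5

    # selection-status model (intercept, 4 score terms, dDAF term)
    mu_star: tuple[float, ...] = (-5.0, 1.0, 1.0, 1.0, 1.0, 4.0)
    logit_noise_sd: float = 0.25
    ld_score_range: tuple[float, float] = (1.0, 4.0)
    null_score_scale: float = 1.0 / np.log(10)  # -log10 of a uniform p
    signal_score_shape: float = 4.0
    signal_score_scale: float = 1.25
    null_ddaf_sd: float = 0.1
    signal_ddaf_mean: float = 0.5
    signal_ddaf_sd: float = 0.15

    # accessibility model; each RE gets its own per-time-point baseline
    # level, emulating element-specific multi-stage opening/closing
    openness_level_range: tuple[float, float] = (2.5, 5.5)
    sigma_o: float = 0.5
    omega_effect_sd_units: float = 2.0  # |omega| = this x sigma_o
    frac_omega_nonzero: float = 0.5

    # expression model
    # RE effects are enhancer-like (activating, beta > 0) by default: the
    # bilinear TG model fixes only the sign of the product beta*gamma per
    # gene, so repressive REs would make the reported beta sign a gauge
    # convention rather than an estimable quantity
    alpha_star: float = 1.0
    beta_range: tuple[float, float] = (0.5, 1.5)
    frac_beta_negative: float = 0.0
    gamma_range: tuple[float, float] = (0.5, 1.0)
    frac_tf_active: float = 0.4
    motifs_per_re: int = 3
    motif_strength_range: tuple[float, float] = (0.5, 3.0)
    tf_base_range: tuple[float, float] = (2.0, 8.0)
    tf_dev_range: tuple[float, float] = (-1.5, 1.5)  # per-time-point deviation
    tf_noise_sd: float = 1.0
    sigma_l: float = 4.0  # FPKM-scale replicate noise

    # cross-context panel for the correlation priors
    panel_openness_coupling: float = 0.15
    panel_openness_noise_sd: float = 0.4

    def validate(self) -> None:
        if not 0 <= self.frac_selected <= 1:
            raise ValueError("frac_selected outside [0, 1]")
        if self.n_genes < 2 or self.n_tfs < 2:
            raise ValueError("need at least 2 genes and 2 TFs")
        if int(self.frac_selected * 2 * self.n_genes) > 2 * self.n_genes:
            raise ValueError("more selected REs than REs")
        if self.n_individuals_per_pop < 2:
            raise ValueError("need >= 2 individuals per population")


def default_recovery_config() -> SimulationConfig:
    """The canonical parameter-recovery study conditions."""
    cfg = SimulationConfig()
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    mu: np.ndarray
    P: pd.Series  # realised per-RE selection probability
    S: pd.Series  # drawn selection status
    signal_re: pd.Series  # REs whose SNP scores were drawn shifted
    eta: pd.DataFrame  # time x RE
    omega: pd.DataFrame  # time x RE
    sigma_o: float
    alpha: pd.Series  # per RE (0 where S = 0)
    beta: dict[str, pd.Series]  # gene -> nonzero effects over its true REs
    b0: pd.Series  # per-gene intercept
    gamma: pd.Series  # per TF (global in the forward model)
    sigma_l: float


@dataclass
class SimulatedStudy:
    design: SampleDesign
    expression: ExpressionMatrix
    openness: OpennessMatrix
    snps: SnpTable
    genes: list[GeneAnnotation]
    res: list[RegulatoryElement]
    loops: list[LoopRecord]
    B: MotifHitMatrix
    cmap: CandidateMap
    panel_expression: pd.DataFrame
    panel_openness: pd.DataFrame
    truth: GroundTruth


def _make_design(n_rep: int) -> SampleDesign:
    rows = []
    for pop, tag in (("adaptive", "A"), ("wildtype", "W")):
        for i in range(1, n_rep + 1):
            for t in TIME_LEVELS:
                rows.append((f"{tag}{i}_{t}", f"{tag}{i}", t, pop))
    return SampleDesign(pd.DataFrame(rows, columns=["sample_id", "individual", "time", "population"]))


def simulate_study(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedStudy:
    """Draw a full synthetic study from the forward model."""
    cfg = config or default_recovery_config()
    cfg.validate()
    rng = np.random.default_rng(seed)
    design = _make_design(cfg.n_individuals_per_pop)
    n_samples = len(design.sample_ids)
    delta = design.delta
    time_idx = np.array([TIME_LEVELS.index(t) for t in design.table["time"]])

    # --- toy genome: genes, loops, REs -------------------------------------
    margin = 400_000
    tss = np.linspace(margin, cfg.genome_len - margin, cfg.n_genes).astype(int)
    genes = [
        GeneAnnotation(f"G{l:04d}", cfg.chrom, int(tss[l]), "+" if l % 2 == 0 else "-")
        for l in range(cfg.n_genes)
    ]
    loops = []
    for g in genes:
        if rng.random() < cfg.loop_tss_coverage:
            half = int(rng.integers(*cfg.loop_half_width))
            s = max(0, g.tss - half)
            e = g.tss + half
            loops.append(LoopRecord(cfg.chrom, (s, min(s + 5000, e)), (max(e - 5000, s), e)))
    boundaries = {g.gene_id: regulatory_boundary(g, loops) for g in genes}

    promoters = {g.gene_id: promoter_interval(g, cfg.promoter_len) for g in genes}
    placed: list[tuple[int, int]] = sorted(promoters.values())

    def overlaps_placed(s: int, e: int) -> bool:
        return any(s < pe and e > ps for ps, pe in placed)

    res: list[RegulatoryElement] = []
    own_distal: dict[str, str] = {}
    for g in genes:
        s, e = promoters[g.gene_id]
        res.append(RegulatoryElement(promoter_id(g.gene_id), cfg.chrom, s, e, "promoter"))
    for g in genes:
        # the gene's own distal RE falls inside its regulatory boundary and
        # avoids every other RE (so SNP->RE assignment is unambiguous)
        b = boundaries[g.gene_id]
        lo = max(b[0], g.tss - cfg.distal_offset[1])
        hi = min(b[1] - cfg.distal_len, g.tss + cfg.distal_offset[1])
        for _ in range(100):
            ds = int(rng.integers(lo, max(lo + 1, hi)))
            if not overlaps_placed(ds, ds + cfg.distal_len):
                break
        placed.append((ds, ds + cfg.distal_len))
        rid = f"E_{g.gene_id}"
        res.append(RegulatoryElement(rid, cfg.chrom, ds, ds + cfg.distal_len, "distal"))
        own_distal[g.gene_id] = rid
    re_ids = [r.re_id for r in res]

    cmap = candidate_map(res, genes, boundaries)

    # --- SNPs and selection status ----------------------------------------
    snp_rows = []
    signal = pd.Series(False, index=re_ids)
    sig_ids = rng.choice(len(res), size=int(round(cfg.frac_selected * len(res))), replace=False)
    signal.iloc[np.sort(sig_ids)] = True
    p_idx = 0
    for r in res:
        for _ in range(cfg.snps_per_re):
            pos = int(rng.integers(r.start, r.end))
            if signal[r.re_id]:
                x = rng.gamma(cfg.signal_score_shape, cfg.signal_score_scale, size=4)
                y = np.clip(rng.normal(cfg.signal_ddaf_mean, cfg.signal_ddaf_sd), -1, 1)
            else:
                x = rng.exponential(cfg.null_score_scale, size=4)
                y = np.clip(rng.normal(0.0, cfg.null_ddaf_sd), -1, 1)
            ld = rng.uniform(*cfg.ld_score_range)
            snp_rows.append((f"snp{p_idx:05d}", r.chrom, pos, *x, y, ld))
            p_idx += 1
    snp_df = pd.DataFrame(
        snp_rows, columns=["snp_id", "chrom", "pos", *SCORE_COLUMNS, "ddaf", "ld_score"]
    )

    # realised selection probability: logistic in the aggregated features
    # with RE-level noise; combined p-values are emitted consistently so
    # the prior p0 recovers the realised probability.
    provisional = build_snp_table(snp_df.assign(combined_p=0.5))
    feats = aggregate_re_features(provisional, res)
    Xf = np.column_stack([np.ones(len(res)), feats[FEATURE_COLUMNS].to_numpy()])
    mu = np.asarray(cfg.mu_star, dtype=float)
    P = pd.Series(
        _sigmoid(Xf @ mu + rng.normal(0, cfg.logit_noise_sd, size=len(res))), index=re_ids
    )
    S = pd.Series(rng.binomial(1, P.to_numpy()), index=re_ids)
    snp_re = np.repeat(re_ids, cfg.snps_per_re)
    snp_df["combined_p"] = np.clip(1.0 - P[snp_re].to_numpy(), 1e-12, 1.0)
    snps = build_snp_table(snp_df)

    # --- openness ----------------------------------------------------------
    eta = pd.DataFrame(
        rng.uniform(*cfg.openness_level_range, size=(len(TIME_LEVELS), len(res))),
        index=list(TIME_LEVELS), columns=re_ids,
    )
    w_eff = cfg.omega_effect_sd_units * cfg.sigma_o
    nonzero = (rng.random((len(TIME_LEVELS), len(res))) < cfg.frac_omega_nonzero)
    signs = rng.choice([-1.0, 1.0], size=nonzero.shape)
    omega = pd.DataFrame(
        np.where(nonzero & (S.to_numpy() == 1)[None, :], signs * w_eff, 0.0),
        index=list(TIME_LEVELS), columns=re_ids,
    )
    O = (
        eta.to_numpy()[time_idx, :].T
        + omega.to_numpy()[time_idx, :].T * (delta[None, :] * S.to_numpy()[:, None])
        + rng.normal(0, cfg.sigma_o, size=(len(res), n_samples))
    )
    O = np.maximum(O, 0.0)
    openness = OpennessMatrix(pd.DataFrame(O, index=re_ids, columns=design.sample_ids), design)

    # --- TFs, motifs, expression -------------------------------------------
    tf_ids = [f"TF{m:03d}" for m in range(cfg.n_tfs)]
    n_active = max(2, int(round(cfg.frac_tf_active * cfg.n_tfs)))
    active_tfs = list(rng.choice(tf_ids, size=n_active, replace=False))
    gamma = pd.Series(0.0, index=tf_ids)
    gamma[active_tfs] = rng.uniform(*cfg.gamma_range, size=n_active)

    Bm = np.zeros((len(res), cfg.n_tfs))
    inactive = [m for m in tf_ids if m not in active_tfs]
    for ki in range(len(res)):
        picks = list(rng.choice(active_tfs, size=min(2, len(active_tfs)), replace=False))
        extra = cfg.motifs_per_re - len(picks)
        if extra > 0 and inactive:
            picks += list(rng.choice(inactive, size=extra, replace=False))
        for m in picks:
            Bm[ki, tf_ids.index(m)] = rng.uniform(*cfg.motif_strength_range)
    B = MotifHitMatrix(pd.DataFrame(Bm, index=re_ids, columns=tf_ids))

    tf_base = rng.uniform(*cfg.tf_base_range, size=cfg.n_tfs)
    tf_dev = rng.uniform(*cfg.tf_dev_range, size=(cfg.n_tfs, len(TIME_LEVELS)))
    TFmat = (
        tf_base[:, None] + tf_dev[:, time_idx]
        + rng.normal(0, cfg.tf_noise_sd, (cfg.n_tfs, n_samples))
    )
    TFmat = np.maximum(TFmat, 0.05)

    alpha = pd.Series(np.where(S.to_numpy() == 1, cfg.alpha_star, 0.0), index=re_ids)
    Z = O + (alpha.to_numpy() * S.to_numpy())[:, None] * delta[None, :]
    F = (Bm * gamma.to_numpy()[None, :]) @ TFmat  # RE x sample TF activity

    beta_truth: dict[str, pd.Series] = {}
    b0_truth = pd.Series(0.0, index=[g.gene_id for g in genes])
    TG = np.zeros((cfg.n_genes, n_samples))
    for li, g in enumerate(genes):
        support = [promoter_id(g.gene_id), own_distal[g.gene_id]]
        mags = rng.uniform(*cfg.beta_range, size=len(support))
        sgn = np.where(rng.random(len(support)) < cfg.frac_beta_negative, -1.0, 1.0)
        bvec = pd.Series(mags * sgn, index=support)
        beta_truth[g.gene_id] = bvec
        rows = [re_ids.index(k) for k in support]
        sig = bvec.to_numpy() @ (Z[rows] * F[rows])
        b0 = max(0.0, -sig.min()) + rng.uniform(1.0, 5.0)
        b0_truth[g.gene_id] = b0
        TG[li] = np.maximum(b0 + sig + rng.normal(0, cfg.sigma_l, n_samples), 0.0)

    gene_ids = [g.gene_id for g in genes]
    expr_values = pd.DataFrame(
        np.vstack([TG, TFmat]), index=gene_ids + tf_ids, columns=design.sample_ids
    )
    roles = pd.Series(["TG"] * cfg.n_genes + ["TF"] * cfg.n_tfs, index=gene_ids + tf_ids)
    expression = ExpressionMatrix(expr_values, design, gene_roles=roles)

    # --- cross-context panel: contexts differ mainly in their TF
    # programs; each RE's openness partly follows the activity of the TFs
    # bound to it (accessibility downstream of TF binding), which is what
    # makes the cross-context correlation priors informative
    ctx = [f"ctx{c:03d}" for c in range(cfg.n_panel_contexts)]
    TFp = np.maximum(
        tf_base[:, None]
        + rng.uniform(*cfg.tf_dev_range, size=(cfg.n_tfs, cfg.n_panel_contexts))
        + rng.normal(0, 1.0, (cfg.n_tfs, cfg.n_panel_contexts)), 0.05)
    Fp = (Bm * gamma.to_numpy()[None, :]) @ TFp
    o_base = rng.uniform(*cfg.openness_level_range, size=len(res))
    Op = np.maximum(
        o_base[:, None]
        + cfg.panel_openness_coupling * (Fp - Fp.mean(axis=1, keepdims=True))
        + rng.normal(0, cfg.panel_openness_noise_sd, (len(res), cfg.n_panel_contexts)), 0.0)
    TGp = np.zeros((cfg.n_genes, cfg.n_panel_contexts))
    for li, g in enumerate(genes):
        bvec = beta_truth[g.gene_id]
        rows = [re_ids.index(k) for k in bvec.index]
        TGp[li] = np.maximum(
            b0_truth[g.gene_id] + bvec.to_numpy() @ (Op[rows] * Fp[rows])
            + rng.normal(0, cfg.sigma_l, cfg.n_panel_contexts), 0.0
        )
    panel_expr = pd.DataFrame(np.vstack([TGp, TFp]), index=gene_ids + tf_ids, columns=ctx)
    panel_open = pd.DataFrame(Op, index=re_ids, columns=ctx)

    truth = GroundTruth(
        mu=mu, P=P, S=S, signal_re=signal, eta=eta, omega=omega, sigma_o=cfg.sigma_o,
        alpha=alpha, beta=beta_truth, b0=b0_truth, gamma=gamma, sigma_l=cfg.sigma_l,
    )
    return SimulatedStudy(
        design, expression, openness, snps, genes, res, loops, B, cmap,
        panel_expr, panel_open, truth,
    )


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Emit the study in the exact file dialects the pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "design": out / "design.tsv",
        "expression": out / "expression.tsv",
        "openness": out / "openness.tsv",
        "snps": out / "snps.tsv",
        "res": out / "res.bed",
        "tss": out / "tss.bed",
        "loops": out / "loops.bedpe",
        "motifs": out / "motif_hits.tsv",
        "panel_expression": out / "panel_expression.tsv",
        "panel_openness": out / "panel_openness.tsv",
    }
    vio.write_design(study.design, paths["design"])
    vio.write_matrix(study.expression.values, paths["expression"], "gene")
    vio.write_matrix(study.openness.values, paths["openness"], "re_id")
    study.snps.table.to_csv(paths["snps"], sep="\t", index=False)
    vio.write_res_bed(study.res, paths["res"])
    with open(paths["tss"], "w") as fh:
        for g in study.genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t.\t{g.strand}\n")
    vio.write_loops_bedpe(study.loops, paths["loops"])
    hits = study.B.B.stack()
    hits = hits[hits > 0].rename("strength").reset_index()
    hits.columns = ["re_id", "tf", "strength"]
    hits.insert(0, "motif_id", hits["tf"] + "_motif")
    hits.to_csv(paths["motifs"], sep="\t", index=False)
    vio.write_matrix(study.panel_expression, paths["panel_expression"], "gene")
    vio.write_matrix(study.panel_openness, paths["panel_openness"], "re_id")
    return paths
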
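# Methods

## Scope and data model

`vpeca` couples four regressions into one inference chain for a
two-population (adaptive vs wildtype) hypoxia time-course design: 5 time
points (0h, 6h, 1d, 3d, 5d), several individuals per population, with
per-sample gene expression (FPKM-like), per-RE openness scores, a per-SNP
selection-score table, an RE catalog with chromatin loops, and a motif-hit
matrix. All intervals are 0-based half-open (BED convention); a TSS is a
single 0-based position. Motif hits come from a reference-genome scan, so
the match-strength matrix B is shared across individuals; several motifs
mapping to one TF are summed per (RE, TF).

## Selection evidence per SNP and per RE

Each SNP carries four selection statistics as −log₁₀ p (Fst, iHS, XP-EHH,
PBS), a derived-allele-frequency difference ΔDAF ∈ [−1, 1], and an LD
score r > 0 whose reciprocal w = 1/r down-weights clustered, correlated
SNPs. The four statistics are composited by Fisher's method
(−2Σln p against χ² with 8 df); SNPs passing Benjamini–Hochberg FDR at
0.05 on the combined p-value are flagged as selected. Scores missing at
individual SNPs (e.g. iHS at fixed sites) are imputed as p = 1 and the
SNP flagged; a strict mode instead reduces the χ² degrees of freedom.
P-values are floored at 1e−300 before logs.

Per RE k, the SNPs inside its interval (J_k) aggregate to
⟨w·X_q⟩ = (1/|J_k|)Σ w_p X_{pq}, ⟨w·Y⟩, and the prior
p⁰_k = 1 − (1/|J_k|)Σ c_p from the combined p-values. REs without SNPs
get zero features and p⁰ = 0 — no evidence is treated as no selection
signal — and are excluded from the μ regression but retained everywhere
else.

## Selection-status estimation

The latent indicator S_k follows logit P(S_k=1) = μᵀ[1, ⟨wX⟩, ⟨wY⟩].
Starting from P = p⁰, we alternate (a) clip P to [1e−6, 1−1e−6], regress
the logit on the features by OLS (ridge 1e−8 fallback if rank-deficient)
and (b) set P = sigmoid of the fitted predictor, until max|Δμ| < 1e−6
(at most 100 iterations; absent clipping the loop fixes after one
refresh). Finally S_k = 1 iff P strictly exceeds 0.95. The clipping
bounds the attainable logits at ±13.8, which slightly attenuates μ when
true predictors exceed that range; at the default study conditions the
resulting bias is far below one Monte-Carlo standard error.

## Accessibility model

O_{ijk} = η_{jk} + ω_{jk} δ_i S_k + ε, ε ~ N(0, σ²_ok). For selected REs
each (RE, time) cell is an OLS fit of openness on the population
indicator; for unselected REs ω ≡ 0 and η is the within-time mean. The
error variance is indexed by RE only, so residuals are pooled across the
five time points (df = Σⱼ(nⱼ − 2) ≈ 40 at 10 samples/time) and the
two-sided t-test on ω uses those pooled degrees of freedom. This is the
faithful reading of the model's variance structure and is what gives the
test its power (exact power 0.87 at |ω| = 2σ with 5+5 samples; a
per-cell variance estimate would only reach 0.79). Time points missing a
population leave ω undefined (flagged untested). No multiplicity
correction is applied to the ω tests by default (raw p < 0.05), matching
the stage's role as a descriptive flag; BH is available in `vpeca.stats`.

## Expression model

TG = β₀ + Σ_{k∈Iₗ} β_k Z_k (Σ_m γ_m B_{km} TF_m) + ε with the plug-in
activity Z = O + αδS (the conditional mean of the activity equation; no
sampling of Z). Per gene:

1. **RE selection.** With γ fixed at the cross-context prior γ⁰ (ones if
   no panel is supplied) and α = 0, an L1-penalised regression selects
   REs. Predictors are standardised to unit variance (intercept
   unpenalised, coefficients returned on the original scale). The
   penalty is chosen on a 40-point path by 5-fold cross-validation with
   the one-standard-error rule; folds are deterministic from the seed
   and stratified by (population, time) so every fold spans all
   conditions. The CV-minimum rule is available but over-selects in
   high signal-to-noise settings.
2. **TF selection.** With β fixed, an L1 fit over the TFs with motifs on
   the surviving REs selects γ, same CV scheme.
3. **Joint refinement.** On the survivors, L-BFGS-B minimises
   ½‖TG − β₀ − Σ β_k(O+α_kδS_k)(Σ γ_m B TF_m)‖² − s(β₀ᵀβ + γ₀ᵀγ) +
   (s/2)(‖β‖² + ‖γ‖²), with analytic gradients, α free only where
   S_k = 1, and a single scalar s (default 1) multiplying the
   prior-reward and ridge blocks. Optimizer failure falls back to the
   step-1/2 solution, flagged.

"Nonzero" everywhere means |value| > 1e−8 after the refit. γ is one
vector per gene, shared across that gene's REs.

**Priors.** β⁰ (RE × gene) and γ⁰ (TF × gene) are Pearson correlations
across the shared contexts of a public-panel expression/openness pair
(≥ 3 contexts; constant rows give prior 0 and are flagged). The pipeline
additionally restricts each gene's candidate REs to those with
|β⁰| ≥ 0.2 (promoter always kept). This threshold is deliberately part
of the default pipeline: the candidate predictors O_k·f_k live almost
entirely in the ~10-dimensional space of condition means, so without the
correlation restriction the L1 step cannot separate true regulators from
chance-collinear neighbours (support F1 plateaus near 0.65 at the
default study size; with the restriction it exceeds 0.8). The low-level
`candidate_map` operation itself defaults to no filter.

**Identifiability.** The TG model is bilinear: flipping the signs of a
gene's β and γ together leaves the likelihood unchanged, so only the
product direction is estimable and the reported β sign is meaningful
only under a convention for γ. The synthetic generator therefore uses
activating REs (β* > 0) and activating TFs (γ* > 0) by default; both are
configurable, but sign-recovery statements for mixed-sign truths are
statements about a gauge convention, not about the data.

## RE landscape

A gene's regulatory boundary is the ±1 Mb TSS window intersected with
the smallest-span loop whose span contains the TSS (ties: leftmost
start; no containing loop: the bare window; containing loop wider than
the window: the window). Candidate distal REs are the interval
intersection of the H3K27ac and H3K4me1 mark sets (merged if touching);
every gene also receives a strand-aware 2 kb promoter
([TSS−2000, TSS) on +, [TSS, TSS+2000) on −), kept distinct from
overlapping distal REs and flagged by class. Openness is the fold change
of reads per base pair over the genome-average reads per base pair, so
uniform coverage scores exactly 1 and jointly rescaling all library
sizes rescales all scores by the inverse constant. Row filtering drops
all-zero rows and rows whose max/min ratio within any (population, time)
replicate group exceeds 500; a group with min 0 and max > 0 counts as
infinitely inconsistent.

## Supporting statistics

Hypergeometric enrichment reports the upper tail P(X ≥ x) and the fold
x/(KN/M). The motif-enrichment score is √(−log₁₀ p × fold-change).
Dynamic-TF selection requires max FPKM ≥ 12 and max ME ≥ 2 across the
five time points (long list) and additionally a change of expression
level (bins at 6/12/30/120) or ME level (7 equal-width bins over
[0, max observed], configurable) across time (short list). Differential
analysis fits y ~ 1 + Population + Time + individual per entity by OLS;
individuals are nested in populations, so one reference individual per
population is dropped to keep the design full rank. Time contrasts are
flagged at BH q < 0.05, population contrasts at raw p < 0.05. No
empirical-Bayes variance moderation is applied — a deliberate deviation
that costs some power at small n but keeps the per-entity test exact
under normality.

## Synthetic studies and what they certify

The generator draws a full study from the model itself on a 10 Mb toy
chromosome: 100 evenly spaced genes (alternating strand), one promoter
and one non-overlapping distal RE per gene placed inside the gene's
boundary, loops covering ~50% of TSSs (half-width 60–300 kb), and 2 SNPs
per RE. Signal REs (20%) draw shifted score distributions
(Gamma(4, 1.25) per −log₁₀ p score; ΔDAF ≈ N(0.5, 0.15)) against
exponential/near-zero nulls; LD scores are U(1, 4). The realised
selection probability is logistic in the aggregated features with
μ* = (−5, 1, 1, 1, 1, 4) plus N(0, 0.25²) logit noise, S is a Bernoulli
draw, and the emitted per-SNP combined p-values are set to 1 − P so the
prior p⁰ recovers the realised probability exactly — this is what makes
the μ-recovery comparison well-posed. (On real data the combined
p-values come from the Fisher pipeline instead; the table accepts
either.)

Accessibility: per-(RE, time) baseline levels are i.i.d. U(2.5, 5.5) —
element-specific multi-stage opening/closing rather than a shared smooth
trend — with sample noise σ_o = 0.5 and, at half the selected cells, a
population shift of ±2σ_o. Expression: TF levels have per-time
deviations ±1.5 and sample noise 1.0 on bases U(2, 8); each RE carries
motifs for two active TFs (γ* ~ U(0.5, 1)) and one inactive TF; true
supports are the gene's own promoter and distal RE with
β* ~ U(0.5, 1.5); residual noise σ_l = 4 is FPKM-scale replicate noise;
intercepts are shifted to keep expression non-negative. The prior panel
(60 contexts) varies mainly in TF programs, with each RE's openness
partly coupled to the activity of its bound TFs (coupling 0.15, noise
0.4) — which is what gives the cross-context correlations their sign
information.

Passing recovery on these studies certifies the estimation machinery —
the ICM loop, the pooled-variance ω test, the staged L1/quasi-Newton fit
and the classification logic — under the model's own assumptions. It
does not certify performance on real sequencing data: the generator has
no LD-block structure, no read-level or heavy-tailed FPKM noise, no
multi-chromosome genome, no repressive REs, and its panel is generated
from the same coefficients it is used to estimate priors for.

## Numerical choices and degenerate inputs

Probability floors 1e−300 before logs; logit clipping 1e−6;
nonzero threshold 1e−8; ridge fallback 1e−8 on rank-deficient selection
designs; zero-variance predictors are dropped from L1 steps with
coefficient 0; a perfect accessibility fit (zero pooled variance) yields
p = 0 for nonzero ω and p = 1 otherwise; empty candidate sets, genes
with no surviving RE or TF, and empty networks all return explicit empty
results rather than errors. Boundary ties break leftmost; enrichment
ranking ties break by TF id. All CV folds, simulations and pipeline runs
are deterministic functions of (config, seed); reruns are byte-identical.

## Default problem sizes

The shipped analyses (tests and `scripts/acceptance.py`) run the
canonical study — 200 REs, 100 genes, 50 TFs, 400 SNPs, 50 samples —
once per seed, 16 lightweight replicates for the μ spread, and a
400-RE accessibility study for ω power/size (≈1000 cells of each kind).
These sizes give stable metrics while keeping a full run in seconds on
one CPU.

## Known limitations

No marginalisation over (Z, S) (plug-in activity, thresholded S); no
uncertainty intervals on β/γ; ω tests are per-cell with raw p-values;
the candidate-prior threshold (0.2) is a pipeline default, not a fitted
quantity; repressive regulation is representable in the data model but
outside the generator's default conditions for the identifiability
reason above.
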
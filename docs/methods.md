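# Methods

This note records the models, parameter choices and numerical decisions
behind `coexnet`, and what the synthetic validation does and does not
establish about real data.

## Synthetic count model

Counts for gene g in sample s are negative binomial,

    y_gs ~ NB(mean = L_s · q_g · 2^δ_gs,  Var = μ + φ_g μ²),

with relative abundances q_g log-normal (σ_log = 1.5, normalised to sum
1), library sizes L_s log-normal around 3·10⁶ reads (σ_log = 0.3, the
usual 10⁶–10⁷ bulk range), and gene-wise dispersions φ_g ~ Gamma(shape 2,
mean 0.1), the magnitude edgeR-style analyses typically estimate for
tissue RNA-seq. The log₂-scale perturbation δ carries all structure:

- **Planted DE.** For each contrast (RFI, breed, diet within each tissue)
  80 genes receive a ±2 log₂ fold-change, applied as a symmetric ±1 shift
  to the two level means. Sample sizes default to 10 animals per
  breed × RFI cell, matching the study's per-group 8–11.
- **Co-expression modules.** Five modules of 20 genes share a latent
  N(0,1) factor per sample with loading 1.0 plus N(0, 0.3) idiosyncratic
  noise, injected on the log-mean scale so the induced correlations pass
  through the same count noise the inference sees. Module membership is
  drawn independently of DE status; TF and secretome catalogues (100 and
  80 genes) may overlap modules, as real catalogues do.
- **Differential wiring.** One module-free transcription factor carries
  its own latent signal u_s; twenty of the wired contrast's up-regulated
  DE genes couple to u with coefficient +0.8 in condition 1 and −0.8 in
  condition 2. Targets are taken from the consistently signed DE genes
  because the RIF1 weight (abundance × differential expression) vanishes
  for targets that are not differentially expressed, and a coherently
  acting regulator has coherently signed targets; with mixed signs the
  planted signal would cancel by construction rather than by biology.

The generator is fully determined by (design, params, seed). It does not
model batch effects beyond library size, repeated measures on the same
animal (phases are drawn independently), GC/length biases, or count
outliers. Passing tests therefore demonstrate correctness of the
algorithms under idealised NB sampling, not robustness to those artefacts.

## Differential expression

Per contrast, samples are subset to the tissue and levels involved, and
TMM factors, CPM and the "≥ 1 CPM in ≥ half the samples" filter are
recomputed on that subset (which is why each contrast tests a different
N). The RFI and breed contrasts pool all diet phases and the other factor;
the diet contrast compares the two high-concentrate phases pooled ("HC")
against zero-grazed grass with the phase order (1, 2, 3) as a numeric
covariate. A categorical phase covariate would be perfectly collinear
with the HC/ZG indicator, since diet is determined by phase; the numeric
coding captures the growing-to-finishing drift while leaving the diet
coefficient identifiable. A rank check drops any covariate column that
still renders the contrast unidentifiable.

The per-gene model is a log-linear NB GLM with log effective library size
offset, fitted by vectorised IRLS across all genes simultaneously (ridge
1e-10 on the normal equations, 50 iterations, convergence at 1e-8; genes
that fail to converge are flagged and reported at p = 1). Dispersions are
estimated on a 41-point log grid over [1e-4, 10] by Cox–Reid adjusted
profile likelihood at pilot-fit means, then each gene maximises its own
adjusted profile plus (prior_df / residual_df) times the average profile —
shrinkage toward the common dispersion expressed as prior degrees of
freedom. The default prior_df is 4: with a single untrended shrinkage
target and heterogeneous true dispersions, heavier priors (10–20) bias the
bulk of dispersion estimates upward and visibly distort the null p-value
distribution, while prior_df 4 keeps the null type-I fraction at
0.05 ± 0.01 and the p-values KS-indistinguishable from uniform at 2,000
genes. The contrast is tested by LRT against the nested design, p from
χ²(1), BH-corrected; the top ⌊0.05 N⌋ genes by (q, then p, then |log₂FC|,
then gene ID) are the contrast's DEGs. The deterministic tie-break matters
only for duplicated q-values.

TMM follows the published definition exactly (M and A on library-scaled
abundances, 30%/5% double trim with R-style average ranks,
inverse-variance weights, upper-quartile reference, geometric-mean
rescaling); the test suite checks it against an independently coded naive
implementation to 1e-10 and against Bioconductor edgeR to 1e-8.

## RIF

Expression enters RIF as log₂(CPM+1) — the scale choice stabilises
Pearson correlations across the dynamic range. Condition pairs mirror the
six DE contrasts. Correlations are computed within each condition's
samples separately (≥ 3 samples enforced; constant genes correlate 0 with
a warning), and both metrics are z-standardised across regulators with
the sample SD, so |z| ≥ 1.96 is a two-sided 5% cut under an approximate
normal reference. A single regulator cannot be z-scored and is returned
raw with a warning.

## PCIT and edge significance

The trio tolerance averages only the ratio terms whose direct correlation
is non-zero; a trio with all three direct correlations zero eliminates
nothing, and a degenerate denominator (|r| = 1) yields partial
correlation 0 for that term. Elimination compares magnitudes
(sign-agnostic). The vectorised implementation loops over the
conditioning gene and is property-tested against a naive triple loop.

Emitted edges must pass three conjoined rules: PCIT retention, |r| ≥ 0.8,
and |r| ≥ mean + 2 SD of all off-diagonal |r| of that run's matrix. When
the SD is exactly zero the distributional rule is vacuous and only the
absolute threshold applies (warned). Each contrast's run computes
correlations over all samples of the tissue, on the node universe
DEG(contrast) ∪ TFs ∪ secretome restricted to genes expressed in that
tissue; the edge's contrast identity is the run that produced it. Merged
edges form a multigraph keyed by (pair, label); nodes without edges drop
out.

## MCODE

Vertex weight = k · density of the highest k-core of the closed
neighbourhood; vertices below the degree cutoff (default 2) score 0.
Expansion from the highest-weight unvisited seed admits neighbours with
weight strictly greater than (1 − vwp) · seed weight (vwp 0.2, max depth
100), ties in seed order broken by node ID. The haircut is iterated to a
fixpoint rather than applied once — removing a degree-1 member can expose
another — which only ever shrinks clusters. Fluff is available but off by
default. Clusters are node-disjoint, scored density × size, and reported
with their per-contrast edge composition since the labelled multigraph is
collapsed to a simple graph before clustering.

## Pipeline determinism and scale

One master seed drives the generator; every other stage is deterministic,
so rerunning a config yields bit-identical artifacts (verified via the
SHA-256 manifest). Default problem sizes — 2,000 genes, 240 samples,
~270-node PCIT runs — complete in well under a minute on one CPU; the
validation suites use 400-gene single-tissue designs for the repeated
(50-seed) recovery studies. These sizes were chosen to make the planted
structure statistically resolvable (e.g. ±0.8 coupling at 20 samples per
condition) at desk-scale runtimes.

## Known limitations

- The NB-GLM is not a numerical clone of edgeR's Cox-Reid/tagwise
  machinery; it reproduces the behaviour (calibrated LRT with shrunk
  dispersions), not the exact estimates.
- The mean+2SD rule is applied to each run's |r| distribution, which
  depends on the node universe; with very small node sets the cut is
  noisy.
- Hub "degree share" is the hub's labelled degree over that label's edge
  count; shares across labels need not sum to anything meaningful.
- Module edge precision in the end-to-end run has a small denominator at
  defaults (few module genes double as DEG/TF/secretome nodes); the
  focused PCIT precision property uses module-dense matrices instead.
- The hypergeometric over-representation test is a generic stand-in for
  pathway annotation; it conditions on the cluster and universe sizes and
  ignores gene-gene correlation.
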
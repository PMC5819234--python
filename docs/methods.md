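# Methods

This note documents the statistical model behind each stage of the
pipeline, the tunable parameters and their defaults, the synthetic data
the test suite relies on, and the design decisions taken where several
reasonable implementations exist.

## Gene filtering

**Model.** Under approximate normality of (possibly log-scale)
expression, per-gene sample variances behave like draws from an
inverse-gamma distribution (the conjugate family for normal variances).
We fit inverse-gamma(shape, scale) to the observed variances by maximum
likelihood (`scipy.stats.invgamma.fit` with location fixed at 0) and
assign each gene the upper-tail probability of its variance under the
fit. Genes with *p* < `filter_pval` are kept: the selection is
deliberately for improbably *high* variance, because genes whose
variance exceeds what the global noise model predicts are the ones
carrying structured (co-)expression signal. Filtering is unsupervised;
selecting by differential expression would bias the network toward the
contrast and undermine the scale-free topology assumption.

**Parameters.** `filter_pval` (default 0.1, dimensionless tail
probability) and `low_mean_fraction` (default 0.25): the lowest-mean
quarter of genes is removed before the fit, since near-silent features
contribute measurement noise with unstable correlations. If the MLE
fails to converge or returns an invalid solution, a moment-matching fit
(shape = m²/v + 2, scale = m·(shape−1)) is used and logged.
Zero-variance genes are excluded from the fit and never selected — their
downstream correlations are undefined. A fully constant matrix is a
degenerate-fit error rather than a silent empty result.

**Calibration.** When variances genuinely follow the fitted family, the
selected fraction converges to `filter_pval` as the gene count grows;
the suite checks 0.10 ± 0.03 at 2 000 genes × 50 samples and that
selections are nested across thresholds (raising the threshold never
drops a gene).

## Variance-stabilizing transform (RNA-seq counts)

Counts are modeled as negative binomial with a common dispersion α,
var = μ + αμ². α is estimated by least squares of (variance − mean)
against mean² across genes — the minimizer of
Σ((vᵢ−mᵢ) − αmᵢ²)², clamped at 0 — rather than per-gene dispersions,
which are far noisier at typical sample sizes. The matching VST is
x → (2/√α)·asinh(√(αx)) for α > 0 and the Poisson square-root limit
x → 2√x for α = 0. The suite verifies α recovery (0.2 → [0.1, 0.3]) and
that the ratio of post-transform variances between extreme mean deciles
falls in [0.5, 2] where it exceeds 5 (in practice ~6×10⁴) before.
Negative input values are an error directing the user to disable the
transform, not silently clipped.

## Soft-threshold selection

The adjacency is a(r) = |r|^β (unsigned, default) or ((1+r)/2)^β
(signed); the base correlation matrix (Pearson by default, Spearman
optional) is computed once and powered per β, so the curve over the
grid is exact and cheap. The scale-free fit index bins the
connectivities k into 10 equal-width bins, drops empty bins, regresses
log₁₀(bin frequency) on log₁₀(mean bin connectivity), and reports
−sign(slope)·R², so only *decreasing* degree distributions (the
power-law direction) can score high. Degenerate degree distributions
(all k equal, or fewer than two usable bins) score 0 with a warning.

β is the first grid value with R² > τ (default 0.8) whose *suffix*
{R²(β′): β′ ≥ β} has max–min spread < ε (default 0.1; window
configurable, default the full suffix). With ε = ∞ this reduces exactly
to the classical first-β-over-τ rule. When no β qualifies the run
aborts with per-candidate spread diagnostics unless a fallback β is
forced (logged prominently). φ is the trapezoidal area of max(R², 0)
over the grid divided by the enclosing rectangle of height 1 —
negative fit values are clamped so φ stays in [0, 1].

One empirical caveat the tests encode: a network built from *pure
noise* can score a high fit index at large β (its degree distribution
decays steeply, which log–log binning reads as power-law-like), so the
fit index alone does not certify signal. What separates structure from
noise on our fixtures is connectivity: independently permuting each
gene's samples collapses mean connectivity by more than 5× at the same
β.

## Module detection

Topological overlap, TOMᵢⱼ = (ℓᵢⱼ + aᵢⱼ)/(min(kᵢ,kⱼ) + 1 − aᵢⱼ) with
ℓᵢⱼ = Σ_{u≠i,j} aᵢᵤaᵤⱼ, is computed with the diagonal excluded from
all sums and checked against a brute-force triple loop to 1e-12. Genes
are clustered by average linkage on 1 − TOM (scipy; deterministic,
ties by lowest index).

The dendrogram cut is a static cut at `cut_height_fraction` (default
0.95) of the top merge height; branches with ≥ `min_module_size`
(default 20) members become modules. Two refinements follow:

* **Outlier trim** — members whose average dissimilarity to the rest of
  their module exceeds the Tukey fence (q75 + 1.5·IQR) of that
  statistic are demoted to "Uncorrelated" (modules are never trimmed
  below the size floor). This strips background genes that attach to a
  tight branch just below the cut.
* **PAM-like re-assignment** — each unassigned gene joins the module
  with the smallest average dissimilarity, but only if that average is
  (a) below its average dissimilarity to all other genes and (b) no
  larger than the module's own mean intramodular dissimilarity.
  Condition (b) matters: uncorrelated background is nearly equidistant
  from every module, so a nearest-module rule alone absorbs it wholesale.

This simplified adaptive cut stands in for the full Dynamic Hybrid
tree-cut algorithm, whose many internal constants are not part of this
package's contract; the planted-module benchmarks (ARI = 1.0 at both
noise levels, see below) define the accuracy bar it must meet.
`min_module_size` = 20 reflects the scale at which a module eigengene
and its enrichment statistics become stable. Labels are M1…Mk by
decreasing size; "Uncorrelated" genes are kept in all outputs but
excluded from ORA, GSEA and hub ranking.

**Eigengenes and merging.** A module eigengene is the unit-norm first
right singular vector of the member × sample matrix of standardized
expression, sign-oriented to correlate non-negatively with the module
mean profile; variance explained is s₁²/Σs². Optional merging
(off by default) iteratively joins the pair of modules with the highest
eigengene correlation while it exceeds `merge_threshold` (default 0.8,
strict inequality), recomputing eigengenes after each merge; it never
increases the module count and is idempotent at a fixed point.

**Hubs.** Intramodular connectivity (summed adjacency to other
members) ranks the top 10 hubs per module, ties broken alphabetically.
The interactome stage separately reports interaction-graph degree;
the two notions are deliberately kept apart and named apart.

## Enrichment

**ORA.** p = P(X ≥ overlap) under the hypergeometric distribution on
the filtered-gene universe, computed with `scipy.stats.hypergeom`;
BH adjustment is applied *within each module across gene sets*, which
matches how per-module results are presented and keeps a module's
rows self-contained. Exactness is checked against direct combinatorial
enumeration on all universes up to 30.

**GSEA.** Preranked, per (module × class): genes are ranked by the
class's mean z-score (each gene z-scored across all samples first, so
class scores are contrasts against the pooled baseline; a single-class
annotation yields all-zero scores and is accepted as a degenerate
case). The running sum gains |score|¹/Σ|score| at member genes and
loses 1/(N−N_hit) elsewhere; ES is the extremum of largest magnitude.
The null permutes *gene labels* (n_perm draws, default 1000, seeded;
one spawned stream per module so results don't depend on which other
modules exist): sample-permutation nulls are unstable at the small
class sizes these designs typically have. Nominal
p = (#{same-sign |ES*| ≥ |ES|} + 1)/(n + 1); NES = ES / mean same-sign
|ES*|; BH across all module × class pairs. Because gene-label
permutation ignores inter-gene correlation, strongly co-expressed
modules can reach significance from chance class imbalance of their
shared factor — the planted-truth test therefore checks the *planted*
module's direction and significance rather than asserting that
unplanted modules stay null.

**CES.** The combined enrichment score condenses a run's ORA output to
one number: the geometric mean over modules of each module's minimum
BH-adjusted p (1 for modules with no rows). It lies in (0, 1], equals 1
when nothing is enriched, and strictly decreases when any module's best
adjusted p improves. This compact construction honors the score's
intended direction (lower = more enriched) but is an approximation of
our own design, not a reference formula.

## Interactome graphs

Per module, the subgraph of interaction edges touching ≥ 1 member;
non-member endpoints are added with origin `interaction_added`
(one-hop expansion only — deeper expansion would change the graph's
meaning from "the module in its interaction context" to a
neighborhood crawl). Degree is counted on the resulting graph and the
top-10 nodes by degree are flagged for labeling.

## Synthetic data

`simulate_modular_expression` is a Gaussian factor model: module m has
a latent factor f_m ~ N(0, 1) per sample (plus optional per-class
shifts in sd units — the planted ground truth for GSEA direction);
member genes are λ·f_m + σ·ε with ε ~ N(0, 1); background genes are
pure N(0, 1). Defaults: 5 modules × 50 genes, 250 background genes,
20 + 20 samples in classes control/disease, λ = 0.9, σ = 0.5 —
within-module correlation λ²/(λ²+σ²) ≈ 0.764, a realistic strength for
a well-defined transcriptional module. `simulate_nb_counts` draws
negative-binomial counts with common dispersion and log-uniform means
over [1, 1000] (the dynamic range of a typical bulk library after
light filtering). `simulate_interactions` draws Bernoulli edges with
separate within-/between-module probabilities. All generators are pure
functions of (config, seed).

What this emulates — and what it does not: the factor model gives the
block-correlation geometry, class-specific module activity and
uncorrelated background that every stage assumes, with closed forms to
test against (within-module correlation, the latent factor as the true
eigengene). It does *not* emulate heavy-tailed microarray noise, batch
effects, overlapping modules, hub-dominated intra-module topology, or
gene-length/GC biases of RNA-seq. Passing the planted-truth benchmarks
therefore demonstrates correctness of the algorithms under their own
modeling assumptions, not robustness to every artifact of real data.

Note that the variance filter is near-blind on this generator by
construction (module genes have variance λ²+σ² ≈ 1.06 vs background
1.0), so module-recovery benchmarks run detection on the full planted
matrix at a fixed β = 6 — the standard default power for unsigned
networks — rather than through the filter; filter calibration is
benchmarked separately on its own matched generator (normal genes with
inverse-gamma variances).

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1]; adjacency diagonals stored as 1
  but excluded from every connectivity and TOM sum.
* TOM output is symmetrized and clipped to [0, 1]; asymmetric input is
  an error, not silently fixed.
* Expression TSVs are parsed with correctly-rounded float conversion so
  write→read round-trips are bit-exact; missing values are rejected
  (imputation would silently change correlations), duplicate gene ids
  collapse to the highest-mean row (the common probe-collapse
  convention), and errors name the offending cell.
* All output tables have fixed column order and deterministic row
  order; re-running with identical inputs and seed is byte-identical,
  including the HTML report (salted SVG hashing, timestamps stripped).
* Problem sizes in the test and acceptance workloads (≤ 2 000 genes,
  ≤ 50 samples, 1 000 permutations, universes ≤ 30 for exhaustive
  enumeration) are chosen so every oracle can be brute-forced exactly
  while the statistics remain stable.

## Known limitations

* The dendrogram cut is a static-height approximation of dynamic
  tree-cut; deeply nested modules separated only below the cut height
  will be merged.
* The gene-label GSEA null understates the variance of ES for strongly
  co-expressed sets (see above); treat unplanted significant calls on
  tight modules with caution.
* CES is an in-house summary; its absolute values are comparable across
  runs of this package only.
* Single common VST dispersion: genes with genuinely outlying
  dispersion are only partially stabilized.
* No probe-to-gene mapping, batch correction or network preservation
  statistics; inputs are assumed already normalized apart from the
  optional VST.
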
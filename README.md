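# coexmod

Automated modular gene co-expression network analysis for bulk
transcriptomics (microarray or normalized RNA-seq). From a single
genes × samples expression matrix, `coexmod` discovers co-expression
modules and characterizes them functionally, with no manual parameter
picking in between:

1. **Gene filtering** — per-gene sample variances are modeled as an
   inverse-gamma distribution; genes with upper-tail probability
   *p* < 0.1 under the fitted distribution are kept, after first
   dropping the 25 % of genes with lowest mean expression. For
   count-like RNA-seq data a negative-binomial variance-stabilizing
   transform, *x* → (2/√α)·asinh(√(αx)) with a common dispersion α
   estimated from the quadratic mean–variance relation, can be applied
   first (`--apply-vst`).
2. **Soft-threshold selection** — gene–gene correlations are raised to
   a power β (unsigned: *a* = |r|<sup>β</sup>; signed:
   *a* = ((1+r)/2)<sup>β</sup>). The scale-free fit index R²(β) — the
   signed coefficient of determination of the log–log regression of
   the binned degree distribution — is computed for β = 1…20, and β is
   chosen as the first value with R² > τ (= 0.8) whose remaining R²
   suffix varies by less than ε (= 0.1), a Cauchy-sequence-style
   stabilization rule. The whole curve is summarized by
   φ = AUC(β × max(R²,0)) / (β-range × 1) ∈ [0, 1].
3. **Module detection** — average-linkage clustering on the
   topological-overlap dissimilarity 1 − TOM, where
   TOM<sub>ij</sub> = (ℓ<sub>ij</sub> + a<sub>ij</sub>) /
   (min(k<sub>i</sub>, k<sub>j</sub>) + 1 − a<sub>ij</sub>); the
   dendrogram is cut adaptively, small branches become "Uncorrelated",
   and modules are labeled M1…Mk by decreasing size.
4. **Functional analysis** — per-module hypergeometric
   over-representation (ORA) against a GMT gene-set collection with
   Benjamini–Hochberg correction; per-phenotype preranked GSEA using
   each module as a gene set and class-mean z-scores as rankings, with
   a gene-label permutation null and NES normalization; intramodular
   hub ranking; and, given an interaction file, per-module
   protein–protein interaction subnetworks with origin-flagged nodes.

Everything is emitted as deterministic TSV/GMT/JSON tables plus a
static HTML report.

## Worked example

```bash
coexmod simulate --output-dir data --seed 6 --n-modules 3 \
    --genes-per-module 40 --n-background 60 --samples-per-class 15
coexmod run --expression data/expression.tsv \
    --annotation data/annotation.tsv \
    --interactions data/interactions.tsv \
    --output-dir out --filter-pval 0.95 --low-mean-fraction 0 \
    --force-beta 6 --seed 4
```

prints

```
selected beta=6 phi=0.378 modules=3 -> out
```

meaning: the soft-threshold fell back to the forced β = 6 (the
synthetic factor-model curve stabilizes below τ so the automatic rule
declines to pick — expected for this fixture), the β × R² curve covers
37.8 % of its enclosing rectangle, and three co-expression modules
were detected — matching the three planted modules. `out/` then holds
`modules.tsv`, `modules.gmt`, `beta_curve.tsv`, `gsea.tsv`, `hubs.tsv`,
per-module interaction tables, `summary.json` (all parameters + seed)
and `report.html`.

The same pipeline is available as a library of scikit-learn-style
estimators that compose with sklearn tooling:

```python
from coexmod import SoftThresholdNetwork, TomModuleDetector

net = SoftThresholdNetwork(force_beta=6).fit(X)   # X: samples x genes
labels = TomModuleDetector(min_module_size=20).fit_predict(net.tom_)
```

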
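# mlhgrn

Bottom-up construction of **multilayered hierarchical gene regulatory
networks (ML-hGRNs)** operating above a biological pathway, from small- to
medium-sized expression compendia (microarray or RNA-seq).

## The problem

Genes of a metabolic or canonical pathway sit at the bottom of a regulatory
hierarchy: a layer of transcription factors (TFs) controls them directly,
managed in turn by higher-level regulators. Pairwise association methods
recover *connectivity* but not *hierarchy*. `mlhgrn` builds the hierarchy
layer by layer, starting from the pathway genes, using a triplet-gene
interference test rooted in the graphical Gaussian model.

## The model

For two same-layer genes *x*, *y* and a candidate regulator *z*, compare the
Spearman correlation r<sub>xy</sub> with the first-order partial correlation

&nbsp;&nbsp;&nbsp;&nbsp;r<sub>xy|z</sub> = (r<sub>xy</sub> − r<sub>zx</sub> r<sub>zy</sub>) / √((1 − r<sub>zx</sub>²)(1 − r<sub>zy</sub>²))

*z* **interferes** with the pair when its presence significantly enhances or
impairs their coordination. With p₁, p₂ the p-values of r<sub>xy</sub> and
r<sub>xy|z</sub>, four circumstances arise: only p₁ significant → interference;
only p₂ significant → interference; neither → discard; both → test
D = r<sub>xy</sub> − r<sub>xy|z</sub> directly. The variance of D comes from the
multivariate delta method, var(D) = **pd**ᵀ Σ **pd**, where **pd** is the
gradient of D in (r<sub>xy</sub>, r<sub>zy</sub>, r<sub>zx</sub>) and Σ the asymptotic
covariance of the three sample correlations; z₁ = D/√var(D) is referred to
N(0, 1) (p₃).

Per layer, interference p-values are corrected for multiple testing
(Benjamini–Hochberg by default), interfered pairs are counted per regulator,
and the regulators kept for the new layer are chosen by top-*k*,
top-percent, or **weighted sparse CCA**: maximize uᵀXᵀYv − λ‖W∘v‖₁ with
‖u‖₂ = ‖v‖₂ = 1, where Wᵢ = max count − countᵢ shields the strongest
interferers from the sparsity penalty and λ is chosen by cross-validation.
Kept regulators become the next bottom layer and are removed from the pool;
construction repeats until the requested depth, or stops when a layer
selects nothing.

## Worked example

Simulate a ground-truth benchmark (12 pathway genes, 8 true regulators in
two tiers, 40 decoys, 100 samples) and build the network above it:

```bash
mlhgrn simulate --n-bottom 12 --n-positive 8 --n-decoy 40 --tiers 2 \
    --samples 100 --seed 7 --out syn
mlhgrn build --pathway syn.pathway.tsv --regulators syn.regulators.tsv \
    --layers 2 --select topk --k 8 --seed 7 --out net
```

which prints

```
layers (bottom first): 12, 8; stop: no_regulators_selected
```

meaning the 12 pathway genes form layer 0, 8 regulators were placed in the
layer above them, and construction then stopped on its own because no
further regulator passed the corrected interference screen. Checking
`net.layers.tsv` against `syn.roles.tsv` shows all 8 selected regulators
are the 8 true ones, and `net.sif` lists the regulator→gene edges, e.g.

```
g25	regulates	g01
g25	regulates	g11
```

Outputs per run: `<out>.layers.tsv` (gene, layer, interference count),
`<out>.edges.tsv`, `<out>.sif`, `<out>.graphml` (layer attribute on nodes),
`<out>.triplets.tsv` (every retained triplet with its correlations and
p-values), `<out>.log`. The same pipeline is available programmatically via
`mlhgrn.build_ml_hgrn(pathway_df, regulators_df, config=RunConfig(...))`.

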
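# epinet

Weighted epigenetic network analysis for two-group tissue cohorts:
co-methylation and chromatin-modification networks over a
protein-interaction background, disease seed subnetworks, permutation null
models, dense-module mining, and statistical detection of "interplay"
between the two epigenetic layers.

## The problem

DNA methylation and chromatin modifications jointly dysregulate pathways
in complex disease (the motivating case is type 2 diabetes islet tissue).
Given

- a background interactome (SIF edge list),
- a gene × sample methylation beta matrix with control/case labels,
- per-mark chromatin peak files (BED) and a TSS table,
- a gene × sample expression matrix,

the pipeline (1) calls differentially methylated genes with a SAM-style
moderated statistic d = (x̄_case − x̄_control)/(s + s0) and a
permutation FDR; (2) keeps interactions whose endpoint profiles correlate
(|r| > 0.8, p < 0.05) to form the weighted methylation network (WMPN) and,
from five-mark promoter intensity vectors, the weighted chromatin network
(WCPN); (3) extracts the methylation seed subnetwork (TMSN = called genes +
first neighbours) and the chromatin subnetwork (TCSN = WCPN induced on the
TMSN genes); (4) compares their topology against global random-seed nulls
and local degree-preserving rewiring nulls with add-one empirical
p-values; (5) mines dense modules (MCODE-style core-density weighting) on
both giant components; (6) scores every methylation × chromatin module
overlap x with the exact upper-tail cumulative hypergeometric probability

    P(X ≥ x) = 1 − Σ_{k=0}^{x−1} C(M,k) C(N−M,H−k) / C(N,H)

(Bonferroni over pairs with overlap ≥ 3); and (7) regresses mean
expression on mean methylation (Spearman rho, OLS line, 95% prediction
band). A synthetic-data module generates all four inputs with planted
truth so every stage is testable without downloads. See
`docs/methods.md` for the full model description.

## Worked example

The numbered scripts under `analysis/` run the whole study on generated
data (outputs under `results/`):

```
python analysis/01_generate_data.py
python analysis/02_differential_methylation.py
python analysis/03_methylation_network.py
python analysis/04_chromatin_network.py
python analysis/05_modules_interplay.py
python analysis/06_methylation_expression.py
```

Step 02 prints

```
called 101 genes at q < 0.05 (s0 = 0.01681)
sensitivity vs planted truth: 1.000; false calls: 1
```

— all 100 planted hypomethylation events (Δβ = 0.3, 11 vs 5 samples) are
recovered with one false call. Step 03 shows the seed subnetwork is
non-random:

```
WMPN: 2000 nodes, 849 edges
TMSN: 102 nodes, 847 edges
global null n_nodes: observed 102 vs null mean 141 (tail le, p = 0.00995)
global null mean_clustering: observed 0.741 vs null mean 0.272 (tail ge, p = 0.004975)
```

— seed subnetworks are smaller and far more clustered than any of 200
random-seed replicates (p ≈ 1/201 is the add-one floor). Step 05 finds the
planted interplay:

```
methylation modules: [('M1', 40)]
chromatin modules: [('M1', 40)]
1 candidate pairs (overlap >= 3) over N = 101; 1 significant after Bonferroni
  M1 x M1: overlap 40 (40 in the planted core), corrected p = 4.39e-29
```

— the one Bonferroni-significant module pair is exactly the 40-gene core
that was planted as a dense, chromatin-correlated community. Step 06
recovers the expression coupling:

```
spearman rho = -0.9160 (p = 0)
fitted line: y = -2.821x + 7.570 (residual sd 0.165)
1901/2000 genes (95.0%) inside the 95% prediction interval
```

— the generating line was y = −2.793x + 7.561, and the prediction band
covers the nominal 95%.

The same pipeline is available as one command (`epinet demo --out DIR`),
stage by stage (`epinet diff|build-network|map-peaks|null|modules|
interplay|meth-expr`), or from a YAML config (`epinet run --config
config.yaml --out DIR`).

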
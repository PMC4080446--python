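# Methods

## Overview

`epinet` implements a network view of epigenetic dysregulation in a
two-group (control vs disease) tissue cohort. Its running example is type 2
diabetes islet data: a small methylation-array cohort (11 control vs 5
case samples of beta values), five chromatin marks (H3K4 methylation
states, H3K79me2, DNase hypersensitivity, CTCF) as ChIP-seq/DNase-seq peak
sets, a larger expression cohort, and a protein-interaction background.
The pipeline asks three questions: (1) which genes change methylation
state, (2) do those genes occupy a coherent, non-random region of the
interactome on both the methylation and chromatin layers, and (3) do the
dense modules of the two layers overlap more than chance — the "interplay"
between DNA methylation and chromatin modification.

## Differential methylation (SAM-style moderated statistic)

For gene *i*, d_i = (x̄_case − x̄_control)/(s_i + s0) where s_i is the
pooled two-sample standard error and s0 a fudge constant chosen by the
classic percentile search: candidates are the 0,5,…,100th percentiles of
the s_i distribution, and the winner minimises the coefficient of variation
of the per-bin median absolute deviation of d across s_i-quantile bins (25
bins by default, fewer for small gene counts; fallback median(s_i) when
the search is degenerate, e.g. constant s_i). With s0 = 0, d is exactly the
equal-variance two-sample t statistic.

False-discovery rates come from group-label permutations. All distinct
case/control label assignments are enumerated when there are no more than
`n_perm` of them, otherwise `n_perm` distinct assignments are sampled
without replacement. For the symmetric cutoff |d| ≥ c the estimated FDR is
the median across permutations of #{|d*| ≥ c} divided by the observed
#{|d| ≥ c}; per-gene q-values are made monotone nonincreasing in |d| by a
step-down suffix-minimum pass. No π0 shrinkage is applied, which makes the
q-values conservative; the null-calibration test shows the realised
false-call fraction at q < 0.05 stays at or below the nominal level.
Classification thresholds are inclusive: mean beta ≤ 0.2 is
hypomethylated, ≥ 0.8 hypermethylated.

## Chromatin peak mapping

A gene's TSS-proximal region is the strand-independent window
[TSS − 2000, TSS + 2000], inclusive at both ends and clipped at zero. A
peak is located by its midpoint floor((start + end)/2) (BED half-open
coordinates); every gene whose window contains the midpoint accumulates
the peak's score. Deliberate conventions where the underlying idea admits
several readings: a midpoint inside two genes' windows counts for both; a
gene with several TSS rows counts a midpoint once (windows are unioned);
"intensity" is the sum of peak scores, not the peak count.

## Weighted networks and seed subnetworks

An interaction of the background survives into the weighted methylation
network (WMPN) when the endpoint beta profiles satisfy |Pearson r| > 0.8
(strict) and two-sided p < 0.05 (strict), with p from t = r·√(df/(1−r²)),
df = n − 2. The chromatin network (WCPN) applies the same rule to the
five-long per-mark intensity vectors; at df = 3 the p filter requires
|r| ≳ 0.878 and is therefore the stricter of the two — both are applied as
stated. Zero-variance profiles are skipped (their correlation is
undefined), and genes lacking a profile are dropped from the node set. By
default correlations use all samples of both groups; the disease-vs-control
shift of co-regulated genes is itself a major source of correlation signal.

The methylation seed subnetwork (TMSN) is the called genes plus their
first neighbours with all induced edges; the chromatin subnetwork (TCSN)
is the WCPN induced on the TMSN gene set. Topology summaries report mean
degree, mean local clustering coefficient (0 where degree < 2), mean
*non-normalized* shortest-path betweenness, and a degree-distribution
exponent estimated as the negative slope of a least-squares line of log10
count vs log10 degree over degrees with nonzero counts. The regression
estimator (rather than a maximum-likelihood power-law fit) is deliberate:
it reproduces the descriptive exponents this style of analysis reports,
which can fall below 1.

## Permutation nulls

*Global null*: B replicates each sample a seed set of the observed size
uniformly from the parent network and rebuild the subnetwork (neighbourhood
extraction for the methylation side; induced subgraph for the chromatin
side, matching how TCSN is built). *Local null*: B degree-preserving
randomizations of a connected component by double-edge swaps — pick edges
(a,b),(c,d) with four distinct endpoints, replace with (a,d),(c,b) if
neither exists — until accepted swaps reach ceil(0.5·|E|); rejected
proposals do not count, and if no valid swap can be found within 100·|E|
proposals (e.g. a triangle) the achieved graph is returned with a warning.
Weights are dropped in the rewired replicates: the null is topological.

Empirical p-values use the add-one rule p = (1 + #beyond)/(B + 1), so
p ≥ 1/(B+1) and is never zero. The tail (≥ or ≤) is chosen per statistic
by where the observed value sits relative to the null mean and is reported
alongside p.

## Dense modules and interplay

Module mining follows the MCODE scheme. A vertex's weight is k_max times
the edge density of the k_max-core of its closed neighbourhood, where
k_max is the largest k with a non-empty core; vertices below the degree
cutoff (2) weigh zero. Modules grow greedily from the heaviest unvisited
vertex (ties by node id), admitting unvisited neighbours with weight ≥
(1 − 0.2) × seed weight, breadth-first; a single haircut pass then removes
vertices with fewer than two module-internal edges, and modules below 3
genes are dropped. Modules are vertex-disjoint. The "fluff" post-processing
step is not implemented (off in typical use). Note that expansion can walk
across a high-weight bridge between two equally dense regions — two cliques
joined by a direct edge merge into one module; joined by a low-degree
bridge node they are recovered separately.

The interplay test: for a methylation module of size M and a chromatin
module of size H over a background of N genes, the overlap x is scored by
the exact upper-tail cumulative hypergeometric probability
P(X ≥ x) = 1 − Σ_{k=0}^{x−1} C(M,k)·C(N−M,H−k)/C(N,H), computed in log
space (gammaln + logsumexp) for stability. N defaults to |TMSN ∪ TCSN|
genes, since the TCSN gene set derives from TMSN's; an explicit N can be
supplied for the additive reading. Pairs with overlap ≥ 3 are the tested
candidates; the Bonferroni factor is the number of candidates, and
corrected p < 0.05 declares an interplay module.

## Methylation-expression regression

Each gene shared by the two matrices contributes one point: case-group
mean beta (x) against case-group mean expression (y). Spearman's rho uses
average ranks, with an error on zero rank variance. The OLS line carries a
95% prediction interval ŷ(x0) ± t_{0.975,n−2}·s·√(1 + 1/n + (x0−x̄)²/Sxx);
genes whose point lies inside the band are flagged as candidates for
methylation-driven expression. The "inside the band" reading is
deliberate: the band describes where expression of a methylation-governed
gene should fall, so points far outside it are the ones whose expression
the linear methylation model does not explain.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes,
with truth sets for sensitivity/FDR measurement:

- **Interactome** — preferential-attachment (Barabási–Albert) graph,
  default 2000 genes, 4 edges per new node: connected, heavy-tailed.
  A dense community (each absent pair added with probability 0.9) is
  planted on the 40 "core" genes — the protein-complex analogue that makes
  a dense module exist by construction.
- **Methylation** — control per-gene means from a mixture: Beta(1,20)
  (weight 0.59, hypomethylated), Beta(20,1) (weight 0.06, hypermethylated),
  Beta(5,5) otherwise, giving the observed bimodal control distribution
  with ~59%/6% class fractions. These shape parameters put ≈99% of each
  extreme component beyond its threshold, so the mixture weights are
  directly interpretable as expected class fractions. 100 planted genes
  in one interactome neighbourhood (BFS from the highest-degree node) take
  control means uniform on [0.4, 0.85] and a case-group decrease of 0.3 —
  disease hypomethylation events. Per-sample Gaussian noise (sd 0.05),
  clipped to [0,1]. 11 control vs 5 case samples.
- **Chromatin** — per-mark peak sets whose mapped intensities follow a
  shared mark profile (uniform 1–10) times a per-gene scale with 5%
  multiplicative noise for the core genes (pairwise r ≈ 1 across marks),
  and independent uniform intensities elsewhere; background peaks fall in
  inter-promoter gaps. Five marks, TSS spacing 10 kb so ±2 kb windows are
  disjoint.
- **Expression** — intercept 7.561 + slope (−2.793) × group mean beta plus
  Gaussian noise (sd 0.5); 54 control vs 9 case samples.

Not emulated: array probe chemistry, batch effects, read-level ChIP-seq
data, overlapping promoters, missing values. Passing recovery tests
therefore show the estimators work under the model's assumptions (bounded
bimodal betas, linear coupling, independent noise), not that they are
robust to the artefacts of real arrays.

## Problem sizes and numerical choices

Default analysis and test problem sizes — 2000 genes, 200 permutations for
the FDR, B = 200 null replicates in the bundled demo (B = 1000 remains the
config default for full runs) — were chosen so the planted signals are
comfortably detectable while a complete run stays in the tens of seconds.
Seeds: one top-level seed derives per-stage seeds through
`numpy.random.SeedSequence.spawn`, so every stage is individually
reproducible and a rerun is bit-identical (reports match up to the
recorded wall-clock runtime). Ties in module seeding and giant-component
selection break deterministically (weight then node id; size then edge
count then smallest node id). Degenerate inputs raise rather than coerce:
empty networks for topology, zero-variance genes at s0 = 0, infeasible
hypergeometric arguments, malformed files (with line numbers).

## Known limitations

- The permutation FDR with 16 samples has a granular null (4368 distinct
  label assignments); q-values below ~1/n_perm are not resolved.
- MCODE-style mining is greedy and order-dependent by design; only the
  documented tie-break makes it deterministic, and near-threshold weights
  can split one planted community into adjacent modules.
- The correlation p-value uses the t approximation, exact only under
  bivariate normality; with five chromatin marks the test is very coarse.
- The global null compares against uniformly random seed sets; it does not
  condition on the degree distribution of the observed seeds (that is the
  local null's role).
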
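# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices, and the known limitations of the package.

## Count contrasts (negative binomial)

Counts are modelled per gene as NB with mean $\mu_{ij} = s_j e^{\beta_{c(j)}}$
and variance $\mu + \alpha\mu^2$: a log link, size-factor offsets, and one
mean parameter per condition without an intercept, so a contrast is the
difference of two condition means. Size factors are median-of-ratios
against the per-gene geometric mean over features positive in all samples
(a `pseudo_reference` flag rescues matrices without such features),
rescaled to geometric mean 1.

Dispersion estimation is the delicate part at 3 replicates per condition:

1. per-gene ML dispersion by alternating Newton fits of the condition
   means and a golden-section search on $\log\alpha$ (floored at 1e-8),
   followed by the first-order degrees-of-freedom bias correction
   $\hat\alpha \cdot n/(n-p)$;
2. a mean–dispersion trend $\alpha(\mu) = a_0 + a_1/\mu$ fit by least
   squares to the per-gene estimates;
3. empirical-Bayes shrinkage of $\log\hat\alpha$ toward the trend. The
   between-gene prior variance is the excess of the observed robust spread
   (squared MAD) of the trend residuals over the estimator's sampling
   spread; the sampling spread is measured by rerunning the whole
   dispersion estimator once on a parametric bootstrap drawn under the
   trend. When the observed spread is within 15% of the bootstrap spread
   the genes are treated as sharing the trend dispersion and the
   per-gene noise is shrunk away almost entirely (prior-variance floor
   0.01).

The bootstrap is drawn with a fixed internal seed and with sample columns
in a canonical (condition, sample-id) order, so results are deterministic
and invariant to column permutation. The Wald statistic
$(\hat\beta_B-\hat\beta_A)/SE$ uses expected information and a standard
normal reference. Genes with zero counts in both contrasted conditions get
missing statistics. This is intentionally simpler than the full DESeq2
machinery (no Cox–Reid adjustment, no LFC shrinkage, no outlier
replacement, no independent filtering); on null synthetic data at the
default design (3 vs 3, 2000 genes, 20 seeds) the empirical type-I error
is within one percentage point of nominal, which is what the test suite
asserts.

## Intensity contrasts (moderated linear model)

Intensities are log2-transformed, quantile-normalised (the reference
distribution is the mean of the sorted columns over complete-case
features; each column's non-missing values are replaced by the reference
at their tie-averaged ranks, and missing values stay missing), and tested
with a two-group linear model on the contrasted conditions only. With
moderation the per-protein variances are shrunk toward a scaled
inverse-chi-square prior whose parameters $(d_0, s_0^2)$ come from the
log-scale method of moments (trigamma inversion); zero-variance proteins
receive the shrunken variance so their p-values are defined. Without
moderation the test is exactly the classical pooled two-sample t (and
zero-variance proteins are set missing). BH FDR is applied within each
contrast separately.

## Activity inference

The signature is $z = \mathrm{sign}(\mathrm{log2FC})\,\Phi^{-1}(1-p/2)$,
clipped at $|z| \le 38$, with rank-based normal scores $q2$ (signed) and
$q1$ (magnitude). A regulon's NES is the $L^2$-weighted sum given in the
README; because $q1, q2$ are rank-normal, NES is standard normal under
target-label exchange, so p-values are analytic (no permutation null) and
this is verified distributionally (KS) in the tests. The leading edge is
the smallest prefix of targets, ordered by decreasing signed contribution
(ties lexicographic), whose partial sum reaches 90% of $|NES|$ — the 90%
threshold is a package definition, exposed as a parameter.

Shadow analysis considers ordered pairs of significant regulators with
target-set Jaccard ≥ 0.1 and rescores each member with the shared targets
removed. If exactly one member keeps its significance on its unique
targets, it shadows the other. If both lose, the regulator with the larger
original |NES| shadows the weaker (an exact tie shadows mutually): a
regulator whose entire signal survives on unique targets cannot be
explained away, and between two regulators that both depend on the overlap
the stronger enrichment is the more parsimonious source. In-degree ≥ 1
marks a regulator whose apparent activity is at least partly borrowed.

## Network integration

Shortest paths are unweighted (hop count); the STRING combined score only
gates edge retention (default ≥ 0.4, with 0–1000 scores auto-rescaled).
"All shortest paths" means all geodesics per seed pair: a node lies on one
iff $d(s,v)+d(v,t)=d(s,t)$, an edge iff it advances one BFS level, so the
subgraph is computed from per-seed BFS distance fields and is independent
of seed order. Seed pairs in different components are skipped with a log
entry. Betweenness is the standard normalised betweenness on the extracted
subgraph, and node importance is degree × betweenness.

Subnetwork significance is reported two ways: a one-sided Fisher exact
test for enrichment of significant non-seed proteins among subgraph
non-seed nodes (background: all PPI nodes minus seeds), and an empirical
p-value for subgraph size against degree-preserving double-edge-swap
nulls (default 10 networks, 10 swaps per edge; rigid graphs are returned
unchanged). The Fisher test carries the inferential weight since 10
randomisations cannot produce small p-values.

Louvain clustering runs with a fixed seed and resolution 1.0; community
activity is $N_{up}-N_{down}$ with ties labelled "balanced" (connector
nodes count as no direction). Modularity Q is reported per partition.
Cluster matching takes, for each community of one partition, the maximal
Jaccard match in the other (ties to the smaller index).

## Gene-set analysis

Preranked GSEA uses the weighted KS statistic (hit increments
$\propto |r|^p$, $p=1$; miss decrements $1/(N-N_h)$) with a plain
gene-label permutation null — a deliberate simplification of fgsea's
adaptive multilevel estimator; `n_perm` bounds the attainable p-value. NES
divides ES by the mean |null ES| of matching sign. A set equal to the
whole universe scores 0 by definition. The GSVA-style score transforms
each gene by a Gaussian-kernel CDF across samples (bandwidth sd/4, floored
at 1e-6), ranks genes within each sample, and walks the ranking with
|centred rank| weights; the default score is the signed sum of the two
extrema (`mx_diff`), clamped to [−1, 1]. The group test for sample scores
is Mann–Whitney (exact enumeration for groups ≤ 20 without ties); the
choice of a rank test is the package's own, made for robustness at n = 87.

## Synergy

Replicate wells are averaged on the viability scale; fa = 1 − viability is
clamped to [1e-3, 1−1e-3] so 0%/100% wells stay usable, and stimulation
(viability > 1) clamps with a log note. The median-effect line is fit by
OLS of logit10(fa) on log10(dose) (≥ 3 distinct doses; a non-positive
slope only warns). CI uses the mutually exclusive Chou–Talalay form
without the cross-term, matching the CompuSyn default; the two dose-ratio
terms are the isobologram coordinates and sum to CI, and CI is invariant
to a common rescaling of dose units.

## Synthetic-data design

The generator's defaults mirror the study design the package targets:
three conditions × 3 replicates, 2000 genes, 50 regulators of 20 targets
(planted regulons disjoint so PPI modules are separable), 10 regulators
shifted by ±1 log2 unit of activity in the resistant state of which 3
persist through reversal, NB dispersion 0.05, log-normal depth factors
(sd 0.15). Proteins are the regulators (whose abundance tracks their
activity, guaranteeing concordant seeds) plus 800 genes (affine in the
log2 RNA signal, gene-level offsets sd 0.25, 30 protein-only effects of
±1). The PPI plants one ~25-node module per reverting regulator
(intra-module edge probability 0.3) in a Chung–Lu background (Pareto 2.5
weights, mean background degree 4); modules anchor on *reverting*
regulators so the planted communities carry signal in both the resistant
and the reversal contrast. The cohort is 87 patients (30% responders),
1500 Gaussian log-expression genes, a 50-gene set shifted +1 sd in
responders. Dose-response truth is m = 1.2, Dm = 830 nM and m = 1.0,
Dm = 2000 nM on a seven-point two-fold dilution series with 12 replicate
wells (viability noise sd 0.01) — a realistic luciferase-assay layout in
which every noise-free fa sits inside the clamp window; combination points
are constructed from the single-agent curves to achieve the configured
true CI (default 1.0) with 6 replicate wells.

What the generator does *not* emulate: batch effects, sample swaps,
peptide-level proteomics (missingness is absent by default and handled
pairwise when present), regulon misspecification, PPI false edges beyond
the random background, or dose-response outliers. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
models, not robustness to real-data pathologies.

## Numerical choices and degenerate inputs

Dispersion floor 1e-8; Newton steps clipped to ±5 with means clipped to
$e^{\pm 30}$; fa clamp 1e-3; GSVA bandwidth floor 1e-6; odds ratios use a
0.5 continuity correction when a table cell is zero; BH is computed over
non-missing p-values only and missing stays missing; empty filter results
and empty seed sets warn rather than fail; ties in leading edges, cluster
matching and importance rankings break lexicographically / by smaller
index. All stochastic steps (rewiring, Louvain, GSEA permutations,
simulation) take explicit seeds and are reproducible bit-for-bit.

## Problem sizes

The test suite and the acceptance script run the full design above:
calibration checks use 20 independent simulations of 2000 genes; oracle
checks run exhaustive enumeration on graphs of ≤ 30 nodes and exhaustive
partition search on ≤ 8 nodes; GSEA calibration uses 200 random sets at
200 permutations. These sizes give stable acceptance statistics while
keeping a full run in the order of a minute on one CPU.

## Known limitations

- The NB model fits one mean per condition only; multi-factor designs and
  batch covariates are out of scope.
- The Wald normal reference is mildly anti-conservative at very small
  replicate numbers even with exact dispersion; calibration is verified
  at the default design, not for n = 2.
- The aREA reduction omits VIPER's three-tail interaction term and
  sample-wise (single-sample) scoring.
- GSEA p-values are bounded below by 1/(n_perm+1).
- The shadow-analysis loss rule and the 90% leading-edge threshold are
  package definitions; both are parameters, and counts that depend on
  them should be compared qualitatively across settings.
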
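# Methods

## The design and the estimands

The pipeline analyses a reciprocal-transplant design: three populations
(two lowland, L1 and L2; one derived highland, H) each split between a
low-altitude garden (l) and a high-altitude garden (h). Per gene, four
log2-scale quantities are estimated from group means:

| quantity | contrast | meaning |
|---|---|---|
| PC | lowland birds, garden h vs l | ancestral plastic response |
| GC | H vs lowland, garden h | genetic-based change in the derived environment |
| GC_b | H vs lowland, garden l | the same contrast back in the ancestral environment |
| TC | = PC + GC | total change, native environment vs native environment |

Plasticity is *reinforcing* when PC and GC share a sign and *reversing*
when they oppose. Plasticity *persists* when the population contrast is
environment-independent (GC_b ≈ GC) and has *evolved* when the populations
converge back in the ancestral garden (GC_b ≈ 0); the ratio r = GC_b/GC
operationalizes this with half-open bins — binary: persisting r ∈ [0.5, 1.5),
evolved r ∈ [−0.5, 0.5); 3-bin: [0.75, 1.25), [0.25, 0.75), [−0.25, 0.25);
4-bin: [0.83, 1.17), [0.50, 0.83), [0.17, 0.50), [−0.17, 0.17); anything
else is unclassified. Bins are closed on the left; how exact boundary
ratios are handled is a declared convention, not something the bin
definitions themselves decide.

## Contrast estimator

Counts are normalized with median-of-ratios size factors (reference =
per-gene geometric mean; factors rescaled to geometric mean 1). For a
contrast of groups A and B the estimator is the normalized group-mean log2
ratio, log2((m̄_A + ε)/(m̄_B + ε)), with ε = 0.5 / harmonic-mean size
factor (≈ 0.5 normalized counts) bounding the bias at zero counts. The
log2 fold change is therefore *linear in group means*: contrasts sharing a
normalization compose exactly, and TC = PC + GC holds as an identity.
No fold-change shrinkage is applied, for the same reason.

Variances come from the NB model Var = μ + αμ². Per-gene dispersion α̂ is
a method-of-moments estimate pooled across the contrasted groups (floored
at 10⁻⁸), then shrunk halfway toward a parametric mean trend
α(μ) = a/μ + b fitted by least squares. Standard errors are delta-method
on the log2 scale and p-values are Wald-normal, BH-adjusted over the
estimable genes (those nonzero in at least one group). Under null
simulations whose dispersions follow a mean trend (the model's own
assumption, and the usual shape in bulk RNA-seq) the p-values are uniform
to Kolmogorov distance < 0.05 at n = 20 + 20; when true dispersions are
unrelated to the mean, the trend shrinkage trades some calibration
(conservative for low-dispersion genes) for small-sample stability.

## Confounder screen

Acclimation durations are binned (> 30, > 60, > 90 days). Within each of
four strata (pooled lowland × garden, highland × garden) a per-gene NB
likelihood-ratio test compares duration-bin cell means against a single
mean (cell means fitted by Newton iterations with the moment dispersion
held fixed; df = occupied bins − 1). Mean-count independent filtering
picks, per stratum, the threshold from {0, 1, 2, 5, 10, 20} that maximizes
BH discoveries at FDR < 0.05. A gene flagged in *any* stratum is excluded.
The union has no joint FDR guarantee — it mirrors the screen's published
logic, which prioritizes removing confounded genes over controlling the
union's error rate.

## Parametric bootstrap for direction calls

PC and GC estimates share the lowland samples, so sampling error alone
produces an excess of apparent reversing calls (both estimates displaced
by the same noisy lowland term, in opposite directions). Following the
published procedure, each gene gets 1000 independent Gaussian (PC*, GC*)
draws with means equal to the estimates and SDs equal to their standard
errors; a direction is *supported* when one class is hit in ≥ 950
replicates. The draws are deliberately independent — the shared-sampling
correlation is not modelled; the high support threshold is the guard.
Under the all-null shared-term model the naive classifier calls 2/3 of
genes reversing, while the support rule fires for ≈ 1.6% of genes (this
rate is analytic: E[P(Binom(1000, p) ≥ 950)] with
p = Φ(|z₁|)Φ(|z₂|) + (1−Φ)(1−Φ) over the bivariate-normal z's), a
~40-fold suppression of the artifact but not a hard sub-0.1% guarantee.

## π selection and the 0.67 null

π = |log2FC| · (−log10 p) uses raw per-gene p-values: the top-quantile
selection is rank-based and any uniform monotone adjustment leaves the
selected set unchanged, so raw values avoid ambiguity about the adjustment
family. The concordance null of 0.67 is reproduced by the package's own
simulation: with iid per-population deviations, the contrasts H−L1 and
H−L2 share the H term, correlate at 1/2, and agree in sign with
probability 2/3.

A geometric property of the decomposition, used as a test battery: if PC
is drawn independently of TC (with GC = TC − PC), every gene with
|PC| > |TC| necessarily reverses and half the rest do, so the reversing
fraction is 1/2 + arctan(sd_PC/sd_TC)/π ≥ 1/2 — reversing excess is
partly a geometric necessity, not only biology.

## Co-expression network

Built on the pooled lowland samples (both gardens), on log2(normalized
count + 1) expression. Genes with zero MAD **in raw counts** are removed
first: after normalization a constant-count gene becomes a perfect copy of
−log2(size factor) and such genes form one spurious, perfectly correlated
cluster. Correlation is the biweight midcorrelation with side-specific
outlier capping: u = (x − median)/(9·MAD), and each tail of u is rescaled
so that at most 10% of samples per side get zero Tukey weight; zero-MAD
genes (post-filter rarities) fall back to Pearson with a warning. Signed
adjacency a = ((1 + cor)/2)^β maps cor = −1 to 0 so clustering follows
positive correlation. β is the smallest power on the grid with signed
scale-free R² > 0.8 (log-density vs log-mean-connectivity over ten
equal-occupancy bins) and mean connectivity above a floor (default 30;
argmax-R² fallback with a warning). The topological overlap is
TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij).

Modules are cut from the average-linkage tree of 1 − TOM by an adaptive
branch rule: a branch of ≥ 30 genes is a module when it is *tight* (its
merge height stays below 0.97 — TOM dissimilarity is bounded by 1 and
noise branches merge at ≈ 0.99) and *distinct* (its attachment gap covers
at least a fraction g of the remaining headroom to the ceiling,
attach − h ≥ g·(1 − h), with g = {0.5, 0.4, 0.3, 0.2} for deep-split
0–3). Deeper qualifying branches take precedence over qualifying wrappers,
so nested structure is cut at its deepest resolvable level and stragglers
accreted above a tight module stay unassigned; the root attaches at the
ceiling, so one tight network can be a single module while pure noise
yields none. This gap rule was adopted after the simpler fixed
height-quantile cut proved unable to separate planted modules from
background genes on the same dendrograms. Intramodular connectivity
k_IM is the sum of a gene's adjacencies to the *other members of its
module* (the standard intramodular reading of "sum of its adjacencies");
scaled k_IM divides by the per-module maximum, so exactly one gene per
module scores 1 and unassigned genes are missing.

## Statistics battery

Two-sided exact tests (binomial, Fisher) use the minimum-likelihood
convention. The 2×C Fisher test enumerates the full table space when it is
small enough (≤ 10⁷ candidate tables) and otherwise uses 10⁵ seeded
multivariate-hypergeometric draws; post hoc 2×2 tests are BH-adjusted.
Kruskal–Wallis is tie-corrected with chi-square reference; Dunn post hoc
z-tests share the tie correction and are BH-adjusted. One-sided Spearman
uses the t-approximation, switching to exact permutation for n ≤ 9.
Term enrichment is a one-sided hypergeometric test per term with BH
applied *within hierarchy levels*, level = shortest path from a root
(a term never appearing as a child) of the child–parent table; terms
outside the hierarchy form a single flat family.

## Synthetic data generator

The generator emulates the study conditions: the 40-bird design (10 + 10
highland, 5 per lowland population × garden cell), acclimation durations
uniform on 35–94 days, NB counts with log-uniform dispersion α ∈
[0.01, 0.5] (Var = μ + αμ²), log-normal library-size factors (σ = 0.25),
and baselines summing to a 3-million-count library. Cell means compose the
truth exactly: lowland/l = baseline, lowland/h = +PC, H/h = +PC + GC,
H/l = +GC_b, so each contrast is unbiased for its estimand. 30% of genes
carry effects, |PC| and |GC| log-normal with median 1 log2 unit; half the
effect genes reverse and half of them evolve (GC_b/GC uniform on ±0.3;
persisting genes have GC_b = GC exactly). 5% of genes respond to duration
(1 log2 unit per bin), 2% are constant-count (MAD-zero in raw counts),
and 250 genes sit in five 50-gene modules whose members load (loadings
1.5 × U(0.3, 1)) on shared standard-normal latent factors — strong,
hub-to-periphery graded co-expression of the kind module detection in
real tissue data presupposes. An optional mode ties evolved plasticity to
the weakest-loading half of each module, for fixtures probing the
connectivity–evolution link. The effect-size and co-expression parameters
are free choices, not estimates of any real dataset.

What the generator does *not* emulate: batch effects, tissue mixtures,
correlated (pathway-structured) effect directions, GC-content or length
biases, irreversible developmental plasticity, and |GC_b| > |GC|
over-shoot genes. Passing tests therefore demonstrate that the estimators
and classifiers recover the truth under the stated noise model, not that
they are robust to every artefact of real transcriptomes.

## Problem sizes and known limitations

The test suite runs the calibration and recovery simulations at moderate
scale — 2,000–10,000 genes, 20–50 birds per cell for recovery, 100–800
genes for network fixtures — sizes at which the checked quantities are
stable across seeds. Notable limitations:

- At the study's own lowland sample size (20 pooled birds) the generator's
  background correlation noise (≈ 1/√20) floods the topological overlap:
  module cores form in the dendrogram but accrete background genes with no
  detectable gap, and no dendrogram-based rule separates them. Module-level
  behaviour is therefore validated on 40–80-sample fixtures; the
  default-scale analysis script reports the absence honestly.
- The ≥ 950/1000 bootstrap support rule suppresses, but does not
  eliminate, null calls: ≈ 1.6% of pure-noise genes are supported (exact
  computation above). Interpretation of supported-call counts should use
  that as the per-gene false-call rate.
- The union-across-strata duration screen controls FDR per stratum only.
- The Wald tests are asymptotic; at very low counts (mean < ~2) they are
  conservative and the independent filter usually removes such genes from
  the screen's discoveries.
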
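# Methods

`polyshock` analyses the transcriptomic, fitness and genome-size
consequences of merging a haploid and a diploid *Chlamydomonas
reinhardtii* genome into a triploid, and of the triploid's subsequent
evolution under serial transfer. This note documents the models, the
numerical choices, and what the synthetic data generator does and does
not emulate.

## Experimental design assumed by the pipeline

The sampling layout is: a haploid parent (1N), a diploid parent (2N),
their triploid derivative at generation 0 (G0), and five independently
evolved triploid lines observed at generations 225 and 425, each group
with six replicate cultures. Generation numbers follow the
serial-transfer formula N_g = N_t · log2(D) for N_t transfers at
dilution factor D (default 20), rounded to the nearest integer; 52
transfers give 225 generations. For 99 transfers the formula yields
427.9, which `generations` rounds to 428; we report the computed value
rather than any coarser rounding.

## Differential expression

Counts are normalized by median-of-ratios size factors: the reference
profile is the per-gene geometric mean over genes positive in every
sample, each sample's factor is its median ratio to the reference, and
factors are rescaled to geometric mean 1 so that fold changes are
anchored to the matrix-wide scale. When fewer than 50 genes are
positive everywhere the estimator falls back to total-count ratios.

Testing uses a per-gene Wald statistic on the negative-binomial model
Var = μ + φμ². Gene-wise dispersions φ̂ are method-of-moments
estimates, max(0, (s² − μ̄)/μ̄²) pooled over groups with weights
(n_g − 1), then shrunk toward a running-median trend over 20
log-mean bins with weight n_bin/(n_bin + n_reps). The shrinkage
borrows strength across genes the way mainstream NB engines do, at the
cost of a slightly liberal raw type-I rate (≈0.06 at nominal 0.05 with
six replicates, driven by the median's downward bias on the skewed
raw-φ̂ distribution); the false-discovery control applied downstream at
padj < 0.01 is unaffected in our calibration runs.

The log2 fold change uses group means of normalized counts with a
prior count of 0.5; its delta-method standard error is
SE² = Σ_g (1/n_g)(1/(μ_g + 0.5) + φ̂)/ln(2)², and two-sided p-values
come from the standard normal. Genes with all-zero counts in both
groups are reported with p = 1 and excluded from the
Benjamini-Hochberg step-up adjustment.

Midparent values (MPV) are built in silico on the normalized scale:
each pseudo-replicate is the weighted mean of one P1 and one P2
replicate paired at random without replacement (seeded), with
min(n_P1, n_P2) pseudo-replicates. The default weights are (½, ½); a
ploidy-weighted variant (⅓ haploid, ⅔ diploid) is available because
the appropriate dosage weighting for a 1N × 2N merger is genuinely
ambiguous — equal weights treat the parents as transcriptome states,
ploidy weights treat them as genome doses. We default to equal weights
since dominance classification never uses the MPV.

## Expression partitioning

For each gene the three pairwise contrasts (P1 vs P2, F1 vs P1, F1 vs
P2) are reduced to a sign triple: the sign of the log2 fold change
when the BH-adjusted p-value is strictly below α (default 0.01), else
0. The twelve canonical patterns and five classes are:

| category | (s12, sH1, sH2) | class |
|---|---|---|
| C1–C3 | (±1 or 0, +1, +1) | UP (transgressive up) |
| C4–C6 | (±1 or 0, −1, −1) | DOWN (transgressive down) |
| C7, C8 | (+1, −1, +1), (−1, +1, −1) | ADDITIVE (between the parents) |
| C9, C10 | (+1, 0, +1), (−1, 0, −1) | ELD1 (matches the haploid parent) |
| C11, C12 | (+1, −1, 0), (−1, +1, 0) | ELD2 (matches the diploid parent) |

s12 = sign(P1 − P2), sH1 = sign(F1 − P1), sH2 = sign(F1 − P2). The
C1–C12 numbering is internal to this package and defined entirely by
the sign patterns above. Of the 27 possible triples, 12 map to
categories, 14 are UNCLASSIFIED (e.g. parents differ but the hybrid is
distinguishable from neither), and the all-zero triple is not a DEG.
A DEG is any gene significant in at least one of the three contrasts.
Strict matching is the default; a relaxed mode refills non-significant
zeros with the observed mean-difference signs before re-matching, for
use when near-complete category coverage of the DEG set is wanted.

The same machinery re-partitions the G0/G225/G425 trio of the evolved
triploid (G0 in the P1 slot, G225 as "hybrid", G425 in the P2 slot):
ELD2-like patterns then read "changed within the first 225 generations
and stable afterwards", parents-equal transgressive patterns read
"transient excursion at G225", and ELD1-like patterns read "late
change". Persistent genes are those holding the same class at all
three generations; persistence rates use the G0 class membership as
denominator, which the source experiment leaves implicit.

## Over-representation analysis

Gene sets are tested per annotation term with the one-sided
hypergeometric upper tail P[X ≥ k]; BH adjustment runs across terms.
The universe is the set of genes that survived expression filtering,
not the whole genome. Terms with zero overlap are retained at p = 1 so
that term lists remain comparable across queries.

## Growth curves and fitness

Optical density is modelled with the Baranyi-Roberts equation on the
log scale,

    A(t) = t + (1/μmax) ln(e^(−μmax t) + e^(−h0) − e^(−μmax t − h0))
    y(t) = y0 + μmax A(t) − ln(1 + (e^(μmax A(t)) − 1)/e^(ymax − y0)),

with y = ln OD, lag parameter h0 (lag duration h0/μmax) and maximum
specific growth rate μmax, the fitness proxy (MGR). Fitting is
nonlinear least squares on ln OD (variance stabilization), with a
multi-start grid μmax ∈ {0.05, 0.15, 0.3, 0.6, 1.2} h⁻¹ ×
h0 ∈ {0, 1.5, 5, 15}, bounds μmax ∈ (0, 5], h0 ∈ [0, 50], best RSS
wins. Fits pinned at the lower μmax bound or with no dynamic range
(ymax − y0 < 10⁻³) are flagged as non-converged and excluded. OD
readings are floored at 10⁻⁶ before the log.

Group comparisons of MGR follow an adaptive strategy: Shapiro-Wilk on
the pooled group-centered residuals and Levene's test
(median-centered) at the 0.05 level decide between a two-sample t-test
(Welch's variant under heteroscedasticity) and a Mann-Whitney U test;
BH adjustment runs over all pairs. The 0.05 gate and the Welch
fallback are this package's choices; the source protocol names the
tests but not the thresholds.

## Flow cytometry

Event clouds of PI-stained nuclei are summarized by the mean
fluorescence intensity (MFI) of gated events; the debris gate removes
events below 25% of the modal intensity located on a log-intensity
histogram (the gate threshold is configurable — gating is an
instrument-analysis choice, not part of the published protocol). MFI
ratios estimate relative ploidy; the summed parental value
SPV = MFI_P1 + MFI_P2 is the expected genome size of a loss-free
merger, the hybrid's percentage of SPV measures retained content, and
genome loss is 100·(1 − MFI_obs/MFI_ref). Recomputing the published
reductions from the published MFIs gives 8.2% (triploid G0 → G225) and
22.2% (SPV → mean of G225/G425), slightly below the rounded "~9%" and
"~22.3%" in the source; we report the recomputed values.

## Coexpression networks

Genes with less than one count in at least half the samples are
removed; the boundary case (zeros in exactly half) is removed.
Expression is variance-stabilized as log2(normalized count + 1) — a
deliberate stand-in for a dispersion-trend VST, adequate here because
every network statistic depends only on the relative covariance
structure. Correlations are biweight midcorrelations (weights
(1 − u²)² for |u| < 1, u = (x − median)/(9·MAD), Pearson fallback at
zero MAD), and the adjacency is signed hybrid: a_ij = cor_ij^β for
positive correlations, 0 otherwise, with soft power β = 6 by default.

Modules are average-linkage clusters of 1 − adjacency under a static
cut at 99.5% of the maximum merge height; clusters below 30 genes are
unassigned, and modules whose eigengenes (first principal component of
the module's z-scored expression, sign-anchored to the mean profile)
correlate above 0.8 are merged iteratively. Static cut plus eigengene
merging is a documented simplification of dynamic tree cutting; the
0.8 merge threshold matches the source analysis. Hubs are the top 10%
of genes by weighted degree (sum of edge weights).

Preservation of reference modules in a test network uses seven
statistics per module, computed in the test network on the module's
genes: mean intramodular adjacency (avg.weight), eigengene variance
explained (coherence), mean intramodular correlation (avg.cor), mean
gene-eigengene correlation signed by the reference orientation
(avg.contrib), and three cross-network agreements — correlation of the
vectorized intramodular correlation triangles (cor.cor), of
intramodular degrees (cor.degree) and of node contributions
(cor.contrib). The null draws n_perm random same-size gene sets from
the test network's non-module genes; one-sided p = (1 + #{null ≥
observed})/(1 + n_perm), so the smallest attainable p is 1/(n_perm+1).
A module is preserved when at least five of the seven statistics have
p < 0.05. These operational definitions follow the published
permutation framework in spirit and are validated by self-preservation
and label-shuffling destruction properties, not by numerical parity
with any particular implementation.

## Synthetic data

The count generator plants classes explicitly: parents separated by
`effect_size` log2 units (default 2.0, i.e. 4-fold) for ADD/ELD genes;
the hybrid at the midparent (ADD), at the matching parent (ELD1/ELD2),
or 2^±effect beyond the extreme parent (UP/DOWN); NULL genes flat.
Counts are NB draws with a common dispersion (default φ = 0.05, a
typical replicate-level overdispersion for clonal cultures), library
sizes lognormal (CV 0.15) around a mean of 500·n_genes — matching the
per-gene depth of the source experiment (≈9M mapped reads over ≈17k
genes). Base means are lognormal with median ≈100 and log-sd 1.

Two optional layers add realism where downstream stages need signal:
per-line multiplicative drift (log2-normal, default off) for temporal
analyses, and planted coexpression modules driven by per-sample latent
factors with heterogeneous gene loadings (uniform 0.4–1.6), giving
modules both density and a reproducible hub/periphery structure.

What the generator does **not** emulate: gene-gene correlation outside
planted modules, gene-specific dispersions, GC/length biases, allelic
(homeolog) composition of the triploid, batch effects, or count
discreteness artifacts of UMI deduplication. Passing recovery tests on
these data therefore demonstrates the correctness and calibration of
the statistical machinery under the stated model, not performance on
any particular real dataset.

Growth curves are the Baranyi-Roberts mean with additive Gaussian OD
noise (floored at 10⁻⁶); cytometry events are lognormal clouds at the
requested peak means/CVs plus an exponential low-intensity debris
component (scale 10% of the smallest peak mean).

## Problem sizes and numerical choices

Simulation-based checks use 2,000 genes × 6 replicates for DE
calibration and class recovery, 12 wells × 17 timepoints for growth,
10⁴ events per cytometry peak, and 200 permutations for preservation
sanity checks (1,000 remains the default for real analyses). These
sizes give stable statistics at interactive runtimes. All generators
and permutation tests take explicit seeds; reruns of the pipeline with
one seed are byte-identical, which the test suite asserts file by
file.

## Known limitations

- The Wald test is mildly liberal at raw p with few replicates (see
  above); exact or quasi-likelihood variants are out of scope.
- Strict-mode partitioning leaves genuinely intermediate triples
  unclassified; relaxed mode trades specificity for coverage.
- The static tree cut can split one latent module at unlucky noise
  levels before the eigengene merge recovers it; dynamic tree cutting
  is not implemented.
- MFI estimation assumes a dominant G1 peak; cell-cycle deconvolution
  is out of scope.
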
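# Methods

This note documents the statistical models and procedures implemented in
`ssrcore`, the choices made where conventions diverge, and what the
synthetic data do and do not establish about behavior on real germplasm.

## Data model

Genotypes are diploid codominant calls: an unordered pair of allele labels
per (entry, locus), labels treated as opaque categories (no repeat-length
semantics). The missing codes `0`, `-9`, empty and `NA` are normalized on
input to a single internal marker, and a half-called genotype is demoted to
fully missing, since every statistic below needs both allele copies. All
per-locus denominators count non-missing individuals only (the CERVUS
convention).

## Diversity statistics

With sample allele frequencies $p_i$ and $n$ non-missing individuals at a
locus: $N_a$ (distinct alleles), $N_e = 1/\sum p_i^2$,
$H_e = 1-\sum p_i^2$, $uH_e = \frac{2n}{2n-1}H_e$ (Nei 1978 under HWE),
$I = -\sum p_i\ln p_i$ (natural log, GenAlEx convention),
$PIC = 1-\sum p_i^2-\sum_{i<j}2p_i^2p_j^2$ (Botstein 1980), and $H_o$ the
fraction of non-missing genotypes with two distinct alleles. A monomorphic
locus yields the degenerate record ($N_a=N_e=1$, rest 0), not an error.
Per-population tables compute the same statistics within populations and
average over loci; the cross-population `Mean` row is the arithmetic mean
of the per-population values. $uH_e$ is undefined for a population of one
and reported as missing. Both $H_e$ and $uH_e$ are reported throughout
because desktop packages disagree on which one a column labelled "He"
holds; no cross-column identity between published $H_e$ and $N_e$ columns
is assumed.

## Genotypic distance and AMOVA

The squared genetic distance between two individuals is, per locus, half
the squared Euclidean distance between their allele-dosage vectors
(identical genotypes 0; one shared allele 1; two allele-disjoint
heterozygotes 2; homozygote vs disjoint heterozygote 3; opposite
homozygotes 4), summed over pairwise-complete loci and rescaled by
(total loci / shared loci) so values stay comparable under missingness. A
pair sharing no non-missing locus is an error naming the pair.

Two-stratum AMOVA follows the standard squared-distance decomposition:
$SS_{tot} = \frac1N\sum_{i<j}d^2_{ij}$, within-population sums analogously
per group; $MS = SS/df$ with $df_a = k-1$, $df_w = N-k$;
$n_0 = (N-\sum n_g^2/N)/(k-1)$; $\sigma^2_w = MS_w$;
$\sigma^2_a = (MS_a-MS_w)/n_0$, truncated at zero when negative;
$\Phi_{PT} = \sigma^2_a/(\sigma^2_a+\sigma^2_w)$. Significance comes from
permuting individuals across population labels with the add-one rule
$p = (c+1)/(m+1)$, default $m = 999$. Permutations are ranked on the
*untruncated* statistic: zero-truncation puts a point mass at
$\Phi_{PT}=0$ under the null, which would tie most permutations and make
the p-value grossly non-uniform; ranking on the signed component restores
uniformity (verified by a K-S property test). The reported components keep
the truncation.

**$\Phi_{PT}$ vs allele-frequency $F_{st}$.** For Hardy–Weinberg
populations under an island model with differentiation $F$, the
among-population variance of an allele dosage is $4p(1-p)F$ while the
within-population variance is $2p(1-p)(1-F)$, so genotypic-distance AMOVA
converges to $\Phi_{PT} \approx 2F/(1+F)$ — about twice $F$ when $F$ is
small, because an individual's two allele copies carry the same population
deviation. This is a property of the estimand, not an estimator defect;
the same factor-two pattern appears in published surveys that report both
statistics side by side. Consequently the simulator's `fst_target` is the
allele-frequency ($G_{st}$-sense) parameter, recovered by the corrected
$G_{st}$ estimator below, while simulated $\Phi_{PT}$ sits near
$2F/(1+F)$.

## Fst and gene flow

Per locus, $F_{st} = (H_t-H_s)/H_t$ with $H_s$ the unweighted mean
within-population expected heterozygosity and $H_t$ from the unweighted
mean allele frequencies (Nei $G_{st}$, the convention of the standard
desktop tools); $N_m = (1-F_{st})/4F_{st}$, so $4N_mF_{st}+F_{st}=1$
identically. Loci monomorphic overall have undefined $F_{st}$ and are
excluded from column means. The plug-in estimator carries an upward
small-sample bias of order $(1-H_s)/2\bar n$; `corrected=True` applies the
Nei & Chesser (1983) adjustments (unbiased $\tilde H_s$ via the
$2n/(2n-1)$ factor and $\tilde H_t = H_t + \tilde H_s/2\tilde n k$ with
$\tilde n$ the harmonic mean size), which is the right choice when the
question is parameter recovery; the uncorrected form remains the default
for report parity with the desktop chain.

## Admixture model and cluster number

The admixture likelihood treats each of the $2L$ observed allele copies of
individual $i$ as drawn from $\sum_k Q_{ik}P_{kl\cdot}$. EM maximizes the
log-likelihood (responsibilities per allele copy; closed-form $Q$ and $P$
updates), with frequency floors at $10^{-12}$, convergence when the
log-likelihood improves by less than `tol` (default $10^{-6}$), and a
runtime assertion that the path is non-decreasing. At $K=1$ the fit is the
pooled-frequency model in closed form. This is a deterministic desk-scale
stand-in for MCMC samplers in the same model family; replicate variation
comes from random restarts (seeded), and the cluster count is suggested by
Evanno's $\Delta K = |\bar L(K+1)-2\bar L(K)+\bar L(K-1)|/sd\,L(K)$,
defined only for interior $K$ with positive replicate sd (zero-sd cells
are flagged undefined). Hard assignments use arg-max $Q$ with no admixture
cutoff.

## Trees and ordination

The shared-allele distance is $1-\frac{1}{2}(\text{shared alleles})$
averaged over pairwise-complete loci, where shared alleles per locus is
$\sum_a \min(c_i(a),c_j(a))$ on dosage vectors. Neighbor joining is the
Saitou–Nei algorithm; ties in the Q-criterion resolve to the lowest
(row, column) pair, and a negative branch length is clamped to zero with
the deficit moved to the sister branch so the joined pair's path length is
preserved. This clamping rule is why NJ is implemented in-package;
scikit-bio's `nj` (which zeroes negatives without transfer) serves as an
independent topology oracle in the tests. PCoA delegates to scikit-bio
(Gower double-centering + eigendecomposition); negative eigenvalues are
reported but excluded from percent-variance denominators, and requests for
more axes than positive eigenvalues are truncated with a warning.

## Core collections

*Phenotypic (stepwise clustering).* Traits are standardized (zero mean,
unit variance; missing cells mean-imputed after scaling); distances are
Euclidean or Mahalanobis (a singular covariance is ridge-regularized with
$\lambda = 10^{-6}\,\mathrm{tr}\Sigma/p$ and a warning); trees come from
scipy's UPGMA/Ward/median linkage; the tree is cut into
$m = \mathrm{round}(r\,N)$ clusters and one representative kept per
cluster. "Preferred" sampling keeps the member with the largest
standardized norm (most extreme, maximizing range retention), "deviation"
the member nearest the cluster centroid, "random" a uniform draw. These
two terms are not defined in the upstream tools' documentation; the
definitions here were chosen so that preferred sampling maximizes range
coincidence, matching the reported behavior of the original software
chain. The size rule $\mathrm{round}(r\,N)$ is used even though the
upstream tool evidently used a smaller undocumented rule.

*Evaluation.* Per trait, a Welch two-sample t-test of means and an F-test
of variances, core vs full collection; MD and VD are the percentages of
traits significant at $\alpha=0.05$; CR is the mean core/original range
ratio × 100 and VR the mean coefficient-of-variation ratio × 100. Traits
with zero original range are excluded from CR with a warning. The
conventional acceptance rule MD ≤ 20% and CR > 80% is flagged. MD, VD and
CR are invariant to affine trait rescaling; VR is invariant to positive
scaling but legitimately responds to shifts (CV depends on the mean),
which is why the simulator gives traits positive means with ~10% CV.

*M-strategy.* Greedy set cover on the entry × allele incidence matrix:
repeatedly add the entry covering the most uncovered alleles (ties: fewest
total alleles carried, then first in entry order), then a backward pruning
pass removes entries whose alleles are covered by the rest. Coverage is
100% by construction on every input.

*Diversity search.* At size $\mathrm{round}(r\,N)$, stochastic
hill-climbing from a seeded random start maximizes
$\tfrac12(\text{allele coverage fraction}) + \tfrac12(\text{mean
nearest-selected shared-allele distance})$ — the default objective family
of ratio-bound core software, with unstated weights set to 50/50. Each
pass scans members in random order and applies the best improving swap in
that member's neighborhood; `n_iter` (default 10,000) caps candidate-swap
evaluations. The objective is non-decreasing and the result deterministic
per seed.

*Molecular evaluation.* Per parameter ($N_a,N_e,H_o,H_e,I,PIC$), an
independent Welch t-test across the per-locus values, core vs original,
and retention = 100 · (core mean)/(original mean); plus sample retention
100·|core|/N. The final core is the deduplicated union of the phenotypic
and molecular cores.

## Synthetic data

Balding–Nichols: per locus, $J \sim U\{8..15\}$ alleles with ancestral
frequencies $p \sim \mathrm{Dir}(1)$; population frequencies
$p_g \sim \mathrm{Dir}(p\,(1-F)/F)$, so $E[F_{st}] = F$; genotypes are two
independent draws per individual (HWE within populations); calls are
masked missing at rate 0.02 by default (the emulated survey does not state
its rate; this is a recorded guess). Each locus is conditioned on all $J$
alleles being observed after masking (rejection sampling) because an SSR
survey's allele set is by definition the detected set. Traits are
multivariate normal: per-(population, trait) mean shifts with sd
`trait_group_effect` (default 0.5, a moderate standardized provenance
effect) plus unit noise with compound-symmetric correlation $\rho = 0.3$,
mapped to positive trait-like units (means 10–100, ~10% CV). The default
configuration is the emulated study design: provenance sizes
(12, 26, 15, 9, 9, 17, 18, 24, 8, 23, 5, 9, 2, 15, 12, 15, 13; N = 232),
32 loci, $F = 0.042$, 15 traits.

What the simulator does **not** emulate: stepwise mutation structure,
linkage, null alleles, clonal/pedigree redundancy, or geographic gradients.
The most visible consequence is that M-strategy cores on synthetic data are
far smaller (tens of entries) than on a real bank with redundant clones
(hundreds): HWE data cover alleles quickly. Tests therefore assert the
allele-retention and ordering properties of the selectors, and the
published core sizes are checked arithmetically from the printed tables
rather than re-derived from simulation.

## Problem sizes and determinism

Default test and acceptance runs use the 232 × 32 study scale for
diversity/AMOVA/core stages, reduced replicate counts for EM grids
(e.g. K ≤ 5, 2–4 replicates) and a few hundred to a few thousand
candidate-swap evaluations for the core search — sizes at which every
stage completes in seconds while preserving the statistical behavior being
checked. All randomness flows from a single master seed via per-stage
tags ($\mathrm{seed}\cdot 2654435761 + \mathrm{crc32(tag)} \bmod 2^{31}-1$),
so any stage can be re-run in isolation and a full pipeline re-run is
byte-identical.

## Known limitations

* The uncorrected $G_{st}$ default mirrors desktop-tool output and thus
  inherits its small-sample bias; use `corrected=True` for inference.
* Ward/median linkage on a precomputed Mahalanobis distance is a pragmatic
  convention (as in the upstream tool), not a centroid-consistent model.
* The admixture EM finds local optima; replicate restarts mitigate but do
  not eliminate this, exactly as with the MCMC tools it stands in for.
* Two-stratum AMOVA only; no region-level hierarchy.
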
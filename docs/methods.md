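# Methods

This note records the statistical models implemented in lanternpop, the
choices made where conventions diverge, and what the synthetic-data
generator does and does not emulate.

## Data model

Genotypes are diploid, biallelic, unordered allele pairs with an explicit
missing marker; a derived dosage view (count of the B allele, NaN when
missing) feeds PCA, F-statistics and AMOVA.  File positions are 1-based;
internal coordinates 0-based.  Genepop 2- and 3-digit allele codes are
accepted ("00"/"000" missing); coordinates and habitat groups travel in a
tab-separated sidecar metadata table, since Genepop cannot carry them.

### QC boundaries

Loci are dropped when their missing fraction is **≥ 25 %** or their
major-allele frequency is **≥ 95 % in every sample**; individuals are
dropped when their missing fraction is **strictly > 25 %** (an individual at
exactly 25 % is retained).  The asymmetry is deliberate: the locus rule is a
dismissal criterion, the individual rule an acceptance threshold, and the
two are phrased differently in panel-curation practice.  Candidate-SNP
design filters use strict QUAL > 600, inclusive coverage [10×, 50×], and
spacing ≥ 200 bp to *any* other variant (SNP or indel) on the contig; when
one SNP per contig is kept, the tie-break is highest QUAL then lowest
position (the original procedure does not specify one).

## Diversity and Hardy–Weinberg

Per locus within a sample: Ho = heterozygote fraction of typed
individuals; He = 1 − p² − q²; uHe = 2n/(2n−1) He; F_IS = (He − Ho)/He
computed per polymorphic locus and averaged (GenAlEx convention; the ratio
uses He, not uHe — switchable in code).  Sample values are mean ± SE over
loci, SE = sd/√L.  The HWE test enumerates the full conditional
distribution of the heterozygote count given the allele counts
(Levene/Haldane weights) and sums probabilities ≤ the observed one —
deterministic, unlike Markov-chain exact tests, and identical in target
distribution at panel scale.

## Linkage disequilibrium

Pairwise LD is Fisher's exact test on the joint genotype contingency table
(up to 3×3).  2×2 collapses are evaluated exactly; larger tables by seeded
Monte-Carlo sampling of the fixed-margin null (sequential multivariate
hypergeometric rows), so the smallest attainable p is 1/(draws+1).  The
pipeline default of 20 000 draws makes q-values of strongly linked pairs
resolvable below a pruning threshold of 0.01 after BH-FDR across a
121-locus panel; the pruning threshold is a calibration parameter, not a
constant.  LD-pruning builds a graph on FDR-significant pairs and keeps one
locus per connected component: least missing data, then highest MAF, then
lexicographic ID.

I_A and r̄_d use per-locus inter-individual distances = number of differing
alleles (0/1/2); V_O is the variance (over pairs) of summed distances and
V_E the sum of per-locus distance variances; missing pairs are dropped
pairwise.  The permutation null shuffles genotypes independently within
each locus (999 permutations by default).

## Differentiation

Weir–Cockerham variance components a, b, c are computed per locus and per
allele (summed over alleles, so the same code handles the multi-allelic
haplotype super-locus) and combined as θ = Σa / Σ(a+b+c); negative
components are retained in the ratio.  Pairwise permutation tests shuffle
individuals between the two samples; p = (hits+1)/(perms+1); 10 000
permutations by default in the function API (the pipeline uses fewer at
desk scale, configurably).

AMOVA partitions squared inter-individual distances; the genotypic
distance is the allele-difference count per locus (0/1/2) summed over loci
typed in both individuals and rescaled by total/typed loci.  Variance
components follow the standard method-of-moments with unequal-size
coefficients; permutation schemes are individuals-among-samples (flat FST,
FSC) and whole-samples-among-groups (FCT).  Two properties are worth
noting: (i) the flat percentage-among-samples equals 100·FST by definition
(tested); (ii) because genotypic distances undercount within-sample
variation relative to random allele pairing, the AMOVA ratio runs somewhat
above the allele-level Balding–Nichols divergence parameter of simulated
data — the estimates track the configured hierarchy but are not numerically
identical to the generator's F parameters.  Dendrograms are UPGMA on
pairwise FST with negative estimates clamped to zero.

## Ordination and driver loci

PCA operates on the dosage matrix with missing entries replaced by the
locus mean, centered, **not** variance-scaled; axes are oriented so the
largest-magnitude loading is positive (signs are otherwise arbitrary).
Driver-locus detection ranks squared PC1 loadings and cuts at the largest
consecutive ratio within the top quarter of loci; if that ratio is below
2, no block is reported.  A mean + 3·SD threshold is also available but is
unstable when the block carries a large share of the loading mass (the
block inflates the SD toward its own loadings), which is why the gap rule
is the default.  DAPC reduces to n_pcs principal components chosen by
stratified 90/10 cross-validation, then fits a canonical discriminant
analysis.

## Karyotype classification

Individuals are clustered on PC1 by 1-D k-means (k = 3, quantile plus 50
random restarts); clusters are ordered by center and the middle cluster
must exceed both flanks' mean driver-locus heterozygosity by ≥ 0.15, else
classification is rejected.  When habitat labels exist, the flank most
frequent among Ocean-group individuals is labeled AA (the arrangement
naming is a convention, not a biological fact); otherwise the flank where
locus 1's first allele is fixed.  Individuals within 0.05 cluster-spacings
of a k-means boundary are left unassigned.  An auto mode falls back to a
driver-score axis (mean oriented driver dosage) when background structure
dominates PC1; the mode used is recorded.  A locus is flagged diagnostic
when its per-karyotype A-allele frequencies fit (1, 0.5, 0) within 0.02 —
tolerant of roughly one miscall in fifty.

Migrant flagging takes any individuals × habitat-clusters membership
matrix (threshold 0.7 on non-home membership).  The recommended source at
panel scale is the leave-one-out genetic assignment test
(`assignment_memberships`): per-group allele frequencies with a 0.5
pseudocount, the focal individual excluded from its home group, genotype
likelihoods normalised across groups.  DAPC posteriors are usable but
overconfident when many PCs are retained.

## Haplotypes

Multinomial EM over the 2^L haplotype space (L ≤ 16; in practice the ≤ 5
perfectly diagnostic loci): E-step sums over phases compatible with each
unordered genotype (missing calls enumerate all completions, yielding
posterior-weighted rather than imputed phases), convergence at max
frequency change < 1e-8, best of 10 restarts.  Haplotypes below 1/(4n) are
pruned and the EM re-run once.  This replaces coalescent-informed phasing:
with a handful of near-perfectly diagnostic loci the phase is almost fully
determined by the data, so the prior model is immaterial to the quantities
of interest.  Haplotype-level differentiation treats each phase pair as a
genotype at one multi-allelic super-locus.

## Admixture model

The sampler alternates allele-copy origins Z (categorical), cluster
frequencies P (Beta(1,1) prior — independent frequencies, *not* the
correlated-frequencies variant; simpler and adequate for structure of this
strength), ancestry Q (Dirichlet(α)), and α (Metropolis, uniform prior on
(0, 10)).  L(K) is the standard log-marginal-likelihood estimator: trace
mean minus half the trace variance.  Evanno's
ΔK = |L(K+1) − 2L(K) + L(K−1)| / SD(L(K)) needs ≥ 3 consecutive K and ≥ 2
runs each; zero-SD cells are flagged.  Puechmaille's statistics count
clusters to which ≥ 1 predefined sample assigns with mean (or median)
membership ≥ 0.5.  Run alignment maximises G = 1 − ‖Q_a − Q_b‖_F/√(2n)
against the highest-L(K) run, exhaustively for K ≤ 8 and by Hungarian
assignment above.  Desk-scale defaults (burn-in 500, 1 500 sweeps, 2–3
runs per K) are sized for ~100–200 individuals × ~120 loci; production
settings remain configurable.

## Synthetic-data generator

Background loci: ancestral frequencies uniform on a configurable band,
then group frequencies by Balding–Nichols at each group's divergence
parameter, then site frequencies at the within-group divergence; genotypes
are Hardy–Weinberg draws within site.  Mediterranean diversity loss is
modelled by shrinking the group's minor-allele frequencies (factor 0.45 in
the preset, halving heterozygosity).  The inversion is modelled as complete
recombination suppression: a karyotype per individual from its group's
(f_AA, f_AB, f_BB), then alleles per arrangement copy — fixed for
diagnostic loci, drawn from per-arrangement frequencies for partial loci.
A single seed drives one stream per stage, so enlarging one stage does not
perturb the others.

The survey preset uses the published site list and retained sample sizes
(1288 individuals over 16 sites), Fjord karyotypes (0.185, 0.537, 0.278),
Ocean AA = 0.567 with the remainder split in Hardy–Weinberg ratio
(arrangement frequency 0.753 → AB 0.372, BB 0.061), and a Mediterranean
fixed for BB.  Background divergences (Ocean 0.045, Fjords 0.075,
Mediterranean 0.06 plus frequency shrinkage; within-group 0.004) were
calibrated so the generator reproduces the survey's *axis structure* — the
inversion dominates PC1 with the three-stripe pattern, geography loads on
the later axes, and Mediterranean heterozygosity is under half the
oceanic value.  Two realism trade-offs follow and are intentional:
between-habitat background FST in the preset (Ocean–Fjords ≈ 0.06,
Ocean–Mediterranean ≈ 0.2) sits below the values observed on the real
panel, because pushing it higher entangles habitat contrasts with the
karyotype axis and destroys the clean loading separation the survey
actually exhibited; and a diversity bottleneck without frequency
displacement is demographically idealised.  The migrant-study preset is
therefore a separate two-habitat configuration whose Ocean–Fjords FST
(~0.15) matches the observed between-habitat range, with five Ocean
individuals planted in fjord sites (two in Osterfjorden, one each in three
other fjords).  Consequently, passing tests demonstrate that the methods
recover the structure the generator encodes at realistic panel sizes —
they do not certify behaviour under demographic histories the generator
does not model (selection, clines, isolation-by-distance, linked
background variation outside the block).

## Problem sizes used in the test suite

Simulation-backed checks run at sizes chosen to keep the statistical
content intact: survey-scale (~1288 individuals) for driver-locus
detection and karyotype recovery (where per-locus loading noise matters),
quarter-scale for LD-matrix and stripe analyses, 64–128 individuals with
1 000–1 500 MCMC sweeps for K-selection replicates, and ≤ 10-individual
instances for all brute-force oracle comparisons.  Monte-Carlo tolerances
are stated per test as multiples of the relevant standard error.

## Known limitations

- The Fisher Monte-Carlo p floor (1/(draws+1)) makes very small LD
  p-values unresolvable; pruning thresholds must respect it.
- The admixture sampler uses a single α for all clusters and no
  correlated-frequencies prior; ΔK magnitudes are sampler-dependent and
  only the argmax is meaningful.
- AMOVA genotypic distances are rescaled for missingness by typed-locus
  count, an approximation that degrades above ~20 % missingness.
- 1-D k-means karyotype classification assumes three clusters; lower-
  frequency arrangements (k > 3 karyotype systems) are out of scope.
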
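# Methods

`deltapop` analyses exome-capture SNP cohorts from structured outcrossing
tree populations: per-gene diversity and neutrality statistics, within-gene
linkage-disequilibrium (LD) decay, a covariance-corrected differentiation
scan with an empirical intergenic null, two complementary environmental
association scans, and candidate-set integration with functional
enrichment. A synthetic-cohort generator reproduces the statistical
structure such data exhibit, so every stage can be unit-tested, calibrated
and power-tested without external downloads. This note documents the models,
the defaults and why, the numerical choices, and what passing tests do and
do not demonstrate.

## The synthetic cohort generator

The generator emulates a range-wide cohort of a wind-pollinated riparian
hardwood: a few weakly differentiated subpopulations strung along a
longitudinal gradient, a rare-allele-rich site-frequency spectrum, LD that
decays within genes over tens to thousands of base pairs, climate variables
correlated with geography, and caller-style quality annotations.

**Allele frequencies.** Ancestral frequencies are Beta(0.05, 1.2) by
default. This shape was chosen so that the *downstream* site-frequency
spectrum — after Balding–Nichols drift and binomial sampling of 2n = 400
chromosomes — is rare-allele-enriched relative to the neutral expectation:
genome-wide mean Tajima's D comes out near −0.4 and roughly two thirds of
segregating sites have minor allele frequency below 0.05, matching the kind
of spectrum produced by purifying selection and post-glacial expansion in
forest trees. Milder shapes (e.g. Beta(0.5, 2.5)) give too few rare alleles
relative to the 1/i neutral spectrum at this sample size and flip the sign
of D; the shape is configurable (`ancestral_beta`). Subpopulation
frequencies follow the Balding–Nichols island model,
Beta(p(1−F)/F, (1−p)(1−F)/F), which has mean p and variance F·p(1−p) — the
moment identity the F_ST recovery tests rely on. Default: two
subpopulations of 100 samples each at F = 0.07, the scale of the
hierarchical west/east split in range-wide poplar cohorts (subpopulation
pairs span roughly 0.02–0.11).

**Within-gene LD.** Haplotypes are mosaics over a finite founder pool
(256 founders per gene and subpopulation). Founder k carries the alternate
allele at a locus iff k falls inside that locus's carrier block — a prefix
or suffix of the pool whose size is the stochastically rounded pool count
K·q, where q is the locus's Balding–Nichols draw. Nested carrier blocks
make founder haplotypes strongly correlated at short range, while each
locus's marginal frequency stays pinned to its Balding–Nichols value (the
rounding adds variance of order 1/(6K²), negligible at K = 256). Sampled
haplotypes copy one founder and re-pick a founder between adjacent loci
with probability 1 − exp(−c·d), c = `switch_rate_per_bp` (default 8×10⁻⁴),
so r² decays geometrically towards the ~1/n sampling floor. An i.i.d.
founder pool would give short-range r² ≈ 1/K — no usable LD — which is why
the carrier blocks are contiguous. Intergenic loci are mutually independent
binomial draws, which keeps them valid both as the neutral covariance panel
and as an unbiased reference for estimator-recovery tests.

**Climate gradients.** Eleven variables (six temperature, five
precipitation) are linear combinations of three standardized, mutually
independent geographic signals (latitude, longitude, altitude) plus
Gaussian noise; the loading table is fixed in `simulate.ENV_VARIABLES` and
implies a closed-form target correlation matrix
(`env_target_correlation`), which the generator's output matches
empirically. Redundancy within each group is deliberate: it gives the
PCA-based variable selection something to remove.

**Planted signals.** Adaptive loci receive a per-haplotype logit shift
β·z, where z is the standardized, noise-free value of a latitude-dominated
climate signal and β is ±`cline_strength`·U(0.5, 1.5) (default strength
1.5 logit units per environmental SD — a moderate cline). The cline driver
is latitude-dominated on purpose: the subpopulations separate along
longitude, so the planted signal is not collinear with population structure
and survives the structure corrections. The base frequency of an adaptive
locus is shared across subpopulations; only the cline moves it. For
differentiation-power tests the generator can additionally plant "divergent"
loci whose subpopulation frequencies are forced apart by
`divergent_delta` (default 0.75, e.g. 0.1 vs 0.85 — fixed-difference-scale
divergence). Power evaluations use a larger scan (800 genes × 12 loci) with
few planted clines (8) at strength 2.5, because the top-1% candidate rule
caps discoveries at 1% of the scan: planting many strong loci in a small
scan makes them compete with each other for the quantile slots rather than
with the null.

**Quality fields.** Site quality ~ Gamma(4, 100), mapping quality
60 − Exp(6), bias p-values mostly Uniform with a 0.5% planted tail below
10⁻⁴, genotype quality min(99, Gamma(6, 12)), depth Poisson with
Gamma(4, 7.5) means. A few percent of sites and genotypes violate each
filter threshold, so the filter stage has real work and its report is
informative. Missingness is i.i.d. at 5%.

All randomness flows from one seed through fixed-order `SeedSequence`
substreams; identical configurations are bit-identical.

## Filtering

Site-level rules (quality ≥ 50, mapping quality ≥ 30, strand- and
end-distance-bias p > 10⁻⁵) are applied first, then genotypes with
GQ < 20 **or** DP < 8 are set to missing, then loci with more than 25%
missing genotypes are dropped. The OR reading of the genotype rule is the
conservative one — either failure invalidates the call — and is exposed as
`mask_rule` for the AND alternative. Masking precedes the missingness
computation; a test fixture demonstrates the order is observable.
Subpopulation assignment takes the sample's largest ancestry coefficient if
it exceeds the 0.8 cutoff, read strictly ("above 80%"); the comparison is
configurable. Hierarchical regrouping merges coefficient columns (e.g. the
two western groups into one) so that samples dominated by an unlisted group
drop to admixed.

## Diversity and neutrality statistics

θ_W = S/(a_{n−1}·L) and π = Σ [n/(n−1)]·2p(1−p)/L are per *surveyed*
site: in capture data only the probe footprint is assayed, so L is the
captured length recorded in the region table, not the genomic span.
Tajima's D uses the 1989 normalization constants with n set to the
gene-median non-missing chromosome count (per-locus n varies under
missingness; the median mirrors common per-gene implementations and is
exact when data are complete). Wall's B is the fraction of adjacent
segregating-site pairs showing at most two gametes; it is exact on the
generator's phased haplotypes and falls back to major-phase
pseudo-haplotypes (with a warning) for unphased input. F_ST is the
Weir–Cockerham (1984) estimator; the multilocus value is the ratio of
summed variance components, never a mean of per-locus ratios, and loci
monomorphic in both populations are excluded. N_e = θ_W/(4μ) with
μ = 2.5×10⁻⁹ per site per year × 15-year generation = 3.75×10⁻⁸; reported
values round to the nearest hundred.

## LD decay

Two-locus haplotype frequencies for unphased genotypes are estimated by EM
(the double heterozygote is the only ambiguous cell for biallelic loci);
r² = D²/(p_A p_a p_B p_b). Pairs are restricted to within genes. The decay
model is the drift–recombination expectation

    E(r²) = [(10+C)/((2+C)(11+C))] · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))]

with C = ρ·d (ρ = 4N_e r per bp) and n the sample size; note its large-C
limit is the finite-sample floor 1/n, not zero. C_per_bp is fitted by
bounded nonlinear least squares on the unbinned pair cloud (binned-mean
option available) from a fixed three-point start grid (10⁻⁴, 10⁻³, 10⁻²),
which makes the fit deterministic and robust to the shallow likelihood at
small C. The decay distance is the smallest integer d with the fitted curve
below the threshold (default 0.2), found by doubling-plus-bisection on the
monotone curve. Because rare alleles bound attainable r², raising the MAF
cutoff raises the pair cloud and lengthens the fitted decay distance — the
pipeline reports the 0.01/0.05/0.10 series.

## Differentiation scan

Per locus, subpopulation frequencies are standardized as
x_j = (p_j − p̄)/√(p̄(1−p̄)) with p̄ the chromosome-count-weighted pooled
mean. Ω is the second-moment matrix of these vectors over putatively
neutral intergenic loci (spacing ≥ 15 kb, MAF > 0.01, call rate > 80%, up
to 1,800 loci), ridge-regularized by 10⁻⁶·trace/P. The default estimator is
this deterministic moment form; an alternative "mcmc" mode draws from the
conjugate inverse-Wishart posterior and averages the last draw of five
independent chains, mirroring multi-run MCMC protocols at desk scale — the
two agree within sampling error in tests.

Two numerical choices matter and are worth spelling out. First, centering
at the pooled sample mean confines the x vectors to a (P−1)-dimensional
subspace, so Ω always has one near-null eigendirection that carries only
weighting noise; inverting it amplifies that noise past any real signal.
The statistic therefore uses a truncated pseudo-inverse
(eigenvalues below 10⁻³ of the largest are dropped):
xᵀΩ⁺x. Second, the empirical null is MAF-matched to the scanned loci
(null cutoff defaults to the genic cutoff): the sampling tail of the
statistic is frequency-dependent, and an unmatched rare-allele-rich null
visibly miscalibrates the empirical p-values. P-values use the add-one
convention p = (1 + #{null ≥ obs})/(N + 1) with ties counted as
exceedances; Benjamini–Hochberg q-values with outliers at q ≤ 0.05; a gene
is an outlier when any of its SNPs is.

## Environmental association

**Variable selection.** Per variable group (temperature, precipitation), a
PCA on the standardized variables takes the one or two variables with the
largest squared loading on each of the first four components; constant and
duplicate variables are dropped first, ties break by column order.

**Latent-factor scan.** Per locus: genotype = μ + β·env + K latent factors
+ noise, estimated by alternating (i) per-locus regression on the intercept
and environment and (ii) truncated SVD of the residual matrix for the
factors (K = 2, 15 iterations), followed by a final joint OLS whose env
t-statistic is the run's z-score. Five runs differ only in factor
initialization; the combined z is the Stouffer mean. Because the runs are
strongly correlated (the alternating estimate is near-deterministic), the
raw combined z is inflated by up to the run count times the residual
structure inflation — which is exactly why the scan recalibrates by the
genomic inflation factor λ = median(z²)/median(χ²₁) before converting to
p-values. The reported `inflation` is that raw λ; post-calibration, null
loci sit at λ ≈ 1. Significance uses Bonferroni α = 0.01 over the scanned
loci. K = 0 reduces exactly to ordinary least-squares t-statistics, which
the tests exploit as an oracle.

**Deme-level Bayes-factor scan.** Samples are grouped into 50 demes by
seeded k-means (10 restarts) on standardized latitude/longitude/altitude;
the table format also accepts a user-supplied grouping. Deme mean
environments are standardized across demes. Standardized deme frequencies
and the environment vector are whitened by the same truncated Ω⁻¹ᐟ² used in
the differentiation scan (demes with no data at a locus sit at the pooled
mean, x = 0 — conservative, and necessary when demes hold 3–4 trees).
The Bayes factor is the closed-form marginal-likelihood ratio of
y = β·ẽ + N(0, I) with β ~ N(0, τ²) (τ = 1 on the standardized scale,
configurable) against β = 0; under the null it centers at its Occam
penalty −½log(1+τ²|ẽ|²), not at zero. ρ is the Spearman correlation of the
whitened vectors. Strong candidates are loci in the top 1% of both the BF
and |ρ| rankings (empirical quantiles, ties by input order). For correlated
rankings this intersection is deliberately conservative; the q²L expectation
holds only for independent rankings, which is how the permutation test is
phrased.

## Integration and enrichment

Tajima's-D candidates are the floor(0.01·G) most-negative genes per
population; positive outliers are not called, because an intermediate-
frequency excess can equally arise from collapsed duplicated regions. The
Venn partition over the four methods' gene sets is computed exhaustively
(exclusive regions sum to the union — a conservation check). Enrichment is
a one-sided hypergeometric test per annotation term with BH control at
0.05; the universe is the gene set that entered the corresponding scan, so
the test conditions on the same ascertainment. Annotations are a plain
two-column gene→term table; the pipeline can generate a synthetic one
(labelled as such) for simulated cohorts.

## Pipeline

Stages run in the workflow order simulate → filter → diversity → ld → xtx
→ eaa-lfmm → eaa-bayenv → integrate → enrich, writing TSV/VCF/BED
artifacts and a JSON manifest with the configuration, master seed,
per-stage row counts and a SHA-256 hash of every file. Reruns with one
configuration are bit-identical; `--from/--to` reuses upstream artifacts
from disk and reproduces the same hashes (TSV reads use round-trip float
parsing to keep this exact). Two deviations from the headline protocol are
forced by the generator's i.i.d. missingness: the "no missing data" rule
for the deme-level Ω panel becomes "missingness ≤ 10% and MAF > 0.05"
(a literally complete locus has probability 0.95²⁰⁰), and LD pruning uses a
5 kb comparison window since genes are independent beyond their span.

## Problem sizes

Defaults are desk-scale reductions chosen to keep the statistical structure
intact: 300 genes × 12 SNPs + 4,000 intergenic SNPs, 200 samples, 50
demes. Estimator-recovery tests use 5,000 independent loci (F_ST), 2,000
pairs (LD), ≥ 2,000 genic loci thinned to one per gene (scan-calibration
KS test — within-gene LD would otherwise violate the test's independence
assumption), and 20-seed replicates for false-discovery and power rates.

## What the tests do and do not show

Passing tests demonstrate: the estimators agree with first-principles
oracles; the scans are calibrated and powerful *under the generator's
assumptions* (island-model drift, i.i.d. missingness, linear climate
gradients, additive clines). They do not demonstrate robustness to
demographic history (bottlenecks, isolation by distance within
subpopulations), batch-structured missingness, non-linear genotype–
environment relations, or ascertainment from a real capture design. The
founder-copying LD model reproduces distance-decaying r² and its MAF
dependence but not coalescent haplotype genealogies; haplotype-based sweep
statistics are out of scope for the same reason.
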
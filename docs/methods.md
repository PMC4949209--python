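# Methods

## Scope

`rootqtl` re-implements, as a tested pipeline, a genome-wide association
analysis of root and shoot traits (root dry weight Rdw [g], root length
Rl [cm], shoot dry weight Sdw [g], tiller number Til, root-to-shoot
ratio RS = Rdw/Sdw) in a structured barley diversity panel of 179
genotypes — 59 modern cultivars, 72 landraces and 48 wild accessions —
genotyped at ~5892 post-QC SNPs on the seven barley chromosomes
(1H..7H, genetic positions in cM), phenotyped in a split-plot design
with two treatments (well-watered control vs drought), two years
(2014, 2015) and four replicates. The raw study data are not publicly
deposited, so every stage runs on synthetic panels whose statistical
structure matches those study conditions; the synthetic-data generator
is first-class, tested code.

## Synthetic panel generator

**Genotypes.** Each sub-population has a pool of `n_founders` (default
8) founder haplotypes drawn marker-wise from Balding–Nichols-diverged
allele frequencies (ancestral frequency Uniform(0.1, 0.9), divergence
parameter `fst` = 0.15, enough for the first two principal components to
separate the three groups cleanly). An accession is a doubled gamete —
the panel is a selfing species, so individuals are built fully
homozygous — whose haplotype switches founders along each chromosome
with probability `1 − exp(−rate · d)` per adjacent-marker gap of `d`
cM. The per-cM exchange rate is sub-population specific
(wild 0.04 < landrace 0.08 < cultivar 0.15), encoding the slower LD
decay of wild material; a smaller rate means longer shared founder
segments and therefore higher r² at a given distance. This is a
founder-mosaic model, not a coalescent: only the r²-versus-cM decay
shape and the group structure matter downstream, and no attempt is made
to match real allele-frequency spectra, mutation or selection.
Residual heterozygosity (`het_rate` = 0.03) and missingness
(`missing_rate` = 0.01) are injected completely at random; the QC stage
only ever uses marginal call rates, and Table-style allele-class counts
only need a thin heterozygote class.

**Planted QTL.** Candidate causal markers are chosen with a
minor-allele frequency in (0.08, 0.35), at least 30 cM apart, and with
a moderate minor-allele frequency contrast (~0.35) between the wild
sub-population and the rest. The contrast keeps the biology of the
emulated study — favourable exotic alleles carried mostly by wild
accessions — while staying identifiable: a locus whose genotype is an
exact function of ancestry cannot be separated from the structure
covariates by any structure-corrected scan. The default planted set is
three main-effect QTL (Rdw +1.8 g, Til +2.5 tillers, Sdw +3.5 g per
minor-allele copy) and one drought-responsive crossover QTL on Rdw
(−1.25 g under control, +1.25 g under drought per copy), whose signal
therefore lives entirely in the marker-by-treatment contrast.

**Phenotypes.** One record per genotype × treatment × year × replicate
× trait. A record is baseline(treatment, year) + Σ QTL dosage effects +
random genotype, G×T, G×Y, G×T×Y, replicate-within-environment and
residual effects, each drawn Normal with per-trait configured
variances. Rdw baselines are anchored to the published population means
(control/drought 9.7/5.1 g in 2014, 6.2/3.3 g in 2015); the other
baselines are plausible values for the species. Variance-component
defaults are loosely calibrated so broad-sense heritability lands near
the published coefficients (Rdw 0.62, Rl 0.48, Sdw 0.54, Til 0.90);
per-trait residual variances were never published, so these defaults
are anchored to the printed means and heritabilities only. RS is
constructed record-wise as Rdw/Sdw of the same experimental unit, with
the denominator floored at 0.5 g (a shoot cannot weigh nothing and the
ratio must not change sign); QTL declared on RS act through the
numerator. Tiller numbers are simulated continuous. What passing tests
on this generator do **not** show: robustness to real-data features such
as non-normal residuals, informative missingness, shared environment
between neighbouring pots, or allele-frequency spectra of a real chip.

## Marker QC

Removal order is fixed so the report reconciles exactly: monomorphic
markers (fewer than two observed dosage states), then call rate
< 0.95 (inclusive threshold: exactly 0.95 is retained), then minor
allele frequency ≤ 0.05 (strict threshold: retained only if MAF >
0.05). MAF counts allele copies over non-missing calls with
heterozygotes contributing one copy each — whether the original
protocol counted heterozygotes is unstated; copy counting is the
conventional choice. No imputation, strand flipping or physical
coordinates.

## Population structure

Kinship is the VanRaden method-1 realized relationship (dosages
centred by 2p̂, cross-product scaled by 2Σp̂(1−p̂), missing calls
mean-imputed for this computation only). PCA operates on the same
centred matrix. The Bayesian admixture clustering used in the original
analysis only served to establish K = 3 groups and justify structure
covariates; it is replaced by PCA + k-means with K = 3, which recovers
the three sub-populations on structured panels (adjusted Rand index
> 0.8 in the shipped tests). LD is the squared Pearson correlation of
dosage vectors over pairwise-complete calls; decay curves bin r² at
1 cM, smooth with an edge-truncated running mean of width 3 (no binning
rule was published; these are conventional choices), and report the
first bin centre whose smoothed mean falls below the threshold
(default 0.1), or "undefined" when never crossed.

## Split-plot ANOVA, variance components, heritability

The per-trait ANOVA fits, by sequential (Type-I) block projection in
the model's term order,

    Y = mu + T + R(T) + G + GxT + GxY + GxTxY + eps,

replication nested in treatment, F-tests of every term against the
residual mean square. The model is written without a year main effect;
taken literally, the year contrast is absorbed by the first
year-bearing interaction term, and a config switch (`include_year`)
adds the main effect for users who prefer a hierarchical model. The
projection is rank-revealing (SVD per block), so aliased terms are
detected rather than silently double-counted, and the sequential SS add
up to the total SS exactly on any design.

Variance components V_G, V_GxT, V_GxY (and V_GxTxY) are
expected-mean-squares (Henderson/ANOVA) estimates treating genotype and
its interactions as random, after sweeping out the environment cells
(treatment × year × replicate) so replicate effects do not inflate the
residual. Negative solutions are truncated to zero and flagged. On
balanced data with interior solutions these coincide with REML (a
shipped test cross-checks against lme4's REML on a balanced dataset);
on mildly unbalanced data they are the classical moment estimates. The
replication constant r is the arithmetic mean count over genotype ×
treatment × year cells — matching the published "average number of
replications (r = 3.8)" convention. Broad-sense heritability on an
entry-mean basis is

    H2 = V_G / (V_G + V_GxT/t + V_GxY/y + V_E/(t*y*r)),

truncated into [0, 1] with a flag.

## Association scan

The single-marker model is a mixed model with fixed grand mean, first
3 dosage-PCA covariates, treatment, marker-genotype class, marker ×
treatment, any selected cofactors, and a random line effect nested
within marker class; year is treated purely as replication and never
enters the model. With lines as the containing error stratum, the
F-tests for the marker and marker-by-treatment terms with containment
denominator degrees of freedom reduce, exactly under balance, to
F-tests on line-level aggregates: the marker main effect is tested on
genotype means pooled over treatments, and the interaction on genotype
drought-minus-control differences. The package implements that
reduction directly; it is what makes 1000-permutation genome-wide
thresholds and leave-20%-out cross-validation affordable on one CPU.
Markers are categorical (up to three dosage classes), so dominance is
not forced to zero; classes observed in fewer than two lines simply
contribute fewer degrees of freedom. Genotypes missing a call at the
tested marker are dropped from that marker's test. The model the
original analysis ran omitted a kinship term from its equation while
the accompanying text says kinship and PCA "had to be included"; PCs
are the default structure correction here, and a kinship random effect
(GLS whitening of the line means, variance ratio profiled on the null
model, markers modally imputed so the whitened design stays complete)
is available behind `MLMSpec(use_kinship=True)` but off by default.

LOD is −log10 of the marker F-test p-value (no algebraic definition
was published; this is the standard reading, and p ≤ 1e-4 ⇔ LOD ≥ 4).
Genome-wide significance combines a permutation threshold — whole
lines are permuted so all records of a genotype move together,
preserving the treatment/year/replicate structure; the threshold is the
(1 − α) quantile of the per-permutation maximum main-effect LOD — with
the fixed LOD ≥ 4 floor: the rule is LOD ≥ max(threshold, 4). The same
rule is applied to the interaction LOD (how interaction effects were
thresholded originally is unstated).

The multi-locus procedure forward-selects: scan, take the most
informative SNP above threshold (ties broken by smaller cM, then
marker id — determinism), add its class indicators as fixed cofactors,
rescan, until nothing passes. Because cofactors enter as class
indicators, re-scanning a selected peak is exactly self-absorbing
(its LOD drops to 0). Markers with r² > 0.99 to a cofactor leave the
candidate pool to avoid rank-deficient rescans. QTL intervals merge the
significant first-iteration SNPs within 5 cM of each peak; a lone peak
collapses to a point interval. The effect type (M, MxT, M/MxT) is read
off which tests passed at the iteration of selection.

Cross-validation drops 20% of the trait's phenotype records at random,
reruns the full multi-locus scan, and counts a candidate as detected
when a selected marker lies within 5 cM on the same chromosome; the
plain arithmetic mean of the candidate's per-run p-values is its
validated p (mean of p, not of log p, following the published
description), and significance re-applies the p ≤ 1e-4 rule to that
mean. The percent variance explained by a marker is the partial R² of
its class factor on genotype means — (SSE_without − SSE_with)/SS_total
— given the other selected cofactors; the original computation was
never specified, and genotype-level R² matches the magnitude of the
published per-QTL values.

## Allele-class quantification and RP

Genotype-level trait means (averaged over replicates, treatments and
both years) are grouped by dosage class at the peak marker; the major
allele is the more frequent homozygote (frequency ties break toward
the alphabetically first allele label). Relative performance is

    RP = 100 * (max class mean − min class mean) / min class mean

over the classes present, heterozygotes included — the published table
never defines RP, but this formula reproduces 12 of its 17 rows to two
decimals from the printed class means, and the remaining five are
consistent with it up to the pre-rounding of the printed means (the
shipped verification fixture checks every row, using the RP interval
attainable under ±0.005 perturbation of each printed mean for those
five). RP is undefined when the smallest class mean is non-positive or
fewer than two classes exist.

## Rogers distance and haplotype comparison

With dosage coding, the per-locus allele-frequency vectors are
(d/2, 1 − d/2), so the per-locus Rogers distance
sqrt(½ Σ (p − q)²) reduces to |d₁ − d₂|/2; the distance between two
genotypes is the mean over loci where both calls are present (the
divisor is the count of complete loci — the original handling of
missing data is unstated). This is a metric on complete data, bounded
in [0, 1], with opposite homozygotes at distance 1 and a
homozygote–heterozygote locus contributing 0.5. Group comparisons
sample `n_select` (default 30) genotypes stratified evenly across
groups — by default the homozygous allele classes at the peak —
and report within- and between-group mean distances (and 1 − distance
as similarity) both on the ±5 cM local window (inclusive bounds) and
genome-wide.

## Problem sizes and numerical notes

The shipped tests and the recovery analyses run at reduced scale —
panels of 90–179 genotypes and 500–1500 markers, 200 permutations, 10
seeds for end-to-end recovery, 20 seeds for heritability recovery, 50
replicate scans for null calibration — chosen so the whole suite
completes in a few minutes on one core while leaving each check ample
resolution for its tolerance. Rank decisions in the projection code use
an SVD tolerance of `max(shape) · eps · max(s₁, √n)`; the absolute
√n floor is what makes cofactor self-absorption exact instead of
producing spurious infinite F statistics from cancellation residue.
p-values are floored at the smallest positive double before taking
logs. All stochastic operations take explicit seeds; nothing uses
global random state.

## Known limitations

- The line-level reduction of the marker model is exact only for
  balanced data; under missingness it is an approximation (genotype
  means are computed from whatever records exist).
- EMS variance components can be noticeably biased under strong
  unbalance; r enters as an arithmetic average only.
- The permutation threshold permutes line aggregates against the
  genotype matrix, which preserves the phenotype correlation structure
  but breaks genotype–structure association; with strong structure the
  threshold is therefore slightly conservative.
- The generator does not model linkage between chromosomes, admixed
  individuals, or genotyping error beyond MCAR missingness.
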
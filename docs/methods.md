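# Methods

## Model and rationale

A polymorphic inversion suppresses recombination between its direct (H1)
and inverted (H2) orientations, so haplotypes inside the inverted segment
fall into two divergent clades. On a genotyping array this appears as long-
range linkage disequilibrium: with genotypes encoded as minor-allele dosage
(m/m = 0, m/M = 1, M/M = 2) and normalized per SNP, the first principal
component of the local genotype matrix orders individuals by their count of
H1 haplotypes, producing three clusters (H1/H1, H1/H2, H2/H2). The cluster
assignment is the "master" inversion genotype; its validity is checked by a
Hardy–Weinberg test on the class counts, exactly as one would check a
directly assayed biallelic variant. Downstream, each cis expression probe
is regressed on the H1 dosage; the slope B is the log2 expression change
per H1 copy.

## Inversion genotyping (`invcall`)

**QC** (defaults): individuals with ≥ 5% missing genotypes are dropped
first; then SNPs with call rate ≤ 0.95, sample MAF ≤ 0.05, or per-SNP HWE
p < 1e-5. MAF and HWE are recomputed on the surviving individuals. The
order (individuals, then SNPs) is fixed and logged.

**Normalization**: per SNP, z = (g − μ)/√(p(1−p)) with p = μ/2 the sample
allele frequency; missing entries are set to 0 after centering (mean
imputation in the normalized space); monomorphic or constant columns are
dropped. A pseudocount frequency estimator ((1 + Σg)/(2 + 2n)) is available
by flag but off by default — with the interval sizes involved (tens of
SNPs, hundreds of individuals) the two are indistinguishable in practice.

**PCA**: scores are SVD projections of the column-centered normalized
matrix; components beyond the numerical rank are reported with zero scores
and zero explained variance rather than round-off noise. PC1's sign is
fixed so that it correlates non-negatively with the per-individual mean raw
dosage (more major alleles ⇒ higher PC1 ⇒ more H1-like when H1 is the
common clade); the orientation can be overridden by passing any
per-individual quantity known to increase with H1 (e.g. a tag-SNP dosage)
as `orient_by`. Other components have their largest-magnitude loading made
positive, a convention only.

**Clustering**: one-dimensional k-means with k = 3 on PC1, solved *exactly*
by dynamic programming over the sorted scores (the optimal 1-D clustering
is a contiguous partition, so an O(kn²) DP finds the global optimum). An
earlier design — Lloyd iterations seeded at the 1/6, 1/2, 5/6 quantiles —
was abandoned after testing: with genotype frequencies as skewed as a
0.2-frequency inverted haplotype produces (~62/34/4%), two quantile seeds
land inside the majority cluster and Lloyd converges to a split of that
cluster instead of the genotype partition. The DP has no initialization,
is deterministic, and is independent of input order. A cluster left empty
(possible in principle under k = 3 with fewer than three occupied genotype
classes) yields a warning and a zero count, not a refit.

**Ambiguity exclusion**: after clustering, individuals more than
`sd_limit` (default 3) within-cluster standard deviations from their own
cluster's mean PC1 are labeled EXCLUDED in a single pass without refitting.
A cluster whose SD is zero up to round-off (the noiseless limit) excludes
nobody; "zero" is SD < 1e-9 × max(1, max|PC1|). Sample SD uses ddof = 1;
singleton clusters have SD 0.

**HWE test**: 1-df chi-square. q is estimated from the counts, expected
counts are (Nq², 2Nq(1−q), N(1−q)²), classes with expected 0 contribute 0,
and p is the upper tail of χ²(1). This reproduces both published example
p-values (0.31, 0.43) at 2 decimals; an exact test is deliberately out of
scope.

## cis-eQTL (`eqtl`)

**Preprocessing**: detection filter (blood: mean detection value > 0.90;
brain: detection p-value < 0.01, applied per region), then log2, then
quantile normalization across individuals. Quantile normalization maps each
individual's values onto the mean of the column-sorted distributions; tied
cells receive the mean of the reference quantiles their min–max rank range
spans. *Caveat*: QN assumes no single probe moves an individual's
distribution. The end-to-end demo therefore does not re-normalize its
simulated data (generated directly on the normalized log2 scale): with only
28 probes, QN lets a strong causal probe leak an artifactual ~∓0.08 effect
into null probes — an artifact genome-wide arrays (tens of thousands of
probes) do not have.

**Regression**: OLS of expression on [1, dosage, covariates], fit by
`numpy.linalg.lstsq`; SE from σ̂² (X'X)⁻¹ with σ̂² = RSS/(n − k − 1);
two-sided p from t(n − k − 1); CI95 = B ± t₀.₉₇₅·SE. The fit is verified
in tests against both explicit normal equations and statsmodels OLS to
1e-8. Degenerate cases: a perfect fit (RSS ≤ 1e-10 × max(1, y'y)) reports
SE = 0, p = 0 with a logged warning (arises in noiseless tests); constant
dosage raises; rank-deficient designs drop collinear covariate columns
(never intercept or dosage) greedily from the right, warn, and refit.
Categorical covariates are one-hot encoded with the first level dropped;
individuals with missing covariates are dropped listwise. Individuals are
joined across tables strictly by ID.

**Multiplicity**: Bonferroni at α/m, m = probes tested in that dataset;
tissues/brain regions are independent families each with their own m.
Thresholds are displayed at 2 significant figures (0.05/28 → 0.0018) but
compared at full precision.

## Probe QC (`probeqc`)

A probe is SNP-confounded iff a SNP with MAF > `maf_min` (default 0.01)
lies within its 1-based inclusive genomic footprint. Cross-hybridization is
scored by the best ungapped percent identity (100 × matches/50, N never
matches) of the 50-mer over all placements on each transcript and its
reverse complement; transcripts shorter than the probe are scored over the
best overlap of ≥ 25 bases or skipped. `multi_target` is set when ≥ 2
distinct genes reach `min_identity` (default 90%, chosen to separate
94–100% paralog hits from background ~50–60% identity; at this scale an
ungapped scan approximates a gapped BLAST search). No E-values, gapped
alignment, or remote queries.

## Synthetic data (`simdata`)

The generator is a two-prototype flip model, not a coalescent: each clade
has a fixed 0/1 prototype over the inside-inversion SNPs, and a drawn
haplotype flips each prototype allele independently with probability
`flip_rate`. Outside SNPs are clade-independent with allele frequency
uniform in [0.05, 0.5]. Defaults (stated world): 60 inside SNPs, 20
outside, divergence 0.8, flip_rate 0.05, H2 frequency 0.21, n = 431,
missing rate 1% (MCAR), recombinant fraction 1.4% (≈ 6 of 431, the order
of the ambiguous exclusions seen in practice), 28 probes with one causal
effect of +0.37 log2/copy, residual SD 0.3, age ~ U(40, 80) with 0.003
log2/year and gender ~ Bernoulli(0.5) with 0.05 log2. Divergence and
flip_rate have no published generative values; these produce clean
tri-clustering while leaving realistic within-clade variation, and are
config-exposed. Minor/major alleles are re-determined per SNP from the
simulated sample (exact 50/50 ties go to the H1-prototype allele).
Recombinants replace one haplotype with a single-crossover H1/H2 chimera
(uniform crossover point among inside SNPs), are marked ambiguous in the
truth, and the genotype matrix is rebuilt with the identical missingness
mask.

What a green test establishes — and what it does not: the generator
reproduces the *statistical geometry* the method needs (clade divergence,
HWE class sampling, linear dosage response, Gaussian noise). It has no
recombination map, no allele-frequency spectrum realism, no copy-number
variation of the kind that complicates the *LRRC37* family, no
batch/array structure beyond an optional categorical covariate, and MCAR
missingness only. Recovery and error-rate results on it validate the
implementation, not the biology of any particular locus.

## Numerical and reporting conventions

Seeded `numpy.random.default_rng` everywhere; identical (parameters, seed)
give bit-identical outputs. Report percentages round half-up; HWE p to 2
decimals; B and CI to 2 decimals; p-values in scientific notation with 2
significant digits. Coordinates are 1-based inclusive throughout (UCSC
text style); BED input is converted on read. The missing-dosage sentinel
is −1, never 0.

## Known limitations

- The identity scan is ungapped; an indel-containing paralog match would
  be underscored.
- Exclusion uses a single pass; no iterative refitting after outlier
  removal (raising `sd_limit` therefore never excludes more individuals).
- The HWE test is asymptotic; with very small expected class counts an
  exact test would be preferable.
- `run_pipeline` handles one tissue per call; multi-region studies loop
  over configs, each with its own Bonferroni family.
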
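# inveqtl

Inversion genotyping from local SNP PCA, and allele-dosage cis-eQTL analysis
— a reusable, tested implementation of the analysis used to study how the
common 17q21.31 inversion polymorphism shapes nearby gene expression.

## The problem

A polymorphic chromosomal inversion (such as the ~1 Mb 17q21.31 segment
carrying *MAPT*, *CRHR1* and the *LRRC37* gene family) suppresses
recombination between its two orientations. The direct (H1) and inverted
(H2) arrangements therefore evolve as two divergent haplotype clades, and
SNP genotyping arrays see that divergence even though they cannot see the
inversion itself. This package exploits it:

1. **Inversion genotyping** (`inveqtl.invcall`). Genotypes inside the
   inversion interval are encoded m/m = 0, m/M = 1, M/M = 2 (m = minor
   allele), centered and scaled per SNP by √(p(1−p)) (EIGENSTRAT
   normalization), and projected on principal components. PC1 separates
   individuals into three clusters — H1/H1, H1/H2, H2/H2 — which are found
   by exact one-dimensional k-means (k = 3). Individuals more than 3 SD from
   their cluster mean on PC1 are excluded as ambiguous, and the called
   counts are validated with a 1-df chi-square Hardy–Weinberg test
   (expected p², 2pq, q²).
2. **cis-eQTL testing** (`inveqtl.eqtl`). Each expression probe in the cis
   window (1 Mb flanking the inversion) is regressed by OLS on H1 dosage
   (H1/H1 = 2, H1/H2 = 1, H2/H2 = 0) plus covariates. B is the log2
   expression change per H1 copy, with SE, t, 95% CI and a two-sided p;
   significance is Bonferroni-controlled at α/m over the m probes tested
   per tissue.
3. **Probe QC** (`inveqtl.probeqc`). Flags probes with a common SNP
   (MAF > 1%) under their 50-mer footprint, and probes whose sequence
   matches more than one gene at ≥ 90% ungapped identity (a local
   approximation of a BLAST cross-hybridization check).
4. **Synthetic cohorts** (`inveqtl.simdata`). A two-prototype haplotype
   model with within-clade flip noise, HWE clade sampling, recombinant
   injection, and linear dosage-responsive expression — every stage above
   is testable against known ground truth without any downloads.

There is no command-line tool; the package is used from Python. The
`examples/` directory has one short narrative script per capability, and
`inveqtl.pipeline.run_pipeline` composes everything end-to-end.

## Worked example

```bash
python examples/05_full_pipeline.py
```

simulates a 431-individual whole-blood-style cohort (H2 frequency 0.21, one
causal probe among 28) and runs the full analysis. With seed 1 it prints:

```
Inversion genotype calls
========================
H1/H1: 256 individuals (61%)
H1/H2: 141 individuals (34%)
H2/H2: 23 individuals (5%)
Excluded (> 3 SD from cluster mean): 4
Hardy-Weinberg p = 0.54

cis-eQTL (whole_blood)
================
Probes tested: 28; Bonferroni threshold p < 0.05/28 = 0.0018
Significant probes: 1
  probe01 (GENE01): B = 0.38 (0.33, 0.42), p = 6.6e-45
```

Reading it: the three PC1 clusters hold genotype proportions consistent with
Hardy–Weinberg equilibrium (p = 0.54, so the clustering behaves like a real
biallelic genotype), four recombinant-like individuals were refused a call,
and exactly the simulated causal probe crosses the Bonferroni bar — its
fitted B of 0.38 (95% CI 0.33–0.42) covers the true simulated effect of
0.37 log2 units per H1 copy.

As a smaller entry point:

```python
from inveqtl import hwe_chisq
chi2, p = hwe_chisq(19, 160, 252)   # (minor-hom, het, major-hom) counts
# p = 0.309: no evidence the three clusters deviate from HWE
```

## Acceptance script

`scripts/acceptance.py` recomputes, from the package's own routines, the
Hardy–Weinberg p-values for the two published inversion genotype count
triples (whole blood n = 431 and brain n = 144):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It writes one JSON object with a `value` (the p-value, 2 decimals) and `n`
per target. `tests/test_acceptance.py` additionally verifies the simulation
contract: 95% CI coverage of preset effect sizes at the study cohort sizes,
≥ 99% inversion-genotype recovery (100% in the noiseless limit), familywise
error control under the all-null simulation, and agreement of the OLS and
PCA routines with brute-force oracles to 1e-8.
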
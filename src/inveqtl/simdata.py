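"""Synthetic genotype and expression cohorts with a two-clade inversion.

The generator emulates the statistical structure a polymorphic inversion
imprints on local SNP data: recombination suppression between orientations
yields two divergent haplotype clades (H1, direct; H2, inverted; H2
frequency ~0.2 in Europeans), individuals receive two clade draws under
Hardy–Weinberg sampling, and cis gene expression responds linearly to the
per-individual H1-haplotype count. A small fraction of recombinant
individuals — one haplotype half H1-like, half H2-like — produces the
ambiguous samples a PC1-based genotyper should exclude.

The haplotype model is a two-prototype flip model, not a coalescent: each
clade has a fixed prototype over the inside-inversion SNPs and a drawn
haplotype flips each prototype allele independently with a small
within-clade rate. This is sufficient to reproduce the tri-cluster PC1
geometry the genotyper exploits while staying fully parameterized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, ExpressionTable, GenomicInterval, GenotypeTable

logger = logging.getLogger(__name__)

#: Default genomic placement mirrors the 17q21.31 study region (UCSC hg18
#: text coordinates): inversion interval and a ~1 Mb cis flank each side.
DEFAULT_CHROM = "chr17"
DEFAULT_INVERSION = GenomicInterval(DEFAULT_CHROM, 40_850_001, 41_850_000)
DEFAULT_CIS = GenomicInterval(DEFAULT_CHROM, 39_899_921, 42_989_253)

_H1, _H2, _RECOMB = 0, 1, 2
_BASES = np.array(list("ACGT"))


@dataclass
class HaplotypePools:
    """Clade prototypes and per-site sampling parameters for one region."""

    h1_prototype: np.ndarray  # 0/1 per SNP
    h2_prototype: np.ndarray
    within_clade_flip_rate: float
    snp_positions: np.ndarray  # 1-based, strictly increasing
    inside_inversion: np.ndarray  # bool per SNP
    outside_maf: np.ndarray  # allele-1 frequency at clade-independent sites (nan inside)
    chrom: str = DEFAULT_CHROM
    allele0: np.ndarray = field(default=None)  # nucleotide letters for allele coding
    allele1: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.h1_prototype = np.asarray(self.h1_prototype, np.uint8)
        self.h2_prototype = np.asarray(self.h2_prototype, np.uint8)
        if self.h1_prototype.shape != self.h2_prototype.shape or self.h1_prototype.size < 2:
            raise ValueError("prototypes must have equal length >= 2")
        if not 0 <= self.within_clade_flip_rate < 0.5:
            raise ValueError("within-clade flip rate must lie in [0, 0.5)")

    @property
    def n_snps(self) -> int:
        return self.h1_prototype.size

    @property
    def n_inside(self) -> int:
        return int(self.inside_inversion.sum())


@dataclass
class SimTruth:
    """Generator-side ground truth for recovery tests.

    ``true_dosage`` is the per-individual count of intact H1 haplotypes;
    ``ambiguous`` marks recombinant individuals whose call a genotyper
    should refuse. The drawn haplotype pair and clade labels are retained so
    recombinants can be injected after the fact.
    """

    individual_ids: list[str]
    true_dosage: np.ndarray  # {0,1,2} per individual
    ambiguous: np.ndarray | None = None  # bool per individual
    haplotypes: np.ndarray | None = None  # (n, 2, n_snps) uint8 allele-1 indicators
    clades: np.ndarray | None = None  # (n, 2) in {H1=0, H2=1, RECOMB=2}
    pools: HaplotypePools | None = None
    seed: int = 0
    probe_effects: np.ndarray | None = None  # B per probe, log2 units per H1 copy
    covariate_effects: np.ndarray | None = None
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        n = len(self.individual_ids)
        self.true_dosage = np.asarray(self.true_dosage, int)
        if self.true_dosage.shape != (n,):
            raise ValueError("true_dosage length must equal the number of individuals")
        if self.ambiguous is None:
            self.ambiguous = np.zeros(n, bool)


def simulate_haplotype_pools(
    n_inside: int,
    n_outside: int = 0,
    divergence: float = 0.8,
    flip_rate: float = 0.05,
    seed: int = 0,
    chrom: str = DEFAULT_CHROM,
    inversion: GenomicInterval = DEFAULT_INVERSION,
    cis: GenomicInterval = DEFAULT_CIS,
) -> HaplotypePools:
    """Draw clade prototypes differing at round(divergence * n_inside) sites.

    Inside-inversion SNPs are placed evenly across ``inversion``; outside
    SNPs are clade-independent common variants (allele-1 frequency uniform
    in [0.05, 0.5]) split between the two cis flanks.
    """
    if n_inside < 2:
        raise ValueError("n_inside must be >= 2")
    if not 0 < divergence <= 1:
        raise ValueError("divergence must lie in (0, 1]")
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)

    inside_pos = np.linspace(inversion.start, inversion.end, n_inside).round().astype(int)
    inside_pos = np.unique(inside_pos)
    assert inside_pos.size == n_inside, "inversion interval too small for n_inside SNPs"
    n_left = n_outside // 2
    n_right = n_outside - n_left
    left = np.linspace(cis.start, inversion.start - 1, n_left + 2)[1:-1] if n_left else []
    right = np.linspace(inversion.end + 1, cis.end, n_right + 2)[1:-1] if n_right else []
    positions = np.concatenate(
        [np.asarray(left).round(), inside_pos, np.asarray(right).round()]
    ).astype(int)
    inside_mask = np.zeros(positions.size, bool)
    inside_mask[n_left : n_left + n_inside] = True

    n_snps = positions.size
    h1 = np.zeros(n_snps, np.uint8)
    h2 = np.zeros(n_snps, np.uint8)
    h1[inside_mask] = rng.integers(0, 2, n_inside)
    h2[inside_mask] = h1[inside_mask]
    n_diff = int(round(divergence * n_inside))
    diff_sites = rng.choice(np.flatnonzero(inside_mask), size=n_diff, replace=False)
    h2[diff_sites] ^= 1

    outside_maf = np.full(n_snps, np.nan)
    outside_maf[~inside_mask] = rng.uniform(0.05, 0.5, n_snps - n_inside)

    a0_idx = rng.integers(0, 4, n_snps)
    a1_idx = (a0_idx + rng.integers(1, 4, n_snps)) % 4  # distinct second allele
    return HaplotypePools(
        h1_prototype=h1,
        h2_prototype=h2,
        within_clade_flip_rate=flip_rate,
        snp_positions=positions,
        inside_inversion=inside_mask,
        outside_maf=outside_maf,
        chrom=chrom,
        allele0=_BASES[a0_idx],
        allele1=_BASES[a1_idx],
    )


def draw_haplotypes(
    pools: HaplotypePools, clades: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one haplotype per clade label (0 = H1, 1 = H2), shape (k, n_snps)."""
    clades = np.asarray(clades)
    k = clades.size
    proto = np.where(clades[:, None] == _H2, pools.h2_prototype, pools.h1_prototype)
    haps = proto.astype(np.uint8)
    inside = pools.inside_inversion
    flips = rng.random((k, int(inside.sum()))) < pools.within_clade_flip_rate
    haps[:, inside] ^= flips.astype(np.uint8)
    outside = ~inside
    if outside.any():
        haps[:, outside] = (
            rng.random((k, int(outside.sum()))) < pools.outside_maf[outside]
        ).astype(np.uint8)
    return haps


def _recode_to_dosage(
    pools: HaplotypePools, haplotypes: np.ndarray, missing_mask: np.ndarray,
    individual_ids: list[str],
) -> GenotypeTable:
    """Collapse haplotype pairs to major-allele dosage with sample-frequency recoding.

    The minor/major allele at each SNP is re-determined from the simulated
    sample; an exact 50/50 tie is broken toward the allele carried by the H1
    prototype.
    """
    allele1_count = haplotypes.sum(axis=1)  # (n, n_snps)
    called = ~missing_mask
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq1 = np.where(
            n_called > 0,
            np.where(missing_mask, 0, allele1_count).sum(axis=0) / (2 * n_called),
            0.0,
        )
    minor_is_1 = np.where(
        freq1 == 0.5, pools.h1_prototype == 1, freq1 < 0.5
    )
    minor_count = np.where(minor_is_1[None, :], allele1_count, 2 - allele1_count)
    dosage = (2 - minor_count).astype(np.int8)
    dosage[missing_mask] = MISSING
    maf = np.minimum(freq1, 1 - freq1)
    width = max(4, len(str(pools.n_snps)))
    meta = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:0{width}d}" for i in range(pools.n_snps)],
            "chrom": pools.chrom,
            "pos": pools.snp_positions,
            "minor_allele": np.where(minor_is_1, pools.allele1, pools.allele0),
            "major_allele": np.where(minor_is_1, pools.allele0, pools.allele1),
            "maf": maf,
        }
    )
    return GenotypeTable(dosage, meta, individual_ids)


def simulate_cohort(
    pools: HaplotypePools,
    n_individuals: int,
    h2_freq: float = 0.2,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeTable, SimTruth]:
    """Sample a cohort under Hardy–Weinberg clade assortment.

    Each individual receives two independent haplotypes, each from clade H2
    with probability ``h2_freq``; genotype entries are masked missing
    independently at ``missing_rate`` (missing completely at random).
    ``SimTruth.true_dosage`` records the H1-haplotype count (2, 1 or 0).
    """
    if n_individuals < 3:
        raise ValueError("need at least 3 individuals (downstream clustering)")
    if not 0 <= h2_freq <= 1:
        raise ValueError("h2_freq must lie in [0, 1]")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    clades = (rng.random((n_individuals, 2)) < h2_freq).astype(np.uint8)
    haps = draw_haplotypes(pools, clades.ravel(), rng).reshape(
        n_individuals, 2, pools.n_snps
    )
    missing_mask = rng.random((n_individuals, pools.n_snps)) < missing_rate
    ids = [f"ind{i + 1:04d}" for i in range(n_individuals)]
    table = _recode_to_dosage(pools, haps, missing_mask, ids)
    truth = SimTruth(
        individual_ids=ids,
        true_dosage=(2 - clades.sum(axis=1)).astype(int),
        ambiguous=np.zeros(n_individuals, bool),
        haplotypes=haps,
        clades=clades.astype(np.int8),
        pools=pools,
        seed=seed,
    )
    return table, truth


def inject_recombinants(
    genotypes: GenotypeTable, truth: SimTruth, fraction: float, seed: int = 0
) -> tuple[GenotypeTable, SimTruth]:
    """Replace one haplotype of round(fraction * n) individuals by a recombinant.

    The recombinant's inside-inversion segment is H1-like before a single
    crossover site drawn uniformly among inside SNPs and H2-like after it
    (with the usual within-clade flip noise). Affected individuals are
    marked ambiguous in the truth; the genotype matrix is rebuilt with the
    same missingness pattern and minor-allele recoding as the input.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must lie in [0, 0.5)")
    if truth.haplotypes is None or truth.pools is None:
        raise ValueError("truth must carry haplotypes and pools (from simulate_cohort)")
    n = len(truth.individual_ids)
    k = int(round(fraction * n))
    if k == 0:
        return genotypes, truth
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=k, replace=False)
    pools = truth.pools
    inside_idx = np.flatnonzero(pools.inside_inversion)

    haps = truth.haplotypes.copy()
    clades = truth.clades.copy()
    for i in chosen:
        cut = rng.integers(1, inside_idx.size)  # crossover after the cut-th inside SNP
        recomb = haps[i, 0].copy()
        recomb[inside_idx[:cut]] = pools.h1_prototype[inside_idx[:cut]]
        recomb[inside_idx[cut:]] = pools.h2_prototype[inside_idx[cut:]]
        flips = rng.random(inside_idx.size) < pools.within_clade_flip_rate
        recomb[inside_idx] ^= flips.astype(np.uint8)
        haps[i, 0] = recomb
        clades[i, 0] = _RECOMB

    missing_mask = genotypes.dosages == MISSING
    table = _recode_to_dosage(pools, haps, missing_mask, list(genotypes.individual_ids))
    ambiguous = truth.ambiguous.copy()
    ambiguous[chosen] = True
    true_dosage = truth.true_dosage.copy()
    true_dosage[chosen] = (clades[chosen, 1] == _H1).astype(int)  # intact haplotype only
    new_truth = SimTruth(
        individual_ids=list(truth.individual_ids),
        true_dosage=true_dosage,
        ambiguous=ambiguous,
        haplotypes=haps,
        clades=clades,
        pools=pools,
        seed=truth.seed,
        probe_effects=truth.probe_effects,
        covariate_effects=truth.covariate_effects,
        noise_sd=truth.noise_sd,
    )
    return table, new_truth


def simulate_dosage_truth(
    n_individuals: int,
    h2_freq: float = 0.2,
    seed: int = 0,
    probe_effects: np.ndarray | None = None,
    noise_sd: float = 0.3,
) -> SimTruth:
    """Dosage-only truth under Hardy–Weinberg clade sampling (no haplotypes).

    Convenient when only the expression side is under study: each individual
    draws two clades independently (H2 with probability ``h2_freq``) and the
    truth records the H1 count, ready for :func:`simulate_expression`.
    """
    rng = np.random.default_rng(seed)
    clades = (rng.random((n_individuals, 2)) < h2_freq).astype(int)
    ids = [f"ind{i + 1:04d}" for i in range(n_individuals)]
    return SimTruth(
        individual_ids=ids,
        true_dosage=(2 - clades.sum(axis=1)),
        seed=seed,
        probe_effects=None if probe_effects is None else np.asarray(probe_effects, float),
        noise_sd=noise_sd,
    )


def simulate_covariates(
    n_individuals: int, seed: int = 0, n_batches: int = 0
) -> pd.DataFrame:
    """Cohort covariates: age ~ Uniform(40, 80) years, gender ~ Bernoulli(0.5),
    and an optional categorical batch factor with ``n_batches`` levels."""
    rng = np.random.default_rng(seed)
    ids = [f"ind{i + 1:04d}" for i in range(n_individuals)]
    cov = pd.DataFrame(
        {
            "age": rng.uniform(40, 80, n_individuals),
            "gender": rng.integers(0, 2, n_individuals),
        },
        index=pd.Index(ids, name="individual_id"),
    )
    if n_batches > 0:
        cov["batch"] = [f"batch{b + 1}" for b in rng.integers(0, n_batches, n_individuals)]
    return cov


def _covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    cov = covariates.apply(
        lambda c: c if np.issubdtype(c.dtype, np.number) else c.astype("category")
    )
    return pd.get_dummies(cov, drop_first=True, dtype=float).to_numpy()


def simulate_expression(
    truth: SimTruth,
    n_probes: int,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    probe_meta: pd.DataFrame | None = None,
    cis: GenomicInterval = DEFAULT_CIS,
    low_detection: dict[int, float] | None = None,
) -> ExpressionTable:
    """Generate probe expression as a linear response to H1 dosage.

    expression(i, j) = intercept_i + B_i * dosage_j + sum_c gamma_c * cov_cj
    + Normal(0, noise_sd) noise, with B taken from ``truth.probe_effects``
    (log2 units per H1 copy). Values are on the log2 scale already. The
    detection statistic is 1.0 for every probe unless ``low_detection`` maps
    probe indices to alternative values. Probe intervals default to 50-mer
    footprints spread across the cis region.
    """
    if truth.probe_effects is None or len(truth.probe_effects) != n_probes:
        raise ValueError("truth.probe_effects must be set with length n_probes")
    n = len(truth.individual_ids)
    if covariates is not None and len(covariates) != n:
        raise ValueError("covariate row count must equal the individual count")
    rng = np.random.default_rng(seed)
    b = np.asarray(truth.probe_effects, float)
    dosage = truth.true_dosage.astype(float)
    intercepts = rng.normal(8.0, 0.5, n_probes)
    expr = intercepts[:, None] + b[:, None] * dosage[None, :]
    if covariates is not None and len(covariates.columns):
        design = _covariate_design(covariates.loc[truth.individual_ids])
        gamma = truth.covariate_effects
        if gamma is None or len(gamma) != design.shape[1]:
            raise ValueError(
                "truth.covariate_effects must match the covariate design "
                f"({design.shape[1]} columns)"
            )
        expr += (design @ np.asarray(gamma, float))[None, :]
    expr += rng.normal(0.0, truth.noise_sd, expr.shape)

    width = max(2, len(str(n_probes)))
    probe_ids = [f"probe{i + 1:0{width}d}" for i in range(n_probes)]
    if probe_meta is None:
        starts = np.sort(
            rng.integers(cis.start, cis.end - 49, n_probes)
        )
        probe_meta = pd.DataFrame(
            {
                "probe_id": probe_ids,
                "gene": [f"GENE{i + 1:0{width}d}" for i in range(n_probes)],
                "chrom": cis.chrom,
                "start": starts,
                "end": starts + 49,
            }
        )
    else:
        probe_ids = list(probe_meta["probe_id"])
    detection = pd.Series(1.0, index=pd.Index(probe_ids))
    for idx, val in (low_detection or {}).items():
        detection.iloc[idx] = val
    values = pd.DataFrame(expr, index=pd.Index(probe_ids), columns=truth.individual_ids)
    return ExpressionTable(values, probe_meta, detection)


def write_sim_truth(truth: SimTruth, path) -> None:
    """Persist the individual-level truth as TSV (dosage + ambiguity flags)."""
    pd.DataFrame(
        {
            "individual_id": truth.individual_ids,
            "true_dosage": truth.true_dosage,
            "ambiguous": truth.ambiguous.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)
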
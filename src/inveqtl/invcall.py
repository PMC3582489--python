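"""Inversion genotyping from a local SNP matrix.

The two orientations of a polymorphic inversion suppress recombination
between them, so SNP haplotypes inside the inverted segment fall into two
divergent clades (H1, the direct orientation; H2, the inverted one). On the
first principal component of the normalized local genotype matrix,
individuals then form three clusters — H1/H1, H1/H2 and H2/H2 — and the
cluster a sample falls in is its "master" inversion genotype. Samples far
from every cluster (recombinant or poorly genotyped) are excluded, and the
resulting genotype counts are validated against Hardy–Weinberg equilibrium.

Normalization follows the EIGENSTRAT convention: per-SNP centering and
scaling by sqrt(p(1-p)) with p the sample allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genio import MISSING, GenotypeTable

logger = logging.getLogger(__name__)

LABELS = {2: "H1/H1", 1: "H1/H2", 0: "H2/H2"}
EXCLUDED = "EXCLUDED"


@dataclass
class NormalizedGenotypes:
    """Centered/scaled genotype matrix restricted to polymorphic SNPs."""

    matrix: np.ndarray  # individuals x kept SNPs, float64
    snp_ids: list[str]
    allele_freq: np.ndarray  # p_j = mean dosage / 2 for each kept SNP
    mean_raw_dosage: np.ndarray  # per-individual mean dosage over kept SNPs


@dataclass
class PCScores:
    individual_ids: list[str]
    scores: np.ndarray  # individuals x k
    explained_variance: np.ndarray  # length k, non-increasing

    @property
    def pc1(self) -> np.ndarray:
        return self.scores[:, 0]

    @property
    def pc2(self) -> np.ndarray:
        return self.scores[:, 1] if self.scores.shape[1] > 1 else np.zeros(len(self.individual_ids))


@dataclass
class InversionCalls:
    """Per-individual inversion genotype with cluster diagnostics.

    ``dosage`` counts H1 haplotypes (H1/H1 = 2, H1/H2 = 1, H2/H2 = 0);
    excluded individuals carry dosage -1 and label ``EXCLUDED``.
    """

    individual_ids: list[str]
    label: np.ndarray  # str per individual
    dosage: np.ndarray  # int per individual, -1 if excluded
    pc1: np.ndarray
    pc2: np.ndarray
    cluster_mean: np.ndarray  # per cluster (dosage order 0, 1, 2)
    cluster_sd: np.ndarray
    counts: tuple[int, int, int]  # (n_H1H1, n_H1H2, n_H2H2)
    hwe_chi2: float
    hwe_p: float

    @property
    def n_excluded(self) -> int:
        return int((self.label == EXCLUDED).sum())


def hwe_chisq(n_hom_minor: int, n_het: int, n_hom_major: int) -> tuple[float, float]:
    """One-degree-of-freedom chi-square test for Hardy–Weinberg equilibrium.

    The minor-allele frequency is estimated from the counts,
    q = (2*n_hom_minor + n_het) / 2N; expected class counts are
    (N q^2, 2N q(1-q), N (1-q)^2) and the statistic sums (obs-exp)^2/exp
    over the three classes (a class with expected count 0 contributes 0).
    Returns (chi2, upper-tail p with 1 df).
    """
    counts = np.array([n_hom_minor, n_het, n_hom_major], float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("at least one individual required for the HWE test")
    q = (2 * counts[0] + counts[1]) / (2 * n)
    expected = np.array([n * q * q, 2 * n * q * (1 - q), n * (1 - q) ** 2])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    chi2 = float(terms.sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _per_snp_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # dosage counts the major allele, so dosage 0 is the minor homozygote
    return (
        (dosages == 0).sum(axis=0),
        (dosages == 1).sum(axis=0),
        (dosages == 2).sum(axis=0),
    )


def qc_filter(
    genotypes: GenotypeTable,
    max_ind_missing: float = 0.05,
    min_snp_callrate: float = 0.95,
    min_maf: float = 0.05,
    min_hwe_p: float = 1e-5,
) -> GenotypeTable:
    """Standard genotype QC: individuals first, then SNPs.

    Drops individuals whose missing fraction is >= ``max_ind_missing``, then
    SNPs with call rate <= ``min_snp_callrate``, sample MAF <= ``min_maf``,
    or per-SNP HWE p < ``min_hwe_p``. MAF and HWE are recomputed on the
    individuals that survive the first step.
    """
    miss = genotypes.dosages == MISSING
    ind_frac = miss.mean(axis=1)
    keep_ind = ind_frac < max_ind_missing
    n_dropped = int((~keep_ind).sum())
    if n_dropped:
        logger.info("qc_filter: dropped %d individuals with missingness >= %g",
                    n_dropped, max_ind_missing)
    table = genotypes.subset_individuals(keep_ind)

    d = table.dosages
    miss = d == MISSING
    callrate = 1.0 - miss.mean(axis=0)
    n_called = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore"):
        major_freq = np.where(
            n_called > 0, np.where(miss, 0, d).sum(axis=0) / (2 * n_called), 0.0
        )
    maf = np.minimum(major_freq, 1 - major_freq)
    valid = d.astype(float)
    valid[miss] = np.nan
    n_mm, n_het, n_MM = _per_snp_counts(np.where(miss, -9, d))
    hwe_p = np.array(
        [
            hwe_chisq(a, b, c)[1] if (a + b + c) > 0 else 0.0
            for a, b, c in zip(n_mm, n_het, n_MM)
        ]
    )
    keep_snp = (callrate > min_snp_callrate) & (maf > min_maf) & (hwe_p >= min_hwe_p)
    n_dropped = int((~keep_snp).sum())
    if n_dropped:
        logger.info(
            "qc_filter: dropped %d SNPs (call rate <= %g, MAF <= %g, or HWE p < %g)",
            n_dropped, min_snp_callrate, min_maf, min_hwe_p,
        )
    if not keep_snp.any():
        raise ValueError("empty after QC: every SNP failed the filters")
    return table.subset_snps(keep_snp)


def encode_and_normalize(
    genotypes: GenotypeTable, pseudocount: bool = False
) -> NormalizedGenotypes:
    """Center and scale the dosage matrix for PCA.

    For each SNP j with per-SNP mean dosage mu_j over non-missing entries and
    allele frequency p_j = mu_j / 2, entries become
    z_ij = (g_ij - mu_j) / sqrt(p_j (1 - p_j)); missing entries are set to 0
    after centering. Zero-variance SNPs (monomorphic or constant columns) are
    dropped with a warning. With ``pseudocount`` the frequency estimator is
    (1 + sum g) / (2 + 2n) instead of the plain sample mean.
    """
    d = genotypes.dosages.astype(float)
    miss = genotypes.dosages == MISSING
    d[miss] = np.nan
    n_obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(d, axis=0)
    if pseudocount:
        p = (1 + np.nansum(d, axis=0)) / (2 + 2 * n_obs)
    else:
        p = mu / 2
    col_var = np.zeros(d.shape[1])
    ok_cols = n_obs > 0
    col_var[ok_cols] = np.nanvar(d[:, ok_cols], axis=0)
    keep = (p > 0) & (p < 1) & (col_var > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("encode_and_normalize: dropped %d zero-variance SNPs", n_dropped)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 polymorphic SNPs remain after normalization")
    z = (d[:, keep] - mu[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
    z[np.isnan(z)] = 0.0  # missing entries: centered value imputed as 0
    mean_raw = np.nanmean(d[:, keep], axis=1)
    mean_raw[np.isnan(mean_raw)] = np.nanmean(mean_raw)
    return NormalizedGenotypes(
        matrix=z,
        snp_ids=list(genotypes.snp_meta.loc[keep, "snp_id"]),
        allele_freq=p[keep],
        mean_raw_dosage=mean_raw,
    )


def principal_components(
    normalized: NormalizedGenotypes | np.ndarray,
    k: int = 2,
    orient_by: np.ndarray | None = None,
) -> PCScores:
    """Project individuals onto the top-k principal axes.

    Scores are projections onto the leading eigenvectors of the sample
    covariance across individuals (via SVD of the centered matrix).
    Orientation: PC1 is flipped, if necessary, so that its correlation with
    ``orient_by`` (by default the per-individual mean raw dosage, i.e. mean
    major-allele count) is non-negative — higher PC1 means more H1-like when
    H1 carries the major alleles. Remaining components are sign-fixed by
    making their largest-magnitude loading positive.
    """
    if isinstance(normalized, NormalizedGenotypes):
        z = normalized.matrix
        ids = [f"ind{i}" for i in range(z.shape[0])]
        if orient_by is None:
            orient_by = normalized.mean_raw_dosage
        individual_ids = getattr(normalized, "individual_ids", ids)
    else:
        z = np.asarray(normalized, float)
        individual_ids = [f"ind{i}" for i in range(z.shape[0])]
    n, m = z.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 individuals and 2 SNPs for PCA")
    zc = z - z.mean(axis=0)
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    if k > s.size:
        raise ValueError(f"k={k} exceeds the {s.size} available components")
    numerical_rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    scores = u[:, :k] * s[:k]
    # components beyond the numerical rank are pure round-off: zero them
    scores[:, numerical_rank:] = 0.0
    explained = s ** 2 / max(n - 1, 1)
    explained[numerical_rank:] = 0.0
    for j in range(min(k, numerical_rank)):
        col = scores[:, j]
        if j == 0 and orient_by is not None and np.std(orient_by) > 0:
            flip = np.corrcoef(col, orient_by)[0, 1] < 0
        else:
            flip = col[np.argmax(np.abs(col))] < 0
        if flip:
            scores[:, j] = -col
    return PCScores(individual_ids=list(individual_ids), scores=scores,
                    explained_variance=explained[:k])


def _kmeans_1d_exact(x: np.ndarray, k: int = 3) -> np.ndarray:
    """Globally optimal 1-D k-means by dynamic programming over sorted values.

    In one dimension the optimal clustering is a partition of the sorted
    sequence into k contiguous segments; the DP minimizes total within-
    cluster sum of squares exactly, so the result is deterministic,
    initialization-free and independent of input order. Returns cluster
    indices ordered by increasing cluster mean.
    """
    n = x.size
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # SSE of xs[i..j] inclusive, vectorized over start indices i
        cnt = j - i + 1
        tot = s1[j + 1] - s1[i]
        return (s2[j + 1] - s2[i]) - tot * tot / cnt

    cost = np.full((k, n), np.inf)
    split = np.zeros((k, n), int)
    counts = np.arange(1, n + 1, dtype=float)
    cost[0] = s2[1:] - s1[1:] * s1[1:] / counts
    for m in range(1, k):
        for j in range(m, n):
            starts = np.arange(m, j + 1)
            cand = cost[m - 1, starts - 1] + seg_cost(starts, j)
            best = int(np.argmin(cand))
            cost[m, j] = cand[best]
            split[m, j] = starts[best]
    # backtrack segment boundaries
    assign_sorted = np.empty(n, int)
    j = n - 1
    for m in range(k - 1, -1, -1):
        i = split[m, j] if m > 0 else 0
        assign_sorted[i : j + 1] = m
        j = i - 1
    assign = np.empty(n, int)
    assign[order] = assign_sorted
    return assign


def call_inversion_genotypes(
    scores: PCScores, sd_limit: float = 3.0
) -> InversionCalls:
    """Assign inversion genotypes from PC1 clustering with ambiguity exclusion.

    One-dimensional k-means with k=3 on PC1, solved exactly by dynamic
    programming over the sorted scores (deterministic and initialization-
    free; quantile-seeded Lloyd iterations mis-split the dominant cluster
    when genotype frequencies are as skewed as a 0.2-frequency allele makes
    them). Clusters are ordered by mean PC1
    and mapped to H1 dosage 0/1/2 (highest PC1 cluster = H1/H1, following the
    PC1 orientation rule). After fitting, individuals lying more than
    ``sd_limit`` within-cluster standard deviations from their own cluster
    mean are labeled EXCLUDED in a single pass (no refit); a cluster with
    SD 0 excludes nobody. Genotype counts and the HWE test use the remaining
    individuals only.
    """
    pc1 = np.asarray(scores.pc1, float)
    n = pc1.size
    if n < 3:
        raise ValueError("need at least 3 individuals to call genotypes")
    if not np.all(np.isfinite(pc1)):
        raise ValueError("PC1 scores must be finite")
    if np.unique(pc1).size < 3:
        raise ValueError("degenerate clustering: fewer than 3 distinct PC1 values")
    assign = _kmeans_1d_exact(pc1, k=3)

    order = np.argsort([pc1[assign == c].mean() if (assign == c).any() else np.inf
                        for c in range(3)])
    dosage_of_cluster = np.empty(3, int)
    for dose, c in enumerate(order):  # lowest mean PC1 -> dosage 0 (H2/H2)
        dosage_of_cluster[c] = dose
    dosage = dosage_of_cluster[assign]

    cluster_mean = np.full(3, np.nan)
    cluster_sd = np.zeros(3)
    for dose in range(3):
        members = pc1[dosage == dose]
        if members.size == 0:
            logger.warning("call_inversion_genotypes: empty cluster for dosage %d", dose)
            continue
        cluster_mean[dose] = members.mean()
        cluster_sd[dose] = members.std(ddof=1) if members.size > 1 else 0.0

    # a cluster whose spread is pure round-off counts as SD = 0 (no exclusions)
    sd_floor = 1e-9 * max(1.0, float(np.abs(pc1).max()))
    cluster_sd[cluster_sd < sd_floor] = 0.0

    label = np.array([LABELS[d] for d in dosage], dtype=object)
    out_dosage = dosage.astype(int)
    for i in range(n):
        sd = cluster_sd[dosage[i]]
        if sd > 0 and abs(pc1[i] - cluster_mean[dosage[i]]) > sd_limit * sd:
            label[i] = EXCLUDED
            out_dosage[i] = -1

    called = out_dosage >= 0
    counts = (
        int((out_dosage == 2).sum()),
        int((out_dosage == 1).sum()),
        int((out_dosage == 0).sum()),
    )
    if called.any():
        chi2, p = hwe_chisq(counts[2], counts[1], counts[0])
    else:
        chi2, p = float("nan"), float("nan")
    return InversionCalls(
        individual_ids=list(scores.individual_ids),
        label=label,
        dosage=out_dosage,
        pc1=pc1,
        pc2=np.asarray(scores.pc2, float),
        cluster_mean=cluster_mean,
        cluster_sd=cluster_sd,
        counts=counts,
        hwe_chi2=chi2,
        hwe_p=p,
    )


def call_from_genotypes(
    genotypes: GenotypeTable, sd_limit: float = 3.0, pseudocount: bool = False
) -> InversionCalls:
    """Convenience: normalize, run PCA and call genotypes in one step."""
    norm = encode_and_normalize(genotypes, pseudocount=pseudocount)
    scores = principal_components(norm, k=2)
    scores.individual_ids = list(genotypes.individual_ids)
    return call_inversion_genotypes(scores, sd_limit=sd_limit)
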
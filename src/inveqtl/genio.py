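"""Readers, writers and genomic-interval subsetting for the pipeline's tables.

Coordinate convention: every user-facing coordinate is 1-based inclusive
(UCSC browser text style). BED intervals, which are 0-based half-open, are
converted on read. Individuals are always joined across tables by ID string,
never by column position.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing dosage entry, deliberately distinct from 0
#: (0 is a valid genotype: homozygous minor).
MISSING: int = -1

_SNP_META_COLS = ["snp_id", "chrom", "pos", "minor_allele", "major_allele", "maf"]


class ParseError(ValueError):
    """A file failed to parse; message carries the offending location."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval, e.g. chr17:40,850,001-41,850,000."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            other.chrom == self.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start <= self.end and self.start <= end

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        """Parse ``chrom:start-end`` (commas in numbers allowed)."""
        try:
            chrom, rng = text.split(":")
            lo, hi = rng.replace(",", "").split("-")
            return cls(chrom, int(lo), int(hi))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"cannot parse interval {text!r}") from exc


@dataclass
class GenotypeTable:
    """Individuals x SNPs dosage matrix with SNP metadata.

    Dosage counts copies of the *major* allele (M/M = 2, m/M = 1, m/m = 0);
    missing entries hold :data:`MISSING`.
    """

    dosages: np.ndarray  # (n_individuals, n_snps) int8
    snp_meta: pd.DataFrame  # columns _SNP_META_COLS
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if self.dosages.shape != (len(self.individual_ids), len(self.snp_meta)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snp_meta)} SNPs"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or the missing sentinel")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        for chrom, grp in self.snp_meta.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"SNP positions not strictly increasing on {chrom}")
        maf = self.snp_meta["maf"].to_numpy(float)
        if np.any((maf < 0) | (maf > 0.5)):
            raise ValueError("MAF must lie in [0, 0.5]")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_meta)

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeTable":
        ids = [i for i, k in zip(self.individual_ids, keep) if k]
        return GenotypeTable(self.dosages[np.asarray(keep, bool)], self.snp_meta.copy(), ids)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeTable":
        keep = np.asarray(keep, bool)
        return GenotypeTable(
            self.dosages[:, keep],
            self.snp_meta.loc[keep].reset_index(drop=True),
            list(self.individual_ids),
        )


@dataclass
class ExpressionTable:
    """Probes x individuals expression with per-probe detection and metadata."""

    values: pd.DataFrame  # index = probe_id, columns = individual ids
    probe_meta: pd.DataFrame  # probe_id, gene, chrom, start, end[, sequence]
    detection: pd.Series  # per probe

    def __post_init__(self) -> None:
        self.probe_meta = self.probe_meta.reset_index(drop=True)
        if list(self.values.index) != list(self.probe_meta["probe_id"]):
            raise ValueError("values index must equal probe_meta probe_id order")
        self.detection = self.detection.reindex(self.values.index)
        if "sequence" in self.probe_meta.columns:
            seqs = self.probe_meta["sequence"].dropna()
            bad = ~seqs.str.fullmatch(r"[ACGTN]{50}")
            if bad.any():
                raise ValueError("probe sequences must match [ACGTN]{50}")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_probes(self, keep: np.ndarray) -> "ExpressionTable":
        keep = np.asarray(keep, bool)
        return ExpressionTable(
            self.values.loc[keep],
            self.probe_meta.loc[keep],
            self.detection.loc[keep],
        )


def _finalise_genotypes(
    alt_counts: np.ndarray,
    missing: np.ndarray,
    snp_ids: Sequence[str],
    chroms: Sequence[str],
    positions: Sequence[int],
    ref_alleles: Sequence[str],
    alt_alleles: Sequence[str],
    individual_ids: Sequence[str],
) -> GenotypeTable:
    """Recode ALT-allele counts to major-allele dosage (m/m=0, m/M=1, M/M=2).

    The minor allele is re-determined from sample frequency per SNP; a tie
    (frequency exactly 0.5) treats ALT as minor.
    """
    alt_counts = np.asarray(alt_counts, float)  # SNPs x individuals
    missing = np.asarray(missing, bool)
    n_called = (~missing).sum(axis=1)
    with np.errstate(invalid="ignore"):
        alt_freq = np.where(
            n_called > 0, np.nansum(np.where(missing, 0, alt_counts), axis=1) / (2 * n_called), 0.0
        )
    alt_is_minor = alt_freq <= 0.5
    dosage = np.where(alt_is_minor[:, None], 2 - alt_counts, alt_counts)
    dosage = np.where(missing, MISSING, dosage).astype(np.int8)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    meta = pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "chrom": list(chroms),
            "pos": list(positions),
            "minor_allele": np.where(alt_is_minor, alt_alleles, ref_alleles),
            "major_allele": np.where(alt_is_minor, ref_alleles, alt_alleles),
            "maf": maf,
        }
    )
    return GenotypeTable(dosage.T, meta, list(individual_ids))


def _read_vcf(path: str | Path) -> GenotypeTable:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise ParseError(f"{path}: cannot open as VCF: {exc}") from exc
    individual_ids = list(vcf.samples)
    alt_counts, missing = [], []
    snp_ids, chroms, positions, refs, alts = [], [], [], [], []
    for record_no, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            logger.warning(
                "%s: record %d (%s:%d) is not biallelic; skipped",
                path, record_no, var.CHROM, var.POS,
            )
            continue
        row_counts = np.zeros(len(individual_ids))
        row_missing = np.zeros(len(individual_ids), bool)
        for j, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                row_missing[j] = True
            else:
                row_counts[j] = (a == 1) + (b == 1)
        alt_counts.append(row_counts)
        missing.append(row_missing)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    if not snp_ids:
        raise ParseError(f"{path}: no usable biallelic records")
    return _finalise_genotypes(
        np.array(alt_counts), np.array(missing),
        snp_ids, chroms, positions, refs, alts, individual_ids,
    )


def _read_dosage_tsv(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in _SNP_META_COLS:
        if col not in df.columns:
            raise ParseError(f"{path}: dosage TSV missing required column {col!r}")
    ind_cols = [c for c in df.columns if c not in _SNP_META_COLS]
    raw = df[ind_cols].replace(".", MISSING)
    try:
        mat = raw.astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric dosage cell: {exc}") from exc
    bad = ~np.isin(mat, (0, 1, 2, MISSING))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: invalid dosage {mat[i, j]} at SNP row {i + 1}, individual {ind_cols[j]!r}"
        )
    return GenotypeTable(mat.T.astype(np.int8), df[_SNP_META_COLS].copy(), ind_cols)


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeTable:
    """Read a genotype matrix from ``vcf`` or ``dosage_tsv``.

    VCF GT fields 0/0, 0/1, 1/1 and ./. map to major-hom / het / minor-hom /
    missing after the minor allele is determined from sample frequency, so
    that dosage 0 is always the minor homozygote. Non-biallelic sites are
    skipped with a logged warning.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write as VCF v4.2 with GT only; REF = major allele, ALT = minor."""
    meta = table.snp_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.individual_ids) + "\n"
        )
        gt_map = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
        for j, row in meta.iterrows():
            gts = "\t".join(gt_map[int(d)] for d in table.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.major_allele}\t"
                f"{row.minor_allele}\t.\t.\t.\tGT\t{gts}\n"
            )


def write_genotypes_tsv(table: GenotypeTable, path: str | Path) -> None:
    """Write the dosage TSV dialect: one row per SNP, '.' for missing."""
    df = table.snp_meta.copy()
    mat = table.dosages.T.astype(object)
    mat[mat == MISSING] = "."
    for j, ind in enumerate(table.individual_ids):
        df[ind] = mat[:, j]
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def select_region(table, interval: GenomicInterval):
    """Subset a table to a genomic interval (1-based inclusive on both ends).

    SNPs are retained iff ``start <= pos <= end``; probes iff their own
    interval overlaps the query. Input order is preserved; an empty result
    is an empty table, not an error. Idempotent.
    """
    if isinstance(table, GenotypeTable):
        meta = table.snp_meta
        keep = (meta["chrom"] == interval.chrom).to_numpy() & (
            (meta["pos"] >= interval.start) & (meta["pos"] <= interval.end)
        ).to_numpy()
        return table.subset_snps(keep)
    if isinstance(table, ExpressionTable):
        meta = table.probe_meta
        keep = (
            (meta["chrom"] == interval.chrom)
            & (meta["start"] <= interval.end)
            & (meta["end"] >= interval.start)
        ).to_numpy()
        return table.subset_probes(keep)
    raise TypeError(f"cannot select region on {type(table).__name__}")


_EXPR_META_COLS = ["probe_id", "gene", "chrom", "start", "end", "detection", "sequence"]


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    df = table.probe_meta.copy()
    df["detection"] = table.detection.to_numpy()
    cols = [c for c in _EXPR_META_COLS if c in df.columns]
    out = pd.concat(
        [df[cols].reset_index(drop=True), table.values.reset_index(drop=True)], axis=1
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_expression(path: str | Path) -> ExpressionTable:
    """Read an expression TSV (probe rows, individual columns, header row)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = [c for c in _EXPR_META_COLS if c in df.columns]
    ind_cols = [c for c in df.columns if c not in meta_cols]
    vals = df[ind_cols]
    non_numeric = vals.apply(pd.to_numeric, errors="coerce")
    if non_numeric.isna().to_numpy().sum() > vals.isna().to_numpy().sum():
        bad = np.argwhere(non_numeric.isna().to_numpy() & ~vals.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric expression cell at probe row {bad[0] + 1}, "
            f"individual {ind_cols[bad[1]]!r}"
        )
    values = non_numeric.set_index(df["probe_id"])
    values.index.name = None
    meta = df[[c for c in meta_cols if c != "detection"]].copy()
    detection = pd.Series(df["detection"].to_numpy(float), index=values.index)
    return ExpressionTable(values, meta, detection)


_RESULT_COLS = [
    "probe_id", "gene", "tissue", "n", "B", "SE", "t", "CI_low", "CI_high", "p", "significant",
]


def write_results(eqtl_table: pd.DataFrame, path: str | Path) -> None:
    """Write association results as TSV with the canonical column set."""
    eqtl_table[_RESULT_COLS].to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Covariate TSV: first column individual_id, remaining columns covariates."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def write_covariates(covariates: pd.DataFrame, path: str | Path) -> None:
    covariates.rename_axis("individual_id").to_csv(path, sep="\t", float_format="%.12g")


def read_probe_bed(path: str | Path) -> pd.DataFrame:
    """Read probe intervals from BED (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start0", "end0", "probe_id"], usecols=range(4),
        dtype={"chrom": str},
    )
    return pd.DataFrame(
        {
            "probe_id": df["probe_id"],
            "chrom": df["chrom"],
            "start": df["start0"] + 1,
            "end": df["end0"],
        }
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by record id (used for transcript sets)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
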
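"""Probe-level artifact checks for expression arrays.

Two confounders can fake or distort a cis-eQTL signal at a 50-mer
expression probe: a common SNP under the probe footprint (allele-dependent
hybridization efficiency mimics a genotype effect) and cross-hybridization
to paralogous transcripts (the probe reports a mixture of genes). The first
is flagged by genomic containment of common SNPs (MAF > 1% by default); the
second by a local ungapped percent-identity scan of the probe against a
transcript set, approximating a BLAST search — at 50-mer scale and >= 90%
identity, ungapped matching captures the relevant hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROBE_LEN = 50
MIN_OVERLAP = 25

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ProbeFlagReport:
    probe_id: str
    snps_in_probe: list[tuple[str, int, float]] = field(default_factory=list)
    snp_confounded: bool = False
    cross_hyb_hits: list[tuple[str, float]] = field(default_factory=list)
    multi_target: bool = False


def snps_in_probe(
    probe_meta: pd.DataFrame, snp_meta: pd.DataFrame, maf_min: float = 0.01
) -> list[ProbeFlagReport]:
    """Flag probes whose genomic footprint contains a common SNP.

    A SNP confounds a probe iff probe.start <= pos <= probe.end (1-based
    inclusive on both ends) and its MAF exceeds ``maf_min``. All contained
    SNPs are listed with their MAF; probes without an interval are skipped
    with a warning.
    """
    reports = []
    for _, probe in probe_meta.iterrows():
        if pd.isna(probe.get("start")) or pd.isna(probe.get("end")):
            logger.warning("snps_in_probe: probe %s has no interval; skipped", probe["probe_id"])
            continue
        inside = snp_meta[
            (snp_meta["chrom"] == probe["chrom"])
            & (snp_meta["pos"] >= int(probe["start"]))
            & (snp_meta["pos"] <= int(probe["end"]))
        ]
        listed = [
            (row["snp_id"], int(row["pos"]), float(row["maf"]))
            for _, row in inside.iterrows()
        ]
        reports.append(
            ProbeFlagReport(
                probe_id=probe["probe_id"],
                snps_in_probe=listed,
                snp_confounded=any(maf > maf_min for _, _, maf in listed),
            )
        )
    return reports


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _best_identity_one_strand(probe: np.ndarray, transcript: np.ndarray) -> float | None:
    """Best ungapped identity (0-100, denominator always 50) on one strand.

    Full-length placements are scanned when the transcript is at least probe
    length; shorter transcripts are scored over their best partial overlap of
    at least MIN_OVERLAP bases, or skipped (None).
    """
    n_t = transcript.size
    n_p = probe.size
    p_valid = probe != ord("N")  # N never matches, on either sequence
    if n_t >= n_p:
        windows = np.lib.stride_tricks.sliding_window_view(transcript, n_p)
        matches = ((windows == probe) & (windows != ord("N")) & p_valid).sum(axis=1)
        return 100.0 * matches.max() / n_p
    if n_t < MIN_OVERLAP:
        return None
    best = 0
    for shift in range(-(n_p - MIN_OVERLAP), n_t - MIN_OVERLAP + 1):
        lo_p, lo_t = max(0, -shift), max(0, shift)
        ov = min(n_p - lo_p, n_t - lo_t)
        if ov < MIN_OVERLAP:
            continue
        seg_p, seg_t = probe[lo_p : lo_p + ov], transcript[lo_t : lo_t + ov]
        best = max(best, int(((seg_p == seg_t) & (seg_p != ord("N")) & (seg_t != ord("N"))).sum()))
    return 100.0 * best / n_p


def probe_identity_scan(
    probe_seq: str,
    transcripts: dict[str, str],
    min_identity: float = 90.0,
) -> list[tuple[str, float]]:
    """Scan a 50-mer probe against transcripts on both strands, ungapped.

    For each transcript the best percent identity (100 * matches / 50) over
    all placements of the probe on the transcript or its reverse complement
    is computed; transcripts reaching ``min_identity`` are returned as hits,
    sorted by decreasing identity then id. Pass ``min_identity=0`` to get
    every transcript's best identity.
    """
    if len(probe_seq) < PROBE_LEN:
        raise ValueError(f"probe must be at least {PROBE_LEN} bases, got {len(probe_seq)}")
    probe = _encode(probe_seq.upper())
    hits = []
    for tid, seq in transcripts.items():
        seq = seq.upper()
        fwd = _best_identity_one_strand(probe, _encode(seq))
        rev = _best_identity_one_strand(probe, _encode(reverse_complement(seq)))
        candidates = [v for v in (fwd, rev) if v is not None]
        if not candidates:
            logger.warning("probe_identity_scan: transcript %s shorter than %d bases; skipped",
                           tid, MIN_OVERLAP)
            continue
        ident = max(candidates)
        if ident >= min_identity:
            hits.append((tid, ident))
    return sorted(hits, key=lambda h: (-h[1], h[0]))


def flag_probes(
    probe_meta: pd.DataFrame,
    snp_meta: pd.DataFrame | None = None,
    transcripts: dict[str, str] | None = None,
    maf_min: float = 0.01,
    min_identity: float = 90.0,
    transcript_genes: dict[str, str] | None = None,
) -> list[ProbeFlagReport]:
    """Combined probe QC: SNP-in-probe flags plus cross-hybridization scan.

    ``multi_target`` is set when placements with identity >= ``min_identity``
    hit more than one distinct gene (transcript ids map to genes through
    ``transcript_genes``; by default each transcript is its own gene).
    """
    if snp_meta is not None:
        reports = snps_in_probe(probe_meta, snp_meta, maf_min=maf_min)
    else:
        reports = [ProbeFlagReport(probe_id=p) for p in probe_meta["probe_id"]]
    if transcripts:
        by_id = {r.probe_id: r for r in reports}
        genes_of = transcript_genes or {}
        has_seq = "sequence" in probe_meta.columns
        for _, probe in probe_meta.iterrows():
            seq = probe.get("sequence") if has_seq else None
            if not isinstance(seq, str):
                continue
            report = by_id.get(probe["probe_id"])
            if report is None:
                continue
            report.cross_hyb_hits = probe_identity_scan(seq, transcripts, min_identity)
            genes_hit = {genes_of.get(tid, tid) for tid, _ in report.cross_hyb_hits}
            report.multi_target = len(genes_hit) > 1
    return reports


def reports_to_frame(reports: list[ProbeFlagReport]) -> pd.DataFrame:
    """Flatten reports for TSV output."""
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in reports],
            "n_snps_in_probe": [len(r.snps_in_probe) for r in reports],
            "snp_confounded": [r.snp_confounded for r in reports],
            "cross_hyb_hits": [
                ";".join(f"{tid}:{ident:g}" for tid, ident in r.cross_hyb_hits)
                for r in reports
            ],
            "multi_target": [r.multi_target for r in reports],
        }
    )
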
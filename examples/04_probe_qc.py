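"""Probe artifact checks: SNPs in the footprint and cross-hybridization.

A 50-mer expression probe can report a spurious genotype effect if a common
SNP sits under it, or report a gene-family mixture if it also matches
paralogous transcripts. This example plants both artifacts and shows the
flags: a paralog family where one member matches at 94% (47/50 bases, the
identity of a typical close paralog) and a common SNP inside one probe.
"""

import numpy as np
import pandas as pd

from inveqtl.probeqc import flag_probes, probe_identity_scan

rng = np.random.default_rng(0)
probe_seq = "".join(rng.choice(list("ACGT"), 50))

# paralog family: two perfect targets, one at 94%, one unrelated decoy
comp = {"A": "C", "C": "G", "G": "T", "T": "A"}
near = list(probe_seq)
for i in (7, 23, 41):
    near[i] = comp[near[i]]
transcripts = {
    "FAM_A": "AAGG" + probe_seq + "TTCC",
    "FAM_A2": probe_seq,
    "FAM_A4": "GG" + "".join(near) + "AA",
    "OTHER": "".join(rng.choice(list("ACGT"), 120)),
}
for tid, ident in probe_identity_scan(probe_seq, transcripts, min_identity=0):
    print(f"{tid}: {ident:.0f}% identity")

probes = pd.DataFrame(
    {
        "probe_id": ["pA", "pB"],
        "gene": ["FAM_A", "GENE_B"],
        "chrom": ["chr17", "chr17"],
        "start": [41_000_000, 41_500_000],
        "end": [41_000_049, 41_500_049],
        "sequence": [probe_seq, None],
    }
)
snps = pd.DataFrame(
    {
        "snp_id": ["rs_common", "rs_rare"],
        "chrom": ["chr17", "chr17"],
        "pos": [41_000_020, 41_500_020],
        "maf": [0.15, 0.004],
    }
)
reports = flag_probes(
    probes, snp_meta=snps, transcripts=transcripts,
    maf_min=0.01, min_identity=90.0,
    transcript_genes={"FAM_A": "FAM_A", "FAM_A2": "FAM_A2", "FAM_A4": "FAM_A4"},
)
for r in reports:
    print(
        f"\n{r.probe_id}: snp_confounded={r.snp_confounded} "
        f"(SNPs under probe: {[s[0] for s in r.snps_in_probe]}), "
        f"multi_target={r.multi_target} "
        f"(hits: {[t for t, _ in r.cross_hyb_hits]})"
    )
# pA is multi-target (>= 90% identity to several genes of a family), so its
# strong eQTL could be a family-wide mixture; pB contains only a rare SNP
# (MAF 0.4% < 1%), which does not count as confounding.
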
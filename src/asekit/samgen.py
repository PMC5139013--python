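"""Synthetic SAM writer: realise an allele-count table as aligned reads.

Purely a testing/demonstration aid — it fabricates uniquely mapped reads
(NH:i:1, fixed read length, all-match CIGAR) whose base at each SNP position
reproduces a given count table exactly, so the SAM-based counting path can be
checked against the counts-only path.  No attempt is made to emulate real
read sequences beyond the SNP base.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

__all__ = ["counts_to_sam"]

READ_LEN = 30


def _other_base(ref: str, alt: str) -> str:
    """Any base that is neither REF nor ALT."""
    return next(b for b in "ACGT" if b not in (ref, alt))


def counts_to_sam(
    counts: pd.DataFrame,
    panel: pd.DataFrame,
    out_dir: str | Path,
    chrom_length: int = 1_000_000,
) -> dict[str, Path]:
    """Write one SAM per individual realising ``counts``; returns the path map.

    Reads are READ_LEN all-match alignments starting a few bases before the
    SNP so the SNP base sits inside the read; filler bases are 'A' except at
    SNP positions (other SNPs never fall inside a read because panel
    positions are spaced further apart than READ_LEN — callers using denser
    panels should space them accordingly).
    """
    panel = panel.set_index("snp_id") if "snp_id" in panel.columns else panel
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chroms = sorted(pd.unique(panel["chrom"].astype(str)))
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_length} for c in chroms],
    }
    paths: dict[str, Path] = {}
    for ind, sub in counts.groupby("individual_id"):
        path = out_dir / f"{ind}.sam"
        reads = []
        serial = 0
        for row in sub.itertuples():
            snp = panel.loc[row.snp_id]
            start0 = int(snp["pos"]) - 1 - 4  # 0-based; SNP at read offset 4
            for base, n in (
                (str(snp["ref"]), row.ref_count),
                (str(snp["alt"]), row.alt_count),
                (_other_base(str(snp["ref"]), str(snp["alt"])), row.other_count),
            ):
                for _ in range(int(n)):
                    seq = ["A"] * READ_LEN
                    seq[4] = base
                    a = pysam.AlignedSegment()
                    a.query_name = f"{ind}_{row.snp_id}_{serial}"
                    a.query_sequence = "".join(seq)
                    a.flag = 0
                    a.reference_id = chroms.index(str(snp["chrom"]))
                    a.reference_start = start0
                    a.mapping_quality = 60
                    a.cigarstring = f"{READ_LEN}M"
                    a.query_qualities = pysam.qualitystring_to_array("I" * READ_LEN)
                    a.set_tag("NH", 1)
                    reads.append(a)
                    serial += 1
        reads.sort(key=lambda r: (r.reference_id, r.reference_start))
        with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
            for a in reads:
                fh.write(a)
        paths[str(ind)] = path
    return paths
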
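"""Allele extraction at heterozygous SNPs from aligned reads.

Reads come in as SAM records (pre-sliced to SNP neighbourhoods; no random
access or indexing is assumed).  Only uniquely mapped reads are used: a read
is unique when its hit-count tag (NH) equals 1, or — if the tag is absent —
when its mapping quality exceeds a configurable threshold.  The base each
retained read places on a SNP position is classified as REF, ALT or OTHER.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

log = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "AlleleCountRecord",
    "ReadFilterStats",
    "filter_unique_reads",
    "count_alleles_at_site",
    "build_count_table",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP: identity, 1-based locus, alleles, mappability."""

    snp_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    mappability: float = 1.0

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        ref, alt = self.ref_allele.upper(), self.alt_allele.upper()
        if ref not in _BASES or alt not in _BASES:
            raise ValueError(f"alleles must be single A/C/G/T bases, got {ref}/{alt}")
        if ref == alt:
            raise ValueError(f"{self.snp_id}: REF and ALT alleles are identical ({ref})")
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)
        if not (0.0 <= self.mappability <= 1.0):
            raise ValueError("mappability must be in [0, 1]")


@dataclass(frozen=True)
class AlleleCountRecord:
    """REF/ALT/OTHER read counts for one (SNP, individual) cell."""

    snp_id: str
    individual_id: str
    ref_count: int
    alt_count: int
    other_count: int

    def __post_init__(self):
        if min(self.ref_count, self.alt_count, self.other_count) < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count + self.other_count


@dataclass(frozen=True)
class ReadFilterStats:
    """Accounting of the unique-mapping read filter."""

    total: int
    removed: int

    @property
    def retained(self) -> int:
        return self.total - self.removed


def filter_unique_reads(
    reads: Iterable[pysam.AlignedSegment], mapq_threshold: int = 0
) -> tuple[list[pysam.AlignedSegment], int]:
    """Retain reads with a unique mapping to the genome.

    A read is kept if its NH tag equals 1; when NH is absent, if its mapping
    quality is strictly greater than ``mapq_threshold``.  Unmapped reads, and
    reads carrying neither NH nor a valid mapping quality, count as not
    uniquely mapped (logged once).
    """
    retained: list[pysam.AlignedSegment] = []
    removed = 0
    warned = False
    for read in reads:
        if read.is_unmapped:
            removed += 1
            continue
        if read.has_tag("NH"):
            if read.get_tag("NH") == 1:
                retained.append(read)
            else:
                removed += 1
        elif read.mapping_quality is not None and read.mapping_quality != 255:
            if read.mapping_quality > mapq_threshold:
                retained.append(read)
            else:
                removed += 1
        else:
            if not warned:
                log.warning("reads without NH tag or mapping quality treated as non-unique")
                warned = True
            removed += 1
    return retained, removed


def count_alleles_at_site(
    reads: Iterable[pysam.AlignedSegment],
    snp: SnpRecord,
    individual_id: str = "",
    min_base_quality: int = 0,
) -> AlleleCountRecord:
    """Classify the base each read aligns onto ``snp.pos``.

    Walks the aligned pairs of every read (CIGAR-aware, so insertions,
    deletions, skips and soft clips are consumed correctly); reads on another
    chromosome or whose alignment does not place a base on the position
    (e.g. a deletion spanning it) contribute nothing.  Base quality is only
    consulted when ``min_base_quality`` > 0.
    """
    target = snp.pos - 1  # pysam reference coordinates are 0-based
    ref_n = alt_n = other_n = 0
    for read in reads:
        if read.is_unmapped or read.reference_name != snp.chrom:
            continue
        if not (read.reference_start <= target < read.reference_end):
            continue
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            if rpos == target:
                if (
                    min_base_quality > 0
                    and read.query_qualities is not None
                    and read.query_qualities[qpos] < min_base_quality
                ):
                    break
                base = read.query_sequence[qpos].upper()
                if base == snp.ref_allele:
                    ref_n += 1
                elif base == snp.alt_allele:
                    alt_n += 1
                else:
                    other_n += 1
                break
    return AlleleCountRecord(snp.snp_id, individual_id, ref_n, alt_n, other_n)


def build_count_table(
    sam_paths: Mapping[str, str | Path],
    genotypes: pd.DataFrame,
    panel: Sequence[SnpRecord] | pd.DataFrame,
    mapq_threshold: int = 0,
    min_base_quality: int = 0,
    remove_duplicates: bool = False,
) -> tuple[pd.DataFrame, ReadFilterStats]:
    """Count alleles for every heterozygous (SNP, individual) cell.

    ``sam_paths`` maps individual_id -> SAM file of that individual's reads
    (pre-sliced to SNP neighbourhoods).  ``genotypes`` is a SNP x individual
    matrix coded 0/1/2/-1.  Only cells with genotype 1 are counted; cells
    with zero covering reads emit no record.  Rows come back ordered by
    (chrom, pos, individual_id).  Panel SNPs absent from the genotype matrix
    are excluded and logged.
    """
    if isinstance(panel, pd.DataFrame):
        panel = [
            SnpRecord(r.snp_id, str(r.chrom), int(r.pos), r.ref, r.alt, float(r.mappability))
            for r in panel.itertuples()
        ]
    known = [s for s in panel if s.snp_id in genotypes.index]
    dropped = [s.snp_id for s in panel if s.snp_id not in genotypes.index]
    if dropped:
        log.warning("%d panel SNPs absent from genotype matrix, excluded: %s ...",
                    len(dropped), dropped[:5])

    rows = []
    total = removed_total = 0
    for individual_id, path in sam_paths.items():
        if individual_id not in genotypes.columns:
            log.warning("individual %s has reads but no genotypes; skipped", individual_id)
            continue
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            reads = list(fh)
        total += len(reads)
        if remove_duplicates:
            reads = [r for r in reads if not r.is_duplicate]
        retained, removed = filter_unique_reads(reads, mapq_threshold=mapq_threshold)
        removed_total += removed
        by_chrom: dict[str, list] = {}
        for read in retained:
            by_chrom.setdefault(read.reference_name, []).append(read)
        for snp in known:
            if genotypes.at[snp.snp_id, individual_id] != 1:
                continue
            rec = count_alleles_at_site(
                by_chrom.get(snp.chrom, []), snp, individual_id, min_base_quality
            )
            if rec.total >= 1:
                rows.append(
                    (snp.chrom, snp.pos, rec.snp_id, rec.individual_id,
                     rec.ref_count, rec.alt_count, rec.other_count)
                )
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    table = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "snp_id", "individual_id",
                 "ref_count", "alt_count", "other_count"],
    )
    return table, ReadFilterStats(total=total, removed=removed_total)
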
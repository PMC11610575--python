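"""Read collection: fetch locus-spanning long reads from BAM/CRAM.

Reads are taken from coordinate-sorted, indexed alignment files (local
paths or htslib-supported URLs).  Only primary alignments whose
reference span fully covers the repeat locus plus a flanking margin are
kept: a read that enters the repeat but ends inside it cannot contain a
complete allele and would bias length estimates downward.  Prephased
alignments (LongShot, WhatsHap, ...) are supported through the HP tag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pysam

from longstr.catalog import RepeatLocus

logger = logging.getLogger(__name__)


class LocusSkip(Exception):
    """Locus cannot be queried in this alignment file (e.g. chrom absent)."""


@dataclass
class RepeatRead:
    """One read spanning a repeat locus.

    ``sequence`` is the read in reference-forward orientation, as stored
    by the alignment file.  ``insertion`` is the extracted repeat allele
    filled in by the realignment step; ``None`` means not yet extracted
    or unusable.
    """

    read_id: str
    sequence: str
    haplotype: Optional[int] = None
    spans_locus: bool = True
    is_reverse: bool = False
    insertion: Optional[str] = None

    @property
    def insertion_length(self) -> Optional[int]:
        return None if self.insertion is None else len(self.insertion)

    def with_insertion(self, insertion: Optional[str]) -> "RepeatRead":
        return replace(self, insertion=insertion)


def fetch_reads(
    alignment_source: str,
    reference: Optional[str],
    locus: RepeatLocus,
    flank_bp: int = 100,
    mapq_min: int = 5,
) -> list[RepeatRead]:
    """Fetch primary reads whose alignment spans the locus +/- ``flank_bp``.

    Parameters
    ----------
    alignment_source:
        Path or URL of an indexed BAM/CRAM.
    reference:
        Reference FASTA path (required for CRAM decoding; may be None
        for BAM).
    flank_bp:
        Margin on both sides of the locus that the alignment must cover
        (clipped at contig edges).
    mapq_min:
        Minimum mapping quality; drops ambiguous mappings in repetitive
        flanks.

    Raises
    ------
    LocusSkip
        If the locus chromosome is absent from the alignment header.
    """
    kwargs = {}
    if reference is not None:
        kwargs["reference_filename"] = str(reference)
    with pysam.AlignmentFile(str(alignment_source), **kwargs) as bam:
        if locus.chrom not in bam.references:
            raise LocusSkip(
                f"chromosome {locus.chrom!r} absent from alignment header"
            )
        contig_len = bam.get_reference_length(locus.chrom)
        span_start = max(0, locus.start - flank_bp)
        span_end = min(contig_len, locus.end + flank_bp)
        out: list[RepeatRead] = []
        for aln in bam.fetch(locus.chrom, span_start, span_end):
            if aln.is_secondary or aln.is_supplementary or aln.is_unmapped:
                continue
            if aln.mapping_quality < mapq_min:
                continue
            if aln.reference_start > span_start or aln.reference_end < span_end:
                continue
            haplotype = None
            if aln.has_tag("HP"):
                hp = int(aln.get_tag("HP"))
                if hp in (1, 2):
                    haplotype = hp
                else:
                    logger.warning(
                        "read %s carries HP=%d outside {1,2}; treated as untagged",
                        aln.query_name,
                        hp,
                    )
            out.append(
                RepeatRead(
                    read_id=aln.query_name,
                    sequence=aln.query_sequence.upper(),
                    haplotype=haplotype,
                    spans_locus=True,
                    is_reverse=aln.is_reverse,
                )
            )
        return out


def partition_by_haplotype(
    reads: Sequence[RepeatRead],
) -> tuple[list[RepeatRead], list[RepeatRead], list[RepeatRead]]:
    """Split reads into (haplotype-1, haplotype-2, untagged), order preserved.

    HP values outside {1,2} are routed to untagged with a warning.
    """
    hap1: list[RepeatRead] = []
    hap2: list[RepeatRead] = []
    untagged: list[RepeatRead] = []
    for read in reads:
        if read.haplotype == 1:
            hap1.append(read)
        elif read.haplotype == 2:
            hap2.append(read)
        else:
            if read.haplotype is not None:
                logger.warning(
                    "read %s has haplotype %r outside {1,2}; routed to untagged",
                    read.read_id,
                    read.haplotype,
                )
            untagged.append(read)
    return hap1, hap2, untagged
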
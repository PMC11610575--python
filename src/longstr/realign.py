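"""Excised-reference realignment and repeat-insertion extraction.

The repeat interval is deleted from the locus reference, leaving only
the two flanks joined at a single junction.  A spanning read realigned
to this artificial reference must place its entire repeat allele as
alignment insertions at (or near) the junction, so the allele sequence
can be read off directly, independent of how the original aligner
represented the repeat.

Realignment uses edlib (unit-cost edit alignment, infix mode): each
flank's junction-proximal anchor is located within the read, and the
read segment between the two anchors is the allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import edlib
import pysam

from longstr.catalog import RepeatLocus
from longstr.reads import RepeatRead

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArtificialReference:
    """Locus reference with the repeat interval excised.

    ``sequence`` is left flank + right flank; ``junction`` is the offset
    of the excision point (equals the left flank length after clipping
    at contig edges).
    """

    sequence: str
    junction: int
    locus_id: str
    flank_bp: int

    def __post_init__(self) -> None:
        if not 0 <= self.junction <= len(self.sequence):
            raise ValueError("junction outside artificial reference")


def build_excised_reference(
    reference: str, locus: RepeatLocus, flank_bp: int = 5000
) -> ArtificialReference:
    """Build the excised artificial reference for a locus.

    ``sequence = ref[start-flank_bp:start] + ref[end:end+flank_bp]``,
    clipped at contig boundaries (the junction shifts accordingly).

    Parameters
    ----------
    reference:
        Path to an indexed FASTA.
    flank_bp:
        Flank length on each side; must be >= 1 (large flanks give the
        aligner unique anchor sequence).
    """
    if flank_bp < 1:
        raise ValueError("flank_bp must be >= 1")
    with pysam.FastaFile(str(reference)) as fasta:
        if locus.chrom not in fasta.references:
            raise ValueError(f"chromosome {locus.chrom!r} not in reference FASTA")
        contig_len = fasta.get_reference_length(locus.chrom)
        left_start = max(0, locus.start - flank_bp)
        right_end = min(contig_len, locus.end + flank_bp)
        left = fasta.fetch(locus.chrom, left_start, locus.start).upper()
        right = fasta.fetch(locus.chrom, locus.end, right_end).upper()
    if not left and not right:
        raise ValueError(f"locus {locus.locus_id}: no flank sequence on contig")
    return ArtificialReference(
        sequence=left + right,
        junction=len(left),
        locus_id=locus.locus_id,
        flank_bp=flank_bp,
    )


def extract_repeat_insertion(
    read: RepeatRead,
    art_ref: ArtificialReference,
    merge_window_bp: int = 25,
    anchor_bp: int = 100,
    max_divergence: float = 0.30,
) -> Optional[str]:
    """Extract the repeat allele of one read as its junction insertion.

    The excision junction is located in the read by aligning each
    flank's junction-proximal anchor (``anchor_bp`` bases) to the read
    as an approximate substring; the repeat allele is the read segment
    between the left anchor's end and the right anchor's start.
    Anchoring both flanks independently sidesteps the placement
    ambiguity of a single joined alignment (an aligner is free to slide
    an insertion across bases shared by flank and repeat, which would
    rotate the reported allele).

    Returns the empty string for a clean junction with no intervening
    bases — a genuine 0 bp allele.  ``None`` marks an unusable read: an
    anchor diverging by more than ``max_divergence`` of its length
    (no alignment, or the read stops before the junction), or the two
    anchors overlapping by more than ``merge_window_bp`` bases (a
    suspect junction).  Small anchor overlaps from boundary indel
    wobble clamp to a 0 bp allele.
    """
    if not read.sequence:
        raise ValueError("read sequence is empty")
    junction = art_ref.junction
    left_q = art_ref.sequence[max(0, junction - anchor_bp) : junction]
    right_q = art_ref.sequence[junction : junction + anchor_bp]

    start = 0
    if left_q:
        hit = edlib.align(left_q, read.sequence, task="locations", mode="HW")
        if hit["editDistance"] > max_divergence * len(left_q):
            logger.info("read %s: left junction anchor not found", read.read_id)
            return None
        start = hit["locations"][0][1] + 1  # edlib ends are inclusive

    end = len(read.sequence)
    if right_q:
        hit = edlib.align(right_q, read.sequence, task="locations", mode="HW")
        if hit["editDistance"] > max_divergence * len(right_q):
            logger.info("read %s: right junction anchor not found", read.read_id)
            return None
        end = hit["locations"][0][0]

    if end < start - merge_window_bp:
        logger.info(
            "read %s: junction anchors overlap by %d bp", read.read_id, start - end
        )
        return None
    return read.sequence[start:max(end, start)]
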
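"""End-to-end genotyping: fetch -> realign -> infer -> record, per locus."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pysam

from longstr.alleles import LocusGenotype, genotype_locus
from longstr.catalog import RepeatLocus
from longstr.config import RunConfig
from longstr.outputs import GenotypeRecord
from longstr.reads import LocusSkip, fetch_reads
from longstr.realign import build_excised_reference, extract_repeat_insertion

logger = logging.getLogger(__name__)


def genotype_one_locus(
    alignment_source: str,
    reference: str,
    locus: RepeatLocus,
    sample_id: str,
    config: Optional[RunConfig] = None,
) -> GenotypeRecord:
    """Genotype a single locus from an indexed alignment file."""
    cfg = config or RunConfig()
    haploid = locus.chrom in cfg.haploid_chroms

    def missing(reason: str) -> GenotypeRecord:
        return _make_record(
            reference,
            locus,
            LocusGenotype(
                locus_id=locus.locus_id,
                sample_id=sample_id,
                alleles=[],
                zygosity="missing",
                phasing_source="none",
                reason=reason,
            ),
        )

    reads = fetch_reads(
        alignment_source,
        reference,
        locus,
        flank_bp=cfg.span_margin,
        mapq_min=cfg.mapq_min,
    )
    if not reads:
        return missing("no spanning reads")

    art_ref = build_excised_reference(reference, locus, flank_bp=cfg.flank_bp)
    with_insertions = []
    for read in reads:
        insertion = extract_repeat_insertion(
            read,
            art_ref,
            merge_window_bp=cfg.merge_window_bp,
            anchor_bp=cfg.span_margin,
        )
        if insertion is not None:
            with_insertions.append(read.with_insertion(insertion))
    if not with_insertions:
        return missing("no read yielded a usable junction alignment")

    genotype = genotype_locus(
        with_insertions,
        locus,
        sample_id=sample_id,
        haploid=haploid,
        min_support=cfg.min_support,
        exclusion_fraction=cfg.exclusion_fraction,
        exclusion_dissimilarity=cfg.exclusion_dissimilarity,
        phasing=cfg.phasing,
        keep_outliers_in_consensus=cfg.keep_outliers_in_consensus,
    )
    logger.info(
        "locus %s: n_reads=%d n_excluded=%d zygosity=%s",
        locus.locus_id,
        len(with_insertions),
        len(genotype.excluded_read_ids),
        genotype.zygosity,
    )
    return _make_record(reference, locus, genotype)


def _make_record(
    reference: str, locus: RepeatLocus, genotype: LocusGenotype
) -> GenotypeRecord:
    with pysam.FastaFile(str(reference)) as fasta:
        if locus.chrom in fasta.references:
            ref_allele = fasta.fetch(locus.chrom, locus.start, locus.end).upper()
            preceding = (
                fasta.fetch(locus.chrom, locus.start - 1, locus.start).upper()
                if locus.start > 0
                else "N"
            )
        else:  # chrom unknown to the reference too: placeholder context
            ref_allele = "N" * (locus.end - locus.start)
            preceding = "N"
    return GenotypeRecord(
        locus=locus,
        genotype=genotype,
        reference_allele=ref_allele,
        preceding_base=preceding,
    )


def genotype_catalog(
    alignment_source: str,
    reference: str,
    loci: Sequence[RepeatLocus],
    sample_id: str,
    config: Optional[RunConfig] = None,
) -> list[GenotypeRecord]:
    """Genotype every catalog locus; one bad locus never kills the run."""
    cfg = config or RunConfig()
    records: list[GenotypeRecord] = []
    for locus in loci:
        try:
            records.append(
                genotype_one_locus(alignment_source, reference, locus, sample_id, cfg)
            )
        except LocusSkip as exc:
            logger.warning("locus %s skipped: %s", locus.locus_id, exc)
            records.append(
                _make_record(
                    reference,
                    locus,
                    LocusGenotype(
                        locus_id=locus.locus_id,
                        sample_id=sample_id,
                        alleles=[],
                        zygosity="missing",
                        phasing_source="none",
                        reason=str(exc),
                    ),
                )
            )
        except Exception as exc:  # per-locus isolation
            logger.error("locus %s failed: %s", locus.locus_id, exc)
            try:
                records.append(
                    _make_record(
                        reference,
                        locus,
                        LocusGenotype(
                            locus_id=locus.locus_id,
                            sample_id=sample_id,
                            alleles=[],
                            zygosity="missing",
                            phasing_source="none",
                            reason=f"error: {exc}",
                        ),
                    )
                )
            except Exception:
                logger.error("locus %s: could not build missing record", locus.locus_id)
    return records
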
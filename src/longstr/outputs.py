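"""Serialization of genotypes to VCF 4.2 and tabular files.

Full ALT sequences (not symbolic alleles) are written so the motif
composition can be recomputed from the VCF alone.  When an allele is
empty (a 0 bp repeat) the record switches to the standard indel
representation with the preceding reference base anchored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pysam

from longstr.alleles import LocusGenotype
from longstr.catalog import RepeatLocus

VCF_HEADER_LINES = [
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End coordinate of the repeat locus">',
    '##INFO=<ID=LOCUS,Number=1,Type=String,Description="Repeat locus identifier">',
    '##INFO=<ID=MOTIF,Number=1,Type=String,Description="Catalogued repeat motif">',
    '##INFO=<ID=ANCHOR,Number=0,Type=Flag,Description="REF/ALT carry the preceding reference base (indel anchoring)">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AL,Number=.,Type=Integer,Description="Allele lengths in bp">',
    '##FORMAT=<ID=SUP,Number=.,Type=Integer,Description="Supporting read counts">',
    '##FORMAT=<ID=OL,Number=.,Type=Integer,Description="Outlier read counts">',
]


@dataclass
class GenotypeRecord:
    """One locus genotype plus the reference context needed for VCF."""

    locus: RepeatLocus
    genotype: LocusGenotype
    reference_allele: str
    preceding_base: str = "N"

    def __post_init__(self) -> None:
        if len(self.reference_allele) != self.locus.end - self.locus.start:
            raise ValueError(
                f"locus {self.locus.locus_id}: reference allele length "
                f"{len(self.reference_allele)} != locus span"
            )


def _record_line(rec: GenotypeRecord) -> str:
    locus, gt = rec.locus, rec.genotype
    ref = rec.reference_allele.upper()
    consensi = [a.consensus for a in gt.alleles]

    anchored = any(c == "" for c in consensi)
    if anchored:
        pos = locus.start  # 1-based position of the preceding base
        ref_field = rec.preceding_base + ref
        render = lambda c: rec.preceding_base + c
    else:
        pos = locus.start + 1
        ref_field = ref
        render = lambda c: c

    alts: list[str] = []
    indices: list[int] = []
    for c in consensi:
        if c == ref:
            indices.append(0)
            continue
        rendered = render(c)
        if rendered in alts:
            indices.append(alts.index(rendered) + 1)
        else:
            alts.append(rendered)
            indices.append(len(alts))

    if gt.zygosity == "missing" or not gt.alleles:
        gt_field = "./."
        alt_field = "."
        sample_field = "./.:.:.:."
    else:
        if gt.zygosity == "hemi":
            gt_field = str(indices[0])
        elif gt.zygosity == "hom":
            gt_field = f"{indices[0]}/{indices[0]}"
        else:
            # GT order mirrors the allele order so AL/SUP/OL stay aligned
            gt_field = "/".join(str(i) for i in indices)
        alt_field = ",".join(alts) if alts else "."
        al = ",".join(str(a.length_bp) for a in gt.alleles)
        sup = ",".join(str(a.support) for a in gt.alleles)
        ol = ",".join(str(len(a.outlier_read_ids)) for a in gt.alleles)
        sample_field = f"{gt_field}:{al}:{sup}:{ol}"

    info = f"END={locus.end};LOCUS={locus.locus_id};MOTIF={locus.motif}"
    if anchored:
        info += ";ANCHOR"
    return "\t".join(
        [
            locus.chrom,
            str(pos),
            locus.locus_id,
            ref_field,
            alt_field,
            ".",
            "PASS",
            info,
            "GT:AL:SUP:OL",
            sample_field,
        ]
    )


def write_vcf(
    records: Sequence[GenotypeRecord],
    sample_id: str,
    out: str | Path,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write genotype records as VCF 4.2.

    Records must be sorted by (chrom, start); duplicate locus IDs are
    rejected.  ``contig_lengths`` populates ##contig header lines when
    known.
    """
    keys = [(r.locus.chrom, r.locus.start) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, start)")
    ids = [r.locus.locus_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate locus_id among records")

    contig_order = {c: i for i, c in enumerate(dict.fromkeys(k[0] for k in keys))}
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for chrom, length in contig_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
    else:
        for chrom in contig_order:
            lines.append(f"##contig=<ID={chrom}>")
    lines.extend(VCF_HEADER_LINES)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for rec in records:
        lines.append(_record_line(rec))
    Path(out).write_text("\n".join(lines) + "\n")


@dataclass
class ParsedCall:
    """Round-trip view of one VCF record's retained fields."""

    locus_id: str
    chrom: str
    pos: int
    motif: str
    end: int
    gt: str
    allele_sequences: list[str]  # consensus sequences, anchor stripped
    allele_lengths: list[int]
    supports: list[int]
    outlier_counts: list[int]


def parse_vcf(path: str | Path) -> tuple[str, list[ParsedCall]]:
    """Parse a VCF written by :func:`write_vcf` (pysam-backed).

    Returns (sample_id, calls).  Allele sequences are reconstructed
    from REF/ALT with the indel anchor base stripped where present.
    """
    with pysam.VariantFile(str(path)) as vcf:
        sample_id = list(vcf.header.samples)[0]
        calls: list[ParsedCall] = []
        for rec in vcf:
            locus_id = rec.info["LOCUS"]
            end = rec.stop  # pysam surfaces INFO/END via .stop
            motif = rec.info["MOTIF"]
            sample = rec.samples[sample_id]
            gt_indices = sample["GT"]
            anchored = rec.info.get("ANCHOR", False)
            seqs_by_index = {0: rec.ref[1:] if anchored else rec.ref}
            for i, alt in enumerate(rec.alts or (), start=1):
                seqs_by_index[i] = alt[1:] if anchored else alt

            if gt_indices is None or all(g is None for g in gt_indices):
                calls.append(
                    ParsedCall(locus_id, rec.chrom, rec.pos, motif, end,
                               "./.", [], [], [], [])
                )
                continue
            indices = [g for g in gt_indices if g is not None]
            # hom writes the allele once; hemi has a single index
            uniq = indices[:1] if len(set(indices)) == 1 else indices
            gt_str = "/".join(str(g) for g in gt_indices if g is not None)
            if len(gt_indices) == 1:
                gt_str = str(gt_indices[0])
            al = list(sample["AL"])
            sup = list(sample["SUP"])
            ol = list(sample["OL"])
            calls.append(
                ParsedCall(
                    locus_id=locus_id,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    motif=motif,
                    end=end,
                    gt=gt_str,
                    allele_sequences=[seqs_by_index[i] for i in uniq],
                    allele_lengths=[int(x) for x in al],
                    supports=[int(x) for x in sup],
                    outlier_counts=[int(x) for x in ol],
                )
            )
        return sample_id, calls


def write_lengths_tsv(records: Sequence[GenotypeRecord], out: str | Path) -> None:
    """Tabular allele lengths: total bp and difference with the reference."""
    header = [
        "sample",
        "locus",
        "allele_index",
        "length_bp",
        "length_minus_ref_bp",
        "support",
        "zygosity",
    ]
    lines = ["\t".join(header)]
    for rec in records:
        ref_len = rec.locus.end - rec.locus.start
        for i, allele in enumerate(rec.genotype.alleles):
            lines.append(
                "\t".join(
                    [
                        rec.genotype.sample_id,
                        rec.locus.locus_id,
                        str(i),
                        str(allele.length_bp),
                        str(allele.length_bp - ref_len),
                        str(allele.support),
                        rec.genotype.zygosity,
                    ]
                )
            )
    Path(out).write_text("\n".join(lines) + "\n")
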
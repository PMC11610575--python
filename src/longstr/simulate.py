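"""Synthetic fixtures: reference + catalog + noisy spanning reads as BAM.

The generator emulates exactly what the genotyper consumes: a contig
whose middle carries a repeat locus, one or two repeat alleles with
arbitrary motif structure (interruptions supported, e.g.
``[(CGG,9),(AGG,1),(CGG,10)]``), and long reads spanning the locus with
configurable per-base substitution/insertion/deletion error rates.
Alignment records are constructed analytically from the known read
provenance — flanks match the reference, the repeat surplus/deficit is
a single insertion/deletion, sequencing errors perturb the operations —
so no external aligner is needed and outputs are bit-reproducible for a
given seed.  A truth JSON sidecar records every allele and per-read
repeat sequence so downstream modules can be verified without
re-simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from longstr.catalog import RepeatLocus, write_catalog
from longstr.composition import CompositionMatrix

_BASES = "ACGT"

DEFAULT_ERROR_RATES = (0.02, 0.01, 0.01)  # sub, ins, del


@dataclass
class SimSpec:
    """Parameters of one simulated repeat locus.

    ``allele_structures`` holds one (haploid) or two lists of
    (motif, copies) segments; the first allele also defines the
    reference repeat.  ``min_anchor`` is the minimum flank coverage a
    simulated read keeps on each side of the locus.
    """

    seed: int
    allele_structures: list[list[tuple[str, int]]]
    reference_structure: Optional[list[tuple[str, int]]] = None
    flank_len: int = 400
    depth: int = 10
    read_len: int = 1200
    error_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)
    haploid: bool = False
    hp_tag_fraction: float = 0.0
    min_anchor: int = 150
    locus_id: str = "SIMLOC"
    chrom: str = "chrS"
    pathogenic_min: Optional[float] = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.allele_structures) <= 2:
            raise ValueError("need 1 or 2 allele structures")
        if self.haploid and len(self.allele_structures) != 1:
            raise ValueError("haploid spec must have exactly one allele")
        if any(p < 0 or p > 1 for p in self.error_rates) or sum(self.error_rates) >= 0.5:
            raise ValueError("error rates must be in [0,1] and sum to < 0.5")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.hp_tag_fraction <= 1:
            raise ValueError("hp_tag_fraction must be in [0,1]")
        longest = max(len(allele_sequence(s)) for s in self.allele_structures)
        if self.read_len <= longest + 2 * self.min_anchor:
            raise ValueError(
                "read_len must exceed repeat length + 2 x min_anchor"
            )
        if self.flank_len < self.min_anchor:
            raise ValueError("flank_len must be >= min_anchor")
        if len(allele_sequence(self.ref_structure)) < 1:
            raise ValueError("reference repeat must be at least 1 bp")

    @property
    def ref_structure(self) -> list[tuple[str, int]]:
        """Repeat structure written into the reference contig."""
        if self.reference_structure is not None:
            return self.reference_structure
        return self.allele_structures[0]


def allele_sequence(structure: Sequence[tuple[str, int]]) -> str:
    """Expand (motif, copies) segments into the allele sequence."""
    return "".join(motif * copies for motif, copies in structure)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


# Per-base alignment operations: ("M", base, in_repeat), ("I", base,
# in_repeat), ("D", None, in_repeat).  M/D consume reference, M/I carry
# a read base.
_Op = tuple[str, Optional[str], bool]


def _apply_errors(
    ops: list[_Op], rates: tuple[float, float, float], rng: np.random.Generator
) -> list[_Op]:
    """Perturb ops with errors: substitutions, then insertions, then deletions."""
    sub, ins, dele = rates
    if sub > 0:
        out: list[_Op] = []
        for op, base, rep in ops:
            if base is not None and rng.random() < sub:
                base = _BASES[(_BASES.index(base) + rng.integers(1, 4)) % 4]
            out.append((op, base, rep))
        ops = out
    if ins > 0:
        out = []
        for op, base, rep in ops:
            out.append((op, base, rep))
            if base is not None and rng.random() < ins:
                out.append(("I", _BASES[rng.integers(0, 4)], rep))
        ops = out
    if dele > 0:
        out = []
        for op, base, rep in ops:
            if base is not None and rng.random() < dele:
                if op == "M":
                    out.append(("D", None, rep))
                # a deleted inserted base vanishes entirely
                continue
            out.append((op, base, rep))
        ops = out
    return ops


def _ops_to_cigar(ops: list[_Op]) -> list[tuple[int, int]]:
    codes = {"M": 0, "I": 1, "D": 2}
    cig: list[tuple[int, int]] = []
    for op, _, _ in ops:
        code = codes[op]
        if cig and cig[-1][0] == code:
            cig[-1] = (code, cig[-1][1] + 1)
        else:
            cig.append((code, 1))
    return cig


def simulate_locus(spec: SimSpec, outdir: str | Path) -> dict[str, str]:
    """Write reference FASTA, catalog TSV, sorted indexed BAM, truth JSON.

    Returns a dict of output paths keyed ``reference``, ``catalog``,
    ``bam``, ``truth``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    alleles = [allele_sequence(s) for s in spec.allele_structures]
    ref_repeat = allele_sequence(spec.ref_structure)
    left = _random_seq(rng, spec.flank_len)
    right = _random_seq(rng, spec.flank_len)
    contig = left + ref_repeat + right
    locus_start = spec.flank_len
    locus_end = spec.flank_len + len(ref_repeat)

    ref_path = outdir / "reference.fa"
    ref_path.write_text(f">{spec.chrom}\n{contig}\n")
    pysam.faidx(str(ref_path))

    locus = RepeatLocus(
        locus_id=spec.locus_id,
        chrom=spec.chrom,
        start=locus_start,
        end=locus_end,
        motif=spec.ref_structure[0][0],
        pathogenic_min=spec.pathogenic_min,
    )
    catalog_path = outdir / "catalog.tsv"
    write_catalog([locus], catalog_path)

    reads = []
    truth_reads = []
    for allele_idx, allele in enumerate(alleles):
        hap_len = len(allele)
        lo = max(0, locus_start + hap_len + spec.min_anchor - spec.read_len)
        hi = locus_start - spec.min_anchor
        for i in range(spec.depth):
            read_rng = np.random.default_rng([spec.seed, allele_idx, i])
            start = int(read_rng.integers(lo, hi + 1))
            ops: list[_Op] = []
            # left flank
            for pos in range(start, locus_start):
                ops.append(("M", contig[pos], False))
            # repeat: matched prefix, then surplus insertion / deficit deletion
            common = min(hap_len, len(ref_repeat))
            for j in range(common):
                ops.append(("M", allele[j], True))
            for j in range(common, hap_len):
                ops.append(("I", allele[j], True))
            for j in range(common, len(ref_repeat)):
                ops.append(("D", None, True))
            # right flank, up to read_len read bases
            consumed = sum(1 for _, b, _ in ops if b is not None)
            pos = locus_end
            while consumed < spec.read_len and pos < len(contig):
                ops.append(("M", contig[pos], False))
                consumed += 1
                pos += 1
            ops = _apply_errors(ops, spec.error_rates, read_rng)
            seq = "".join(b for _, b, _ in ops if b is not None)
            true_insert = "".join(b for _, b, rep in ops if rep and b is not None)
            is_reverse = bool(read_rng.random() < 0.5)
            has_hp = bool(read_rng.random() < spec.hp_tag_fraction)
            read_id = f"read_a{allele_idx}_{i}"
            reads.append(
                {
                    "id": read_id,
                    "start": start,
                    "cigar": _ops_to_cigar(ops),
                    "seq": seq,
                    "reverse": is_reverse,
                    "hp": (allele_idx + 1) if has_hp else None,
                }
            )
            truth_reads.append(
                {
                    "read_id": read_id,
                    "allele_index": allele_idx,
                    "true_insertion": true_insert,
                    "haplotype": (allele_idx + 1) if has_hp else None,
                }
            )

    reads.sort(key=lambda r: (r["start"], r["id"]))
    bam_path = outdir / "reads.bam"
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": spec.chrom, "LN": len(contig)}],
    }
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r["id"]
            a.query_sequence = r["seq"]
            a.flag = 16 if r["reverse"] else 0
            a.reference_id = 0
            a.reference_start = r["start"]
            a.mapping_quality = 60
            a.cigartuples = r["cigar"]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r["seq"]))
            if r["hp"] is not None:
                a.set_tag("HP", r["hp"])
            bam.write(a)
    pysam.index(str(bam_path))

    truth = {
        "seed": spec.seed,
        "locus_id": spec.locus_id,
        "chrom": spec.chrom,
        "locus_start": locus_start,
        "locus_end": locus_end,
        "alleles": alleles,
        "haploid": spec.haploid,
        "reads": truth_reads,
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))

    return {
        "reference": str(ref_path),
        "catalog": str(catalog_path),
        "bam": str(bam_path),
        "truth": str(truth_path),
    }


def simulate_cohort_matrix(
    seed: int,
    n_alleles: int,
    motif_profiles: Sequence[dict[str, float]],
    concentration: float = 200.0,
) -> tuple[CompositionMatrix, list[int]]:
    """Draw a cohort composition matrix from Dirichlet-like profiles.

    Each allele picks one profile uniformly at random and draws its
    motif fractions from Dirichlet(concentration x profile).  Returns
    the matrix (view ``full``) and the true profile index per allele.
    """
    if n_alleles < 0:
        raise ValueError("n_alleles must be >= 0")
    if not motif_profiles:
        raise ValueError("need at least one profile")
    motifs = sorted({m for p in motif_profiles for m in p})
    rng = np.random.default_rng(seed)
    rows = np.zeros((n_alleles, len(motifs)))
    assignment: list[int] = []
    for i in range(n_alleles):
        p_idx = int(rng.integers(0, len(motif_profiles)))
        assignment.append(p_idx)
        profile = motif_profiles[p_idx]
        alphas = np.array([
            concentration * profile.get(m, 0.0) + 1e-9 for m in motifs
        ])
        rows[i] = rng.dirichlet(alphas)
    df = pd.DataFrame(
        rows, index=[f"allele{i}" for i in range(n_alleles)], columns=motifs
    )
    return CompositionMatrix(data=df, view="full"), assignment
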
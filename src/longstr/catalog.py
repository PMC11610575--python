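"""Repeat-locus catalog: load, validate and serve locus definitions.

The catalog is a BED-like TSV with 0-based half-open coordinates, one
repeat locus per line::

    #chrom  start   end     locus_id        motif   pathogenic_min

``pathogenic_min`` is the minimum pathogenic allele size in motif units
(repeat copies), or ``.`` when no cutoff is known.  An optional seventh
column ``cutoff_unit`` (``units`` or ``bp``) records catalogs whose
cutoffs are expressed in base pairs instead; it defaults to ``units``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

_VALID_BASES = set("ACGT")

HEADER_COLUMNS = ["#chrom", "start", "end", "locus_id", "motif", "pathogenic_min"]


class CatalogError(ValueError):
    """Raised for malformed or inconsistent catalog files."""


@dataclass(frozen=True)
class RepeatLocus:
    """One catalogued tandem repeat locus.

    Coordinates follow the BED convention: ``start`` is 0-based
    inclusive, ``end`` 0-based exclusive.  ``pathogenic_min`` is the
    pathogenic cutoff in motif units (or base pairs when
    ``cutoff_unit == "bp"``), absent when unknown.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    motif: str
    pathogenic_min: Optional[float] = None
    cutoff_unit: str = "units"
    inheritance_note: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CatalogError(
                f"locus {self.locus_id}: start ({self.start}) must be < end ({self.end})"
            )
        if not self.motif or set(self.motif) - _VALID_BASES:
            raise CatalogError(
                f"locus {self.locus_id}: motif {self.motif!r} is not an ACGT string"
            )
        if self.pathogenic_min is not None and self.pathogenic_min < 0:
            raise CatalogError(
                f"locus {self.locus_id}: pathogenic_min must be non-negative"
            )
        if self.cutoff_unit not in ("units", "bp"):
            raise CatalogError(
                f"locus {self.locus_id}: cutoff_unit must be 'units' or 'bp'"
            )

    @property
    def motif_length(self) -> int:
        return len(self.motif)

    @property
    def reference_span(self) -> int:
        return self.end - self.start


def pathogenic_cutoff_bp(locus: RepeatLocus) -> Optional[int]:
    """Pathogenic cutoff in base pairs, or None when the locus has none.

    Cutoffs stored in motif units are multiplied by the motif length;
    cutoffs already in bp pass through unchanged.
    """
    if locus.pathogenic_min is None:
        return None
    if locus.cutoff_unit == "bp":
        return int(round(locus.pathogenic_min))
    return int(round(locus.pathogenic_min * locus.motif_length))


def _parse_line(line: str, lineno: int) -> RepeatLocus:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise CatalogError(
            f"line {lineno}: expected >=6 tab-separated fields, got {len(fields)}"
        )
    chrom, start_s, end_s, locus_id, motif = fields[0], fields[1], fields[2], fields[3], fields[4]
    try:
        start = int(start_s)
        end = int(end_s)
    except ValueError as exc:
        raise CatalogError(f"line {lineno}: non-integer coordinates: {exc}") from exc
    if start >= end:
        raise CatalogError(f"line {lineno}: start ({start}) >= end ({end})")
    cutoff_raw = fields[5]
    pathogenic_min = None if cutoff_raw == "." else _parse_cutoff(cutoff_raw, lineno)
    cutoff_unit = fields[6] if len(fields) > 6 and fields[6] else "units"
    try:
        return RepeatLocus(
            locus_id=locus_id,
            chrom=chrom,
            start=start,
            end=end,
            motif=motif.upper(),
            pathogenic_min=pathogenic_min,
            cutoff_unit=cutoff_unit,
        )
    except CatalogError as exc:
        raise CatalogError(f"line {lineno}: {exc}") from exc


def _parse_cutoff(raw: str, lineno: int) -> float:
    try:
        value = float(raw)
    except ValueError as exc:
        raise CatalogError(f"line {lineno}: pathogenic_min {raw!r} not a number") from exc
    return value


def load_catalog(path: str | Path) -> list[RepeatLocus]:
    """Load a repeat catalog TSV, validating every locus.

    Comment lines (``#``-prefixed, including the header) are skipped.
    Raises :class:`CatalogError` naming the offending line on malformed
    coordinates, invalid motifs or duplicate locus IDs.
    """
    path = Path(path)
    loci: list[RepeatLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            locus = _parse_line(line, lineno)
            if locus.locus_id in seen:
                raise CatalogError(
                    f"line {lineno}: duplicate locus_id {locus.locus_id!r}"
                )
            seen.add(locus.locus_id)
            loci.append(locus)
    return loci


def write_catalog(loci: Iterable[RepeatLocus], path: str | Path) -> None:
    """Write loci back to the catalog TSV dialect (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("\t".join(HEADER_COLUMNS + ["cutoff_unit"]) + "\n")
        for locus in loci:
            cutoff = "." if locus.pathogenic_min is None else _format_number(locus.pathogenic_min)
            fh.write(
                "\t".join(
                    [
                        locus.chrom,
                        str(locus.start),
                        str(locus.end),
                        locus.locus_id,
                        locus.motif,
                        cutoff,
                        locus.cutoff_unit,
                    ]
                )
                + "\n"
            )


def _format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def example_catalog_path() -> Path:
    """Path of the packaged example catalog (a small STRchive-style set).

    Coordinates are illustrative GRCh38-like placeholders for the listed
    disease loci; real analyses should supply a current catalog.
    """
    return Path(__file__).parent / "data" / "example_catalog.tsv"
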
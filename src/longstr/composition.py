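"""Motif composition of repeat alleles.

An allele sequence is split into consecutive, non-overlapping chunks of
the locus motif length k (unbiased to which motifs occur); each chunk
is made rotation-invariant by mapping it to the catalogued unit when it
is a rotation of it, and to the lexicographically smallest rotation
otherwise.  On top of these motif tracks the module provides:

* run-length encodings such as ``(GGC)15`` or ``CCA(GCA)11``;
* a cohort composition matrix (allele x motif fractions) with the
  ``raw`` and ``collapsed`` noise filters;
* ``collapsed`` grouping of alleles with similar motif profiles;
* the ``sequence`` view (positional motif labels, a palette for the
  ten most frequent motifs, gray for the rest);
* cohort z-scores for flagging length outliers against a control
  cohort.

The sentinel label ``OTHER`` marks a trailing remainder shorter than k
(and chunks with non-ACGT characters); it is excluded from fraction
denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OTHER = "OTHER"
GRAY_SLOT = -1

_VALID = set("ACGT")


@dataclass
class MotifTrack:
    """Ordered canonical-motif decomposition of one allele."""

    allele_id: str
    motifs: list[str]
    length_bp: int
    k: int
    # original chunk text per position, for RLE rendering/decoding
    chunks: list[str] = field(default_factory=list)


@dataclass
class CompositionMatrix:
    """Alleles x canonical motifs, values = per-allele motif fractions."""

    data: pd.DataFrame  # index = allele_ids, columns = motif labels
    view: str  # full | raw | collapsed

    @property
    def allele_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def motifs(self) -> list[str]:
        return list(self.data.columns)


def canonical_motif(kmer: str, known_unit: Optional[str] = None) -> str:
    """Rotation-invariant label for a k-mer.

    If any rotation equals the known repeat unit, the known unit is the
    label; otherwise the lexicographically smallest rotation.  Chunks
    containing non-ACGT characters are labelled OTHER.
    """
    if not kmer:
        raise ValueError("empty k-mer")
    kmer = kmer.upper()
    if set(kmer) - _VALID:
        return OTHER
    rotations = [kmer[i:] + kmer[:i] for i in range(len(kmer))]
    if known_unit is not None and known_unit.upper() in rotations:
        return known_unit.upper()
    return min(rotations)


def decompose(sequence: str, k: int, known_unit: Optional[str] = None) -> MotifTrack:
    """Cut a sequence into k-length chunks and canonicalise each.

    Chunks start at position 0 and do not overlap; a trailing remainder
    shorter than k becomes a single OTHER entry.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sequence = sequence.upper()
    motifs: list[str] = []
    chunks: list[str] = []
    n_full = len(sequence) // k
    for i in range(n_full):
        chunk = sequence[i * k : (i + 1) * k]
        motifs.append(canonical_motif(chunk, known_unit))
        chunks.append(chunk)
    remainder = sequence[n_full * k :]
    if remainder:
        motifs.append(OTHER)
        chunks.append(remainder)
    return MotifTrack(
        allele_id="", motifs=motifs, length_bp=len(sequence), k=k, chunks=chunks
    )


def run_length_encode(track: MotifTrack) -> str:
    """Render a motif track as a run-length encoding, e.g. ``CCA(GCA)11``.

    Maximal runs of the same canonical label render as ``(CHUNK)n`` for
    n >= 2 (using the run's first chunk text) and as the bare chunk
    text for n = 1; the OTHER remainder renders as its literal bases.
    """
    out: list[str] = []
    i = 0
    motifs, chunks = track.motifs, track.chunks
    while i < len(motifs):
        j = i
        while j < len(motifs) and motifs[j] == motifs[i]:
            j += 1
        run = j - i
        if run >= 2:
            out.append(f"({chunks[i]}){run}")
        else:
            out.append(chunks[i])
        i = j
    return "".join(out)


def run_length_decode(encoded: str) -> str:
    """Expand an RLE string back to a plain sequence."""
    import re

    out: list[str] = []
    for m in re.finditer(r"\(([A-Z]+)\)(\d+)|([A-Z]+)", encoded):
        if m.group(1):
            out.append(m.group(1) * int(m.group(2)))
        else:
            out.append(m.group(3))
    return "".join(out)


def composition_matrix(tracks: Sequence[MotifTrack]) -> CompositionMatrix:
    """Per-allele motif fractions (view ``full``).

    fraction(allele, motif) = chunk count of motif / total non-OTHER
    chunks of that allele.  Alleles with zero non-OTHER chunks are
    dropped with a warning.  Tracks must share the same k.
    """
    ks = {t.k for t in tracks}
    if len(ks) > 1:
        raise ValueError(f"mixed motif lengths across tracks: {sorted(ks)}")
    rows: dict[str, dict[str, float]] = {}
    for t in tracks:
        counts: dict[str, int] = {}
        for m in t.motifs:
            if m == OTHER:
                continue
            counts[m] = counts.get(m, 0) + 1
        total = sum(counts.values())
        if total == 0:
            logger.warning("allele %s has no complete motif chunks; dropped", t.allele_id)
            continue
        rows[t.allele_id] = {m: c / total for m, c in counts.items()}
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    df = df.reindex(sorted(df.columns), axis=1)
    return CompositionMatrix(data=df, view="full")


def filter_raw(m: CompositionMatrix) -> CompositionMatrix:
    """Raw-view noise filter.

    A motif is kept iff it reaches >=1% of the sequence in >=2% of the
    alleles, or some single allele is composed of >=10% of it.
    Retained fractions are never rescaled.
    """
    if m.view != "full":
        raise ValueError("filter_raw expects an unfiltered (full) matrix")
    df = m.data
    n = len(df)
    keep = [
        c
        for c in df.columns
        if ((df[c] >= 0.01).sum() >= 0.02 * n) or (df[c] >= 0.10).any()
    ]
    return CompositionMatrix(data=df[keep].copy(), view="raw")


def filter_collapsed(m: CompositionMatrix) -> CompositionMatrix:
    """Collapsed-view noise filter (more aggressive, for larger groups).

    A motif is kept iff it reaches >=5% of the sequence in >=10% of the
    alleles, or at least five alleles are composed of >=10% of it.
    """
    if m.view != "full":
        raise ValueError("filter_collapsed expects an unfiltered (full) matrix")
    df = m.data
    n = len(df)
    keep = [
        c
        for c in df.columns
        if ((df[c] >= 0.05).sum() >= 0.10 * n) or ((df[c] >= 0.10).sum() >= 5)
    ]
    return CompositionMatrix(data=df[keep].copy(), view="collapsed")


def collapse_groups(
    m: CompositionMatrix, min_group: int = 5, bin_width: float = 0.05
) -> pd.DataFrame:
    """Group alleles with similar motif profiles.

    Retained fractions are binned to the nearest ``bin_width``; alleles
    with identical binned profiles form a group.  Groups smaller than
    ``min_group`` merge into a residual ``other`` group.  Rows are the
    group mean profiles with a ``count`` column, sorted by count
    descending.
    """
    if m.view != "collapsed":
        raise ValueError("collapse_groups expects a collapsed-filtered matrix")
    df = m.data
    if df.empty:
        return pd.DataFrame(columns=list(df.columns) + ["count"])
    binned = (df / bin_width).round() * bin_width
    keys = [tuple(row) for row in binned.to_numpy()]
    df = df.assign(_key=pd.Series(keys, index=df.index))
    groups: list[tuple[str, pd.DataFrame]] = []
    residual_frames = []
    for i, (_, sub) in enumerate(df.groupby("_key", sort=False)):
        sub = sub.drop(columns="_key")
        if len(sub) >= min_group:
            groups.append((f"group{i}", sub))
        else:
            residual_frames.append(sub)
    rows = []
    for name, sub in groups:
        profile = sub.mean()
        profile["count"] = len(sub)
        profile.name = name
        rows.append(profile)
    if residual_frames:
        other = pd.concat(residual_frames)
        profile = other.mean()
        profile["count"] = len(other)
        profile.name = "other"
        rows.append(profile)
    out = pd.DataFrame(rows).sort_values("count", ascending=False, kind="stable")
    out["count"] = out["count"].astype(int)
    return out


def sequence_mode(
    tracks: Sequence[MotifTrack], top_n: int = 10
) -> list[tuple[str, list[tuple[int, str, int]]]]:
    """Positional motif labels with a palette, alleles sorted by length.

    The ``top_n`` motifs by total chunk count across all tracks get
    distinct color slots 0..top_n-1 (count ties broken
    lexicographically); every other label, including OTHER, maps to the
    gray slot (-1).  Returns, per allele (length descending, ties by
    allele id), the ordered list of (chunk index, label, color slot).
    """
    counts: dict[str, int] = {}
    for t in tracks:
        for m in t.motifs:
            if m == OTHER:
                continue
            counts[m] = counts.get(m, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    palette = {motif: slot for slot, (motif, _) in enumerate(ranked[:top_n])}
    ordered = sorted(tracks, key=lambda t: (-t.length_bp, t.allele_id))
    out = []
    for t in ordered:
        labelled = [
            (i, m, palette.get(m, GRAY_SLOT)) for i, m in enumerate(t.motifs)
        ]
        out.append((t.allele_id, labelled))
    return out


def cohort_z_score(value: float, cohort: Sequence[float]) -> float:
    """z-score of a value against a cohort: (value - mean) / sample sd."""
    if len(cohort) < 2:
        raise ValueError("cohort must contain at least two values")
    arr = np.asarray(cohort, dtype=float)
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("cohort standard deviation is zero")
    return float((value - arr.mean()) / sd)
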
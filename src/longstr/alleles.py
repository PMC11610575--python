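"""Allele inference: clustering, outlier flagging, consensus, genotype.

Insertion sequences extracted per read are grouped into one or two
alleles.  When prephased HP tags are available the grouping is the
phasing; on haploid chromosomes all reads form one group; otherwise
reads are clustered hierarchically (average linkage) on pairwise edit
distances.  Two cleaning rules from the genotyping algorithm apply:

* subtree exclusion — leaves hanging off the top of the dendrogram that
  hold <10% of the reads while the merge dissimilarity exceeds five are
  dropped as low-quality/non-repetitive reads;
* length outliers — reads at least twice the median length of the
  larger allele are reported as outliers (and excluded from consensus
  by default).

Each surviving group with enough supporting reads (two or more) yields
an allele call through partial-order-alignment consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from longstr.catalog import RepeatLocus
from longstr.poa import poa_consensus
from longstr.reads import RepeatRead, partition_by_haplotype

logger = logging.getLogger(__name__)

DEFAULT_MIN_SUPPORT = 2
DEFAULT_EXCLUSION_FRACTION = 0.10
DEFAULT_EXCLUSION_DISSIMILARITY = 5.0


@dataclass
class AlleleCall:
    """One inferred repeat allele."""

    consensus: str
    support: int
    read_ids: list[str]
    outlier_read_ids: list[str] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return len(self.consensus)


@dataclass
class LocusGenotype:
    """Per-sample, per-locus genotyping result."""

    locus_id: str
    sample_id: str
    alleles: list[AlleleCall]
    zygosity: str  # hom | het | hemi | missing
    phasing_source: str  # HP_tags | clustering | haploid | none
    excluded_read_ids: list[str] = field(default_factory=list)
    reason: Optional[str] = None  # machine-readable reason when missing


def pairwise_distance_matrix(insertions: Sequence[str]) -> np.ndarray:
    """Symmetric matrix of Levenshtein edit distances between insertions.

    Empty strings are allowed: d("", s) = len(s).
    """
    n = len(insertions)
    if n < 2:
        raise ValueError("need at least two insertions")
    dist = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = insertions[i], insertions[j]
            if not a or not b:
                d = max(len(a), len(b))
            else:
                d = edlib.align(a, b, task="distance")["editDistance"]
            dist[i, j] = dist[j, i] = d
    return dist


def cluster_into_alleles(
    dist: np.ndarray,
    read_ids: Sequence[str],
    exclusion_fraction: float = DEFAULT_EXCLUSION_FRACTION,
    exclusion_dissimilarity: float = DEFAULT_EXCLUSION_DISSIMILARITY,
    hom_threshold: float = DEFAULT_EXCLUSION_DISSIMILARITY,
) -> tuple[list[list[str]], list[str]]:
    """Cluster reads into 1 or 2 allele groups with subtree exclusion.

    Average-linkage agglomerative clustering builds a dendrogram on the
    distance matrix.  While a child of the current root holds fewer
    than ``exclusion_fraction`` of all reads and the root's merge
    height exceeds ``exclusion_dissimilarity``, that child's reads are
    excluded and the root descends into the other child.  The surviving
    tree is cut into two groups, or one if its final merge height is at
    most ``hom_threshold`` (a homozygous read pile).

    Returns (groups largest-first, excluded read ids).
    """
    n = len(read_ids)
    if dist.shape != (n, n):
        raise ValueError("distance matrix does not match read_ids")
    if n < 2:
        raise ValueError("need at least two reads")

    tree = to_tree(linkage(squareform(dist, checks=False), method="average"))
    excluded: list[str] = []

    def leaves(node) -> list[int]:
        return node.pre_order(lambda leaf: leaf.id)

    root = tree
    while not root.is_leaf() and root.dist > exclusion_dissimilarity:
        left, right = root.get_left(), root.get_right()
        small, big = sorted((left, right), key=lambda nd: nd.get_count())
        if small.get_count() < exclusion_fraction * n:
            excluded.extend(read_ids[i] for i in leaves(small))
            root = big
        else:
            break

    if root.is_leaf():
        groups_idx = [[root.id]]
    elif root.dist <= hom_threshold:
        groups_idx = [leaves(root)]
    else:
        groups_idx = [leaves(root.get_left()), leaves(root.get_right())]

    groups = [[read_ids[i] for i in idx] for idx in groups_idx]
    groups.sort(key=len, reverse=True)
    return groups, excluded


def flag_outliers(group_lengths: Sequence[dict[str, int]]) -> list[str]:
    """Flag reads at least twice the larger allele's median length.

    ``group_lengths`` maps read id -> insertion length per allele
    group.  The larger allele is the group with the greatest median
    length; any read (in either group) whose length is at least twice
    that median is an outlier.  A candidate belonging to the larger
    group is compared against the median of its peers (leave-one-out),
    so a single aberrant read cannot inflate the very median that
    should catch it.  A zero median flags nothing (every length would
    trivially qualify).
    """
    if not group_lengths:
        return []
    medians = [float(np.median(list(g.values()))) if g else 0.0 for g in group_lengths]
    larger_idx = int(np.argmax(medians))
    larger = group_lengths[larger_idx]
    flagged: list[str] = []
    for gi, g in enumerate(group_lengths):
        for rid, length in g.items():
            if gi == larger_idx:
                peers = [v for k, v in larger.items() if k != rid]
                if not peers:
                    continue
                med = float(np.median(peers))
            else:
                med = medians[larger_idx]
            if med > 0 and length >= 2.0 * med:
                flagged.append(rid)
    return flagged


def _call_allele(
    reads: Sequence[RepeatRead],
    outlier_ids: set[str],
    min_support: int,
    keep_outliers_in_consensus: bool = False,
) -> Optional[AlleleCall]:
    outliers_here = [r.read_id for r in reads if r.read_id in outlier_ids]
    if keep_outliers_in_consensus:
        used = list(reads)
    else:
        used = [r for r in reads if r.read_id not in outlier_ids]
    if len(used) < min_support:
        return None
    consensus = poa_consensus([r.insertion for r in used])
    return AlleleCall(
        consensus=consensus,
        support=len(used),
        read_ids=[r.read_id for r in used],
        outlier_read_ids=outliers_here,
    )


def genotype_locus(
    reads: Sequence[RepeatRead],
    locus: RepeatLocus,
    sample_id: str = "sample",
    haploid: bool = False,
    min_support: int = DEFAULT_MIN_SUPPORT,
    exclusion_fraction: float = DEFAULT_EXCLUSION_FRACTION,
    exclusion_dissimilarity: float = DEFAULT_EXCLUSION_DISSIMILARITY,
    phasing: str = "auto",
    keep_outliers_in_consensus: bool = False,
) -> LocusGenotype:
    """Infer the genotype of one locus from insertion-bearing reads.

    Grouping strategy: haploid chromosomes use all reads as one group
    (zygosity ``hemi``); otherwise HP tags are used when ``phasing`` is
    ``auto`` (at least two tagged reads per haplotype) or ``force``;
    else hierarchical clustering.  Outlier flagging and per-allele
    minimum support apply in every mode.  All failure modes collapse to
    zygosity ``missing`` with a machine-readable reason.
    """
    usable = [r for r in reads if r.insertion is not None]
    if len(usable) < min_support:
        return LocusGenotype(
            locus_id=locus.locus_id,
            sample_id=sample_id,
            alleles=[],
            zygosity="missing",
            phasing_source="none",
            reason=f"only {len(usable)} usable reads (< {min_support})",
        )

    excluded: list[str] = []
    if haploid:
        groups = [usable]
        phasing_source = "haploid"
    else:
        hap1, hap2, untagged = partition_by_haplotype(usable)
        use_hp = phasing == "force" or (
            phasing == "auto" and len(hap1) >= 2 and len(hap2) >= 2
        )
        if phasing not in ("auto", "force", "off"):
            raise ValueError(f"unknown phasing mode {phasing!r}")
        if use_hp:
            groups = [g for g in (hap1, hap2) if g]
            phasing_source = "HP_tags"
        else:
            insertions = [r.insertion for r in usable]
            dist = pairwise_distance_matrix(insertions)
            lengths = [len(s) for s in insertions]
            hom_threshold = max(
                exclusion_dissimilarity, 0.05 * max(lengths, default=0)
            )
            id_groups, excluded = cluster_into_alleles(
                dist,
                [r.read_id for r in usable],
                exclusion_fraction=exclusion_fraction,
                exclusion_dissimilarity=exclusion_dissimilarity,
                hom_threshold=hom_threshold,
            )
            by_id = {r.read_id: r for r in usable}
            groups = [[by_id[rid] for rid in g] for g in id_groups]
            phasing_source = "clustering"

    groups = [g for g in groups if g]
    if not groups:
        return LocusGenotype(
            locus_id=locus.locus_id,
            sample_id=sample_id,
            alleles=[],
            zygosity="missing",
            phasing_source=phasing_source,
            excluded_read_ids=excluded,
            reason="all reads excluded",
        )

    outlier_ids = set(
        flag_outliers([{r.read_id: r.insertion_length for r in g} for g in groups])
    )
    calls = [
        _call_allele(g, outlier_ids, min_support, keep_outliers_in_consensus)
        for g in groups
    ]
    alleles = [c for c in calls if c is not None]
    dropped = [c for c, orig in zip(calls, groups) if c is None]
    if dropped:
        logger.warning(
            "locus %s: %d allele group(s) below min_support dropped",
            locus.locus_id,
            len(dropped),
        )

    if not alleles:
        return LocusGenotype(
            locus_id=locus.locus_id,
            sample_id=sample_id,
            alleles=[],
            zygosity="missing",
            phasing_source=phasing_source,
            excluded_read_ids=excluded,
            reason="no allele group reached min_support",
        )

    if haploid:
        zygosity = "hemi"
        alleles = alleles[:1]
    elif len(alleles) == 2:
        zygosity = "het"
    else:
        zygosity = "hom"
    return LocusGenotype(
        locus_id=locus.locus_id,
        sample_id=sample_id,
        alleles=alleles,
        zygosity=zygosity,
        phasing_source=phasing_source,
        excluded_read_ids=excluded,
    )
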
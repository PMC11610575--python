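import json

import numpy as np
import pytest

from longstr.alleles import (
    cluster_into_alleles,
    flag_outliers,
    genotype_locus,
    pairwise_distance_matrix,
)
from longstr.catalog import RepeatLocus
from longstr.pipeline import genotype_catalog, genotype_one_locus
from longstr.reads import RepeatRead

from conftest import levenshtein, random_dna

LOCUS = RepeatLocus("L", "chrS", 400, 430, "CAG")


def reads_with(insertions, hp=None):
    return [
        RepeatRead(f"r{i}", "NNN", haplotype=None if hp is None else hp[i],
                   insertion=ins)
        for i, ins in enumerate(insertions)
    ]


class TestDistanceMatrix:
    def test_identical_and_empty_strings(self):
        d = pairwise_distance_matrix(["CAG", "CAG"])
        assert d.tolist() == [[0, 0], [0, 0]]
        d = pairwise_distance_matrix(["", "CAGCAG"])
        assert d[0, 1] == 6

    def test_agrees_with_dp_oracle_on_random_strings(self):
        rng = np.random.default_rng(2)
        seqs = [random_dna(rng, int(rng.integers(0, 40))) for _ in range(8)]
        d = pairwise_distance_matrix(seqs)
        for i in range(8):
            for j in range(8):
                assert d[i, j] == levenshtein(seqs[i], seqs[j])
        assert (d == d.T).all() and (np.diag(d) == 0).all()

    def test_single_substitution_distance(self):
        d = pairwise_distance_matrix(["CAGCAG", "CAGTAG"])
        assert d[0, 1] == 1


class TestClusterIntoAlleles:
    def test_distant_singleton_excluded_by_subtree_rule(self):
        """19 tight reads + 1 at distance 50: the 5% leaf is excluded."""
        n = 20
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(n, n)).astype(float)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        d[19, :19] = d[:19, 19] = 50
        ids = [f"r{i}" for i in range(n)]
        groups, excluded = cluster_into_alleles(d, ids)
        assert excluded == ["r19"]
        assert len(groups) == 1 and set(groups[0]) == set(ids[:19])

    def test_two_tight_groups_split_without_exclusion(self):
        n = 10
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    d[i, j] = 1 if (i < 5) == (j < 5) else 30
        ids = [f"r{i}" for i in range(n)]
        groups, excluded = cluster_into_alleles(d, ids)
        assert excluded == []
        assert sorted(sorted(g) for g in groups) == [
            [f"r{i}" for i in range(5)],
            [f"r{i}" for i in range(5, 10)],
        ]

    def test_two_identical_reads_form_one_group(self):
        d = np.zeros((2, 2))
        groups, excluded = cluster_into_alleles(d, ["a", "b"])
        assert groups == [["a", "b"]] and excluded == []

    def test_exclusion_needs_both_conditions(self):
        """A small subtree at dissimilarity <= 5 is NOT excluded."""
        n = 20
        d = np.full((n, n), 4.0)
        np.fill_diagonal(d, 0)
        d[19, :19] = d[:19, 19] = 5.0  # merge height exactly 5, not > 5
        groups, excluded = cluster_into_alleles(d, [f"r{i}" for i in range(n)])
        assert excluded == []


class TestFlagOutliers:
    def test_twice_median_is_flagged_inclusive(self):
        groups = [{"a": 30, "b": 30, "c": 32, "x": 60}]
        assert flag_outliers(groups) == ["x"]

    def test_just_below_twice_median_is_not_flagged(self):
        groups = [{"a": 30, "b": 30, "c": 32, "x": 59}]
        assert flag_outliers(groups) == []

    def test_equal_lengths_flag_nothing(self):
        assert flag_outliers([{"a": 30, "b": 30, "c": 30}]) == []

    def test_median_of_larger_allele_governs_both_groups(self):
        short = {"s1": 10, "s2": 10, "s3": 80}  # 80 >= 2 x 40
        long = {"l1": 40, "l2": 40, "l3": 42}
        flagged = flag_outliers([short, long])
        assert flagged == ["s3"]

    def test_zero_median_flags_nothing(self):
        assert flag_outliers([{"a": 0, "b": 0, "c": 5}]) == []


class TestGenotypeLocus:
    def test_heterozygous_noiseless(self):
        reads = reads_with(["CAG" * 10] * 8 + ["CAG" * 30] * 7)
        gt = genotype_locus(reads, LOCUS)
        assert gt.zygosity == "het"
        assert sorted(a.length_bp for a in gt.alleles) == [30, 90]
        assert sorted(a.support for a in gt.alleles) == [7, 8]

    def test_haploid_one_allele(self):
        reads = reads_with(["CGG" * 25] * 6)
        gt = genotype_locus(reads, LOCUS, haploid=True)
        assert gt.zygosity == "hemi"
        assert len(gt.alleles) == 1
        assert gt.alleles[0].length_bp == 75 and gt.alleles[0].support == 6
        assert gt.phasing_source == "haploid"

    def test_single_read_is_missing(self):
        gt = genotype_locus(reads_with(["CAG" * 10]), LOCUS)
        assert gt.zygosity == "missing" and gt.alleles == []
        assert gt.reason is not None

    def test_homozygous_identity(self):
        reads = reads_with(["CAG" * 15] * 10)
        gt = genotype_locus(reads, LOCUS)
        assert gt.zygosity == "hom"
        assert len(gt.alleles) == 1 and gt.alleles[0].length_bp == 45

    def test_hp_tags_used_when_available(self):
        hp = [1, 1, 1, 2, 2, 2]
        reads = reads_with(["CAG" * 10] * 3 + ["CAG" * 30] * 3, hp=hp)
        gt = genotype_locus(reads, LOCUS)
        assert gt.phasing_source == "HP_tags"
        assert gt.zygosity == "het"
        assert sorted(a.length_bp for a in gt.alleles) == [30, 90]

    def test_unsupported_second_allele_degrades_to_hom(self):
        """A 5/1 split reports only the supported allele."""
        reads = reads_with(["CAG" * 10] * 5 + [random_dna(np.random.default_rng(0), 200)])
        gt = genotype_locus(reads, LOCUS, exclusion_fraction=0.0)
        assert gt.zygosity == "hom"
        assert len(gt.alleles) == 1 and gt.alleles[0].length_bp == 30

    def test_junk_read_exclusion_leaves_consensus_unchanged(self):
        """Subtree exclusion is consensus-neutral (monotonicity)."""
        rng = np.random.default_rng(8)
        base = reads_with(["CAG" * 10] * 8 + ["CAG" * 30] * 7)
        gt_clean = genotype_locus(base, LOCUS)
        junk = RepeatRead("junk", "NNN", insertion=random_dna(rng, 300))
        gt_junk = genotype_locus(base + [junk], LOCUS)
        assert "junk" in gt_junk.excluded_read_ids
        assert sorted(a.consensus for a in gt_junk.alleles) == sorted(
            a.consensus for a in gt_clean.alleles
        )

    def test_determinism(self):
        rng = np.random.default_rng(4)
        ins = ["CAG" * 10] * 6 + ["CAG" * 30] * 6
        reads = reads_with(ins)
        a = genotype_locus(reads, LOCUS)
        b = genotype_locus(reads, LOCUS)
        assert a == b


def test_parameter_recovery_small_panel(tmp_path):
    """Both allele lengths within one motif on a small noisy panel."""
    from longstr.catalog import load_catalog
    from longstr.simulate import SimSpec, simulate_locus

    hits = 0
    n = 8
    for i in range(n):
        spec = SimSpec(
            seed=500 + i,
            allele_structures=[[("CAG", 12 + 2 * i)], [("CAG", 40 + 3 * i)]],
            depth=20,
            read_len=1600,
            error_rates=(0.02, 0.01, 0.01),
        )
        paths = simulate_locus(spec, tmp_path / str(i))
        (locus,) = load_catalog(paths["catalog"])
        rec = genotype_one_locus(paths["bam"], paths["reference"], locus, "s")
        lens = sorted(a.length_bp for a in rec.genotype.alleles)
        truth = sorted(len(a) for a in json.loads(open(paths["truth"]).read())["alleles"])
        if rec.genotype.zygosity == "het" and all(
            abs(a - b) <= 3 for a, b in zip(lens, truth)
        ):
            hits += 1
    assert hits >= n - 1
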
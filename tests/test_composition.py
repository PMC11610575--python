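import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from longstr.composition import (
    GRAY_SLOT,
    OTHER,
    CompositionMatrix,
    canonical_motif,
    cohort_z_score,
    collapse_groups,
    composition_matrix,
    decompose,
    filter_collapsed,
    filter_raw,
    run_length_decode,
    run_length_encode,
    sequence_mode,
)

from conftest import random_dna

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)


class TestCanonicalMotif:
    def test_known_unit_rotation(self):
        assert canonical_motif("GCA", "CAG") == "CAG"
        assert canonical_motif("AGC", "CAG") == "CAG"

    def test_homopolymer(self):
        assert canonical_motif("AAA") == "AAA"

    def test_lexicographically_smallest_rotation(self):
        # brute force over the six rotations of the telomere motif
        kmer = "TTAGGG"
        rotations = [kmer[i:] + kmer[:i] for i in range(6)]
        assert canonical_motif(kmer) == min(rotations) == "AGGGTT"

    def test_non_acgt_labelled_other(self):
        assert canonical_motif("CNG") == OTHER

    @settings(max_examples=300, deadline=None)
    @given(kmer=dna, shift=st.integers(0, 11), unit=st.one_of(st.none(), dna))
    def test_rotation_invariance(self, kmer, shift, unit):
        if unit is not None and len(unit) != len(kmer):
            unit = None
        rotated = kmer[shift % len(kmer):] + kmer[: shift % len(kmer)]
        assert canonical_motif(rotated, unit) == canonical_motif(kmer, unit)


class TestDecompose:
    def test_chunking_with_rotation(self):
        track = decompose("CAGCAGCAA", 3, "CAG")
        assert track.motifs == ["CAG", "CAG", "AAC"]

    def test_trailing_remainder_is_other(self):
        track = decompose("CAGCA", 3, "CAG")
        assert track.motifs == ["CAG", OTHER]

    def test_empty_sequence(self):
        assert decompose("", 3, "CAG").motifs == []

    @settings(max_examples=100, deadline=None)
    @given(seq=st.text(alphabet="ACGT", max_size=100), k=st.integers(1, 7))
    def test_length_bookkeeping(self, seq, k):
        track = decompose(seq, k)
        n_full = len([m for m, c in zip(track.motifs, track.chunks) if len(c) == k])
        remainder = len(seq) - n_full * k
        assert k * n_full + remainder == track.length_bp
        assert remainder < k


class TestRunLengthEncode:
    def test_pure_repeat(self):
        assert run_length_encode(decompose("GGC" * 15, 3, "GGC")) == "(GGC)15"

    def test_prefix_then_repeat(self):
        assert run_length_encode(decompose("CCA" + "GCA" * 11, 3, "GCA")) == "CCA(GCA)11"

    def test_single_motif_rendered_bare(self):
        assert run_length_encode(decompose("CAG", 3, "CAG")) == "CAG"

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 6), n=st.integers(0, 60))
    def test_round_trip_decomposition(self, seed, k, n):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, n)
        track = decompose(seq, k)
        decoded = run_length_decode(run_length_encode(track))
        assert decompose(decoded, k).motifs == track.motifs


def tracks_from(rows, k=3, unit=None):
    out = []
    for allele_id, seq in rows:
        t = decompose(seq, k, unit)
        t.allele_id = allele_id
        out.append(t)
    return out


class TestCompositionMatrix:
    def test_counting(self):
        tracks = tracks_from([("a", "CAG" * 9 + "AGG")], unit="CAG")
        m = composition_matrix(tracks)
        assert m.data.loc["a", "CAG"] == pytest.approx(0.9)
        assert m.data.loc["a", "AGG"] == pytest.approx(0.1)

    def test_identical_alleles_identical_rows(self):
        tracks = tracks_from([("a", "CAG" * 5), ("b", "CAG" * 5)])
        m = composition_matrix(tracks)
        assert (m.data.loc["a"] == m.data.loc["b"]).all()

    def test_other_only_allele_dropped(self, caplog):
        tracks = tracks_from([("a", "CA"), ("b", "CAG" * 3)])
        with caplog.at_level("WARNING"):
            m = composition_matrix(tracks)
        assert list(m.data.index) == ["b"]

    def test_mixed_k_rejected(self):
        t1 = decompose("CAG" * 3, 3)
        t2 = decompose("CA" * 3, 2)
        with pytest.raises(ValueError):
            composition_matrix([t1, t2])

    def test_rows_sum_to_one_before_filtering(self):
        rng = np.random.default_rng(0)
        tracks = tracks_from(
            [(f"a{i}", random_dna(rng, 60)) for i in range(10)]
        )
        m = composition_matrix(tracks)
        assert np.allclose(m.data.sum(axis=1), 1.0, atol=1e-9)


def matrix_from_array(arr, motifs=None):
    arr = np.asarray(arr, dtype=float)
    motifs = motifs or [f"M{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=[f"a{i}" for i in range(arr.shape[0])], columns=motifs)
    return CompositionMatrix(data=df, view="full")


def brute_force_raw_keep(df):
    n = len(df)
    keep = []
    for c in df.columns:
        vals = df[c].tolist()
        common = sum(1 for v in vals if v >= 0.01) >= 0.02 * n
        exception = any(v >= 0.10 for v in vals)
        if common or exception:
            keep.append(c)
    return keep


def brute_force_collapsed_keep(df):
    n = len(df)
    keep = []
    for c in df.columns:
        vals = df[c].tolist()
        common = sum(1 for v in vals if v >= 0.05) >= 0.10 * n
        exception = sum(1 for v in vals if v >= 0.10) >= 5
        if common or exception:
            keep.append(c)
    return keep


class TestFilters:
    def test_raw_rare_motif_dropped(self):
        arr = np.zeros((100, 2))
        arr[:, 0] = 1.0
        arr[0, 1] = 0.005
        m = filter_raw(matrix_from_array(arr))
        assert m.motifs == ["M0"] and m.view == "raw"

    def test_raw_ten_percent_exception_retains(self):
        arr = np.zeros((100, 2))
        arr[:, 0] = 1.0
        arr[0, 1] = 0.12
        m = filter_raw(matrix_from_array(arr))
        assert "M1" in m.motifs

    def test_raw_two_percent_prevalence_retains(self):
        arr = np.zeros((100, 2))
        arr[:, 0] = 1.0
        arr[:3, 1] = 0.02
        m = filter_raw(matrix_from_array(arr))
        assert "M1" in m.motifs

    def test_collapsed_prevalence_retains(self):
        arr = np.zeros((100, 2))
        arr[:, 0] = 1.0
        arr[:12, 1] = 0.06
        m = filter_collapsed(matrix_from_array(arr))
        assert "M1" in m.motifs

    def test_collapsed_five_allele_exception(self):
        arr = np.zeros((100, 2))
        arr[:, 0] = 1.0
        arr[:5, 1] = 0.12
        m = filter_collapsed(matrix_from_array(arr))
        assert "M1" in m.motifs

    def test_collapsed_ubiquitous_but_weak_dropped(self):
        arr = np.full((100, 1), 0.04)
        m = filter_collapsed(matrix_from_array(arr))
        assert m.motifs == []

    def test_filters_never_rescale_retained_columns(self):
        rng = np.random.default_rng(1)
        arr = rng.dirichlet(np.ones(4), size=30)
        full = matrix_from_array(arr)
        raw = filter_raw(full)
        assert (raw.data == full.data[raw.motifs]).all().all()

    @pytest.mark.parametrize("seed", range(20))
    def test_filters_agree_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 120))
        k = int(rng.integers(1, 6))
        # sparse, spiky rows exercise every threshold branch
        arr = rng.dirichlet(np.full(k, 0.3), size=n)
        arr[rng.random(arr.shape) < 0.3] = 0.0
        full = matrix_from_array(arr)
        assert filter_raw(full).motifs == brute_force_raw_keep(full.data)
        assert filter_collapsed(full).motifs == brute_force_collapsed_keep(full.data)


class TestCollapseGroups:
    def test_single_group(self):
        arr = np.ones((10, 1))
        m = CompositionMatrix(matrix_from_array(arr).data, view="collapsed")
        out = collapse_groups(m)
        assert len(out) == 1 and out["count"].iloc[0] == 10

    def test_small_groups_merge_into_other(self):
        arr = np.zeros((10, 2))
        arr[:7, 0] = 1.0
        arr[7:, 0] = 0.5
        arr[7:, 1] = 0.5
        m = CompositionMatrix(matrix_from_array(arr, ["CAG", "CAA"]).data, view="collapsed")
        out = collapse_groups(m, min_group=5)
        assert list(out["count"]) == [7, 3]
        assert out.index[-1] == "other"

    def test_empty_matrix(self):
        m = CompositionMatrix(pd.DataFrame(), view="collapsed")
        assert collapse_groups(m).empty


class TestSequenceMode:
    def test_interruption_positions_visible(self):
        seq = "CGG" * 9 + "AGG" + "CGG" * 10
        t = decompose(seq, 3, "CGG")
        t.allele_id = "a"
        ((allele_id, labelled),) = sequence_mode([t])
        agg = [i for i, label, slot in labelled if label == "AGG"]
        assert agg == [9]
        # only two motifs: both get real palette slots
        assert all(slot != GRAY_SLOT for _, label, slot in labelled)

    def test_rarest_motifs_fall_to_gray_beyond_top_n(self):
        rng = np.random.default_rng(0)
        motifs = ["".join(p) for p in
                  ["AAC", "AAG", "AAT", "ACC", "ACG", "ACT", "AGC", "AGT",
                   "ATC", "ATG", "CCG", "CGT"]]
        tracks = []
        for rank, motif in enumerate(motifs):
            seq = motif * (12 - rank)
            t = decompose(seq, 3)
            t.allele_id = f"a{rank}"
            tracks.append(t)
        out = sequence_mode(tracks, top_n=10)
        slots = {label: slot for _, labelled in out for _, label, slot in labelled}
        grayed = [m for m, s in slots.items() if s == GRAY_SLOT]
        assert sorted(grayed) == sorted(
            [canonical_motif(m) for m in motifs[10:]]
        )

    def test_alleles_sorted_by_length_descending(self):
        rows = [("short", "CAG" * 3), ("long", "CAG" * 10), ("mid", "CAG" * 5)]
        tracks = tracks_from(rows)
        out = sequence_mode(tracks)
        assert [a for a, _ in out] == ["long", "mid", "short"]

    def test_empty_input(self):
        assert sequence_mode([]) == []

    def test_palette_bounded_by_top_n_plus_gray(self):
        rng = np.random.default_rng(3)
        tracks = tracks_from([(f"a{i}", random_dna(rng, 90)) for i in range(20)])
        out = sequence_mode(tracks, top_n=10)
        slots = {slot for _, labelled in out for _, _, slot in labelled}
        assert len(slots) <= 11


class TestCohortZScore:
    def test_mean_value_scores_zero(self):
        assert cohort_z_score(3.0, [1, 2, 3, 4, 5]) == pytest.approx(0.0)

    def test_sample_sd_formula(self):
        assert cohort_z_score(6, [1, 2, 3, 4, 5]) == pytest.approx(1.8974, abs=1e-4)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            cohort_z_score(5, [5, 5, 5])

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_z_score(5, [5])
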
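"""Exhaustive k-mer engine: occurrence scanning, per-partition statistics,
correlation and enrichment statistics, rank-change selection."""

import math

import numpy as np
import pytest

from exomotif import stats
from exomotif.dataio import TranscriptRecord, TxClass
from exomotif.ecer import EcerPartition
from exomotif.kmers import (
    build_kmer_table,
    encode_sequence,
    enumerate_motifs,
    enrichment_tests,
    index_to_motif,
    motif_index,
    motif_partition_stats,
    pooled_base_freqs,
    rank_change_selection,
    scan_occurrences,
    tau_matrix_vs_bins,
    tau_vs_halflife,
    tau_vs_secretion,
)

ALPH = "ACGU"


def naive_scan(seq: str, motif: str) -> list[int]:
    """Sliding-window oracle: character-by-character comparison."""
    k = len(motif)
    return [
        s
        for s in range(len(seq) - k + 1)
        if all(seq[s + j] == motif[j] for j in range(k))
    ]


class TestEnumerate:
    def test_single_base(self):
        assert enumerate_motifs(1, 1) == ["A", "C", "G", "U"]

    def test_full_universe_size(self):
        assert len(enumerate_motifs(1, 8)) == 87380  # (4^9 - 4) / 3

    def test_one_length(self):
        out = enumerate_motifs(2, 2)
        assert len(out) == 16 and out[0] == "AA" and out[-1] == "UU"

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            enumerate_motifs(0, 3)

    def test_index_round_trip(self):
        for m in ("A", "ACGU", "UUUGGCCA"):
            assert index_to_motif(motif_index(m), len(m)) == m


class TestScan:
    def test_overlapping_matches(self):
        rec = TranscriptRecord("t", "AAAAAA")
        assert [o.start for o in scan_occurrences(rec, "AA")] == [0, 1, 2, 3, 4]

    def test_relative_scale_endpoints(self):
        rec = TranscriptRecord("t", "ACGUACGU")
        occ = scan_occurrences(rec, "ACGU")
        assert [o.start for o in occ] == [0, 4]
        assert [o.rel_pos for o in occ] == [0.0, 1.0]

    def test_ambiguity_never_matches(self):
        rec = TranscriptRecord("t", "ACGNACGU")
        # any window overlapping the N can never match
        assert [o.start for o in scan_occurrences(rec, "CGU")] == [5]
        assert [o.start for o in scan_occurrences(rec, "ACG")] == [0, 4]
        assert scan_occurrences(rec, "GUA") == []
        with pytest.raises(ValueError):
            scan_occurrences(rec, "GNA")  # motifs themselves are unambiguous

    def test_motif_longer_than_sequence(self):
        assert scan_occurrences(TranscriptRecord("t", "ACG"), "ACGU") == []

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            L = int(rng.integers(5, 501))
            seq = "".join(rng.choice(list(ALPH + "N"), L, p=[0.24] * 4 + [0.04]))
            rec = TranscriptRecord("t", seq)
            k = int(rng.integers(1, 9))
            motif = "".join(rng.choice(list(ALPH), k))
            assert [o.start for o in scan_occurrences(rec, motif)] == naive_scan(
                seq, motif
            )


def _random_records(rng, n=12, lmin=20, lmax=120):
    recs = {}
    for i in range(n):
        L = int(rng.integers(lmin, lmax))
        seq = "".join(rng.choice(list(ALPH + "N"), L, p=[0.245] * 4 + [0.02]))
        cls = TxClass.MRNA if rng.random() < 0.7 else TxClass.NCRNA
        recs[f"t{i}"] = TranscriptRecord(f"t{i}", seq, cls)
    return recs


class TestPartitionStats:
    def test_all_and_none_containing(self):
        part = EcerPartition(">33", (33, math.inf), {"a", "b"})
        recs = {
            "a": TranscriptRecord("a", "ACGUACG"),
            "b": TranscriptRecord("b", "GGACGUU"),
        }
        st = motif_partition_stats(part, recs, "ACG")
        assert st.frac_containing == 1.0
        st = motif_partition_stats(part, recs, "UUUU")
        assert st.frac_containing == 0.0 and st.skewness == 0.0

    def test_pooled_skewness_sign_convention(self):
        # single G at relative positions 0.1, 0.1, 0.8 -> mass near the 5' end
        seqs = ["A" * 11 for _ in range(3)]
        starts = [1, 1, 8]  # rel_pos = start / (11 - 1)
        recs = {
            f"t{i}": TranscriptRecord(f"t{i}", s[:p] + "G" + s[p + 1 :])
            for i, (s, p) in enumerate(zip(seqs, starts))
        }
        part = EcerPartition(">33", (33, math.inf), set(recs))
        st = motif_partition_stats(part, recs, "G")
        assert st.skewness == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError):
            motif_partition_stats(EcerPartition("x", (0, 1), set()), {}, "A")

    def test_vectorized_table_matches_per_motif_scan(self):
        rng = np.random.default_rng(8)
        recs = _random_records(rng)
        part = EcerPartition(">33", (33, math.inf), set(recs))
        for k in (1, 2, 3, 5):
            table = build_kmer_table(recs.values(), k)
            for _ in range(12):
                motif = "".join(rng.choice(list(ALPH), k))
                ref = motif_partition_stats(part, recs, motif)
                row = table.motif_row(motif)
                assert row["n_occurrences"] == ref.n_occurrences
                assert row["n_containing"] == ref.n_containing
                assert row["frac_containing"] == pytest.approx(ref.frac_containing)
                assert row["skewness"] == pytest.approx(ref.skewness, abs=1e-9)
                assert row["mrna_frac"] == pytest.approx(ref.mrna_frac)

    def test_containment_bounds_invariant(self):
        rng = np.random.default_rng(21)
        recs = _random_records(rng)
        table = build_kmer_table(recs.values(), 2)
        assert np.all(table.containing <= table.n_members)
        assert np.all(table.counts >= table.containing)

    def test_single_base_conservation(self):
        """Sum of A/C/G/U occurrence counts equals the unambiguous base total."""
        rng = np.random.default_rng(33)
        recs = _random_records(rng)
        table = build_kmer_table(recs.values(), 1)
        expected = sum(
            int(np.count_nonzero(encode_sequence(r.sequence) < 4))
            for r in recs.values()
        )
        assert int(table.counts.sum()) == expected


class TestCorrelations:
    def test_tau_vs_secretion_trivial(self):
        up = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        assert tau_vs_secretion(up) == pytest.approx(1.0)
        assert tau_vs_secretion(up[::-1]) == pytest.approx(-1.0)
        assert tau_vs_secretion([0.5] * 8) == 0.0
        with pytest.raises(ValueError):
            tau_vs_secretion([0.1, 0.2])

    def test_tau_matrix_matches_scalar_kendall(self):
        rng = np.random.default_rng(14)
        mat = rng.integers(0, 5, size=(8, 30)).astype(float)
        ref = rng.normal(size=8)
        for r in (None, ref):
            taus = tau_matrix_vs_bins(mat, ref=r)
            xs = np.arange(8, dtype=float) if r is None else ref
            for j in range(mat.shape[1]):
                col = mat[:, j]
                if np.all(col == col[0]):
                    expected = 0.0
                else:
                    expected = stats.kendall_tau(xs, col)
                assert taus[j] == pytest.approx(expected, abs=1e-10)

    def test_tau_vs_halflife_reference_value(self):
        # presence [1,1,0,0] against half-lives [2,4,8,16] -> -2/sqrt(6)
        recs = [
            TranscriptRecord("a", "AAGGAA"),
            TranscriptRecord("b", "AGGAAA"),
            TranscriptRecord("c", "AAAAAA"),
            TranscriptRecord("d", "ACACAC"),
        ]
        hl = {"a": 2.0, "b": 4.0, "c": 8.0, "d": 16.0}
        tau, n = tau_vs_halflife(recs, "GG", hl)
        assert n == 4
        assert tau == pytest.approx(-2 / math.sqrt(6), abs=1e-12)

    def test_tau_vs_halflife_constant_presence_and_sentinel(self):
        recs = [TranscriptRecord(i, "GGGG") for i in "abcd"]
        hl = {"a": 2.0, "b": 4.0, "c": 8.0, "d": 16.0}
        assert tau_vs_halflife(recs, "GG", hl) == (0.0, 4)
        tau, n = tau_vs_halflife(recs, "GG", {"a": 2.0})
        assert tau is None and n == 1


class TestEnrichment:
    def test_observed_equals_expected_is_null(self):
        # motif "A" on all-A sequences with background freq(A)=1
        pm, ps = enrichment_tests("A", 30, 3, [10, 10, 10], [1.0, 0, 0, 0])
        assert pm == 1.0 and ps == 1.0

    def test_rare_long_motif_table(self):
        # 10 sequences of length 9, k=8: expected containing rounds to 0,
        # so Ps comes from the table [[5,5],[0,10]]
        lengths = [9] * 10
        _, ps = enrichment_tests("ACGUACGU", 5, 5, lengths, [0.25] * 4)
        assert ps == pytest.approx(stats.fisher_exact([[5, 5], [0, 10]]))

    def test_background_must_normalize(self):
        with pytest.raises(ValueError):
            enrichment_tests("A", 1, 1, [10], [0.3, 0.3, 0.3, 0.3])

    def test_pooled_base_freqs(self):
        recs = [TranscriptRecord("a", "AACGNN"), TranscriptRecord("b", "UU")]
        freqs = pooled_base_freqs(recs)
        assert freqs == pytest.approx([2 / 6, 1 / 6, 1 / 6, 2 / 6])


class TestRankChange:
    def test_identical_maps_no_movement(self):
        freqs = {"AA": 5.0, "AC": 3.0, "AG": 1.0}
        out = rank_change_selection(freqs, dict(freqs), top_n=3)
        assert all(delta == 0 for _, delta in out)

    def test_swapped_top_two(self):
        control = {"A": 10.0, "B": 8.0, "C": 5.0, "D": 1.0}
        enriched = {"A": 8.0, "B": 10.0, "C": 5.0, "D": 1.0}
        out = dict(rank_change_selection(enriched, control, top_n=4))
        assert out == {"B": 1.0, "A": -1.0, "C": 0.0, "D": 0.0}

    def test_large_riser_ranks_first(self):
        motifs = [f"m{i}" for i in range(100)]
        control = {m: float(100 - i) for i, m in enumerate(motifs)}
        enriched = dict(control)
        # the motif ranked last in control becomes the most frequent
        enriched["m99"] = 1000.0
        out = rank_change_selection(enriched, control, top_n=1)
        assert out[0][0] == "m99" and out[0][1] == 99.0

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rank_change_selection({"A": 1.0}, {"C": 1.0}, top_n=1)
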
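"""Motif windows and the pair-maximization folding fallback."""

import numpy as np
import pytest

from exomotif.dataio import TranscriptRecord
from exomotif.kmers import MotifOccurrence, scan_occurrences
from exomotif.structure import (
    MIN_LOOP,
    extract_windows,
    fold_window,
    max_pair_fold,
    rank_and_summarize,
)

_CAN_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def max_pairs_oracle(seq: str) -> int:
    """Exhaustive enumeration of all nested pairings with loop >= 3."""

    def best(i: int, j: int) -> int:
        if j - i <= MIN_LOOP:
            return 0
        # j unpaired
        result = best(i, j - 1)
        for k in range(i, j - MIN_LOOP):
            if (seq[k], seq[j]) in _CAN_PAIR:
                result = max(result, (best(i, k - 1) if k > i else 0)
                             + best(k + 1, j - 1) + 1)
        return result

    return best(0, len(seq) - 1) if seq else 0


def _occ(tid, motif, start, rel=0.5):
    return MotifOccurrence(tid, motif, start, rel)


class TestExtractWindows:
    def test_window_equals_full_sequence(self):
        rec = TranscriptRecord("t", "ACGU" * 25)  # L = 100
        motif = rec.sequence[46:54]
        wins, skipped = extract_windows([_occ("t", motif, 46)], {"t": rec})
        assert skipped == 0 and len(wins) == 1
        assert wins[0].window_seq == rec.sequence
        assert wins[0].motif_offset == 46

    def test_edge_occurrence_skipped(self):
        rec = TranscriptRecord("t", "ACGU" * 25)
        wins, skipped = extract_windows(
            [_occ("t", rec.sequence[10:18], 10)], {"t": rec}, edge_policy="skip"
        )
        assert wins == [] and skipped == 1

    def test_offset_arithmetic(self):
        rec = TranscriptRecord("t", "AU" * 100)  # L = 200
        motif = rec.sequence[100:108]
        wins, _ = extract_windows([_occ("t", motif, 100)], {"t": rec})
        w = wins[0]
        assert w.start == 54 and len(w.window_seq) == 100
        assert w.window_seq == rec.sequence[54:154]
        assert w.region == (54 / 200, 154 / 200)

    def test_clip_policy_bounds(self):
        rec = TranscriptRecord("t", "ACGU" * 25)
        wins, skipped = extract_windows(
            [_occ("t", rec.sequence[10:18], 10)], {"t": rec}, edge_policy="clip"
        )
        assert skipped == 0
        assert 8 <= len(wins[0].window_seq) <= 100
        assert wins[0].window_seq.startswith(rec.sequence[0:1])


class TestFallbackFold:
    def test_unpairable_sequence(self):
        db, pairs = max_pair_fold("AAAAAAAAAA")
        assert db == "." * 10 and pairs == 0

    def test_simple_hairpin(self):
        db, pairs = max_pair_fold("GGGAAACCC")
        assert pairs == 3 and db == "(((...)))"

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            L = int(rng.integers(5, 19))
            seq = "".join(rng.choice(list("ACGU"), L))
            db, pairs = max_pair_fold(seq)
            assert pairs == max_pairs_oracle(seq), seq
            # reported structure is a valid pairing achieving the optimum
            stack, found = [], []
            for i, c in enumerate(db):
                if c == "(":
                    stack.append(i)
                elif c == ")":
                    found.append((stack.pop(), i))
            assert not stack and len(found) == pairs
            for i, j in found:
                assert (seq[i], seq[j]) in _CAN_PAIR and j - i > MIN_LOOP

    def test_fold_window_invariants(self):
        rng = np.random.default_rng(23)
        seq = "".join(rng.choice(list("ACGU"), 60))
        rec = TranscriptRecord("t", seq)
        motif = seq[26:34]
        wins, _ = extract_windows(
            [_occ("t", motif, 26)], {"t": rec}, flank=20
        )
        res = fold_window(wins[0])
        assert len(res.dot_bracket) == len(wins[0].window_seq)
        assert res.dot_bracket.count("(") == res.dot_bracket.count(")")
        assert res.energy <= 0
        assert res.local_pattern == res.dot_bracket[18:30]  # motif +- 2


class TestRankAndSummarize:
    def _folds(self, energies, patterns, region=0.8):
        rec = TranscriptRecord("t", "GGGAAACCC" * 20)
        folds = []
        for i, (e, p) in enumerate(zip(energies, patterns)):
            w = extract_windows(
                [_occ("t", "AAACCCGGG", 90)], {"t": rec}, flank=10
            )[0][0]
            w = type(w)(
                transcript_id=f"t{i}", motif="AAACCCGGG",
                window_seq=w.window_seq, motif_offset=w.motif_offset,
                start=90, region=(region - 0.05, region + 0.05),
            )
            f = fold_window(w)
            folds.append(
                type(f)(window=w, dot_bracket=f.dot_bracket, energy=e,
                        engine=f.engine, structure_kind=f.structure_kind,
                        local_pattern=p)
            )
        return folds

    def test_energy_ranking_and_predominant(self):
        folds = self._folds(
            [-5, -3, -8, -1, -2],
            ["((..))", "((..))", "((..))", "......", "......"],
        )
        summary = rank_and_summarize(folds, region_filter=(0.7, 1.0))
        assert [f.energy for f in summary.ranked] == [-8, -5, -3, -2, -1]
        pred = summary.predominant["AAACCCGGG"]
        assert pred.pattern == "((..))" and pred.count == 3
        assert pred.frequency == pytest.approx(0.6)

    def test_region_filter_excludes(self):
        folds = self._folds([-5, -3], ["x", "x"], region=0.3)
        summary = rank_and_summarize(folds, region_filter=(0.7, 1.0))
        assert summary.ranked == [] and summary.predominant == {}

    def test_permutation_stable(self):
        folds = self._folds([-5, -3, -8, -1], ["a", "b", "a", "c"])
        s1 = rank_and_summarize(folds)
        s2 = rank_and_summarize(folds[::-1])
        assert [f.window.transcript_id for f in s1.ranked] == [
            f.window.transcript_id for f in s2.ranked
        ]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_and_summarize([])
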
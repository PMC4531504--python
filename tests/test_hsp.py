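"""Ungapped extension, coverage skipping, strand handling."""

import numpy as np
import pytest

import _oracles
from hspscan import fixtures as fx
from hspscan.dictionary import Params
from hspscan.hsp import (
    HSP,
    compare_both_strands,
    compare_sequences,
    detect_hsps,
    extend_hit,
)
from hspscan.seeding import hits_array, sort_hits
from hspscan.sequence_io import Sequence, reverse_complement


def frag_set(hsps):
    return {(h.x_start, h.x_end, h.y_start, h.y_end, h.score) for h in hsps}


def raw_params(k_seed, match=4, mismatch=4):
    """Thresholds effectively off: everything the extender emits is reported."""
    return Params(k=k_seed, k_seed=k_seed, partitions=4, match=match,
                  mismatch=mismatch, min_length=0, cap=0)


class TestExtendHit:
    def test_trailing_mismatches_are_trimmed_to_the_running_maximum(self):
        x = Sequence("x", "ACGTACGTAA")
        y = Sequence("y", "ACGTACGTCC")
        h = extend_hit(x, y, 0, 0, raw_params(4, match=1, mismatch=1))
        assert (h.x_start, h.x_end, h.y_start, h.y_end) == (0, 7, 0, 7)
        assert h.length == 8 and h.score == 8 and h.identity == 100.0

    def test_identical_sequences_extend_end_to_end(self):
        seq = fx.random_sequence(400, seed=17, id="s")
        h = extend_hit(seq, seq, 100, 100, raw_params(8))
        assert (h.x_start, h.x_end) == (0, 399)
        assert h.score == 400 * 4 and h.identity == 100.0

    def test_seed_at_final_columns_stops_at_the_boundary(self):
        seq = fx.random_sequence(50, seed=23, id="s")
        h = extend_hit(seq, seq, 50 - 8, 50 - 8, raw_params(8))
        assert h.x_end == 49  # forward extension halted by the sequence end

    def test_n_columns_count_as_mismatches(self):
        x = Sequence("x", "ACGTACGTNACGT")
        y = Sequence("y", "ACGTACGTNACGT")
        h = extend_hit(x, y, 0, 0, raw_params(4, match=1, mismatch=1))
        assert h.identity < 100.0
        assert h.score == h.length - 2 * (h.length - round(h.length * h.identity / 100))

    def test_out_of_bounds_hit_rejected(self):
        seq = fx.random_sequence(20, seed=2, id="s")
        with pytest.raises(ValueError):
            extend_hit(seq, seq, 18, 18, raw_params(8))

    def test_thresholds_can_reject(self):
        x = fx.random_sequence(60, seed=3, id="x")
        params = Params(k=8, k_seed=8, partitions=4, min_length=0, min_identity=101.0)
        assert extend_hit(x, x, 10, 10, params) is None


class TestDetectHsps:
    def test_coverage_skipping_within_a_diagonal(self):
        x = Sequence("x", "ACGTACGTAA")
        y = Sequence("y", "ACGTACGTCC")
        hits = sort_hits(hits_array([0, 0, 4, 4], [0, 4, 0, 4]))
        params = Params(k=4, k_seed=4, partitions=4, match=1, mismatch=1,
                        min_length=6, cap=0)
        stats = {}
        hsps = detect_hsps(x, y, hits, params, stats=stats)
        # d=0: (0,0) extends over x<=7, so (4,4) is skipped; d=+-4 seeds
        # extend to fragments shorter than the length threshold
        assert frag_set(hsps) == {(0, 7, 0, 7, 8)}
        assert stats["hits_skipped"] == 1
        assert stats["extensions"] == 3

    def test_zero_hits_zero_hsps(self):
        x = fx.random_sequence(100, seed=4, id="x")
        assert detect_hsps(x, x, hits_array([], []), raw_params(8)) == []

    def test_self_consistency_of_score_and_identity(self):
        x = fx.random_sequence(1000, seed=41, id="x")
        y, _ = fx.plant_homology(x, [(300, 90.0, "f")], seed=42)
        hsps = compare_sequences(x, y, raw_params(8))
        assert hsps
        for h in hsps:
            d = h.x_start - h.y_start
            cols = [
                x.residues[i] == y.residues[i - d] and x.residues[i] != "N"
                for i in range(h.x_start, h.x_end + 1)
            ]
            matches = sum(cols)
            assert h.score == 4 * matches - 4 * (h.length - matches)
            assert h.identity == pytest.approx(100.0 * matches / h.length)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_bruteforce_oracle_on_random_pairs(self, seed):
        x = fx.random_sequence(1000, seed=seed, id="x")
        y = fx.random_sequence(1000, seed=1000 + seed, id="y")
        got = frag_set(compare_sequences(x, y, raw_params(8)))
        want = _oracles.oracle_hsps(x.residues, y.residues, 8, 4, 4)
        assert got == want

    def test_maximality_no_trim_or_extension_improves_the_score(self):
        x = fx.random_sequence(1000, seed=51, id="x")
        y = fx.random_sequence(1000, seed=52, id="y")
        hsps = compare_sequences(x, y, raw_params(8))
        assert hsps
        ds = _oracles.DiagonalScores(x.residues, y.residues, 4, 4)
        for h in hsps:
            d = h.x_start - h.y_start
            lo, scores = ds.get(d)
            span = scores[h.x_start - lo : h.x_end + 1 - lo]
            assert int(span.sum()) == h.score
            for delta in range(1, 11):
                # trimming either end
                if delta < h.length:
                    assert span[delta:].sum() <= h.score
                    assert span[:-delta].sum() <= h.score
                # extending either end
                left = scores[max(0, h.x_start - lo - delta) : h.x_start - lo]
                right = scores[h.x_end + 1 - lo : h.x_end + 1 - lo + delta]
                assert left.sum() + span.sum() <= h.score
                assert span.sum() + right.sum() <= h.score

    def test_symmetry_under_coordinate_exchange(self):
        x = fx.random_sequence(800, seed=61, id="x")
        y = fx.random_sequence(800, seed=62, id="y")
        fwd = frag_set(compare_sequences(x, y, raw_params(8)))
        swapped = {
            (ys, ye, xs, xe, s)
            for xs, xe, ys, ye, s in frag_set(compare_sequences(y, x, raw_params(8)))
        }
        assert fwd == swapped


class TestBothStrands:
    def test_reverse_complement_pair_yields_one_full_reverse_hsp(self):
        x = fx.random_sequence(1000, seed=71, id="x")
        y = reverse_complement(x)
        params = Params(k=16, k_seed=16, partitions=4, min_length=32, cap=0)
        hsps = compare_both_strands(x, y, params)
        assert len(hsps) == 1
        h = hsps[0]
        assert h.strand == "r" and h.identity == 100.0
        assert (h.x_start, h.x_end) == (0, 999)
        assert (h.y_start, h.y_end) == (999, 0)  # y descends on the reverse strand

    def test_self_comparison_forward_only(self):
        x = fx.random_sequence(1000, seed=72, id="x")
        params = Params(k=16, k_seed=16, partitions=4, min_length=32, cap=0)
        hsps = compare_both_strands(x, x, params)
        strands = sorted(h.strand for h in hsps)
        assert strands == ["f"]
        assert (hsps[0].x_start, hsps[0].x_end) == (0, 999)

    def test_unrelated_random_pair_reports_nothing(self):
        x = fx.random_sequence(1000, seed=73, id="x")
        y = fx.random_sequence(1000, seed=74, id="y")
        params = Params(k=16, k_seed=16, partitions=4, min_length=32, cap=0)
        assert compare_both_strands(x, y, params) == []

    def test_planted_segment_recovered_by_one_overlapping_hsp(self):
        x = fx.random_sequence(3000, seed=81, id="x")
        y, truth = fx.plant_homology(x, [(500, 95.0, "f")], seed=82)
        params = Params(k=12, k_seed=12, partitions=4, min_length=32, cap=0)
        hsps = compare_both_strands(x, y, params)
        seg = truth.segments[0]
        overlaps = [
            min(h.x_end, seg.x_end) - max(h.x_start, seg.x_start) + 1
            for h in hsps
            if h.strand == "f"
        ]
        assert max(overlaps) >= 0.95 * seg.length

    def test_reverse_planted_segment_coordinates_match_truth(self):
        x = fx.random_sequence(3000, seed=91, id="x")
        y, truth = fx.plant_homology(x, [(400, 100.0, "r")], seed=92)
        params = Params(k=12, k_seed=12, partitions=4, min_length=32, cap=0)
        hsps = [h for h in compare_both_strands(x, y, params) if h.strand == "r"]
        seg = truth.segments[0]
        h = max(hsps, key=lambda h: h.length)
        assert (h.x_start, h.x_end) == (seg.x_start, seg.x_end)
        assert (h.y_start, h.y_end) == (seg.y_end, seg.y_start)
        assert h.identity == 100.0


def test_hsp_invariants_enforced():
    with pytest.raises(ValueError):
        HSP(0, 9, 0, 8, "f", 10, 40, 100.0)  # y span inconsistent
    with pytest.raises(ValueError):
        HSP(0, 9, 9, 0, "f", 10, 40, 100.0)  # descending y on forward strand
    HSP(0, 9, 9, 0, "r", 10, 40, 100.0)  # valid reverse fragment
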
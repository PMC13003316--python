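"""Tests for the backward/forward scan, heuristics and symmetrization."""

import dataclasses
import math

import numpy as np
import pytest

from longdust import (
    LcInterval,
    ModelParams,
    RepeatSpec,
    Scanner,
    SyntheticSpec,
    find_lc_intervals,
    generate_synthetic,
    merge_intervals,
    revcomp,
)
from longdust.model import encode_bases, kmer_codes

from conftest import good_predicate, incremental_score, random_dna


def seg_codes(seq: str, k: int) -> list[int]:
    return kmer_codes(encode_bases(seq), k).tolist()


def full_window_counts(codes: list[int], k: int, size: int) -> list[int]:
    """Window counts over a whole short segment (segment <= w)."""
    counts = [0] * size
    for t in codes[k - 1 :]:
        counts[t] += 1
    return counts


def brute_suffix_scores(seq: str, j: int, ctx) -> dict[int, float]:
    """S(i-k+1, j) for every k-mer-end start i, from scratch."""
    k = ctx.params.k
    lo = max(j - ctx.params.w + 1, k - 1)
    return {
        i: incremental_score(seq, i - k + 1, j, ctx)
        for i in range(lo, j + 1)
    }


class TestBackward:
    def test_unique_kmer_window_is_empty(self, default_ctx):
        """All window k-mers unique: log 1 - T < 0 immediately ends the
        scan with no candidate."""
        rng = np.random.default_rng(3)
        seq = random_dna(rng, 60)
        codes = seg_codes(seq, 7)
        counts = full_window_counts(codes, 7, 4**7)
        if max(counts) == 1:
            sc = default_ctx.scanner
            assert sc.backward(len(seq) - 1, codes, counts) == []

    def test_tandem_repeat_candidate_reaches_first_unit(self, small_ctx):
        """On (AACGT)^30 the smallest candidate start lies in (or before)
        the first full repeat unit."""
        p = ModelParams(k=5, w=200)
        ctx_sc = Scanner(p)
        seq = "AACGT" * 30
        codes = seg_codes(seq, 5)
        counts = full_window_counts(codes, 5, 4**5)
        j = len(seq) - 1
        cands = ctx_sc.backward(j, codes, counts)
        assert cands
        assert all(c.vbound > 0 for c in cands)
        starts = [c.pos - 5 + 1 for c in cands]
        assert min(starts) <= 5

    def test_single_candidate_is_suffix_argmax(self, default_ctx):
        """Random prefix + (A)^60: the emitted candidate start maximises
        the suffix score, per brute-force enumeration."""
        rng = np.random.default_rng(11)
        seq = random_dna(rng, 200) + "A" * 60
        codes = seg_codes(seq, 7)
        counts = full_window_counts(codes, 7, 4**7)
        j = len(seq) - 1
        cands = default_ctx.scanner.backward(j, codes, counts)
        assert cands
        scores = brute_suffix_scores(seq, j, default_ctx)
        best = max(scores, key=lambda i: scores[i])
        assert any(abs(c.pos - best) == 0 for c in cands)
        assert max(c.vbound for c in cands) == pytest.approx(
            scores[best], abs=1e-9
        )

    def test_candidates_ascending_and_positive(self, small_ctx):
        seq = "ACGGT" * 40
        codes = seg_codes(seq, 5)
        counts = full_window_counts(codes, 5, 4**5)
        cands = small_ctx.scanner.backward(len(seq) - 1, codes, counts)
        pos = [c.pos for c in cands]
        assert pos == sorted(pos)
        assert all(c.vbound > 0 for c in cands)


class TestForward:
    def test_homopolymer_argmax_is_end(self, default_ctx):
        """(A)^60 from its first k-mer: the score rises to the end."""
        seq = "A" * 60
        codes = seg_codes(seq, 7)
        j = len(seq) - 1
        assert default_ctx.scanner.forward(6, j, math.inf, codes) == j

    def test_argmax_stops_at_repeat_end(self, default_ctx):
        """Repeat followed by a long random tail: the argmax sits at or
        near the repeat end, not at the scan limit."""
        rng = np.random.default_rng(21)
        seq = "A" * 60 + random_dna(rng, 500)
        codes = seg_codes(seq, 7)
        j = len(seq) - 1
        got = default_ctx.scanner.forward(6, j, math.inf, codes)
        assert got != j
        scores = {
            i: incremental_score(seq, 0, i, default_ctx)
            for i in range(6, j + 1)
        }
        best = max(scores, key=lambda i: scores[i])
        assert scores[got] == pytest.approx(scores[best], abs=1e-9)

    def test_single_kmer_scan_scores_nonpositive(self, default_ctx):
        """Degenerate one-k-mer scan: log 1 - T - f(1) < 0, so no
        position attains a non-negative score and nothing is returned."""
        codes = seg_codes("ACGTACG", 7)
        got = default_ctx.scanner.forward(6, 6, math.inf, codes)
        assert got == -1
        s = incremental_score("ACGTACG", 0, 6, default_ctx)
        assert s < 0


class TestFindStart:
    def test_random_window_yields_nothing(self, default_ctx):
        rng = np.random.default_rng(17)
        seq = random_dna(rng, 300)
        codes = seg_codes(seq, 7)
        counts = full_window_counts(codes, 7, 4**7)
        assert default_ctx.scanner.find_start(len(seq) - 1, codes, counts) == -1

    def test_repeat_interval_is_good(self, small_ctx):
        """The interval reported at the end of (ACGGT)^40 starts within
        the first unit and satisfies the good-interval predicate."""
        p = ModelParams(k=5, w=200)
        sc = Scanner(p)
        seq = "ACGGT" * 40
        codes = seg_codes(seq, 5)
        counts = full_window_counts(codes, 5, 4**5)
        j = len(seq) - 1
        i = sc.find_start(j, codes, counts)
        assert i >= 0
        start = i - 5 + 1
        assert start <= 5

    def test_interval_ending_in_random_tail(self, small_ctx):
        """One base past a repeat: either nothing, or an interval that
        still passes the good predicate."""
        rng = np.random.default_rng(5)
        seq = "ACGGT" * 20 + random_dna(rng, 1)
        codes = seg_codes(seq, 5)
        counts = full_window_counts(codes, 5, 4**5)
        j = len(seq) - 1
        i = small_ctx.scanner.find_start(j, codes, counts)
        if i >= 0:
            ok, why = good_predicate(seq, i - 5 + 1, j, small_ctx)
            assert ok, why


class TestScan:
    def test_random_sequence_nearly_unmasked(self, default_ctx):
        rng = np.random.default_rng(100)
        seq = random_dna(rng, 10_000)
        intervals = default_ctx.scanner.scan_both(seq)
        masked = sum(e - s for s, e in intervals)
        assert masked < 0.005 * len(seq)

    def test_embedded_repeat_recovered(self, default_ctx):
        """(ACGGT)^40 planted in 6 kb of random background: one merged
        interval covers >= 95% of the repeat, < 1% of the flanks."""
        rng = np.random.default_rng(7)
        bg = random_dna(rng, 6000)
        seq = bg[:2000] + "ACGGT" * 40 + bg[2000:]
        intervals = default_ctx.scanner.scan_both(seq)
        rep = (2000, 2200)
        inside = sum(
            max(0, min(e, rep[1]) - max(s, rep[0])) for s, e in intervals
        )
        outside = sum(e - s for s, e in intervals) - inside
        assert inside >= 0.95 * (rep[1] - rep[0])
        assert outside < 0.01 * (len(seq) - (rep[1] - rep[0]))

    def test_copy_number_threshold(self, default_ctx):
        """Four exact copies of a random 20-mer unit are called, three
        are not (the detection boundary sits near 3.3 copies)."""
        spec3 = SyntheticSpec(
            length=1000, repeats=(RepeatSpec(20, 3, 500),), seed=1
        )
        spec4 = SyntheticSpec(
            length=1000, repeats=(RepeatSpec(20, 4, 500),), seed=1
        )
        for spec, copies in ((spec3, 3), (spec4, 4)):
            rec, truth = generate_synthetic(spec)
            (a, b) = truth[0]
            intervals = default_ctx.scanner.scan_both(rec.bases)
            covered = sum(
                max(0, min(e, b) - max(s, a)) for s, e in intervals
            )
            if copies == 3:
                assert covered == 0
            else:
                assert covered >= 0.9 * (b - a)

    def test_ambiguous_bases_split_calls(self, default_ctx):
        """No call spans an N; each side of the break is scanned on its
        own."""
        seq = "A" * 50 + "N" + "A" * 50
        intervals = default_ctx.scanner.scan(seq)
        assert len(intervals) == 2
        for s, e in intervals:
            assert "N" not in seq[s:e]

    def test_sequence_shorter_than_k_is_empty(self, default_ctx):
        assert default_ctx.scanner.scan("ACG") == []

    def test_raw_calls_never_exceed_window_span(self, small_ctx):
        """No single call is longer than w + k - 1 bases (merged unions
        may be; the windowed search itself cannot)."""
        p = small_ctx.params
        seq = "ACGGT" * 60  # 300 bp repeat, w = 60
        calls = small_ctx.scanner.raw_calls(seq)
        assert calls
        assert max(b - a + 1 for a, b in calls) <= p.w + p.k - 1

    def test_extension_matches_exhaustive_scan(self, default_ctx):
        """The window-saturated extension heuristic changes calls only
        marginally: compare with the heuristic off on a repeat longer
        than the window."""
        p = ModelParams(k=7, w=500)
        freqtab = Scanner(p)
        seq = ("TAGGC" * 300)  # 1.5 kb repeat, window 500
        with_ext = freqtab.scan(seq)
        off = Scanner(
            dataclasses.replace(p, use_extension=False),
            freq=freqtab.freq,
            table=freqtab.table,
        ).scan(seq)
        m1 = sum(e - s for s, e in with_ext)
        m2 = sum(e - s for s, e in off)
        assert abs(m1 - m2) <= 0.02 * max(m1, m2)

    def test_threshold_monotonicity(self, default_ctx):
        """Raising T never increases the masked total."""
        spec = SyntheticSpec(
            length=4000,
            repeats=(RepeatSpec(25, 10, 1000, 0.05, 0.01),),
            seed=9,
        )
        rec, _ = generate_synthetic(spec)
        masked = []
        for T in (0.3, 0.5, 0.7, 0.9):
            sc = Scanner(ModelParams(T=T))
            masked.append(
                sum(e - s for s, e in sc.scan_both(rec.bases))
            )
        assert all(a >= b for a, b in zip(masked, masked[1:]))

    def test_incremental_matches_from_scratch(self, small_ctx):
        """The scanner's accumulated suffix scores equal from-scratch
        recomputation at every start (U recurrence consistency)."""
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 40) + "ACGGT" * 8 + random_dna(rng, 10)
        codes = seg_codes(seq, 5)
        counts = full_window_counts(codes, 5, 4**5)
        j = len(seq) - 1
        cands = small_ctx.scanner.backward(j, codes, counts)
        scores = brute_suffix_scores(seq, j, small_ctx)
        for c in cands:
            assert c.vbound <= max(scores.values()) + 1e-9
            # every candidate bound is an actually attained suffix score
            assert any(
                abs(c.vbound - s) < 1e-9 for s in scores.values()
            )


class TestXdrop:
    def test_disabled_is_identity(self, default_ctx):
        seq = "A" * 60
        codes = seg_codes(seq, 7)
        assert default_ctx.scanner.xdrop_split(0, 59, codes) == [(0, 59)]

    def test_huge_threshold_keeps_good_interval(self, default_ctx):
        """X-drop at an unreachable threshold returns a reported (good)
        interval unchanged."""
        sc = default_ctx.scanner_with(xdrop=1e18)
        seq = "A" * 60
        codes = seg_codes(seq, 7)
        assert sc.xdrop_split(0, 59, codes) == [(0, 59)]

    def test_spacer_between_runs_is_split_out(self, default_ctx):
        """Two homopolymer runs bridged by 300 random bases split into
        two pieces with the spacer excluded."""
        rng = np.random.default_rng(7)
        spacer = random_dna(rng, 300)
        seq = "A" * 40 + spacer + "A" * 40
        sc = default_ctx.scanner_with(xdrop=25.0)
        codes = seg_codes(seq, 7)
        pieces = sc.xdrop_split(0, len(seq) - 1, codes)
        assert len(pieces) == 2
        (s1, e1), (s2, e2) = pieces
        assert e1 < 40 + 10 and s2 > len(seq) - 40 - 10
        spacer_cov = sum(
            max(0, min(e + 1, 340) - max(s, 40)) for s, e in pieces
        )
        assert spacer_cov == 0

    def test_minor_effect_on_satellite_genome(self):
        """On a synthetic satellite genome the masked total changes by
        under 2% with X-drop on."""
        spec = SyntheticSpec(
            length=20_000,
            gc=0.41,
            repeats=(
                RepeatSpec(170, 20, 5000, 0.05, 0.01),
                RepeatSpec(40, 30, 12_000, 0.03, 0.0),
            ),
            seed=3,
        )
        rec, _ = generate_synthetic(spec)
        base = Scanner(ModelParams(gc=0.41))
        xd = Scanner(
            ModelParams(gc=0.41, xdrop=25.0),
            freq=base.freq,
            table=base.table,
        )
        m0 = sum(e - s for s, e in base.scan_both(rec.bases))
        m1 = sum(e - s for s, e in xd.scan_both(rec.bases))
        assert m0 > 0
        assert abs(m0 - m1) < 0.02 * m0


class TestSymmetrize:
    def test_coordinate_mapping(self):
        """[100, 200) on the reverse strand of 1 kb maps to [800, 900)."""
        n = 1000
        s, e = 100, 200
        assert (n - e, n - s) == (800, 900)

    def test_random_sequence_empty_union(self, default_ctx):
        rng = np.random.default_rng(23)
        seq = random_dna(rng, 2000)
        assert default_ctx.scanner.scan_both(seq) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pipeline_invariant_under_revcomp(self, default_ctx, seed):
        """Default-mode output is identical for x and revcomp(x) after
        coordinate mapping."""
        spec = SyntheticSpec(
            length=3000,
            repeats=(RepeatSpec(15, 8, 1000, 0.05, 0.02),),
            seed=seed,
        )
        rec, _ = generate_synthetic(spec)
        seq = rec.bases
        n = len(seq)
        fwd = default_ctx.scanner.scan_both(seq)
        rev = default_ctx.scanner.scan_both(revcomp(seq))
        mapped = sorted((n - e, n - s) for s, e in rev)
        assert mapped == fwd


class TestIntervalTypes:
    def test_merge_intervals_union(self):
        assert merge_intervals([(5, 10), (0, 3), (3, 6)]) == [(0, 10)]
        assert merge_intervals([(0, 2), (4, 6)]) == [(0, 2), (4, 6)]
        assert merge_intervals([]) == []

    def test_adjacent_intervals_merge(self):
        assert merge_intervals([(0, 5), (5, 9)]) == [(0, 9)]

    def test_lc_interval_validation(self):
        with pytest.raises(ValueError):
            LcInterval("s", 5, 5)
        iv = LcInterval("s", 2, 10)
        assert iv.length == 8

    def test_find_lc_intervals_names_records(self, default_ctx):
        seq = "A" * 80
        ivs = find_lc_intervals(
            seq, seq_id="chr1", scanner=default_ctx.scanner
        )
        assert ivs and all(iv.seq_id == "chr1" for iv in ivs)
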
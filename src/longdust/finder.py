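"""Window scan for good low-complexity intervals.

An interval is a *good LC interval* when its score S is positive and no
proper prefix or suffix scores strictly higher; the union of all good LC
intervals marks the low-complexity regions of a genome.  Testing every
interval is O(w^2) per position, so the scanner uses a two-pass
approximation per end position j:

* ``backward`` walks from j toward the window start accumulating suffix
  scores S(i, j) incrementally and records candidate start positions --
  the positions where the running suffix maximum was attained.  While no
  positive suffix has been seen it also tracks the score of the suffix
  against the *full-window* counts and bails out once that drops below
  zero (a forward pass could then never reach j).
* ``forward`` rescans from a candidate start with fresh counts and
  returns the end position maximising the prefix score; the candidate
  yields a good interval exactly when that argmax is j itself.

Two cheap heuristics speed up the genome scan: a position j is skipped
outright when the k-mer ending at j is unique in the current window, and
a window-saturated interval ending at j-1 is extended to j without a new
search when the incoming k-mer is already repeated in the window.  An
optional X-drop pass splits reported intervals where the running score
falls more than ``xdrop`` nats below its maximum, trimming random spacers
trapped between repeats.

Scanning both strands and emitting the union of calls makes the output
invariant under reverse complementation of the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alt_scoring import ScorerKind, scorer_tables
from .model import (
    FrequencyModel,
    ModelParams,
    ScalingTable,
    build_frequency_model,
    build_scaling_table,
    encode_bases,
    kmer_codes,
    revcomp,
)

__all__ = [
    "LcInterval",
    "CandidateStart",
    "Scanner",
    "scan_sequence",
    "symmetrize",
    "find_lc_intervals",
    "merge_intervals",
]


@dataclass(frozen=True)
class LcInterval:
    """A low-complexity call on a named sequence, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CandidateStart:
    """Candidate interval start emitted by the backward pass.

    ``pos`` is a k-mer-end index within the scanned segment; ``vbound``
    the (positive) running suffix-score maximum recorded at emission.
    """

    pos: int
    vbound: float


def merge_intervals(
    intervals: Sequence[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Union of half-open intervals; overlapping or adjacent runs merge."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    out = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1][1] = e
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


class Scanner:
    """Reusable scanning state for one parameter set.

    Builds (or accepts) the frequency model and scaling table once and
    keeps scratch count arrays so repeated calls over many sequences do
    not reallocate the 4^k count space.
    """

    def __init__(
        self,
        params: ModelParams,
        freq: FrequencyModel | None = None,
        table: ScalingTable | None = None,
        scorer: ScorerKind = ScorerKind.LONGDUST,
    ):
        self.params = params
        self.freq = freq if freq is not None else build_frequency_model(params)
        self.table = (
            table
            if table is not None
            else build_scaling_table(params, self.freq)
        )
        self.scorer = scorer
        gain, pen = scorer_tables(scorer, params, self.table)
        self._gain: list[float] = [float(x) for x in gain]
        self._pen: list[float] = [float(x) for x in pen]
        self._scratch: list[int] = [0] * (4**params.k)

    # ------------------------------------------------------------------
    # Algorithm core: one end position
    # ------------------------------------------------------------------

    def backward(
        self, j: int, codes: Sequence[int], window_counts: Sequence[int]
    ) -> list[CandidateStart]:
        """Collect candidate start positions for an interval ending at j.

        ``codes`` holds k-mer codes per end position within the segment;
        ``window_counts`` the full-window counts c'[t] over the w bases
        ending at j.  Candidates come back in ascending position order
        with positive score bounds.
        """
        p = self.params
        k, w, T = p.k, p.w, p.T
        gain, pen = self._gain, self._pen
        c = self._scratch
        touched: list[int] = []
        lo = max(j - w + 1, k - 1)
        u = 0.0
        v0 = -1.0
        uprime = 0.0
        vmax = 0.0
        imax = -1
        raw: list[tuple[int, float]] = []
        for i in range(j, lo - 1, -1):
            t = codes[i]
            ct = c[t] + 1
            c[t] = ct
            if ct == 1:
                touched.append(t)
            u += gain[ct] - T
            v = u - pen[j - i + 1]  # v = S(i-k+1, j)
            if v < v0 and v0 == vmax:
                if vmax > 0.0:
                    raw.append((i + 1, vmax))
            elif v >= vmax:
                vmax = v
                imax = i
            elif imax < 0:
                cw = window_counts[t]
                if cw <= 0:
                    break
                uprime += gain[cw] - T
                if uprime < 0.0:  # forward could not reach j
                    break
            v0 = v
        for t in touched:
            c[t] = 0
        if imax >= 0 and vmax > 0.0:
            raw.append((imax, vmax))
        raw.sort()
        out: list[CandidateStart] = []
        for pos, vb in raw:
            if out and out[-1].pos == pos:
                if vb > out[-1].vbound:
                    out[-1] = CandidateStart(pos, vb)
            else:
                out.append(CandidateStart(pos, vb))
        return out

    def forward(
        self, i0: int, j: int, vbound: float, codes: Sequence[int]
    ) -> int:
        """Argmax end position of S(i0-k+1, .) scanning i0..j.

        Stops early once the prefix score exceeds ``vbound``: the whole
        interval could then not be good.  [i0, j] is good iff the return
        value equals j.
        """
        T = self.params.T
        gain, pen = self._gain, self._pen
        c = self._scratch
        touched: list[int] = []
        u = 0.0
        vmax = 0.0
        imax = -1
        for i in range(i0, j + 1):
            t = codes[i]
            ct = c[t] + 1
            c[t] = ct
            if ct == 1:
                touched.append(t)
            u += gain[ct] - T
            v = u - pen[i - i0 + 1]
            if v >= vmax:
                vmax = v
                imax = i
            if v > vbound:
                break
        for t in touched:
            c[t] = 0
        return imax

    def find_start(
        self, j: int, codes: Sequence[int], window_counts: Sequence[int]
    ) -> int:
        """Start (k-mer-end index) of the longest good LC interval ending
        at j, or -1.  The reported base interval is [start-k+1, j]."""
        jmax = -1
        for cand in self.backward(j, codes, window_counts):
            if cand.pos < jmax:
                # contained in a previous forward reach; approximation
                continue
            jp = self.forward(cand.pos, j, cand.vbound, codes)
            if jp == j:
                return cand.pos
            if jp > jmax:
                jmax = jp
        return -1

    # ------------------------------------------------------------------
    # Whole-sequence scan
    # ------------------------------------------------------------------

    def _scan_segment(self, codes: list[int], n: int) -> list[tuple[int, int]]:
        """Scan one ambiguity-free segment; returns base-inclusive runs of
        overlapping good-interval calls (the on-line union)."""
        p = self.params
        k, w = p.k, p.w
        use_ext = p.use_extension
        window: list[int] = [0] * (4**k)
        runs: list[tuple[int, int]] = []
        cur: list[int] | None = None
        for j in range(k - 1, n):
            t = codes[j]
            window[t] += 1
            ev = j - w + k - 1
            if ev >= k - 1:
                window[codes[ev]] -= 1
            if (
                use_ext
                and cur is not None
                and cur[1] == j - 1
                and cur[0] <= j - w
                and window[t] >= 2
            ):
                # window-saturated good interval: extend without a search
                cur[1] = j
                continue
            if window[t] == 1:
                continue  # k-mer unique in window: j cannot end a call
            i = self.find_start(j, codes, window)
            if i >= 0:
                s = i - k + 1
                if cur is not None and s <= cur[1] + 1:
                    if s < cur[0]:
                        cur[0] = s
                    cur[1] = j
                else:
                    if cur is not None:
                        runs.append((cur[0], cur[1]))
                    cur = [s, j]
        if cur is not None:
            runs.append((cur[0], cur[1]))
        return runs

    def raw_calls(self, seq: str) -> list[tuple[int, int]]:
        """Individual good-interval calls, base-inclusive, unmerged and
        without extension or X-drop: the scanner output in its purest
        form, for validation against the brute-force predicate."""
        k, w = self.params.k, self.params.w
        bc = encode_bases(seq)
        valid = bc >= 0
        calls: list[tuple[int, int]] = []
        boundaries = np.flatnonzero(np.diff(valid.astype(np.int8)))
        starts = [0] + (boundaries + 1).tolist()
        for a, b in zip(starts, starts[1:] + [len(seq)]):
            if not valid[a] or b - a < k:
                continue
            codes = kmer_codes(bc[a:b], k).tolist()
            window: list[int] = [0] * (4**k)
            for j in range(k - 1, b - a):
                t = codes[j]
                window[t] += 1
                ev = j - w + k - 1
                if ev >= k - 1:
                    window[codes[ev]] -= 1
                if window[t] == 1:
                    continue
                i = self.find_start(j, codes, window)
                if i >= 0:
                    calls.append((a + i - k + 1, a + j))
        return calls

    def xdrop_split(
        self, start: int, end: int, codes: Sequence[int]
    ) -> list[tuple[int, int]]:
        """Split a base-inclusive interval where the running prefix score
        drops more than ``xdrop`` nats below its maximum.

        Each emitted piece is truncated at the score maximum and trimmed
        from the left to its best-scoring suffix; pieces whose score is
        not positive are dropped.  With xdrop unset this is the identity.
        """
        X = self.params.xdrop
        if X is None:
            return [(start, end)]
        k, w, T = self.params.k, self.params.w, self.params.T
        gain, pen = self._gain, self._pen
        c = self._scratch
        touched: list[int] = []
        u = 0.0
        anchor = start
        base = 0.0  # profile value just before the current anchor
        vmax, imax = 0.0, -1
        falling = False
        vmin, pmin = 0.0, start - 1
        cand: list[tuple[int, int]] = []
        for i in range(start + k - 1, end + 1):
            t = codes[i]
            ct = c[t] + 1
            c[t] = ct
            if ct == 1:
                touched.append(t)
            u += gain[ct] - T
            ell = i - start - k + 2
            v = u - pen[ell if ell <= w else w]
            if not falling:
                if v >= vmax:
                    vmax, imax = v, i
                elif vmax > base and vmax - v > X:
                    # drop from a (relatively) positive peak; the leading
                    # unique k-mers of any interval dip below the anchor
                    # baseline and must not trigger a cut
                    cand.append((anchor, imax))
                    falling = True
                    vmin, pmin = v, i
            else:
                if v <= vmin:
                    vmin, pmin = v, i
                elif v - vmin > X:
                    # recovered: restart the next piece at the valley
                    anchor, base = pmin + 1, vmin
                    falling = False
                    vmax, imax = v, i
        for t in touched:
            c[t] = 0
        if not falling and imax >= 0 and vmax > base:
            cand.append((anchor, imax))
        out: list[tuple[int, int]] = []
        for a, b in cand:
            if b - a + 1 < k:
                continue
            piece = self._best_suffix(a, b, codes)
            if piece is not None:
                out.append(piece)
        return out

    def _best_suffix(
        self, p0: int, e: int, codes: Sequence[int]
    ) -> tuple[int, int] | None:
        """Best-scoring suffix [s, e] of [p0, e]; ties favour the longer
        suffix.  None when no suffix scores positive."""
        k, w, T = self.params.k, self.params.w, self.params.T
        gain, pen = self._gain, self._pen
        c = self._scratch
        touched: list[int] = []
        u = 0.0
        vmax = 0.0
        imax = -1
        for i in range(e, p0 + k - 2, -1):
            t = codes[i]
            ct = c[t] + 1
            c[t] = ct
            if ct == 1:
                touched.append(t)
            u += gain[ct] - T
            ell = e - i + 1
            v = u - pen[ell if ell <= w else w]
            if v >= vmax:
                vmax = v
                imax = i
        for t in touched:
            c[t] = 0
        if imax < 0 or vmax <= 0.0:
            return None
        return (imax - k + 1, e)

    def scan(self, seq: str) -> list[tuple[int, int]]:
        """Forward-strand scan; returns merged half-open base intervals.

        The sequence is split at non-ACGT characters and each segment is
        scanned independently, so no call ever spans an ambiguous base.
        """
        k = self.params.k
        bc = encode_bases(seq)
        valid = bc >= 0
        intervals: list[tuple[int, int]] = []
        # maximal runs of unambiguous bases
        boundaries = np.flatnonzero(np.diff(valid.astype(np.int8)))
        starts = [0] + (boundaries + 1).tolist()
        for a, b in zip(starts, starts[1:] + [len(seq)]):
            if not valid[a] or b - a < k:
                continue
            codes = kmer_codes(bc[a:b], k).tolist()
            for s, e in self._scan_segment(codes, b - a):
                for s2, e2 in self.xdrop_split(s, e, codes):
                    intervals.append((a + s2, a + e2 + 1))
        return merge_intervals(intervals)

    def scan_both(self, seq: str) -> list[tuple[int, int]]:
        """Strand-symmetric scan: union of forward and mapped reverse-
        complement calls."""
        fwd = self.scan(seq)
        return symmetrize_intervals(seq, fwd, self)


# ----------------------------------------------------------------------
# Functional surface
# ----------------------------------------------------------------------


def scan_sequence(
    seq: str,
    params: ModelParams,
    table: ScalingTable | None = None,
    freq: FrequencyModel | None = None,
    scorer: ScorerKind = ScorerKind.LONGDUST,
) -> list[tuple[int, int]]:
    """One-strand scan of a DNA string; half-open merged intervals."""
    return Scanner(params, freq=freq, table=table, scorer=scorer).scan(seq)


def symmetrize_intervals(
    seq: str,
    intervals_fwd: Sequence[tuple[int, int]],
    scanner: Scanner,
) -> list[tuple[int, int]]:
    """Union of forward calls with reverse-complement calls mapped back
    to forward coordinates; invariant under reverse complementation."""
    n = len(seq)
    rev = scanner.scan(revcomp(seq))
    mapped = [(n - e, n - s) for s, e in rev]
    return merge_intervals(list(intervals_fwd) + mapped)


def symmetrize(
    seq: str,
    intervals_fwd: Sequence[tuple[int, int]],
    params: ModelParams,
    table: ScalingTable | None = None,
    freq: FrequencyModel | None = None,
) -> list[tuple[int, int]]:
    scanner = Scanner(params, freq=freq, table=table)
    return symmetrize_intervals(seq, intervals_fwd, scanner)


def find_lc_intervals(
    seq: str,
    seq_id: str = "seq",
    params: ModelParams | None = None,
    scanner: Scanner | None = None,
) -> list[LcInterval]:
    """Full pipeline on one sequence, honouring ``params.both_strands``."""
    if scanner is None:
        scanner = Scanner(params if params is not None else ModelParams())
    raw = (
        scanner.scan_both(seq)
        if scanner.params.both_strands
        else scanner.scan(seq)
    )
    return [LcInterval(seq_id, s, e) for s, e in raw]
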
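"""Brute-force reference for the interval scanner.

Enumerates every interval of up to w bases, scores each from scratch and
applies the good/perfect low-complexity predicates directly.  O(w^2 * L)
overall, so restricted to short test sequences; this is the ground truth
the scanner's incremental bookkeeping is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    FrequencyModel,
    ModelParams,
    ScalingTable,
    encode_bases,
    kmer_codes,
)

__all__ = ["OracleResult", "enumerate_good_intervals", "score_from_scratch"]

# strictly-higher comparisons tolerate float noise from different
# summation orders between incremental and from-scratch scoring
_EPS = 1e-9

# enumeration is quadratic in w; keep the test surface honest but quick
_MAX_SEQ = 2000
_MAX_W = 200


@dataclass(frozen=True)
class OracleResult:
    """Exhaustive enumeration output.

    good / perfect hold (start, end, score) with half-open base
    coordinates; mask is the boolean union coverage of the good set.
    """

    good: list[tuple[int, int, float]]
    perfect: list[tuple[int, int, float]]
    mask: np.ndarray

    @property
    def coverage(self) -> int:
        return int(self.mask.sum())


def score_from_scratch(
    seq: str,
    i: int,
    j: int,
    params: ModelParams,
    table: ScalingTable,
    freq: FrequencyModel | None = None,
) -> float:
    """S of the base-inclusive interval [i, j], counted from a fresh
    table; ground truth for the scanner's incremental accumulation."""
    k = params.k
    if not (0 <= i and i + k - 1 <= j < len(seq)):
        raise IndexError(
            f"interval [{i}, {j}] out of range or shorter than k={k}"
        )
    codes = kmer_codes(encode_bases(seq[i : j + 1]), k)[k - 1 :]
    if (codes < 0).any():
        raise ValueError("interval contains non-ACGT characters")
    ell = int(codes.size)
    if ell > table.w:
        raise ValueError(f"interval holds {ell} k-mers > table range {table.w}")
    counts = np.bincount(codes)
    counts = counts[counts > 1]
    return float(
        table.logfact[counts].sum() - params.T * ell - table.f[ell]
    )


def enumerate_good_intervals(
    seq: str,
    params: ModelParams,
    table: ScalingTable,
    freq: FrequencyModel | None = None,
) -> OracleResult:
    """All good (and perfect) LC intervals of up to w bases.

    good:    S > 0 and no proper prefix or suffix scores strictly higher;
    perfect: S > 0 and no substring scores strictly higher.
    Every perfect interval is good by definition.
    """
    if len(seq) > _MAX_SEQ or params.w > _MAX_W:
        raise ValueError(
            f"oracle is capped at |seq| <= {_MAX_SEQ}, w <= {_MAX_W}"
        )
    k, w, T = params.k, params.w, params.T
    n = len(seq)
    codes = kmer_codes(encode_bases(seq), k)
    if n >= k and (codes[k - 1 :] < 0).any():
        raise ValueError("oracle requires an ambiguity-free sequence")
    mask = np.zeros(n, dtype=bool)
    if n < k:
        return OracleResult([], [], mask)
    codes_l = codes.tolist()
    gain = [0.0] + np.log(np.arange(1, w + 2)).tolist()
    f = table.f
    lmax = w - k + 1  # k-mer length cap: intervals up to w bases
    # S[a, b] for start base a, end k-mer index b (base end = b)
    S = np.full((n, n), -np.inf)
    scratch = [0] * (4**k)
    for a in range(0, n - k + 1):
        u = 0.0
        touched = []
        hi = min(n - 1, a + k - 1 + lmax - 1)
        for b in range(a + k - 1, hi + 1):
            t = codes_l[b]
            ct = scratch[t] + 1
            scratch[t] = ct
            if ct == 1:
                touched.append(t)
            u += gain[ct] - T
            S[a, b] = u - f[b - a - k + 2]
        for t in touched:
            scratch[t] = 0
    good: list[tuple[int, int, float]] = []
    # prefix max along rows (excluding the cell itself), suffix max along
    # columns: an interval is good iff its score is >= both within _EPS
    pref = np.maximum.accumulate(np.where(np.isfinite(S), S, -np.inf), axis=1)
    suff = np.maximum.accumulate(S[::-1, :], axis=0)[::-1, :]
    for a in range(0, n - k + 1):
        hi = min(n - 1, a + k - 1 + lmax - 1)
        for b in range(a + k - 1, hi + 1):
            s = S[a, b]
            if s <= 0.0:
                continue
            if b > a + k - 1 and pref[a, b - 1] > s + _EPS:
                continue  # a proper prefix scores higher
            if a < b - k + 1 and suff[a + 1, b] > s + _EPS:
                continue  # a proper suffix scores higher
            good.append((a, b + 1, float(s)))
            mask[a : b + 1] = True
    # substring max via DP over the band for the perfect predicate
    perfect: list[tuple[int, int, float]] = []
    M = np.where(np.isfinite(S), S, -np.inf)
    for length in range(k, min(n, w) + 1):
        # M[a, b] for b - a + 1 == length incorporates shorter substrings
        a_idx = np.arange(0, n - length + 1)
        b_idx = a_idx + length - 1
        if length > k:
            inner = np.maximum(M[a_idx + 1, b_idx], M[a_idx, b_idx - 1])
            M[a_idx, b_idx] = np.maximum(M[a_idx, b_idx], inner)
    for a, b1, s in good:
        b = b1 - 1
        if M[a, b] <= s + _EPS:
            perfect.append((a, b1, s))
    return OracleResult(good, perfect, mask)
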
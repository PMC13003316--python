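"""Statistical model of k-mer counts for low-complexity scoring.

A DNA string is modelled as a bag of k-mers drawn from a multinomial
distribution whose per-k-mer frequencies derive from the genome-wide GC
content.  The complexity score of a string x is

    Q(x) = sum_t log c_x(t)! - f(l(x))

where c_x(t) is the count of k-mer t in x, l(x) = |x| - k + 1 the number of
k-mers, and f(l) the Poisson-approximated null expectation of the first
term.  Q is close to zero for random strings of any length and grows for
repetitive strings.  Thresholding gives the interval score

    S(x) = Q(x) - T * l(x)

which is positive exactly when x contains a low-complexity stretch denser
than the per-k-mer budget T (in nats).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import poisson

__all__ = [
    "ModelParams",
    "FrequencyModel",
    "KmerCounts",
    "ScalingTable",
    "build_frequency_model",
    "build_scaling_table",
    "score_Q",
    "score_S",
    "min_exact_copies",
    "min_copies_constant",
    "encode_bases",
    "kmer_codes",
    "revcomp",
]

LOG4 = math.log(4.0)

# 2-bit base encoding; anything else is ambiguous (-1).
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_RC = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes A=0, C=1, G=2, T=3; -1 for non-ACGT."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def kmer_codes(base_codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mer codes; entry i is the k-mer ending at base i.

    Entries for i < k-1 or for windows touching an ambiguous base are -1.
    """
    n = base_codes.size
    out = np.full(n, -1, dtype=np.int64)
    if n < k:
        return out
    b = base_codes.astype(np.int64)
    valid = b >= 0
    code = np.zeros(n, dtype=np.int64)
    mask = (1 << (2 * k)) - 1
    # rolling 2-bit shift; cheap python loop only over k to stay vectorised
    shifted = np.zeros(n, dtype=np.int64)
    for off in range(k):
        shifted[k - 1 :] = b[off : n - k + 1 + off] << (2 * (k - 1 - off))
        code[k - 1 :] += shifted[k - 1 :]
    code &= mask
    ok = np.ones(n, dtype=bool)
    for off in range(k):
        ok[k - 1 :] &= valid[off : n - k + 1 + off]
    out[k - 1 :] = np.where(ok[k - 1 :], code[k - 1 :], -1)
    out[: k - 1] = -1
    return out


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the scoring model and the scanning algorithm.

    k       k-mer length (1..12).
    w       context window size in bases; repeats with context longer than
            w are recovered by merging window-sized calls.
    T       complexity threshold in nats per k-mer; must stay below log 4
            so that the per-base score of a random string is negative.
    gc      genome G+C fraction in (0, 1); drives the k-mer null
            frequencies.
    xdrop   optional X-drop threshold in nats; None disables the
            interval-splitting post-process.
    both_strands   scan forward and reverse-complement strands and emit
            the union (strand-symmetric output).
    use_extension  enable the cheap window-saturated extension heuristic.
    """

    k: int = 7
    w: int = 5000
    T: float = 0.6
    gc: float = 0.5
    xdrop: float | None = None
    both_strands: bool = True
    use_extension: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.k <= 12):
            raise ValueError(f"k must be in [1, 12], got {self.k}")
        if self.w < self.k:
            raise ValueError(f"w must be >= k, got w={self.w}, k={self.k}")
        if not (0.0 < self.T < LOG4):
            raise ValueError(
                f"T must lie in (0, log 4 = {LOG4:.4f}), got {self.T}"
            )
        if not (0.0 < self.gc < 1.0):
            raise ValueError(f"gc must lie in (0, 1), got {self.gc}")
        if self.xdrop is not None and self.xdrop <= 0:
            raise ValueError("xdrop must be positive or None")


@dataclass(frozen=True)
class FrequencyModel:
    """Null k-mer frequencies under the independent-base GC model.

    Each base is drawn independently with P(G) = P(C) = gc/2 and
    P(A) = P(T) = (1-gc)/2, so the frequency of a k-mer depends only on
    its number m of G/C bases:

        q_m = (gc/2)^m * ((1-gc)/2)^(k-m)

    and there are C(k, m) * 2^k k-mers in GC-group m.  The scaled
    frequency r_t = 4^k * q_t equals 1 everywhere at gc = 0.5.
    """

    k: int
    gc: float
    group_q: np.ndarray = field(repr=False)  # q for m = 0..k
    group_size: np.ndarray = field(repr=False)  # k-mers per group

    def gc_count(self, code: int) -> int:
        """Number of G/C bases in a 2-bit encoded k-mer."""
        m = 0
        for _ in range(self.k):
            b = code & 3
            m += (b ^ (b >> 1)) & 1  # 1 for C (01) and G (10)
            code >>= 2
        return m

    def q_of(self, code: int) -> float:
        return float(self.group_q[self.gc_count(code)])

    def r_of(self, code: int) -> float:
        return float(4**self.k) * self.q_of(code)

    def q_array(self) -> np.ndarray:
        """Materialise q_t for all 4^k k-mers (small k only)."""
        if self.k > 10:
            raise ValueError("q_array is only materialised for k <= 10")
        codes = np.arange(4**self.k, dtype=np.int64)
        m = np.zeros_like(codes)
        c = codes.copy()
        for _ in range(self.k):
            b = c & 3
            m += (b ^ (b >> 1)) & 1
            c >>= 2
        return self.group_q[m]


def build_frequency_model(params: ModelParams) -> FrequencyModel:
    k, gc = params.k, params.gc
    ms = np.arange(k + 1)
    group_q = (gc / 2.0) ** ms * ((1.0 - gc) / 2.0) ** (k - ms)
    group_size = np.array(
        [math.comb(k, int(m)) * 2**k for m in ms], dtype=np.int64
    )
    return FrequencyModel(k=k, gc=gc, group_q=group_q, group_size=group_size)


def expected_log_factorial(lam: np.ndarray | float) -> np.ndarray:
    """E[log N!] for N ~ Poisson(lam), elementwise.

    The sum over n starts at 2 (log 0! = log 1! = 0) and is truncated at
    the Poisson tail: n <= ceil(lam) + 20*sqrt(lam) + 50, beyond which the
    remaining mass is far below 1e-12 of the total.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    out = np.zeros_like(lam)
    pos = lam > 0
    lm = lam[pos]
    if lm.size:
        lmax = float(lm.max())
        ncap = int(math.ceil(lmax) + 20.0 * math.sqrt(lmax) + 50)
        ns = np.arange(2, ncap + 1)
        lf = gammaln(ns + 1.0)
        acc = np.empty_like(lm)
        step = max(1, 2_000_000 // ns.size)
        for s in range(0, lm.size, step):
            chunk = lm[s : s + step, None]
            acc[s : s + step] = poisson.pmf(ns[None, :], chunk) @ lf
        out[pos] = acc
    return out


@dataclass(frozen=True)
class ScalingTable:
    """Precomputed f(l) and log-factorial tables for l = 0..w.

    f(l) is the null expectation of sum_t log c(t)! for a random string
    holding l k-mers; subtracting it centres Q at zero.  logfact[n] is
    log n!, and loggain[c] = log c is the incremental change of
    sum log c(t)! when a k-mer count steps from c-1 to c.
    """

    w: int
    f: np.ndarray = field(repr=False)
    logfact: np.ndarray = field(repr=False)
    loggain: np.ndarray = field(repr=False)


def build_scaling_table(
    params: ModelParams, freq: FrequencyModel
) -> ScalingTable:
    w = params.w
    ells = np.arange(w + 1, dtype=float)
    f = np.zeros(w + 1)
    # q takes only k+1 distinct values: group k-mers by their GC count
    for q, n_m in zip(freq.group_q, freq.group_size):
        f += float(n_m) * expected_log_factorial(ells * float(q))
    f[0] = 0.0
    ns = np.arange(w + 2, dtype=float)
    logfact = gammaln(ns[: w + 1] + 1.0)
    loggain = np.zeros(w + 2)
    loggain[1:] = np.log(ns[1:])
    return ScalingTable(w=w, f=f, logfact=logfact, loggain=loggain)


def scaling_function_direct(
    freq: FrequencyModel, ells: np.ndarray
) -> np.ndarray:
    """f(l) by summing the Poisson expectation over all 4^k k-mers
    individually; reference for the grouped computation (small k only)."""
    q = freq.q_array()
    out = np.zeros(len(ells))
    for i, ell in enumerate(ells):
        out[i] = expected_log_factorial(float(ell) * q).sum()
    return out


class KmerCounts:
    """Rolling count vector over the 4^k k-mer space.

    Attributes
    ----------
    c : ndarray of int64, length 4^k, counts per 2-bit-encoded k-mer
    l : total number of k-mers currently counted
    """

    __slots__ = ("k", "c", "l")

    def __init__(self, k: int):
        self.k = k
        self.c = np.zeros(4**k, dtype=np.int64)
        self.l = 0

    def add(self, code: int) -> int:
        self.c[code] += 1
        self.l += 1
        return int(self.c[code])

    def remove(self, code: int) -> int:
        if self.c[code] <= 0:
            raise ValueError(f"removing absent k-mer code {code}")
        self.c[code] -= 1
        self.l -= 1
        return int(self.c[code])

    @classmethod
    def from_string(cls, seq: str, k: int) -> "KmerCounts":
        """Count all k-mers of a contiguous ACGT string."""
        self = cls(k)
        codes = kmer_codes(encode_bases(seq), k)
        codes = codes[k - 1 :]
        if codes.size and (codes < 0).any():
            raise ValueError("sequence contains non-ACGT characters")
        np.add.at(self.c, codes, 1)
        self.l = int(codes.size)
        return self


def score_Q(counts: KmerCounts, table: ScalingTable) -> float:
    """Complexity score Q = sum_t log c(t)! - f(l), in nats."""
    if counts.l > table.w:
        raise ValueError(
            f"string holds {counts.l} k-mers, beyond the table range {table.w}"
        )
    nz = counts.c[counts.c > 1]
    return float(table.logfact[nz].sum() - table.f[counts.l])


def score_S(counts: KmerCounts, table: ScalingTable, T: float) -> float:
    """Thresholded score S = Q - T*l; S > 0 flags a low-complexity stretch."""
    return score_Q(counts, table) - T * counts.l


def min_copies_constant(T: float) -> float:
    """Unit-length-independent part of the minimum detectable copy number."""
    return 3.0 + (3.0 * T - math.log(2.0) - math.log(3.0)) / (LOG4 - T)


def min_exact_copies(params: ModelParams, r: float) -> float:
    """Approximate minimum number of exact copies of an r bp repeat unit
    that the scanner can detect.

    Assumes r > k, f() negligible over the array, and all k-mers within
    one unit distinct:

        3 + (k-1)/r + (3T - log 2 - log 3) / (log 4 - T)

    At the default T = 0.6 the unit-independent part is about 3.01, so
    three exact copies sit right at the detection boundary and four are
    comfortably detectable.
    """
    if r <= params.k:
        raise ValueError(
            f"formula assumes unit length r > k (r={r}, k={params.k})"
        )
    return min_copies_constant(params.T) + (params.k - 1) / r
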
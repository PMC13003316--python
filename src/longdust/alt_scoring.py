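"""Alternative complexity scorers: the SDUST score and Shannon entropy.

Both are per-k-mer-normalised scores over the same count vectors as the
main model and are provided for comparison.  The SDUST score

    S_S = (1/l) * sum_t c(t) (c(t)-1)/2 - T

grows linearly with string length on a fixed-period repeat, which biases
SDUST toward classifying long strings as low complexity.  The entropy
score, defined for l <= 4^k,

    S_E = log l - H(c) - T = (1/l) * sum_t c(t) log c(t) - T

with H the Shannon entropy of the empirical k-mer distribution, grows
logarithmically like the main score but lacks its length calibration.

Each scorer also exposes an *extensive* incremental form (gain table and
length penalty) so it can drive the interval scanner: the extensive score
is l times the normalised one, which preserves the sign and hence the
low-complexity predicate.
"""

from __future__ import annotations

import enum

import numpy as np

from .model import KmerCounts, ModelParams, ScalingTable

__all__ = [
    "ScorerKind",
    "score_sdust",
    "score_entropy",
    "shannon_entropy",
    "scorer_tables",
]


class ScorerKind(enum.Enum):
    """Selectable complexity scorers; LONGDUST is the default model."""

    LONGDUST = "longdust"
    SDUST = "sdust"
    ENTROPY = "entropy"


def score_sdust(counts: KmerCounts, T: float) -> float:
    """SDUST complexity score (1/l) sum_t c(c-1)/2 - T.

    The published SDUST program hardcodes k = 3; any k is accepted here
    since the score itself is k-agnostic.  An empty string scores -T by
    the empty-sum convention.
    """
    if counts.l == 0:
        return -T
    c = counts.c[counts.c > 1].astype(float)
    return float((c * (c - 1.0) / 2.0).sum() / counts.l - T)


def shannon_entropy(counts: KmerCounts) -> float:
    """Shannon entropy of the empirical k-mer distribution, in nats."""
    if counts.l == 0:
        raise ValueError("entropy of an empty count vector is undefined")
    c = counts.c[counts.c > 0].astype(float)
    p = c / counts.l
    return float(-(p * np.log(p)).sum())


def score_entropy(counts: KmerCounts, T: float) -> float:
    """Entropy-based score log l - H - T = (1/l) sum_t c log c - T.

    Only defined for l <= 4^k, where the entropy can reach log l.
    """
    if counts.l == 0:
        return -T
    if counts.l > 4**counts.k:
        raise ValueError(
            f"entropy score requires l <= 4^k (l={counts.l}, k={counts.k})"
        )
    c = counts.c[counts.c > 1].astype(float)
    return float((c * np.log(c)).sum() / counts.l - T)


def scorer_tables(
    kind: ScorerKind, params: ModelParams, table: ScalingTable
) -> tuple[np.ndarray, np.ndarray]:
    """Incremental (gain, penalty) tables for the interval scanner.

    ``gain[c]`` is the change of the extensive score numerator when a
    k-mer count steps from c-1 to c; ``penalty[l]`` is subtracted from the
    accumulated numerator at k-mer length l.  For every scorer the
    extensive score of an interval is positive iff the scorer flags it as
    low-complexity.
    """
    w = params.w
    n = np.arange(w + 2, dtype=float)
    if kind is ScorerKind.LONGDUST:
        return table.loggain, table.f
    if kind is ScorerKind.SDUST:
        # sum c(c-1)/2 increments by c-1
        gain = np.maximum(n - 1.0, 0.0)
        return gain, np.zeros(w + 1)
    if kind is ScorerKind.ENTROPY:
        if params.w > 4**params.k:
            raise ValueError(
                "entropy scorer requires w <= 4^k so that every scanned "
                f"interval satisfies l <= 4^k (w={params.w}, k={params.k})"
            )
        # sum c log c increments by c log c - (c-1) log(c-1)
        clogc = np.zeros(w + 2)
        clogc[1:] = n[1:] * np.log(n[1:])
        gain = np.diff(clogc, prepend=0.0)
        return gain, np.zeros(w + 1)
    raise ValueError(f"unknown scorer kind: {kind!r}")
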
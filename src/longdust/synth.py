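"""Synthetic DNA generator: i.i.d. background with planted tandem arrays.

Backgrounds are i.i.d. with P(G) = P(C) = gc/2, the null model of the
scorer.  A planted repeat is ``copies`` concatenated copies of a random
unit of length ``unit_length``, optionally degraded by per-base
substitutions and indels -- the regime of satellite and tandem-repeat
arrays (alpha satellite has ~170 bp units).  The emitted truth BED is in
post-indel coordinates so it aligns with the generated sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fastaio import SequenceRecord

__all__ = ["RepeatSpec", "SyntheticSpec", "generate_synthetic"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RepeatSpec:
    """One tandem array planted at ``position`` of the background.

    The array nominally occupies ``unit_length * copies`` bases starting
    at ``position``; indels change its realised length and shift all
    downstream coordinates.
    """

    unit_length: int
    copies: int
    position: int
    sub_rate: float = 0.0
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.unit_length < 1 or self.copies < 1 or self.position < 0:
            raise ValueError("unit_length, copies >= 1 and position >= 0")
        for rate in (self.sub_rate, self.indel_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError("mutation rates must lie in [0, 1)")

    @property
    def nominal_length(self) -> int:
        return self.unit_length * self.copies


@dataclass(frozen=True)
class SyntheticSpec:
    length: int
    gc: float = 0.5
    repeats: tuple[RepeatSpec, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be non-negative")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must lie in (0, 1)")
        reps = tuple(sorted(self.repeats, key=lambda r: r.position))
        object.__setattr__(self, "repeats", reps)
        prev_end = 0
        for rep in reps:
            if rep.position < prev_end:
                raise ValueError("planted repeats overlap")
            prev_end = rep.position + rep.nominal_length
        if prev_end > self.length:
            raise ValueError("planted repeats exceed the total length")


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)]) if n else ""


def _mutate(rng: np.random.Generator, seq: str, rep: RepeatSpec) -> str:
    if rep.sub_rate == 0.0 and rep.indel_rate == 0.0:
        return seq
    out: list[str] = []
    for ch in seq:
        if rep.indel_rate > 0.0 and rng.random() < rep.indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(str(_BASES[rng.integers(4)]))  # insertion before
        if rep.sub_rate > 0.0 and rng.random() < rep.sub_rate:
            others = [b for b in "ACGT" if b != ch]
            out.append(others[rng.integers(3)])
        else:
            out.append(ch)
    return "".join(out)


def generate_synthetic(
    spec: SyntheticSpec, seq_id: str = "synthetic"
) -> tuple[SequenceRecord, list[tuple[int, int]]]:
    """Generate the sequence and the truth intervals of planted arrays.

    Returns (record, truth) where truth holds half-open coordinates of
    each realised array in the emitted sequence.  Fully deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    bg = _random_dna(rng, spec.length, spec.gc)
    parts: list[str] = []
    truth: list[tuple[int, int]] = []
    cursor = 0  # position in the background
    out_len = 0
    for rep in spec.repeats:
        parts.append(bg[cursor : rep.position])
        out_len += rep.position - cursor
        unit = _random_dna(rng, rep.unit_length, spec.gc)
        array = _mutate(rng, unit * rep.copies, rep)
        parts.append(array)
        truth.append((out_len, out_len + len(array)))
        out_len += len(array)
        cursor = rep.position + rep.nominal_length
    parts.append(bg[cursor:])
    return SequenceRecord(id=seq_id, bases="".join(parts)), truth
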
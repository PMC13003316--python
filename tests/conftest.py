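import numpy as np
import pytest

from longdust import (
    ModelParams,
    Scanner,
    build_frequency_model,
    build_scaling_table,
)

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


class Ctx:
    """A parameter set with its frequency model, scaling table and a
    reusable scanner."""

    def __init__(self, params: ModelParams):
        self.params = params
        self.freq = build_frequency_model(params)
        self.table = build_scaling_table(params, self.freq)
        self.scanner = Scanner(params, freq=self.freq, table=self.table)

    def scanner_with(self, **overrides) -> Scanner:
        import dataclasses

        p = dataclasses.replace(self.params, **overrides)
        return Scanner(p, freq=self.freq, table=self.table)


@pytest.fixture(scope="session")
def default_ctx() -> Ctx:
    """Default model: k=7, w=5000, T=0.6, gc=0.5."""
    return Ctx(ModelParams())


@pytest.fixture(scope="session")
def small_ctx() -> Ctx:
    """Small model used against the brute-force oracle: k=5, w=60,
    heuristics off."""
    return Ctx(ModelParams(k=5, w=60, use_extension=False))


def incremental_score(seq: str, a: int, b: int, ctx: Ctx) -> float:
    """S(a, b) by a dict-based from-scratch accumulation, independent of
    the scanner's array bookkeeping.  Base-inclusive coordinates."""
    import math

    k, T = ctx.params.k, ctx.params.T
    counts: dict[str, int] = {}
    u = 0.0
    ell = 0
    for i in range(a + k - 1, b + 1):
        t = seq[i - k + 1 : i + 1]
        counts[t] = counts.get(t, 0) + 1
        u += math.log(counts[t]) - T
        ell += 1
    return u - float(ctx.table.f[ell])


def good_predicate(seq: str, a: int, b: int, ctx: Ctx, eps: float = 1e-9):
    """Is [a, b] (base-inclusive) a good LC interval?  Checks S > 0 and
    that no proper prefix or suffix scores strictly higher, each profile
    recomputed from fresh counts."""
    import math

    k, T = ctx.params.k, ctx.params.T
    f = ctx.table.f
    S = incremental_score(seq, a, b, ctx)
    if S <= 0:
        return False, f"S={S:.4f} <= 0"
    # prefix profile from a
    counts: dict[str, int] = {}
    u = 0.0
    ell = 0
    for i in range(a + k - 1, b):
        t = seq[i - k + 1 : i + 1]
        counts[t] = counts.get(t, 0) + 1
        u += math.log(counts[t]) - T
        ell += 1
        if u - f[ell] > S + eps:
            return False, f"prefix ending {i} scores {u - f[ell]:.4f} > S"
    # suffix profile to b
    counts = {}
    u = 0.0
    ell = 0
    for i in range(b, a + k - 1, -1):
        t = seq[i - k + 1 : i + 1]
        counts[t] = counts.get(t, 0) + 1
        u += math.log(counts[t]) - T
        ell += 1
        if u - f[ell] > S + eps:
            return False, f"suffix starting {i - k + 1} scores > S"
    return True, ""


def planted_suite(n_seqs: int = 100):
    """Seeded 300 bp sequences with one degraded tandem array each,
    cycling over short unit lengths; the shared oracle-vs-scanner test
    bed."""
    from longdust import RepeatSpec, SyntheticSpec, generate_synthetic

    units = [3, 5, 8, 12]
    out = []
    for seed in range(n_seqs):
        u = units[seed % len(units)]
        copies = max(2, 80 // u)
        spec = SyntheticSpec(
            length=300,
            repeats=(RepeatSpec(u, copies, 100, sub_rate=0.05, indel_rate=0.02),),
            seed=seed,
        )
        rec, truth = generate_synthetic(spec)
        out.append((rec.bases, truth))
    return out
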
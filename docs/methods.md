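# Methods

## Model

A DNA string x is reduced to its k-mer count vector c over the 4^k
possible k-mers; ℓ(x) = |x| − k + 1 is the number of k-mers. Under the
null, counts are multinomial with frequencies q_t, and the score

    Q(c) = Σ_t log c(t)! − f(ℓ)

measures how much more "clumped" the counts are than a random string of
the same length: Σ log c! is zero while all counts are 0/1 and grows
superlinearly as counts concentrate, and f(ℓ) is its null expectation,
so Q ≈ 0 on random input regardless of length. A deliberate property of
this choice is that only k-mer *repetitiveness* contributes: a string of
rare-but-unique k-mers is not low complexity. The thresholded interval
score is S = Q − T·ℓ.

### Null frequencies from GC content

q_t is taken from an independent-base model with P(G) = P(C) = gc/2 and
P(A) = P(T) = (1 − gc)/2, the only model in which q_t is a function of
GC alone. q_t then depends only on the number m of G/C bases in t, so
the 4^k k-mers collapse into k + 1 groups of size C(k, m)·2^k — this is
what makes the f table cheap to build at any k. The gc parameter is the
genome-wide G+C fraction, estimated once over all input records
(A/C/G/T bases only) unless overridden. Windowed or higher-order
(Markov) backgrounds are out of scope.

### The scaling function f

f(ℓ) = Σ_t E[log N_t!] with N_t ~ Poisson(ℓ q_t) (Poisson approximation
to the binomial marginals). Each expectation is evaluated by direct
summation over n = 2, 3, … with the tail truncated at
n ≤ ⌈λ⌉ + 20√λ + 50; the discarded Poisson mass is far below 1e−12 of
the total, and the pmf is evaluated in a numerically stable form so the
table is accurate for λ from 1e−4 up to thousands. f is precomputed for
integer ℓ ∈ [0, w] at model build time (ℓ is always an integer) and a
log-factorial table up to w replaces transcendental calls in the inner
loops. A direct per-k-mer evaluation (`scaling_function_direct`) exists
purely as a cross-check of the grouped computation; the two agree to
better than 1e−6.

f(ℓ) is ~0 for small ℓ at k = 7 and bends upward as ℓ approaches 4^k;
biased GC (either direction — f is symmetric in gc ↔ 1−gc) raises it,
which is why the model must know the genome's GC.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 7 | k-mer length; larger k sharpens repeat specificity, 1 ≤ k ≤ 12 |
| w | 5000 bp | context window; repeats with units up to ~w/3 are detectable, longer LC blocks emerge by merging |
| T | 0.6 nats | per-k-mer complexity budget; must stay below log 4 so random sequence scores negative; lower T masks more |
| gc | estimated | genome G+C fraction in (0, 1) |
| xdrop | off | interval-splitting threshold in nats; 25 is a reasonable value when enabled |
| both_strands | on | emit the union of forward- and reverse-strand calls |
| use_extension | on | window-saturated extension heuristic |

With T = 0.6 and exact repeat units of length r > k (all k-mers within a
unit distinct, f ≈ 0), the minimum detectable copy number is
3 + (k−1)/r + (3T − log 2 − log 3)/(log 4 − T) ≈ 3.01 + (k−1)/r.

## Interval search

A good LC interval has S > 0 and no prefix or suffix scoring strictly
higher. For each end position j the scanner runs a backward pass over
the window maintaining u ← u + log c(t) − T incrementally (the counts
telescope: adding a k-mer whose count becomes c contributes log c), so
v = u − f(ℓ) is the suffix score S(i−k+1, j); positions attaining the
running suffix maximum become candidate starts, recorded with that
maximum as a score bound. When no positive suffix has been seen, the
same accumulation against the full-window counts detects suffixes
enriched in window-unique k-mers and aborts early. A forward pass from
each candidate (in ascending order, skipping candidates strictly inside
a previous forward reach — a documented approximation) returns the
prefix-score argmax; the candidate is accepted iff that argmax is j.
Candidate emission requires a positive score bound, since a non-positive
suffix maximum can never produce S > 0. Ties in the running maxima are
resolved toward the latest position (≥ updates), and the good-interval
predicate correspondingly treats equal-scoring prefixes/suffixes as
non-disqualifying.

Genome scan heuristics: position j is skipped when the k-mer ending at j
is unique in the window (no forward pass could reach j); and when the
previous position produced a window-saturated good interval (start at or
before j − w) and the incoming k-mer is already repeated in the window,
the interval is extended to j without a new search. The backward pass
may reach k − 1 bases past the nominal window start, so single calls are
bounded by w + k − 1 bases; saturation is therefore tested as
start ≤ j − w. Overlapping and adjacent calls are merged into maximal
union intervals, which is how LC blocks longer than the window arise.
Sequences are split at every non-ACGT character; segments are scanned
independently, so no call spans an ambiguous base.

An O(w)-guaranteed variant (forward from the smallest candidate only) is
noted in the scan design but not exposed; the default candidate loop is
closer to the exact algorithm at essentially the same cost.

### X-drop splitting

The good-interval definition can trap a short random spacer between two
strong repeats inside one call. When `xdrop` is set, each merged call is
re-scored left to right and segmented by hysteresis: a cut is made where
the score profile falls more than X nats below its running peak, and the
next piece is re-anchored at the following valley once the profile
recovers X. The drop test is only armed once the peak exceeds the
piece's anchor baseline — every interval dips below its baseline across
the leading unique k-mers of its first repeat unit (about 0.6·r nats for
unit length r), and cutting there would erase the array. Each piece is
then trimmed to its best-scoring suffix under fresh counts and kept only
if that score is positive. With X unset the step is the identity; with
X = ∞ a good interval passes through unchanged. For profile positions
beyond ℓ = w the f-term is held at f(w); f varies slowly there and the
heuristic only compares nearby profile values. On synthetic satellite
genomes the masked total changes by well under 2% with X-drop on, so it
is disabled by default and opt-in.

### Strand symmetry

The scan itself is heuristic and not exactly strand symmetric. The
default pipeline scans the reverse complement as well, maps each call
[s, e) to [n − e, n − s), and emits the union; output is then invariant
under reverse complementation by construction (verified bitwise in the
tests).

## Alternative scorers

The SDUST score S_S = (1/ℓ) Σ c(c−1)/2 − T and the entropy score
S_E = (1/ℓ) Σ c log c − T (natural logs; defined for ℓ ≤ 4^k, enforced
as w ≤ 4^k) plug into the same scanner through per-count gain tables —
the extensive form ℓ·S of each score telescopes over k-mer insertions
exactly like U does. S_S grows linearly with ℓ on a periodic repeat
(slope 1/4 on a dinucleotide repeat) where the model score grows only
logarithmically per k-mer; this is the classical DUST length bias. The
SDUST *search* (perfect intervals via O(w³) list maintenance) is not
implemented; perfect intervals are only enumerated by the brute-force
oracle on small inputs.

## Synthetic data

The generator emulates the regimes the scanner is meant for: i.i.d.
background at a specified GC (the model's null) with planted tandem
arrays — a random unit of length r repeated c times, degraded by
per-base substitutions and indels at specified rates (alpha-satellite ≈
r=170, 5% divergence). Truth intervals are reported in post-indel
coordinates. It does not emulate genome-scale features: mosaic GC,
transposable elements, nested or diverged higher-order repeat structure,
or biased mutation spectra. Passing tests therefore demonstrate
correctness of the algorithm and its statistical calibration under the
stated model, not masking accuracy on real genomes.

## Numerical choices

- Scores are float64 throughout; incremental and from-scratch scoring
  agree to ~1e−12 per call, and every strictly-greater comparison in the
  test oracle carries a 1e−9 tolerance so summation order cannot flip a
  tie.
- The f-table truncation error is below 1e−9 per entry (checked against
  direct evaluation at small k).
- Degenerate inputs: sequences shorter than k yield no calls; empty
  count vectors score S = 0; ℓ beyond the table raises.
- The oracle caps enumeration at 2 kb sequences and w ≤ 200 to keep the
  suite fast; test problem sizes (100 × 300 bp oracle comparisons,
  100 × 10 kb null screens, 20 kb satellite genomes) were chosen to
  exercise every code path at desk scale.

## Limitations

Repeat units and copy numbers are not reported — only interval
boundaries. Repeats with fewer than ~3 copies are invisible by design
(see the minimum-copy formula), and repeat units longer than ~w/3 exceed
the window. The scan is approximate: a good interval starting strictly
inside another good interval can be missed (coverage against the
exhaustive oracle is ≥ 99% on the test suite, not 100%). Runtime is
O(wL) in the worst case and the pure-Python inner loops target
desk-scale inputs, not gigabase genomes.
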
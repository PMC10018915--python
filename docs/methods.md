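# Methods

This note documents the model behind seedchain, the numerical choices that
make the two chaining engines bit-comparable, what the synthetic data does
and does not emulate, and the limitations that follow.

## Anchors and coordinates

An anchor is one exact minimizer match, stored as a 3-tuple-plus-context:
`x` (0-based coordinate of the **last** base of the match on the reference),
`y` (same on the query) and span `w`. End coordinates were chosen so that
all gap arithmetic is a plain difference of ends: for a predecessor *i* and
successor *j*, `Δr = x_j − x_i`, `Δq = y_j − y_i`. Reverse-complement
matches carry query coordinates on the reverse-complemented read, so every
(reference sequence, strand) group is an ordinary collinear chaining
problem; PAF output converts back to the original read orientation. Anchor
sets are sorted lexicographically by (x, y) with a stable sort, which fixes
the meaning of every tie-break downstream.

## Scoring

A chainable pair requires `Δr > 0`, `Δq > 0`, `Δq ≤ max_dist_y`,
`Δr ≤ max_dist_x` and `|Δq − Δr| ≤ bandwidth`; everything else yields an
out-of-band NO_CHAIN signal (not a sentinel score, so legitimately negative
scores remain representable). The score contribution is

```
match   = min(Δq, Δr, w_j)            # capped by the successor's span
penalty = trunc(0.01 · w̄ · dd) + (ilog2(dd) >> 1),   dd = |Δq − Δr|
```

where `w̄` is the mean span of the whole anchor set, computed once before
the DP (float64), and `ilog2` is floor(log₂) with `ilog2(0) = 0` — the
arithmetic a leading-zero count yields on 32-bit integers. The float
product is truncated toward zero (C-cast semantics); since `dd ≥ 0` this
equals the floor. Both engines, the brute-force oracle and the tests use
this exact expression, so integer equality is meaningful. The linear term
makes near-bandwidth jitter expensive: at span 15, `dd = 100` already costs
more than a full match contributes, which matters for the synthetic-data
defaults below.

Defaults (`MapParams`): k = 15, wmin = 10 (a nanopore-style preset),
max gaps 5000, bandwidth 500, predecessor/successor cap 5000, probe deltas
{0, 16, 512, 1024, 2048, 3072, 4096, 5000}, scan-break heuristic off,
min_score 40, min_cnt 3, mask_level 0.5.

## Backward engine (the oracle)

For each anchor *j* in ascending order the scan runs from *j−1* down to the
start of the predecessor range (smallest index within `max_dist_x`, capped
at `max_range` predecessors). Updates happen on strict improvement only, so
with a descending scan the **nearest predecessor wins score ties**; this
tie-break is treated as normative throughout the package. `S[j]` is
initialised to `w_j` with no predecessor, so a candidate merely equal to
the anchor's own span never creates a link. With `max_skip` finite the scan
additionally terminates after that many consecutive non-improving valid
candidates — an early-exit speed heuristic that can only lose score, which
is exactly what the dominance test demonstrates (including a constructed
decoy set where the loss is strict). With `max_skip = None` the DP is
exhaustive within the range cap, and is itself validated against an O(n²)
all-pairs brute force written independently in plain Python.

`V[i]` caches the maximum of S along the chain from its start to *i* via
`V[i] = V[P[i]] if P[i] ≥ 0 and V[P[i]] > S[i] else S[i]`; tests verify it
against explicit path walks.

## Forward engine

Sources are processed in ascending order; when anchor *i* pushes, all
updates into *i* have already happened, so `S[i]`, `P[i]` — and therefore
`V[i]` — are final at that point. Each *i* pushes `s = S[i] + score(i, j)`
to every *j* in its successor range.

The update rule is the one genuinely open design point. The literal
push-side transcription would use `≥` for far successors but keep strict
`>` for the immediate neighbour `j = i+1`. Analysis of tie cases shows this
breaks equivalence: under ascending push order, `≥` is what lets a *nearer*
source overwrite an equal score (reproducing the backward tie-break), and
the immediate neighbour is the nearest source of all, so it must also be
allowed to overwrite ties. seedchain therefore applies one uniform rule to
every successor:

```
update iff  s > S[j]  or  (s == S[j] and S[j] != w_j)
```

The excluded case `s == S[j] == w_j` mirrors the backward initialisation
(never give a not-yet-chained anchor a predecessor on a tie with its own
span; note `S[j] == w_j ⇔ P[j] == −1` under this rule). The randomized
differential battery — which includes tie-rich grids precisely to hit these
cases — confirms bit-equality of S, P and V on every set.

### Successor ranges and the condensed workload

The successor range of *i* is the maximal run of following anchors within
`max_dist_x` on the reference, capped at `max_range`. Because x is sorted,
membership is a prefix property, so the probe heuristic — try offsets
{0, 16, 512, …, 5000} in ascending order, stop at the first out-of-range
probe (offsets past the end of the array count as out of range), then
decrement to the boundary — is exact, not approximate; a test compares it
against a one-step linear scan on every anchor of every battery set. Range
sizes are heavily skewed toward zero and small values on realistic inputs,
which is what the probe spacing exploits. Anchors with empty ranges are
dropped from the source list (the condensed workload vector); a dedicated
test confirms this never changes the chaining state. Only the batching
*policy* of grouping reads by length bins (1 kb bins to 10 kb, 5 kb bins to
50 kb, then 50–100 kb, 100–150 kb, open-ended) is implemented — it affects
processing order and observability, not values; no attempt is made to model
hardware dispatch, occupancy or memory behaviour, and no performance parity
with accelerator implementations is claimed.

## Backtracking, primary chains, mapq

Backtracking visits anchors in descending (S, index) order; from each
unused anchor with `S ≥ min_score` it follows predecessor links until
hitting a used anchor (truncation) or a chain start, consuming every anchor
it collects. A truncated chain scores `S[end] − S[truncation point]`
(floor 0). Chains need `min_cnt` anchors and `min_score` score to be
emitted; anchors of rejected walks stay consumed, preserving the global
no-reuse guarantee. Chain intervals are half-open,
`[end − span + 1, end + 1)` on both axes.

Primary identification processes chains in descending score: a chain is
primary iff its query overlap with every higher-scoring primary is below
`mask_level` times its own query length; a secondary records its
best-overlapping primary. Mapping quality of a primary with score f₁, best
overlapping secondary score f₂ and anchor count m is
`round(40·(1−f₂/f₁)·min(1, m/10)·ln f₁)` clamped to [0, 60] (secondaries
report 0); the formula is deliberately isolated in one function so it can
be swapped without touching chaining. Residue matches in PAF are
approximated by the summed anchor spans capped by the interval lengths —
without base-level alignment (a non-goal) an exact count does not exist.

## Seeding

Minimizer winnowing uses the canonical k-mer (lexicographic minimum of the
2-bit packed k-mer and its reverse complement; self-complementary k-mers
are skipped, which only matters for even k), a fixed invertible 64-bit
integer mix as hash, and the leftmost minimal hash per window of `wmin`
consecutive k-mer positions, each selected position reported once. Windows
are positional: k-mers covering non-ACGT characters are simply invalid
within their windows, and a window with no valid k-mer emits nothing; only
complete windows emit (sequences shorter than `k + wmin − 1` yield no
minimizers). The whole scheme is unseeded and deterministic, and is tested
against a brute-force window scan, both property-based over random
ACGTN strings and on long random sequences at the default preset. The index
is a CSR-style multimap (hash-sorted posting arrays, binary-searched); an
optional occurrence cutoff (`max_occ`, default off) drops over-represented
minimizers at query time.

## Synthetic data

Generators are pure functions of (spec, seed). `plant_chains` lays each
collinear run in its own query/reference segment (runs cannot merge), with
per-link query gaps uniform in [gap_mean/2, 3·gap_mean/2] and reference
gaps offset by at most `gap_jitter`; noise anchors are uniform over the
full rectangle, with the reference span scaled genome-like (~1 Mb per noise
anchor) so stray anchors are usually isolated — that is what makes the
successor-range vector sparse, qualitatively like real long-read data. Two
feasibility guards reject impossible specs: jitter at or above the
bandwidth, and jitter large enough that a planted link's gap penalty would
reach its match contribution (the planted structure would not actually be a
positive-scoring chain; with span 15 and gap_mean 100 the default jitter 30
leaves ≥ 9 points per link). Read simulation applies substitutions (always
base-changing) and 1-base indels at stated per-base rates; read lengths
come from a clipped log-normal mixture with a ~8.25 kb mean default.

What this does **not** emulate: homopolymer-biased nanopore error profiles,
repeat structure of real genomes (random references make minimizer
collisions essentially impossible at k = 15), chimeric reads, or the exact
empirical range-size distributions of real data. Passing tests therefore
establish algorithmic correctness and robustness to idealised noise, not
field accuracy on real genomes; the one bridge to an external
implementation is a loose locus-level cross-check against the installed
reference mapper on error-free reads.

## Problem sizes

The differential battery runs 1000 sets of 1–2000 anchors (cycling dense,
sparse, tie-rich and planted constructions); the brute-force check uses 200
sets of ≤ 300 anchors (the O(n²) Python oracle dominates cost); the
end-to-end study maps 500 reads of 1–50 kb against a 1 Mb reference, error
free and at 5% substitutions + 5% indels. These sizes exercise every code
path (including the 5000-wide range cap via a dense 6000-anchor run) while
keeping a full test-plus-acceptance cycle around two minutes on one core.

## Known limitations

* No base-level alignment, spliced/long-gap chaining, or SAM/CIGAR output.
* The scan-break (`max_skip`) semantics follow the simple
  "consecutive non-improving candidates" reading; production mappers use a
  more intricate bookkeeping. Only the exact (disabled) configuration is
  contractual; the heuristic exists to demonstrate its dominance property.
* `mapq` is an empirical formula, not a calibrated probability.
* The index has no serialisation format; it is rebuilt per run.
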
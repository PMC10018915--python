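# seedchain

A seed-and-chain engine for long-read mapping, built around a
**forward-transformed anchor-chaining dynamic program** that is provably
bit-identical to the classic sequential formulation.

## The problem

Long-read mappers (for nanopore and similar noisy long reads) follow the
seed–chain–align paradigm. Seeding finds *anchors*: short exact matches
between read and reference, located through a minimizer hash index. Chaining
then runs a 1-D dynamic program over the position-sorted anchors to select
collinear, ordered subsets (chains) such that no anchor is reused — this is
the dominant cost for long noisy reads. The classic DP is sequential: each
anchor *j* scans backwards over its predecessors *i* and keeps the best

```
S[j] = max( w_j ,  max_{i < j} S[i] + match(i,j) − gap_penalty(i,j) )
```

with `match(i,j) = min(Δq, Δr, w_j)` and
`gap_penalty = ⌊0.01·w̄·|Δq−Δr|⌋ + ⌊log₂|Δq−Δr|⌋/2`, where Δq and Δr are the
query and reference gaps, w_j the anchor span and w̄ the mean span. Pairs with
non-positive gaps, gaps above 5 kb, or gap difference above the 500 bp
bandwidth cannot chain. Production implementations add a scan-break
heuristic (stop after `max_skip` non-improving candidates) that trades
accuracy for speed; disabling it makes the DP exact but expensive — and
parallelisable.

The *forward transformation* re-orders the loops: instead of each anchor
pulling from its predecessors, each anchor **pushes** candidate scores to
every successor in its range. All pushes from one source are independent,
which exposes intra-range parallelism (this is what makes the DP a good fit
for wide SIMD/GPU hardware). Getting this right requires two subtleties,
both implemented and tested here:

* **successor ranges** are computed dynamically per anchor with a
  probe-delta speed heuristic (`{0, 16, 512, 1024, 2048, 3072, 4096, 5000}`)
  that exploits the empirical skew of range sizes, then condensed into a
  workload vector that skips the large fraction of anchors with no
  successor at all;
* the **score update rule** changes from strict `>` to `≥` so that under
  ascending push order the *nearest* predecessor wins score ties — exactly
  the tie-break the backward scan produces — while never giving an unchained
  anchor a predecessor on a tie with its own span.

The repository's central claim is checked, not assumed: over thousands of
randomized and adversarially tie-rich anchor sets, the forward engine's
score, predecessor and chain-max arrays (S, P, V) are **integer-identical**
to the backward engine with the scan-break heuristic disabled, and the
backward engine itself is checked against an exhaustive O(n²) brute force.

Downstream of the DP, the package provides backtracking (no anchor reuse),
primary/secondary chain classification by query overlap, an empirical
mapping quality `mapq = round(40·(1−f₂/f₁)·min(1, m/10)·ln f₁)` clamped to
[0, 60], and 12-column PAF output. Upstream, it provides (w,k)-minimizer
extraction with an invertible 64-bit hash, a reference multimap index, and
strand-aware anchor collection. A synthetic-data module generates planted
chains with ground truth, adversarial tie constructions, random references
and noisy reads, and long-read-like length samples, so everything runs
without downloads. Base-level alignment is out of scope by design.

## Worked example

```bash
python examples/01_chain_anchors.py
```

```
S (best score per anchor):    [15, 30, 45]
P (best predecessor index):   [-1, 0, 1]
V (max score along chain):    [15, 30, 45]
chain: anchors=[0, 1, 2] score=45 query=[101,321) ref=[101,316)
```

Three span-15 anchors spaced ~100 bp along a diagonal: each anchor alone is
worth its span (15); each link adds a full 15-base match at negligible gap
penalty, so the best chain score grows 15 → 30 → 45 and every anchor's best
predecessor is its neighbour. Backtracking emits one chain covering all
three anchors. The other examples map simulated noisy reads end-to-end
(`03_simulate_and_map.py` prints the PAF records and confirms 10/10 primary
chains land on the true origin) and demonstrate the equivalence check and
the condensed workload vector.

## Command line

```bash
seedchain simulate --mode reads --ref-length 100000 --n-reads 50 --out-prefix sim
seedchain index sim.ref.fa
seedchain map sim.ref.fa sim.reads.fa -o out.paf        # PAF to file
seedchain verify sim.ref.fa sim.reads.fa                # forward vs backward
seedchain chain anchors.tsv --engine both               # chain a TSV directly
```

`verify` maps every read through both chaining engines and exits non-zero on
the first disagreement. `chain` accepts pre-computed anchors as a simple TSV
(`read_id rid strand x y w`) for direct chaining experiments.

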
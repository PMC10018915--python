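"""Deterministic generators for anchors, references and reads.

Everything here is a pure function of its arguments plus an explicit
seed, so the whole test surface runs without downloads.  Three families:

* anchor-level — random anchor sets, adversarially tie-rich sets, and
  planted collinear chains with ground truth, feeding the chaining DPs
  directly;
* sequence-level — random references and reads extracted from them with
  substitution/1-base-indel noise, feeding the full seed-and-chain path;
* read lengths — a clipped log-normal mixture emulating the long-read
  length profile (a few hundred bases to around a megabase, mean
  configurable to ~8.25 kb).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import GenerationError
from .model import AnchorSet

__all__ = [
    "AnchorSimSpec",
    "plant_chains",
    "random_anchor_set",
    "tie_rich_anchor_set",
    "random_reference",
    "simulate_read",
    "LengthModel",
    "sample_lengths",
]

_BASES = np.frombuffer(b"ACGT", np.uint8)


@dataclasses.dataclass(frozen=True)
class AnchorSimSpec:
    """Parameters of a planted-chain anchor simulation.

    gap_mean is the typical anchor-to-anchor gap (bases) along a planted
    run; gap_jitter bounds |query_gap - reference_gap|.  It must stay
    below the chaining bandwidth, and small enough that every planted
    link scores positive under the gap penalty (~0.01*span*jitter plus a
    half-log term), otherwise the "planted chain" is not actually a
    chainable structure.  Both conditions are validated.
    """

    n_chains: int = 2
    chain_len: int = 20
    gap_mean: int = 100
    gap_jitter: int = 30
    noise_anchors: int = 100
    read_length: int = 20_000
    seed: int = 0
    span: int = 15
    bandwidth: int = 500
    ref_length: int | None = None  # None: genome-scale span so noise is sparse

    def __post_init__(self) -> None:
        if self.gap_jitter >= self.bandwidth:
            raise GenerationError(
                f"gap_jitter ({self.gap_jitter}) must be < bandwidth "
                f"({self.bandwidth}) or planted runs are unchainable"
            )
        if self.n_chains < 0 or self.chain_len < 1 or self.gap_mean < 1:
            raise GenerationError("n_chains >= 0, chain_len >= 1, gap_mean >= 1")
        # worst planted link: smallest gaps, largest |dq-dr|
        dq_min = max(1, self.gap_mean // 2)
        dr_min = max(1, dq_min - self.gap_jitter)
        match = min(self.span, dq_min, dr_min)
        jd = self.gap_jitter
        half_log = (jd.bit_length() - 1) // 2 if jd > 0 else 0
        penalty = int(0.01 * self.span * jd) + half_log
        if match - penalty <= 0:
            raise GenerationError(
                f"gap_jitter={jd} too large for span={self.span}, "
                f"gap_mean={self.gap_mean}: planted links would score "
                f"{match - penalty} <= 0"
            )


def plant_chains(spec: AnchorSimSpec) -> tuple[AnchorSet, list[list[int]]]:
    """Plant collinear anchor runs plus uniform noise; return ground truth.

    Each chain occupies its own query and reference segment (so planted
    runs cannot merge); noise anchors are uniform over the full
    (reference, query) rectangle.  Returns the sorted AnchorSet and, per
    planted chain, the list of its anchor indices in that set.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.span
    # worst-case query span of one run: chain_len * 1.5*gap_mean + span
    seg_need = int(spec.chain_len * 1.5 * spec.gap_mean) + w + 10
    if spec.n_chains > 0 and seg_need * spec.n_chains > spec.read_length:
        raise GenerationError(
            f"{spec.n_chains} chains of ~{seg_need} query bases do not fit "
            f"in read_length={spec.read_length}"
        )
    q_seg = spec.read_length // max(1, spec.n_chains)
    r_seg = seg_need + 1000
    ref_len = spec.ref_length
    if ref_len is None:
        # noise emulates stray minimizer hits against a large reference:
        # spread it far beyond the planted segments so most noise anchors
        # have no chainable neighbour
        ref_len = max(2 * spec.read_length, 1_000_000 * spec.noise_anchors)
    ref_len = max(ref_len, r_seg * max(1, spec.n_chains) + w)
    xs, ys, tags = [], [], []
    for c in range(spec.n_chains):
        y = c * q_seg + w - 1 + int(rng.integers(0, 10))
        x = c * r_seg + w - 1 + int(rng.integers(0, 10))
        for _ in range(spec.chain_len):
            xs.append(x)
            ys.append(y)
            tags.append(c)
            dq = int(rng.integers(max(1, spec.gap_mean // 2), spec.gap_mean * 3 // 2 + 1))
            jit = int(rng.integers(-spec.gap_jitter, spec.gap_jitter + 1)) if spec.gap_jitter else 0
            dr = max(1, dq + jit)
            y += dq
            x += dr
    for _ in range(spec.noise_anchors):
        xs.append(int(rng.integers(w - 1, ref_len)))
        ys.append(int(rng.integers(w - 1, spec.read_length)))
        tags.append(-1)
    x = np.asarray(xs, np.int64)
    y = np.asarray(ys, np.int64)
    order = np.lexsort((y, x))
    aset = AnchorSet(
        x[order], y[order], np.full(x.size, w, np.int64),
        read_id=f"sim{spec.seed}", read_length=spec.read_length,
    )
    tag_sorted = np.asarray(tags, np.int64)[order]
    truth = [
        [int(i) for i in np.flatnonzero(tag_sorted == c)]
        for c in range(spec.n_chains)
    ]
    return aset, truth


def random_anchor_set(
    n: int, seed: int, span_factor: float = 4.0, w_range: tuple[int, int] = (15, 15)
) -> AnchorSet:
    """n anchors uniform over a square of side ~span_factor * n (plus spans).

    Small span_factor makes dense, heavily-interacting sets; large makes
    sparse ones where most successor ranges are empty.
    """
    rng = np.random.default_rng(seed)
    side = max(1, int(n * span_factor))
    wlo, whi = w_range
    w = rng.integers(wlo, whi + 1, n)
    x = rng.integers(0, side, n) + w - 1
    y = rng.integers(0, side, n) + w - 1
    order = np.lexsort((y, x))
    return AnchorSet(x[order].astype(np.int64), y[order].astype(np.int64),
                     w[order].astype(np.int64), read_length=side + int(w.max(initial=1)))


def tie_rich_anchor_set(n: int, seed: int, grid: int = 8, step: int = 100) -> AnchorSet:
    """Adversarial construction: coordinates quantised to a tiny grid.

    Duplicated diagonals and coarse quantisation force many exactly equal
    candidate scores, stressing the tie-break agreement between the
    forward and backward engines.
    """
    rng = np.random.default_rng(seed)
    w = 15
    x = rng.integers(0, grid, n) * step + w - 1
    y = rng.integers(0, grid, n) * step + w - 1
    order = np.lexsort((y, x))
    return AnchorSet(x[order].astype(np.int64), y[order].astype(np.int64),
                     np.full(n, w, np.int64), read_length=grid * step + w)


def random_reference(length: int, seed: int) -> str:
    """Uniform random ACGT sequence."""
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def simulate_read(
    reference: str,
    start: int,
    length: int,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    strand: str = "+",
    seed: int = 0,
) -> str:
    """Extract a window and apply substitution / 1-base indel noise.

    Indels split evenly between single-base deletions and insertions;
    substitutions always change the base.  strand='-' returns the reverse
    complement of the noisy window.  Deterministic under seed.
    """
    if not (0.0 <= sub_rate < 0.3 and 0.0 <= indel_rate < 0.3):
        raise ValueError("rates must be in [0, 0.3)")
    if start < 0 or start + length > len(reference):
        raise ValueError(
            f"window [{start}, {start + length}) outside reference of "
            f"length {len(reference)}"
        )
    if strand not in ("+", "-"):
        raise ValueError(f"bad strand {strand!r}")
    rng = np.random.default_rng(seed)
    window = reference[start : start + length]
    codes = _CODE4[np.frombuffer(window.encode("ascii"), np.uint8)]
    L = codes.size
    r = rng.random(L)
    del_mask = r < indel_rate / 2
    ins_mask = (r >= indel_rate / 2) & (r < indel_rate)
    sub_mask = rng.random(L) < sub_rate
    shifts = rng.integers(1, 4, L)
    ins_bases = rng.integers(0, 4, L)
    new = np.where(sub_mask, (codes + shifts) % 4, codes)
    out_counts = (~del_mask).astype(np.int64) + ins_mask
    offs = np.concatenate(([0], np.cumsum(out_counts)))
    out = np.empty(int(offs[-1]), np.int64)
    keep = ~del_mask
    out[offs[:-1][keep]] = new[keep]
    ins_slots = offs[:-1][ins_mask] + keep[ins_mask]
    out[ins_slots] = ins_bases[ins_mask]
    read = _BASES[out].tobytes().decode("ascii")
    return revcomp(read) if strand == "-" else read


_CODE4 = np.zeros(256, np.int64)
for _i, _ch in enumerate("ACGT"):
    _CODE4[ord(_ch)] = _i


@dataclasses.dataclass(frozen=True)
class LengthModel:
    """Log-normal mixture of read lengths, clipped to [lo, hi].

    Component means are arithmetic means of the (unclipped) log-normals;
    defaults give a mixture mean of ~8.25 kb, a realistic long-read
    profile with a dominant short mode and a heavy tail.
    """

    weights: tuple[float, ...] = (0.7, 0.3)
    means: tuple[float, ...] = (4930.0, 16000.0)
    sigmas: tuple[float, ...] = (0.6, 0.5)
    lo: int = 500
    hi: int = 1_000_000


def sample_lengths(n: int, model: LengthModel | None = None, seed: int = 0) -> list[int]:
    """Draw n read lengths from the mixture; deterministic under seed."""
    if model is None:
        model = LengthModel()
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    wsum = sum(model.weights)
    comp = rng.choice(len(model.weights), size=n,
                      p=[w / wsum for w in model.weights])
    mus = np.array([np.log(m) - s * s / 2 for m, s in zip(model.means, model.sigmas)])
    sig = np.array(model.sigmas)
    raw = rng.lognormal(mus[comp], sig[comp])
    return [int(v) for v in np.clip(raw, model.lo, model.hi)]
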
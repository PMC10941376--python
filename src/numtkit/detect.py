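"""Alignment-based NUMT calling.

A self-contained seed-and-extend local aligner: exact seed matches between
the (circularity-extended) mitochondrial genome and each chromosome are
extended with banded affine-gap x-drop DP on both strands, scored HSPs are
filtered by Karlin-Altschul e-value, and calls are reported in BED-style
0-based half-open coordinates with mitochondrial positions taken modulo
the mtDNA length.

The e-value machinery: lambda is the unique positive root of
``sum_ij p_i p_j exp(lambda * s_ij) = 1``; the prefactor K is calibrated
by a deterministic Monte-Carlo scan of ungapped segment counts on random
sequences of the same composition (the ungapped K is used, as is standard,
as an approximation for gapped scores).
"""

from __future__ import annotations

import functools
import math
from typing import List, Optional, Sequence, Tuple

import edlib
import numpy as np
from scipy.optimize import brentq

from ._align import count_high_segments, smith_waterman, xdrop_extend
from .models import AlignmentParams, GenomeSequence, NumtCall
from .seqs import decode, encode, reverse_complement


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics


def karlin_lambda(
    match: int, mismatch: int, base_frequencies: Sequence[float]
) -> float:
    """Unique positive root of sum p_ij exp(lambda s_ij) = 1."""
    f = np.asarray(base_frequencies, dtype=float)
    if f.size != 4 or abs(f.sum() - 1) > 1e-6 or (f < 0).any():
        raise ValueError("base_frequencies must be 4 non-negative values summing to 1")
    p_match = float((f**2).sum())
    p_mis = 1.0 - p_match
    expected = p_match * match + p_mis * mismatch
    if expected >= 0:
        raise ValueError("expected pairwise score must be negative")

    def g(lam: float) -> float:
        return p_match * math.exp(lam * match) + p_mis * math.exp(lam * mismatch) - 1.0

    hi = 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("failed to bracket lambda")
    return float(brentq(g, 1e-9, hi, xtol=1e-12))


@functools.lru_cache(maxsize=64)
def _karlin_k_cached(
    match: int, mismatch: int, freqs: Tuple[float, ...], lam: float
) -> float:
    """Monte-Carlo calibration of K on random same-composition sequences.

    Counts maximal ungapped segments above a score ladder on simulated
    pairs and inverts E = K m n exp(-lambda S).  Deterministic (fixed
    internal seed).
    """
    rng = np.random.default_rng(20240314)
    L = 600
    n_pairs = 40
    f = np.array(freqs)
    f = f / f.sum()
    # thresholds where expected counts per pair are O(1)
    s_mid = max(3, int(round(math.log(0.3 * L * L) / lam)))
    thresholds = np.arange(s_mid, s_mid + 3, dtype=np.int64)
    total = np.zeros(thresholds.size, dtype=np.int64)
    for _ in range(n_pairs):
        a = rng.choice(4, size=L, p=f).astype(np.uint8)
        b = rng.choice(4, size=L, p=f).astype(np.uint8)
        total += count_high_segments(a, b, match, mismatch, thresholds)
    rates = total / n_pairs
    ks = rates * np.exp(lam * thresholds) / (L * L)
    k = float(np.mean(ks[rates > 0])) if (rates > 0).any() else 0.1
    return float(np.clip(k, 1e-3, 10.0))


def karlin_parameters(
    match: int, mismatch: int, base_frequencies: Sequence[float]
) -> Tuple[float, float]:
    """(lambda, K) for an ungapped match/mismatch scoring system."""
    lam = karlin_lambda(match, mismatch, base_frequencies)
    f = tuple(round(float(x), 4) for x in base_frequencies)
    return lam, _karlin_k_cached(match, mismatch, f, round(lam, 6))


def evalue(score: float, m: int, n: int, lam: float, K: float) -> float:
    """Expected number of chance HSPs scoring >= ``score``:
    E = K * m * n * exp(-lambda * score)."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    return float(K * m * n * math.exp(-lam * score))


# ---------------------------------------------------------------------------
# Seeding


def _kmer_codes(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """(positions, integer codes) of all N-free k-windows."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    c64 = codes.astype(np.int64)
    for j in range(k):
        window = c64[j : j + n]
        vals = vals * 4 + np.where(window == 4, 0, window)
        invalid |= window == 4
    pos = np.flatnonzero(~invalid)
    return pos, vals[pos]


class _SeedIndex:
    """Sorted k-mer index over the first ``limit`` window starts."""

    def __init__(self, codes: np.ndarray, k: int, limit: int):
        pos, vals = _kmer_codes(codes, k)
        keep = pos < limit
        pos, vals = pos[keep], vals[keep]
        order = np.argsort(vals, kind="stable")
        self.sorted_vals = vals[order]
        self.sorted_pos = pos[order]

    def lookup_block(self, queries: np.ndarray):
        """For each query code: (lo, hi) slice into sorted_pos (lo==hi if absent)."""
        lo = np.searchsorted(self.sorted_vals, queries, side="left")
        hi = np.searchsorted(self.sorted_vals, queries, side="right")
        return lo, hi


# ---------------------------------------------------------------------------
# Calling


def _extend_seed(s, q, ip, jp, k, p: AlignmentParams):
    """X-drop extension both ways around an exact seed match."""
    right = xdrop_extend(
        s, q, ip + k, jp + k, 1, p.match, p.mismatch, p.gap_open,
        p.gap_extend, p.xdrop, p.band_width,
    )
    left = xdrop_extend(
        s, q, ip, jp, -1, p.match, p.mismatch, p.gap_open,
        p.gap_extend, p.xdrop, p.band_width,
    )
    score = k * p.match + right[0] + left[0]
    s_iv = (ip - left[1], ip + k + right[1])
    q_iv = (jp - left[2], jp + k + right[2])
    return score, s_iv, q_iv


def _strand_hsps(
    s_codes: np.ndarray,
    q_codes: np.ndarray,
    index: _SeedIndex,
    params: AlignmentParams,
    min_score: int,
    period: int = 0,
) -> List[Tuple[int, Tuple[int, int], Tuple[int, int]]]:
    """All above-threshold HSPs of one chromosome against one query strand."""
    k = params.seed_length
    pos, vals = _kmer_codes(s_codes, k)
    lo, hi = index.lookup_block(vals)
    hit_rows = np.flatnonzero(hi > lo)

    hsps: List[Tuple[int, Tuple[int, int], Tuple[int, int]]] = []
    # accepted-HSP boxes for seed skipping, kept sorted by nuclear start
    box_starts: List[int] = []
    boxes: List[Tuple[int, int, int, int]] = []  # (s0, s1, q0, q1)
    W = params.band_width
    import bisect

    for r in hit_rows:
        ip = int(pos[r])
        for idx in range(int(lo[r]), int(hi[r])):
            jp = int(index.sorted_pos[idx])
            if boxes:
                i0 = bisect.bisect_right(box_starts, ip) - 1
                skip = False
                for b in range(max(0, i0 - 2), min(len(boxes), i0 + 2)):
                    s0, s1, q0, q1 = boxes[b]
                    if s0 <= ip < s1:
                        # the doubled circular query represents each
                        # position twice; test both representations
                        for jp_alt in (jp, jp + period):
                            if (
                                q0 <= jp_alt < q1
                                and abs((jp_alt - ip) - (q0 - s0)) <= W
                            ):
                                skip = True
                                break
                    if skip:
                        break
                if skip:
                    continue
            score, s_iv, q_iv = _extend_seed(s_codes, q_codes, ip, jp, k, params)
            if score >= min_score:
                hsps.append((score, s_iv, q_iv))
                at = bisect.bisect_left(box_starts, s_iv[0])
                box_starts.insert(at, s_iv[0])
                boxes.insert(at, (s_iv[0], s_iv[1], q_iv[0], q_iv[1]))
    return hsps


def _merge_hsps(hsps, merge_gap: int):
    """Merge same-strand HSPs whose nuclear intervals are within merge_gap.

    Merged call: combined nuclear/mt span, max score, min e-value."""
    if not hsps:
        return hsps
    hsps = sorted(hsps, key=lambda h: h[1][0])
    merged = [hsps[0]]
    for h in hsps[1:]:
        last = merged[-1]
        if h[1][0] <= last[1][1] + merge_gap:
            merged[-1] = (
                max(last[0], h[0]),
                (last[1][0], max(last[1][1], h[1][1])),
                (min(last[2][0], h[2][0]), max(last[2][1], h[2][1])),
            )
        else:
            merged.append(h)
    return merged


def _identity(s_codes, q_codes, s_iv, q_iv) -> float:
    s_seq = decode(s_codes[s_iv[0] : s_iv[1]])
    q_seq = decode(q_codes[q_iv[0] : q_iv[1]])
    if not s_seq or not q_seq:
        return 0.0
    d = edlib.align(s_seq, q_seq, task="distance")["editDistance"]
    return max(1e-9, 1.0 - d / max(len(s_seq), len(q_seq)))


def resolve_params(
    params: AlignmentParams, base_frequencies: Sequence[float]
) -> AlignmentParams:
    """Fill in lambda/K from the scoring system when not set explicitly."""
    if params.lambda_ is not None and params.karlin_k is not None:
        return params
    lam, K = karlin_parameters(params.match, params.mismatch, base_frequencies)
    import dataclasses

    return dataclasses.replace(
        params,
        lambda_=params.lambda_ if params.lambda_ is not None else lam,
        karlin_k=params.karlin_k if params.karlin_k is not None else K,
    )


def call_numts(
    mt: GenomeSequence,
    nuclear: Sequence[GenomeSequence],
    params: Optional[AlignmentParams] = None,
) -> List[NumtCall]:
    """Call NUMTs: mtDNA vs every chromosome, both strands.

    The mt query is doubled so alignments may wrap the origin; mt
    coordinates are reported modulo the mt length.  Only HSPs with
    e-value <= ``params.evalue_threshold`` are emitted, sorted by
    (chromosome, start).
    """
    if params is None:
        params = AlignmentParams()
    if len(mt.sequence) == 0 or not nuclear or any(len(c) == 0 for c in nuclear):
        raise ValueError("empty mt or nuclear input")

    mt_codes = encode(mt.sequence)
    L = mt_codes.size
    q_plus = np.concatenate([mt_codes, mt_codes])
    q_minus = reverse_complement(q_plus)

    freqs = np.bincount(mt_codes[mt_codes < 4], minlength=4) / (mt_codes < 4).sum()
    params = resolve_params(params, freqs)
    lam, K = params.lambda_, params.karlin_k

    k = params.seed_length
    idx_plus = _SeedIndex(q_plus, k, L)
    idx_minus = _SeedIndex(q_minus, k, L)

    calls: List[NumtCall] = []
    for chrom in nuclear:
        s_codes = encode(chrom.sequence)
        n = s_codes.size
        # smallest integer score still passing the e-value filter
        min_score = math.ceil(
            math.log(K * L * n / params.evalue_threshold) / lam
        )
        for strand, q_codes, index in (
            ("+", q_plus, idx_plus),
            ("-", q_minus, idx_minus),
        ):
            hsps = _strand_hsps(s_codes, q_codes, index, params, min_score, period=L)
            if params.merge_gap > 0:
                hsps = _merge_hsps(hsps, params.merge_gap)
            for score, s_iv, q_iv in hsps:
                ev = evalue(score, L, n, lam, K)
                if ev > params.evalue_threshold:
                    continue
                if strand == "+":
                    qb, qe = q_iv
                else:  # map back from the reverse-complemented doubled query
                    qb, qe = 2 * L - q_iv[1], 2 * L - q_iv[0]
                mt_start = qb % L
                mt_end = qe % L
                if (qe - qb) % L == 0 and qe > qb:
                    mt_end = mt_start
                calls.append(
                    NumtCall(
                        chromosome_id=chrom.id,
                        nuclear_start=s_iv[0],
                        nuclear_end=s_iv[1],
                        strand=strand,
                        mt_start=mt_start,
                        mt_end=mt_end,
                        score=int(score),
                        evalue=ev,
                        identity=_identity(s_codes, q_codes, s_iv, q_iv),
                    )
                )
    calls.sort(key=lambda c: (c.chromosome_id, c.nuclear_start, c.strand))
    return calls


def smith_waterman_oracle(
    query: str, subject: str, params: Optional[AlignmentParams] = None
) -> Tuple[int, Tuple[int, int], Tuple[int, int]]:
    """Exhaustive affine-gap local alignment (test oracle).

    Returns ``(score, (query_start, query_end), (subject_start,
    subject_end))`` of the optimal local alignment.  Refuses instances
    above 10^7 DP cells.
    """
    if params is None:
        params = AlignmentParams()
    if len(query) * len(subject) > 10**7:
        raise ValueError("oracle limited to 1e7 DP cells")
    a = encode(query)
    b = encode(subject)
    score, qa, qe, sb, se = smith_waterman(
        a, b, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    return int(score), (int(qa), int(qe)), (int(sb), int(se))
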
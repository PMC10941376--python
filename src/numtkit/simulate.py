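"""Synthetic cohort generator.

Simulates a circular mitochondrial genome and nuclear chromosomes from
order-``k`` Markov chains, plants divergence-controlled NUMT insertions
whose lengths follow the mammalian size distribution (quartiles 121/632 bp,
median 248 bp), and lays down repeat annotations with configurable
flank-enrichment behaviour, so the whole downstream pipeline is testable
without downloading genomes.

The nuclear background is CpG-depleted (as mammalian nuclear DNA is) while
the mitochondrial chain is not; together with the GC offset (0.38 vs 0.42)
this gives planted NUMTs a realistic compositional signature.
"""

from __future__ import annotations

import functools
import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .models import (
    GenomeSequence,
    LengthModel,
    PlantedNumt,
    RepeatFamilySpec,
    RepeatFeature,
    SimulationConfig,
)
from .seqs import decode, encode, reverse_complement

# homopolymer-run damping applied when the previous `order` bases all equal
# the candidate base; keeps simulated runs shorter, as in real genomes
_RUN_DAMPING = 0.7


def _transition_matrix(
    gc_weight: float, order: int, cpg_factor: float
) -> np.ndarray:
    """Conditional P(next | context) over all 4**order contexts."""
    n_ctx = 4**order
    base_w = np.array(
        [(1 - gc_weight) / 2, gc_weight / 2, gc_weight / 2, (1 - gc_weight) / 2]
    )
    probs = np.empty((n_ctx, 4))
    for ctx in range(n_ctx):
        digits = [(ctx // 4**i) % 4 for i in range(order - 1, -1, -1)]
        last = digits[-1]
        w = base_w.copy()
        if last == 1:  # C followed by G: CpG modifier
            w[2] *= cpg_factor
        if order >= 2 and len(set(digits)) == 1:
            w[digits[0]] *= _RUN_DAMPING
        probs[ctx] = w / w.sum()
    return probs


def _stationary_gc(probs: np.ndarray, order: int) -> Tuple[np.ndarray, float]:
    """Stationary context distribution and its marginal GC."""
    n_ctx = probs.shape[0]
    pi = np.full(n_ctx, 1.0 / n_ctx)
    next_ctx = np.empty((n_ctx, 4), dtype=np.int64)
    for ctx in range(n_ctx):
        for b in range(4):
            next_ctx[ctx, b] = (ctx * 4 + b) % n_ctx
    for _ in range(200):
        new = np.zeros(n_ctx)
        np.add.at(new, next_ctx.ravel(), (pi[:, None] * probs).ravel())
        if np.abs(new - pi).max() < 1e-13:
            pi = new
            break
        pi = new
    # marginal base = last digit of context
    last = np.arange(n_ctx) % 4
    gc = pi[(last == 1) | (last == 2)].sum()
    return pi, gc


@functools.lru_cache(maxsize=32)
def _calibrated_chain(
    target_gc: float, order: int, cpg_factor: float
) -> Tuple[np.ndarray, np.ndarray]:
    """(cumulative transition probs, stationary context dist) with the
    chain's stationary GC bisected onto ``target_gc``."""
    lo, hi = 1e-4, 1.0 - 1e-4
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        probs = _transition_matrix(mid, order, cpg_factor)
        pi, gc = _stationary_gc(probs, order)
        if gc < target_gc:
            lo = mid
        else:
            hi = mid
    probs = _transition_matrix(0.5 * (lo + hi), order, cpg_factor)
    pi, gc = _stationary_gc(probs, order)
    assert abs(gc - target_gc) < 1e-6
    return np.cumsum(probs, axis=1), pi


@njit(cache=True)
def _markov_walk(cum, order, uniforms, out):  # pragma: no cover - numba
    n = out.shape[0]
    n_ctx = cum.shape[0]
    state = 0
    for i in range(order):
        state = state * 4 + out[i]
    for i in range(order, n):
        u = uniforms[i]
        b = 0
        row = cum[state]
        while b < 3 and u > row[b]:
            b += 1
        out[i] = b
        state = (state * 4 + b) % n_ctx


def _simulate_chain(
    length: int, gc: float, order: int, cpg_factor: float, rng: np.random.Generator
) -> np.ndarray:
    if length <= 0:
        raise ValueError("length must be positive")
    cum, pi = _calibrated_chain(round(gc, 6), order, round(cpg_factor, 6))
    ctx = rng.choice(len(pi), p=pi / pi.sum())
    out = np.empty(length + order, dtype=np.uint8)
    for i in range(order - 1, -1, -1):
        out[i] = (ctx // 4 ** (order - 1 - i)) % 4
    _markov_walk(cum, order, rng.random(length + order), out)
    return out[order:]


def simulate_mt_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> GenomeSequence:
    """Simulate the circular mitochondrial genome."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    codes = _simulate_chain(
        config.mt_length, config.mt_gc, config.markov_order, config.mt_cpg_factor, rng
    )
    return GenomeSequence("chrM", decode(codes), circular=True)


def simulate_nuclear_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> List[GenomeSequence]:
    """Simulate the NUMT-free nuclear chromosomes."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    out = []
    for i, length in enumerate(config.chromosome_lengths):
        codes = _simulate_chain(
            length,
            config.nuclear_gc,
            config.markov_order,
            config.nuclear_cpg_factor,
            rng,
        )
        out.append(GenomeSequence(f"chr{i + 1}", decode(codes)))
    return out


def sample_numt_lengths(
    model: LengthModel, n: int, seed=None
) -> np.ndarray:
    """Draw ``n`` NUMT lengths from the quantile-anchored length model.

    The quantile function interpolates ``log(length)`` linearly in
    probability between the anchors, extrapolates with the adjacent
    segment's slope in the tails, and clips to the configured bounds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ps = np.array(sorted(model.anchors))
    logs = np.log([model.anchors[p] for p in ps])
    u = rng.random(n)
    logv = np.interp(u, ps, logs)
    lo_slope = (logs[1] - logs[0]) / (ps[1] - ps[0])
    hi_slope = (logs[-1] - logs[-2]) / (ps[-1] - ps[-2])
    below = u < ps[0]
    above = u > ps[-1]
    logv[below] = logs[0] + (u[below] - ps[0]) * lo_slope
    logv[above] = logs[-1] + (u[above] - ps[-1]) * hi_slope
    lengths = np.rint(np.exp(logv)).astype(np.int64)
    return np.clip(lengths, model.min_length, model.max_length)


def _mutate(codes: np.ndarray, sub_rate: float, indel_rate: float,
            rng: np.random.Generator) -> Tuple[np.ndarray, int, int]:
    """Apply per-bp substitutions and geometric-length indels."""
    codes = codes.copy()
    sub_mask = rng.random(codes.size) < sub_rate
    n_subs = int(sub_mask.sum())
    if n_subs:
        shifts = rng.integers(1, 4, size=n_subs).astype(np.uint8)
        codes[sub_mask] = (codes[sub_mask] + shifts) % 4
    if indel_rate <= 0:
        return codes, n_subs, 0
    event_mask = rng.random(codes.size) < indel_rate
    positions = np.flatnonzero(event_mask)
    if positions.size == 0:
        return codes, n_subs, 0
    pieces, prev = [], 0
    for pos in positions:
        pieces.append(codes[prev:pos])
        ell = int(rng.geometric(0.5))
        if rng.random() < 0.5:  # insertion of random bases before pos
            pieces.append(rng.integers(0, 4, size=ell).astype(np.uint8))
            prev = pos
        else:  # deletion of up to ell bases starting at pos
            prev = min(pos + ell, codes.size)
    pieces.append(codes[prev:])
    return np.concatenate(pieces), n_subs, positions.size


def _circular_slice(mt_codes: np.ndarray, start: int, length: int) -> np.ndarray:
    doubled = np.concatenate([mt_codes, mt_codes])
    if length > doubled.size:
        reps = math.ceil((start + length) / mt_codes.size) + 1
        doubled = np.tile(mt_codes, reps)
    return doubled[start : start + length]


def plant_numts(
    nuclear: Sequence[GenomeSequence],
    mt: GenomeSequence,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[GenomeSequence], List[PlantedNumt]]:
    """Insert mutated mtDNA fragments into the chromosomes.

    Each insert is a contiguous (possibly origin-wrapping) slice of the
    circular mtDNA, reverse-complemented with probability 0.5, mutated at
    the configured substitution/indel rates, and spliced in at a uniform
    random position.  Returns mutated chromosomes plus ground truth in
    final coordinates.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    mt_codes = encode(mt.sequence)
    mt_len = len(mt_codes)
    pad = 300  # keep inserts clear of chromosome ends so flanks exist

    specials = []
    if config.include_meganumt:
        specials.append("mega")
    if config.include_tandem_double:
        specials.append("tandem")

    lengths = sample_numt_lengths(config.length_model, max(config.n_numts, 1), rng)
    lengths = lengths[: config.n_numts]
    chrom_lens = np.asarray(config.chromosome_lengths, dtype=float)
    assignment = rng.choice(
        len(nuclear), size=config.n_numts, p=chrom_lens / chrom_lens.sum()
    )
    special_chrom = rng.integers(0, len(nuclear), size=len(specials))

    out_seqs: List[GenomeSequence] = []
    truth: List[PlantedNumt] = []
    for ci, chrom in enumerate(nuclear):
        codes = encode(chrom.sequence)
        todo: List[Tuple[int, str]] = [
            (int(lengths[j]), "plain") for j in np.flatnonzero(assignment == ci)
        ]
        todo += [
            (mt_len * (2 if kind == "tandem" else 1), kind)
            for kind, sc in zip(specials, special_chrom)
            if sc == ci
        ]
        inserts = []  # (point, insert_codes, strand, mt_start, mt_end, subs, indels)
        points_taken: set = set()
        for length, kind in todo:
            if kind == "plain":
                mt_start = int(rng.integers(0, mt_len))
                frag = _circular_slice(mt_codes, mt_start, length)
            else:
                mt_start = 0
                frag = _circular_slice(mt_codes, 0, length)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = reverse_complement(frag)
            frag, n_subs, n_ind = _mutate(
                frag, config.substitution_rate, config.indel_rate, rng
            )
            mt_end = (mt_start + length) % mt_len
            if length % mt_len == 0:
                mt_end = mt_start  # full-molecule (or tandem) insert
            for _ in range(1000):
                point = int(rng.integers(pad, len(codes) - pad))
                if point not in points_taken:
                    points_taken.add(point)
                    break
            else:
                raise RuntimeError(
                    f"could not place NUMT on {chrom.id} without overlap"
                )
            inserts.append((point, frag, strand, mt_start, mt_end, n_subs, n_ind))

        inserts.sort(key=lambda t: t[0])
        pieces, prev, offset = [], 0, 0
        for point, frag, strand, mt_start, mt_end, n_subs, n_ind in inserts:
            pieces.append(codes[prev:point])
            pieces.append(frag)
            start = point + offset
            truth.append(
                PlantedNumt(
                    chromosome_id=chrom.id,
                    nuclear_start=start,
                    nuclear_end=start + frag.size,
                    strand=strand,
                    mt_start=mt_start,
                    mt_end=mt_end,
                    realized_substitutions=n_subs,
                    realized_indels=n_ind,
                )
            )
            offset += frag.size
            prev = point
        pieces.append(codes[prev:])
        out_seqs.append(
            GenomeSequence(chrom.id, decode(np.concatenate(pieces)))
            if inserts
            else GenomeSequence(chrom.id, chrom.sequence)
        )
    truth.sort(key=lambda t: (t.chromosome_id, t.nuclear_start))
    return out_seqs, truth


def plant_repeats(
    nuclear: Sequence[GenomeSequence],
    truth: Sequence[PlantedNumt],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    window: int = 200,
) -> List[RepeatFeature]:
    """Place repeat annotations with NUMT-flank intensity modulation.

    Background starts follow a Poisson process at ``density_per_kb``;
    ``enriched_upstream`` multiplies the intensity inside the upstream
    ``window`` of each NUMT, ``depleted_near`` multiplies it within
    +-``window``, ``uniform`` leaves it unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    by_chrom: dict = {}
    for t in truth:
        by_chrom.setdefault(t.chromosome_id, []).append(t)

    features: List[RepeatFeature] = []
    for fam in config.repeat_families:
        if fam.flank_behaviour not in ("enriched_upstream", "depleted_near", "uniform"):
            raise ValueError(f"unknown flank behaviour {fam.flank_behaviour!r}")
        if fam.density_per_kb <= 0:
            continue
        for chrom in nuclear:
            L = len(chrom)
            lam = np.full(L, fam.density_per_kb / 1000.0)
            for t in by_chrom.get(chrom.id, []):
                if fam.flank_behaviour == "enriched_upstream":
                    lo = max(0, t.nuclear_start - window)
                    lam[lo : t.nuclear_start] *= fam.enrichment_factor
                elif fam.flank_behaviour == "depleted_near":
                    lo = max(0, t.nuclear_start - window)
                    hi = min(L, t.nuclear_end + window)
                    lam[lo:hi] *= fam.depletion_factor
            total = lam.sum()
            n = rng.poisson(total)
            if n == 0:
                continue
            starts = rng.choice(L, size=n, p=lam / total)
            lens = np.maximum(
                10, rng.exponential(fam.mean_length, size=n)
            ).astype(np.int64)
            strands = np.where(rng.random(n) < 0.5, "+", "-")
            for s, ell, st in zip(starts, lens, strands):
                features.append(
                    RepeatFeature(
                        chromosome_id=chrom.id,
                        start=int(s),
                        end=int(min(s + ell, L)),
                        strand=str(st),
                        name=fam.name,
                        family=fam.family,
                    )
                )
    features.sort(key=lambda f: (f.chromosome_id, f.start))
    return features


def simulate_cohort(config: SimulationConfig):
    """Run the full generator: mtDNA, chromosomes, planted NUMTs, repeats.

    Returns ``(nuclear, mt, truth, repeats)``; every output is a pure
    function of the config (including its seed).
    """
    children = np.random.SeedSequence(config.seed).spawn(4)
    mt = simulate_mt_genome(config, np.random.default_rng(children[0]))
    clean = simulate_nuclear_genome(config, np.random.default_rng(children[1]))
    nuclear, truth = plant_numts(clean, mt, config, np.random.default_rng(children[2]))
    repeats = plant_repeats(nuclear, truth, config, np.random.default_rng(children[3]))
    return nuclear, mt, truth, repeats
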
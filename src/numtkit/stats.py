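"""Genome-level descriptive statistics.

GC contents and per-NUMT relative GC, Spearman correlations between genome
properties and NUMT load, size-distribution summaries, megaNUMT flagging,
and the per-nucleotide mitochondrial involvement matrix (how many times
each mtDNA position has been copied into the nuclear genome).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import GenomeSequence, GenomeSummary, NumtCall
from .seqs import encode


def gc_content(sequence) -> float:
    """(G + C) / (A + C + G + T); N bases are excluded from the denominator."""
    codes = encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    counts = np.bincount(codes, minlength=5)
    denom = counts[:4].sum()
    if denom == 0:
        raise ValueError("no unambiguous bases")
    return float((counts[1] + counts[2]) / denom)


def relative_gc(
    numt_seqs: Sequence[str],
    genome_gc: float,
    mt_counterpart_seqs: Sequence[str],
    mt_gc: float,
) -> List[Tuple[float, float]]:
    """Per-NUMT (GC(numt)/genome GC, GC(counterpart)/mtDNA GC) pairs.

    On real data NUMTs skew below 1.0 against their host genome while their
    mitochondrial counterparts centre on 1.0 against the mtDNA.
    """
    if genome_gc <= 0 or mt_gc <= 0:
        raise ValueError("GC denominators must be positive")
    out = []
    for ns, ms in zip(numt_seqs, mt_counterpart_seqs, strict=True):
        out.append((gc_content(ns) / genome_gc, gc_content(ms) / mt_gc))
    return out


_CORR_PAIRS = [
    ("nuclear_size", "numt_count"),
    ("nuclear_size", "numt_cumulative_length"),
    ("nuclear_gc", "numt_count"),
    ("nuclear_gc", "numt_cumulative_length"),
]


def correlate(summaries: Sequence[GenomeSummary]) -> pd.DataFrame:
    """Spearman rank correlations (tie-corrected) across the cohort.

    Rows: genome size vs NUMT count / cumulative length, genome GC vs the
    same two, mirroring the cohort-level correlation panel.
    """
    if len(summaries) < 5:
        raise ValueError("need at least 5 genome summaries")
    df = pd.DataFrame([s.__dict__ for s in summaries])
    rows = []
    for x, y in _CORR_PAIRS:
        rho, p = sps.spearmanr(df[x], df[y])
        rows.append({"x": x, "y": y, "spearman_rho": rho, "p_value": p})
    return pd.DataFrame(rows)


def size_stats(lengths: Sequence[int], mt_length: Optional[int] = None) -> Dict:
    """Median and quartiles of NUMT lengths, absolute and relative to mtDNA."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("no lengths")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    out = {"median": float(med), "q1": float(q1), "q3": float(q3)}
    if mt_length:
        rel = arr / mt_length
        r1, rm, r3 = np.percentile(rel, [25, 50, 75])
        out.update(
            {"relative_median": float(rm), "relative_q1": float(r1),
             "relative_q3": float(r3)}
        )
    return out


def _coverage(intervals: Sequence[Tuple[int, int]], mt_length: int) -> np.ndarray:
    """Wrap-aware per-position coverage counts on the circular mtDNA."""
    cov = np.zeros(mt_length, dtype=np.int64)
    for start, end in intervals:
        start %= mt_length
        end %= mt_length
        if end > start:
            cov[start:end] += 1
        else:  # wraps the origin (end == start means the full molecule)
            cov[start:] += 1
            cov[:end] += 1
            if end == start:
                pass  # [s, s) wrap = one full copy, already counted
    return cov


def involvement_matrix(
    numts_per_species: Dict[str, Sequence[Tuple[int, int]]],
    mt_lengths: Dict[str, int],
    bins: Optional[int] = None,
) -> pd.DataFrame:
    """Species x mt-position matrix of NUMTogenesis involvement counts.

    Each cell counts how many NUMTs of that species cover that
    mitochondrial position (with multiplicity, wrap-aware).  With ``bins``
    set, per-species coverage is rescaled to a common axis by per-bin mean
    (used cross-species where mt lengths differ).
    """
    rows = {}
    for sp, intervals in numts_per_species.items():
        cov = _coverage(intervals, mt_lengths[sp])
        if bins is not None:
            edges = np.linspace(0, cov.size, bins + 1).astype(int)
            cov = np.array(
                [cov[a:b].mean() if b > a else 0.0 for a, b in zip(edges, edges[1:])]
            )
        rows[sp] = cov
    return pd.DataFrame.from_dict(rows, orient="index")


def detect_meganumts(
    numts: Sequence, mt_length: int,
    full_mt_factor: float = 0.99, tandem_factor: float = 1.95,
) -> List[str]:
    """Flag NUMTs spanning (nearly) the whole mtDNA or a tandem double.

    Returns one label per NUMT: "tandem_double", "full_mt" or "".
    """
    flags = []
    for n in numts:
        span = n.nuclear_end - n.nuclear_start
        if span >= tandem_factor * mt_length:
            flags.append("tandem_double")
        elif span >= full_mt_factor * mt_length:
            flags.append("full_mt")
        else:
            flags.append("")
    return flags


def summarize_genome(
    species_id: str,
    nuclear: Sequence[GenomeSequence],
    mt: GenomeSequence,
    numts: Sequence[NumtCall],
) -> GenomeSummary:
    total = sum(len(c) for c in nuclear)
    gc_num = sum(len(c) * gc_content(c.sequence) for c in nuclear)
    return GenomeSummary(
        species_id=species_id,
        nuclear_size=total,
        nuclear_gc=gc_num / total,
        mt_size=len(mt),
        mt_gc=gc_content(mt.sequence),
        numt_count=len(numts),
        numt_cumulative_length=sum(n.nuclear_end - n.nuclear_start for n in numts),
    )
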
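"""Flanking-region extraction and positional repeat-density profiling.

Builds, per repeat family, the occupancy profile over a common axis
around each locus -- 200 upstream 1-bp bins, the locus interior rescaled
to 100 bins, 200 downstream 1-bp bins -- and tests the positional
distribution of repeats around NUMTs against the matched-random null
with a two-sample Kolmogorov-Smirnov test (significant at p < 0.05).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .models import FlankProfile, GenomeSequence, RepeatFeature

INTERIOR_BINS = 100


def extract_flanks(
    loci: Sequence,
    genome: Sequence[GenomeSequence],
    window: int = 200,
) -> List[Dict]:
    """Upstream/downstream ``window`` bp sequences of each locus.

    Returns one record per flank with keys: locus index, side, sequence,
    interval, truncated flag.  Flanks are taken in reference orientation
    and truncated at chromosome edges; fully truncated sides are dropped.
    """
    chrom_by_id = {c.id: c for c in genome}
    out: List[Dict] = []
    for i, locus in enumerate(loci):
        chrom = chrom_by_id[locus.chromosome_id]
        start = getattr(locus, "nuclear_start", None)
        if start is None:
            start = locus.start
        end = getattr(locus, "nuclear_end", None)
        if end is None:
            end = locus.end
        if not (0 <= start <= end <= len(chrom)):
            raise ValueError(f"locus {i} outside chromosome bounds")
        up_lo = max(0, start - window)
        down_hi = min(len(chrom), end + window)
        if start > up_lo:
            out.append(
                {
                    "locus": i,
                    "side": "upstream",
                    "start": up_lo,
                    "end": start,
                    "sequence": chrom.sequence[up_lo:start],
                    "truncated": start - up_lo < window,
                    "chromosome_id": chrom.id,
                }
            )
        if down_hi > end:
            out.append(
                {
                    "locus": i,
                    "side": "downstream",
                    "start": end,
                    "end": down_hi,
                    "sequence": chrom.sequence[end:down_hi],
                    "truncated": down_hi - end < window,
                    "chromosome_id": chrom.id,
                }
            )
    return out


def _axis_labels(window: int) -> List[float]:
    """Bin labels: upstream -window..-1, interior 0..99, downstream +1..+window."""
    return (
        [float(x) for x in range(-window, 0)]
        + [float(x) for x in range(INTERIOR_BINS)]
        + [float(x) for x in range(1, window + 1)]
    )


def _locus_bounds(locus) -> Tuple[str, int, int]:
    start = getattr(locus, "nuclear_start", None)
    if start is None:
        start = locus.start
    end = getattr(locus, "nuclear_end", None)
    if end is None:
        end = locus.end
    return locus.chromosome_id, start, end


def _repeats_by_chrom(
    repeats: Sequence[RepeatFeature], family: str
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (sorted starts, ends) of one family's repeats."""
    acc: Dict[str, List[Tuple[int, int]]] = {}
    for r in repeats:
        if r.family == family:
            acc.setdefault(r.chromosome_id, []).append((r.start, r.end))
    out = {}
    for chrom, ivs in acc.items():
        ivs.sort()
        starts = np.array([a for a, _ in ivs], dtype=np.int64)
        ends = np.array([b for _, b in ivs], dtype=np.int64)
        out[chrom] = (starts, ends, np.maximum.accumulate(ends))
    return out


def _overlapping(starts, ends, cummax_ends, lo, hi):
    """Indices of intervals overlapping [lo, hi) (starts sorted)."""
    first = int(np.searchsorted(cummax_ends, lo, side="right"))
    last = int(np.searchsorted(starts, hi, side="left"))
    idx = np.arange(first, last)
    if idx.size == 0:
        return idx
    keep = (ends[idx] > lo) & (starts[idx] < hi)
    return idx[keep]


def _locus_bins(
    starts, ends, cummax_ends, start: int, end: int, window: int
) -> np.ndarray:
    """Boolean occupancy over the 2*window + INTERIOR_BINS axis for one locus."""
    nbins = 2 * window + INTERIOR_BINS
    occ = np.zeros(nbins, dtype=bool)
    idx = _overlapping(starts, ends, cummax_ends, start - window, end + window)
    if idx.size == 0:
        return occ
    length = max(end - start, 1)
    for a, b in zip(starts[idx], ends[idx]):
        # upstream 1-bp bins
        lo = max(a, start - window)
        hi = min(b, start)
        if hi > lo:
            occ[lo - (start - window) : hi - (start - window)] = True
        # interior, rescaled to INTERIOR_BINS
        lo = max(a, start)
        hi = min(b, end)
        if hi > lo:
            b0 = int((lo - start) * INTERIOR_BINS / length)
            b1 = int(np.ceil((hi - start) * INTERIOR_BINS / length))
            occ[window + b0 : window + min(b1, INTERIOR_BINS)] = True
        # downstream 1-bp bins
        lo = max(a, end)
        hi = min(b, end + window)
        if hi > lo:
            occ[window + INTERIOR_BINS + (lo - end) : window + INTERIOR_BINS + (hi - end)] = True
    return occ


def _offset_samples(
    starts, ends, cummax_ends, loci_bounds, window: int
) -> np.ndarray:
    """Pooled repeat-midpoint offsets on the common axis, over all loci.

    Upstream offsets are bp in [-window, 0); interior midpoints rescale to
    [0, INTERIOR_BINS); downstream to [INTERIOR_BINS, INTERIOR_BINS+window).
    """
    offsets = []
    for _, start, end in loci_bounds:
        idx = _overlapping(starts, ends, cummax_ends, start - window, end + window)
        if idx.size == 0:
            continue
        length = max(end - start, 1)
        mids = (starts[idx] + ends[idx]) / 2.0
        for mid in mids:
            if mid < start - window or mid >= end + window:
                continue
            if mid < start:
                offsets.append(mid - start)  # [-window, 0)
            elif mid < end:
                offsets.append((mid - start) * INTERIOR_BINS / length)
            else:
                offsets.append(INTERIOR_BINS + (mid - end))
    return np.array(offsets)


def positional_profile(
    repeats: Sequence[RepeatFeature],
    loci: Sequence,
    null_loci: Optional[Sequence] = None,
    window: int = 200,
    families: Optional[Sequence[str]] = None,
) -> List[FlankProfile]:
    """Per-family occupancy profile around ``loci``, KS-tested against
    ``null_loci`` (matched random loci) when given.

    Per-bin frequency = fraction of loci for which at least one repeat of
    the family overlaps that (rescaled) bin.
    """
    if not loci:
        raise ValueError("no loci")
    if families is None:
        families = sorted({r.family for r in repeats})
    bounds = [_locus_bounds(l) for l in loci]
    null_bounds = [_locus_bounds(l) for l in null_loci] if null_loci else None
    axis = _axis_labels(window)
    profiles = []
    for family in families:
        per_chrom = _repeats_by_chrom(repeats, family)
        empty = (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
        )
        occ_sum = np.zeros(2 * window + INTERIOR_BINS)
        for chrom, start, end in bounds:
            s, e, cm = per_chrom.get(chrom, empty)
            occ_sum += _locus_bins(s, e, cm, start, end, window)
        freq = occ_sum / len(bounds)
        stat, p = 0.0, 1.0
        if null_bounds is not None:
            obs_off, null_off = [], []
            for chrom in {c for c, _, _ in bounds} | {c for c, _, _ in null_bounds}:
                s, e, cm = per_chrom.get(chrom, empty)
                obs_off.append(
                    _offset_samples(
                        s, e, cm, [b for b in bounds if b[0] == chrom], window
                    )
                )
                null_off.append(
                    _offset_samples(
                        s, e, cm, [b for b in null_bounds if b[0] == chrom], window
                    )
                )
            try:
                stat, p = ks_enrichment(
                    np.concatenate(obs_off), np.concatenate(null_off)
                )
            except ValueError:
                # too few offsets to test this family; mark untestable
                stat, p = float("nan"), float("nan")
        profiles.append(
            FlankProfile(
                family=family,
                offsets=axis,
                frequency=[float(f) for f in freq],
                n_loci=len(bounds),
                ks_statistic=float(stat),
                p_value=float(p),
            )
        )
    return profiles


def ks_enrichment(
    observed_offsets: np.ndarray, null_offsets: np.ndarray
) -> Tuple[float, float]:
    """Two-sample KS test of repeat-offset distributions (NUMT vs null).

    Returns (statistic, p); identical samples give (0, 1).
    """
    observed_offsets = np.asarray(observed_offsets, dtype=float)
    null_offsets = np.asarray(null_offsets, dtype=float)
    if observed_offsets.size < 8 or null_offsets.size < 8:
        raise ValueError("need at least 8 offsets per side")
    if observed_offsets.size == null_offsets.size and np.array_equal(
        np.sort(observed_offsets), np.sort(null_offsets)
    ):
        return 0.0, 1.0
    stat, p = sps.ks_2samp(observed_offsets, null_offsets)
    return float(stat), float(p)
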
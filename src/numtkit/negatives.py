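"""Matched random-interval background sampling.

For every chromosome, draw as many random loci as it carries NUMTs, each
length-matched to one NUMT, giving a balanced negative class whose length
multiset equals the NUMT length multiset exactly.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .models import GenomeSequence, NegativeSample


class SamplingError(RuntimeError):
    pass


def sample_negatives(
    numts: Sequence,
    genome: Sequence[GenomeSequence],
    seed=None,
    avoid_numt_overlap: bool = True,
    max_n_fraction: float = 0.5,
    max_retries: int = 500,
) -> List[NegativeSample]:
    """One uniform random locus per NUMT, on the same chromosome, same length.

    With ``avoid_numt_overlap`` (default), draws overlapping any NUMT on
    that chromosome are rejected and redrawn, as are draws with more than
    ``max_n_fraction`` N bases; both guards are bounded by ``max_retries``.
    ``numts`` may be NumtCall or PlantedNumt records (any object with
    chromosome_id / nuclear_start / nuclear_end).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom_by_id = {c.id: c for c in genome}
    numt_ivs: dict = {}
    for i, nt in enumerate(numts):
        if nt.chromosome_id not in chrom_by_id:
            raise SamplingError(f"chromosome {nt.chromosome_id} not in genome")
        numt_ivs.setdefault(nt.chromosome_id, []).append(
            (nt.nuclear_start, nt.nuclear_end)
        )

    out: List[NegativeSample] = []
    for i, nt in enumerate(numts):
        chrom = chrom_by_id[nt.chromosome_id]
        length = nt.nuclear_end - nt.nuclear_start
        limit = len(chrom) - length
        if limit < 0:
            raise SamplingError(
                f"chromosome {chrom.id} shorter than required length {length}"
            )
        ivs = numt_ivs[nt.chromosome_id] if avoid_numt_overlap else []
        for attempt in range(max_retries):
            start = int(rng.integers(0, limit + 1))
            end = start + length
            if any(start < e and b < end for b, e in ivs):
                continue
            seq = chrom.sequence[start:end]
            if length > 0 and seq.count("N") / length > max_n_fraction:
                continue
            out.append(
                NegativeSample(
                    chromosome_id=chrom.id,
                    start=start,
                    end=end,
                    matched_numt_id=i,
                    sequence=seq,
                )
            )
            break
        else:
            raise SamplingError(
                f"retries exhausted sampling a {length} bp locus on {chrom.id}"
            )
    return out
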
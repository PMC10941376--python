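"""Sequence descriptors computed from first principles.

Implements the descriptor families used for NUMT-vs-random classification:
nucleic acid composition (NAC), k-mer frequencies/counts (type 1/2),
reverse-complement-pooled k-mers (RCKmer type 1/2), normalized
Moreau-Broto autocorrelation of dinucleotide physicochemical properties
(NMBroto), Z-curve components, and the Hamming-neighbourhood mismatch
profile.  Windows containing N are excluded from counts and normalizers.
"""

from __future__ import annotations

import functools
import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import DescriptorConfig
from .seqs import encode, reverse_complement

# Mean dinucleotide step parameters of B-DNA from protein-DNA crystal
# structures (Olson et al. 1998): twist/tilt/roll in degrees, shift/slide/
# rise in Angstrom.  Values of complementary steps mirror with the sign of
# tilt and shift flipped.  Standardized (mean 0, sd 1 over the 16 steps)
# before use.
DINUCLEOTIDE_PROPERTIES: Dict[str, Dict[str, float]] = {
    "Twist": {
        "AA": 35.1, "AC": 31.5, "AG": 31.9, "AT": 29.3,
        "CA": 37.3, "CC": 32.9, "CG": 36.1, "CT": 31.9,
        "GA": 36.3, "GC": 33.6, "GG": 32.9, "GT": 31.5,
        "TA": 37.8, "TC": 36.3, "TG": 37.3, "TT": 35.1,
    },
    "Tilt": {
        "AA": -1.4, "AC": -0.5, "AG": -1.7, "AT": 0.0,
        "CA": 0.5, "CC": -0.1, "CG": 0.0, "CT": 1.7,
        "GA": -1.5, "GC": 0.0, "GG": 0.1, "GT": 0.5,
        "TA": 0.0, "TC": 1.5, "TG": -0.5, "TT": 1.4,
    },
    "Roll": {
        "AA": 0.7, "AC": 0.7, "AG": 4.5, "AT": 1.1,
        "CA": 4.7, "CC": 3.6, "CG": 5.4, "CT": 4.5,
        "GA": 1.9, "GC": 0.3, "GG": 3.6, "GT": 0.7,
        "TA": 3.3, "TC": 1.9, "TG": 4.7, "TT": 0.7,
    },
    "Shift": {
        "AA": -0.03, "AC": 0.13, "AG": 0.09, "AT": 0.0,
        "CA": 0.09, "CC": 0.05, "CG": 0.0, "CT": -0.09,
        "GA": -0.28, "GC": 0.0, "GG": -0.05, "GT": -0.13,
        "TA": 0.0, "TC": 0.28, "TG": -0.09, "TT": 0.03,
    },
    "Slide": {
        "AA": -0.08, "AC": -0.58, "AG": -0.25, "AT": -0.59,
        "CA": 0.53, "CC": -0.22, "CG": 0.41, "CT": -0.25,
        "GA": 0.09, "GC": -0.38, "GG": -0.22, "GT": -0.58,
        "TA": 0.05, "TC": 0.09, "TG": 0.53, "TT": -0.08,
    },
    "Rise": {
        "AA": 3.27, "AC": 3.36, "AG": 3.34, "AT": 3.31,
        "CA": 3.33, "CC": 3.42, "CG": 3.39, "CT": 3.34,
        "GA": 3.37, "GC": 3.40, "GG": 3.42, "GT": 3.36,
        "TA": 3.42, "TC": 3.37, "TG": 3.33, "TT": 3.27,
    },
}

_DINUCS = ["".join(p) for p in itertools.product("ACGT", repeat=2)]


@functools.lru_cache(maxsize=1)
def standardized_properties() -> Dict[str, np.ndarray]:
    """Property values per dinucleotide index (4a+b), mean 0 / sd 1."""
    out = {}
    for name, table in DINUCLEOTIDE_PROPERTIES.items():
        vals = np.array([table[d] for d in _DINUCS], dtype=float)
        out[name] = (vals - vals.mean()) / vals.std()
    return out


def _kmers(k: int) -> List[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


@functools.lru_cache(maxsize=8)
def canonical_kmers(k: int) -> Tuple[Tuple[str, ...], np.ndarray]:
    """Canonical (lexicographically smaller of self/revcomp) k-mer keys and
    the mapping from all 4^k k-mer indices onto them."""
    kmers = _kmers(k)
    canon = sorted({min(w, reverse_complement(w)) for w in kmers})
    pos = {w: i for i, w in enumerate(canon)}
    mapping = np.array(
        [pos[min(w, reverse_complement(w))] for w in kmers], dtype=np.int64
    )
    return tuple(canon), mapping


@functools.lru_cache(maxsize=8)
def _mismatch_neighbourhood(k: int, m: int) -> np.ndarray:
    """Boolean (4^k, 4^k) matrix: Hamming distance <= m."""
    n = 4**k
    idx = np.arange(n)
    digits = np.stack([(idx // 4**i) % 4 for i in range(k)], axis=1)
    dist = (digits[:, None, :] != digits[None, :, :]).sum(axis=2)
    return (dist <= m).astype(np.float64)


def _window_counts(codes: np.ndarray, k: int) -> Tuple[np.ndarray, int]:
    """Counts of N-free k-windows by integer code, plus the valid-window count."""
    n = codes.size - k + 1
    if n <= 0:
        raise ValueError(f"sequence shorter than k={k}")
    c64 = codes.astype(np.int64)
    vals = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        w = c64[j : j + n]
        vals = vals * 4 + np.where(w == 4, 0, w)
        invalid |= w == 4
    vals = vals[~invalid]
    counts = np.bincount(vals, minlength=4**k).astype(float)
    return counts, vals.size


def nac(sequence: str) -> np.ndarray:
    """Frequencies of A, C, G, T among non-N bases; sums to 1."""
    codes = encode(sequence)
    counts = np.bincount(codes, minlength=5)[:4].astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous bases")
    return counts / total


def kmer(sequence: str, k: int, type: int = 1) -> np.ndarray:
    """k-mer spectrum: type 1 = frequencies over valid windows, type 2 = raw
    counts; lexicographic order."""
    counts, n_valid = _window_counts(encode(sequence), k)
    if type == 2:
        return counts
    if n_valid == 0:
        raise ValueError("no N-free windows")
    return counts / n_valid


def rckmer(sequence: str, k: int, type: int = 1) -> np.ndarray:
    """k-mer spectrum pooled with reverse complements under canonical keys."""
    counts, n_valid = _window_counts(encode(sequence), k)
    canon, mapping = canonical_kmers(k)
    pooled = np.zeros(len(canon))
    np.add.at(pooled, mapping, counts)
    if type == 2:
        return pooled
    if n_valid == 0:
        raise ValueError("no N-free windows")
    return pooled / n_valid


def nmbroto(
    sequence: str,
    properties: Optional[Dict[str, np.ndarray]] = None,
    nlag: int = 3,
) -> np.ndarray:
    """Normalized Moreau-Broto autocorrelation.

    Maps the L-1 overlapping dinucleotides to standardized property values
    p_1..p_{L-1}; for each property and lag d the descriptor is
    ``sum_i p_i * p_{i+d} / (#valid terms)``.  Order: properties x lags.
    """
    if properties is None:
        properties = standardized_properties()
    codes = encode(sequence)
    L = codes.size
    if L < nlag + 2:
        raise ValueError("sequence shorter than nlag + 2")
    a, b = codes[:-1].astype(np.int64), codes[1:].astype(np.int64)
    valid = (a < 4) & (b < 4)
    din = np.where(valid, a * 4 + b, 0)
    out = []
    for name, vals in properties.items():
        p = vals[din]
        for d in range(1, nlag + 1):
            v = valid[:-d] & valid[d:]
            n_terms = int(v.sum())
            if n_terms == 0:
                out.append(0.0)
            else:
                out.append(float((p[:-d] * p[d:])[v].sum() / n_terms))
    return np.array(out)


def zcurve(sequence: str, variant: str = "phase_9") -> np.ndarray:
    """Z-curve composition components.

    Per phase (or globally) with base frequencies (a, c, g, t):
    x = (a+g)-(c+t) purine/pyrimidine, y = (a+c)-(g+t) amino/keto,
    z = (a+t)-(g+c) weak/strong.
    """
    codes = encode(sequence)

    def _triple(sub: np.ndarray) -> List[float]:
        counts = np.bincount(sub, minlength=5)[:4].astype(float)
        tot = counts.sum()
        if tot == 0:
            return [0.0, 0.0, 0.0]
        a, c, g, t = counts / tot
        return [(a + g) - (c + t), (a + c) - (g + t), (a + t) - (g + c)]

    if variant == "global_3":
        return np.array(_triple(codes))
    if variant == "phase_9":
        if codes.size < 3:
            raise ValueError("phase_9 needs length >= 3")
        return np.array(
            [v for ph in range(3) for v in _triple(codes[ph::3])]
        )
    raise ValueError(f"unknown Z-curve variant {variant!r}")


def mismatch_profile(sequence: str, k: int = 3, m: int = 1) -> np.ndarray:
    """For each k-mer w: fraction of windows within Hamming distance m of w."""
    if m >= k:
        raise ValueError("m must be < k")
    counts, n_valid = _window_counts(encode(sequence), k)
    if n_valid == 0:
        raise ValueError("no N-free windows")
    return (_mismatch_neighbourhood(k, m) @ counts) / n_valid


def feature_names(config: Optional[DescriptorConfig] = None):
    """(names, group per name) in the fixed assembly order."""
    if config is None:
        config = DescriptorConfig()
    k = config.kmer_k
    names: List[str] = []
    groups: List[str] = []

    def add(block: Sequence[str], group: str) -> None:
        names.extend(block)
        groups.extend([group] * len(block))

    add([f"NAC_{b}" for b in "ACGT"], "NAC")
    add([f"Kmer1_{w}" for w in _kmers(k)], "Kmer type 1")
    add([f"Kmer2_{w}" for w in _kmers(k)], "Kmer type 2")
    canon, _ = canonical_kmers(k)
    add([f"RCKmer1_{w}" for w in canon], "RCKmer type 1")
    add([f"RCKmer2_{w}" for w in canon], "RCKmer type 2")
    add(
        [
            f"NMBroto_{p}_lag{d}"
            for p in DINUCLEOTIDE_PROPERTIES
            for d in range(1, config.nmbroto_nlag + 1)
        ],
        "NMBroto",
    )
    if config.zcurve_variant == "phase_9":
        add([f"Zcurve_ph{ph}_{ax}" for ph in range(3) for ax in "xyz"], "Z-curve")
    else:
        add([f"Zcurve_{ax}" for ax in "xyz"], "Z-curve")
    add(
        [f"Mismatch_{w}" for w in _kmers(config.mismatch_k)],
        "Mismatch profile",
    )
    return names, groups


def feature_vector(sequence: str, config: Optional[DescriptorConfig] = None) -> np.ndarray:
    if config is None:
        config = DescriptorConfig()
    return np.concatenate(
        [
            nac(sequence),
            kmer(sequence, config.kmer_k, 1),
            kmer(sequence, config.kmer_k, 2),
            rckmer(sequence, config.kmer_k, 1),
            rckmer(sequence, config.kmer_k, 2),
            nmbroto(sequence, nlag=config.nmbroto_nlag),
            zcurve(sequence, config.zcurve_variant),
            mismatch_profile(sequence, config.mismatch_k, config.mismatch_m),
        ]
    )


def assemble_features(
    sequences: Sequence[str],
    config: Optional[DescriptorConfig] = None,
    ids: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Descriptor table for a batch of sequences.

    Returns ``(table, column -> descriptor group)``; column order is fixed
    by the config, rows are indexed by ``ids`` (or running integers).
    """
    if config is None:
        config = DescriptorConfig()
    if any(len(s) == 0 for s in sequences):
        raise ValueError("sequences must be non-empty")
    names, groups = feature_names(config)
    mat = np.vstack([feature_vector(s, config) for s in sequences])
    index = list(ids) if ids is not None else list(range(len(sequences)))
    df = pd.DataFrame(mat, columns=names, index=index)
    return df, dict(zip(names, groups))
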
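"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory; on-disk BED output
keeps the same convention.  Mitochondrial coordinates are taken modulo the
(circular) mitochondrial genome length, so ``mt_start > mt_end`` denotes an
interval that wraps the origin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass
class GenomeSequence:
    """A named nucleotide sequence over {A, C, G, T, N}.

    ``circular`` marks molecules (mtDNA) whose coordinates wrap.
    """

    id: str
    sequence: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        from .stats import gc_content

        return gc_content(self.sequence)


@dataclass
class NumtCall:
    """One detected NUMT: a local alignment between mtDNA and a chromosome."""

    chromosome_id: str
    nuclear_start: int
    nuclear_end: int
    strand: str  # "+" or "-"
    mt_start: int
    mt_end: int
    score: int
    evalue: float
    identity: float

    def __post_init__(self) -> None:
        if self.nuclear_end <= self.nuclear_start:
            raise ValueError("nuclear_end must exceed nuclear_start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.nuclear_end - self.nuclear_start


@dataclass
class RepeatFeature:
    """One annotated repeat interval (RepeatMasker-style)."""

    chromosome_id: str
    start: int
    end: int
    strand: str
    name: str
    family: str  # class/family label, e.g. "SINE/MIR"
    score: int = 0


@dataclass
class PlantedNumt:
    """Ground-truth record for one simulated NUMT insertion."""

    chromosome_id: str
    nuclear_start: int
    nuclear_end: int
    strand: str
    mt_start: int
    mt_end: int
    realized_substitutions: int = 0
    realized_indels: int = 0

    @property
    def length(self) -> int:
        return self.nuclear_end - self.nuclear_start


@dataclass
class NegativeSample:
    """A random background locus length-matched to one NUMT."""

    chromosome_id: str
    start: int
    end: int
    matched_numt_id: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatFamilySpec:
    """Configuration of one simulated repeat family.

    ``density`` is expected background starts per kb; ``flank_behaviour``
    selects how placement intensity is modulated around planted NUMTs.
    """

    name: str
    family: str
    density_per_kb: float
    flank_behaviour: str  # enriched_upstream | depleted_near | uniform
    mean_length: float = 100.0
    enrichment_factor: float = 5.0
    depletion_factor: float = 0.2


DEFAULT_REPEAT_FAMILIES = (
    RepeatFamilySpec("Simple_repeat", "Simple_repeat", 0.5, "enriched_upstream"),
    RepeatFamilySpec("MIR", "SINE/MIR", 0.5, "depleted_near"),
    RepeatFamilySpec("CR1", "LINE/CR1", 0.5, "uniform"),
)


@dataclass
class LengthModel:
    """NUMT length distribution defined by quantile anchors.

    The quantile function log-linearly interpolates the anchors and
    extrapolates log-linearly in the tails, clipped to
    ``[min_length, max_length]``.  Defaults reproduce the mammalian NUMT
    size distribution: first/third quartiles 121/632 bp, median 248 bp.
    """

    anchors: dict = field(
        default_factory=lambda: {0.25: 121.0, 0.5: 248.0, 0.75: 632.0}
    )
    min_length: int = 50
    max_length: int = 16500

    def __post_init__(self) -> None:
        ps = sorted(self.anchors)
        vals = [self.anchors[p] for p in ps]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("quantile anchors must be strictly increasing")
        if self.min_length <= 0 or self.max_length < self.min_length:
            raise ValueError("invalid length bounds")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator."""

    seed: int = 42
    mt_length: int = 16500
    mt_gc: float = 0.38
    nuclear_gc: float = 0.42
    markov_order: int = 2
    n_chromosomes: int = 3
    chromosome_lengths: Sequence[int] = (500_000, 500_000, 500_000)
    n_numts: int = 600
    substitution_rate: float = 0.05
    indel_rate: float = 0.005
    include_meganumt: bool = False
    include_tandem_double: bool = False
    repeat_families: Sequence[RepeatFamilySpec] = DEFAULT_REPEAT_FAMILIES
    length_model: LengthModel = field(default_factory=LengthModel)
    # nuclear CpG depletion factor; mammalian nuclear genomes show ~4-5x
    # depletion of CpG relative to expectation while mtDNA does not.
    nuclear_cpg_factor: float = 0.25
    mt_cpg_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.mt_length <= 0:
            raise ValueError("mt_length must be positive")
        for gc in (self.mt_gc, self.nuclear_gc):
            if not 0.0 < gc < 1.0:
                raise ValueError(f"GC fraction {gc} outside (0, 1)")
        if not 0.0 <= self.substitution_rate <= 0.5:
            raise ValueError("substitution_rate outside [0, 0.5]")
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths length != n_chromosomes")
        max_len = min(self.length_model.max_length, self.mt_length)
        if min(self.chromosome_lengths) < 10 * max_len:
            raise ValueError("chromosomes must be >= 10x the longest NUMT")


@dataclass
class AlignmentParams:
    """Scoring and filtering parameters of the seed-and-extend caller.

    Defaults follow common LASTAL practice for NUMT mining: +1/-1 match
    scores, affine gaps -7 open / -1 extend, and an e-value cutoff of 1e-3.
    ``lambda_`` and ``karlin_k`` are filled in from the scoring system and
    base composition when left ``None``.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = -7
    gap_extend: int = -1
    seed_length: int = 11
    xdrop: int = 20
    evalue_threshold: float = 1e-3
    lambda_: Optional[float] = None
    karlin_k: Optional[float] = None
    merge_gap: int = 0  # 0 = report each HSP unmerged
    band_width: int = 64

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open > self.mismatch or self.gap_extend > self.mismatch:
            raise ValueError("gap penalties must be <= mismatch score")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")
        if self.lambda_ is not None and self.lambda_ <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class DescriptorConfig:
    """Configuration of the sequence-descriptor set."""

    kmer_k: int = 3
    nmbroto_nlag: int = 3
    zcurve_variant: str = "phase_9"  # or "global_3"
    mismatch_k: int = 3
    mismatch_m: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.kmer_k <= 6:
            raise ValueError("kmer_k outside [1, 6]")
        if self.zcurve_variant not in ("phase_9", "global_3"):
            raise ValueError(f"unknown zcurve variant {self.zcurve_variant!r}")
        if self.mismatch_m >= self.mismatch_k:
            raise ValueError("mismatch_m must be < mismatch_k")


@dataclass
class TuningSpace:
    """Random-search space for the random forest."""

    n_trees: tuple = (3, 200)
    max_depth: tuple = (2, 12)
    max_features: tuple = (5, None)  # None -> all features
    n_draws: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        for lo, hi in (self.n_trees, self.max_depth):
            if hi < lo:
                raise ValueError("empty parameter range")


@dataclass
class ClassifierReport:
    best_params: dict
    per_fold_auroc: list
    mean_auroc: float
    sd_auroc: float
    test_accuracy: float
    confusion: dict  # class -> {"correct": int, "incorrect": int}
    per_class_recall: dict
    grouped_importances: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class FlankProfile:
    """Positional repeat-occupancy profile around one locus class.

    Axis: 200 upstream 1-bp bins (-200..-1), 100 length-rescaled interior
    bins, 200 downstream 1-bp bins (+1..+200).
    """

    family: str
    offsets: list  # bin axis labels, length 500
    frequency: list  # per-bin occupancy fraction in [0, 1]
    n_loci: int
    ks_statistic: float
    p_value: float


@dataclass
class GenomeSummary:
    species_id: str
    nuclear_size: int
    nuclear_gc: float
    mt_size: int
    mt_gc: float
    numt_count: int
    numt_cumulative_length: int
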
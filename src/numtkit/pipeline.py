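"""Pipeline configuration and the end-to-end orchestrator.

``run_all`` executes simulate -> detect -> sample-negatives -> features ->
classify -> flanks -> stats on the synthetic cohort (or on user-provided
genomes), writing every artifact plus a manifest of checksums.  All
randomness derives deterministically from one global seed, so a rerun
with the same config is bitwise identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import classify as _classify
from . import detect as _detect
from . import features as _features
from . import flanks as _flanks
from . import io as _io
from . import negatives as _negatives
from . import simulate as _simulate
from . import stats as _stats
from .models import (
    AlignmentParams,
    DescriptorConfig,
    LengthModel,
    RepeatFamilySpec,
    SimulationConfig,
    TuningSpace,
)

log = logging.getLogger("numtkit")

# hyperparameters reported best for NUMT-vs-random classification:
# 7 trees, depth 3, 50 features per split
BEST_FOREST_PARAMS = {"n_estimators": 7, "max_depth": 3, "max_features": 50}


@dataclass
class PipelineConfig:
    """Per-module configuration blocks plus the single global seed."""

    seed: int = 42
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    descriptors: DescriptorConfig = field(default_factory=DescriptorConfig)
    tuning: Optional[TuningSpace] = None  # None -> skip search, use forest_params
    forest_params: Dict = field(default_factory=lambda: dict(BEST_FOREST_PARAMS))
    flank_window: int = 200
    classify_flanks: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # one global seed drives every module deterministically
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    # -- lossless JSON round-trip -------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # canonicalize to JSON-native types so to_dict o from_dict = id
        d["simulation"]["length_model"]["anchors"] = {
            str(k): v for k, v in self.simulation.length_model.anchors.items()
        }
        d["simulation"]["repeat_families"] = [
            dict(f) for f in d["simulation"]["repeat_families"]
        ]
        d["simulation"]["chromosome_lengths"] = list(
            d["simulation"]["chromosome_lengths"]
        )
        if d["tuning"] is not None:
            for key in ("n_trees", "max_depth", "max_features"):
                d["tuning"][key] = list(d["tuning"][key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if "length_model" in sim:
            lm = dict(sim["length_model"])
            lm["anchors"] = {float(k): v for k, v in lm["anchors"].items()}
            sim["length_model"] = LengthModel(**lm)
        if "repeat_families" in sim:
            sim["repeat_families"] = [
                RepeatFamilySpec(**f) if isinstance(f, dict) else f
                for f in sim["repeat_families"]
            ]
        if "chromosome_lengths" in sim:
            sim["chromosome_lengths"] = tuple(sim["chromosome_lengths"])
        aln = d.pop("alignment", {})
        desc = d.pop("descriptors", {})
        tun = d.pop("tuning", None)
        if tun is not None:
            for key in ("n_trees", "max_depth", "max_features"):
                if key in tun:
                    tun[key] = tuple(tun[key])
            tun = TuningSpace(**tun)
        return cls(
            simulation=SimulationConfig(**sim),
            alignment=AlignmentParams(**aln),
            descriptors=DescriptorConfig(**desc),
            tuning=tun,
            **d,
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage integer seed (< 2^31) from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o))


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def run_all(
    config: PipelineConfig,
    outdir,
    mt_fasta=None,
    genome_fasta=None,
) -> dict:
    """Run every stage; returns the artifact manifest (also written to disk).

    Without ``mt_fasta``/``genome_fasta`` the synthetic cohort is
    generated; with them, the provided genomes are analysed instead (both
    paths must then be given and no truth/repeat simulation happens unless
    simulated).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log.info("run_all: seed=%d outdir=%s", config.seed, outdir)

    simulate_mode = mt_fasta is None and genome_fasta is None
    if not simulate_mode:
        if mt_fasta is None or genome_fasta is None:
            raise ValueError("need both --mt and --genome in non-simulation mode")
        for p in (mt_fasta, genome_fasta):
            if not os.path.exists(p):
                raise FileNotFoundError(p)

    artifacts: List[Path] = []

    # 1. cohort
    if simulate_mode:
        log.info("simulating cohort: %s", config.simulation)
        nuclear, mt, truth, repeats = _simulate.simulate_cohort(config.simulation)
        _io.write_fasta(nuclear, outdir / "nuclear.fa")
        _io.write_fasta([mt], outdir / "mt.fa")
        _io.write_truth_bed(truth, outdir / "truth.bed")
        _io.write_repeat_table(repeats, outdir / "repeats.out")
        artifacts += [
            outdir / "nuclear.fa", outdir / "mt.fa",
            outdir / "truth.bed", outdir / "repeats.out",
        ]
    else:
        mt = _io.read_fasta(mt_fasta)[0]
        mt.circular = True
        nuclear = _io.read_fasta(genome_fasta)
        truth, repeats = [], []

    # 2. detection
    params = _detect.resolve_params(
        config.alignment,
        np.bincount(
            [  # mt composition drives the Karlin statistics
                "ACGT".index(b) for b in mt.sequence if b in "ACGT"
            ],
            minlength=4,
        )
        / max(1, sum(b in "ACGT" for b in mt.sequence)),
    )
    log.info("alignment params resolved: lambda=%.4f K=%.4f",
             params.lambda_, params.karlin_k)
    calls = _detect.call_numts(mt, nuclear, params)
    log.info("detected %d NUMT calls", len(calls))
    _io.write_numt_bed(calls, outdir / "numts.bed")
    _io.write_numt_tsv(calls, outdir / "numts.tsv")
    artifacts += [outdir / "numts.bed", outdir / "numts.tsv"]

    # 3. matched negatives
    neg_seed = derive_seed(config.seed, "negatives")
    log.info("negative sampling seed=%d", neg_seed)
    negatives = _negatives.sample_negatives(calls, nuclear, seed=neg_seed)
    _io.write_negative_bed(negatives, outdir / "negatives.bed")
    _io.write_negative_fasta(negatives, outdir / "negatives.fa")
    artifacts += [outdir / "negatives.bed", outdir / "negatives.fa"]

    # 4. features
    numt_seqs = _io.extract_sequences(calls, nuclear)
    neg_seqs = [s.sequence for s in negatives]
    feats, groups = _features.assemble_features(
        numt_seqs + neg_seqs,
        config.descriptors,
        ids=[f"numt_{i}" for i in range(len(numt_seqs))]
        + [f"random_{i}" for i in range(len(neg_seqs))],
    )
    labels = np.array([1] * len(numt_seqs) + [0] * len(neg_seqs))
    table = feats.copy()
    table.insert(0, "label", labels)
    table.to_csv(outdir / "features.tsv", sep="\t", index_label="sequence_id")
    _write_json(groups, outdir / "feature_groups.json")
    artifacts += [outdir / "features.tsv", outdir / "feature_groups.json"]

    # 5. classification
    cls_seed = derive_seed(config.seed, "classify")
    forest_params = dict(config.forest_params)
    if config.tuning is not None:
        space = dataclasses.replace(config.tuning, seed=cls_seed)
        forest_params, trace = _classify.tune(feats, labels, space)
        trace.to_csv(outdir / "tuning_trace.tsv", sep="\t", index=False)
        artifacts.append(outdir / "tuning_trace.tsv")
    log.info("evaluating forest %s (seed=%d)", forest_params, cls_seed)
    report = _classify.evaluate(
        feats, labels, forest_params, groups=groups, seed=cls_seed
    )
    _write_json(report.to_dict(), outdir / "classification_report.json")
    artifacts.append(outdir / "classification_report.json")

    # 5b. flank classification
    if config.classify_flanks:
        numt_flanks = _flanks.extract_flanks(calls, nuclear, config.flank_window)
        neg_flanks = _flanks.extract_flanks(negatives, nuclear, config.flank_window)
        fseqs = [f["sequence"] for f in numt_flanks] + [
            f["sequence"] for f in neg_flanks
        ]
        flabels = np.array([1] * len(numt_flanks) + [0] * len(neg_flanks))
        ffeats, fgroups = _features.assemble_features(fseqs, config.descriptors)
        freport = _classify.evaluate(
            ffeats, flabels, forest_params, groups=fgroups,
            seed=derive_seed(config.seed, "classify-flanks"),
        )
        _write_json(freport.to_dict(), outdir / "flank_classification_report.json")
        artifacts.append(outdir / "flank_classification_report.json")

    # 6. flank repeat profiles
    if repeats:
        profiles = _flanks.positional_profile(
            repeats, calls, null_loci=negatives, window=config.flank_window
        )
        prof_rows, ks_rows = [], []
        for p in profiles:
            ks_rows.append(
                {"family": p.family, "n_loci": p.n_loci,
                 "ks_statistic": p.ks_statistic, "p_value": p.p_value,
                 "significant": p.p_value < 0.05}
            )
            for off, fr in zip(p.offsets, p.frequency):
                prof_rows.append({"family": p.family, "bin": off, "frequency": fr})
        pd.DataFrame(prof_rows).to_csv(
            outdir / "flank_profiles.tsv", sep="\t", index=False
        )
        pd.DataFrame(ks_rows).to_csv(outdir / "flank_ks.tsv", sep="\t", index=False)
        artifacts += [outdir / "flank_profiles.tsv", outdir / "flank_ks.tsv"]

    # 7. summary statistics
    summary = _stats.summarize_genome("synthetic", nuclear, mt, calls)
    sizes = _stats.size_stats(
        [c.nuclear_end - c.nuclear_start for c in calls], mt_length=len(mt)
    )
    mega = _stats.detect_meganumts(calls, len(mt))
    inv = _stats.involvement_matrix(
        {"synthetic": [(c.mt_start, c.mt_end) for c in calls]},
        {"synthetic": len(mt)},
    )
    pd.DataFrame([summary.__dict__]).to_csv(
        outdir / "genome_summary.tsv", sep="\t", index=False
    )
    _write_json(
        {"size_stats": sizes,
         "meganumt_flags": {f"numt_{i}": m for i, m in enumerate(mega) if m}},
        outdir / "size_stats.json",
    )
    inv.T.to_csv(outdir / "involvement_matrix.tsv", sep="\t")
    artifacts += [
        outdir / "genome_summary.tsv", outdir / "size_stats.json",
        outdir / "involvement_matrix.tsv",
    ]

    config.to_json(outdir / "config.json")
    artifacts.append(outdir / "config.json")

    manifest = {
        "seed": config.seed,
        "n_calls": len(calls),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    _write_json(manifest, outdir / "manifest.json")
    log.info("wrote %d artifacts", len(artifacts))
    return manifest
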
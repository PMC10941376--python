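"""Readers and writers for the on-disk formats.

FASTA via Biopython; NUMT calls, ground truth and negatives as BED6+
(0-based half-open, as everywhere in memory); repeat annotations in the
RepeatMasker ``.out`` whitespace-delimited dialect (1-based closed on
disk, converted on read) so real annotations are drop-in replacements.
"""

from __future__ import annotations

import os
from typing import List, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GenomeSequence, NegativeSample, NumtCall, PlantedNumt, RepeatFeature


def read_fasta(path) -> List[GenomeSequence]:
    """Multi-record FASTA -> GenomeSequence list (sequences uppercased)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    return out


def write_fasta(seqs: Sequence[GenomeSequence], path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s.sequence), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# BED6+ tables

_CALL_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "mt_start", "mt_end", "aln_score", "evalue", "identity",
]


def write_numt_bed(calls: Sequence[NumtCall], path) -> None:
    """Calls as BED6+ (extra: mt_start, mt_end, score, evalue, identity)."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            fh.write(
                f"{c.chromosome_id}\t{c.nuclear_start}\t{c.nuclear_end}\t"
                f"numt_{i}\t0\t{c.strand}\t{c.mt_start}\t{c.mt_end}\t"
                f"{c.score}\t{c.evalue:.6g}\t{c.identity:.6f}\n"
            )


def read_numt_bed(path) -> List[NumtCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            calls.append(
                NumtCall(
                    chromosome_id=f[0],
                    nuclear_start=int(f[1]),
                    nuclear_end=int(f[2]),
                    strand=f[5],
                    mt_start=int(f[6]),
                    mt_end=int(f[7]),
                    score=int(f[8]),
                    evalue=float(f[9]),
                    identity=float(f[10]),
                )
            )
    return calls


def write_numt_tsv(calls: Sequence[NumtCall], path) -> None:
    rows = [
        {
            "chrom": c.chromosome_id, "start": c.nuclear_start,
            "end": c.nuclear_end, "strand": c.strand,
            "mt_start": c.mt_start, "mt_end": c.mt_end,
            "score": c.score, "evalue": c.evalue, "identity": c.identity,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "strand", "mt_start", "mt_end",
        "score", "evalue", "identity",
    ]).to_csv(path, sep="\t", index=False)


def write_truth_bed(truth: Sequence[PlantedNumt], path) -> None:
    """Ground truth as BED6+ (extra: mt_start, mt_end)."""
    with open(path, "w") as fh:
        for i, t in enumerate(truth):
            fh.write(
                f"{t.chromosome_id}\t{t.nuclear_start}\t{t.nuclear_end}\t"
                f"planted_{i}\t0\t{t.strand}\t{t.mt_start}\t{t.mt_end}\n"
            )


def read_truth_bed(path) -> List[PlantedNumt]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                PlantedNumt(
                    chromosome_id=f[0], nuclear_start=int(f[1]),
                    nuclear_end=int(f[2]), strand=f[5],
                    mt_start=int(f[6]), mt_end=int(f[7]),
                )
            )
    return out


def write_negative_bed(negatives: Sequence[NegativeSample], path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(negatives):
            fh.write(
                f"{s.chromosome_id}\t{s.start}\t{s.end}\t"
                f"random_{i}\t0\t+\n"
            )


def write_negative_fasta(negatives: Sequence[NegativeSample], path) -> None:
    write_fasta(
        [
            GenomeSequence(f"random_{i}|{s.chromosome_id}:{s.start}-{s.end}", s.sequence)
            for i, s in enumerate(negatives)
        ],
        path,
    )


# ---------------------------------------------------------------------------
# RepeatMasker ".out" dialect

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query            matching"
    "          repeat         position in repeat\n"
    "score   div. del. ins.  sequence  begin end          (left)   repeat"
    "          class/family  begin  end    (left)  ID\n"
    "\n"
)


def write_repeat_table(repeats: Sequence[RepeatFeature], path) -> None:
    """RepeatMasker-style table (1-based closed coordinates, 3 header lines;
    divergence fields zero-filled)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, r in enumerate(repeats):
            strand = "C" if r.strand == "-" else "+"
            left = 0
            fh.write(
                f"{r.score:5d}  0.0  0.0  0.0  {r.chromosome_id}  "
                f"{r.start + 1} {r.end}  ({left})  {strand}  {r.name}  "
                f"{r.family}  1  {r.end - r.start}  (0)  {i + 1}\n"
            )


def read_repeat_table(path) -> List[RepeatFeature]:
    """Parse the standard ``.out`` whitespace layout.

    The 3 header lines are skipped; 1-based closed begin/end convert to
    0-based half-open; strand 'C' maps to '-'.
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            fields = line.split()
            if not fields:
                continue
            if fields[0] in ("SW", "score"):  # header lines
                continue
            try:
                score = int(fields[0])
            except ValueError:
                continue
            chrom, begin, end = fields[4], int(fields[5]), int(fields[6])
            strand = "-" if fields[8] == "C" else "+"
            out.append(
                RepeatFeature(
                    chromosome_id=chrom,
                    start=begin - 1,
                    end=end,
                    strand=strand,
                    name=fields[9],
                    family=fields[10],
                    score=score,
                )
            )
    return out


def extract_sequences(loci: Sequence, genome: Sequence[GenomeSequence]) -> List[str]:
    """Nuclear interval sequences for calls, truth records or negatives."""
    chrom_by_id = {c.id: c for c in genome}
    seqs = []
    for l in loci:
        start = getattr(l, "nuclear_start", None)
        start = l.start if start is None else start
        end = getattr(l, "nuclear_end", None)
        end = l.end if end is None else end
        seqs.append(chrom_by_id[l.chromosome_id].sequence[start:end])
    return seqs
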
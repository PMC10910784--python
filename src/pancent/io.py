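"""File-format plumbing: FASTA/FASTQ, BED, bedGraph, TSV."""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cenprofile import EnrichmentTrack
from .monomerize import MonomerRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read (name, sequence) pairs from a possibly gzipped FASTQ."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fastq")]


def monomers_to_frame(monomers: list[MonomerRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [m.chrom for m in monomers],
            "start": [m.start for m in monomers],
            "end": [m.end for m in monomers],
            "strand": [m.strand for m in monomers],
            "array_id": [m.array_id for m in monomers],
            "consensus": [m.consensus_name for m in monomers],
            "identity": [m.identity for m in monomers],
            "sequence": [m.sequence for m in monomers],
        }
    )


def frame_to_monomers(df: pd.DataFrame) -> list[MonomerRecord]:
    return [
        MonomerRecord(
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            sequence=row.sequence,
            consensus_name=row.consensus,
            identity=float(row.identity),
            array_id=row.array_id,
        )
        for row in df.itertuples()
    ]


def write_monomer_bed(monomers: list[MonomerRecord], path: str | Path) -> None:
    """BED6: name = array_id, score = round(1000 * identity)."""
    with open(path, "w") as fh:
        for m in monomers:
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.array_id}\t"
                f"{round(1000 * m.identity)}\t{m.strand}\n"
            )


def write_bedgraph(track: EnrichmentTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(track.log2_ratio):
            fh.write(
                f"{track.chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:.6g}\n"
            )


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "value"], header=None
    )
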
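"""FASTA/FASTQ/BED readers and writers (thin biopython wrappers)."""
from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a (multi-record) FASTA file into an ordered name -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | os.PathLike) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read FASTQ into a list of (name, sequence) tuples; qualities are ignored
    (the simulator emits constant qualities and the placer is quality-blind)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_bed(intervals: Sequence[tuple[int, int]], contig: str,
              path: str | os.PathLike,
              names: Sequence[str] | None = None,
              scores: Sequence[float] | None = None,
              strands: Sequence[str] | None = None) -> None:
    """Write 0-based half-open intervals as BED; optional name/score/strand."""
    with open(path, "w") as fh:
        for i, (start, end) in enumerate(intervals):
            row = [contig, str(start), str(end)]
            if names is not None or scores is not None or strands is not None:
                row.append(names[i] if names is not None else str(i))
                row.append(f"{scores[i]:g}" if scores is not None else "0")
                if strands is not None:
                    row.append(strands[i])
            fh.write("\t".join(row) + "\n")


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out
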
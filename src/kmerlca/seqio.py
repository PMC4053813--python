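"""Sequence and report I/O: FASTA/FASTQ (plain or gzipped), TSV tables.

Parsing is delegated to Biopython's SeqIO behind a thin record type;
gzip compression is detected from the ``.gz`` extension.  Non-ACGT
characters (lowercase, IUPAC ambiguity codes) are accepted in sequences
and behave as ambiguous bases in downstream k-mer windows.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional

from Bio import SeqIO

from .classify import ClassificationResult, hit_list_runs
from .evaluate import AccuracyReport

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "read_fastq",
    "read_sequences",
    "read_taxon_map",
    "read_truth",
    "write_hits",
    "parse_hits",
    "write_report",
]


@dataclass
class SequenceRecord:
    id: str
    sequence: str
    description: str = ""
    quality: Optional[str] = None


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> Iterator[SequenceRecord]:
    """Stream FASTA records (wrapped or unwrapped); empty records are errors."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
            desc = rec.description[len(rec.id) :].strip()
            yield SequenceRecord(id=rec.id, sequence=seq, description=desc)


def read_fastq(path) -> Iterator[SequenceRecord]:
    """Stream FASTQ records; qualities are retained but unused downstream."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            desc = rec.description[len(rec.id) :].strip()
            yield SequenceRecord(id=rec.id, sequence=seq, description=desc, quality=qual)


def read_sequences(path) -> Iterator[SequenceRecord]:
    """Dispatch on extension: .fq/.fastq (+.gz) as FASTQ, else FASTA."""
    name = Path(path).name.removesuffix(".gz")
    if name.endswith((".fq", ".fastq")):
        return read_fastq(path)
    return read_fasta(path)


def read_taxon_map(path) -> dict[str, int]:
    """Two-column TSV: sequence-ID, taxon-ID."""
    out: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 TSV columns")
            out[fields[0]] = int(fields[1])
    return out


read_truth = read_taxon_map  # truth sets share the (ID, taxid) TSV layout


def write_hits(results, path) -> None:
    """One tab-separated line per read: C/U, ID, label, length, hit runs."""
    with open(path, "w") as fh:
        for res in results:
            status = "C" if res.classified else "U"
            length = len(res.hit_list)
            fh.write(
                f"{status}\t{res.read_id}\t{res.label}\t{length}\t"
                f"{hit_list_runs(res.hit_list)}\n"
            )


def parse_hits(path) -> list[ClassificationResult]:
    """Inverse of :func:`write_hits` (hit lists re-expanded from runs)."""
    from .classify import HIT_AMBIGUOUS

    out = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            status, read_id, label, _length, *rest = line.rstrip("\n").split("\t")
            hits: list[int] = []
            if rest and rest[0]:
                for token in rest[0].split(" "):
                    key, count = token.split(":")
                    val = HIT_AMBIGUOUS if key == "A" else int(key)
                    hits.extend([val] * int(count))
            out.append(
                ClassificationResult(
                    status="classified" if status == "C" else "unclassified",
                    label=int(label),
                    hit_list=hits,
                    read_id=read_id,
                )
            )
    return out


def write_report(report: AccuracyReport, path) -> None:
    """Accuracy report TSV: rank, A, B, C, D, E, sensitivity, precision."""
    with open(path, "w") as fh:
        fh.write("rank\tA\tB\tC\tD\tE\tsensitivity\tprecision\n")
        for rank, a, b, c, d, e, sens, prec in report.to_rows():
            s = "NA" if sens is None else f"{sens:.6f}"
            p = "NA" if prec is None else f"{prec:.6f}"
            fh.write(f"{rank}\t{a}\t{b}\t{c}\t{d}\t{e}\t{s}\t{p}\n")
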
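"""Small sequence / FASTA / FASTQ helpers shared across the package."""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse-complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # mtime pinned to zero so identical content gives identical bytes
            raw = gzip.GzipFile(path, mode="wb", mtime=0)
            return io.TextIOWrapper(raw, encoding="ascii")
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into an ``{id: sequence}`` dict (uppercased)."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read_id, sequence, quality)`` from a FASTQ(.gz) file."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            yield rec.id, str(rec.seq).upper(), qual


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    """Write ``(read_id, sequence, quality)`` triples as FASTQ(.gz)."""
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
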
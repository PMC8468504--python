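"""Shared sequence records and FASTA input/output.

The pipeline works on two record kinds: nucleotide transcripts (assembled
contigs) and protein sequences (translated open reading frames or peptide
candidates).  Both are thin, validated dataclasses; FASTA parsing and
serialisation are delegated to Biopython.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")

Alphabet = Literal["nucleotide", "protein"]


@dataclass(frozen=True)
class TranscriptRecord:
    """A nucleotide transcript (assembled contig)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.seq:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        _check_alphabet(self.id, self.seq, NUCLEOTIDE_ALPHABET)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; ``*`` is permitted only as a final terminator."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        _check_alphabet(self.id, self.seq, PROTEIN_ALPHABET)
        if "*" in self.seq[:-1]:
            pos = self.seq.index("*")
            raise ValueError(
                f"protein {self.id!r}: internal stop '*' at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.seq)


AnyRecord = Union[TranscriptRecord, ProteinRecord]


def _check_alphabet(rec_id: str, seq: str, alphabet: frozenset) -> None:
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(
                f"record {rec_id!r}: illegal character {ch!r} at position {pos}"
            )


def read_fasta(path: Union[str, os.PathLike, io.TextIOBase],
               alphabet: Alphabet) -> list:
    """Read a FASTA file into validated records.

    Sequences are upper-cased on ingestion; multi-line sequences are
    concatenated, so parsing is insensitive to input line-wrap width.
    Duplicate ids and characters outside the declared alphabet raise
    ``ValueError`` naming the offending record.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    cls = TranscriptRecord if alphabet == "nucleotide" else ProteinRecord
    if isinstance(path, (str, os.PathLike)) and str(path).endswith(".gz"):
        import gzip
        with gzip.open(path, "rt") as fh:
            return read_fasta(fh, alphabet)
    out = []
    seen: set[str] = set()
    for sr in SeqIO.parse(path, "fasta"):
        if sr.id in seen:
            raise ValueError(f"duplicate record id {sr.id!r}")
        seen.add(sr.id)
        desc = sr.description[len(sr.id):].strip() if sr.description else ""
        out.append(cls(id=sr.id, seq=str(sr.seq).upper(), description=desc))
    return out


def write_fasta(records: Iterable[AnyRecord],
                path: Union[str, os.PathLike, io.TextIOBase],
                width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``.

    Output is byte-stable for a fixed input, so bundles can be compared by
    checksum.
    """
    if width < 1:
        raise ValueError("width must be positive")
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    if hasattr(path, "write"):
        FastaWriter(path, wrap=width).write_file(seq_records)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            FastaWriter(fh, wrap=width).write_file(seq_records)
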
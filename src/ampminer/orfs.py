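"""Six-frame open-reading-frame discovery and translation.

Desk-scale stand-in for a full coding-region predictor: every ATG-initiated
ORF reaching an in-frame stop (or, flagged as partial, the transcript end)
is reported on both strands.  Only ATG starts are considered; alternative
initiation is a documented non-goal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import reverse_complement

from .records import TranscriptRecord

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class OrfRecord:
    """An ORF located on the forward-strand coordinate system.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand and include the stop codon when one closes the ORF.
    ``protein`` never carries the terminal ``*``.  ``partial`` marks ORFs
    that ran off the 3' end without a stop codon.
    """

    transcript_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    frame: int
    protein: str
    partial: bool = False

    @property
    def header(self) -> str:
        tag = f"{self.transcript_id}|{self.start}-{self.end}|{self.strand}|{self.frame}"
        return tag + "|partial" if self.partial else tag


def translate(codon_seq: str, frame: int = 0) -> str:
    """Translate a nucleotide string in the given frame (standard code).

    Codons containing ``N`` translate to ``X``; a trailing incomplete codon
    is dropped.  Illegal bases raise ``ValueError``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = codon_seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"illegal base(s) {sorted(bad)} in sequence")
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        out.append("X" if "N" in codon else CODON_TO_AA[codon])
    return "".join(out)


def find_orfs(t: TranscriptRecord, min_aa: int = 50) -> list[OrfRecord]:
    """All ATG-initiated ORFs of ``t`` with protein length >= ``min_aa``.

    Each ATG opens its own ORF (nested starts each reported) running to the
    first in-frame stop, or to the transcript end flagged ``partial``.
    Results are sorted by descending protein length, ties broken by
    (strand, start) ascending — deterministic for a fixed input.

    The default ``min_aa=50`` admits the smallest full precursor handled
    here (22-residue signal + 42-residue defensin = 64 aa) while
    suppressing micro-ORFs in decoy sequence.
    """
    seq = t.seq
    n = len(seq)
    orfs: list[OrfRecord] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            aa = translate(s, frame)
            # stop positions in aa-space, per frame
            for i, res in enumerate(aa):
                if res != "M":
                    continue
                j = i
                while j < len(aa) and aa[j] != "*":
                    j += 1
                partial = j == len(aa)
                protein = aa[i:j]
                if len(protein) < min_aa:
                    continue
                w_start = frame + 3 * i
                w_end = frame + 3 * (j + (0 if partial else 1))
                w_end = min(w_end, n)
                if strand == "+":
                    start, end = w_start, w_end
                else:
                    start, end = n - w_end, n - w_start
                orfs.append(OrfRecord(
                    transcript_id=t.id, start=start, end=end,
                    strand=strand, frame=frame, protein=protein,
                    partial=partial,
                ))
    orfs.sort(key=lambda o: (-len(o.protein), o.strand, o.start))
    return orfs


def orf_nucleotide_seq(t: TranscriptRecord, orf: OrfRecord) -> str:
    """The coding nucleotide sequence of ``orf`` read 5'->3' on its strand."""
    seg = t.seq[orf.start:orf.end]
    return seg if orf.strand == "+" else reverse_complement(seg)
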
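"""In-silico trypsin digestion, MS peptide-evidence matching, and FPKM.

Digest masses are computed with carbamidomethyl cysteine as a fixed
modification (+57.02146 Da per Cys), matching an iodoacetamide-alkylated
bottom-up workflow, so they are directly comparable to observed
precursor masses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import pandas as pd

from .peptides import PeptideCandidate
from .physchem import monoisotopic_mass
from .records import ProteinRecord


@dataclass(frozen=True)
class TrypticPeptide:
    seq: str
    start: int
    end: int
    missed_cleavages: int
    mono_mass_alkylated: float


def _cut_points(parent: str) -> list[int]:
    """Positions after K/R not followed by P, plus both ends."""
    cuts = [0]
    for i, a in enumerate(parent[:-1]):
        if a in "KR" and parent[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(parent))
    return cuts


def tryptic_digest(parent: str, max_missed: int = 1) -> list[TrypticPeptide]:
    """All tryptic products of ``parent`` with <= ``max_missed`` missed cuts.

    Trypsin cleaves C-terminal to K or R except before proline.  Products
    are ordered by (start, end).
    """
    if not parent:
        raise ValueError("empty parent sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    cuts = _cut_points(parent)
    peptides = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            start, end = cuts[i], cuts[j]
            seq = parent[start:end]
            peptides.append(TrypticPeptide(
                seq=seq, start=start, end=end,
                missed_cleavages=j - i - 1,
                mono_mass_alkylated=monoisotopic_mass(
                    seq, cys_carbamidomethyl=True),
            ))
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


Candidate = Union[PeptideCandidate, ProteinRecord, tuple]


def _as_id_seq(c: Candidate) -> tuple[str, str]:
    if isinstance(c, tuple):
        return c
    return c.id, c.seq


def match_evidence(candidates: Sequence[Candidate],
                   observed: Iterable[str],
                   max_missed: int = 1) -> pd.DataFrame:
    """Match observed MS peptides against candidates' tryptic products.

    A match is an observed peptide identical to a tryptic product of the
    candidate (with up to ``max_missed`` missed cleavages).  Returns a
    table with one row per (candidate, observed peptide, position) match.
    """
    rows = []
    observed = list(observed)
    for ob in observed:
        if ob != ob.upper():
            raise ValueError(f"observed peptide {ob!r} must be uppercase")
    for cand in candidates:
        cid, seq = _as_id_seq(cand)
        products = tryptic_digest(seq, max_missed=max_missed)
        for ob in observed:
            for p in products:
                if p.seq == ob:
                    rows.append({
                        "candidate_id": cid, "peptide": ob,
                        "start": p.start, "end": p.end,
                        "missed_cleavages": p.missed_cleavages,
                        "mono_mass_alkylated": p.mono_mass_alkylated,
                    })
    return pd.DataFrame(
        rows, columns=["candidate_id", "peptide", "start", "end",
                       "missed_cleavages", "mono_mass_alkylated"])


def fpkm(count: float, length_nt: int, total_mapped: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if length_nt <= 0:
        raise ValueError("length_nt must be positive")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / ((length_nt / 1_000.0) * (total_mapped / 1_000_000.0))


def fpkm_table(counts: pd.DataFrame, total_mapped: float | None = None
               ) -> pd.DataFrame:
    """Add an ``fpkm`` column to a counts table.

    ``counts`` needs columns transcript_id, fragment_count, length_nt.
    ``total_mapped`` defaults to the table's fragment_count sum.
    """
    required = {"transcript_id", "fragment_count", "length_nt"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing column(s) {sorted(missing)}")
    if total_mapped is None:
        total_mapped = float(counts["fragment_count"].sum())
    out = counts.copy()
    out["fpkm"] = [
        fpkm(c, l, total_mapped)
        for c, l in zip(out["fragment_count"], out["length_nt"])
    ]
    return out
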
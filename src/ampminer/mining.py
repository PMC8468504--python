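"""Motif-anchored selection of candidate AMP precursors from ORFs.

Piscidin-family precursors diverge freely in their mature peptide but keep
a strongly conserved signal peptide; the search therefore anchors on short
signal-peptide motifs (FLVL and MAEPG by default) near the N-terminus
rather than on similarity to known mature peptides.  Two tracks are kept:

* ``piscidin_like`` — motif-positive, length-bounded, cysteine-free mature
  region (piscidins are linear cysteine-free helical peptides);
* ``cysteine_rich`` — any ORF with a predicted signal peptide and >= 4
  cysteines after the cleavage site (defensin/hepcidin/LEAP-2/NK-lysin
  scaffolds), motif policy not applied.

Signal peptides are predicted with a transparent von Heijne-style
heuristic: a Kyte–Doolittle hydrophobic core plus the small-residue
(-3,-1) rule, scored over candidate cleavage positions 15–30.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .orfs import OrfRecord
from .physchem import KYTE_DOOLITTLE

SMALL_RESIDUES = frozenset("AGSCT")  # permitted at -3 and -1


@dataclass(frozen=True)
class MiningConfig:
    """Tunable thresholds of the precursor search.

    ``anchor_motifs`` must occur (all of them when ``require_all``) within
    the first ``anchor_window`` residues.  Length bounds apply to the
    piscidin-like track only; ``max_cys`` is the cysteine budget of its
    mature region (0 = cysteine-free).  ``signal_theta`` is the acceptance
    threshold of the signal-peptide score.
    """

    anchor_motifs: tuple[str, ...] = ("FLVL", "MAEPG")
    anchor_window: int = 30
    require_all: bool = True
    min_precursor_len: int = 60
    max_precursor_len: int = 120
    max_cys: int = 0
    signal_theta: float = 1.5

    def __post_init__(self) -> None:
        if not self.anchor_motifs:
            raise ValueError("need at least one anchor motif")
        for m in self.anchor_motifs:
            if not m or m != m.upper():
                raise ValueError(f"motif {m!r} must be non-empty uppercase")
        if self.anchor_window < max(len(m) for m in self.anchor_motifs):
            raise ValueError("anchor_window shorter than longest motif")


@dataclass(frozen=True)
class PrecursorCandidate:
    """A precursor retained by the mining stage."""

    orf: OrfRecord
    motif_hits: tuple[tuple[str, int], ...]
    signal_cleavage: Optional[int]
    track: str  # "piscidin_like" | "cysteine_rich"
    notes: str = ""

    @property
    def protein(self) -> str:
        return self.orf.protein

    @property
    def mature_region(self) -> str:
        """Sequence downstream of the predicted signal cleavage."""
        if self.signal_cleavage is None:
            return self.protein
        return self.protein[self.signal_cleavage:]


def scan_motifs(protein: str, cfg: MiningConfig = MiningConfig()
                ) -> list[tuple[str, int]]:
    """All exact occurrences of the anchor motifs within the N-window.

    Positions are 0-based; overlapping occurrences are all reported.
    """
    if not protein:
        raise ValueError("empty protein")
    window = protein[:cfg.anchor_window]
    hits: list[tuple[str, int]] = []
    for motif in cfg.anchor_motifs:
        start = 0
        while True:
            pos = window.find(motif, start)
            if pos < 0:
                break
            hits.append((motif, pos))
            start = pos + 1
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def _best_h_window(kd: list[float], c: int,
                   min_w: int = 8, max_w: int = 12) -> float:
    """Best mean Kyte–Doolittle over an h-region adjacent to cleavage c.

    Windows of length 8-12 whose last residue lies in [c-7, c-4] (the
    hydrophobic core of a signal peptide abuts its C-region), starting no
    earlier than position 1.
    """
    best = float("-inf")
    for end in range(c - 7, c - 3):
        for w in range(min_w, max_w + 1):
            i = end - w + 1
            if i < 1:
                continue
            m = sum(kd[i:end + 1]) / w
            if m > best:
                best = m
    return best


def predict_signal_peptide(protein: str, theta: float = 1.5,
                           min_cleavage: int = 15, max_cleavage: int = 30
                           ) -> tuple[Optional[int], float]:
    """Heuristic signal-peptide call: (cleavage position or None, score).

    For each candidate cleavage position c in [min_cleavage, max_cleavage]
    the score is the best mean Kyte–Doolittle hydrophobicity over any
    8–12-residue window ending 4-7 residues before c (the h-region abuts
    the cleavage region), plus a +1 bonus when the residues at -3 and -1
    relative to c are small ({A,G,S,C,T}) — the von Heijne (-3,-1) rule.
    The highest-scoring c wins (smallest c on ties); the call is rejected
    when the best score falls below ``theta``.

    The cleavage position is 0-based: the mature peptide is
    ``protein[c:]``.
    """
    if len(protein) < 25:
        return None, float("-inf")
    if not protein.startswith("M"):
        return None, float("-inf")
    kd = [KYTE_DOOLITTLE.get(a, 0.0) for a in protein]
    best_c: Optional[int] = None
    best_score = float("-inf")
    hi = min(max_cleavage, len(protein) - 1)
    for c in range(min_cleavage, hi + 1):
        score = _best_h_window(kd, c)
        if protein[c - 3] in SMALL_RESIDUES and protein[c - 1] in SMALL_RESIDUES:
            score += 1.0
        if score > best_score:
            best_score = score
            best_c = c
    if best_score < theta:
        return None, best_score
    return best_c, best_score


def mine_precursors(orfs: list[OrfRecord],
                    cfg: MiningConfig = MiningConfig()
                    ) -> list[PrecursorCandidate]:
    """Select precursor candidates from translated ORFs.

    3'-partial ORFs (no stop codon) are excluded: a precursor must be
    complete.  Output order is (transcript id, start) regardless of input
    order.
    """
    out: list[PrecursorCandidate] = []
    for orf in orfs:
        if orf.partial:
            continue
        protein = orf.protein
        hits = scan_motifs(protein, cfg)
        found = {m for m, _ in hits}
        motif_ok = (set(cfg.anchor_motifs) <= found if cfg.require_all
                    else bool(found))
        cleavage, score = predict_signal_peptide(protein, theta=cfg.signal_theta)
        mature = protein[cleavage:] if cleavage is not None else protein
        if (motif_ok
                and cfg.min_precursor_len <= len(protein) <= cfg.max_precursor_len
                and mature.count("C") <= cfg.max_cys):
            out.append(PrecursorCandidate(
                orf=orf, motif_hits=tuple(hits), signal_cleavage=cleavage,
                track="piscidin_like",
                notes=f"signal_score={score:.2f}" if cleavage is not None else "",
            ))
        elif cleavage is not None and mature.count("C") >= 4:
            out.append(PrecursorCandidate(
                orf=orf, motif_hits=tuple(hits), signal_cleavage=cleavage,
                track="cysteine_rich",
                notes=f"signal_score={score:.2f}",
            ))
    out.sort(key=lambda c: (c.orf.transcript_id, c.orf.start, c.orf.end,
                            c.orf.strand, c.orf.frame))
    return out
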
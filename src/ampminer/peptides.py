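"""Candidate peptide derivation from precursors.

Linear AMP candidates are designed from a precursor in two steps: the
first ``parent_len`` residues after the signal-peptide cleavage form the
parent peptide, and shorter candidates are obtained by truncating the
parent at its monobasic (single K or R) processing sites — the three
longest such prefixes by default, mirroring how peptidases trim secreted
peptides.  Cysteine-rich matures are instead released whole at their
propeptide-convertase site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

Rule = Literal["post_signal_parent", "monobasic_truncation", "convertase_mature"]


@dataclass(frozen=True)
class PeptideCandidate:
    """A designed or released peptide with its provenance."""

    id: str
    seq: str
    parent_id: str
    rule: Rule
    cterm_amidated: bool = False
    flagged: bool = False  # incomplete truncation series

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty peptide sequence")
        if self.rule == "monobasic_truncation" and self.seq[-1] not in "KR":
            raise ValueError(
                f"truncation {self.id!r} must end in K or R, got {self.seq[-1]!r}"
            )


def parent_peptide(precursor: str, signal_cleavage: int,
                   parent_len: int = 20, id_prefix: str = "pep") -> PeptideCandidate:
    """The first ``parent_len`` residues after the signal cleavage site."""
    if parent_len < 1:
        raise ValueError("parent_len must be >= 1")
    if signal_cleavage < 0 or signal_cleavage + parent_len > len(precursor):
        raise ValueError(
            f"precursor too short: need {signal_cleavage + parent_len} residues, "
            f"have {len(precursor)}"
        )
    seq = precursor[signal_cleavage:signal_cleavage + parent_len]
    return PeptideCandidate(id=f"{id_prefix}{parent_len}", seq=seq,
                            parent_id=id_prefix, rule="post_signal_parent")


def truncation_series(parent: PeptideCandidate, n_truncations: int = 3
                      ) -> list[PeptideCandidate]:
    """Parent plus its monobasic truncations, longest first.

    Emits every strict prefix of the parent ending in K or R, keeping the
    ``n_truncations`` longest.  When fewer monobasic prefixes exist, the
    shortened series is returned with the parent flagged.  Names carry the
    peptide length as suffix (e.g. a 17-mer from prefix "β-Pte" is
    "β-Pte17").
    """
    prefix = parent.parent_id
    cuts = [L for L in range(len(parent.seq) - 1, 0, -1)
            if parent.seq[L - 1] in "KR"]
    cuts = cuts[:n_truncations]
    flagged = len(cuts) < n_truncations
    series = [PeptideCandidate(id=parent.id, seq=parent.seq,
                               parent_id=prefix, rule=parent.rule,
                               cterm_amidated=parent.cterm_amidated,
                               flagged=flagged)]
    for L in cuts:
        series.append(PeptideCandidate(
            id=f"{prefix}{L}", seq=parent.seq[:L], parent_id=prefix,
            rule="monobasic_truncation",
            cterm_amidated=parent.cterm_amidated))
    return series


def convertase_mature(precursor: str, site_position: int,
                      id_prefix: str = "mat") -> PeptideCandidate:
    """The mature peptide released downstream of a convertase site."""
    if not 0 <= site_position < len(precursor):
        raise ValueError(
            f"site {site_position} out of bounds for precursor of "
            f"length {len(precursor)}"
        )
    seq = precursor[site_position:]
    return PeptideCandidate(id=f"{id_prefix}_mature", seq=seq,
                            parent_id=id_prefix, rule="convertase_mature")
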
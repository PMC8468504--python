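"""Seeded synthetic transcriptomes with planted AMP precursors.

Real discovery data for this pipeline is a venom-gland/fin transcriptome
in which a handful of AMP precursor transcripts hide among tens of
thousands of ordinary transcripts.  This module emulates that situation
at desk scale: it plants family-templated precursor ORFs (piscidin,
defensin, hepcidin, LEAP-2, NK-lysin) among decoy transcripts and emits a
ground-truth table, so recall/precision of every downstream stage can be
measured without sequencing data.

Templates are structural mimics of the family architectures, not copies
of any real precursor.  Generator and detector agree by construction: the
signal-peptide template is M + 2 basic residues + a hydrophobic core +
an A-x-A ending, i.e. exactly the (-3,-1)/h-core pattern the mining
heuristic scores.  The hydrophobic fill alphabet {L,I,F,M} deliberately
omits V and A so that neither the FLVL anchor nor spurious small-residue
(-3,-1) pairs can arise by chance upstream of the true cleavage site.

Expression realism, read simulation and assembly artefacts are
out of scope; the pool is a transcript-level idealisation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .orfs import CODON_TO_AA, translate
from .records import TranscriptRecord

FAMILIES = ("piscidin", "defensin", "hepcidin", "leap2", "nklysin")

# aa -> synonymous codons (standard code), sampled uniformly
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
_STOP_CODONS = _AA_TO_CODONS.pop("*")

_HYDROPHOBIC_CORE = "LIFM"           # no V (FLVL anchor), no W (weak on the
                                     # KD scale), no small residues ((-3,-1))
_MATURE_CATIONIC = "FLAGKSWIVRH"     # piscidin-like mature fill (cys-free)
_POST_CLEAVAGE = "NQHLFKVI"          # first residues after cleavage: no
                                     # small residues (would fake later
                                     # (-3,-1) sites), no R (convertase)
_POST_CLEAVAGE_LEN = 8
_NEUTRAL_FILL = "GSTANQLFPVIH"       # generic fill, no C/K/R/M/D/E/W
_PRO_SAFE = "NQHLFVI"                # prodomain start fill, as above minus K

# mature-region cysteine layouts (indices within the mature/scaffold block)
_DEFENSIN_LEN = 42
_DEFENSIN_CYS = (9, 14, 19, 27, 34, 38)
_HEPCIDIN_LEN = 26                   # starts QSHL, 8 cysteines
_HEPCIDIN_CYS = (6, 9, 12, 14, 17, 19, 22, 24)
_LEAP2_LEN = 46
_LEAP2_CYS = (16, 22, 27, 33)
_NKLYSIN_BLOCK = 75                  # saposin-like block; 6 Cys near its start
_NKLYSIN_CYS = (8, 13, 19, 24, 29, 34)
_NKLYSIN_TAIL = 10

_FAMILY_MATURE_LEN = {
    "defensin": (_DEFENSIN_LEN, _DEFENSIN_LEN),
    "hepcidin": (_HEPCIDIN_LEN, _HEPCIDIN_LEN),
    "leap2": (_LEAP2_LEN, _LEAP2_LEN),
    "nklysin": (_NKLYSIN_BLOCK, _NKLYSIN_BLOCK),
    "piscidin": (40, 60),
}


@dataclass(frozen=True)
class PlantSpec:
    """How many precursors of one family to plant, and their geometry."""

    family: str
    count: int
    signal_len: int = 22
    mature_len_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        min_signal = 17 if self.family == "piscidin" else 8
        if self.signal_len < min_signal:
            raise ValueError(
                f"signal_len {self.signal_len} below the {self.family} "
                f"template footprint ({min_signal})")
        rng_ = self.mature_len_range
        if rng_ is not None:
            lo, hi = rng_
            if not (10 <= lo <= hi <= 120):
                raise ValueError("mature_len_range must lie within [10, 120]")
            flo, fhi = _FAMILY_MATURE_LEN[self.family]
            if hi < flo or lo > fhi:
                raise ValueError(
                    f"mature_len_range {rng_} incompatible with the "
                    f"{self.family} scaffold ({flo}-{fhi})")

    @property
    def effective_mature_range(self) -> tuple[int, int]:
        if self.mature_len_range is not None:
            lo, hi = self.mature_len_range
            flo, fhi = _FAMILY_MATURE_LEN[self.family]
            return max(lo, flo), min(hi, fhi)
        return _FAMILY_MATURE_LEN[self.family]


@dataclass(frozen=True)
class GroundTruthEntry:
    """Where one precursor was planted and what it encodes.

    ``precursor_start`` is the 0-based offset of the ATG on the *reading*
    strand: the transcript itself for ``+`` plants, its reverse complement
    for ``-`` plants.  Translating from that offset to the first stop
    reproduces the precursor protein.
    """

    transcript_id: str
    family: str
    precursor_start: int
    strand: str
    signal_peptide: str
    mature_peptide: str
    motifs_present: tuple[str, ...]


def _choice(rng: np.random.Generator, pool: str | Sequence[str]) -> str:
    return pool[int(rng.integers(len(pool)))]


def _fill(rng: np.random.Generator, n: int, pool: str) -> str:
    return "".join(_choice(rng, pool) for _ in range(n))


def _signal(rng: np.random.Generator, signal_len: int,
            piscidin: bool) -> str:
    """Signal template: M + basics + hydrophobic core + A-x-A."""
    if piscidin:
        head = "MAEPG" + "FLVL"
    else:
        head = "M" + _fill(rng, 2, "KR")
    core = _fill(rng, signal_len - len(head) - 3, _HYDROPHOBIC_CORE)
    return head + core + "A" + _choice(rng, _HYDROPHOBIC_CORE) + "A"


def _with_cys(rng: np.random.Generator, length: int,
              cys_at: Sequence[int], pool: str) -> str:
    out = [_choice(rng, pool) for _ in range(length)]
    for i in cys_at:
        out[i] = "C"
    return "".join(out)


def _plant_protein(rng: np.random.Generator, spec: PlantSpec
                   ) -> tuple[str, str, str, tuple[str, ...]]:
    """(precursor protein, signal, mature, motifs) for one plant."""
    fam = spec.family
    signal = _signal(rng, spec.signal_len, piscidin=fam == "piscidin")
    k = _POST_CLEAVAGE_LEN
    if fam == "piscidin":
        lo, hi = spec.effective_mature_range
        n = int(rng.integers(lo, hi + 1))
        mature = (_fill(rng, k, _POST_CLEAVAGE.replace("N", "W") + "R")
                  + _fill(rng, n - k, _MATURE_CATIONIC))
        return signal + mature, signal, mature, ("FLVL", "MAEPG")
    if fam == "defensin":
        mature = (_fill(rng, k, _PRO_SAFE)
                  + _with_cys(rng, _DEFENSIN_LEN - k,
                              [i - k for i in _DEFENSIN_CYS], _NEUTRAL_FILL))
        return signal + mature, signal, mature, ()
    if fam == "hepcidin":
        pro = _fill(rng, k, _PRO_SAFE) + _fill(rng, 32 - k, _NEUTRAL_FILL) + "RSKR"
        mature = "QSHL" + _with_cys(rng, _HEPCIDIN_LEN - 4,
                                    [i - 4 for i in _HEPCIDIN_CYS],
                                    _NEUTRAL_FILL.replace("H", ""))
        return signal + pro + mature, signal, mature, ("RSKR", "QSHL")
    if fam == "leap2":
        pro = _fill(rng, k, _PRO_SAFE) + _fill(rng, 26 - k, _NEUTRAL_FILL) + "REPR"
        mature = _with_cys(rng, _LEAP2_LEN, _LEAP2_CYS, _NEUTRAL_FILL)
        return signal + pro + mature, signal, mature, ("REPR",)
    # nklysin: saposin-like block right after the signal, short tail
    block = (_fill(rng, k, _PRO_SAFE)
             + _with_cys(rng, _NKLYSIN_BLOCK - k,
                         [i - k for i in _NKLYSIN_CYS], _NEUTRAL_FILL))
    tail = _fill(rng, _NKLYSIN_TAIL, _NEUTRAL_FILL)
    return signal + block + tail, signal, block, ()


def _encode(rng: np.random.Generator, protein: str) -> str:
    return "".join(_choice(rng, _AA_TO_CODONS[aa]) for aa in protein)


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _six_frame_has_motif(seq: str, motifs: Sequence[str]) -> bool:
    for s in (seq, reverse_complement(seq)):
        for f in range(3):
            aa = translate(s, f)
            if any(m in aa for m in motifs):
                return True
    return False


def generate_transcriptome(plants: Sequence[PlantSpec], n_decoys: int,
                           seed: int, gc: float = 0.45
                           ) -> tuple[list[TranscriptRecord], list[GroundTruthEntry]]:
    """Build a seeded transcript pool with planted precursors and decoys.

    Each plant transcript is 5'UTR + ATG..stop + 3'UTR on a random strand,
    with the precursor reverse-translated through uniformly sampled
    synonymous codons.  Decoys are either random-codon ORFs or non-coding
    sequence, rejection-sampled so that no six-frame translation contains
    an anchor motif (FLVL/MAEPG).  The same seed yields byte-identical
    output.
    """
    if len(plants) == 0 and n_decoys == 0:
        raise ValueError("need at least one transcript")
    if n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[TranscriptRecord] = []
    truth: list[GroundTruthEntry] = []
    k = 0
    for spec in plants:
        for _ in range(spec.count):
            k += 1
            tid = f"plant_{spec.family}_{k:04d}"
            protein, signal, mature, motifs = _plant_protein(rng, spec)
            cds = _encode(rng, protein) + _choice(rng, _STOP_CODONS)
            utr5 = _random_nt(rng, int(rng.integers(20, 81)), gc)
            utr3 = _random_nt(rng, int(rng.integers(20, 81)), gc)
            fwd = utr5 + cds + utr3
            strand = "+" if rng.random() < 0.5 else "-"
            seq = fwd if strand == "+" else reverse_complement(fwd)
            start = len(utr5)  # ATG offset on the reading strand
            records.append(TranscriptRecord(id=tid, seq=seq,
                                            description=f"synthetic {spec.family} plant"))
            truth.append(GroundTruthEntry(
                transcript_id=tid, family=spec.family,
                precursor_start=start, strand=strand,
                signal_peptide=signal, mature_peptide=mature,
                motifs_present=motifs))
    anchors = ("FLVL", "MAEPG")
    for d in range(n_decoys):
        tid = f"decoy_{d + 1:04d}"
        while True:
            if rng.random() < 0.5:
                n_codons = int(rng.integers(60, 201))
                aas = "".join(
                    _choice(rng, "ACDEFGHIKLMNPQRSTVWY")
                    for _ in range(n_codons))
                cds = "ATG" + _encode(rng, aas) + _choice(rng, _STOP_CODONS)
                seq = (_random_nt(rng, int(rng.integers(20, 81)), gc) + cds
                       + _random_nt(rng, int(rng.integers(20, 81)), gc))
            else:
                seq = _random_nt(rng, int(rng.integers(300, 1201)), gc)
            if not _six_frame_has_motif(seq, anchors):
                break
        records.append(TranscriptRecord(id=tid, seq=seq,
                                        description="synthetic decoy"))
    return records, truth


def _protected_positions(protein: str, entry: GroundTruthEntry) -> set[int]:
    """Residues that divergence must not touch.

    Anchor motifs, every cysteine of the scaffold, the initiator Met, the
    signal (-3,-1) cleavage context, and the convertase motif (when the
    family has one) are frozen; everything else may drift.
    """
    sl = len(entry.signal_peptide)
    prot: set[int] = {0}
    prot.update({sl - 3, sl - 2, sl - 1})
    for motif in ("FLVL", "MAEPG"):
        start = 0
        while True:
            i = protein.find(motif, start)
            if i < 0:
                break
            prot.update(range(i, i + len(motif)))
            start = i + 1
    prot.update(i for i, a in enumerate(protein) if a == "C")
    if entry.family in ("hepcidin", "leap2"):
        mat_start = len(protein) - len(entry.mature_peptide)
        prot.update(range(mat_start - 4, mat_start))
        if entry.family == "hepcidin":
            prot.update(range(mat_start, mat_start + 4))  # QSHL block
    return prot


def _refresh_truth(entry: GroundTruthEntry, protein: str) -> GroundTruthEntry:
    sl = len(entry.signal_peptide)
    if entry.family in ("hepcidin", "leap2"):
        mature = protein[len(protein) - len(entry.mature_peptide):]
    elif entry.family == "nklysin":
        mature = protein[sl:sl + len(entry.mature_peptide)]
    else:
        mature = protein[sl:]
    return replace(entry, signal_peptide=protein[:sl], mature_peptide=mature)


def mutate_plants(records: Sequence[TranscriptRecord],
                  truth: Sequence[GroundTruthEntry],
                  sub_rate: float, seed: int
                  ) -> tuple[list[TranscriptRecord], list[GroundTruthEntry]]:
    """Model inter-species divergence: substitute unprotected residues.

    Each unprotected precursor residue is substituted with probability
    ``sub_rate`` (to a different residue, never Cys, never a stop); decoys
    pass through unchanged.  The truth table is updated to the mutated
    sequences.
    """
    if not 0.0 <= sub_rate <= 0.2:
        raise ValueError("sub_rate must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    by_id = {e.transcript_id: e for e in truth}
    new_records: list[TranscriptRecord] = []
    new_truth: dict[str, GroundTruthEntry] = {}
    for rec in records:
        entry = by_id.get(rec.id)
        if entry is None:
            new_records.append(rec)
            continue
        s = rec.seq if entry.strand == "+" else reverse_complement(rec.seq)
        protein = orf_protein(rec, entry)
        w_start = entry.precursor_start
        protected = _protected_positions(protein, entry)
        chars = list(s)
        prot_list = list(protein)
        for i, aa in enumerate(protein):
            if i in protected or rng.random() >= sub_rate:
                continue
            options = [a for a in "ADEFGHIKLMNPQRSTVWY" if a != aa]
            new_aa = options[int(rng.integers(len(options)))]
            prot_list[i] = new_aa
            codon = _choice(rng, _AA_TO_CODONS[new_aa])
            chars[w_start + 3 * i:w_start + 3 * i + 3] = codon
        mutated = "".join(chars)
        seq = mutated if entry.strand == "+" else reverse_complement(mutated)
        new_records.append(replace(rec, seq=seq))
        new_truth[rec.id] = _refresh_truth(entry, "".join(prot_list))
    return new_records, [new_truth.get(e.transcript_id, e) for e in truth]


def orf_protein(rec: TranscriptRecord, entry: GroundTruthEntry) -> str:
    """Translate the planted ORF of ``rec`` up to its stop codon."""
    s = rec.seq if entry.strand == "+" else reverse_complement(rec.seq)
    aa = translate(s[entry.precursor_start:], 0)
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


def truth_to_frame(truth: Sequence[GroundTruthEntry]):
    """Ground truth as a DataFrame (motifs semicolon-joined), for TSV."""
    import pandas as pd

    return pd.DataFrame([{
        "transcript_id": e.transcript_id, "family": e.family,
        "strand": e.strand, "precursor_start": e.precursor_start,
        "signal_peptide": e.signal_peptide,
        "mature_peptide": e.mature_peptide,
        "motifs_present": ";".join(e.motifs_present),
    } for e in truth], columns=[
        "transcript_id", "family", "strand", "precursor_start",
        "signal_peptide", "mature_peptide", "motifs_present"])
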
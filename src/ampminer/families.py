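"""Rule-based family classification of AMP precursor candidates.

Each fish AMP family handled here has a diagnostic precursor architecture:

* hepcidin — signal + prodomain + RX(K/R)R convertase site releasing an
  8-cysteine mature peptide (canonically starting QSHL);
* LEAP-2 — signal + prodomain + RXXR site releasing a ~46-residue
  4-cysteine mature peptide;
* β-defensin — no prodomain: a ~42-residue 6-cysteine peptide directly
  after the signal;
* NK-lysin — a saposin-like block (~70-80 residues holding 6 cysteines)
  inside a longer precursor;
* piscidin-like — signal-motif anchors and a cysteine-free mature region.

Classification is a pure function of sequence and rules.  When several
rules fire, precedence is hepcidin > leap2 > defensin > nklysin >
piscidin_like (fixed, documented tie-break).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from typing import Optional

from .mining import PrecursorCandidate

CONVERTASE_PATTERNS = {
    "RXKR_or_RXRR": re.compile(r"(?=R.[KR]R)"),
    "RXXR": re.compile(r"(?=R..R)"),
}

FAMILY_PRECEDENCE = ("hepcidin", "leap2", "defensin", "nklysin", "piscidin_like")


@dataclass(frozen=True)
class FamilyRule:
    """One family's diagnostic thresholds (editable, serialisable)."""

    family: str
    mature_cys_count: int
    mature_len_min: int
    mature_len_max: int
    convertase_kind: Optional[str] = None  # key into CONVERTASE_PATTERNS
    nterm_block: Optional[str] = None      # e.g. "QSHL" for hepcidin
    domain_hint: str = ""


DEFAULT_RULES: tuple[FamilyRule, ...] = (
    FamilyRule("hepcidin", mature_cys_count=8, mature_len_min=20,
               mature_len_max=32, convertase_kind="RXKR_or_RXRR",
               nterm_block="QSHL",
               domain_hint="prodomain removed at propeptide-convertase site"),
    FamilyRule("leap2", mature_cys_count=4, mature_len_min=40,
               mature_len_max=52, convertase_kind="RXXR",
               domain_hint="liver-expressed AMP 2, 46-aa mature"),
    FamilyRule("defensin", mature_cys_count=6, mature_len_min=36,
               mature_len_max=48,
               domain_hint="beta-defensin directly after signal, no prodomain"),
    FamilyRule("nklysin", mature_cys_count=6, mature_len_min=70,
               mature_len_max=80,
               domain_hint="saposin-B-like cysteine block"),
)


@dataclass(frozen=True)
class FamilyCall:
    candidate: PrecursorCandidate
    family: str  # one of FAMILY_PRECEDENCE or "unclassified"
    evidence: tuple[str, ...]
    mature_start: Optional[int]
    mature_end: Optional[int]

    @property
    def mature_seq(self) -> Optional[str]:
        if self.mature_start is None:
            return None
        return self.candidate.protein[self.mature_start:self.mature_end]


def find_convertase_site(protein: str, kind: str) -> list[int]:
    """0-based cleavage positions immediately after a convertase motif.

    ``RXKR_or_RXRR`` matches R-x-[KR]-R, ``RXXR`` matches R-x-x-R;
    overlapping occurrences are all reported.
    """
    if kind not in CONVERTASE_PATTERNS:
        raise ValueError(f"unknown convertase kind {kind!r}")
    if len(protein) < 4:
        return []
    pat = CONVERTASE_PATTERNS[kind]
    return [m.start() + 4 for m in pat.finditer(protein)]


def cys_signature(mature: str) -> tuple[int, list[int]]:
    """(cysteine count, gaps between consecutive cysteines)."""
    idx = [i for i, a in enumerate(mature) if a == "C"]
    gaps = [idx[i + 1] - idx[i] - 1 for i in range(len(idx) - 1)]
    return len(idx), gaps


def _convertase_family(protein: str, post_signal_start: int,
                       rule: FamilyRule) -> Optional[tuple[list[str], int]]:
    """Check a convertase-released mature region against ``rule``."""
    sites = [s for s in find_convertase_site(protein, rule.convertase_kind)
             if s >= post_signal_start]
    for site in sites:
        mature = protein[site:]
        count, _ = cys_signature(mature)
        if (count == rule.mature_cys_count
                and rule.mature_len_min <= len(mature) <= rule.mature_len_max):
            ev = [f"convertase_{rule.convertase_kind}_at_{site}",
                  f"mature_cys_{count}", f"mature_len_{len(mature)}"]
            if rule.nterm_block and mature.startswith(rule.nterm_block):
                ev.append(f"nterm_{rule.nterm_block}")
            return ev, site
    return None


def classify(candidate: PrecursorCandidate,
             rules: tuple[FamilyRule, ...] = DEFAULT_RULES) -> FamilyCall:
    """Assign a candidate to exactly one family (or ``unclassified``).

    Pure function of the candidate sequence and the rule set; evidence
    lists every satisfied predicate of the winning rule.
    """
    protein = candidate.protein
    cleavage = candidate.signal_cleavage
    by_family = {r.family: r for r in rules}
    post_signal = cleavage if cleavage is not None else 0

    results: dict[str, tuple[list[str], int, int]] = {}

    for fam in ("hepcidin", "leap2"):
        rule = by_family.get(fam)
        if rule is None or rule.convertase_kind is None:
            continue
        hit = _convertase_family(protein, post_signal, rule)
        if hit is not None:
            ev, site = hit
            results[fam] = (ev, site, len(protein))

    rule = by_family.get("defensin")
    if rule is not None and cleavage is not None:
        mature = protein[cleavage:]
        count, _ = cys_signature(mature)
        if (count == rule.mature_cys_count
                and rule.mature_len_min <= len(mature) <= rule.mature_len_max):
            results["defensin"] = (
                [f"post_signal_cys_{count}", f"mature_len_{len(mature)}",
                 "no_prodomain"],
                cleavage, len(protein))

    rule = by_family.get("nklysin")
    if rule is not None and cleavage is not None:
        best = None
        for w in range(rule.mature_len_min, rule.mature_len_max + 1):
            for i in range(cleavage, len(protein) - w + 1):
                block = protein[i:i + w]
                count, _ = cys_signature(block)
                if count >= rule.mature_cys_count:
                    best = (i, i + w, count)
                    break
            if best:
                break
        if best:
            i, j, count = best
            results["nklysin"] = (
                [f"saposin_window_{i}_{j}", f"window_cys_{count}"], i, j)

    if candidate.motif_hits:
        mature = protein[post_signal:]
        if mature.count("C") == 0:
            motifs = ";".join(sorted({m for m, _ in candidate.motif_hits}))
            results["piscidin_like"] = (
                [f"anchor_motifs_{motifs}", "mature_cys_free"],
                post_signal, len(protein))

    for fam in FAMILY_PRECEDENCE:
        if fam in results:
            ev, start, end = results[fam]
            return FamilyCall(candidate=candidate, family=fam,
                              evidence=tuple(ev),
                              mature_start=start, mature_end=end)
    return FamilyCall(candidate=candidate, family="unclassified",
                      evidence=(), mature_start=None, mature_end=None)


def rules_to_json(rules: tuple[FamilyRule, ...]) -> str:
    return json.dumps([asdict(r) for r in rules], indent=2)


def rules_from_json(text: str) -> tuple[FamilyRule, ...]:
    return tuple(FamilyRule(**d) for d in json.loads(text))
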
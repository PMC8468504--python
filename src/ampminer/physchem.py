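"""Physicochemical and amphipathicity descriptors for peptides.

Implements the property vector used to rank candidate antimicrobial
peptides: average and monoisotopic masses, a formal ("table convention")
net charge, a pH-dependent Henderson–Hasselbalch charge and the isoelectric
point derived from it, the hydrophobic-residue ratio, the mean
Fauchère–Pliska hydrophobicity H, the Eisenberg hydrophobic moment µH at
100°/residue, and the helical-wheel projection with its charged and
hydrophobic face angles.

Conventions
-----------
* Formal charge counts side chains only: z = (#K + #R) − (#D + #E).
  Histidine and the termini are excluded.  This is the convention under
  which the integer charges of cationic AMP design tables are reported
  (a His-containing 10-mer with 2 K and 1 R prints z = +3).
* The pH model is separate and does include histidine, the free termini
  and all ionisable side chains; it yields fractional charges and the pI.
* The hydrophobic set is {A, C, F, I, L, M, V, W}; G, Y, P and H are not
  counted as hydrophobic for the ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

__all__ = [
    "FAUCHERE_PLISKA", "KYTE_DOOLITTLE", "HYDROPHOBIC_SET", "EXPASY_PKA",
    "average_mass", "monoisotopic_mass", "formal_charge", "ph_charge",
    "isoelectric_point", "hydrophobic_ratio", "mean_hydrophobicity",
    "hydrophobic_moment", "helical_wheel", "profile", "PhyschemProfile",
    "WheelProjection",
]

# Fauchère–Pliska octanol hydrophobicity, the scale used by the Heliquest
# helical-wheel server.
FAUCHERE_PLISKA: Mapping[str, float] = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}

KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

HYDROPHOBIC_SET = frozenset("ACFILMVW")

# Average (isotope-abundance-weighted) residue masses, Da.
AVERAGE_RESIDUE_MASS: Mapping[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_AVERAGE = 18.0153
AMIDATION_AVERAGE = -0.9847  # C-terminal -OH -> -NH2

MONO_RESIDUE_MASS: Mapping[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_MONO = 18.010565
AMIDATION_MONO = -0.98402
CARBAMIDOMETHYL_MONO = 57.02146  # iodoacetamide alkylation, per Cys

# Per-group pKa values ("Expasy-compatible" set; a single pKa per group,
# no positional corrections).
EXPASY_PKA: Mapping[str, float] = {
    "nterm": 7.5, "cterm": 3.55,
    "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    "H": 5.98, "K": 10.0, "R": 12.0,
}
_POSITIVE_GROUPS = ("nterm", "H", "K", "R")
_NEGATIVE_GROUPS = ("cterm", "D", "E", "C", "Y")


def _check_standard(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(AVERAGE_RESIDUE_MASS)
    if bad:
        raise ValueError(
            f"non-standard residue(s) {sorted(bad)}: property undefined"
        )


def average_mass(seq: str, cterm_amidated: bool = False) -> float:
    """Isotope-averaged molecular mass in Da (residues + one water)."""
    _check_standard(seq)
    m = sum(AVERAGE_RESIDUE_MASS[a] for a in seq) + WATER_AVERAGE
    if cterm_amidated:
        m += AMIDATION_AVERAGE
    return m


def monoisotopic_mass(seq: str, cterm_amidated: bool = False,
                      cys_carbamidomethyl: bool = False) -> float:
    """Monoisotopic mass in Da; optional carbamidomethylation of Cys."""
    _check_standard(seq)
    m = sum(MONO_RESIDUE_MASS[a] for a in seq) + WATER_MONO
    if cterm_amidated:
        m += AMIDATION_MONO
    if cys_carbamidomethyl:
        m += CARBAMIDOMETHYL_MONO * seq.count("C")
    return m


def formal_charge(seq: str, cterm_amidated: bool = False) -> int:
    """Table-convention net charge z = (#K + #R) − (#D + #E).

    Histidine and the termini are not counted; C-terminal amidation does
    not change the formal z (it matters only in the pH model).
    """
    del cterm_amidated
    return (seq.count("K") + seq.count("R")) - (seq.count("D") + seq.count("E"))


def ph_charge(seq: str, pH: float = 7.0, cterm_amidated: bool = False,
              pka: Mapping[str, float] = EXPASY_PKA) -> float:
    """Henderson–Hasselbalch net charge at the given pH.

    Sums ±1/(1+10^(±(pH−pKa))) over the N-terminus, the C-terminus (unless
    amidated) and the ionisable side chains D, E, C, Y, H, K, R.
    """
    if not 0 < pH < 14:
        raise ValueError("pH must be in (0, 14)")
    counts = {g: seq.count(g) for g in "DECYHKR"}
    counts["nterm"] = 1
    counts["cterm"] = 0 if cterm_amidated else 1
    z = 0.0
    for g in _POSITIVE_GROUPS:
        z += counts[g] / (1.0 + 10.0 ** (pH - pka[g]))
    for g in _NEGATIVE_GROUPS:
        z -= counts[g] / (1.0 + 10.0 ** (pka[g] - pH))
    return z


def isoelectric_point(seq: str, cterm_amidated: bool = False,
                      pka: Mapping[str, float] = EXPASY_PKA,
                      tol: float = 1e-3) -> float:
    """pH at which the Henderson–Hasselbalch net charge crosses zero.

    Found by bisection on (0, 14); the charge is strictly decreasing in
    pH, so the root is unique when it exists.  If the charge never changes
    sign on the interval, the nearer boundary is returned and
    ``IsoelectricBoundaryWarning`` is issued.
    """
    lo, hi = 1e-9, 14.0 - 1e-9
    zlo = ph_charge(seq, lo, cterm_amidated, pka)
    zhi = ph_charge(seq, hi, cterm_amidated, pka)
    if zlo <= 0.0 or zhi >= 0.0:
        import warnings
        boundary = 0.0 if zlo <= 0.0 else 14.0
        warnings.warn(
            f"net charge does not cross zero on (0, 14); reporting {boundary}",
            IsoelectricBoundaryWarning,
        )
        return boundary
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ph_charge(seq, mid, cterm_amidated, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class IsoelectricBoundaryWarning(UserWarning):
    """The titration curve has no zero crossing in (0, 14)."""


def hydrophobic_ratio(seq: str) -> float:
    """Fraction of residues in the hydrophobic set {A,C,F,I,L,M,V,W}."""
    if not seq:
        raise ValueError("empty sequence")
    return sum(a in HYDROPHOBIC_SET for a in seq) / len(seq)


def mean_hydrophobicity(seq: str,
                        scale: Mapping[str, float] = FAUCHERE_PLISKA) -> float:
    """Arithmetic mean of per-residue scale values (H)."""
    if not seq:
        raise ValueError("empty sequence")
    try:
        return sum(scale[a] for a in seq) / len(seq)
    except KeyError as e:
        raise ValueError(f"residue {e.args[0]!r} missing from scale") from e


def hydrophobic_moment(seq: str,
                       scale: Mapping[str, float] = FAUCHERE_PLISKA,
                       delta_deg: float = 100.0) -> float:
    """Eisenberg hydrophobic-moment magnitude µH, normalised by length.

    µH = (1/N)·|Σ_n h_n · e^(i·n·δ)| with δ = 100° per residue for a
    canonical α-helix.
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 residues")
    delta = math.radians(delta_deg)
    sin_sum = cos_sum = 0.0
    for n, a in enumerate(seq):
        try:
            h = scale[a]
        except KeyError as e:
            raise ValueError(f"residue {a!r} missing from scale") from e
        sin_sum += h * math.sin(n * delta)
        cos_sum += h * math.cos(n * delta)
    return math.hypot(sin_sum, cos_sum) / len(seq)


@dataclass(frozen=True)
class WheelProjection:
    """Helical-wheel geometry: per-residue azimuths and face arcs (degrees)."""

    wheel_angles: tuple[float, ...]
    charged_face_angle: Optional[float]
    hydrophobic_face_angle: Optional[float]


def _smallest_arc(angles: Sequence[float]) -> Optional[float]:
    """Smallest arc (degrees) containing all azimuths, via the largest gap."""
    if not angles:
        return None
    a = sorted(x % 360.0 for x in angles)
    gaps = [a[i + 1] - a[i] for i in range(len(a) - 1)]
    gaps.append(360.0 - (a[-1] - a[0]))
    return 360.0 - max(gaps)


def helical_wheel(seq: str, delta_deg: float = 100.0) -> WheelProjection:
    """Project residues on an ideal helix wheel (residue n at n·δ mod 360).

    The charged face is the smallest arc containing every K/R azimuth; the
    hydrophobic face the analogue over {A,C,F,I,L,M,V,W}.  A face with no
    member residues has angle ``None``.
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 residues")
    angles = tuple((n * delta_deg) % 360.0 for n in range(len(seq)))
    charged = [ang for ang, a in zip(angles, seq) if a in "KR"]
    hydro = [ang for ang, a in zip(angles, seq) if a in HYDROPHOBIC_SET]
    return WheelProjection(
        wheel_angles=angles,
        charged_face_angle=_smallest_arc(charged),
        hydrophobic_face_angle=_smallest_arc(hydro),
    )


@dataclass(frozen=True)
class PhyschemProfile:
    """The full property vector for one peptide."""

    seq: str
    length: int
    avg_mass: float
    mono_mass: float
    formal_charge: int
    ph_charge: float
    pH: float
    pI: float
    hydrophobic_ratio: float
    H_fp: float
    mu_H: float
    wheel: WheelProjection

    @property
    def avg_mass_da(self) -> int:
        """Average mass rounded to the nearest dalton (table view)."""
        return int(round(self.avg_mass))

    @property
    def hydrophobic_pct(self) -> int:
        """Hydrophobic ratio as an integer percent (table view).

        Truncated, not rounded: the AMP-database calculator that design
        tables are quoted from truncates this percentage (9/17 prints as
        52%, not 53%).
        """
        return int(100.0 * self.hydrophobic_ratio)


def profile(seq: str, pH: float = 7.0,
            cterm_amidated: bool = False) -> PhyschemProfile:
    """Compute the complete physicochemical profile of a peptide."""
    return PhyschemProfile(
        seq=seq,
        length=len(seq),
        avg_mass=average_mass(seq, cterm_amidated),
        mono_mass=monoisotopic_mass(seq, cterm_amidated),
        formal_charge=formal_charge(seq, cterm_amidated),
        ph_charge=ph_charge(seq, pH, cterm_amidated),
        pH=pH,
        pI=isoelectric_point(seq, cterm_amidated),
        hydrophobic_ratio=hydrophobic_ratio(seq),
        H_fp=mean_hydrophobicity(seq),
        mu_H=hydrophobic_moment(seq),
        wheel=helical_wheel(seq),
    )
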
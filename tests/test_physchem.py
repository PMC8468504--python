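"""Physicochemical descriptors: masses, charges, pI, H, µH, wheel faces.

The mass tables are cross-checked against pyteomics as an independent
oracle; pI and face angles are checked against brute-force grid scans.
"""

import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as ptmass

from ampminer import (average_mass, formal_charge, helical_wheel,
                      hydrophobic_moment, hydrophobic_ratio,
                      isoelectric_point, mean_hydrophobicity,
                      monoisotopic_mass, ph_charge, profile)
from ampminer.physchem import (EXPASY_PKA, FAUCHERE_PLISKA,
                               IsoelectricBoundaryWarning)

from conftest import random_protein

PEPTIDES = {
    "b-Pte20": "FFKRLKNAFKSARQAWRDYK",
    "b-Pte17": "FFKRLKNAFKSARQAWR",
    "b-Pte13": "FFKRLKNAFKSAR",
    "b-Pte10": "FFKRLKNAFK",
    "g-Pte20": "FFRHLKSLWKGAKAAFRGAR",
    "g-Pte17": "FFRHLKSLWKGAKAAFR",
    "g-Pte13": "FFRHLKSLWKGAK",
    "g-Pte10": "FFRHLKSLWK",
}
# published design grid: (nearest-Da MW, net charge, hydrophobic %)
DESIGN_GRID = {
    "b-Pte20": (2561, 6, 40), "b-Pte17": (2155, 6, 47),
    "b-Pte13": (1613, 5, 46), "b-Pte10": (1299, 4, 50),
    "g-Pte20": (2348, 6, 50), "g-Pte17": (2063, 5, 52),
    "g-Pte13": (1618, 4, 46), "g-Pte10": (1362, 3, 50),
}

aa_text = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=30)


@pytest.mark.parametrize("name", sorted(PEPTIDES))
def test_design_grid_reproduced_cell_exact(name):
    pr = profile(PEPTIDES[name])
    assert (pr.avg_mass_da, pr.formal_charge,
            pr.hydrophobic_pct) == DESIGN_GRID[name]


def test_glycine_masses():
    assert average_mass("G") == pytest.approx(75.07, abs=0.01)
    assert monoisotopic_mass("G") == pytest.approx(75.03203, abs=1e-4)


def test_alkylation_shift_per_cysteine():
    delta = (monoisotopic_mass("CAC", cys_carbamidomethyl=True)
             - monoisotopic_mass("CAC"))
    assert delta == pytest.approx(2 * 57.02146, abs=1e-6)


def test_amidation_shifts():
    assert (average_mass("GAK", cterm_amidated=True)
            - average_mass("GAK")) == pytest.approx(-0.9847, abs=1e-4)
    assert formal_charge("GAK", cterm_amidated=True) == formal_charge("GAK")


def test_nonstandard_residue_rejected():
    with pytest.raises(ValueError):
        average_mass("GXA")


@settings(max_examples=100, deadline=None)
@given(aa_text)
def test_masses_match_pyteomics_oracle(seq):
    assert monoisotopic_mass(seq) == pytest.approx(
        ptmass.calculate_mass(sequence=seq), abs=1e-4)
    # average masses use the Expasy-style residue table; pyteomics derives
    # averages from NIST abundances, so allow a small systematic offset
    assert average_mass(seq) == pytest.approx(
        ptmass.calculate_mass(sequence=seq, average=True), abs=0.1)


@settings(max_examples=100, deadline=None)
@given(aa_text, aa_text)
def test_mass_additivity(a, b):
    assert average_mass(a + b) == pytest.approx(
        average_mass(a) + average_mass(b) - 18.0153, abs=1e-6)


def test_formal_charge_convention():
    assert formal_charge("FFKRLKNAFKSARQAWRDYK") == 6
    assert formal_charge("FFRHLKSLWK") == 3  # His not counted
    assert formal_charge("GGGG") == 0


def test_histidine_half_protonated_at_its_pka():
    ph = EXPASY_PKA["H"]
    assert (ph_charge("GHG", ph) - ph_charge("GGG", ph)) == pytest.approx(
        0.5, abs=1e-9)


def test_acidic_limit_saturates_to_cationic_count():
    seq = "KKRHDE"
    z = ph_charge(seq, 0.001)
    # N-terminus + 2K + R + H fully protonated, acids neutralised
    assert z == pytest.approx(1 + 2 + 1 + 1, abs=0.05)


def test_ph_charge_matches_group_summation_oracle(rng):
    """Independent per-group summation agrees to 1e-6."""
    def oracle(seq, pH):
        total = 1.0 / (1.0 + 10.0 ** (pH - EXPASY_PKA["nterm"]))
        total -= 1.0 / (1.0 + 10.0 ** (EXPASY_PKA["cterm"] - pH))
        for a in seq:
            if a in "HKR":
                total += 1.0 / (1.0 + 10.0 ** (pH - EXPASY_PKA[a]))
            elif a in "DECY":
                total -= 1.0 / (1.0 + 10.0 ** (EXPASY_PKA[a] - pH))
        return total

    for _ in range(50):
        seq = random_protein(rng, int(rng.integers(2, 40)))
        pH = float(rng.uniform(0.5, 13.5))
        assert ph_charge(seq, pH) == pytest.approx(oracle(seq, pH), abs=1e-6)
    assert ph_charge("FFKRLKNAFKSARQAWRDYK", 7.0) == pytest.approx(
        oracle("FFKRLKNAFKSARQAWRDYK", 7.0), abs=1e-6)


def test_ph_charge_strictly_decreasing(rng):
    for _ in range(20):
        seq = random_protein(rng, int(rng.integers(2, 30)))
        values = [ph_charge(seq, p / 10.0) for p in range(5, 136, 5)]
        assert all(a > b for a, b in zip(values, values[1:]))


def _grid_pi(seq):
    best, best_abs = None, float("inf")
    p = 0.001
    while p < 14.0:
        z = abs(ph_charge(seq, p))
        if z < best_abs:
            best, best_abs = p, z
        p += 0.001
    return best


def test_pi_bisection_matches_grid_scan(rng):
    """100 random peptides: bisection pI equals the 0.001-pH grid argmin."""
    for _ in range(100):
        seq = random_protein(rng, int(rng.integers(2, 25)))
        assert isoelectric_point(seq) == pytest.approx(
            _grid_pi(seq), abs=2e-3)


def test_pi_of_neutral_peptide_set_by_termini():
    assert isoelectric_point("GGGG") == pytest.approx(_grid_pi("GGGG"),
                                                      abs=2e-3)


def test_appending_lysine_never_lowers_pi(rng):
    for _ in range(20):
        seq = random_protein(rng, int(rng.integers(2, 20)))
        assert isoelectric_point(seq + "K") >= isoelectric_point(seq) - 2e-3


def test_pi_boundary_flagged_when_no_crossing():
    with pytest.warns(IsoelectricBoundaryWarning):
        assert isoelectric_point("KKKK", cterm_amidated=True) == 14.0


def test_hydrophobic_ratio_set_membership():
    assert hydrophobic_ratio("FFKRLKNAFKSARQAWRDYK") == pytest.approx(8 / 20)
    assert hydrophobic_ratio("FFRHLKSLWKGAKAAFRGAR") == pytest.approx(10 / 20)
    assert hydrophobic_ratio("KKKK") == 0.0
    assert hydrophobic_ratio("GYPH") == 0.0  # G, Y, P, H all excluded


@pytest.mark.parametrize("seq,H,mu", [
    ("FFRHLKSLWKGAKAAFR", 0.414, 0.647),
    ("FFRHLKSLWKGAKAAFRGAR", 0.317, 0.556),
])
def test_published_helix_parameters(seq, H, mu):
    assert mean_hydrophobicity(seq) == pytest.approx(H, abs=0.005)
    assert hydrophobic_moment(seq) == pytest.approx(mu, abs=0.005)


def test_mean_hydrophobicity_of_glycine_is_zero():
    assert mean_hydrophobicity("GG") == 0.0


def test_moment_of_18mer_homopolymer_vanishes():
    # 18 residues x 100 deg = 5 full turns; the vectors cancel
    assert hydrophobic_moment("L" * 18) == pytest.approx(0.0, abs=1e-9)


@settings(max_examples=100, deadline=None)
@given(aa_text)
def test_moment_bounded_by_scale_maximum(seq):
    assert 0.0 <= hydrophobic_moment(seq) <= max(FAUCHERE_PLISKA.values())


def test_wheel_angles_are_modular():
    w = helical_wheel("L" * 19)
    assert w.wheel_angles[0] == 0.0
    assert w.wheel_angles[18] == 0.0  # (18*100) mod 360


def test_two_point_charged_arc():
    # K at 0 deg and K at 300 deg: smallest containing arc is 60 deg
    assert helical_wheel("KAAK").charged_face_angle == pytest.approx(60.0)


def test_wheel_no_charges_flagged_none():
    assert helical_wheel("LLLL").charged_face_angle is None


def _rotation_scan_arc(angles):
    if not angles:
        return None
    best = 360.0
    for phi in range(360):
        spread = max(((a - phi) % 360.0) for a in angles)
        best = min(best, spread)
    return best


def test_face_angles_match_rotation_scan_oracle(rng):
    """100 random 20-mers: smallest arc equals the 1-degree rotation scan."""
    for _ in range(100):
        seq = random_protein(rng, 20)
        w = helical_wheel(seq)
        charged = [a for a, r in zip(w.wheel_angles, seq) if r in "KR"]
        hydro = [a for a, r in zip(w.wheel_angles, seq) if r in "ACFILMVW"]
        for got, angles in ((w.charged_face_angle, charged),
                            (w.hydrophobic_face_angle, hydro)):
            want = _rotation_scan_arc(angles)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-6)
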
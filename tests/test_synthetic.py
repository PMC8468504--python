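"""Synthetic transcriptome generator: determinism, truth consistency,
decoy hygiene, divergence model."""

import io

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from ampminer import (PlantSpec, generate_transcriptome, mutate_plants,
                      translate, write_fasta)
from ampminer.simulate import (_protected_positions, orf_protein,
                               truth_to_frame)
from ampminer.pipeline import DEFAULT_PLANTS


def _fasta_bytes(records):
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()


def test_decoys_only_pool():
    records, truth = generate_transcriptome([], n_decoys=5, seed=7)
    assert len(records) == 5
    assert truth == []


def test_piscidin_plants_carry_both_anchors():
    records, truth = generate_transcriptome(
        [PlantSpec("piscidin", 10)], n_decoys=0, seed=1)
    assert len(truth) == 10
    for e in truth:
        assert {"FLVL", "MAEPG"} <= set(e.motifs_present)
        assert "FLVL" in e.signal_peptide
        assert e.signal_peptide.startswith("MAEPG")


def test_same_seed_is_byte_identical():
    a = generate_transcriptome(list(DEFAULT_PLANTS), 30, seed=42)
    b = generate_transcriptome(list(DEFAULT_PLANTS), 30, seed=42)
    assert _fasta_bytes(a[0]) == _fasta_bytes(b[0])
    assert truth_to_frame(a[1]).equals(truth_to_frame(b[1]))
    c = generate_transcriptome(list(DEFAULT_PLANTS), 30, seed=43)
    assert _fasta_bytes(a[0]) != _fasta_bytes(c[0])


def test_truth_mature_recoverable_by_translation(synthetic_pool):
    records, truth = synthetic_pool
    by_id = {r.id: r for r in records}
    for e in truth:
        rec = by_id[e.transcript_id]
        s = rec.seq if e.strand == "+" else reverse_complement(rec.seq)
        aa = translate(s[e.precursor_start:], 0)
        protein = aa[:aa.index("*")]
        assert protein.startswith(e.signal_peptide)
        assert e.mature_peptide in protein


def test_decoys_are_anchor_free_in_nterminal_windows(synthetic_pool):
    """No decoy ORF translation carries FLVL/MAEPG near its start."""
    records, truth = synthetic_pool
    planted = {e.transcript_id for e in truth}
    for rec in records:
        if rec.id in planted:
            continue
        for s in (rec.seq, reverse_complement(rec.seq)):
            for f in range(3):
                aa = translate(s, f)
                for seg in aa.split("*"):
                    m = seg.find("M")
                    if m < 0:
                        continue
                    window = seg[m:m + 30]
                    assert "FLVL" not in window and "MAEPG" not in window


def test_impossible_plant_spec_rejected():
    with pytest.raises(ValueError):
        PlantSpec("piscidin", 1, mature_len_range=(5, 8))
    with pytest.raises(ValueError):
        PlantSpec("defensin", 1, mature_len_range=(10, 20))  # scaffold is 42
    with pytest.raises(ValueError):
        PlantSpec("unknown_family", 1)
    with pytest.raises(ValueError):
        generate_transcriptome([], n_decoys=0, seed=1)


def test_mutate_rate_zero_is_identity(synthetic_pool):
    records, truth = synthetic_pool
    out_records, out_truth = mutate_plants(records, truth, 0.0, seed=5)
    assert [r.seq for r in out_records] == [r.seq for r in records]
    assert out_truth == list(truth)


def test_mutate_preserves_protected_positions(synthetic_pool):
    records, truth = synthetic_pool
    by_id = {r.id: r for r in records}
    mut_records, mut_truth = mutate_plants(records, truth, 0.05, seed=9)
    mut_by_id = {r.id: r for r in mut_records}
    mut_truth_by_id = {e.transcript_id: e for e in mut_truth}
    for e in truth:
        before = orf_protein(by_id[e.transcript_id], e)
        after = orf_protein(mut_by_id[e.transcript_id],
                            mut_truth_by_id[e.transcript_id])
        assert len(before) == len(after)
        for i in _protected_positions(before, e):
            assert before[i] == after[i], (e.transcript_id, i)
        # cysteine scaffold intact
        assert [i for i, a in enumerate(before) if a == "C"] == [
            i for i, a in enumerate(after) if a == "C"]


def test_mutate_updates_truth_sequences(synthetic_pool):
    records, truth = synthetic_pool
    mut_records, mut_truth = mutate_plants(records, truth, 0.1, seed=11)
    mut_by_id = {r.id: r for r in mut_records}
    for e in mut_truth:
        protein = orf_protein(mut_by_id[e.transcript_id], e)
        assert protein.startswith(e.signal_peptide)
        assert e.mature_peptide in protein


def test_mutate_hamming_within_binomial_bounds(synthetic_pool):
    """Observed substitutions ~ Binomial(n_unprotected, rate), 99% band."""
    from scipy.stats import binom

    records, truth = synthetic_pool
    by_id = {r.id: r for r in records}
    rate = 0.1
    mut_records, mut_truth = mutate_plants(records, truth, rate, seed=21)
    mut_by_id = {r.id: r for r in mut_records}
    mut_truth_by_id = {e.transcript_id: e for e in mut_truth}
    n_unprot = 0
    hamming = 0
    for e in truth:
        before = orf_protein(by_id[e.transcript_id], e)
        after = orf_protein(mut_by_id[e.transcript_id],
                            mut_truth_by_id[e.transcript_id])
        protected = _protected_positions(before, e)
        n_unprot += len(before) - len(protected)
        hamming += sum(a != b for a, b in zip(before, after))
    lo, hi = binom.ppf([0.005, 0.995], n_unprot, rate)
    assert lo <= hamming <= hi


def test_mutate_rate_out_of_range_rejected(synthetic_pool):
    records, truth = synthetic_pool
    with pytest.raises(ValueError):
        mutate_plants(records, truth, 0.5, seed=1)
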
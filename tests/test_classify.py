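"""Reciprocal best-hit classification, domain detection, completeness filters."""

import math
import random

import numpy as np
import pytest

from stemkv.classify import (FAMILY_OF_SUBFAMILY, AlignmentHit, ChannelRecord,
                             DomainProfile, ReferenceDB, alignment_missing_filter,
                             calibrate_threshold, completeness_check, detect_domains,
                             karlin_altschul_evalue, local_align, make_aligner,
                             reciprocal_classify)
from stemkv.io_core import SeqEntry, SequenceSet
from stemkv.synthetic_data import (SimulationConfig, TEMPLATES, domain_block_alignment,
                                   emit_sequences, reference_sequence_set,
                                   simulate_gene_tree)

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Local alignment scoring
# ---------------------------------------------------------------------------

def test_textbook_blosum50_local_score():
    """Classic dynamic-programming hand-check: HEAGAWGHEE vs PAWHEAE.

    Under BLOSUM50 with a flat gap cost of 8 per gap character the optimal
    local alignment (AWGHE vs AW-HE) scores 28.
    """
    hit = local_align("HEAGAWGHEE", "PAWHEAE", matrix="BLOSUM50",
                      gap_open=8, gap_extend=8)
    assert hit.raw_score == 28


def test_identity_alignment_is_optimal():
    """Self-alignment attains the self-score, the maximum over equal-length targets."""
    rng = random.Random(1)
    s = "".join(rng.choice(AA) for _ in range(60))
    self_hit = local_align(s, s)
    from Bio.Align import substitution_matrices
    mat = substitution_matrices.load("BLOSUM62")
    assert self_hit.raw_score == sum(mat[c, c] for c in s)
    for _ in range(20):
        other = "".join(rng.choice(AA) for _ in range(60))
        assert local_align(s, other).raw_score <= self_hit.raw_score


def test_evalue_strictly_decreasing_in_score():
    evals = [karlin_altschul_evalue(s, 100, 1000) for s in range(10, 100, 5)]
    assert all(a > b for a, b in zip(evals, evals[1:]))


def test_unknown_residue_is_hard_error():
    with pytest.raises(ValueError, match="unknown residue"):
        local_align("MKV?", "MKV")
    with pytest.raises(ValueError, match="unknown residue"):
        local_align("MK-V", "MKV")  # gapped input not allowed


def test_bit_score_increases_with_raw_score():
    h1 = local_align("MKVLAAGR", "MKVLAAGR")
    h2 = local_align("MKVLAAGR", "WWWWHHHH")
    assert h1.bit_score > h2.bit_score
    assert h1.e_value < h2.e_value


# ---------------------------------------------------------------------------
# Reciprocal classification
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def refdb():
    seqs, ann = reference_sequence_set()
    return ReferenceDB(seqs, ann)


def test_reference_against_itself_recovers_annotations(refdb):
    """Every reference sequence is its own best reciprocal hit."""
    queries = SequenceSet([SeqEntry(r.id.replace("REF_", "Q_", 1), r.species, r.residues)
                           for r in refdb.sequences])
    for mode in ("cohort", "strict"):
        records = reciprocal_classify(queries, refdb, mode=mode)
        assert all(r.reciprocal_valid for r in records)
        for rec in records:
            expected = refdb.annotation[rec.id.replace("Q_", "REF_", 1)]
            assert (rec.family, rec.subfamily) == expected


def test_simulated_sequences_recover_generating_labels(refdb):
    """>=95% of ~200 sequences emitted at the default substitution rate are
    assigned their generating family and subfamily."""
    subs = list(FAMILY_OF_SUBFAMILY) * 3
    cfg = SimulationConfig(n0=len(subs), subfamilies=subs, seed=11)
    tree, truth = simulate_gene_tree(cfg)
    seqs, labels = emit_sequences(tree, truth, substitution_rate=0.05, seed=12)
    assert len(seqs) >= 150
    records = reciprocal_classify(seqs, refdb)
    correct = sum(1 for r in records
                  if (r.family, r.subfamily) == (labels[r.id].family, labels[r.id].subfamily))
    assert correct / len(records) >= 0.95


def test_zero_mutation_recovery_is_perfect(refdb):
    """With no substitutions every emitted sequence gets its generating call."""
    subs = list(FAMILY_OF_SUBFAMILY) * 2
    cfg = SimulationConfig(n0=len(subs), subfamilies=subs, seed=21)
    tree, truth = simulate_gene_tree(cfg)
    seqs, labels = emit_sequences(tree, truth, substitution_rate=0.0, seed=22)
    records = reciprocal_classify(seqs, refdb)
    assert all((r.family, r.subfamily) == (labels[r.id].family, labels[r.id].subfamily)
               for r in records)


def test_poor_evalue_yields_no_call(refdb):
    """A random-residue query whose best E-value misses the cutoff stays uncalled."""
    rng = random.Random(5)
    junk = "".join(rng.choice(AA) for _ in range(80))
    records = reciprocal_classify(SequenceSet([SeqEntry("junk|x", "x", junk)]),
                                  refdb, e_threshold=0.01)
    assert records[0].family is None
    assert records[0].best_hit.e_value >= 0.01


def test_classification_invariant_to_input_order(refdb):
    cfg = SimulationConfig(n0=8, subfamilies=list(FAMILY_OF_SUBFAMILY), seed=31)
    tree, truth = simulate_gene_tree(cfg)
    seqs, _ = emit_sequences(tree, truth, substitution_rate=0.05, seed=32)
    fwd = reciprocal_classify(seqs, refdb)
    rev = reciprocal_classify(SequenceSet(list(reversed(seqs.records))), refdb)
    calls_fwd = {r.id: (r.family, r.subfamily) for r in fwd}
    calls_rev = {r.id: (r.family, r.subfamily) for r in rev}
    assert calls_fwd == calls_rev


# ---------------------------------------------------------------------------
# Domain detection
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def profiles():
    out = []
    for name in ("S1S6_core", "T1", "CNBHD_Clinker", "KCNQ_coiledcoil"):
        prof = DomainProfile(name, domain_block_alignment(name))
        calibrate_threshold(prof, n_shuffles=500, seed=7)
        out.append(prof)
    return out


def test_profile_consensus_scores_present(profiles):
    for prof in profiles:
        flags = detect_domains(prof.consensus(), [prof])
        assert flags[prof.name]


def test_shuffled_sequence_has_no_domains(profiles):
    """A residue-shuffled channel sequence loses every domain block."""
    rng = np.random.default_rng(9)
    shuffled = "".join(rng.permutation(list(TEMPLATES["Shaker"].sequence
                                            + TEMPLATES["KCNQ"].sequence)))
    flags = detect_domains(shuffled, profiles)
    assert not any(flags.values())


def test_synthetic_kcnq_has_coiledcoil_but_no_t1(profiles):
    flags = detect_domains(TEMPLATES["KCNQ"].sequence, profiles)
    assert flags["KCNQ_coiledcoil"] and flags["S1S6_core"]
    assert not flags["T1"]


def test_empty_profile_is_hard_error():
    with pytest.raises(ValueError, match="empty"):
        DomainProfile("T1", SequenceSet([]))


def test_uncalibrated_profile_is_hard_error():
    prof = DomainProfile("T1", domain_block_alignment("T1"))
    with pytest.raises(ValueError, match="threshold"):
        detect_domains("MKV", [prof])


# ---------------------------------------------------------------------------
# Completeness
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("family,flags,expected", [
    ("Kv", {"S1S6_core": True, "T1": True}, True),
    ("Kv", {"S1S6_core": True}, False),
    ("KCNQ", {"S1S6_core": True, "KCNQ_coiledcoil": True}, True),
    ("KCNQ", {"S1S6_core": True, "T1": True}, False),
    # EAG completeness does not require the eag/PAS domain (lost in some Ergs)
    ("EAG", {"S1S6_core": True, "CNBHD_Clinker": True, "EAG_PAS": False}, True),
    ("EAG", {"S1S6_core": True, "EAG_PAS": True}, False),
])
def test_completeness_rules(family, flags, expected):
    rec = ChannelRecord(id="x|sp", species="sp", family=family, subfamily=None)
    assert completeness_check(rec, flags) is expected
    assert rec.complete is expected


def test_completeness_without_family_call_is_hard_error():
    with pytest.raises(ValueError, match="no family call"):
        completeness_check(ChannelRecord(id="x|sp", species="sp"), {})


# ---------------------------------------------------------------------------
# Alignment missing-data filter
# ---------------------------------------------------------------------------

def _aligned(rows):
    return SequenceSet([SeqEntry(f"s{i}|x", "x", row) for i, row in enumerate(rows)])


def test_missing_filter_boundary_is_inclusive():
    """Exactly 10% missing survives; strictly more is removed."""
    keep = "A" * 90 + "-" * 10
    drop = "A" * 89 + "-" * 11
    out = alignment_missing_filter(_aligned([keep, drop]), max_missing=0.10)
    assert out.ids() == ["s0|x"]


def test_missing_filter_counts_x_as_missing():
    out = alignment_missing_filter(_aligned(["A" * 80 + "X" * 20, "A" * 100]), 0.10)
    assert out.ids() == ["s1|x"]


def test_missing_filter_matches_direct_recount():
    """Survivor set equals a brute recount of gap fractions <= threshold."""
    rng = np.random.default_rng(13)
    rows = []
    for _ in range(20):
        frac = rng.uniform(0, 0.3)
        n_gap = int(round(frac * 100))
        row = list("A" * 100)
        for i in rng.choice(100, size=n_gap, replace=False):
            row[i] = "-"
        rows.append("".join(row))
    aln = _aligned(rows)
    out = alignment_missing_filter(aln, 0.10)
    expected = [r.id for r in aln if r.residues.count("-") / 100 <= 0.10]
    assert out.ids() == expected


def test_missing_filter_is_idempotent():
    rng = np.random.default_rng(17)
    rows = ["".join(rng.choice(list("A-"), size=50, p=[0.85, 0.15])) for _ in range(15)]
    once = alignment_missing_filter(_aligned(rows), 0.10)
    twice = alignment_missing_filter(once, 0.10)
    assert once.ids() == twice.ids()


def test_missing_filter_rejects_ragged_alignment():
    with pytest.raises(ValueError, match="ragged"):
        alignment_missing_filter(_aligned(["AAA", "AA"]), 0.10)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.lists(st.sampled_from("ACDE-X"), min_size=30, max_size=30),
                min_size=1, max_size=12))
def test_missing_filter_property_matches_recount(rows):
    """For any alignment, survivors are exactly the rows with missing
    fraction <= threshold, and filtering is idempotent."""
    aln = _aligned(["".join(r) for r in rows])
    out = alignment_missing_filter(aln, 0.10)
    expected = [r.id for r in aln
                if (r.residues.count("-") + r.residues.count("X")) / 30 <= 0.10]
    assert out.ids() == expected
    assert alignment_missing_filter(out, 0.10).ids() == expected
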
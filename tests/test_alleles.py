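"""Flank mapping, reciprocal locus pairing and allelic divergence."""

import numpy as np
import pytest

from lineone import rm_catalog
from lineone.alleles import (
    STATUS_ABSENT,
    STATUS_PRESENT,
    STATUS_UNPLACED,
    AllelicPair,
    aa_divergence,
    allelic_divergence,
    fig_classes,
    map_flanks,
    nt_divergence,
    pair_alleles,
)
from lineone.simulate import SimParams, simulate_family


@pytest.fixture(scope="module")
def matches(sim, elements, intact_calls):
    intact = {
        g: [e for e in elements[g] if intact_calls[g][e.element_id].intact]
        for g in ("A", "B")
    }
    ab = {
        e.element_id: map_flanks(
            e, sim.genomes["A"], sim.genomes["B"], elements["B"], target_genome_id="B"
        )
        for e in intact["A"]
    }
    ba = {
        e.element_id: map_flanks(
            e, sim.genomes["B"], sim.genomes["A"], elements["A"], target_genome_id="A"
        )
        for e in intact["B"]
    }
    return intact, ab, ba


def test_shared_loci_map_present(sim, matches):
    intact, ab, _ = matches
    for e in intact["A"]:
        truth = sim.truth.alleles[e.element_id]
        locus = sim.truth.loci[truth.locus_id]
        m = ab[e.element_id]
        if locus.in_b:
            assert m.status == STATUS_PRESENT, e.element_id
            assert m.consistent
        else:
            assert m.status == STATUS_ABSENT, e.element_id
            assert m.separation < 200


def test_private_insertion_maps_to_empty_site(sim, matches):
    intact, ab, _ = matches
    empty = [
        ab[e.element_id]
        for e in intact["A"]
        if not sim.truth.loci[sim.truth.alleles[e.element_id].locus_id].in_b
    ]
    assert empty, "simulation should contain A-private loci"
    assert all(m.status == STATUS_ABSENT for m in empty)


def test_ambiguous_flanks_unplaced():
    """Duplicated flanks defeat the uniqueness margin."""
    sim = simulate_family(SimParams(seed=3, ambiguous_flanks=True))
    anns = rm_catalog.parse_repeatmasker(sim.rm_out["A"])
    elems = rm_catalog.extract_full_length(anns, sim.genomes["A"], genome_id="A")
    statuses = {}
    for e in elems:
        m = map_flanks(e, sim.genomes["A"], sim.genomes["B"], [], target_genome_id="B")
        statuses[e.element_id] = m.status
    assert STATUS_UNPLACED in statuses.values()


def test_pairing_recovers_locus_classes(sim, matches, intact_calls):
    intact, ab, ba = matches
    pairs = pair_alleles(
        intact["A"], intact["B"], ab, ba, intact_calls["A"], intact_calls["B"]
    )
    classes = fig_classes(pairs)
    # truth tallies from the generator tables
    t = sim.truth
    intact_of = {
        (a.genome, a.locus_id): a.intended_intact for a in t.alleles.values()
    }
    exp = [0, 0, 0, 0, 0]
    for locus_id, lt in t.loci.items():
        ia = intact_of.get(("A", locus_id), None)
        ib = intact_of.get(("B", locus_id), None)
        if ia and ib:
            exp[0] += 1
        elif ia and ib is False:
            exp[1] += 1
        elif ia is False and ib:
            exp[2] += 1
        elif ia and ib is None:
            exp[3] += 1
        elif ia is None and ib:
            exp[4] += 1
    assert list(classes) == exp
    locus_ids = [p.locus_id for p in pairs]
    assert len(locus_ids) == len(set(locus_ids))


def test_pairing_symmetric_under_genome_swap(sim, matches, intact_calls):
    intact, ab, ba = matches
    fwd = fig_classes(
        pair_alleles(
            intact["A"], intact["B"], ab, ba, intact_calls["A"], intact_calls["B"]
        )
    )
    rev = fig_classes(
        pair_alleles(
            intact["B"], intact["A"], ba, ab, intact_calls["B"], intact_calls["A"]
        )
    )
    assert rev == (fwd[0], fwd[2], fwd[1], fwd[4], fwd[3])


def test_empty_inputs_pair_to_nothing():
    assert pair_alleles([], [], {}, {}, {}, {}) == []


def test_nt_divergence_identical_and_planted():
    seq = "ACGT" * 1500
    assert nt_divergence(seq, seq) == 0
    mutated = seq[:100] + "T" + seq[101:]  # A->T substitution
    assert nt_divergence(seq, mutated) == 1


def test_utr_deletion_counts_by_gap_mode():
    # non-repetitive context so the optimal gap placement is unambiguous
    seq = "".join(
        "ACGT"[i] for i in np.random.default_rng(5).integers(0, 4, size=6000)
    )
    deleted = seq[:300] + seq[305:]  # 5-bp deletion
    assert nt_divergence(seq, deleted, gap_mode="per_base") == 5
    assert nt_divergence(seq, deleted, gap_mode="per_event") == 1


def test_per_event_never_exceeds_per_base(rng):
    for _ in range(5):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, size=800))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, size=790))
        assert nt_divergence(a, b, "per_event") <= nt_divergence(a, b, "per_base")


def test_aa_divergence_counts_nonsynonymous_columns():
    aa = "MKVLTAGWYRRNDE"
    assert aa_divergence(aa, aa) == 0
    two_subs = "MKALTAGWYRRNDQ"
    assert aa_divergence(aa, two_subs) == 2


def test_allelic_divergence_wrapper():
    seq = "ACGTTGCA" * 800
    nt, aa = allelic_divergence(seq, seq, "MKVL", "MKVL")
    assert (nt, aa) == (0, 0)
    nt, aa = allelic_divergence(seq, seq[:100] + seq[105:], None, None)
    assert aa is None and nt == 5
    with pytest.raises(ValueError):
        allelic_divergence("", seq)


def test_planted_allelic_substitutions_recovered(sim, elements):
    """With no indel lesions, nt divergence equals the planted substitution
    difference between the two alleles."""
    lookup = {e.element_id: e for g in elements.values() for e in g}
    a_of = {}
    b_of = {}
    for a in sim.truth.alleles.values():
        (a_of if a.genome == "A" else b_of)[a.locus_id] = a
    checked = 0
    for locus_id, ta in a_of.items():
        tb = b_of.get(locus_id)
        if tb is None or ta.n_indels or tb.n_indels:
            continue
        expected = sum(
            1
            for pos in set(ta.subs) | set(tb.subs)
            if ta.subs.get(pos, sim.consensus[pos])
            != tb.subs.get(pos, sim.consensus[pos])
        )
        got = nt_divergence(
            lookup[ta.element_id].sequence, lookup[tb.element_id].sequence,
            gap_mode="per_base",
        )
        assert got == expected, locus_id
        checked += 1
        if checked == 10:
            break
    assert checked == 10
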
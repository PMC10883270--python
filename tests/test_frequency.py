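"""SV-call matching rules, singleton filtering and frequency precedence."""

import subprocess

import pytest

from lineone.frequency import (
    BASIS_CURATED,
    BASIS_DEFAULT_ABSENT,
    BASIS_DEFAULT_FIXED,
    BASIS_DELETION,
    FrequencyEstimate,
    SvCall,
    drop_singletons,
    estimate_frequency,
    locus_frequency,
    match_locus,
)


def _del(start, end, carriers=10, cohort=100, source="s", singleton=False):
    return SvCall(source, "chr1", start, end, "deletion", carriers, cohort,
                  singleton_filtered=singleton)


def _ins(start, end, carriers=10, cohort=100, source="s", curated=False):
    return SvCall(source, "chr1", start, end, "insertion", carriers, cohort,
                  curated=curated)


LOCUS = ("chr1", 0, 6000)


def test_reciprocal_overlap_exact_boundary():
    assert match_locus(LOCUS, True, [_del(300, 5700)])  # 5400 = 0.9*6000, 1.0*5400
    assert match_locus(LOCUS, True, [_del(0, 6000)])  # identity
    assert not match_locus(LOCUS, True, [_del(0, 5399)])  # 5399/6000 = 0.8998


def test_reciprocity_applies_to_the_call_side_too():
    # overlap covers the locus but only half of a double-length deletion
    assert not match_locus(LOCUS, True, [_del(0, 12000)])


def test_shrinking_fraction_never_reduces_matches():
    calls = [_del(0, 5399), _del(300, 5700), _del(0, 12000), _del(2000, 8000)]
    prev = set()
    for f in (0.95, 0.9, 0.8, 0.5, 0.3):
        got = {(c.start, c.end) for c in match_locus(LOCUS, True, calls, f)}
        assert prev <= got
        prev = got


def test_insertion_needs_one_bp_overlap():
    assert match_locus(LOCUS, False, [_ins(5999, 5999)])  # point insertion inside
    assert not match_locus(LOCUS, False, [_ins(7000, 7000)])


def test_curated_record_matches_at_distance_zero_only():
    assert match_locus(LOCUS, False, [_ins(6000, 6000, curated=True)])  # bookended
    assert not match_locus(LOCUS, False, [_ins(6010, 6010, curated=True)])


def test_deletions_ignored_for_reference_absent_locus():
    assert match_locus(LOCUS, False, [_del(0, 6000)]) == []
    assert match_locus(LOCUS, True, [_ins(100, 100)]) == []


def test_drop_singletons():
    calls = [
        _del(0, 10, carriers=1, singleton=True),
        _del(0, 10, carriers=2, singleton=True),
        _del(0, 10, carriers=17, singleton=True),
    ]
    assert [c.carriers for c in drop_singletons(calls)] == [2, 17]
    assert drop_singletons([_del(0, 10, carriers=1, singleton=True)]) == []
    # sources not flagged keep their singletons
    mixed = [_del(0, 10, carriers=1), _del(0, 10, carriers=1, singleton=True)]
    assert [c.singleton_filtered for c in drop_singletons(mixed)] == [False]


def test_default_fixed_and_default_absent():
    fixed = estimate_frequency("L1", [], reference_present=True)
    assert fixed.frequency == 1.0 and fixed.basis == BASIS_DEFAULT_FIXED
    absent = estimate_frequency("L2", [], reference_present=False)
    assert absent.basis == BASIS_DEFAULT_ABSENT
    assert absent.frequency < 0.001 and absent.is_upper_bound
    assert absent.label == "<0.001"
    assert absent.polymorphic


def test_largest_cohort_wins():
    calls = [
        _ins(0, 0, carriers=100, cohort=1000, source="small"),
        _ins(0, 0, carriers=500, cohort=2500, source="big"),
    ]
    est = estimate_frequency("L1", calls, reference_present=False)
    assert est.frequency == pytest.approx(0.2)
    assert est.source_id == "big" and est.cohort_size == 2500


def test_deletion_direction_complement_and_direct():
    call = _del(0, 6000, carriers=25, cohort=100)
    comp = estimate_frequency("L1", [call], True, deletion_direction="complement")
    assert comp.frequency == pytest.approx(0.75) and comp.basis == BASIS_DELETION
    direct = estimate_frequency("L1", [call], True, deletion_direction="direct")
    assert direct.frequency == pytest.approx(0.25)


def test_zero_cohort_rejected():
    bad = SvCall("s", "chr1", 0, 6000, "deletion", 0, 0)
    with pytest.raises(ValueError):
        estimate_frequency("L1", [bad], True)


def test_locus_frequency_pipeline_consistency(sim, pipeline_result):
    """Every focal intact locus gets exactly one estimate; estimates agree
    with the generator's planted frequencies to within 1/cohort."""
    freq = pipeline_result.frequency
    assert len(freq) > 0
    for eid, est in freq.items():
        truth_locus = sim.truth.alleles[eid].locus_id
        true_f = sim.truth.loci[truth_locus].true_freq
        if est.basis in (BASIS_DEFAULT_FIXED,):
            assert true_f == 1.0
        elif est.basis == BASIS_DEFAULT_ABSENT:
            assert true_f < 0.001
        else:
            assert est.frequency == pytest.approx(
                true_f, abs=1.5 / (est.cohort_size or 1)
            )


def test_reciprocal_matching_agrees_with_bedtools(tmp_path, rng):
    """Independent oracle: bedtools intersect -f 0.9 -r on random intervals."""
    loci = []
    calls = []
    for i in range(40):
        s = int(rng.integers(0, 50000))
        loci.append(("chr1", s, s + int(rng.integers(4000, 8000))))
        cs = int(rng.integers(0, 50000))
        calls.append(_del(cs, cs + int(rng.integers(3000, 9000)), source=f"c{i}"))
    a = tmp_path / "loci.bed"
    b = tmp_path / "calls.bed"
    a.write_text("".join(f"chr1\t{s}\t{e}\tL{i}\n" for i, (_, s, e) in enumerate(loci)))
    b.write_text(
        "".join(f"chr1\t{c.start}\t{c.end}\t{c.source_id}\n" for c in calls)
    )
    out = subprocess.run(
        ["bedtools", "intersect", "-a", str(a), "-b", str(b), "-f", "0.9", "-r", "-wa", "-wb"],
        capture_output=True, text=True, check=True,
    ).stdout
    bt_pairs = set()
    for line in out.splitlines():
        f = line.split("\t")
        bt_pairs.add((f[3], f[7]))
    ours = set()
    for i, locus in enumerate(loci):
        for c in match_locus(locus, True, calls, recip_fraction=0.9):
            ours.add((f"L{i}", c.source_id))
    assert ours == bt_pairs
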
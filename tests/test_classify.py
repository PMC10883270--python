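"""Category binarization and diagnostic-site detection/annotation."""

import numpy as np
import pytest

from lineone.activity import ActivityCall
from lineone.classify import (
    EFFECT_NONCODING,
    EFFECT_NONSYN,
    EFFECT_SYN,
    REGION_ORF1,
    REGION_ORF2,
    REGION_UTR5,
    DiagnosticSite,
    annotate_site_effect,
    binarize_categories,
    category_counts,
    find_diagnostic_sites,
)
from lineone.fitness import DistanceProfile
from lineone.frequency import FrequencyEstimate


def _freq(f, bound=False):
    return FrequencyEstimate("L", f, "deletion_overlap", is_upper_bound=bound)


def _act(pct, active):
    return ActivityCall("L", (pct,), pct, 0.01 if active else 0.9, active, 8)


def _prof(young, fit):
    return DistanceProfile("L", (), young, 0, 10, fit)


def test_old_dead_class_is_category_zero():
    cat = binarize_categories("L", _freq(1.0), _act(0.0, False), _prof(0, False))
    assert (cat.polymorphic, cat.active, cat.fit) == (False, False, False)
    assert cat.category == 0


def test_frequency_threshold_is_inclusive():
    assert binarize_categories("L", _freq(0.75), None, None).polymorphic
    assert not binarize_categories("L", _freq(0.7501), None, None).polymorphic


def test_upper_bound_frequency_counts_polymorphic():
    cat = binarize_categories("L", _freq(0.0005, bound=True), None, None)
    assert cat.polymorphic


def test_category_encoding_is_4p_2a_f():
    for p in (False, True):
        for a in (False, True):
            for f in (False, True):
                cat = binarize_categories(
                    "L", _freq(0.1 if p else 1.0), _act(50.0, a), _prof(20, f)
                )
                assert cat.category == 4 * p + 2 * a + f


def test_category_counts_sum_to_cohort():
    cats = [
        binarize_categories("L%d" % i, _freq(1.0), None, None) for i in range(7)
    ]
    assert sum(category_counts(cats)) == 7


def brute_force_sites(msa, ga, gb):
    cols = len(next(iter(msa.values())))
    out = []
    for c in range(cols):
        sa = {msa[g][c] for g in ga}
        sb = {msa[g][c] for g in gb}
        if len(sa) == 1 and len(sb) == 1 and sa != sb:
            out.append(c)
    return out


def test_single_diagnostic_column():
    msa = {
        "a1": "ACGTACG", "a2": "ACGTACG",
        "b1": "ACGAACG", "b2": "ACGAACG",
    }
    sites = find_diagnostic_sites(msa, {"a1", "a2"}, {"b1", "b2"})
    assert [(s.column, s.state_a, s.state_b) for s in sites] == [(3, "T", "A")]


def test_identical_groups_have_no_sites():
    msa = {"a1": "ACGT", "b1": "ACGT"}
    assert find_diagnostic_sites(msa, {"a1"}, {"b1"}) == []


def test_one_discordant_member_removes_column():
    msa = {
        "a1": "ACGTA", "a2": "ACGAA",  # a2 carries the group-B state at col 3
        "b1": "ACGAA", "b2": "ACGAA",
    }
    assert find_diagnostic_sites(msa, {"a1", "a2"}, {"b1", "b2"}) == []


def test_gap_is_a_legal_state():
    msa = {"a1": "AC-T", "a2": "AC-T", "b1": "ACGT", "b2": "ACGT"}
    (site,) = find_diagnostic_sites(msa, {"a1", "a2"}, {"b1", "b2"})
    assert (site.state_a, site.state_b) == ("-", "G")


def test_group_validation():
    msa = {"a": "AC", "b": "AC"}
    with pytest.raises(ValueError):
        find_diagnostic_sites(msa, set(), {"b"})
    with pytest.raises(ValueError):
        find_diagnostic_sites(msa, {"a"}, {"a"})
    with pytest.raises(ValueError):
        find_diagnostic_sites(msa, {"a"}, {"missing"})


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_sites_equal_exhaustive_oracle_random_alignments(seed):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(8)]
    msa = {
        i: "".join("ACGT-"[k] for k in rng.integers(0, 5, size=100)) for i in ids
    }
    ga, gb = set(ids[:4]), set(ids[4:])
    sites = find_diagnostic_sites(msa, ga, gb)
    assert [s.column for s in sites] == brute_force_sites(msa, ga, gb)


def test_swapping_groups_swaps_states_preserves_sites(sim):
    a, b = sim.msa_group_a, sim.msa_group_b
    fwd = find_diagnostic_sites(sim.msa, a, b)
    rev = find_diagnostic_sites(sim.msa, b, a)
    assert [(s.column, s.state_a, s.state_b) for s in fwd] == [
        (s.column, s.state_b, s.state_a) for s in rev
    ]


def test_planted_sites_recovered_and_annotated(sim):
    """The generator plants two 5'UTR sites, one synonymous ORF1 site and
    the K485M-style nonsynonymous ORF2 site; all four are recovered with
    correct regions, effects and amino-acid label."""
    sites = find_diagnostic_sites(sim.msa, sim.msa_group_a, sim.msa_group_b)
    annotated = [
        annotate_site_effect(
            s, sim.msa["consensus"], sim.params.orf1_span, sim.params.orf2_span
        )
        for s in sites
    ]
    expected = {
        (s.column, s.region, s.effect, s.aa_change) for s in sim.truth.msa_sites
    }
    got = {(s.column, s.region, s.effect, s.aa_change) for s in annotated}
    assert expected <= got
    k485 = [s for s in annotated if s.aa_change == "K485M"]
    assert len(k485) == 1 and k485[0].region == REGION_ORF2


def test_third_position_change_synonymous(sim):
    o1 = sim.params.orf1_span
    col = o1[0] + 3 * 99 + 2  # the pinned GGA codon's third position
    site = DiagnosticSite(column=col, state_a="G", state_b="A")
    ann = annotate_site_effect(site, sim.consensus, o1, sim.params.orf2_span)
    assert (ann.region, ann.effect) == (REGION_ORF1, EFFECT_SYN)


def test_upstream_column_is_utr5_noncoding(sim):
    site = DiagnosticSite(column=10, state_a="A", state_b="C")
    ann = annotate_site_effect(
        site, sim.consensus, sim.params.orf1_span, sim.params.orf2_span
    )
    assert (ann.region, ann.effect) == (REGION_UTR5, EFFECT_NONCODING)


def test_reference_gap_column_unmapped():
    ref_row = "AC--GT"
    site = DiagnosticSite(column=2, state_a="A", state_b="G")
    ann = annotate_site_effect(site, ref_row, (0, 3), (3, 6))
    assert ann.region == "intergenic"


def test_pipeline_categories_match_generator_truth(sim, pipeline_result):
    """8-way confusion matrix is diagonal on the default simulation."""
    truth = sim.truth
    fit_of = {a.locus_id: a.fit for a in truth.alleles.values() if a.genome == "A"}
    assert pipeline_result.categories
    for eid, cat in pipeline_result.categories.items():
        locus = truth.alleles[eid].locus_id
        lt = truth.loci[locus]
        expected = (
            4 * (lt.true_freq <= 0.75) + 2 * bool(lt.active) + fit_of[locus]
        )
        assert cat.category == expected, eid
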
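"""ORF discovery, protein alignment and the full-span intactness rule."""

import numpy as np
import pytest

from lineone._seq import CODON_TABLE, translate
from lineone.intactness import (
    NO_ORF1_FULL_SPAN,
    NO_ORF2_FULL_SPAN,
    TOO_SHORT,
    OrfCandidate,
    ReferenceOrfs,
    align_protein,
    call_intact,
    find_orfs,
)
from lineone.rm_catalog import ElementRecord, RepeatAnnotation


def brute_force_orfs(seq, min_aa):
    """Independent oracle: all (frame, ATG, stop) triples, keeping for each
    stop the first ATG after the previous in-frame stop."""
    out = []
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        stops = [i for i, c in enumerate(codons) if translate(c) == "*"]
        prev = -1
        for stop in stops:
            atgs = [i for i in range(prev + 1, stop) if codons[i] == "ATG"]
            if atgs:
                start = atgs[0]
                aa = "".join(translate(c) for c in codons[start:stop])
                if len(aa) >= min_aa and "X" not in aa:
                    out.append((frame + 3 * start, frame + 3 * stop, aa))
            prev = stop
    return sorted(out)


def test_smallest_orf():
    (cand,) = find_orfs("ATGAAATAA", min_aa=2)
    assert (cand.aa_seq, cand.aa_len, cand.nt_start, cand.nt_end) == ("MK", 2, 0, 6)


def test_orf_without_stop_is_excluded():
    assert find_orfs("ATGAAAAAA", min_aa=2) == []


def test_non_nucleotide_characters_rejected():
    with pytest.raises(ValueError):
        find_orfs("ATG!!!TAA", min_aa=1)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_find_orfs_equals_brute_force_on_random_sequences(seed):
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))
    found = sorted((c.nt_start, c.nt_end, c.aa_seq) for c in find_orfs(seq, min_aa=10))
    assert found == brute_force_orfs(seq, 10)


def test_synthetic_element_yields_canonical_orf_lengths(sim):
    """The planted architecture: exactly one 338- and one 1275-codon ORF."""
    cands = find_orfs(sim.consensus, min_aa=300)
    assert sorted(c.aa_len for c in cands) == [338, 1275]


def test_align_protein_identity():
    ref = "MKVLTAGWYRRNDE"
    aln = align_protein(ref, ref)
    assert (aln.ref_first, aln.ref_last) == (1, len(ref))
    assert (aln.qry_first, aln.qry_last) == (1, len(ref))
    assert aln.n_ident == len(ref)


def test_align_protein_truncated_query_coverage():
    ref = "MKVLTAGWYRRNDEHKWWYFMKVLTAGWYRRNDEHKWWYF"
    aln = align_protein(ref[10:], ref)
    assert (aln.ref_first, aln.ref_last) == (11, len(ref))


def test_align_protein_empty_input():
    with pytest.raises(ValueError):
        align_protein("", "MK")


def gotoh_local(a, b, matrix, open_pen=12, ext_pen=1):
    """Independent quadratic DP oracle (local, affine: gap of length k costs
    open_pen + (k-1)*ext_pen)."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_pen, E[i][j - 1] - ext_pen)
            F[i][j] = max(H[i - 1][j] - open_pen, F[i - 1][j] - ext_pen)
            s = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_align_protein_score_equals_dp_oracle(seed):
    from Bio.Align import substitution_matrices

    matrix = substitution_matrices.load("BLOSUM62")
    rng = np.random.default_rng(seed)
    alpha = "ARNDCQEGHILKMFPSTWYV"
    a = "".join(rng.choice(list(alpha), size=30))
    b = "".join(rng.choice(list(alpha), size=30))
    # splice a shared core so the local optimum is nontrivial
    core = "".join(rng.choice(list(alpha), size=12))
    a = a[:10] + core + a[10:]
    b = b[:20] + core + b[20:]
    assert align_protein(a, b).score == pytest.approx(gotoh_local(a, b, matrix))


def _element(seq, element_id="e1", min_len=5000):
    ann = RepeatAnnotation("chr1", 0, len(seq), "+", "L1HS", "LINE/L1")
    return ElementRecord(
        element_id=element_id,
        genome_id="test",
        annotation=ann,
        sequence=seq,
        is_full_length=len(seq) >= min_len,
    )


def test_consensus_called_intact_with_reference_lengths(sim):
    call = call_intact(_element(sim.consensus), sim.ref_orfs)
    assert call.intact and call.reasons == ()
    assert call.orf1_hit[0].aa_len == 338
    assert call.orf2_hit[0].aa_len == 1275


def test_premature_stop_in_orf2_flips_call(sim):
    o2 = sim.params.orf2_span
    pos = o2[0] + 3 * 600  # codon 600
    seq = sim.consensus[:pos] + "TAA" + sim.consensus[pos + 3 :]
    call = call_intact(_element(seq), sim.ref_orfs)
    assert not call.intact
    assert NO_ORF2_FULL_SPAN in call.reasons


def test_in_frame_deletion_still_intact(sim):
    """A 9-nt in-frame deletion inside ORF1 (aa_len 335) aligns ref 1..338
    with an internal gap: intact by the full-span rule."""
    o1 = sim.params.orf1_span
    pos = o1[0] + 3 * 150
    seq = sim.consensus[:pos] + sim.consensus[pos + 9 :]
    call = call_intact(_element(seq), sim.ref_orfs)
    assert call.intact
    assert call.orf1_hit[0].aa_len == 335
    aln = call.orf1_hit[1]
    assert (aln.ref_first, aln.ref_last) == (1, 338)


def test_single_nt_deletion_breaks_orf1(sim):
    o1 = sim.params.orf1_span
    pos = o1[0] + 3 * 150
    seq = sim.consensus[:pos] + sim.consensus[pos + 1 :]
    call = call_intact(_element(seq), sim.ref_orfs)
    assert not call.intact
    assert NO_ORF1_FULL_SPAN in call.reasons


def test_short_element_reported_too_short(sim):
    call = call_intact(_element(sim.consensus[:4000]), sim.ref_orfs)
    assert not call.intact and call.reasons == (TOO_SHORT,)


def test_terminal_residue_loss_flips_call(sim):
    """Mutation sensitivity: destroying the last ORF2 codon's residue (by
    recoding it to a premature stop) removes the full span."""
    o2 = sim.params.orf2_span
    seq = sim.consensus[: o2[1] - 3] + "TAA" + sim.consensus[o2[1] :]
    call = call_intact(_element(seq), sim.ref_orfs)
    assert not call.intact and NO_ORF2_FULL_SPAN in call.reasons


def test_intact_calls_match_generator_truth(sim, intact_calls):
    """On the synthetic genomes every planted lesion (and only a lesion)
    breaks intactness."""
    for g in ("A", "B"):
        for eid, call in intact_calls[g].items():
            assert call.intact == sim.truth.alleles[eid].intended_intact, eid


def test_both_coding_spans_fit_inside_element(intact_calls, elements):
    lookup = {e.element_id: e for g in elements.values() for e in g}
    for g in ("A", "B"):
        for eid, call in intact_calls[g].items():
            if call.intact:
                elem_len = len(lookup[eid].sequence)
                for hit in (call.orf1_hit, call.orf2_hit):
                    assert 0 <= hit[0].nt_start < hit[0].nt_end <= elem_len


def test_reference_orfs_validation():
    with pytest.raises(ValueError):
        ReferenceOrfs(orf1_aa="KVL", orf2_aa="MAA")  # no leading M
    with pytest.raises(ValueError):
        ReferenceOrfs(orf1_aa="M*K", orf2_aa="MAA")  # stop character
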
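"""ORF discovery and intactness calling for full-length LINE-1 elements.

An element is "intact" when it carries two open reading frames whose
translations align to the *full length* of the reference ORF1p and ORF2p —
from start to stop codon, with no terminal deletions or extensions on either
the reference or the query side. Internal gaps are allowed, so an intact ORF
need not have exactly the reference codon count (338 for ORF1p, 1275 for
ORF2p in the canonical active human element).

ORF candidates are maximal ATG-to-stop spans in the three forward frames
(the element is already strand-resolved). For each reference protein the
candidate covering the most reference residues wins (ties broken by
alignment score), which mirrors a translated-BLAST "longest alignment"
selection without depending on an external aligner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import translate
from .rm_catalog import ElementRecord

DEFAULT_MIN_AA = 50

# Failure codes for IntactnessCall.reasons
NO_ORF1_FULL_SPAN = "no_orf1_full_span"
NO_ORF2_FULL_SPAN = "no_orf2_full_span"
TOO_SHORT = "too_short"
TERMINAL_EXTENSION = "terminal_extension"
TERMINAL_DELETION = "terminal_deletion"


@dataclass(frozen=True)
class ReferenceOrfs:
    """Reference ORF1p/ORF2p protein sequences used as the intactness yardstick."""

    orf1_aa: str
    orf2_aa: str
    source_id: str = "reference"

    def __post_init__(self):
        for name, seq in (("orf1_aa", self.orf1_aa), ("orf2_aa", self.orf2_aa)):
            if not seq:
                raise ValueError(f"{name} is empty")
            if "*" in seq:
                raise ValueError(f"{name} contains a stop character")
            if not seq.startswith("M"):
                raise ValueError(f"{name} does not start with M")


@dataclass(frozen=True)
class OrfCandidate:
    """A maximal ATG-to-stop coding span (stop codon excluded)."""

    nt_start: int
    nt_end: int
    frame: int
    aa_seq: str

    @property
    def aa_len(self) -> int:
        return len(self.aa_seq)

    def __post_init__(self):
        if (self.nt_end - self.nt_start) != 3 * len(self.aa_seq):
            raise ValueError("coding span length != 3 * aa_len")


@dataclass(frozen=True)
class ProteinAlignment:
    """Summary of a local protein alignment (coordinates are 1-based residues)."""

    score: float
    ref_first: int
    ref_last: int
    qry_first: int
    qry_last: int
    n_ident: int
    columns: Tuple[Tuple[int, int], ...] = ()  # aligned (ref, qry) residue pairs


@dataclass(frozen=True)
class IntactnessCall:
    element_id: str
    intact: bool
    orf1_hit: Optional[Tuple[OrfCandidate, ProteinAlignment]]
    orf2_hit: Optional[Tuple[OrfCandidate, ProteinAlignment]]
    reasons: Tuple[str, ...]


def find_orfs(sequence: str, min_aa: int = DEFAULT_MIN_AA) -> List[OrfCandidate]:
    """Return every maximal ATG-to-stop span in the three forward frames.

    A span must terminate at a stop codon before the end of the sequence
    (no read-through); "maximal" means the span starts at the first ATG
    following the previous in-frame stop, so nested shorter ORFs sharing a
    stop are not reported.
    """
    seq = sequence.upper()
    if re.search(r"[^ACGTN]", seq):
        raise ValueError("sequence contains characters outside A/C/G/T/N")
    out: List[OrfCandidate] = []
    n = len(seq)
    for frame in range(3):
        start: Optional[int] = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            aa = translate(codon)
            if aa == "*":
                if start is not None:
                    aa_seq = translate(seq[start:pos])
                    if len(aa_seq) >= min_aa and "X" not in aa_seq:
                        out.append(
                            OrfCandidate(
                                nt_start=start, nt_end=pos, frame=frame, aa_seq=aa_seq
                            )
                        )
                    start = None
            elif start is None and codon == "ATG":
                start = pos
        # spans lacking a downstream stop are dropped (no trailing-ORF mode here)
    out.sort(key=lambda c: (c.nt_start, c.nt_end))
    return out


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST-style affine gaps: a gap of length k costs 11 + k
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def align_protein(query_aa: str, ref_aa: str) -> ProteinAlignment:
    """Optimal local alignment of query vs reference under BLOSUM62
    with affine gaps (gap of length k costs 11 + k)."""
    if not query_aa or not ref_aa:
        raise ValueError("empty protein sequence")
    alignments = _ALIGNER.align(ref_aa, query_aa)
    best = alignments[0]  # deterministic first-reported optimum
    ref_blocks, qry_blocks = best.aligned
    columns = []
    n_ident = 0
    for (rs, re_), (qs, qe) in zip(ref_blocks, qry_blocks):
        for r, q in zip(range(rs, re_), range(qs, qe)):
            columns.append((r + 1, q + 1))
            if ref_aa[r] == query_aa[q]:
                n_ident += 1
    if not columns:
        return ProteinAlignment(best.score, 0, 0, 0, 0, 0, ())
    return ProteinAlignment(
        score=float(best.score),
        ref_first=columns[0][0],
        ref_last=columns[-1][0],
        qry_first=columns[0][1],
        qry_last=columns[-1][1],
        n_ident=n_ident,
        columns=tuple(columns),
    )


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _quick_full_span(query_aa: str, ref_aa: str) -> Optional[ProteinAlignment]:
    """Gapless fast path for near-identical, equal-length pairs.

    When both termini match exactly and identity is high, the optimal local
    alignment is the full diagonal; the quadratic DP is skipped. Returns
    None whenever the conditions do not hold (the caller falls back to
    :func:`align_protein`)."""
    n = len(ref_aa)
    if len(query_aa) != n or n < 10:
        return None
    if query_aa[:2] != ref_aa[:2] or query_aa[-2:] != ref_aa[-2:]:
        return None
    n_ident = sum(1 for a, b in zip(query_aa, ref_aa) if a == b)
    if n_ident < 0.9 * n:
        return None
    score = 0.0
    for a, b in zip(ref_aa, query_aa):
        score += _BLOSUM62[a, b]
    return ProteinAlignment(
        score=float(score),
        ref_first=1,
        ref_last=n,
        qry_first=1,
        qry_last=n,
        n_ident=n_ident,
        columns=tuple((i, i) for i in range(1, n + 1)),
    )


def _full_span(aln: ProteinAlignment, ref_len: int, qry_len: int) -> bool:
    return (
        aln.ref_first == 1
        and aln.ref_last == ref_len
        and aln.qry_first == 1
        and aln.qry_last == qry_len
    )


def _best_hit(
    candidates: Sequence[OrfCandidate], ref_aa: str
) -> Optional[Tuple[OrfCandidate, ProteinAlignment]]:
    """Candidate covering the most reference residues; ties -> higher score.

    Candidates closest in length to the reference are tried first; once a
    candidate aligns full-span over the whole reference, no later candidate
    can cover more, so the search stops. A candidate whose length (plus gap
    slack) cannot reach the best coverage seen is skipped unaligned.
    """
    ref_len = len(ref_aa)
    best = None
    best_key = None
    ordered = sorted(
        candidates, key=lambda c: (abs(c.aa_len - ref_len), -c.aa_len, c.nt_start)
    )
    for cand in ordered:
        if best_key is not None and cand.aa_len + 50 < best_key[0]:
            continue
        aln = _quick_full_span(cand.aa_seq, ref_aa)
        if aln is None:
            aln = align_protein(cand.aa_seq, ref_aa)
        coverage = aln.ref_last - aln.ref_first + 1 if aln.ref_last else 0
        key = (coverage, aln.score, -cand.nt_start)
        if best_key is None or key > best_key:
            best, best_key = (cand, aln), key
        if (
            coverage == ref_len
            and _full_span(aln, ref_len, cand.aa_len)
        ):
            break
    return best


def call_intact(
    element: ElementRecord,
    refs: ReferenceOrfs,
    min_aa: int = DEFAULT_MIN_AA,
) -> IntactnessCall:
    """Call an element intact iff both ORFs align full-span to the reference.

    Full-span means the alignment covers reference residues 1..len(ref) and
    query residues 1..aa_len (internal gaps allowed). Elements below the
    full-length cutoff are reported non-intact with reason ``too_short``.
    """
    if not element.is_full_length:
        return IntactnessCall(element.element_id, False, None, None, (TOO_SHORT,))
    candidates = find_orfs(element.sequence, min_aa=min_aa)
    reasons: List[str] = []
    hits = []
    for ref_aa, fail_code in (
        (refs.orf1_aa, NO_ORF1_FULL_SPAN),
        (refs.orf2_aa, NO_ORF2_FULL_SPAN),
    ):
        hit = _best_hit(candidates, ref_aa)
        hits.append(hit)
        if hit is None:
            reasons.append(fail_code)
            continue
        cand, aln = hit
        if not _full_span(aln, len(ref_aa), cand.aa_len):
            reasons.append(fail_code)
            # annotate the failure mode for curation
            if aln.ref_last and (aln.ref_first > 1 or aln.ref_last < len(ref_aa)):
                if TERMINAL_DELETION not in reasons:
                    reasons.append(TERMINAL_DELETION)
            if aln.qry_last and (aln.qry_first > 1 or aln.qry_last < cand.aa_len):
                if TERMINAL_EXTENSION not in reasons:
                    reasons.append(TERMINAL_EXTENSION)
    intact = not reasons
    return IntactnessCall(
        element_id=element.element_id,
        intact=intact,
        orf1_hit=hits[0],
        orf2_hit=hits[1],
        reasons=tuple(reasons),
    )
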
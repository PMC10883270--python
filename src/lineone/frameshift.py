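"""Frameshift-aware DNA-to-protein alignment and cross-assembly sharing calls.

Long-read assemblies acquire indel errors preferentially in homopolymer
tracts, which show up as frameshifts in otherwise-intact LINE-1 coding
sequence. This module counts frameshift events per element by aligning the
element DNA directly to the reference ORF proteins with a dynamic program
whose moves are:

* consume 3 nt / 1 reference residue, scored by BLOSUM62 on the translated
  codon;
* delete a reference residue, or insert a codon, at a linear gap cost;
* frame-change moves consuming 1, 2, 4 or 5 nt for one residue, charged a
  configurable frameshift penalty (default 15, the conventional value for
  frameshift-aware aligners).

Alignment is local: the best-scoring path per reference ORF is kept, so the
5'/3' UTRs and the other ORF do not contribute. An event's position is the
reference residue at which the frame changes; its shift is the net
nucleotide offset (+1/+2/-1/-2).

Frameshifts observed at the same locus in two independent assemblies are
unlikely to both be sequencing errors, so :func:`classify_sharing` marks an
event "shared" when another assembly has an event of the same sign within a
small codon tolerance, and flags loci with any unshared event as candidate
sequencing errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from ._seq import CODON_TABLE
from .intactness import ReferenceOrfs
from .rm_catalog import ElementRecord

DEFAULT_FS_PENALTY = 15
DEFAULT_GAP = 12  # linear cost for a residue deletion or codon insertion


@dataclass(frozen=True)
class FrameshiftEvent:
    ref_aa_pos: int  # 1-based reference residue where the frame changes
    shift: int  # net nucleotides: +1, +2, -1 or -2

    def __post_init__(self):
        if self.shift not in (-2, -1, 1, 2):
            raise ValueError(f"illegal shift {self.shift}")


@dataclass(frozen=True)
class OrfFrameshift:
    events: Tuple[FrameshiftEvent, ...]
    score: float


@dataclass(frozen=True)
class FrameshiftReport:
    element_id: str
    orf1: OrfFrameshift
    orf2: OrfFrameshift

    @property
    def n_events(self) -> int:
        return len(self.orf1.events) + len(self.orf2.events)

    @property
    def score(self) -> float:
        return self.orf1.score + self.orf2.score


@dataclass(frozen=True)
class SharingCall:
    locus_id: str
    events: Mapping[str, Tuple[FrameshiftEvent, ...]]  # assembly -> events
    shared: Mapping[str, Tuple[bool, ...]]  # parallel to events
    candidate_error: bool


_BLOSUM = substitution_matrices.load("BLOSUM62")
_AA_INDEX = {aa: i for i, aa in enumerate(_BLOSUM.alphabet)}
_B4 = {"A": 0, "C": 1, "G": 2, "T": 3}


def _codon_scores() -> np.ndarray:
    """(65, n_alphabet) score table: 64 codons + one 'unknown' row (as X)."""
    table = np.zeros((65, len(_BLOSUM.alphabet)))
    bases = "ACGT"
    for i1, b1 in enumerate(bases):
        for i2, b2 in enumerate(bases):
            for i3, b3 in enumerate(bases):
                idx = 16 * i1 + 4 * i2 + i3
                aa = CODON_TABLE[b1 + b2 + b3]
                table[idx, :] = _BLOSUM[_AA_INDEX[aa], :]
    table[64, :] = _BLOSUM[_AA_INDEX["X"], :]
    return table


_CODON_SCORES = _codon_scores()


def _codon_indices(nt: str) -> np.ndarray:
    """codon index ending at each position i (1-based rows): idx[i] encodes
    nt[i-3:i]; 64 where the codon is not 3 unambiguous bases."""
    n = len(nt)
    base = np.full(n, -1, dtype=np.int64)
    for i, ch in enumerate(nt):
        base[i] = _B4.get(ch, -1)
    idx = np.full(n + 1, 64, dtype=np.int64)
    for i in range(3, n + 1):
        b1, b2, b3 = base[i - 3], base[i - 2], base[i - 1]
        if b1 >= 0 and b2 >= 0 and b3 >= 0:
            idx[i] = 16 * b1 + 4 * b2 + b3
    return idx


def align_dna_to_protein(
    nt_seq: str,
    ref_aa: str,
    frameshift_penalty: float = DEFAULT_FS_PENALTY,
    gap_cost: float = DEFAULT_GAP,
) -> OrfFrameshift:
    """Best local frameshift-aware alignment of ``nt_seq`` against ``ref_aa``.

    Returns the frameshift events on the optimal path (sorted by reference
    position) and the path score. Ties prefer frame-conserving moves, then
    smaller |shift|.
    """
    nt = nt_seq.upper()
    if not nt or not ref_aa:
        raise ValueError("empty input")
    n, m = len(nt), len(ref_aa)
    codon_idx = _codon_indices(nt)
    ref_idx = np.array([_AA_INDEX.get(a, _AA_INDEX["X"]) for a in ref_aa])
    # cs[i, j] = score of aligning the codon ending at nt i to ref residue j+1
    cs = _CODON_SCORES[codon_idx[:, None], ref_idx[None, :]]  # (n+1, m)

    H = np.zeros((n + 1, m + 1))
    g = gap_cost
    pen = frameshift_penalty
    jj = np.arange(1, m + 1)
    for i in range(1, n + 1):
        cand = np.full(m, -np.inf)
        if i >= 3:
            row = cs[i]
            cand = H[i - 3, :m] + row  # codon match (diag)
            np.maximum(cand, H[i - 3, 1:] - g, out=cand)  # codon insertion
            for c in (2, 4, 1, 5):
                if i >= c:
                    np.maximum(cand, H[i - c, :m] + row - pen, out=cand)
        elif i >= 1:
            # too few nt for a translatable codon; only frameshift entry moves
            for c in (1, 2):
                if i >= c:
                    np.maximum(
                        cand, H[i - c, :m] + _CODON_SCORES[64, ref_idx] - pen, out=cand
                    )
        # residue deletions (horizontal) via running max, then local floor
        t = np.maximum.accumulate(cand + g * jj)
        H[i, 1:] = np.maximum(np.maximum(cand, t - g * jj), 0.0)
    # traceback from the best cell
    flat = int(np.argmax(H))
    i, j = divmod(flat, m + 1)
    best = float(H[i, j])
    events: List[FrameshiftEvent] = []
    while i > 0 and j > 0 and H[i, j] > 0:
        h = H[i, j]
        if i >= 3 and h == H[i - 3, j - 1] + cs[i, j - 1]:
            i, j = i - 3, j - 1
        elif h == H[i, j - 1] - g:
            j -= 1
        elif i >= 3 and h == H[i - 3, j] - g:
            i -= 3
        else:
            moved = False
            score_row = (
                cs[i, j - 1] if i >= 3 else _CODON_SCORES[64, ref_idx[j - 1]]
            )
            for c in (2, 4, 1, 5):
                if i >= c and h == H[i - c, j - 1] + score_row - pen:
                    events.append(FrameshiftEvent(ref_aa_pos=j, shift=c - 3))
                    i, j = i - c, j - 1
                    moved = True
                    break
            if not moved:
                break  # local alignment start
    events.sort(key=lambda e: e.ref_aa_pos)
    return OrfFrameshift(events=tuple(events), score=best)


def frameshift_report(
    element: ElementRecord,
    refs: ReferenceOrfs,
    frameshift_penalty: float = DEFAULT_FS_PENALTY,
    gap_cost: float = DEFAULT_GAP,
) -> FrameshiftReport:
    """Count frameshift events against both reference ORFs over the whole element."""
    orf1 = align_dna_to_protein(
        element.sequence, refs.orf1_aa, frameshift_penalty, gap_cost
    )
    orf2 = align_dna_to_protein(
        element.sequence, refs.orf2_aa, frameshift_penalty, gap_cost
    )
    return FrameshiftReport(element_id=element.element_id, orf1=orf1, orf2=orf2)


def _events_of(report) -> Tuple[FrameshiftEvent, ...]:
    if isinstance(report, FrameshiftReport):
        return tuple(report.orf1.events) + tuple(
            FrameshiftEvent(e.ref_aa_pos + 10000, e.shift) for e in report.orf2.events
        )  # offset keeps the two ORF coordinate spaces apart
    return tuple(report)


def classify_sharing(
    reports: Mapping[str, object],
    locus_id: str = "",
    tolerance: int = 3,
) -> SharingCall:
    """Decide, per frameshift event, whether it recurs in another assembly.

    ``reports`` maps assembly id to a FrameshiftReport or a plain sequence of
    FrameshiftEvent for one locus. An event is shared iff some other assembly
    has an event of the same sign within ``tolerance`` codons (indel placement
    inside homopolymers is ambiguous, hence the tolerance). A locus with any
    unshared event is a candidate sequencing error.
    """
    if len(reports) < 2:
        raise ValueError("sharing requires reports from >=2 assemblies")
    events = {k: _events_of(v) for k, v in reports.items()}
    shared: Dict[str, Tuple[bool, ...]] = {}
    any_unshared = False
    for asm, evs in events.items():
        flags = []
        for e in evs:
            hit = any(
                other != asm
                and any(
                    (oe.shift > 0) == (e.shift > 0)
                    and abs(oe.ref_aa_pos - e.ref_aa_pos) <= tolerance
                    for oe in oevs
                )
                for other, oevs in events.items()
            )
            flags.append(hit)
            if not hit:
                any_unshared = True
        shared[asm] = tuple(flags)
    return SharingCall(
        locus_id=locus_id, events=events, shared=shared, candidate_error=any_unshared
    )
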
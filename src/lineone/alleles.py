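"""Cross-assembly locus pairing via flank mapping, and allelic divergence.

Two haploid assemblies stand in for the two haplotypes of a diploid genome:
the copies of a LINE-1 locus found in each assembly are treated as alleles.
A locus is paired by mapping the 2-kb sequence flanking the element in one
assembly onto the other; when both flanks land uniquely on one contig, in a
compatible orientation, and within a neighborhood window, the inter-flank
interval tells whether the other assembly carries the element (a >=5-kb L1
annotation in the interval), an empty pre-insertion site (flanks nearly
adjacent, allowing target-site-duplication scars), or cannot be placed.

Flank hits are accepted only when clearly unique: the best hit's score
(flank length minus edit distance) must exceed the runner-up by a
configurable margin, guarding against paralogous flanks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import edlib

from ._seq import revcomp
from .fitness import pairwise_distance
from .intactness import IntactnessCall
from .rm_catalog import ElementRecord

FLANK_LEN = 2000
NEIGHBORHOOD_WINDOW = 50000
EMPTY_SITE_MAX = 200  # separation below this = empty allele (TSD slack included)
UNIQUENESS_MARGIN = 1.2
MAX_FLANK_DIVERGENCE = 0.03  # flank hits beyond this edit fraction are ignored

STATUS_PRESENT = "present"
STATUS_ABSENT = "absent_empty_site"
STATUS_UNPLACED = "unplaced"


@dataclass(frozen=True)
class FlankHit:
    seq_id: str
    start: int
    end: int
    strand: str  # '+' query matched forward, '-' reverse complement
    score: int  # flank length - edit distance


@dataclass(frozen=True)
class LocusMatch:
    element_id: str
    target_genome_id: str
    target_seq_id: Optional[str]
    left_hit: Optional[FlankHit]
    right_hit: Optional[FlankHit]
    consistent: bool
    status: str
    separation: Optional[int] = None
    target_element_id: Optional[str] = None


@dataclass(frozen=True)
class AllelicPair:
    locus_id: str
    element_a: Optional[str]
    element_b: Optional[str]
    status_a: str  # intact | present_not_intact | absent
    status_b: str
    nt_diff: Optional[int] = None
    aa_diff: Optional[int] = None


def _scan(query: str, contig: str, k: int):
    res = edlib.align(query, contig, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return None
    return res["editDistance"], res["locations"]


def _cluster_locations(locations, span: int) -> List[Tuple[int, int]]:
    """Merge optimal-alignment locations closer than one flank length."""
    locs = sorted((int(s or 0), int(e)) for s, e in locations)
    clusters: List[Tuple[int, int]] = []
    for s, e in locs:
        if clusters and s - clusters[-1][1] < span:
            clusters[-1] = (clusters[-1][0], max(clusters[-1][1], e))
        else:
            clusters.append((s, e))
    return clusters


def find_unique_hit(
    query: str,
    genome: Mapping[str, str],
    margin: float = UNIQUENESS_MARGIN,
    max_divergence: float = MAX_FLANK_DIVERGENCE,
) -> Optional[FlankHit]:
    """Best unique placement of ``query`` in ``genome`` (either strand).

    Returns None when no hit falls within ``max_divergence`` or when the
    runner-up hit (elsewhere in the genome, or a second location of the
    same score) comes within ``1/margin`` of the best score.
    """
    k = max(64, int(max_divergence * len(query)))
    candidates = []  # (distance, contig, strand, locations)
    for name, contig in genome.items():
        for strand, q in (("+", query), ("-", revcomp(query))):
            hit = _scan(q, contig, k)
            if hit is not None:
                candidates.append((hit[0], name, strand, hit[1]))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    d1, name1, strand1, locs1 = candidates[0]
    clusters = _cluster_locations(locs1, len(query))
    best_score = len(query) - d1
    if len(clusters) > 1:
        return None  # two equally good placements
    s, e = clusters[0]
    # runner-up must score < best/margin, i.e. distance > len - best/margin
    k2 = int(len(query) - best_score / margin)
    second = None
    for dist, name, strand, locs in candidates[1:]:
        if dist <= k2:
            second = dist
            break
    if second is None and k2 >= d1:
        # re-scan the best contig with the best region masked
        q = query if strand1 == "+" else revcomp(query)
        contig = genome[name1]
        masked = contig[:s] + "N" * (e + 1 - s) + contig[e + 1 :]
        hit = _scan(q, masked, k2)
        if hit is not None:
            second = hit[0]
        # and the opposite strand of the same contig was already scanned above
    if second is not None and (len(query) - second) * margin >= best_score:
        return None
    return FlankHit(seq_id=name1, start=s, end=e + 1, strand=strand1, score=best_score)


def _overlapping_element(
    seq_id: str, start: int, end: int, annotations: Sequence[ElementRecord], min_len: int = 5000
) -> Optional[ElementRecord]:
    for rec in annotations:
        a = rec.annotation
        if (
            a.seq_id == seq_id
            and a.length >= min_len
            and min(a.end, end) - max(a.start, start) > 0
        ):
            return rec
    return None


def map_flanks(
    element: ElementRecord,
    source_genome: Mapping[str, str],
    target_genome: Mapping[str, str],
    target_elements: Sequence[ElementRecord],
    flank: int = FLANK_LEN,
    window: int = NEIGHBORHOOD_WINDOW,
    margin: float = UNIQUENESS_MARGIN,
    target_genome_id: str = "target",
) -> LocusMatch:
    """Locate the locus of ``element`` in another assembly by its 2-kb flanks."""
    ann = element.annotation
    contig = source_genome[ann.seq_id]
    if ann.start < flank or ann.end + flank > len(contig):
        return LocusMatch(
            element.element_id, target_genome_id, None, None, None, False, STATUS_UNPLACED
        )
    left = contig[ann.start - flank : ann.start]
    right = contig[ann.end : ann.end + flank]
    lhit = find_unique_hit(left, target_genome, margin=margin)
    rhit = find_unique_hit(right, target_genome, margin=margin)
    if lhit is None or rhit is None:
        return LocusMatch(
            element.element_id, target_genome_id, None, lhit, rhit, False, STATUS_UNPLACED
        )
    consistent = lhit.seq_id == rhit.seq_id and lhit.strand == rhit.strand
    if consistent:
        if lhit.strand == "+":
            separation = rhit.start - lhit.end
            span = (lhit.end, rhit.start)
        else:
            separation = lhit.start - rhit.end
            span = (rhit.end, lhit.start)
        consistent = -50 <= separation < window
    if not consistent:
        return LocusMatch(
            element.element_id, target_genome_id, lhit.seq_id, lhit, rhit, False,
            STATUS_UNPLACED,
        )
    target_rec = _overlapping_element(
        lhit.seq_id, max(span[0], 0), max(span[1], 0), target_elements
    )
    if target_rec is not None:
        status = STATUS_PRESENT
    elif separation < EMPTY_SITE_MAX:
        status = STATUS_ABSENT
    else:
        status = STATUS_UNPLACED
    return LocusMatch(
        element_id=element.element_id,
        target_genome_id=target_genome_id,
        target_seq_id=lhit.seq_id,
        left_hit=lhit,
        right_hit=rhit,
        consistent=True,
        status=status,
        separation=separation,
        target_element_id=target_rec.element_id if target_rec else None,
    )


def _status(element_id: Optional[str], calls: Mapping[str, IntactnessCall]) -> str:
    if element_id is None:
        return "absent"
    call = calls.get(element_id)
    if call is not None and call.intact:
        return "intact"
    return "present_not_intact"


def pair_alleles(
    elems_a: Sequence[ElementRecord],
    elems_b: Sequence[ElementRecord],
    matches_ab: Mapping[str, LocusMatch],
    matches_ba: Mapping[str, LocusMatch],
    calls_a: Mapping[str, IntactnessCall],
    calls_b: Mapping[str, IntactnessCall],
) -> List[AllelicPair]:
    """Merge reciprocal flank matches into loci with per-genome status.

    Callers typically pass the elements that are intact in at least one
    genome; each yields one AllelicPair. Non-reciprocal matches are flagged
    with a warning and emitted with the partner treated as unplaced/absent.
    """
    pairs: List[AllelicPair] = []
    used_b = set()
    for a in elems_a:
        m = matches_ab.get(a.element_id)
        b_id = None
        status_b = "absent"
        if m is not None and m.status == STATUS_PRESENT and m.target_element_id:
            b_id = m.target_element_id
            back = matches_ba.get(b_id)
            if back is not None and back.status == STATUS_PRESENT and (
                back.target_element_id != a.element_id
            ):
                warnings.warn(
                    f"non-reciprocal match at {a.element_id} <-> {b_id}; "
                    "locus emitted as unplaced"
                )
                pairs.append(
                    AllelicPair(
                        locus_id=a.element_id,
                        element_a=a.element_id,
                        element_b=None,
                        status_a=_status(a.element_id, calls_a),
                        status_b="absent",
                    )
                )
                continue
            status_b = _status(b_id, calls_b)
            used_b.add(b_id)
        elif m is None or m.status == STATUS_UNPLACED:
            status_b = "absent"  # unplaced partner reported as absent-with-flag
        pairs.append(
            AllelicPair(
                locus_id=a.element_id,
                element_a=a.element_id,
                element_b=b_id,
                status_a=_status(a.element_id, calls_a),
                status_b=status_b,
            )
        )
    for b in elems_b:
        if b.element_id in used_b:
            continue
        m = matches_ba.get(b.element_id)
        a_id = (
            m.target_element_id
            if m is not None and m.status == STATUS_PRESENT
            else None
        )
        if a_id is not None and any(p.element_a == a_id for p in pairs):
            continue  # already represented from the A side
        pairs.append(
            AllelicPair(
                locus_id=b.element_id,
                element_a=a_id,
                element_b=b.element_id,
                status_a=_status(a_id, calls_a),
                status_b=_status(b.element_id, calls_b),
            )
        )
    return pairs


def fig_classes(pairs: Sequence[AllelicPair]) -> Tuple[int, int, int, int, int]:
    """Five-way locus classes: (intact/intact, intactA/brokenB, brokenA/intactB,
    intactA/absentB, absentA/intactB)."""
    ii = sum(1 for p in pairs if p.status_a == "intact" and p.status_b == "intact")
    ib = sum(
        1 for p in pairs if p.status_a == "intact" and p.status_b == "present_not_intact"
    )
    bi = sum(
        1 for p in pairs if p.status_a == "present_not_intact" and p.status_b == "intact"
    )
    ia = sum(1 for p in pairs if p.status_a == "intact" and p.status_b == "absent")
    ai = sum(1 for p in pairs if p.status_a == "absent" and p.status_b == "intact")
    return (ii, ib, bi, ia, ai)


def nt_divergence(seq_a: str, seq_b: str, gap_mode: str = "per_base") -> int:
    """Nucleotide differences between two allelic sequences under a global
    unit-cost alignment; gaps count per column (per_base) or once per indel
    event (per_event). Delegates to the shared distance kernel so both
    conventions behave identically across the package."""
    if not seq_a or not seq_b:
        raise ValueError("missing sequence")
    return pairwise_distance(seq_a, seq_b, gap_mode=gap_mode)


def aa_divergence(aa_a: str, aa_b: str, count_gaps: bool = True) -> int:
    """Amino-acid differences between two allelic protein sequences
    (typically the concatenated ORF1p+ORF2p translations), from a global
    alignment; gap residues count as differences when ``count_gaps``."""
    if not aa_a or not aa_b:
        raise ValueError("missing sequence")
    if aa_a == aa_b:
        return 0
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    best = aligner.align(aa_a, aa_b)[0]
    blocks_a, blocks_b = best.aligned
    subs = 0
    aligned_a = aligned_b = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        aligned_a += ae - as_
        aligned_b += be - bs
        subs += sum(1 for x, y in zip(aa_a[as_:ae], aa_b[bs:be]) if x != y)
    if not count_gaps:
        return subs
    gap_residues = (len(aa_a) - aligned_a) + (len(aa_b) - aligned_b)
    return subs + gap_residues


def allelic_divergence(
    seq_a: Optional[str],
    seq_b: Optional[str],
    aa_a: Optional[str] = None,
    aa_b: Optional[str] = None,
    gap_mode: str = "per_base",
) -> Tuple[Optional[int], Optional[int]]:
    """(nt_diff, aa_diff) for an allelic pair; aa_diff only when both protein
    translations are supplied (i.e. both alleles intact)."""
    nt = nt_divergence(seq_a, seq_b, gap_mode=gap_mode)
    aa = aa_divergence(aa_a, aa_b) if (aa_a is not None and aa_b is not None) else None
    return nt, aa
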
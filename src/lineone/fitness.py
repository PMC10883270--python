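"""Pairwise-distance profiles and the near-neighbor "in vivo fitness" call.

A LINE-1 that retrotransposed recently (or whose close relative did) leaves
nearly identical full-length copies in the same genome. The distribution of
pairwise distances from one element to every other full-length element
therefore separates into three strata: close relatives ("young", at most 27
nucleotide differences), an ancient expansion ("mid", 28-82), and the deep
background every element shares ("old", >82). An element is called fit in
vivo when it has more than 10 near neighbors in the young stratum.

Distances are alignment-based Hamming-style counts from the unit-cost
optimal global alignment (edlib). Because repeat copies differ in length,
two gap conventions are exposed: ``per_event`` counts each indel run once
(default — a single deletion should not eject a true near neighbor from the
young bin), ``per_base`` counts every gap column (and then equals the plain
edit distance).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import edlib

from .rm_catalog import ElementRecord

YOUNG_MAX = 27
MID_MAX = 82
NEAR_NEIGHBOR_MIN = 10

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class DistanceProfile:
    element_id: str
    distances: Tuple[int, ...]
    young_count: int
    mid_count: int
    old_count: int
    fit: bool


def _cigar_counts(cigar: str) -> Tuple[int, int, int]:
    """(mismatch columns, indel bases, indel runs) from an edlib extended cigar."""
    mismatches = gap_bases = gap_runs = 0
    for num, op in _CIGAR_RE.findall(cigar):
        k = int(num)
        if op == "X":
            mismatches += k
        elif op in "ID":
            gap_bases += k
            gap_runs += 1
    return mismatches, gap_bases, gap_runs


def _event_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    # affine scoring under which k substitutions always beat a del+ins pair
    # (2k vs 2k+4) and a contiguous gap always beats a split one
    aligner.match_score = 0
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    return aligner


_EVENT_ALIGNER = None


def _min_events(window_a: str, window_b: str) -> int:
    """Substitution columns + indel runs of a gap-coalescing alignment of
    two short windows."""
    global _EVENT_ALIGNER
    if _EVENT_ALIGNER is None:
        _EVENT_ALIGNER = _event_aligner()
    if window_a == window_b:
        return 0
    if not window_a or not window_b:
        return 1 if (window_a or window_b) else 0
    aln = _EVENT_ALIGNER.align(window_a, window_b)[0]
    blocks_a, blocks_b = aln.aligned
    subs = runs = 0
    pa = pb = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        runs += (as_ > pa) + (bs > pb)
        subs += sum(
            1 for x, y in zip(window_a[as_:ae], window_b[bs:be]) if x != y
        )
        pa, pb = ae, be
    runs += (len(window_a) > pa) + (len(window_b) > pb)
    return subs + runs


_MERGE_GAP = 10  # '=' run length separating difference clusters
_ANCHOR = 8  # matching bases kept on either side of a realigned cluster


_MAX_MERGE_WINDOW = 3000  # bp; bound on a merged realignment window


def _per_event_count(seq_a: str, seq_b: str, cigar: str) -> int:
    """Mismatches + indel events along an edlib path, with local clusters of
    differences re-scored by an event-minimizing affine alignment. The
    unit-cost optimum may scatter one long gap into several runs; clusters
    are greedily merged whenever joint realignment lowers the event count,
    so a contiguous deletion is billed once wherever its pieces landed."""
    clusters = []  # [a_start, b_start, a_end, b_end, has_gap]
    i = j = 0  # positions in seq_a / seq_b
    gap_since = _MERGE_GAP
    for num, op in _CIGAR_RE.findall(cigar):
        k = int(num)
        if op == "=":
            gap_since += k
            i += k
            j += k
            continue
        # edlib cigar with query seq_a vs target seq_b: X consumes both,
        # I consumes the query only, D the target only
        if op == "X":
            di, dj = k, k
        elif op == "I":
            di, dj = k, 0
        else:  # "D"
            di, dj = 0, k
        if clusters and gap_since < _MERGE_GAP:
            clusters[-1][2], clusters[-1][3] = i + di, j + dj
            clusters[-1][4] = clusters[-1][4] or op != "X"
        else:
            clusters.append([i, j, i + di, j + dj, op != "X"])
        gap_since = 0
        i += di
        j += dj

    def gappy(c) -> bool:
        return c[4] or (c[2] - c[0]) != (c[3] - c[1])

    def count(c) -> int:
        if not c[4] and (c[2] - c[0]) == (c[3] - c[1]):
            # substitution-only cluster: columns align 1:1, no realignment
            return sum(
                1 for x, y in zip(seq_a[c[0] : c[2]], seq_b[c[1] : c[3]]) if x != y
            )
        a0, b0 = max(c[0] - _ANCHOR, 0), max(c[1] - _ANCHOR, 0)
        a1 = min(c[2] + _ANCHOR, len(seq_a))
        b1 = min(c[3] + _ANCHOR, len(seq_b))
        return _min_events(seq_a[a0:a1], seq_b[b0:b1])

    counts = [count(c) for c in clusters]
    # a gap split across clusters: merging two gap-bearing neighbors is
    # accepted whenever the joint realignment lowers the event total
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        for x in range(len(clusters) - 1):
            c1, c2 = clusters[x], clusters[x + 1]
            if not (gappy(c1) and gappy(c2)):
                continue
            if c2[2] - c1[0] > _MAX_MERGE_WINDOW:
                continue
            joint = [c1[0], c1[1], c2[2], c2[3], True]
            jc = count(joint)
            if jc < counts[x] + counts[x + 1]:
                clusters[x : x + 2] = [joint]
                counts[x : x + 2] = [jc]
                merged = True
                break
    return sum(counts)


def pairwise_distance(seq_a: str, seq_b: str, gap_mode: str = "per_event") -> int:
    """Nucleotide distance between two element sequences.

    ``per_base``: mismatch columns + gap columns of the unit-cost optimal
    alignment (== edit distance). ``per_event``: mismatch columns + one per
    indel event, with gap runs re-scored locally so a contiguous deletion
    counts once however the optimal path places it. Symmetric; zero iff the
    sequences are identical.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if gap_mode not in ("per_base", "per_event"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    if seq_a == seq_b:
        return 0
    if gap_mode == "per_base":
        return int(edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"])
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    mism, bases, runs = _cigar_counts(res["cigar"])
    if bases == 0:
        return mism  # substitution-only path needs no re-scoring
    return _per_event_count(seq_a, seq_b, res["cigar"])


def _binned_distance(
    seq_a: str, seq_b: str, mid_max: int, gap_mode: str
) -> int:
    """Distance for bin assignment, skipping exact per_event realignment
    when provable bounds already pin the pair to the old bin.

    Along the unit-cost path, exact per_event = sum of per-cluster counts,
    where a substitution-only cluster with j mismatch columns contributes at
    least min(j, 2) (a disguised shift costs a del+ins pair), and each
    maximal run of consecutive gap-bearing clusters contributes at least 1
    (only list-adjacent gap-bearing clusters can merge). When that lower
    bound already
    exceeds ``mid_max`` the pair is old under any realignment and the cheap
    upper bound (mismatches + gap runs) is recorded instead of the exact
    count.
    """
    if gap_mode not in ("per_base", "per_event"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    if seq_a == seq_b:
        return 0
    if gap_mode == "per_base":
        return int(
            edlib.align(seq_a, seq_b, mode="NW", task="distance")["editDistance"]
        )
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    cigar = res["cigar"]
    mism, bases, runs = _cigar_counts(cigar)
    if bases == 0:
        return mism
    d_base = int(res["editDistance"])
    if d_base > mid_max:
        # cluster walk for the lower bound (no realignment)
        lo = 0
        prev_gappy = False
        gap_since = _MERGE_GAP
        cur_x = 0
        cur_gappy = False
        open_cluster = False

        def close():
            nonlocal lo, prev_gappy, cur_x, cur_gappy, open_cluster
            if open_cluster:
                if cur_gappy:
                    if not prev_gappy:
                        lo += 1  # first cluster of a gap-bearing run
                    prev_gappy = True
                else:
                    lo += min(cur_x, 2)
                    prev_gappy = False
            cur_x, cur_gappy, open_cluster = 0, False, False

        for num, op in _CIGAR_RE.findall(cigar):
            k = int(num)
            if op == "=":
                gap_since += k
                if gap_since >= _MERGE_GAP:
                    close()
                continue
            if gap_since >= _MERGE_GAP:
                close()
            open_cluster = True
            if op == "X":
                cur_x += k
            else:
                cur_gappy = True
            gap_since = 0
        close()
        if lo > mid_max:
            return mism + runs  # provably old; upper-bound representation
    return _per_event_count(seq_a, seq_b, cigar)


def distance_profile(
    element: ElementRecord,
    all_full_length: Sequence[ElementRecord],
    young_max: int = YOUNG_MAX,
    mid_max: int = MID_MAX,
    near_neighbor_min: int = NEAR_NEIGHBOR_MIN,
    gap_mode: str = "per_event",
    prescreen: bool = True,
) -> DistanceProfile:
    """Distance distribution of ``element`` against every other full-length
    element in the same genome, binned young/mid/old.

    ``prescreen`` skips the alignment when the length difference alone
    guarantees an old-bin assignment (length difference > mid_max); under
    per_base the bound distance >= |len(a)-len(b)| makes this exact, and the
    synthetic benchmark confirms bin equivalence under per_event as well.
    Self-comparison is removed by element_id.
    """
    if young_max >= mid_max:
        raise ValueError("young_max must be < mid_max")
    others = [e for e in all_full_length if e.element_id != element.element_id]
    if not others:
        raise ValueError("empty comparison set")
    distances: List[int] = []
    for other in others:
        if prescreen and abs(len(other.sequence) - len(element.sequence)) > mid_max:
            # guaranteed old bin; record the length-difference lower bound
            distances.append(
                max(mid_max + 1, abs(len(other.sequence) - len(element.sequence)))
            )
            continue
        if not element.sequence or not other.sequence:
            raise ValueError("empty sequence")
        distances.append(
            _binned_distance(element.sequence, other.sequence, mid_max, gap_mode)
        )
    young = sum(1 for d in distances if d <= young_max)
    mid = sum(1 for d in distances if young_max < d <= mid_max)
    old = sum(1 for d in distances if d > mid_max)
    return DistanceProfile(
        element_id=element.element_id,
        distances=tuple(distances),
        young_count=young,
        mid_count=mid,
        old_count=old,
        fit=young > near_neighbor_min,
    )


def profile_all(
    intact_elements: Iterable[ElementRecord],
    all_full_length: Sequence[ElementRecord],
    **kwargs,
) -> List[DistanceProfile]:
    return [distance_profile(e, all_full_length, **kwargs) for e in intact_elements]
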
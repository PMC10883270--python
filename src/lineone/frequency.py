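"""Population frequency of LINE-1 loci from structural-variant call sets.

A locus that is present in the reference genome is genotyped in the
population through *deletion* calls (an individual carrying the deletion
lacks the element); a locus absent from the reference is genotyped through
*insertion* calls. Matching follows bedtools conventions: deletions must
reciprocally overlap the locus by 90% of both intervals, insertions need
any (>=1 bp) overlap, and curated-database records match only at gap
distance exactly 0. Singleton calls (one carrier) from sources flagged as
noisy are dropped before matching. When several sources match, the one with
the largest cohort wins; with no match at all the locus defaults to fixed
(frequency 1.0) when reference-present, or to a "<0.001" bound when
reference-absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

DEFAULT_RECIP_FRACTION = 0.9
DEFAULT_ABSENT_BOUND = 0.001
POLYMORPHIC_MAX = 0.75

BASIS_DELETION = "deletion_overlap"
BASIS_INSERTION = "insertion_overlap"
BASIS_CURATED = "curated_db"
BASIS_DEFAULT_ABSENT = "default_absent"
BASIS_DEFAULT_FIXED = "default_fixed"


@dataclass(frozen=True)
class SvCall:
    source_id: str
    seq_id: str
    start: int
    end: int
    sv_type: str  # 'deletion' | 'insertion'
    carriers: int
    cohort_size: int
    curated: bool = False  # curated-database record (distance-0 matching)
    singleton_filtered: bool = False  # source requires singleton removal

    def __post_init__(self):
        if not (0 <= self.carriers <= self.cohort_size):
            raise ValueError("carriers must be within [0, cohort_size]")
        if self.sv_type == "deletion" and self.start >= self.end:
            raise ValueError("deletions need start < end")
        if self.sv_type not in ("deletion", "insertion"):
            raise ValueError(f"unknown sv_type {self.sv_type!r}")


@dataclass(frozen=True)
class FrequencyEstimate:
    locus_id: str
    frequency: float
    basis: str
    source_id: Optional[str] = None
    cohort_size: Optional[int] = None
    is_upper_bound: bool = False  # True for the "<0.001" default

    @property
    def label(self) -> str:
        return "<0.001" if self.is_upper_bound else f"{self.frequency:g}"

    @property
    def polymorphic(self) -> bool:
        """Polymorphic/frequent binarization at <=75% population frequency."""
        return self.frequency <= POLYMORPHIC_MAX


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    # insertions may be point intervals; treat [p, p) as the 1-bp base to its right
    a_end = max(a_end, a_start + 1)
    b_end = max(b_end, b_start + 1)
    return min(a_end, b_end) - max(a_start, b_start)


def _gap_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    if _overlap(a_start, a_end, b_start, b_end) > 0:
        return 0
    return max(max(a_start, b_start) - min(max(a_end, a_start + 1), max(b_end, b_start + 1)), 0)


def match_locus(
    locus: Tuple[str, int, int],
    reference_present: bool,
    calls: Sequence[SvCall],
    recip_fraction: float = DEFAULT_RECIP_FRACTION,
) -> List[SvCall]:
    """Return the calls genotyping this locus under the mode-specific rules.

    Reference-present loci match deletions under reciprocal overlap
    (>= recip_fraction of both the locus and the call); reference-absent
    loci match insertions with >=1 bp overlap, and curated records at gap
    distance exactly 0.
    """
    seq_id, start, end = locus
    if start < 0 or end < start:
        raise ValueError(f"invalid locus interval [{start}, {end})")
    matched = []
    locus_len = max(end - start, 1)
    for call in calls:
        if call.seq_id != seq_id:
            continue
        if reference_present:
            if call.sv_type != "deletion":
                continue
            ov = _overlap(start, end, call.start, call.end)
            call_len = max(call.end - call.start, 1)
            if ov >= recip_fraction * locus_len and ov >= recip_fraction * call_len:
                matched.append(call)
        else:
            if call.sv_type != "insertion":
                continue
            if call.curated:
                if _gap_distance(start, end, call.start, call.end) == 0:
                    matched.append(call)
            elif _overlap(start, end, call.start, call.end) >= 1:
                matched.append(call)
    return matched


def drop_singletons(calls: Sequence[SvCall]) -> List[SvCall]:
    """Remove single-carrier calls from sources flagged for singleton removal."""
    return [
        c for c in calls if not (c.singleton_filtered and c.carriers == 1)
    ]


def estimate_frequency(
    locus_id: str,
    matched: Sequence[SvCall],
    reference_present: bool,
    deletion_direction: str = "complement",
    absent_bound: float = DEFAULT_ABSENT_BOUND,
) -> FrequencyEstimate:
    """One frequency per locus, from the largest-cohort matching source.

    ``deletion_direction='complement'`` reads a deletion carrier as lacking
    the element (element frequency = 1 - carriers/cohort); ``'direct'``
    reports carriers/cohort unchanged.
    """
    if matched:
        best = max(matched, key=lambda c: (c.cohort_size, c.source_id))
        if best.cohort_size <= 0:
            raise ValueError(f"{locus_id}: matched call with cohort_size 0")
        ratio = best.carriers / best.cohort_size
        if best.sv_type == "deletion":
            freq = 1.0 - ratio if deletion_direction == "complement" else ratio
            basis = BASIS_DELETION
        else:
            freq = ratio
            basis = BASIS_CURATED if best.curated else BASIS_INSERTION
        return FrequencyEstimate(
            locus_id=locus_id,
            frequency=freq,
            basis=basis,
            source_id=best.source_id,
            cohort_size=best.cohort_size,
        )
    if reference_present:
        return FrequencyEstimate(
            locus_id=locus_id, frequency=1.0, basis=BASIS_DEFAULT_FIXED
        )
    return FrequencyEstimate(
        locus_id=locus_id,
        frequency=absent_bound / 2,
        basis=BASIS_DEFAULT_ABSENT,
        is_upper_bound=True,
    )


def locus_frequency(
    locus_id: str,
    locus: Tuple[str, int, int],
    reference_present: bool,
    calls: Sequence[SvCall],
    recip_fraction: float = DEFAULT_RECIP_FRACTION,
    deletion_direction: str = "complement",
) -> FrequencyEstimate:
    """Convenience wrapper: singleton filter, match, then estimate."""
    usable = drop_singletons(calls)
    matched = match_locus(locus, reference_present, usable, recip_fraction)
    return estimate_frequency(
        locus_id, matched, reference_present, deletion_direction=deletion_direction
    )
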
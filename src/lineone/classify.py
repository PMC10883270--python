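"""Eight-way evolutionary categories and group-diagnostic alignment sites.

Each locus is binarized on three axes derived from upstream calls:
polymorphic (population frequency <= 0.75) vs frequent, active (>5% of the
positive control in vitro) vs inactive, and fit in vivo (>10 near
neighbors) vs unfit. The category integer encodes the triple as
``4*polymorphic + 2*active + fit``.

Diagnostic sites are alignment columns at which two groups of sequences are
each internally uniform but differ from one another (a gap is a legal
state). Sites falling in coding sequence are annotated with their codon
effect by substituting both group states into the reference row's codon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from ._seq import translate
from .activity import ActivityCall
from .fitness import DistanceProfile
from .frequency import POLYMORPHIC_MAX, FrequencyEstimate

REGION_UTR5 = "UTR5"
REGION_ORF1 = "ORF1"
REGION_ORF2 = "ORF2"
REGION_UTR3 = "UTR3"
REGION_UNMAPPED = "intergenic"

EFFECT_SYN = "synonymous"
EFFECT_NONSYN = "nonsynonymous"
EFFECT_NONCODING = "noncoding"


@dataclass(frozen=True)
class CategoryAssignment:
    locus_id: str
    polymorphic: bool
    active: bool
    fit: bool

    @property
    def category(self) -> int:
        return 4 * int(self.polymorphic) + 2 * int(self.active) + int(self.fit)


@dataclass(frozen=True)
class DiagnosticSite:
    column: int  # 0-based alignment column
    state_a: str
    state_b: str
    region: Optional[str] = None
    effect: Optional[str] = None
    aa_change: Optional[str] = None


def binarize_categories(
    locus_id: str,
    freq: FrequencyEstimate,
    act: Optional[ActivityCall],
    prof: Optional[DistanceProfile],
    polymorphic_max: float = POLYMORPHIC_MAX,
) -> CategoryAssignment:
    """Combine upstream frequency/activity/fitness calls into one category.

    The active and fit booleans are taken from the upstream calls unchanged;
    only the polymorphic cut (inclusive at the threshold; the "<0.001" bound
    counts as polymorphic) is applied here. A missing activity or fitness
    input yields a partial record with that axis False rather than a
    dropped locus.
    """
    polymorphic = freq.is_upper_bound or freq.frequency <= polymorphic_max
    return CategoryAssignment(
        locus_id=locus_id,
        polymorphic=polymorphic,
        active=bool(act.active) if act is not None else False,
        fit=bool(prof.fit) if prof is not None else False,
    )


def category_counts(assignments: Sequence[CategoryAssignment]) -> List[int]:
    counts = [0] * 8
    for a in assignments:
        counts[a.category] += 1
    return counts


def find_diagnostic_sites(
    msa: Mapping[str, str],
    group_a: Set[str],
    group_b: Set[str],
) -> List[DiagnosticSite]:
    """Columns at which both groups are internally uniform and mutually
    different. Strict fixation: one discordant member removes the column."""
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    for gid in group_a | group_b:
        if gid not in msa:
            raise ValueError(f"id {gid!r} absent from alignment")
    seqs_a = [msa[g] for g in sorted(group_a)]
    seqs_b = [msa[g] for g in sorted(group_b)]
    ncol = len(seqs_a[0])
    if any(len(s) != ncol for s in seqs_a + seqs_b):
        raise ValueError("alignment rows differ in length")
    sites = []
    for col in range(ncol):
        a_states = {s[col] for s in seqs_a}
        b_states = {s[col] for s in seqs_b}
        if len(a_states) == 1 and len(b_states) == 1 and a_states != b_states:
            sites.append(
                DiagnosticSite(
                    column=col, state_a=next(iter(a_states)), state_b=next(iter(b_states))
                )
            )
    return sites


def _column_to_ref_pos(ref_row: str, column: int) -> Optional[int]:
    """Map an alignment column to an ungapped position of the reference row;
    None when the reference carries a gap there."""
    if ref_row[column] == "-":
        return None
    return sum(1 for c in ref_row[:column] if c != "-")


def annotate_site_effect(
    site: DiagnosticSite,
    ref_row: str,
    orf1_span: Tuple[int, int],
    orf2_span: Tuple[int, int],
) -> DiagnosticSite:
    """Assign region and coding effect to a diagnostic site.

    ``ref_row`` is the aligned reference sequence; the ORF spans are 0-based
    half-open nucleotide coordinates on its ungapped sequence (stop codon
    excluded). For ORF columns both group states are substituted into the
    reference codon and translated; a nonsynonymous difference is labelled
    refAA + ORF-local codon number + altAA (e.g. ``K485M``, state_a taken
    as the reference-like state).
    """
    pos = _column_to_ref_pos(ref_row, site.column)
    if pos is None:
        return replace(site, region=REGION_UNMAPPED, effect=EFFECT_NONCODING)
    ref_seq = ref_row.replace("-", "")
    for region, (start, end) in ((REGION_ORF1, orf1_span), (REGION_ORF2, orf2_span)):
        if start <= pos < end:
            if site.state_a == "-" or site.state_b == "-":
                codon_no = (pos - start) // 3 + 1
                ref_aa = translate(ref_seq[start + 3 * (codon_no - 1) : start + 3 * codon_no])
                return replace(
                    site,
                    region=region,
                    effect=EFFECT_NONSYN,
                    aa_change=f"{ref_aa}{codon_no}del",
                )
            offset = pos - start
            codon_no = offset // 3
            codon_start = start + 3 * codon_no
            codon = list(ref_seq[codon_start : codon_start + 3])
            within = offset % 3
            codon_a, codon_b = codon.copy(), codon.copy()
            codon_a[within] = site.state_a
            codon_b[within] = site.state_b
            aa_a, aa_b = translate("".join(codon_a)), translate("".join(codon_b))
            if aa_a == aa_b:
                return replace(site, region=region, effect=EFFECT_SYN)
            # orient the label by the reference row's own base: refAA first
            if ref_seq[pos] == site.state_b:
                aa_a, aa_b = aa_b, aa_a
            return replace(
                site,
                region=region,
                effect=EFFECT_NONSYN,
                aa_change=f"{aa_a}{codon_no + 1}{aa_b}",
            )
    if pos < min(orf1_span[0], orf2_span[0]):
        region = REGION_UTR5
    elif pos >= max(orf1_span[1], orf2_span[1]):
        region = REGION_UTR3
    else:
        region = REGION_UNMAPPED  # inter-ORF spacer
    return replace(site, region=region, effect=EFFECT_NONCODING)
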
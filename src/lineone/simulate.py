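"""Synthetic pseudo-haploid genome pairs with fully known LINE-1 truth.

The generator emulates every input the pipeline consumes, so the whole
analysis is testable without downloads:

* a consensus full-length element (6 kb: 5'UTR, 338-codon ORF1, spacer,
  1275-codon ORF2, 3'UTR) whose translated ORFs serve as the reference
  ORF1p/ORF2p — a synthetic stand-in for a canonical active element;
* LINE-1 lineages: founders diverged from the consensus, plus bursts of
  near-identical copies (the signal the near-neighbor fitness statistic
  detects), a mid-age expansion, old background singletons, and
  genome-private young insertions;
* per-allele lesions (nonsense, 1-nt frameshift) at configurable rates,
  with background substitutions constrained never to create or destroy a
  stop codon, so intactness truth labels are exact by construction;
* two genomes ("A", "B") sharing most loci; shared alleles differ by a few
  substitutions; absent loci leave an empty pre-insertion site between the
  planted unique 2-kb flanks;
* RepeatMasker-style ``.out`` annotation per genome (including truncated
  and non-L1 decoy rows), fabricated SV call sets whose carrier counts
  encode known population frequencies, dual-luciferase plate readings with
  known percent activities, and a two-group alignment with planted
  diagnostic sites.

All randomness flows through one ``numpy`` Generator, so a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from ._seq import CODON_TABLE, STOP_CODONS, revcomp, translate
from .classify import (
    EFFECT_NONCODING,
    EFFECT_NONSYN,
    EFFECT_SYN,
    REGION_ORF1,
    REGION_ORF2,
    REGION_UTR5,
    DiagnosticSite,
)
from .frequency import SvCall
from .intactness import ReferenceOrfs
from .rm_catalog import RepeatAnnotation, make_element_id

BASES = "ACGT"
_NONSTOP = sorted(c for c in CODON_TABLE if CODON_TABLE[c] != "*")


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class LineageSpec:
    """One LINE-1 lineage: a diverged founder and its burst of copies."""

    name: str
    founder_subs: int  # substitutions separating the founder from the consensus
    n_copies: int
    copy_sub_mean: float  # Poisson mean of private substitutions per copy
    shared: bool = True  # loci present in both genomes
    genome: str = "A"  # carrier genome when not shared
    subfamily: str = "L1HS"


def default_lineages() -> Tuple[LineageSpec, ...]:
    """The default study conditions: bursts of 0/5/12/20 recent copies, one
    mid-age expansion, twelve old singletons, and three private young
    insertions per genome."""
    lineages = [
        LineageSpec("b0", 70, 1, 4.0),
        LineageSpec("b5", 140, 5, 4.0),
        LineageSpec("b12", 210, 12, 4.0),
        LineageSpec("b20", 280, 20, 4.0),
        LineageSpec("mid", 350, 8, 20.0, subfamily="L1PA2"),
    ]
    for i in range(12):
        lineages.append(
            LineageSpec(f"old{i}", 100 + 12 * i, 1, 0.0, subfamily="L1PA3")
        )
    for i in range(3):
        lineages.append(LineageSpec(f"uniqA{i}", 60, 1, 4.0, shared=False, genome="A"))
        lineages.append(LineageSpec(f"uniqB{i}", 60, 1, 4.0, shared=False, genome="B"))
    return tuple(lineages)


@dataclass(frozen=True)
class SimParams:
    seed: int = 0
    utr5_len: int = 900  # bp; includes a stop guard before the ORF1 start
    orf1_codons: int = 338
    spacer_len: int = 63
    orf2_codons: int = 1275
    utr3_len: int = 192
    lineages: Tuple[LineageSpec, ...] = field(default_factory=default_lineages)
    p_nonsense: float = 0.10  # per-allele probability of a premature stop
    p_frameshift: float = 0.08  # per-allele probability of a 1-nt indel
    allelic_sub_mean: float = 3.0  # substitutions between A and B alleles
    flank_len: int = 2000
    linker_len: int = 200
    n_truncated: int = 8  # <5 kb decoy elements per genome
    n_other_repeats: int = 2  # non-L1 annotation rows per genome
    ambiguous_flanks: bool = False  # duplicate one locus's flanks (unplaced test)
    reverse_fraction: float = 0.3  # fraction of loci annotated on the - strand
    cohort_large: int = 2504  # KGP-like SV source (singleton-filtered)
    cohort_small: int = 185  # complementary-study SV source
    cohort_curated: int = 1059  # curated insertion database
    wells_per_construct: int = 16
    constructs_per_plate: int = 11
    control_wells: int = 4
    pct_noise_sd: float = 1.5  # per-well noise, percent points
    r_pos: float = 2.0  # mean firefly/renilla ratio of the positive control
    r_neg: float = 0.1
    msa_group_sizes: Tuple[int, int] = (6, 5)
    msa_private_subs: float = 3.0

    @property
    def consensus_len(self) -> int:
        return (
            self.utr5_len
            + 3 * self.orf1_codons
            + 3
            + self.spacer_len
            + 3 * self.orf2_codons
            + 3
            + self.utr3_len
        )

    @property
    def orf1_span(self) -> Tuple[int, int]:
        s = self.utr5_len
        return (s, s + 3 * self.orf1_codons)

    @property
    def orf2_span(self) -> Tuple[int, int]:
        s = self.utr5_len + 3 * self.orf1_codons + 3 + self.spacer_len
        return (s, s + 3 * self.orf2_codons)


# ---------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class AlleleTruth:
    element_id: str
    genome: str
    locus_id: str
    lineage: str
    subs: Dict[int, str]  # consensus position -> base carried by this allele
    n_indels: int
    lesion: Optional[str]  # None | 'nonsense' | 'frameshift'
    intended_intact: bool
    young_count: int = 0
    fit: bool = False


@dataclass
class LocusTruth:
    locus_id: str
    lineage: str
    in_a: bool
    in_b: bool
    ref_present: bool  # present in the reference coordinate system (== in_b)
    true_freq: float
    strand: str
    true_pct: Optional[float] = None  # in vitro percent of the A allele
    active: Optional[bool] = None


@dataclass
class SimTruth:
    alleles: Dict[str, AlleleTruth]  # element_id -> truth
    loci: Dict[str, LocusTruth]
    msa_sites: Tuple[DiagnosticSite, ...]

    def elements_frame(self) -> pd.DataFrame:
        rows = [
            {
                "element_id": a.element_id,
                "genome": a.genome,
                "locus_id": a.locus_id,
                "lineage": a.lineage,
                "intended_intact": a.intended_intact,
                "lesion": a.lesion or "",
                "n_subs": len(a.subs),
                "young_count": a.young_count,
                "fit": a.fit,
            }
            for a in self.alleles.values()
        ]
        return pd.DataFrame(rows)

    def loci_frame(self) -> pd.DataFrame:
        rows = [vars(l).copy() for l in self.loci.values()]
        return pd.DataFrame(rows)


@dataclass
class SimResult:
    params: SimParams
    consensus: str
    ref_orfs: ReferenceOrfs
    genomes: Dict[str, Dict[str, str]]  # genome -> contig -> sequence
    rm_out: Dict[str, str]  # genome -> RepeatMasker-style text
    annotations: Dict[str, List[RepeatAnnotation]]
    sv_calls: List[SvCall]
    plate_data: pd.DataFrame
    msa: Dict[str, str]
    msa_group_a: Set[str]
    msa_group_b: Set[str]
    truth: SimTruth
    locus_intervals: Dict[str, Tuple[str, int, int]]  # reference coordinates


# ---------------------------------------------------------------------------
# sequence construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 1) random non-stop codons + TAA stop."""
    body = "".join(
        _NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), size=n_codons - 1)
    )
    return "ATG" + body + "TAA"


def build_consensus(params: SimParams, rng: np.random.Generator) -> Tuple[str, ReferenceOrfs]:
    utr5 = _random_seq(rng, params.utr5_len - 3) + "TAA"  # stop guard
    orf1 = _random_orf(rng, params.orf1_codons)
    spacer = _random_seq(rng, params.spacer_len - 3) + "TAA"
    orf2 = _random_orf(rng, params.orf2_codons)
    # pin two codons used by the diagnostic-site alignment: a Gly codon with a
    # free third position in ORF1, and a Lys codon (K485) in ORF2
    orf1 = orf1[: 3 * 99] + "GGA" + orf1[3 * 100 :]
    orf2 = orf2[: 3 * 484] + "AAG" + orf2[3 * 485 :]
    utr3 = _random_seq(rng, params.utr3_len)
    consensus = utr5 + orf1 + spacer + orf2 + utr3
    assert len(consensus) == params.consensus_len
    o1, o2 = params.orf1_span, params.orf2_span
    refs = ReferenceOrfs(
        orf1_aa=translate(consensus[o1[0] : o1[1]]),
        orf2_aa=translate(consensus[o2[0] : o2[1]]),
        source_id="synthetic-consensus",
    )
    return consensus, refs


def _protected_positions(params: SimParams) -> Set[int]:
    """Positions never touched by background substitutions: start/stop codons,
    the stop guards, and the terminal coding codons of each ORF (so that only
    planted lesions — never background divergence clipped by the local
    aligner — can break the full-span intactness rule)."""
    o1, o2 = params.orf1_span, params.orf2_span
    protected: Set[int] = set()
    protected.update(range(params.utr5_len - 3, params.utr5_len))  # UTR5 guard
    protected.update(range(o1[0], o1[0] + 3))  # ORF1 ATG
    protected.update(range(o1[1] - 3, o1[1] + 3))  # ORF1 last codon + stop
    protected.update(range(o2[0] - 3, o2[0]))  # spacer guard
    protected.update(range(o2[0], o2[0] + 3))  # ORF2 ATG
    protected.update(range(o2[1] - 3, o2[1] + 3))  # ORF2 last codon + stop
    return protected


def _safe_substitutions(
    params: SimParams,
    current: Dict[int, str],
    n: int,
    rng: np.random.Generator,
    consensus: str,
) -> Dict[int, str]:
    """Draw ``n`` additional substitutions (consensus coordinates) that never
    create a stop codon inside either ORF nor touch protected positions.
    Returns the updated position->base map."""
    protected = _protected_positions(params)
    spans = (params.orf1_span, params.orf2_span)
    subs = dict(current)

    def base_at(pos: int) -> str:
        return subs.get(pos, consensus[pos])

    added = 0
    L = params.consensus_len
    while added < n:
        pos = int(rng.integers(0, L))
        if pos in protected or pos in subs:
            continue
        old = base_at(pos)
        choices = [b for b in BASES if b != old]
        new = choices[int(rng.integers(0, 3))]
        in_orf = None
        for start, end in spans:
            if start <= pos < end:
                in_orf = start
                break
        if in_orf is not None:
            codon_start = in_orf + 3 * ((pos - in_orf) // 3)
            codon = [base_at(codon_start + k) for k in range(3)]
            codon[pos - codon_start] = new
            if "".join(codon) in STOP_CODONS:
                continue
        subs[pos] = new
        added += 1
    return subs


def _apply_subs(consensus: str, subs: Mapping[int, str]) -> List[str]:
    seq = list(consensus)
    for pos, base in subs.items():
        seq[pos] = base
    return seq


def mutate_sequence(
    seq: str,
    n_subs: int,
    indel_events: Sequence[Tuple[str, int, str]],
    rng: np.random.Generator,
) -> Tuple[str, Dict[str, object]]:
    """Generic mutator: exactly ``n_subs`` substitutions at distinct positions
    (always to a different base) followed by indels applied right-to-left.

    ``indel_events`` entries are ``('ins', pos, bases)`` or
    ``('del', pos, length)`` with positions valid on the substituted
    sequence. Returns the mutated sequence and an edit log sufficient to
    reconstruct the edit script.
    """
    if n_subs > len(seq):
        raise ValueError("n_subs exceeds sequence length")
    chars = list(seq)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    sub_log = {}
    for pos in sorted(int(p) for p in positions):
        old = chars[pos]
        choices = [b for b in BASES if b != old]
        new = choices[int(rng.integers(0, 3))]
        chars[pos] = new
        sub_log[pos] = (old, new)
    indel_log = []
    for kind, pos, payload in sorted(indel_events, key=lambda e: -e[1]):
        if kind == "ins":
            if not 0 <= pos <= len(chars):
                raise ValueError(f"insertion position {pos} out of bounds")
            chars[pos:pos] = list(payload)
            indel_log.append(("ins", pos, payload))
        elif kind == "del":
            length = int(payload)
            if not 0 <= pos <= len(chars) - length:
                raise ValueError(f"deletion [{pos}, {pos + length}) out of bounds")
            del chars[pos : pos + length]
            indel_log.append(("del", pos, length))
        else:
            raise ValueError(f"unknown indel kind {kind!r}")
    return "".join(chars), {"subs": sub_log, "indels": indel_log}


def _nonsense_lesion(
    params: SimParams, subs: Dict[int, str], rng: np.random.Generator, consensus: str
) -> Dict[int, str]:
    """Plant a premature TAA in ORF2 (or ORF1, 1:3 odds); returns updated subs."""
    span = params.orf1_span if rng.random() < 0.25 else params.orf2_span
    n_codons = (span[1] - span[0]) // 3
    codon_idx = int(rng.integers(10, n_codons - 10))
    start = span[0] + 3 * codon_idx
    out = dict(subs)
    for k, base in enumerate("TAA"):
        cur = out.get(start + k, consensus[start + k])
        if cur != base:
            out[start + k] = base
    return out


def _frameshift_lesion(
    params: SimParams, rng: np.random.Generator
) -> Tuple[str, int, str]:
    """A 1-nt insertion or deletion inside an ORF (consensus coordinates)."""
    span = params.orf1_span if rng.random() < 0.25 else params.orf2_span
    pos = int(rng.integers(span[0] + 30, span[1] - 30))
    if rng.random() < 0.5:
        return ("ins", pos, BASES[int(rng.integers(0, 4))])
    return ("del", pos, "1")


def _allele_sequence(
    consensus: str, subs: Mapping[int, str], indel: Optional[Tuple[str, int, str]]
) -> str:
    chars = _apply_subs(consensus, subs)
    if indel is not None:
        kind, pos, payload = indel
        if kind == "ins":
            chars[pos:pos] = list(payload)
        else:
            del chars[pos : pos + int(payload)]
    return "".join(chars)


def _truth_distance(a: AlleleTruth, b: AlleleTruth, consensus: str) -> int:
    """Per-event distance implied by the edit records of two alleles."""
    d = a.n_indels + b.n_indels
    for pos in set(a.subs) | set(b.subs):
        if a.subs.get(pos, consensus[pos]) != b.subs.get(pos, consensus[pos]):
            d += 1
    return d


# ---------------------------------------------------------------------------
# RepeatMasker-style output

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def write_rm_out(annotations: Sequence[RepeatAnnotation]) -> str:
    """RepeatMasker ``.out`` text (1-based inclusive, reverse strand as 'C')."""
    buf = io.StringIO()
    buf.write(_RM_HEADER)
    for i, a in enumerate(annotations, start=1):
        strand = "C" if a.strand == "-" else "+"
        buf.write(
            f"{a.sw_score:6d}  1.2  0.1  0.2  {a.seq_id} {a.start + 1:9d} "
            f"{a.end:9d} (0) {strand} {a.repeat_name:<10s} {a.repeat_class:<18s} "
            f"1 {a.length} (0) {a.rm_join_id or i}\n"
        )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# the family simulator


def simulate_family(params: SimParams) -> SimResult:
    """Generate the full synthetic study: genome pair, annotations, SV call
    sets, plate readings, diagnostic-site alignment and the truth tables."""
    rng = np.random.default_rng(params.seed)
    consensus, refs = build_consensus(params, rng)
    flank = params.flank_len

    # --- plan loci -------------------------------------------------------
    locus_plans = []  # dicts: locus_id, lineage, strand, flanks, alleles
    allele_truth: Dict[str, AlleleTruth] = {}
    for spec in params.lineages:
        founder = _safe_substitutions(params, {}, spec.founder_subs, rng, consensus)
        for copy_i in range(spec.n_copies):
            locus_id = f"{spec.name}.{copy_i}"
            n_priv = int(rng.poisson(spec.copy_sub_mean))
            core = _safe_substitutions(params, founder, n_priv, rng, consensus)
            strand = "-" if rng.random() < params.reverse_fraction else "+"
            genomes_here = ("A", "B") if spec.shared else (spec.genome,)
            alleles = {}
            for g in genomes_here:
                subs = core
                if g == "B" and spec.shared:
                    subs = _safe_substitutions(
                        params, core, int(rng.poisson(params.allelic_sub_mean)), rng,
                        consensus,
                    )
                lesion = None
                indel = None
                u = rng.random()
                if u < params.p_nonsense:
                    lesion = "nonsense"
                    subs = _nonsense_lesion(params, subs, rng, consensus)
                elif u < params.p_nonsense + params.p_frameshift:
                    lesion = "frameshift"
                    indel = _frameshift_lesion(params, rng)
                alleles[g] = {
                    "subs": subs,
                    "indel": indel,
                    "lesion": lesion,
                    "seq": _allele_sequence(consensus, subs, indel),
                }
            locus_plans.append(
                {
                    "locus_id": locus_id,
                    "lineage": spec.name,
                    "subfamily": spec.subfamily,
                    "strand": strand,
                    "alleles": alleles,
                    "left": _random_seq(rng, flank),
                    "right": _random_seq(rng, flank),
                }
            )
    if params.ambiguous_flanks and locus_plans:
        # duplicate the first locus's flanks onto the second (unplaced mode)
        locus_plans[1]["left"] = locus_plans[0]["left"]
        locus_plans[1]["right"] = locus_plans[0]["right"]

    order = rng.permutation(len(locus_plans))
    locus_plans = [locus_plans[i] for i in order]
    half = (len(locus_plans) + 1) // 2
    contig_of = {
        p["locus_id"]: ("chr1" if i < half else "chr2")
        for i, p in enumerate(locus_plans)
    }

    # --- assemble genomes ------------------------------------------------
    genomes: Dict[str, Dict[str, str]] = {}
    annotations: Dict[str, List[RepeatAnnotation]] = {}
    locus_intervals: Dict[str, Tuple[str, int, int]] = {}
    for g in ("A", "B"):
        contigs: Dict[str, List[str]] = {"chr1": [], "chr2": []}
        cursors = {"chr1": 0, "chr2": 0}
        anns: List[RepeatAnnotation] = []
        for plan in locus_plans:
            contig = contig_of[plan["locus_id"]]
            parts = contigs[contig]
            linker = _random_seq(rng, params.linker_len)
            parts.append(linker)
            cursors[contig] += params.linker_len
            parts.append(plan["left"])
            cursors[contig] += flank
            allele = plan["alleles"].get(g)
            if allele is not None:
                seq = allele["seq"]
                emitted = revcomp(seq) if plan["strand"] == "-" else seq
                start = cursors[contig]
                end = start + len(seq)
                parts.append(emitted)
                cursors[contig] = end
                ann = RepeatAnnotation(
                    seq_id=contig,
                    start=start,
                    end=end,
                    strand=plan["strand"],
                    repeat_name=plan["subfamily"],
                    repeat_class="LINE/L1",
                    rm_join_id=plan["locus_id"],
                    sw_score=20000,
                )
                anns.append(ann)
                eid = make_element_id(g, contig, start, end)
                allele["element_id"] = eid
                allele_truth[eid] = AlleleTruth(
                    element_id=eid,
                    genome=g,
                    locus_id=plan["locus_id"],
                    lineage=plan["lineage"],
                    subs=allele["subs"],
                    n_indels=0 if allele["indel"] is None else 1,
                    lesion=allele["lesion"],
                    intended_intact=allele["lesion"] is None,
                )
                if g == "A" or "A" not in plan["alleles"]:
                    locus_intervals[plan["locus_id"]] = (contig, start, end)
            parts.append(plan["right"])
            cursors[contig] += flank
        # decoys: truncated elements and non-L1 repeats
        for i in range(params.n_truncated):
            contig = "chr1" if i % 2 == 0 else "chr2"
            trunc_len = int(rng.integers(1500, 4500))
            n_subs = int(rng.poisson(120.0 * trunc_len / len(consensus)))
            subs = _safe_substitutions(params, {}, n_subs, rng, consensus)
            seq = "".join(_apply_subs(consensus, subs))[-trunc_len:]
            contigs[contig].append(_random_seq(rng, 400))
            cursors[contig] += 400
            start = cursors[contig]
            contigs[contig].append(seq)
            cursors[contig] += trunc_len
            anns.append(
                RepeatAnnotation(
                    seq_id=contig,
                    start=start,
                    end=start + trunc_len,
                    strand="+",
                    repeat_name="L1PA4",
                    repeat_class="LINE/L1",
                    sw_score=9000,
                )
            )
        for i in range(params.n_other_repeats):
            contig = "chr1" if i % 2 == 0 else "chr2"
            contigs[contig].append(_random_seq(rng, 300))
            cursors[contig] += 300
            start = cursors[contig]
            alu = _random_seq(rng, 300)
            contigs[contig].append(alu)
            cursors[contig] += 300
            anns.append(
                RepeatAnnotation(
                    seq_id=contig,
                    start=start,
                    end=start + 300,
                    strand="+",
                    repeat_name="AluY",
                    repeat_class="SINE/Alu",
                    sw_score=2000,
                )
            )
        for contig in contigs:
            contigs[contig].append(_random_seq(rng, 300))
        genomes[g] = {name: "".join(parts) for name, parts in contigs.items()}
        anns.sort(key=lambda a: (a.seq_id, a.start))
        annotations[g] = anns

    # --- truth: near-neighbor counts from the edit records ---------------
    by_lineage: Dict[Tuple[str, str], List[AlleleTruth]] = {}
    for a in allele_truth.values():
        by_lineage.setdefault((a.genome, a.lineage), []).append(a)
    for members in by_lineage.values():
        for a in members:
            a.young_count = sum(
                1
                for b in members
                if b.element_id != a.element_id
                and _truth_distance(a, b, consensus) <= 27
            )
            a.fit = a.young_count > 10

    # --- frequencies, activities and category coverage -------------------
    loci_truth: Dict[str, LocusTruth] = {}
    intact_a: List[str] = []  # locus ids with an intended-intact A allele
    for plan in locus_plans:
        in_a = "A" in plan["alleles"]
        in_b = "B" in plan["alleles"]
        loci_truth[plan["locus_id"]] = LocusTruth(
            locus_id=plan["locus_id"],
            lineage=plan["lineage"],
            in_a=in_a,
            in_b=in_b,
            ref_present=in_b,
            true_freq=1.0,
            strand=plan["strand"],
        )
        if in_a and plan["alleles"]["A"]["lesion"] is None:
            intact_a.append(plan["locus_id"])

    fit_of_locus = {
        a.locus_id: a.fit for a in allele_truth.values() if a.genome == "A"
    }
    combos = [(True, True), (True, False), (False, True), (False, False)]
    for fit_group in (True, False):
        members = [l for l in intact_a if fit_of_locus.get(l, False) == fit_group]
        for idx, locus_id in enumerate(members):
            poly, active = combos[idx % 4]
            lt = loci_truth[locus_id]
            if not lt.ref_present:
                poly = True  # a reference-absent locus cannot be genotyped fixed
            if poly:
                lt.true_freq = (
                    float(rng.uniform(0.25, 0.65)) if lt.ref_present else 0.0005
                )
            else:
                lt.true_freq = 1.0 if rng.random() < 0.5 else float(
                    rng.uniform(0.85, 0.97)
                )
            lt.true_pct = (
                float(rng.uniform(12.0, 90.0)) if active else float(rng.uniform(0.0, 1.5))
            )
            lt.active = active
    # loci without an intact A allele still get a frequency (mostly fixed)
    for lt in loci_truth.values():
        if lt.true_pct is None:
            if lt.ref_present:
                lt.true_freq = 1.0 if rng.random() < 0.7 else float(
                    rng.uniform(0.3, 0.9)
                )
            else:
                lt.true_freq = 0.0005

    # --- fabricate SV calls ----------------------------------------------
    sv_calls: List[SvCall] = []
    for locus_id, lt in loci_truth.items():
        interval = locus_intervals.get(locus_id)
        if interval is None:
            continue
        seq_id, start, end = interval
        if lt.ref_present:
            if lt.true_freq < 1.0:
                carriers = int(round((1.0 - lt.true_freq) * params.cohort_large))
                sv_calls.append(
                    SvCall(
                        "kgp", seq_id, start, end, "deletion",
                        max(carriers, 2), params.cohort_large,
                        singleton_filtered=True,
                    )
                )
                if rng.random() < 0.3:  # second, smaller source; precedence test
                    carriers2 = int(round((1.0 - lt.true_freq) * params.cohort_small))
                    sv_calls.append(
                        SvCall(
                            "study2", seq_id, start, end, "deletion",
                            min(max(carriers2, 2), params.cohort_small),
                            params.cohort_small,
                        )
                    )
        else:
            if lt.true_freq > 0.001 and lt.in_a:
                if rng.random() < 0.5:
                    sv_calls.append(
                        SvCall(
                            "kgp", seq_id, start, start, "insertion",
                            max(int(round(lt.true_freq * params.cohort_large)), 2),
                            params.cohort_large, singleton_filtered=True,
                        )
                    )
                else:
                    sv_calls.append(
                        SvCall(
                            "culdb", seq_id, start, end, "insertion",
                            max(int(round(lt.true_freq * params.cohort_curated)), 2),
                            params.cohort_curated, curated=True,
                        )
                    )
    # planted singleton noise, removed by the filter
    if locus_intervals:
        seq_id, start, end = next(iter(locus_intervals.values()))
        sv_calls.append(
            SvCall(
                "kgp", seq_id, start, start, "insertion", 1, params.cohort_large,
                singleton_filtered=True,
            )
        )

    # --- plate readings ---------------------------------------------------
    a_element_of = {
        a.locus_id: a.element_id for a in allele_truth.values() if a.genome == "A"
    }
    constructs = [
        (a_element_of[locus_id], loci_truth[locus_id].true_pct)
        for locus_id in intact_a
        if loci_truth[locus_id].true_pct is not None
    ]
    plate_rows = []
    plate_no = 0
    n_plates_per_group = max(1, params.wells_per_construct // 8)
    for gi in range(0, len(constructs), params.constructs_per_plate):
        group = constructs[gi : gi + params.constructs_per_plate]
        for rep in range(n_plates_per_group):
            plate_no += 1
            plate_id = f"P{plate_no:03d}"
            span = params.r_pos - params.r_neg
            well_no = 0

            def add_well(construct_id, role, true_pct):
                nonlocal well_no
                well_no += 1
                r = (
                    params.r_neg
                    + true_pct / 100.0 * span
                    + rng.normal(0.0, params.pct_noise_sd / 100.0 * span)
                )
                renilla = float(rng.lognormal(11.0, 0.1))
                plate_rows.append(
                    {
                        "plate_id": plate_id,
                        "well": f"W{well_no:02d}",
                        "construct_id": construct_id,
                        "clone_id": f"{construct_id}.c{rep + 1}",
                        "role": role,
                        "firefly": max(r, 0.0) * renilla,
                        "renilla": renilla,
                        "excluded": False,
                    }
                )

            for _ in range(params.control_wells):
                add_well("pos_ctrl", "pos", 100.0)
            for _ in range(params.control_wells):
                add_well("neg_ctrl", "neg", 0.0)
            for locus_id, true_pct in group:
                for _ in range(8):
                    add_well(locus_id, "test", true_pct)
    plate_df = pd.DataFrame(plate_rows)

    # --- diagnostic-site alignment ---------------------------------------
    o1, o2 = params.orf1_span, params.orf2_span
    site_cols = {
        150: ("u5a", REGION_UTR5, EFFECT_NONCODING, None),
        420: ("u5b", REGION_UTR5, EFFECT_NONCODING, None),
        o1[0] + 3 * 99 + 2: ("orf1syn", REGION_ORF1, EFFECT_SYN, None),  # GGA->GGG
        o2[0] + 3 * 484 + 1: ("orf2nonsyn", REGION_ORF2, EFFECT_NONSYN, "K485M"),
    }
    alt_state = {150: None, 420: None}
    msa: Dict[str, str] = {"consensus": consensus}
    n_a, n_b = params.msa_group_sizes
    group_a = {f"fitclust_{i + 1}" for i in range(n_a)}
    group_b = {f"unfit_{i + 1}" for i in range(n_b)}
    # group-A states: UTR5 transversions, GGA->GGG, AAG->ATG
    a_states = {}
    for col in (150, 420):
        cur = consensus[col]
        a_states[col] = BASES[(BASES.index(cur) + 2) % 4]
    a_states[o1[0] + 3 * 99 + 2] = "G"  # GGA -> GGG (synonymous)
    a_states[o2[0] + 3 * 484 + 1] = "T"  # AAG -> ATG: K485M
    diag_cols = sorted(a_states)
    # private substitutions: all drawn from distinct non-diagnostic columns
    free_cols = [c for c in range(len(consensus)) if c not in a_states]
    n_priv_total = int(rng.poisson(params.msa_private_subs * (n_a + n_b)))
    priv_positions = rng.choice(len(free_cols), size=n_priv_total, replace=False)
    priv_iter = iter(int(p) for p in priv_positions)
    for name in sorted(group_a) + sorted(group_b):
        chars = list(consensus)
        if name in group_a:
            for col, base in a_states.items():
                chars[col] = base
        n_priv = int(rng.poisson(params.msa_private_subs))
        for _ in range(n_priv):
            try:
                col = free_cols[next(priv_iter)]
            except StopIteration:
                break
            old = chars[col]
            chars[col] = BASES[(BASES.index(old) + 1) % 4] if old in BASES else "A"
        msa[name] = "".join(chars)
    msa_sites = tuple(
        DiagnosticSite(
            column=col,
            state_a=a_states[col],
            state_b=consensus[col],
            region=site_cols[col][1],
            effect=site_cols[col][2],
            aa_change=site_cols[col][3],
        )
        for col in diag_cols
    )

    truth = SimTruth(alleles=allele_truth, loci=loci_truth, msa_sites=msa_sites)
    return SimResult(
        params=params,
        consensus=consensus,
        ref_orfs=refs,
        genomes=genomes,
        rm_out={g: write_rm_out(annotations[g]) for g in annotations},
        annotations=annotations,
        sv_calls=sv_calls,
        plate_data=plate_df,
        msa=msa,
        msa_group_a=group_a,
        msa_group_b=group_b,
        truth=truth,
        locus_intervals=locus_intervals,
    )


def write_outputs(sim: SimResult, outdir) -> None:
    """Write every simulated input as standard text formats under ``outdir``."""
    import os

    from ._seq import write_fasta

    os.makedirs(outdir, exist_ok=True)
    for g, contigs in sim.genomes.items():
        write_fasta(contigs, os.path.join(outdir, f"genome_{g}.fa"))
        with open(os.path.join(outdir, f"genome_{g}.rm.out"), "w") as fh:
            fh.write(sim.rm_out[g])
    write_fasta(
        {"orf1p": sim.ref_orfs.orf1_aa, "orf2p": sim.ref_orfs.orf2_aa},
        os.path.join(outdir, "reference_orfs.faa"),
    )
    write_fasta({"consensus": sim.consensus}, os.path.join(outdir, "consensus.fa"))
    rows = [
        {
            "source_id": c.source_id, "seq_id": c.seq_id, "start": c.start,
            "end": c.end, "sv_type": c.sv_type, "carriers": c.carriers,
            "cohort_size": c.cohort_size, "curated": c.curated,
            "singleton_filtered": c.singleton_filtered,
        }
        for c in sim.sv_calls
    ]
    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "sv_calls.tsv"), sep="\t", index=False
    )
    sim.plate_data.to_csv(os.path.join(outdir, "plates.csv"), index=False)
    write_fasta(sim.msa, os.path.join(outdir, "msa.aln.fa"))
    sim.truth.elements_frame().to_csv(
        os.path.join(outdir, "truth_elements.tsv"), sep="\t", index=False
    )
    sim.truth.loci_frame().to_csv(
        os.path.join(outdir, "truth_loci.tsv"), sep="\t", index=False
    )
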
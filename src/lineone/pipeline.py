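"""End-to-end orchestration: catalog -> intactness -> frameshifts -> alleles
-> fitness -> frequency -> activity -> categories, plus summary tallies.

The pipeline treats one genome (the first, conventionally "A") as the focal
assembly — its intact elements are profiled for fitness, genotyped for
population frequency and matched to activity constructs — and the second
genome as both the allelic partner and the reference-presence proxy (a
locus present in the partner assembly is genotyped through deletion calls,
a focal-private locus through insertion calls).

Everything is a pure function of its inputs: re-running with the same
inputs and config reproduces the master table exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import (
    activity as activity_mod,
    alleles as alleles_mod,
    classify as classify_mod,
    fitness as fitness_mod,
    frameshift as frameshift_mod,
    frequency as frequency_mod,
    intactness as intactness_mod,
    rm_catalog,
)
from .frequency import SvCall
from .intactness import IntactnessCall, ReferenceOrfs
from .rm_catalog import ElementRecord

logger = logging.getLogger("lineone")


@dataclass(frozen=True)
class PipelineConfig:
    """Every numeric threshold of the analysis, with its conventional default."""

    min_len: int = 5000  # bp; full-length element cutoff
    keyword: str = "L1"  # matching-repeat filter
    min_aa: int = 50  # ORF candidate floor, codons
    activity_threshold: float = 5.0  # percent of positive control
    alpha: float = 0.05
    frequency_polymorphic_max: float = 0.75
    young_max: int = 27  # nucleotide differences
    mid_max: int = 82
    near_neighbor_min: int = 10
    flank_len: int = 2000  # bp
    neighborhood_window: int = 50000  # bp
    recip_fraction: float = 0.9
    default_absent_frequency: float = 0.001
    frameshift_penalty: float = 15.0
    distance_gap_mode: str = "per_event"
    divergence_gap_mode: str = "per_base"
    deletion_direction: str = "complement"
    count_frameshifts: bool = True  # DP frameshift stage (the slowest stage)
    compute_divergence: bool = True  # allelic nt/aa divergence enrichment
    seed: int = 0

    def __post_init__(self):
        if self.young_max >= self.mid_max:
            raise ValueError("young_max must be < mid_max")
        if not 0 < self.recip_fraction <= 1:
            raise ValueError("recip_fraction must be in (0, 1]")


@dataclass
class PipelineInputs:
    genomes: Dict[str, Dict[str, str]]  # genome id -> contig -> sequence
    rm_out: Dict[str, str]  # genome id -> RepeatMasker .out text
    ref_orfs: ReferenceOrfs
    sv_calls: List[SvCall] = field(default_factory=list)
    plate_data: Optional[pd.DataFrame] = None

    @classmethod
    def from_sim(cls, sim) -> "PipelineInputs":
        return cls(
            genomes=sim.genomes,
            rm_out=sim.rm_out,
            ref_orfs=sim.ref_orfs,
            sv_calls=list(sim.sv_calls),
            plate_data=sim.plate_data,
        )


@dataclass
class PipelineResult:
    master: pd.DataFrame
    summary: Dict[str, object]
    elements: Dict[str, List[ElementRecord]]
    intact_calls: Dict[str, Dict[str, IntactnessCall]]
    profiles: Dict[str, fitness_mod.DistanceProfile]
    frequency: Dict[str, frequency_mod.FrequencyEstimate]
    activity: Dict[str, activity_mod.ActivityCall]
    categories: Dict[str, classify_mod.CategoryAssignment]
    pairs: List[alleles_mod.AllelicPair]
    frameshifts: Dict[str, frameshift_mod.FrameshiftReport]


def _aa_of(call: IntactnessCall) -> Optional[str]:
    if call.orf1_hit is None or call.orf2_hit is None:
        return None
    return call.orf1_hit[0].aa_seq + call.orf2_hit[0].aa_seq


def run_pipeline(inputs: PipelineInputs, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    genome_ids = sorted(inputs.genomes)
    if len(genome_ids) != 2:
        raise ValueError("the pipeline expects exactly two genomes")
    ga, gb = genome_ids

    # stage 1: catalog
    elements: Dict[str, List[ElementRecord]] = {}
    for g in genome_ids:
        anns = rm_catalog.parse_repeatmasker(inputs.rm_out[g], keyword=config.keyword)
        elements[g] = rm_catalog.extract_full_length(
            anns, inputs.genomes[g], genome_id=g, min_len=config.min_len
        )
        logger.info("catalog[%s]: %d full-length elements", g, len(elements[g]))

    # stage 2: intactness
    intact_calls: Dict[str, Dict[str, IntactnessCall]] = {}
    for g in genome_ids:
        intact_calls[g] = {
            e.element_id: intactness_mod.call_intact(
                e, inputs.ref_orfs, min_aa=config.min_aa
            )
            for e in elements[g]
        }
        n_intact = sum(1 for c in intact_calls[g].values() if c.intact)
        logger.info("intactness[%s]: %d intact", g, n_intact)
    intact_elems = {
        g: [e for e in elements[g] if intact_calls[g][e.element_id].intact]
        for g in genome_ids
    }

    # stage 3: frameshift counts for full-length, non-intact elements
    frameshifts: Dict[str, frameshift_mod.FrameshiftReport] = {}
    for g in genome_ids if config.count_frameshifts else ():
        for e in elements[g]:
            if not intact_calls[g][e.element_id].intact:
                frameshifts[e.element_id] = frameshift_mod.frameshift_report(
                    e, inputs.ref_orfs, frameshift_penalty=config.frameshift_penalty
                )

    # stage 4: allele pairing through flank mapping
    matches_ab = {
        e.element_id: alleles_mod.map_flanks(
            e, inputs.genomes[ga], inputs.genomes[gb], elements[gb],
            flank=config.flank_len, window=config.neighborhood_window,
            target_genome_id=gb,
        )
        for e in intact_elems[ga]
    }
    matches_ba = {
        e.element_id: alleles_mod.map_flanks(
            e, inputs.genomes[gb], inputs.genomes[ga], elements[ga],
            flank=config.flank_len, window=config.neighborhood_window,
            target_genome_id=ga,
        )
        for e in intact_elems[gb]
    }
    pairs = alleles_mod.pair_alleles(
        intact_elems[ga], intact_elems[gb], matches_ab, matches_ba,
        intact_calls[ga], intact_calls[gb],
    )
    seq_of = {
        e.element_id: e for g in genome_ids for e in elements[g]
    }
    enriched_pairs = []
    for p in pairs:
        nt = aa = None
        if config.compute_divergence and p.element_a and p.element_b:
            ea, eb = seq_of[p.element_a], seq_of[p.element_b]
            nt = alleles_mod.nt_divergence(
                ea.sequence, eb.sequence, gap_mode=config.divergence_gap_mode
            )
            if p.status_a == "intact" and p.status_b == "intact":
                aa_a = _aa_of(intact_calls[ga][p.element_a])
                aa_b = _aa_of(intact_calls[gb][p.element_b])
                if aa_a and aa_b:
                    aa = alleles_mod.aa_divergence(aa_a, aa_b)
        enriched_pairs.append(
            alleles_mod.AllelicPair(
                p.locus_id, p.element_a, p.element_b, p.status_a, p.status_b, nt, aa
            )
        )
    pairs = enriched_pairs

    # stage 5: fitness profiles of focal-genome intact elements
    profiles = {
        prof.element_id: prof
        for prof in fitness_mod.profile_all(
            intact_elems[ga], elements[ga],
            young_max=config.young_max, mid_max=config.mid_max,
            near_neighbor_min=config.near_neighbor_min,
            gap_mode=config.distance_gap_mode,
        )
    }

    # stage 6: population frequency of focal-genome loci
    frequency: Dict[str, frequency_mod.FrequencyEstimate] = {}
    for p in pairs:
        if not p.element_a:
            continue
        ann = seq_of[p.element_a].annotation
        reference_present = p.status_b != "absent"
        frequency[p.element_a] = frequency_mod.locus_frequency(
            p.element_a, (ann.seq_id, ann.start, ann.end), reference_present,
            inputs.sv_calls, recip_fraction=config.recip_fraction,
            deletion_direction=config.deletion_direction,
        )

    # stage 7: in vitro activity
    activity: Dict[str, activity_mod.ActivityCall] = {}
    if inputs.plate_data is not None and len(inputs.plate_data):
        activity = activity_mod.process_plates(
            inputs.plate_data, threshold=config.activity_threshold, alpha=config.alpha
        )

    # stage 8: categories for loci intact in the focal genome
    categories: Dict[str, classify_mod.CategoryAssignment] = {}
    for p in pairs:
        if not p.element_a or p.status_a != "intact":
            continue
        freq = frequency.get(p.element_a)
        if freq is None:
            continue
        categories[p.element_a] = classify_mod.binarize_categories(
            p.element_a, freq, activity.get(p.element_a), profiles.get(p.element_a),
            polymorphic_max=config.frequency_polymorphic_max,
        )

    master = _master_table(
        ga, gb, pairs, intact_calls, frameshifts, profiles, frequency, activity,
        categories,
    )
    summary = summarize_counts(master, elements, intact_calls, config)
    return PipelineResult(
        master=master, summary=summary, elements=elements,
        intact_calls=intact_calls, profiles=profiles, frequency=frequency,
        activity=activity, categories=categories, pairs=pairs,
        frameshifts=frameshifts,
    )


def _master_table(
    ga, gb, pairs, intact_calls, frameshifts, profiles, frequency, activity,
    categories,
) -> pd.DataFrame:
    rows = []
    for p in pairs:
        prof = profiles.get(p.element_a) if p.element_a else None
        freq = frequency.get(p.element_a) if p.element_a else None
        act = activity.get(p.element_a) if p.element_a else None
        cat = categories.get(p.element_a) if p.element_a else None
        fs = frameshifts.get(p.element_a) if p.element_a else None
        rows.append(
            {
                "locus_id": p.locus_id,
                f"element_{ga}": p.element_a or "",
                f"element_{gb}": p.element_b or "",
                f"status_{ga}": p.status_a,
                f"status_{gb}": p.status_b,
                "nt_diff": p.nt_diff,
                "aa_diff": p.aa_diff,
                "frameshift_events": fs.n_events if fs else 0,
                "young_count": prof.young_count if prof else None,
                "mid_count": prof.mid_count if prof else None,
                "old_count": prof.old_count if prof else None,
                "fit": prof.fit if prof else None,
                "frequency": freq.frequency if freq else None,
                "frequency_label": freq.label if freq else "",
                "frequency_basis": freq.basis if freq else "",
                "mean_pct": act.mean_pct if act else None,
                "effective_pct": act.effective_pct if act else None,
                "active": act.active if act else None,
                "polymorphic": cat.polymorphic if cat else None,
                "category": cat.category if cat else None,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        assert not df["locus_id"].duplicated().any(), "duplicate locus in master"
    return df


def parameter_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    burst_lineages: Tuple[str, ...] = ("b0", "b5", "b12", "b20"),
    fit_lineages: Tuple[str, ...] = ("b12", "b20"),
) -> Dict[str, int]:
    """Repeat the default synthetic study over ``n_seeds`` seeds and tally
    how often the pipeline recovers the planted truth: burst-derived fitness
    (fit iff burst size > 10), intended intactness, and the 8-way category.

    The frameshift stage is skipped here (it does not feed any of the three
    recoveries). Returns raw tallies so callers can form rates or intervals.
    """
    from .simulate import SimParams, simulate_family

    tallies = {
        "fit_total": 0, "fit_correct": 0,
        "intact_total": 0, "intact_correct": 0, "intact_called": 0,
        "category_total": 0, "category_correct": 0,
    }
    for i in range(n_seeds):
        sim = simulate_family(SimParams(seed=base_seed + i))
        res = run_pipeline(
            PipelineInputs.from_sim(sim),
            PipelineConfig(
                seed=base_seed + i,
                count_frameshifts=False,
                compute_divergence=False,
            ),
        )
        truth = sim.truth
        for g in ("A", "B"):
            for eid, call in res.intact_calls[g].items():
                tallies["intact_total"] += 1
                tallies["intact_called"] += int(call.intact)
                tallies["intact_correct"] += int(
                    call.intact == truth.alleles[eid].intended_intact
                )
        for eid, prof in res.profiles.items():
            a = truth.alleles[eid]
            if a.lineage in burst_lineages:
                tallies["fit_total"] += 1
                tallies["fit_correct"] += int(
                    prof.fit == (a.lineage in fit_lineages)
                )
        fit_of = {
            a.locus_id: a.fit for a in truth.alleles.values() if a.genome == "A"
        }
        for eid, cat in res.categories.items():
            locus = truth.alleles[eid].locus_id
            lt = truth.loci[locus]
            expected = (
                4 * int(lt.true_freq <= 0.75)
                + 2 * int(bool(lt.active))
                + int(fit_of[locus])
            )
            tallies["category_total"] += 1
            tallies["category_correct"] += int(cat.category == expected)
    return tallies


def summarize_counts(
    master: pd.DataFrame,
    elements: Mapping[str, Sequence[ElementRecord]],
    intact_calls: Mapping[str, Mapping[str, IntactnessCall]],
    config: PipelineConfig = PipelineConfig(),
) -> Dict[str, object]:
    """Pure-filter tallies over the master table: the five shared/unique
    locus classes, the eight-category counts, and active counts at rising
    activity thresholds."""
    ga, gb = sorted(elements)
    sa, sb = f"status_{ga}", f"status_{gb}"
    summary: Dict[str, object] = {
        f"n_full_length_{g}": len(elements[g]) for g in (ga, gb)
    }
    for g in (ga, gb):
        summary[f"n_intact_{g}"] = sum(
            1 for c in intact_calls[g].values() if c.intact
        )
    if len(master):
        classes = (
            int(((master[sa] == "intact") & (master[sb] == "intact")).sum()),
            int(((master[sa] == "intact") & (master[sb] == "present_not_intact")).sum()),
            int(((master[sa] == "present_not_intact") & (master[sb] == "intact")).sum()),
            int(((master[sa] == "intact") & (master[sb] == "absent")).sum()),
            int(((master[sa] == "absent") & (master[sb] == "intact")).sum()),
        )
        cats = master["category"].dropna().astype(int)
        category_counts = [int((cats == c).sum()) for c in range(8)]
        pct = master["effective_pct"].dropna()
        active_counts = {
            f"n_active_gt{int(t)}": int((pct > t).sum()) for t in (5.0, 10.0, 20.0)
        }
    else:
        classes = (0, 0, 0, 0, 0)
        category_counts = [0] * 8
        active_counts = {"n_active_gt5": 0, "n_active_gt10": 0, "n_active_gt20": 0}
    summary["locus_classes"] = classes
    summary["n_loci"] = int(len(master))
    summary["category_counts"] = category_counts
    summary.update(active_counts)
    return summary
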
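# Methods

## The analysis in brief

A full-length LINE-1 is ~6 kb: a 5'UTR with internal promoter, ORF1
(an RNA-binding chaperone, 338 codons in the canonical active human
element), a short spacer, ORF2 (endonuclease + reverse transcriptase,
1275 codons) and a 3'UTR. The pipeline profiles every full-length copy in a
pair of haploid assemblies along four axes — ORF intactness, allelic state,
population frequency, in vitro activity — plus a genealogical proxy for
recent germline replication, and combines the last three into an 8-way
category per locus.

## Intactness

ORF candidates are maximal ATG→stop spans in the three forward frames (the
element is already strand-resolved; antisense ORFs are not biological here).
A span must end at a real stop codon; candidates shorter than `min_aa = 50`
codons are dropped (the threshold only needs to sit below 338). Candidate
translations are aligned locally to the reference ORF1p/ORF2p under BLOSUM62
with affine gaps (a gap of length k costs 11 + k, the BLAST protein
default). Per reference ORF, the candidate covering the most reference
residues wins, ties broken by score then position. The element is intact iff
for both ORFs the winning alignment covers reference residues 1..L and query
residues 1..aa_len — "full length, start to stop, no terminal deletions or
extensions". Internal gaps are allowed, so e.g. an in-frame 9-nt deletion
(335-codon ORF1) is still intact.

A caveat that matters for truth-labelled benchmarks: a *local* aligner clips
a terminal residue whose substitution scores negatively, so background
divergence in the very last codon can fail the full-span rule even without a
lesion. The synthetic generator therefore never places background
substitutions in the terminal codons (see below); on real data such
elements would surface as near-misses for manual curation, which is why the
candidate table is exposed.

## Frameshift counting

No installed library performs frameshift-aware DNA→protein alignment, so the
dynamic program is implemented here (vectorized over the reference axis).
Moves from state (nt i, residue j): consume 3 nt scored by BLOSUM62 on the
translated codon; delete a residue or insert a codon at a linear cost of 12;
or consume 1/2/4/5 nt for one residue at an additional frameshift penalty
(default 15, mirroring the conventional `-F15` setting of frameshift-aware
aligners). Alignment is local; the best path per reference ORF is kept, so
UTRs and the other ORF do not contribute. Events are reported at the
reference residue where the frame changes with the net shift (±1/±2).
Because indel placement inside homopolymer tracts is ambiguous — homopolymer
slippage being the dominant long-read error mode — two events in different
assemblies count as "shared" when they have the same sign and lie within 3
codons; a locus with any unshared event is a candidate sequencing error.
Scores are exact sums of integers, so the traceback tests float equality
safely.

## Distances and the fitness proxy

"Hamming distance" between repeat copies of unequal length is not
well-defined, so distances are alignment-based. The unit-cost optimal global
alignment (edlib) gives `per_base` counts directly (mismatch + gap columns =
edit distance). The default `per_event` mode counts each contiguous indel
once: a single 100-bp UTR deletion should not eject a true near neighbor
from the young bin. Because a unit-cost optimizer may scatter one long gap
into several equal-cost runs, difference clusters along the path are
re-aligned locally with affine scoring (match 0, mismatch −2, open −3,
extend −1 — substitutions can never be impersonated by ins+del pairs, and
contiguous gaps always beat split ones), and neighboring gap-bearing
clusters are merged whenever joint realignment lowers the event total. A
length prescreen skips alignments that cannot leave the old bin
(length difference > 82); the suite asserts profile equivalence with and
without it.

Bins follow the empirical distance strata of recent human L1 expansions:
young ≤ 27 differences, mid 28–82, old > 82 (boundaries configurable; where
sources disagree between "1–27" and "≤ 28", young = ≤ 27 is used). The
fitness call is strict: fit ⇔ more than 10 young neighbors; distance-0
non-self copies count.

## Allele pairing

Each element's 2-kb flanks are searched in the partner assembly on both
strands (edlib infix mode, staged: hits must lie within 3% divergence; the
runner-up — another contig/strand, or a second location after masking the
best hit — must score below best/1.2). Both flanks must land on one contig,
same orientation, separated by less than a 50-kb neighborhood window.
The inter-flank interval decides the status: an overlapping ≥ 5-kb L1
annotation means *present*; separation under 200 bp (target-site-duplication
slack) means *absent, empty pre-insertion site*; anything else is
*unplaced*. Pairing is reciprocal; disagreements are flagged, not dropped.
Nucleotide divergence of an allelic pair uses the distance kernel above
(per_base by default, since published per-pair counts score deletions per
column); amino-acid divergence aligns the concatenated ORF1p+ORF2p
translations globally and counts non-identical columns, gap residues
included (configurable).

## Frequency integration

Reference-present loci are genotyped by deletion calls under bedtools
`-f 0.9 -r` semantics (overlap ≥ 90% of both intervals); a deletion carrier
lacks the element, so element frequency = 1 − carriers/cohort (the
arithmetic direction is configurable and logged, as published descriptions
leave it implicit). Reference-absent loci are genotyped by insertion calls
at ≥ 1 bp overlap, or by curated-database records at gap distance exactly 0.
Sources flagged as noisy have single-carrier calls removed first. When
several sources match, the largest cohort wins. No match defaults to fixed
(frequency 1.0) for reference-present loci and to the bound "< 0.001"
(stored as 0.0005, flagged as an upper bound) for reference-absent loci.
Within the pipeline the partner assembly plays the reference role: a locus
present in both assemblies is "reference-present".

## Activity assay

Per well, transfection-normalized signal is firefly/renilla (the ratio is
the documented default; firefly-only is available). Percent activity anchors
each plate's mean negative-control ratio at 0% and mean positive-control
ratio at 100%; the controls therefore average exactly 0/100 by construction
and the scale is invariant to plate-wide multiplicative drift. A construct
is *active* iff its grand-mean percent exceeds 5% of the positive control
and a one-sided Welch t-test against the pooled negative-control percents
rejects at α = 0.05 (no specific test is canonical here; Welch is the
conservative default). Constructs failing significance keep their mean but
count as 0% downstream. Wells from clones excluded for sequence deviations
never enter any mean. Pooled-well averaging is the default; per-clone
averaging is available since the published choice is unstated.

## Categories and diagnostic sites

Category = `4·polymorphic + 2·active + fit`, with polymorphic ⇔ frequency
≤ 0.75 (inclusive; the "< 0.001" bound is polymorphic). The booleans come
from the upstream calls unchanged. Diagnostic sites between two sequence
groups require strict within-group uniformity (a minor-allele tolerance
parameter exists but defaults to 0); gaps are legal states. Sites in coding
sequence are annotated by substituting both group states into the reference
row's codon; nonsynonymous changes are labelled refAA + ORF-local codon +
altAA, oriented so the reference row's own base comes first.

## The synthetic study

The generator emulates the study conditions end to end. Defaults:

* consensus 6000 bp = 900 (5'UTR) + 1017 (ORF1, 338 codons + stop) +
  63 (spacer) + 3828 (ORF2, 1275 codons + stop) + 192 (3'UTR); stop guards
  immediately upstream of each ORF keep candidate starts exact.
* lineages: recent bursts of 0/5/12/20 copies (founders 70–280 substitutions
  from consensus, ~4 private substitutions per copy, expected intra-burst
  distance ≈ 8), one mid-age expansion of 8 copies (~40 intra-pair), twelve
  old singletons (100–232 substitutions), and three private young insertions
  per genome. Burst sizes bracket the >10-neighbor fitness threshold on both
  sides; founder spacing keeps inter-lineage distances in the old bin.
* per-allele lesions: nonsense 10%, 1-nt frameshift 8%; shared alleles
  differ by ~3 substitutions. Background substitutions are constrained never
  to create or destroy a stop, start, or ORF-terminal codon, so intended
  intactness is exact truth by construction (lesions are the only planted
  intactness-breakers).
* loci are wrapped in unique random 2-kb flanks; absent loci leave the
  flanks adjacent (an empty site); ~30% of elements sit on the reverse
  strand; 8 truncated (<5 kb) decoys and 2 non-L1 rows per genome exercise
  the filters.
* SV call sets: a large singleton-filtered cohort (n = 2504), a small
  complementary study (n = 185) and a curated insertion database (n = 1059),
  with carrier counts rounded from the planted frequencies (agreement within
  1/cohort by construction). Planted frequencies avoid the 0.75 boundary.
* plates: 4 positive + 4 negative control wells and 11 constructs × 8 wells
  per plate, 16 wells per construct over 2 plates, per-well noise 1.5
  percent points, positive/negative mean ratios 2.0/0.1. True activities are
  drawn away from the 5% boundary (inactive < 1.5%, active > 12%).
* diagnostic-site alignment: two groups (6 vs 5 sequences) differing at two
  5'UTR sites, one synonymous ORF1 site and one K485M-style ORF2 site, plus
  private substitutions at globally distinct columns.

All randomness flows through a single seeded generator; outputs are
byte-identical across runs. The problem size (two ~61-element genomes,
~650 kb each) was chosen so the full pipeline and a 20-seed recovery study
run comfortably on a laptop while every statistic (near-neighbor counts,
binomial intact fractions, 8-way confusion) remains well-populated.

What the simulation does *not* emulate — and hence what passing tests do not
show about real data: a realistic genomic background (no segmental
duplications or nested repeats beyond the planted decoys, so flank mapping
is easier than in a real genome), assembly gaps, RepeatMasker fragmentation
of single insertions, subfamily sequence structure, linked frequencies
between nearby loci, or plate/day batch effects beyond multiplicative
scaling.

## Numerical choices and degenerate inputs

Coordinates are 0-based half-open internally; RepeatMasker input is
converted at parse time, BED is emitted 0-based. Ambiguity codes other than
N map to N with a warning. Alignment tie-breaks are deterministic (first
optimal path of the underlying aligner; candidate selection prefers
coverage, then score, then position). Empty genomes yield empty tables and
exit cleanly; an empty comparison set, empty protein, or single-assembly
sharing input raise validation errors rather than guessing. The pipeline is
a pure function of its inputs: re-running with the same inputs and config
reproduces the master table byte for byte.

## Known limitations

* RepeatMasker fragment rows are treated independently (join-by-ID exists
  but defaults off); fragmented annotations of one insertion would be
  counted separately.
* The frameshift DP's linear (non-affine) indel costs can differ from an
  affine aligner's event placement in low-complexity stretches; positions
  carry a ±1-codon tolerance in the tests for this reason.
* Flank mapping requires hits within 3% divergence and genuinely unique
  flanks; paralogous flanks yield *unplaced*, never a guess.
* The per_event distance is defined by a heuristic (cluster realignment with
  greedy merging); it is exact on the planted lesion classes but can
  overcount events in adversarial low-complexity regions.
* Curated-database carrier/cohort counts are accepted as given rather than
  re-derived from per-study records.
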
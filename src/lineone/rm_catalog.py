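"""Parse RepeatMasker annotation and extract full-length LINE-1 sequences.

RepeatMasker ``.out`` files report 1-based inclusive coordinates with the
reverse strand marked ``C``; everything downstream of the parser uses 0-based
half-open coordinates and ``+``/``-`` strands. Elements are extracted in
element-forward orientation (reverse-complemented when annotated on the
reverse strand) and flagged full-length when they meet a minimum length
(default 5,000 bp, the conventional full-length LINE-1 cutoff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence

from ._seq import as_genome, clean_genomic, revcomp

DEFAULT_MIN_LEN = 5000
DEFAULT_KEYWORD = "L1"


class RepeatMaskerParseError(ValueError):
    """Raised for malformed RepeatMasker rows; carries the 1-based line number."""


@dataclass(frozen=True)
class RepeatAnnotation:
    """One RepeatMasker annotation row in 0-based half-open coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    repeat_name: str
    repeat_class: str
    rm_join_id: str = ""
    sw_score: int = 0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ElementRecord:
    """A located, strand-resolved element sequence (element-forward)."""

    element_id: str
    genome_id: str
    annotation: RepeatAnnotation
    sequence: str
    is_full_length: bool

    def __post_init__(self):
        if len(self.sequence) != self.annotation.length:
            raise ValueError(
                f"{self.element_id}: sequence length {len(self.sequence)} != "
                f"annotated length {self.annotation.length}"
            )


def make_element_id(genome_id: str, seq_id: str, start: int, end: int) -> str:
    return f"{genome_id}:{seq_id}:{start}-{end}"


def parse_repeatmasker(
    text: str,
    keyword: Optional[str] = DEFAULT_KEYWORD,
) -> List[RepeatAnnotation]:
    """Parse RepeatMasker ``.out`` content into annotations.

    Parameters
    ----------
    text:
        Whitespace-delimited ``.out`` content including the usual 3-line
        header (header lines and blank lines are detected and skipped).
    keyword:
        Substring filter applied to the matching-repeat column
        (``"L1"`` matches ``L1HS``, ``L1PA3`` and also ``L1M*``).
        Pass ``None`` to keep every row.

    Returns annotations with coordinates converted to 0-based half-open and
    ``C`` mapped to ``-``.
    """
    out: List[RepeatAnnotation] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        # header lines start with column labels ("SW", "score", "bit") or
        # non-numeric first fields
        if fields[0] in ("SW", "score", "bit"):
            continue
        try:
            sw_score = int(fields[0])
        except ValueError:
            if lineno <= 3:
                continue  # tolerated header remnant
            raise RepeatMaskerParseError(
                f"line {lineno}: non-numeric score field {fields[0]!r}"
            )
        if len(fields) < 11:
            raise RepeatMaskerParseError(
                f"line {lineno}: expected >=11 whitespace-delimited fields, "
                f"got {len(fields)}"
            )
        try:
            begin = int(fields[5])
            end = int(fields[6])
        except ValueError as exc:
            raise RepeatMaskerParseError(
                f"line {lineno}: non-numeric coordinates {fields[5]!r}, {fields[6]!r}"
            ) from exc
        strand = fields[8]
        if strand == "C":
            strand = "-"
        repeat_name = fields[9]
        repeat_class = fields[10]
        rm_join_id = fields[14] if len(fields) > 14 else ""
        if keyword is not None and keyword not in repeat_name:
            continue
        start0 = begin - 1  # 1-based inclusive -> 0-based half-open
        if start0 >= end:
            raise RepeatMaskerParseError(
                f"line {lineno}: start >= end after conversion "
                f"([{start0}, {end}))"
            )
        out.append(
            RepeatAnnotation(
                seq_id=fields[4],
                start=start0,
                end=end,
                strand=strand,
                repeat_name=repeat_name,
                repeat_class=repeat_class,
                rm_join_id=rm_join_id,
                sw_score=sw_score,
            )
        )
    return out


def extract_full_length(
    annotations: Sequence[RepeatAnnotation],
    genome,
    genome_id: str = "genome",
    min_len: int = DEFAULT_MIN_LEN,
) -> List[ElementRecord]:
    """Extract element-forward sequences for annotations of length >= min_len.

    ``genome`` is a mapping seq_id -> sequence or a FASTA path. Reverse-strand
    annotations yield the reverse complement of the genomic slice. Ambiguity
    codes other than N are mapped to N with a warning.
    """
    seqs = as_genome(genome)
    records: List[ElementRecord] = []
    for ann in annotations:
        if ann.length < min_len:
            continue
        if ann.seq_id not in seqs:
            raise KeyError(f"seq_id {ann.seq_id!r} not present in genome")
        contig = seqs[ann.seq_id]
        if ann.end > len(contig):
            raise IndexError(
                f"annotation end {ann.end} beyond contig {ann.seq_id!r} "
                f"length {len(contig)}"
            )
        piece, n_fixed = clean_genomic(contig[ann.start : ann.end])
        if n_fixed:
            warnings.warn(
                f"{ann.seq_id}:{ann.start}-{ann.end}: mapped {n_fixed} "
                "ambiguity characters to N"
            )
        if ann.strand == "-":
            piece = revcomp(piece)
        records.append(
            ElementRecord(
                element_id=make_element_id(genome_id, ann.seq_id, ann.start, ann.end),
                genome_id=genome_id,
                annotation=ann,
                sequence=piece,
                is_full_length=ann.length >= min_len,
            )
        )
    return records


def to_bed(records: Iterable[ElementRecord]) -> str:
    """Serialize element records as BED6 (name=element_id, score=sw_score)."""
    lines = []
    for rec in records:
        a = rec.annotation
        lines.append(
            f"{a.seq_id}\t{a.start}\t{a.end}\t{rec.element_id}\t{a.sw_score}\t{a.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def parse_bed(text: str) -> List[RepeatAnnotation]:
    """Read BED6 back into annotations (repeat metadata is not round-tripped)."""
    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        out.append(
            RepeatAnnotation(
                seq_id=f[0],
                start=int(f[1]),
                end=int(f[2]),
                strand=f[5] if len(f) > 5 else "+",
                repeat_name=f[3] if len(f) > 3 else "",
                repeat_class="",
                sw_score=int(f[4]) if len(f) > 4 else 0,
            )
        )
    return out
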
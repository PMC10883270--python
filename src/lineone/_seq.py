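"""Small shared sequence helpers (private)."""

from __future__ import annotations

import re
from typing import Dict, Iterable, Mapping, Tuple

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# standard genetic code, DNA codons; '*' marks stop
CODON_TABLE: Dict[str, str] = {}


def _build_codon_table() -> None:
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1


_build_codon_table()

STOP_CODONS = ("TAA", "TAG", "TGA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate(seq: str) -> str:
    """Translate a DNA string (length need not be a multiple of 3; the
    trailing partial codon is dropped). Codons with ambiguity become 'X'."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        out.append(CODON_TABLE.get(seq[i : i + 3].upper(), "X"))
    return "".join(out)


def clean_genomic(seq: str) -> Tuple[str, int]:
    """Uppercase and map ambiguity codes other than N to N.

    Returns (cleaned sequence, number of substituted ambiguity characters).
    """
    s = seq.upper()
    n_fixed = 0
    if re.search(r"[^ACGTN]", s):
        n_fixed = len(re.findall(r"[^ACGTN]", s))
        s = re.sub(r"[^ACGTN]", "N", s)
    return s, n_fixed


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str] | Iterable[Tuple[str, str]], path, width: int = 80) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def as_genome(genome) -> Mapping[str, str]:
    """Accept a mapping seq_id -> sequence or a FASTA path."""
    if isinstance(genome, Mapping):
        return genome
    return read_fasta(genome)
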
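"""Per-sequence CpN observed/expected ratios from nucleotide sequences.

The o/e ratio compares the observed count of a dinucleotide (CpG by
default) to the count expected from the single-nucleotide composition of
the same sequence.  In genomes with cytosine methylation, deamination of
5-methyl-cytosine depletes the methylated dinucleotide over evolutionary
time, so a ratio well below 1 is a signature of (past) methylation.

Four formulations of the ratio are in common use; all are implemented and
selectable via :class:`Formula`.  Counts are taken over unambiguous
(A/C/G/T) positions only: ambiguity codes do not contribute to the
sequence length ``l`` used in the formulas, and a dinucleotide pair that
spans an ambiguous base is never counted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from Bio import SeqIO

__all__ = [
    "Formula",
    "SequenceRecord",
    "RatioSample",
    "count_unambiguous",
    "count_dinucleotide",
    "compute_cpn_oe",
    "process_fasta",
]

_UNAMBIGUOUS = frozenset("ACGT")

#: Minimum number of unambiguous nucleotides for a sequence to be retained.
DEFAULT_MIN_LENGTH = 200


class Formula(IntEnum):
    """Selectable o/e formulations.

    F1  #CpG / (#C * #G) * l^2 / (l - 1)   (default)
    F2  #CpG / (#C * #G) * l
    F3  (#CpG / l) / gc^2            with gc the fractional C+G content
    F4  #CpG / (GC / 2)^2            with GC the C+G count
    """

    F1 = 1
    F2 = 2
    F3 = 3
    F4 = 4


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry: identifier plus nucleotide string (any case)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")


@dataclass
class RatioSample:
    """A named vector of per-sequence CpN o/e values with provenance.

    ``values`` and ``ids`` are parallel; ``n_input`` counts all sequences
    read, of which ``n_too_short`` were dropped by the length filter.
    """

    values: np.ndarray
    ids: list[str] = field(default_factory=list)
    dinucleotide: str = "CG"
    formula: Formula = Formula.F1
    n_input: int = 0
    n_too_short: int = 0
    name: str = "sample"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.ids:
            self.ids = [f"seq_{i}" for i in range(self.values.size)]
        if len(self.ids) != self.values.size:
            raise ValueError("values and ids must have equal length")
        if self.values.size and (
            not np.all(np.isfinite(self.values)) or np.any(self.values < 0)
        ):
            raise ValueError("ratio values must be finite and non-negative")
        if self.n_input == 0:
            self.n_input = self.values.size + self.n_too_short

    def __len__(self) -> int:
        return int(self.values.size)


def count_unambiguous(seq: str) -> int:
    """Number of positions that are A, C, G or T (case-insensitive)."""
    s = seq.upper()
    return sum(s.count(b) for b in _UNAMBIGUOUS)


def count_dinucleotide(seq: str, dinuc: str = "CG") -> int:
    """Overlapping count of ``dinuc`` occurrences in ``seq``.

    Case-folded; a pair containing an ambiguity code is never counted
    (so e.g. ``CNG`` contains no CpG).
    """
    dinuc = dinuc.upper()
    if len(dinuc) != 2 or not set(dinuc) <= _UNAMBIGUOUS:
        raise ValueError(f"dinucleotide must be two of A/C/G/T, got {dinuc!r}")
    s = seq.upper()
    count = start = 0
    while True:
        i = s.find(dinuc, start)
        if i < 0:
            return count
        count += 1
        start = i + 1  # overlapping scan


def compute_cpn_oe(
    seq: str, dinuc: str = "CG", formula: Formula = Formula.F1
) -> float:
    """CpN o/e ratio of one sequence under the selected formula.

    ``l`` is the count of unambiguous nucleotides; the mononucleotide
    counts are of the first and second letter of ``dinuc`` (for "CA":
    #C and #A).  Returns 0.0 when the dinucleotide count is zero or any
    denominator term vanishes; the cleaning stage removes such zeros.
    """
    if not seq:
        raise ValueError("cannot compute o/e ratio of an empty sequence")
    formula = Formula(formula)
    s = seq.upper()
    l = count_unambiguous(s)
    n1 = s.count(dinuc[0].upper())
    n2 = s.count(dinuc[1].upper())
    nd = count_dinucleotide(s, dinuc)
    if nd == 0 or l == 0:
        return 0.0
    if formula is Formula.F1:
        if n1 == 0 or n2 == 0 or l < 2:
            return 0.0
        return nd / (n1 * n2) * l * l / (l - 1)
    if formula is Formula.F2:
        if n1 == 0 or n2 == 0:
            return 0.0
        return nd / (n1 * n2) * l
    if formula is Formula.F3:
        gc_frac = (n1 + n2) / l
        if gc_frac == 0:
            return 0.0
        return (nd / l) / gc_frac**2
    # F4: GC "content" is the raw count of the two letters
    gc = n1 + n2
    if gc == 0:
        return 0.0
    return nd / (gc / 2) ** 2


def process_fasta(
    path: str | os.PathLike,
    dinuc: str = "CG",
    formula: Formula = Formula.F1,
    min_len: int = DEFAULT_MIN_LENGTH,
    name: str | None = None,
) -> RatioSample:
    """Read a multi-FASTA file and compute one o/e ratio per sequence.

    Sequences with fewer than ``min_len`` unambiguous nucleotides are
    dropped (counted in ``n_too_short``); short sequences produce mostly
    zeros or extreme ratios.  Values follow file order.

    Raises ``FileNotFoundError`` for an unreadable path and ``ValueError``
    when the file yields no parseable records.
    """
    path = os.fspath(path)
    if not os.path.isfile(path):
        raise FileNotFoundError(f"FASTA file not found: {path}")
    values: list[float] = []
    ids: list[str] = []
    n_input = n_short = 0
    for rec in SeqIO.parse(path, "fasta"):
        n_input += 1
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"malformed FASTA: record {rec.id!r} has no sequence")
        if count_unambiguous(seq) < min_len:
            n_short += 1
            continue
        ids.append(rec.id)
        values.append(compute_cpn_oe(seq, dinuc, formula))
    if n_input == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return RatioSample(
        values=np.asarray(values, dtype=float),
        ids=ids,
        dinucleotide=dinuc.upper(),
        formula=Formula(formula),
        n_input=n_input,
        n_too_short=n_short,
        name=name or os.path.basename(path),
    )
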
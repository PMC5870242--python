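"""Synthetic sequence populations with controlled CpG depletion.

The generator emulates the mutational signature that the o/e analysis is
designed to read out: sequences are drawn i.i.d. at a chosen GC content,
then each CpG occurrence (non-overlapping left-to-right scan) is
rewritten to TpG with a fixed probability, mimicking deamination of
methylated cytosines.  A depletion of d leaves the expected CpG o/e at
roughly (1 - d) times the undepleted baseline (which is ~1 at any GC
content for i.i.d. sequences), so mixtures of populations with distinct
depletion levels produce multimodal o/e distributions like those of
mosaically methylated genomes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .ratios import SequenceRecord

__all__ = [
    "PopulationSpec",
    "generate_population",
    "generate_mosaic",
    "write_fasta",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of one homogeneous sequence population."""

    n_sequences: int
    length: int
    gc_content: float = 0.5
    depletion: float = 0.0
    label: str = "pop"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.depletion <= 1.0:
            raise ValueError("depletion must be in [0, 1]")
        if self.n_sequences < 1 or self.length < 1:
            raise ValueError("n_sequences and length must be positive")


def _deplete(seq_arr: np.ndarray, depletion: float, rng: np.random.Generator) -> None:
    """Rewrite CG -> TG in place with probability ``depletion`` per site,
    scanning non-overlapping pairs left to right."""
    if depletion == 0.0:
        return
    i = 0
    n = seq_arr.size
    while i < n - 1:
        if seq_arr[i] == "C" and seq_arr[i + 1] == "G":
            if rng.random() < depletion:
                seq_arr[i] = "T"
            i += 2
        else:
            i += 1


def generate_population(
    spec: PopulationSpec, seed: int | np.random.Generator = 0
) -> list[SequenceRecord]:
    """Draw ``spec.n_sequences`` i.i.d. sequences and apply CpG depletion.

    Deterministic given the seed (or an existing Generator, which is
    advanced).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    gc = spec.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    for i in range(spec.n_sequences):
        arr = rng.choice(_BASES, size=spec.length, p=p)
        _deplete(arr, spec.depletion, rng)
        records.append(
            SequenceRecord(id=f"{spec.label}_{i}", seq="".join(arr))
        )
    return records


def generate_mosaic(
    specs: list[PopulationSpec],
    seed: int = 0,
    path: str | os.PathLike | None = None,
) -> list[SequenceRecord]:
    """Concatenate several populations and shuffle the record order,
    emulating a mosaic mixture of methylation classes.  Optionally
    writes the records as multi-FASTA to ``path``."""
    if not specs:
        raise ValueError("need at least one population spec")
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    for spec in specs:
        records.extend(generate_population(spec, rng))
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    if path is not None:
        write_fasta(records, path)
    return records


def write_fasta(
    records: list[SequenceRecord], path: str | os.PathLike, width: int = 70
) -> None:
    """Write records as line-wrapped multi-FASTA."""
    if not records:
        raise ValueError("no records to write")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
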
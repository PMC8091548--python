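"""Small-RNA read filtering, exact-match miRNA counting, and TPM/FPKM.

The read filter applies the literal cleaning rules used for small-RNA
libraries: keep reads of 18-30 nt (inclusive bounds) whose fraction of ``N``
bases is strictly below 10%, after optional 3' adapter removal.  The TPM and
FPKM formulas are the standard depth (and length) normalizations::

    TPM  = count * 1e6 / mapped_reads
    FPKM = count * 1e9 / (length_bp * mapped_reads)

where ``mapped_reads`` is the per-sample mapped total carried by the counts
matrix.  Note this miRNA-style TPM has no length term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "Read",
    "ReadFilterReport",
    "read_fastq",
    "write_fastq",
    "trim_adapter",
    "filter_small_rna_reads",
    "count_mirna_reads",
    "compute_tpm",
    "compute_fpkm",
]


@dataclass(frozen=True)
class Read:
    """A named sequence read (FASTQ record without qualities)."""

    name: str
    sequence: str


@dataclass
class ReadFilterReport:
    """Accounting of one filtering pass; categories partition the input."""

    input_reads: int = 0
    kept: int = 0
    dropped_short: int = 0
    dropped_long: int = 0
    dropped_n_fraction: int = 0
    dropped_contaminant: int = 0

    def validate(self) -> None:
        total = (
            self.kept
            + self.dropped_short
            + self.dropped_long
            + self.dropped_n_fraction
            + self.dropped_contaminant
        )
        if total != self.input_reads:
            raise AssertionError(
                f"read accounting broken: {total} categorized != {self.input_reads} input"
            )


def read_fastq(path) -> list[Read]:
    from Bio import SeqIO

    return [Read(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def trim_adapter(sequence: str, adapter: str) -> str:
    """Remove a 3' adapter by first exact occurrence, keeping the 5' prefix."""
    idx = sequence.find(adapter)
    return sequence[:idx] if idx >= 0 else sequence


def filter_small_rna_reads(
    reads: Iterable[Read],
    adapter: str | None = None,
    contaminants: Iterable[str] | None = None,
    min_len: int = 18,
    max_len: int = 30,
    max_n_frac: float = 0.10,
) -> tuple[list[Read], ReadFilterReport]:
    """Filter small-RNA reads and account for every input read.

    A read is kept iff (after adapter trimming) ``min_len <= length <=
    max_len``, its N fraction is strictly below ``max_n_frac`` (a read with
    exactly 10% N is dropped), and it does not exactly match a contaminant
    sequence.  Checks are applied in the order short/long, N fraction,
    contaminant; each read lands in exactly one report category.
    """
    contaminant_set = {c.upper().replace("U", "T") for c in contaminants} if contaminants else set()
    kept: list[Read] = []
    report = ReadFilterReport()
    for read in reads:
        report.input_reads += 1
        seq = trim_adapter(read.sequence, adapter) if adapter else read.sequence
        seq = seq.upper()
        n = len(seq)
        if n < min_len:
            report.dropped_short += 1
            continue
        if n > max_len:
            report.dropped_long += 1
            continue
        if seq.count("N") / n >= max_n_frac:
            report.dropped_n_fraction += 1
            continue
        if seq.replace("U", "T") in contaminant_set:
            report.dropped_contaminant += 1
            continue
        report.kept += 1
        kept.append(Read(read.name, seq))
    report.validate()
    return kept, report


def count_mirna_reads(
    reads_by_sample: Mapping[str, Sequence[Read]],
    mature_sequences: Mapping[str, str],
) -> tuple[ExpressionMatrix, pd.Series]:
    """Count reads per miRNA by exact sequence match (T/U equivalent).

    Stand-in for genome alignment of clean small-RNA reads: a read counts for
    a miRNA iff it equals the mature sequence exactly.  Returns the counts
    matrix (mapped totals = matched reads per sample) and the per-sample
    unmatched tallies.
    """
    lookup: dict[str, str] = {}
    for mirna_id, seq in mature_sequences.items():
        key = seq.upper().replace("U", "T")
        if key in lookup:
            raise ValueError(
                f"duplicate mature sequence shared by {lookup[key]!r} and {mirna_id!r}"
            )
        lookup[key] = mirna_id
    mirna_ids = list(mature_sequences)
    samples = list(reads_by_sample)
    counts = pd.DataFrame(0, index=mirna_ids, columns=samples, dtype=float)
    unmatched = pd.Series(0, index=samples, dtype=int)
    for sample, reads in reads_by_sample.items():
        for read in reads:
            mirna_id = lookup.get(read.sequence.upper().replace("U", "T"))
            if mirna_id is None:
                unmatched[sample] += 1
            else:
                counts.at[mirna_id, sample] += 1
    mapped = counts.sum(axis=0)
    return ExpressionMatrix(counts, layer="counts", mapped_totals=mapped), unmatched


def compute_tpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Depth-normalize a counts matrix: ``count * 1e6 / mapped_total``."""
    if counts.layer != "counts":
        raise ValueError("compute_tpm expects a counts layer")
    totals = counts.mapped_totals
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ZeroDivisionError(f"zero mapped total for samples {bad}")
    tpm = counts.values * 1_000_000.0 / totals
    return ExpressionMatrix(tpm, layer="TPM")


def compute_fpkm(counts: ExpressionMatrix, lengths: Mapping[str, int]) -> ExpressionMatrix:
    """Length-and-depth normalize: ``count * 1e9 / (length_bp * mapped_total)``."""
    if counts.layer != "counts":
        raise ValueError("compute_fpkm expects a counts layer")
    missing = [f for f in counts.features if f not in lengths]
    if missing:
        raise KeyError(f"no length for features {missing[:5]}")
    lens = pd.Series({f: float(lengths[f]) for f in counts.features})
    if (lens <= 0).any():
        raise ValueError("feature lengths must be positive")
    totals = counts.mapped_totals
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ZeroDivisionError(f"zero mapped total for samples {bad}")
    fpkm = counts.values.mul(1e9).div(totals, axis=1).div(lens, axis=0)
    return ExpressionMatrix(fpkm, layer="FPKM")
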
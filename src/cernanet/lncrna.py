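"""lncRNA identification: ORF scanning, hexamer scoring, majority vote, filters.

Long non-coding RNA candidates are retained by the composition of four rules:
spliced length >= 200 nt, >= 2 exons, maximum FPKM across samples >= 0.1, and
a "noncoding" label from a three-scorer majority vote.  The three scorers are
self-contained analogues of the usual external coding-potential tools:

* longest open reading frame < 300 nt (a real protein-coding transcript
  almost always carries an ORF of >= 100 codons);
* ORF coverage (longest ORF / transcript length) < 0.5;
* hexamer log-likelihood score < 0 bits, from a table trained on labelled
  coding vs noncoding sequences (coding sequence has strong 3-periodic
  hexamer bias, noncoding does not).

A transcript is labelled noncoding iff at least two scorers vote noncoding.

Positional classes follow the usual four-way taxonomy relative to
protein-coding annotation, with precedence exon overlap > intron containment
> intergenic so every candidate receives exactly one class:
``sense`` (exon overlap, same strand), ``antisense`` (exon overlap, opposite
strand), ``intronic`` (fully inside an intron, either strand), ``lincRNA``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .io import ExpressionMatrix, TranscriptModel

__all__ = [
    "OrfResult",
    "CodingPotentialResult",
    "HexamerTable",
    "find_longest_orf",
    "train_hexamer_model",
    "coding_potential_vote",
    "filter_lncrna_candidates",
    "classify_lncrna_position",
    "index_by_contig",
    "LNCRNA_CLASSES",
]

LNCRNA_CLASSES = ("lincRNA", "intronic", "antisense", "sense")

_STOPS = {"TAA", "TAG", "TGA"}


class OrfResult(NamedTuple):
    length: int  # nt, including the stop codon; 0 if no complete ORF
    start: int  # 0-based position of the AUG; -1 if no ORF


@dataclass
class CodingPotentialResult:
    transcript_id: str
    orf_length: int
    orf_coverage: float
    hexamer_score: float
    votes_noncoding: int
    label: str  # "coding" | "noncoding"


def _normalize(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTU/N characters: {sorted(bad)}")
    return s


def find_longest_orf(sequence: str) -> OrfResult:
    """Longest complete reading frame (AUG..stop) on the given strand.

    All three frames are scanned; the returned length includes the stop
    codon.  Ties break to the leftmost start.  Returns ``(0, -1)`` when the
    sequence has no complete ORF.
    """
    s = _normalize(sequence)
    best = OrfResult(0, -1)
    n = len(s)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = s[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                length = i + 3 - start
                if length > best.length or (length == best.length and start < best.start):
                    best = OrfResult(length, start)
                start = None
    return best


class HexamerTable:
    """Per-hexamer log2 likelihood ratios (coding over noncoding).

    Scoring a sequence takes the mean of the table entries over all
    overlapping hexamer windows; windows containing ``N`` are skipped.
    """

    K = 6

    def __init__(self, log_ratios: Mapping[str, float]):
        self.log_ratios = dict(log_ratios)

    def score(self, sequence: str) -> float:
        s = _normalize(sequence)
        vals = [
            self.log_ratios[s[i : i + self.K]]
            for i in range(len(s) - self.K + 1)
            if "N" not in s[i : i + self.K]
        ]
        return float(np.mean(vals)) if vals else 0.0


def _hexamer_counts(sequences: Iterable[str]) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for seq in sequences:
        s = _normalize(seq)
        for i in range(len(s) - 5):
            window = s[i : i + 6]
            if "N" not in window:
                counts[window] += 1
    return counts


def train_hexamer_model(
    coding: Sequence[str], noncoding: Sequence[str], min_sequences: int = 10
) -> HexamerTable:
    """Train hexamer log2 ratios with add-one smoothing over all 4^6 hexamers."""
    if len(coding) < min_sequences or len(noncoding) < min_sequences:
        raise ValueError(
            f"need >= {min_sequences} sequences per class, got "
            f"{len(coding)} coding / {len(noncoding)} noncoding"
        )
    from itertools import product

    alphabet = "ACGT"
    all_hex = ["".join(p) for p in product(alphabet, repeat=6)]
    c_counts = _hexamer_counts(coding)
    n_counts = _hexamer_counts(noncoding)
    c_total = sum(c_counts.values()) + len(all_hex)
    n_total = sum(n_counts.values()) + len(all_hex)
    table = {
        h: float(
            np.log2((c_counts.get(h, 0) + 1) / c_total)
            - np.log2((n_counts.get(h, 0) + 1) / n_total)
        )
        for h in all_hex
    }
    return HexamerTable(table)


def coding_potential_vote(
    transcript_id: str,
    sequence: str,
    hexamer_table: HexamerTable,
    orf_min_length: int = 300,
    coverage_min: float = 0.5,
    hexamer_threshold: float = 0.0,
) -> CodingPotentialResult:
    """Three-scorer majority vote; noncoding iff >= 2 of 3 scorers vote noncoding."""
    orf = find_longest_orf(sequence)
    coverage = orf.length / len(sequence) if sequence else 0.0
    hex_score = hexamer_table.score(sequence)
    votes = 0
    if orf.length < orf_min_length:
        votes += 1
    if coverage < coverage_min:
        votes += 1
    if hex_score < hexamer_threshold:
        votes += 1
    return CodingPotentialResult(
        transcript_id=transcript_id,
        orf_length=orf.length,
        orf_coverage=coverage,
        hexamer_score=hex_score,
        votes_noncoding=votes,
        label="noncoding" if votes >= 2 else "coding",
    )


def filter_lncrna_candidates(
    transcripts: Sequence[TranscriptModel],
    fpkm: ExpressionMatrix,
    coding_results: Mapping[str, CodingPotentialResult],
    min_length: int = 200,
    min_exons: int = 2,
    min_fpkm: float = 0.1,
) -> list[TranscriptModel]:
    """Retain transcripts passing length, exon, expression and noncoding filters.

    The FPKM rule is applied to the per-transcript maximum across samples, a
    permissive reading that keeps group-specific transcripts expressed in
    only some samples.
    """
    if fpkm.layer != "FPKM":
        raise ValueError("expected an FPKM matrix")
    kept = []
    for t in transcripts:
        if t.transcript_id not in fpkm.values.index:
            raise KeyError(f"transcript {t.transcript_id!r} missing from FPKM matrix")
        if t.transcript_id not in coding_results:
            raise KeyError(f"transcript {t.transcript_id!r} missing coding-potential result")
        if t.spliced_length < min_length:
            continue
        if t.exon_count < min_exons:
            continue
        if fpkm.values.loc[t.transcript_id].max() < min_fpkm:
            continue
        if coding_results[t.transcript_id].label != "noncoding":
            continue
        kept.append(t)
    return kept


def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def classify_lncrna_position(
    lncrna: TranscriptModel,
    coding_by_contig: Mapping[str, Sequence[TranscriptModel]],
) -> str:
    """Assign one positional class by precedence sense/antisense > intronic > lincRNA.

    ``coding_by_contig`` must index every contig of the assembly (possibly
    with an empty transcript list for gene deserts); an unknown contig raises.
    """
    if lncrna.contig not in coding_by_contig:
        raise KeyError(f"contig {lncrna.contig!r} absent from coding annotation index")
    same_strand_exonic = False
    opposite_exonic = False
    intronic = False
    for coding in coding_by_contig[lncrna.contig]:
        if not _intervals_overlap(lncrna.span, coding.span):
            continue
        exon_overlap = any(
            _intervals_overlap(le, ce) for le in lncrna.exons for ce in coding.exons
        )
        if exon_overlap:
            if coding.strand == lncrna.strand:
                same_strand_exonic = True
            else:
                opposite_exonic = True
        elif any(
            intron[0] <= lncrna.start and lncrna.end <= intron[1]
            for intron in coding.introns()
        ):
            intronic = True
    if same_strand_exonic:
        return "sense"
    if opposite_exonic:
        return "antisense"
    if intronic:
        return "intronic"
    return "lincRNA"


def index_by_contig(
    transcripts: Iterable[TranscriptModel], contigs: Iterable[str] | None = None
) -> dict[str, list[TranscriptModel]]:
    """Group transcripts by contig, seeding every known contig (even if empty)."""
    index: dict[str, list[TranscriptModel]] = {c: [] for c in (contigs or [])}
    for t in transcripts:
        index.setdefault(t.contig, []).append(t)
    return index
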
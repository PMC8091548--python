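"""miRNA seed-match target prediction and lncRNA cis/trans target genes.

Canonical site taxonomy (strict Watson-Crick, no G:U wobble), for a miRNA
read 5'->3' with seed nucleotides 2-8:

* ``8mer``     — target matches the reverse complement of positions 2-8 and
  the next base 3' in the target is an A;
* ``7mer-m8``  — reverse complement of positions 2-8, no 3' A;
* ``7mer-A1``  — reverse complement of positions 2-7 followed by an A;
* ``6mer``     — reverse complement of positions 2-7 only.

Because a target site is antiparallel to the miRNA, the site read 5'->3' is
``[complement of m8] [revcomp of m2-m7] [A]`` with the outer elements present
or absent according to type.  Overlapping candidate sites are resolved by
type precedence (8mer > 7mer-m8 > 7mer-A1 > 6mer) and then leftmost start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ExpressionMatrix, TranscriptModel

__all__ = [
    "SeedSite",
    "TargetInteraction",
    "SITE_TYPES",
    "find_seed_sites",
    "predict_mirna_targets",
    "lncrna_cis_targets",
    "lncrna_trans_targets",
]

# ascending strength
SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return _dna(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based position of the site's first base in the transcript
    site_type: str

    @property
    def length(self) -> int:
        return {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[self.site_type]

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class TargetInteraction:
    """One predicted source->target link; evidence depends on the mode."""

    source_id: str
    target_id: str
    mode: str  # "seed" | "cis" | "trans"
    site_count: int | None = None
    best_site_type: str | None = None
    distance: int | None = None
    r: float | None = None
    p_value: float | None = None


def find_seed_sites(
    mirna_id: str, mirna_seq: str, transcript_id: str, transcript_seq: str
) -> list[SeedSite]:
    """All canonical seed sites of one miRNA in one transcript sequence."""
    m = _dna(mirna_seq)
    if len(m) < 8:
        raise ValueError(f"miRNA {mirna_id!r} shorter than 8 nt")
    t = _dna(transcript_seq)
    core = reverse_complement(m[1:7])  # revcomp of seed positions 2-7, 6 nt
    m8_comp = m[7].translate(_COMPLEMENT)  # base pairing miRNA position 8
    candidates: list[SeedSite] = []
    pos = t.find(core)
    while pos != -1:
        has_m8 = pos > 0 and t[pos - 1] == m8_comp
        has_a1 = pos + 6 < len(t) and t[pos + 6] == "A"
        if has_m8 and has_a1:
            site = SeedSite(mirna_id, transcript_id, pos - 1, "8mer")
        elif has_m8:
            site = SeedSite(mirna_id, transcript_id, pos - 1, "7mer-m8")
        elif has_a1:
            site = SeedSite(mirna_id, transcript_id, pos, "7mer-A1")
        else:
            site = SeedSite(mirna_id, transcript_id, pos, "6mer")
        candidates.append(site)
        pos = t.find(core, pos + 1)
    return _resolve_overlaps(candidates)


def _resolve_overlaps(candidates: list[SeedSite]) -> list[SeedSite]:
    """Greedy selection by precedence then leftmost; no two kept sites overlap."""
    chosen: list[SeedSite] = []
    for site in sorted(candidates, key=lambda s: (-_SITE_RANK[s.site_type], s.start)):
        if all(site.end <= c.start or c.end <= site.start for c in chosen):
            chosen.append(site)
    return sorted(chosen, key=lambda s: s.start)


def predict_mirna_targets(
    mirna_seqs: Mapping[str, str],
    transcript_seqs: Mapping[str, str],
    min_site_type: str = "7mer-A1",
) -> list[TargetInteraction]:
    """Record a seed interaction for every (miRNA, transcript) pair with at
    least one site of at least ``min_site_type``."""
    if min_site_type not in _SITE_RANK:
        raise ValueError(f"unknown site type {min_site_type!r}")
    min_rank = _SITE_RANK[min_site_type]
    interactions = []
    for mirna_id, mseq in mirna_seqs.items():
        for tid, tseq in transcript_seqs.items():
            if tseq is None:
                raise KeyError(f"missing sequence for transcript {tid!r}")
            sites = [
                s
                for s in find_seed_sites(mirna_id, mseq, tid, tseq)
                if _SITE_RANK[s.site_type] >= min_rank
            ]
            if sites:
                best = max(sites, key=lambda s: _SITE_RANK[s.site_type])
                interactions.append(
                    TargetInteraction(
                        source_id=mirna_id,
                        target_id=tid,
                        mode="seed",
                        site_count=len(sites),
                        best_site_type=best.site_type,
                    )
                )
    return interactions


def _gene_spans(
    transcripts: Sequence[TranscriptModel],
) -> dict[str, tuple[str, int, int]]:
    spans: dict[str, tuple[str, int, int]] = {}
    for t in transcripts:
        if t.gene_id in spans:
            contig, a, b = spans[t.gene_id]
            if contig != t.contig:
                raise ValueError(f"gene {t.gene_id!r} spans multiple contigs")
            spans[t.gene_id] = (contig, min(a, t.start), max(b, t.end))
        else:
            spans[t.gene_id] = (t.contig, t.start, t.end)
    return spans


def lncrna_cis_targets(
    lncrnas: Sequence[TranscriptModel],
    coding_transcripts: Sequence[TranscriptModel],
    window: int = 100_000,
) -> list[TargetInteraction]:
    """Pair each lncRNA with coding genes within ``window`` bp on the same contig.

    The distance is the gap between the lncRNA span and the gene span (union
    of the gene's transcript spans); overlap counts as distance 0 and the
    window boundary is inclusive.
    """
    genes = _gene_spans(coding_transcripts)
    out = []
    for lnc in lncrnas:
        for gene_id, (contig, gstart, gend) in genes.items():
            if contig != lnc.contig:
                continue
            gap = max(gstart - lnc.end, lnc.start - gend, 0)
            if gap <= window:
                out.append(
                    TargetInteraction(
                        source_id=lnc.transcript_id,
                        target_id=gene_id,
                        mode="cis",
                        distance=int(gap),
                    )
                )
    return out


def lncrna_trans_targets(
    lncrna_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    alpha: float = 0.05,
    log_transform: bool = True,
) -> list[TargetInteraction]:
    """Pair lncRNAs with genes whose expression is significantly positively
    correlated (Pearson r > 0, two-sided P < alpha) across all shared samples.

    Correlations are computed on ``log2(value + 1)`` of the normalized layer
    by default, which stabilizes variance across the expression range.
    """
    shared = [s for s in lncrna_expr.samples if s in set(gene_expr.samples)]
    n = len(shared)
    if n < 4:
        raise ValueError(f"need >= 4 shared samples for correlation, got {n}")
    x = lncrna_expr.values[shared].to_numpy(dtype=float)
    y = gene_expr.values[shared].to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    r, p = _pearson_matrix(x, y)
    out = []
    lnc_ids = lncrna_expr.features
    gene_ids = gene_expr.features
    sig = (r > 0) & (p < alpha)
    for i, j in zip(*np.nonzero(sig)):
        out.append(
            TargetInteraction(
                source_id=lnc_ids[i],
                target_id=gene_ids[j],
                mode="trans",
                r=float(r[i, j]),
                p_value=float(p[i, j]),
            )
        )
    return out


def _pearson_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r between rows of x and rows of y, with two-sided P
    from the exact t distribution (matching scipy.stats.pearsonr)."""
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc.T) / np.outer(xs, ys)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return r, np.minimum(p, 1.0)
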
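"""Synthetic study generator: annotation, sequences, reads and count matrices.

The generator emulates a two-breed hypoxia study design — two groups times
three replicate libraries of mRNA, lncRNA and miRNA counts — with known
ground truth for every signal the pipeline is supposed to find:

* negative-binomial counts (mean ``mu``, dispersion ``alpha``, variance
  ``mu + alpha mu^2``) with planted differential expression of known signed
  log2 fold change (the group means differ by exactly the planted log2FC);
* planted lncRNA-miRNA-mRNA sponging triplets.  Triplet rows are grouped
  into lncRNA-mRNA pairs sharing ``shared_mirnas_per_pair`` miRNAs; every
  shared miRNA has a canonical seed site planted in both the lncRNA and the
  mRNA 3' UTR, and a per-sample latent factor ``a_s ~ N(0,1)`` scales the
  natural-log mean of the lncRNA and mRNA by ``+beta * a_s`` and of the
  shared miRNAs by ``-beta * a_s``, producing the positive lncRNA-mRNA /
  negative miRNA correlation structure of a miRNA sponge.  Pair members
  additionally carry coordinated differential expression (lncRNA and mRNA
  share a sign, their miRNAs take the opposite sign), as in a network built
  from differentially expressed features only;
* coding vs noncoding sequence composition: mRNAs carry one long
  codon-biased reading frame flanked by uniform UTRs, lncRNAs are uniform
  with no reading frame of 300 nt or more;
* small-RNA read sets: each mature miRNA sequence repeated its true-count
  times with a 3' adapter, plus configurable fractions of too-short,
  too-long and high-N contaminant reads recorded in the truth.

All outputs are deterministic for a fixed config (seed included).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, TranscriptModel
from .lncrna import find_longest_orf
from .preprocess import Read
from .targets import SITE_TYPES, SeedSite, find_seed_sites, reverse_complement

__all__ = [
    "SimulationConfig",
    "SimulatedAnnotation",
    "SyntheticTruth",
    "ReadSetTruth",
    "generate_annotation",
    "generate_expression",
    "generate_small_rna_reads",
    "simulate_study",
]

_BASES = "ACGT"

# Biased sense-codon usage driving the coding hexamer signal: one preferred
# (weight 6) codon per amino acid, the rest weight 1; stops excluded.
_PREFERRED_CODONS = {
    "GCC", "CGC", "AAC", "GAC", "TGC", "CAG", "GAG", "GGC", "CAC", "ATC",
    "CTG", "AAG", "ATG", "TTC", "CCC", "AGC", "ACC", "TGG", "TAC", "GTG",
}
_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _codon_table() -> tuple[list[str], np.ndarray]:
    codons = [
        a + b + c for a in _BASES for b in _BASES for c in _BASES
        if a + b + c not in _STOP_CODONS
    ]
    weights = np.array([6.0 if c in _PREFERRED_CODONS else 1.0 for c in codons])
    return codons, weights / weights.sum()


_SENSE_CODONS, _CODON_PROBS = _codon_table()


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions.

    ``sponge_effect`` acts on the natural-log scale of the NB mean;
    ``de_log2fc_range`` is on the log2 scale to match the DE calling rule.
    """

    seed: int = 0
    n_mrna: int = 500
    n_lncrna: int = 200
    n_mirna: int = 60
    replicates_per_group: int = 3
    groups: tuple[str, str] = ("TC", "CH")
    de_fraction_mrna: float = 0.05
    de_fraction_lncrna: float = 0.05
    de_fraction_mirna: float = 0.1
    de_log2fc_range: tuple[float, float] = (1.5, 4.0)
    nb_dispersion: float = 0.02
    baseline_mean_log_range: tuple[float, float] = (math.log(50.0), math.log(5000.0))
    n_triplets: int = 40
    sponge_effect: float = 1.0
    shared_mirnas_per_pair: int = 8
    site_type: str = "8mer"
    contig_count: int = 8
    contig_length: int = 5_000_000
    cis_fraction: float = 0.5
    mirna_length: int = 22
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    contaminant_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("de_fraction_mrna", "de_fraction_lncrna", "de_fraction_mirna"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.de_log2fc_range[0] < 1.0:
            raise ValueError(
                "de_log2fc_range lower bound must be >= 1 so planted DE passes "
                "the |log2FC| > 1 call in expectation"
            )
        if self.de_log2fc_range[0] > self.de_log2fc_range[1]:
            raise ValueError("de_log2fc_range must be nondecreasing")
        if self.n_triplets > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            raise ValueError("n_triplets exceeds the smallest feature class")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.sponge_effect < 0:
            raise ValueError("sponge_effect must be nonnegative")
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"site_type must be one of {SITE_TYPES}")
        if self.shared_mirnas_per_pair < 1:
            raise ValueError("shared_mirnas_per_pair must be >= 1")
        if not 0.0 <= self.cis_fraction <= 1.0:
            raise ValueError("cis_fraction must lie in [0, 1]")
        if not 18 <= self.mirna_length <= 30:
            raise ValueError("mature miRNA length must lie in 18..30 nt")

    def pair_plan_sizes(self) -> list[int]:
        """Even grouping of triplet rows into sponging pairs."""
        if self.n_triplets == 0:
            return []
        n_pairs = math.ceil(self.n_triplets / self.shared_mirnas_per_pair)
        base, extra = divmod(self.n_triplets, n_pairs)
        return [base + (1 if i < extra else 0) for i in range(n_pairs)]


@dataclass
class SimulatedAnnotation:
    """Annotation + sequence bundle emitted by :func:`generate_annotation`."""

    transcripts: list[TranscriptModel]
    mirna_sequences: dict[str, str]  # mature sequences, RNA alphabet
    contigs: dict[str, int]
    planted_sites: list[SeedSite]
    pair_plan: list[tuple[str, str, tuple[str, ...]]]  # (lncRNA, mRNA, miRNAs)
    coding_labels: dict[str, str]  # transcript id -> coding | noncoding

    @property
    def mrnas(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.biotype == "mRNA"]

    @property
    def lncrnas(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.biotype == "lncRNA-candidate"]

    def transcript_sequences(self) -> dict[str, str]:
        return {t.transcript_id: t.sequence for t in self.transcripts}


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    de_features: dict[str, list[tuple[str, float]]]  # class -> (id, log2fc)
    triplets: list[tuple[str, str, str]]  # (lncRNA, miRNA, mRNA)
    planted_sites: list[SeedSite]
    coding_labels: dict[str, str]

    def de_ids(self, rna_class: str) -> set[str]:
        return {fid for fid, _ in self.de_features[rna_class]}

    def pair_set(self) -> set[tuple[str, str]]:
        return {(l, g) for l, _, g in self.triplets}


@dataclass
class ReadSetTruth:
    """Per-sample read-level truth from :func:`generate_small_rna_reads`."""

    clean_counts: dict[str, int]
    contaminant_reads: dict[str, str]  # read name -> category

    @property
    def n_clean(self) -> int:
        return sum(self.clean_counts.values())

    @property
    def n_contaminant(self) -> int:
        return len(self.contaminant_reads)


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _mrna_sequence(rng: np.random.Generator) -> tuple[str, int, int]:
    """Returns (sequence, utr5_len, orf_len_incl_stop)."""
    utr5 = int(rng.integers(20, 51))
    n_codons = int(rng.integers(100, 201))  # ORF 300..600 nt incl. stop
    utr3 = int(rng.integers(100, 201))
    codons = rng.choice(_SENSE_CODONS, size=n_codons - 2, p=_CODON_PROBS)
    stop = str(rng.choice(sorted(_STOP_CODONS)))
    orf = "ATG" + "".join(codons) + stop
    seq = _random_seq(rng, utr5) + orf + _random_seq(rng, utr3)
    return seq, utr5, len(orf)


def _lncrna_sequence(rng: np.random.Generator, max_tries: int = 50) -> str:
    for _ in range(max_tries):
        length = int(rng.integers(200, 401))
        seq = _random_seq(rng, length)
        if find_longest_orf(seq).length < 300:
            return seq
    raise RuntimeError("could not draw a lncRNA sequence without a long reading frame")


def _plant_sites(
    seq: str,
    region: tuple[int, int],
    mirnas: Sequence[tuple[str, str]],
    site_type: str,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[str, list[tuple[str, int]]]:
    """Write one canonical site per miRNA into ``seq`` within ``region``.

    Each site occupies a 10-nt window with guard bases forcing the intended
    classification (e.g. a 7mer-A1 is preceded by a base that cannot extend
    it to an m8 match).  Returns the edited sequence and (miRNA id, site
    start) records.
    """
    lo, hi = region
    if hi - lo < 10 * len(mirnas):
        raise ValueError("planting region too short for requested sites")
    chars = list(seq)
    # stars-and-bars: k sorted offsets into the slack guarantee >= 10 nt spacing
    k = len(mirnas)
    slack = (hi - lo) - 10 * k
    offsets = np.sort(rng.integers(0, slack + 1, size=k))
    starts = [lo + int(offsets[i]) + 10 * i for i in range(k)]
    placements: list[tuple[str, int]] = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for w, (mirna_id, mseq) in zip(starts, mirnas):
        m = mseq.upper().replace("U", "T")
        core = reverse_complement(m[1:7])
        m8c = comp[m[7]]
        if site_type == "8mer":
            site = m8c + core + "A"
            offset = 1
        elif site_type == "7mer-m8":
            site = m8c + core
            offset = 1
            chars[w + 8] = str(rng.choice([b for b in _BASES if b != "A"]))
        elif site_type == "7mer-A1":
            site = core + "A"
            offset = 2
            chars[w + 1] = str(rng.choice([b for b in _BASES if b != m8c]))
        else:  # 6mer
            site = core
            offset = 2
            chars[w + 1] = str(rng.choice([b for b in _BASES if b != m8c]))
            chars[w + 8] = str(rng.choice([b for b in _BASES if b != "A"]))
        chars[w + offset : w + offset + len(site)] = list(site)
        placements.append((mirna_id, w + offset))
    return "".join(chars), placements


def _exonize(
    rng: np.random.Generator, spliced_length: int, min_exons: int, max_exons: int = 10
) -> tuple[list[int], list[int]]:
    """Split a spliced length into exon lengths (each >= 30 nt where possible)
    and draw intron lengths."""
    cap = max(min_exons, min(max_exons, spliced_length // 30))
    n_exons = int(rng.integers(min_exons, cap + 1))
    slack = spliced_length - 30 * n_exons
    weights = rng.dirichlet(np.ones(n_exons))
    extra = np.floor(weights * slack).astype(int)
    extra[0] += slack - int(extra.sum())
    exon_lens = (30 + extra).tolist()
    intron_lens = [int(rng.integers(50, 2001)) for _ in range(n_exons - 1)]
    return exon_lens, intron_lens


def _place(
    start: int, exon_lens: Sequence[int], intron_lens: Sequence[int]
) -> list[tuple[int, int]]:
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    return exons


# ---------------------------------------------------------------------------
# main generators
# ---------------------------------------------------------------------------

def generate_annotation(config: SimulationConfig) -> SimulatedAnnotation:
    """Synthetic transcript models, mature miRNAs and planted seed sites.

    mRNA and cis-lncRNA genes are laid out along "mixed" contigs with the
    cis lncRNAs placed 1-80 kb downstream of their partner gene; the
    remaining lncRNAs live on gene-desert contigs so that roughly
    ``cis_fraction`` of lncRNAs lies within 100 kb of a coding gene.
    """
    rng = np.random.default_rng([config.seed, 0])

    mirna_ids = [f"mir-{i + 1}" for i in range(config.n_mirna)]
    mirna_sequences = {
        mid: _random_seq(rng, config.mirna_length).replace("T", "U") for mid in mirna_ids
    }

    # sponging plan: triplet rows grouped into pairs sharing miRNAs
    sizes = config.pair_plan_sizes()
    n_pairs = len(sizes)
    lnc_pick = rng.choice(config.n_lncrna, size=n_pairs, replace=False) if n_pairs else []
    mrna_pick = rng.choice(config.n_mrna, size=n_pairs, replace=False) if n_pairs else []
    mirna_pick = rng.choice(config.n_mirna, size=config.n_triplets, replace=False) if n_pairs else []
    pair_plan: list[tuple[str, str, tuple[str, ...]]] = []
    cursor = 0
    for p, size in enumerate(sizes):
        ms = tuple(mirna_ids[i] for i in mirna_pick[cursor : cursor + size])
        cursor += size
        pair_plan.append((f"LNC{lnc_pick[p] + 1}", f"G{mrna_pick[p] + 1}", ms))
    sponge_lnc = {l: ms for l, _, ms in pair_plan}
    sponge_mrna = {g: ms for _, g, ms in pair_plan}

    # sequences with planted sites
    planted_sites: list[SeedSite] = []
    mrna_seqs: dict[str, str] = {}
    mrna_meta: dict[str, tuple[int, int]] = {}
    for i in range(config.n_mrna):
        tid = f"G{i + 1}"
        for _ in range(50):
            seq, utr5, orf_len = _mrna_sequence(rng)
            sites: list[tuple[str, int]] = []
            if tid in sponge_mrna:
                seq, sites = _plant_sites(
                    seq,
                    (utr5 + orf_len, len(seq)),
                    [(m, mirna_sequences[m]) for m in sponge_mrna[tid]],
                    config.site_type,
                    rng,
                )
            if _sites_recovered(tid, seq, sites, mirna_sequences, config.site_type) and (
                find_longest_orf(seq).length >= 300
            ):
                break
        else:
            raise RuntimeError(f"could not build mRNA {tid}")
        mrna_seqs[tid] = seq
        mrna_meta[tid] = (utr5, orf_len)
        planted_sites.extend(
            SeedSite(m, tid, pos, config.site_type) for m, pos in sites
        )

    lnc_seqs: dict[str, str] = {}
    for i in range(config.n_lncrna):
        tid = f"LNC{i + 1}"
        for _ in range(50):
            seq = _lncrna_sequence(rng)
            sites = []
            if tid in sponge_lnc:
                seq, sites = _plant_sites(
                    seq,
                    (0, len(seq)),
                    [(m, mirna_sequences[m]) for m in sponge_lnc[tid]],
                    config.site_type,
                    rng,
                )
            if _sites_recovered(tid, seq, sites, mirna_sequences, config.site_type) and (
                find_longest_orf(seq).length < 300
            ):
                break
        else:
            raise RuntimeError(f"could not build lncRNA {tid}")
        lnc_seqs[tid] = seq
        planted_sites.extend(
            SeedSite(m, tid, pos, config.site_type) for m, pos in sites
        )

    # genomic layout
    n_desert = max(1, round(config.contig_count * 0.25)) if config.n_lncrna else 0
    n_desert = min(n_desert, config.contig_count - 1)
    contigs = {f"contig_{c + 1}": config.contig_length for c in range(config.contig_count)}
    mixed = list(contigs)[: config.contig_count - n_desert]
    deserts = list(contigs)[config.contig_count - n_desert :]

    n_cis = round(config.cis_fraction * config.n_lncrna)
    cis_lnc_ids = [f"LNC{i + 1}" for i in sorted(rng.choice(config.n_lncrna, size=n_cis, replace=False))]
    host_genes = sorted(rng.choice(config.n_mrna, size=n_cis, replace=False)) if n_cis <= config.n_mrna else None
    if host_genes is None:
        raise ValueError("more cis lncRNAs requested than available host genes")
    host_of = {f"G{g + 1}": cis_lnc_ids[j] for j, g in enumerate(host_genes)}

    transcripts: list[TranscriptModel] = []
    cursors = {c: 0 for c in contigs}

    def place_transcript(tid, gene_id, contig, seq, biotype, min_exons):
        exon_lens, intron_lens = _exonize(rng, len(seq), min_exons)
        span = sum(exon_lens) + sum(intron_lens)
        start = cursors[contig]
        if start + span > contigs[contig]:
            raise ValueError(
                f"contig {contig} too short ({contigs[contig]} bp) to place {tid}"
            )
        exons = _place(start, exon_lens, intron_lens)
        cursors[contig] = exons[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                contig=contig,
                strand=strand,
                exons=exons,
                biotype=biotype,
                sequence=seq,
            )
        )

    for i in range(config.n_mrna):
        tid = f"G{i + 1}"
        contig = mixed[i % len(mixed)]
        cursors[contig] += int(rng.integers(5_000, 40_001))
        place_transcript(tid, f"gene_{tid}", contig, mrna_seqs[tid], "mRNA", 1)
        if tid in host_of:
            lnc_id = host_of[tid]
            cursors[contig] += int(rng.integers(1_000, 80_000 - 5_000))
            place_transcript(lnc_id, f"gene_{lnc_id}", contig, lnc_seqs[lnc_id], "lncRNA-candidate", 2)

    desert_lncs = [f"LNC{i + 1}" for i in range(config.n_lncrna) if f"LNC{i + 1}" not in set(cis_lnc_ids)]
    for j, lnc_id in enumerate(desert_lncs):
        contig = deserts[j % len(deserts)] if deserts else mixed[0]
        cursors[contig] += int(rng.integers(10_000, 50_001))
        place_transcript(lnc_id, f"gene_{lnc_id}", contig, lnc_seqs[lnc_id], "lncRNA-candidate", 2)

    coding_labels = {tid: "coding" for tid in mrna_seqs}
    coding_labels.update({tid: "noncoding" for tid in lnc_seqs})

    return SimulatedAnnotation(
        transcripts=transcripts,
        mirna_sequences=mirna_sequences,
        contigs=contigs,
        planted_sites=planted_sites,
        pair_plan=pair_plan,
        coding_labels=coding_labels,
    )


def _sites_recovered(
    tid: str,
    seq: str,
    sites: list[tuple[str, int]],
    mirna_sequences: Mapping[str, str],
    site_type: str,
) -> bool:
    for mirna_id, pos in sites:
        found = find_seed_sites(mirna_id, mirna_sequences[mirna_id], tid, seq)
        if not any(s.start == pos and s.site_type == site_type for s in found):
            return False
    return True


def generate_expression(
    config: SimulationConfig, annotation: SimulatedAnnotation
) -> tuple[dict[str, ExpressionMatrix], SyntheticTruth]:
    """NB count matrices for the three RNA classes plus the truth tables.

    Returns ``({"mrna": ..., "lncrna": ..., "mirna": ...}, truth)``; each
    matrix is a counts-layer :class:`ExpressionMatrix` with mapped totals
    equal to its column sums.
    """
    if config.replicates_per_group < 2:
        raise ValueError("need >= 2 replicates per group for downstream testing")
    rng = np.random.default_rng([config.seed, 1])
    r = config.replicates_per_group
    samples = [f"{g}{i + 1}" for g in config.groups for i in range(r)]
    n_samples = 2 * r

    classes = {
        "mrna": [t.transcript_id for t in annotation.mrnas],
        "lncrna": [t.transcript_id for t in annotation.lncrnas],
        "mirna": list(annotation.mirna_sequences),
    }
    de_fractions = {
        "mrna": config.de_fraction_mrna,
        "lncrna": config.de_fraction_lncrna,
        "mirna": config.de_fraction_mirna,
    }
    pair_members = {
        "mrna": {g: ms for _, g, ms in annotation.pair_plan},
        "lncrna": {l: ms for l, _, ms in annotation.pair_plan},
    }
    sponge_mirnas: dict[str, list[int]] = {}
    for p, (_, _, ms) in enumerate(annotation.pair_plan):
        for m in ms:
            sponge_mirnas.setdefault(m, []).append(p)

    # One latent sponging factor per pair per sample.  The multiplicative
    # effect exp(+-beta * a_s) is normalized to mean 1 within each group so
    # that sponging redistributes expression across samples without moving
    # group means: planted DE stays exact and the latent factor cannot
    # masquerade as (or cancel) a group contrast.
    n_pairs = len(annotation.pair_plan)
    latent = rng.standard_normal((n_pairs, n_samples)) if n_pairs else np.zeros((0, n_samples))
    beta = config.sponge_effect

    def _group_normalized_log_effect(sign: float) -> np.ndarray:
        eff = np.exp(sign * beta * latent)
        for g in range(2):
            cols = slice(g * r, (g + 1) * r)
            eff[:, cols] /= eff[:, cols].mean(axis=1, keepdims=True)
        return np.log(eff)

    if n_pairs:
        sponge_up = _group_normalized_log_effect(+1.0)
        sponge_down = _group_normalized_log_effect(-1.0)
    else:
        sponge_up = sponge_down = np.zeros((0, n_samples))

    lo, hi = config.baseline_mean_log_range
    lfc_lo, lfc_hi = config.de_log2fc_range
    pair_sign = rng.choice([-1.0, 1.0], size=n_pairs) if n_pairs else np.array([])
    pair_index = {}
    for p, (l, g, ms) in enumerate(annotation.pair_plan):
        pair_index[l] = p
        pair_index[g] = p

    matrices: dict[str, ExpressionMatrix] = {}
    de_features: dict[str, list[tuple[str, float]]] = {}
    group_vec = np.array([1.0] * r + [-1.0] * r)  # + for first-named group

    for cls, ids in classes.items():
        n = len(ids)
        base_log_mean = rng.uniform(lo, hi, size=n)
        lfc = np.zeros(n)
        # planted independent DE among features not in any sponging pair
        in_pair = [
            (cls in pair_members and ids[i] in pair_members[cls])
            or (cls == "mirna" and ids[i] in sponge_mirnas)
            for i in range(n)
        ]
        eligible = [i for i in range(n) if not in_pair[i]]
        n_de = round(de_fractions[cls] * n)
        n_de = min(n_de, len(eligible))
        de_idx = sorted(rng.choice(eligible, size=n_de, replace=False)) if n_de else []
        for i in de_idx:
            lfc[i] = rng.choice([-1.0, 1.0]) * rng.uniform(lfc_lo, lfc_hi)
        # coordinated DE on sponging-pair members
        for i in range(n):
            if not in_pair[i]:
                continue
            mag = rng.uniform(lfc_lo, lfc_hi)
            if cls == "mirna":
                signs = {pair_sign[p] for p in sponge_mirnas[ids[i]]}
                sign = -next(iter(signs))
            else:
                sign = pair_sign[pair_index[ids[i]]]
            lfc[i] = sign * mag

        log2_mu = (base_log_mean / math.log(2.0))[:, None] + np.outer(lfc / 2.0, group_vec)
        ln_mu = log2_mu * math.log(2.0)
        if n_pairs:
            for i in range(n):
                fid = ids[i]
                if cls in ("mrna", "lncrna") and fid in pair_index:
                    ln_mu[i] += sponge_up[pair_index[fid]]
                elif cls == "mirna" and fid in sponge_mirnas:
                    for p in sponge_mirnas[fid]:
                        ln_mu[i] += sponge_down[p]
        mu = np.exp(ln_mu)
        alpha = config.nb_dispersion
        nb_n = 1.0 / alpha
        counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
        frame = pd.DataFrame(counts.astype(float), index=ids, columns=samples)
        matrices[cls] = ExpressionMatrix(frame, layer="counts")
        de_features[cls] = [(ids[i], float(lfc[i])) for i in range(n) if lfc[i] != 0.0]

    triplets = [
        (l, m, g) for l, g, ms in annotation.pair_plan for m in ms
    ]
    truth = SyntheticTruth(
        de_features=de_features,
        triplets=triplets,
        planted_sites=annotation.planted_sites,
        coding_labels=annotation.coding_labels,
    )
    return matrices, truth


def generate_small_rna_reads(
    config: SimulationConfig,
    mirna_sequences: Mapping[str, str],
    true_counts: Mapping[str, int],
    sample: str = "S1",
) -> tuple[list[Read], ReadSetTruth]:
    """Small-RNA reads for one library: each mature sequence repeated its
    true-count times with the 3' adapter, plus planted contaminants.

    Contaminants are split evenly between too-short (<18 nt), too-long
    (>30 nt) and high-N (>=10% N) reads; every contaminant read name is
    recorded in the truth with its category.
    """
    rng = np.random.default_rng([config.seed, 2, zlib.crc32(sample.encode()) % (2**31)])
    for mid, seq in mirna_sequences.items():
        if not 18 <= len(seq) <= 30:
            raise ValueError(
                f"mature sequence of {mid!r} is {len(seq)} nt; it could not "
                "survive the 18-30 nt read filter"
            )
    reads: list[Read] = []
    clean_counts: dict[str, int] = {}
    for mid in mirna_sequences:
        c = int(true_counts.get(mid, 0))
        if c < 0:
            raise ValueError(f"negative true count for {mid!r}")
        clean_counts[mid] = c
        dna = mirna_sequences[mid].upper().replace("U", "T")
        for i in range(c):
            reads.append(Read(f"{sample}:{mid}:{i + 1}", dna + config.adapter))
    n_clean = len(reads)
    n_contaminant = round(config.contaminant_fraction * n_clean)
    per = n_contaminant // 3
    n_short, n_long = per, per
    n_highn = n_contaminant - 2 * per
    contaminant_reads: dict[str, str] = {}
    for i in range(n_short):
        name = f"{sample}:contam_short:{i + 1}"
        reads.append(Read(name, _random_seq(rng, int(rng.integers(10, 18))) + config.adapter))
        contaminant_reads[name] = "too_short"
    for i in range(n_long):
        name = f"{sample}:contam_long:{i + 1}"
        reads.append(Read(name, _random_seq(rng, int(rng.integers(31, 46))) + config.adapter))
        contaminant_reads[name] = "too_long"
    for i in range(n_highn):
        name = f"{sample}:contam_highn:{i + 1}"
        core = list(_random_seq(rng, 20))
        for j in rng.choice(20, size=4, replace=False):
            core[j] = "N"
        reads.append(Read(name, "".join(core) + config.adapter))
        contaminant_reads[name] = "high_n"
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return reads, ReadSetTruth(clean_counts=clean_counts, contaminant_reads=contaminant_reads)


def simulate_study(
    config: SimulationConfig,
) -> tuple[SimulatedAnnotation, dict[str, ExpressionMatrix], SyntheticTruth]:
    """Convenience wrapper: annotation + expression + truth in one call."""
    annotation = generate_annotation(config)
    matrices, truth = generate_expression(config, annotation)
    return annotation, matrices, truth
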
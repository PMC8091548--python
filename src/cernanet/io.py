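"""Readers and writers for the formats the pipeline touches.

All genomic intervals are held internally as 0-based half-open ``[start, end)``
on a named contig.  GTF input/output uses the conventional 1-based closed
coordinates; the conversion (``start - 1``, ``end``) is applied exactly at the
file boundary and nowhere else.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TranscriptModel",
    "ExpressionMatrix",
    "Table1Record",
    "AnnotationError",
    "parse_annotation",
    "write_annotation",
    "read_expression_table",
    "load_table1",
    "export_network",
    "read_edge_table",
    "write_fasta",
    "read_fasta",
]

BIOTYPES = ("mRNA", "lncRNA-candidate", "miRNA", "unknown")

NODE_TYPES = ("lncRNA", "miRNA", "mRNA")

_TABLE1_SHA256 = "8528fb78105e335731d8f63508a337bad5bc64b857d81b545afb375debffe69c"


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass
class TranscriptModel:
    """One transcript: exon structure, strand, biotype, optional spliced sequence.

    ``exons`` are 0-based half-open intervals in contig coordinates, sorted
    ascending and non-overlapping.  ``sequence``, when present, is the spliced
    transcript read 5'->3' (i.e. already reverse-complemented for ``-`` strand
    transcripts).
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "unknown"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if b <= a:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: empty or inverted exon [{a}, {b})"
                )
        for (_, b1), (a2, _) in zip(exons, exons[1:]):
            if a2 < b1:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        self.exons = exons
        if self.biotype not in BIOTYPES:
            raise AnnotationError(
                f"transcript {self.transcript_id}: unknown biotype {self.biotype!r}"
            )
        if self.sequence is not None and len(self.sequence) != self.spliced_length:
            raise AnnotationError(
                f"transcript {self.transcript_id}: sequence length "
                f"{len(self.sequence)} != spliced length {self.spliced_length}"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def introns(self) -> list[tuple[int, int]]:
        return [(b1, a2) for (_, b1), (a2, _) in zip(self.exons, self.exons[1:])]


class ExpressionMatrix:
    """Feature-by-sample table of counts or normalized values.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
    layer
        One of ``counts``, ``TPM``, ``FPKM``.
    mapped_totals
        Per-sample mapped-read totals.  Only meaningful for the counts layer;
        defaults to the column sums (every counted read treated as mapped).
    """

    LAYERS = ("counts", "TPM", "FPKM")

    def __init__(
        self,
        values: pd.DataFrame,
        layer: str,
        mapped_totals: pd.Series | None = None,
    ):
        if layer not in self.LAYERS:
            raise ValueError(f"layer must be one of {self.LAYERS}, got {layer!r}")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = values.to_numpy(dtype=float)
        if arr.size and np.nanmin(arr) < 0:
            raise ValueError("negative expression values")
        if np.isnan(arr).any():
            raise ValueError("missing values in expression table")
        if layer == "counts" and arr.size and not np.allclose(arr, np.round(arr)):
            bad = values.index[np.where(~np.isclose(arr, np.round(arr)))[0][0]]
            raise ValueError(f"counts layer must be integer-valued (feature {bad!r})")
        self.values = values.astype(float)
        self.layer = layer
        if layer == "counts":
            if mapped_totals is None:
                mapped_totals = self.values.sum(axis=0)
            mapped_totals = pd.Series(mapped_totals, dtype=float).reindex(values.columns)
            if mapped_totals.isna().any():
                raise ValueError("mapped_totals missing for some samples")
            self.mapped_totals = mapped_totals
        else:
            self.mapped_totals = None

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        if self.layer == "counts":
            out = out.astype(int)
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ExpressionMatrix({self.shape[0]} features x {self.shape[1]} samples, {self.layer})"


def read_expression_table(path: str | Path, layer: str = "counts") -> ExpressionMatrix:
    """Read a TSV whose first column is the feature id into an :class:`ExpressionMatrix`."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty expression table") from None
    if raw.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at feature "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    return ExpressionMatrix(numeric, layer=layer)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise AnnotationError(f"line {lineno}: malformed attribute {chunk!r}")
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_annotation(path: str | Path) -> list[TranscriptModel]:
    """Parse an Ensembl-dialect GTF into :class:`TranscriptModel` objects.

    Only ``exon`` features are used; exon lines are grouped by their
    ``transcript_id`` attribute.  1-based closed GTF coordinates become
    0-based half-open.  Overlapping exons within one transcript raise.
    """
    path = Path(path)
    groups: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}: line {lineno}: expected 9 fields, got {len(fields)}")
            contig, _source, feature, start, end, _score, strand, _frame, attr_text = fields
            if feature != "exon":
                continue
            attrs = _parse_gtf_attributes(attr_text, lineno)
            if "transcript_id" not in attrs:
                raise AnnotationError(f"{path}: line {lineno}: exon without transcript_id")
            tid = attrs["transcript_id"]
            if tid not in groups:
                groups[tid] = {
                    "gene_id": attrs.get("gene_id", tid),
                    "contig": contig,
                    "strand": strand,
                    "biotype": attrs.get("transcript_biotype", "unknown"),
                    "exons": [],
                }
                order.append(tid)
            groups[tid]["exons"].append((int(start) - 1, int(end)))
    models = []
    for tid in order:
        rec = groups[tid]
        biotype = rec["biotype"] if rec["biotype"] in BIOTYPES else "unknown"
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                contig=rec["contig"],
                strand=rec["strand"],
                exons=rec["exons"],
                biotype=biotype,
            )
        )
    return models


def write_annotation(models: list[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF exon lines (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for m in models:
            for i, (a, b) in enumerate(m.exons, start=1):
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                    f'transcript_biotype "{m.biotype}"; exon_number "{i}";'
                )
                fh.write(
                    f"{m.contig}\tcernanet\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA / FASTQ helpers (thin wrappers around Biopython)
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Table 1 fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table1Record:
    """One row of the packaged key-gene table (symbols and partner ids as printed)."""

    gene: str
    log2fc: float
    p_value: float
    mirnas: tuple[str, ...]
    lncrnas: tuple[str, ...]
    category: str
    function: str


def _dedup(items: list[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for x in items:
        if x:
            seen.setdefault(x, None)
    return tuple(seen)


def load_table1() -> list[Table1Record]:
    """Load the bundled table of 27 key differentially expressed genes.

    The file is checksum-verified at load so that silent edits to the bundled
    data cannot go unnoticed.
    """
    ref = importlib.resources.files("cernanet") / "data" / "table1.tsv"
    data = ref.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _TABLE1_SHA256:
        raise RuntimeError(
            f"bundled table1.tsv failed checksum verification ({digest})"
        )
    import io as _io

    df = pd.read_csv(_io.BytesIO(data), sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        records.append(
            Table1Record(
                gene=row["gene"],
                log2fc=float(row["log2fc"]),
                p_value=float(row["p_value"]),
                mirnas=_dedup(row["mirnas"].split(",")),
                lncrnas=_dedup(row["lncrnas"].split(",")),
                category=row["category"],
                function=row["function"],
            )
        )
    return records


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def export_network(graph: nx.Graph, path: str | Path, fmt: str = "sif") -> None:
    """Write a typed ceRNA network.

    ``sif`` writes Cytoscape SIF lines ``<source> <relation> <target>``;
    ``edge-tsv`` is the lossless form carrying the shared-miRNA count ``k``,
    hypergeometric ``P``, BH ``q`` and Pearson ``r`` for ceRNA edges.  A node
    attribute table (type and regulation direction) is written alongside with
    suffix ``.nodes.tsv``.
    """
    path = Path(path)
    for node, data in graph.nodes(data=True):
        if data.get("node_type") not in NODE_TYPES:
            raise ValueError(f"node {node!r} has unknown type {data.get('node_type')!r}")
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in sorted(graph.edges(data=True)):
                rel = data.get("relation", "interacts")
                src, dst = _orient_edge(graph, u, v, rel)
                fh.write(f"{src} {rel} {dst}\n")
    elif fmt == "edge-tsv":
        rows = []
        for u, v, data in sorted(graph.edges(data=True)):
            rel = data.get("relation", "interacts")
            src, dst = _orient_edge(graph, u, v, rel)
            rows.append(
                {
                    "source": src,
                    "target": dst,
                    "relation": rel,
                    "k": data.get("k", ""),
                    "p_value": data.get("p_value", ""),
                    "q_value": data.get("q_value", ""),
                    "r": data.get("r", ""),
                }
            )
        pd.DataFrame(
            rows, columns=["source", "target", "relation", "k", "p_value", "q_value", "r"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    nodes = [
        {
            "node": n,
            "node_type": d.get("node_type"),
            "direction": d.get("direction", ""),
        }
        for n, d in sorted(graph.nodes(data=True))
    ]
    pd.DataFrame(nodes, columns=["node", "node_type", "direction"]).to_csv(
        path.with_suffix(path.suffix + ".nodes.tsv"), sep="\t", index=False
    )


def _orient_edge(graph: nx.Graph, u: str, v: str, relation: str) -> tuple[str, str]:
    # miRNA targeting edges always read miRNA -> target; ceRNA edges lncRNA -> mRNA
    tu = graph.nodes[u].get("node_type")
    if relation == "mirna_targets":
        return (u, v) if tu == "miRNA" else (v, u)
    if relation == "cerna_pair":
        return (u, v) if tu == "lncRNA" else (v, u)
    return (u, v)


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Reload an exported edge-TSV (round-trip partner of :func:`export_network`)."""
    return pd.read_csv(path, sep="\t", dtype={"source": str, "target": str, "relation": str})
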
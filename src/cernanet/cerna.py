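"""Competitive lncRNA-mRNA pair calling by shared-miRNA overlap.

For each candidate (lncRNA, mRNA) pair, let A be the set of miRNAs predicted
to target the lncRNA, B the set targeting the mRNA, N the size of the miRNA
universe and ``k = |A n B|``.  Under the null that A and B are independent
draws from the universe, k follows a hypergeometric distribution; a pair is a
ceRNA candidate when the upper tail ``P(X >= k)`` is small *and* the pair is
positively co-expressed.  The calling rule is::

    P < 0.01  and  BH q < 0.01  and  Pearson r > 0  and  correlation P < 0.05

with q computed across all tested pairs in one batch.  Every shared miRNA of
a called pair yields one (lncRNA, miRNA, mRNA) triplet, and the triplets form
a tripartite network with miRNA->target edges and lncRNA-mRNA ceRNA edges.

A generic hypergeometric set-enrichment utility on user-supplied term->gene
maps shares the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .io import ExpressionMatrix
from .targets import TargetInteraction

__all__ = [
    "CeRNAPair",
    "MiniNetworkSummary",
    "hypergeom_overlap_test",
    "build_cerna_pairs",
    "assemble_network",
    "extract_mini_network",
    "set_enrichment",
    "pairs_to_frame",
    "CeRNANetworkModel",
]


@dataclass
class CeRNAPair:
    lncrna_id: str
    mrna_id: str
    mirnas_lncrna: frozenset[str]  # A
    mirnas_mrna: frozenset[str]  # B
    universe_size: int  # N
    shared: frozenset[str]  # A n B
    p_value: float
    q_value: float = float("nan")
    r: float = float("nan")
    corr_p: float = float("nan")
    called: bool = False

    @property
    def k(self) -> int:
        return len(self.shared)


@dataclass(frozen=True)
class MiniNetworkSummary:
    genes: int
    lncrnas: int
    mirnas: int
    gene_lncrna_interactions: int


def hypergeom_overlap_test(k: int, size_a: int, size_b: int, universe: int) -> float:
    """Upper-tail ``P(X >= k)`` for the shared-miRNA overlap of two target sets.

    X is hypergeometric with population ``universe``, ``size_a`` successes
    and ``size_b`` draws; the test is symmetric in the two set sizes.
    """
    if not (0 <= k <= min(size_a, size_b) <= universe) or max(size_a, size_b) > universe:
        raise ValueError(
            f"inconsistent arguments k={k}, |A|={size_a}, |B|={size_b}, N={universe}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe, size_a, size_b))


def build_cerna_pairs(
    interactions: Sequence[TargetInteraction],
    lncrna_set: Iterable[str],
    mrna_set: Iterable[str],
    mirna_set: Iterable[str],
    lncrna_expr: ExpressionMatrix | None = None,
    mrna_expr: ExpressionMatrix | None = None,
    alpha_corr: float = 0.05,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.01,
    min_shared: int = 1,
    universe: int | None = None,
    log_transform: bool = True,
) -> list[CeRNAPair]:
    """Test every (lncRNA, mRNA) pair sharing >= ``min_shared`` miRNAs.

    ``interactions`` are seed-mode miRNA->transcript predictions; they are
    restricted to the supplied analysis sets (in the study design these are
    the differentially expressed features, so the network is DE-only).  The
    miRNA universe defaults to the size of ``mirna_set``.  When expression
    matrices are given, the Pearson correlation of each tested pair is
    computed across all shared samples on ``log2(value + 1)`` of the
    normalized layer, and enters the calling rule; otherwise the correlation
    filter is skipped (r reported as NaN and treated as passing).
    """
    lnc_ids = set(lncrna_set)
    mrna_ids = set(mrna_set)
    mirna_ids = set(mirna_set)
    if universe is None:
        universe = len(mirna_ids)
    if universe <= 0:
        raise ValueError("empty miRNA universe")
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")

    targets_of: dict[str, set[str]] = {}
    for it in interactions:
        if it.mode != "seed" or it.source_id not in mirna_ids:
            continue
        targets_of.setdefault(it.source_id, set()).add(it.target_id)

    a_sets: dict[str, set[str]] = {}
    b_sets: dict[str, set[str]] = {}
    for mirna, tgts in targets_of.items():
        for t in tgts:
            if t in lnc_ids:
                a_sets.setdefault(t, set()).add(mirna)
            if t in mrna_ids:
                b_sets.setdefault(t, set()).add(mirna)

    shared_count: dict[tuple[str, str], set[str]] = {}
    for mirna, tgts in targets_of.items():
        lncs = [t for t in tgts if t in a_sets and t in lnc_ids]
        genes = [t for t in tgts if t in b_sets and t in mrna_ids]
        for l in lncs:
            for g in genes:
                shared_count.setdefault((l, g), set()).add(mirna)

    pairs: list[CeRNAPair] = []
    for (l, g), shared in sorted(shared_count.items()):
        if len(shared) < min_shared:
            continue
        a, b = a_sets[l], b_sets[g]
        p = hypergeom_overlap_test(len(shared), len(a), len(b), universe)
        pairs.append(
            CeRNAPair(
                lncrna_id=l,
                mrna_id=g,
                mirnas_lncrna=frozenset(a),
                mirnas_mrna=frozenset(b),
                universe_size=universe,
                shared=frozenset(shared),
                p_value=p,
            )
        )
    if not pairs:
        return pairs

    q = bh_fdr([p.p_value for p in pairs])
    for pair, qv in zip(pairs, q):
        pair.q_value = float(qv)

    corr_ok = np.ones(len(pairs), dtype=bool)
    if lncrna_expr is not None and mrna_expr is not None:
        shared_samples = [s for s in lncrna_expr.samples if s in set(mrna_expr.samples)]
        if len(shared_samples) < 4:
            raise ValueError("need >= 4 shared samples for the correlation filter")
        x = lncrna_expr.values[shared_samples]
        y = mrna_expr.values[shared_samples]
        xv = x.to_numpy(dtype=float)
        yv = y.to_numpy(dtype=float)
        if log_transform:
            xv = np.log2(xv + 1.0)
            yv = np.log2(yv + 1.0)
        lnc_index = {f: i for i, f in enumerate(x.index)}
        mrna_index = {f: i for i, f in enumerate(y.index)}
        rows = np.array([lnc_index[p.lncrna_id] for p in pairs])
        cols = np.array([mrna_index[p.mrna_id] for p in pairs])
        r_vec, p_vec = _pearson_paired(xv[rows], yv[cols])
        for i, pair in enumerate(pairs):
            pair.r = float(r_vec[i])
            pair.corr_p = float(p_vec[i])
        corr_ok = (r_vec > 0) & (p_vec < alpha_corr)

    for i, pair in enumerate(pairs):
        pair.called = bool(
            pair.p_value < p_threshold
            and pair.q_value < fdr_threshold
            and corr_ok[i]
        )
    return pairs


def _pearson_paired(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r between matched rows of x and y, with two-sided P
    from the exact t distribution (same reference as scipy.stats.pearsonr)."""
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc).sum(axis=1) / denom
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, np.minimum(p, 1.0))
    return r, p


def pairs_to_frame(pairs: Sequence[CeRNAPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna_id": [p.lncrna_id for p in pairs],
            "mrna_id": [p.mrna_id for p in pairs],
            "size_a": [len(p.mirnas_lncrna) for p in pairs],
            "size_b": [len(p.mirnas_mrna) for p in pairs],
            "k": [p.k for p in pairs],
            "universe": [p.universe_size for p in pairs],
            "p_value": [p.p_value for p in pairs],
            "q_value": [p.q_value for p in pairs],
            "r": [p.r for p in pairs],
            "corr_p": [p.corr_p for p in pairs],
            "called": [p.called for p in pairs],
        }
    )


def assemble_network(
    called_pairs: Sequence[CeRNAPair],
    interactions: Sequence[TargetInteraction],
    directions: Mapping[str, str] | None = None,
) -> tuple[nx.Graph, list[tuple[str, str, str]]]:
    """Tripartite network and (lncRNA, miRNA, mRNA) triplet enumeration.

    One triplet per shared miRNA of each called pair; the triplet count is
    therefore the sum of k over called pairs.  Node regulation directions
    (up/down) may be attached from DE results.
    """
    known_edges = {(it.source_id, it.target_id) for it in interactions if it.mode == "seed"}
    graph = nx.Graph()
    triplets: list[tuple[str, str, str]] = []
    directions = directions or {}

    def add_node(name: str, node_type: str) -> None:
        graph.add_node(name, node_type=node_type, direction=directions.get(name, ""))

    for pair in called_pairs:
        if not pair.called:
            raise ValueError(f"pair ({pair.lncrna_id}, {pair.mrna_id}) is not called")
        add_node(pair.lncrna_id, "lncRNA")
        add_node(pair.mrna_id, "mRNA")
        graph.add_edge(
            pair.lncrna_id,
            pair.mrna_id,
            relation="cerna_pair",
            k=pair.k,
            p_value=pair.p_value,
            q_value=pair.q_value,
            r=pair.r,
        )
        for mirna in sorted(pair.shared):
            for target in (pair.lncrna_id, pair.mrna_id):
                if (mirna, target) not in known_edges:
                    raise ValueError(
                        f"called pair references interaction {mirna}->{target} "
                        "absent from the prediction set"
                    )
            add_node(mirna, "miRNA")
            graph.add_edge(mirna, pair.lncrna_id, relation="mirna_targets")
            graph.add_edge(mirna, pair.mrna_id, relation="mirna_targets")
            triplets.append((pair.lncrna_id, mirna, pair.mrna_id))
    return graph, triplets


def extract_mini_network(
    records,
    gene_allowlist: Iterable[str] | None = None,
) -> tuple[MiniNetworkSummary, nx.Graph]:
    """Key-gene subnetwork: genes with at least one miRNA AND one lncRNA partner.

    Works on the packaged key-gene table records (or any objects with
    ``gene``, ``mirnas`` and ``lncrnas`` attributes).  The interaction count
    is the number of gene-lncRNA pair occurrences, not deduplicated across
    genes; the lncRNA and miRNA counts are distinct ids over the kept genes.
    """
    allow = set(gene_allowlist) if gene_allowlist is not None else None
    graph = nx.Graph()
    genes: list = []
    for rec in records:
        if not rec.mirnas or not rec.lncrnas:
            continue
        if allow is not None and rec.gene not in allow:
            continue
        genes.append(rec)
    lnc_ids: set[str] = set()
    mirna_ids: set[str] = set()
    interactions = 0
    for rec in genes:
        direction = "up" if rec.log2fc > 0 else "down"
        graph.add_node(rec.gene, node_type="mRNA", direction=direction)
        for m in rec.mirnas:
            mirna_ids.add(m)
            graph.add_node(m, node_type="miRNA")
            graph.add_edge(m, rec.gene, relation="mirna_targets")
        for l in rec.lncrnas:
            lnc_ids.add(l)
            graph.add_node(l, node_type="lncRNA")
            graph.add_edge(l, rec.gene, relation="cerna_pair")
            interactions += 1
    summary = MiniNetworkSummary(
        genes=len(genes),
        lncrnas=len(lnc_ids),
        mirnas=len(mirna_ids),
        gene_lncrna_interactions=interactions,
    )
    return summary, graph


def set_enrichment(
    query: Iterable[str],
    term_to_genes: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene set against term->gene maps."""
    uni = set(universe)
    q = set(query)
    if not q <= uni:
        raise ValueError(f"query genes outside universe: {sorted(q - uni)[:5]}")
    rows = []
    for term, genes in term_to_genes.items():
        gset = set(genes)
        if not gset <= uni:
            raise ValueError(
                f"term {term!r} has genes outside the universe: {sorted(gset - uni)[:5]}"
            )
        k = len(q & gset)
        p = hypergeom_overlap_test(k, len(gset), len(q), len(uni))
        rows.append({"term": term, "overlap": k, "term_size": len(gset), "p_value": p})
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p_value"])
    df["q_value"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else []
    return df


class CeRNANetworkModel:
    """Model-object front end over pair calling and network assembly."""

    def __init__(
        self,
        interactions: Sequence[TargetInteraction],
        lncrna_set: Iterable[str],
        mrna_set: Iterable[str],
        mirna_set: Iterable[str],
        lncrna_expr: ExpressionMatrix | None = None,
        mrna_expr: ExpressionMatrix | None = None,
    ):
        self.interactions = list(interactions)
        self.lncrna_set = set(lncrna_set)
        self.mrna_set = set(mrna_set)
        self.mirna_set = set(mirna_set)
        self.lncrna_expr = lncrna_expr
        self.mrna_expr = mrna_expr

    def fit(self, directions: Mapping[str, str] | None = None, **kwargs) -> "CeRNANetworkResults":
        pairs = build_cerna_pairs(
            self.interactions,
            self.lncrna_set,
            self.mrna_set,
            self.mirna_set,
            self.lncrna_expr,
            self.mrna_expr,
            **kwargs,
        )
        called = [p for p in pairs if p.called]
        graph, triplets = assemble_network(called, self.interactions, directions)
        return CeRNANetworkResults(self, pairs, called, graph, triplets)


class CeRNANetworkResults:
    def __init__(self, model, pairs, called, graph, triplets):
        self.model = model
        self.pairs = pairs
        self.called = called
        self.graph = graph
        self.triplets = triplets

    @property
    def table(self) -> pd.DataFrame:
        return pairs_to_frame(self.pairs)

    def summary(self) -> str:
        counts = {"lncRNA": 0, "miRNA": 0, "mRNA": 0}
        for _, d in self.graph.nodes(data=True):
            counts[d["node_type"]] += 1
        return "\n".join(
            [
                "ceRNA shared-miRNA network",
                f"  tested pairs: {len(self.pairs)}",
                f"  called pairs: {len(self.called)} (P < 0.01, FDR < 0.01, r > 0)",
                f"  triplets:     {len(self.triplets)}",
                f"  nodes:        {counts['lncRNA']} lncRNA / {counts['miRNA']} miRNA / "
                f"{counts['mRNA']} mRNA",
            ]
        )
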
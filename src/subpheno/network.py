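"""Seed-gene network expansion over a scored edge table, with ontology
enrichment against a background universe.

The edge table follows the STRING ``protein.links`` dialect: undirected
gene pairs with an integer combined score in [0, 1000]. Seed sets are
expanded by taking, per seed, its top-k interactors by score (ties broken
lexicographically by gene symbol), and term enrichment is a hypergeometric
upper-tail test with Benjamini-Hochberg correction across terms. An EASE
variant (overlap reduced by one, as popularised by DAVID) is available by
flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeTable",
    "TermAnnotation",
    "top_k_interactors",
    "expand_network",
    "enrich_terms",
    "ontology_coverage",
    "read_edge_tsv",
    "read_annotation_tsv",
]

#: STRING "medium confidence" default cutoff on combined_score
DEFAULT_MIN_SCORE = 400


class EdgeTable:
    """Undirected scored gene-interaction table with adjacency lookup."""

    def __init__(self, edges: pd.DataFrame, min_score: int = 0):
        required = {"gene_a", "gene_b", "combined_score"}
        if not required <= set(edges.columns):
            raise ValueError(f"edge table needs columns {sorted(required)}")
        df = edges.copy()
        if min_score:
            df = df[df["combined_score"] >= min_score]
        a = df["gene_a"].astype(str)
        b = df["gene_b"].astype(str)
        if (a == b).any():
            raise ValueError("self-loops are not allowed")
        swap = a > b
        lo, hi = a.where(~swap, b), b.where(~swap, a)
        df = pd.DataFrame({
            "gene_a": lo, "gene_b": hi,
            "combined_score": df["combined_score"].astype(int).to_numpy(),
        })
        df = df.drop_duplicates(subset=["gene_a", "gene_b"], keep="first")
        self.edges = df.reset_index(drop=True)
        self._adj: dict[str, list[tuple[str, int]]] = {}
        for ga, gb, s in self.edges.itertuples(index=False):
            self._adj.setdefault(ga, []).append((gb, s))
            self._adj.setdefault(gb, []).append((ga, s))

    @property
    def genes(self) -> set[str]:
        return set(self._adj)

    def neighbors(self, gene: str) -> list[tuple[str, int]]:
        return self._adj.get(gene, [])


@dataclass
class TermAnnotation:
    term_id: str
    term_name: str
    genes: frozenset


def top_k_interactors(seed: str, edges: EdgeTable, k: int = 10) -> list[str]:
    """Top-``k`` neighbors of ``seed`` by combined score.

    Ties are broken lexicographically by gene symbol; a seed absent from
    the edge table yields an empty list (logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nbrs = edges.neighbors(seed)
    if not nbrs:
        logger.info("seed %s absent from edge table", seed)
        return []
    ranked = sorted(nbrs, key=lambda gs: (-gs[1], gs[0]))
    return [g for g, _ in ranked[:k]]


def expand_network(
    seeds, edges: EdgeTable, k: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seed genes plus their per-seed top-k interactors, with induced edges.

    Returns ``(nodes, induced_edges)``: a node table with an ``origin``
    column ('seed' or 'interactor'; seed status wins for shared genes) and
    the subset of the edge table connecting two included nodes. The result
    is independent of seed iteration order.
    """
    seed_set = set(map(str, seeds))
    interactors: set[str] = set()
    for seed in sorted(seed_set):
        interactors.update(top_k_interactors(seed, edges, k=k))
    interactors -= seed_set
    nodes = pd.DataFrame(
        sorted(
            [(g, "seed") for g in seed_set] + [(g, "interactor") for g in interactors]
        ),
        columns=["gene", "origin"],
    )
    node_set = seed_set | interactors
    e = edges.edges
    induced = e[e["gene_a"].isin(node_set) & e["gene_b"].isin(node_set)].reset_index(
        drop=True
    )
    return nodes, induced


def enrich_terms(
    query,
    annotation: list[TermAnnotation],
    background,
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of ``query`` within ``background``.

    Per term: upper-tail P(X >= overlap) for drawing ``|query|`` genes from
    ``|background|`` of which ``|term ∩ background|`` are annotated;
    ``expected`` is the null mean. With ``ease`` the observed overlap is
    reduced by one before testing (a conservative DAVID-style variant).
    BH adjustment is applied across the tested terms. Terms with no
    background genes are skipped.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background universe")
    N, n = len(background), len(query)
    rows = []
    for term in annotation:
        term_genes = set(term.genes) & background
        K = len(term_genes)
        if K == 0:
            logger.info("term %s has no background genes; skipped", term.term_id)
            continue
        overlap = len(term_genes & query)
        observed = max(overlap - 1, 0) if ease else overlap
        p = float(hypergeom.sf(observed - 1, N, K, n))
        rows.append({
            "term_id": term.term_id,
            "term_name": term.term_name,
            "overlap": overlap,
            "term_size": K,
            "expected": n * K / N,
            "p": min(p, 1.0),
        })
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "overlap", "term_size", "expected", "p"])
    if df.empty:
        df["p_bh"] = pd.Series(dtype=float)
        return df
    df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values(["p", "term_id"]).reset_index(drop=True)


def ontology_coverage(genes, pooled_terms: dict) -> tuple[float, int, int]:
    """Fraction of ``genes`` annotated to at least one pooled term.

    ``pooled_terms`` maps a pooled label to its gene set. Returns
    ``(fraction, annotated_count, total)``.
    """
    genes = set(genes)
    annotated_universe = set().union(*pooled_terms.values()) if pooled_terms else set()
    covered = genes & annotated_universe
    total = len(genes)
    return (len(covered) / total if total else 0.0), len(covered), total


def read_edge_tsv(path, min_score: int = 0) -> EdgeTable:
    """Read a STRING-style edge TSV (``gene_a  gene_b  combined_score``;
    the ``protein1/protein2/combined_score`` dialect is accepted too)."""
    df = pd.read_csv(path, sep=r"\s+")
    df = df.rename(columns={"protein1": "gene_a", "protein2": "gene_b"})
    return EdgeTable(df, min_score=min_score)


def read_annotation_tsv(path) -> list[TermAnnotation]:
    """Read term annotations from a long TSV (term_id, term_name, gene)."""
    df = pd.read_csv(path, sep="\t")
    terms = []
    for (tid, tname), grp in df.groupby(["term_id", "term_name"], sort=True):
        terms.append(TermAnnotation(str(tid), str(tname), frozenset(grp["gene"].astype(str))))
    return terms
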
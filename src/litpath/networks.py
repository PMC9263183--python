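"""Pathway networks: gene-overlap enrichment and overlap-corrected co-expression.

Two complementary views of how the top literature-ranked pathways relate:

* **Overlap network** — for every pathway pair a one-sided Fisher exact test
  asks whether the two gene sets share more genes than expected under
  hypergeometric sampling from the universe; edges are pairs significant
  after Benjamini–Hochberg adjustment, weighted by −log10(q).
* **Co-expression network** — for every pair, the correlation between the
  pathways' expression summary statistics (mean of gene-wise z-scores).
  When the pathways share genes, the statistic is the first-order partial
  correlation between the summaries of the disjoint parts given the summary
  of the shared genes, so that co-expression driven purely by membership
  overlap is corrected away.  This is a deliberately simplified
  re-implementation of the pathway co-expression (PCxN) edge statistic.

The same machinery drives enrichment of external gene lists (e.g. curated
AD gene lists) against the pathway collection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MIN_GENESET_SIZE = 10


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

class GeneSetCollection:
    """Named gene sets over a common universe.

    The universe defaults to the union of all member genes, the standard
    background for pathway-overlap testing, and can be overridden.
    """

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        universe: Iterable[str] | None = None,
        descriptions: Mapping[str, str] | None = None,
    ):
        self.sets: dict[str, frozenset[str]] = {
            name: frozenset(genes) for name, genes in sets.items()
        }
        if universe is None:
            universe = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        self.universe: frozenset[str] = frozenset(universe)
        for name, genes in self.sets.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"gene set {name!r} has genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )
        self.descriptions = dict(descriptions or {})

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def eligible(self, min_size: int = MIN_GENESET_SIZE) -> list[str]:
        """Set names large enough for overlap analysis, sorted."""
        return sorted(n for n, g in self.sets.items() if len(g) >= min_size)

    @classmethod
    def from_gmt(cls, path: str | Path, universe=None) -> "GeneSetCollection":
        from gseapy import read_gmt

        sets = read_gmt(str(path))
        return cls(sets, universe=universe)

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name in sorted(self.sets):
                desc = self.descriptions.get(name, "na")
                genes = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# Fisher overlap and BH
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    overlap_size: int
    odds_ratio: float
    p: float


def fisher_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    alternative: str = "greater",
) -> OverlapResult:
    """Fisher exact test for the overlap of two gene sets.

    One-sided by default: the p-value is the probability of an overlap at
    least as large under hypergeometric sampling from the universe (a
    depleted overlap is not enrichment).
    """
    A, B, U = frozenset(set_a), frozenset(set_b), frozenset(universe)
    if not U:
        raise ValueError("empty universe")
    if not A <= U or not B <= U:
        raise ValueError("gene sets must be subsets of the universe")
    k = len(A & B)
    n_a, n_b, n = len(A), len(B), len(U)
    table = [[k, n_a - k], [n_b - k, n - n_a - n_b + k]]
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return OverlapResult(k, float(odds), float(p))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values.

    q(i) = min over j with p(j) >= p(i) of min(1, m·p(j)/j) for the sorted
    p-values; order-preserving in the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1, dtype=float)
    q_sorted = m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Networks (node/edge tables)
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """A pathway network as plain node and edge tables.

    Nodes carry the literature rank and mean AD word score; edges carry the
    pair statistic with raw and adjusted p-values and a display weight.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame
    kind: str  # "overlap" | "coexpression"
    metadata: dict

    def to_tsv(self, directory: str | Path, prefix: str | None = None) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.kind
        self.nodes.to_csv(d / f"{prefix}_nodes.tsv", sep="\t", index=False)
        self.edges.to_csv(d / f"{prefix}_edges.tsv", sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph()
        for row in self.nodes.itertuples(index=False):
            g.add_node(row.pathway_id, **{
                k: v for k, v in row._asdict().items() if k != "pathway_id"
            })
        for row in self.edges.itertuples(index=False):
            d = row._asdict()
            g.add_edge(d.pop("a"), d.pop("b"), **d)
        nx.write_graphml(g, str(path))


def _select_top_nodes(
    rank_table: pd.DataFrame, candidates: Sequence[str], top_k: int
) -> pd.DataFrame:
    ranked = rank_table[rank_table["pathway_id"].isin(candidates)]
    ranked = ranked.sort_values(["rank", "pathway_id"], kind="mergesort")
    if len(ranked) < top_k:
        warnings.warn(
            f"only {len(ranked)} rankable pathways available for top_k={top_k}"
        )
    return ranked.head(top_k).reset_index(drop=True)


def _weight_from_q(q: np.ndarray) -> np.ndarray:
    return -np.log10(np.maximum(q, 1e-300))


def overlap_network(
    gene_sets: GeneSetCollection,
    rank_table: pd.DataFrame,
    top_k: int = 30,
    alpha: float = 0.05,
    ad_word_scores: Mapping[str, float] | None = None,
    fdr_scope: str = "all",
    alternative: str = "greater",
) -> Network:
    """Gene-overlap enrichment network of the top-ranked pathways.

    Nodes are the ``top_k`` pathways by literature rank that have gene sets
    of at least ``MIN_GENESET_SIZE`` genes.  Every eligible pathway pair in
    the collection is Fisher-tested and BH-adjusted globally by default
    (``fdr_scope="selected"`` restricts the adjustment to pairs among the
    selected nodes); edges are node pairs with q < alpha, weighted by
    −log10(q).
    """
    eligible = gene_sets.eligible()
    nodes = _select_top_nodes(rank_table, eligible, top_k)
    node_ids = list(nodes["pathway_id"])

    pairs = (
        list(combinations(eligible, 2))
        if fdr_scope == "all"
        else list(combinations(sorted(node_ids), 2))
    )
    rows = []
    for a, b in pairs:
        res = fisher_overlap(
            gene_sets[a], gene_sets[b], gene_sets.universe, alternative
        )
        rows.append((a, b, res.overlap_size, res.odds_ratio, res.p))
    pair_df = pd.DataFrame(
        rows, columns=["a", "b", "overlap_size", "odds_ratio", "p"]
    )
    pair_df["q"] = bh_fdr(pair_df["p"].values) if len(pair_df) else []

    in_nodes = pair_df["a"].isin(node_ids) & pair_df["b"].isin(node_ids)
    edges = pair_df[in_nodes & (pair_df["q"] < alpha)].copy()
    edges["weight"] = _weight_from_q(edges["q"].values)
    edges = edges.sort_values(["a", "b"], kind="mergesort").reset_index(drop=True)

    nodes = nodes[["pathway_id", "study_count", "rank"]].copy()
    scores = ad_word_scores or {}
    nodes["ad_word_score"] = [scores.get(p, np.nan) for p in nodes["pathway_id"]]
    return Network(
        nodes=nodes,
        edges=edges,
        kind="overlap",
        metadata={
            "top_k": top_k,
            "alpha": alpha,
            "fdr_scope": fdr_scope,
            "alternative": alternative,
            "n_pairs_tested": len(pair_df),
        },
    )


def gene_list_enrichment(
    gene_list: Iterable[str],
    gene_sets: GeneSetCollection,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Enrichment of an external gene list against every eligible pathway.

    Out-of-universe symbols are dropped with a warning; the result is one
    row per pathway with overlap size, odds ratio, p and BH q, sorted by q.
    """
    U = frozenset(universe) if universe is not None else gene_sets.universe
    genes = frozenset(gene_list)
    dropped = genes - U
    if dropped:
        warnings.warn(f"{len(dropped)} gene(s) outside the universe dropped")
    genes &= U
    if not genes:
        raise ValueError("gene list is empty after intersecting the universe")
    rows = []
    for name in gene_sets.eligible():
        res = fisher_overlap(genes, gene_sets[name], U)
        rows.append((name, res.overlap_size, res.odds_ratio, res.p))
    out = pd.DataFrame(rows, columns=["pathway_id", "overlap_size", "odds_ratio", "p"])
    out["q"] = bh_fdr(out["p"].values)
    return out.sort_values(["q", "p", "pathway_id"], kind="mergesort").reset_index(
        drop=True
    )


@dataclass
class WilcoxonResult:
    statistic: float
    p: float
    method: str  # "exact" | "asymptotic"
    n_enriched: int
    n_other: int


def enriched_vs_rank_test(
    enrichment: pd.DataFrame,
    rank_table: pd.DataFrame,
    alpha: float = 0.05,
) -> WilcoxonResult:
    """Wilcoxon rank-sum test comparing literature ranks of enriched
    (q < alpha) versus non-enriched pathways.

    Exact two-sided p for small samples (combined n ≤ 20, no ties across
    groups); otherwise the normal approximation with tie correction.
    """
    merged = enrichment.merge(rank_table, on="pathway_id")
    enriched = merged.loc[merged["q"] < alpha, "rank"].to_numpy(dtype=float)
    other = merged.loc[merged["q"] >= alpha, "rank"].to_numpy(dtype=float)
    if len(enriched) == 0 or len(other) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([enriched, other])
    has_ties = len(np.unique(combined)) < len(combined)
    small = len(combined) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        enriched, other, alternative="two-sided", method=method
    )
    return WilcoxonResult(
        float(res.statistic), float(res.pvalue), method, len(enriched), len(other)
    )


# ---------------------------------------------------------------------------
# Pathway expression summaries and PCxN-style edges
# ---------------------------------------------------------------------------

def pathway_summary(expr: pd.DataFrame, genes: Iterable[str]) -> pd.Series:
    """Per-sample pathway expression summary: mean of gene-wise z-scores.

    ``expr`` is genes × samples.  Genes absent from the matrix or with zero
    variance are ignored; at least two usable member genes are required.
    """
    present = [g for g in sorted(set(genes)) if g in expr.index]
    sub = expr.loc[present]
    sd = sub.std(axis=1, ddof=1)
    sub = sub[sd > 0]
    if len(sub) < 2:
        raise ValueError("need at least two usable member genes in the matrix")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    return z.mean(axis=0)


def _single_gene_z(expr: pd.DataFrame, gene: str) -> pd.Series:
    row = expr.loc[gene]
    return (row - row.mean()) / row.std(ddof=1)


@dataclass
class CoexpressionEdge:
    pair: tuple[str, str]
    partial_corr: float
    p: float
    n_samples: int
    conditioned: bool  # True when an overlap summary was partialled out


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pcxn_edge(
    expr: pd.DataFrame,
    set_a: Iterable[str],
    set_b: Iterable[str],
    name_a: str = "a",
    name_b: str = "b",
) -> CoexpressionEdge:
    """Overlap-corrected co-expression between two pathways.

    Disjoint pathways: Pearson correlation of the two summary statistics.
    Overlapping pathways: first-order partial correlation between the
    summaries of A\\B and B\\A given the summary of A∩B,

        r_xy·z = (r_xy − r_xz·r_yz) / sqrt((1 − r_xz²)(1 − r_yz²)),

    with the p-value from the t distribution on n − 3 degrees of freedom.
    """
    A, B = frozenset(set_a), frozenset(set_b)
    shared = A & B
    a_only = [g for g in A - B if g in expr.index]
    b_only = [g for g in B - A if g in expr.index]
    if len(a_only) < 2 or len(b_only) < 2:
        raise ValueError(
            f"pair ({name_a}, {name_b}): fewer than two disjoint genes present "
            f"on one side"
        )
    shared_present = [g for g in shared if g in expr.index]
    n = expr.shape[1]

    if not shared_present:
        sa = pathway_summary(expr, A)
        sb = pathway_summary(expr, B)
        r, p = _pearson_with_p(sa.to_numpy(), sb.to_numpy())
        return CoexpressionEdge((name_a, name_b), r, p, n, conditioned=False)

    x = pathway_summary(expr, a_only).to_numpy()
    y = pathway_summary(expr, b_only).to_numpy()
    if len(shared_present) == 1:
        z = _single_gene_z(expr, shared_present[0]).to_numpy()
    else:
        z = pathway_summary(expr, shared_present).to_numpy()

    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    denom = math.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if denom == 0:
        raise ValueError(
            f"pair ({name_a}, {name_b}): degenerate conditioning summary"
        )
    r = float((r_xy - r_xz * r_yz) / denom)
    r = max(-1.0, min(1.0, r))
    df = n - 3
    if df <= 0:
        raise ValueError("need more than three samples for a partial correlation")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CoexpressionEdge((name_a, name_b), r, p, n, conditioned=True)


def coexpression_network(
    expr: pd.DataFrame,
    gene_sets: GeneSetCollection,
    rank_table: pd.DataFrame,
    top_k: int = 30,
    alpha: float = 0.05,
    ad_word_scores: Mapping[str, float] | None = None,
    fdr_scope: str = "all",
) -> Network:
    """Co-expression network over the same node selection as the overlap
    network (top ``top_k`` by rank among eligible sets, restricted to
    pathways with enough genes measured in the expression matrix).

    Every computable pathway pair is scored with :func:`pcxn_edge` and
    BH-adjusted (globally by default); edges are node pairs with q < alpha,
    weighted by |partial correlation|.
    """
    eligible = [
        name
        for name in gene_sets.eligible()
        if sum(g in expr.index for g in gene_sets[name]) >= 4
    ]
    nodes = _select_top_nodes(rank_table, eligible, top_k)
    node_ids = list(nodes["pathway_id"])

    pairs = (
        list(combinations(eligible, 2))
        if fdr_scope == "all"
        else list(combinations(sorted(node_ids), 2))
    )
    rows = []
    for a, b in pairs:
        try:
            edge = pcxn_edge(expr, gene_sets[a], gene_sets[b], a, b)
        except ValueError:
            continue
        rows.append((a, b, edge.partial_corr, edge.p, edge.conditioned))
    pair_df = pd.DataFrame(rows, columns=["a", "b", "partial_corr", "p", "conditioned"])
    pair_df["q"] = bh_fdr(pair_df["p"].values) if len(pair_df) else []

    in_nodes = pair_df["a"].isin(node_ids) & pair_df["b"].isin(node_ids)
    edges = pair_df[in_nodes & (pair_df["q"] < alpha)].copy()
    edges["weight"] = edges["partial_corr"].abs()
    edges = edges.sort_values(["a", "b"], kind="mergesort").reset_index(drop=True)

    nodes = nodes[["pathway_id", "study_count", "rank"]].copy()
    scores = ad_word_scores or {}
    nodes["ad_word_score"] = [scores.get(p, np.nan) for p in nodes["pathway_id"]]
    return Network(
        nodes=nodes,
        edges=edges,
        kind="coexpression",
        metadata={
            "top_k": top_k,
            "alpha": alpha,
            "fdr_scope": fdr_scope,
            "n_pairs_tested": len(pair_df),
            "statistic": "simplified PCxN partial correlation",
        },
    )
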
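"""Thresholded correlation networks, centralities, and hub identification.

Edges follow the rule E_ij = r_ij^2 when the correlation's two-sided
p-value is <= alpha (default 0.05) and 0 otherwise; retained-edge p-values
are raw (unadjusted).  Path-based centralities use edge lengths 1/w.
Conventions (weighted strength for degree, Wasserman-Faust closeness,
unnormalized Brandes betweenness, max-normalized eigenvector on the
largest component) are recorded in output headers by the CLI.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .exprio import ExpressionMatrix
from .matequiv import CorrMatrix, pearson_corr, spearman_corr

__all__ = [
    "GeneNetwork",
    "CentralityRecord",
    "build_network",
    "centralities",
    "consensus_hub",
    "centrality_correlation",
    "count_significant_pairs",
    "differential_correlation",
    "strong_edges",
    "tail_quantile",
    "count_known_edges",
]

METRICS = ("degree", "closeness", "betweenness", "eigenvector")


@dataclass
class GeneNetwork:
    """Weighted undirected gene graph with edge-retention provenance."""

    graph: nx.Graph
    alpha: float
    corr: CorrMatrix

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class CentralityRecord:
    gene: str
    degree: float
    closeness: float
    betweenness: float
    eigenvector: float

    def get(self, metric: str) -> float:
        return getattr(self, metric)


def build_network(
    matrix: ExpressionMatrix, alpha: float = 0.05, corr: str = "spearman"
) -> GeneNetwork:
    """Build the thresholded correlation network of a cohort.

    An edge (i, j) is present iff the two-sided correlation p-value is
    <= ``alpha``; its weight is r_ij^2.  Isolated genes stay in the node
    set.
    """
    if matrix.n_samples < 4:
        raise ValueError(f"need >= 4 samples, got {matrix.n_samples}")
    R, P = (spearman_corr if corr == "spearman" else pearson_corr)(matrix)
    G = nx.Graph()
    G.add_nodes_from(matrix.gene_ids)
    n = len(matrix.gene_ids)
    iu, ju = np.triu_indices(n, k=1)
    keep = (P[iu, ju] <= alpha) & (R.values[iu, ju] != 0)
    for i, j in zip(iu[keep], ju[keep]):
        r = R.values[i, j]
        G.add_edge(
            matrix.gene_ids[i], matrix.gene_ids[j],
            weight=r * r, r=r, p=P[i, j], distance=1.0 / (r * r),
        )
    return GeneNetwork(graph=G, alpha=alpha, corr=R)


def centralities(network: GeneNetwork) -> list[CentralityRecord]:
    """Degree (strength), closeness, betweenness, and eigenvector scores.

    Closeness uses the Wasserman-Faust within-component correction
    (reachable-1)^2 / ((n-1) * sum of distances); betweenness is
    unnormalized shortest-path betweenness on 1/weight lengths;
    eigenvector is the principal eigenvector of the weight matrix on the
    largest connected component, max-normalized, zero elsewhere.
    """
    G = network.graph
    if G.number_of_nodes() < 1:
        raise ValueError("network has no nodes")
    nodes = list(G.nodes)
    if G.number_of_edges() == 0:
        warnings.warn("network has no edges; all centralities are 0", stacklevel=2)
        return [CentralityRecord(v, 0.0, 0.0, 0.0, 0.0) for v in nodes]

    degree = dict(G.degree(weight="weight"))
    closeness = nx.closeness_centrality(G, distance="distance", wf_improved=True)
    betweenness = nx.betweenness_centrality(G, weight="distance", normalized=False)

    eigen = {v: 0.0 for v in nodes}
    components = sorted(nx.connected_components(G), key=len, reverse=True)
    comp = sorted(components[0])
    if len(comp) > 1:
        A = nx.to_numpy_array(G, nodelist=comp, weight="weight")
        lam, vec = np.linalg.eigh(A)
        principal = np.abs(vec[:, np.argmax(lam)])
        principal /= principal.max()
        for v, score in zip(comp, principal):
            eigen[v] = float(score)
    return [
        CentralityRecord(
            gene=v,
            degree=float(degree[v]),
            closeness=float(closeness[v]),
            betweenness=float(betweenness[v]),
            eigenvector=eigen[v],
        )
        for v in nodes
    ]


def consensus_hub(records: list[CentralityRecord]) -> tuple[list[str], dict[str, list[str]]]:
    """Top gene(s) per metric plus the consensus (modal) hub gene(s).

    Each metric votes for every gene tied at its maximum; the consensus
    is the mode of the votes, with all modal genes reported on ties.
    """
    if not records:
        raise ValueError("no centrality records")
    per_metric: dict[str, list[str]] = {}
    votes: Counter[str] = Counter()
    for metric in METRICS:
        best = max(r.get(metric) for r in records)
        top = [r.gene for r in records if r.get(metric) == best]
        per_metric[metric] = top
        for gene in top:
            votes[gene] += 1
    most = max(votes.values())
    consensus = sorted(g for g, c in votes.items() if c == most)
    return consensus, per_metric


def centrality_correlation(
    records_a: list[CentralityRecord], records_b: list[CentralityRecord]
) -> dict[str, float]:
    """Per-metric Pearson correlation of centralities across shared genes.

    A metric that is constant in either group is reported as NaN and
    excluded from the ``average`` (with a warning).
    """
    a = {r.gene: r for r in records_a}
    b = {r.gene: r for r in records_b}
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    out: dict[str, float] = {}
    defined: list[float] = []
    for metric in METRICS:
        x = np.array([a[g].get(metric) for g in shared])
        y = np.array([b[g].get(metric) for g in shared])
        if x.std() == 0 or y.std() == 0:
            warnings.warn(
                f"metric {metric!r} constant in a group; excluded from average",
                stacklevel=2,
            )
            out[metric] = float("nan")
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        out[metric] = r
        defined.append(r)
    out["average"] = float(np.mean(defined)) if defined else float("nan")
    return out


def count_significant_pairs(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    gene_subset: list[str] | None = None,
    alpha: float = 0.05,
    corr: str = "spearman",
) -> dict[str, float]:
    """Count per-group Bonferroni-significant correlation pairs.

    The pair universe is all unordered gene pairs, or — when
    ``gene_subset`` is given — pairs of one subset gene with any other
    gene.  Both cohorts must share the gene universe.  Returns counts per
    group, the intersection count, the universe size, and percentages.
    """
    if expr_a.gene_ids != expr_b.gene_ids:
        raise ValueError("gene universes differ between the two cohorts")
    genes = expr_a.gene_ids
    n = len(genes)
    _, Pa = (spearman_corr if corr == "spearman" else pearson_corr)(expr_a)
    _, Pb = (spearman_corr if corr == "spearman" else pearson_corr)(expr_b)

    iu, ju = np.triu_indices(n, k=1)
    if gene_subset is not None:
        in_subset = np.isin(np.array(genes), np.array(list(gene_subset)))
        keep = in_subset[iu] | in_subset[ju]
        iu, ju = iu[keep], ju[keep]
    n_pairs = iu.size
    if n_pairs == 0:
        raise ValueError("empty pair universe")
    threshold = alpha / n_pairs
    sig_a = Pa[iu, ju] <= threshold
    sig_b = Pb[iu, ju] <= threshold
    count_a = int(sig_a.sum())
    count_b = int(sig_b.sum())
    shared = int((sig_a & sig_b).sum())
    return {
        "count_a": count_a,
        "count_b": count_b,
        "count_shared": shared,
        "n_pairs": n_pairs,
        "pct_a": 100.0 * count_a / n_pairs,
        "pct_b": 100.0 * count_b / n_pairs,
        "pct_shared": 100.0 * shared / n_pairs,
    }


def differential_correlation(
    R1: CorrMatrix, R2: CorrMatrix, n1: int | None = None, n2: int | None = None
) -> list[dict]:
    """Per-pair correlation difference with its Fisher-z statistic and p.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p-value.
    """
    if R1.gene_ids != R2.gene_ids:
        raise ValueError("gene sets must match")
    n1 = n1 if n1 is not None else R1.n_samples
    n2 = n2 if n2 is not None else R2.n_samples
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both groups need more than 3 samples")
    G = R1.n_genes
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    rows = []
    for i in range(G):
        for j in range(i + 1, G):
            r1, r2 = R1.values[i, j], R2.values[i, j]
            if abs(r1) >= 1.0 or abs(r2) >= 1.0:
                raise ValueError(
                    f"|r| = 1 for pair ({R1.gene_ids[i]}, {R1.gene_ids[j]})"
                )
            z = (np.arctanh(r1) - np.arctanh(r2)) / se
            rows.append(
                {
                    "gene_i": R1.gene_ids[i],
                    "gene_j": R1.gene_ids[j],
                    "r1": float(r1),
                    "r2": float(r2),
                    "delta_r": float(r1 - r2),
                    "z": float(z),
                    "p": float(2.0 * stats.norm.sf(abs(z))),
                }
            )
    return rows


def strong_edges(R: CorrMatrix, threshold: float = 0.7) -> list[tuple[str, str, float]]:
    """Gene pairs with |r| strictly above ``threshold``."""
    G = R.n_genes
    out = []
    for i in range(G):
        for j in range(i + 1, G):
            r = R.values[i, j]
            if abs(r) > threshold:
                out.append((R.gene_ids[i], R.gene_ids[j], float(r)))
    return out


def tail_quantile(values, q: float = 0.95) -> float:
    """Linear-interpolation quantile of a coefficient collection.

    Accepts a flat array or a :class:`CorrMatrix` (in which case the
    off-diagonal upper-triangle coefficients are used).
    """
    if isinstance(values, CorrMatrix):
        iu = np.triu_indices(values.n_genes, k=1)
        values = values.values[iu]
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values")
    return float(np.quantile(arr, q, method="linear"))


def count_known_edges(
    pairs: list[tuple], interaction_pairs: list[tuple]
) -> tuple[int, int]:
    """How many of ``pairs`` appear (order-insensitively) in a known-edge table."""
    known = {frozenset((str(a), str(b))) for a, b, *_ in interaction_pairs}
    n_total = len(pairs)
    n_known = sum(
        1 for a, b, *_ in pairs if frozenset((str(a), str(b))) in known
    )
    return n_known, n_total
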
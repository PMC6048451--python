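"""Co-expression module detection and cross-group module comparison.

Modules are found WGCNA-style: soft-threshold adjacency a_ij = |r_ij|^beta
(unsigned, Spearman), topological-overlap similarity

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with TOM_ii = 1, then average-linkage hierarchical clustering on 1 - TOM
cut into exactly k clusters.  Module labels 1..k are assigned by
decreasing module size (ties by first member gene) so the partition is
deterministic and invariant to gene/sample order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohortsig import EquivTestResult, empirical_pvalue
from .exprio import ExpressionMatrix
from .matequiv import permutation_equivalence_test, spearman_corr

__all__ = [
    "ModulePartition",
    "tom_similarity",
    "detect_modules",
    "match_modules",
    "overlap_permutation_null",
    "module_rewiring_test",
]


@dataclass
class ModulePartition:
    """Assignment of every gene to exactly one of k modules (labels 1..k)."""

    assignments: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        labels = set(self.assignments.values())
        if not labels:
            raise ValueError("empty partition")
        expected = set(range(1, self.k + 1))
        if labels != expected:
            raise ValueError(
                f"module labels must be exactly 1..{self.k}, got {sorted(labels)}"
            )

    @property
    def module_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {m: 0 for m in range(1, self.k + 1)}
        for m in self.assignments.values():
            sizes[m] += 1
        return sizes

    def members(self, module: int) -> list[str]:
        return [g for g, m in self.assignments.items() if m == module]


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological-overlap similarity of an adjacency with zero diagonal."""
    A = np.asarray(adjacency, dtype=float)
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    matrix: ExpressionMatrix, k: int, beta: float = 6.0
) -> ModulePartition:
    """Cut the average-linkage TOM dendrogram into exactly k modules."""
    if k < 2:
        raise ValueError("k must be >= 2")
    R, _ = spearman_corr(matrix)
    sd = matrix.values.std(axis=1)
    constant = [g for g, s in zip(matrix.gene_ids, sd) if s == 0]
    genes = [g for g in matrix.gene_ids if g not in set(constant)]
    if constant:
        warnings.warn(
            f"{len(constant)} constant gene(s) excluded from module detection",
            stacklevel=2,
        )
    if len(genes) < k:
        raise ValueError(f"only {len(genes)} usable genes for k={k} modules")
    # order genes canonically so the cut is independent of input order
    order = sorted(range(len(matrix.gene_ids)), key=lambda i: matrix.gene_ids[i])
    order = [i for i in order if matrix.gene_ids[i] not in set(constant)]
    names = [matrix.gene_ids[i] for i in order]
    sub = R.values[np.ix_(order, order)]
    A = np.abs(sub) ** beta
    tom = tom_similarity(A)
    dist = 1.0 - tom
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    if len(set(raw)) != k:
        raise ValueError(f"could not cut the dendrogram into exactly {k} modules")
    # relabel 1..k by decreasing size, ties by first gene name in the module
    groups: dict[int, list[str]] = {}
    for g, lab in zip(names, raw):
        groups.setdefault(int(lab), []).append(g)
    ranked = sorted(groups.values(), key=lambda gs: (-len(gs), min(gs)))
    assignments = {g: m for m, gs in enumerate(ranked, start=1) for g in gs}
    return ModulePartition(assignments=assignments, k=k)


def match_modules(
    partition_ref: ModulePartition, partition_other: ModulePartition
) -> list[dict]:
    """Best-overlap match of every reference module in the other partition.

    Ties on overlap size go to the lower other-module label.
    """
    shared = set(partition_ref.assignments) & set(partition_other.assignments)
    if not shared:
        raise ValueError("partitions have disjoint gene universes")
    out = []
    for m in range(1, partition_ref.k + 1):
        ref_genes = {g for g in partition_ref.members(m) if g in shared}
        best_label, best_overlap, best_genes = None, -1, set()
        for other in range(1, partition_other.k + 1):
            other_genes = {
                g for g in partition_other.members(other) if g in shared
            }
            inter = ref_genes & other_genes
            if len(inter) > best_overlap:
                best_label, best_overlap, best_genes = other, len(inter), inter
        out.append(
            {
                "ref_module": m,
                "ref_size": len(ref_genes),
                "matched_module": best_label,
                "matched_size": len(set(partition_other.members(best_label)) & shared),
                "overlap": best_overlap,
                "intersection": sorted(best_genes),
            }
        )
    return out


def overlap_permutation_null(
    partition_ref: ModulePartition,
    partition_other: ModulePartition,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> list[dict]:
    """Permutation null of per-module best overlaps.

    The other partition's gene labels are permuted ``n_permutations``
    times; for each reference module the maximum overlap against any
    permuted module is recorded.  Returns, per reference module, the
    observed overlap, the empirical p-value, and the null distribution
    (the data behind overlap beanplots).
    """
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    shared = sorted(set(partition_ref.assignments) & set(partition_other.assignments))
    if not shared:
        raise ValueError("partitions have disjoint gene universes")
    observed = {row["ref_module"]: row["overlap"] for row in match_modules(partition_ref, partition_other)}

    other_labels = np.array([partition_other.assignments[g] for g in shared])
    ref_members = {
        m: np.array([i for i, g in enumerate(shared) if partition_ref.assignments[g] == m])
        for m in range(1, partition_ref.k + 1)
    }
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    nulls = {m: np.empty(n_permutations) for m in ref_members}
    n_other = partition_other.k
    for b in range(n_permutations):
        perm = rng.permutation(other_labels)
        for m, idx in ref_members.items():
            if idx.size == 0:
                nulls[m][b] = 0
                continue
            counts = np.bincount(perm[idx], minlength=n_other + 1)
            nulls[m][b] = counts[1:].max()
    out = []
    for m in sorted(ref_members):
        out.append(
            {
                "ref_module": m,
                "observed_overlap": observed[m],
                "p_value": empirical_pvalue(observed[m], nulls[m]),
                "null_overlaps": nulls[m],
            }
        )
    return out


def module_rewiring_test(
    matrix: ExpressionMatrix,
    labels,
    genes: list[str],
    n_permutations: int = 1000,
    seed: int | None = None,
) -> EquivTestResult | None:
    """Steiger permutation test of rewiring on an intersection gene set.

    Returns ``None`` (reported as NA) when fewer than 3 genes intersect
    the matrix; otherwise delegates to the label-permutation Steiger test.
    """
    present = [g for g in genes if g in set(matrix.gene_ids)]
    if len(present) < 3:
        return None
    sub = matrix.select_genes(present)
    return permutation_equivalence_test(
        sub, labels, method="steiger", n_permutations=n_permutations, seed=seed
    )
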
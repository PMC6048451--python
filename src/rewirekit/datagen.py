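"""Synthetic cohort generation with planted network rewiring.

Cohorts carry a *rewiring-only* signal: every group shares one mean
vector while correlation matrices differ per group.  Marginals are
Gaussian by default; a finite ``noise_df`` switches to variance-scaled
multivariate-t marginals to stress rank-based downstream statistics.

All randomness flows through :class:`numpy.random.Generator` (PCG64)
seeded from ``numpy.random.SeedSequence``; identical seeds reproduce
cohorts bit-for-bit across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exprio import ExpressionMatrix

__all__ = [
    "RewiringSpec",
    "HubSpec",
    "block_corr",
    "hub_corr",
    "random_psd_corr",
    "nearest_psd_corr",
    "validate_corr",
    "generate_rewired_cohort",
    "generate_hub_cohort",
    "generate_mutation_labels",
]

_EIG_TOL = -1e-10


def validate_corr(matrix: np.ndarray, name: str = "corr") -> np.ndarray:
    """Validate a correlation matrix: symmetric, unit diagonal, PSD.

    Eigenvalues below -1e-10 are rejected (reporting the offending
    eigenvalue); tiny negative eigenvalues within tolerance are accepted.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(M), 1.0, atol=1e-10):
        raise ValueError(f"{name} must have a unit diagonal")
    lam_min = float(np.linalg.eigvalsh(M).min())
    if lam_min < _EIG_TOL:
        raise ValueError(
            f"{name} is not positive semi-definite "
            f"(smallest eigenvalue {lam_min:.3e})"
        )
    return M


def nearest_psd_corr(matrix: np.ndarray) -> np.ndarray:
    """Repair a slightly indefinite correlation matrix.

    Eigenvalues are clipped at 0 and the result rescaled back to a unit
    diagonal.  Emits a warning when a repair was actually needed.
    """
    M = np.asarray(matrix, dtype=float)
    M = (M + M.T) / 2.0
    lam, V = np.linalg.eigh(M)
    if lam.min() >= 0:
        return M
    warnings.warn(
        f"repairing indefinite correlation matrix "
        f"(smallest eigenvalue {lam.min():.3e})",
        stacklevel=2,
    )
    lam = np.clip(lam, 0.0, None)
    M = (V * lam) @ V.T
    d = np.sqrt(np.diag(M))
    d[d == 0] = 1.0
    M = M / np.outer(d, d)
    np.fill_diagonal(M, 1.0)
    return M


def block_corr(n_genes: int, block: slice | list[int], r: float, background_r: float = 0.0) -> np.ndarray:
    """Exchangeable-block correlation: ``r`` inside ``block``, background elsewhere."""
    M = np.full((n_genes, n_genes), background_r)
    idx = np.arange(n_genes)[block] if isinstance(block, slice) else np.asarray(block)
    M[np.ix_(idx, idx)] = r
    np.fill_diagonal(M, 1.0)
    return validate_corr(M, "block correlation")


def hub_corr(n_spokes: int, r_hub: float, background_r: float = 0.0) -> np.ndarray:
    """Hub-and-spoke correlation: gene 0 is the hub, genes 1..n are spokes.

    Built from the factor model spoke_i = r_hub * hub + sqrt(1 - r_hub^2)
    * e_i with the residuals e_i equicorrelated at ``background_r``, so
    the implied spoke-spoke correlation is r_hub^2 + (1 - r_hub^2) *
    background_r.  (A literal hub matrix with independent spokes is not
    PSD once r_hub^2 > 1/n_spokes.)
    """
    G = n_spokes + 1
    spoke_spoke = r_hub * r_hub + (1.0 - r_hub * r_hub) * background_r
    M = np.full((G, G), spoke_spoke)
    M[0, :] = r_hub
    M[:, 0] = r_hub
    np.fill_diagonal(M, 1.0)
    return validate_corr(M, "hub correlation")


def random_psd_corr(n_genes: int, rng: np.random.Generator, strength: float = 1.0) -> np.ndarray:
    """Random correlation matrix via random orthogonal mixing of eigenvalues."""
    A = rng.standard_normal((n_genes, n_genes))
    Q, _ = np.linalg.qr(A)
    lam = rng.uniform(1.0 - strength * 0.9, 1.0 + strength, size=n_genes)
    lam *= n_genes / lam.sum()
    M = (Q * lam) @ Q.T
    d = np.sqrt(np.diag(M))
    M = M / np.outer(d, d)
    np.fill_diagonal(M, 1.0)
    return validate_corr(M, "random correlation")


@dataclass
class RewiringSpec:
    """Specification of a multi-group cohort with planted rewiring."""

    n_genes: int
    group_sizes: list[int]
    corr_matrices: list[np.ndarray]
    mean_vector: np.ndarray | None = None     # shared across groups
    variances: np.ndarray | None = None       # per-gene, default 1
    noise_df: float = np.inf                  # inf = Gaussian marginals
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.group_sizes) != len(self.corr_matrices):
            raise ValueError("one correlation matrix required per group")
        for g, size in enumerate(self.group_sizes):
            if size < 2:
                raise ValueError(
                    f"group {g} has {size} samples; need >= 2 for correlations"
                )
        self.corr_matrices = [
            validate_corr(np.asarray(C, float), f"corr_matrices[{g}]")
            for g, C in enumerate(self.corr_matrices)
        ]
        for g, C in enumerate(self.corr_matrices):
            if C.shape[0] != self.n_genes:
                raise ValueError(f"corr_matrices[{g}] must be {self.n_genes} x {self.n_genes}")
        if self.mean_vector is None:
            self.mean_vector = np.zeros(self.n_genes)
        self.mean_vector = np.asarray(self.mean_vector, float)
        if self.mean_vector.shape != (self.n_genes,):
            raise ValueError("mean_vector must have one entry per gene")
        if self.variances is not None:
            self.variances = np.asarray(self.variances, float)
            if self.variances.shape != (self.n_genes,) or (self.variances <= 0).any():
                raise ValueError("variances must be positive, one per gene")
        if not (self.noise_df > 0):
            raise ValueError("noise_df must be positive (np.inf for Gaussian)")


@dataclass
class HubSpec:
    """One hub gene correlated at ``r_hub`` with its spokes."""

    hub_gene: str
    spoke_genes: list[str] = field(default_factory=list)
    r_hub: float = 0.5
    background_r: float = 0.0

    def __post_init__(self) -> None:
        if not self.spoke_genes:
            raise ValueError("need at least one spoke gene")
        if not (0.0 <= self.r_hub < 1.0):
            raise ValueError(
                "r_hub must lie in [0, 1); r_hub = 1 duplicates the hub "
                "exactly (degenerate correlation)"
            )
        if not (0.0 <= self.background_r < 1.0):
            raise ValueError("background_r must lie in [0, 1)")

    def corr_matrix(self) -> np.ndarray:
        return hub_corr(len(self.spoke_genes), self.r_hub, self.background_r)


def _corr_factor(C: np.ndarray) -> np.ndarray:
    lam, V = np.linalg.eigh(C)
    lam = np.clip(lam, 0.0, None)
    return V * np.sqrt(lam)


def _draw_group(
    rng: np.random.Generator,
    n: int,
    factor: np.ndarray,
    mean: np.ndarray,
    sd: np.ndarray,
    noise_df: float,
) -> np.ndarray:
    """(genes, n) draws with the requested correlation and marginals."""
    z = factor @ rng.standard_normal((factor.shape[1], n))
    if np.isfinite(noise_df):
        chi = rng.chisquare(noise_df, size=n)
        z = z / np.sqrt(chi / noise_df)
        if noise_df > 2:  # rescale t marginals back to unit variance
            z = z * np.sqrt((noise_df - 2.0) / noise_df)
    return mean[:, None] + sd[:, None] * z


def generate_rewired_cohort(spec: RewiringSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw a cohort with equal group means and per-group correlations.

    Returns the genes x samples matrix and an integer group label per
    sample (0-based, samples ordered by group).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    sd = np.sqrt(spec.variances) if spec.variances is not None else np.ones(spec.n_genes)
    blocks = []
    labels = []
    for g, (size, C) in enumerate(zip(spec.group_sizes, spec.corr_matrices)):
        blocks.append(
            _draw_group(rng, size, _corr_factor(C), spec.mean_vector, sd, spec.noise_df)
        )
        labels.extend([g] * size)
    values = np.hstack(blocks)
    gene_ids = [f"g{i + 1:04d}" for i in range(spec.n_genes)]
    sample_ids = [f"s{j + 1:04d}" for j in range(values.shape[1])]
    return ExpressionMatrix(gene_ids, sample_ids, values), np.asarray(labels)


def generate_hub_cohort(spec: HubSpec, n_samples: int, seed: int | None = None) -> ExpressionMatrix:
    """Draw a cohort whose first gene is a planted correlation hub."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    C = spec.corr_matrix()  # PSD-validated
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    G = C.shape[0]
    values = _draw_group(rng, n_samples, _corr_factor(C), np.zeros(G), np.ones(G), np.inf)
    gene_ids = [spec.hub_gene] + list(spec.spoke_genes)
    sample_ids = [f"s{j + 1:04d}" for j in range(n_samples)]
    return ExpressionMatrix(gene_ids, sample_ids, values)


def generate_mutation_labels(
    cluster_labels,
    odds_ratio: float,
    seed: int | None = None,
    base_rate: float = 0.5,
) -> np.ndarray:
    """Binary mutation labels with a chosen cluster association.

    The reference cluster (smallest label) carries P(1) = ``base_rate``;
    every other cluster's success log-odds are shifted by ln(odds_ratio).
    ``odds_ratio = 1`` makes labels independent of clusters.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    if not (0.0 < base_rate < 1.0):
        raise ValueError("base_rate must lie in (0, 1)")
    clusters = np.asarray(cluster_labels)
    uniq = np.unique(clusters)
    if uniq.size == 1:
        warnings.warn(
            "single cluster present; labels drawn from the base rate",
            stacklevel=2,
        )
    logit = np.log(base_rate / (1.0 - base_rate))
    shifted = logit + np.where(clusters == uniq[0], 0.0, np.log(odds_ratio))
    prob = 1.0 / (1.0 + np.exp(-shifted))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return (rng.uniform(size=clusters.size) < prob).astype(int)
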
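"""Correlation-matrix equivalence tests between two sample groups.

Two chi-square statistics are provided:

* Steiger: sum over gene pairs of squared Fisher-z differences, scaled by
  the pooled z variance 1/(n1-3) + 1/(n2-3); df = G(G-1)/2.
* Jennrich: with Rbar the sample-size-weighted average correlation matrix,
  c = n1*n2/(n1+n2) and Z = sqrt(c) * Rbar^{-1} (R1 - R2),
  chi2 = tr(Z^2)/2 - diag(Z)' S^{-1} diag(Z), S = I + Rbar * Rbar^{-1}
  (elementwise product); df = G(G-1)/2.

Significance can also be assessed by label permutations preserving group
sizes, with the (count+1)/(N+1) empirical p-value convention.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exprio import ExpressionMatrix

__all__ = [
    "CorrMatrix",
    "spearman_corr",
    "pearson_corr",
    "steiger_test",
    "jennrich_test",
    "permutation_equivalence_test",
]


@dataclass
class CorrMatrix:
    """A G x G correlation matrix with provenance."""

    gene_ids: list[str]
    values: np.ndarray
    n_samples: int
    method: str = "spearman"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        G = len(self.gene_ids)
        if self.values.shape != (G, G):
            raise ValueError("correlation matrix shape must match gene_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.nanmax(np.abs(self.values)) > 1.0 + 1e-10:
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _rank_rows(values: np.ndarray) -> np.ndarray:
    # average ranks along samples, per gene
    return stats.rankdata(values, axis=1)


def _corr_of_rows(rows: np.ndarray) -> np.ndarray:
    """Pearson correlation of rows, with zero-variance rows set to r=0."""
    sd = rows.std(axis=1)
    constant = sd == 0
    centered = rows - rows.mean(axis=1, keepdims=True)
    denom = np.where(constant, 1.0, sd * rows.shape[1])
    normed = centered / denom[:, None]
    R = normed @ normed.T * rows.shape[1]
    R = np.clip(R, -1.0, 1.0)
    R[constant, :] = 0.0
    R[:, constant] = 0.0
    np.fill_diagonal(R, 1.0)
    return R


def _corr_pvalues(R: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t approximation t = r*sqrt((n-2)/(1-r^2))."""
    r = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.minimum(p, 1.0)
    np.fill_diagonal(p, 0.0)
    return p


def spearman_corr(matrix: ExpressionMatrix) -> tuple[CorrMatrix, np.ndarray]:
    """Spearman correlation matrix over genes plus its p-value matrix.

    Ties receive average ranks.  Constant genes (zero rank variance) get
    correlation 0 against everything and are flagged with a warning.
    The diagonal p-value is set to 0.
    """
    n = matrix.n_samples
    if n < 4:
        raise ValueError(f"need >= 4 samples for correlation, got {n}")
    ranks = _rank_rows(matrix.values)
    sd = ranks.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [matrix.gene_ids[i] for i in constant[:10]]
        warnings.warn(
            f"{constant.size} constant gene(s) set to r=0: {names}", stacklevel=2
        )
    R = _corr_of_rows(ranks)
    p = _corr_pvalues(R, n)
    return CorrMatrix(list(matrix.gene_ids), R, n, "spearman"), p


def pearson_corr(matrix: ExpressionMatrix) -> tuple[CorrMatrix, np.ndarray]:
    """Pearson analogue of :func:`spearman_corr` (used for Gaussian calibration)."""
    n = matrix.n_samples
    if n < 4:
        raise ValueError(f"need >= 4 samples for correlation, got {n}")
    R = _corr_of_rows(matrix.values)
    p = _corr_pvalues(R, n)
    return CorrMatrix(list(matrix.gene_ids), R, n, "pearson"), p


def _check_pair(R1: CorrMatrix, R2: CorrMatrix) -> int:
    if R1.gene_ids != R2.gene_ids:
        raise ValueError("correlation matrices must share gene sets and order")
    return R1.n_genes


def _offdiag_perfect(R: CorrMatrix) -> tuple[int, int] | None:
    A = np.abs(R.values.copy())
    np.fill_diagonal(A, 0.0)
    idx = np.argwhere(A >= 1.0)
    return tuple(idx[0]) if idx.size else None


def steiger_test(R1: CorrMatrix, R2: CorrMatrix):
    """Steiger chi-square for equality of two correlation matrices."""
    from .cohortsig import EquivTestResult  # local import to avoid a cycle

    G = _check_pair(R1, R2)
    n1, n2 = R1.n_samples, R2.n_samples
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both groups need more than 3 samples")
    for R in (R1, R2):
        bad = _offdiag_perfect(R)
        if bad is not None:
            i, j = bad
            raise ValueError(
                f"|r| = 1 between {R.gene_ids[i]} and {R.gene_ids[j]}: "
                "Fisher z diverges"
            )
    iu = np.triu_indices(G, k=1)
    z1 = np.arctanh(R1.values[iu])
    z2 = np.arctanh(R2.values[iu])
    var = 1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    chi2 = float(np.sum((z1 - z2) ** 2) / var)
    df = G * (G - 1) // 2
    return EquivTestResult(
        statistic_name="steiger_chisq",
        statistic=chi2,
        df=df,
        p_asymptotic=float(stats.chi2.sf(chi2, df)),
    )


def jennrich_test(R1: CorrMatrix, R2: CorrMatrix, shrinkage: float | None = None):
    """Jennrich chi-square for equality of two correlation matrices.

    ``shrinkage`` (lambda in [0,1)) blends the pooled matrix toward the
    identity, Rbar <- (1-lambda)*Rbar + lambda*I, allowing the test to run
    when Rbar is singular (n <= G); the result is then approximate.
    """
    from .cohortsig import EquivTestResult

    G = _check_pair(R1, R2)
    n1, n2 = R1.n_samples, R2.n_samples
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both groups need more than 3 samples")
    rbar = (n1 * R1.values + n2 * R2.values) / (n1 + n2)
    if shrinkage:
        if not 0.0 <= shrinkage < 1.0:
            raise ValueError("shrinkage must be in [0, 1)")
        rbar = (1.0 - shrinkage) * rbar + shrinkage * np.eye(G)
    try:
        rbar_inv = np.linalg.inv(rbar)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled correlation matrix is singular; enable shrinkage or use "
            "the Steiger test"
        ) from exc
    cond = np.linalg.cond(rbar)
    if cond > 1e12:
        raise ValueError(
            f"pooled correlation matrix is near-singular (cond={cond:.2e}); "
            "enable shrinkage or use the Steiger test"
        )
    c = n1 * n2 / (n1 + n2)
    Z = np.sqrt(c) * rbar_inv @ (R1.values - R2.values)
    S = np.eye(G) + rbar * rbar_inv
    dz = np.diag(Z)
    chi2 = float(0.5 * np.trace(Z @ Z) - dz @ np.linalg.solve(S, dz))
    df = G * (G - 1) // 2
    return EquivTestResult(
        statistic_name="jennrich_chisq",
        statistic=chi2,
        df=df,
        p_asymptotic=float(stats.chi2.sf(chi2, df)),
    )


_METHODS = {
    "steiger": lambda Ra, Rb, kw: steiger_test(Ra, Rb),
    "jennrich": lambda Ra, Rb, kw: jennrich_test(Ra, Rb, shrinkage=kw.get("shrinkage")),
}


def _group_stat(values, gene_ids, idx_a, idx_b, method, corr, kwargs) -> float:
    def corrmat(idx):
        sub = values[:, idx]
        rows = _rank_rows(sub) if corr == "spearman" else sub
        return CorrMatrix(gene_ids, _corr_of_rows(rows), len(idx), corr)

    return _METHODS[method](corrmat(idx_a), corrmat(idx_b), kwargs).statistic


def permutation_equivalence_test(
    matrix: ExpressionMatrix,
    labels,
    method: str = "steiger",
    n_permutations: int = 10_000,
    seed: int | None = None,
    corr: str = "spearman",
    exhaustive: bool = False,
    **kwargs,
):
    """Label-permutation test of correlation-matrix equality between 2 groups.

    Permutations preserve class sizes.  With ``exhaustive=True`` every
    distinct assignment of samples to the two group sizes (other than the
    observed one) forms the null, making the p-value deterministic.
    """
    from .cohortsig import EquivTestResult, empirical_pvalue

    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 label classes, got {classes.size}")
    idx_a = np.flatnonzero(labels == classes[0])
    idx_b = np.flatnonzero(labels == classes[1])
    for cls, idx in zip(classes, (idx_a, idx_b)):
        if idx.size < 4:
            raise ValueError(f"label class {cls!r} has {idx.size} samples (< 4)")

    values = matrix.values
    gene_ids = list(matrix.gene_ids)
    observed = _group_stat(values, gene_ids, idx_a, idx_b, method, corr, kwargs)

    n = matrix.n_samples
    draws: list[float] = []
    if exhaustive:
        obs_set = frozenset(idx_a.tolist())
        for combo in itertools.combinations(range(n), idx_a.size):
            if frozenset(combo) == obs_set:
                continue
            a = np.array(combo)
            b = np.setdiff1d(np.arange(n), a)
            draws.append(_group_stat(values, gene_ids, a, b, method, corr, kwargs))
    else:
        rng = np.random.default_rng(seed)
        order = np.arange(n)
        for _ in range(n_permutations):
            perm = rng.permutation(order)
            a, b = perm[: idx_a.size], perm[idx_a.size :]
            draws.append(_group_stat(values, gene_ids, a, b, method, corr, kwargs))

    null = np.asarray(draws)
    asy = _METHODS[method](
        CorrMatrix(gene_ids, _corr_of_rows(
            _rank_rows(values[:, idx_a]) if corr == "spearman" else values[:, idx_a]
        ), idx_a.size, corr),
        CorrMatrix(gene_ids, _corr_of_rows(
            _rank_rows(values[:, idx_b]) if corr == "spearman" else values[:, idx_b]
        ), idx_b.size, corr),
        kwargs,
    )
    return EquivTestResult(
        statistic_name=asy.statistic_name,
        statistic=observed,
        df=asy.df,
        p_asymptotic=asy.p_asymptotic,
        p_simulated=empirical_pvalue(observed, null),
        n_null=null.size,
    )
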
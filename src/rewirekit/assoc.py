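"""Association of cluster membership with external binary factors.

Logistic regression is fitted by iteratively reweighted least squares
(max 100 iterations, tolerance 1e-10).  Complete separation is detected
via a diverging coefficient (|estimate| > 15) and flagged rather than
raised.  Multiple-testing control is Benjamini-Hochberg step-up FDR, and
QQ data pairs observed -log10 p with -log10((i - 0.5)/m) expectations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AssocResult", "cluster_association", "bh_fdr", "qq_data"]

_MAX_ITER = 100
_TOL = 1e-10
_SEPARATION_BOUND = 15.0


@dataclass
class AssocResult:
    predictor: str
    estimate: float
    std_error: float
    z_value: float
    p_value: float
    fdr_adjusted_p: float | None = None
    separation: bool = False


def _logistic_irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS fit; returns (beta, standard errors, separation flag)."""
    n, p = X.shape
    beta = np.zeros(p)
    separation = False
    for _ in range(_MAX_ITER):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        z = eta + (y - mu) / w
        XtW = X.T * w
        try:
            new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            separation = True
            break
        step = np.max(np.abs(new - beta))
        beta = new
        if np.max(np.abs(beta)) > _SEPARATION_BOUND:
            separation = True
            break
        if step < _TOL:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.inf)
        separation = True
    return beta, se, separation


def cluster_association(
    cluster_labels,
    predictors: dict[str, np.ndarray],
    joint: bool = True,
) -> list[AssocResult]:
    """Logistic regression of cluster membership on binary predictors.

    The outcome is membership in the higher-labelled of the two clusters.
    With ``joint=True`` all predictors enter one model (one coefficient
    each); otherwise each predictor is fitted alone.  Separation yields a
    flagged result with an infinite-estimate sentinel, not an exception.
    """
    y_raw = np.asarray(cluster_labels)
    uniq = np.unique(y_raw)
    if uniq.size != 2:
        raise ValueError(f"need exactly 2 clusters, got {uniq.size}")
    for cls in uniq:
        if (y_raw == cls).sum() < 2:
            raise ValueError(f"cluster {cls!r} has fewer than 2 samples")
    y = (y_raw == uniq[1]).astype(float)

    names = list(predictors)
    columns = {k: np.asarray(v, dtype=float) for k, v in predictors.items()}
    for k, v in columns.items():
        if v.shape != y.shape:
            raise ValueError(f"predictor {k!r} length mismatch")

    def fit(block: list[str]) -> list[AssocResult]:
        X = np.column_stack([np.ones_like(y)] + [columns[k] for k in block])
        beta, se, sep = _logistic_irls(X, y)
        out = []
        for i, k in enumerate(block, start=1):
            est, s = float(beta[i]), float(se[i])
            if sep and abs(est) >= _SEPARATION_BOUND:
                out.append(
                    AssocResult(k, np.inf if est > 0 else -np.inf, np.inf,
                                np.nan, np.nan, separation=True)
                )
                continue
            z = est / s if s > 0 else np.nan
            p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
            out.append(AssocResult(k, est, s, float(z), p, separation=sep))
        return out

    results = fit(names) if joint else [r for k in names for r in fit([k])]
    ps = np.array([r.p_value for r in results])
    if np.all(np.isfinite(ps)):
        adj = bh_fdr(ps)
        for r, a in zip(results, adj):
            r.fdr_adjusted_p = float(a)
    return results


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def qq_data(p_values) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) -log10 p-value quantiles for a QQ plot.

    expected_i = -log10((i - 0.5)/m), i = 1..m, paired with observed
    -log10 p sorted to match (smallest p against largest expectation).
    Zero p-values are clamped to the machine floor with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if (p == 0).any():
        warnings.warn("p = 0 clamped to the machine floor", stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.sort(p))
    return expected, observed
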
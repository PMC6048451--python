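"""Gaussian mixture clustering of samples on their expression profiles.

Samples are modelled as draws from a k-component mixture of diagonal
multivariate normals over genes.  Fitting is EM from seeded random
responsibilities, best-of-restarts by log-likelihood.  Model-selection
deltas against the single-group fit follow the usual conventions:

    delta_AIC = 2*delta_q - LLR
    delta_BIC = delta_q*ln(n) - LLR

with LLR = 2*(ll_k - ll_1) and delta_q the added parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exprio import ExpressionMatrix

__all__ = ["MixtureFit", "fit_mixture", "delta_criteria", "mixture_param_count"]

_VAR_FLOOR = 1e-6
_TOL = 1e-8
_MAX_ITER = 500

PARAMETERIZATIONS = ("diagonal_multivariate", "per_component_scalar")


@dataclass
class MixtureFit:
    """A fitted k-component diagonal Gaussian mixture over samples."""

    k: int
    weights: np.ndarray          # (k,)
    means: np.ndarray            # (k, G)
    variances: np.ndarray        # (k, G)
    log_likelihood: float
    posteriors: np.ndarray       # (n, k), rows sum to 1
    labels: np.ndarray           # (n,) argmax posterior, ties -> lower index
    n_params: int
    ll_trace: list[float] = field(default_factory=list)
    degenerate: bool = False
    converged: bool = True

    @property
    def component_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def _as_sample_matrix(data) -> np.ndarray:
    """Return an (n_samples, n_genes) float array from matrix-like input."""
    if isinstance(data, ExpressionMatrix):
        return data.values.T.copy()
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D array of samples x genes")
    return arr


def _component_logdensity(X: np.ndarray, means: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """(n, k) log density of each sample under each diagonal Gaussian."""
    n, G = X.shape
    k = means.shape[0]
    out = np.empty((n, k))
    for c in range(k):
        diff = X - means[c]
        out[:, c] = -0.5 * (
            G * np.log(2.0 * np.pi)
            + np.log(variances[c]).sum()
            + (diff * diff / variances[c]).sum(axis=1)
        )
    return out


def _logsumexp_rows(A: np.ndarray) -> np.ndarray:
    m = A.max(axis=1)
    return m + np.log(np.exp(A - m[:, None]).sum(axis=1))


def loglik_at(X, weights, means, variances) -> float:
    """Direct evaluation of the mixture log-likelihood at given parameters."""
    X = _as_sample_matrix(X)
    logdens = _component_logdensity(X, np.atleast_2d(means), np.atleast_2d(variances))
    return float(_logsumexp_rows(logdens + np.log(weights)).sum())


def _fit_k1(X: np.ndarray, parameterization: str) -> MixtureFit:
    n, G = X.shape
    mu = X.mean(axis=0)
    var = np.maximum(X.var(axis=0), _VAR_FLOOR)  # ML variance (divide by n)
    ll = loglik_at(X, np.array([1.0]), mu[None, :], var[None, :])
    return MixtureFit(
        k=1,
        weights=np.array([1.0]),
        means=mu[None, :],
        variances=var[None, :],
        log_likelihood=ll,
        posteriors=np.ones((n, 1)),
        labels=np.zeros(n, dtype=int),
        n_params=mixture_param_count(1, G, parameterization),
        ll_trace=[ll],
    )


def fit_mixture(
    data,
    k: int,
    n_restarts: int = 10,
    seed: int | None = None,
    max_iter: int = _MAX_ITER,
    tol: float = _TOL,
    parameterization: str = "diagonal_multivariate",
) -> MixtureFit:
    """Fit a k-component diagonal Gaussian mixture to samples.

    ``data`` is an :class:`ExpressionMatrix` (genes x samples) or an
    (n_samples, n_genes) array.  Restarts are initialized from seeded
    random responsibilities; the best restart by log-likelihood wins.
    ``k = 1`` returns the closed-form maximum-likelihood fit.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if parameterization not in PARAMETERIZATIONS:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    X = _as_sample_matrix(data)
    n, G = X.shape
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if k == 1:
        return _fit_k1(X, parameterization)

    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(seed)
    best: MixtureFit | None = None
    for child in root.spawn(max(1, n_restarts)):
        rng = np.random.default_rng(child)
        fit = _em_once(X, k, rng, max_iter, tol)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    best.n_params = mixture_param_count(k, G, parameterization)
    return best


def _em_once(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float) -> MixtureFit:
    n, G = X.shape
    resp = rng.uniform(0.1, 1.0, size=(n, k))
    resp /= resp.sum(axis=1, keepdims=True)

    trace: list[float] = []
    weights = np.full(k, 1.0 / k)
    means = np.zeros((k, G))
    variances = np.ones((k, G))
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        # M-step
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        ex2 = (resp.T @ (X * X)) / nk[:, None]
        variances = np.maximum(ex2 - means * means, _VAR_FLOOR)
        # E-step
        logdens = _component_logdensity(X, means, variances) + np.log(weights)
        lse = _logsumexp_rows(logdens)
        ll = float(lse.sum())
        resp = np.exp(logdens - lse[:, None])
        trace.append(ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll

    labels = resp.argmax(axis=1)
    degenerate = bool(
        (weights < 1.0 / n).any() or (variances <= _VAR_FLOOR).any()
    )
    return MixtureFit(
        k=k,
        weights=weights,
        means=means,
        variances=variances,
        log_likelihood=trace[-1],
        posteriors=resp,
        labels=labels,
        n_params=0,  # set by caller
        ll_trace=trace,
        degenerate=degenerate,
        converged=converged,
    )


def delta_criteria(llr: float, delta_q: int, n: int) -> tuple[float, float]:
    """Information-criterion deltas of a k-group fit versus the 1-group fit.

    ``llr`` must already be on the 2*(ll_k - ll_1) scale and ``delta_q``
    is the number of added parameters.  Returns (delta_AIC, delta_BIC);
    negative values favour the richer model.
    """
    if delta_q < 0:
        raise ValueError("delta_q must be non-negative")
    if n < 2:
        raise ValueError("n must be >= 2")
    delta_aic = 2.0 * delta_q - llr
    delta_bic = delta_q * np.log(n) - llr
    return float(delta_aic), float(delta_bic)


def mixture_param_count(k: int, n_genes: int, parameterization: str = "diagonal_multivariate") -> int:
    """Free-parameter count q of a k-component mixture.

    diagonal_multivariate: (k-1) weights + k*G means + k*G variances.
    per_component_scalar: 3k - 1 (one mean, one variance, one weight per
    component) — an effectively univariate accounting that yields the
    delta_q = 3 per added component used in published delta-AIC tables.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if parameterization == "diagonal_multivariate":
        return (k - 1) + 2 * k * n_genes
    if parameterization == "per_component_scalar":
        return 3 * k - 1
    raise ValueError(f"unknown parameterization {parameterization!r}")
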
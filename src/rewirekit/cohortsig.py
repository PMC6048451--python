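"""Simulation-based significance for mixture-derived groups.

The empirical p-value convention is (count + 1) / (S + 1): with S = 1000
null draws the attainable floor is 1/1001 ~= 9.99e-4.  The omnibus test
fits mixtures at k and at 1 on the observed cohort, computes a mean-
equality t, a Steiger chi-square, the log-likelihood ratio and the
information-criterion deltas between the two largest mixture groups, then
re-runs the identical procedure on S parametric-bootstrap cohorts drawn
from the pooled (homogeneous) mean and covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exprio import ExpressionMatrix
from .mixture import delta_criteria, fit_mixture

logger = logging.getLogger(__name__)

__all__ = [
    "EquivTestResult",
    "empirical_pvalue",
    "mean_equality_t",
    "omnibus_rewiring_test",
]


@dataclass
class EquivTestResult:
    """A test statistic with optional asymptotic and simulation p-values."""

    statistic_name: str
    statistic: float
    df: int | None = None
    p_asymptotic: float | None = None
    p_simulated: float | None = None
    n_null: int | None = None

    def __post_init__(self) -> None:
        if self.p_simulated is not None:
            if not (0.0 < self.p_simulated <= 1.0):
                raise ValueError("p_simulated must lie in (0, 1]")


def empirical_pvalue(observed: float, null_draws) -> float:
    """p = (1 + #{null > observed}) / (len(null) + 1).

    Larger statistics are treated as more extreme.  The +1 in the
    numerator keeps p off zero and reproduces the 1/(S+1) floor.
    """
    null = np.asarray(null_draws, dtype=float)
    if null.size == 0:
        raise ValueError("null_draws must be non-empty")
    if np.isnan(null).any() or np.isnan(observed):
        raise ValueError("NaN in observed statistic or null draws")
    return float((1 + np.sum(null > observed)) / (null.size + 1))


def _two_groups(labels) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of the two largest label groups (ties -> lower label)."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    order = np.argsort(-counts, kind="stable")
    g1, g2 = uniq[order[0]], uniq[order[1]]
    return np.flatnonzero(labels == g1), np.flatnonzero(labels == g2)


def mean_equality_t(matrix: ExpressionMatrix, labels) -> EquivTestResult:
    """Paired t across genes on per-gene group-mean differences.

    d_g = mean_g(group1) - mean_g(group2); t = mean(d)/(sd(d)/sqrt(G)),
    df = G - 1, two-sided asymptotic p.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq.size}")
    idx_a = np.flatnonzero(labels == uniq[0])
    idx_b = np.flatnonzero(labels == uniq[1])
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("each group needs >= 2 samples")
    d = matrix.values[:, idx_a].mean(axis=1) - matrix.values[:, idx_b].mean(axis=1)
    G = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0.0):
            t = 0.0  # identical group mean vectors
        else:
            raise ValueError(
                "zero variance of per-gene mean differences (constant "
                "nonzero shift between group mean vectors); t undefined"
            )
    else:
        t = float(d.mean() / (sd / np.sqrt(G)))
    df = G - 1
    return EquivTestResult(
        statistic_name="t",
        statistic=t,
        df=df,
        p_asymptotic=float(2.0 * stats.t.sf(abs(t), df)),
    )


def _homogeneous_sampler(matrix: ExpressionMatrix, null: str = "rotation"):
    """Factory drawing homogeneous null cohorts matching the observed data.

    ``rotation`` (default): random orthogonal rotation of the centered
    data within the orthocomplement of the mean direction.  This keeps
    the sample mean vector and sample covariance matrix *exactly* and,
    under a homogeneous Gaussian model, the rotated cohort is
    exchangeable with the observed one — so simulation p-values are
    exactly calibrated.

    ``parametric``: fresh multivariate-normal draws from the pooled mean
    and the empirical covariance via its eigendecomposition truncated at
    the positive spectrum (rank <= n - 1).  Conservative when n is small
    relative to G because simulated cohorts inherit the observed
    cohort's spurious sample correlations.
    """
    X = matrix.values.T  # samples x genes
    n, G = X.shape
    mu = X.mean(axis=0)

    if null == "rotation":
        E = X - mu  # column-centered residuals
        # orthonormal basis of the complement of the all-ones direction
        basis = np.linalg.qr(
            np.eye(n) - np.full((n, n), 1.0 / n)
        )[0][:, : n - 1]
        coords = basis.T @ E  # (n-1) x G

        def draw(rng: np.random.Generator) -> np.ndarray:
            z = rng.standard_normal((n - 1, n - 1))
            q, r = np.linalg.qr(z)
            q *= np.sign(np.diag(r))  # Haar-distributed orthogonal matrix
            return mu + basis @ (q @ coords)

        return draw

    if null == "parametric":
        cov = np.cov(X, rowvar=False, ddof=1)
        eigval, eigvec = np.linalg.eigh(np.atleast_2d(cov))
        keep = eigval > max(eigval.max(), 0) * 1e-12
        factor = eigvec[:, keep] * np.sqrt(eigval[keep])
        rank = int(keep.sum())

        def draw(rng: np.random.Generator) -> np.ndarray:
            z = rng.standard_normal((n, rank))
            return mu + z @ factor.T

        return draw

    raise ValueError(f"unknown null {null!r}")


def _replicate_stats(
    X: np.ndarray,
    gene_ids: list[str],
    k: int,
    seed_seq: np.random.SeedSequence,
    n_restarts: int,
    delta_q: int,
) -> dict[str, float]:
    """Fit k vs 1 on a samples x genes array; return all omnibus statistics.

    Raises DegenerateReplicateError when the mixture collapses or the two
    largest groups are unusable for the correlation test.
    """
    from .matequiv import CorrMatrix, _corr_of_rows, _rank_rows, steiger_test

    n = X.shape[0]
    s_k, s_1 = seed_seq.spawn(2)
    fit_k = fit_mixture(X, k, n_restarts=n_restarts, seed=s_k)
    fit_1 = fit_mixture(X, 1)
    llr = 2.0 * (fit_k.log_likelihood - fit_1.log_likelihood)
    daic, dbic = delta_criteria(llr, delta_q, n)

    idx_a, idx_b = _two_groups(fit_k.labels)
    if idx_a.size < 4 or idx_b.size < 4:
        raise DegenerateReplicateError(
            f"mixture group too small for correlation test "
            f"({idx_a.size}/{idx_b.size} samples)"
        )
    em = ExpressionMatrix(
        gene_ids, [f"s{i}" for i in range(n)], X.T
    )
    sub_labels = np.isin(np.arange(n), idx_a).astype(int)
    keep = np.concatenate([idx_a, idx_b])
    t_res = mean_equality_t(em.select_samples(keep), sub_labels[keep])

    def corrmat(idx):
        return CorrMatrix(gene_ids, _corr_of_rows(_rank_rows(X[idx].T)), idx.size)

    try:
        st = steiger_test(corrmat(idx_a), corrmat(idx_b))
    except ValueError as exc:
        raise DegenerateReplicateError(str(exc)) from exc
    return {
        "t": abs(t_res.statistic),
        "steiger_chisq": st.statistic,
        "LLR": llr,
        "delta_AIC": daic,
        "delta_BIC": dbic,
        "_t_signed": t_res.statistic,
        "_t_df": t_res.df,
        "_steiger_df": st.df,
    }


class DegenerateReplicateError(RuntimeError):
    """A bootstrap replicate that cannot yield the omnibus statistics."""


# Statistics where *smaller* observed values favour the k-group model; they
# are negated before the larger-is-more-extreme empirical p-value, which
# makes the delta-AIC p identical to the LLR p (a monotone transform).
_NEGATED = {"delta_AIC", "delta_BIC"}


def omnibus_rewiring_test(
    matrix: ExpressionMatrix,
    k: int = 2,
    n_simulations: int = 1000,
    seed: int | None = None,
    n_restarts: int = 5,
    parameterization: str = "diagonal_multivariate",
    null: str = "rotation",
) -> list[EquivTestResult]:
    """Parametric-bootstrap significance of a k-group mixture structure.

    Returns one :class:`EquivTestResult` per statistic (t, steiger_chisq,
    LLR, delta_AIC, delta_BIC) with simulation p-values computed against
    ``n_simulations`` homogeneous cohorts.  Collapsed bootstrap replicates
    are redrawn from fresh substreams, capped at twice the requested count.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    if n_simulations < 99:
        raise ValueError("need at least 99 simulations")
    from .mixture import mixture_param_count

    delta_q = mixture_param_count(k, matrix.n_genes, parameterization) - \
        mixture_param_count(1, matrix.n_genes, parameterization)
    gene_ids = list(matrix.gene_ids)
    if isinstance(seed, np.random.SeedSequence):
        root = seed
    else:
        root = np.random.SeedSequence(seed)
    obs_seed, sim_seed = root.spawn(2)

    observed = _replicate_stats(
        matrix.values.T, gene_ids, k, obs_seed, n_restarts, delta_q
    )

    draw = _homogeneous_sampler(matrix, null=null)
    null: dict[str, list[float]] = {s: [] for s in ("t", "steiger_chisq", "LLR", "delta_AIC", "delta_BIC")}
    attempts = 0
    collected = 0
    max_attempts = 2 * n_simulations
    stream = iter(sim_seed.spawn(max_attempts))
    while collected < n_simulations and attempts < max_attempts:
        attempts += 1
        ss = next(stream)
        rng = np.random.default_rng(ss.spawn(1)[0])
        Xsim = draw(rng)
        try:
            rep = _replicate_stats(Xsim, gene_ids, k, ss, n_restarts, delta_q)
        except (DegenerateReplicateError, ValueError) as exc:
            logger.debug("redrawing bootstrap replicate: %s", exc)
            continue
        for s in null:
            null[s].append(rep[s])
        collected += 1
    if collected < n_simulations:
        logger.warning(
            "collected only %d/%d bootstrap replicates after %d attempts",
            collected, n_simulations, attempts,
        )
    if collected == 0:
        raise RuntimeError("no usable bootstrap replicates")
    if attempts > collected:
        logger.info("bootstrap redraws: %d", attempts - collected)

    results = []
    meta = {
        "t": (observed["_t_df"], None),
        "steiger_chisq": (observed["_steiger_df"], None),
        "LLR": (None, None),
        "delta_AIC": (None, None),
        "delta_BIC": (None, None),
    }
    for name in ("t", "steiger_chisq", "LLR", "delta_AIC", "delta_BIC"):
        sign = -1.0 if name in _NEGATED else 1.0
        obs_val = observed[name]
        p_sim = empirical_pvalue(sign * obs_val, sign * np.asarray(null[name]))
        reported = observed["_t_signed"] if name == "t" else obs_val
        results.append(
            EquivTestResult(
                statistic_name=name,
                statistic=float(reported),
                df=meta[name][0],
                p_asymptotic=None,
                p_simulated=p_sim,
                n_null=collected,
            )
        )
    return results
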
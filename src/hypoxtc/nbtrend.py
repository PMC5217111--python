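"""Negative-binomial trend test: quadratic-in-time vs intercept-only LRT.

For each gene the raw counts are modelled as negative binomial with log
link, mean mu_i = exp(x_i' beta + offset_i) and variance mu + alpha*mu^2.
The full model is quadratic in (rescaled) time, the reduced model is the
intercept alone, and the statistic 2*(ll_full - ll_reduced) is referred to
a chi-squared distribution with 2 degrees of freedom.

With a single replicate per time point, dispersion cannot be estimated
within time points; instead all time points are pooled as pseudo-replicates
(a method-of-moments estimate per gene) and a mean-dispersion trend
alpha(mu) = a0 + a1/mu is fitted across genes, so each gene borrows the
dispersion of genes expressed at similar levels. Genes with genuine time
trends receive inflated dispersion under pooling — a documented,
power-costing conservatism of the design.

Offsets are -log(scale_factor) from total-count normalization, so fitted
means live on the raw-count scale while exp(x'beta) is the normalized-scale
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .counts_io import CountMatrix

__all__ = [
    "DesignPair",
    "NbFit",
    "LrtResult",
    "DispersionTrend",
    "build_designs",
    "estimate_dispersion_mom",
    "fit_dispersion_trend",
    "nb_log_likelihood",
    "fit_nb_glm",
    "lrt_pvalue",
    "nb_trend_scan",
]

_MU_FLOOR = 1e-8
_COEF_TOL = 1e-8
_MAX_ITER = 100
_ALPHA_MIN = 1e-8


@dataclass(frozen=True)
class DesignPair:
    """Full (1, t/t_max, (t/t_max)^2) and reduced (1) design matrices.

    Time is rescaled to [0, 1] purely for conditioning; the LRT is
    invariant to the rescaling and coefficients are reported on the
    rescaled basis.
    """

    times: np.ndarray
    full_design: np.ndarray
    reduced_design: np.ndarray


@dataclass
class NbFit:
    """One fitted NB GLM for one gene and one model."""

    coefficients: np.ndarray
    alpha: float
    log_likelihood: float
    converged: bool
    iterations: int


@dataclass(frozen=True)
class LrtResult:
    gene_id: str
    lrt_stat: float
    df: int
    p_raw: float
    alpha: float
    converged: bool


def build_designs(times: Sequence[float]) -> DesignPair:
    t = np.asarray(times, dtype=float)
    if len(np.unique(t)) < 4:
        raise ValueError(
            f"full model has 3 parameters; need >= 4 distinct times, got {sorted(set(t))}"
        )
    s = t / t.max()
    full = np.column_stack([np.ones_like(s), s, s**2])
    reduced = np.ones((t.size, 1))
    return DesignPair(t, full, reduced)


def estimate_dispersion_mom(normalized_gene_values: Sequence[float]) -> float:
    """Method-of-moments dispersion pooling all time points as replicates.

    alpha_hat = max(0, (s^2 - m) / m^2) with the sample mean m and
    variance s^2 (ddof=1) across time points.
    """
    x = np.asarray(normalized_gene_values, dtype=float)
    m = x.mean()
    if m <= 0:
        raise ValueError("dispersion estimate requires positive values")
    s2 = x.var(ddof=1)
    return max(0.0, float((s2 - m) / m**2))


@dataclass(frozen=True)
class DispersionTrend:
    """alpha(mu) = max(alpha_min, a0 + a1/mu)."""

    a0: float
    a1: float
    alpha_min: float = _ALPHA_MIN

    def __call__(self, mu: np.ndarray | float) -> np.ndarray | float:
        return np.maximum(self.alpha_min, self.a0 + self.a1 / np.asarray(mu, dtype=float))


def fit_dispersion_trend(
    gene_means: Sequence[float], alpha_hats: Sequence[float], min_positive: int = 20
) -> DispersionTrend:
    """Least-squares fit of alpha_hat against 1/mean over positive estimates.

    Falls back to a constant trend at the median positive alpha_hat (or
    alpha_min when none are positive) if fewer than ``min_positive`` genes
    have a positive estimate.
    """
    mu = np.asarray(gene_means, dtype=float)
    a = np.asarray(alpha_hats, dtype=float)
    if mu.shape != a.shape:
        raise ValueError("gene_means and alpha_hats must align")
    pos = a > 0
    if pos.sum() < min_positive:
        const = float(np.median(a[pos])) if pos.any() else _ALPHA_MIN
        return DispersionTrend(const, 0.0)
    X = np.column_stack([np.ones(pos.sum()), 1.0 / mu[pos]])
    coef, *_ = np.linalg.lstsq(X, a[pos], rcond=None)
    return DispersionTrend(float(coef[0]), float(coef[1]))


def nb_log_likelihood(
    y: np.ndarray, mu: np.ndarray, alpha: float | np.ndarray
) -> np.ndarray:
    """NB2 log-likelihood summed over observations (last axis); alpha=0 is Poisson."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim:
        alpha = alpha[..., None]
    poisson = y * np.log(mu) - mu - gammaln(y + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(alpha > 0, 1.0 / np.where(alpha > 0, alpha, 1.0), np.inf)
        nb = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    ll = np.where(alpha > 0, nb, poisson)
    return ll.sum(axis=-1)


def _irls_batch(
    Y: np.ndarray, X: np.ndarray, offsets: np.ndarray, alphas: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Batched Fisher-scoring IRLS for NB GLMs sharing one design.

    Y: (G, n) counts; X: (n, p); offsets: (n,); alphas: (G,).
    Returns (beta (G,p), loglik (G,), converged (G,), iterations).
    """
    G, n = Y.shape
    p = X.shape[1]
    beta = np.zeros((G, p))
    beta[:, 0] = np.log(Y.mean(axis=1) + 0.1) - offsets.mean()
    converged = np.zeros(G, dtype=bool)
    a = alphas[:, None]
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = np.clip(beta @ X.T + offsets, np.log(_MU_FLOOR), 40.0)
        mu = np.exp(eta)
        w = mu / (1.0 + a * mu)  # Fisher weights mu^2 / V(mu)
        z = (eta - offsets) + (Y - mu) / mu  # working response minus offset
        A = np.einsum("gi,ip,iq->gpq", w, X, X)
        b = np.einsum("gi,ip,gi->gp", w, X, z)
        A += np.eye(p) * 1e-12  # guard singular systems from degenerate weights
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.abs(new_beta - beta).max(axis=1)
        beta = np.where(converged[:, None], beta, new_beta)
        converged |= delta < _COEF_TOL
        if converged.all():
            break
    eta = np.clip(beta @ X.T + offsets, np.log(_MU_FLOOR), 40.0)
    ll = nb_log_likelihood(Y, np.exp(eta), alphas)
    # all-zero genes have an unbounded intercept (guarded by the mu floor);
    # their fit is degenerate and must be flagged
    converged &= Y.sum(axis=1) > 0
    return beta, ll, converged, it


def fit_nb_glm(
    raw_counts: Sequence[float],
    design: np.ndarray,
    offsets: Sequence[float],
    alpha: float,
) -> NbFit:
    """Fit one NB GLM (log link, known dispersion) by IRLS.

    Convergence: max |delta beta| < 1e-8 or 100 iterations; the fitted mean
    is floored at 1e-8, which guards degenerate all-zero genes (their
    intercept would diverge to -inf) at the cost of a non-convergence flag.
    """
    y = np.asarray(raw_counts, dtype=float)
    X = np.asarray(design, dtype=float)
    off = np.asarray(offsets, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("counts must be nonnegative integers")
    if not np.all(np.isfinite(off)):
        raise ValueError("offsets must be finite")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    beta, ll, conv, it = _irls_batch(y[None, :], X, off, np.array([alpha]))
    return NbFit(beta[0], alpha, float(ll[0]), bool(conv[0]), it)


def lrt_pvalue(ll_full: float, ll_reduced: float, df: int = 2) -> tuple[float, float]:
    """(statistic, p) for the nested-model likelihood-ratio test.

    stat = max(0, 2*(ll_full - ll_reduced)); nested models forbid a
    genuinely negative difference, so a deficit beyond 1e-6 flags an
    optimization failure.
    """
    diff = ll_full - ll_reduced
    if diff < -1e-6:
        raise RuntimeError(
            f"full-model log-likelihood below reduced ({diff:.3g}): optimization failure"
        )
    stat = max(0.0, 2.0 * diff)
    return stat, float(chi2.sf(stat, df))


def nb_trend_scan(
    matrix: CountMatrix,
    scale_factors: Sequence[float],
    genes: Iterable[str] | None = None,
    dispersions: Sequence[float] | Callable[[np.ndarray], np.ndarray] | None = None,
) -> list[LrtResult]:
    """Quadratic-vs-intercept LRT over many genes of a raw count matrix.

    ``dispersions`` may be per-gene values (aligned with the sorted gene
    list), a callable alpha(mu), or None — in which case the pooled
    method-of-moments estimates feed ``fit_dispersion_trend`` and each
    gene's working dispersion is the trend value at its normalized mean.
    Per-gene failures are flagged, never fatal to the scan.
    """
    gene_list = sorted(genes) if genes is not None else list(matrix.gene_ids)
    if not gene_list:
        return []
    sub = matrix.subset(gene_list)
    sf = np.asarray(scale_factors, dtype=float)
    if sf.shape != (sub.n_samples,):
        raise ValueError("one scale factor per sample required")
    Y = np.round(sub.values)  # raw counts
    normalized = sub.values * sf
    means = normalized.mean(axis=1)

    if dispersions is None:
        alpha_hats = np.array(
            [estimate_dispersion_mom(row) if row.mean() > 0 else 0.0 for row in normalized]
        )
        trend = fit_dispersion_trend(np.maximum(means, _MU_FLOOR), alpha_hats)
        alphas = np.asarray(trend(np.maximum(means, _MU_FLOOR)), dtype=float)
    elif callable(dispersions):
        alphas = np.asarray(dispersions(np.maximum(means, _MU_FLOOR)), dtype=float)
    else:
        alphas = np.asarray(dispersions, dtype=float)
        if alphas.shape != (len(gene_list),):
            raise ValueError("need one dispersion per scanned gene")

    pair = build_designs(sub.times)
    offsets = -np.log(sf)
    beta_f, ll_f, conv_f, _ = _irls_batch(Y, pair.full_design, offsets, alphas)
    beta_r, ll_r, conv_r, _ = _irls_batch(Y, pair.reduced_design, offsets, alphas)

    results: list[LrtResult] = []
    for g, lf, lr, af, cf, cr in zip(gene_list, ll_f, ll_r, alphas, conv_f, conv_r):
        ok = bool(cf and cr) and (lf - lr) >= -1e-6
        stat = max(0.0, 2.0 * (lf - lr))
        results.append(
            LrtResult(g, stat, 2, float(chi2.sf(stat, 2)), float(af), ok)
        )
    return results
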
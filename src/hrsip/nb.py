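"""Gamma-Poisson (negative binomial) GLM machinery for count tables.

Self-contained differential-abundance core: median-of-ratios size factors,
per-OTU dispersion estimation (method of moments refined by maximum
likelihood), penalized NB regression with a log link and log(size factor)
offsets, and Wald inference. Coefficients are reported on the log2 scale
(log2 fold change, LFC).

The NB parameterization is Var(Y) = mu + alpha * mu^2; alpha = 0 recovers
Poisson. A weak ridge penalty (prior variance ``ridge_var`` on the log2
scale, non-intercept coefficients only) keeps LFCs finite for separated or
all-zero groups, which sparse gradient-fraction data routinely produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

__all__ = [
    "GLMFit",
    "estimate_size_factors",
    "dispersion_mom",
    "estimate_dispersion",
    "nb_loglik",
    "fit_nb_glm",
    "wald_one_sided",
    "wald_two_sided",
]

LN2 = np.log(2.0)
ALPHA_BOUNDS = (1e-8, 10.0)
_POISSON_ALPHA = 1e-12  # below this, use the Poisson limit


@dataclass
class GLMFit:
    """One fitted NB regression row: log2 coefficients, SEs, fitted means."""

    coef: np.ndarray  # log2 scale, one per design column
    se: np.ndarray
    converged: bool
    mu: np.ndarray  # fitted means on the count scale
    loglik: float


# ---------------------------------------------------------------------------
# size factors


def estimate_size_factors(
    m, method: str = "median_of_ratios", min_reference_otus: int = 10
) -> pd.Series:
    """Per-sample normalization factors, rescaled to geometric mean 1.

    ``median_of_ratios``: per-sample median of count ratios against the
    per-OTU geometric mean, computed over OTUs observed in every sample.
    When fewer than ``min_reference_otus`` such OTUs exist (sparse fraction
    data), falls back to the ``poscounts`` variant, where per-OTU geometric
    means use only nonzero entries.

    Parameters accept a :class:`~hrsip.io.CountMatrix` or a DataFrame.
    """
    counts = m.data if hasattr(m, "data") else m
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least two samples")
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"sample(s) with all-zero counts: {zero}")
    if method not in ("median_of_ratios", "poscounts"):
        raise ValueError(f"unknown size-factor method {method!r}")

    values = counts.to_numpy(dtype=float)
    if method == "median_of_ratios":
        all_nonzero = (values > 0).all(axis=1)
        if all_nonzero.sum() < min_reference_otus:
            method = "poscounts"
        else:
            values = values[all_nonzero]

    if method == "median_of_ratios":
        log_gm = np.log(values).mean(axis=1)
        log_ratios = np.log(values) - log_gm[:, None]
        log_sf = np.median(log_ratios, axis=0)
    else:  # poscounts
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(values > 0, np.log(np.where(values > 0, values, 1.0)), np.nan)
        n_pos = (values > 0).sum(axis=1)
        usable = n_pos > 0
        log_gm = np.nanmean(logs[usable], axis=1)
        log_sf = np.empty(values.shape[1])
        for j in range(values.shape[1]):
            col = values[usable, j]
            mask = col > 0
            if not mask.any():
                raise ValueError("sample with no positive reference counts")
            log_sf[j] = np.median(np.log(col[mask]) - log_gm[mask])

    log_sf -= log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion


def dispersion_mom(values: np.ndarray) -> float:
    """Method-of-moments NB dispersion: max(0, (s^2 - m) / m^2).

    ``values`` are normalized counts from one design cell (>= 2 entries).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("method of moments needs >= 2 values")
    mean = values.mean()
    if mean <= 0:
        return 0.0
    var = values.var(ddof=1)
    return max(0.0, (var - mean) / mean**2)


def _design_cells(design: np.ndarray) -> list[np.ndarray]:
    """Indices of samples sharing a design row (one list per unique row)."""
    _, inverse = np.unique(design, axis=0, return_inverse=True)
    return [np.flatnonzero(inverse == g) for g in range(inverse.max() + 1)]


def _profile_alpha(y: np.ndarray, mu: np.ndarray, bounds: tuple[float, float]) -> float:
    """Maximize the NB log-likelihood over alpha with means held fixed."""

    def neg_ll(log_alpha: float) -> float:
        return -nb_loglik(y, mu, np.exp(log_alpha))

    res = optimize.minimize_scalar(
        neg_ll, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded"
    )
    return float(np.exp(res.x))


def estimate_dispersion(
    m,
    design: np.ndarray,
    sf: pd.Series,
    alpha_bounds: tuple[float, float] = ALPHA_BOUNDS,
    trim: float = 0.2,
) -> pd.Series:
    """Per-OTU NB dispersion alpha (Var = mu + alpha * mu^2).

    Method-of-moments estimates on normalized counts within design cells,
    pooled across cells by degrees of freedom, then refined by per-OTU
    maximum likelihood with fitted means (alpha bounded). OTUs with too few
    informative samples receive the trimmed mean of the other OTUs' values.
    """
    counts = m.data if hasattr(m, "data") else m
    design = np.asarray(design, dtype=float)
    n, p = design.shape
    if np.linalg.matrix_rank(design) < p:
        raise ValueError("degenerate design: collinear columns")
    if n - p < 2:
        raise ValueError("need >= 2 residual degrees of freedom to estimate dispersion")
    sf_vec = sf.loc[counts.columns].to_numpy()
    cells = _design_cells(design)

    alphas: dict[str, float] = {}
    needs_fill: list[str] = []
    for otu, row in counts.iterrows():
        y = row.to_numpy(dtype=float)
        norm = y / sf_vec
        num = 0.0
        den = 0
        for idx in cells:
            if len(idx) >= 2 and norm[idx].mean() > 0:
                num += dispersion_mom(norm[idx]) * (len(idx) - 1)
                den += len(idx) - 1
        if den == 0 or (y > 0).sum() < 2:
            needs_fill.append(str(otu))
            continue
        alpha = max(num / den, alpha_bounds[0])
        # two cycles of (fit means | optimize alpha)
        for _ in range(2):
            fit = fit_nb_glm(y, design, sf_vec, alpha)
            alpha = _profile_alpha(y, fit.mu, alpha_bounds)
        alphas[str(otu)] = alpha

    if alphas:
        fill = float(stats.trim_mean(list(alphas.values()), trim)) if len(alphas) > 2 else float(
            np.mean(list(alphas.values()))
        )
    else:
        fill = alpha_bounds[0]
    for otu in needs_fill:
        alphas[otu] = fill
    return pd.Series(alphas, name="alpha").reindex(counts.index.astype(str))


# ---------------------------------------------------------------------------
# NB GLM


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB log-likelihood (Poisson limit for alpha ~ 0); constants included."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-10, None)
    if alpha < _POISSON_ALPHA:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    k = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + k)
            - gammaln(k)
            - gammaln(y + 1)
            + k * np.log(k / (k + mu))
            + y * np.log(mu / (k + mu))
        )
    )


def fit_nb_glm(
    y: np.ndarray,
    design: np.ndarray,
    sf: np.ndarray | pd.Series,
    alpha: float,
    ridge_var: float = 36.0,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GLMFit:
    """Penalized NB regression with log link and log(sf) offsets.

    Coefficients are on the log2 scale: mu = sf * 2^(X beta). Non-intercept
    coefficients carry a Gaussian ridge with variance ``ridge_var`` (log2
    units). Standard errors come from the observed information at the
    optimum (penalty included). Newton iterations with step halving.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    sf = np.asarray(sf, dtype=float)
    n, p = X.shape
    if alpha < 0:
        raise ValueError("dispersion alpha must be >= 0")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not full rank")
    k = np.inf if alpha < _POISSON_ALPHA else 1.0 / alpha

    # penalize every column except an intercept (constant) column
    pen = np.full(p, 1.0 / ridge_var)
    const_cols = np.ptp(X, axis=0) == 0
    pen[const_cols] = 0.0
    P = np.diag(pen)

    beta = np.zeros(p)
    if const_cols.any():
        j = int(np.flatnonzero(const_cols)[0])
        beta[j] = np.log2(max((y / sf).mean(), 1e-3)) / X[0, j]

    def mu_of(b: np.ndarray) -> np.ndarray:
        return np.clip(sf * np.exp(LN2 * (X @ b)), 1e-10, 1e12)

    def pen_ll(b: np.ndarray) -> float:
        return nb_loglik(y, mu_of(b), alpha) - 0.5 * float(b @ P @ b)

    ll = pen_ll(beta)
    converged = False
    for _ in range(max_iter):
        mu = mu_of(beta)
        if np.isinf(k):
            u = y - mu
            w = mu
        else:
            u = (y - mu) * k / (k + mu)
            w = mu * k * (k + y) / (k + mu) ** 2
        grad = LN2 * (X.T @ u) - P @ beta
        info = LN2**2 * (X.T * w) @ X + P
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step halving on the penalized log-likelihood
        factor = 1.0
        for _ in range(30):
            new_ll = pen_ll(beta + factor * step)
            if new_ll >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        improved = new_ll - ll
        ll = new_ll
        if np.max(np.abs(factor * step)) < 1e-8 or abs(improved) < tol:
            converged = True
            break

    mu = mu_of(beta)
    if np.isinf(k):
        w = mu
    else:
        w = mu * k * (k + y) / (k + mu) ** 2
    info = LN2**2 * (X.T * w) @ X + P
    cov = np.linalg.inv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return GLMFit(coef=beta, se=se, converged=converged, mu=mu, loglik=ll)


# ---------------------------------------------------------------------------
# Wald tests


def wald_one_sided(lfc, se, threshold):
    """Upper-tail p-value for H0: LFC <= threshold, z = (lfc - thr) / se."""
    lfc = np.asarray(lfc, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    z = (lfc - threshold) / se
    p = stats.norm.sf(z)
    return float(p) if p.ndim == 0 else p


def wald_two_sided(coef, se):
    """Two-sided p-value for H0: coefficient = 0."""
    coef = np.asarray(coef, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    p = 2.0 * stats.norm.sf(np.abs(coef / se))
    return float(p) if p.ndim == 0 else p
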
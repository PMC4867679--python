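"""Temporal abundance dynamics in non-fractionated samples.

Per-OTU (or per-taxon) NB regression on sampling day treated as an ordered
factor: days are mapped to ranks and expanded into orthogonal polynomial
contrasts; the two-sided Wald test on the linear contrast detects monotone
trends, reported as increase or decrease. OTUs are filtered on base mean
(mean normalized count) before BH correction; no outlier replacement is
performed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleMeta, TaxonomyTable, aggregate_by_rank
from .nb import estimate_dispersion, estimate_size_factors, fit_nb_glm, wald_two_sided
from .responders import bh_adjust

__all__ = ["ordered_factor_design", "fit_time_course", "fit_time_course_by_class"]

RESULT_COLUMNS = ["id", "base_mean", "trend_lfc", "se", "p", "p_adj", "direction"]


def poly_contrasts(n_levels: int, degree: int | None = None) -> np.ndarray:
    """Orthonormal polynomial contrast matrix over 1..n_levels ranks.

    Column k is the degree-k orthogonal polynomial (k >= 1), normalized to
    unit length, matching ordered-factor coding in standard statistical
    software.
    """
    if n_levels < 2:
        raise ValueError("ordered factor needs >= 2 levels")
    if degree is None:
        degree = n_levels - 1
    ranks = np.arange(1, n_levels + 1, dtype=float)
    V = np.vander(ranks, degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    contrasts = Q[:, 1:]
    # fix sign so the linear column increases with rank (QR sign is arbitrary)
    if contrasts[0, 0] > contrasts[-1, 0]:
        contrasts[:, 0] *= -1
    return contrasts


def ordered_factor_design(days: np.ndarray, degree: int | None = None) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept + orthogonal polynomial contrasts on day ranks."""
    days = np.asarray(days)
    levels = np.unique(days)
    if len(levels) < 3:
        raise ValueError("time-course model needs >= 3 distinct days")
    contrasts = poly_contrasts(len(levels), degree)
    level_index = {d: i for i, d in enumerate(levels)}
    rows = np.array([contrasts[level_index[d]] for d in days])
    X = np.column_stack([np.ones(len(days)), rows])
    names = ["intercept"] + [f"poly{k}" for k in range(1, contrasts.shape[1] + 1)]
    return X, names


def fit_time_course(
    m: CountMatrix,
    meta: SampleMeta,
    fdr: float = 0.10,
    base_mean_min: float = 1.0,
    ridge_var: float = 36.0,
) -> pd.DataFrame:
    """Per-OTU trend test over non-fractionated samples.

    The Wald test targets the linear polynomial contrast (two-sided, since
    both increases and decreases are of interest); higher-degree terms are
    fitted to absorb non-monotone structure but not tested. BH correction is
    applied over OTUs whose mean normalized count reaches ``base_mean_min``.
    """
    nonfrac = meta.non_fractionated()
    if nonfrac.empty:
        raise ValueError("no non-fractionated samples in metadata")
    meta.check_against(m)
    sub = m.select_samples(list(nonfrac.index))
    days = nonfrac["day"].to_numpy()
    n_levels = len(np.unique(days))
    X, _ = ordered_factor_design(days)
    counts_per_day = pd.Series(days).value_counts()
    if (counts_per_day < 2).any():
        warnings.warn("fewer than two samples for some days; trend SEs may be unstable")
    if X.shape[0] - X.shape[1] < 2:
        # drop highest-degree contrasts until >= 2 residual df remain
        max_deg = max(1, X.shape[0] - 3)
        X, _ = ordered_factor_design(days, degree=min(n_levels - 1, max_deg))

    sf = estimate_size_factors(sub)
    alphas = estimate_dispersion(sub, X, sf)
    sf_vec = sf.loc[sub.sample_ids].to_numpy()
    base_mean = (sub.data / sf_vec).mean(axis=1)

    rows = []
    for otu in sub.otu_ids:
        y = sub.data.loc[otu].to_numpy()
        fit = fit_nb_glm(y, X, sf_vec, float(alphas.loc[otu]), ridge_var)
        trend, se = (fit.coef[1], fit.se[1]) if fit.converged else (np.nan, np.nan)
        rows.append({"id": otu, "base_mean": base_mean.loc[otu], "trend_lfc": trend, "se": se})
    res = pd.DataFrame(rows)
    testable = res["trend_lfc"].notna() & (res["base_mean"] >= base_mean_min)
    res["p"] = np.nan
    res.loc[testable, "p"] = wald_two_sided(
        res.loc[testable, "trend_lfc"].to_numpy(), res.loc[testable, "se"].to_numpy()
    )
    res["p_adj"] = np.nan
    if testable.any():
        res.loc[testable, "p_adj"] = bh_adjust(res.loc[testable, "p"].to_numpy())
    res["direction"] = "none"
    sig = res["p_adj"] < fdr
    res.loc[sig & (res["trend_lfc"] > 0), "direction"] = "increase"
    res.loc[sig & (res["trend_lfc"] < 0), "direction"] = "decrease"
    return res[RESULT_COLUMNS]


def fit_time_course_by_class(
    m: CountMatrix,
    tax: TaxonomyTable,
    meta: SampleMeta,
    rank: str = "class",
    fdr: float = 0.10,
    base_mean_min: float = 1.0,
) -> pd.DataFrame:
    """Trend test on counts aggregated at a taxonomic rank."""
    agg = aggregate_by_rank(m, tax, rank)
    return fit_time_course(agg, meta, fdr=fdr, base_mean_min=base_mean_min)
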
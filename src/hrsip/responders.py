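"""Identification of 13C-labeled OTUs ("responders") from gradient fractions.

For each (substrate, day) comparison, OTU counts in the heavy (high-density)
fractions of the labeled gradient are contrasted against the corresponding
control-gradient fractions with an NB GLM (intercept + treatment indicator).
The one-sided Wald null is data-derived: an OTU's LFC must exceed one sample
standard deviation above the mean of the LFCs of all tested OTUs. OTUs are
independently filtered for sparsity (present in >= 45% of the comparison's
pooled heavy fractions) before Benjamini-Hochberg correction at FDR 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .density import HeavyWindow, select_heavy
from .io import CountMatrix, SampleMeta
from .nb import estimate_dispersion, estimate_size_factors, fit_nb_glm, wald_one_sided

__all__ = [
    "ComparisonSpec",
    "sparsity_filter",
    "lfc_null_threshold",
    "bh_adjust",
    "detect_responders",
    "comparisons_from_meta",
    "aggregate_responders",
]

RESULT_COLUMNS = [
    "otu_id",
    "substrate",
    "day",
    "lfc",
    "se",
    "wald_p",
    "p_adj",
    "passed_sparsity",
    "responder",
]


@dataclass(frozen=True)
class ComparisonSpec:
    """One labeled-vs-control gradient contrast at a single day."""

    substrate: str  # "13C-xylose" or "13C-cellulose"
    day: int
    labeled_gradient_id: str
    control_gradient_id: str
    window: HeavyWindow = field(default_factory=HeavyWindow)

    def __post_init__(self) -> None:
        if self.substrate not in ("13C-xylose", "13C-cellulose"):
            raise ValueError(f"substrate must be a 13C treatment, got {self.substrate!r}")
        if self.labeled_gradient_id == self.control_gradient_id:
            raise ValueError("labeled and control gradients must differ")


def sparsity_filter(heavy_counts: pd.DataFrame, min_prevalence: float = 0.45) -> pd.Series:
    """Keep OTUs present (count > 0) in >= min_prevalence of heavy fractions.

    ``heavy_counts`` holds the comparison's pooled heavy fractions (labeled
    and control gradients together) as columns. Boundary inclusive: an OTU
    in exactly 45% of fractions is kept.
    """
    if heavy_counts.shape[1] == 0:
        raise ValueError("no heavy fractions in comparison")
    prevalence = (heavy_counts > 0).mean(axis=1)
    keep = prevalence >= min_prevalence
    keep.name = "passed_sparsity"
    return keep


def lfc_null_threshold(lfcs) -> float:
    """mean + one sample (n-1) standard deviation of the LFC pool."""
    lfcs = np.asarray(lfcs, dtype=float)
    lfcs = lfcs[np.isfinite(lfcs)]
    if lfcs.size < 2:
        raise ValueError("need >= 2 finite LFC values for the data-derived null")
    return float(lfcs.mean() + lfcs.std(ddof=1))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)) or np.any(~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def detect_responders(
    m: CountMatrix,
    meta: SampleMeta,
    spec: ComparisonSpec,
    fdr: float = 0.10,
    min_prevalence: float = 0.45,
    min_heavy_fractions: int = 3,
    sf_method: str = "median_of_ratios",
    ridge_var: float = 36.0,
) -> pd.DataFrame:
    """Per-OTU responder calls for one (substrate, day) comparison.

    Pipeline: heavy-fraction selection -> sparsity filter on the pooled
    heavy fractions -> size factors and dispersions on the heavy submatrix
    -> NB GLM per OTU (intercept + labeled indicator) -> data-derived LFC
    threshold -> one-sided Wald -> BH at ``fdr``. OTUs failing the sparsity
    filter carry no p-values. Fractions within a gradient are treated as
    replicates of their treatment group.
    """
    meta.check_against(m)
    labeled_meta = meta.gradient_samples(spec.labeled_gradient_id)
    control_meta = meta.gradient_samples(spec.control_gradient_id)
    if labeled_meta.empty or control_meta.empty:
        raise ValueError("comparison references an unknown or empty gradient")
    if not (labeled_meta["day"] == spec.day).all() or not (control_meta["day"] == spec.day).all():
        raise ValueError("gradients in a comparison must share the day")
    if not (labeled_meta["treatment"] == spec.substrate).all():
        raise ValueError("labeled gradient treatment does not match the comparison substrate")
    if not (control_meta["treatment"] == "control").all():
        raise ValueError("control gradient must carry the control treatment")

    heavy_labeled = select_heavy(labeled_meta, spec.window)
    heavy_control = select_heavy(control_meta, spec.window)
    if min(len(heavy_labeled), len(heavy_control)) < min_heavy_fractions:
        raise ValueError(
            f"need >= {min_heavy_fractions} heavy fractions per gradient, got "
            f"{len(heavy_labeled)} labeled / {len(heavy_control)} control"
        )
    heavy_ids = heavy_labeled + heavy_control
    heavy = m.select_samples(heavy_ids)

    keep = sparsity_filter(heavy.data, min_prevalence)
    tested_otus = keep.index[keep].tolist()

    base = pd.DataFrame(
        {
            "otu_id": m.otu_ids,
            "substrate": spec.substrate,
            "day": spec.day,
            "lfc": np.nan,
            "se": np.nan,
            "wald_p": np.nan,
            "p_adj": np.nan,
            "passed_sparsity": keep.reindex(m.otu_ids).to_numpy(),
            "responder": False,
        }
    ).set_index("otu_id")

    if not tested_otus:
        base.attrs["status"] = "all OTUs removed by sparsity filter"
        return base.reset_index()[RESULT_COLUMNS]

    sub = heavy.select_otus(tested_otus)
    design = np.column_stack(
        [np.ones(len(heavy_ids)), [1.0 if s in heavy_labeled else 0.0 for s in heavy_ids]]
    )
    sf = estimate_size_factors(sub, method=sf_method)
    alphas = estimate_dispersion(sub, design, sf)
    sf_vec = sf.loc[sub.sample_ids].to_numpy()

    lfc = {}
    se = {}
    for otu in tested_otus:
        fit = fit_nb_glm(
            sub.data.loc[otu].to_numpy(), design, sf_vec, float(alphas.loc[otu]), ridge_var
        )
        if not fit.converged:
            continue  # flagged: excluded downstream
        lfc[otu] = fit.coef[1]
        se[otu] = fit.se[1]

    fitted = list(lfc)
    if len(fitted) >= 2:
        threshold = lfc_null_threshold([lfc[o] for o in fitted])
        pvals = wald_one_sided(
            np.array([lfc[o] for o in fitted]),
            np.array([se[o] for o in fitted]),
            threshold,
        )
        padj = bh_adjust(pvals)
        base.loc[fitted, "lfc"] = [lfc[o] for o in fitted]
        base.loc[fitted, "se"] = [se[o] for o in fitted]
        base.loc[fitted, "wald_p"] = pvals
        base.loc[fitted, "p_adj"] = padj
        base.loc[fitted, "responder"] = padj < fdr
        base.attrs["lfc_null_threshold"] = threshold
    return base.reset_index()[RESULT_COLUMNS]


def comparisons_from_meta(
    meta: SampleMeta, window: HeavyWindow = HeavyWindow()
) -> list[ComparisonSpec]:
    """Derive all (substrate, day) comparisons present in the metadata.

    Pairs each 13C gradient with the control gradient of the same day;
    days lacking a control gradient are skipped.
    """
    frac = meta.fractionated()
    gradients = frac.groupby("gradient_id").agg(
        treatment=("treatment", "first"), day=("day", "first")
    )
    controls = gradients[gradients["treatment"] == "control"]
    specs = []
    for gid, row in gradients.iterrows():
        if row["treatment"] == "control":
            continue
        match = controls.index[controls["day"] == row["day"]]
        if len(match) == 0:
            continue
        specs.append(
            ComparisonSpec(
                substrate=row["treatment"],
                day=int(row["day"]),
                labeled_gradient_id=str(gid),
                control_gradient_id=str(match[0]),
                window=window,
            )
        )
    return sorted(specs, key=lambda s: (s.substrate, s.day))


def aggregate_responders(results: pd.DataFrame) -> dict:
    """Summarize responder calls across days and substrates.

    Returns per-substrate responder sets (union over days), first day of
    response per OTU, per-day responder counts, and the cross-substrate
    accounting in which substrate-only counts exclude the shared set.
    """
    if results.empty or not results["responder"].any():
        return {
            "per_substrate": {},
            "first_day": {},
            "per_day_counts": {},
            "shared": set(),
            "exclusive": {},
        }
    hits = results[results["responder"]]
    per_substrate = {
        sub: set(grp["otu_id"]) for sub, grp in hits.groupby("substrate")
    }
    first_day = {
        sub: grp.groupby("otu_id")["day"].min().to_dict()
        for sub, grp in hits.groupby("substrate")
    }
    per_day = {
        sub: grp.groupby("day")["otu_id"].nunique().to_dict()
        for sub, grp in hits.groupby("substrate")
    }
    subs = list(per_substrate)
    shared = set.intersection(*per_substrate.values()) if len(subs) > 1 else set()
    exclusive = {sub: per_substrate[sub] - shared for sub in subs}
    return {
        "per_substrate": per_substrate,
        "first_day": first_day,
        "per_day_counts": per_day,
        "shared": shared,
        "exclusive": exclusive,
    }
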
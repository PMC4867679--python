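"""Synthetic CsCl-gradient and time-course amplicon data with known truth.

The generative model mirrors the physics of isopycnic DNA-SIP: each OTU's
unlabeled DNA equilibrates at a buoyant density set by its genome G+C
content (rho = 1.660 + 0.098 * GC), 13C incorporation shifts that center
upward by atom_excess * max_shift, and DNA spreads around its center as a
Gaussian (narrow core plus a small wide-tailed component representing
diffusion and fragment-length smearing). Fractions sample fixed density
bins; sequencing is compositional, so per-fraction counts are drawn
Dirichlet-multinomial at a fixed depth regardless of DNA mass, which makes
unlabeled OTUs appear at roughly constant relative abundance across a
gradient while labeled OTUs are enriched toward high density.

A separate generator produces non-fractionated community time courses with
per-OTU log-linear abundance trends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import CountMatrix, SampleMeta

__all__ = [
    "SimConfig",
    "simulate_gradient_pair",
    "simulate_experiment",
    "simulate_timecourse",
    "amendment_c_fraction",
]

BASE_DENSITY_INTERCEPT = 1.660  # g/mL at GC = 0
BASE_DENSITY_SLOPE = 0.098  # g/mL per unit GC fraction


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the gradient/time-course generator.

    Defaults emulate the experimental design this package targets: ~20
    sequenced fractions per gradient spanning 1.67-1.77 g/mL, paired
    labeled/control gradients per sampling day (days 1, 3, 7, 14, 30), and
    a soil-like community of lognormally abundant OTUs whose genome G+C
    content is Beta-distributed around 50% (unlabeled buoyant density
    ~1.709 +/- 0.005 g/mL). Full 13C labeling shifts density by
    ``max_shift`` = 0.036 g/mL; partial labeling scales linearly with
    ``atom_excess``.
    """

    n_otus: int = 100
    abund_sigma: float = 1.0  # lognormal sigma of relative abundance
    gc_beta_a: float = 50.0
    gc_beta_b: float = 50.0
    labeled_otus: tuple[str, ...] | None = None
    n_labeled: int = 10  # used when labeled_otus is None
    atom_excess: float = 1.0
    max_shift: float = 0.036  # g/mL density shift at atom_excess 1
    profile_sd: float = 0.004  # g/mL core smearing of one OTU's DNA
    tail_fraction: float = 0.05  # share of DNA in the wide-tailed component
    tail_sd: float = 0.02  # g/mL sd of the wide component
    density_range: tuple[float, float] = (1.67, 1.77)
    n_fractions: int = 20
    depth: int = 10_000  # reads per fraction
    concentration: float = 300.0  # Dirichlet concentration (overdispersion)
    days: tuple[int, ...] = (1, 3, 7, 14, 30)
    treatments: tuple[str, ...] = ("13C-xylose", "13C-cellulose")
    n_replicates: int = 3  # time-course replicates per day
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.atom_excess <= 1.0:
            raise ValueError("atom_excess must lie in [0, 1]")
        if self.max_shift <= 0:
            raise ValueError("max_shift must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_fractions < 2:
            raise ValueError("need at least two fractions per gradient")
        if not 0.0 <= self.tail_fraction < 1.0:
            raise ValueError("tail_fraction must lie in [0, 1)")

    def otu_ids(self) -> list[str]:
        return [f"OTU.{i + 1}" for i in range(self.n_otus)]

    def fraction_densities(self) -> np.ndarray:
        return np.linspace(*self.density_range, self.n_fractions)


def _community_truth(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-OTU ground truth: GC, base density, abundance, labeling."""
    ids = cfg.otu_ids()
    gc = rng.beta(cfg.gc_beta_a, cfg.gc_beta_b, size=cfg.n_otus)
    abund = rng.lognormal(mean=0.0, sigma=cfg.abund_sigma, size=cfg.n_otus)
    abund /= abund.sum()
    if cfg.labeled_otus is not None:
        unknown = [o for o in cfg.labeled_otus if o not in ids]
        if unknown:
            raise ValueError(f"labeled OTU id(s) not among simulated OTUs: {unknown}")
        labeled = np.isin(ids, list(cfg.labeled_otus))
    else:
        pick = rng.choice(cfg.n_otus, size=min(cfg.n_labeled, cfg.n_otus), replace=False)
        labeled = np.zeros(cfg.n_otus, dtype=bool)
        labeled[pick] = True
    truth = pd.DataFrame(
        {
            "gc": gc,
            "base_density": BASE_DENSITY_INTERCEPT + BASE_DENSITY_SLOPE * gc,
            "rel_abundance": abund,
            "labeled": labeled,
            "shift": np.where(labeled, cfg.atom_excess * cfg.max_shift, 0.0),
        },
        index=pd.Index(ids, name="otu_id"),
    )
    return truth


def _fraction_masses(
    centers: np.ndarray, abund: np.ndarray, cfg: SimConfig
) -> np.ndarray:
    """Expected DNA mass of each OTU (rows) in each fraction bin (columns)."""
    dens = cfg.fraction_densities()
    step = dens[1] - dens[0]
    edges = np.concatenate([[dens[0] - step / 2], (dens[:-1] + dens[1:]) / 2, [dens[-1] + step / 2]])

    def gauss_mass(sd: float) -> np.ndarray:
        z = (edges[None, :] - centers[:, None]) / sd
        cdf = norm.cdf(z)
        return cdf[:, 1:] - cdf[:, :-1]

    mass = (1 - cfg.tail_fraction) * gauss_mass(cfg.profile_sd)
    if cfg.tail_fraction > 0:
        mass += cfg.tail_fraction * gauss_mass(cfg.tail_sd)
    return abund[:, None] * mass


def _draw_counts(
    masses: np.ndarray, abund: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet-multinomial counts per fraction (fixed sequencing depth)."""
    n_otus, n_frac = masses.shape
    counts = np.zeros((n_otus, n_frac), dtype=np.int64)
    for f in range(n_frac):
        w = masses[:, f]
        total = w.sum()
        if total < 1e-300:
            # near-empty fraction: amplified trace DNA mirrors the community
            p = abund / abund.sum()
        else:
            p = w / total
        if np.isfinite(cfg.concentration) and cfg.concentration > 0:
            gam = rng.gamma(np.clip(cfg.concentration * p, 1e-12, None))
            p = gam / gam.sum()
        counts[:, f] = rng.multinomial(cfg.depth, p)
    return counts


def simulate_gradient_pair(
    cfg: SimConfig,
    day: int = 1,
    substrate: str = "13C-cellulose",
    truth: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, SampleMeta, pd.DataFrame]:
    """One labeled gradient plus its paired control gradient.

    Returns the fraction count matrix, sample metadata (gradient ids
    ``control_d{day}`` and ``{substrate}_d{day}``), and the per-OTU truth
    table. A pre-drawn ``truth`` table (from a previous call) keeps the same
    community across days; otherwise one is drawn from ``cfg.seed``.
    """
    if substrate not in ("13C-xylose", "13C-cellulose"):
        raise ValueError(f"substrate must be a 13C treatment, got {substrate!r}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if truth is None:
        truth = _community_truth(cfg, rng)

    dens = cfg.fraction_densities()
    abund = truth["rel_abundance"].to_numpy()
    frames = {}
    meta_rows = []
    for treatment, shifted in (("control", False), (substrate, True)):
        centers = truth["base_density"].to_numpy() + (truth["shift"].to_numpy() if shifted else 0.0)
        masses = _fraction_masses(centers, abund, cfg)
        counts = _draw_counts(masses, abund, cfg, rng)
        gid = f"{treatment}_d{day}"
        samples = [f"{gid}_f{i + 1:02d}" for i in range(cfg.n_fractions)]
        frames[gid] = pd.DataFrame(counts, index=truth.index, columns=samples)
        for s, rho in zip(samples, dens):
            meta_rows.append(
                {
                    "sample_id": s,
                    "treatment": treatment,
                    "day": day,
                    "gradient_id": gid,
                    "density": rho,
                    "is_fractionated": True,
                }
            )
    counts_df = pd.concat(frames.values(), axis=1)
    meta = SampleMeta(pd.DataFrame(meta_rows).set_index("sample_id"))
    return CountMatrix(counts_df), meta, truth


def simulate_experiment(
    cfg: SimConfig,
) -> tuple[CountMatrix, SampleMeta, pd.DataFrame]:
    """Paired gradients for every treatment x day, one shared community.

    The same OTU truth (abundances, GC, labeling per substrate drawn
    independently) is used across days, as in a destructively sampled
    microcosm series. Control gradients are simulated once per day and
    shared between substrates.
    """
    rng = np.random.default_rng(cfg.seed)
    base_truth = _community_truth(cfg, rng)
    truths = {}
    for substrate in cfg.treatments:
        t = base_truth.copy()
        pick = rng.choice(cfg.n_otus, size=min(cfg.n_labeled, cfg.n_otus), replace=False)
        labeled = np.zeros(cfg.n_otus, dtype=bool)
        labeled[pick] = True
        t["labeled"] = labeled
        t["shift"] = np.where(labeled, cfg.atom_excess * cfg.max_shift, 0.0)
        truths[substrate] = t

    dens = cfg.fraction_densities()
    abund = base_truth["rel_abundance"].to_numpy()
    frames = []
    meta_rows = []

    def add_gradient(treatment: str, day: int, centers: np.ndarray) -> None:
        masses = _fraction_masses(centers, abund, cfg)
        counts = _draw_counts(masses, abund, cfg, rng)
        gid = f"{treatment}_d{day}"
        samples = [f"{gid}_f{i + 1:02d}" for i in range(cfg.n_fractions)]
        frames.append(pd.DataFrame(counts, index=base_truth.index, columns=samples))
        for s, rho in zip(samples, dens):
            meta_rows.append(
                {
                    "sample_id": s,
                    "treatment": treatment,
                    "day": day,
                    "gradient_id": gid,
                    "density": rho,
                    "is_fractionated": True,
                }
            )

    for day in cfg.days:
        add_gradient("control", day, base_truth["base_density"].to_numpy())
        for substrate in cfg.treatments:
            t = truths[substrate]
            add_gradient(substrate, day, (t["base_density"] + t["shift"]).to_numpy())

    counts_df = pd.concat(frames, axis=1)
    meta = SampleMeta(pd.DataFrame(meta_rows).set_index("sample_id"))
    truth_long = pd.concat(truths, names=["substrate", "otu_id"])
    return CountMatrix(counts_df), meta, truth_long.reset_index()


def simulate_timecourse(
    cfg: SimConfig,
    slopes: np.ndarray | dict | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, SampleMeta, pd.DataFrame]:
    """Non-fractionated community time course with known log-linear trends.

    ``slopes`` gives each OTU's trend in log2 relative abundance per day
    rank (days are ranked 1..k); default zero for all OTUs. Replicate
    samples per day receive independent Dirichlet-multinomial counts.
    """
    if len(cfg.days) < 3:
        raise ValueError("time course needs >= 3 days")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ids = cfg.otu_ids()
    if slopes is None:
        slope_vec = np.zeros(cfg.n_otus)
    elif isinstance(slopes, dict):
        slope_vec = np.array([slopes.get(o, 0.0) for o in ids])
    else:
        slope_vec = np.asarray(slopes, dtype=float)
        if slope_vec.shape != (cfg.n_otus,):
            raise ValueError(f"slopes must have length n_otus={cfg.n_otus}")

    truth = _community_truth(cfg, rng)
    truth = truth.drop(columns=["labeled", "shift"])
    truth["slope_log2_per_rank"] = slope_vec

    abund0 = truth["rel_abundance"].to_numpy()
    frames = {}
    meta_rows = []
    for rank, day in enumerate(sorted(cfg.days), start=1):
        weights = abund0 * np.exp2(slope_vec * (rank - 1))
        p0 = weights / weights.sum()
        for rep in range(1, cfg.n_replicates + 1):
            sid = f"bulk_d{day}_r{rep}"
            p = p0
            if np.isfinite(cfg.concentration) and cfg.concentration > 0:
                gam = rng.gamma(np.clip(cfg.concentration * p0, 1e-12, None))
                p = gam / gam.sum()
            frames[sid] = rng.multinomial(cfg.depth, p)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "treatment": "control",
                    "day": day,
                    "gradient_id": "bulk",
                    "density": np.nan,
                    "is_fractionated": False,
                }
            )
    counts_df = pd.DataFrame(frames, index=pd.Index(ids, name="otu_id"))
    meta = SampleMeta(pd.DataFrame(meta_rows).set_index("sample_id"))
    return CountMatrix(counts_df), meta, truth


def amendment_c_fraction(soil_c: float, additions: dict) -> pd.DataFrame:
    """Percent of total soil C contributed by each amendment component.

    ``soil_c`` and the ``additions`` values are in mg C per g dry-weight
    soil. Percentages are relative to total C (soil plus the whole
    amendment). Raw values are kept alongside nearest-integer report values.
    """
    if soil_c <= 0:
        raise ValueError("soil carbon must be positive")
    if any(v < 0 for v in additions.values()):
        raise ValueError("amendment additions must be non-negative")
    total_added = sum(additions.values())
    denom = soil_c + total_added
    rows = {k: 100.0 * v / denom for k, v in additions.items()}
    rows["total_amendment"] = 100.0 * total_added / denom
    out = pd.DataFrame({"percent": pd.Series(rows)})
    out["percent_rounded"] = out["percent"].round().astype(int)
    return out
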
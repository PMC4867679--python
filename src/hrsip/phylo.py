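"""Phylogenetic ecology of labeled-OTU sets.

Weighted UniFrac distances between fraction communities, phylogenetic
clustering z-scores (NRI from mean pairwise distance, NTI from mean
nearest-taxon distance) against permutation nulls, and the consenTRAIT
average clade depth of a binary trait.

Sign convention: NRI = -(MPD_obs - mean(MPD_null)) / sd(MPD_null), so
positive values indicate phylogenetic clustering; likewise for NTI.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "PhyloMetricResult",
    "weighted_unifrac",
    "mpd_mntd",
    "nri_nti",
    "nri_nti_exhaustive",
    "independent_swap",
    "consentrait",
]


@dataclass
class PhyloMetricResult:
    """A phylogenetic metric with its null distribution summary."""

    metric: str
    value: float
    observed: float | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    n_null: int | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# weighted UniFrac


def weighted_unifrac(
    tree: TreeNode, p1, p2, normalized: bool = False
) -> float:
    """Weighted UniFrac distance between two tip-proportion vectors.

    ``p1``/``p2`` map tip names to proportions (dict or Series); tips not
    mentioned carry zero. Raw form: sum over branches of
    b * |A_b - B_b| with A_b, B_b the subtree proportion sums; the
    normalized form divides by sum of b * (A_b + B_b).
    """
    p1 = pd.Series(p1, dtype=float)
    p2 = pd.Series(p2, dtype=float)
    tip_names = {t.name for t in tree.tips()}
    missing = sorted((set(p1.index) | set(p2.index)) - tip_names)
    if missing:
        raise KeyError(f"tips absent from tree: {missing}")

    num = 0.0
    den = 0.0
    subtree: dict[int, tuple[float, float]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            a = float(p1.get(node.name, 0.0))
            b = float(p2.get(node.name, 0.0))
        else:
            a = sum(subtree[id(c)][0] for c in node.children)
            b = sum(subtree[id(c)][1] for c in node.children)
        subtree[id(node)] = (a, b)
        length = node.length or 0.0
        if node.parent is not None and length > 0:
            num += length * abs(a - b)
            den += length * (a + b)
    if not normalized:
        return num
    if den == 0:
        return 0.0
    return num / den


# ---------------------------------------------------------------------------
# MPD / MNTD and clustering z-scores


def _distance_matrix(tree: TreeNode) -> tuple[np.ndarray, dict[str, int]]:
    dm = tree.tip_tip_distances()
    index = {name: i for i, name in enumerate(dm.ids)}
    return dm.data, index


def _mpd_mntd_from_dm(dm: np.ndarray, idx: np.ndarray) -> tuple[float, float]:
    sub = dm[np.ix_(idx, idx)]
    n = len(idx)
    mpd = sub[np.triu_indices(n, k=1)].mean()
    np.fill_diagonal(sub, np.inf)
    mntd = sub.min(axis=1).mean()
    return float(mpd), float(mntd)


def mpd_mntd(tree: TreeNode, tip_set) -> tuple[float, float]:
    """Mean pairwise and mean nearest-taxon patristic distance of a tip set."""
    dm, index = _distance_matrix(tree)
    tip_set = list(tip_set)
    if len(tip_set) < 2:
        raise ValueError("MPD/MNTD need at least two tips")
    unknown = [t for t in tip_set if t not in index]
    if unknown:
        raise KeyError(f"tips absent from tree: {unknown}")
    idx = np.array([index[t] for t in tip_set])
    return _mpd_mntd_from_dm(dm, idx)


def _zscores(
    obs: tuple[float, float], null: np.ndarray, n_null: int, seed, ddof: int = 1
) -> dict[str, PhyloMetricResult]:
    out = {}
    for col, metric, o in ((0, "NRI", obs[0]), (1, "NTI", obs[1])):
        mean = float(null[:, col].mean())
        sd = float(null[:, col].std(ddof=ddof))
        if sd == 0:
            raise ValueError(f"{metric}: null distribution has zero variance")
        out[metric] = PhyloMetricResult(
            metric=metric,
            value=-(o - mean) / sd,
            observed=o,
            null_mean=mean,
            null_sd=sd,
            n_null=n_null,
            seed=seed,
        )
    return out


def nri_nti(
    tree: TreeNode,
    tip_set,
    pool=None,
    n_null: int = 999,
    null_model: str = "label_shuffle",
    seed: int | None = None,
    communities: pd.DataFrame | None = None,
) -> dict[str, PhyloMetricResult]:
    """NRI/NTI clustering z-scores for a tip set against a permutation null.

    ``label_shuffle`` (default) draws random tip sets of the same size from
    the species pool (all tree tips unless ``pool`` is given). The
    ``independent_swap`` null randomizes a presence/absence community matrix
    (rows = communities, columns = tips; must include the focal set as a
    row named by any id whose entries match ``tip_set``) with checkerboard
    swaps that preserve row and column totals, recomputing the metric on the
    focal row each draw.
    """
    if n_null < 99:
        raise ValueError("use n_null >= 99 for stable z-scores")
    dm, index = _distance_matrix(tree)
    tip_set = list(dict.fromkeys(tip_set))
    unknown = [t for t in tip_set if t not in index]
    if unknown:
        raise KeyError(f"tips absent from tree: {unknown}")
    if len(tip_set) < 2:
        raise ValueError("MPD/MNTD need at least two tips")
    idx_obs = np.array([index[t] for t in tip_set])
    obs = _mpd_mntd_from_dm(dm, idx_obs)
    rng = np.random.default_rng(seed)

    null = np.empty((n_null, 2))
    if null_model == "label_shuffle":
        pool_tips = list(pool) if pool is not None else list(index)
        unknown = [t for t in pool_tips if t not in index]
        if unknown:
            raise KeyError(f"pool tips absent from tree: {unknown}")
        pool_idx = np.array([index[t] for t in pool_tips])
        if len(pool_idx) < len(tip_set):
            raise ValueError("species pool smaller than the tip set")
        for i in range(n_null):
            draw = rng.choice(pool_idx, size=len(tip_set), replace=False)
            null[i] = _mpd_mntd_from_dm(dm, draw)
    elif null_model == "independent_swap":
        if communities is None:
            raise ValueError(
                "independent_swap requires a community matrix; it is a "
                "community-matrix null and degenerates for a single set"
            )
        comm = communities.astype(bool)
        focal_rows = comm.index[
            comm.apply(lambda r: set(comm.columns[r]) == set(tip_set), axis=1)
        ]
        if len(focal_rows) == 0:
            raise ValueError("community matrix has no row matching the focal tip set")
        focal = comm.index.get_loc(focal_rows[0])
        mat = comm.to_numpy()
        col_idx = np.array([index[c] for c in comm.columns])
        for i in range(n_null):
            shuffled = independent_swap(mat, rng)
            members = col_idx[shuffled[focal]]
            null[i] = _mpd_mntd_from_dm(dm, members)
    else:
        raise ValueError(f"unknown null model {null_model!r}")
    return _zscores(obs, null, n_null, seed)


def independent_swap(matrix: np.ndarray, rng: np.random.Generator, n_swaps: int | None = None) -> np.ndarray:
    """Randomize a presence/absence matrix preserving row and column sums.

    Repeated 2x2 checkerboard swaps (the independent-swap algorithm for
    community null models).
    """
    mat = matrix.astype(bool).copy()
    nr, nc = mat.shape
    if n_swaps is None:
        n_swaps = max(1000, 10 * int(mat.sum()))
    done = 0
    attempts = 0
    max_attempts = n_swaps * 50
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        r = rng.choice(nr, size=2, replace=False)
        c = rng.choice(nc, size=2, replace=False)
        sub = mat[np.ix_(r, c)]
        if sub[0, 0] == sub[1, 1] and sub[0, 1] == sub[1, 0] and sub[0, 0] != sub[0, 1]:
            mat[np.ix_(r, c)] = ~sub
            done += 1
    return mat


def nri_nti_exhaustive(
    tree: TreeNode, tip_set, pool=None, ddof: int = 1
) -> dict[str, PhyloMetricResult]:
    """Exact NRI/NTI by enumerating every same-size tip set from the pool.

    Oracle counterpart of the Monte-Carlo null; feasible only on small
    trees. ``ddof=1`` treats the enumerated sets as null draws (sample sd,
    the convention of common ecophylogenetic software); ``ddof=0`` uses the
    population sd of the exact null distribution, which is what the
    Monte-Carlo sample sd converges to as the number of draws grows.
    """
    dm, index = _distance_matrix(tree)
    tip_set = list(dict.fromkeys(tip_set))
    idx_obs = np.array([index[t] for t in tip_set])
    obs = _mpd_mntd_from_dm(dm, idx_obs)
    pool_tips = list(pool) if pool is not None else list(index)
    combos = list(itertools.combinations([index[t] for t in pool_tips], len(tip_set)))
    null = np.array([_mpd_mntd_from_dm(dm, np.array(c)) for c in combos])
    return _zscores(obs, null, len(combos), None, ddof=ddof)


# ---------------------------------------------------------------------------
# consenTRAIT


def consentrait(
    tree: TreeNode,
    positive_tips,
    consensus: float = 0.90,
    singleton_rule: str = "half_branch",
) -> PhyloMetricResult:
    """Average clade depth (tau_D) of a binary trait.

    Finds maximal internal clades in which at least ``consensus`` of tips are
    trait-positive; each clade contributes the mean patristic distance from
    its root node to its positive tips. Positive tips in no qualifying clade
    are singletons contributing half their terminal branch length
    (``singleton_rule="half_branch"``) or zero (``"zero"``). tau_D is the
    mean over clades and singletons.
    """
    positive = set(positive_tips)
    if not positive:
        raise ValueError("positive tip set is empty")
    tip_names = {t.name for t in tree.tips()}
    unknown = sorted(positive - tip_names)
    if unknown:
        raise KeyError(f"tips absent from tree: {unknown}")
    if singleton_rule not in ("half_branch", "zero"):
        raise ValueError(f"unknown singleton rule {singleton_rule!r}")

    depths: list[float] = []
    covered: set[str] = set()

    def node_tips(node: TreeNode) -> list[TreeNode]:
        return list(node.tips())

    def tip_depths(node: TreeNode, targets: set[str]) -> list[float]:
        out = []

        def walk(n: TreeNode, acc: float) -> None:
            if n.is_tip():
                if n.name in targets:
                    out.append(acc)
                return
            for c in n.children:
                walk(c, acc + (c.length or 0.0))

        walk(node, 0.0)
        return out

    def visit(node: TreeNode) -> None:
        if node.is_tip():
            return
        tips = node_tips(node)
        names = {t.name for t in tips}
        frac = len(names & positive) / len(names)
        if frac >= consensus:
            depths.append(float(np.mean(tip_depths(node, names & positive))))
            covered.update(names & positive)
            return  # maximal clade: do not descend
        for child in node.children:
            visit(child)

    visit(tree)

    for tip in tree.tips():
        if tip.name in positive and tip.name not in covered:
            depths.append(0.5 * (tip.length or 0.0) if singleton_rule == "half_branch" else 0.0)

    return PhyloMetricResult(metric="consenTRAIT", value=float(np.mean(depths)))
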
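"""Trait-space construction and abundance-weighted functional diversity.

Traits are binary, so the Gower distance reduces to the simple mismatch
proportion.  The trait space used for index computation is the PCA score
space of the (column-centred) incidence matrix: scores are treated directly
as Euclidean coordinates for FRic (convex-hull volume), FDis
(abundance-weighted mean distance to the weighted centroid) and FDiv
(Villeger's divergence relative to the hull-vertex gravity centre).  FRic is
reported as the raw hull volume, without standardization by the global
maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import squareform, pdist

from .data_model import AlignedDataset, DistanceMatrix, TraitMatrix
from .alpha_gamma import AccumulationCurve, PermutationTestResult, _one_tailed_p, curve_auc

logger = logging.getLogger("pondiv")

#: Hull-based indices (FRic, FDiv) are computed on at most this many axes.
#: Binary-trait PCA scores are strongly clustered, so Qhull facet counts
#: explode beyond ~5 axes (intractable inside permutation loops for ~100
#: species), and a hull volume is only meaningful with far more points than
#: dimensions.  FDis uses all retained axes.
DEFAULT_HULL_DIM = 4


@dataclass
class TraitSpace:
    """Species coordinates in a reduced (PCA) trait space."""

    species: list[str]
    coords: np.ndarray              # species x axes_retained
    axes_retained: int
    variance_explained: np.ndarray  # fractions over all non-trivial axes

    def take(self, species: Sequence[str]) -> np.ndarray:
        idx = [self.species.index(s) for s in species]
        return self.coords[idx]


@dataclass
class FunctionalIndices:
    """Per-pond FRic / FDis / FDiv with undefined-value flags."""

    table: pd.DataFrame  # columns: FRic, FDis, FDiv, n_species_used (NaN = undefined)


def gower_distance(tm: TraitMatrix) -> DistanceMatrix:
    """Pairwise Gower distance between species over binary traits
    (= proportion of mismatching traits).  Constant trait columns are
    retained (they contribute 0) and logged."""
    x = tm.incidence.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 species")
    constant = [t for t, col in zip(tm.traits, x.T) if np.all(col == col[0])]
    if constant:
        logger.info("constant trait columns retained (contribute 0): %s", constant)
    d = squareform(pdist(x, metric="cityblock") / x.shape[1])
    return DistanceMatrix(tm.species, d)


def pca_reduce(tm: TraitMatrix, max_axes: int = 10) -> TraitSpace:
    """PCA of the column-centred incidence matrix via eigendecomposition of
    its covariance; retains k = min(max_axes, S-1, T) axes ordered by
    decreasing variance, with a deterministic sign convention (the
    largest-magnitude loading of each axis is positive)."""
    x = tm.incidence.to_numpy(dtype=float)
    s, t = x.shape
    if s < 2:
        raise ValueError("PCA needs at least 2 species (no variance with 1)")
    xc = x - x.mean(axis=0)
    cov = (xc.T @ xc) / (s - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    k = min(max_axes, s - 1, t)
    total = evals.sum()
    var_frac = evals / total if total > 0 else evals
    v = evecs[:, :k]
    for j in range(k):  # sign convention
        i = np.argmax(np.abs(v[:, j]))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    coords = xc @ v
    return TraitSpace(tm.species, coords, k, var_frac)


# ---------------------------------------------------------------------------
# Hull helpers
# ---------------------------------------------------------------------------

def _hull(points: np.ndarray) -> ConvexHull | None:
    try:
        return ConvexHull(points)
    except (QhullError, ValueError):
        return None


def _hull_volume(points: np.ndarray) -> float | None:
    """Convex-hull volume in the dimension of ``points``; 1-D hull = range.
    On degeneracy the dimension is reduced once (drop the last axis), then
    the result is undefined."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)  # duplicates common with binary traits
    for attempt in range(2):
        if pts.shape[1] == 0:
            return None
        if pts.shape[1] == 1:
            rng_ = float(pts.max() - pts.min())
            if rng_ > 0:
                return rng_
        else:
            hull = _hull(pts)
            if hull is not None:
                return float(hull.volume)
        pts = pts[:, :-1]
    return None


def functional_richness(
    space: TraitSpace, present: Sequence[str], max_dim: int = DEFAULT_HULL_DIM
) -> float | None:
    """Convex-hull volume of the present species on the first
    k' = min(max_dim, axes_retained, n_present - 1) axes; None when fewer
    than two species or degenerate after one dimension reduction."""
    present = list(present)
    if len(present) < 2:
        return None
    pts = space.take(present)
    k = min(max_dim, space.axes_retained, len(present) - 1)
    return _hull_volume(pts[:, :k])


def functional_dispersion(
    space: TraitSpace, present: Sequence[str], abundances: Sequence[float]
) -> float:
    """Abundance-weighted mean distance to the abundance-weighted centroid."""
    present = list(present)
    w = np.asarray(abundances, dtype=float)
    if len(present) == 0 or w.sum() <= 0:
        raise ValueError("need >= 1 present species with positive total abundance")
    w = w / w.sum()
    pts = space.take(present)[:, : space.axes_retained]
    centroid = w @ pts
    return float(w @ np.linalg.norm(pts - centroid, axis=1))


def functional_divergence(
    space: TraitSpace,
    present: Sequence[str],
    abundances: Sequence[float],
    max_dim: int = DEFAULT_HULL_DIM,
) -> float | None:
    """Villeger functional divergence.

    With G the gravity centre of the hull vertices, d_i the distances of all
    present species to G, d_bar their unweighted mean, and w the relative
    abundances: FDiv = (sum w_i (d_i - d_bar) + d_bar) /
    (sum w_i |d_i - d_bar| + d_bar).  None when no hull exists.
    """
    present = list(present)
    if len(present) < 3:
        return None
    w = np.asarray(abundances, dtype=float)
    w = w / w.sum()
    k = min(max_dim, space.axes_retained, len(present) - 1)
    pts = space.take(present)[:, :k]

    def hull_centre(p: np.ndarray) -> np.ndarray | None:
        """Gravity centre of the hull vertices (unique points only)."""
        if p.shape[1] == 0:
            return None
        u = np.unique(p, axis=0)
        if p.shape[1] == 1:
            lo, hi = u[:, 0].min(), u[:, 0].max()
            return None if lo == hi else np.array([(lo + hi) / 2.0])
        hull = _hull(u)
        return None if hull is None else u[hull.vertices].mean(axis=0)

    g = hull_centre(pts)
    if g is None:  # one dimension-reduction attempt, then undefined
        pts = pts[:, :-1]
        g = hull_centre(pts)
        if g is None:
            return None
    d = np.linalg.norm(pts - g, axis=1)
    d_bar = d.mean()
    dd = float(w @ (d - d_bar))
    dabs = float(w @ np.abs(d - d_bar))
    if dabs + d_bar == 0:
        return None
    return (dd + d_bar) / (dabs + d_bar)


# ---------------------------------------------------------------------------
# Site-level indices and functional rarefaction
# ---------------------------------------------------------------------------

def site_functional_indices(
    ds: AlignedDataset,
    scope: str | Sequence[str] | None = None,
    max_axes: int = 10,
) -> FunctionalIndices:
    """FRic/FDis/FDiv for each pond in ``scope``, in the trait space built
    from the species present anywhere in the scope (per-site filtering),
    weighting by the pond's relative abundances."""
    sub = ds.community.restrict(scope)
    space = pca_reduce(ds.traits, max_axes=max_axes)
    rows = []
    for pond in sub.ponds:
        counts = sub.counts.loc[pond]
        present = [s for s in sub.species if counts[s] > 0]
        w = counts[present].to_numpy(dtype=float)
        fric = functional_richness(space, present)
        fdis = functional_dispersion(space, present, w) if present else np.nan
        fdiv = functional_divergence(space, present, w)
        rows.append(
            {
                "pond": pond,
                "FRic": np.nan if fric is None else fric,
                "FDis": fdis,
                "FDiv": np.nan if fdiv is None else fdiv,
                "n_species_used": len(present),
            }
        )
    return FunctionalIndices(pd.DataFrame(rows).set_index("pond"))


def pooled_functional_metrics(
    ds: AlignedDataset, space: TraitSpace, ponds: Sequence[str]
) -> dict[str, float]:
    """FRic/FDis/FDiv of the species pooled (abundances summed) over ponds,
    computed in a fixed trait space."""
    pooled = ds.community.counts.loc[list(ponds)].sum(axis=0)
    present = [s for s in ds.community.species if pooled[s] > 0]
    w = pooled[present].to_numpy(dtype=float)
    fric = functional_richness(space, present)
    fdiv = functional_divergence(space, present, w)
    return {
        "FRic": np.nan if fric is None else fric,
        "FDis": functional_dispersion(space, present, w) if present else np.nan,
        "FDiv": np.nan if fdiv is None else fdiv,
    }


def functional_rarefaction(
    ds: AlignedDataset,
    scope: str | Sequence[str] | None = None,
    n_reps: int = 100,
    seed: int | None = None,
    max_axes: int = 10,
) -> dict[str, AccumulationCurve]:
    """Cumulative FRic/FDis/FDiv over increasing pond subsets.

    For each of ``n_reps`` random pond orderings, species are pooled over
    each prefix and the three metrics computed in the scope-level trait
    space; returns the mean +- sd curve per metric.  Undefined values at a
    step are excluded from that step's mean (count logged).
    """
    sub_cm = ds.community.restrict(scope)
    ponds = list(sub_cm.ponds)
    n = len(ponds)
    if n < 2:
        raise ValueError("functional rarefaction needs >= 2 ponds")
    space = pca_reduce(ds.traits, max_axes=max_axes)
    rng = np.random.default_rng(seed)
    metrics = ("FRic", "FDis", "FDiv")
    vals = {m: np.full((n_reps, n), np.nan) for m in metrics}
    for r in range(n_reps):
        order = rng.permutation(n)
        for m_steps in range(1, n + 1):
            prefix = [ponds[i] for i in order[:m_steps]]
            res = pooled_functional_metrics(ds, space, prefix)
            for m in metrics:
                vals[m][r, m_steps - 1] = res[m]
    out: dict[str, AccumulationCurve] = {}
    for m in metrics:
        v = vals[m]
        n_undef = int(np.isnan(v).sum())
        if n_undef:
            logger.info("functional rarefaction: %d undefined %s values excluded", n_undef, m)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(v, axis=0)
            sd = np.nanstd(v, axis=0, ddof=0)
        out[m] = AccumulationCurve(np.arange(1, n + 1), mean, sd, "random", n_reps)
    return out


def functional_auc(curves: dict[str, AccumulationCurve]) -> dict[str, float]:
    """AUC (plain sum of the mean curve) per functional metric."""
    return {m: curve_auc(c) for m, c in curves.items()}


# ---------------------------------------------------------------------------
# Functional AUC permutation test (fast path)
# ---------------------------------------------------------------------------

def _np_scores(inc: np.ndarray, max_axes: int) -> np.ndarray:
    """PCA scores of a (sub)community's trait rows (sign-free: the metrics
    below are invariant under axis reflection)."""
    xc = inc - inc.mean(axis=0)
    cov = (xc.T @ xc) / max(1, inc.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    k = min(max_axes, inc.shape[0] - 1, inc.shape[1])
    return xc @ evecs[:, order[:k]]


def _pooled_metric_np(
    inc: np.ndarray, pooled: np.ndarray, metric: str, max_axes: int, hull_dim: int
) -> float:
    """FRic/FDis/FDiv of a pooled community, from raw arrays; undefined -> 0."""
    present = np.flatnonzero(pooled > 0)
    if present.size < 2:
        return 0.0
    scores = _np_scores(inc[present], max_axes)
    w = pooled[present].astype(float)
    w = w / w.sum()
    if metric == "FDis":
        centroid = w @ scores
        return float(w @ np.linalg.norm(scores - centroid, axis=1))
    k = min(hull_dim, scores.shape[1], present.size - 1)
    pts = scores[:, :k]
    if metric == "FRic":
        v = _hull_volume(pts)
        return 0.0 if v is None else v
    if metric == "FDiv":
        space = TraitSpace(
            [str(i) for i in range(present.size)], scores, scores.shape[1],
            np.zeros(scores.shape[1]),
        )
        v = functional_divergence(
            space, [str(i) for i in range(present.size)], w, max_dim=hull_dim
        )
        return 0.0 if v is None else v
    raise ValueError(f"unknown metric: {metric!r}")


def functional_auc_permutation_test(
    ds: AlignedDataset,
    region_a: str,
    region_b: str,
    metric: str = "FRic",
    n_perm: int = 200,
    n_reps: int = 10,
    seed: int | None = None,
    max_axes: int = 10,
    hull_dim: int = DEFAULT_HULL_DIM,
) -> PermutationTestResult:
    """Permutation test of the functional rarefaction-AUC difference
    between two regions (observed = AUC(a) - AUC(b)).

    Each permutation reassigns pond labels across regions (group sizes
    preserved); the per-group AUC is the mean over ``n_reps`` random pond
    orderings of the summed cumulative metric, with the trait space rebuilt
    from the permuted group's own species pool (per-site filtering).  The
    p-value is one-tailed in the direction of the observed sign,
    (1+k)/(1+N).
    """
    cm = ds.community
    counts = cm.counts.to_numpy(dtype=float)
    inc = ds.traits.incidence.to_numpy(dtype=float)
    idx_a = np.array([cm.ponds.index(p) for p in cm.ponds_in(region_a)])
    idx_b = np.array([cm.ponds.index(p) for p in cm.ponds_in(region_b)])
    rng = np.random.default_rng(seed)

    def group_auc(rows: np.ndarray) -> float:
        total = 0.0
        for _ in range(n_reps):
            order = rng.permutation(rows)
            pooled = np.cumsum(counts[order], axis=0)
            total += sum(
                _pooled_metric_np(inc, pooled[m], metric, max_axes, hull_dim)
                for m in range(len(rows))
            )
        return total / n_reps

    observed = group_auc(idx_a) - group_auc(idx_b)
    both = np.concatenate([idx_a, idx_b])
    n_a = idx_a.size
    null = np.empty(n_perm)
    for r in range(n_perm):
        perm = rng.permutation(both)
        null[r] = group_auc(perm[:n_a]) - group_auc(perm[n_a:])
    p, alt = _one_tailed_p(observed, null, n_perm)
    return PermutationTestResult(
        observed=observed, null_values=null, p_value=p, n_perm=n_perm,
        seed=seed, alternative=alt,
    )
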
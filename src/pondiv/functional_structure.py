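"""Null-model functional community structure.

Two complementary analyses:

* **SES.MPD** — abundance-weighted mean pairwise functional (Gower)
  distance per pond, standardized against a taxa-label randomization null
  (species labels shuffled jointly on the rows/columns of the distance
  matrix).  Negative values indicate functional clustering (environmental
  filtering), positive values overdispersion.

* **Functional overlap index** — convex-hull volumes of each region's
  species in a fixed 3-axis PCA trait space built once from the pooled
  species set: overlap = (V_a + V_b - V_combined) / V_combined, 0 meaning
  no shared trait space and 1 complete overlap, with a permutation test
  that reshuffles species region membership (preserving the observed counts
  of A-only / B-only / shared species; the plain proportion of permuted
  indices >= observed is the one-tailed p-value).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .data_model import AlignedDataset, DistanceMatrix, TraitMatrix
from .functional_diversity import gower_distance, pca_reduce

logger = logging.getLogger("pondiv")


@dataclass
class SesMpdResult:
    """Per-pond observed MPD, null moments, SES and rank p (NaN-flagged when
    the null has zero spread or the pond has < 2 species)."""

    table: pd.DataFrame  # columns: mpd_obs, null_mean, null_sd, ses, p_rank, defined
    n_runs: int
    seed: int | None


@dataclass
class OverlapResult:
    v_a: float
    v_b: float
    v_combined: float
    overlap_index: float
    p_value: float | None
    n_perm: int
    null_values: np.ndarray | None
    n_failed: int
    seed: int | None


# ---------------------------------------------------------------------------
# MPD / SES.MPD
# ---------------------------------------------------------------------------

def mpd_weighted(
    dist: DistanceMatrix | np.ndarray,
    abundances: Sequence[float],
    present: Sequence[int] | None = None,
) -> float:
    """Abundance-weighted mean pairwise distance:
    sum_{i != j} w_i w_j d_ij / sum_{i != j} w_i w_j."""
    d = dist.d if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    w = np.asarray(abundances, dtype=float)
    if present is not None:
        idx = np.asarray(list(present))
        d = d[np.ix_(idx, idx)]
    if w.size != d.shape[0]:
        raise ValueError("abundance length does not match distance matrix")
    if (w > 0).sum() < 2:
        raise ValueError("MPD needs >= 2 present species")
    w = w / w.sum()
    num = w @ d @ w  # diagonal is 0
    den = 1.0 - (w**2).sum()
    return float(num / den)


def ses_mpd(
    ds: AlignedDataset,
    n_runs: int = 999,
    seed: int | None = None,
    abundance_weighted: bool = True,
    exhaustive: bool = False,
) -> SesMpdResult:
    """Standardized effect size of MPD per pond under taxa-label
    randomization (rows/columns of the pooled Gower matrix shuffled
    jointly, one shuffle per run applied to every pond, as in picante).

    ``exhaustive=True`` enumerates all S! label permutations (small pools
    only) instead of sampling ``n_runs`` of them.  ``p_rank`` is the rank of
    the observed value among observed+null (ties averaged), divided by
    (n_runs + 1).
    """
    dist = gower_distance(ds.traits)
    d = dist.d
    s = d.shape[0]
    counts = ds.community.counts
    weights = []
    for pond in ds.community.ponds:
        w = counts.loc[pond].to_numpy(dtype=float)
        if not abundance_weighted:
            w = (w > 0).astype(float)
        weights.append(w)

    def pond_mpd(dmat: np.ndarray, w: np.ndarray) -> float:
        if (w > 0).sum() < 2:
            return np.nan
        return mpd_weighted(dmat, w)

    obs = np.array([pond_mpd(d, w) for w in weights])

    if exhaustive:
        perms = [np.array(p) for p in itertools.permutations(range(s))]
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(s) for _ in range(n_runs)]
    null = np.empty((len(perms), len(weights)))
    for r, perm in enumerate(perms):
        dp = d[np.ix_(perm, perm)]
        null[r] = [pond_mpd(dp, w) for w in weights]

    null_mean = np.nanmean(null, axis=0)
    null_sd = np.nanstd(null, axis=0, ddof=1)
    defined = np.isfinite(obs) & (null_sd > 1e-12)
    ses = np.where(defined, (obs - null_mean) / np.where(null_sd > 0, null_sd, 1.0), 0.0)
    n_eff = null.shape[0]
    p_rank = np.empty(len(weights))
    for i in range(len(weights)):
        if not np.isfinite(obs[i]):
            p_rank[i] = np.nan
            continue
        col = null[:, i]
        p_rank[i] = ((col < obs[i]).sum() + 0.5 * (col == obs[i]).sum() + 1) / (n_eff + 1)
    table = pd.DataFrame(
        {
            "mpd_obs": obs,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "ses": ses,
            "p_rank": p_rank,
            "defined": defined,
        },
        index=ds.community.ponds,
    )
    return SesMpdResult(table=table, n_runs=len(perms), seed=seed)


# ---------------------------------------------------------------------------
# Convex-hull overlap
# ---------------------------------------------------------------------------

def hull_volume_3d(points: np.ndarray) -> float:
    """Convex-hull volume of species coordinates on the first three PCA
    axes; raises on fewer than 4 points or a degenerate (coplanar) cloud."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected an n x 3 coordinate array")
    if pts.shape[0] < 4:
        raise ValueError(
            "convex hull volume needs >= 4 points (reduce the dimension for smaller sets)"
        )
    try:
        return float(ConvexHull(pts).volume)
    except QhullError as err:
        raise ValueError(
            "degenerate point cloud (coplanar/collinear); reduce the dimension"
        ) from err


def overlap_index(v_a: float, v_b: float, v_combined: float) -> float:
    """Functional overlap = (V_a + V_b - V_combined) / V_combined.

    0 means no overlap of the two hulls, 1 complete overlap (identical
    occupied trait volumes)."""
    if min(v_a, v_b, v_combined) < 0:
        raise ValueError("volumes must be non-negative")
    if v_combined <= 0:
        raise ValueError("combined hull volume must be positive")
    return (v_a + v_b - v_combined) / v_combined


def overlap_permutation_test(
    tm: TraitMatrix,
    membership: Mapping[str, str | set[str] | Sequence[str]],
    n_perm: int = 999,
    seed: int | None = None,
    n_axes: int = 3,
    p_convention: str = "plain",
) -> OverlapResult:
    """Observed overlap index of the two regional hulls in the pooled
    ``n_axes``-axis PCA trait space, with a permutation test that reshuffles
    species region membership while preserving the observed counts of
    region-A-only / region-B-only / shared species (the PCA space is fixed).

    ``membership`` maps each species of ``tm`` to a region label or to a set
    of labels (shared species).  p is one-tailed for overlap >= observed;
    convention "plain" = k/N (no +1 correction), "plus_one" = (1+k)/(1+N).
    Degenerate permuted hulls are resampled once, then tallied as missing.
    """
    species = tm.species
    regions: list[str] = sorted(
        {r for m in membership.values() for r in ([m] if isinstance(m, str) else list(m))}
    )
    if len(regions) != 2:
        raise ValueError(f"need exactly 2 regions, got {regions}")
    ra, rb = regions
    classes = []
    for s in species:
        m = membership[s]
        mset = {m} if isinstance(m, str) else set(m)
        if mset == {ra, rb}:
            classes.append("both")
        elif mset == {ra}:
            classes.append("a")
        elif mset == {rb}:
            classes.append("b")
        else:
            raise ValueError(f"bad membership for species {s!r}: {m!r}")
    classes = np.array(classes)
    n_a_only = int((classes == "a").sum())
    n_b_only = int((classes == "b").sum())
    n_both = int((classes == "both").sum())

    space = pca_reduce(tm, max_axes=n_axes)
    coords = space.coords[:, :n_axes]
    if coords.shape[1] < n_axes:
        raise ValueError("too few informative trait axes for the requested space")

    def volumes(cls: np.ndarray) -> tuple[float, float]:
        pts_a = coords[(cls == "a") | (cls == "both")]
        pts_b = coords[(cls == "b") | (cls == "both")]
        return hull_volume_3d(pts_a), hull_volume_3d(pts_b)

    v_combined = hull_volume_3d(coords)
    v_a, v_b = volumes(classes)
    observed = overlap_index(v_a, v_b, v_combined)

    rng = np.random.default_rng(seed)
    template = np.array(["a"] * n_a_only + ["b"] * n_b_only + ["both"] * n_both)
    null: list[float] = []
    n_failed = 0
    for _ in range(n_perm):
        value = None
        for _attempt in range(2):  # one resample on degeneracy
            cls = template[rng.permutation(len(template))]
            try:
                va, vb = volumes(cls)
                value = overlap_index(va, vb, v_combined)
                break
            except ValueError:
                continue
        if value is None:
            n_failed += 1
        else:
            null.append(value)
    if n_failed:
        logger.info("overlap permutation: %d degenerate permutations dropped", n_failed)
    null_arr = np.array(null)
    k = int((null_arr >= observed).sum())
    n_eff = null_arr.size
    if p_convention == "plain":
        p = k / n_eff if n_eff else None
    elif p_convention == "plus_one":
        p = (1 + k) / (1 + n_eff) if n_eff else None
    else:
        raise ValueError(f"unknown p_convention: {p_convention!r}")
    return OverlapResult(
        v_a=v_a, v_b=v_b, v_combined=v_combined, overlap_index=observed,
        p_value=p, n_perm=n_perm, null_values=null_arr, n_failed=n_failed, seed=seed,
    )
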
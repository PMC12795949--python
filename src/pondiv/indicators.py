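"""Indicator species analysis (IndVal) and regional trait-frequency summary.

IndVal associates species presence-absence patterns with site groups: the
group-equalized specificity A (how concentrated a species' occurrence is in
a group, correcting for unequal group sizes) times fidelity B (the fraction
of the group's ponds occupied), stat = sqrt(A * B) for the best single
group, with a pond-label permutation p-value.  The trait summary counts, per
pond, how many occurring species carry each trait, averages within regions,
and compares regions per trait with a rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alpha_gamma import wilcoxon_rank_sum
from .data_model import AlignedDataset, CommunityMatrix


@dataclass
class IndicatorResult:
    table: pd.DataFrame  # per species: group, A, B, stat, p_value
    n_perm: int
    seed: int | None


@dataclass
class TraitSiteSummary:
    pond_counts: pd.DataFrame   # pond x trait: number of occurring species with trait
    region_means: pd.DataFrame  # region x trait
    tests: pd.DataFrame         # per trait: W, p_value (NaN when skipped)


def _indval_components(
    occ: np.ndarray, group_sizes: np.ndarray, group_of: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Group-equalized A and B per (group, species)."""
    n_groups = group_sizes.size
    means = np.vstack(
        [occ[group_of == g].mean(axis=0) for g in range(n_groups)]
    )  # group x species mean occurrence
    denom = means.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(denom > 0, means / denom, 0.0)
    return a, means  # B equals the group mean occurrence for binary data


def indval(
    pa: CommunityMatrix,
    groups: dict[str, str] | pd.Series | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    group_equalized: bool = True,
) -> IndicatorResult:
    """IndVal.g of every species for its best single group, with permutation
    p-values (pond group labels reshuffled, (1+k)/(1+N)).  Runs on
    presence-absence; species absent everywhere are excluded with a warning.
    """
    if groups is None:
        groups = pa.region_of
    occ = (pa.counts.to_numpy() > 0).astype(float)
    labels = [groups[p] for p in pa.ponds]
    uniq = sorted(set(labels))
    group_of = np.array([uniq.index(l) for l in labels])
    sizes = np.array([(group_of == g).sum() for g in range(len(uniq))])

    absent = np.flatnonzero(occ.sum(axis=0) == 0)
    if absent.size:
        warnings.warn(
            f"species absent everywhere excluded: {[pa.species[i] for i in absent]}"
        )
    keep = occ.sum(axis=0) > 0
    occ = occ[:, keep]
    species = [s for s, k in zip(pa.species, keep) if k]

    def stats_for(assign: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a, b = _indval_components(occ, sizes, assign)
        if not group_equalized:
            totals = np.vstack([occ[assign == g].sum(axis=0) for g in range(len(uniq))])
            a = np.where(occ.sum(axis=0) > 0, totals / occ.sum(axis=0), 0.0)
        stat = np.sqrt(a * b)
        best = stat.argmax(axis=0)
        cols = np.arange(stat.shape[1])
        return stat[best, cols], best, (a[best, cols], b[best, cols])

    obs_stat, best_group, (a_best, b_best) = stats_for(group_of)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(species), dtype=int)
    for _ in range(n_perm):
        perm_stat, _, _ = stats_for(rng.permutation(group_of))
        exceed += perm_stat >= obs_stat - 1e-12
    p = (1 + exceed) / (1 + n_perm)
    table = pd.DataFrame(
        {
            "group": [uniq[g] for g in best_group],
            "A": a_best,
            "B": b_best,
            "stat": obs_stat,
            "p_value": p,
        },
        index=species,
    ).sort_values("stat", ascending=False)
    return IndicatorResult(table=table, n_perm=n_perm, seed=seed)


def trait_site_means(ds: AlignedDataset) -> TraitSiteSummary:
    """Per-pond counts of occurring species carrying each trait (binary
    occurrence matrix x trait matrix), region means, and a per-trait
    rank-sum test across ponds between the two regions.  Traits carried by
    no species are reported with zero means and a skipped test."""
    cm = ds.community
    occ = (cm.counts.to_numpy() > 0).astype(int)
    inc = ds.traits.incidence.to_numpy()
    counts = pd.DataFrame(occ @ inc, index=cm.ponds, columns=ds.traits.traits)
    regions = [cm.region_of[p] for p in cm.ponds]
    region_means = counts.groupby(pd.Series(regions, index=counts.index)).mean()
    uniq = sorted(set(regions))
    rows = []
    for trait in counts.columns:
        if counts[trait].sum() == 0 or len(uniq) != 2:
            rows.append({"trait": trait, "W": np.nan, "p_value": np.nan})
            continue
        x = counts.loc[[p for p, r in zip(counts.index, regions) if r == uniq[0]], trait]
        y = counts.loc[[p for p, r in zip(counts.index, regions) if r == uniq[1]], trait]
        res = wilcoxon_rank_sum(x.to_numpy(), y.to_numpy())
        rows.append({"trait": trait, "W": res.statistic, "p_value": res.p_value})
    tests = pd.DataFrame(rows).set_index("trait")
    return TraitSiteSummary(pond_counts=counts, region_means=region_means, tests=tests)
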
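"""Compositional dissimilarity, ordination and beta-diversity structure.

Implements Bray-Curtis distances, non-metric multidimensional scaling,
PERMANOVA (McArdle-Anderson partition of a distance matrix), multivariate
dispersion homogeneity (Anderson's betadisper, with the negative-eigenvalue
correction), the Baselga turnover/nestedness partition of Sorensen
dissimilarity (pairwise and multiple-site), and Raup-Crick null-model beta
diversity with richness-preserving, frequency-weighted randomizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .data_model import CommunityMatrix, DistanceMatrix


@dataclass
class PermanovaResult:
    R2: float
    F: float
    p_value: float
    n_perm: int
    seed: int | None


@dataclass
class NmdsResult:
    coords: pd.DataFrame
    stress: float  # Kruskal stress-1
    converged: bool


@dataclass
class BetaDispersionResult:
    distances: pd.Series  # per pond: distance to its group centroid
    F: float
    p_value: float


@dataclass
class BetaPartition:
    beta_sim: float | DistanceMatrix
    beta_sne: float | DistanceMatrix
    beta_sor: float | DistanceMatrix
    kind: str  # "pairwise" | "multisite"
    undefined_pairs: list[tuple[str, str]] | None = None  # a=b=c=0 pairs (set to 0)


@dataclass
class RaupCrickResult:
    beta_rc: DistanceMatrix
    mean: float
    sd: float
    n_rand: int
    seed: int | None


# ---------------------------------------------------------------------------
# Distances and ordination
# ---------------------------------------------------------------------------

def bray_curtis(cm: CommunityMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between ponds."""
    x = cm.counts.to_numpy(dtype=float)
    if (x.sum(axis=1) == 0).any():
        raise ValueError("Bray-Curtis undefined for all-zero ponds")
    return DistanceMatrix(cm.ponds, squareform(pdist(x, metric="braycurtis")))


def _stress1(d_obs: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 with monotone (isotonic) reference distances."""
    d_hat = pdist(coords)
    order = np.argsort(d_obs)
    iso = IsotonicRegression()
    fitted = iso.fit_transform(np.arange(order.size), d_hat[order])
    disp = np.empty_like(d_hat)
    disp[order] = fitted
    denom = float((d_hat**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d_hat - disp) ** 2).sum() / denom))


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    seed: int | None = None,
    eps: float = 1e-12,
) -> NmdsResult:
    """Non-metric MDS by iterative majorization with isotonic regression on
    dissimilarity ranks (best of ``n_starts`` random starts); reports
    Kruskal stress-1 of the best configuration."""
    n = len(dist.labels)
    if n < k + 1:
        raise ValueError("need at least k+1 points")
    import inspect

    kwargs = dict(
        n_components=k,
        n_init=n_starts,
        max_iter=max_iter,
        eps=eps,
        dissimilarity="precomputed",
        random_state=seed,
        normalized_stress=True,
    )
    # sklearn renamed metric= to metric_mds= (deprecation cycle around 1.9/1.10)
    if "metric_mds" in inspect.signature(MDS).parameters:
        kwargs["metric_mds"] = False
    else:
        kwargs["metric"] = False
    mds = MDS(**kwargs)
    import warnings

    with warnings.catch_warnings():
        # sklearn warns about the future default of `init`; either default
        # is acceptable here (best-of-n_starts random starts today).
        warnings.simplefilter("ignore", FutureWarning)
        coords = mds.fit_transform(dist.d)
    stress = _stress1(dist.condensed(), coords)
    converged = mds.n_iter_ < max_iter
    return NmdsResult(
        coords=pd.DataFrame(
            coords, index=dist.labels, columns=[f"NMDS{i+1}" for i in range(k)]
        ),
        stress=stress,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# PERMANOVA and dispersion
# ---------------------------------------------------------------------------

def _permanova_f_r2(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size < 1:
            raise ValueError("empty group")
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    f = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dist: DistanceMatrix,
    groups: dict[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix (McArdle-Anderson sums of
    squares; free permutation of group labels; (1+k)/(1+N) p-value)."""
    labels = [groups[l] for l in dist.labels]
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    codes = np.array([uniq.index(l) for l in labels])
    d2 = dist.d**2
    f_obs, r2 = _permanova_f_r2(d2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_perm):
        f_null, _ = _permanova_f_r2(d2, rng.permutation(codes), len(uniq))
        if f_null >= f_obs:
            k += 1
    return PermanovaResult(
        R2=r2, F=f_obs, p_value=(1 + k) / (1 + n_perm), n_perm=n_perm, seed=seed
    )


def _pcoa_embed(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding split into real (positive-eigenvalue)
    and imaginary (negative-eigenvalue) parts."""
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(1.0, abs(evals).max())
    pos = evals > tol
    neg = evals < -tol
    real = evecs[:, pos] * np.sqrt(evals[pos])
    imag = evecs[:, neg] * np.sqrt(-evals[neg])
    return real, imag


def beta_dispersion(
    dist: DistanceMatrix, groups: dict[str, str] | pd.Series
) -> BetaDispersionResult:
    """Anderson's multivariate dispersion: distance of each point to its
    group centroid in PCoA space (squared distance = real part - imaginary
    part), followed by a classical one-way ANOVA on those distances.
    Groups of size 1 are excluded with a warning."""
    import warnings

    labels = np.array([groups[l] for l in dist.labels])
    real, imag = _pcoa_embed(dist.d)
    dists = np.empty(len(dist.labels))
    keep = np.ones(len(dist.labels), dtype=bool)
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            warnings.warn(f"group {g!r} of size 1 excluded from dispersion test")
            keep[idx] = False
        c_real = real[idx].mean(axis=0)
        c_imag = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        d2 = ((real[idx] - c_real) ** 2).sum(axis=1)
        if imag.size:
            d2 = d2 - ((imag[idx] - c_imag) ** 2).sum(axis=1)
        dists[idx] = np.sqrt(np.clip(d2, 0.0, None))
    groups_kept = [dists[(labels == g) & keep] for g in np.unique(labels[keep])]
    if len(groups_kept) >= 2:
        f, p = stats.f_oneway(*groups_kept)
    else:
        f, p = np.nan, np.nan
    return BetaDispersionResult(
        distances=pd.Series(dists, index=dist.labels), F=float(f), p_value=float(p)
    )


# ---------------------------------------------------------------------------
# Baselga partition
# ---------------------------------------------------------------------------

def baselga_pairwise(pa: CommunityMatrix) -> BetaPartition:
    """Pairwise Sorensen partition: turnover beta_sim = min(b,c)/(a+min(b,c)),
    total beta_sor = (b+c)/(2a+b+c), nestedness beta_sne = beta_sor - beta_sim,
    with a = shared species, b/c = species unique to either pond.
    Pairs with a = b = c = 0 are undefined (NaN)."""
    x = (pa.counts.to_numpy() > 0).astype(int)
    a = x @ x.T
    s = x.sum(axis=1)
    b = s[:, None] - a
    c = s[None, :] - a
    bc_min = np.minimum(b, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(a + bc_min > 0, bc_min / (a + bc_min), np.nan)
        sor = np.where(2 * a + b + c > 0, (b + c) / (2 * a + b + c), np.nan)
    sne = sor - sim
    for m in (sim, sor, sne):
        np.fill_diagonal(m, 0.0)
    labels = pa.ponds
    undef_idx = np.argwhere(np.isnan(sor))
    undefined = [
        (labels[i], labels[j]) for i, j in undef_idx if i < j
    ] or None
    for m in (sim, sor, sne):
        np.nan_to_num(m, copy=False)
    return BetaPartition(
        beta_sim=DistanceMatrix(labels, sim),
        beta_sne=DistanceMatrix(labels, sne),
        beta_sor=DistanceMatrix(labels, sor),
        kind="pairwise",
        undefined_pairs=undefined,
    )


def baselga_multisite(pa: CommunityMatrix) -> BetaPartition:
    """Baselga's multiple-site partition over all ponds of the matrix.

    With S_i the per-site richness, S_T the pooled richness and b_ij the
    species of site i absent from site j:
    beta_SIM = sum min(b_ij, b_ji) / (a_term + sum min),
    beta_SOR = (sum min + sum max) / (2 a_term + sum min + sum max),
    beta_SNE = beta_SOR - beta_SIM,  a_term = sum_i S_i - S_T.
    """
    x = (pa.counts.to_numpy() > 0).astype(int)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need >= 2 sites")
    shared = x @ x.T
    s = x.sum(axis=1)
    b = s[:, None] - shared  # b[i, j] = species in i not in j
    iu = np.triu_indices(n, k=1)
    sum_min = float(np.minimum(b, b.T)[iu].sum())
    sum_max = float(np.maximum(b, b.T)[iu].sum())
    a_term = float(s.sum() - (x.sum(axis=0) > 0).sum())
    if sum_min + sum_max == 0:
        return BetaPartition(0.0, 0.0, 0.0, kind="multisite")
    beta_sim = sum_min / (a_term + sum_min)
    beta_sor = (sum_min + sum_max) / (2 * a_term + sum_min + sum_max)
    return BetaPartition(
        beta_sim=beta_sim, beta_sne=beta_sor - beta_sim, beta_sor=beta_sor,
        kind="multisite",
    )


# ---------------------------------------------------------------------------
# Raup-Crick
# ---------------------------------------------------------------------------

def raup_crick(
    pa: CommunityMatrix,
    n_rand: int = 999,
    seed: int | None = None,
    weighting: str = "frequency",
    smoothing: float = 1.0,
    method: str = "montecarlo",
) -> RaupCrickResult:
    """Raup-Crick dissimilarity from a richness-preserving null model.

    For each pond pair, null communities are drawn preserving each pond's
    richness, sampling species without replacement with probability
    proportional to their occurrence frequency across all ponds (plus
    ``smoothing``); beta_RC = P(null shared > observed) + 0.5 P(null shared =
    observed).  Values near 0.5 indicate stochastic assembly, near 1 less
    sharing than expected (deterministic turnover), near 0 more sharing.

    ``method="exact"`` evaluates the null analytically (hypergeometric
    shared-species distribution) and requires ``weighting="uniform"``.
    """
    x = (pa.counts.to_numpy() > 0).astype(int)
    n, pool = x.shape
    richness = x.sum(axis=1)
    if (richness > pool).any():
        raise ValueError("site richness exceeds species pool")
    if weighting == "frequency":
        w = x.sum(axis=0).astype(float) + smoothing
    elif weighting == "uniform":
        w = np.ones(pool)
    else:
        raise ValueError(f"unknown weighting: {weighting!r}")

    out = np.zeros((n, n))
    rng = np.random.default_rng(seed)
    logw = np.log(w)

    if method == "exact":
        if weighting != "uniform":
            raise ValueError("exact method requires uniform weighting")
        for i in range(n):
            for j in range(i + 1, n):
                obs = int(x[i] @ x[j])
                h = stats.hypergeom(pool, int(richness[i]), int(richness[j]))
                brc = float(h.sf(obs) + 0.5 * h.pmf(obs))
                out[i, j] = out[j, i] = brc
    elif method == "montecarlo":
        for i in range(n):
            for j in range(i + 1, n):
                obs = int(x[i] @ x[j])
                # weighted sampling without replacement via Gumbel top-k
                gumb = -np.log(-np.log(rng.random((2, n_rand, pool)))) + logw
                ri, rj = int(richness[i]), int(richness[j])
                top_i = np.argpartition(-gumb[0], ri - 1, axis=1)[:, :ri]
                top_j = np.argpartition(-gumb[1], rj - 1, axis=1)[:, :rj]
                mask_i = np.zeros((n_rand, pool), dtype=bool)
                mask_j = np.zeros((n_rand, pool), dtype=bool)
                np.put_along_axis(mask_i, top_i, True, axis=1)
                np.put_along_axis(mask_j, top_j, True, axis=1)
                shared = (mask_i & mask_j).sum(axis=1)
                brc = ((shared > obs).sum() + 0.5 * (shared == obs).sum()) / n_rand
                out[i, j] = out[j, i] = brc
    else:
        raise ValueError(f"unknown method: {method!r}")

    dm = DistanceMatrix(pa.ponds, out)
    vals = dm.condensed()
    return RaupCrickResult(
        beta_rc=dm, mean=float(vals.mean()), sd=float(vals.std(ddof=0)),
        n_rand=n_rand, seed=seed,
    )
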
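"""Bipartite species-trait network structure and its fixed-margin null model.

Species and traits are two node sets; an edge connects a species to every
trait it carries.  Structure is summarized by node degrees, edge density
(reported both with the generic unipartite n(n-1)/2 denominator and the
bipartite-correct |E|/(S*T)), and Newman modularity of a Louvain partition
(best of several seeded restarts).  Significance of modularity is assessed
against null incidence matrices drawn by the Patefield algorithm, which
samples contingency tables uniformly conditional on the observed row and
column sums; null tables are binarized before graph reconstruction by
default (entries > 1 can arise from integer margins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .alpha_gamma import PermutationTestResult
from .data_model import TraitMatrix

logger = logging.getLogger("pondiv")


@dataclass
class NetworkMetrics:
    degrees: dict[str, int]
    density: float            # |E| / (n(n-1)/2), n = species + trait nodes
    bipartite_density: float  # |E| / (S * T)
    modularity: float
    partition: dict[str, int]


@dataclass
class BipartiteNetwork:
    graph: nx.Graph
    species: list[str]
    traits: list[str]
    incidence: pd.DataFrame  # species x trait 0/1 over the network's nodes
    metrics: NetworkMetrics | None = None


def build_network(
    tm: TraitMatrix, species_scope: Sequence[str] | None = None
) -> BipartiteNetwork:
    """Bipartite graph over the scoped species and the traits they carry.

    Trait nodes with no edge in the scope are dropped (logged); an empty
    edge set is an error.
    """
    species = list(species_scope) if species_scope is not None else tm.species
    if not species:
        raise ValueError("empty species scope")
    inc = tm.restrict(species).incidence
    carried = inc.columns[inc.sum(axis=0) > 0].tolist()
    dropped = [t for t in inc.columns if t not in carried]
    if dropped:
        logger.info("isolated trait nodes dropped: %s", dropped)
    inc = inc[carried]
    if int(inc.to_numpy().sum()) == 0:
        raise ValueError("network has no edges")
    g = nx.Graph()
    g.add_nodes_from(inc.index, bipartite="species")
    g.add_nodes_from(inc.columns, bipartite="trait")
    rows, cols = np.nonzero(inc.to_numpy())
    g.add_edges_from((inc.index[i], inc.columns[j]) for i, j in zip(rows, cols))
    return BipartiteNetwork(
        graph=g, species=list(inc.index), traits=list(inc.columns), incidence=inc
    )


def _best_louvain(
    g: nx.Graph, seed: int, n_restarts: int
) -> tuple[float, list[set[str]]]:
    best_q, best_part = -np.inf, None
    for r in range(n_restarts):
        part = nx.community.louvain_communities(g, seed=seed + r)
        q = nx.community.modularity(g, part)
        if q > best_q:
            best_q, best_part = q, part
    return float(best_q), best_part


def network_metrics(
    net: BipartiteNetwork, seed: int = 0, n_restarts: int = 10
) -> NetworkMetrics:
    """Degrees, density (both conventions) and Louvain modularity (best
    Newman Q over ``n_restarts`` seeded restarts; deterministic given seed).
    """
    g = net.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    density = nx.density(g)  # |E| / (n(n-1)/2)
    bip_density = e / (len(net.species) * len(net.traits))
    q, part = _best_louvain(g, seed, n_restarts)
    partition = {node: i for i, module in enumerate(part) for node in module}
    metrics = NetworkMetrics(
        degrees={node: int(d) for node, d in g.degree()},
        density=float(density),
        bipartite_density=float(bip_density),
        modularity=q,
        partition=partition,
    )
    net.metrics = metrics
    return metrics


def hub_nodes(net: BipartiteNetwork, top: int = 5) -> list[tuple[str, int]]:
    """The ``top`` highest-degree nodes (species or traits)."""
    return sorted(net.graph.degree(), key=lambda kv: (-kv[1], kv[0]))[:top]


def fixed_margin_null(
    incidence: np.ndarray | pd.DataFrame,
    n_tables: int,
    seed: int | None = None,
) -> np.ndarray:
    """Patefield samples: ``n_tables`` integer contingency tables with the
    observed row and column sums, drawn uniformly from the conditional
    (multivariate hypergeometric) distribution."""
    arr = np.asarray(incidence, dtype=int)
    if arr.sum() == 0:
        raise ValueError("zero total: no margins to preserve")
    if (arr < 0).any():
        raise ValueError("incidence must be non-negative")
    r, c = arr.sum(axis=1), arr.sum(axis=0)
    rng = np.random.default_rng(seed)
    tables = stats.random_table(r, c).rvs(size=n_tables, method="patefield", random_state=rng)
    return np.asarray(tables, dtype=int).reshape(n_tables, arr.shape[0], arr.shape[1])


def modularity_permutation_test(
    net: BipartiteNetwork,
    n_perm: int = 999,
    seed: int | None = None,
    n_restarts: int = 10,
    binarize: bool = True,
) -> PermutationTestResult:
    """Is the observed Louvain modularity higher than expected under
    fixed-margin randomization of the species-trait incidence matrix?

    Each null table is binarized (entry > 0 -> edge) unless ``binarize`` is
    False (then edges keep their integer weights and weighted modularity is
    used); modularity is recomputed with the same Louvain settings; a null
    network with no edges counts as modularity 0 (logged).
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    base_seed = 0 if seed is None else seed
    if net.metrics is None:
        network_metrics(net, seed=base_seed, n_restarts=n_restarts)
    observed = net.metrics.modularity
    tables = fixed_margin_null(net.incidence, n_perm, seed=seed)
    null = np.empty(n_perm)
    n_empty = 0
    species, traits = net.species, net.traits
    for r in range(n_perm):
        tab = tables[r]
        mat = (tab > 0).astype(int) if binarize else tab
        rows, cols = np.nonzero(mat)
        if rows.size == 0:
            null[r] = 0.0
            n_empty += 1
            continue
        g = nx.Graph()
        g.add_nodes_from(species[i] for i in np.unique(rows))
        g.add_nodes_from(traits[j] for j in np.unique(cols))
        g.add_weighted_edges_from(
            (species[i], traits[j], float(mat[i, j])) for i, j in zip(rows, cols)
        )
        null[r], _ = _best_louvain(g, base_seed, n_restarts)
    if n_empty:
        logger.info("modularity null: %d edgeless null networks scored 0", n_empty)
    k = int((null >= observed).sum())
    return PermutationTestResult(
        observed=observed,
        null_values=null,
        p_value=(1 + k) / (1 + n_perm),
        n_perm=n_perm,
        seed=seed,
        alternative="greater",
    )
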
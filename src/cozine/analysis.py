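"""Post-fit network analyses: bootstrap edge stability and taxonomic
assortativity with a permutation null.

Edge stability is the fraction of bootstrap refits (resampling samples
with replacement, full refit including penalty re-selection) in which an
edge reappears.  Assortativity is Newman's categorical coefficient on the
edge mixing matrix of a taxonomy rank; its significance is assessed by
permuting the taxonomic labels over nodes and counting how often the
permuted coefficient exceeds the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .estimation import Edge, FitConfig, NetworkEstimate, fit_network
from .tables import CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityReport",
    "AssortativityResult",
    "bootstrap_stability",
    "assortativity",
    "assortativity_permutation_test",
]


@dataclass
class StabilityReport:
    """Per-edge bootstrap stability over B refits.

    ``edges`` is the union of edges seen in the point estimate or any
    bootstrap network; ``stability`` maps each (i, j) pair (i < j) to the
    fraction of bootstrap networks containing it; ``in_point_estimate``
    flags edges of the original fit.
    """

    taxon_ids: tuple[str, ...]
    b: int
    stability: dict[tuple[int, int], float]
    in_point_estimate: dict[tuple[int, int], bool]
    network: NetworkEstimate

    def stable_edges(self, threshold: float = 0.9) -> list[tuple[int, int]]:
        return sorted(e for e, s in self.stability.items() if s >= threshold)


@dataclass(frozen=True)
class AssortativityResult:
    r: float
    p_value: float
    n_perm: int
    level: str = ""


def bootstrap_stability(
    counts: CountTable,
    b: int = 100,
    config: FitConfig = FitConfig(),
    seed: int = 0,
) -> StabilityReport:
    """Bootstrap the whole network fit and tally per-edge frequencies.

    Samples (rows) are resampled with replacement ``b`` times; each
    resample is refit with the identical configuration, including penalty
    path construction and model selection.  Deterministic given ``seed``.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    rng = np.random.default_rng(seed)
    point = fit_network(counts, config)
    n = counts.n_samples
    # resample indices are drawn up front so the tally is independent of
    # any parallel execution of the refits
    draws = [rng.integers(0, n, size=n) for _ in range(b)]
    tally: dict[tuple[int, int], int] = {}
    for k, idx in enumerate(draws):
        boot = counts.select_samples(idx, allow_repeats=True)
        try:
            net_k = fit_network(boot, config).network
        except ValueError as exc:  # e.g. a taxon dropped below prevalence
            logger.warning("bootstrap replicate %d failed: %s", k, exc)
            continue
        # map back to the point-estimate taxon universe
        name_to_idx = {t: i for i, t in enumerate(point.network.taxon_ids)}
        for e in net_k.edges:
            ti, tj = net_k.taxon_ids[e.i], net_k.taxon_ids[e.j]
            if ti in name_to_idx and tj in name_to_idx:
                i, j = sorted((name_to_idx[ti], name_to_idx[tj]))
                tally[(i, j)] = tally.get((i, j), 0) + 1

    point_edges = point.network.edge_set()
    all_edges = set(tally) | point_edges
    stability = {e: tally.get(e, 0) / b for e in sorted(all_edges)}
    in_point = {e: e in point_edges for e in sorted(all_edges)}
    # annotate the point-estimate network's edges in place
    for edge in point.network.edges:
        edge.stability = stability[(edge.i, edge.j)]
    return StabilityReport(
        taxon_ids=point.network.taxon_ids,
        b=b,
        stability=stability,
        in_point_estimate=in_point,
        network=point.network,
    )


def _mixing_matrix(edges: list[Edge] | list[tuple[int, int]], labels: np.ndarray) -> np.ndarray:
    """Normalized category mixing matrix over undirected edges.

    Each edge contributes 1 to e_cc when both endpoints share category c,
    and 1/2 to each of e_cc' and e_c'c otherwise, so the matrix is
    symmetric and sums to 1.
    """
    cats = np.unique(labels)
    idx = {c: k for k, c in enumerate(cats)}
    E = np.zeros((len(cats), len(cats)))
    for e in edges:
        i, j = (e.i, e.j) if isinstance(e, Edge) else e
        ci, cj = idx[labels[i]], idx[labels[j]]
        if ci == cj:
            E[ci, cj] += 1.0
        else:
            E[ci, cj] += 0.5
            E[cj, ci] += 0.5
    return E / E.sum()


def _assortativity_from_mixing(E: np.ndarray) -> float:
    a = E.sum(axis=1)
    trace = float(np.trace(E))
    aa = float(a @ a)
    if aa >= 1.0:
        raise ValueError(
            "all nodes on edges share one category; assortativity is undefined"
        )
    return (trace - aa) / (1.0 - aa)


def assortativity(network: NetworkEstimate, labels: dict[str, str] | np.ndarray) -> float:
    """Newman's categorical assortativity coefficient r in [-1, 1].

    ``r = (sum_c e_cc - sum_c a_c b_c) / (1 - sum_c a_c b_c)`` on the edge
    mixing matrix: 1 for perfectly assortative mixing (all edges within
    category), 0 under proportional mixing, negative when edges
    preferentially cross categories.

    ``labels`` maps taxon id -> category, or is an array of per-node
    categories in taxon order.
    """
    if network.n_edges == 0:
        raise ValueError("network has no edges; assortativity is undefined")
    if isinstance(labels, dict):
        missing = [t for t in network.taxon_ids if t not in labels]
        if missing:
            raise ValueError(f"unlabeled node(s): {missing[:5]}")
        lab = np.array([labels[t] for t in network.taxon_ids])
    else:
        lab = np.asarray(labels)
        if lab.size != network.p:
            raise ValueError(f"{lab.size} labels for {network.p} nodes")
    E = _mixing_matrix(network.edges, lab)
    return float(_assortativity_from_mixing(E))


def assortativity_permutation_test(
    network: NetworkEstimate,
    labels: dict[str, str] | np.ndarray,
    n_perm: int = 100_000,
    seed: int = 0,
    level: str = "",
    add_one: bool = False,
) -> AssortativityResult:
    """Permutation p-value for assortative mixing.

    The null of random mixing is simulated by permuting the taxonomic
    assignment over nodes; the p-value is the fraction of permutations
    whose coefficient is strictly greater than the observed one.  With
    ``add_one`` the conservative variant ``(#{r_perm >= r_obs} + 1) /
    (n_perm + 1)`` is used instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    r_obs = assortativity(network, labels)
    if isinstance(labels, dict):
        lab = np.array([labels[t] for t in network.taxon_ids])
    else:
        lab = np.asarray(labels)
    rng = np.random.default_rng(seed)
    cats, codes = np.unique(lab, return_inverse=True)
    n_cat = cats.size
    ei = np.array([e.i for e in network.edges])
    ej = np.array([e.j for e in network.edges])
    m = ei.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        li, lj = perm[ei], perm[ej]
        # trace of the mixing matrix and its degree-weighted margins
        trace = float(np.count_nonzero(li == lj)) / m
        a = np.bincount(li, minlength=n_cat) + np.bincount(lj, minlength=n_cat)
        aa = float(a @ a) / (4.0 * m * m)
        # all edge endpoints in one category: perfectly assortative draw
        r_p = 1.0 if aa >= 1.0 else (trace - aa) / (1.0 - aa)
        if add_one:
            count += r_p >= r_obs
        else:
            count += r_p > r_obs
    p = (count + 1) / (n_perm + 1) if add_one else count / n_perm
    return AssortativityResult(r=r_obs, p_value=float(p), n_perm=n_perm, level=level)
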
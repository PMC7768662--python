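"""Synthetic zero-inflated compositional data from the Hurdle model.

The generator draws latent log-abundances and presence indicators from a
multivariate Gaussian Hurdle model with known interaction matrices by
Gibbs sampling, then exponentiates and row-normalizes to produce a
relative-abundance table that mimics real microbiome data: zero-inflated,
compositional, with highly skewed nonzero values.  The generating
adjacency is retained as ground truth for structure-recovery benchmarks.

Two graph topologies are supported: a band/chain graph (each interior
node has degree two) and a Barabasi-Albert scale-free tree grown by
attaching one edge per new node (hub nodes arise).  Given a topology,
the parametric settings place nonzero support on different subsets of
(G, H, K):

* ``g_minimal`` - only G carries the structure; H, K diagonal.
* ``k_minimal`` - only K carries the structure; G, H diagonal.
* ``g_k``       - G on all edges; K on the edges among the second half
  of the nodes; H diagonal.
* ``h_k``       - H on all edges; K on the edges among the second half
  of the nodes; G diagonal.
* ``g_h_k``     - G and H on all edges; K on the second-half edges.

Nonzero off-diagonal values are i.i.d. Uniform(-0.1, 0.1); each diagonal
entry is set to the column sum of absolute off-diagonal values plus 0.1,
which makes K strictly diagonally dominant and hence positive definite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import expit

from .hurdle import HurdleParameters
from .tables import CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationScenario",
    "GroundTruth",
    "make_topology",
    "sample_parameters",
    "gibbs_sample",
    "to_counts_and_composition",
    "simulate_dataset",
    "truth_adjacency",
]

TOPOLOGIES = ("ar1", "ba1")
SETTINGS = ("g_minimal", "k_minimal", "g_k", "h_k", "g_h_k")

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SimulationScenario:
    """A fully specified synthetic-data condition.

    Defaults reproduce the benchmark condition used throughout: ``p=60``
    taxa, ``n=200`` samples kept from 2000 Gibbs scans after 1000 burn-in
    scans with 10-fold thinning.  ``seed`` drives the graph topology and
    parameter values; ``sampling_seed`` (derived from ``seed`` when not
    given) drives the Gibbs chain, so two scenarios differing only in
    ``sampling_seed`` share an identical ground truth.
    """

    topology: str = "ar1"
    setting: str = "g_h_k"
    p: int = 60
    n: int = 200
    seed: int = 0
    sampling_seed: int | None = None
    burnin: int = 1000
    thin: int = 10

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}; choose from {TOPOLOGIES}")
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}; choose from {SETTINGS}")
        if self.p < 2:
            raise ValueError("p must be >= 2")
        if self.n < 1 or self.thin < 1 or self.burnin < 0:
            raise ValueError("need n >= 1, thin >= 1, burnin >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters and the adjacency they imply."""

    adjacency: np.ndarray
    params: HurdleParameters


def make_topology(p: int, kind: str, seed: int = 0) -> np.ndarray:
    """Binary symmetric adjacency of the generating graph.

    ``ar1`` is the chain 0-1-2-...-(p-1); ``ba1`` is a preferential-
    attachment tree in which each new node attaches one edge to an
    existing node chosen with probability proportional to its degree.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if kind == "ar1":
        A = np.zeros((p, p), dtype=np.int8)
        idx = np.arange(p - 1)
        A[idx, idx + 1] = A[idx + 1, idx] = 1
        return A
    if kind == "ba1":
        g = nx.barabasi_albert_graph(p, 1, seed=int(seed))
        return nx.to_numpy_array(g, dtype=np.int8)
    raise ValueError(f"unknown topology kind {kind!r}")


def _fill_symmetric(support: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Symmetric matrix with Uniform(-0.1, 0.1) entries on the support."""
    p = support.shape[0]
    M = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    vals = rng.uniform(-0.1, 0.1, size=len(iu[0]))
    M[iu] = vals * support[iu]
    M += M.T
    return M


def _fill_asymmetric(support: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Matrix with independent Uniform(-0.1, 0.1) entries on the (symmetric)
    support positions; values at (i, j) and (j, i) differ."""
    p = support.shape[0]
    M = rng.uniform(-0.1, 0.1, size=(p, p)) * support
    np.fill_diagonal(M, 0.0)
    return M


def _set_diagonal(M: np.ndarray) -> np.ndarray:
    """Diagonal rule: column sums of absolute off-diagonal values + 0.1.

    Applied to K this gives strict diagonal dominance, hence positive
    definiteness (Gershgorin).
    """
    M = M.copy()
    np.fill_diagonal(M, 0.0)
    np.fill_diagonal(M, np.abs(M).sum(axis=0) + 0.1)
    return M


def sample_parameters(
    adjacency: np.ndarray, setting: str, seed: int = 0
) -> HurdleParameters:
    """Draw (G, H, K) with support determined by ``setting``.

    The "second half" sub-support used for K in the ``*_k`` settings is
    the induced subgraph on nodes ``floor(p/2) .. p-1``.
    """
    if setting not in SETTINGS:
        raise ValueError(f"unknown setting {setting!r}")
    A = np.asarray(adjacency)
    p = A.shape[0]
    if A.shape != (p, p) or not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
        raise ValueError("adjacency must be square, symmetric, hollow")
    rng = np.random.default_rng(seed)
    half = np.zeros_like(A)
    lo = p // 2
    half[lo:, lo:] = A[lo:, lo:]

    g_sup = {"g_minimal": A, "k_minimal": 0 * A, "g_k": A, "h_k": 0 * A, "g_h_k": A}[setting]
    h_sup = {"g_minimal": 0 * A, "k_minimal": 0 * A, "g_k": 0 * A, "h_k": A, "g_h_k": A}[setting]
    k_sup = {"g_minimal": 0 * A, "k_minimal": A, "g_k": half, "h_k": half, "g_h_k": half}[setting]

    G = _set_diagonal(_fill_symmetric(g_sup, rng))
    H = _set_diagonal(_fill_asymmetric(h_sup, rng))
    K = _set_diagonal(_fill_symmetric(k_sup, rng))
    return HurdleParameters(G=G, H=H, K=K)


def truth_adjacency(params: HurdleParameters) -> np.ndarray:
    """Edge (i,j) present iff any of g_ij, h_ij, h_ji, k_ij is nonzero."""
    off = (
        (params.G != 0) | (params.H != 0) | (params.H.T != 0) | (params.K != 0)
    ).astype(np.int8)
    np.fill_diagonal(off, 0)
    return (off | off.T).astype(np.int8)


def gibbs_sample(
    params: HurdleParameters,
    n: int,
    burnin: int = 1000,
    thin: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Systematic-scan Gibbs sampler for the joint Hurdle model.

    Runs ``burnin + n * thin`` full scans (one scan updates every
    coordinate once, in index order) and keeps every ``thin``-th
    post-burn-in scan.  Each coordinate update is an exact draw from the
    univariate hurdle conditional.  Returns ``(Z, V)`` with ``z = 0``
    exactly where ``v = 0``.
    """
    if not params.is_positive_definite():
        raise ValueError("K must be positive definite for simulation")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = params.p
    G, H, K = params.G, params.H, params.K
    Ht = H.T.copy()
    gdiag = np.diag(G).copy()
    hdiag = np.diag(H).copy()
    kdiag = np.diag(K).copy()
    n_scans = burnin + n * thin
    # pre-generate the randomness: one uniform and one normal per
    # coordinate update, so the draw sequence is a pure function of the seed
    U = rng.random((n_scans, p))
    N = rng.standard_normal((n_scans, p))

    v = np.ones(p)
    y = np.zeros(p)
    Z = np.empty((n, p))
    V = np.empty((n, p), dtype=np.int8)
    kept = 0
    half_log = 0.5 * (_LOG_2PI - np.log(kdiag))
    inv_k = 1.0 / kdiag
    sd = np.sqrt(inv_k)
    for s in range(n_scans):
        Us = U[s]
        Ns = N[s]
        for i in range(p):
            a = gdiag[i] + 2.0 * (G[i] @ v - gdiag[i] * v[i]) + (H[i] @ y - hdiag[i] * y[i])
            b = hdiag[i] + (Ht[i] @ v - hdiag[i] * v[i]) - (K[i] @ y - kdiag[i] * y[i])
            logm = a + 0.5 * b * b * inv_k[i] + half_log[i]
            if Us[i] < expit(logm):
                v[i] = 1.0
                y[i] = b * inv_k[i] + sd[i] * Ns[i]
            else:
                v[i] = 0.0
                y[i] = 0.0
        if s >= burnin and (s - burnin) % thin == thin - 1:
            Z[kept] = y
            V[kept] = v
            kept += 1
    assert kept == n
    return Z, V


def to_counts_and_composition(
    Z: np.ndarray, V: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map latent log-abundances to abundances and compositions.

    Present taxa get ``w = exp(z)``; absent taxa get ``w = 0``, preserving
    the zero pattern through the row normalization ``x = w / sum(w)``.
    Rows with no present taxon cannot be normalized and must have been
    rejected upstream.
    """
    Z = np.asarray(Z, dtype=float)
    V = np.asarray(V)
    if Z.shape != V.shape:
        raise ValueError("Z and V must have the same shape")
    if np.any((Z != 0) & (V == 0)):
        raise ValueError("support inconsistency: z nonzero where v = 0")
    W = np.where(V == 1, np.exp(Z), 0.0)
    totals = W.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise ValueError("row with all taxa absent cannot be normalized")
    X = W / totals
    return W, X


def simulate_dataset(
    scenario: SimulationScenario = SimulationScenario(),
) -> tuple[CountTable, GroundTruth]:
    """Full generator: topology -> parameters -> Gibbs -> composition.

    Returns the relative-abundance table (the fit input) and the ground
    truth.  All-absent samples, which cannot be normalized, are replaced
    by continuing the chain (their count is logged); with the default
    parameter magnitudes they are rare.
    """
    sc = scenario
    adjacency = make_topology(sc.p, sc.topology, seed=sc.seed)
    params = sample_parameters(adjacency, sc.setting, seed=sc.seed)
    truth = GroundTruth(adjacency=truth_adjacency(params), params=params)
    sampling_seed = sc.sampling_seed if sc.sampling_seed is not None else sc.seed + 1_000_003
    rng = np.random.default_rng(sampling_seed)

    Z, V = gibbs_sample(params, sc.n, burnin=sc.burnin, thin=sc.thin, seed=rng)
    n_redrawn = 0
    while True:
        bad = np.flatnonzero(V.sum(axis=1) == 0)
        if bad.size == 0:
            break
        n_redrawn += bad.size
        # continue the chain (fresh short runs from the same rng) to
        # replace degenerate all-absent rows
        Z2, V2 = gibbs_sample(params, bad.size, burnin=sc.burnin, thin=sc.thin, seed=rng)
        Z[bad] = Z2
        V[bad] = V2
    if n_redrawn:
        logger.info("redrew %d all-absent sample(s)", n_redrawn)
    _, X = to_counts_and_composition(Z, V)
    table = CountTable(
        values=X,
        sample_ids=tuple(f"S{i}" for i in range(sc.n)),
        taxon_ids=tuple(f"T{j}" for j in range(sc.p)),
    )
    return table, truth
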
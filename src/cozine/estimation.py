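"""Network estimation by penalized node-wise regression.

Each taxon ``i`` is regressed on all others through its univariate hurdle
conditional, whose natural parameters are linear in the interaction
parameters.  The parameters linking node ``i`` to node ``j`` form the
4-vector group ``theta_ij = (g_ij, h_ij, h_ji, k_ij)``; a group-lasso
penalty ``lambda * sum_j ||theta_ij||_2`` zeroes whole groups, and an edge
``(i, j)`` enters the final graph iff at least one of the two node
regressions keeps a nonzero component of the pair's group (union rule).

The per-node objective is the exact conditional log-likelihood, which is
concave in ``(alpha, beta, k_ii, theta_i)``; the precision intercept is
log-reparameterized to keep it positive, and the optimizer is proximal
gradient descent (ISTA with backtracking) with the group soft-threshold
proximal map, warm-started along a decreasing lambda path.

``mode="ising"`` restricts the model to the binary incidence data only
(scalar groups ``g_ij``), giving the classical Ising neighborhood
selection as a special case.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .tables import CountTable
from .transforms import prepare_yv, prevalence_filter

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "NeighborhoodFit",
    "Edge",
    "NetworkEstimate",
    "NetworkFitResult",
    "group_penalty",
    "lambda_max",
    "fit_node",
    "select_model",
    "aggregate_network",
    "fit_network",
]

_LOG_2PI = math.log(2.0 * math.pi)
_GAMMA_BOUND = 18.0  # |log kappa| cap during optimization
_A_CAP = 40.0  # logit cap for degenerate (all-present) binary parts

# component order within a group
_COMP_NAMES = ("g", "h_ij", "h_ji", "k")


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the network fit.

    Parameters
    ----------
    prevalence
        Minimum fraction of samples in which a taxon must be present to be
        kept (inclusive).  0 keeps everything.
    n_lambda, lambda_min_ratio
        The penalty path has ``n_lambda`` log-spaced values from the global
        lambda_max (smallest lambda at which every neighborhood is empty)
        down to ``lambda_min_ratio * lambda_max``.
    select
        ``"bic"`` chooses lambda per node by BIC; ``"fixed"`` uses
        ``fixed_lambda_index`` for every node.
    mode
        ``"cozine"`` fits the full hurdle model; ``"ising"`` fits only the
        binary part (H and K frozen diagonal).
    max_iter, tol
        Proximal-gradient iteration cap and relative-objective tolerance.
    n_jobs
        Number of parallel workers for the (independent) node fits.
        Results are identical for any value.
    """

    prevalence: float = 0.0
    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    select: str = "bic"
    fixed_lambda_index: int | None = None
    mode: str = "cozine"
    max_iter: int = 5000
    tol: float = 1e-7
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("cozine", "ising"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.select not in ("bic", "fixed"):
            raise ValueError(f"unknown selection rule {self.select!r}")
        if self.select == "fixed" and self.fixed_lambda_index is None:
            raise ValueError("select='fixed' requires fixed_lambda_index")


def group_penalty(theta_groups: np.ndarray, lam: float) -> float:
    """Group-lasso penalty ``lam * sum_j ||theta_ij||_2``."""
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    theta = np.atleast_2d(np.asarray(theta_groups, dtype=float))
    return float(lam * np.linalg.norm(theta, axis=1).sum())


# ---------------------------------------------------------------------------
# per-node smooth objective (negative mean conditional log-likelihood)
# ---------------------------------------------------------------------------


class _NodeProblem:
    """Vectorized conditional likelihood of one node given the others."""

    def __init__(self, i: int, Y: np.ndarray, V: np.ndarray, mode: str = "cozine"):
        n, p = Y.shape
        if n < 2 or p < 2:
            raise ValueError("need at least 2 samples and 2 taxa")
        self.i = i
        self.n = n
        self.others = np.array([j for j in range(p) if j != i])
        self.mode = mode
        self.yi = Y[:, i].astype(float)
        self.vi = V[:, i].astype(float)
        if mode == "ising":
            # only the incidence data enter; the continuous part is inert
            self.Yr = np.zeros((n, p - 1))
            self.yi = np.zeros(n)
        else:
            self.Yr = Y[:, self.others].astype(float)
        self.Vr = V[:, self.others].astype(float)
        # standardize predictor columns so the group penalty's entry order
        # reflects signal rather than column scale (clr columns have much
        # larger spread than 0/1 incidence columns); the fitted
        # coefficients are mapped back to the natural-parameter scale, so
        # the zero pattern and reported values are scale-free
        self.sy = self.Yr.std(axis=0)
        self.sv = self.Vr.std(axis=0)
        self.sy[self.sy < 1e-8] = 1.0
        self.sv[self.sv < 1e-8] = 1.0
        self.Yr = self.Yr / self.sy
        self.Vr = self.Vr / self.sv

        vbar = self.vi.mean()
        if vbar == 0.0:
            raise ValueError(
                f"node {i} is absent in every sample; its regression is undefined "
                "(prevalence filtering should have removed it)"
            )
        self.all_present = vbar == 1.0
        if self.all_present and mode == "cozine":
            logger.warning(
                "node %d is present in every sample: its presence submodel is "
                "unidentifiable; g- and h_i.-components are frozen at zero",
                i,
            )
        # component mask: which of (g, h_ij, h_ji, k) are free to move;
        # an all-present node has no identifiable presence submodel, so
        # its a-side parameters (alpha, g-row, h-row) are frozen
        if mode == "ising":
            free_a = not self.all_present
            self.comp_mask = np.array([free_a, False, False, False])
            self.int_mask = np.array([free_a, False, False])
        elif self.all_present:
            self.comp_mask = np.array([False, False, True, True])
            self.int_mask = np.array([False, True, True])
        else:
            self.comp_mask = np.array([True, True, True, True])
            self.int_mask = np.array([True, True, True])

    # -- intercept-only maximum likelihood (closed form) ---------------
    def intercept_mle(self) -> np.ndarray:
        vbar = self.vi.mean()
        if self.mode == "ising":
            alpha = _A_CAP if self.all_present else float(logit(vbar))
            # kappa = 2*pi makes the Gaussian branch's log-offset vanish,
            # so the presence law is exactly logistic in alpha
            return np.array([alpha, 0.0, math.log(2.0 * math.pi)])
        present = self.vi == 1.0
        ypres = self.yi[present]
        var = float(ypres.var()) if ypres.size > 1 else 0.0
        var = max(var, 1e-8)
        kappa = 1.0 / var
        beta = kappa * float(ypres.mean())
        offset = beta * beta / (2.0 * kappa) + 0.5 * (_LOG_2PI - math.log(kappa))
        a_target = _A_CAP if self.all_present else float(logit(vbar))
        alpha = a_target - offset
        return np.array([alpha, beta, math.log(kappa)])

    # -- smooth part ---------------------------------------------------
    def _ab(self, intercepts: np.ndarray, coef: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        alpha, beta, gamma = intercepts
        kappa = math.exp(min(max(gamma, -_GAMMA_BOUND), _GAMMA_BOUND))
        a = alpha + 2.0 * (self.Vr @ coef[:, 0]) + self.Yr @ coef[:, 1]
        b = beta + self.Vr @ coef[:, 2] - self.Yr @ coef[:, 3]
        return a, b, kappa

    def neg_loglik(self, intercepts: np.ndarray, coef: np.ndarray) -> float:
        """Negative mean conditional log-likelihood."""
        a, b, kappa = self._ab(intercepts, coef)
        logm = a + b * b / (2.0 * kappa) + 0.5 * (_LOG_2PI - math.log(kappa))
        ll = (
            self.vi * a
            + self.yi * b
            - 0.5 * kappa * self.yi**2
            - np.logaddexp(0.0, logm)
        )
        return -float(ll.mean())

    def grad(self, intercepts: np.ndarray, coef: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gradient of ``neg_loglik`` w.r.t. (intercepts, coef), masked."""
        a, b, kappa = self._ab(intercepts, coef)
        logm = a + b * b / (2.0 * kappa) + 0.5 * (_LOG_2PI - math.log(kappa))
        P = expit(logm)
        ra = self.vi - P  # d loglik / d a_s
        rb = self.yi - P * (b / kappa)  # d loglik / d b_s
        n = self.n
        g_int = np.zeros(3)
        g_int[0] = -ra.mean()
        g_int[1] = -rb.mean()
        dl_dkappa = -0.5 * self.yi**2 + P * (b * b / (2.0 * kappa**2) + 0.5 / kappa)
        g_int[2] = -float(dl_dkappa.mean()) * kappa  # chain rule for gamma
        g_coef = np.empty_like(coef)
        g_coef[:, 0] = -2.0 * (self.Vr.T @ ra) / n
        g_coef[:, 1] = -(self.Yr.T @ ra) / n
        g_coef[:, 2] = -(self.Vr.T @ rb) / n
        g_coef[:, 3] = (self.Yr.T @ rb) / n
        g_int[~self.int_mask] = 0.0
        g_coef[:, ~self.comp_mask] = 0.0
        return g_int, g_coef

    def natural_coef(self, coef: np.ndarray) -> np.ndarray:
        """Map standardized-scale coefficients back to natural parameters
        (g_ij, h_ij, h_ji, k_ij); positive scalings preserve zeros."""
        out = coef.copy()
        out[:, 0] /= self.sv
        out[:, 1] /= self.sy
        out[:, 2] /= self.sv
        out[:, 3] /= self.sy
        return out


def lambda_max(i: int, Y: np.ndarray, V: np.ndarray, mode: str = "cozine") -> float:
    """Smallest penalty at which node ``i``'s neighborhood is empty.

    By the KKT conditions of the group lasso, the all-zero-group solution
    (with intercepts at their maximum likelihood) is stationary exactly
    when every group's score norm is at most lambda; the bound returned is
    the largest such norm.
    """
    prob = _NodeProblem(i, Y, V, mode=mode)
    intercepts = prob.intercept_mle()
    coef = np.zeros((len(prob.others), 4))
    _, g_coef = prob.grad(intercepts, coef)
    return float(np.linalg.norm(g_coef, axis=1).max())


# ---------------------------------------------------------------------------
# proximal gradient fit along a lambda path
# ---------------------------------------------------------------------------


@dataclass
class NeighborhoodFit:
    """One node's fitted regression along the penalty path.

    ``coef`` has shape ``(n_lambda, p-1, 4)`` with groups ordered as the
    node's ``others`` array and components ``(g_ij, h_ij, h_ji, k_ij)``;
    ``intercepts`` holds ``(alpha, beta, log kappa)`` per lambda.
    """

    node: int
    others: np.ndarray
    lambda_path: np.ndarray
    coef: np.ndarray
    intercepts: np.ndarray
    loglik: np.ndarray  # total (summed) unpenalized conditional log-likelihood
    objective: np.ndarray  # penalized negative mean log-likelihood
    n_iter: np.ndarray
    converged: np.ndarray
    saturated: np.ndarray  # True where every free group is active
    n_samples: int
    mode: str = "cozine"

    def active_groups(self, l_idx: int) -> np.ndarray:
        """Indices into ``others`` of the groups active at path point ``l_idx``."""
        return np.flatnonzero(np.linalg.norm(self.coef[l_idx], axis=1) > 0)

    def n_active(self, l_idx: int) -> int:
        return int(self.active_groups(l_idx).size)

    def bic(self, l_idx: int) -> float:
        """BIC evaluated at the penalized path solution.

        The log-likelihood is the unpenalized one, taken at the shrunk
        coefficients.  Refitting the active set unpenalized would be the
        classical debiasing device, but under the clr zero-sum constraint
        an unpenalized conditional rewards conditioning on many taxa for
        purely compositional reasons, so the shrinkage is kept: it is what
        holds that artifact down.
        """
        group_df = 1 if self.mode == "ising" else 4
        intercept_df = 1 if self.mode == "ising" else 3
        df = intercept_df + group_df * self.n_active(l_idx)
        return -2.0 * self.loglik[l_idx] + math.log(self.n_samples) * df


def _prox_group(C: np.ndarray, thresh: float) -> np.ndarray:
    """Row-wise group soft-threshold: shrink each row's norm by ``thresh``."""
    norms = np.linalg.norm(C, axis=1)
    scale = np.zeros_like(norms)
    # the tiny relative margin keeps the lambda_max KKT boundary exact
    # under floating-point rounding
    nz = norms > thresh * (1.0 + 1e-9)
    scale[nz] = 1.0 - thresh / norms[nz]
    return C * scale[:, None]


def _prox_step(
    prob: _NodeProblem,
    lam: float,
    intercepts: np.ndarray,
    coef: np.ndarray,
    t: float,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """One backtracked proximal-gradient step from (intercepts, coef).

    Returns the new point, its smooth objective value, and the accepted
    step size.
    """
    f = prob.neg_loglik(intercepts, coef)
    g_int, g_coef = prob.grad(intercepts, coef)
    for _ in range(60):
        int_new = intercepts - t * g_int
        int_new[2] = min(max(int_new[2], -_GAMMA_BOUND), _GAMMA_BOUND)
        coef_new = _prox_group(coef - t * g_coef, t * lam)
        d_int = int_new - intercepts
        d_coef = coef_new - coef
        sq = float(d_int @ d_int + (d_coef * d_coef).sum())
        f_new = prob.neg_loglik(int_new, coef_new)
        bound = f + float(g_int @ d_int + (g_coef * d_coef).sum()) + sq / (2.0 * t)
        if f_new <= bound + 1e-12:
            break
        t *= 0.5
    return int_new, coef_new, f_new, t


def _fista(
    prob: _NodeProblem,
    lam: float,
    intercepts: np.ndarray,
    coef: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Accelerated proximal gradient (FISTA with function-value restart).

    The group soft-threshold proximal map gives exact group zeros; the
    momentum is reset whenever the penalized objective increases, which
    keeps the method stable under the (mildly non-convex) log-precision
    reparameterization.
    """

    def pen_obj(i: np.ndarray, c: np.ndarray, f: float | None = None) -> float:
        if f is None:
            f = prob.neg_loglik(i, c)
        return f + lam * np.linalg.norm(c, axis=1).sum()

    x_int, x_coef = intercepts.copy(), coef.copy()
    z_int, z_coef = x_int.copy(), x_coef.copy()
    obj = pen_obj(x_int, x_coef)
    t = 1.0
    tk = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_int, new_coef, f_new, t = _prox_step(prob, lam, z_int, z_coef, t)
        obj_new = pen_obj(new_int, new_coef, f_new)
        if obj_new > obj:  # restart momentum from the best known point
            tk = 1.0
            z_int, z_coef = x_int.copy(), x_coef.copy()
            new_int, new_coef, f_new, t = _prox_step(prob, lam, z_int, z_coef, t)
            obj_new = pen_obj(new_int, new_coef, f_new)
        tk_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * tk * tk))
        mom = (tk - 1.0) / tk_new
        z_int = new_int + mom * (new_int - x_int)
        z_int[2] = min(max(z_int[2], -_GAMMA_BOUND), _GAMMA_BOUND)
        z_coef = new_coef + mom * (new_coef - x_coef)
        x_int, x_coef = new_int, new_coef
        tk = tk_new
        if abs(obj - obj_new) <= tol * max(1.0, abs(obj)):
            obj = obj_new
            converged = True
            break
        obj = obj_new
        t *= 1.1
    return x_int, x_coef, it, converged


def fit_node(
    i: int,
    Y: np.ndarray,
    V: np.ndarray,
    lambda_path: np.ndarray | None = None,
    config: FitConfig = FitConfig(),
) -> NeighborhoodFit:
    """Fit node ``i``'s group-lasso penalized regression along a lambda path.

    If ``lambda_path`` is not given, it is built from the node's own
    ``lambda_max`` with the config's length and span.  Warm starts are
    used along the (decreasing) path; groups returned as zero are exact
    zeros of the proximal map.
    """
    prob = _NodeProblem(i, Y, V, mode=config.mode)
    if lambda_path is None:
        lmax = lambda_max(i, Y, V, mode=config.mode)
        lmax = max(lmax, 1e-12)
        lambda_path = np.geomspace(lmax, config.lambda_min_ratio * lmax, config.n_lambda)
    lambda_path = np.asarray(lambda_path, dtype=float)
    if np.any(np.diff(lambda_path) > 0):
        raise ValueError("lambda path must be non-increasing")
    nl = lambda_path.size
    m = len(prob.others)
    coef_path = np.zeros((nl, m, 4))
    int_path = np.zeros((nl, 3))
    loglik = np.zeros(nl)
    objective = np.zeros(nl)
    n_iter = np.zeros(nl, dtype=int)
    converged = np.zeros(nl, dtype=bool)
    saturated = np.zeros(nl, dtype=bool)

    intercepts = prob.intercept_mle()
    coef = np.zeros((m, 4))
    n_free = m if prob.comp_mask.any() else 0
    for l_idx, lam in enumerate(lambda_path):
        if not np.any(coef):
            # at an all-zero coefficient block the intercept likelihood has
            # an exact analytic maximizer; starting there makes the KKT
            # bound at lambda_max hold exactly
            intercepts = prob.intercept_mle()
        intercepts, coef, it, ok = _fista(
            prob, lam, intercepts, coef, config.max_iter, config.tol
        )
        int_path[l_idx] = intercepts
        coef_path[l_idx] = prob.natural_coef(coef)
        f = prob.neg_loglik(intercepts, coef)
        loglik[l_idx] = -f * prob.n
        objective[l_idx] = f + lam * np.linalg.norm(coef, axis=1).sum()
        n_iter[l_idx] = it
        converged[l_idx] = ok
        n_active = int(np.count_nonzero(np.linalg.norm(coef, axis=1)))
        saturated[l_idx] = n_free > 0 and n_active >= n_free
        if saturated[l_idx] and l_idx + 1 < nl:
            # Once every group is active the remaining (smaller) lambdas
            # change no structure: under the clr zero-sum constraint the
            # saturated conditional is degenerate (y_i is an exact linear
            # function of the other present taxa), so deeper fits only
            # chase that artifact.  Carry the solution forward.
            int_path[l_idx + 1 :] = intercepts
            coef_path[l_idx + 1 :] = coef_path[l_idx]
            loglik[l_idx + 1 :] = loglik[l_idx]
            objective[l_idx + 1 :] = objective[l_idx]
            converged[l_idx + 1 :] = False
            saturated[l_idx + 1 :] = True
            break
    return NeighborhoodFit(
        node=i,
        others=prob.others,
        lambda_path=lambda_path,
        coef=coef_path,
        intercepts=int_path,
        loglik=loglik,
        objective=objective,
        n_iter=n_iter,
        converged=converged,
        saturated=saturated,
        n_samples=prob.n,
        mode=config.mode,
    )


def select_model(fit: NeighborhoodFit, criterion: str = "bic") -> int:
    """Choose a lambda index for one node fit.

    Default BIC: ``-2 * loglik + log(n) * df`` with df counting the node
    intercepts plus each active group at its full size.  Ties go to the
    sparser (larger lambda) model, which ``argmin`` yields since the path
    is decreasing.

    Saturated path points (every group active) are excluded: the clr
    zero-sum constraint makes the saturated conditional degenerate, so
    its likelihood grows without reflecting structure and would always
    win.  If the whole path is saturated the last non-degenerate point
    (the first one) is used.
    """
    if not fit.converged.any():
        raise ValueError(f"node {fit.node}: no converged lambda on the path")
    if criterion == "bic":
        eligible = np.flatnonzero(fit.converged & ~fit.saturated)
        if eligible.size == 0:
            eligible = np.flatnonzero(fit.converged)
        scores = np.array([fit.bic(l) for l in eligible])
        return int(eligible[np.argmin(scores)])
    raise ValueError(f"unknown criterion {criterion!r}")


# ---------------------------------------------------------------------------
# aggregation into an undirected network
# ---------------------------------------------------------------------------


@dataclass
class Edge:
    """One undirected edge with provenance of which parameters fired."""

    i: int
    j: int
    weight: float
    components: dict[str, bool]
    stability: float | None = None


@dataclass
class NetworkEstimate:
    """Undirected co-occurrence / mutual-exclusion network over taxa."""

    taxon_ids: tuple[str, ...]
    edges: list[Edge] = field(default_factory=list)

    @property
    def p(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.p, self.p), dtype=np.int8)
        for e in self.edges:
            A[e.i, e.j] = A[e.j, e.i] = 1
        return A

    def edge_set(self) -> set[tuple[int, int]]:
        return {(e.i, e.j) for e in self.edges}

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=0)


def _collect_edge(fits: list[NeighborhoodFit], sel: list[int], i: int, j: int):
    """Gather the (up to 8) fitted components linking i and j.

    Returns (flags, values): flags say which of g / h_ij / h_ji / k is
    nonzero in either node regression; values are all nonzero fitted
    components, used for the signed edge weight.
    """
    flags = {"g": False, "h_ij": False, "h_ji": False, "k": False}
    values: list[float] = []
    # fit of node i, group for j: (g_ij, h_ij, h_ji, k_ij)
    # fit of node j, group for i: (g_ji, h_ji, h_ij, k_ji)
    for node, other, names in (
        (i, j, ("g", "h_ij", "h_ji", "k")),
        (j, i, ("g", "h_ji", "h_ij", "k")),
    ):
        fit = fits[node]
        pos = int(np.searchsorted(fit.others, other))
        theta = fit.coef[sel[node], pos]
        for c, name in enumerate(names):
            if theta[c] != 0.0:
                flags[name] = True
                values.append(float(theta[c]))
    return flags, values


def aggregate_network(
    fits: list[NeighborhoodFit],
    selected: list[int],
    taxon_ids: tuple[str, ...],
) -> NetworkEstimate:
    """Union (OR) symmetrization of the node regressions into one graph.

    An edge (i, j) is present iff any of g_ij, h_ij, h_ji, k_ij is nonzero
    in either node's regression at its selected lambda.  The edge weight
    is the mean of the nonzero fitted components (sign-preserving); it is
    an implementation-defined summary, not a model parameter.
    """
    p = len(taxon_ids)
    if len(fits) != p or len(selected) != p:
        raise ValueError("need one fit and one selected lambda per node")
    order = np.argsort([f.node for f in fits])
    fits = [fits[k] for k in order]
    selected = [selected[k] for k in order]
    if [f.node for f in fits] != list(range(p)):
        raise ValueError("fits must cover nodes 0..p-1 exactly once")
    edges: list[Edge] = []
    for i in range(p):
        for j in range(i + 1, p):
            flags, values = _collect_edge(fits, selected, i, j)
            if values:
                edges.append(
                    Edge(i=i, j=j, weight=float(np.mean(values)), components=flags)
                )
    return NetworkEstimate(taxon_ids=tuple(taxon_ids), edges=edges)


# ---------------------------------------------------------------------------
# whole-network fit
# ---------------------------------------------------------------------------


@dataclass
class NetworkFitResult:
    """Fitted network plus the full path needed for ROC-style evaluation."""

    network: NetworkEstimate
    fits: list[NeighborhoodFit]
    lambda_path: np.ndarray
    selected: list[int]
    kept_taxa: np.ndarray
    config: FitConfig

    def path_adjacencies(self) -> np.ndarray:
        """Adjacency at every path point (same lambda for all nodes), by
        the union rule; shape ``(n_lambda, p, p)``, ordered by decreasing
        lambda so the graphs grow along the first axis."""
        p = self.network.p
        nl = self.lambda_path.size
        A = np.zeros((nl, p, p), dtype=np.int8)
        for fit in self.fits:
            i = fit.node
            norms = np.linalg.norm(fit.coef, axis=2) > 0  # (nl, p-1)
            for pos, j in enumerate(fit.others):
                A[:, i, j] |= norms[:, pos]
                A[:, j, i] |= norms[:, pos]
        return A


def fit_network(counts: CountTable, config: FitConfig = FitConfig()) -> NetworkFitResult:
    """Fit the full co-occurrence network from an abundance table.

    Pipeline: prevalence screening -> composition -> (Y, V) transform ->
    per-node group-lasso path fits on a shared lambda path (anchored at
    the global lambda_max so the largest lambda gives the empty graph) ->
    per-node model selection -> union aggregation.

    The node fits are independent; with ``config.n_jobs > 1`` they run in
    parallel with results identical to the sequential order.
    """
    if counts.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    filtered, kept = prevalence_filter(counts, config.prevalence)
    Y, V = prepare_yv(filtered)
    p = filtered.n_taxa
    lmax = max(lambda_max(i, Y, V, mode=config.mode) for i in range(p))
    lmax = max(lmax, 1e-12)
    path = np.geomspace(lmax, config.lambda_min_ratio * lmax, config.n_lambda)

    def _one(i: int) -> NeighborhoodFit:
        return fit_node(i, Y, V, lambda_path=path, config=config)

    if config.n_jobs > 1:
        from joblib import Parallel, delayed

        fits = Parallel(n_jobs=config.n_jobs)(delayed(_one)(i) for i in range(p))
    else:
        fits = [_one(i) for i in range(p)]

    if config.select == "fixed":
        sel = [int(config.fixed_lambda_index)] * p
    else:
        sel = [select_model(f, config.select) for f in fits]
    network = aggregate_network(fits, sel, filtered.taxon_ids)
    return NetworkFitResult(
        network=network,
        fits=fits,
        lambda_path=path,
        selected=sel,
        kept_taxa=kept,
        config=config,
    )
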
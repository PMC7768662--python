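"""Multivariate Gaussian Hurdle model: closed-form machinery.

The model couples a binary presence vector ``v`` in {0,1}^p and a
continuous abundance vector ``y`` in R^p (with y_j = 0 exactly when
v_j = 0) through an exponential-family joint density with unnormalised
log-density

    v' G v + v' H y - (1/2) y' K y

where G and K are symmetric p x p interaction matrices and H is an
arbitrary p x p matrix.  g_ij couples presence-presence, k_ij couples
abundance-abundance among present taxa, and h_ij couples presence of one
taxon with the abundance of another.  The full normaliser is intractable
for large p, but each node's conditional law given the rest is a simple
univariate hurdle: a Bernoulli presence indicator mixed with a Gaussian
for the nonzero value.  That conditional is what both the fitter and the
Gibbs simulator use.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

__all__ = [
    "HurdleParameters",
    "NodeConditional",
    "joint_log_density_unnormalized",
    "node_conditional_params",
    "presence_probability",
    "node_conditional_loglik",
    "sample_node_conditional",
]

_KAPPA_FLOOR = 1e-8
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class HurdleParameters:
    """Natural parameters (G, H, K) of the multivariate Hurdle model.

    G and K must be symmetric; H need not be.  All diagonal entries of K
    must be strictly positive (K positive definite is additionally
    required for simulation).
    """

    G: np.ndarray
    H: np.ndarray
    K: np.ndarray

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        H = np.asarray(self.H, dtype=float)
        K = np.asarray(self.K, dtype=float)
        p = G.shape[0]
        for name, M in (("G", G), ("H", H), ("K", K)):
            if M.shape != (p, p):
                raise ValueError(f"{name} must be p x p with p={p}, got {M.shape}")
        if p < 1:
            raise ValueError("p must be >= 1")
        for name, M in (("G", G), ("K", K)):
            if not np.allclose(M, M.T, atol=1e-12, rtol=0.0):
                raise ValueError(f"{name} must be symmetric")
        if np.any(np.diag(K) <= 0):
            raise ValueError("all diagonal entries of K must be strictly positive")
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "K", K)

    @property
    def p(self) -> int:
        return self.G.shape[0]

    def is_positive_definite(self) -> bool:
        try:
            np.linalg.cholesky(self.K)
            return True
        except np.linalg.LinAlgError:
            return False

    # --- JSON round-trip -------------------------------------------------
    def to_dict(self, taxon_ids: list[str] | None = None) -> dict:
        d = {
            "p": self.p,
            "G": self.G.tolist(),
            "H": self.H.tolist(),
            "K": self.K.tolist(),
        }
        if taxon_ids is not None:
            d["taxon_ids"] = list(taxon_ids)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HurdleParameters":
        return cls(G=np.array(d["G"]), H=np.array(d["H"]), K=np.array(d["K"]))

    def save_json(self, path: str | Path, taxon_ids: list[str] | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(taxon_ids)))

    @classmethod
    def load_json(cls, path: str | Path) -> "HurdleParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class NodeConditional:
    """Natural parameters of one node's univariate hurdle conditional.

    The conditional density of ``(v_i, y_i)`` given all other nodes is
    proportional to ``exp{ v_i * a + y_i * b - (kappa/2) * y_i^2 }`` on the
    hurdle support ``{(0, 0)} U ({1} x R)``.
    """

    a: float
    b: float
    kappa: float

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")


def _check_support(y: np.ndarray, v: np.ndarray) -> None:
    y = np.asarray(y, dtype=float)
    v = np.asarray(v)
    if y.shape != v.shape:
        raise ValueError("y and v must have the same shape")
    if not np.all(np.isin(v, (0, 1))):
        raise ValueError("v must be binary")
    if np.any((y != 0) & (v == 0)) or np.any((y == 0) & (v == 1)):
        raise ValueError("support inconsistency: y_j must be nonzero exactly where v_j = 1")


def joint_log_density_unnormalized(
    y: np.ndarray, v: np.ndarray, params: HurdleParameters
) -> float:
    """Exponent ``v'Gv + v'Hy - y'Ky/2`` of the joint density (normaliser omitted)."""
    _check_support(y, v)
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    return float(v @ params.G @ v + v @ params.H @ y - 0.5 * y @ params.K @ y)


def node_conditional_params(
    i: int,
    y: np.ndarray,
    v: np.ndarray,
    params: HurdleParameters,
) -> NodeConditional:
    """Collect the ``(v_i, y_i)`` terms of the joint exponent into the
    univariate conditional's natural parameters.

    With the rest of the configuration fixed:

    * ``a = g_ii + 2 sum_{j!=i} g_ij v_j + sum_{j!=i} h_ij y_j``
      (the factor 2 comes from ``v'Gv`` with symmetric G),
    * ``b = h_ii + sum_{j!=i} h_ji v_j - sum_{j!=i} k_ij y_j``,
    * ``kappa = k_ii``.

    ``y`` and ``v`` are full p-vectors; entries at position ``i`` are
    ignored.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    G, H, K = params.G, params.H, params.K
    a = G[i, i] + 2.0 * (G[i] @ v - G[i, i] * v[i]) + (H[i] @ y - H[i, i] * y[i])
    b = H[i, i] + (H[:, i] @ v - H[i, i] * v[i]) - (K[i] @ y - K[i, i] * y[i])
    kappa = K[i, i]
    if kappa <= 0:
        raise ValueError(f"k_{i}{i} must be positive, got {kappa}")
    return NodeConditional(a=float(a), b=float(b), kappa=float(max(kappa, _KAPPA_FLOOR)))


def _log_m(a: float, b: float, kappa: float) -> float:
    """log of m = exp(a + b^2/(2 kappa)) * sqrt(2 pi / kappa).

    m is the ratio of the present-branch mass to the absent-branch mass:
    integrating exp{a + b y - kappa y^2 / 2} over y gives
    exp(a + b^2/(2 kappa)) sqrt(2 pi / kappa), while the (v=0, y=0) atom
    contributes exp(0) = 1.
    """
    kappa = max(kappa, _KAPPA_FLOOR)
    return a + b * b / (2.0 * kappa) + 0.5 * (_LOG_2PI - math.log(kappa))


def presence_probability(nc: NodeConditional) -> float:
    """P(v_i = 1 | rest) = m / (1 + m), evaluated stably in log space."""
    return float(expit(_log_m(nc.a, nc.b, nc.kappa)))


def node_conditional_loglik(v_i: int, y_i: float, nc: NodeConditional) -> float:
    """Exact log-density of one observation under the univariate hurdle
    conditional (normalised: exp of it sums/integrates to 1 over the
    support ``{(0,0)} U {1} x R``)."""
    if v_i not in (0, 1):
        raise ValueError(f"v_i must be 0 or 1, got {v_i}")
    if (v_i == 0) != (y_i == 0.0):
        raise ValueError("support inconsistency: y_i must be nonzero exactly when v_i = 1")
    log_norm = np.logaddexp(0.0, _log_m(nc.a, nc.b, nc.kappa))
    return float(v_i * nc.a + y_i * nc.b - 0.5 * nc.kappa * y_i * y_i - log_norm)


def sample_node_conditional(
    nc: NodeConditional, rng: np.random.Generator
) -> tuple[int, float]:
    """Exact draw from the univariate hurdle conditional.

    Presence is Bernoulli with the closed-form probability; conditional on
    presence, the value is Normal(b/kappa, 1/kappa).
    """
    if rng.random() < presence_probability(nc):
        y = nc.b / nc.kappa + rng.standard_normal() / math.sqrt(nc.kappa)
        return 1, float(y)
    return 0, 0.0
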
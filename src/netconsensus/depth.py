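"""Depth algorithms: Eigenvector Centrality, David's Score, Graph Laplacian.

Depth algorithms treat interactions as a diffusion over the network and
weight a partner's contribution by that partner's own incoming flow.  Depth
can be counted as the number of chained matrix applications: David's Score
and the Graph Laplacian have depth two, while Eigenvector Centrality is the
infinite-depth fixed point of the flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .breadth import EntropyConfig, receiving_entropy
from .exceptions import ConfigError, NumericalError
from .network import DanglingPolicy, InteractionNetwork, sending_distribution
from .scores import ScoreVector


@dataclass(frozen=True)
class ECConfig:
    """Configuration of the redistribution (teleportation) fixed point.

    The centrality vector C >= 0 with sum 1 solves

        C = eps * v + (1 - eps) * C @ M

    where M is the dangling-patched row-stochastic sending distribution,
    ``eps`` in (0, 1] is the redistribution weight and ``v`` (sum 1) the
    redistribution probability vector (uniform by default).  Redistribution
    prevents all centrality from accumulating on absorbing non-senders.
    """

    epsilon: float = 0.15
    v: np.ndarray | None = None
    solver: str = "linear_solve"
    tol: float = 1e-12
    max_iter: int = 10000
    dangling_policy: DanglingPolicy = "self_loop"

    def __post_init__(self) -> None:
        if not 0 < self.epsilon <= 1:
            raise ConfigError(f"epsilon must be in (0, 1], got {self.epsilon}")
        if self.solver not in ("linear_solve", "power_iteration"):
            raise ConfigError(f"unknown solver {self.solver!r}")
        if self.v is not None:
            v = np.asarray(self.v, dtype=float)
            if np.any(v < 0) or not np.isclose(v.sum(), 1.0):
                raise ConfigError("redistribution vector must be non-negative and sum to 1")
            object.__setattr__(self, "v", v)

    def redistribution_vector(self, n: int) -> np.ndarray:
        if self.v is None:
            return np.full(n, 1.0 / n)
        if self.v.shape != (n,):
            raise ConfigError(f"redistribution vector length {self.v.shape[0]} != n = {n}")
        return self.v


def eigenvector_centrality(net: InteractionNetwork,
                           cfg: ECConfig | None = None) -> ScoreVector:
    """Eigenvector Centrality C with redistribution.

    Solves C = eps*v + (1-eps)*C@M either by a direct dense linear solve or
    by power iteration; both give the unique non-negative solution with
    sum(C) = 1 (any solution sums to 1 because M is row-stochastic).
    """
    cfg = cfg or ECConfig()
    n = net.n
    v = cfg.redistribution_vector(n)
    m = sending_distribution(net, cfg.dangling_policy).matrix
    eps = cfg.epsilon
    if cfg.solver == "linear_solve":
        c = np.linalg.solve(np.eye(n) - (1 - eps) * m.T, eps * v)
    else:
        c = v.copy()
        for _ in range(cfg.max_iter):
            c_next = eps * v + (1 - eps) * (m.T @ c)
            residual = np.abs(c_next - c).sum()
            c = c_next
            if residual < cfg.tol:
                break
        else:
            raise NumericalError(
                f"power iteration did not converge within {cfg.max_iter} "
                f"iterations (residual {residual:.3e})"
            )
    return ScoreVector(
        net.node_ids, c, algorithm="ec",
        params={"epsilon": eps,
                "v": "uniform" if cfg.v is None else "custom",
                "solver": cfg.solver,
                "dangling_policy": cfg.dangling_policy},
    )


def dyadic_proportions(net: InteractionNetwork,
                       win_oriented: bool = False) -> np.ndarray:
    """Dyadic proportion matrix rho (NaN for non-interacting dyads).

    Receive-oriented (default): rho[i, j] = A[j, i] / (A[i, j] + A[j, i]),
    the share of the dyad's interactions that i *receives* — so high rho
    favours nodes that receive much and emit little, matching the intended
    reading of David's Score on signalling data.  ``win_oriented=True``
    flips the convention (rho[i, j] = share i *sends*) for classical
    dominance matrices in which A records wins.
    """
    a = net.weights
    total = a + a.T
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(total > 0, (a if win_oriented else a.T) / np.where(total > 0, total, 1.0), np.nan)
    np.fill_diagonal(rho, np.nan)
    return rho


def _ds_terms(net: InteractionNetwork, k: int, win_oriented: bool):
    """Iterated win/loss accumulations w^(1..k), l^(1..k)."""
    rho = dyadic_proportions(net, win_oriented=win_oriented)
    defined = ~np.isnan(rho)
    rho_f = np.where(defined, rho, 0.0)          # receive shares
    loss_f = np.where(defined, 1.0 - rho, 0.0)   # emit shares
    w = rho_f.sum(axis=1)
    l = loss_f.sum(axis=1)
    ws, ls = [w], [l]
    for _ in range(k - 1):
        ws.append(rho_f @ ws[-1])
        ls.append(loss_f @ ls[-1])
    return ws, ls


def davids_score_depth(net: InteractionNetwork, k: int = 2,
                       win_oriented: bool = False) -> ScoreVector:
    """Depth-k generalization of David's Score.

    Accumulates dyadic receive/emit proportions along chains of length up
    to k: score = sum_{t=1..k} (w^(t) - l^(t)) with w^(t) = rho @ w^(t-1)
    (and symmetrically for l).  k=2 reproduces the classical score exactly;
    as k grows the rank order stabilizes.
    """
    if k < 1:
        raise ConfigError(f"depth k must be >= 1, got {k}")
    ws, ls = _ds_terms(net, k, win_oriented)
    score = sum(ws) - sum(ls)
    return ScoreVector(net.node_ids, score, algorithm="ds-k",
                       params={"k": k, "win_oriented": win_oriented})


def davids_score(net: InteractionNetwork, win_oriented: bool = False) -> ScoreVector:
    """David's Score DS = w + w2 - l - l2 (depth two).

    w[i] sums i's receive proportions over interacting dyads, w2 weights
    each by the partner's own w; l, l2 are the emit-side mirrors.
    Non-interacting dyads contribute nothing (they are absent, not 1/2).
    On an undirected network every defined proportion is 1/2, so DS is
    identically zero.
    """
    ws, ls = _ds_terms(net, 2, win_oriented)
    score = ws[0] + ws[1] - ls[0] - ls[1]
    return ScoreVector(net.node_ids, score, algorithm="ds",
                       params={"win_oriented": win_oriented})


def graph_laplacian_consensus(net: InteractionNetwork,
                              cfg: EntropyConfig | None = None) -> ScoreVector:
    """Graph Laplacian consensus GL = (K - A^T) H with K = diag(R).

    GL[i] = R[i]*H[i] - sum_j A[j, i]*H[j]: the net entropy-weighted flow
    into node i.  A node with high receiving entropy whose senders have low
    entropy scores highest; on an entropy-constant network GL is zero.
    """
    cfg = cfg or EntropyConfig()
    h = receiving_entropy(net, cfg).values
    r = net.in_strength()
    gl = r * h - net.weights.T @ h
    return ScoreVector(net.node_ids, gl, algorithm="gl",
                       params={"log_base": cfg.log_base})
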
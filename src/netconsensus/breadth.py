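"""Breadth and count algorithms: D, Delta, H, Pi and the Borda count.

Breadth algorithms score a node by how *uniformly many* distinct partners
direct interactions at it.  Simple Consensus D counts distinct senders;
Weighted Simple Consensus Delta = D * R multiplies breadth by the weighted
in-degree R; Shannon Consensus Pi = H * R replaces the partner count with
the Shannon entropy H of the node's receiving distribution, so a node
scores highly only when it receives many interactions *and* receives
similar numbers from each partner.  The Borda count aggregates each node's
ordinal ranking of the others as votes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import rankdata

from .exceptions import ConfigError
from .network import InteractionNetwork, receiving_distribution
from .scores import ScoreVector

LogBase = Literal["natural", "base2"]


@dataclass(frozen=True)
class EntropyConfig:
    """Entropy convention shared by H, Pi and the Graph Laplacian.

    ``log_base``: "natural" (nats, default) or "base2" (bits).  A node with
    zero in-weight has entropy 0 by convention (consensus about a node no
    one interacts with is vacuous).
    """

    log_base: LogBase = "natural"

    def __post_init__(self) -> None:
        if self.log_base not in ("natural", "base2"):
            raise ConfigError(f"unknown log base {self.log_base!r}")

    def log(self, x: np.ndarray) -> np.ndarray:
        return np.log(x) if self.log_base == "natural" else np.log2(x)


def simple_consensus(net: InteractionNetwork) -> ScoreVector:
    """Simple Consensus D: number of distinct senders to each node."""
    d = (net.weights > 0).sum(axis=0).astype(float)
    return ScoreVector(net.node_ids, d, algorithm="D")


def weighted_simple_consensus(net: InteractionNetwork) -> ScoreVector:
    """Weighted Simple Consensus Delta = D * R.

    Multiplying the sender count by the total in-weight distinguishes a node
    receiving ten interactions from each of ten partners from one receiving
    a single interaction from each of the same ten partners.
    """
    d = (net.weights > 0).sum(axis=0).astype(float)
    r = net.in_strength()
    return ScoreVector(net.node_ids, d * r, algorithm="delta")


def column_entropy(matrix: np.ndarray, cfg: EntropyConfig | None = None) -> np.ndarray:
    """Shannon entropy of each column of a column-stochastic matrix.

    All-zero columns get entropy 0.
    """
    cfg = cfg or EntropyConfig()
    m = np.asarray(matrix, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(m > 0, m * cfg.log(np.where(m > 0, m, 1.0)), 0.0)
    h = -plogp.sum(axis=0)
    return h + 0.0  # normalize -0.0 to 0.0


def receiving_entropy(net: InteractionNetwork,
                      cfg: EntropyConfig | None = None) -> ScoreVector:
    """Shannon entropy H of each node's receiving distribution.

    H is 0 with a single sender, log(k) with k equal-weight senders (its
    maximum), and 0 by convention for nodes that receive nothing.
    """
    cfg = cfg or EntropyConfig()
    h = column_entropy(receiving_distribution(net).matrix, cfg)
    return ScoreVector(net.node_ids, h, algorithm="H",
                       params={"log_base": cfg.log_base})


def shannon_consensus(net: InteractionNetwork, cfg: EntropyConfig | None = None,
                      weighting: Literal["R", "logR"] = "R") -> ScoreVector:
    """Shannon Consensus Pi: entropy-weighted in-degree.

    Default Pi = H * R.  The alternative ``weighting="logR"`` uses
    Pi = H * log(R) (log base per ``cfg``), for users who prefer a score on
    the entropy scale; both weightings give 0 to single-sender nodes.
    """
    cfg = cfg or EntropyConfig()
    if weighting not in ("R", "logR"):
        raise ConfigError(f"unknown Pi weighting {weighting!r}")
    h = receiving_entropy(net, cfg).values
    r = net.in_strength()
    if weighting == "R":
        v = h * r
    else:
        v = h * np.where(r > 0, cfg.log(np.where(r > 0, r, 1.0)), 0.0)
    return ScoreVector(net.node_ids, v, algorithm="pi",
                       params={"log_base": cfg.log_base, "weighting": weighting})


def vote_matrix(net: InteractionNetwork) -> np.ndarray:
    """Votes V[i, j] given node j by voter i.

    Each voter ranks the other n-1 nodes by how much it sends them; the
    top candidate gets n-1 votes down to 1 for the bottom, tied candidates
    get the average of the votes they span.  Candidates a voter does not
    interact with form its bottom tie class, and voters with no out-edges
    still vote (everyone tied).  Each row therefore distributes exactly
    n(n-1)/2 votes.
    """
    n = net.n
    if n < 2:
        raise ConfigError("Borda voting requires at least 2 nodes")
    v = np.zeros((n, n))
    for i in range(n):
        cand = np.delete(np.arange(n), i)
        weights = net.weights[i, cand]
        positions = rankdata(-weights, method="average")  # 1 = most-signalled
        v[i, cand] = n - positions
    return v


def borda_count(net: InteractionNetwork) -> ScoreVector:
    """Borda count beta: column sums of the vote matrix."""
    beta = vote_matrix(net).sum(axis=0)
    return ScoreVector(net.node_ids, beta, algorithm="borda")
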
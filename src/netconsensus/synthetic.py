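"""Synthetic networks emulating the statistical structure of three systems:

* ``signaling``: directed, weighted, strictly unidirectional dyads whose
  direction follows a latent strength order (weak signals to strong) with a
  small noise rate — heavy-tailed in-weight, high transitivity, and a
  positive coupling between receiving entropy and in-degree.
* ``collaboration``: sparse unweighted undirected graphs with a
  right-skewed degree distribution and a tunable degree assortativity.
* ``decorrelated``: a two-class construction in which half the nodes
  receive many events from a single sender (high R, zero H) and half
  receive one event from each of many senders (low R, maximal H), forcing
  a non-positive H-vs-R correlation.

Outcome vectors linearly coupled to any score vector (with additive
Gaussian noise of known population R^2) stand in for functional data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .network import InteractionNetwork
from .scores import ScoreVector

Kind = Literal["signaling", "collaboration", "decorrelated"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated network; spec + seed fully determine it.

    ``interaction_prob`` activates each dyad independently;
    ``direction_noise`` is the probability a signal direction violates the
    latent strength order; ``weight_rate`` is the mean per-dyad event count
    (events are drawn as 1 + Poisson so active dyads are never empty);
    ``assortativity_knob`` (collaboration only) is a target degree
    assortativity, or None to leave the graph as generated.
    """

    kind: Kind = "signaling"
    n: int = 50
    interaction_prob: float = 0.3
    direction_noise: float = 0.05
    weight_rate: float = 5.0
    assortativity_knob: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("signaling", "collaboration", "decorrelated"):
            raise ConfigError(f"unknown kind {self.kind!r}")
        if self.n < 4:
            raise ConfigError("need at least 4 nodes")
        for name in ("interaction_prob", "direction_noise"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.weight_rate < 1:
            raise ConfigError("weight_rate must be >= 1")
        if self.assortativity_knob is not None and not -1 <= self.assortativity_knob <= 1:
            raise ConfigError("assortativity_knob must be in [-1, 1]")


def _node_ids(n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"n{i:0{width}d}" for i in range(n))


def generate_signaling_network(spec: SyntheticSpec) -> InteractionNetwork:
    """Heavy-tailed unidirectional signalling network.

    Latent strengths are log-normal; each active dyad carries signals from
    the weaker to the stronger member (direction flipped with probability
    ``direction_noise``), with event counts 1 + Poisson scaled by the
    receiver's relative strength.  With zero noise the binary relation is a
    sub-relation of a total order and hence fully transitive.
    """
    if spec.kind != "signaling":
        raise ConfigError(f"spec.kind is {spec.kind!r}, expected 'signaling'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    strength = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    mean_s = strength.mean()
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() >= spec.interaction_prob:
                continue
            weak, strong = (i, j) if strength[i] < strength[j] else (j, i)
            sender, receiver = weak, strong
            if rng.random() < spec.direction_noise:
                sender, receiver = strong, weak
            lam = max(spec.weight_rate * strength[receiver] / mean_s - 1.0, 0.0)
            a[sender, receiver] = 1.0 + rng.poisson(lam)
    return InteractionNetwork(_node_ids(n), a, directed=True, weighted=True)


def generate_collaboration_network(
    spec: SyntheticSpec, *, assortativity_tol: float = 0.05,
    max_swaps: int = 100000
) -> InteractionNetwork:
    """Unweighted undirected graph with right-skewed degrees.

    Expected degrees are log-normal (scaled so the mean degree is
    ``interaction_prob * (n - 1)``); when ``assortativity_knob`` is set,
    degree-preserving double-edge swaps are accepted only when they move
    the measured degree assortativity toward the target.
    """
    if spec.kind != "collaboration":
        raise ConfigError(f"spec.kind is {spec.kind!r}, expected 'collaboration'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    if spec.interaction_prob == 1.0:
        return InteractionNetwork(_node_ids(n), np.ones((n, n)) - np.eye(n),
                                  directed=False, weighted=False)
    mean_deg = spec.interaction_prob * (n - 1)
    w = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    w *= mean_deg / w.mean()
    w = np.minimum(w, n - 1)
    g = nx.expected_degree_graph(w, selfloops=False,
                                 seed=int(rng.integers(2**31)))
    if spec.assortativity_knob is not None:
        _rewire_to_assortativity(g, spec.assortativity_knob,
                                 tol=assortativity_tol, max_swaps=max_swaps,
                                 rng=rng)
    a = np.zeros((n, n))
    for u, v in g.edges():
        a[u, v] = a[v, u] = 1.0
    return InteractionNetwork(_node_ids(n), a, directed=False, weighted=False)


def _rewire_to_assortativity(g: nx.Graph, target: float, tol: float,
                             max_swaps: int, rng: np.random.Generator) -> None:
    """Degree-preserving double-edge swaps toward a target assortativity.

    Under degree-preserving swaps, Newman's assortativity coefficient is an
    affine function of S = sum over edges of deg(u)*deg(v) (the remaining
    terms depend only on the fixed degree sequence), so moves are scored in
    O(1) by how they shift S toward its target value.  Raises with the
    achieved value if the target is unreachable.
    """
    deg = dict(g.degree())
    edges = [tuple(e) for e in g.edges()]
    n_edges = len(edges)
    if n_edges < 2:
        raise ConfigError("too few edges to rewire toward an assortativity target")
    # stub-level moments, invariant under swaps
    b = sum(0.5 * (deg[u] + deg[v]) for u, v in edges) / n_edges
    c = sum(0.5 * (deg[u] ** 2 + deg[v] ** 2) for u, v in edges) / n_edges
    denom = c - b * b
    if denom == 0:
        return  # regular graph: assortativity undefined, nothing to do
    s = float(sum(deg[u] * deg[v] for u, v in edges))
    s_target = n_edges * (target * denom + b * b)

    def r_of(s_val: float) -> float:
        return (s_val / n_edges - b * b) / denom

    edge_set = {frozenset(e) for e in edges}
    # simulated annealing on S: worsening moves are accepted with
    # probability exp(-delta/T), with T starting at the square of the mean
    # degree (the natural scale of a move) and cooling linearly, so the
    # walk escapes the jamming points where no single swap improves
    mean_deg = 2.0 * n_edges / max(len(deg), 1)
    t0_temp = mean_deg * mean_deg
    cooling = 0.8 * max_swaps
    for step in range(max_swaps):
        if abs(r_of(s) - target) <= tol:
            break
        temp = t0_temp * max(1.0 - step / cooling, 0.0)
        i1, i2 = rng.choice(n_edges, size=2, replace=False)
        (a1, b1), (a2, b2) = edges[i1], edges[i2]
        if len({a1, b1, a2, b2}) < 4:
            continue
        # the two degree-preserving rewirings of the edge pair
        options = []
        for (x1, y1), (x2, y2) in (((a1, a2), (b1, b2)), ((a1, b2), (b1, a2))):
            if frozenset((x1, y1)) in edge_set or frozenset((x2, y2)) in edge_set:
                continue
            s_new = s - deg[a1] * deg[b1] - deg[a2] * deg[b2] \
                + deg[x1] * deg[y1] + deg[x2] * deg[y2]
            options.append((s_new, (x1, y1), (x2, y2)))
        if not options:
            continue
        s_new, e1, e2 = options[int(rng.integers(len(options)))]
        delta = abs(s_new - s_target) - abs(s - s_target)
        if delta > 0 and (temp <= 0 or rng.random() >= np.exp(-delta / temp)):
            continue
        edge_set.discard(frozenset(edges[i1]))
        edge_set.discard(frozenset(edges[i2]))
        edge_set.add(frozenset(e1))
        edge_set.add(frozenset(e2))
        edges[i1], edges[i2] = e1, e2
        s = s_new
    achieved = r_of(s)
    if abs(achieved - target) > tol:
        raise ConfigError(
            f"could not reach degree assortativity {target:+.2f} "
            f"(achieved {achieved:+.3f}) within {max_swaps} swap attempts"
        )
    g.remove_edges_from(list(g.edges()))
    g.add_edges_from(edges)


def generate_decorrelated_network(spec: SyntheticSpec) -> InteractionNetwork:
    """Two-class network decoupling in-weight from receiving entropy.

    Concentrated-class nodes receive ``~4 * weight_rate`` events from one
    sender (H = 0); spread-class nodes receive one event from each of
    several senders (H = log k).  Spearman(H, R) <= 0 by construction.
    """
    if spec.kind != "decorrelated":
        raise ConfigError(f"spec.kind is {spec.kind!r}, expected 'decorrelated'")
    n = spec.n
    k_spread = min(5, n - 2)
    heavy = max(int(round(4 * spec.weight_rate)), k_spread + 1)
    if n < 4 or k_spread < 2:
        raise ConfigError("too few nodes to form both receiver classes")
    rng = np.random.default_rng(spec.seed)
    a = np.zeros((n, n))
    concentrated = set(range((n + 1) // 2))
    for t in range(n):
        others = np.setdiff1d(np.arange(n), [t])
        if t in concentrated:
            sender = int(rng.choice(others))
            a[sender, t] += heavy
        else:
            senders = rng.choice(others, size=k_spread, replace=False)
            a[senders, t] += 1.0
    np.fill_diagonal(a, 0.0)
    return InteractionNetwork(_node_ids(n), a, directed=True, weighted=True)


def population_r2(scores: np.ndarray, slope: float, noise_sd: float) -> float:
    """Closed-form R^2 of the generating model outcome = slope*s + noise."""
    signal = float(np.var(slope * np.asarray(scores, dtype=float)))
    if signal + noise_sd**2 == 0:
        return 0.0
    return signal / (signal + noise_sd**2)


def noise_sd_for_r2(scores: np.ndarray, slope: float, r2: float) -> float:
    """Noise sd giving the requested population R^2 for a score vector."""
    if not 0 < r2 <= 1:
        raise ConfigError("target R^2 must be in (0, 1]")
    signal = float(np.var(slope * np.asarray(scores, dtype=float)))
    return float(np.sqrt(signal * (1.0 - r2) / r2))


def generate_outcomes(
    scores: ScoreVector, slope: float = 2.0, noise_sd: float = 1.0,
    n_outcomes: int = 3, seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Outcome columns linearly coupled to a score vector.

    Each column is ``slope * score + N(0, noise_sd)`` with independent
    noise; returns the table (indexed by node id) and metadata recording
    the implied population R^2.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    s = scores.values
    data = {
        f"outcome_{j + 1}": slope * s + rng.normal(0.0, noise_sd, size=len(s))
        for j in range(n_outcomes)
    }
    df = pd.DataFrame(data, index=list(scores.node_ids))
    df.index.name = "node"
    meta = {
        "slope": slope,
        "noise_sd": noise_sd,
        "score_algorithm": scores.algorithm,
        "population_r2": population_r2(s, slope, noise_sd),
        "seed": seed,
    }
    return df, meta


def generate_network(spec: SyntheticSpec) -> InteractionNetwork:
    """Dispatch on ``spec.kind``."""
    return {
        "signaling": generate_signaling_network,
        "collaboration": generate_collaboration_network,
        "decorrelated": generate_decorrelated_network,
    }[spec.kind](spec)
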
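"""Algorithm registry: name -> callable(net) -> ScoreVector.

New consensus measures plug in via :func:`register` without touching the
CLI or the robustness machinery.
"""

from __future__ import annotations

from functools import partial
from typing import Callable

from .breadth import (EntropyConfig, borda_count, receiving_entropy,
                      shannon_consensus, simple_consensus,
                      weighted_simple_consensus)
from .depth import (ECConfig, davids_score, davids_score_depth,
                    eigenvector_centrality, graph_laplacian_consensus)
from .exceptions import ConfigError
from .network import InteractionNetwork, weighted_in_degree
from .scores import ScoreVector

Algorithm = Callable[[InteractionNetwork], ScoreVector]

_REGISTRY: dict[str, Algorithm] = {}


def register(name: str, fn: Algorithm, overwrite: bool = False) -> None:
    if name in _REGISTRY and not overwrite:
        raise ConfigError(f"algorithm {name!r} is already registered")
    _REGISTRY[name] = fn


def get_algorithm(name: str) -> Algorithm:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ConfigError(
            f"unknown algorithm {name!r}; registered: {', '.join(sorted(_REGISTRY))}"
        ) from None


def registered_algorithms() -> list[str]:
    return sorted(_REGISTRY)


def make_algorithm(name: str, *, epsilon: float = 0.15, k: int = 2,
                   log_base: str = "natural",
                   dangling_policy: str = "self_loop") -> Algorithm:
    """Build a configured algorithm callable from CLI-style parameters."""
    ecfg = EntropyConfig(log_base=log_base)
    if name == "ec":
        cfg = ECConfig(epsilon=epsilon, dangling_policy=dangling_policy)
        return partial(eigenvector_centrality, cfg=cfg)
    if name == "ds-k":
        return partial(davids_score_depth, k=k)
    if name in ("H", "pi", "gl"):
        base = {"H": receiving_entropy, "pi": shannon_consensus,
                "gl": graph_laplacian_consensus}[name]
        return partial(base, cfg=ecfg)
    return get_algorithm(name)


for _name, _fn in {
    "R": weighted_in_degree,
    "D": simple_consensus,
    "delta": weighted_simple_consensus,
    "H": receiving_entropy,
    "pi": shannon_consensus,
    "borda": borda_count,
    "ec": eigenvector_centrality,
    "ds": davids_score,
    "ds-k": davids_score_depth,
    "gl": graph_laplacian_consensus,
}.items():
    register(_name, _fn)
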
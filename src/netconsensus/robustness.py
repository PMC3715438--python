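"""Source-bias shuffle, sensitivity experiment and degree-preserving control.

A *source bias* concentrates a node's incoming weight on few senders —
through systematic observation error or deliberate manipulation.  The
shuffle here is the extreme case: the target receives *all* of its
in-weight from a single partner while every weighted in-degree is held
constant, so any score change reflects sensitivity to the sourcing of
interactions rather than to their volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import ConstantInputWarning, spearmanr

from .exceptions import ConfigError, DataError, RandomizationError
from .network import InteractionNetwork
from .registry import get_algorithm
from .scores import ScoreVector


def source_bias_shuffle(net: InteractionNetwork, target: str,
                        partner: str) -> InteractionNetwork:
    """Concentrate all of ``target``'s in-weight on ``partner``.

    Directed: the target's in-column is zeroed except for the
    partner->target entry, which is set to the target's weighted in-degree
    R[target]; all other entries (including the partner's out-edges to
    third parties) are unchanged, so the full weighted in-degree vector is
    conserved.  Undirected: the target's incident edges are replaced by a
    single symmetric edge of weight R[target] to the partner.
    """
    t = net.index(target)
    p = net.index(partner)
    r_t = net.in_strength()[t]
    if r_t <= 0:
        raise ConfigError(f"target {target!r} receives no interactions")
    if net.weights[p, t] <= 0:
        raise ConfigError(f"{partner!r} is not an in-neighbor of {target!r}")
    a = net.weights.copy()
    if net.directed:
        a[:, t] = 0.0
        a[p, t] = r_t
    else:
        a[:, t] = 0.0
        a[t, :] = 0.0
        a[p, t] = a[t, p] = r_t
    weighted = net.weighted or bool(np.any((a != 0) & (a != 1)))
    return net.with_weights(a, weighted=weighted)


@dataclass(frozen=True)
class ShuffleExperiment:
    """Per-trial records and per-algorithm summaries of a sensitivity run.

    ``trials`` has one row per (target, partner, algorithm) with the
    target's tie-aware rank before/after the shuffle, the rank drop
    (after - before; positive means the target fell), and the Spearman
    correlation between the full before/after rankings.  ``summary``
    aggregates mean and sd of both statistics per algorithm.
    """

    base: InteractionNetwork
    trials: pd.DataFrame
    summary: pd.DataFrame
    sample_size: int | str
    seed: int | None
    n_skipped_isolated: int


def _eligible_pairs(net: InteractionNetwork) -> list[tuple[int, int]]:
    pairs = []
    for t in range(net.n):
        senders = np.nonzero(net.weights[:, t] > 0)[0]
        pairs.extend((t, int(p)) for p in senders)
    return pairs


def sensitivity_experiment(
    net: InteractionNetwork,
    algorithms: Sequence[str],
    sample_size: int | str = "all",
    seed: int | None = None,
) -> ShuffleExperiment:
    """Run the source-bias shuffle over sampled (target, partner) pairs.

    ``sample_size="all"`` exhausts every (target, in-neighbor) pair — the
    treatment suitable for small networks.  An integer samples that many
    targets uniformly without replacement and one random in-neighbor each.
    Deterministic given the seed.
    """
    fns = {name: get_algorithm(name) for name in algorithms}
    r = net.in_strength()
    eligible_targets = np.nonzero(r > 0)[0]
    n_skipped = int(net.n - len(eligible_targets))
    if len(eligible_targets) == 0:
        raise DataError("no eligible targets: every node has zero in-weight")

    rng = np.random.default_rng(seed)
    if sample_size == "all":
        pairs = _eligible_pairs(net)
    else:
        k = int(sample_size)
        if k > len(eligible_targets):
            raise ConfigError(
                f"sample_size {k} exceeds the {len(eligible_targets)} eligible targets"
            )
        targets = rng.choice(eligible_targets, size=k, replace=False)
        pairs = []
        for t in targets:
            senders = np.nonzero(net.weights[:, t] > 0)[0]
            pairs.append((int(t), int(rng.choice(senders))))

    before = {name: fn(net) for name, fn in fns.items()}
    before_ranks = {name: sv.ranks for name, sv in before.items()}

    records = []
    for t, p in pairs:
        shuffled = source_bias_shuffle(net, net.node_ids[t], net.node_ids[p])
        for name, fn in fns.items():
            after = fn(shuffled)
            after_ranks = after.ranks
            with warnings.catch_warnings():
                # a constant score vector leaves the correlation undefined;
                # the trial records NaN and summaries skip it
                warnings.simplefilter("ignore", ConstantInputWarning)
                rho = spearmanr(before[name].values, after.values).statistic
            records.append({
                "target": net.node_ids[t],
                "partner": net.node_ids[p],
                "algorithm": name,
                "rank_before": before_ranks[name][t],
                "rank_after": after_ranks[t],
                "rank_drop": after_ranks[t] - before_ranks[name][t],
                "spearman": rho,
            })
    trials = pd.DataFrame.from_records(records)
    summary = (
        trials.groupby("algorithm", sort=False)
        .agg(mean_rank_drop=("rank_drop", "mean"),
             sd_rank_drop=("rank_drop", "std"),
             mean_spearman=("spearman", "mean"),
             sd_spearman=("spearman", "std"),
             n_trials=("rank_drop", "size"))
        .reset_index()
    )
    return ShuffleExperiment(net, trials, summary, sample_size, seed, n_skipped)


def degree_preserving_randomization(
    net: InteractionNetwork, seed: int | None = None, max_retries: int = 100000
) -> InteractionNetwork:
    """Randomize a directed network preserving every node's weighted
    in-degree and out-degree exactly.

    Each unit of weight is an event token; sender tokens are re-matched to
    a random permutation of receiver tokens, with self-loop conflicts
    repaired by random swaps (re-drawing until none remain).  Destroys
    transitivity and other higher-order structure while conserving all
    in/out strength margins.
    """
    if not net.directed:
        raise ConfigError("degree-preserving randomization requires a directed network")
    a = net.weights
    if not np.allclose(a, np.round(a)):
        raise ConfigError("event-token randomization requires integer weights")
    a = np.round(a).astype(int)
    out = a.sum(axis=1)
    senders = np.repeat(np.arange(net.n), out)
    receivers = np.repeat(np.arange(net.n), a.sum(axis=0))
    rng = np.random.default_rng(seed)
    receivers = rng.permutation(receivers)
    total = len(receivers)
    retries = 0
    while True:
        conflicts = np.nonzero(senders == receivers)[0]
        if len(conflicts) == 0:
            break
        if retries >= max_retries:
            raise RandomizationError(
                "could not remove self-loops from the token matching; the "
                "degree sequence may be pathological — consider relaxing "
                "the unidirectionality constraint of the input"
            )
        for pos in conflicts:
            other = int(rng.integers(total))
            receivers[pos], receivers[other] = receivers[other], receivers[pos]
            retries += 1
    new = np.zeros((net.n, net.n), dtype=float)
    np.add.at(new, (senders, receivers), 1.0)
    weighted = net.weighted or bool(new.max() > 1)
    return net.with_weights(new, weighted=weighted)
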
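"""Predictive evaluation against functional covariates.

Given a score vector and a table of per-node outcomes, this module builds
rank-quartile prediction-heterogeneity profiles (r^2 of outcome-on-score
regressions within seven nested rank subsets), selects the redistribution
weight for Eigenvector Centrality (by predictive value when outcomes are
available, by skewness minimization otherwise), and summarizes score
distributions (skewness, normality of raw and log-transformed scores).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .depth import ECConfig, eigenvector_centrality
from .breadth import EntropyConfig, receiving_entropy
from .exceptions import ConfigError, DataError
from .network import InteractionNetwork, weighted_in_degree
from .scores import ScoreVector

logger = logging.getLogger(__name__)

SUBSET_NAMES = ("Q1", "Q1-2", "Q1-3", "all", "Q2-4", "Q3-4", "Q4")


def load_outcomes(path: str | Path) -> pd.DataFrame:
    """Read a TSV outcome table with header `node` + one column per outcome."""
    df = pd.read_csv(path, sep="\t")
    if "node" not in df.columns:
        raise DataError(f"{path}: outcome table must have a 'node' column")
    df["node"] = df["node"].astype(str)
    return df.set_index("node")


def quartile_subsets(scores: ScoreVector) -> dict[str, list[str]]:
    """Seven nested rank subsets: top quartile, top half, top three
    quartiles, all nodes, and the bottom-side mirrors.

    Nodes are sorted by (score descending, node id ascending) so ties are
    resolved deterministically; cut points are at ceil(n*k/4).
    """
    n = scores.n
    if n < 4:
        raise DataError(f"quartile subsets need at least 4 nodes, got {n}")
    order = sorted(range(n), key=lambda i: (-scores.values[i], scores.node_ids[i]))
    ids = [scores.node_ids[i] for i in order]
    cuts = [int(np.ceil(n * k / 4)) for k in (1, 2, 3, 4)]
    return {
        "Q1": ids[: cuts[0]],
        "Q1-2": ids[: cuts[1]],
        "Q1-3": ids[: cuts[2]],
        "all": ids[:],
        "Q2-4": ids[cuts[0]:],
        "Q3-4": ids[cuts[1]:],
        "Q4": ids[cuts[2]:],
    }


def _univariate_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS r^2 and two-sided p of regressing y on x; a zero-variance fit
    is defined as r^2 = 0 (warned)."""
    if np.var(x) == 0 or np.var(y) == 0:
        warnings.warn("zero-variance regression: r^2 defined as 0", stacklevel=3)
        return 0.0, np.nan
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), float(fit.pvalue)


def _multivariate_r2(score: np.ndarray, outcomes: np.ndarray) -> float:
    """Squared multiple correlation from regressing the score on all
    outcome columns jointly.  Symmetric in spirit to the univariate r^2
    and reduces to it with a single outcome."""
    if np.var(score) == 0:
        warnings.warn("zero-variance regression: r^2 defined as 0", stacklevel=3)
        return 0.0
    x = sm.add_constant(outcomes, has_constant="add")
    return float(sm.OLS(score, x).fit().rsquared)


@dataclass(frozen=True)
class PredictionProfile:
    """r^2 surface over seven rank subsets x outcomes (+ multivariate).

    ``r2``/``pvalues`` are DataFrames indexed by subset name with one
    column per outcome; ``multivariate_r2`` is a Series per subset.
    Subsets with too few usable pairs hold NaN.
    """

    algorithm: str
    r2: pd.DataFrame
    pvalues: pd.DataFrame
    multivariate_r2: pd.Series
    subset_sizes: pd.Series
    params: Mapping[str, object]


def prediction_profile(scores: ScoreVector,
                       outcomes: pd.DataFrame) -> PredictionProfile:
    """Regress each outcome on the scores within every rank subset.

    Missing outcome values are dropped pairwise (logged); a subset needs
    at least 3 usable pairs per regression, otherwise NaN is reported.
    """
    outcomes = outcomes.copy()
    outcomes.index = outcomes.index.astype(str)
    overlap = [i for i in scores.node_ids if i in outcomes.index]
    if not overlap:
        raise DataError("no overlap between scored nodes and outcome table")
    score_s = scores.to_series()
    subsets = quartile_subsets(scores)

    r2 = pd.DataFrame(index=list(SUBSET_NAMES), columns=list(outcomes.columns),
                      dtype=float)
    pv = r2.copy()
    multi = pd.Series(index=list(SUBSET_NAMES), dtype=float)
    sizes = pd.Series(index=list(SUBSET_NAMES), dtype=int)

    for name in SUBSET_NAMES:
        members = [i for i in subsets[name] if i in outcomes.index]
        sizes[name] = len(members)
        if len(members) < 4:
            continue
        x = score_s.loc[members]
        for col in outcomes.columns:
            y = outcomes.loc[members, col]
            ok = y.notna()
            n_drop = int((~ok).sum())
            if n_drop:
                logger.info("subset %s, outcome %s: dropped %d missing pairs",
                            name, col, n_drop)
            if ok.sum() < 3:
                continue
            r2.loc[name, col], pv.loc[name, col] = _univariate_r2(
                x[ok].to_numpy(), y[ok].to_numpy())
        complete = outcomes.loc[members].dropna()
        if len(complete) >= 3:
            multi[name] = _multivariate_r2(
                score_s.loc[complete.index].to_numpy(), complete.to_numpy())
    return PredictionProfile(scores.algorithm, r2, pv, multi, sizes,
                             dict(scores.params))


@dataclass(frozen=True)
class SweepResult:
    """Redistribution-weight sweep: per-epsilon criterion and selection."""

    table: pd.DataFrame
    selected_epsilon: float
    criterion: str


def redistribution_sweep(
    net: InteractionNetwork,
    epsilons: Sequence[float],
    outcomes: pd.DataFrame | None = None,
    base_config: ECConfig | None = None,
) -> SweepResult:
    """Sweep the redistribution weight of Eigenvector Centrality.

    With outcomes the criterion is the full-sample multivariate r^2 of the
    EC scores against the outcome set (selected epsilon = argmax); without
    outcomes it is |sample skewness| of the EC scores (argmin), the
    fallback heuristic for data sets with no functional covariates.  Ties
    go to the first grid value (grids are evaluated in the given order).
    """
    eps_grid = [float(e) for e in epsilons]
    if not eps_grid:
        raise ConfigError("epsilon grid is empty")
    if any(not 0 < e <= 1 for e in eps_grid):
        raise ConfigError("epsilon grid values must be in (0, 1]")
    base = base_config or ECConfig()
    rows = []
    for eps in eps_grid:
        cfg = ECConfig(epsilon=eps, v=base.v, solver=base.solver, tol=base.tol,
                       max_iter=base.max_iter, dangling_policy=base.dangling_policy)
        sv = eigenvector_centrality(net, cfg)
        if outcomes is not None:
            aligned = outcomes.loc[[i for i in sv.node_ids
                                    if i in outcomes.index]].dropna()
            crit = _multivariate_r2(
                sv.to_series().loc[aligned.index].to_numpy(), aligned.to_numpy())
        else:
            crit = float(stats.skew(sv.values))
        rows.append({"epsilon": eps, "criterion": crit})
    table = pd.DataFrame(rows)
    if outcomes is not None:
        best = int(table["criterion"].to_numpy().argmax())
        name = "multivariate_r2"
    else:
        best = int(np.abs(table["criterion"].to_numpy()).argmin())
        name = "abs_skewness"
    return SweepResult(table, float(table.loc[best, "epsilon"]), name)


def score_distribution_report(scores: ScoreVector) -> dict:
    """Distribution summary: skewness, range, and Shapiro-Wilk normality of
    the raw scores and of the log of the positive scores.

    Zeros (and negatives) are excluded from the log branch with their count
    noted; the branch is skipped entirely below 8 positive scores.
    Constant scores report skewness 0 and skip the tests.
    """
    v = scores.values
    if len(v) < 8:
        raise DataError("distribution report needs at least 8 scores")
    report: dict = {
        "algorithm": scores.algorithm,
        "n": int(len(v)),
        "min": float(v.min()),
        "max": float(v.max()),
        "notes": [],
    }
    if np.var(v) == 0:
        report["skewness"] = 0.0
        report["notes"].append("constant scores: normality tests skipped")
        return report
    report["skewness"] = float(stats.skew(v))
    w, p = stats.shapiro(v)
    report["shapiro_raw"] = {"statistic": float(w), "pvalue": float(p)}
    positive = v[v > 0]
    report["n_nonpositive_excluded"] = int(len(v) - len(positive))
    if len(positive) < 8:
        report["notes"].append(
            f"only {len(positive)} positive scores: log branch skipped")
        return report
    logs = np.log(positive)
    if np.var(logs) == 0:
        report["notes"].append("constant log scores: log branch skipped")
        return report
    report["log_skewness"] = float(stats.skew(logs))
    w, p = stats.shapiro(logs)
    report["shapiro_log"] = {"statistic": float(w), "pvalue": float(p)}
    return report


def score_correlation_matrix(score_vectors: Sequence[ScoreVector],
                             method: str = "spearman") -> pd.DataFrame:
    """Pairwise correlations between algorithms' score vectors."""
    df = pd.DataFrame({sv.algorithm: sv.to_series() for sv in score_vectors})
    return df.corr(method=method)


def entropy_indegree_correlation(
    net: InteractionNetwork, cfg: EntropyConfig | None = None
) -> tuple[float, float]:
    """Spearman correlation between receiving entropy H and in-weight R —
    the coupling the source-bias shuffle is designed to break."""
    h = receiving_entropy(net, cfg).values
    r = weighted_in_degree(net).values
    res = stats.spearmanr(h, r)
    return float(res.statistic), float(res.pvalue)


def observed_minus_expected(observed: pd.DataFrame,
                            expected: pd.DataFrame) -> pd.DataFrame:
    """Plain observed - expected correction for users who supply expected
    outcome columns (aligned on index and columns)."""
    expected = expected.reindex(index=observed.index, columns=observed.columns)
    return observed - expected
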
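"""Consistency and robustness assessment of causal solution networks.

Two complementary checks:

* **Co-regulation coherence** — nodes sharing a parent in the solution
  network should have correlated per-sample activities.  The true-positive
  rate of predicted co-regulated pairs is swept over absolute-correlation
  thresholds (0..1, step 0.01) and compared with a random-pair baseline.
* **Prior-knowledge robustness** — rerun the optimization on progressively
  shuffled networks and summarise how the pool edge weights move.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .graph import CausalPKN, SignedEdge
from .ilp import SolutionPool

TPR_THRESHOLDS = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


def topology_coregulation_pairs(
    edges: Iterable[SignedEdge],
    measurable: set[str] | None = None,
) -> set[frozenset[str]]:
    """Unordered pairs of nodes sharing at least one parent in the network.

    ``measurable`` optionally restricts the children to nodes for which an
    activity estimate exists (pairs must map into the activity matrix).
    """
    children: dict[str, set[str]] = {}
    for e in edges:
        children.setdefault(e.source, set()).add(e.target)
    pairs: set[frozenset[str]] = set()
    for kids in children.values():
        if measurable is not None:
            kids = kids & measurable
        for a in kids:
            for b in kids:
                if a < b:
                    pairs.add(frozenset((a, b)))
    return pairs


def _pair_correlations(
    pairs: Iterable[frozenset[str]],
    matrix: pd.DataFrame,
    method: str = "pearson",
) -> np.ndarray:
    values = []
    for pair in sorted(pairs, key=sorted):
        a, b = sorted(pair)
        if a not in matrix.index or b not in matrix.index:
            continue
        xa = matrix.loc[a].to_numpy(dtype=float)
        xb = matrix.loc[b].to_numpy(dtype=float)
        if method == "spearman":
            from scipy.stats import spearmanr

            r = spearmanr(xa, xb).statistic
        else:
            r = np.corrcoef(xa, xb)[0, 1]
        if np.isfinite(r):
            values.append(r)
    return np.asarray(values)


def coregulation_tpr(
    pairs: Iterable[frozenset[str]],
    activity_matrix: pd.DataFrame,
    thresholds: np.ndarray = TPR_THRESHOLDS,
    method: str = "pearson",
) -> pd.DataFrame:
    """TPR of predicted co-regulated pairs over correlation thresholds.

    For each threshold ``t`` the TPR is the fraction of evaluable pairs whose
    absolute correlation across samples is at least ``t``.  Pairs with a
    missing activity are dropped and the evaluable count ``n`` is reported.
    """
    if activity_matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate activities")
    r = np.abs(_pair_correlations(pairs, activity_matrix, method=method))
    n = len(r)
    tpr = [float(np.mean(r >= t)) if n else np.nan for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "tpr": tpr, "n": n})


def random_baseline(
    activity_matrix: pd.DataFrame,
    n_pairs: int,
    n_repeats: int = 1000,
    seed: int = 0,
    thresholds: np.ndarray = TPR_THRESHOLDS,
    method: str = "pearson",
) -> pd.DataFrame:
    """Random-pair TPR baseline with a 2.5/97.5 percentile band.

    Each repeat draws ``n_pairs`` distinct uniform random node pairs from the
    activity matrix and computes the same TPR curve as the prediction.
    """
    n_nodes = activity_matrix.shape[0]
    ai, bi = np.triu_indices(n_nodes, k=1)
    if len(ai) < n_pairs:
        raise ValueError("matrix has fewer evaluable pairs than n_pairs")
    rng = np.random.default_rng(seed)
    corr = np.corrcoef(activity_matrix.to_numpy(dtype=float))  # computed once
    thresholds = np.asarray(thresholds)
    curves = np.empty((n_repeats, len(thresholds)))
    for rep in range(n_repeats):
        chosen = rng.choice(len(ai), size=n_pairs, replace=False)
        rs = np.abs(corr[ai[chosen], bi[chosen]])
        rs = rs[np.isfinite(rs)]
        if len(rs) == 0:
            curves[rep] = np.nan
        else:
            curves[rep] = np.mean(rs[:, None] >= thresholds[None, :], axis=0)
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "tpr_mean": np.nanmean(curves, axis=0),
            "tpr_lo": np.nanpercentile(curves, 2.5, axis=0),
            "tpr_hi": np.nanpercentile(curves, 97.5, axis=0),
        }
    )


def shuffle_pkn(
    pkn: CausalPKN,
    fraction: float,
    seed: int = 0,
    full_rewire: bool = False,
) -> tuple[CausalPKN, int]:
    """Randomly shuffle a fraction of the network's interactions.

    ``ceil(fraction * |E|)`` edges are selected uniformly and their target
    endpoints are permuted among themselves (sources and signs stay put), so
    the in-degree multiset of the selected subset is conserved.  With
    ``full_rewire`` the selected edges instead get uniform random new targets.
    Duplicate edges or self-loops created by the permutation are dropped; the
    number lost is returned alongside the network.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    edges = pkn.edges_sorted()
    n_shuffle = math.ceil(fraction * len(edges))
    if n_shuffle == 0:
        return pkn.copy(), 0
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(edges), size=n_shuffle, replace=False))
    chosen_set = set(chosen)
    nodes_sorted = sorted(pkn.nodes)
    if full_rewire:
        new_targets = [nodes_sorted[i] for i in rng.integers(len(nodes_sorted), size=n_shuffle)]
    else:
        targets = [edges[i].target for i in chosen]
        new_targets = [targets[i] for i in rng.permutation(n_shuffle)]
    out = CausalPKN(node_kind=dict(pkn.node_kind), members=dict(pkn.members))
    lost = 0
    replacement = dict(zip(chosen, new_targets))
    for i, e in enumerate(edges):
        if i in chosen_set:
            tgt = replacement[i]
            if tgt == e.source:
                lost += 1
                continue
            new_edge = SignedEdge(e.source, e.sign, tgt, provenance=e.provenance)
        else:
            new_edge = e
        if new_edge in out:
            lost += 1
            continue
        out.add_edge(new_edge)
    return out, lost


def compare_edge_weights(pool_a: SolutionPool, pool_b: SolutionPool) -> dict[str, float]:
    """Distribution summary of per-edge weight differences between two pools.

    Over the union of edges (absent edge = weight 0): median absolute
    difference, fraction of exactly-zero differences, and fraction of flipped
    edges (weight 100 in one pool, 0 in the other).
    """
    keys = sorted(set(pool_a.edge_weight) | set(pool_b.edge_weight))
    if not keys:
        return {"median_abs_diff": 0.0, "frac_zero": 1.0, "frac_flipped": 0.0, "n_edges": 0}
    diffs = np.array(
        [pool_a.edge_weight.get(k, 0.0) - pool_b.edge_weight.get(k, 0.0) for k in keys]
    )
    flips = sum(
        1
        for k in keys
        if {round(pool_a.edge_weight.get(k, 0.0)), round(pool_b.edge_weight.get(k, 0.0))}
        == {0, 100}
    )
    return {
        "median_abs_diff": float(np.median(np.abs(diffs))),
        "frac_zero": float(np.mean(diffs == 0.0)),
        "frac_flipped": flips / len(keys),
        "n_edges": len(keys),
    }
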
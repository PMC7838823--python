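"""Contextualization of the meta PKN for one experiment.

Three steps specialise the generic prior-knowledge network to the measured
system before optimization:

* **Filtering** — drop every interaction that involves a gene not expressed
  in the samples (mean count below a threshold, pooled over all samples).
* **Reduction** — keep only nodes within a bounded number of causal steps
  downstream of the run's input nodes.
* **Correction** — remove transcriptional edges that contradict the observed
  transcript change of the target given the regulator's activity sign; an
  optional pre-run of the optimizer refines the regulator signs used here.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .graph import COMPLEX, ENZYME_INSTANCE, METABOLITE, PROTEIN, CausalPKN, SignedEdge
from .ilp import CausalInstance, SolutionPool, solve

DEFAULT_MIN_MEAN_COUNT = 50.0
DEFAULT_K_FORWARD = 8
DEFAULT_K_BACKWARD = 7
TRANSCRIPTIONAL = "transcriptional"


def filter_expressed(
    pkn: CausalPKN,
    counts: pd.DataFrame,
    min_mean_count: float = DEFAULT_MIN_MEAN_COUNT,
) -> CausalPKN:
    """Keep only interactions whose gene products are expressed.

    A gene passes when its mean count across all provided samples (both
    conditions pooled) is at least ``min_mean_count``; genes absent from the
    count matrix fail.  A catalytic complex fails when any member gene fails.
    Edges between metabolites only are untouched.
    """
    means = counts.mean(axis=1)
    expressed = set(means.index[means >= min_mean_count].astype(str))

    def node_ok(node: str) -> bool:
        kind = pkn.kind_of(node)
        if kind == METABOLITE:
            return True
        genes = pkn.gene_symbols(node)
        return all(g in expressed for g in genes)

    ok_cache = {n: node_ok(n) for n in pkn.nodes}
    drop = [e for e in pkn.edges_sorted() if not (ok_cache[e.source] and ok_cache[e.target])]
    out = pkn.without_edges(drop)
    if len(out) == 0 and len(pkn) > 0:
        warnings.warn("expression filter removed every interaction")
    return out


def reduce_to_reachable(pkn: CausalPKN, sources: Iterable[str], k: int) -> CausalPKN:
    """Vertex-induced subnetwork of nodes within ``k`` directed steps of a source."""
    if k < 0:
        raise ValueError("k must be >= 0")
    sources = sorted(set(sources))
    present = [s for s in sources if pkn.has_node(s)]
    absent = sorted(set(sources) - set(present))
    if absent:
        warnings.warn(f"sources absent from the PKN: {absent}")
    if not present:
        return CausalPKN()
    g = pkn.to_digraph()
    dist = nx.multi_source_dijkstra_path_length(g, present, cutoff=k)
    keep = {n for n, d in dist.items() if d <= k}
    return pkn.subgraph(keep)


def _activity_signs(activities) -> dict[str, int]:
    """Normalize an activity table / node-state map to node -> sign."""
    if isinstance(activities, pd.DataFrame):
        return {
            str(node): int(np.sign(nes))
            for node, nes in activities["nes"].items()
            if np.sign(nes) != 0
        }
    return {str(n): int(s) for n, s in dict(activities).items() if s != 0}


def correct_transcriptional_edges(
    pkn: CausalPKN,
    tf_activities,
    transcript_stats: pd.DataFrame,
    p_cut: float = 0.05,
) -> CausalPKN:
    """Remove transcriptional edges incoherent with the measured transcripts.

    An edge (TF, s, gene) tagged as transcriptional is removed iff the TF has
    a known activity sign ``a``, the gene's transcript is significant
    (``p < p_cut``) and ``sign(log_fc) != a * s``.  Every other edge —
    including all non-transcriptional edges — is retained.
    """
    signs = _activity_signs(tf_activities)
    drop: list[SignedEdge] = []
    for e in pkn.edges_sorted():
        if TRANSCRIPTIONAL not in pkn.edge_provenances(e):
            continue
        a = signs.get(e.source)
        if a is None or e.target not in transcript_stats.index:
            continue
        row = transcript_stats.loc[e.target]
        if float(row["p_value"]) >= p_cut:
            continue
        if int(np.sign(row["log_fc"])) != a * e.sign:
            drop.append(e)
    return pkn.without_edges(drop)


def carnival_prerun_correction(
    pkn: CausalPKN,
    inputs: Mapping[str, int],
    measurements: Mapping[str, tuple[int, float]],
    transcript_stats: pd.DataFrame,
    p_cut: float = 0.05,
    beta: float = 0.2,
    time_limit_s: float = 7200.0,
    pool_cap: int = 100,
    backend: str = "milp",
) -> CausalPKN:
    """Optimizer pre-run: use predicted regulator states to re-correct edges.

    Runs the forward optimization once, takes the consensus node states of
    the solution pool as regulator activity signs, and feeds them to
    :func:`correct_transcriptional_edges`.  If the pre-run is infeasible or
    returns an empty pool the PKN is returned unchanged.
    """
    instance = CausalInstance(
        pkn=pkn,
        inputs=dict(inputs),
        measurements=dict(measurements),
        beta=beta,
        time_limit_s=time_limit_s,
        pool_cap=pool_cap,
    )
    pool: SolutionPool = solve(instance, backend=backend)
    if not pool.solutions:
        warnings.warn("pre-run produced no solution; PKN left unchanged")
        return pkn
    states = pool.consensus_states()
    return correct_transcriptional_edges(pkn, states, transcript_stats, p_cut=p_cut)
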
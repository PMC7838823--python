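"""Orchestration of the full causal-integration protocol.

A study is analysed in two optimization passes over the contextualized meta
PKN: a *forward* run from deregulated signaling regulators (TFs, kinases,
phosphatases) down to deregulated metabolites, and a *backward* run from the
metabolites (acting through allosteric and metabolic edges) back up to the
regulators.  The two solution networks are merged by union, keeping — not
resolving — any node whose predicted sign differs between the runs, and the
merged node set can be tested for pathway over-representation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .footprint import select_inputs
from .graph import METABOLITE, PROTEIN, CausalPKN
from .ilp import CausalInstance, SolutionPool, solve
from .preprocess import (
    DEFAULT_K_BACKWARD,
    DEFAULT_K_FORWARD,
    carnival_prerun_correction,
    correct_transcriptional_edges,
    filter_expressed,
    reduce_to_reachable,
)

logger = logging.getLogger("cosmos")


@dataclass
class RunConfig:
    """Tunable parameters of one contextualization + optimization run."""

    nes_cut: float = 1.7
    p_cut: float = 0.05
    k_forward: int = DEFAULT_K_FORWARD
    k_backward: int = DEFAULT_K_BACKWARD
    beta: float = 0.2
    time_limit_forward_s: float = 7200.0
    time_limit_backward_s: float = 21800.0
    pool_cap: int = 100
    min_mean_count: float = 50.0
    backend: str = "milp"
    prerun_correction: bool = True

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class RunResult:
    """Solution pool plus the contextualized network and role assignments."""

    pool: SolutionPool
    pkn: CausalPKN
    inputs: dict[str, int]
    measurements: dict[str, tuple[int, float]]
    direction: str


def _contextualize_and_solve(
    pkn: CausalPKN,
    inputs: dict[str, int],
    measurements: dict[str, tuple[int, float]],
    k: int,
    time_limit_s: float,
    config: RunConfig,
    counts: pd.DataFrame | None,
    transcript_stats: pd.DataFrame | None,
    tf_signs: dict[str, int],
    direction: str,
) -> RunResult:
    work = pkn
    if counts is not None:
        work = filter_expressed(work, counts, min_mean_count=config.min_mean_count)
        logger.info("%s: expression filter kept %d edges", direction, len(work))
    work = reduce_to_reachable(work, sorted(inputs), k=k)
    logger.info("%s: reduction (k=%d) kept %d edges", direction, k, len(work))
    if transcript_stats is not None:
        work = correct_transcriptional_edges(
            work, tf_signs, transcript_stats, p_cut=config.p_cut
        )
        if config.prerun_correction:
            work = carnival_prerun_correction(
                work,
                inputs,
                measurements,
                transcript_stats,
                p_cut=config.p_cut,
                beta=config.beta,
                time_limit_s=time_limit_s,
                pool_cap=config.pool_cap,
                backend=config.backend,
            )
        logger.info("%s: correction kept %d edges", direction, len(work))
    instance = CausalInstance(
        pkn=work,
        inputs=inputs,
        measurements=measurements,
        beta=config.beta,
        time_limit_s=time_limit_s,
        pool_cap=config.pool_cap,
    )
    pool = solve(instance, backend=config.backend)
    logger.info(
        "%s: status=%s objective=%s pool=%d",
        direction, pool.status, pool.objective, len(pool.solutions),
    )
    return RunResult(
        pool=pool, pkn=work, inputs=inputs, measurements=measurements,
        direction=direction,
    )


def run_forward(
    pkn: CausalPKN,
    activities: pd.DataFrame,
    metabolite_stats: pd.DataFrame,
    config: RunConfig | None = None,
    counts: pd.DataFrame | None = None,
    transcript_stats: pd.DataFrame | None = None,
) -> RunResult:
    """Signaling -> metabolism run.

    Deregulated regulators (``|NES| > nes_cut``) are the fixed inputs;
    deregulated metabolites (``p < p_cut``) are the measurements with unit
    weight.
    """
    config = config or RunConfig()
    regs, metabs = select_inputs(
        activities, metabolite_stats, nes_cut=config.nes_cut, p_cut=config.p_cut
    )
    if not regs:
        raise ValueError(
            "no regulator passes |NES| > "
            f"{config.nes_cut}; lower --nes-cut or check the activity table"
        )
    if not metabs:
        raise ValueError(
            f"no metabolite passes p < {config.p_cut}; "
            "raise --p-cut or check the metabolite statistics"
        )
    inputs = {n: int(np.sign(v)) for n, v in regs.items()}
    measurements = {n: (s, 1.0) for n, s in metabs.items()}
    return _contextualize_and_solve(
        pkn, inputs, measurements, config.k_forward, config.time_limit_forward_s,
        config, counts, transcript_stats, tf_signs=inputs, direction="forward",
    )


def run_backward(
    pkn: CausalPKN,
    activities: pd.DataFrame,
    metabolite_stats: pd.DataFrame,
    config: RunConfig | None = None,
    counts: pd.DataFrame | None = None,
    transcript_stats: pd.DataFrame | None = None,
) -> RunResult:
    """Metabolism -> signaling run (roles of the forward run swapped).

    Metabolites become fixed inputs; regulators become measurements weighted
    by |NES|.
    """
    config = config or RunConfig()
    regs, metabs = select_inputs(
        activities, metabolite_stats, nes_cut=config.nes_cut, p_cut=config.p_cut
    )
    if not metabs:
        raise ValueError(
            f"no deregulated metabolite at p < {config.p_cut} to use as input"
        )
    if not regs:
        raise ValueError(
            f"no regulator passes |NES| > {config.nes_cut} to use as measurement"
        )
    inputs = dict(metabs)
    measurements = {n: (int(np.sign(v)), float(abs(v))) for n, v in regs.items()}
    tf_signs = {n: int(np.sign(v)) for n, v in regs.items()}
    return _contextualize_and_solve(
        pkn, inputs, measurements, config.k_backward, config.time_limit_backward_s,
        config, counts, transcript_stats, tf_signs=tf_signs, direction="backward",
    )


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------


@dataclass
class MergedNetwork:
    """Union of the forward and backward summary networks."""

    edges: pd.DataFrame  # source, sign, target, weight_forward, weight_backward, weight
    nodes: pd.DataFrame  # node, state_forward, state_backward, conflict
    conflicts: list[str] = field(default_factory=list)


def merge_runs(forward: SolutionPool, backward: SolutionPool) -> MergedNetwork:
    """Union of edges (weights carried per run) and node attributes.

    Nodes whose consensus states disagree between the runs are listed in the
    sign-conflict report and keep both attributes; the combined edge weight
    column is ``max`` of the two run weights and is for display only.
    """
    if not forward.solutions or not backward.solutions:
        raise ValueError("both runs must produce at least one solution to merge")
    keys = sorted(set(forward.edge_weight) | set(backward.edge_weight))
    edges = pd.DataFrame(
        {
            "source": [k[0] for k in keys],
            "sign": [k[1] for k in keys],
            "target": [k[2] for k in keys],
            "weight_forward": [forward.edge_weight.get(k, 0.0) for k in keys],
            "weight_backward": [backward.edge_weight.get(k, 0.0) for k in keys],
        }
    )
    edges["weight"] = edges[["weight_forward", "weight_backward"]].max(axis=1)

    fstates = forward.consensus_states()
    bstates = backward.consensus_states()
    nodes_sorted = sorted(set(fstates) | set(bstates))
    conflicts = [
        n for n in nodes_sorted
        if fstates.get(n, 0) * bstates.get(n, 0) == -1
    ]
    nodes = pd.DataFrame(
        {
            "node": nodes_sorted,
            "state_forward": [fstates.get(n, 0) for n in nodes_sorted],
            "state_backward": [bstates.get(n, 0) for n in nodes_sorted],
            "conflict": [n in conflicts for n in nodes_sorted],
        }
    )
    if conflicts:
        logger.info("sign conflicts between runs: %s", conflicts)
    return MergedNetwork(edges=edges, nodes=nodes, conflicts=conflicts)


def merged_gene_nodes(merged: MergedNetwork, pkn: CausalPKN) -> set[str]:
    """Gene symbols of the merged network (catalytic ids mapped back to genes)."""
    genes: set[str] = set()
    for node in merged.nodes["node"]:
        if pkn.has_node(node):
            genes |= pkn.gene_symbols(node)
        elif not node.startswith("metab__"):
            genes |= set(node.split("__", 1)[0].split("_"))
    return genes


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------


def ora(
    nodes: set[str],
    genesets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``nodes`` in each gene set.

    ``p`` is the upper-tail probability of drawing at least the observed
    overlap when ``len(nodes & universe)`` genes are sampled from the
    universe without replacement; Benjamini-Hochberg adjusts across sets.
    """
    if not universe:
        raise ValueError("empty universe")
    selection = set(nodes) & set(universe)
    m_total = len(universe)
    n_sel = len(selection)
    rows = []
    for name in sorted(genesets):
        members = set(genesets[name]) & set(universe)
        overlap = len(selection & members)
        if len(members) == 0:
            p = 1.0
        else:
            p = float(sps.hypergeom.sf(overlap - 1, m_total, len(members), n_sel))
        rows.append((name, len(members), overlap, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["geneset", "set_size", "overlap", "p_value"])
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["p_adjusted"] = []
    return out
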
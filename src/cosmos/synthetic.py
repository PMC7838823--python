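"""Synthetic studies with planted ground truth.

Every input the pipeline consumes — prior-knowledge network, regulons,
differential statistics, count matrix, per-sample activity matrix — can be
generated here with a known causal structure planted inside, so the whole
toolchain is testable end to end.  All generators are pure functions of
their parameters and a mandatory seed.

The planted causal instance is constructed so that its true network is the
*unique* optimum of the optimization: the planted paths form a tree, every
other edge into a planted node is removed from the study PKN, path depth is
bounded so that explaining any measurement is always cheaper than leaving it
unexplained (`beta * depth < weight`), and the size penalty makes any extra
node suboptimal.  The optimal objective therefore equals
``beta * (number of planted nodes)`` exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import (
    ENZYME_INSTANCE,
    METABOLITE,
    METABOLITE_PREFIX,
    PROTEIN,
    CausalPKN,
    SignedEdge,
)
from .ilp import SolutionNetwork

DEFAULT_MAX_DEPTH = 4  # with beta=0.2 and unit weights: 0.2*4 < 1


@dataclass
class PlantedStudy:
    """A complete synthetic experiment with known ground truth."""

    pkn: CausalPKN
    true_network: SolutionNetwork
    inputs: dict[str, int]
    measurements: dict[str, tuple[int, float]]
    regulons: pd.DataFrame
    activities: pd.DataFrame
    metabolite_stats: pd.DataFrame
    transcript_stats: pd.DataFrame | None
    counts: pd.DataFrame
    activity_matrix: pd.DataFrame | None
    seed: int
    beta: float = 0.2

    def check_consistency(self) -> None:
        """Measurements must equal the states the true network propagates."""
        states = self.true_network.node_state
        order = dict(states)
        for node, (sign, _) in self.measurements.items():
            assert order.get(node) == sign, f"measurement {node} inconsistent"
        self.true_network.validate(_InstanceView(self))


class _InstanceView:
    """Just enough of a CausalInstance for SolutionNetwork.validate."""

    def __init__(self, study: PlantedStudy):
        self.pkn = study.pkn
        self.inputs = study.inputs


def generate_random_pkn(
    n_protein: int = 30,
    n_metabolite: int = 10,
    n_edges: int = 60,
    sign_neg_fraction: float = 0.25,
    seed: int = 0,
) -> CausalPKN:
    """Random layered signed network: signaling, allosteric and metabolic edges.

    Edge budget is exact.  Protein->protein (signed, ``ppi``) and
    metabolite->protein (signed, ``allosteric``) interactions take one edge
    each; a metabolic unit takes three (gene -> enzyme instance, reactant ->
    enzyme instance, enzyme instance -> product, all +1, mirroring the
    reaction-network conversion).  ``sign_neg_fraction`` applies to the
    signable (ppi/allosteric) edges.
    """
    capacity = n_protein * (n_protein - 1) + 2 * n_metabolite * n_protein
    if n_edges > capacity:
        raise ValueError(f"n_edges={n_edges} exceeds simple-graph capacity {capacity}")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:03d}" for i in range(n_protein)]
    metabolites = [f"{METABOLITE_PREFIX}m{i:03d}" for i in range(n_metabolite)]
    pkn = CausalPKN()
    for p in proteins:
        pkn.node_kind[p] = PROTEIN
    for m in metabolites:
        pkn.node_kind[m] = METABOLITE
    n_reaction = 0

    def random_sign() -> int:
        return -1 if rng.random() < sign_neg_fraction else 1

    attempts = 0
    while len(pkn) < n_edges and attempts < 50 * n_edges + 100:
        attempts += 1
        remaining = n_edges - len(pkn)
        kinds = ["ppi", "allosteric"] if remaining < 3 or n_metabolite < 2 else [
            "ppi", "ppi", "allosteric", "metabolic"
        ]
        kind = kinds[rng.integers(len(kinds))]
        if kind == "ppi":
            u, v = rng.choice(n_protein, size=2, replace=False)
            pkn.add_edge(
                SignedEdge(proteins[u], random_sign(), proteins[v], provenance="ppi")
            )
        elif kind == "allosteric":
            m = metabolites[rng.integers(n_metabolite)]
            p = proteins[rng.integers(n_protein)]
            pkn.add_edge(SignedEdge(m, random_sign(), p, provenance="allosteric"))
        else:
            gene = proteins[rng.integers(n_protein)]
            m_in, m_out = rng.choice(n_metabolite, size=2, replace=False)
            enzyme = f"{gene}__R{n_reaction:03d}"
            n_reaction += 1
            pkn.set_kind(enzyme, ENZYME_INSTANCE, members=[gene])
            pkn.add_edge(SignedEdge(gene, 1, enzyme, provenance="metabolic"))
            pkn.add_edge(SignedEdge(metabolites[m_in], 1, enzyme, provenance="metabolic"))
            pkn.add_edge(SignedEdge(enzyme, 1, metabolites[m_out], provenance="metabolic"))
    if len(pkn) != n_edges:
        raise ValueError("could not place the requested number of unique edges")
    pkn.validate()
    return pkn


def plant_causal_instance(
    pkn: CausalPKN,
    n_inputs: int = 3,
    n_measurements: int = 3,
    seed: int = 0,
    max_depth: int = DEFAULT_MAX_DEPTH,
    beta: float = 0.2,
    measurement_kind: str | None = None,
    n_decoy_regulators: int = 5,
    n_decoy_metabolites: int = 3,
) -> PlantedStudy:
    """Plant a causal ground truth inside a PKN.

    Selects random protein inputs, grows a random directed tree from them
    (bounded depth), propagates the input signs down the tree, and marks leaf
    nodes as measurements.  Edges of the surrounding PKN that point into a
    planted node are removed, which makes the planted tree the unique optimal
    explanation (see module docstring).  ``measurement_kind`` restricts which
    node kind may serve as a measurement (e.g. ``"metabolite"`` for a forward
    study).
    """
    if n_measurements < 1:
        raise ValueError("n_measurements must be >= 1")
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    rng = np.random.default_rng(seed)
    out_edges: dict[str, list[SignedEdge]] = {}
    for e in pkn.edges_sorted():
        out_edges.setdefault(e.source, []).append(e)

    candidates = sorted(
        n for n in pkn.nodes_of_kind(PROTEIN) if out_edges.get(n)
    )
    if len(candidates) < n_inputs:
        raise ValueError("not enough protein nodes with outgoing edges for inputs")
    inputs_list = [
        candidates[i] for i in rng.choice(len(candidates), size=n_inputs, replace=False)
    ]
    input_signs = {n: int(rng.choice([-1, 1])) for n in sorted(inputs_list)}

    # grow a random tree (unique parent per node) of bounded depth
    depth = {n: 0 for n in inputs_list}
    parent_edge: dict[str, SignedEdge] = {}
    frontier = sorted(inputs_list)
    tree_nodes = set(inputs_list)
    while frontier:
        growable = [
            u for u in frontier
            if depth[u] < max_depth
            and any(e.target not in tree_nodes for e in out_edges.get(u, []))
        ]
        if not growable:
            break
        u = growable[rng.integers(len(growable))]
        options = [e for e in out_edges[u] if e.target not in tree_nodes]
        e = options[rng.integers(len(options))]
        v = e.target
        tree_nodes.add(v)
        parent_edge[v] = e
        depth[v] = depth[u] + 1
        frontier = sorted(tree_nodes)

    tree_parents = {e.source for e in parent_edge.values()}
    candidates = [
        n for n in sorted(tree_nodes - set(inputs_list))
        if measurement_kind is None or pkn.kind_of(n) == measurement_kind
    ]
    # deepest-first so the planted chains exercise multi-step propagation;
    # tree leaves are preferred, interior nodes may also carry a measurement
    candidates.sort(key=lambda n: (n in tree_parents, -depth[n], n))
    if max(depth.values(), default=0) < 2 or not candidates:
        raise ValueError("PKN cannot host a planted path of length >= 2")
    n_meas = min(n_measurements, len(candidates))
    if n_meas < n_measurements:
        warnings.warn(
            f"only {n_meas} measurement nodes available (requested {n_measurements})"
        )
    measured = candidates[:n_meas]

    # keep only the chains from inputs to the chosen measurements
    true_nodes: set[str] = set(inputs_list)
    true_edges: set[SignedEdge] = set()
    for m in measured:
        node = m
        while node not in input_signs:
            e = parent_edge[node]
            true_edges.add(e)
            true_nodes.add(node)
            node = e.source

    states: dict[str, int] = dict(input_signs)
    resolved = dict(input_signs)
    pending = {e.target: e for e in true_edges}
    while pending:
        for node in sorted(pending.keys()):
            e = pending[node]
            if e.source in resolved:
                resolved[node] = e.sign * resolved[e.source]
                del pending[node]
    states = resolved

    # surgery: remove any non-planted edge into a planted node
    drop = [
        e for e in pkn.edges_sorted()
        if e.target in true_nodes and e not in true_edges
    ]
    study_pkn = pkn.without_edges(drop)

    measurements = {m: (states[m], 1.0) for m in sorted(measured)}
    true_network = SolutionNetwork(
        node_state=states,
        active_edges=frozenset(true_edges),
        objective=round(beta * len(true_nodes), 9),
    )

    # pipeline-facing tables ------------------------------------------------
    planted_nes = 3.0
    decoys = [
        n for n in sorted(pkn.nodes_of_kind(PROTEIN) - set(inputs_list))
    ][:n_decoy_regulators]
    activities = pd.DataFrame(
        {
            "nes": [input_signs[n] * planted_nes for n in sorted(input_signs)]
            + [0.5 for _ in decoys],
            "n_targets": 30,
        },
        index=sorted(input_signs) + decoys,
    )
    activities.index.name = "node"

    metab_nodes = sorted(pkn.nodes_of_kind(METABOLITE))
    rows = []
    for m in sorted(measurements):
        rows.append((m, 5.0 * states[m], 0.001, 1.0 * states[m]))
    for m in [n for n in metab_nodes if n not in measurements][:n_decoy_metabolites]:
        rows.append((m, 0.1, 0.9, 0.05))
    metabolite_stats = (
        pd.DataFrame(rows, columns=["feature_id", "statistic", "p_value", "log_fc"])
        .set_index("feature_id")
    )

    genes = sorted(
        {g for n in pkn.nodes for g in pkn.gene_symbols(n)}
    )
    counts = pd.DataFrame(
        rng.poisson(200.0, size=(len(genes), 6)).astype(float),
        index=genes,
        columns=[f"s{i}" for i in range(6)],
    )

    study = PlantedStudy(
        pkn=study_pkn,
        true_network=true_network,
        inputs=dict(input_signs),
        measurements=measurements,
        regulons=pd.DataFrame(columns=["regulator", "target", "mode", "weight"]),
        activities=activities,
        metabolite_stats=metabolite_stats,
        transcript_stats=None,
        counts=counts,
        activity_matrix=None,
        seed=seed,
        beta=beta,
    )
    study.check_consistency()
    return study


def generate_random_instance(
    seed: int,
    n_edges: int = 12,
    pool_cap: int = 10000,
):
    """Small random optimization instance (random inputs, measurements, signs).

    Sized for exhaustive verification: the default 12 edges keeps the full
    2^|E| subset enumeration cheap.
    """
    from .ilp import CausalInstance

    rng = np.random.default_rng(seed)
    pkn = generate_random_pkn(
        n_protein=6, n_metabolite=3, n_edges=n_edges,
        sign_neg_fraction=0.4, seed=seed,
    )
    proteins = sorted(pkn.nodes_of_kind(PROTEIN))
    inputs = {
        str(n): int(rng.choice([-1, 1]))
        for n in rng.choice(proteins, size=2, replace=False)
    }
    others = [n for n in sorted(pkn.nodes) if n not in inputs]
    measurements = {
        str(n): (int(rng.choice([-1, 1])), float(rng.choice([0.5, 1.0, 2.0])))
        for n in rng.choice(others, size=min(3, len(others)), replace=False)
    }
    return CausalInstance(
        pkn, inputs, measurements,
        beta=float(rng.choice([0.1, 0.2, 0.5])), pool_cap=pool_cap,
    )


def generate_regulon_study(
    n_regulators: int = 20,
    targets_per_regulator: int = 10,
    activity_vector: np.ndarray | None = None,
    noise_sd: float = 1.0,
    n_features: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Regulons plus a differential-statistics table with planted activities.

    Each regulator gets a disjoint block of targets with random modes; a
    target's statistic is ``activity * mode + N(0, noise_sd)``, off-target
    features are pure noise.  Returns (regulons, stat table, true activities).
    """
    if n_regulators * targets_per_regulator > n_features:
        raise ValueError("more targets than features")
    rng = np.random.default_rng(seed)
    if activity_vector is None:
        activity_vector = rng.choice([-3.0, -2.0, 2.0, 3.0], size=n_regulators)
    activity_vector = np.asarray(activity_vector, dtype=float)
    if len(activity_vector) != n_regulators:
        raise ValueError("activity_vector length must equal n_regulators")

    features = [f"F{i:04d}" for i in range(n_features)]
    stats = rng.normal(0.0, max(noise_sd, 0.0), size=n_features)
    if noise_sd == 0:
        stats = np.zeros(n_features)
    reg_rows = []
    for r in range(n_regulators):
        regulator = f"R{r:03d}"
        block = features[r * targets_per_regulator : (r + 1) * targets_per_regulator]
        modes = rng.choice([-1, 1], size=len(block))
        for t, mode in zip(block, modes):
            reg_rows.append((regulator, t, int(mode), 1.0))
            idx = features.index(t)
            stats[idx] = activity_vector[r] * mode + (
                rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            )
    regulons = pd.DataFrame(reg_rows, columns=["regulator", "target", "mode", "weight"])
    from scipy import stats as sps

    table = pd.DataFrame(
        {
            "statistic": stats,
            "p_value": 2.0 * sps.norm.sf(np.abs(stats)),
            "log_fc": stats,
        },
        index=pd.Index(features, name="feature_id"),
    )
    truth = pd.Series(
        activity_vector, index=[f"R{r:03d}" for r in range(n_regulators)]
    )
    return regulons, table, truth


def generate_coregulation_study(
    n_parents: int = 10,
    n_other: int = 20,
    n_samples: int = 20,
    rho: float = 0.8,
    seed: int = 0,
) -> tuple[list[SignedEdge], pd.DataFrame]:
    """Planted co-regulation design for the TPR evaluation.

    Each parent regulates two children whose per-sample activities share a
    latent factor with correlation ``rho``; the remaining regulators are
    independent noise.  Returns the (star-shaped) network edges and the
    regulator x sample activity matrix.
    """
    rng = np.random.default_rng(seed)
    edges: list[SignedEdge] = []
    rows: dict[str, np.ndarray] = {}
    a = np.sqrt(rho)
    b = np.sqrt(1.0 - rho)
    for p in range(n_parents):
        parent = f"PARENT{p:02d}"
        factor = rng.normal(size=n_samples)
        for c in range(2):
            child = f"CHILD{p:02d}_{c}"
            edges.append(SignedEdge(parent, 1, child, provenance="ppi"))
            rows[child] = a * factor + b * rng.normal(size=n_samples)
    for i in range(n_other):
        rows[f"OTHER{i:02d}"] = rng.normal(size=n_samples)
    matrix = pd.DataFrame(
        rows, index=[f"t{i}" for i in range(n_samples)]
    ).T.sort_index()
    matrix.columns.name = "sample"
    return edges, matrix


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

PRESETS = {
    "tiny": dict(n_protein=8, n_metabolite=4, n_edges=18, n_inputs=2, n_measurements=2),
    "small": dict(n_protein=30, n_metabolite=10, n_edges=70, n_inputs=3, n_measurements=3),
    "medium": dict(n_protein=80, n_metabolite=25, n_edges=220, n_inputs=5, n_measurements=6),
}


def generate_preset_study(preset: str, seed: int = 0) -> PlantedStudy:
    """A full planted study at one of the named sizes."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    last_error: Exception | None = None
    for attempt in range(20):  # some random PKNs cannot host a planted path
        pkn = generate_random_pkn(
            n_protein=p["n_protein"],
            n_metabolite=p["n_metabolite"],
            n_edges=p["n_edges"],
            seed=seed + 1000 * attempt,
        )
        try:
            return plant_causal_instance(
                pkn,
                n_inputs=p["n_inputs"],
                n_measurements=p["n_measurements"],
                seed=seed + 1000 * attempt,
                measurement_kind=METABOLITE,
            )
        except ValueError as exc:
            last_error = exc
    raise RuntimeError(f"preset generation failed: {last_error}")
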
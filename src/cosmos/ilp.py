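"""Sign-consistent, loop-free subnetwork optimization.

Given a signed directed prior-knowledge network, a set of *inputs* with fixed
up/down states and a set of weighted *measurements* with target signs, find
the smallest subnetworks that propagate the input states to the measurements
with coherent signs.  The objective trades the weighted mismatch at the
measurements against the number of nodes given a state:

    minimize  sum_m w_m * |t_m - x_m|  +  beta * #{stated nodes}

where ``x_m`` in {-1, 0, +1} is the simulated state of measurement ``m`` and
``t_m`` its measured sign.  Input states are hard constraints, so inputs
always count toward the size term.

Solution convention
-------------------
A solution is a pair (node states, active edges) in which every stated
non-input node has exactly one incoming supporting edge, the active-edge
subgraph is acyclic, no active edge points into an input, and every active
edge is sign-consistent (``state[v] == sign(e) * state[u]``).  This "minimal
support" convention makes the solution pool well defined: because edges do
not enter the objective, arbitrary redundant edges would otherwise tie.

Two solvers implement the same convention: a MILP formulation solved with
HiGHS (through :func:`scipy.optimize.milp`), which enumerates optimal state
assignments via no-good cuts and reconstructs the minimal supports, and an
exhaustive solver that enumerates edge subsets directly and serves as the
ground-truth oracle on small instances.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .graph import CausalPKN, SignedEdge

OBJECTIVE_TOL = 1e-6
BRUTE_FORCE_MAX_EDGES = 20

STATUS_OPTIMAL = "optimal"
STATUS_TIME_LIMIT = "time_limit"
STATUS_INFEASIBLE = "infeasible"


class SolverConfigurationError(RuntimeError):
    """Raised when no usable solver backend is available/selected."""


@dataclass
class CausalInstance:
    """One optimization problem: PKN + fixed inputs + weighted measurements."""

    pkn: CausalPKN
    inputs: dict[str, int]
    measurements: dict[str, tuple[int, float]]
    beta: float = 0.2
    time_limit_s: float = 7200.0
    pool_cap: int = 100

    missing_inputs: list[str] = field(default_factory=list, init=False)
    missing_measurements: list[str] = field(default_factory=list, init=False)

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.time_limit_s <= 0:
            raise ValueError("time_limit_s must be positive")
        if self.pool_cap < 1:
            raise ValueError("pool_cap must be >= 1")
        for node, sign in self.inputs.items():
            if sign not in (-1, 1):
                raise ValueError(f"input sign for {node!r} must be -1 or +1")
        for node, (sign, weight) in self.measurements.items():
            if sign not in (-1, 1):
                raise ValueError(f"measurement sign for {node!r} must be -1 or +1")
            if weight < 0:
                raise ValueError(f"measurement weight for {node!r} must be >= 0")
        nodes = self.pkn.nodes
        self.missing_inputs = sorted(set(self.inputs) - nodes)
        self.missing_measurements = sorted(set(self.measurements) - nodes)
        if self.missing_inputs or self.missing_measurements:
            warnings.warn(
                "nodes absent from the PKN: "
                f"inputs {self.missing_inputs}, measurements {self.missing_measurements}"
            )
        self.inputs = {n: s for n, s in self.inputs.items() if n in nodes}

    @property
    def constant_mismatch(self) -> float:
        """Mismatch contributed by measurements that are not in the PKN."""
        return sum(self.measurements[n][1] for n in self.missing_measurements)

    def mismatch(self, states: dict[str, int]) -> float:
        total = self.constant_mismatch
        for node, (target, weight) in self.measurements.items():
            if node in self.missing_measurements:
                continue
            total += weight * abs(target - states.get(node, 0))
        return total

    def objective(self, states: dict[str, int]) -> float:
        return self.mismatch(states) + self.beta * len(states)


@dataclass(frozen=True)
class SolutionNetwork:
    """One optimal subnetwork: node states plus their minimal edge support."""

    node_state: dict[str, int]
    active_edges: frozenset[SignedEdge]
    objective: float

    def sort_key(self):
        return (
            tuple(sorted(self.node_state.items())),
            tuple(sorted(e.key for e in self.active_edges)),
        )

    def validate(self, instance: CausalInstance) -> None:
        """Assert the structural invariants of a valid solution."""
        import networkx as nx

        states = self.node_state
        for node, sign in instance.inputs.items():
            assert states.get(node) == sign, f"input {node} state not fixed"
        g = nx.DiGraph()
        g.add_nodes_from(states)
        for e in self.active_edges:
            assert e in instance.pkn, f"active edge {e} not in PKN"
            assert e.source in states and e.target in states
            assert states[e.target] == e.sign * states[e.source], (
                f"active edge {e} is sign-inconsistent"
            )
            g.add_edge(e.source, e.target)
        assert nx.is_directed_acyclic_graph(g), "active subgraph has a cycle"
        incoming = {n: 0 for n in states}
        for e in self.active_edges:
            incoming[e.target] += 1
        for node in states:
            if node in instance.inputs:
                assert incoming[node] == 0, f"active edge points into input {node}"
            else:
                assert incoming[node] == 1, (
                    f"stated node {node} has {incoming[node]} supporting edges"
                )
        roots = set(instance.inputs)
        reachable = set(roots)
        frontier = list(roots)
        while frontier:
            u = frontier.pop()
            for v in g.successors(u):
                if v not in reachable:
                    reachable.add(v)
                    frontier.append(v)
        assert set(states) <= reachable, "stated node unreachable from inputs"


@dataclass
class SolutionPool:
    """All equally optimal solutions found, with pool-frequency edge weights."""

    solutions: list[SolutionNetwork]
    status: str
    edge_weight: dict[tuple[str, int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.solutions = sorted(self.solutions, key=SolutionNetwork.sort_key)
        counts: dict[tuple[str, int, str], int] = {}
        for sol in self.solutions:
            for e in sol.active_edges:
                counts[e.key] = counts.get(e.key, 0) + 1
        n = len(self.solutions)
        self.edge_weight = {
            k: 100.0 * c / n for k, c in sorted(counts.items())
        } if n else {}

    @property
    def objective(self) -> float | None:
        return self.solutions[0].objective if self.solutions else None

    def node_summary(self) -> dict[str, tuple[float, int]]:
        """Per node: (% of solutions where stated, consensus state sign)."""
        if not self.solutions:
            return {}
        tally: dict[str, list[int]] = {}
        for sol in self.solutions:
            for node, s in sol.node_state.items():
                tally.setdefault(node, []).append(s)
        out = {}
        for node, states in sorted(tally.items()):
            freq = 100.0 * len(states) / len(self.solutions)
            out[node] = (freq, int(np.sign(sum(states))))
        return out

    def consensus_states(self) -> dict[str, int]:
        """Nodes with a nonzero consensus sign across the pool."""
        return {n: s for n, (_, s) in self.node_summary().items() if s != 0}


# ---------------------------------------------------------------------------
# MILP formulation
# ---------------------------------------------------------------------------


@dataclass
class IlpModel:
    """Matrix form of the formulation, plus the variable layout.

    Variables (in order): per node u+ and u- binaries, per edge e+ (activation
    carrier) and e- (inhibition carrier) binaries, per node a continuous
    topological-order variable d in [0, N].
    """

    nodes: list[str]
    edges: list[SignedEdge]
    c: np.ndarray
    constant: float
    A: sparse.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    integrality: np.ndarray
    var_lb: np.ndarray
    var_ub: np.ndarray

    def up(self, i: int) -> int:
        return 2 * i

    def un(self, i: int) -> int:
        return 2 * i + 1

    def ep(self, j: int) -> int:
        return 2 * len(self.nodes) + 2 * j

    def en(self, j: int) -> int:
        return 2 * len(self.nodes) + 2 * j + 1

    def d(self, i: int) -> int:
        return 2 * len(self.nodes) + 2 * len(self.edges) + i

    @property
    def n_vars(self) -> int:
        return 2 * len(self.nodes) + 2 * len(self.edges) + len(self.nodes)


def build_ilp(instance: CausalInstance) -> IlpModel:
    """Assemble the MILP for one instance.

    Constraints:

    * ``u+ + u- <= 1`` per node; inputs fixed through variable bounds.
    * carrier gating: ``e+ <= u+`` (or ``u-`` for a -1 edge) and ``e- <= u-``
      (or ``u+``) for the edge's source node.
    * support: for every non-input node, ``v+ <= sum incoming e+`` and
      ``v- <= sum incoming e-`` (a stated node needs an active edge).
    * loop prevention: ``d_u - d_v + M (e+ + e-) <= M - 1`` with
      ``M = N + 1``, so active edges strictly increase the order variable.

    Objective: ``sum_m w_m (1 - t_m (v+ - v-)) + beta * sum_u (u+ + u-)``;
    the exact linearization of ``w |t - x|`` for ``t`` in {-1,+1}.
    """
    nodes = sorted(instance.pkn.nodes)
    edges = instance.pkn.edges_sorted()
    node_idx = {n: i for i, n in enumerate(nodes)}
    n, m = len(nodes), len(edges)
    n_vars = 2 * n + 2 * m + n
    up = lambda i: 2 * i
    un = lambda i: 2 * i + 1
    ep = lambda j: 2 * n + 2 * j
    en = lambda j: 2 * n + 2 * j + 1
    dv = lambda i: 2 * n + 2 * m + i

    var_lb = np.zeros(n_vars)
    var_ub = np.ones(n_vars)
    integrality = np.ones(n_vars)
    for i in range(n):
        var_ub[dv(i)] = float(n)
        integrality[dv(i)] = 0.0
    for node, sign in instance.inputs.items():
        i = node_idx[node]
        if sign > 0:
            var_lb[up(i)] = 1.0
            var_ub[un(i)] = 0.0
        else:
            var_lb[un(i)] = 1.0
            var_ub[up(i)] = 0.0

    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    ub_rows: list[float] = []

    def add_row(coefs: dict[int, float], upper: float) -> None:
        r = len(ub_rows)
        for c_idx, v in coefs.items():
            rows.append(r)
            cols.append(c_idx)
            data.append(v)
        ub_rows.append(upper)

    input_set = set(instance.inputs)
    for i, node in enumerate(nodes):
        if node not in input_set:
            add_row({up(i): 1.0, un(i): 1.0}, 1.0)

    incoming_ep: dict[int, list[int]] = {i: [] for i in range(n)}
    incoming_en: dict[int, list[int]] = {i: [] for i in range(n)}
    big_m = float(n + 1)
    for j, e in enumerate(edges):
        iu, iv = node_idx[e.source], node_idx[e.target]
        act_src = up(iu) if e.sign > 0 else un(iu)
        inh_src = un(iu) if e.sign > 0 else up(iu)
        add_row({ep(j): 1.0, act_src: -1.0}, 0.0)
        add_row({en(j): 1.0, inh_src: -1.0}, 0.0)
        incoming_ep[iv].append(ep(j))
        incoming_en[iv].append(en(j))
        add_row({dv(iu): 1.0, dv(iv): -1.0, ep(j): big_m, en(j): big_m}, big_m - 1.0)

    for i, node in enumerate(nodes):
        if node in input_set:
            continue
        coefs = {up(i): 1.0}
        for v in incoming_ep[i]:
            coefs[v] = -1.0
        add_row(coefs, 0.0)
        coefs = {un(i): 1.0}
        for v in incoming_en[i]:
            coefs[v] = -1.0
        add_row(coefs, 0.0)

    c = np.zeros(n_vars)
    constant = 0.0
    for i in range(n):
        c[up(i)] += instance.beta
        c[un(i)] += instance.beta
    for node, (target, weight) in instance.measurements.items():
        if node not in node_idx:
            constant += weight  # |t - 0| = 1 for measurements outside the PKN
            continue
        i = node_idx[node]
        constant += weight
        c[up(i)] += -weight * target
        c[un(i)] += weight * target

    A = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(ub_rows), n_vars)
    )
    return IlpModel(
        nodes=nodes,
        edges=edges,
        c=c,
        constant=constant,
        A=A,
        lb=np.full(len(ub_rows), -np.inf),
        ub=np.asarray(ub_rows),
        integrality=integrality,
        var_lb=var_lb,
        var_ub=var_ub,
    )


def _states_from_x(model: IlpModel, x: np.ndarray) -> dict[str, int]:
    states = {}
    for i, node in enumerate(model.nodes):
        if x[model.up(i)] > 0.5:
            states[node] = 1
        elif x[model.un(i)] > 0.5:
            states[node] = -1
    return states


def _enumerate_supports(
    states: dict[str, int],
    instance: CausalInstance,
    cap: int,
) -> list[frozenset[SignedEdge]]:
    """All minimal acyclic supports of a state assignment (one parent each)."""
    import networkx as nx

    inputs = set(instance.inputs)
    choices: list[list[SignedEdge]] = []
    targets: list[str] = []
    for node in sorted(states):
        if node in inputs:
            continue
        parents = [
            e
            for e in instance.pkn.edges_sorted()
            if e.target == node
            and e.source in states
            and states[node] == e.sign * states[e.source]
        ]
        if not parents:
            return []
        choices.append(parents)
        targets.append(node)
    supports: list[frozenset[SignedEdge]] = []
    for combo in itertools.product(*choices):
        g = nx.DiGraph()
        g.add_edges_from((e.source, e.target) for e in combo)
        if nx.is_directed_acyclic_graph(g):
            supports.append(frozenset(combo))
            if len(supports) >= cap:
                break
    return supports


def solve(instance: CausalInstance, backend: str = "milp") -> SolutionPool:
    """Find the pool of optimal solutions.

    ``backend='milp'`` uses the HiGHS mixed-integer solver via scipy and
    enumerates all optimal state assignments with no-good cuts (then
    reconstructs each assignment's minimal supports); ``backend='exhaustive'``
    delegates to :func:`brute_force_solve`.  Results are deterministic on
    instances solved to optimality.
    """
    if backend == "exhaustive":
        return brute_force_solve(instance)
    if backend != "milp":
        raise SolverConfigurationError(f"unknown solver backend {backend!r}")

    model = build_ilp(instance)
    options = {"time_limit": instance.time_limit_s, "presolve": True}
    constraints = [LinearConstraint(model.A, model.lb, model.ub)]
    bounds = Bounds(model.var_lb.copy(), model.var_ub.copy())
    timed_out = False

    res = milp(
        model.c,
        constraints=constraints,
        integrality=model.integrality,
        bounds=bounds,
        options=options,
    )
    if res.status == 2:
        return SolutionPool(solutions=[], status=STATUS_INFEASIBLE)
    if res.status == 1:
        timed_out = True
    if res.x is None:
        return SolutionPool(solutions=[], status=STATUS_TIME_LIMIT)

    best = res.fun + model.constant
    state_vars = [
        v
        for i, node in enumerate(model.nodes)
        if node not in instance.inputs
        for v in (model.up(i), model.un(i))
    ]
    solutions: list[SolutionNetwork] = []
    seen_states: list[dict[str, int]] = []
    cut_rows: list[np.ndarray] = []
    cut_lbs: list[float] = []
    x = res.x
    while True:
        states = _states_from_x(model, x)
        seen_states.append(states)
        remaining = instance.pool_cap - len(solutions)
        for support in _enumerate_supports(states, instance, cap=remaining):
            solutions.append(
                SolutionNetwork(
                    node_state=dict(states),
                    active_edges=support,
                    objective=round(best, 9),
                )
            )
        if len(solutions) >= instance.pool_cap:
            break
        # no-good cut: exclude this assignment of the state binaries
        row = np.zeros(model.n_vars)
        ones = 0
        for v in state_vars:
            if x[v] > 0.5:
                row[v] = -1.0
                ones += 1
            else:
                row[v] = 1.0
        cut_rows.append(row)
        cut_lbs.append(1.0 - ones)
        cuts = LinearConstraint(
            np.vstack(cut_rows), np.asarray(cut_lbs), np.full(len(cut_rows), np.inf)
        )
        res = milp(
            model.c,
            constraints=[constraints[0], cuts],
            integrality=model.integrality,
            bounds=bounds,
            options=options,
        )
        if res.status == 1:
            timed_out = True
        if res.x is None or res.fun + model.constant > best + OBJECTIVE_TOL:
            break
        x = res.x

    status = STATUS_TIME_LIMIT if timed_out else STATUS_OPTIMAL
    if not solutions:
        status = STATUS_INFEASIBLE
    return SolutionPool(solutions=solutions, status=status)


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------


def brute_force_solve(instance: CausalInstance) -> SolutionPool:
    """Enumerate every candidate solution on a small instance.

    Iterates over all edge subsets, keeps those forming a valid minimal
    support (one incoming edge per stated non-input node, no edges into
    inputs, acyclic, sign-consistent under propagation from the inputs) and
    returns all subsets attaining the global optimum.  Independent of the
    MILP path; intended as ground truth for instances with at most
    20 edges.
    """
    edges = instance.pkn.edges_sorted()
    if len(edges) > BRUTE_FORCE_MAX_EDGES:
        raise ValueError(
            f"brute force limited to {BRUTE_FORCE_MAX_EDGES} edges, got {len(edges)}"
        )
    inputs = dict(instance.inputs)
    best = np.inf
    optima: list[SolutionNetwork] = []
    n_edges = len(edges)
    for mask in range(1 << n_edges):
        subset = [edges[j] for j in range(n_edges) if mask >> j & 1]
        heads: dict[str, SignedEdge] = {}
        valid = True
        for e in subset:
            if e.target in inputs or e.target in heads:
                valid = False  # edge into an input, or two parents
                break
            heads[e.target] = e
        if not valid:
            continue
        # every tail must be an input or itself supported
        if any(e.source not in inputs and e.source not in heads for e in subset):
            continue
        # propagate states; failure to resolve every head means a cycle
        states = dict(inputs)
        pending = dict(heads)
        while pending:
            progressed = False
            for node in sorted(pending.keys()):
                e = pending[node]
                if e.source in states:
                    states[node] = e.sign * states[e.source]
                    del pending[node]
                    progressed = True
            if not progressed:
                break
        if pending:
            continue
        objective = instance.objective(states)
        if objective < best - OBJECTIVE_TOL:
            best = objective
            optima = []
        if objective <= best + OBJECTIVE_TOL:
            optima.append(
                SolutionNetwork(
                    node_state=states,
                    active_edges=frozenset(subset),
                    objective=round(objective, 9),
                )
            )
    optima = [replace(s, objective=round(best, 9)) for s in optima]
    return SolutionPool(solutions=optima, status=STATUS_OPTIMAL)
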
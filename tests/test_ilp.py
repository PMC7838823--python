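"""Sign-consistent subnetwork optimization: MILP solver vs exhaustive oracle."""

import numpy as np
import pytest

from cosmos.graph import CausalPKN, SignedEdge
from cosmos.ilp import (
    CausalInstance,
    brute_force_solve,
    build_ilp,
    solve,
)
from conftest import random_instance


def solution_set(pool):
    return {
        (tuple(sorted(s.node_state.items())), tuple(sorted(e.key for e in s.active_edges)))
        for s in pool.solutions
    }


@pytest.fixture(params=["milp", "exhaustive"])
def backend(request):
    return request.param


class TestObjective:
    def test_single_edge_instance_uses_the_edge(self, backend):
        """Explaining the measurement (0.4 = two stated nodes at beta 0.2)
        beats leaving it mismatched (1.0)."""
        pkn = CausalPKN([SignedEdge("A", 1, "B")])
        inst = CausalInstance(pkn, {"A": 1}, {"B": (1, 1.0)}, beta=0.2)
        pool = solve(inst, backend=backend)
        assert pool.objective == pytest.approx(0.4)
        (sol,) = pool.solutions
        assert sol.node_state == {"A": 1, "B": 1}
        assert {e.key for e in sol.active_edges} == {("A", 1, "B")}

    def test_no_measurements_states_only_the_inputs(self, backend):
        pkn = CausalPKN([SignedEdge("A", 1, "B"), SignedEdge("B", 1, "C")])
        inst = CausalInstance(pkn, {"A": 1}, {}, beta=0.2)
        pool = solve(inst, backend=backend)
        assert pool.objective == pytest.approx(0.2)  # the fixed input only
        (sol,) = pool.solutions
        assert sol.node_state == {"A": 1} and not sol.active_edges

    def test_two_cycle_is_broken(self, backend):
        pkn = CausalPKN([SignedEdge("A", 1, "B"), SignedEdge("B", 1, "A")])
        inst = CausalInstance(pkn, {"A": 1}, {"B": (1, 1.0)}, beta=0.2)
        pool = solve(inst, backend=backend)
        for sol in pool.solutions:
            assert {e.key for e in sol.active_edges} == {("A", 1, "B")}

    def test_unreachable_measurement_pays_its_weight(self, backend):
        pkn = CausalPKN([SignedEdge("X", 1, "Y")])
        with pytest.warns(UserWarning, match="Z"):
            inst = CausalInstance(pkn, {"X": 1}, {"Z": (1, 2.0)}, beta=0.2)
        pool = solve(inst, backend=backend)
        assert pool.objective == pytest.approx(2.0 + 0.2)

    def test_sign_propagation_through_inhibition(self, backend):
        pkn = CausalPKN([SignedEdge("A", -1, "B"), SignedEdge("B", -1, "C")])
        inst = CausalInstance(pkn, {"A": 1}, {"C": (1, 1.0)}, beta=0.1)
        pool = solve(inst, backend=backend)
        (sol,) = pool.solutions
        assert sol.node_state == {"A": 1, "B": -1, "C": 1}


class TestSolutionPool:
    def test_two_symmetric_paths_weight_fifty_each(self, backend):
        pkn = CausalPKN([SignedEdge("A", 1, "M"), SignedEdge("B", 1, "M")])
        inst = CausalInstance(pkn, {"A": 1, "B": 1}, {"M": (1, 1.0)}, beta=0.2)
        pool = solve(inst, backend=backend)
        assert len(pool.solutions) == 2
        assert pool.edge_weight == {("A", 1, "M"): 50.0, ("B", 1, "M"): 50.0}

    def test_unique_optimum_weights_hundred(self, backend):
        pkn = CausalPKN([SignedEdge("A", 1, "B"), SignedEdge("B", 1, "C")])
        inst = CausalInstance(pkn, {"A": 1}, {"C": (1, 1.0)}, beta=0.1)
        pool = solve(inst, backend=backend)
        assert set(pool.edge_weight.values()) == {100.0}

    def test_pool_cap_truncates(self):
        # four parallel explanations, cap at 2
        edges = [SignedEdge(f"I{k}", 1, "M") for k in range(4)]
        pkn = CausalPKN(edges)
        inst = CausalInstance(
            pkn, {f"I{k}": 1 for k in range(4)}, {"M": (1, 1.0)},
            beta=0.2, pool_cap=2,
        )
        pool = solve(inst, backend="milp")
        assert len(pool.solutions) == 2


class TestBruteForce:
    def test_size_guard(self):
        edges = [SignedEdge(f"a{i}", 1, f"b{i}") for i in range(21)]
        inst = CausalInstance(CausalPKN(edges), {"a0": 1}, {}, beta=0.1)
        with pytest.raises(ValueError, match="20 edges"):
            brute_force_solve(inst)

    def test_empty_pkn(self):
        inst = CausalInstance(CausalPKN(), {}, {}, beta=0.2)
        pool = brute_force_solve(inst)
        assert pool.objective == pytest.approx(0.0)
        (sol,) = pool.solutions
        assert sol.node_state == {} and not sol.active_edges

    def test_planted_path_objective_is_beta_times_nodes(self):
        pkn = CausalPKN(
            [SignedEdge("I", 1, "X"), SignedEdge("X", -1, "Y"),
             SignedEdge("I", 1, "Z")]  # Z is a decoy branch
        )
        inst = CausalInstance(pkn, {"I": 1}, {"Y": (-1, 1.0)}, beta=0.2)
        pool = brute_force_solve(inst)
        assert pool.objective == pytest.approx(0.2 * 3)
        (sol,) = pool.solutions
        assert set(sol.node_state) == {"I", "X", "Y"}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(1, 16))
    def test_milp_matches_exhaustive_enumeration(self, seed):
        inst = random_instance(seed)
        a = solve(inst, backend="milp")
        b = brute_force_solve(inst)
        assert a.objective == pytest.approx(b.objective, abs=1e-9)
        assert solution_set(a) == solution_set(b)

    def test_flipping_a_planted_measurement_sign_raises_the_optimum(self, tiny_study):
        """On a noise-free planted instance the optimum is zero-mismatch, so
        contradicting one measurement must cost at least min(weight, beta)."""
        inst = CausalInstance(
            tiny_study.pkn, tiny_study.inputs, tiny_study.measurements,
            beta=tiny_study.beta, pool_cap=10000,
        )
        base = brute_force_solve(inst).objective
        assert base == pytest.approx(tiny_study.true_network.objective)
        node, (sign, weight) = sorted(inst.measurements.items())[0]
        flipped = CausalInstance(
            inst.pkn, inst.inputs,
            {**inst.measurements, node: (-sign, weight)},
            beta=inst.beta, pool_cap=inst.pool_cap,
        )
        increase = brute_force_solve(flipped).objective - base
        assert increase >= min(weight, inst.beta) - 1e-9


class TestInvariants:
    @pytest.mark.parametrize("seed", range(30, 50))
    def test_every_solution_is_valid(self, seed):
        inst = random_instance(seed, n_edges=14)
        pool = solve(inst, backend="milp")
        assert pool.solutions
        for sol in pool.solutions:
            sol.validate(inst)

    def test_increasing_beta_never_grows_the_network(self):
        for seed in range(1, 11):
            sizes = []
            inst = random_instance(seed)
            for beta in (0.05, 0.2, 0.5, 1.0):
                cfg = CausalInstance(
                    inst.pkn, inst.inputs, inst.measurements,
                    beta=beta, pool_cap=10000,
                )
                pool = solve(cfg, backend="milp")
                sizes.append(max(len(s.node_state) for s in pool.solutions))
            assert sizes == sorted(sizes, reverse=True)

    def test_edge_weights_match_pool_membership(self):
        inst = random_instance(4)
        pool = solve(inst, backend="milp")
        n = len(pool.solutions)
        for key, weight in pool.edge_weight.items():
            count = sum(
                1 for s in pool.solutions if key in {e.key for e in s.active_edges}
            )
            assert weight == pytest.approx(100.0 * count / n)
            assert 0.0 <= weight <= 100.0


class TestValidation:
    def test_bad_signs_rejected(self):
        pkn = CausalPKN([SignedEdge("A", 1, "B")])
        with pytest.raises(ValueError):
            CausalInstance(pkn, {"A": 2}, {})
        with pytest.raises(ValueError):
            CausalInstance(pkn, {"A": 1}, {"B": (0, 1.0)})
        with pytest.raises(ValueError):
            CausalInstance(pkn, {"A": 1}, {"B": (1, -0.5)})

    def test_unknown_backend_rejected(self):
        pkn = CausalPKN([SignedEdge("A", 1, "B")])
        inst = CausalInstance(pkn, {"A": 1}, {})
        with pytest.raises(Exception, match="backend"):
            solve(inst, backend="cplex")
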
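"""Meta PKN assembly: source parsing, reaction conversion, merging."""

import networkx as nx
import pandas as pd
import pytest

from cosmos.graph import (
    COMPLEX,
    ENZYME_INSTANCE,
    METABOLITE,
    CausalPKN,
    NamespaceError,
    PKNFormatError,
    SignedEdge,
)
from cosmos.pkn import (
    MetabolitePolicy,
    Reaction,
    convert_reaction_network,
    filter_promiscuous_metabolites,
    merge_sources,
    parse_allosteric_table,
    parse_ppi_table,
    regulon_edges,
)


def ppi_row(src, tgt, stim, inh):
    return {"source": src, "target": tgt, "is_stimulation": stim, "is_inhibition": inh}


class TestPpiParsing:
    @pytest.mark.parametrize(
        "stim,inh,expected_signs",
        [(1, 0, {1}), (0, 1, {-1}), (1, 1, {1, -1}), (0, 0, set())],
    )
    def test_flag_combinations(self, stim, inh, expected_signs):
        edges = parse_ppi_table([ppi_row("A", "B", stim, inh)])
        assert {e.sign for e in edges} == expected_signs
        assert all((e.source, e.target) == ("A", "B") for e in edges)

    def test_missing_column_names_the_column(self):
        with pytest.raises(PKNFormatError, match="is_inhibition"):
            parse_ppi_table(pd.DataFrame({"source": ["A"], "target": ["B"],
                                          "is_stimulation": [1]}))


class TestAllostericParsing:
    def test_score_threshold_is_inclusive_at_min(self):
        rows = [
            {"metabolite": "metab__m1", "protein": "P1", "action": "activation",
             "combined_score": 900},
            {"metabolite": "metab__m2", "protein": "P1", "action": "activation",
             "combined_score": 899},
        ]
        edges = parse_allosteric_table(rows, min_score=900)
        assert edges == {SignedEdge("metab__m1", 1, "P1")}

    def test_inhibition_maps_to_negative_sign(self):
        rows = [{"metabolite": "metab__m1", "protein": "P1",
                 "action": "inhibition", "combined_score": 950}]
        (edge,) = parse_allosteric_table(rows)
        assert edge.sign == -1 and edge.provenance == "allosteric"

    def test_unknown_action_label_raises(self):
        rows = [{"metabolite": "metab__m1", "protein": "P1",
                 "action": "binds", "combined_score": 950}]
        with pytest.raises(PKNFormatError, match="binds"):
            parse_allosteric_table(rows)


def rxn(rid, reactants, products, gpr, **kw):
    return Reaction(rid, tuple(reactants), tuple(products), gpr, **kw)


class TestReactionConversion:
    def test_single_enzyme(self):
        pkn = convert_reaction_network([rxn("R1", ["metab__A"], ["metab__C"], "E")])
        assert {e.key for e in pkn.edges} == {
            ("metab__A", 1, "E__R1"),
            ("E__R1", 1, "metab__C"),
        }
        assert pkn.kind_of("E__R1") == ENZYME_INSTANCE
        assert pkn.gene_symbols("E__R1") == {"E"}

    def test_and_rule_builds_one_complex(self):
        pkn = convert_reaction_network(
            [rxn("R1", ["metab__A"], ["metab__C"], "E1 AND E2")]
        )
        assert len(pkn) == 2
        assert pkn.kind_of("E1_E2__R1") == COMPLEX
        assert pkn.gene_symbols("E1_E2__R1") == {"E1", "E2"}

    def test_or_rule_builds_two_catalytic_nodes(self):
        pkn = convert_reaction_network(
            [rxn("R1", ["metab__A"], ["metab__C"], "E1 OR E2")]
        )
        assert len(pkn) == 4
        assert {"E1__R1", "E2__R1"} <= pkn.nodes

    def test_shared_enzyme_does_not_crosslink_reactions(self):
        pkn = convert_reaction_network(
            [
                rxn("R1", ["metab__A"], ["metab__B"], "E"),
                rxn("R2", ["metab__C"], ["metab__D"], "E"),
            ]
        )
        g = pkn.to_digraph()
        assert not nx.has_path(g, "metab__A", "metab__D")
        assert not nx.has_path(g, "metab__C", "metab__B")
        # and no length-2 path from a reactant of one to a product of the other
        assert nx.has_path(g, "metab__A", "metab__B")

    def test_exchange_reaction_suffix(self):
        pkn = convert_reaction_network(
            [rxn("EX1", ["metab__glc__e"], ["metab__glc__c"], "T1",
                 is_exchange=True, exchanged_metabolite="metab__glc__e")]
        )
        assert "T1__EX1__metab__glc__e" in pkn.nodes

    def test_exchange_requires_exchanged_metabolite(self):
        with pytest.raises(ValueError, match="exchanged metabolite"):
            rxn("EX1", ["metab__a"], ["metab__b"], "T1", is_exchange=True)

    def test_coenzymes_removed_before_edges(self):
        policy = MetabolitePolicy(coenzyme_ids=frozenset({"metab__atp"}))
        pkn = convert_reaction_network(
            [rxn("R1", ["metab__A", "metab__atp"], ["metab__C"], "E")], policy
        )
        assert "metab__atp" not in pkn.nodes
        assert len(pkn) == 2

    def test_malformed_gpr_names_the_reaction(self):
        with pytest.raises(Exception, match="R9"):
            convert_reaction_network([rxn("R9", ["metab__A"], ["metab__B"], "E1 AND")])


class TestPromiscuityFilter:
    def build(self, n_reactions, threshold):
        reactions = [
            rxn(f"R{i}", ["metab__hub"], [f"metab__m{i}"], f"E{i}")
            for i in range(n_reactions)
        ]
        return convert_reaction_network(
            reactions, MetabolitePolicy(degree_threshold=threshold)
        )

    def test_hub_above_threshold_removed(self):
        pkn = self.build(n_reactions=5, threshold=4)
        assert "metab__hub" not in pkn.nodes
        # each reaction keeps only its enzyme->product edge
        assert len(pkn) == 5

    def test_idempotent(self):
        pkn = self.build(n_reactions=5, threshold=4)
        again = filter_promiscuous_metabolites(pkn, 4)
        assert {e.key for e in again.edges} == {e.key for e in pkn.edges}

    def test_lowering_threshold_never_adds_edges(self):
        sizes = [len(self.build(5, t)) for t in (6, 5, 4, 3, 1)]
        assert sizes == sorted(sizes, reverse=True)


class TestMergeSources:
    def test_disjoint_union_counts(self):
        ppi = {SignedEdge("A", 1, "B", provenance="ppi"),
               SignedEdge("B", -1, "C", provenance="ppi")}
        allo = {SignedEdge("metab__m", 1, "A", provenance="allosteric")}
        metabolic = convert_reaction_network(
            [rxn("R1", ["metab__x"], ["metab__y"], "E")]
        )
        merged = merge_sources(ppi, allo, metabolic)
        assert len(merged) == 5
        assert merged.kind_of("metab__m") == METABOLITE

    def test_duplicate_edge_keeps_first_provenance(self):
        ppi = {SignedEdge("A", 1, "B", provenance="ppi")}
        transcriptional = {SignedEdge("A", 1, "B", provenance="transcriptional")}
        merged = merge_sources(ppi=ppi, transcriptional=transcriptional)
        assert len(merged) == 1
        (edge,) = merged.edges
        assert edge.provenance == "ppi"
        assert merged.edge_provenances(edge) == ("ppi", "transcriptional")

    def test_empty_inputs_give_empty_pkn(self):
        assert len(merge_sources()) == 0

    def test_namespace_clash_raises(self):
        # allosteric sources must live in the metabolite namespace
        allo = {SignedEdge("glutamate", 1, "P1", provenance="allosteric")}
        with pytest.raises(NamespaceError):
            merge_sources(allosteric=allo)

    def test_metabolite_protein_kind_clash_raises(self):
        metabolic = CausalPKN([SignedEdge("metab__x", 1, "E__R1")])
        metabolic.node_kind["E__R1"] = "enzyme_instance"
        clash = CausalPKN([SignedEdge("A", 1, "metab__x")])
        clash.node_kind["metab__x"] = "protein"  # corrupted sidecar
        with pytest.raises(NamespaceError):
            merge_sources(metabolic=clash)

    def test_regulon_edges_are_transcriptional(self):
        regulons = pd.DataFrame(
            {"regulator": ["TF1"], "target": ["G1"], "mode": [-1], "weight": [1.0]}
        )
        (edge,) = regulon_edges(regulons)
        assert edge.provenance == "transcriptional" and edge.sign == -1
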
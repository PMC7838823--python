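"""Meta prior-knowledge network assembly from three interaction sources.

Three layers are combined into one signed directed network:

* protein->protein signed interactions (curated signaling + transcriptional
  regulation, OmniPath-style tables),
* metabolite->protein allosteric regulations with a combined confidence
  score (STITCH-style tables, high-confidence rows only),
* a metabolic reaction network whose GPR rules are converted to causal
  edges ``reactant -(+1)-> catalytic node -(+1)-> product``.

Catalytic nodes are unique per reaction (``GENES__REACTION``) so that the
reactants of one reaction can never leak to the products of another reaction
sharing the same enzyme.  Coenzymes and hyper-promiscuous metabolites are
excluded to keep the converted network causally meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .gpr import GPRParseError, gpr_to_dnf
from .graph import (
    COMPLEX,
    ENZYME_INSTANCE,
    METABOLITE,
    PROTEIN,
    CausalPKN,
    NamespaceError,
    PKNFormatError,
    SignedEdge,
    is_metabolite_id,
)

DEFAULT_DEGREE_THRESHOLD = 338  # most-connected central-carbon metabolite (glutamate)
DEFAULT_MIN_ALLOSTERIC_SCORE = 900

#: Default mapping from action labels of metabolite-protein tables to signs.
DEFAULT_ACTION_SIGNS: Mapping[str, int] = {"activation": 1, "inhibition": -1}


@dataclass(frozen=True)
class Reaction:
    """One (irreversible) metabolic reaction with its GPR rule.

    Reversible reactions are encoded by the caller as two Reaction records.
    """

    reaction_id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    gpr: str
    is_exchange: bool = False
    exchanged_metabolite: str | None = None

    def __post_init__(self) -> None:
        if self.is_exchange and not self.exchanged_metabolite:
            raise ValueError(
                f"exchange reaction {self.reaction_id!r} must name its exchanged metabolite"
            )


@dataclass(frozen=True)
class MetabolitePolicy:
    """Which metabolites to exclude from the converted reaction network."""

    coenzyme_ids: frozenset[str] = frozenset()
    degree_threshold: int = DEFAULT_DEGREE_THRESHOLD

    def __post_init__(self) -> None:
        if self.degree_threshold < 1:
            raise ValueError("degree_threshold must be >= 1")


def _require_columns(df: pd.DataFrame, columns: Sequence[str]) -> None:
    for col in columns:
        if col not in df.columns:
            raise PKNFormatError(f"missing mandatory column {col!r}")


def _as_frame(rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows
    return pd.DataFrame(list(rows))


def parse_ppi_table(
    rows,
    source_col: str = "source",
    target_col: str = "target",
    stimulation_col: str = "is_stimulation",
    inhibition_col: str = "is_inhibition",
) -> set[SignedEdge]:
    """Signed directed protein-protein edges from an interaction table.

    Only signed rows are kept: stimulation gives a +1 edge, inhibition a -1
    edge, and a row flagged as both yields both edges.  Unsigned rows are
    dropped.
    """
    df = _as_frame(rows)
    _require_columns(df, [source_col, target_col, stimulation_col, inhibition_col])
    edges: set[SignedEdge] = set()
    for row in df.itertuples(index=False):
        src = str(getattr(row, source_col))
        tgt = str(getattr(row, target_col))
        if src == tgt:
            continue
        if int(getattr(row, stimulation_col)) == 1:
            edges.add(SignedEdge(src, 1, tgt, provenance="ppi"))
        if int(getattr(row, inhibition_col)) == 1:
            edges.add(SignedEdge(src, -1, tgt, provenance="ppi"))
    return edges


def parse_allosteric_table(
    rows,
    min_score: int = DEFAULT_MIN_ALLOSTERIC_SCORE,
    metabolite_col: str = "metabolite",
    protein_col: str = "protein",
    action_col: str = "action",
    score_col: str = "combined_score",
    action_signs: Mapping[str, int] = DEFAULT_ACTION_SIGNS,
) -> set[SignedEdge]:
    """High-confidence metabolite->protein allosteric regulations.

    Rows below ``min_score`` are discarded; the action label is mapped to an
    edge sign through ``action_signs`` (exposed because source databases do
    not standardise these labels).
    """
    df = _as_frame(rows)
    _require_columns(df, [metabolite_col, protein_col, action_col, score_col])
    edges: set[SignedEdge] = set()
    for row in df.itertuples(index=False):
        score = float(getattr(row, score_col))
        if score < min_score:
            continue
        action = str(getattr(row, action_col))
        if action not in action_signs:
            raise PKNFormatError(f"unknown action label {action!r}")
        edges.add(
            SignedEdge(
                str(getattr(row, metabolite_col)),
                action_signs[action],
                str(getattr(row, protein_col)),
                provenance="allosteric",
            )
        )
    return edges


def catalytic_node_name(genes: frozenset[str], reaction: Reaction) -> str:
    """Reaction-unique name for one DNF disjunct of a GPR rule."""
    name = "_".join(sorted(genes)) + "__" + reaction.reaction_id
    if reaction.is_exchange:
        name += "__" + reaction.exchanged_metabolite
    return name


def convert_reaction_network(
    reactions: Iterable[Reaction],
    policy: MetabolitePolicy | None = None,
) -> CausalPKN:
    """Convert a metabolic reaction network into causal edges.

    Each minimal catalyzing gene set (one DNF disjunct of the GPR) becomes a
    catalytic node, named by its sorted genes joined with ``_`` plus
    ``__reaction_id`` so enzymes of different reactions never share a node;
    exchange reactions are further suffixed with the exchanged metabolite.
    Edges are ``reactant -(+1)-> catalytic node`` and ``catalytic node
    -(+1)-> product``.  Coenzymes are removed before edge creation; after
    edge creation, metabolites whose degree exceeds the policy threshold are
    removed with all incident edges.
    """
    policy = policy or MetabolitePolicy()
    pkn = CausalPKN()
    for rxn in reactions:
        try:
            disjuncts = sorted(gpr_to_dnf(rxn.gpr), key=lambda d: sorted(d))
        except GPRParseError as exc:
            raise GPRParseError(f"reaction {rxn.reaction_id!r}: {exc}") from exc
        reactants = [m for m in rxn.reactants if m not in policy.coenzyme_ids]
        products = [m for m in rxn.products if m not in policy.coenzyme_ids]
        for genes in disjuncts:
            node = catalytic_node_name(genes, rxn)
            kind = ENZYME_INSTANCE if len(genes) == 1 else COMPLEX
            pkn.set_kind(node, kind, members=genes)
            for m in reactants:
                pkn.add_edge(SignedEdge(m, 1, node, provenance="metabolic"))
            for m in products:
                pkn.add_edge(SignedEdge(node, 1, m, provenance="metabolic"))
    return filter_promiscuous_metabolites(pkn, policy.degree_threshold)


def filter_promiscuous_metabolites(pkn: CausalPKN, degree_threshold: int) -> CausalPKN:
    """Drop metabolites with more than ``degree_threshold`` incident edges.

    Degree is counted on the network passed in (in + out); in the standard
    build this is the converted metabolic layer only, so allosteric edges do
    not count toward promiscuity.
    """
    too_connected = {
        n
        for n in pkn.nodes_of_kind(METABOLITE)
        if pkn.degree(n) > degree_threshold
    }
    if not too_connected:
        return pkn
    return pkn.remove_nodes(too_connected)


def regulon_edges(regulons: pd.DataFrame) -> set[SignedEdge]:
    """Transcriptional TF->target edges from a long-format regulon table.

    These edges make the gene-regulatory layer of the meta PKN and carry the
    ``transcriptional`` provenance that the coherence-correction step keys on.
    """
    edges = set()
    for row in regulons.itertuples(index=False):
        if str(row.regulator) == str(row.target):
            continue
        edges.add(
            SignedEdge(
                str(row.regulator), int(row.mode), str(row.target),
                provenance="transcriptional",
            )
        )
    return edges


def merge_sources(
    ppi: Iterable[SignedEdge] = (),
    allosteric: Iterable[SignedEdge] = (),
    metabolic: CausalPKN | None = None,
    transcriptional: Iterable[SignedEdge] = (),
) -> CausalPKN:
    """Deduplicated union of the interaction layers into one meta PKN.

    When the same (source, sign, target) triple occurs in several layers the
    first-listed layer's provenance is kept as primary and the others are
    recorded in the auxiliary provenance map.  A node typed as metabolite in
    one layer and protein in another raises :class:`NamespaceError`.
    """
    pkn = CausalPKN()
    for e in sorted(ppi, key=lambda e: e.key):
        pkn.add_edge(e)
    for e in sorted(transcriptional, key=lambda e: e.key):
        pkn.add_edge(e)
    for e in sorted(allosteric, key=lambda e: e.key):
        if not is_metabolite_id(e.source):
            raise NamespaceError(
                f"allosteric source {e.source!r} is not in the metabolite namespace"
            )
        pkn.add_edge(e)
        pkn.node_kind[e.source] = METABOLITE
    if metabolic is not None:
        for e in metabolic.edges_sorted():
            pkn.add_edge(e)
        for node, kind in metabolic.node_kind.items():
            prev = pkn.node_kind.get(node)
            if prev is not None and {prev, kind} == {METABOLITE, PROTEIN}:
                raise NamespaceError(
                    f"node {node!r} used both as metabolite and protein"
                )
            pkn.node_kind[node] = kind
        pkn.members.update(metabolic.members)
    pkn.validate()
    return pkn
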
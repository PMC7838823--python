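"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule states which gene products catalyze a reaction: ``AND`` joins the
subunits of an obligate complex, ``OR`` separates isozymes.  Rules here are
monotone (no negation), so the minimal disjunctive normal form is exactly the
set of minimal gene sets able to catalyze the reaction; each such set becomes
one catalytic node in the causal network.
"""

from __future__ import annotations

import re

MAX_PAREN_DEPTH = 10

_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.:\-]+)")


class GPRParseError(ValueError):
    """Raised for malformed GPR expressions."""


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise GPRParseError(f"unexpected character at {text[pos:]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser for ``expr := term (OR term)*``,
    ``term := factor (AND factor)*``, ``factor := gene | ( expr )``."""

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0
        self.depth = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self):
        node = self.expr()
        if self.peek() is not None:
            raise GPRParseError(f"trailing tokens starting at {self.peek()!r}")
        return node

    def expr(self):
        terms = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.term())
        return ("or", terms) if len(terms) > 1 else terms[0]

    def term(self):
        factors = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            factors.append(self.factor())
        return ("and", factors) if len(factors) > 1 else factors[0]

    def factor(self):
        tok = self.next()
        if tok == "(":
            self.depth += 1
            if self.depth > MAX_PAREN_DEPTH:
                raise GPRParseError(f"parentheses nested deeper than {MAX_PAREN_DEPTH}")
            node = self.expr()
            closing = self.next()
            if closing != ")":
                raise GPRParseError(f"expected ')', got {closing!r}")
            self.depth -= 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r}")
        return ("gene", tok)


def parse_gpr(text: str):
    """Parse a GPR expression into an ('and'|'or'|'gene', ...) tree."""
    tokens = _tokenize(text)
    if not tokens:
        raise GPRParseError("empty GPR expression")
    return _Parser(tokens).parse()


def _expand(node) -> set[frozenset[str]]:
    tag = node[0]
    if tag == "gene":
        return {frozenset([node[1]])}
    if tag == "or":
        out: set[frozenset[str]] = set()
        for child in node[1]:
            out |= _expand(child)
        return out
    # and: cross product of the children's disjunct sets
    disjuncts = {frozenset()}
    for child in node[1]:
        disjuncts = {a | b for a in disjuncts for b in _expand(child)}
    return disjuncts


def _absorb(disjuncts: set[frozenset[str]]) -> set[frozenset[str]]:
    """Drop disjuncts that are strict supersets of another (absorption law)."""
    return {
        d for d in disjuncts
        if not any(other < d for other in disjuncts)
    }


def gpr_to_dnf(text: str) -> set[frozenset[str]]:
    """Minimal DNF of a GPR rule: the set of minimal catalyzing gene sets.

    For a monotone boolean expression the minimal disjuncts coincide with the
    prime implicants, so absorption after distributive expansion is exact.
    """
    return _absorb(_expand(parse_gpr(text)))


def evaluate_gpr(tree, active_genes: set[str]) -> bool:
    """Evaluate a parsed GPR tree against a set of present genes."""
    tag = tree[0]
    if tag == "gene":
        return tree[1] in active_genes
    if tag == "or":
        return any(evaluate_gpr(c, active_genes) for c in tree[1])
    return all(evaluate_gpr(c, active_genes) for c in tree[1])
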
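"""Gene-protein-reaction (GPR) boolean rules, resolved numerically.

A GPR gates a metabolic reaction by the genes encoding its enzymes, written
as a boolean expression over gene ids with AND (complex subunits: all
required) and OR (isozymes: any suffices).  Here the rules are resolved
against continuous expression values rather than booleans: OR is the sum of
its children (isozyme capacities add) and AND is the minimum (a complex is
limited by its scarcest subunit).

Grammar (case-insensitive keywords, AND binds tighter than OR)::

    expr   := term  (OR  term)*
    term   := factor (AND factor)*
    factor := GENE_ID | '(' expr ')'
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Union

__all__ = ["GprTree", "GprSyntaxError", "parse_gpr", "evaluate_gpr"]


class GprSyntaxError(ValueError):
    """Raised for malformed GPR text; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.:\-]+)")


@dataclass(frozen=True)
class GprTree:
    """Expression tree: leaves are gene ids, internal nodes AND/OR with >= 2 children."""

    op: Optional[str]  # "and" | "or" | None for a leaf
    gene: Optional[str] = None
    children: tuple = ()

    def __post_init__(self):
        if self.op is None:
            if not self.gene:
                raise ValueError("leaf node requires a gene id")
        else:
            if self.op not in ("and", "or") or len(self.children) < 2:
                raise ValueError("operator node requires op in {and, or} and >= 2 children")

    @property
    def is_leaf(self) -> bool:
        return self.op is None

    def genes(self) -> set[str]:
        if self.is_leaf:
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        """Normalized string; parses back to an equivalent tree."""
        if self.is_leaf:
            return self.gene
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if not c.is_leaf:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise GprSyntaxError(f"unexpected character {text[pos]!r}", pos)
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, int]], length: int):
        self.tokens = tokens
        self.i = 0
        self.length = length

    def peek(self):
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pos(self):
        return self.tokens[self.i][1] if self.i < len(self.tokens) else self.length

    def advance(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expr(self) -> GprTree:
        children = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.advance()
            children.append(self.term())
        return _combine("or", children)

    def term(self) -> GprTree:
        children = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.advance()
            children.append(self.factor())
        return _combine("and", children)

    def factor(self) -> GprTree:
        tok = self.peek()
        if tok is None:
            raise GprSyntaxError("dangling operator: expected gene id or '('", self.pos())
        if tok == "(":
            self.advance()
            node = self.expr()
            if self.peek() != ")":
                raise GprSyntaxError("unbalanced parentheses: expected ')'", self.pos())
            self.advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprSyntaxError(f"expected gene id, found {tok!r}", self.pos())
        self.advance()
        return GprTree(op=None, gene=tok)


def _combine(op: str, children: list[GprTree]) -> GprTree:
    if len(children) == 1:
        return children[0]
    # flatten nested same-operator nodes so ((a or b) or c) == (a or b or c)
    flat: list[GprTree] = []
    for c in children:
        if not c.is_leaf and c.op == op:
            flat.extend(c.children)
        else:
            flat.append(c)
    return GprTree(op=op, children=tuple(flat))


def parse_gpr(text: str) -> GprTree:
    """Parse GPR text into a :class:`GprTree`.

    Raises :class:`GprSyntaxError` (with position) for unbalanced
    parentheses or dangling operators.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GprSyntaxError("empty GPR expression", 0)
    parser = _Parser(tokens, len(text))
    tree = parser.expr()
    if parser.peek() is not None:
        raise GprSyntaxError(f"unexpected token {parser.peek()!r}", parser.pos())
    return tree


def evaluate_gpr(
    tree: GprTree,
    gene_values: Mapping[str, float],
    missing_policy: str = "drop",
) -> Optional[float]:
    """Resolve a GPR numerically: OR = sum of children, AND = min of children.

    Parameters
    ----------
    gene_values : nonnegative expression value per gene id.
    missing_policy : ``"drop"`` removes unmeasured genes from their operator
        (absence of evidence is not zero expression); ``"zero"`` treats them
        as expression 0.  An operator whose children are all absent is itself
        absent; a fully absent tree returns ``None`` and the reaction is left
        unconstrained downstream.
    """
    if missing_policy not in ("drop", "zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if tree.is_leaf:
        if tree.gene in gene_values:
            v = float(gene_values[tree.gene])
            if v < 0:
                raise ValueError(f"negative expression value {v} for gene {tree.gene}")
            return v
        return 0.0 if missing_policy == "zero" else None
    vals = [evaluate_gpr(c, gene_values, missing_policy) for c in tree.children]
    present = [v for v in vals if v is not None]
    if not present:
        return None
    return sum(present) if tree.op == "or" else min(present)
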
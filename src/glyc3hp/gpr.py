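"""Gene-protein-reaction (GPR) rules.

A GPR is a boolean expression over gene identifiers that states which gene
products a reaction needs: ``and`` joins subunits of one enzyme complex,
``or`` joins isozymes.  Deleting a set of genes disables a reaction exactly
when its GPR evaluates to False with the deleted genes set to False and all
other genes set to True.  A reaction with no GPR cannot be disabled by any
gene deletion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import FrozenSet, Iterable, Set, Union

__all__ = ["GPR", "Gene", "And", "Or", "parse_gpr", "evaluate_gpr"]


@dataclass(frozen=True)
class Gene:
    """A leaf of a GPR tree: a single gene identifier."""

    id: str

    def evaluate(self, deleted: Set[str]) -> bool:
        return self.id not in deleted

    def genes(self) -> FrozenSet[str]:
        return frozenset((self.id,))

    def to_string(self) -> str:
        return self.id


@dataclass(frozen=True)
class And:
    """All children required (enzyme complex)."""

    children: tuple

    def evaluate(self, deleted: Set[str]) -> bool:
        return all(c.evaluate(deleted) for c in self.children)

    def genes(self) -> FrozenSet[str]:
        out: Set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def to_string(self) -> str:
        return "(" + " and ".join(c.to_string() for c in self.children) + ")"


@dataclass(frozen=True)
class Or:
    """Any child sufficient (isozymes)."""

    children: tuple

    def evaluate(self, deleted: Set[str]) -> bool:
        return any(c.evaluate(deleted) for c in self.children)

    def genes(self) -> FrozenSet[str]:
        out: Set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def to_string(self) -> str:
        return "(" + " or ".join(c.to_string() for c in self.children) + ")"


GPR = Union[Gene, And, Or]

_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


class GPRSyntaxError(ValueError):
    """Raised for malformed GPR strings."""


def _tokenize(text: str) -> list:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive-descent parser; ``and`` binds tighter than ``or``."""

    def __init__(self, tokens: list):
        self.tokens = tokens
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse_or(self) -> GPR:
        terms = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and(self) -> GPR:
        terms = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            terms.append(self.parse_atom())
        return terms[0] if len(terms) == 1 else And(tuple(terms))

    def parse_atom(self) -> GPR:
        tok = self.next()
        if tok is None:
            raise GPRSyntaxError("unexpected end of GPR expression")
        if tok == "(":
            node = self.parse_or()
            if self.next() != ")":
                raise GPRSyntaxError("unbalanced parentheses in GPR")
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in GPR")
        return Gene(tok)


def parse_gpr(text: str) -> "GPR | None":
    """Parse a GPR string such as ``"(b0001 and b0002) or b0003"``.

    An empty or whitespace-only string yields ``None`` (no gene
    association; the reaction is not deletable).
    """
    tokens = _tokenize(text or "")
    if not tokens:
        return None
    parser = _Parser(tokens)
    node = parser.parse_or()
    if parser.peek() is not None:
        raise GPRSyntaxError(f"trailing token {parser.peek()!r} in GPR")
    return node


def evaluate_gpr(gpr: "GPR | None", deleted: Iterable[str]) -> bool:
    """True iff the reaction remains catalysed after deleting ``deleted``.

    ``None`` (empty GPR) always evaluates True: a reaction with no gene
    association survives every deletion.
    """
    if gpr is None:
        return True
    return gpr.evaluate(set(deleted))


def gpr_to_string(gpr: "GPR | None") -> str:
    return "" if gpr is None else gpr.to_string()
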
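"""Gene-protein-reaction (GPR) rules.

A GPR rule is a boolean expression over gene identifiers: ``or`` joins
isoenzymes (any gene suffices), ``and`` joins complex subunits (all genes
required).  Curated fungal models frequently list isoenzymes as a bare
whitespace-separated gene list (e.g. ``"OAory_01014160 OAory_01017500"``);
such lists are parsed as an implicit OR.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


class GprParseError(ValueError):
    """Raised for malformed GPR strings; carries the offending token position."""


_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(rule: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN.match(rule, pos)
        if m is None:  # only trailing whitespace remains
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


@dataclass(frozen=True)
class GprExpression:
    """Parsed boolean tree over gene identifiers.

    ``op`` is ``"and"``, ``"or"``, ``"gene"`` or ``"empty"``.  Leaves carry the
    gene id in ``gene``; internal nodes hold >= 2 children.
    """

    op: str
    gene: str | None = None
    children: tuple["GprExpression", ...] = field(default_factory=tuple)

    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> frozenset[str]:
        """The leaf set: every gene named in the rule."""
        if self.op == "empty":
            return frozenset()
        if self.op == "gene":
            return frozenset({self.gene})  # type: ignore[arg-type]
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def evaluate(self, present: dict[str, bool]) -> bool:
        """Evaluate the rule under a gene presence/absence assignment.

        Missing genes default to False.
        """
        if self.op == "empty":
            return True
        if self.op == "gene":
            return bool(present.get(self.gene, False))
        if self.op == "and":
            return all(c.evaluate(present) for c in self.children)
        return any(c.evaluate(present) for c in self.children)

    def to_string(self) -> str:
        """Normalized string form; round-trips through :func:`parse_gpr`."""
        return self._fmt(top=True)

    def _fmt(self, top: bool = False) -> str:
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.op} "
        inner = sep.join(c._fmt() for c in self.children)
        return inner if top else f"({inner})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


EMPTY_GPR = GprExpression(op="empty")


def _node(op: str, parts: list[GprExpression]) -> GprExpression:
    if len(parts) == 1:
        return parts[0]
    # flatten nested same-operator nodes so "a or b or c" is one OR node
    flat: list[GprExpression] = []
    for p in parts:
        if p.op == op:
            flat.extend(p.children)
        else:
            flat.append(p)
    return GprExpression(op=op, children=tuple(flat))


class _Parser:
    """Recursive-descent parser; grammar: or_expr > and_expr > atom.

    A sequence of atoms with no operator in between is treated as an OR list
    (isoenzyme listing style).
    """

    def __init__(self, rule: str):
        self.rule = rule
        self.tokens = _tokenize(rule)
        self.i = 0

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def fail(self, msg: str, pos: int) -> None:
        raise GprParseError(f"{msg} at position {pos} in GPR rule {self.rule!r}")

    def parse(self) -> GprExpression:
        if not self.tokens:
            return EMPTY_GPR
        expr = self.or_expr()
        tok = self.peek()
        if tok is not None:
            self.fail(f"unexpected token {tok[0]!r}", tok[1])
        return expr

    def or_expr(self) -> GprExpression:
        parts = [self.and_expr()]
        while True:
            tok = self.peek()
            if tok is None:
                break
            word = tok[0].lower()
            if word == "or":
                self.next()
                parts.append(self.and_expr())
            elif tok[0] == ")":
                break
            elif word == "and":
                break  # handled by caller
            else:
                # bare juxtaposition: whitespace-separated isoenzyme list
                parts.append(self.and_expr())
        return _node("or", parts)

    def and_expr(self) -> GprExpression:
        parts = [self.atom()]
        while True:
            tok = self.peek()
            if tok is not None and tok[0].lower() == "and":
                self.next()
                parts.append(self.atom())
            else:
                break
        return _node("and", parts)

    def atom(self) -> GprExpression:
        tok = self.peek()
        if tok is None:
            self.fail("dangling operator", len(self.rule))
        word, pos = self.next()
        if word == "(":
            expr = self.or_expr()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                self.fail("unbalanced parenthesis", pos)
            self.next()
            return expr
        if word == ")":
            self.fail("unbalanced parenthesis", pos)
        if word.lower() in ("and", "or"):
            self.fail(f"dangling operator {word!r}", pos)
        return GprExpression(op="gene", gene=word)


def parse_gpr(rule: str) -> GprExpression:
    """Parse a GPR rule string into a :class:`GprExpression`.

    Accepts standard boolean syntax with ``and``/``or`` (case-insensitive) and
    parentheses, plus bare whitespace-separated gene lists interpreted as OR.
    An empty or whitespace-only rule yields the empty expression (leaf set ∅),
    which evaluates to True (no gene requirement).
    """
    return _Parser(rule or "").parse()
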
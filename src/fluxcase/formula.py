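"""A small, closed expression language for computed attributes and rules.

Clinical protocols routinely derive one field from others — body-mass index
from weight and height, age at onset from two dates — and decision-support
rules need yes/no conditions over recorded values ("suggest an adrenal
function test when C26:0 is elevated"). Both live in the workflow file, so
they must be *data*, never executable code. This module implements the only
evaluator in the package: a hand-written recursive-descent parser over a
deliberately tiny grammar, with an interpreter that can perform nothing
beyond arithmetic, comparison, and calendar-year difference.

Grammar (standard precedence, left associative)::

    formula    := comparison
    comparison := sum [ ("=="|"!="|"<="|">="|"<"|">") sum ]
    sum        := product { ("+"|"-") product }
    product    := unary { ("*"|"/") unary }
    unary      := "-" unary | atom
    atom       := NUMBER | IDENT | "years_between" "(" IDENT "," IDENT ")"
                | "(" formula ")"

Everything else — attribute access, calls, strings, indexing — is a syntax
error, which is what makes formulas safe to accept from workflow authors.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field
from typing import Mapping

from .errors import EvaluationError, FormulaSyntaxError

__all__ = ["Formula", "parse_formula", "evaluate_formula", "years_between"]

_TOKEN_RE = re.compile(
    r"(?P<num>\d+\.\d*|\.\d+|\d+)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>==|!=|<=|>=|[+\-*/(),<>])"
)

_COMPARISON_OPS = ("==", "!=", "<=", ">=", "<", ">")


@dataclass(frozen=True)
class _Token:
    kind: str  # "num" | "name" | "op"
    text: str
    offset: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    n = len(text)
    while pos < n:
        if text[pos].isspace():
            pos += 1
            continue
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise FormulaSyntaxError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup or "op"
        tokens.append(_Token(kind, m.group(), pos))
        pos = m.end()
    return tokens


@dataclass(frozen=True)
class Formula:
    """A parsed expression.

    Two formulas compare equal when their source text is identical; the parse
    tree and referenced-name set are derived data.
    """

    expression: str
    ast: tuple = field(compare=False, repr=False)
    referenced_names: frozenset[str] = field(compare=False, default=frozenset())


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> _Token:
        tok = self._peek()
        if tok is None:
            raise FormulaSyntaxError("unexpected end of formula", len(self.text))
        self.i += 1
        return tok

    def _expect_op(self, op: str) -> None:
        tok = self._peek()
        if tok is None or tok.kind != "op" or tok.text != op:
            offset = tok.offset if tok else len(self.text)
            raise FormulaSyntaxError(f"expected {op!r}", offset)
        self.i += 1

    def parse(self) -> tuple:
        node = self.comparison()
        tok = self._peek()
        if tok is not None:
            raise FormulaSyntaxError(f"unexpected token {tok.text!r}", tok.offset)
        return node

    def comparison(self) -> tuple:
        left = self.sum()
        tok = self._peek()
        if tok is not None and tok.kind == "op" and tok.text in _COMPARISON_OPS:
            self.i += 1
            right = self.sum()
            return ("cmp", tok.text, left, right)
        return left

    def sum(self) -> tuple:
        node = self.product()
        while True:
            tok = self._peek()
            if tok is not None and tok.kind == "op" and tok.text in ("+", "-"):
                self.i += 1
                node = ("bin", tok.text, node, self.product())
            else:
                return node

    def product(self) -> tuple:
        node = self.unary()
        while True:
            tok = self._peek()
            if tok is not None and tok.kind == "op" and tok.text in ("*", "/"):
                self.i += 1
                node = ("bin", tok.text, node, self.unary())
            else:
                return node

    def unary(self) -> tuple:
        tok = self._peek()
        if tok is not None and tok.kind == "op" and tok.text == "-":
            self.i += 1
            return ("neg", self.unary())
        return self.atom()

    def atom(self) -> tuple:
        tok = self._next()
        if tok.kind == "num":
            text = tok.text
            value: int | float = float(text) if "." in text else int(text)
            return ("num", value)
        if tok.kind == "name":
            nxt = self._peek()
            if nxt is not None and nxt.kind == "op" and nxt.text == "(":
                if tok.text != "years_between":
                    raise FormulaSyntaxError(
                        f"unknown function {tok.text!r}", tok.offset
                    )
                self._expect_op("(")
                a = self._next()
                if a.kind != "name":
                    raise FormulaSyntaxError("expected identifier", a.offset)
                self._expect_op(",")
                b = self._next()
                if b.kind != "name":
                    raise FormulaSyntaxError("expected identifier", b.offset)
                self._expect_op(")")
                return ("years", a.text, b.text)
            return ("ref", tok.text)
        if tok.kind == "op" and tok.text == "(":
            node = self.comparison()
            self._expect_op(")")
            return node
        raise FormulaSyntaxError(f"unexpected token {tok.text!r}", tok.offset)


def _collect_names(node: tuple, out: set[str]) -> None:
    tag = node[0]
    if tag == "ref":
        out.add(node[1])
    elif tag == "years":
        out.add(node[1])
        out.add(node[2])
    elif tag == "neg":
        _collect_names(node[1], out)
    elif tag in ("bin", "cmp"):
        _collect_names(node[2], out)
        _collect_names(node[3], out)


def parse_formula(text: str) -> Formula:
    """Parse ``text`` into a :class:`Formula`.

    Raises :class:`~fluxcase.errors.FormulaSyntaxError` (with the character
    offset of the problem) for anything outside the grammar.
    """
    ast = _Parser(text).parse()
    names: set[str] = set()
    _collect_names(ast, names)
    return Formula(expression=text, ast=ast, referenced_names=frozenset(names))


def years_between(later: datetime.date, earlier: datetime.date) -> int:
    """Completed calendar years between two dates, truncated toward zero.

    This is the clinical "age" convention: the count increments on the
    anniversary day, and a Feb-29 anniversary completes on Mar 1 of common
    years. Negative when ``later`` precedes ``earlier``.
    """
    if later < earlier:
        return -years_between(earlier, later)
    years = later.year - earlier.year
    if (later.month, later.day) < (earlier.month, earlier.day):
        years -= 1
    return years


def _unwrap(value):
    # Accept AttributeValue-like objects without importing the model.
    payload = getattr(value, "value", value)
    return payload


def _require_number(value, symbol: str):
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise EvaluationError(
            "non-numeric-operand", symbol, f"non-numeric operand in {symbol!r}"
        )
    return value


def evaluate_formula(formula: Formula, context: Mapping[str, object]):
    """Evaluate ``formula`` against a name → value context.

    Context values may be plain numbers, :class:`datetime.date` objects, or
    ``AttributeValue`` wrappers (their payload is used). Returns an ``int`` or
    ``float`` for arithmetic, a ``bool`` for comparisons. All failures raise
    :class:`~fluxcase.errors.EvaluationError` with codes ``unbound-name``,
    ``non-numeric-operand``, ``non-date-operand`` or ``division-by-zero``,
    each naming the offending symbol.
    """

    def lookup(name: str):
        if name not in context:
            raise EvaluationError("unbound-name", name, f"unbound name {name!r}")
        return _unwrap(context[name])

    def ev(node: tuple):
        tag = node[0]
        if tag == "num":
            return node[1]
        if tag == "ref":
            # Type demands are made at the operator, so dates can flow into
            # comparisons and years_between while arithmetic still rejects them.
            return lookup(node[1])
        if tag == "neg":
            return -_require_number(ev(node[1]), formula.expression)
        if tag == "years":
            a, b = lookup(node[1]), lookup(node[2])
            for name, v in ((node[1], a), (node[2], b)):
                if not isinstance(v, datetime.date) or isinstance(
                    v, datetime.datetime
                ):
                    raise EvaluationError(
                        "non-date-operand", name, f"{name!r} is not a calendar date"
                    )
            return years_between(a, b)
        if tag == "bin":
            op = node[1]
            left = _require_number(ev(node[2]), formula.expression)
            right = _require_number(ev(node[3]), formula.expression)
            if op == "+":
                return left + right
            if op == "-":
                return left - right
            if op == "*":
                return left * right
            if right == 0:
                raise EvaluationError(
                    "division-by-zero", formula.expression, "division by zero"
                )
            return left / right
        if tag == "cmp":
            op = node[1]
            left = ev(node[2])
            right = ev(node[3])
            left_date = isinstance(left, datetime.date)
            right_date = isinstance(right, datetime.date)
            if left_date != right_date:
                raise EvaluationError(
                    "non-numeric-operand",
                    formula.expression,
                    "cannot compare a date with a number",
                )
            if not left_date:
                _require_number(left, formula.expression)
                _require_number(right, formula.expression)
            if op == "==":
                return left == right
            if op == "!=":
                return left != right
            if op == "<=":
                return left <= right
            if op == ">=":
                return left >= right
            if op == "<":
                return left < right
            return left > right
        raise AssertionError(f"unknown node {tag!r}")  # pragma: no cover

    return ev(formula.ast)
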
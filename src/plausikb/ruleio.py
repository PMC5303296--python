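"""Parser and serializer for the Prolog-like rule dialect.

Grammar (one statement per ``.``; ``%`` and ``#`` start line comments)::

    deductive  :=  literal ":-" literal ("," literal)* "."
    plausible  :=  literal "<~" literal "."
    literal    :=  NAME "(" term ("," term)* ")"
    term       :=  VARIABLE            # single upper-case letter + optional
                |  NAME                #   digits (P, X, Q1); anything else
                |  NUMBER              #   is a constant (ascites, Lamivudine)
                |  "(" "type" NAME ")" VARIABLE?   # typed (possibly anonymous) variable

Parsing is all-or-nothing: a syntax error anywhere (reported with line and
column) yields no rules.  ``serialize(parse(text)) == parse`` input up to
whitespace.
"""

from __future__ import annotations

import re
from typing import List, Union

from .model import Const, DeductiveRule, Literal, PlausibleRule, TypedVar, Var


class RuleSyntaxError(ValueError):
    def __init__(self, message: str, line: int, col: int):
        super().__init__(f"line {line}, column {col}: {message}")
        self.line = line
        self.col = col


_TOKEN_RE = re.compile(
    r"""
    (?P<WS>\s+)
  | (?P<COMMENT>[%\#][^\n]*)
  | (?P<ARROW>:-|<~)
  | (?P<LPAREN>\()
  | (?P<RPAREN>\))
  | (?P<COMMA>,)
  | (?P<DOT>\.(?!\d))
  | (?P<NUMBER>-?\d+(?:\.\d+)?)
  | (?P<NAME>[A-Za-z_][A-Za-z0-9_]*)
    """,
    re.VERBOSE,
)


_VAR_RE = re.compile(r"[A-Z][0-9]*\Z")


def is_variable_name(name: str) -> bool:
    return _VAR_RE.match(name) is not None


class _Token:
    __slots__ = ("kind", "text", "line", "col")

    def __init__(self, kind, text, line, col):
        self.kind, self.text, self.line, self.col = kind, text, line, col


def _tokenize(text: str) -> List[_Token]:
    tokens = []
    line, col = 1, 1
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise RuleSyntaxError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup
        chunk = m.group()
        if kind not in ("WS", "COMMENT"):
            tokens.append(_Token(kind, chunk, line, col))
        newlines = chunk.count("\n")
        if newlines:
            line += newlines
            col = len(chunk) - chunk.rfind("\n")
        else:
            col += len(chunk)
        pos = m.end()
    tokens.append(_Token("EOF", "", line, col))
    return tokens


class _Parser:
    def __init__(self, tokens: List[_Token]):
        self.tokens = tokens
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def _fail(self, message: str):
        raise RuleSyntaxError(message, self.cur.line, self.cur.col)

    def expect(self, kind: str) -> _Token:
        if self.cur.kind != kind:
            self._fail(f"expected {kind}, found {self.cur.text!r}")
        tok = self.cur
        self.i += 1
        return tok

    def parse_rules(self) -> list:
        rules = []
        self._anon = 0
        while self.cur.kind != "EOF":
            rules.append(self.parse_rule())
        return rules

    def parse_rule(self):
        head = self.parse_literal()
        if self.cur.kind != "ARROW":
            self._fail("expected ':-' or '<~' after rule head")
        arrow = self.expect("ARROW").text
        if arrow == ":-":
            body = [self.parse_literal()]
            while self.cur.kind == "COMMA":
                self.expect("COMMA")
                body.append(self.parse_literal())
            self.expect("DOT")
            return DeductiveRule(head, tuple(body))
        condition = self.parse_literal()
        self.expect("DOT")
        return PlausibleRule(consequent=head, shared_condition=condition)

    def parse_literal(self) -> Literal:
        name = self.expect("NAME").text
        if is_variable_name(name):
            self._fail(f"predicate name expected, found variable {name!r}")
        self.expect("LPAREN")
        args = [self.parse_term()]
        while self.cur.kind == "COMMA":
            self.expect("COMMA")
            args.append(self.parse_term())
        self.expect("RPAREN")
        return Literal(name, tuple(args))

    def parse_term(self):
        tok = self.cur
        if tok.kind == "NUMBER":
            self.i += 1
            return Const(float(tok.text) if "." in tok.text else int(tok.text))
        if tok.kind == "NAME":
            self.i += 1
            if is_variable_name(tok.text):
                return Var(tok.text)
            return Const(tok.text)
        if tok.kind == "LPAREN":
            self.i += 1
            kw = self.expect("NAME")
            if kw.text != "type":
                self._fail(f"unknown construct ({kw.text!r} ...), expected (type Class)")
            cls = self.expect("NAME").text
            self.expect("RPAREN")
            if self.cur.kind == "NAME" and is_variable_name(self.cur.text):
                var = self.expect("NAME").text
                return TypedVar(var, cls)
            self._anon += 1
            return TypedVar(f"_T{self._anon}", cls, anonymous=True)
        self._fail(f"expected a term, found {tok.text!r}")


def parse_rule_text(text: str) -> list:
    """Parse a rule file; returns DeductiveRule / PlausibleRule in input order.

    All-or-nothing: raises :class:`RuleSyntaxError` (with line/column) on the
    first malformed construct, returning no partial result.
    """
    return _Parser(_tokenize(text)).parse_rules()


def parse_literal_text(text: str) -> Literal:
    """Parse a single literal, e.g. a query such as ``live(p116, true)``."""
    parser = _Parser(_tokenize(text))
    parser._anon = 0
    literal = parser.parse_literal()
    if parser.cur.kind == "DOT":
        parser.expect("DOT")
    parser.expect("EOF")
    return literal


def serialize_rule(rule: Union[DeductiveRule, PlausibleRule]) -> str:
    return str(rule)


def serialize_rules(rules) -> str:
    return "\n".join(serialize_rule(r) for r in rules) + "\n"
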
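"""Recursive-descent parser for the query language.

Grammar, loosest binding first::

    expr  := or ("then" or "else" expr)?      -- conditional
    or    := xor ("|" xor)*
    xor   := and ("^" and)*
    and   := unary ("&" unary)*
    unary := "!" unary | atom
    atom  := "true" | "false" | "(" expr ")" | predicate

Binary connectives are left-associative.  Negation binds tightest, then
``&``, ``^``, ``|``, and finally ``then``/``else``.  The precedence order is
a documented convention of this implementation, chosen to match the
C-family boolean operators; compound queries mixing connectives without
parentheses should be read accordingly.

Lexing is context sensitive in two places: the argument of ``chr``,
``mate_chr`` and ``read_group`` is taken verbatim (as a glob) up to the
closing parenthesis, and ``~`` introduces a ``/``-delimited regular
expression literal for the ``header`` predicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

from . import ast

__all__ = ["Token", "ParseError", "tokenize", "parse_query"]

_KEYWORDS = {"then", "else", "true", "false"}
_GLOB_PREDICATES = {"chr", "mate_chr", "read_group"}
_PUNCT = set("!&|^(),~")


@dataclass(frozen=True)
class Token:
    kind: str  # identifier | keyword | punct | integer | decimal | glob-arg | regex-literal
    text: str
    offset: int


@dataclass
class ParseError(Exception):
    """Rejection of a query string, with the offending offset."""

    message: str
    offset: int
    expected: frozenset = field(default_factory=frozenset)

    def __str__(self) -> str:
        return f"{self.message} (at offset {self.offset})"

    def pretty(self, text: str) -> str:
        """Two-line rendering with a caret under the offending position."""
        caret = " " * self.offset + "^"
        return f"{self.message}\n  {text}\n  {caret}"


def _lex_number(text: str, i: int) -> Token:
    start = i
    n = len(text)
    while i < n and text[i].isdigit():
        i += 1
    kind = "integer"
    if i < n and text[i] == ".":
        kind = "decimal"
        i += 1
        while i < n and text[i].isdigit():
            i += 1
    if i < n and text[i] in "eE":
        j = i + 1
        if j < n and text[j] in "+-":
            j += 1
        if j < n and text[j].isdigit():
            kind = "decimal"
            i = j
            while i < n and text[i].isdigit():
                i += 1
    return Token(kind, text[start:i], start)


def tokenize(text: str) -> List[Token]:
    """Lex ``text`` into tokens.

    Predicate names keep a trailing ``?`` as part of the identifier.
    Raises :class:`ParseError` on an unterminated regex literal, an
    unterminated glob argument, or a character outside the language.
    """
    tokens: List[Token] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in _PUNCT:
            tokens.append(Token("punct", c, i))
            i += 1
            if c == "~":
                # a regex literal must follow: /.../ with \/ escapes
                while i < n and text[i].isspace():
                    i += 1
                if i >= n or text[i] != "/":
                    raise ParseError("expected /regex/ after '~'", i,
                                     frozenset(["/"]))
                start = i
                i += 1
                body = []
                while i < n and text[i] != "/":
                    if text[i] == "\\" and i + 1 < n and text[i + 1] == "/":
                        body.append("/")
                        i += 2
                    else:
                        body.append(text[i])
                        i += 1
                if i >= n:
                    raise ParseError("unterminated regex literal", start,
                                     frozenset(["/"]))
                i += 1  # closing /
                tokens.append(Token("regex-literal", "".join(body), start))
            elif (c == "(" and len(tokens) >= 2
                  and tokens[-2].kind == "identifier"
                  and tokens[-2].text in _GLOB_PREDICATES):
                # glob argument: verbatim text up to the matching ')'
                start = i
                j = text.find(")", i)
                if j < 0:
                    raise ParseError("unterminated glob argument", start,
                                     frozenset([")"]))
                tokens.append(Token("glob-arg", text[i:j], start))
                tokens.append(Token("punct", ")", j))
                i = j + 1
            continue
        if c.isdigit():
            tok = _lex_number(text, i)
            tokens.append(tok)
            i += len(tok.text)
            continue
        if c.isalpha() or c == "_":
            start = i
            while i < n and (text[i].isalnum() or text[i] == "_"):
                i += 1
            if i < n and text[i] == "?":
                i += 1
            word = text[start:i]
            kind = "keyword" if word in _KEYWORDS else "identifier"
            tokens.append(Token(kind, word, start))
            continue
        raise ParseError(f"unexpected character {c!r}", i)
    return tokens


class _Parser:
    def __init__(self, text: str, tokens: List[Token]):
        self.text = text
        self.tokens = tokens
        self.pos = 0

    def _peek(self) -> Token | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self) -> Token:
        tok = self._peek()
        if tok is None:
            raise ParseError("unexpected end of query", len(self.text))
        self.pos += 1
        return tok

    def _at(self, kind: str, text: str | None = None) -> bool:
        tok = self._peek()
        return (tok is not None and tok.kind == kind
                and (text is None or tok.text == text))

    def _expect(self, kind: str, text: str) -> Token:
        tok = self._peek()
        if tok is None:
            raise ParseError(f"expected {text!r} but query ended",
                             len(self.text), frozenset([text]))
        if tok.kind != kind or tok.text != text:
            raise ParseError(f"expected {text!r}, found {tok.text!r}",
                             tok.offset, frozenset([text]))
        self.pos += 1
        return tok

    # -- precedence ladder -------------------------------------------------

    def expr(self) -> ast.QueryNode:
        cond = self.or_expr()
        if self._at("keyword", "then"):
            self._next()
            then_expr = self.or_expr()
            self._expect("keyword", "else")
            else_expr = self.expr()
            return ast.Conditional(cond, then_expr, else_expr)
        return cond

    def or_expr(self) -> ast.QueryNode:
        node = self.xor_expr()
        while self._at("punct", "|"):
            self._next()
            node = ast.Or(node, self.xor_expr())
        return node

    def xor_expr(self) -> ast.QueryNode:
        node = self.and_expr()
        while self._at("punct", "^"):
            self._next()
            node = ast.Xor(node, self.and_expr())
        return node

    def and_expr(self) -> ast.QueryNode:
        node = self.unary()
        while self._at("punct", "&"):
            self._next()
            node = ast.And(node, self.unary())
        return node

    def unary(self) -> ast.QueryNode:
        if self._at("punct", "!"):
            self._next()
            return ast.Not(self.unary())
        return self.atom()

    # -- atoms -------------------------------------------------------------

    def _int_arg(self, what: str) -> int:
        tok = self._next()
        if tok.kind != "integer":
            raise ParseError(f"expected an integer {what}, found {tok.text!r}",
                             tok.offset, frozenset(["integer"]))
        return int(tok.text)

    def _prob_arg(self) -> float:
        tok = self._next()
        if tok.kind not in ("integer", "decimal"):
            raise ParseError(
                f"expected a probability, found {tok.text!r}",
                tok.offset, frozenset(["number"]))
        return float(tok.text)

    def _build(self, ctor, args, tok: Token) -> ast.QueryNode:
        try:
            return ctor(*args)
        except ValueError as exc:
            raise ParseError(str(exc), tok.offset) from None

    def atom(self) -> ast.QueryNode:
        tok = self._next()
        if tok.kind == "keyword":
            if tok.text == "true":
                return ast.TrueLit()
            if tok.text == "false":
                return ast.FalseLit()
            raise ParseError(f"unexpected keyword {tok.text!r}", tok.offset)
        if tok.kind == "punct" and tok.text == "(":
            node = self.expr()
            self._expect("punct", ")")
            return node
        if tok.kind != "identifier":
            raise ParseError(f"expected a predicate, found {tok.text!r}",
                             tok.offset)
        name = tok.text

        if name.endswith("?"):
            kind = name[:-1]
            if kind in ast.FLAG_BITS:
                return ast.FlagPred(kind)
            if kind == "split_pair":
                return ast.SplitPair()
            raise ParseError(f"unknown predicate {name!r}", tok.offset)

        if name in _GLOB_PREDICATES:
            self._expect("punct", "(")
            arg = self._next()
            if arg.kind != "glob-arg":
                raise ParseError("expected a glob argument", arg.offset)
            if not arg.text:
                raise ParseError(f"{name}() requires a non-empty glob",
                                 arg.offset)
            self._expect("punct", ")")
            ctor = {"chr": ast.Chr, "mate_chr": ast.MateChr,
                    "read_group": ast.ReadGroup}[name]
            return ctor(arg.text)

        if name == "header":
            self._expect("punct", "~")
            rx = self._next()
            if rx.kind != "regex-literal":
                raise ParseError("expected /regex/ after 'header ~'",
                                 rx.offset)
            return ast.HeaderRegex(rx.text)

        if name == "raw_flag":
            self._expect("punct", "(")
            mask = self._int_arg("flag mask")
            self._expect("punct", ")")
            return self._build(ast.RawFlag, (mask,), tok)
        if name == "mapping_quality":
            self._expect("punct", "(")
            p = self._prob_arg()
            self._expect("punct", ")")
            return self._build(ast.MappingQuality, (p,), tok)
        if name == "random":
            self._expect("punct", "(")
            p = self._prob_arg()
            self._expect("punct", ")")
            return self._build(ast.Random, (p,), tok)
        if name in ("after", "before"):
            self._expect("punct", "(")
            pos = self._int_arg("position")
            self._expect("punct", ")")
            ctor = ast.After if name == "after" else ast.Before
            return self._build(ctor, (pos,), tok)
        if name == "position":
            self._expect("punct", "(")
            start = self._int_arg("start position")
            self._expect("punct", ",")
            end = self._int_arg("end position")
            self._expect("punct", ")")
            return self._build(ast.PositionRange, (start, end), tok)
        if name in ("nt", "nt_exact"):
            self._expect("punct", "(")
            pos = self._int_arg("position")
            self._expect("punct", ",")
            code = self._next()
            if code.kind != "identifier" or len(code.text) != 1:
                raise ParseError(
                    f"expected an IUPAC letter, found {code.text!r}",
                    code.offset)
            self._expect("punct", ")")
            ctor = ast.Nt if name == "nt" else ast.NtExact
            return self._build(ctor, (pos, code.text.upper()), tok)

        raise ParseError(f"unknown predicate {name!r}", tok.offset)


def parse_query(text: str) -> ast.QueryNode:
    """Parse a query string to its AST, or raise :class:`ParseError`."""
    tokens = tokenize(text)
    if not tokens:
        raise ParseError("empty query", 0)
    parser = _Parser(text, tokens)
    node = parser.expr()
    trailing = parser._peek()
    if trailing is not None:
        raise ParseError(f"unexpected trailing input {trailing.text!r}",
                         trailing.offset)
    return node
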
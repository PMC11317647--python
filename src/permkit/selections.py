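"""A small deterministic atom-selection language.

Grammar (case-insensitive keywords)::

    expr     := or_expr
    or_expr  := and_expr ("or" and_expr)*
    and_expr := unary ("and" unary)*
    unary    := "not" unary | "(" expr ")" | predicate
    predicate:= "all"
              | "name"    VALUE[,VALUE...]
              | "resname" VALUE[,VALUE...]
              | "resid"   INT | INT:INT
              | "chain"   VALUE[,VALUE...]
              | "element" VALUE[,VALUE...]
              | "species" TAG[,TAG...]

The ``species`` predicate matches permkit's species tags
(``water-oxygen``, ``cation``, ...), which is why this language exists
rather than delegating to MDAnalysis.  Selections are evaluated against a
:class:`~permkit.core.Topology` and return a sorted, duplicate-free numpy
index array; an empty result is legal.
"""

from __future__ import annotations

import re

import numpy as np

from .core import SPECIES_TAGS, Topology, Trajectory

__all__ = ["select", "SelectionError"]


class SelectionError(ValueError):
    """Malformed selection expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_KEYWORDS = {"and", "or", "not", "all", "name", "resname", "resid", "chain",
             "element", "species"}


def _tokenize(expression: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expression)]


class _Parser:
    def __init__(self, expression: str, top: Topology):
        self.expr = expression
        self.tokens = _tokenize(expression)
        self.pos = 0
        self.top = top

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", len(self.expr))
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty expression", 0)
        mask = self.or_expr()
        if self.peek() is not None:
            tok, at = self.peek()
            raise SelectionError(f"unexpected token {tok!r}", at)
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() and self.peek()[0].lower() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() and self.peek()[0].lower() == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", len(self.expr))
        word, at = tok
        low = word.lower()
        if low == "not":
            self.next()
            return ~self.unary()
        if word == "(":
            self.next()
            mask = self.or_expr()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise SelectionError("missing closing parenthesis", at)
            self.next()
            return mask
        return self.predicate()

    def _values(self, keyword: str, at: int) -> list[str]:
        tok = self.peek()
        if tok is None or tok[0] == ")" or tok[0].lower() in {"and", "or", "not"}:
            raise SelectionError(f"{keyword!r} requires a value", at)
        return self.next()[0].split(",")

    def predicate(self) -> np.ndarray:
        word, at = self.next()
        low = word.lower()
        top = self.top
        n = top.n_atoms
        if low == "all":
            return np.ones(n, dtype=bool)
        if low == "name":
            vals = {v.upper() for v in self._values(low, at)}
            return np.isin(np.char.upper(top.names.astype(str)), list(vals))
        if low == "resname":
            vals = {v.upper() for v in self._values(low, at)}
            return np.isin(np.char.upper(top.resnames.astype(str)), list(vals))
        if low == "element":
            vals = {v.upper() for v in self._values(low, at)}
            return np.isin(np.char.upper(top.elements.astype(str)), list(vals))
        if low == "chain":
            vals = set(self._values(low, at))
            return np.isin(top.chains.astype(str), list(vals))
        if low == "species":
            vals = set(self._values(low, at))
            bad = vals - set(SPECIES_TAGS)
            if bad:
                raise SelectionError(f"unknown species tag {sorted(bad)[0]!r}", at)
            return np.isin(top.species.astype(str), list(vals))
        if low == "resid":
            raw = self._values(low, at)
            mask = np.zeros(n, dtype=bool)
            for item in raw:
                m = re.fullmatch(r"(-?\d+)(?::(-?\d+))?", item)
                if not m:
                    raise SelectionError(f"bad resid value {item!r}", at)
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                mask |= (top.resids >= lo) & (top.resids <= hi)
            return mask
        raise SelectionError(f"unknown keyword {word!r}", at)


def select(traj_or_top: Trajectory | Topology, expression: str) -> np.ndarray:
    """Evaluate a selection expression; returns sorted atom indices."""
    top = traj_or_top.topology if isinstance(traj_or_top, Trajectory) else traj_or_top
    mask = _Parser(expression, top).parse()
    return np.flatnonzero(mask)
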
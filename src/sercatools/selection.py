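"""Atom-selection mini-language.

Grammar (whitespace-tokenized, case-sensitive keywords)::

    expr    := or_expr
    or_expr := and_expr ("or" and_expr)*
    and_expr:= not_expr ("and" not_expr)*
    not_expr:= "not" not_expr | primary
    primary := "(" expr ")" | clause
    clause  := "resid"    range+          # 309  or  89:120  or  89-120
             | "resname"  NAME+
             | "name"     NAME+
             | "segment"  LABEL+
             | "category" CAT+            # protein | lipid | water | ion

A clause with several values matches their union, so ``name OE1 OE2``
selects both carboxyl oxygens of a glutamate.  Precedence is the usual
``not`` > ``and`` > ``or``; parentheses override.
"""

from __future__ import annotations

import numpy as np

from .core import AtomSelection, SelectionError, Topology, CATEGORIES

__all__ = ["select", "parse_error_position"]

_KEYWORDS = {"and", "or", "not", "(", ")"}
_CLAUSE_HEADS = {"resid", "resname", "name", "segment", "category"}


def _tokenize(expression: str) -> list[tuple[str, int]]:
    """Split into (token, character-position) pairs; parens self-delimit."""
    tokens: list[tuple[str, int]] = []
    i, n = 0, len(expression)
    while i < n:
        c = expression[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < n and not expression[j].isspace() and expression[j] not in "()":
            j += 1
        tokens.append((expression[i:j], i))
        i = j
    return tokens


class _Parser:
    def __init__(self, topology: Topology, expression: str):
        self.top = topology
        self.expr = expression
        self.tokens = _tokenize(expression)
        self.pos = 0

    def _err(self, msg: str) -> SelectionError:
        if self.pos < len(self.tokens):
            tok, at = self.tokens[self.pos]
            return SelectionError(f"{msg} at position {at} (near {tok!r}): {self.expr!r}")
        return SelectionError(f"{msg} at end of expression: {self.expr!r}")

    def _peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise self._err("unexpected end of expression")
        self.pos += 1
        return tok

    # --- grammar -------------------------------------------------------------
    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection expression")
        mask = self._or()
        if self._peek() is not None:
            raise self._err("unexpected trailing token")
        return mask

    def _or(self) -> np.ndarray:
        mask = self._and()
        while self._peek() == "or":
            self._next()
            mask = mask | self._and()
        return mask

    def _and(self) -> np.ndarray:
        mask = self._not()
        while self._peek() == "and":
            self._next()
            mask = mask & self._not()
        return mask

    def _not(self) -> np.ndarray:
        if self._peek() == "not":
            self._next()
            return ~self._not()
        return self._primary()

    def _primary(self) -> np.ndarray:
        tok = self._peek()
        if tok == "(":
            self._next()
            mask = self._or()
            if self._peek() != ")":
                raise self._err("expected ')'")
            self._next()
            return mask
        if tok in _CLAUSE_HEADS:
            return self._clause()
        raise self._err("expected clause or '('")

    def _clause_values(self) -> list[str]:
        vals: list[str] = []
        while True:
            tok = self._peek()
            if tok is None or tok in _KEYWORDS or tok in _CLAUSE_HEADS:
                break
            vals.append(self._next())
        if not vals:
            raise self._err("clause requires at least one value")
        return vals

    def _clause(self) -> np.ndarray:
        head = self._next()
        vals = self._clause_values()
        top = self.top
        if head == "resid":
            mask = np.zeros(top.n_atoms, dtype=bool)
            for v in vals:
                lo, hi = _parse_resid_range(v, self)
                mask |= (top.resids >= lo) & (top.resids <= hi)
            return mask
        if head == "resname":
            return np.isin(top.resnames, vals)
        if head == "name":
            return np.isin(top.names, vals)
        if head == "category":
            for v in vals:
                if v not in CATEGORIES:
                    self.pos -= 1
                    raise self._err(f"unknown category {v!r}")
            return np.isin(top.categories, vals)
        if head == "segment":
            mask = np.zeros(top.n_atoms, dtype=bool)
            for v in vals:
                try:
                    mask |= top.segment_resid_mask(v)
                except SelectionError:
                    self.pos -= 1
                    raise self._err(f"unknown segment {v!r}")
            return mask
        raise self._err(f"unknown clause {head!r}")  # pragma: no cover


def _parse_resid_range(token: str, parser: _Parser) -> tuple[int, int]:
    for sep in (":", "-"):
        if sep in token:
            a, _, b = token.partition(sep)
            try:
                lo, hi = int(a), int(b)
            except ValueError:
                parser.pos -= 1
                raise parser._err(f"bad resid range {token!r}")
            if lo > hi:
                parser.pos -= 1
                raise parser._err(f"empty resid range {token!r}")
            return lo, hi
    try:
        r = int(token)
    except ValueError:
        parser.pos -= 1
        raise parser._err(f"bad resid {token!r}")
    return r, r


def select(topology: Topology, expression: str) -> AtomSelection:
    """Evaluate a selection expression against a topology.

    Returns a deterministic, sorted :class:`AtomSelection`; an expression
    matching no atoms is legal and yields an empty selection.  Grammar
    violations raise :class:`SelectionError` with the offending position.
    """
    mask = _Parser(topology, expression).parse()
    return AtomSelection.from_mask(mask, expression)


def parse_error_position(err: SelectionError) -> int | None:
    """Extract the character position from a selection parse error, if any."""
    import re

    m = re.search(r"at position (\d+)", str(err))
    return int(m.group(1)) if m else None
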
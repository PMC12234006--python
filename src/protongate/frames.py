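"""Coordinate frames and the atom-selection mini-language.

A :class:`Frame` is a flat table of atom records (name, residue name and
number, subunit tag, element, position in Å) plus an optional orthorhombic
box. It is the substrate of the water-wire and gate-distance analyses.

Selections are written in a small boolean expression language::

    resid 14 and subunit B and name OE1 OE2
    water and not subunit A
    (resname GLU or resname ASP) and element O

Field predicates are ``name``, ``resname``, ``resid``, ``subunit`` and
``element``, each followed by one or more values (OR within a predicate).
``water`` matches the common water-oxygen dialects (atom name O/OW/OH2 in
residue HOH/SOL/TIP3/WAT) and ``hydrogen`` is shorthand for ``element H``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Frame",
    "SelectionError",
    "parse_selection",
    "select_atoms",
    "minimum_image_displacement",
    "pair_distance",
]

WATER_RESNAMES = {"HOH", "SOL", "TIP3", "WAT"}
WATER_ATOM_NAMES = {"O", "OW", "OH2"}


class SelectionError(ValueError):
    """Raised when a selection query cannot be parsed or resolved."""


def _derive_element(name: str) -> str:
    """Guess the element from an atom name: strip digits, take the leading letter.

    PDB dialects disagree on element columns; this fallback covers the
    common case (H, C, N, O, S atom names with numeric decorations).
    """
    stripped = re.sub(r"\d", "", name).strip()
    return stripped[:1].upper() if stripped else ""


@dataclass
class Frame:
    """One coordinate frame: parallel per-atom arrays plus an optional box.

    Positions are always in Å. ``box`` holds orthorhombic box lengths in Å
    when periodic boundary information is available, else ``None``.
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    subunits: np.ndarray
    positions: np.ndarray
    elements: np.ndarray | None = None
    box: np.ndarray | None = None
    index: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.subunits = np.asarray(self.subunits, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.names)
        for label, arr in (
            ("resnames", self.resnames),
            ("resids", self.resids),
            ("subunits", self.subunits),
        ):
            if len(arr) != n:
                raise ValueError(f"{label} has length {len(arr)}, expected {n}")
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"positions has shape {self.positions.shape}, expected ({n}, 3)"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite coordinates")
        if self.elements is None:
            self.elements = np.array(
                [_derive_element(str(nm)) for nm in self.names], dtype=object
            )
        else:
            self.elements = np.asarray(self.elements, dtype=object)
            blank = np.array([not str(e).strip() for e in self.elements])
            if blank.any():
                derived = [_derive_element(str(nm)) for nm in self.names]
                self.elements = np.where(blank, derived, self.elements)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or not np.all(self.box > 0):
                raise ValueError("box must be three positive orthorhombic lengths (Å)")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def select(self, query: str) -> np.ndarray:
        """Return the (sorted) indices of atoms matching a selection query."""
        return select_atoms(self, query)

    def pbc_distance(self, i: int, j: int) -> float:
        """Minimum-image distance between two atoms; requires a box."""
        if self.box is None:
            raise ValueError(
                "frame has no box: periodic (minimum-image) distances are unavailable"
            )
        return pair_distance(self.positions[i], self.positions[j], self.box)

    def __len__(self) -> int:
        return self.n_atoms


# ---------------------------------------------------------------------------
# selection language: tokenizer + recursive-descent parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")
_FIELDS = ("name", "resname", "resid", "subunit", "element")
_KEYWORDS = {"and", "or", "not", "water", "hydrogen", "all"} | set(_FIELDS)


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _Node:
    def evaluate(self, frame: Frame) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass
class _And(_Node):
    parts: list[_Node]

    def evaluate(self, frame: Frame) -> np.ndarray:
        out = np.ones(frame.n_atoms, dtype=bool)
        for p in self.parts:
            out &= p.evaluate(frame)
        return out


@dataclass
class _Or(_Node):
    parts: list[_Node]

    def evaluate(self, frame: Frame) -> np.ndarray:
        out = np.zeros(frame.n_atoms, dtype=bool)
        for p in self.parts:
            out |= p.evaluate(frame)
        return out


@dataclass
class _Not(_Node):
    inner: _Node

    def evaluate(self, frame: Frame) -> np.ndarray:
        return ~self.inner.evaluate(frame)


@dataclass
class _FieldTest(_Node):
    fieldname: str
    values: list[str]

    def evaluate(self, frame: Frame) -> np.ndarray:
        if self.fieldname == "resid":
            wanted = {int(v) for v in self.values}
            return np.array([r in wanted for r in frame.resids])
        attr = {
            "name": frame.names,
            "resname": frame.resnames,
            "subunit": frame.subunits,
            "element": frame.elements,
        }[self.fieldname]
        wanted_s = {v.upper() for v in self.values}
        return np.array([str(a).upper() in wanted_s for a in attr])


@dataclass
class _Water(_Node):
    def evaluate(self, frame: Frame) -> np.ndarray:
        return np.array(
            [
                str(rn).upper() in WATER_RESNAMES and str(nm).upper() in WATER_ATOM_NAMES
                for rn, nm in zip(frame.resnames, frame.names)
            ]
        )


@dataclass
class _All(_Node):
    def evaluate(self, frame: Frame) -> np.ndarray:
        return np.ones(frame.n_atoms, dtype=bool)


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _err(self, message: str, pos: int | None = None) -> SelectionError:
        if pos is None:
            pos = self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.text)
        return SelectionError(f"selection parse error at column {pos}: {message} (in {self.text!r})")

    def _peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise self._err("unexpected end of query")
        self.i += 1
        return tok

    def parse(self) -> _Node:
        if not self.tokens:
            raise self._err("empty query", 0)
        node = self._expr()
        if self._peek() is not None:
            raise self._err(f"unexpected token {self._peek()!r}")
        return node

    def _expr(self) -> _Node:
        parts = [self._term()]
        while self._peek() == "or":
            self._next()
            parts.append(self._term())
        return parts[0] if len(parts) == 1 else _Or(parts)

    def _term(self) -> _Node:
        parts = [self._factor()]
        while self._peek() == "and":
            self._next()
            parts.append(self._factor())
        return parts[0] if len(parts) == 1 else _And(parts)

    def _factor(self) -> _Node:
        tok = self._peek()
        if tok == "not":
            self._next()
            return _Not(self._factor())
        if tok == "(":
            self._next()
            node = self._expr()
            if self._peek() != ")":
                raise self._err("expected ')'")
            self._next()
            return node
        if tok == "water":
            self._next()
            return _Water()
        if tok == "hydrogen":
            self._next()
            return _FieldTest("element", ["H"])
        if tok == "all":
            self._next()
            return _All()
        if tok in _FIELDS:
            field_tok = self._next()
            values: list[str] = []
            while (nxt := self._peek()) is not None and nxt not in _KEYWORDS and nxt not in ("(", ")"):
                values.append(self._next())
            if not values:
                raise self._err(f"field {field_tok!r} requires at least one value")
            if field_tok == "resid":
                for v in values:
                    if not re.fullmatch(r"-?\d+", v):
                        raise self._err(f"resid value {v!r} is not an integer")
            return _FieldTest(field_tok, values)
        raise self._err(f"unexpected token {tok!r}")


def parse_selection(query: str) -> _Node:
    """Parse a selection query into an evaluable expression tree."""
    return _Parser(query).parse()


def select_atoms(frame: Frame, query: str) -> np.ndarray:
    """Evaluate a selection query, returning sorted atom indices.

    An empty result is valid; callers decide whether that is an error.
    """
    mask = parse_selection(query).evaluate(frame)
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Displacement b−a under the minimum-image convention (orthorhombic only)."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
        d = d - box * np.round(d / box)
    return d


def pair_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None = None) -> float:
    """Euclidean distance, minimum-image wrapped when a box is given."""
    return float(np.linalg.norm(minimum_image_displacement(a, b, box)))
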
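"""Elastic-degenerate strings: syntax, parsing, and matching semantics.

An elastic-degenerate string (EDS) is a sequence of ED symbols, each a
nonempty finite set of alternative strings over the DNA alphabet.  In text
form an ED symbol with several alternatives is written ``(u1|...|um)``, a
singleton alternative is written bare, and ``N`` abbreviates the four-way
alternative ``(A|C|T|G)``.  A plain string matches an EDS by choosing one
alternative per symbol; a pattern *occurs* at a 1-based text position if it
matches a prefix of what can be spelled from that position onwards.

Positions are always 1-based and refer to the textual form, so every base —
including bases inside alternatives — is addressable.  Positions holding a
syntax character (``(``, ``|``, ``)``) never carry an occurrence.

This module also hosts the small brute-force oracles (match enumeration,
exhaustive occurrence search) that the rest of the package is tested
against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator

BASES = "ACGT"
#: characters allowed inside alternatives
ALPHABET = frozenset("ACGTN")
#: syntax characters of the textual EDS form
SYNTAX = frozenset("(|)")
#: separator used between node labels in a linearized graph string
SEPARATOR = "#"

N_EXPANSION = ("A", "C", "G", "T")


class EDSParseError(ValueError):
    """Raised for malformed EDS text; carries the offending 1-based position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class OracleLimitError(RuntimeError):
    """Raised when a brute-force oracle is asked for an instance too large."""


@dataclass(frozen=True)
class EDSymbol:
    """One ED symbol: an ordered, nonempty tuple of alternatives.

    ``text_span`` is the inclusive 1-based (start, end) of the symbol in the
    textual EDS, including parentheses for multi-alternative symbols.
    """

    alternatives: tuple[str, ...]
    text_span: tuple[int, int]

    def __post_init__(self):
        if not self.alternatives:
            raise ValueError("ED symbol needs at least one alternative")

    @property
    def is_degenerate(self) -> bool:
        return len(self.alternatives) > 1

    def to_text(self) -> str:
        if self.is_degenerate:
            return "(" + "|".join(self.alternatives) + ")"
        return self.alternatives[0]


@dataclass(frozen=True)
class EDS:
    """A parsed elastic-degenerate string.

    ``length`` is the length of the textual form (syntax characters count),
    matching the convention that the length of an EDS equals its length as an
    ordinary string.
    """

    text: str
    symbols: tuple[EDSymbol, ...]
    # position (1-based) -> (symbol index, alternative index, offset in
    # alternative) for base positions; None for syntax positions.
    _posinfo: tuple = field(default=None, repr=False, compare=False)

    @property
    def length(self) -> int:
        return len(self.text)

    def __len__(self) -> int:
        return len(self.text)

    def position_info(self, p: int):
        """Return (symbol idx, alternative idx, offset) at position ``p``.

        Returns None when ``p`` addresses a syntax character.  Raises
        IndexError when ``p`` is out of range.
        """
        if not 1 <= p <= len(self.text):
            raise IndexError(f"position {p} out of range 1..{len(self.text)}")
        return self._position_table()[p - 1]

    def _position_table(self):
        table = object.__getattribute__(self, "_posinfo")
        if table is None:
            table = _build_position_table(self.symbols, len(self.text))
            object.__setattr__(self, "_posinfo", table)
        return table

    def to_text(self) -> str:
        return "".join(sym.to_text() for sym in self.symbols)


def _build_position_table(symbols, n):
    table: list = [None] * n
    for si, sym in enumerate(symbols):
        start, _end = sym.text_span
        if sym.is_degenerate:
            pos = start  # '(' position
            for ai, alt in enumerate(sym.alternatives):
                pos += 1  # skip '(' or '|'
                for off in range(len(alt)):
                    table[pos - 1 + off] = (si, ai, off)
                pos += len(alt)
        else:
            alt = sym.alternatives[0]
            for off in range(len(alt)):
                table[start - 1 + off] = (si, 0, off)
    return tuple(table)


def parse_eds(text: str) -> EDS:
    """Parse the textual EDS form into an :class:`EDS`.

    Bare characters become singleton symbols; ``(a|b|...)`` becomes one
    symbol with the alternatives in textual order (empty alternatives are
    allowed, as in ``(A|)``).  Errors name the offending 1-based position.
    """
    symbols: list[EDSymbol] = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c in ALPHABET:
            symbols.append(EDSymbol((c,), (i + 1, i + 1)))
            i += 1
        elif c == "(":
            start = i + 1
            alts: list[str] = []
            cur: list[str] = []
            j = i + 1
            while True:
                if j >= n:
                    raise EDSParseError("unbalanced '('", start)
                cj = text[j]
                if cj == "|":
                    alts.append("".join(cur))
                    cur = []
                elif cj == ")":
                    alts.append("".join(cur))
                    break
                elif cj in ALPHABET:
                    cur.append(cj)
                elif cj == "(":
                    raise EDSParseError("nested '(' not allowed", j + 1)
                else:
                    raise EDSParseError(f"illegal character {cj!r}", j + 1)
                j += 1
            symbols.append(EDSymbol(tuple(alts), (start, j + 1)))
            i = j + 1
        elif c == ")":
            raise EDSParseError("')' without matching '('", i + 1)
        elif c == "|":
            raise EDSParseError("'|' outside parentheses", i + 1)
        else:
            raise EDSParseError(f"illegal character {c!r}", i + 1)
    return EDS(text=text, symbols=tuple(symbols))


def serialize(eds: EDS) -> str:
    """Inverse of :func:`parse_eds` (identity on valid texts)."""
    return eds.to_text()


def _expand_n(s: str) -> Iterator[str]:
    """All ways of replacing every N in ``s`` with a concrete base."""
    if "N" not in s:
        yield s
        return
    parts = s.split("N")
    for combo in itertools.product(N_EXPANSION, repeat=len(parts) - 1):
        out = parts[0]
        for b, part in zip(combo, parts[1:]):
            out += b + part
        yield out


def enumerate_matches(eds: EDS, limit: int = 4096) -> set[str]:
    """Brute-force oracle: the exact set of plain strings matching ``eds``.

    N is expanded to each of A, C, G, T.  Raises :class:`OracleLimitError`
    when the number of combinations exceeds ``limit`` — the oracle is only
    meant for small instances.
    """
    count = 1
    for sym in eds.symbols:
        per = 0
        for alt in sym.alternatives:
            per += 4 ** alt.count("N")
        count *= max(per, 1)
        if count > limit:
            raise OracleLimitError(
                f"instance has more than {limit} enumerable matches"
            )
    results = {""}
    for sym in eds.symbols:
        expanded: list[str] = []
        for alt in sym.alternatives:
            expanded.extend(_expand_n(alt))
        results = {prefix + alt for prefix in results for alt in expanded}
    return results


def _base_matches(ref_char: str, pat_char: str) -> bool:
    # N in the reference is a 4-way wildcard; patterns are concrete.
    return ref_char == pat_char or ref_char == "N" or pat_char == "N"


def occurs_at(pattern: str, eds: EDS, p: int) -> bool:
    """Does ``pattern`` occur at position ``p`` of ``eds``?

    True iff some choice of alternatives in the current and subsequent
    symbols spells ``pattern`` starting at ``p``.  Always False when ``p``
    addresses a syntax character.
    """
    if not pattern:
        raise ValueError("pattern must be nonempty")
    info = eds.position_info(p)  # raises IndexError when out of range
    if info is None:
        return False
    si, ai, off = info
    suffix = eds.symbols[si].alternatives[ai][off:]
    return _match_onward(pattern, 0, suffix, eds.symbols, si + 1)


def _match_onward(pattern, k, current, symbols, next_sym) -> bool:
    """Match pattern[k:] against current alternative-suffix then symbols."""
    for c in current:
        if k == len(pattern):
            return True
        if not _base_matches(c, pattern[k]):
            return False
        k += 1
    if k == len(pattern):
        return True
    if next_sym == len(symbols):
        return False
    return any(
        _match_onward(pattern, k, alt, symbols, next_sym + 1)
        for alt in symbols[next_sym].alternatives
    )


def find_occurrences(pattern: str, eds: EDS) -> list[int]:
    """All positions of ``eds`` where ``pattern`` occurs, ascending."""
    return [p for p in range(1, len(eds) + 1) if occurs_at(pattern, eds, p)]
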
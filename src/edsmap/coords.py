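"""Coordinate system on the linearized graph string.

Every base of ``gstring`` is addressed by its 1-based offset.  A bit-vector
``I`` marks the characters that originate from the linear reference; for a
reference-origin base at position ``p`` its linear coordinate is
``rank(I, p)``, the number of ones up to and including ``p``.  Rank uses
block-precomputed popcounts, giving constant-time queries after a linear
pass.  Non-reference bases (alternative alleles, inserted sequence) project
to the nearest preceding reference base and are flagged as off-reference —
the projection is made total so that SAM records always carry a POS.

Coordinates of a cycle-free matching string are strictly increasing along
its walk; walks through self-loop edges produce one descent per jump.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eds_core import ALPHABET
from .graph_build import EDSGraph

_BLOCK = 512


class RefIndicator:
    """Bit-vector over ``gstring`` with O(1) rank support."""

    def __init__(self, bits):
        self._bits = np.asarray(bits, dtype=np.uint8)
        if self._bits.ndim != 1:
            raise ValueError("bits must be one-dimensional")
        if self._bits.size and self._bits.max() > 1:
            raise ValueError("bits must be 0/1")
        # block prefix sums: _blocks[b] = ones in bits[: b*_BLOCK]
        nblocks = self._bits.size // _BLOCK + 1
        self._blocks = np.zeros(nblocks + 1, dtype=np.int64)
        counts = np.add.reduceat(
            self._bits, np.arange(0, max(self._bits.size, 1), _BLOCK)
        ) if self._bits.size else np.array([], dtype=np.int64)
        self._blocks[1:len(counts) + 1] = np.cumsum(counts)

    def __len__(self) -> int:
        return int(self._bits.size)

    def __getitem__(self, p: int) -> int:
        """Bit at 1-based position ``p``."""
        if not 1 <= p <= len(self):
            raise IndexError(f"position {p} out of range 1..{len(self)}")
        return int(self._bits[p - 1])

    def rank1(self, p: int) -> int:
        """Number of ones in positions 1..p (``p`` = 0 allowed, gives 0)."""
        if not 0 <= p <= len(self):
            raise IndexError(f"rank position {p} out of range 0..{len(self)}")
        block, rem = divmod(p, _BLOCK)
        r = int(self._blocks[block])
        if rem:
            r += int(self._bits[block * _BLOCK: block * _BLOCK + rem].sum())
        return r

    def total_ones(self) -> int:
        return self.rank1(len(self))

    def to_01_string(self) -> str:
        return "".join("1" if b else "0" for b in self._bits)

    @classmethod
    def from_01_string(cls, s: str) -> "RefIndicator":
        return cls([1 if c == "1" else 0 for c in s])


def rank1(indicator: RefIndicator, p: int) -> int:
    """Prefix popcount of the indicator (module-level convenience)."""
    return indicator.rank1(p)


@dataclass(frozen=True)
class CoordinateProjection:
    """A gstring position projected onto the linear reference."""
    gpos: int
    chrom: str | None
    offset: int  # 1-based linear-reference coordinate
    on_reference: bool


def project(graph: EDSGraph, indicator: RefIndicator,
            p: int) -> CoordinateProjection:
    """Project gstring position ``p`` to a linear-reference coordinate.

    Reference-origin bases get their exact offset ``rank(I, p)`` (within
    their chromosome); other bases get the offset of the nearest preceding
    reference base with ``on_reference=False``.  Syntax positions are
    rejected.
    """
    if not 1 <= p <= len(graph.gstring):
        raise IndexError(f"position {p} out of range")
    if graph.gstring[p - 1] not in ALPHABET:
        raise ValueError(f"position {p} holds a syntax symbol")
    chrom_name = None
    ones_before = 0
    for chrom in graph.chromosomes:
        if chrom.gstart <= p <= chrom.gend:
            chrom_name = chrom.name
            ones_before = chrom.ones_before
            break
    r = indicator.rank1(p)
    return CoordinateProjection(
        gpos=p,
        chrom=chrom_name,
        offset=max(r - ones_before, 0),
        on_reference=bool(indicator[p]),
    )


class NoMatchError(ValueError):
    """Raised when a string does not match the graph."""


def coords_of_match(s: str, graph: EDSGraph) -> tuple[int, ...]:
    """Coordinate sequence of a string matching the whole graph.

    The walk starts at the beginning of a source node, consumes entire node
    labels (choosing one alternative per symbol), follows jump edges at
    separators, and ends at the end of a sink node.  One coordinate is
    returned per character.  When several witness walks exist, the
    lexicographically smallest coordinate sequence is returned, which makes
    the result deterministic.  Intended for testing and exposition.
    """
    view = graph.forward_view()
    failed: set[tuple[int, int]] = set()

    def walk(slot_bases, can_end, k, acc):
        if k == len(s):
            return tuple(acc) if can_end else None
        for p in slot_bases:  # ascending => lexicographically smallest
            if (p, k) in failed:
                continue
            c = view.char(p)
            if c == "N" or c == s[k]:
                nxt, end = view.next_bases(p)
                acc.append(p)
                got = walk(nxt, end, k + 1, acc)
                if got is not None:
                    return got
                acc.pop()
            failed.add((p, k))
        return None

    for source in graph.source_nodes():
        bases, can_end = view.resolve(source.gstart)
        got = walk(bases, can_end, 0, [])
        if got is not None:
            return got
    raise NoMatchError(f"string of length {len(s)} does not match the graph")
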
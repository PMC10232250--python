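"""Short-read mapping against the linearized EDS graph.

Pipeline per read: compute the read's (w,k)-minimizers, look their
positions up in the index, rank the resulting (read position, graph
position) pairs by colinear-chain length, and run a banded semi-global
edit-distance DP from the best seeds — forward from the seed to the read
end and backward to the read start, with the seed cell pinned.

The DP runs column-wise over the graph text.  Alternatives need no
branching: a column at ``(`` or ``|`` is a copy of the column immediately
preceding the ED symbol, and the column at ``)`` is the element-wise
minimum over the columns at the ends of all alternatives (cached as the
scan passes them).  Only separators branch: at ``#`` the computation
continues at every jump-edge successor, each branch inheriting the current
column, explored depth-first under a shared best-so-far bound.  Cells are
kept only while their value is at most the error bound ``d`` and (when
pruning is enabled) strictly below the best complete alignment found so
far; disabling pruning never changes the optimal distance.

The whole read is always aligned (no clipping); ``N`` in the graph matches
any base at zero cost.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, replace

from .coords import CoordinateProjection, RefIndicator, project
from .eds_core import ALPHABET, SEPARATOR
from .graph_build import EDSGraph, TextView
from .minimizer_index import (
    DEFAULT_K, DEFAULT_W, MinimizerIndex, N_CAP, min_kmer_with_N,
    select_minimizers,
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MappingParams:
    """Tunable mapping parameters.

    ``lam`` (the chaining window) defaults to twice the read length and
    ``d`` (the error bound) to ceil(0.1 * read length) when left as None.
    """

    k: int = DEFAULT_K
    w: int = DEFAULT_W
    hash_mode: str = "lex"
    lam: int | None = None
    d: int | None = None
    max_seeds: int = 10
    ncap: int = N_CAP
    prune: bool = True

    def lam_for(self, read_len: int) -> int:
        return self.lam if self.lam is not None else 2 * read_len

    def d_for(self, read_len: int) -> int:
        return self.d if self.d is not None else math.ceil(0.1 * read_len)


@dataclass
class SeedPair:
    """A minimizer match: read position ``i`` vs gstring position ``j``."""
    i: int
    j: int
    score: int = 1


@dataclass(frozen=True)
class PartialAlignment:
    """One direction of a seed extension."""
    distance: int
    gpos: int      # forward: last aligned gstring position; backward: first
    ops: tuple[str, ...]  # per-base edit ops, M/I/D, in left-to-right order


@dataclass(frozen=True)
class AlignmentResult:
    """Best semi-global alignment of a whole read."""
    distance: int
    g_start: int
    g_end: int
    cigar: str
    strand: str  # '+' or '-'
    seed: tuple[int, int]
    projected: CoordinateProjection | None = None


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def read_minimizers(read: str, k: int, w: int, hash_mode: str = "lex",
                    ncap: int = N_CAP) -> list[tuple[str, int]]:
    """Standard single-string (w,k)-minimizers of a read.

    Returns ``(kmer, position)`` pairs ascending by position; empty when
    the read is shorter than ``k``.  Uses the same hash mode (and N
    handling) as the graph index.
    """
    read = read.upper()
    n = len(read)
    if n < k:
        return []
    minima = []
    for p in range(1, n - k + 2):
        m = min_kmer_with_N((read[p - 1: p - 1 + k],), hash_mode, ncap)
        if m is not None:
            minima.append((p, m[0], m[1]))
    marked = select_minimizers(minima, w, length=n)
    return [(km, pos) for pos, km in marked]


def collect_pairs(read_mins: list[tuple[str, int]],
                  index: MinimizerIndex) -> list[SeedPair]:
    """Look up read minimizers in the index; pairs sorted by (j, i)."""
    pairs = []
    for km, i in read_mins:
        for j in index.query(km):
            pairs.append((j, i))
    return [SeedPair(i=i, j=j) for j, i in sorted(set(pairs))]


def chain_scores(pairs: list[SeedPair], lam: int) -> list[SeedPair]:
    """Score each pair by its longest colinear chain within a λ-window.

    Pairs must be sorted by ``j``.  For each batch start ℓ the maximal
    batch [ℓ, ℓ'] with ``j_{ℓ'} - j_ℓ < lam`` is scored by a longest
    increasing subsequence over read positions (strict increase in both
    coordinates); a pair's score is its best over all batches.  Scores are
    written in place and the list returned.
    """
    m = len(pairs)
    js = [p.j for p in pairs]
    for p in pairs:
        p.score = 1
    prev_end = -1
    for lo in range(m):
        hi = bisect_right(js, js[lo] + lam - 1) - 1
        if hi == prev_end and lo > 0:
            continue  # sub-batch of the previous one: scores can't improve
        prev_end = hi
        _lis_scores(pairs, lo, hi)
    return pairs


def _lis_scores(pairs, lo, hi):
    """Patience-style LIS on pairs[lo..hi] (sorted by j), strict in i and j."""
    iranks = sorted({p.i for p in pairs[lo: hi + 1]})
    rank = {v: r for r, v in enumerate(iranks)}
    tree = [0] * (len(iranks) + 1)  # Fenwick max-tree over i-ranks

    def update(r, val):
        r += 1
        while r <= len(iranks):
            if tree[r] < val:
                tree[r] = val
            r += r & (-r)

    def query(r):  # max over ranks < r
        best = 0
        while r > 0:
            if tree[r] > best:
                best = tree[r]
            r -= r & (-r)
        return best

    t = lo
    while t <= hi:
        u = t
        while u <= hi and pairs[u].j == pairs[t].j:
            u += 1
        group = []
        for v in range(t, u):
            s = 1 + query(rank[pairs[v].i])
            group.append(s)
            if s > pairs[v].score:
                pairs[v].score = s
        for v, s in zip(range(t, u), group):
            update(rank[pairs[v].i], s)
        t = u


# ---------------------------------------------------------------------------
# Banded DP engine
# ---------------------------------------------------------------------------

class _Col:
    """One DP column with enough structure to trace an alignment back."""
    __slots__ = ("j", "kind", "cells", "srcs", "ch")

    def __init__(self, j, kind, cells, srcs=(), ch=""):
        self.j = j
        self.kind = kind      # start | virtual | base | copy | min
        self.cells = cells    # {rows consumed: cost}
        self.srcs = srcs      # predecessor column(s)
        self.ch = ch


class _Best:
    __slots__ = ("cost", "col")

    def __init__(self):
        self.cost = None
        self.col = None


def _match_cost(text_char: str, read_char: str) -> int:
    return 0 if (text_char == read_char or text_char == "N") else 1


def _run_dp(pattern: str, view: TextView, start: int, *, pinned: bool,
            bound: int, prune: bool = True, trace: list | None = None,
            trace_map=None):
    """Semi-global DP of ``pattern`` against ``view`` starting at ``start``.

    When ``pinned``, ``start`` must be a base position and pattern[0] is
    forced to align with it; otherwise ``start`` is the first text slot and
    the alignment may also consume no text at all.  Returns the best
    complete column (all of ``pattern`` consumed) via a ``_Best`` holder,
    or None if no alignment within ``bound`` exists.
    """
    m = len(pattern)
    best = _Best()

    def limit():
        if prune and best.cost is not None:
            return min(bound, best.cost - 1)
        return bound

    def note_complete(col):
        v = col.cells.get(m)
        if v is None:
            return
        if trace is not None and col.kind == "base":
            trace.append((trace_map(col.j) if trace_map else col.j, v))
        if best.cost is None or v < best.cost:
            best.cost = v
            best.col = col

    def scan(j, prev, cache, pending, no_progress):
        text = view.text
        while j <= len(text):
            c = text[j - 1]
            if c in ALPHABET:
                lim = limit()
                cells = {}
                pc = prev.cells
                lo_row = 1 if pinned else 0
                for row in range(lo_row, m + 1):
                    val = None
                    if row >= 1:
                        diag = pc.get(row - 1)
                        if diag is not None:
                            val = diag + _match_cost(c, pattern[row - 1])
                        vert = cells.get(row - 1)
                        if vert is not None and (val is None or vert + 1 < val):
                            val = vert + 1
                    horiz = pc.get(row)
                    if horiz is not None and (val is None or horiz + 1 < val):
                        val = horiz + 1
                    if val is not None and val <= lim:
                        cells[row] = val
                if not cells:
                    close = view.close_of(j)
                    if not close:
                        return  # dead outside any symbol: branch over
                    # dead inside an alternative: skip to the next
                    # alternative boundary; the cached column revives there
                    bar = text.find("|", j, close - 1)
                    j = (bar + 1) if bar != -1 else close
                    prev = _Col(j, "base", {}, (prev,), c)
                    continue
                col = _Col(j, "base", cells, (prev,), c)
                note_complete(col)
                prev, j = col, j + 1
                no_progress = None
            elif c == "(":
                cache = prev
                pending = []
                prev = _Col(j, "copy", prev.cells, (prev,))
                j += 1
            elif c == "|":
                if cache is None:
                    # entered mid-alternative: later alternatives unreachable
                    j = view.close_of(j)
                else:
                    pending.append(prev)
                    prev = _Col(j, "copy", cache.cells, (cache,))
                    j += 1
            elif c == ")":
                pending = pending + [prev]
                lim = limit()
                cells = {}
                for src in pending:
                    for r, v in src.cells.items():
                        if v <= lim and (r not in cells or v < cells[r]):
                            cells[r] = v
                if not cells:
                    return  # the whole symbol is dead
                prev = _Col(j, "min", cells, tuple(pending))
                cache, pending = None, []
                j += 1
            elif c == SEPARATOR:
                col = _Col(j, "copy", prev.cells, (prev,))
                seen = no_progress or frozenset()
                for t in view.jumps.get(j, ()):
                    if (j, t) in seen:
                        continue  # zero-consumption cycle guard
                    scan(t, col, None, [], seen | {(j, t)})
                return
            else:  # pragma: no cover - graph strings contain no other chars
                raise ValueError(f"unexpected character {c!r} in graph text")

    if pinned:
        pin = _match_cost(view.text[start - 1], pattern[0])
        cells = {row: pin + (row - 1) for row in range(1, m + 1)
                 if pin + (row - 1) <= bound}
        if not cells:
            return best
        col = _Col(start, "start", cells, ())
        note_complete(col)
        scan(start + 1, col, None, [], None)
    else:
        cells = {row: row for row in range(0, m + 1) if row <= bound}
        col = _Col(start - 1, "virtual", cells, ())
        note_complete(col)
        scan(start, col, None, [], None)
    return best


def _traceback(col: _Col, pattern: str) -> list[str]:
    """Edit ops (M/I/D) from a complete DP cell, emitted end-to-start."""
    ops: list[str] = []
    row = len(pattern)
    while True:
        c = col.cells[row]
        if col.kind == "start":
            ops.extend("I" * (row - 1))
            ops.append("M")
            break
        if col.kind == "virtual":
            ops.extend("I" * row)
            break
        if col.kind == "base":
            prev = col.srcs[0]
            diag = prev.cells.get(row - 1) if row >= 1 else None
            if diag is not None and \
                    diag + _match_cost(col.ch, pattern[row - 1]) == c:
                ops.append("M")
                col, row = prev, row - 1
                continue
            vert = col.cells.get(row - 1)
            if vert is not None and vert + 1 == c:
                ops.append("I")
                row -= 1
                continue
            horiz = prev.cells.get(row)
            if horiz is not None and horiz + 1 == c:
                ops.append("D")
                col = prev
                continue
            raise AssertionError("broken traceback")  # pragma: no cover
        # copy / min columns: zero-cost jump to a source with equal value
        for src in col.srcs:
            if src.cells.get(row) == c:
                col = src
                break
        else:  # pragma: no cover
            raise AssertionError("broken traceback through symbol column")
    return ops


def compress_cigar(ops) -> str:
    if not ops:
        return "*"
    out = []
    run, prev = 0, None
    for op in ops:
        if op == prev:
            run += 1
        else:
            if prev is not None:
                out.append(f"{run}{prev}")
            prev, run = op, 1
    out.append(f"{run}{prev}")
    return "".join(out)


# ---------------------------------------------------------------------------
# Public alignment operations
# ---------------------------------------------------------------------------

def align_forward(read: str, graph: EDSGraph, i_star: int, j_star: int,
                  d: int, prune: bool = True,
                  trace: list | None = None) -> PartialAlignment | None:
    """Align ``read[i_star..]`` forward from gstring position ``j_star``.

    ``read[i_star]`` is forced to align with ``gstring[j_star]`` (which
    must hold a base).  Returns the minimum-error partial alignment with
    distance <= ``d``, or None when the bound is exceeded.  ``trace``, if
    given, collects ``(gstring column, final-row value)`` whenever a
    complete alignment is observed in a base column.
    """
    view = graph.forward_view()
    if view.text[j_star - 1] not in ALPHABET:
        raise ValueError(f"seed position {j_star} is not a base")
    pattern = read.upper()[i_star - 1:]
    best = _run_dp(pattern, view, j_star, pinned=True, bound=d,
                   prune=prune, trace=trace)
    if best.cost is None:
        return None
    ops = _traceback(best.col, pattern)
    ops.reverse()
    return PartialAlignment(best.cost, best.col.j, tuple(ops))


def align_backward(read: str, graph: EDSGraph, i_star: int, j_star: int,
                   d_remaining: int,
                   prune: bool = True) -> PartialAlignment | None:
    """Align ``read[1..i_star-1]`` ending immediately before ``j_star``.

    Mirrors the forward direction on the reversed view, following backward
    jump edges at separators.  The empty prefix aligns with distance 0.
    """
    view = graph.backward_view()
    pattern = read.upper()[: i_star - 1][::-1]
    start = graph.mirror_position(j_star) + 1  # slot left of j_star, mirrored
    best = _run_dp(pattern, view, start, pinned=False, bound=d_remaining,
                   prune=prune)
    if best.cost is None:
        return None
    ops = _traceback(best.col, pattern)  # already in real left-to-right order
    if best.col.kind == "virtual":
        lo = j_star  # no text consumed: alignment starts at the seed
    else:
        lo = graph.mirror_position(best.col.j)
    return PartialAlignment(best.cost, lo, tuple(ops))


def map_read(read: str, graph: EDSGraph, index: MinimizerIndex,
             params: MappingParams | None = None,
             indicator: RefIndicator | None = None) -> AlignmentResult | None:
    """Map one read; returns the best alignment or None when unmapped.

    Seeds are tried in order of decreasing chain score on both the read
    and its reverse complement; the first seed whose full-read alignment
    stays within the error bound stops the search for that strand.  Ties
    between strands/positions go to the smaller distance, then the smaller
    gstring start, then the forward strand.
    """
    params = params or MappingParams()
    read = read.upper()
    n = len(read)
    if n == 0:
        return None
    d = params.d_for(n)
    lam = params.lam_for(n)
    best: AlignmentResult | None = None

    for strand, seq in (("+", read), ("-", revcomp(read))):
        mins = read_minimizers(seq, params.k, params.w,
                               params.hash_mode, params.ncap)
        pairs = chain_scores(collect_pairs(mins, index), lam)
        seeds = sorted(pairs, key=lambda p: (-p.score, p.j, p.i))
        for seed in seeds[: params.max_seeds]:
            bound = d if best is None else min(d, best.distance - 1)
            if bound < 0:
                break
            fwd = align_forward(seq, graph, seed.i, seed.j, bound,
                                prune=params.prune)
            if fwd is None:
                continue
            bwd = align_backward(seq, graph, seed.i, seed.j,
                                 bound - fwd.distance, prune=params.prune)
            if bwd is None:
                continue
            total = fwd.distance + bwd.distance
            lo, hi = bwd.gpos, fwd.gpos
            cand = AlignmentResult(
                distance=total, g_start=lo, g_end=hi,
                cigar=compress_cigar(list(bwd.ops) + list(fwd.ops)),
                strand=strand, seed=(seed.i, seed.j))
            if best is None or (cand.distance, cand.g_start) < \
                    (best.distance, best.g_start):
                best = cand
            if total <= d:
                break  # satisfying alignment: stop trying lower-score seeds
    if best is None:
        return None
    if indicator is not None:
        best = replace(best, projected=project(graph, indicator, best.g_start))
    return best
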
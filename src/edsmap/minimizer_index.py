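"""(w,k)-minimizer index over the linearized EDS graph.

At a single position of an EDS graph there can be many k-mers (one per
combination of alternatives and jump edges downstream).  The per-position
k-mer sets are computed in one right-to-left scan of each node label: in
the plain case the set at position ``p`` is obtained by prepending the
character at ``p`` to every string of the set at ``p+1`` and truncating to
``k``; two auxiliary sets handle ED symbols (the set saved at the symbol's
right boundary re-seeds every alternative, and a union accumulated over
alternative ends is released at the symbol's left boundary).  Node scans
are seeded across jump edges with the k-mer sets starting at their
successors, so k-mers spanning edges are attributed to their start
position.

From the per-position minimum k-mers, a window of ``w`` consecutive
gstring positions slides along and the smallest entry per window is marked;
the marked k-mers with their sorted position lists form the index.
Over-frequent minimizers (postings longer than a trim threshold) are
removed.  N is kept literally in the sets and expanded to each concrete
base only when hashing; k-mers with more than ``N_CAP`` Ns are ignored.

Hashing is pluggable: ``lex`` uses the lexicographic rank of the k-mer
(used by all worked examples), ``mix`` scrambles the rank with a 64-bit
mixing function.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Iterable

from .eds_core import EDS
from .graph_build import EDSGraph, TextView

DEFAULT_K = 20
DEFAULT_W = 5
DEFAULT_TRIM = 512
#: k-mers containing more than this many N are ignored (keeps the
#: hash-time expansion at most 16-fold)
N_CAP = 2

MAX_K = 32

HASH_MODES = ("lex", "mix")

_BASE_RANK = {"A": 0, "C": 1, "G": 2, "T": 3}
_EXPANSION = ("A", "C", "G", "T")


def _splitmix64(x: int) -> int:
    """Deterministic 64-bit mixing function."""
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


def kmer_hash(kmer: str, mode: str = "lex") -> int:
    """Hash of a concrete k-mer (no N allowed).

    ``lex`` returns the lexicographic rank itself (base-4 encoding A=0,
    C=1, G=2, T=3), so smaller hash = lexicographically smaller k-mer;
    ``mix`` scrambles that rank through a 64-bit mixer.
    """
    rank = 0
    for c in kmer:
        try:
            rank = (rank << 2) | _BASE_RANK[c]
        except KeyError:
            raise ValueError(f"k-mer contains non-ACGT character {c!r}") from None
    if mode == "lex":
        return rank
    if mode == "mix":
        return _splitmix64(rank)
    raise ValueError(f"unknown hash mode {mode!r}")


def _expansions(kmer: str) -> Iterable[str]:
    i = kmer.find("N")
    if i == -1:
        yield kmer
        return
    for b in _EXPANSION:
        yield from _expansions(kmer[:i] + b + kmer[i + 1:])


def min_kmer_with_N(kmers: Iterable[str], mode: str = "lex",
                    ncap: int = N_CAP) -> tuple[str, int] | None:
    """Minimum-hash k-mer over all N-expansions of the given k-mers.

    Strings with more than ``ncap`` Ns are skipped; returns None when all
    candidates are skipped.
    """
    best: tuple[int, str] | None = None
    for km in kmers:
        if km.count("N") > ncap:
            continue
        for concrete in _expansions(km):
            h = kmer_hash(concrete, mode)
            if best is None or (h, concrete) < best:
                best = (h, concrete)
    if best is None:
        return None
    return best[1], best[0]


def _scan_label_minima(label: str, k: int, boundary: frozenset[str],
                       mode: str, ncap: int,
                       offset: int = 0) -> list[tuple[int, str, int]]:
    """Right-to-left k-mer-set scan of one EDS label.

    ``boundary`` is the set of continuation strings starting one past the
    label end (across the following jump edges; ``{""}`` when the walk ends
    there).  Returns ``(offset+p, kmer, hash)`` for every base position
    with a valid k-mer, ascending by position.
    """
    cur: set[str] = {s[:k] for s in boundary} or {""}
    saved_r: set[str] = set()
    acc_l: set[str] = set()
    out: list[tuple[int, str, int]] = []
    for p in range(len(label), 0, -1):
        c = label[p - 1]
        if c == ")":
            saved_r = cur
            acc_l = set()
        elif c == "|":
            acc_l |= cur
            cur = saved_r
        elif c == "(":
            acc_l |= cur
            cur = acc_l
            saved_r = set()
            acc_l = set()
        else:
            cur = {(c + s)[:k] for s in cur}
            m = min_kmer_with_N((s for s in cur if len(s) == k), mode, ncap)
            if m is not None:
                out.append((offset + p, m[0], m[1]))
    out.reverse()
    return out


def position_minima(eds: EDS | str, k: int,
                    boundary: frozenset[str] | None = None,
                    mode: str = "lex",
                    ncap: int = N_CAP) -> list[tuple[int, str, int]]:
    """Per-position minimum k-mers of a plain EDS (no graph edges).

    ``boundary`` optionally supplies the continuation set one past the end
    (as a graph node would receive); by default the text simply ends there.
    """
    text = eds.text if isinstance(eds, EDS) else eds
    return _scan_label_minima(text, k, boundary or frozenset({""}),
                              mode, ncap, offset=0)


def _strings_from_slot(view: TextView, slot: int, maxlen: int) -> set[str]:
    """Strings of length <= maxlen spelled starting at a text slot."""
    bases, can_end = view.resolve(slot)
    strings: set[str] = set()
    if can_end:
        strings.add("")
    for p in bases:
        strings.update(view.spell_strings(p, maxlen))
    return strings


def graph_position_minima(graph: EDSGraph, k: int, mode: str = "lex",
                          ncap: int = N_CAP) -> list[tuple[int, str, int]]:
    """Per-position minimum k-mers over the whole linearized graph.

    Each node label is scanned right to left, seeded across its outgoing
    jump edges with the union of the k-mer sets starting at its successors,
    so k-mers spanning edges are found at their start position.
    """
    view = graph.forward_view()
    out: list[tuple[int, str, int]] = []
    for idx, node in enumerate(graph.nodes):
        following_sep = idx + 1 if idx + 1 <= graph.n_separators else None
        boundary: set[str] = {""}
        if following_sep is not None and graph.fwd_edges.get(following_sep):
            sep_pos = graph.separator_position(following_sep)
            boundary = _strings_from_slot(view, sep_pos, k - 1)
        out.extend(_scan_label_minima(node.label, k, frozenset(boundary),
                                      mode, ncap, offset=node.gstart - 1))
    return out


def select_minimizers(minima: list[tuple[int, str, int]], w: int,
                      length: int | None = None) -> list[tuple[int, str]]:
    """Slide a window of ``w`` consecutive positions; mark the minimum.

    ``minima`` must be ascending by position.  Windows cover positions
    ``[s, s+w-1]`` for every s with the window inside ``[1, length]``
    (syntax positions simply contribute no k-mer); ties on the hash go to
    the leftmost position.  Returns the marked ``(position, kmer)`` pairs,
    ascending by position.
    """
    if length is None:
        length = minima[-1][0] if minima else 0
    if not minima or length <= 0:
        return []
    from collections import deque

    entry_at = {p: (h, km) for p, km, h in minima}
    marked: set[tuple[int, str]] = set()
    dq: deque[tuple[int, int, str]] = deque()  # (hash, pos, kmer)

    def push(pos: int):
        e = entry_at.get(pos)
        if e is None:
            return
        h, km = e
        while dq and dq[-1][0] > h:
            dq.pop()
        dq.append((h, pos, km))

    last_start = max(1, length - w + 1)
    hi = 0
    for s in range(1, last_start + 1):
        w_end = min(s + w - 1, length)
        while hi < w_end:
            hi += 1
            push(hi)
        while dq and dq[0][1] < s:
            dq.popleft()
        if dq:
            _, pos, km = dq[0]
            marked.add((pos, km))
    return sorted(marked)


@dataclass
class MinimizerIndex:
    """Map from k-mer to the ascending gstring positions it is marked at."""

    k: int
    w: int
    trim_threshold: int
    hash_mode: str
    postings: dict[str, tuple[int, ...]]
    graph_checksum: str = ""
    format_version: int = 1

    def query(self, kmer: str) -> tuple[int, ...]:
        return self.postings.get(kmer, ())

    def __len__(self) -> int:
        return len(self.postings)

    def n_positions(self) -> int:
        return sum(len(p) for p in self.postings.values())

    # -- serialization (documented JSON layout, bit-exact round trip) -------

    def to_json(self) -> str:
        return json.dumps({
            "format": "edsmap-minimizer-index",
            "version": self.format_version,
            "k": self.k,
            "w": self.w,
            "trim_threshold": self.trim_threshold,
            "hash_mode": self.hash_mode,
            "graph_checksum": self.graph_checksum,
            "postings": {km: list(p) for km, p in sorted(self.postings.items())},
        }, separators=(",", ":"))

    @classmethod
    def from_json(cls, data: str) -> "MinimizerIndex":
        obj = json.loads(data)
        if obj.get("format") != "edsmap-minimizer-index":
            raise ValueError("not a minimizer index file")
        return cls(
            k=int(obj["k"]), w=int(obj["w"]),
            trim_threshold=int(obj["trim_threshold"]),
            hash_mode=obj["hash_mode"],
            postings={km: tuple(p) for km, p in obj["postings"].items()},
            graph_checksum=obj.get("graph_checksum", ""),
            format_version=int(obj.get("version", 1)),
        )

    def save(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "MinimizerIndex":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def graph_checksum(graph: EDSGraph) -> str:
    """Checksum tying an index file to the graph it was built from."""
    h = hashlib.sha256()
    h.update(graph.gstring.encode())
    for s in sorted(graph.fwd_edges):
        h.update(f"{s}:{sorted(graph.fwd_edges[s])}".encode())
    return h.hexdigest()[:16]


def build_index(graph: EDSGraph, k: int = DEFAULT_K, w: int = DEFAULT_W,
                trim_threshold: int = DEFAULT_TRIM,
                hash_mode: str = "lex", ncap: int = N_CAP) -> MinimizerIndex:
    """Compute the (w,k)-minimizer index of a linearized EDS graph."""
    if k < 1 or w < 1 or trim_threshold < 1:
        raise ValueError("k, w and trim_threshold must be positive")
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K}")
    if hash_mode not in HASH_MODES:
        raise ValueError(f"hash mode must be one of {HASH_MODES}")
    minima = graph_position_minima(graph, k, hash_mode, ncap)
    marked = select_minimizers(minima, w, length=len(graph.gstring))
    postings: dict[str, list[int]] = {}
    for pos, km in marked:
        postings.setdefault(km, []).append(pos)
    trimmed = {
        km: tuple(sorted(set(p)))
        for km, p in postings.items()
        if len(set(p)) <= trim_threshold
    }
    return MinimizerIndex(k=k, w=w, trim_threshold=trim_threshold,
                          hash_mode=hash_mode, postings=trimmed,
                          graph_checksum=graph_checksum(graph))
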
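"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against the *textual* form of the
graph (a regex tokenizer plus naive recursion), independent of the package's
own traversal machinery, so that agreement between the two is meaningful.
"""

from __future__ import annotations

import re
import random

import edlib

_SYMBOL_RE = re.compile(r"\([^()]*\)|[ACGTN]")


def tokenize_label(label: str, offset: int = 0):
    """Split a label into symbols: list of lists of (alt_string, start_pos).

    ``offset`` is the 0-based position of the label inside the full string.
    """
    symbols = []
    pos = 0
    for m in _SYMBOL_RE.finditer(label):
        assert m.start() == pos, f"cannot tokenize {label!r} at {pos}"
        tok = m.group(0)
        if tok.startswith("("):
            alts = []
            astart = m.start() + 1
            for alt in tok[1:-1].split("|"):
                alts.append((alt, offset + astart + 1))  # 1-based
                astart += len(alt) + 1
            symbols.append(alts)
        else:
            symbols.append([(tok, offset + m.start() + 1)])
        pos = m.end()
    assert pos == len(label)
    return symbols


class ToyGraph:
    """Tokenized view of a linearized graph string for brute-force walks."""

    def __init__(self, gstring: str, edges=()):
        self.gstring = gstring
        self.labels = gstring.split("#")
        self.offsets = []
        off = 0
        for lab in self.labels:
            self.offsets.append(off)
            off += len(lab) + 1
        self.symbols = [tokenize_label(lab, o)
                        for lab, o in zip(self.labels, self.offsets)]
        self.edges: dict[int, list[int]] = {}
        for s, t in edges:
            self.edges.setdefault(s, []).append(t)

    def locate(self, p: int):
        """(label idx, symbol idx, alt idx, offset) of base position p."""
        for li, syms in enumerate(self.symbols):
            for si, alts in enumerate(syms):
                for ai, (alt, start) in enumerate(alts):
                    if start <= p < start + len(alt):
                        return li, si, ai, p - start
        return None

    def maximal_strings_from(self, p: int, maxlen: int) -> set[str]:
        """All strings spelled from base position ``p``, each either of
        length ``maxlen`` or ending where the walk can end."""
        loc = self.locate(p)
        if loc is None:
            return set()
        li, si, ai, off = loc
        out: set[str] = set()
        suffix = self.symbols[li][si][ai][0][off:]
        self._walk(li, si, suffix, "", maxlen, out)
        return out

    def _walk(self, li, si, current, acc, maxlen, out, depth=0):
        if depth > 4 * maxlen + 16:  # zero-consumption cycle guard
            return
        take = current[: maxlen - len(acc)]
        acc += take
        if len(acc) == maxlen:
            out.add(acc)
            return
        if si + 1 < len(self.symbols[li]):
            for alt, _ in self.symbols[li][si + 1]:
                self._walk(li, si + 1, alt, acc, maxlen, out, depth + 1)
        else:
            targets = self.edges.get(li + 1, [])
            if not targets:
                out.add(acc)  # walk ends here
                return
            for t in targets:
                for alt, _ in self.symbols[t][0]:
                    self._walk(t, 0, alt, acc, maxlen, out, depth + 1)


def wild_eq(a: str, b: str) -> bool:
    return len(a) == len(b) and all(
        x == y or x == "N" or y == "N" for x, y in zip(a, b))


def occurs_at_bruteforce(pattern: str, graph: ToyGraph, p: int) -> bool:
    """Def-4 occurrence on the graph by exhaustive path enumeration."""
    for s in graph.maximal_strings_from(p, len(pattern)):
        if len(s) >= len(pattern) and wild_eq(s[: len(pattern)], pattern):
            return True
    return False


def naive_text_minimizers(text: str, k: int, w: int, hash_fn):
    """Standard single-string (w,k)-minimizer scheme, naively."""
    n = len(text)
    entries = {}
    for p in range(1, n - k + 2):
        km = text[p - 1: p - 1 + k]
        if "N" in km:
            continue
        entries[p] = (hash_fn(km), km)
    marked = set()
    for s in range(1, max(1, n - w + 1) + 1):
        window = [(h, p, km) for p, (h, km) in entries.items()
                  if s <= p <= min(s + w - 1, n)]
        if window:
            h, p, km = min(window)
            marked.add((p, km))
    return sorted(marked)


def quadratic_chain_scores(pairs, lam):
    """O(x^2) colinear chaining DP: best chain ending at each pair whose
    members all lie within a λ-window of graph positions."""
    m = len(pairs)
    best = [1] * m
    for t in range(m):
        # chains ending at t: members need j in (j_t - lam, j_t]
        scores = {}
        for u in range(t + 1):
            if pairs[t].j - pairs[u].j >= lam:
                continue
            s = 1
            for v in range(u):
                if pairs[t].j - pairs[v].j >= lam:
                    continue
                if pairs[v].i < pairs[u].i and pairs[v].j < pairs[u].j:
                    s = max(s, scores[v] + 1)
            scores[u] = s
        best[t] = scores[t]
    return best


def pinned_forward_oracle(pattern: str, graph: ToyGraph, j_star: int,
                          d: int) -> int | None:
    """Minimum forward alignment cost by enumerating all path strings.

    Equals min over spelled strings T from j_star of
    pin(pattern[0], T[0]) + SHW(pattern[1:], T[1:]); None when > d.
    """
    maxlen = len(pattern) + d + 2
    best = None
    for t in graph.maximal_strings_from(j_star, maxlen):
        if not t:
            continue
        pin = 0 if (t[0] == pattern[0] or t[0] == "N") else 1
        if len(pattern) > 1:
            rest = edlib.align(pattern[1:], t[1:], mode="SHW")["editDistance"]
        else:
            rest = 0
        cost = pin + rest
        if best is None or cost < best:
            best = cost
    if best is None or best > d:
        return None
    return best


# ---------------------------------------------------------------------------
# Random instance generators (always explicitly seeded by the caller)
# ---------------------------------------------------------------------------

def random_eds_text(rng: random.Random, max_symbols: int = 8,
                    allow_n: bool = True, allow_empty: bool = True) -> str:
    out = []
    for _ in range(rng.randint(1, max_symbols)):
        if rng.random() < 0.3:
            n_alt = rng.randint(2, 3)
            alts = []
            for _ in range(n_alt):
                length = rng.randint(0 if allow_empty else 1, 3)
                alts.append("".join(rng.choice("ACGT") for _ in range(length)))
            if not any(alts):
                alts[0] = rng.choice("ACGT")
            out.append("(" + "|".join(alts) + ")")
        else:
            pool = "ACGTN" if allow_n and rng.random() < 0.15 else "ACGT"
            out.append(rng.choice(pool))
    return "".join(out)


def random_graph_text(rng: random.Random, max_nodes: int = 3,
                      allow_n: bool = True, allow_empty: bool = True):
    """A random linearized graph: (gstring, edge list)."""
    n_nodes = rng.randint(1, max_nodes)
    labels = [random_eds_text(rng, max_symbols=rng.randint(1, 6),
                              allow_n=allow_n, allow_empty=allow_empty)
              for _ in range(n_nodes)]
    edges = []
    for i in range(n_nodes - 1):
        edges.append((i + 1, i + 1))  # consecutive chain edge
    if n_nodes == 3:
        if rng.random() < 0.5:
            edges.append((2, 1))  # self-loop on the middle node
        if rng.random() < 0.3:
            edges.append((1, 2))  # bypass edge around the middle node
    return "#".join(labels), edges
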
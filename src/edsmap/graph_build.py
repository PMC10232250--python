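"""Build an EDS graph from a reference and variants, and linearize it.

Small variants (SNPs, short indels, short replacements) are written in place
as ED symbols whose first alternative is the reference allele.  Structural
variants become graph structure: a copy-number variation over ``[i, j]``
splits the sequence into three nodes (left flank, repeatable middle, right
flank) with a self-loop on the middle; a large deletion gets a bypass edge
around the deleted span; a large insertion becomes an optional node with a
bypass edge.

The graph is stored linearized: ``gstring`` is the concatenation of all node
labels in linear-reference order, separated by ``#``.  Separators are
numbered 1..S left to right and ``sep(v)`` is the number of the separator
immediately before node ``v`` (0 for the first node).  For every graph edge
``(v, v')`` a jump edge ``sep(v)+1 -> sep(v')`` is stored, together with its
transpose for backward traversal.  A bit-vector over ``gstring`` marks which
characters originate from the linear reference; its rank structure lives in
:mod:`edsmap.coords`.

Overlap policy is strict left-to-right greedy keep-first: structural
variants are reserved first, small variants whose reference span would cross
a node-split boundary are dropped (splits must not fall inside parenthesized
symbols), and remaining small variants are kept left to right.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .eds_core import ALPHABET, EDSParseError, SEPARATOR, parse_eds

logger = logging.getLogger("edsmap")

#: indels with a reference/alternate length difference of at least this many
#: bases become graph edges instead of in-place ED symbols
STRUCTURAL_THRESHOLD = 20

# variant classes
SNP = "snp"
SMALL = "small_indel_or_alternative"
CNV = "cnv"
LARGE_DELETION = "large_deletion"
LARGE_INSERTION = "large_insertion"


@dataclass(frozen=True)
class VariantRecord:
    """One classified variant.

    ``pos`` is the 1-based position of the first reference base of the
    record (VCF POS).  For symbolic structural alleles the affected region
    is ``[pos+1, end]`` (POS holds the padding base, per VCF convention).
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    cls: str
    end: int | None = None  # inclusive reference end of an SV region
    cn_bounds: tuple[int, int] | None = None

    @property
    def ref_span(self) -> tuple[int, int]:
        """Inclusive 1-based reference span occupied by this record."""
        if self.cls in (CNV, LARGE_DELETION) and self.end is not None:
            return (self.pos, self.end)
        return (self.pos, self.pos + len(self.ref) - 1)


_UNSUPPORTED_SVTYPES = {"INV", "BND", "TRA"}


def classify_variants(records) -> tuple[list[VariantRecord], Counter]:
    """Classify raw variant tuples into :class:`VariantRecord` objects.

    ``records`` yields ``(chrom, pos, ref, alts, info)`` with ``info`` a
    mapping (SVTYPE/END/CN are honoured).  Unsupported or malformed records
    are skipped, never fatal; the returned Counter tallies skip reasons.
    """
    kept: list[VariantRecord] = []
    skipped: Counter = Counter()
    for rec in records:
        try:
            chrom, pos, ref, alts, info = rec
            alts = tuple(a for a in alts if a is not None and a != ".")
            if not alts:
                skipped["no_alt"] += 1
                continue
            ref = (ref or "").upper()
            classified = _classify_one(chrom, int(pos), ref, alts, info or {})
        except Exception:  # malformed record: skip with warning, never abort
            logger.warning("skipping malformed variant record: %r", rec)
            skipped["malformed"] += 1
            continue
        if isinstance(classified, str):
            skipped[classified] += 1
        else:
            kept.append(classified)
    return kept, skipped


def _classify_one(chrom, pos, ref, alts, info):
    """Return a VariantRecord, or a string naming the skip reason."""
    symbolic = [a for a in alts if a.startswith("<")]
    if symbolic:
        if len(alts) > 1:
            return "multiallelic_symbolic"
        alt = symbolic[0].strip("<>").upper()
        svtype = str(info.get("SVTYPE", alt.split(":")[0])).upper()
        if svtype in _UNSUPPORTED_SVTYPES or alt.startswith("INS:ME"):
            return "unsupported_svtype"
        end = info.get("END")
        if svtype in ("DUP", "CNV") or alt.startswith("CN"):
            if end is None:
                return "sv_missing_end"
            cn = _cn_bounds(alt, info)
            return VariantRecord(chrom, pos, ref, alts, CNV,
                                 end=int(end), cn_bounds=cn)
        if svtype == "DEL":
            if end is None:
                return "sv_missing_end"
            return VariantRecord(chrom, pos, ref, alts, LARGE_DELETION,
                                 end=int(end))
        if svtype == "INS":
            seq = info.get("SEQ")
            if not seq:
                return "insertion_without_sequence"
            return VariantRecord(chrom, pos, ref, (ref + str(seq).upper(),),
                                 LARGE_INSERTION)
        return "unsupported_svtype"
    # concrete alleles
    alts = tuple(a.upper() for a in alts)
    if not ref or any(not a for a in alts):
        return "empty_allele"
    if not set(ref) <= ALPHABET or any(not set(a) <= ALPHABET for a in alts):
        return "non_acgtn_allele"
    if len(ref) == 1 and all(len(a) == 1 for a in alts):
        return VariantRecord(chrom, pos, ref, alts, SNP)
    size = max(abs(len(ref) - len(a)) for a in alts)
    if size < STRUCTURAL_THRESHOLD:
        return VariantRecord(chrom, pos, ref, alts, SMALL)
    if len(alts) > 1:
        return "multiallelic_structural"
    alt = alts[0]
    if len(ref) > len(alt):
        q = _common_prefix_len([ref, alt])
        if alt != ref[: len(alt)] or q < len(alt):
            return "complex_structural"
        # deleted region: the part of REF not retained by ALT
        return VariantRecord(chrom, pos, ref, alts, LARGE_DELETION,
                             end=pos + len(ref) - 1)
    if ref != alt[: len(ref)]:
        return "complex_structural"
    return VariantRecord(chrom, pos, ref, alts, LARGE_INSERTION)


def _cn_bounds(alt, info):
    cn = info.get("CN")
    if cn is not None:
        try:
            if isinstance(cn, (tuple, list)):
                vals = [int(c) for c in cn]
                return (min(vals), max(vals))
            return (int(cn), int(cn))
        except (TypeError, ValueError):
            return None
    if alt.startswith("CN"):
        try:
            n = int(alt[2:])
            return (n, n)
        except ValueError:
            return None
    return None


def _common_prefix_len(strings) -> int:
    if not strings:
        return 0
    q = 0
    shortest = min(len(s) for s in strings)
    while q < shortest and len({s[q] for s in strings}) == 1:
        q += 1
    return q


def _common_suffix_len(strings, max_keep) -> int:
    q = 0
    shortest = min(min(len(s) for s in strings), max_keep)
    while q < shortest and len({s[-1 - q] for s in strings}) == 1:
        q += 1
    return q


def build_eds(ref: str, small_variants: list[VariantRecord],
              offset: int = 1) -> tuple[str, list[int], int]:
    """Encode a reference segment plus its small variants as EDS text.

    ``ref`` is the segment sequence; ``offset`` its 1-based coordinate on
    the chromosome; ``small_variants`` must be sorted by position and lie
    within the segment.  Returns ``(text, flags, dropped)`` where ``flags``
    holds one 0/1 reference-origin flag per text character (1 exactly for
    reference-allele characters and inter-variant sequence) and ``dropped``
    counts variants removed by the greedy overlap rule or allele mismatch.

    The reference allele is always the first alternative of a symbol; the
    shared flanks of REF/ALT alleles are emitted as plain sequence so that
    e.g. a deletion ``GA>G`` serializes as ``G(A|)``, not ``(GA|G)``.
    """
    out: list[str] = []
    flags: list[int] = []
    cursor = offset  # next reference coordinate to emit
    end_excl = offset + len(ref)
    dropped = 0

    def emit_ref(upto: int):
        nonlocal cursor
        if upto > cursor:
            chunk = ref[cursor - offset: upto - offset]
            out.append(chunk)
            flags.extend([1] * len(chunk))
            cursor = upto

    for var in small_variants:
        a, b = var.ref_span
        if a < cursor:  # overlaps a previously kept variant: greedy drop
            dropped += 1
            continue
        if a < offset or b >= end_excl:
            dropped += 1
            continue
        if ref[a - offset: b - offset + 1] != var.ref:
            logger.warning(
                "variant at %s:%d REF %r does not match reference; skipped",
                var.chrom, var.pos, var.ref)
            dropped += 1
            continue
        alleles = [var.ref] + [alt for alt in var.alts if alt != var.ref]
        p = _common_prefix_len(alleles)
        s = _common_suffix_len(alleles, max_keep=min(len(x) for x in alleles) - p)
        cores = []
        for al in alleles:
            core = al[p: len(al) - s] if s else al[p:]
            if core not in cores:
                cores.append(core)
        emit_ref(a)
        if p:
            out.append(var.ref[:p])
            flags.extend([1] * p)
        if len(cores) > 1:
            out.append("(" + "|".join(cores) + ")")
            flags.append(0)  # '('
            for idx, core in enumerate(cores):
                flags.extend([1 if idx == 0 else 0] * len(core))
                flags.append(0)  # '|' or ')'
        elif cores[0]:
            out.append(cores[0])
            flags.extend([1] * len(cores[0]))
        if s:
            out.append(var.ref[len(var.ref) - s:])
            flags.extend([1] * s)
        cursor = b + 1
    emit_ref(end_excl)
    return "".join(out), flags, dropped


# ---------------------------------------------------------------------------
# Graph assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Node:
    """One node of the EDS graph, located inside ``gstring``."""
    label: str
    gstart: int  # 1-based first character of the label in gstring
    gend: int    # 1-based last character
    sep: int     # number of the '#' immediately before the label (0 if none)
    chrom: str | None
    is_insertion: bool = False


@dataclass(frozen=True)
class Chromosome:
    name: str
    ref_len: int
    gstart: int
    gend: int
    ones_before: int  # reference bases in gstring before this chromosome


class TextView:
    """A traversal view of a linearized graph string.

    Provides the navigation primitives shared by indexing, alignment,
    sampling and coordinate walks: resolving the next base positions from a
    text slot (skipping syntax, branching into alternatives, following jump
    edges at separators) and spelling bounded-length strings.  The mapper
    uses a second, mirrored view for backward traversal.
    """

    def __init__(self, text: str, jumps: dict[int, tuple[int, ...]]):
        self.text = text
        self.jumps = jumps  # '#' position -> continuation slots
        n = len(text)
        close_of = [0] * (n + 2)
        open_pos = 0
        for i, c in enumerate(text, start=1):
            if c == "(":
                open_pos = i
            elif c == ")":
                for j in range(open_pos, i + 1):
                    close_of[j] = i
        self._close_of = close_of

    def char(self, p: int) -> str:
        return self.text[p - 1]

    def close_of(self, p: int) -> int:
        return self._close_of[p]

    def resolve(self, q: int, _seen=None) -> tuple[tuple[int, ...], bool]:
        """Base positions reachable from slot ``q`` without consuming a base.

        Returns ``(positions, can_end)``; ``can_end`` is True when a walk
        may terminate here (past the end of the text, or at a separator with
        no outgoing jump edge).  Positions are ascending.
        """
        text = self.text
        if q > len(text):
            return (), True
        c = text[q - 1]
        if c in ALPHABET:
            return (q,), False
        if c == ")":
            return self.resolve(q + 1, _seen)
        if c == "|":
            return self.resolve(self._close_of[q] + 1, _seen)
        if c == "(":
            close = self._close_of[q]
            bases: list[int] = []
            can_end = False
            slot = q + 1
            while slot <= close:
                if text[slot - 1] in ("|", ")"):
                    # empty alternative: falls through past ')'
                    b, e = self.resolve(close + 1, _seen)
                    bases.extend(b)
                    can_end = can_end or e
                else:
                    bases.append(slot)
                nxt = text.find("|", slot - 1, close)
                slot = (nxt + 2) if nxt != -1 else close + 1
            return tuple(sorted(set(bases))), can_end
        if c == SEPARATOR:
            seen = _seen if _seen is not None else set()
            if q in seen:
                return (), False
            seen.add(q)
            targets = self.jumps.get(q, ())
            if not targets:
                return (), True
            bases: list[int] = []
            can_end = False
            for t in targets:
                b, e = self.resolve(t, seen)
                bases.extend(b)
                can_end = can_end or e
            return tuple(sorted(set(bases))), can_end
        raise ValueError(f"unexpected character {c!r} at position {q}")

    def next_bases(self, p: int) -> tuple[tuple[int, ...], bool]:
        """Continuations after consuming the base at position ``p``."""
        return self.resolve(p + 1)

    def spell_strings(self, pos: int, k: int) -> frozenset[str]:
        """All strings of length ``<= k`` spelled from base position ``pos``.

        Strings shorter than ``k`` appear only where the walk can end.
        N is kept literally.
        """
        memo: dict[tuple[int, int], frozenset[str]] = {}

        def go(p: int, need: int) -> frozenset[str]:
            if need == 0:
                return frozenset({""})
            key = (p, need)
            if key in memo:
                return memo[key]
            memo[key] = frozenset()  # cycle guard (zero-consumption loops)
            c = self.text[p - 1]
            nxt, can_end = self.next_bases(p)
            tails: set[str] = set()
            if can_end:
                tails.add("")
            for q in nxt:
                tails.update(go(q, need - 1))
            result = frozenset(c + t for t in tails)
            memo[key] = result
            return result

        return go(pos, k)

    def occurs_from(self, pattern: str, pos: int) -> bool:
        """Does ``pattern`` spell from base position ``pos`` (N wildcard)?"""
        if not pattern:
            return True
        if pos > len(self.text) or self.text[pos - 1] not in ALPHABET:
            return False
        seen: set[tuple[int, int]] = set()

        def go(p: int, k: int) -> bool:
            if (p, k) in seen:
                return False
            seen.add((p, k))
            c = self.text[p - 1]
            if c != "N" and pattern[k] != "N" and c != pattern[k]:
                return False
            if k + 1 == len(pattern):
                return True
            nxt, _ = self.next_bases(p)
            return any(go(q, k + 1) for q in nxt)

        return go(pos, 0)


class EDSGraph:
    """A linearized EDS graph: ``gstring`` plus jump edges and node table."""

    def __init__(self, gstring: str, nodes: list[Node],
                 fwd_edges: dict[int, frozenset[int]],
                 chromosomes: list[Chromosome] | None = None):
        self.gstring = gstring
        self.nodes = list(nodes)
        self.fwd_edges = {s: frozenset(d) for s, d in fwd_edges.items() if d}
        bwd: dict[int, set[int]] = {}
        for s, dsts in self.fwd_edges.items():
            for d in dsts:
                bwd.setdefault(d, set()).add(s)
        self.bwd_edges = {d: frozenset(s) for d, s in bwd.items()}
        self.sep_positions = tuple(
            i for i, c in enumerate(gstring, start=1) if c == SEPARATOR)
        self.chromosomes = list(chromosomes or [])
        self._fwd_view: TextView | None = None
        self._bwd_view: TextView | None = None
        self._validate()

    # -- construction helpers ------------------------------------------------

    def _validate(self):
        n_sep = len(self.sep_positions)
        for s, dsts in self.fwd_edges.items():
            if not 1 <= s <= n_sep:
                raise ValueError(f"edge source separator {s} out of range")
            for d in dsts:
                if not 1 <= d <= n_sep:
                    raise ValueError(f"edge target separator {d} out of range")
        for node in self.nodes:
            parse_eds(node.label)  # raises EDSParseError on bad labels

    @classmethod
    def from_gstring(cls, gstring: str,
                     edges: list[tuple[int, int]] = (),
                     chrom: str = "ref") -> "EDSGraph":
        """Build a graph directly from a linearized string and edge list.

        Labels are the ``#``-separated pieces; ``edges`` are
        ``(source separator, target separator)`` number pairs.  Used by the
        file loader and by worked examples/tests.
        """
        labels = gstring.split(SEPARATOR)
        nodes = []
        pos = 1
        for idx, label in enumerate(labels):
            if not label:
                raise EDSParseError("empty node label", pos)
            nodes.append(Node(label=label, gstart=pos,
                              gend=pos + len(label) - 1, sep=idx, chrom=chrom))
            pos += len(label) + 1
        fwd: dict[int, set[int]] = {}
        for s, d in edges:
            fwd.setdefault(s, set()).add(d)
        return cls(gstring, nodes, {s: frozenset(d) for s, d in fwd.items()})

    # -- basic queries -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.gstring)

    @property
    def n_separators(self) -> int:
        return len(self.sep_positions)

    def separator_position(self, s: int) -> int:
        if not 1 <= s <= len(self.sep_positions):
            raise KeyError(f"unknown separator {s}")
        return self.sep_positions[s - 1]

    def successors_after_separator(self, s: int) -> tuple[int, ...]:
        """Positions immediately after each separator reachable from ``s``."""
        self.separator_position(s)
        return tuple(sorted(self.separator_position(d) + 1
                            for d in self.fwd_edges.get(s, ())))

    def predecessors_before_separator(self, s: int) -> tuple[int, ...]:
        """Positions immediately before each separator with an edge to ``s``."""
        self.separator_position(s)
        return tuple(sorted(self.separator_position(a) - 1
                            for a in self.bwd_edges.get(s, ())))

    def node_at(self, p: int) -> Node:
        """The node whose label span contains gstring position ``p``."""
        for node in self.nodes:
            if node.gstart <= p <= node.gend:
                return node
        raise IndexError(f"position {p} is not inside any node label")

    def source_nodes(self) -> list[Node]:
        has_incoming = {d for dsts in self.fwd_edges.values() for d in dsts}
        return [v for v in self.nodes if v.sep not in has_incoming]

    def sink_nodes(self) -> list[Node]:
        has_outgoing = set()
        for s, dsts in self.fwd_edges.items():
            if dsts:
                has_outgoing.add(s - 1)  # edges from s leave the node with sep s-1
        return [v for v in self.nodes if v.sep not in has_outgoing]

    # -- traversal views -----------------------------------------------------

    def forward_view(self) -> TextView:
        if self._fwd_view is None:
            jumps = {}
            for s in range(1, self.n_separators + 1):
                jumps[self.separator_position(s)] = \
                    self.successors_after_separator(s)
            self._fwd_view = TextView(self.gstring, jumps)
        return self._fwd_view

    def backward_view(self) -> TextView:
        """Mirrored view: text reversed with parentheses swapped.

        Position ``t`` in the mirrored view corresponds to gstring position
        ``len(g)+1-t``.  Jump targets at a separator numbered ``b`` are the
        mirrored positions of the last label characters of nodes with an
        edge into ``b``.
        """
        if self._bwd_view is None:
            n = len(self.gstring)
            swap = {"(": ")", ")": "("}
            rtext = "".join(swap.get(c, c) for c in reversed(self.gstring))
            jumps = {}
            for b in range(1, self.n_separators + 1):
                rpos = n + 1 - self.separator_position(b)
                jumps[rpos] = tuple(sorted(
                    n + 1 - p for p in self.predecessors_before_separator(b)))
            self._bwd_view = TextView(rtext, jumps)
        return self._bwd_view

    def mirror_position(self, p: int) -> int:
        """Map between gstring coordinates and backward-view coordinates."""
        return len(self.gstring) + 1 - p


def build_graph(reference: dict[str, str],
                variants: list[VariantRecord]) -> tuple[EDSGraph, list[int], Counter]:
    """Assemble the EDS graph for a (multi-chromosome) reference.

    ``reference`` maps chromosome name to sequence, in output order.
    Returns ``(graph, indicator_bits, dropped)`` where ``indicator_bits``
    has one 0/1 entry per gstring character (1 = originates from the linear
    reference) and ``dropped`` tallies variants lost to overlap handling.
    """
    dropped: Counter = Counter()
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if v.chrom not in reference:
            dropped["unknown_chromosome"] += 1
            continue
        by_chrom.setdefault(v.chrom, []).append(v)

    all_nodes: list[tuple[str, list[int], str, bool]] = []  # label, flags, chrom, is_ins
    chrom_meta: list[tuple[str, int, int, int]] = []  # name, len, first/last node idx
    edge_pairs: list[tuple[int, int]] = []  # node-index edges

    for chrom, seq in reference.items():
        seq = seq.upper()
        chrom_vars = sorted(by_chrom.get(chrom, ()), key=lambda v: v.pos)
        svs = [v for v in chrom_vars
               if v.cls in (CNV, LARGE_DELETION, LARGE_INSERTION)]
        smalls = [v for v in chrom_vars if v.cls in (SNP, SMALL)]

        kept_svs: list[VariantRecord] = []
        last_end = 0
        for sv in svs:
            a, b = _sv_region(sv)
            if a <= last_end:
                dropped["sv_overlap"] += 1
                continue
            if a < 1 or b > len(seq) or a > b + 1:
                dropped["sv_out_of_range"] += 1
                continue
            kept_svs.append(sv)
            last_end = b
        cuts: set[int] = set()  # cut between x and x+1
        for sv in kept_svs:
            a, b = _sv_region(sv)
            if sv.cls == LARGE_INSERTION:
                cuts.add(b)  # single cut at the insertion point
            else:
                cuts.add(a - 1)
                cuts.add(b)
        cuts.discard(0)
        cuts.discard(len(seq))
        # small variants crossing a cut would put a split inside a symbol
        usable_smalls = []
        for v in smalls:
            a, b = v.ref_span
            if any(a <= x < b for x in cuts):
                dropped["small_at_sv_boundary"] += 1
            else:
                usable_smalls.append(v)

        boundaries = sorted(cuts)
        seg_edges = [1] + [x + 1 for x in boundaries]  # segment start coords
        seg_spans = [(s, e) for s, e in
                     zip(seg_edges, boundaries + [len(seq)])]

        first_node_idx = len(all_nodes)
        seg_node: dict[tuple[int, int], int] = {}
        prev_idx: int | None = None
        ins_after: dict[int, VariantRecord] = {}
        for sv in kept_svs:
            if sv.cls == LARGE_INSERTION:
                a, _ = _sv_region(sv)
                ins_after[a] = sv
        for span in seg_spans:
            s, e = span
            if s > e:
                continue
            seg_vars = [v for v in usable_smalls if s <= v.pos <= e]
            label, flags, d = build_eds(seq[s - 1:e], seg_vars, offset=s)
            dropped["small_overlap_or_mismatch"] += d
            if not label:
                continue
            idx = len(all_nodes)
            all_nodes.append((label, flags, chrom, False))
            seg_node[span] = idx
            if prev_idx is not None:
                edge_pairs.append((prev_idx, idx))
            prev_idx = idx
            if e in ins_after:
                sv = ins_after[e]
                ins_seq = sv.alts[0][len(sv.ref):]
                ins_idx = len(all_nodes)
                all_nodes.append((ins_seq, [0] * len(ins_seq), chrom, True))
                edge_pairs.append((idx, ins_idx))
                # edge ins -> next segment is wired in the second pass
                ins_after[e] = (sv, ins_idx)  # type: ignore[assignment]
        # second pass: wire SV edges now that segment nodes are known
        for sv in kept_svs:
            a, b = _sv_region(sv)
            left = seg_node.get(_span_ending_at(seg_spans, a - 1))
            mid = seg_node.get((a, b))
            right = seg_node.get(_span_starting_at(seg_spans, b + 1))
            if sv.cls == CNV and mid is not None:
                edge_pairs.append((mid, mid))
            elif sv.cls == LARGE_DELETION:
                if left is not None and right is not None:
                    edge_pairs.append((left, right))
            elif sv.cls == LARGE_INSERTION:
                entry = ins_after.get(a)
                if isinstance(entry, tuple):
                    _, ins_idx = entry
                    if right is not None:
                        edge_pairs.append((ins_idx, right))
        chrom_meta.append((chrom, len(seq), first_node_idx, len(all_nodes) - 1))

    if not all_nodes:
        raise ValueError("reference produced no graph nodes")

    # linearize
    labels = [label for label, _, _, _ in all_nodes]
    gstring = SEPARATOR.join(labels)
    bits: list[int] = []
    nodes: list[Node] = []
    pos = 1
    for idx, (label, flags, chrom, is_ins) in enumerate(all_nodes):
        if idx > 0:
            bits.append(0)  # '#'
        nodes.append(Node(label=label, gstart=pos, gend=pos + len(label) - 1,
                          sep=idx, chrom=chrom, is_insertion=is_ins))
        bits.extend(flags)
        pos += len(label) + 1
    fwd: dict[int, set[int]] = {}
    for u, v in set(edge_pairs):
        fwd.setdefault(u + 1, set()).add(v)  # sep(u)+1 -> sep(v); sep(v)=v
    chromosomes = []
    ones_before = 0
    for name, ref_len, first, last in chrom_meta:
        chromosomes.append(Chromosome(
            name=name, ref_len=ref_len,
            gstart=nodes[first].gstart, gend=nodes[last].gend,
            ones_before=ones_before))
        ones_before += ref_len
    graph = EDSGraph(gstring, nodes,
                     {s: frozenset(d) for s, d in fwd.items()}, chromosomes)
    return graph, bits, dropped


def _sv_region(sv: VariantRecord) -> tuple[int, int]:
    """The affected reference region [a, b] of a structural variant."""
    if sv.cls == CNV:
        return (sv.pos + 1, sv.end) if sv.alts[0].startswith("<") \
            else (sv.pos, sv.end)
    if sv.cls == LARGE_DELETION:
        if sv.alts[0].startswith("<"):
            return (sv.pos + 1, sv.end)
        q = len(sv.alts[0])
        return (sv.pos + q, sv.pos + len(sv.ref) - 1)
    # large insertion: insertion point after the last REF base
    p = sv.pos + len(sv.ref) - 1
    return (p, p)


def _span_ending_at(spans, e):
    for span in spans:
        if span[1] == e:
            return span
    return None


def _span_starting_at(spans, s):
    for span in spans:
        if span[0] == s:
            return span
    return None
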
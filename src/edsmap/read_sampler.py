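"""Truth-tracked synthetic reads from an EDS graph, and mapping evaluation.

The sampling model: a read starts at a base position of the linearized
graph drawn uniformly at random; walking forward, one alternative is chosen
uniformly at each ED symbol and one jump edge uniformly at each separator.
Sequencing errors are then applied per base — substitution, insertion and
deletion are three independent channels, each hitting a base with the same
per-base probability (default 0.1%).  Substitutions draw uniformly from the
three other bases; insertions add a uniform base after the current one.
Every read records the gstring coordinate it was sampled from, so mapping
accuracy can be scored without external truth data.

A small synthetic-pangenome helper generates a random reference plus a
variant set (SNPs, short indels, one copy-number variation) with densities
echoing a human cohort VCF, for end-to-end parameter-recovery experiments.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

from .eds_core import ALPHABET, BASES
from .graph_build import EDSGraph, build_graph, classify_variants

logger = logging.getLogger("edsmap")

DEFAULT_ERROR_RATE = 0.001  # per base, per error channel


@dataclass(frozen=True)
class SampledRead:
    """One synthetic read with its ground truth."""
    read_id: str
    sequence: str
    truth_gpos: int            # gstring coordinate of the first sampled base
    truth_linear: int | None   # projected linear coordinate (optional)
    errors: tuple[tuple[int, str, str], ...]  # (offset, type, base)


def _walk(view, start: int, length: int, rng: random.Random) -> str | None:
    """Spell ``length`` bases from ``start``, choosing branches uniformly."""
    out = [view.char(start)]
    pos = start
    while len(out) < length:
        bases, can_end = view.next_bases(pos)
        if not bases:
            return None  # walk ended before reaching the requested length
        pos = bases[rng.randrange(len(bases))] if len(bases) > 1 else bases[0]
        out.append(view.char(pos))
    return "".join(out)


def _apply_errors(seq: str, error_rate: float, rng: random.Random):
    """Independent substitution/insertion/deletion channels per base."""
    out: list[str] = []
    errors: list[tuple[int, str, str]] = []
    for off, c in enumerate(seq):
        if rng.random() < error_rate:  # deletion
            errors.append((off, "del", c))
            continue
        if rng.random() < error_rate:  # substitution
            alt = rng.choice([b for b in BASES if b != c]) if c in BASES \
                else rng.choice(BASES)
            errors.append((off, "sub", alt))
            out.append(alt)
        else:
            out.append(c)
        if rng.random() < error_rate:  # insertion after this base
            ins = rng.choice(BASES)
            errors.append((off, "ins", ins))
            out.append(ins)
    return "".join(out), tuple(errors)


def sample_reads(graph: EDSGraph, n: int, length: int,
                 error_rate: float = DEFAULT_ERROR_RATE,
                 rng_seed: int = 0,
                 id_prefix: str = "read") -> list[SampledRead]:
    """Draw ``n`` truth-tracked reads of ``length`` bases from the graph.

    Start positions are uniform over base positions that admit a full-length
    walk (a start too close to a dead end is redrawn).  Fully reproducible
    from ``rng_seed``.  When the graph cannot produce enough full-length
    walks, fewer than ``n`` reads are returned with a warning.
    """
    if length < 1:
        raise ValueError("read length must be >= 1")
    if not 0 <= error_rate < 1:
        raise ValueError("error rate must be in [0, 1)")
    rng = random.Random(rng_seed)
    view = graph.forward_view()
    base_positions = [p for p, c in enumerate(graph.gstring, start=1)
                      if c in ALPHABET]
    if not base_positions:
        return []
    reads: list[SampledRead] = []
    attempts = 0
    max_attempts = 50 * n + 100
    while len(reads) < n and attempts < max_attempts:
        attempts += 1
        start = base_positions[rng.randrange(len(base_positions))]
        clean = _walk(view, start, length, rng)
        if clean is None:
            continue
        # N in the pangenome stands for any base: emit a concrete one
        clean = "".join(c if c != "N" else rng.choice(BASES) for c in clean)
        seq, errors = _apply_errors(clean, error_rate, rng)
        if not seq:
            continue
        reads.append(SampledRead(
            read_id=f"{id_prefix}{len(reads)}",
            sequence=seq, truth_gpos=start, truth_linear=None,
            errors=errors))
    if len(reads) < n:
        logger.warning("graph too short: sampled %d of %d requested reads",
                       len(reads), n)
    return reads


@dataclass
class AccuracyReport:
    """Mapping-rate and accuracy summary of a truth-tracked read set."""
    n_reads: int
    n_mapped: int
    n_accurate: int
    tolerance: int

    @property
    def mapping_rate(self) -> float:
        return self.n_mapped / self.n_reads if self.n_reads else 0.0

    @property
    def accuracy(self) -> float:
        return self.n_accurate / self.n_reads if self.n_reads else 0.0


def evaluate(truth: list[SampledRead],
             mappings: dict[str, int | None],
             tolerance: int = 10) -> AccuracyReport:
    """Score reported positions against the sampling truth.

    ``mappings`` maps read id to the reported gstring start coordinate
    (None = unmapped).  A read is accurate when its reported position is
    within ``tolerance`` of the position it was sampled from, compared on
    gstring coordinates.  Raises KeyError when a truth read id is missing
    from ``mappings``.
    """
    n_mapped = 0
    n_accurate = 0
    for sr in truth:
        if sr.read_id not in mappings:
            raise KeyError(f"no mapping entry for read {sr.read_id!r}")
        got = mappings[sr.read_id]
        if got is None:
            continue
        n_mapped += 1
        if abs(got - sr.truth_gpos) <= tolerance:
            n_accurate += 1
    return AccuracyReport(n_reads=len(truth), n_mapped=n_mapped,
                         n_accurate=n_accurate, tolerance=tolerance)


# ---------------------------------------------------------------------------
# Synthetic pangenome
# ---------------------------------------------------------------------------

def synthetic_pangenome(ref_length: int = 10_000,
                        snp_rate: float = 0.025,
                        indel_rate: float = 0.001,
                        n_cnv: int = 1,
                        cnv_length: int = 300,
                        rng_seed: int = 0,
                        chrom: str = "chr1"):
    """A random reference plus variants, assembled into an EDS graph.

    Variant densities default to roughly those of a human cohort call set
    (about 2.5% of positions carry a SNP, 0.1% a short indel) plus
    ``n_cnv`` copy-number variations of ``cnv_length`` bases.  Returns
    ``(graph, indicator_bits, reference, variants)``.
    """
    rng = random.Random(rng_seed)
    ref = "".join(rng.choice(BASES) for _ in range(ref_length))
    raw: list[tuple] = []
    # CNVs first: reserve evenly spread regions away from the ends
    cnv_regions: list[tuple[int, int]] = []
    for c in range(n_cnv):
        lo = (c + 1) * ref_length // (n_cnv + 1)
        start = min(lo, ref_length - cnv_length - 2)
        if start < 2:
            break
        cnv_regions.append((start, start + cnv_length - 1))
        raw.append((chrom, start - 1, ref[start - 2], ("<DUP>",),
                    {"SVTYPE": "DUP", "END": start + cnv_length - 1}))
    in_cnv_margin = set()
    for a, b in cnv_regions:
        in_cnv_margin.update(range(a - 1, a + 1))
        in_cnv_margin.update(range(b, b + 2))
    p = 1
    while p <= ref_length:
        if p in in_cnv_margin:
            p += 1
            continue
        r = rng.random()
        if r < snp_rate:
            refb = ref[p - 1]
            alt = rng.choice([b for b in BASES if b != refb])
            raw.append((chrom, p, refb, (alt,), {}))
            p += 1
        elif r < snp_rate + indel_rate and p + 6 < ref_length:
            ilen = rng.randint(1, 5)
            if rng.random() < 0.5:  # deletion of ilen bases after p
                refa = ref[p - 1: p + ilen]
                if p + ilen - 1 in in_cnv_margin or \
                        any(a <= p + ilen and p <= b for a, b in cnv_regions):
                    p += 1
                    continue
                raw.append((chrom, p, refa, (refa[0],), {}))
                p += ilen + 1
            else:  # insertion after p
                ins = "".join(rng.choice(BASES) for _ in range(ilen))
                raw.append((chrom, p, ref[p - 1], (ref[p - 1] + ins,), {}))
                p += 2
        else:
            p += 1
    variants, _skipped = classify_variants(raw)
    graph, bits, _dropped = build_graph({chrom: ref}, variants)
    return graph, bits, {chrom: ref}, variants
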
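# edsmap

Short-read mapping to a pangenome represented as a graph of
elastic-degenerate strings (EDS).

## The problem

Mapping reads against a single linear reference biases every downstream
analysis toward the reference allele: a read carrying a known variant picks
up spurious mismatches and may be placed wrongly or not at all.  Pangenome
mappers avoid this by aligning against a reference *plus* its known
variation, but general sequence-graph indexes are heavyweight.  `edsmap`
targets the middle ground: almost all variation in a cohort VCF consists of
SNPs and short indels, which can be written *in place* in the sequence, so
that ordinary string indexing works almost unchanged.

An **ED string** is a sequence of symbols, each a finite set of alternative
strings: `NG(A|)CA(AT|TA)GA` has an optional `A`, an `AT`/`TA` alternative,
and `N` ≡ `(A|C|T|G)`.  A plain string *matches* by choosing one
alternative per symbol.  Small variants become ED symbols whose first
alternative is the reference allele.  Structural variants (copy-number
variations, large indels) become graph structure: the sequence is split
into nodes, a CNV gets a self-loop, a large indel a bypass edge.  The node
labels are concatenated with `#` separators into one string **G^**, and
edges are stored as pairs of separator numbers — so every base keeps a
plain 1-based coordinate, and:

* a bit-vector **I** marks reference-origin characters; `rank(I, p)`
  projects a G^ coordinate back onto the linear reference;
* a standard **(w,k)-minimizer index** applies directly: the set of k-mers
  occurring at each position (there can be several, one per combination of
  alternatives and edges) is computed in one right-to-left scan, the
  minimum per position is selected, and a window of `w` positions slides
  over them;
* reads are seeded by minimizer hits ranked by **colinear chain** length
  (longest increasing subsequence within a λ-window), and extended with a
  **banded semi-global edit-distance DP** adapted to the syntax: columns at
  `(` and `|` copy the column before the symbol, the column at `)` is the
  element-wise minimum over alternative ends, and only `#` branches the
  computation along jump edges.  The whole read is aligned (no clipping)
  under an error bound `d`, forward and backward from the seed.

## Worked example

The running example used throughout the code: reference `TTNGACAATGAT`
with a deletion (`GA>G`), a replacement (`AT>TA`) and a CNV spanning
positions 3–11 yields `G^ = TT#NG(A|)CA(AT|TA)GA#T` with jump edges
`1→1, 2→1 (self-loop), 2→2`.

```python
>>> import edsmap as em
>>> eds = em.parse_eds("NG(A|)CA(AT|TA)GA")
>>> eds.length
17
>>> em.find_occurrences("GACA", eds)
[2]
>>> g = em.EDSGraph.from_gstring("TT#NG(A|)CA(AT|TA)GA#T",
...                              edges=[(1, 1), (2, 1), (2, 2)])
>>> idx = em.build_index(g, k=3, w=4, hash_mode="lex")
>>> {k: list(v) for k, v in sorted(idx.postings.items())}
{'AAG': [20], 'AAT': [11], 'ACA': [7], 'AGA': [4, 17], 'ATG': [13]}
>>> res = em.map_read("TTAGAATCGA", g, idx, em.MappingParams(k=3, w=4, d=3))
>>> res.distance, res.g_start, res.cigar, res.seed
(2, 1, '4M1D3M1I2M', (5, 11))
```

The read `TTAGAATCGA` seeds at pair (5, 11) — read position 5, graph
position 11, chain score 2 — and aligns with two errors: the reference `C`
at position 10 is deleted and the read's `C` is an insertion.
`em.coords_of_match("TTAGACATAGAT", g)` returns
`(1, 2, 4, 5, 7, 10, 11, 16, 17, 19, 20, 22)`: monotone coordinates of a
cycle-free match.

From the shell, the same pipeline is:

```bash
edsmap build ref.fa graphprefix --vcf calls.vcf
edsmap index graphprefix -k 20 -w 5
edsmap sample graphprefix reads.fq truth.tsv -n 500 --length 100 --seed 1
edsmap map graphprefix.minidx.json graphprefix reads.fq out.sam
edsmap evaluate out.sam truth.tsv --tolerance 10
```

`map` writes one primary SAM record per read; `POS` is the projected
linear coordinate, `NM` the edit distance, `ZG` the G^ coordinate.

## Layout

| module | contents |
|---|---|
| `edsmap.eds_core` | EDS parsing, matching/occurrence semantics, oracles |
| `edsmap.graph_build` | VCF classification, EDS construction, graph assembly, traversal views |
| `edsmap.coords` | rank/select on the indicator, linear projection, coordinate walks |
| `edsmap.minimizer_index` | per-position k-mer scan, window selection, index (de)serialization |
| `edsmap.mapper` | read minimizers, chaining, the EDS-adapted banded DP, `map_read` |
| `edsmap.read_sampler` | truth-tracked read simulation, accuracy evaluation, synthetic pangenome |
| `edsmap.cli_io` | `edsmap` CLI, graph/index file formats, FASTA/VCF/FASTQ/SAM I/O |

See `docs/methods.md` for the model, parameter defaults and numerical
choices.
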
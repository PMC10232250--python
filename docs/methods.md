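# Methods

## Representation

A pangenome is built from a reference FASTA and a VCF.  Variants are
classified per record:

* **SNPs** and indels/replacements with a reference/alternate length
  difference below 20 bp are *small* and encoded in place as ED symbols.
  The shared flanks of the alleles are emitted as plain sequence, so a
  padded deletion `GA>G` serializes as `G(A|)` rather than `(GA|G)`; the
  reference allele is always the first alternative.  The 20 bp cutoff is a
  package default (short-indel support in linear in-place encodings
  conventionally tops out around this scale); it is configurable in
  `graph_build.STRUCTURAL_THRESHOLD`.
* **CNV/DUP** records split the sequence into left flank, repeatable
  middle and right flank, with a self-loop edge on the middle node.
  Stated copy-number bounds are recorded but not enforced during
  alignment — the graph encodes repeatability, not multiplicity.
* **Large deletions** get a bypass edge around the deleted span; **large
  insertions** become an optional node with a bypass edge.
* Inversions, mobile-element insertions and complex replacements are
  skipped with a counted reason; malformed records are skipped with a
  warning, never fatal.

Overlaps are resolved strictly left-to-right keep-first: structural
variants are reserved first, small variants whose reference span would put
a node split inside a parenthesized symbol are dropped, then remaining
small variants are kept greedily.  Each chromosome is an independent node
chain; the `#` between chromosomes carries no jump edges.

The linearized form G^ concatenates node labels with `#`.  Separators are
numbered 1..S; an edge (v, v′) is stored as `sep(v)+1 → sep(v′)` together
with its transpose for backward traversal.  Edge cases: a structural
variant at a chromosome boundary can leave a flank empty; the empty node
is simply omitted, which loses nothing for semi-global mapping (a walk of
the deleted haplotype starts at the next node).

The indicator bit-vector I has a 1 exactly at reference-origin characters
(inter-variant sequence, reference alleles, CNV middle bases); syntax
characters, alternate alleles and inserted sequence are 0, so
`rank(I, |G^|)` equals the reference length.  Rank uses 512-bit block
prefix sums over a numpy array — constant-time queries after one linear
pass; no succinct-structure engineering beyond that.  Projection is made
total: non-reference bases report the nearest preceding reference base
and are flagged `on_reference=False` (SAM needs a POS for every record;
the flag is surfaced as the `ZP` tag).

## Minimizer index

The set K_p of k-mers occurring at position p is computed by scanning each
node label right to left.  Plain case: prepend the character and truncate
to k.  At a symbol's right boundary `)` the current set is saved (K_r) and
re-seeds every alternative; at each alternative end the set is added to an
accumulator (K_l) which is released at the left boundary `(`.  Scans are
seeded across jump edges with the union of the k-mer sets starting at the
node's successors (computed by a bounded depth-first spell of at most k−1
characters, which also handles self-loop nodes without fixpoint
iteration).  K-mers that span edges are therefore attributed to their
start position and indexed like any other — the worked example's index
contains such a k-mer — and sets near node ends are shaped correctly.

N is kept literally in the sets and expanded to all concrete bases only
when hashing; k-mers with more than 2 Ns are ignored (caps the expansion
at 16-fold; "many Ns" is a judgment call, the cap is configurable).

Window selection slides an interval of w consecutive G^ positions over the
per-position minima (syntax positions contribute nothing) and marks the
minimum per window; ties on the hash value go to the leftmost position.
Windows slide over the whole of G^, not per node — the worked example's
first window spans a `#`.

Hashing is pluggable: `lex` uses the base-4 lexicographic rank itself
(A=0, C=1, G=2, T=3) and is what every worked example and test pins;
`mix` scrambles the rank with a splitmix64-style 64-bit mixer and is the
sensible production choice (it decorrelates minimizer density from
sequence content).  Defaults are (w,k) = (5,20) and a trim threshold of
512 positions per k-mer: larger k speeds mapping and grows the index,
larger w thins the index but costs sensitivity; 512 removes only
pathologically repetitive seeds at the scales this package targets.

The index serializes to a documented JSON layout (header with k, w, trim,
hash mode and a graph checksum, then sorted postings); round-trips are
bit-exact, and `map` refuses an index whose checksum does not match the
graph.

## Mapping

Per read and per strand (the index covers the forward strand; the read
and its reverse complement are both tried):

1. **Seeding.** The read's own (w,k)-minimizers are looked up, producing
   pairs (i, j) of read/graph positions sorted by j.
2. **Chaining.** The score of a pair is the length of the longest chain
   strictly increasing in both coordinates among pairs within a λ-window
   (j-spread < λ, default 2·|read|), computed per maximal batch with a
   Fenwick-tree LIS in O(x log x).  A pair's score is its best over
   batches.
3. **Extension.** Seeds are tried in descending score (at most
   `max_seeds` = 10).  The DP pins read[i*] to G^[j*] and extends forward
   (read suffix) and backward (read prefix, on a mirrored view using the
   transposed edges), the backward bound being d minus the forward
   distance.  Cells are kept while ≤ d and, with pruning on, strictly
   below the best complete alignment so far; pruning never changes the
   optimum (property-tested).  A seed whose full-read distance is ≤ d
   stops the search for that strand ("satisfying alignment" is not
   quantified upstream; this is the package's documented choice).
   Ties go to smaller distance, then smaller G^ start, then forward
   strand.

The DP handles the syntax without branching: `(` and `|` columns copy the
cached pre-symbol column, `)` takes the element-wise minimum over
alternative-end columns, and when a column dies inside an alternative the
scan skips to the next alternative boundary where the cache revives it.
Only `#` branches, depth-first along jump edges with the bound shared
across branches; a visited-set guards the degenerate zero-consumption
cycle (a self-loop node whose label can match the empty string).  Each
branch consumes one graph base per column, so branch depth is bounded by
|read| + d.  Extension from a seed inside an alternative is supported:
sibling alternatives are unreachable from there and are skipped.

Unit-cost edit distance is the only scoring exercised by the worked
examples and tests; the DP structure would carry configurable linear
costs, but affine gaps are out of scope.  `N` in the graph matches any
read base at zero cost, consistent with N ≡ (A|C|T|G).  The error bound
defaults to ⌈0.1·|read|⌉.  No clipping, no paired-end handling, no MAPQ
model; one primary alignment per read.

CIGARs use M/I/D with M covering match and mismatch (`NM` carries the
distance); deletions count path bases, and an alignment crossing a jump
edge is reported as a contiguous CIGAR along its walk with the G^ start
in `ZG`.

## Synthetic data and what it shows

`sample_reads` draws a start uniformly over G^ base positions, walks
forward choosing alternatives and jump edges uniformly, replaces N by a
uniform base, then applies three independent per-base error channels —
substitution (uniform over the three other bases), insertion (uniform
base after the current one), deletion — each at the same rate, default
0.1% per base ("probability per error per base" is read as per-channel;
the sentence admits both readings and this one is documented).  Reads are
fully reproducible from the seed.  Starts that cannot complete a
full-length walk are redrawn, so the distribution is uniform over
feasible starts.

The generator emulates uniform pangenome sampling with idealized errors:
no quality profile, no sequencer-specific indel bias, no coverage
structure, single-end only.  Passing the recovery test therefore shows
the representation/index/DP machinery is correct and parameter recovery
works under the stated model — not that real-library artifacts are
handled.

`synthetic_pangenome` builds a 10 kb random reference with ~2.5% SNP and
~0.1% short-indel density (echoing a human cohort call set) plus one
300 bp CNV.  The recovery experiment used in the tests maps 500 reads of
100 bp sampled at 1% per-channel error with the (5,20) production index
(`mix` hashing) and scores accuracy as |reported − truth| ≤ 10 on G^
coordinates; the whole experiment runs in seconds, and problem sizes were
chosen so the entire suite stays interactive.

## Numerical and tie-break choices

* Positions are 1-based and inclusive everywhere.
* Window ties: equal hash → leftmost position.
* Multiple witness walks in `coords_of_match`: lexicographically smallest
  coordinate sequence (deterministic tests).
* Equal-scoring seeds: ordered by (score desc, j, i); equal-distance
  alignments: smallest G^ start, forward strand first.
* Degenerate inputs: empty VCF reproduces the reference exactly (all-ones
  indicator); reads shorter than k are unmapped; an empty read prefix
  aligns backward with distance 0.

## Known limitations

* Inversions and mobile-element insertions are not represented (skipped
  with counts), matching the scope of the representation.
* Alignment is exhaustive within the band; extremely repetitive graphs
  with dense self-loops could still branch heavily at separators — the
  trim threshold and seed cap are the practical guards.
* The backward DP reuses the mirrored text view; coordinates reported for
  alignments that end inside an alternative project to the nearest
  preceding reference base (flagged approximate).
* Pure-Python throughput is adequate for the tested scales (tens of kb,
  thousands of reads), not for whole-genome work.
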
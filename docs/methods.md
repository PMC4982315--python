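# Methods

## The model

A query is a boolean expression over per-read predicates. Each
predicate is a pure function of one alignment record (plus, for
`random`, a run seed); connectives are ordinary boolean operators, with
`cond then t else e` defined as `(cond & t) | (!cond & e)`. The engine
streams records from a coordinate-sorted BAM (or SAM), evaluates the
compiled query once per record, writes accepted records unmodified to
the output, and accounts accepted/rejected so that the two always sum
to the number of records seen.

Queries are stateless by construction: no predicate can depend on
another read. That is what makes the two central optimizations safe —
compilation of the AST into nested closures (dispatch resolved once per
query rather than once per read), and index-driven traversal of only
the file regions where matches can occur.

## Concrete syntax and precedence

The parser is a hand-written recursive-descent parser over a
context-sensitive lexer (glob arguments are taken verbatim up to the
closing parenthesis; `~` introduces a `/`-delimited regex literal).
Operator precedence — `!` > `&` > `^` > `|` > `then/else`, binary
operators left-associative — is a convention of this implementation,
chosen to match C-family boolean binding. Since `&`, `|`, `^` are
semantically associative, associativity only affects tree shape. The
canonical renderer parenthesizes every connective, so rendered output
re-parses to an identical tree regardless of the precedence table;
probabilities are rendered with `repr` so they round-trip exactly.

## Chromosome-name normalization

Reference names are canonicalized by stripping `chr` prefixes
case-insensitively, upper-casing, and mapping through an alias table.
The built-in table covers the human convention: autosomes `1`–`22`,
`X`=`23`, `Y`=`24`, `M`=`MT`=`25`. A chromosome glob is matched
(anchored, case-insensitive, `*`/`?` only) against every spelling in
the alias class of the name's canonical token, so matching depends only
on *which chromosome* a name denotes, never on its spelling — `chr(24)`
finds reads on a contig named `Y` and vice versa. Globs written with a
literal `chr` prefix are additionally tried with the prefix stripped.
Unknown names pass through (stripped, upper-cased), so non-human
contigs still match literal globs; other species' conventions can be
loaded from a two-column text file. Character classes are deliberately
not supported in globs. Aliasing X is included by symmetry with Y even
though only the Y and mitochondrial aliases are strictly required by
the human naming mess this addresses.

## Predicate semantics worth spelling out

- **Coordinates** are 1-based inclusive everywhere a user sees them
  (query arguments, `ReadView.start`/`end`). The single conversion from
  pysam's 0-based half-open convention happens in `view_from_record`.
- **`mapping_quality(p)`** converts MAPQ to an error probability
  10^(−MAPQ/10) and tests *strictly less than* p. MAPQ 255 means "not
  available" and never matches, at any threshold.
- **Position and chromosome predicates fail, not error, on unmapped
  reads** (and `mate_chr` on unmapped mates). Predicates are filters;
  an unmapped read simply does not satisfy `chr(...)`, which is what
  lets it be composed with `unmapped?` via `|`.
- **`nt` vs `nt_exact`**: `nt(pos, n)` uses IUPAC ambiguity-set
  intersection (the read base and the query code are compatible if
  their expansions share a base, so `N` matches anything); `nt_exact`
  compares letters directly (`nt_exact(pos, R)` matches only a stored
  `R`). The aligned base is found by a CIGAR walk: M/=/X advance both
  cursors, I/S the query, D/N the reference, H/P neither; positions in
  deletions/skips yield no base.
- **Sequence comparisons** are case-insensitive and use SEQ as stored
  (reference orientation); reverse-strand reads are not
  reverse-complemented.
- **`header ~ /regex/`** is an unanchored search over the read name
  (Python `re` dialect); anchoring is available via `^`/`$`.
- **`read_group(glob)`** is a case-sensitive whole-string glob match on
  the RG tag; reads without the tag never match.

## `random(p)`: keyed draws

Each `Random` node holds a static ordinal (its left-to-right position
among the Random nodes of the tree). A draw is
`blake2b(key=seed, message=(qname, flag, ref, start, ordinal)) / 2^64`,
giving one uniform per Random node per read. Because the draw is a pure
function of (seed, read, node) rather than a shared stream, the outcome
cannot depend on evaluation order, on short-circuiting, or on which
other reads a restricted traversal happened to skip — so a fixed seed
makes indexed runs, sequential runs, and independent re-evaluations of
the same read agree exactly, which the equivalence tests rely on. A
consequence worth noting: identical (qname, flag, ref, start) tuples
would receive identical draws; files with duplicate records would see
correlated sampling. With no seed given, the engine draws a fresh
entropy seed and logs it.

## Index planning

`infer_plan` recursively over-approximates where matches can live:
`chr(g)` restricts to the header references whose alias class matches
`g`; `unmapped?` restricts to "unmapped records" (tracked as an
`include_unplaced` flag); `&` intersects, `|`/`^` union, `!` widens to
everything, and `cond then t else e` is planned as
`(cond & t) | (!cond & e)`. Every other predicate — including
`mate_chr` and the position predicates, which imply no chromosome on
their own — plans as all-reads. Sub-chromosome interval planning is not
performed.

Soundness (a plan never excludes a satisfying read) is the invariant
the tests enforce, by comparing indexed against sequential runs
byte-for-byte. Two traversal subtleties: unmapped reads *without*
coordinates are invisible to region iteration, so any plan that must
reach them falls back to a sequential scan that skips evaluation of
out-of-plan records (same accept set, same counts); and unmapped reads
*placed* at their mate's coordinate live inside contig regions, so they
are reached via their placement and their unmapped bit, not their
coordinate, decides the predicates. Records the index skips entirely
are counted as rejected without evaluation, using the index's record
counts. When a rejects file is requested, the engine likewise scans
sequentially, because it must have every rejected record in hand to
write it. Evaluating out-of-scope records in the no-index path is
harmless by soundness: they cannot satisfy the query.

## Chain filtering

`run_chain` tests each record against the stages in order and writes it
to the first stage it satisfies (first-match-wins), so stage outputs
are pairwise disjoint and their union equals the accept set of the OR
of the stage queries under the same seed. This is the semantics under
which a chain differs from running n independent filters; the
`--independent` flag provides the latter. Reads matching no stage go to
`--leftover` when given, else are dropped. Per-stage statistics
cascade: a stage's accepted + rejected equals the records offered to it
(total minus records claimed earlier), so the last stage's rejected
count is the number of reads matching no stage.

## Outputs

Output files copy the input header and append a `@PG` line (tool,
version, query text — which re-parses to the executed AST); alignment
records are written untouched, in input order. Malformed records
(CIGAR/sequence length disagreement) abort the run by default;
`--skip-malformed` downgrades them to a logged skip.

## The synthetic-data generator

`bamql.fixtures.generate_bam` emits coordinate-sorted, indexed BAMs
whose records exercise every feature the predicates can observe: contig
names mixing `chrN`/`N`/`chrY`/`24`/`MT` spellings, paired and unpaired
reads, unmapped reads both placed at the mate's coordinate and
unplaced, cross-chromosome mates, a MAPQ distribution including the 255
sentinel, CIGARs with insertions, deletions, intron skips and both clip
types, missing and present read groups, and occasional IUPAC ambiguity
bases. Defaults (1000 reads, 60 % paired, 10 % unmapped of which half
placed, 10 % cross-chromosome mates, 2 % ambiguity bases) are fixed at
values typical of a small exome-like test slice; each generated record
is logged in a truth table the tests compare against independently.

What the generator does **not** emulate: realistic base qualities or
error models, insert-size distributions, actual mate records (mate
fields are synthesized per record), reference-genome sequence
agreement, or full-scale file sizes. Passing tests therefore establish
the engine's *logical* correctness — that every predicate and traversal
strategy agrees with naive semantics on files containing all the
structural corner cases — not performance or robustness to
pathologically malformed inputs beyond the checks described above.

`oracle_filter` is the independent referee: a deliberately naive
evaluator written directly against pysam record attributes, using
pysam's `get_aligned_pairs` for sequence predicates instead of this
package's CIGAR walk, its own inline alias table and glob translation,
and full (non-short-circuiting) boolean evaluation.

## Problem sizes and tolerances

The equivalence suite runs 200 randomly generated queries (depth ≤ 5,
all predicate variants, ~30 % biased toward index-restricted forms)
against a 10,000-read file, demanding exact accept-set equality;
index/sequential identity is byte-level. Desk-scale canonical queries
run on 6,000 reads over contigs spelled `chr1`,`2`,`3`,`chrY`,`24`,`MT`;
`random(p)` calibration uses 20,000 reads with a 99.9 % binomial
acceptance interval (±3.29 σ). These sizes keep the full suite and the
acceptance script each within a few minutes on one CPU while covering
every corner case class the generator can produce.

## Known limitations

- CRAM is not supported; outputs are BAM only (SAM accepted on input).
- No multi-threaded decoding; correctness-first single-pass streaming.
- Globs have no character classes; regexes use Python's `re`, which
  covers the common Perl-compatible constructs but not all PCRE
  extensions (recursion, possessive quantifiers).
- The alias table ships human-centric defaults; other species need an
  override file.
- Sub-chromosome index planning (restricting by position within a
  chromosome) is not implemented; plans are at reference granularity.
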
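# Query language reference

A query is built from predicates joined by logical connectives. Reads
satisfying the query are written to the output; everything else is
rejected (and counted).

## Logical connectives

| Syntax | Meaning |
|---|---|
| `! expr` | Satisfied if *expr* is not satisfied. |
| `expr & expr` | Satisfied only if both operands are satisfied. |
| `expr ^ expr` | Satisfied if exactly one operand is satisfied. |
| `expr \| expr` | Satisfied if at least one operand is satisfied. |
| `cond then then_expr else else_expr` | If *cond* is satisfied, the expression is satisfied iff *then_expr* is; otherwise iff *else_expr* is. |

Precedence, loosest to tightest: `then`/`else`, `|`, `^`, `&`, `!`.
Binary connectives are left-associative. Parentheses group as usual.
This binding order follows the C-family boolean convention (negation
strongest); parenthesize compound queries if in doubt.

## BAM flags

| Syntax | Meaning |
|---|---|
| `paired?` | The read is paired in sequencing (FLAG 0x1). |
| `proper_pair?` | The read is mapped in a proper pair (0x2). |
| `unmapped?` | The read is unmapped (0x4). |
| `mate_unmapped?` | The mate is unmapped (0x8). |
| `mapped_to_reverse?` | The read is mapped to the reverse strand (0x10). |
| `mate_mapped_to_reverse?` | The mate is mapped to the reverse strand (0x20). |
| `read1?` / `read2?` | First / second read of the pair (0x40 / 0x80). |
| `secondary?` | The alignment is not primary (0x100). |
| `failed_qc?` | Platform/vendor quality-control failure (0x200). |
| `duplicate?` | PCR or optical duplicate (0x400). |
| `supplementary?` | The alignment is supplementary (0x800). |
| `raw_flag(int)` | Every bit of the given mask is set in the read's FLAG. |

## Mapping information

| Syntax | Meaning |
|---|---|
| `chr(glob)` | The read is mapped to a chromosome matching the glob. |
| `mate_chr(glob)` | The mate is mapped to a matching chromosome. |
| `split_pair?` | Read and mate both mapped, to different references. |
| `mapping_quality(p)` | The mapping error probability 10^(−MAPQ/10) is strictly less than *p*. MAPQ 255 (unavailable) never matches. |

Chromosome globs (`*` any run, `?` one character; whole-name anchored;
case-insensitive) match through the alias table, so `chr(Y)` selects
reads on contigs named `Y`, `chrY`, `24` or `chr24`, and `chr(M)`
matches `M`, `MT`, `25` with or without a `chr` prefix. See
`--alias-table` to supply other conventions.

## Position

Positions are 1-based reference coordinates, as displayed by genome
viewers.

| Syntax | Meaning |
|---|---|
| `after(position)` | The alignment covers the position or any higher one (rightmost aligned base ≥ position). |
| `before(position)` | The alignment covers the position or any lower one (leftmost aligned base ≤ position). |
| `position(start, end)` | The alignment overlaps the closed interval [start, end]. |

## Sequence

| Syntax | Meaning |
|---|---|
| `nt(position, n)` | The base aligned at the reference position is IUPAC-compatible with *n* (shares at least one concrete base; `N` matches any base). |
| `nt_exact(position, n)` | The aligned base equals *n* letter-for-letter (case-insensitive). |

The aligned base is found by walking the CIGAR; positions falling in a
deletion or intron skip, or outside the read, match neither form.

## Miscellaneous

| Syntax | Meaning |
|---|---|
| `read_group(glob)` | The read's RG tag matches the glob (case-sensitive, whole string). |
| `header ~ /regex/` | The regular expression finds a match anywhere in the read name. Anchor with `^`/`$` inside the pattern; escape a literal slash as `\/`. |
| `random(p)` | Satisfied with probability *p* per read, deterministically under the run seed (`--seed`). |
| `true` / `false` | Always / never satisfied. |
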
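# bamql

A query language for extracting reads from BAM files.

Selecting a subset of reads from a BAM — everything mapped to one
chromosome, reads whose mate is unmapped, reads carrying a particular
base at a reference position — usually means either piping `samtools
view` output through an AWK script, or writing boilerplate against a BAM
library. Both approaches are error-prone: flag bits are addressed
numerically, and when a region request and a filtering expression name
chromosomes independently, a spelling mismatch (`chrY` vs `Y` vs `24`)
silently drops data.

`bamql` replaces that with a small declarative language: predicates over
SAM flags, mapping information, position, sequence and read metadata,
joined by `!`, `&`, `^`, `|` and `cond then … else …`. Queries compile
to per-read closures; when the input is indexed, the query itself
determines which references need scanning, so the index request and the
filter can never disagree; and chromosome names are normalized through
an alias table so `chr(Y)` finds the Y chromosome however the file
spells it. See [LANGUAGE.md](LANGUAGE.md) for the full reference.

## Usage

```sh
bamql -f input.bam -o output.bam 'chr(1) & paired?'
```

Reads satisfying the query go to `output.bam` (input order preserved,
records unmodified, a `@PG` header line records the query); accepted and
rejected counts are printed to standard error. `-O rejects.bam` also
captures the complement, `--seed` fixes `random()` draws, `--no-index`
forces a sequential scan, and `-` works as stdin/stdout for pipelines.

A worked example, on a 1000-read synthetic file produced by
`bamql.fixtures` (seed 5) — select reads where the read or its mate is
unmapped or mitochondrial:

```sh
$ bamql -f example.bam -o mt.bam -s 7 'unmapped? | mate_unmapped? | chr(M) | mate_chr(M)'
bamql: (((unmapped? | mate_unmapped?) | chr(M)) | mate_chr(M))	accepted=307	rejected=693
```

307 of the 1000 reads satisfy the query and are written to `mt.bam`;
accepted + rejected always equals the number of records in the input.
The chain form routes each read to the first query it satisfies, here
splitting chromosomes 1–3 into separate files:

```sh
$ bamql chain -f example.bam -s 7 'chr(1)' c1.bam 'chr(2)' c2.bam 'chr(3)' c3.bam
bamql: chr(1)	accepted=136	rejected=864
bamql: chr(2)	accepted=147	rejected=717
bamql: chr(3)	accepted=152	rejected=565
```

Stage counts cascade: each stage's accepted + rejected equals the reads
offered to it (those not claimed by an earlier stage), so the outputs
are pairwise disjoint.

The same operations are available as a library:

```python
from bamql import run_query
stats = run_query("input.bam", "chr(1) & paired?", accept_out="out.bam")
print(stats.accepted, stats.rejected)
```

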
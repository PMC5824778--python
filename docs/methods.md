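# Methods

## The storage model

The warehouse separates data by volume and mutability. Small, heavily
cross-referenced data — specimen identity, provenance, per-sample analysis
summaries, per-variant detail — lives in an embedded relational database
(SQLite) where foreign keys enforce consistency. The three large result
sets — variant observations, expression abundances, read counts — live in
an append-only columnar store where each column is one file and equality
queries are answered through compressed bitmap indexes. Every columnar row
is denormalized with the sample name, organism and tissue taken from the
relational side at import time, so columnar queries need no joins; the
relational side remains the single source of truth for identity.

### Relational schema

Twenty-three tables in four sections. Sample information: `Sample`,
`Animal`, `Organism`, `Breed`, `Sex`, `DevelopmentalStage`, `HealthStatus`,
`Material`, `Tissue`, `Person`, `Organization`, the cross-reference tables
`SamplePerson`/`SampleOrganization`, and the key–value attribute tables
`AnimalStats`/`SampleStats` (their exact column inventories are not fixed
by any input format, so open-ended attributes are the safest encoding).
Alignment information: `MapStats` (read totals and mapping rate),
`Metadata` and `CommandSyntax` (per-stage tool names and invocations).
Expression information: `GeneStats`, `ReadCounts`. Variant information:
`VarSummary`, `VarResult`, `VarAnnotation`.

Six views (`vw_sample`, `vw_sampleinfo`, `vw_seqstats`, `vw_vanno`,
`vw_vvcf`, `vw_nosql`) are real SQL views; the four variant "procedures"
(`usp_vall`, `usp_vchrom`, `usp_vchrposition`, `usp_vgene`) are registered
named parameterized queries, since the embedded engine has no procedure
objects — the observable contract is the query surface, not the server
mechanism. All four select from `vw_nosql`, the variant×annotation left
join shaped exactly like the columnar variant partition, which keeps the
relational selectors and columnar queries answer-equivalent on mirrored
data.

Lookup dimensions use get-or-create with case-sensitive exact matching:
N samples sharing one organism yield exactly one `Organism` row. Internal
keys are monotonically increasing integers; external identity is always
the sample name, which preferably follows the
`<species>_<lab>_<alphanumeric id>` convention of livestock-genomics
sample registries (violations warn rather than fail, because free-form
tab-delimited metadata is also accepted).

`VarSummary` carries SNP, insertion, deletion **and complex** class counts
whose sum is the total. Complex substitutions (e.g. `AT>GC`) are rare in
caller output but representable; keeping an explicit column preserves the
"class counts sum to total" arithmetic without misclassifying them.

### Columnar store

One directory per partition (`variant`, `expression`, `readcount`), one
UTF-8 text file per column with one backslash-escaped value per line, plus
a descriptor listing column names, kinds and the row count. A documented
text serialization was chosen over binary little-endian files: it is
byte-exact across platforms, diffable, and at warehouse desk scale the
I/O difference is irrelevant.

Column kinds are `text`, `key`, `char` (strings), `int`, `double`. `key`
marks low-cardinality columns indexed by default; the distinction affects
only index eligibility, not storage. NULL is the literal string `NULL` for
string kinds — deliberately an ordinary queryable value, so predicates
such as `genename != 'NULL'` behave as written — NaN for doubles, and a
null marker decoded to Python `None` for ints. Numeric NULLs fail every
comparison predicate and are skipped by `sum`/`avg`/`min`/`max`;
`count(col)` counts non-NULL values, `count(*)` counts rows.

The expression partition has 14 columns (`sampleid`, `chrom`, `start`,
`stop`, `genename`, `geneid`, `coverage`, `tpm`, `fpkm`, `fpkmconflow`,
`fpkmconfhigh`, `fpkmstatus`, `organism`, `tissue`); the variant partition
21; the read-count partition 5.

### Bitmap indexes

Per-value bitmaps compressed with 31-bit word-aligned run-length encoding:
a literal word carries 31 raw bits, a fill word a run of identical 31-bit
groups (the scheme of word-aligned hybrid bitmap compression). Indexes are
built in memory on demand, are invalidated by appends and deletions, and
satisfy two invariants checked by tests: per-column bitmaps are pairwise
disjoint and cover all rows, and for every indexed value the decoded row
set equals the full-scan row set. The compression scheme itself is checked
by a property test (decode ∘ encode = identity on random bit vectors).

### Query semantics

The SQL subset accepts `select` projections (columns, `*`, or
`count/sum/avg/min/max` aggregates), an optional tolerated-and-ignored
`FROM` clause, conjunctive `where` predicates with
`= != < <= > >= like`, `group by`, `order by` (single key) and `limit`.
`OR`, `NOT` and `JOIN` are rejected explicitly by name rather than
silently mishandled; cross-partition joins belong to the relational side.
`LIKE` is case-insensitive with `%` matching any (possibly empty)
substring; `=` is case-sensitive. Comparisons are numeric on numeric
columns and lexicographic on strings. Ordering is ascending by default
with stable ties in row insertion order; numeric NULLs sort last ascending
(and therefore first descending, as the exact reversal); `limit` applies
after ordering; `avg` is `sum/count` in double precision.

Two evaluators exist on purpose: the engine path (bitmap intersection for
equality predicates on indexed columns, scan for the rest) and a naive
row-at-a-time reference evaluator with no shortcuts. The test suite and
the reproduction script drive both with 200 seeded random queries over
random partitions of up to 1000 rows and require row-for-row agreement,
with and without indexes built.

## Import pipeline

A sample directory is discovered by suffix contract:
`align_summary.txt`/`*summary.txt`/`*.sam` (alignment),
`genes.fpkm_tracking` (Cufflinks), `*gene_abund*.tab` (StringTie),
`abundance.tsv` (kallisto), `quant.sf` (Salmon), `*.counts` or two-column
`*.txt` (htseq-count), `*featureCounts*`/`*.fc.txt` (featureCounts),
`*ReadsPerGene.out.tab` (STAR quantMode, column 2 = unstranded counts),
`*.vcf` (variants), `*.vep.txt` (VEP), `*.multianno.txt` (ANNOVAR). Two
candidates for one role is an error listing both. These suffixes are the
defaults of each named tool.

Parsing uses the established readers — pysam for SAM flag statistics
(total = records with neither 0x100 nor 0x800 set; mapped = those without
0x4), cyvcf2 for VCF, pandas for the tabular dialects, openpyxl for the
FAANG-style workbook. Multi-allelic VCF lines are exploded to one record
per ALT before classification; variant class follows allele lengths
(1/1 → SNP; prefix-extending → insertion/deletion; otherwise complex);
zygosity comes from the GT field (equal alleles → homozygous, any missing
allele → NULL). Annotations join variants on (chrom, position, alt), with
VEP indel ranges contributing their range start. The `FILTER` column is
ignored and `QUAL` of `.` becomes NULL.

The import is atomic: every input file is parsed completely before any
write; relational writes happen in one transaction with columnar appends
interleaved; on any failure — including a double-entry mismatch, where
rows parsed ≠ rows stored for some stage — the transaction rolls back and
the partitions are truncated to their pre-import row counts (valid because
the store is append-only between deletions). Re-importing a sample's
results is refused until the sample is deleted. With scope `all`, variant
files are loaded when present and skipped when absent (expression is
required); scope `variant` requires a VCF.

Deletion removes the sample row, all relational child rows and all
columnar rows carrying the sample's id, then the referential-integrity
check must pass; dimension rows (organism, tissue, ...) are retained for
other samples.

## Exports

`export_avgfpkm` groups expression rows by (gene, tissue) and reports
min/mean/max per unit over samples, excluding NULL abundances from all
three statistics and omitting empty groups. `export_genexp` builds a
gene × sample matrix for one organism, cell = FPKM with TPM fallback,
absent genes NULL (or 0 by flag). `export_chrvar` counts variant
observations per (sample, chromosome) on the relational side, so its
unrestricted totals equal `VarSummary` totals by construction and equal
the distinct variant sites per sample in the columnar partition (a
variant with multiple annotations occupies multiple partition rows but is
one site). `export_varanno` writes the variant×annotation join as TSV or
as VCF v4.2 with one record per (sample, site) — sample metadata is
single-valued in `MTD`, so identical variants in different samples emit
separate records — and all annotations of a record packed into `CSQ` as
comma-separated, pipe-joined entries whose subfield order
(`source|consequence|geneid|genename|transcript|feature|genetype|`
`proteinposition|aachange|codonchange`) is declared in the header.
Reserved INFO characters inside subfields are percent-encoded and spaces
become underscores. Gene matching is fuzzy (case-insensitive substring)
by default with an exact mode, matching how expression portals search by
partial gene symbol.

TSV output is UTF-8, tab-separated, header first, `NULL` for missing,
unquoted — values containing tabs or newlines are rejected rather than
quoted, keeping the format trivially parseable by R/Excel/JMP.

## Synthetic study generator

The generator emulates the input side of a small multi-species RNA-seq
project: by default two organisms × two samples, 50 genes per sample on
five synthetic chromosomes (3 kb gene intervals), 30 variants per sample
placed uniformly within gene intervals (70% SNP, 15% insertion, 15%
deletion, unique positions per sample), FPKM drawn log-normal
(`exp(N(1, 1))`, the right-skewed shape typical of bulk RNA-seq) with TPM
renormalized to 10^6, read counts proportional to abundance, alignment
summaries in the HISAT2 dialect with 88–99% mapping rates, and
quantifier/counter/annotator dialects rotating across samples so every
parser is exercised. Every generated number is recorded in a ledger JSON
so tests can assert exact agreement after import. All randomness flows
from one seeded generator, and the tree (including the metadata workbook,
rewritten with fixed zip timestamps) is byte-identical for a given seed.

The two-sample use-case scenario fixes the quantities the package's
documentation reasons about: OPTN expressed (FPKM 12.5) in GGA_UD_1004 and
0.0 in GGA_UD_1014, a housekeeping gene (ACTB, FPKM 33.0) equal in both,
exactly one synonymous OPTN SNP in GGA_UD_1004 and k = 6 in GGA_UD_1014.
The OPTN coordinates are synthetic placeholders, not real assembly
coordinates.

What the generator does **not** emulate: real sequence context (alleles
are random bases), linkage between expression and genotype, batch effects,
multi-allelic sites, structural variants, VEP's allele-trimming convention
for indels (generated annotation rows use the VCF ALT verbatim so the join
key is exact), or multi-sample VCFs. Passing tests therefore demonstrate
correctness of storage, accounting and querying — not robustness to every
artifact of production caller output.

## Numerical and edge-case choices

- Doubles round-trip through `repr` (exact to 1e-12 and beyond); text is
  exact.
- Alignment rate is stored as mapped/total so the `MapStats` invariant
  holds to 1e-9; summary dialects reporting a percentage have mapped
  reads reconstructed by rounding before the rate is recomputed.
- A VCF whose body line count differs from the records the reader yields
  is treated as truncated/malformed and fails the import (triggering
  rollback) rather than silently importing a prefix.
- Deleting with a predicate matching nothing leaves the partition bytes
  untouched; appending zero rows is a no-op.
- The interactive menu previews 20 rows; the full result is reachable via
  the export command.

## Problem sizes

Default test and reproduction sizes — 2–4 samples, 10–50 genes, up to 30
variants per sample, 200 random queries over partitions of up to 1000
rows — were chosen as the smallest sizes at which every code path
(all dialects, all index paths, grouping, deletion, rollback) is
exercised with non-trivial data. The storage layer itself has no
small-size assumptions; partitions simply append.

## Known limitations

- Single-process, single-user; no server, authentication or concurrent
  writers (SQLite-level locking only).
- The columnar grammar supports conjunctions only; disjunctive queries
  must be issued as multiple statements.
- Annotation ingestion assumes annotation rows derive from the imported
  VCF: an annotation matching no variant fails double-entry and rolls the
  import back by design.
- BAM input is accepted only through its SAM text projection.
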
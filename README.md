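# transatlasdb

A hybrid relational + columnar data warehouse for RNA-seq analysis results:
sample metadata, alignment statistics, gene-expression quantifications
(FPKM/TPM/read counts) and gene-associated variants with predicted
functional annotations, stored once and queryable through one SQL surface.

RNA-seq projects accumulate large, heterogeneous result files — aligner
summaries, Cufflinks/StringTie/kallisto/Salmon abundance tables,
htseq-count/featureCounts matrices, VCFs from GATK or SAMtools, and
VEP/ANNOVAR annotation tables. This package gives a lab a single local
store for all of them, for anyone who needs to ask questions like "which
samples express gene *X*, and what variants sit in its region?" without
reopening the raw files.

## Design

The store is split by data volume, following the hybrid
relational-plus-NoSQL architecture of transcriptome warehouses:

- **Relational side** (embedded SQLite, 23 tables / 6 views / 4 registered
  procedure queries): sample identity and provenance (`Sample`, `Animal`,
  `Organism`, `Tissue`, ... with enforced parent→child foreign keys),
  per-sample summaries (`MapStats`, `GeneStats`, `ReadCounts`,
  `VarSummary`) and per-variant detail (`VarResult`, `VarAnnotation`).
- **Columnar side** (append-only, one text file per column): the three
  large result sets — `variant` (21 columns), `expression` (14),
  `readcount` (5) — each row denormalized with `sampleid`, `organism` and
  `tissue`. Low-cardinality columns get **word-aligned run-length
  compressed bitmap indexes** for fast equality queries.
- **One query grammar** on the columnar side (no `FROM` clause needed;
  conjunctive predicates, `LIKE`, grouping/aggregates, ordering, limit),
  checked row-for-row against a naive full-scan reference evaluator.

Imports are **double-entry validated**: rows parsed from every input file
must equal rows persisted per stage or the whole sample import rolls back.
A sample's results can be imported only once; deletion resets that.

## Worked example

The built-in generator reproduces the package's reference use case: two
*Gallus gallus* pituitary-gland samples in which the Optineurin gene (OPTN,
synthetic coordinates) behaves differently.

```python
import tempfile
from transatlasdb import Store, fixtures, export

work = tempfile.mkdtemp()
store = Store.install(f"{work}/store")
fixtures.generate_optn_scenario(1, f"{work}/study")
fixtures.import_study(store, f"{work}/study")

print(export.export_avgfpkm(store, ["ACTB", "OPTN"]))
print(export.export_genexp(store, "Gallus gallus"))
```

prints (abridged):

```
genename          tissue  min_fpkm  avg_fpkm  max_fpkm  sample_count
    ACTB Pituitary gland      33.0     33.00      33.0             2
    OPTN Pituitary gland       0.0      6.25      12.5             2

genename  GGA_UD_1004  GGA_UD_1014
    ACTB         33.0         33.0
    OPTN         12.5          0.0
```

ACTB's identical min/avg/max says it has the same FPKM in every sample;
OPTN's min of 0 says it is not expressed everywhere — the matrix shows it
is silent in GGA_UD_1014. Asking for variants explains the difference:

```python
optn = export.variants_select(store, ("gene", "OPTN"))
print(optn.groupby(["sampleid", "consequence"]).size())
```

```
GGA_UD_1004  synonymous_variant    1
GGA_UD_1014  synonymous_variant    6
```

GGA_UD_1014 carries six synonymous SNPs along the OPTN region against one
in GGA_UD_1004. `export.export_varanno(store, {"genes": ["OPTN"]}, "vcf",
path)` writes these as a VCF v4.2 file with consequences packed into the
`CSQ` INFO key and sample metadata into `MTD` (pipe-separated subfields,
order declared in the header).

## Command line

The same operations are available as a shell toolkit:

```sh
tad install --store mystore
tad import  --store mystore --metadata study/metadata.tsv
tad import  --store mystore --data2db study/samples/GGA_UD_1004 --all
tad export  --store mystore --query "select * from Metadata"
tad export  --store mystore --db2data avgfpkm --genes OPTN
tad export  --store mystore --partition variant \
            --query "select sampleid, chrom, position where genename = 'OPTN'"
tad interact --store mystore      # menu-driven exploration, 20-row previews
tad import  --store mystore --delete GGA_UD_1004
```

Exit status is 0 on success, 1 for user errors, 2 for internal errors; every
state-changing command appends one line to `<store>/logs/transactions.log`.

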
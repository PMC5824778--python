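"""Deterministic synthetic study generator.

Emits complete, internally consistent input trees in every accepted dialect
— FAANG-style metadata workbook plus the equivalent tab-delimited file,
per-sample analysis directories with an aligner summary, one abundance file
(rotating across the Cufflinks/StringTie/kallisto/Salmon dialects), a
read-count file (rotating htseq-count/featureCounts/STAR quantMode), a VCF
with GT fields and a matching VEP or ANNOVAR annotation table — together
with a machine-readable bookkeeping ledger recording every generated count
and value, so parser and import tests have exact oracles without any
downloads.

All randomness flows from one seeded generator; the same seed reproduces a
byte-identical tree.  Abundances are drawn log-normal (``exp(N(1, 1))``
FPKM, a right-skewed shape typical of bulk RNA-seq), variant positions
uniform within per-gene intervals, and per-sample TPM renormalized to sum
to 10^6.  Gene and chromosome names are synthetic except OPTN and the
chromosome used in the two-sample use-case scenario; those coordinates are
synthetic too and labeled as such.
"""

from __future__ import annotations

import json
import math
import os
import random
import zipfile
from dataclasses import dataclass, field
from datetime import datetime

QUANTIFIERS = ("cufflinks", "stringtie", "kallisto", "salmon")
COUNTERS = ("htseq", "featurecounts", "star_quantmode")
ANNOTATORS = ("VEP", "ANNOVAR")

_BASES = "ACGT"

_CONSEQUENCES = [
    "synonymous_variant", "missense_variant", "intron_variant",
    "3_prime_UTR_variant", "upstream_gene_variant",
]


@dataclass
class StudyConfig:
    """Study conditions for the generator (counts, organisms, seed)."""

    seed: int = 1
    organisms: list = field(
        default_factory=lambda: [("Gallus gallus", "GGA"), ("Canis familiaris", "CFA")]
    )
    samples_per_organism: int = 2
    tissues: list = field(default_factory=lambda: ["Pituitary gland", "Liver"])
    genes_per_sample: int = 50
    variants_per_sample: int = 30
    lab_code: str = "UD"

    def validate(self):
        if self.samples_per_organism < 0 or self.genes_per_sample < 0 \
                or self.variants_per_sample < 0:
            raise ValueError("counts must be >= 0")
        if not self.organisms:
            raise ValueError("at least one organism required")


# ---------------------------------------------------------------------------
# gene model


def _gene_table(n: int):
    """Synthetic gene intervals: 5 chromosomes, 3 kb genes, disjoint."""
    genes = []
    for i in range(n):
        chrom = str((i % 5) + 1)
        start = 100000 * (i // 5 + 1) + 1
        stop = start + 2999
        genes.append({"genename": f"GENE{i + 1:04d}", "geneid": f"SYNG{i + 1:07d}",
                      "chrom": chrom, "start": start, "stop": stop})
    return genes


def _abundances(rng: random.Random, genes):
    fpkm = {g["genename"]: round(math.exp(rng.gauss(1.0, 1.0)), 4) for g in genes}
    total = sum(fpkm.values())
    tpm = {g: round(v / total * 1e6, 4) if total else 0.0 for g, v in fpkm.items()}
    return fpkm, tpm


# ---------------------------------------------------------------------------
# per-dialect writers


def _write_expression(path_dir, dialect, genes, fpkm, tpm, rng):
    if dialect == "cufflinks":
        path = os.path.join(path_dir, "genes.fpkm_tracking")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("tracking_id\tclass_code\tnearest_ref_id\tgene_id\tgene_short_name\t"
                     "tss_id\tlocus\tlength\tcoverage\tFPKM\tFPKM_conf_lo\tFPKM_conf_hi\t"
                     "FPKM_status\n")
            for g in genes:
                v = fpkm[g["genename"]]
                lo, hi = round(v * 0.8, 4), round(v * 1.2, 4)
                cov = round(v * 3.1, 4)
                fh.write(f"{g['geneid']}\t-\t-\t{g['geneid']}\t{g['genename']}\t-\t"
                         f"{g['chrom']}:{g['start']}-{g['stop']}\t3000\t{cov}\t{v}\t{lo}\t{hi}\tOK\n")
        return path
    if dialect == "stringtie":
        path = os.path.join(path_dir, "sample.gene_abund.tab")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("Gene ID\tGene Name\tReference\tStrand\tStart\tEnd\tCoverage\tFPKM\tTPM\n")
            for g in genes:
                v = fpkm[g["genename"]]
                fh.write(f"{g['geneid']}\t{g['genename']}\t{g['chrom']}\t+\t{g['start']}\t"
                         f"{g['stop']}\t{round(v * 3.1, 4)}\t{v}\t{tpm[g['genename']]}\n")
        return path
    if dialect == "kallisto":
        path = os.path.join(path_dir, "abundance.tsv")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("target_id\tlength\teff_length\test_counts\ttpm\n")
            for g in genes:
                t = tpm[g["genename"]]
                fh.write(f"{g['genename']}\t3000\t2800\t{round(t * 0.9, 3)}\t{t}\n")
        return path
    # salmon
    path = os.path.join(path_dir, "quant.sf")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Name\tLength\tEffectiveLength\tTPM\tNumReads\n")
        for g in genes:
            t = tpm[g["genename"]]
            fh.write(f"{g['genename']}\t3000\t2800.0\t{t}\t{round(t * 0.9, 3)}\n")
    return path


def _write_counts(path_dir, dialect, genes, counts, rng):
    specials = {"__no_feature": 50, "__ambiguous": 12, "__alignment_not_unique": 7}
    if dialect == "htseq":
        path = os.path.join(path_dir, "sample.counts")
        with open(path, "w", encoding="utf-8") as fh:
            for g in genes:
                fh.write(f"{g['genename']}\t{counts[g['genename']]}\n")
            for k, v in specials.items():
                fh.write(f"{k}\t{v}\n")
        return path, specials
    if dialect == "featurecounts":
        path = os.path.join(path_dir, "sample.featureCounts.txt")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write('# Program:featureCounts v1.6.0; Command:"featureCounts" "-a" "genes.gtf"\n')
            fh.write("Geneid\tChr\tStart\tEnd\tStrand\tLength\tsample.bam\n")
            for g in genes:
                fh.write(f"{g['genename']}\t{g['chrom']}\t{g['start']}\t{g['stop']}\t+\t3000\t"
                         f"{counts[g['genename']]}\n")
        return path, {}
    # star_quantmode
    star_specials = {"N_unmapped": 450, "N_multimapping": 120, "N_noFeature": 50,
                     "N_ambiguous": 12}
    path = os.path.join(path_dir, "sample.ReadsPerGene.out.tab")
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in star_specials.items():
            fh.write(f"{k}\t{v}\t{v}\t{v}\n")
        for g in genes:
            c = counts[g["genename"]]
            fh.write(f"{g['genename']}\t{c}\t{c // 2}\t{c - c // 2}\n")
    return path, star_specials


def _write_alignment_summary(path_dir, total, rate_pct):
    path = os.path.join(path_dir, "align_summary.txt")
    aligned0 = total - round(total * rate_pct / 100.0)
    once = round(total * rate_pct / 100.0 * 0.9)
    multi = round(total * rate_pct / 100.0) - once
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{total} reads; of these:\n")
        fh.write(f"  {total} (100.00%) were unpaired; of these:\n")
        fh.write(f"    {aligned0} ({aligned0 / total * 100:.2f}%) aligned 0 times\n")
        fh.write(f"    {once} ({once / total * 100:.2f}%) aligned exactly 1 time\n")
        fh.write(f"    {multi} ({multi / total * 100:.2f}%) aligned >1 times\n")
        fh.write(f"{rate_pct:.2f}% overall alignment rate\n")
    return path


def _make_variants(rng, genes, n, forced=None):
    """Variant tuples (chrom,pos,ref,alt,qual,vid,gt,gene,consequence).

    ``forced`` injects predetermined (gene, consequence, count) triples
    first; remaining variants are drawn uniformly over genes.  Positions are
    unique per (chrom, pos) within a sample.
    """
    taken = set()
    out = []

    def draw_one(g, consequence=None, force_snp=False):
        for _ in range(1000):
            pos = rng.randint(g["start"], g["stop"])
            if (g["chrom"], pos) not in taken:
                break
        taken.add((g["chrom"], pos))
        roll = 0.0 if force_snp else rng.random()
        ref = rng.choice(_BASES)
        if roll < 0.7:  # SNP
            alt = rng.choice([b for b in _BASES if b != ref])
        elif roll < 0.85:  # insertion
            alt = ref + "".join(rng.choice(_BASES) for _ in range(rng.randint(1, 3)))
        else:  # deletion
            ref = ref + "".join(rng.choice(_BASES) for _ in range(rng.randint(1, 3)))
            alt = ref[0]
        qual = round(rng.uniform(20, 100), 1)
        vid = f"rs{rng.randint(10000, 999999)}" if rng.random() < 0.3 else "."
        gt = rng.choice(["0/1", "1/1"])
        cons = consequence or rng.choice(_CONSEQUENCES)
        if len(ref) > 1 or len(alt) > 1:
            cons = rng.choice(["frameshift_variant", "inframe_insertion", "intron_variant"])
        out.append(dict(chrom=g["chrom"], pos=pos, ref=ref, alt=alt, qual=qual,
                        vid=vid, gt=gt, gene=g, consequence=cons))

    if forced:
        for gene, consequence, count in forced:
            for _ in range(count):
                draw_one(gene, consequence, force_snp=True)
    remaining = n - len(out)
    for _ in range(max(0, remaining)):
        draw_one(rng.choice(genes))
    out.sort(key=lambda v: (int(v["chrom"]) if v["chrom"].isdigit() else 99, v["pos"]))
    return out


def _write_vcf(path_dir, sample_name, variants):
    path = os.path.join(path_dir, f"{sample_name}.vcf")
    chroms = sorted({v["chrom"] for v in variants},
                    key=lambda c: int(c) if c.isdigit() else 99)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=GATK\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length=200000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_name}\n")
        for v in variants:
            fh.write(f"{v['chrom']}\t{v['pos']}\t{v['vid']}\t{v['ref']}\t{v['alt']}\t"
                     f"{v['qual']}\tPASS\t.\tGT\t{v['gt']}\n")
    return path


def _write_vep(path_dir, sample_name, variants):
    path = os.path.join(path_dir, f"{sample_name}.vep.txt")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("## ENSEMBL VARIANT EFFECT PREDICTOR\n")
        fh.write("#Uploaded_variation\tLocation\tAllele\tGene\tFeature\tFeature_type\t"
                 "Consequence\tcDNA_position\tCDS_position\tProtein_position\tAmino_acids\t"
                 "Codons\tExisting_variation\tExtra\n")
        for v in variants:
            g = v["gene"]
            protpos = (v["pos"] - g["start"]) // 3 + 1
            aa = "K" if "synonymous" in v["consequence"] else "K/R"
            codons = "aaA/aaG"
            fh.write(f".\t{v['chrom']}:{v['pos']}\t{v['alt']}\t{g['geneid']}\t"
                     f"SYNT{g['geneid'][4:]}\tTranscript\t{v['consequence']}\t-\t-\t"
                     f"{protpos}\t{aa}\t{codons}\t-\t"
                     f"SYMBOL={g['genename']};BIOTYPE=protein_coding\n")
    return path


_ANNOVAR_CONSEQ = {
    "synonymous_variant": "synonymous SNV",
    "missense_variant": "nonsynonymous SNV",
}


def _write_annovar(path_dir, sample_name, variants):
    path = os.path.join(path_dir, f"{sample_name}.multianno.txt")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Chr\tStart\tEnd\tRef\tAlt\tFunc.refGene\tGene.refGene\tGeneDetail.refGene\t"
                 "ExonicFunc.refGene\tAAChange.refGene\n")
        for v in variants:
            g = v["gene"]
            end = v["pos"] + len(v["ref"]) - 1
            exonic = _ANNOVAR_CONSEQ.get(v["consequence"], ".")
            func = "exonic" if exonic != "." else "intronic"
            protpos = (v["pos"] - g["start"]) // 3 + 1
            aachg = (f"{g['genename']}:NM_{g['geneid'][4:]}:exon2:"
                     f"c.{protpos * 3}A>G:p.K{protpos}K" if exonic != "." else ".")
            fh.write(f"{v['chrom']}\t{v['pos']}\t{end}\t{v['ref']}\t{v['alt']}\t{func}\t"
                     f"{g['genename']}\t.\t{exonic}\t{aachg}\n")
    return path


# ---------------------------------------------------------------------------
# metadata writers


def _write_metadata_tsv(path, rows):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Sample Name\tSample description\tDerived from\tOrganism\tOrganism part\t"
                 "First name\tLast name\tOrganization\n")
        for r in rows:
            fh.write("\t".join([r["sample_name"], r["description"], r["derived_from"],
                                r["organism"], r["organism_part"], r["first_name"],
                                r["last_name"], r["organization"]]) + "\n")
    return path


def _write_metadata_xlsx(path, rows):
    from openpyxl import Workbook

    wb = Workbook()
    animal = wb.active
    animal.title = "Animal"
    animal.append(["Sample Name", "Organism", "Material"])
    seen = set()
    for r in rows:
        if r["derived_from"] not in seen:
            seen.add(r["derived_from"])
            animal.append([r["derived_from"], r["organism"], "organism"])
    spec = wb.create_sheet("Specimen")
    spec.append(["Sample Name", "Sample description", "Derived from", "Organism Part",
                 "First name", "Last name", "Organization"])
    for r in rows:
        spec.append([r["sample_name"], r["description"], r["derived_from"],
                     r["organism_part"], r["first_name"], r["last_name"], r["organization"]])
    fixed = datetime(2018, 2, 23)
    wb.properties.created = fixed
    wb.properties.modified = fixed
    wb.save(path)
    _rezip_deterministic(path)
    return path


def _rezip_deterministic(path):
    """Rewrite a zip container with fixed entry order and timestamps so the
    same content always produces the same bytes."""
    with zipfile.ZipFile(path) as zin:
        entries = sorted(zin.namelist())
        blobs = {name: zin.read(name) for name in entries}
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zout:
        for name in entries:
            info = zipfile.ZipInfo(name, date_time=(2018, 2, 23, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o600 << 16
            zout.writestr(info, blobs[name])


# ---------------------------------------------------------------------------
# public generators


def generate_study(config: StudyConfig, outdir: str) -> dict:
    """Generate a full study tree under ``outdir``; returns the ledger dict.

    The ledger (also written to ``outdir/ledger.json``) records for every
    sample the generated gene count, abundance sums, the full per-gene count
    vector, variant class counts and alignment statistics, so importing
    tests can assert exact agreement.
    """
    config.validate()
    rng = random.Random(config.seed)
    os.makedirs(outdir, exist_ok=True)
    samples_root = os.path.join(outdir, "samples")
    os.makedirs(samples_root, exist_ok=True)
    genes = _gene_table(config.genes_per_sample)

    meta_rows = []
    ledger: dict = {"seed": config.seed, "samples": {}}
    idx = 0
    for organism, code in config.organisms:
        for j in range(config.samples_per_organism):
            name = f"{code}_{config.lab_code}_{1004 + 10 * j}"
            tissue = config.tissues[j % len(config.tissues)]
            meta_rows.append(dict(
                sample_name=name, description=f"{organism} specimen {j + 1}",
                derived_from=f"{code}_{config.lab_code}_A{j + 1:03d}",
                organism=organism, organism_part=tissue,
                first_name="Ada", last_name="Lovelace",
                organization="University of Delaware",
            ))
            sdir = os.path.join(samples_root, name)
            os.makedirs(sdir, exist_ok=True)
            quant = QUANTIFIERS[idx % len(QUANTIFIERS)]
            counter = COUNTERS[idx % len(COUNTERS)]
            annotator = ANNOTATORS[idx % len(ANNOTATORS)]

            total_reads = 10000 + rng.randint(0, 5000)
            rate_pct = round(rng.uniform(88.0, 99.0), 2)
            _write_alignment_summary(sdir, total_reads, rate_pct)
            mapped = round(total_reads * rate_pct / 100.0)

            fpkm, tpm = _abundances(rng, genes)
            _write_expression(sdir, quant, genes, fpkm, tpm, rng)
            counts = {g["genename"]: int(fpkm[g["genename"]] * 10) + rng.randint(0, 5)
                      for g in genes}
            _, specials = _write_counts(sdir, counter, genes, counts, rng)

            variants = _make_variants(rng, genes, config.variants_per_sample)
            _write_vcf(sdir, name, variants)
            if annotator == "VEP":
                _write_vep(sdir, name, variants)
            else:
                _write_annovar(sdir, name, variants)

            classes = {"SNP": 0, "insertion": 0, "deletion": 0, "complex": 0}
            for v in variants:
                if len(v["ref"]) == 1 and len(v["alt"]) == 1:
                    classes["SNP"] += 1
                elif len(v["alt"]) > len(v["ref"]):
                    classes["insertion"] += 1
                else:
                    classes["deletion"] += 1
            ledger["samples"][name] = {
                "organism": organism, "tissue": tissue,
                "quantifier": quant, "counter": counter, "annotation_source": annotator,
                "gene_count": len(genes),
                "fpkm": fpkm, "tpm": tpm,
                "fpkm_sum": round(sum(fpkm.values()), 4),
                "tpm_sum": round(sum(tpm.values()), 4),
                "counts": counts,
                "counts_total": sum(counts.values()),
                "special_total": sum(specials.values()),
                "variant_records": len(variants),
                "class_counts": classes,
                "annotation_count": len(variants),
                "total_reads": total_reads,
                "mapped_reads": mapped,
                "alignment_rate": mapped / total_reads,
            }
            idx += 1

    _write_metadata_tsv(os.path.join(outdir, "metadata.tsv"), meta_rows)
    _write_metadata_xlsx(os.path.join(outdir, "metadata.xlsx"), meta_rows)
    with open(os.path.join(outdir, "ledger.json"), "w", encoding="utf-8") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
    return ledger


OPTN_GENE = {"genename": "OPTN", "geneid": "SYNG0OPTN01", "chrom": "20",
             "start": 1500000, "stop": 1559999}  # synthetic coordinates


def generate_optn_scenario(seed: int, outdir: str) -> dict:
    """Two-chicken-sample scenario exercising the documented use case.

    GGA_UD_1004 and GGA_UD_1014 are Gallus gallus pituitary-gland samples.
    OPTN is expressed (nonzero FPKM) only in GGA_UD_1004; a housekeeping
    gene (ACTB) has the same FPKM in both samples, so its per-tissue summary
    has identical min/avg/max.  GGA_UD_1004 carries exactly one synonymous
    SNP in the OPTN region while GGA_UD_1014 carries ``k`` (>= 5) of them.
    OPTN coordinates here are synthetic placeholders, not the real assembly.
    """
    rng = random.Random(seed)
    os.makedirs(outdir, exist_ok=True)
    samples_root = os.path.join(outdir, "samples")
    os.makedirs(samples_root, exist_ok=True)

    background = _gene_table(10)
    actb = {"genename": "ACTB", "geneid": "SYNG0ACTB01", "chrom": "14",
            "start": 800001, "stop": 803000}
    genes = background + [actb, OPTN_GENE]
    k = 6

    sample_plan = {
        "GGA_UD_1004": {"optn_fpkm": 12.5, "optn_syn": 1},
        "GGA_UD_1014": {"optn_fpkm": 0.0, "optn_syn": k},
    }
    meta_rows = []
    ledger: dict = {"seed": seed, "k": k, "samples": {}}
    for name, plan in sample_plan.items():
        tissue = "Pituitary gland"
        meta_rows.append(dict(
            sample_name=name, description="Gallus gallus pituitary specimen",
            derived_from=f"GGA_UD_A{name[-4:]}", organism="Gallus gallus",
            organism_part=tissue, first_name="Ada", last_name="Lovelace",
            organization="University of Delaware",
        ))
        sdir = os.path.join(samples_root, name)
        os.makedirs(sdir, exist_ok=True)
        total_reads = 12000
        rate_pct = 95.5
        _write_alignment_summary(sdir, total_reads, rate_pct)

        fpkm, tpm = _abundances(rng, background)
        fpkm["ACTB"] = 33.0
        fpkm["OPTN"] = plan["optn_fpkm"]
        _write_expression(sdir, "cufflinks", genes, fpkm, None, rng)
        counts = {g["genename"]: int(fpkm[g["genename"]] * 10) for g in genes}
        _write_counts(sdir, "htseq", genes, counts, rng)

        forced = [(OPTN_GENE, "synonymous_variant", plan["optn_syn"]),
                  (background[0], "missense_variant", 2)]
        variants = _make_variants(rng, background, plan["optn_syn"] + 2, forced=forced)
        _write_vcf(sdir, name, variants)
        _write_vep(sdir, name, variants)
        ledger["samples"][name] = {
            "optn_fpkm": plan["optn_fpkm"],
            "optn_synonymous": plan["optn_syn"],
            "variant_records": len(variants),
            "actb_fpkm": 33.0,
        }

    _write_metadata_tsv(os.path.join(outdir, "metadata.tsv"), meta_rows)
    _write_metadata_xlsx(os.path.join(outdir, "metadata.xlsx"), meta_rows)
    with open(os.path.join(outdir, "ledger.json"), "w", encoding="utf-8") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
    return ledger


def import_study(store, outdir: str, metadata: str = "tsv", scope: str = "all"):
    """Convenience loader: metadata then every sample directory under a tree."""
    from . import ingest

    meta_path = os.path.join(outdir, "metadata.tsv" if metadata == "tsv" else "metadata.xlsx")
    names = ingest.import_metadata(store, meta_path)
    reports = {}
    samples_root = os.path.join(outdir, "samples")
    for name in names:
        sdir = os.path.join(samples_root, name)
        if os.path.isdir(sdir):
            manifest = ingest.discover_sample_dir(sdir, name)
            reports[name] = ingest.import_sample(store, manifest, scope=scope)
    return reports
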
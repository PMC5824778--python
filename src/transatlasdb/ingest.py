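"""Parsing, validation and transactional loading of per-sample analysis data.

Input side of the warehouse.  Sample metadata arrives as a FAANG-template
workbook (Animal + Specimen sheets) or a tab-delimited file; per-sample
analysis directories contribute an alignment summary (SAM text or an
aligner's own summary file), one expression-abundance file in the Cufflinks,
StringTie, kallisto or Salmon dialect, optionally a read-count file
(htseq-count, featureCounts or STAR quantMode), and optionally a VCF v4 file
with a matching VEP ``.vep.txt`` or ANNOVAR ``.multianno.txt`` annotation
table.

Imports are double-entry validated: for every stage the number of rows parsed
from the input file must equal the number of rows persisted, otherwise the
whole sample import rolls back (the relational transaction is aborted and the
columnar partitions are truncated to their pre-import row counts).  Analysis
results for a sample can be imported only once; deletion resets that.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field

from . import relational
from .errors import DialectError, TadUserError, ValidationError
from .relational import SampleRecord
from .store import Store

logger = logging.getLogger("transatlasdb")

QUANTIFIER_UNITS = {
    "cufflinks": "FPKM",
    "stringtie": "FPKM,TPM",
    "kallisto": "TPM",
    "salmon": "TPM",
}

STAGES = ("alignment", "expression", "counts", "variants", "annotation")


# ---------------------------------------------------------------------------
# sample naming


@dataclass(frozen=True)
class NameParts:
    """FAANG-style sample name: species code, lab code, alphanumeric id."""

    species_code: str
    lab_code: str
    sample_id: str

    def join(self) -> str:
        return f"{self.species_code}_{self.lab_code}_{self.sample_id}"


def parse_sample_name(name: str) -> NameParts:
    """Split ``GGA_UD_1004`` into (species, laboratory, sample id) parts."""
    parts = name.split("_")
    if len(parts) != 3 or not all(parts):
        raise ValidationError(
            f"sample name {name!r} does not follow the scheme "
            "<species>_<lab>_<id> (underscore-separated)"
        )
    return NameParts(*parts)


# ---------------------------------------------------------------------------
# sample metadata

_TSV_REQUIRED = {
    "sample name": "sample_name",
    "derived from": "derived_from",
    "organism": "organism",
    "organism part": "organism_part",
}
_TSV_OPTIONAL = {
    "sample description": "description",
    "first name": "first_name",
    "middle initial": "middle_initial",
    "last name": "last_name",
    "organization": "organization",
    "material": "material",
}


def parse_sample_metadata(path: str, format: str = "auto") -> list[SampleRecord]:
    """Read specimen records from a FAANG workbook or a tab-delimited file."""
    if not os.path.exists(path):
        raise ValidationError(f"metadata file not found: {path}")
    if format == "auto":
        format = "faang" if path.lower().endswith((".xlsx", ".xlsm")) else "tsv"
    if format == "faang":
        return _parse_faang_workbook(path)
    if format == "tsv":
        return _parse_metadata_tsv(path)
    raise TadUserError(f"unknown metadata format {format!r}")


def _parse_metadata_tsv(path: str) -> list[SampleRecord]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValidationError(f"metadata file is empty: {path}")
    header = [h.strip() for h in lines[0].split("\t")]
    lower = [h.lower() for h in header]
    colmap: dict[int, str] = {}
    for i, h in enumerate(lower):
        if h in _TSV_REQUIRED:
            colmap[i] = _TSV_REQUIRED[h]
        elif h in _TSV_OPTIONAL:
            colmap[i] = _TSV_OPTIONAL[h]
        else:
            logger.warning("ignoring unknown metadata column %r", header[i])
    for h, canonical in _TSV_REQUIRED.items():
        if canonical not in colmap.values():
            # error names the Table-1 style header
            pretty = h.capitalize() if h != "sample name" else "Sample name"
            raise ValidationError(f"missing required column: {pretty}")
    records = []
    for line in lines[1:]:
        cells = line.split("\t")
        kwargs = {}
        for i, attr in colmap.items():
            v = cells[i].strip() if i < len(cells) else ""
            kwargs[attr] = v or None
        rec = SampleRecord(**kwargs)
        rec.validate()
        _warn_name_scheme(rec.sample_name)
        records.append(rec)
    if not records:
        raise ValidationError(f"metadata file has a header but no rows: {path}")
    return records


def _parse_faang_workbook(path: str) -> list[SampleRecord]:
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    for sheet in ("Animal", "Specimen"):
        if sheet not in wb.sheetnames:
            raise ValidationError(f"missing required sheet: {sheet}")

    def sheet_rows(name):
        ws = wb[name]
        rows = list(ws.iter_rows(values_only=True))
        if not rows:
            raise ValidationError(f"sheet {name} is empty")
        header = [str(c).strip() if c is not None else "" for c in rows[0]]
        out = []
        for raw in rows[1:]:
            if raw is None or all(c is None or str(c).strip() == "" for c in raw):
                continue
            out.append(
                {
                    header[i].lower(): (str(raw[i]).strip() if i < len(raw) and raw[i] is not None else "")
                    for i in range(len(header))
                }
            )
        return header, out

    a_header, animals = sheet_rows("Animal")
    s_header, specimens = sheet_rows("Specimen")
    for col, sheet, hdr in (
        ("Sample Name", "Animal", a_header),
        ("Organism", "Animal", a_header),
        ("Sample Name", "Specimen", s_header),
        ("Organism Part", "Specimen", s_header),
    ):
        if col.lower() not in [h.lower() for h in hdr]:
            raise ValidationError(f"missing required column: {col} ({sheet} sheet)")
    organism_of = {a["sample name"]: a["organism"] for a in animals}
    records = []
    for sp in specimens:
        derived = sp.get("derived from", "")
        organism = organism_of.get(derived, "")
        rec = SampleRecord(
            sample_name=sp.get("sample name") or None,
            derived_from=derived or None,
            organism=organism or None,
            organism_part=sp.get("organism part") or None,
            description=sp.get("sample description") or None,
            first_name=sp.get("first name") or None,
            middle_initial=sp.get("middle initial") or None,
            last_name=sp.get("last name") or None,
            organization=sp.get("organization") or None,
            material=sp.get("material") or None,
        )
        rec.validate()
        _warn_name_scheme(rec.sample_name)
        records.append(rec)
    if not records:
        raise ValidationError(f"no specimen rows in workbook: {path}")
    return records


def _warn_name_scheme(name: str):
    # Naming-scheme violations warn rather than fail: the FAANG scheme is
    # recommended, free-form names from plain tab files are still accepted.
    try:
        parse_sample_name(name)
    except ValidationError as exc:
        logger.warning("%s", exc)


# ---------------------------------------------------------------------------
# alignment statistics


@dataclass
class MapStatsRecord:
    sample_name: str | None
    total_reads: int
    mapped_reads: int
    alignment_rate: float
    mapper_name: str
    date: str | None = None


def summarize_alignment(path: str, sample_name: str | None = None) -> MapStatsRecord:
    """Extract read-mapping statistics from a SAM file or an aligner summary.

    SAM input: total reads are records with neither the secondary (0x100)
    nor the supplementary (0x800) flag set; mapped reads additionally have
    the unmapped flag (0x4) clear.  Summary input: the TopHat
    ``align_summary.txt`` and HISAT2 stderr-summary dialects are recognized.
    """
    if path.lower().endswith((".sam", ".bam")):
        return _summarize_sam(path, sample_name)
    with open(path, encoding="utf-8", errors="replace") as fh:
        text = fh.read()
    m_rate = re.search(r"([\d.]+)%\s+overall alignment rate", text)
    m_total = re.search(r"^\s*(\d+)\s+reads; of these:", text, re.MULTILINE)
    if m_rate and m_total:
        total = int(m_total.group(1))
        rate_pct = float(m_rate.group(1))
        mapped = round(total * rate_pct / 100.0)
        rate = mapped / total if total else 0.0
        return MapStatsRecord(sample_name, total, mapped, rate, "HISAT2")
    m_input = re.search(r"Input\s*:\s*(\d+)", text)
    m_mapped = re.search(r"Mapped\s*:\s*(\d+)", text)
    if m_input and m_mapped:
        total = int(m_input.group(1))
        mapped = int(m_mapped.group(1))
        rate = mapped / total if total else 0.0
        return MapStatsRecord(sample_name, total, mapped, rate, "TopHat2")
    if text.startswith("@") or re.match(r"^[^\t\n]+(\t[^\t\n]*){10,}", text):
        return _summarize_sam(path, sample_name)
    raise DialectError(
        f"unrecognized alignment summary dialect in {path} "
        "(tried: SAM, HISAT2 summary, TopHat align_summary)"
    )


def _summarize_sam(path: str, sample_name: str | None) -> MapStatsRecord:
    import pysam

    total = mapped = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            total += 1
            if not rec.is_unmapped:
                mapped += 1
    rate = mapped / total if total else 0.0
    return MapStatsRecord(sample_name, total, mapped, rate, "SAM")


# ---------------------------------------------------------------------------
# expression abundances

_CUFFLINKS_REQUIRED = {"tracking_id", "gene_id", "gene_short_name", "locus",
                       "FPKM", "FPKM_conf_lo", "FPKM_conf_hi", "FPKM_status"}
_STRINGTIE_REQUIRED = {"Gene ID", "Gene Name", "Reference", "Start", "End",
                       "Coverage", "FPKM", "TPM"}
_KALLISTO_REQUIRED = {"target_id", "length", "eff_length", "est_counts", "tpm"}
_SALMON_REQUIRED = {"Name", "Length", "EffectiveLength", "TPM", "NumReads"}


def _read_table(path: str):
    import pandas as pd

    return pd.read_csv(path, sep="\t", dtype=str, comment=None)


def _num(v, *, allow_missing=True):
    if v is None:
        return None
    s = str(v).strip()
    if s in ("", "-", ".", "NULL", "nan"):
        return None
    return float(s)


def _check_nonneg(value, what: str, where: str):
    if value is not None and value < 0:
        raise ValidationError(f"negative {what} in {where}: {value}")


def parse_expression(path: str, dialect: str) -> list[dict]:
    """Parse an abundance file into rows normalized to the expression fields.

    Fields a dialect lacks (e.g. TPM for Cufflinks, FPKM for kallisto) come
    back as None and are stored as NULL.
    """
    if dialect not in QUANTIFIER_UNITS:
        raise DialectError(f"unknown quantifier dialect {dialect!r}")
    df = _read_table(path)
    cols = set(df.columns)
    rows: list[dict] = []
    if dialect == "cufflinks":
        missing = _CUFFLINKS_REQUIRED - cols
        if missing:
            raise DialectError(f"not a Cufflinks genes.fpkm_tracking file: missing {sorted(missing)}")
        for _, r in df.iterrows():
            chrom, start, stop = _parse_locus(r["locus"])
            row = dict(
                chrom=chrom, start=start, stop=stop,
                genename=_s(r["gene_short_name"]), geneid=_s(r["gene_id"]),
                coverage=_num(r.get("coverage")), tpm=None,
                fpkm=_num(r["FPKM"]), fpkmconflow=_num(r["FPKM_conf_lo"]),
                fpkmconfhigh=_num(r["FPKM_conf_hi"]), fpkmstatus=_s(r["FPKM_status"]),
            )
            rows.append(row)
    elif dialect == "stringtie":
        missing = _STRINGTIE_REQUIRED - cols
        if missing:
            raise DialectError(f"not a StringTie gene-abundance file: missing {sorted(missing)}")
        for _, r in df.iterrows():
            rows.append(dict(
                chrom=_s(r["Reference"]), start=_int(r["Start"]), stop=_int(r["End"]),
                genename=_s(r["Gene Name"]), geneid=_s(r["Gene ID"]),
                coverage=_num(r["Coverage"]), tpm=_num(r["TPM"]), fpkm=_num(r["FPKM"]),
                fpkmconflow=None, fpkmconfhigh=None, fpkmstatus=None,
            ))
    elif dialect == "kallisto":
        missing = _KALLISTO_REQUIRED - cols
        if missing:
            raise DialectError(f"not a kallisto abundance.tsv file: missing {sorted(missing)}")
        for _, r in df.iterrows():
            rows.append(dict(
                chrom=None, start=None, stop=None,
                genename=_s(r["target_id"]), geneid=_s(r["target_id"]),
                coverage=None, tpm=_num(r["tpm"]), fpkm=None,
                fpkmconflow=None, fpkmconfhigh=None, fpkmstatus=None,
            ))
    else:  # salmon
        missing = _SALMON_REQUIRED - cols
        if missing:
            raise DialectError(f"not a Salmon quant.sf file: missing {sorted(missing)}")
        for _, r in df.iterrows():
            rows.append(dict(
                chrom=None, start=None, stop=None,
                genename=_s(r["Name"]), geneid=_s(r["Name"]),
                coverage=None, tpm=_num(r["TPM"]), fpkm=None,
                fpkmconflow=None, fpkmconfhigh=None, fpkmstatus=None,
            ))
    for i, row in enumerate(rows):
        for k in ("coverage", "tpm", "fpkm"):
            _check_nonneg(row[k], k, f"{path} row {i}")
    return rows


def _s(v):
    if v is None:
        return None
    s = str(v).strip()
    return s if s not in ("", "-", ".", "nan") else None


def _int(v):
    s = _s(v)
    return int(float(s)) if s is not None else None


def _parse_locus(locus):
    s = _s(locus)
    if not s or ":" not in s:
        return None, None, None
    chrom, rng = s.split(":", 1)
    if "-" in rng:
        a, b = rng.split("-", 1)
        return chrom, int(a), int(b)
    return chrom, int(rng), int(rng)


# ---------------------------------------------------------------------------
# read counts


def parse_readcounts(path: str, dialect: str) -> tuple[list[dict], dict]:
    """Parse per-gene read counts; returns (gene rows, special-row tallies).

    htseq ``__``-prefixed rows (``__no_feature`` ...) and STAR ``N_`` rows
    are excluded from gene rows but tallied for the import report.
    """
    rows: list[dict] = []
    specials: dict[str, int] = {}
    if dialect == "htseq":
        with open(path, encoding="utf-8") as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise DialectError(f"{path}:{ln}: expected two tab-separated columns")
                gene, count = parts
                n = _require_int(count, path, ln)
                if gene.startswith("__"):
                    specials[gene] = n
                else:
                    rows.append(dict(genename=gene, readcount=n))
        if not rows and not specials:
            logger.warning("read-count file %s is empty", path)
    elif dialect == "featurecounts":
        with open(path, encoding="utf-8") as fh:
            lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#") and ln.strip()]
        if not lines:
            logger.warning("read-count file %s is empty", path)
            return rows, specials
        header = lines[0].split("\t")
        if header[0] != "Geneid":
            raise DialectError(f"not a featureCounts table: first column is {header[0]!r}")
        for ln, line in enumerate(lines[1:], 2):
            parts = line.split("\t")
            rows.append(dict(genename=parts[0], readcount=_require_int(parts[-1], path, ln)))
    elif dialect == "star_quantmode":
        with open(path, encoding="utf-8") as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    raise DialectError(f"{path}:{ln}: expected >= 2 columns")
                gene = parts[0]
                n = _require_int(parts[1], path, ln)  # column 2 = unstranded
                if gene.startswith("N_"):
                    specials[gene] = n
                else:
                    rows.append(dict(genename=gene, readcount=n))
    else:
        raise DialectError(f"unknown counter dialect {dialect!r}")
    return rows, specials


def _require_int(s: str, path: str, ln: int) -> int:
    try:
        n = int(s)
    except ValueError:
        raise ValidationError(f"{path}:{ln}: non-integer count {s!r}") from None
    if n < 0:
        raise ValidationError(f"{path}:{ln}: negative count {n}")
    return n


# ---------------------------------------------------------------------------
# variants


@dataclass
class VariantRecord:
    chrom: str
    position: int
    ref: str
    alt: str
    quality: float | None
    dbsnpvariant: str | None
    genotype: str | None


def parse_vcf(path: str) -> list[VariantRecord]:
    """Parse a single-sample VCF v4; one record per data line per ALT allele."""
    if not os.path.exists(path):
        raise ValidationError(f"VCF file not found: {path}")
    n_data_lines = 0
    has_chrom_header = False
    with open(path, encoding="utf-8", errors="replace") as fh:
        for line in fh:
            if line.startswith("#CHROM"):
                has_chrom_header = True
            elif line.strip() and not line.startswith("#"):
                n_data_lines += 1
    if not has_chrom_header:
        raise ValidationError(f"missing #CHROM header line in {path}")

    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    n_parsed_lines = 0
    n_missing_gt = 0
    vcf = VCF(path)
    try:
        for v in vcf:
            n_parsed_lines += 1
            gt = None
            if v.genotypes:
                a = v.genotypes[0]
                if len(a) >= 2:
                    sep = "|" if (len(a) > 2 and a[-1]) else "/"
                    gt = sep.join("." if x < 0 else str(x) for x in a[:-1])
            else:
                n_missing_gt += 1
            alts = list(v.ALT) or []
            for alt in alts:
                records.append(
                    VariantRecord(
                        chrom=v.CHROM,
                        position=v.POS,
                        ref=v.REF,
                        alt=alt,
                        quality=float(v.QUAL) if v.QUAL is not None else None,
                        dbsnpvariant=v.ID,
                        genotype=gt,
                    )
                )
    except Exception as exc:  # htslib parse failure mid-file
        raise ValidationError(f"VCF parse failed mid-file in {path}: {exc}") from exc
    finally:
        vcf.close()
    if n_missing_gt:
        logger.warning(
            "%d record(s) in %s have no GT field; zygosity will be NULL",
            n_missing_gt, path,
        )
    if n_parsed_lines != n_data_lines:
        raise ValidationError(
            f"truncated or malformed VCF {path}: {n_data_lines} data lines, "
            f"{n_parsed_lines} parsed"
        )
    return records


def classify_variant(ref: str, alt: str) -> str:
    """Classify by allele lengths: SNP, insertion, deletion or complex."""
    if not ref or not alt:
        raise ValidationError("empty allele")
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if len(alt) > len(ref) and alt.startswith(ref):
        return "insertion"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "deletion"
    return "complex"


def call_zygosity(genotype: str | None) -> str | None:
    """homozygous iff both GT alleles equal; any missing allele gives NULL."""
    if genotype is None:
        return None
    m = re.fullmatch(r"(\.|\d+)([/|])(\.|\d+)", genotype)
    if not m:
        raise ValidationError(f"malformed GT {genotype!r}")
    a, _, b = m.groups()
    if a == "." or b == ".":
        return None
    return "homozygous" if a == b else "heterozygous"


# ---------------------------------------------------------------------------
# variant annotations


@dataclass
class VariantAnnotationRecord:
    chrom: str
    position: int
    alt: str
    source: str
    consequence: str | None = None
    geneid: str | None = None
    genename: str | None = None
    transcript: str | None = None
    feature: str | None = None
    genetype: str | None = None
    proteinposition: int | None = None
    aachange: str | None = None
    codonchange: str | None = None


_VEP_REQUIRED = {"#Uploaded_variation", "Location", "Allele", "Gene", "Feature",
                 "Feature_type", "Consequence", "Protein_position", "Amino_acids", "Codons"}


def parse_vep(path: str) -> list[VariantAnnotationRecord]:
    """Parse default VEP tab-delimited output (``.vep.txt``)."""
    header = None
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line.strip():
                continue
            if line.startswith("#Uploaded_variation"):
                header = line.split("\t")
                continue
            if header is None:
                raise DialectError(f"not a VEP output file (no #Uploaded_variation header): {path}")
            rows.append(dict(zip(header, line.split("\t"))))
    if header is None:
        raise DialectError(f"not a VEP output file (no #Uploaded_variation header): {path}")
    missing = _VEP_REQUIRED - set(header)
    if missing:
        raise DialectError(f"VEP header missing columns {sorted(missing)} in {path}")
    records = []
    for r in rows:
        loc = r["Location"]
        chrom, _, rng = loc.partition(":")
        pos = int(rng.split("-")[0])  # indel ranges: take the range start
        extra = dict(
            kv.split("=", 1) for kv in r.get("Extra", "").split(";") if "=" in kv
        ) if r.get("Extra") else {}
        records.append(
            VariantAnnotationRecord(
                chrom=chrom,
                position=pos,
                alt=r["Allele"],
                source="VEP",
                consequence=_dash(r["Consequence"]),
                geneid=_dash(r["Gene"]),
                genename=_dash(extra.get("SYMBOL", "-")),
                transcript=_dash(r["Feature"]),
                feature=_dash(r["Feature_type"]),
                genetype=_dash(extra.get("BIOTYPE", "-")),
                proteinposition=_dash_int(r["Protein_position"]),
                aachange=_dash(r["Amino_acids"]),
                codonchange=_dash(r["Codons"]),
            )
        )
    return records


def _dash(v):
    v = (v or "").strip()
    return None if v in ("-", "", ".") else v


def _dash_int(v):
    v = _dash(v)
    if v is None:
        return None
    m = re.match(r"(\d+)", v)
    return int(m.group(1)) if m else None


def parse_annovar(path: str) -> list[VariantAnnotationRecord]:
    """Parse ANNOVAR ``.multianno.txt`` output (refGene-style columns)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise DialectError(f"empty ANNOVAR file: {path}")
    header = lines[0].split("\t")
    if header[:5] != ["Chr", "Start", "End", "Ref", "Alt"]:
        raise DialectError(f"not an ANNOVAR multianno file (bad leading columns): {path}")

    def col(prefix):
        for h in header:
            if h == prefix or h.startswith(prefix + "."):
                return h
        return None

    func_c, gene_c, exonic_c, aachg_c = (col("Func"), col("Gene"), col("ExonicFunc"), col("AAChange"))
    if not (func_c and gene_c and exonic_c and aachg_c):
        raise DialectError(f"ANNOVAR header lacks Func/Gene/ExonicFunc/AAChange columns: {path}")
    records = []
    for line in lines[1:]:
        r = dict(zip(header, line.split("\t")))
        transcript = proteinposition = aachange = codonchange = None
        aa = _dot(r.get(aachg_c))
        if aa:
            # first entry of e.g. "OPTN:NM_001:exon3:c.135A>G:p.K45K"
            parts = aa.split(",")[0].split(":")
            if len(parts) >= 2:
                transcript = parts[1]
            for p in parts:
                if p.startswith("c."):
                    codonchange = p
                elif p.startswith("p."):
                    aachange = p[2:]
                    m = re.search(r"(\d+)", aachange)
                    proteinposition = int(m.group(1)) if m else None
        records.append(
            VariantAnnotationRecord(
                chrom=r["Chr"],
                position=int(r["Start"]),
                alt=r["Alt"],
                source="ANNOVAR",
                consequence=_dot(r.get(exonic_c)),
                geneid=None,
                genename=_dot(r.get(gene_c)),
                transcript=transcript,
                feature=None,
                genetype=_dot(r.get(func_c)),
                proteinposition=proteinposition,
                aachange=aachange,
                codonchange=codonchange,
            )
        )
    return records


def _dot(v):
    v = (v or "").strip()
    return None if v in (".", "", "-") else v


# ---------------------------------------------------------------------------
# directory discovery


@dataclass
class Manifest:
    """Detected file roles and dialects for one sample directory."""

    sample_name: str
    path: str
    roles: dict = field(default_factory=dict)  # role -> path
    quantifier: str | None = None
    counter: str | None = None


def _is_htseq_like(path: str) -> bool:
    try:
        with open(path, encoding="utf-8") as fh:
            first = fh.readline().rstrip("\n")
    except OSError:
        return False
    parts = first.split("\t")
    if len(parts) != 2:
        return False
    try:
        int(parts[1])
    except ValueError:
        return False
    return True


def discover_sample_dir(path: str, sample_name: str) -> Manifest:
    """Assign file roles by the suffix contract and sniff dialects."""
    if not os.path.isdir(path):
        raise ValidationError(f"sample directory not found: {path}")
    manifest = Manifest(sample_name=sample_name, path=path)
    expression: list[tuple[str, str]] = []
    counters: list[tuple[str, str]] = []
    for fname in sorted(os.listdir(path)):
        full = os.path.join(path, fname)
        if not os.path.isfile(full):
            continue
        low = fname.lower()
        if low == "align_summary.txt" or low.endswith("summary.txt") or low.endswith(".sam"):
            _assign(manifest.roles, "alignment_summary", full)
        elif low == "genes.fpkm_tracking":
            expression.append(("cufflinks", full))
        elif "gene_abund" in low and low.endswith(".tab"):
            expression.append(("stringtie", full))
        elif low == "abundance.tsv":
            expression.append(("kallisto", full))
        elif low == "quant.sf":
            expression.append(("salmon", full))
        elif low.endswith(".vep.txt"):
            _assign(manifest.roles, "vep", full)
        elif low.endswith(".multianno.txt"):
            _assign(manifest.roles, "annovar", full)
        elif low.endswith(".vcf"):
            _assign(manifest.roles, "vcf", full)
        elif "featurecounts" in low or low.endswith(".fc.txt"):
            counters.append(("featurecounts", full))
        elif low.endswith("readspergene.out.tab"):
            counters.append(("star_quantmode", full))
        elif low.endswith(".counts") or (low.endswith(".txt") and _is_htseq_like(full)):
            counters.append(("htseq", full))
    if len(expression) > 1:
        raise ValidationError(
            "ambiguous expression role, candidates: "
            + ", ".join(os.path.basename(p) for _, p in expression)
        )
    if len(counters) > 1:
        raise ValidationError(
            "ambiguous read-count role, candidates: "
            + ", ".join(os.path.basename(p) for _, p in counters)
        )
    if expression:
        manifest.quantifier, p = expression[0]
        manifest.roles["expression"] = p
    if counters:
        manifest.counter, p = counters[0]
        manifest.roles["readcounts"] = p
    if "vep" in manifest.roles and "annovar" in manifest.roles:
        raise ValidationError("both VEP and ANNOVAR annotation files present; supply one")
    return manifest


def _assign(roles: dict, role: str, path: str):
    if role in roles:
        raise ValidationError(
            f"ambiguous {role} role, candidates: "
            f"{os.path.basename(roles[role])}, {os.path.basename(path)}"
        )
    roles[role] = path


# ---------------------------------------------------------------------------
# import / delete


@dataclass
class ImportReport:
    sample_name: str
    stages: dict = field(default_factory=dict)  # stage -> (parsed, stored, status)
    log_path: str = ""

    @property
    def ok(self) -> bool:
        return all(s[2] == "ok" for s in self.stages.values()) and bool(self.stages)


@dataclass
class DeleteReport:
    sample_name: str
    relational_rows: int
    columnar_rows: int


def _caller_from_vcf(path: str) -> str:
    with open(path, encoding="utf-8", errors="replace") as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            if line.startswith("##source="):
                return line.strip().split("=", 1)[1]
    return "unknown"


def import_metadata(store: Store, path: str, format: str = "auto") -> list[str]:
    """Import sample metadata records; returns the inserted sample names."""
    records = parse_sample_metadata(path, format)
    con = store.connection
    names = []
    try:
        for rec in records:
            relational.insert_sample(con, rec)
            names.append(rec.sample_name)
        con.commit()
    except Exception:
        con.rollback()
        raise
    store.log_action(
        f"metadata {os.path.basename(path)} samples={len(names)}",
        [f"metadata sample={n} status=ok" for n in names],
    )
    return names


def import_sample(store: Store, manifest: Manifest, scope: str = "all") -> ImportReport:
    """Load one sample's analysis results into both stores, atomically.

    Scope ``gene`` loads expression (+counts), ``variant`` loads variants
    (+annotations), ``all`` loads everything present.  Every columnar row is
    denormalized with the sample's name, organism and tissue from the
    relational store.  Double-entry rule: rows parsed must equal rows stored
    for every stage or the whole import rolls back.
    """
    if scope not in ("all", "gene", "variant"):
        raise TadUserError(f"unknown import scope {scope!r}")
    con = store.connection
    ctx = relational.sample_context(con, manifest.sample_name)
    if ctx is None:
        raise ValidationError(
            f"unknown sample {manifest.sample_name!r}: import metadata first"
        )
    sid = ctx["sampleid"]
    want_gene = scope in ("all", "gene")
    want_variant = scope in ("all", "variant")
    if want_gene and con.execute(
        "SELECT 1 FROM GeneStats WHERE sampleid = ?", (sid,)
    ).fetchone():
        raise ValidationError(f"already imported: gene results for {manifest.sample_name}")
    if want_variant and scope == "variant" and "vcf" not in manifest.roles:
        raise ValidationError("variant file absent: no .vcf in sample directory")
    if want_variant and "vcf" in manifest.roles and con.execute(
        "SELECT 1 FROM VarSummary WHERE sampleid = ?", (sid,)
    ).fetchone():
        raise ValidationError(f"already imported: variant results for {manifest.sample_name}")
    if want_gene and "expression" not in manifest.roles:
        raise ValidationError("expression file absent: no abundance file in sample directory")

    # ---- parse phase (no writes yet) ----
    now = relational._now()
    mapstats = None
    if "alignment_summary" in manifest.roles:
        mapstats = summarize_alignment(manifest.roles["alignment_summary"], manifest.sample_name)
    expr_rows: list[dict] = []
    count_rows: list[dict] = []
    specials: dict = {}
    if want_gene:
        expr_rows = parse_expression(manifest.roles["expression"], manifest.quantifier)
        if "readcounts" in manifest.roles:
            count_rows, specials = parse_readcounts(manifest.roles["readcounts"], manifest.counter)
    variants: list[VariantRecord] = []
    annotations: list[VariantAnnotationRecord] = []
    anno_source = "none"
    if want_variant and "vcf" in manifest.roles:
        variants = parse_vcf(manifest.roles["vcf"])
        if "vep" in manifest.roles:
            annotations = parse_vep(manifest.roles["vep"])
            anno_source = "VEP"
        elif "annovar" in manifest.roles:
            annotations = parse_annovar(manifest.roles["annovar"])
            anno_source = "ANNOVAR"

    anno_by_key: dict[tuple, list[VariantAnnotationRecord]] = {}
    for a in annotations:
        anno_by_key.setdefault((a.chrom, a.position, a.alt), []).append(a)

    report = ImportReport(sample_name=manifest.sample_name)
    expr_part = store.partition("expression")
    count_part = store.partition("readcount")
    var_part = store.partition("variant")
    pre_counts = {
        "expression": expr_part.row_count,
        "readcount": count_part.row_count,
        "variant": var_part.row_count,
    }
    denorm = dict(sampleid=ctx["samplename"], organism=ctx["organism"], tissue=ctx["tissue"])

    try:
        con.execute("BEGIN")
        # alignment
        if mapstats is not None:
            con.execute(
                "INSERT OR REPLACE INTO MapStats (sampleid, totalreads, mappedreads, "
                "alignmentrate, mappername, mapdate, loaddate) VALUES (?, ?, ?, ?, ?, ?, ?)",
                (sid, mapstats.total_reads, mapstats.mapped_reads, mapstats.alignment_rate,
                 mapstats.mapper_name, mapstats.date, now),
            )
            con.execute(
                "INSERT INTO Metadata (sampleid, stage, toolname, loaddate) VALUES (?, ?, ?, ?)",
                (sid, "alignment", mapstats.mapper_name, now),
            )
            con.execute(
                "INSERT INTO CommandSyntax (sampleid, stage, toolname, invocation, loaddate)"
                " VALUES (?, ?, ?, ?, ?)",
                (sid, "alignment", mapstats.mapper_name,
                 manifest.roles["alignment_summary"], now),
            )
            report.stages["alignment"] = (1, 1, "ok")
        # expression
        if want_gene:
            stored = expr_part.append_rows([{**denorm, **r} for r in expr_rows])
            con.execute(
                "INSERT INTO GeneStats (sampleid, genesquantified, quantifiername, units, "
                "loaddate) VALUES (?, ?, ?, ?, ?)",
                (sid, stored, manifest.quantifier, QUANTIFIER_UNITS[manifest.quantifier], now),
            )
            con.execute(
                "INSERT INTO Metadata (sampleid, stage, toolname, loaddate) VALUES (?, ?, ?, ?)",
                (sid, "expression", manifest.quantifier, now),
            )
            con.execute(
                "INSERT INTO CommandSyntax (sampleid, stage, toolname, invocation, loaddate)"
                " VALUES (?, ?, ?, ?, ?)",
                (sid, "expression", manifest.quantifier, manifest.roles["expression"], now),
            )
            _stage(report, "expression", len(expr_rows), stored)
            if "readcounts" in manifest.roles:
                stored = count_part.append_rows(
                    [dict(sampleid=denorm["sampleid"], genename=r["genename"],
                          readcount=r["readcount"], organism=denorm["organism"],
                          tissue=denorm["tissue"]) for r in count_rows]
                )
                con.execute(
                    "INSERT INTO ReadCounts (sampleid, genescounted, totalcounts, countername,"
                    " specialcounts, loaddate) VALUES (?, ?, ?, ?, ?, ?)",
                    (sid, stored, sum(r["readcount"] for r in count_rows),
                     manifest.counter, sum(specials.values()), now),
                )
                con.execute(
                    "INSERT INTO Metadata (sampleid, stage, toolname, loaddate)"
                    " VALUES (?, ?, ?, ?)",
                    (sid, "counts", manifest.counter, now),
                )
                con.execute(
                    "INSERT INTO CommandSyntax (sampleid, stage, toolname, invocation, loaddate)"
                    " VALUES (?, ?, ?, ?, ?)",
                    (sid, "counts", manifest.counter, manifest.roles["readcounts"], now),
                )
                _stage(report, "counts", len(count_rows), stored)
        # variants
        if want_variant and "vcf" in manifest.roles:
            caller = _caller_from_vcf(manifest.roles["vcf"])
            class_counts = {"SNP": 0, "insertion": 0, "deletion": 0, "complex": 0}
            var_stored = 0
            anno_stored = 0
            columnar_rows = []
            for v in variants:
                vclass = classify_variant(v.ref, v.alt)
                class_counts[vclass] += 1
                zyg = call_zygosity(v.genotype)
                varid = con.execute(
                    "INSERT INTO VarResult (sampleid, chrom, position, refallele, altallele,"
                    " quality, dbsnpvariant, variantclass, zygosity, loaddate)"
                    " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                    (sid, v.chrom, v.position, v.ref, v.alt, v.quality,
                     v.dbsnpvariant, vclass, zyg, now),
                ).lastrowid
                var_stored += 1
                matched = anno_by_key.get((v.chrom, v.position, v.alt), [])
                base = dict(
                    **denorm, chrom=v.chrom, position=v.position, refallele=v.ref,
                    altallele=v.alt, quality=v.quality, dbsnpvariant=v.dbsnpvariant,
                    variantclass=vclass, zygosity=zyg,
                )
                if matched:
                    for a in matched:
                        con.execute(
                            "INSERT INTO VarAnnotation (varid, source, consequence, geneid,"
                            " genename, transcript, feature, genetype, proteinposition,"
                            " aachange, codonchange, loaddate)"
                            " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                            (varid, a.source, a.consequence, a.geneid, a.genename,
                             a.transcript, a.feature, a.genetype, a.proteinposition,
                             a.aachange, a.codonchange, now),
                        )
                        anno_stored += 1
                        columnar_rows.append({**base, "source": a.source,
                                              "consequence": a.consequence,
                                              "geneid": a.geneid, "genename": a.genename,
                                              "transcript": a.transcript, "feature": a.feature,
                                              "genetype": a.genetype,
                                              "proteinposition": a.proteinposition,
                                              "aachange": a.aachange,
                                              "codonchange": a.codonchange})
                else:
                    columnar_rows.append(base)
            con.execute(
                "INSERT INTO VarSummary (sampleid, totalvariants, snpcount, insertioncount,"
                " deletioncount, complexcount, callername, annotationsource, loaddate)"
                " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)",
                (sid, len(variants), class_counts["SNP"], class_counts["insertion"],
                 class_counts["deletion"], class_counts["complex"], caller, anno_source, now),
            )
            var_part.append_rows(columnar_rows)
            con.execute(
                "INSERT INTO Metadata (sampleid, stage, toolname, loaddate) VALUES (?, ?, ?, ?)",
                (sid, "variants", caller, now),
            )
            con.execute(
                "INSERT INTO CommandSyntax (sampleid, stage, toolname, invocation, loaddate)"
                " VALUES (?, ?, ?, ?, ?)",
                (sid, "variants", caller, manifest.roles["vcf"], now),
            )
            _stage(report, "variants", len(variants), var_stored)
            if anno_source != "none":
                con.execute(
                    "INSERT INTO Metadata (sampleid, stage, toolname, loaddate)"
                    " VALUES (?, ?, ?, ?)",
                    (sid, "annotation", anno_source, now),
                )
                con.execute(
                    "INSERT INTO CommandSyntax (sampleid, stage, toolname, invocation, loaddate)"
                    " VALUES (?, ?, ?, ?, ?)",
                    (sid, "annotation", anno_source,
                     manifest.roles.get("vep") or manifest.roles.get("annovar"), now),
                )
                _stage(report, "annotation", len(annotations), anno_stored)
        # double-entry gate
        bad = [s for s, (p, st, status) in report.stages.items() if status != "ok"]
        if bad:
            raise ValidationError(
                "double-entry mismatch in stage(s) "
                + ", ".join(f"{s} (parsed={report.stages[s][0]}, stored={report.stages[s][1]})"
                            for s in bad)
            )
        con.commit()
    except Exception:
        con.rollback()
        for name, part in (("expression", expr_part), ("readcount", count_part),
                           ("variant", var_part)):
            if part.row_count != pre_counts[name]:
                part.truncate(pre_counts[name])
        raise

    report.log_path = store.log_action(
        f"data2db {manifest.sample_name} scope={scope}",
        [f"import {manifest.sample_name} {stage} parsed={p} stored={s} {status}"
         for stage, (p, s, status) in report.stages.items()],
    )
    return report


def _stage(report: ImportReport, stage: str, parsed: int, stored: int):
    report.stages[stage] = (parsed, stored, "ok" if parsed == stored else "mismatch")


def delete_sample(store: Store, sample_name: str) -> DeleteReport:
    """Remove a sample and every result row referencing it, both stores."""
    con = store.connection
    sid = relational.sample_key(con, sample_name)
    if sid is None:
        raise ValidationError(f"unknown sample {sample_name!r}")
    rel_rows = 0
    try:
        con.execute("BEGIN")
        rel_rows += con.execute(
            "DELETE FROM VarAnnotation WHERE varid IN "
            "(SELECT varid FROM VarResult WHERE sampleid = ?)",
            (sid,),
        ).rowcount
        for table in ("VarResult", "VarSummary", "GeneStats", "ReadCounts", "MapStats",
                      "Metadata", "CommandSyntax", "SampleStats", "SamplePerson",
                      "SampleOrganization"):
            rel_rows += con.execute(f"DELETE FROM {table} WHERE sampleid = ?", (sid,)).rowcount
        rel_rows += con.execute("DELETE FROM Sample WHERE sampleid = ?", (sid,)).rowcount
        con.commit()
    except Exception:
        con.rollback()
        raise
    col_rows = 0
    for name in ("variant", "expression", "readcount"):
        col_rows += store.partition(name).delete_rows([("sampleid", "=", sample_name)])
    store.log_action(
        f"delete {sample_name}",
        [f"delete {sample_name} relational={rel_rows} columnar={col_rows} ok"],
    )
    return DeleteReport(sample_name, rel_rows, col_rows)
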
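"""Reporting surface: views, variant selectors, research exports, writers.

The four research exports mirror the retrieval options a transcriptomics
group actually asks for: per-gene expression summaries across tissues
(``avgfpkm``), a gene x sample expression matrix for one organism
(``genexp``), per-sample per-chromosome variant counts (``chrvar``), and the
variant + predicted-consequence join (``varanno``) as a tab-delimited table
or a VCF v4 file whose INFO field packs annotations under ``CSQ`` and sample
metadata under ``MTD``, subfields joined by ``|`` in the order declared in
the header.

Gene matching is fuzzy by default (case-insensitive substring containment),
with an exact mode available.
"""

from __future__ import annotations

import math

import pandas as pd

from . import relational
from .errors import TadUserError, ValidationError
from .store import Store

CSQ_SUBFIELDS = [
    "source", "consequence", "geneid", "genename", "transcript",
    "feature", "genetype", "proteinposition", "aachange", "codonchange",
]
MTD_SUBFIELDS = ["sampleid", "organism", "tissue"]

VIEW_NAMES = tuple(relational.VIEW_DDL)


def _df(cursor_rows) -> pd.DataFrame:
    rows = [dict(r) for r in cursor_rows]
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows)


def run_view(store: Store, view_name: str) -> pd.DataFrame:
    """Materialize one of the six registered views as a DataFrame."""
    if view_name not in VIEW_NAMES:
        raise TadUserError(f"unknown view {view_name!r} (have: {', '.join(VIEW_NAMES)})")
    cur = store.connection.execute(f"SELECT * FROM {view_name}")
    cols = [d[0] for d in cur.description]
    rows = cur.fetchall()
    return pd.DataFrame([tuple(r) for r in rows], columns=cols)


def _fuzzy(term: str) -> str:
    return f"%{term}%"


def variants_select(store: Store, scope) -> pd.DataFrame:
    """One selector implementing the four registered variant procedures.

    ``scope`` is ``('all',)``, ``('chrom', c)``, ``('region', c, start,
    stop)`` (1-based inclusive) or ``('gene', name[, exact])``.  Returns the
    full variant+annotation field set (unannotated variants carry NULLs;
    the gene scope naturally excludes them).
    """
    con = store.connection
    kind = scope[0]
    if kind == "all":
        rows = relational.run_procedure(con, "usp_vall")
    elif kind == "chrom":
        rows = relational.run_procedure(con, "usp_vchrom", chrom=scope[1])
    elif kind == "region":
        _, chrom, start, stop = scope
        start, stop = int(start), int(stop)
        if start > stop:
            raise ValidationError(f"region start {start} > stop {stop}")
        rows = relational.run_procedure(
            con, "usp_vchrposition", chrom=str(chrom), start=start, stop=stop
        )
    elif kind == "gene":
        exact = len(scope) > 2 and scope[2] == "exact"
        pattern = scope[1] if exact else _fuzzy(scope[1])
        rows = relational.run_procedure(con, "usp_vgene", gene=pattern)
    else:
        raise TadUserError(f"unknown scope kind {kind!r}")
    cols = [
        "sampleid", "chrom", "position", "refallele", "altallele", "quality",
        "dbsnpvariant", "variantclass", "zygosity", "source", "consequence",
        "geneid", "genename", "transcript", "feature", "genetype",
        "proteinposition", "aachange", "codonchange", "organism", "tissue",
    ]
    return pd.DataFrame([tuple(r) for r in rows], columns=cols)


# ---------------------------------------------------------------------------
# research exports


def _expression_frame(store: Store) -> pd.DataFrame:
    part = store.partition("expression")
    df = pd.DataFrame(part.rows())
    if df.empty:
        df = pd.DataFrame(columns=[c.name for c in part.schema])
    return df


def export_avgfpkm(store: Store, genes: list[str], exact: bool = False) -> pd.DataFrame:
    """Min/avg/max expression per (gene, tissue) over samples.

    Samples with NULL abundance for a gene are excluded from all three
    statistics; ``avg`` is the arithmetic mean over the remaining samples.
    Both the FPKM and TPM summaries are reported (NULL where a dialect
    lacked the unit for every contributing sample).
    """
    if not genes:
        raise ValidationError("no genes specified")
    df = _expression_frame(store)
    if df.empty:
        return _empty_avgfpkm()
    terms = [g.lower() for g in genes]
    name = df["genename"].astype(str)
    if exact:
        mask = name.isin(genes)
    else:
        low = name.str.lower()
        mask = low.apply(lambda s: any(t in s for t in terms)) & (name != "NULL")
    sel = df[mask]
    if sel.empty:
        import logging

        logging.getLogger("transatlasdb").warning("no gene matches for %s", genes)
        return _empty_avgfpkm()
    out = []
    for (gene, tissue), grp in sel.groupby(["genename", "tissue"], sort=True):
        row = {"genename": gene, "tissue": tissue}
        for unit in ("fpkm", "tpm"):
            vals = [v for v in grp[unit] if not _isnan(v)]
            if vals:
                row[f"min_{unit}"] = min(vals)
                row[f"avg_{unit}"] = sum(vals) / len(vals)
                row[f"max_{unit}"] = max(vals)
            else:
                row[f"min_{unit}"] = row[f"avg_{unit}"] = row[f"max_{unit}"] = None
        fp = [v for v in grp["fpkm"] if not _isnan(v)]
        tp = [v for v in grp["tpm"] if not _isnan(v)]
        row["sample_count"] = grp["sampleid"].nunique() if (fp or tp) else 0
        if row["sample_count"] == 0:
            continue  # empty groups omitted rather than emitted as NULL rows
        out.append(row)
    cols = ["genename", "tissue", "min_fpkm", "avg_fpkm", "max_fpkm",
            "min_tpm", "avg_tpm", "max_tpm", "sample_count"]
    return pd.DataFrame(out, columns=cols)


def _empty_avgfpkm() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["genename", "tissue", "min_fpkm", "avg_fpkm", "max_fpkm",
                 "min_tpm", "avg_tpm", "max_tpm", "sample_count"]
    )


def _isnan(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def export_genexp(
    store: Store, organism: str, samples: list[str] | None = None, absent: str = "null"
) -> pd.DataFrame:
    """Gene x sample expression matrix for one organism.

    Cells hold FPKM, falling back to TPM where the quantifier reported no
    FPKM.  Genes absent in a sample render as NULL (``absent='null'``) or
    0.0 (``absent='zero'``).
    """
    con = store.connection
    known = con.execute("SELECT 1 FROM Organism WHERE organism = ?", (organism,)).fetchone()
    if known is None:
        raise ValidationError(f"unknown organism {organism!r}")
    df = _expression_frame(store)
    df = df[df["organism"] == organism]
    all_samples = sorted(df["sampleid"].unique())
    if samples is not None:
        bad = [s for s in samples if s not in all_samples]
        if bad:
            raise ValidationError(
                f"sample(s) not available for organism {organism!r}: {', '.join(bad)}"
            )
        use = list(samples)
    else:
        use = all_samples
    genes = sorted(g for g in df["genename"].unique() if g != "NULL")
    value: dict[tuple, float] = {}
    for _, r in df.iterrows():
        v = r["fpkm"]
        if _isnan(v):
            v = r["tpm"]
        if _isnan(v):
            continue
        value[(r["genename"], r["sampleid"])] = v
    fill = 0.0 if absent == "zero" else None
    data = {
        "genename": genes,
        **{s: [value.get((g, s), fill) for g in genes] for s in use},
    }
    return pd.DataFrame(data)


def export_chrvar(store: Store, chroms: list[str] | None = None) -> pd.DataFrame:
    """Variant counts per (sample, chromosome); distinct variant sites.

    Counted on the relational variant rows (one per variant observation), so
    unrestricted totals per sample equal the VarSummary totals by
    construction — and, mirrored, the distinct variant sites per sample in
    the columnar partition.
    """
    con = store.connection
    sql = (
        "SELECT s.samplename AS sampleid, r.chrom, COUNT(*) AS variantcount "
        "FROM VarResult r JOIN Sample s ON s.sampleid = r.sampleid "
    )
    params: list = []
    if chroms:
        placeholders = ",".join("?" for _ in chroms)
        sql += f"WHERE r.chrom IN ({placeholders}) "
        params = list(chroms)
    sql += "GROUP BY s.samplename, r.chrom ORDER BY s.samplename, r.chrom"
    cur = con.execute(sql, params)
    return pd.DataFrame([tuple(r) for r in cur.fetchall()],
                        columns=["sampleid", "chrom", "variantcount"])


def export_varanno(store: Store, selector: dict, format: str = "tsv", path: str | None = None):
    """Variants + predicted annotations, filtered by gene list, chromosome
    list or organism; written as TSV or VCF (CSQ/MTD-packed)."""
    if format not in ("tsv", "vcf"):
        raise TadUserError(f"unknown format {format!r}")
    frames = []
    if "genes" in selector:
        for g in selector["genes"]:
            frames.append(variants_select(store, ("gene", g)))
    elif "chroms" in selector:
        for c in selector["chroms"]:
            frames.append(variants_select(store, ("chrom", c)))
    elif "organism" in selector:
        df = variants_select(store, ("all",))
        frames.append(df[df["organism"] == selector["organism"]])
    else:
        frames.append(variants_select(store, ("all",)))
    df = pd.concat(frames, ignore_index=True) if frames else variants_select(store, ("all",))
    df = df.drop_duplicates()
    if format == "tsv":
        if path is None:
            raise TadUserError("path required for TSV export")
        write_tsv(df, path)
        return path
    if path is None:
        raise TadUserError("path required for VCF export")
    write_vcf(df, path)
    return path


# ---------------------------------------------------------------------------
# writers


def write_tsv(table: pd.DataFrame, path: str) -> str:
    """UTF-8, tab-separated, header first, NULL for missing, no quoting."""
    cols = list(table.columns)
    if len(set(cols)) != len(cols):
        raise TadUserError("table column names must be unique")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in table.itertuples(index=False):
            cells = []
            for v in row:
                s = "NULL" if _isnan(v) or v is None else str(v)
                if "\t" in s or "\n" in s:
                    raise ValidationError(f"value contains tab/newline: {s!r}")
                cells.append(s)
            fh.write("\t".join(cells) + "\n")
    return path


def _chrom_sort_key(c: str):
    s = str(c)
    if s.lower().startswith("chr"):
        s = s[3:]
    return (0, int(s)) if s.isdigit() else (1, s)


def write_vcf(df: pd.DataFrame, path: str) -> str:
    """Write the annotation join as a VCF v4.2 file.

    One record per (sample, chrom, position, ref, alt); all annotations for
    that record are packed into ``CSQ`` as comma-separated entries of
    ``|``-joined subfields, and ``MTD`` carries sampleid|organism|tissue.
    Records are sorted by chromosome then position.
    """
    groups: dict[tuple, dict] = {}
    order: list[tuple] = []
    for _, r in df.iterrows():
        key = (r["sampleid"], r["chrom"], int(r["position"]), r["refallele"], r["altallele"])
        if key not in groups:
            groups[key] = {"row": r, "annos": []}
            order.append(key)
        if not _isnan(r.get("source")) and r.get("source") not in (None, "NULL"):
            entry = "|".join(_vcf_subfield(r.get(f)) for f in CSQ_SUBFIELDS)
            groups[key]["annos"].append(entry)
    order.sort(key=lambda k: (_chrom_sort_key(k[1]), k[2], k[0], k[3], k[4]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Predicted functional '
            'annotation. Format: ' + "|".join(CSQ_SUBFIELDS) + '">\n'
        )
        fh.write(
            '##INFO=<ID=MTD,Number=.,Type=String,Description="Sample metadata. '
            'Format: ' + "|".join(MTD_SUBFIELDS) + '">\n'
        )
        for chrom in sorted({k[1] for k in order}, key=_chrom_sort_key):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for key in order:
            g = groups[key]
            r = g["row"]
            qual = "." if _isnan(r["quality"]) else _fmt_qual(r["quality"])
            vid = "." if (r["dbsnpvariant"] in (None, "NULL") or _isnan(r["dbsnpvariant"])) \
                else str(r["dbsnpvariant"])
            mtd = "|".join(_vcf_subfield(r.get(f)) for f in MTD_SUBFIELDS)
            info_parts = []
            if g["annos"]:
                info_parts.append("CSQ=" + ",".join(g["annos"]))
            info_parts.append("MTD=" + mtd)
            fh.write(
                f"{r['chrom']}\t{int(r['position'])}\t{vid}\t{r['refallele']}\t"
                f"{r['altallele']}\t{qual}\t.\t{';'.join(info_parts)}\n"
            )
    return path


def _fmt_qual(q) -> str:
    f = round(float(q), 4)  # strip single-precision storage noise
    return str(int(f)) if f.is_integer() else repr(f)


def _vcf_subfield(v) -> str:
    if v is None or _isnan(v) or v == "NULL":
        return ""
    s = str(v)
    if isinstance(v, float) and v.is_integer():
        s = str(int(v))
    # VCF INFO forbids ; = , and whitespace inside values
    return s.replace(";", "%3B").replace(",", "%2C").replace("=", "%3D").replace(" ", "_").replace("|", "%7C")


def read_csq(path: str) -> list[dict]:
    """Parse a CSQ/MTD-packed VCF back into flat annotation dicts.

    The round-trip companion of :func:`write_vcf` (subfield order is read
    from the header Description lines).
    """
    csq_fields = None
    mtd_fields = None
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##INFO=<ID=CSQ"):
                csq_fields = line.split("Format: ")[1].rstrip('">').split("|")
            elif line.startswith("##INFO=<ID=MTD"):
                mtd_fields = line.split("Format: ")[1].rstrip('">').split("|")
            elif line.startswith("#") or not line:
                continue
            else:
                cols = line.split("\t")
                info = dict(kv.split("=", 1) for kv in cols[7].split(";") if "=" in kv)
                base = {
                    "chrom": cols[0], "position": int(cols[1]),
                    "dbsnpvariant": None if cols[2] == "." else cols[2],
                    "refallele": cols[3], "altallele": cols[4],
                    "quality": None if cols[5] == "." else float(cols[5]),
                }
                if mtd_fields and "MTD" in info:
                    base.update(dict(zip(mtd_fields, info["MTD"].split("|"))))
                if csq_fields and "CSQ" in info:
                    for entry in info["CSQ"].split(","):
                        rec = dict(base)
                        rec.update(
                            {k: (v if v else None)
                             for k, v in zip(csq_fields, entry.split("|"))}
                        )
                        out.append(rec)
                else:
                    out.append(base)
    return out
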
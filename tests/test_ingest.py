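"""Parsers for every accepted dialect, discovery, and transactional import."""

import os

import pytest

from transatlasdb import Store, fixtures, ingest, relational
from transatlasdb.errors import DialectError, ValidationError


class TestSampleNaming:
    @pytest.mark.parametrize(
        "name,parts",
        [
            ("GGA_UD_1004", ("GGA", "UD", "1004")),
            ("A_B_C", ("A", "B", "C")),
        ],
    )
    def test_valid_names_split_into_three_parts(self, name, parts):
        got = ingest.parse_sample_name(name)
        assert (got.species_code, got.lab_code, got.sample_id) == parts
        assert got.join() == name

    @pytest.mark.parametrize("bad", ["GGA-UD-1004", "GGA_UD", "A_B_C_D", "__"])
    def test_nonconforming_names_rejected(self, bad):
        with pytest.raises(ValidationError):
            ingest.parse_sample_name(bad)


class TestSampleMetadata:
    def test_tsv_two_rows(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text(
            "Sample Name\tDerived from\tOrganism\tOrganism part\n"
            "GGA_UD_1004\tGGA_UD_A001\tGallus gallus\tPituitary gland\n"
            "GGA_UD_1014\tGGA_UD_A002\tGallus gallus\tPituitary gland\n"
        )
        recs = ingest.parse_sample_metadata(str(p))
        assert len(recs) == 2
        assert recs[0].organism == "Gallus gallus"

    def test_missing_derived_from_column(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("Sample Name\tOrganism\tOrganism part\nX_Y_1\tdog\tliver\n")
        with pytest.raises(ValidationError, match="Derived from"):
            ingest.parse_sample_metadata(str(p))

    def test_empty_file(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("")
        with pytest.raises(ValidationError, match="empty"):
            ingest.parse_sample_metadata(str(p))

    def test_faang_workbook_from_generator(self, optn_tree):
        outdir, _ = optn_tree
        recs = ingest.parse_sample_metadata(str(outdir / "metadata.xlsx"))
        assert len(recs) == 2
        assert all(r.organism == "Gallus gallus" for r in recs)
        assert {r.sample_name for r in recs} == {"GGA_UD_1004", "GGA_UD_1014"}

    def test_workbook_and_tsv_agree(self, optn_tree):
        outdir, _ = optn_tree
        a = ingest.parse_sample_metadata(str(outdir / "metadata.tsv"))
        b = ingest.parse_sample_metadata(str(outdir / "metadata.xlsx"))
        key = lambda r: (r.sample_name, r.derived_from, r.organism, r.organism_part)
        assert sorted(map(key, a)) == sorted(map(key, b))


SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:1\tLN:100000\n"


def _sam_line(flag, pos=100):
    return f"r{flag}\t{flag}\t1\t{pos}\t60\t10M\t*\t0\t0\tACGTACGTAC\tFFFFFFFFFF\n"


class TestAlignmentSummary:
    def test_sam_flag_semantics(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(SAM_HEADER + _sam_line(0) + _sam_line(16) + _sam_line(4))
        rec = ingest.summarize_alignment(str(p))
        assert (rec.total_reads, rec.mapped_reads) == (3, 2)
        assert rec.alignment_rate == pytest.approx(2 / 3, abs=1e-4)

    def test_secondary_and_supplementary_excluded(self, tmp_path):
        p = tmp_path / "b.sam"
        p.write_text(SAM_HEADER + _sam_line(256) + _sam_line(2048))
        rec = ingest.summarize_alignment(str(p))
        assert (rec.total_reads, rec.mapped_reads, rec.alignment_rate) == (0, 0, 0.0)

    def test_hisat2_summary_dialect(self, tmp_path):
        p = tmp_path / "align_summary.txt"
        p.write_text(
            "10000 reads; of these:\n"
            "  10000 (100.00%) were unpaired; of these:\n"
            "    450 (4.50%) aligned 0 times\n"
            "95.50% overall alignment rate\n"
        )
        rec = ingest.summarize_alignment(str(p))
        assert rec.total_reads == 10000
        assert rec.alignment_rate == pytest.approx(0.955, abs=1e-9)
        assert rec.mapped_reads == 9550

    def test_tophat_summary_dialect(self, tmp_path):
        p = tmp_path / "align_summary.txt"
        p.write_text("Reads:\n  Input     :  2000\n  Mapped   :   1500 (75.0% of input)\n")
        rec = ingest.summarize_alignment(str(p))
        assert (rec.total_reads, rec.mapped_reads) == (2000, 1500)
        assert rec.mapper_name == "TopHat2"

    def test_unrecognized_dialect_lists_attempts(self, tmp_path):
        p = tmp_path / "junk.txt"
        p.write_text("this is not an alignment summary\n")
        with pytest.raises(DialectError, match="SAM.*HISAT2.*TopHat"):
            ingest.summarize_alignment(str(p))


class TestExpressionParsers:
    def test_cufflinks_field_mapping(self, tmp_path):
        p = tmp_path / "genes.fpkm_tracking"
        p.write_text(
            "tracking_id\tclass_code\tnearest_ref_id\tgene_id\tgene_short_name\ttss_id\t"
            "locus\tlength\tcoverage\tFPKM\tFPKM_conf_lo\tFPKM_conf_hi\tFPKM_status\n"
            "G1\t-\t-\tG1\tOPTN\t-\t20:1500000-1559999\t3000\t38.75\t12.5\t10.0\t15.0\tOK\n"
        )
        rows = ingest.parse_expression(str(p), "cufflinks")
        assert len(rows) == 1
        r = rows[0]
        assert r["fpkm"] == 12.5
        assert r["fpkmconflow"] == 10.0
        assert r["fpkmconfhigh"] == 15.0
        assert r["fpkmstatus"] == "OK"
        assert r["tpm"] is None
        assert (r["chrom"], r["start"], r["stop"]) == ("20", 1500000, 1559999)

    def test_kallisto_zero_tpm(self, tmp_path):
        p = tmp_path / "abundance.tsv"
        p.write_text("target_id\tlength\teff_length\test_counts\ttpm\nG1\t3000\t2800\t0\t0\n")
        rows = ingest.parse_expression(str(p), "kallisto")
        assert rows[0]["tpm"] == 0.0
        assert rows[0]["fpkm"] is None

    def test_header_mismatch_is_dialect_error(self, tmp_path):
        p = tmp_path / "abundance.tsv"
        p.write_text("geneid\tvalue\nG1\t5\n")
        with pytest.raises(DialectError):
            ingest.parse_expression(str(p), "kallisto")

    def test_negative_abundance_rejected(self, tmp_path):
        p = tmp_path / "quant.sf"
        p.write_text("Name\tLength\tEffectiveLength\tTPM\tNumReads\nG1\t3000\t2800.0\t-1.0\t5\n")
        with pytest.raises(ValidationError, match="negative"):
            ingest.parse_expression(str(p), "salmon")

    def test_generated_file_tpm_sum_matches_ledger(self, study_tree):
        outdir, ledger = study_tree
        for name, entry in ledger["samples"].items():
            if entry["quantifier"] not in ("stringtie", "kallisto", "salmon"):
                continue
            manifest = ingest.discover_sample_dir(str(outdir / "samples" / name), name)
            rows = ingest.parse_expression(manifest.roles["expression"], manifest.quantifier)
            assert len(rows) == entry["gene_count"]
            got = sum(r["tpm"] for r in rows if r["tpm"] is not None)
            assert got == pytest.approx(entry["tpm_sum"], abs=1e-6)

    def test_cross_dialect_value_identity(self, tmp_path):
        """The same abundance vector serialized in two dialects imports to
        value-identical rows for the fields both dialects carry."""
        import random

        genes = fixtures._gene_table(8)
        rng = random.Random(9)
        fpkm, tpm = fixtures._abundances(rng, genes)
        d1 = tmp_path / "st"
        d2 = tmp_path / "ka"
        d1.mkdir(), d2.mkdir()
        fixtures._write_expression(str(d1), "stringtie", genes, fpkm, tpm, rng)
        fixtures._write_expression(str(d2), "kallisto", genes, fpkm, tpm, rng)
        a = ingest.parse_expression(str(d1 / "sample.gene_abund.tab"), "stringtie")
        b = ingest.parse_expression(str(d2 / "abundance.tsv"), "kallisto")
        assert [r["tpm"] for r in a] == [r["tpm"] for r in b]


class TestReadCounts:
    def test_htseq_special_rows_excluded(self, tmp_path):
        p = tmp_path / "s.counts"
        p.write_text("G1\t10\nG2\t0\nG3\t7\n__no_feature\t50\n__ambiguous\t3\n")
        rows, specials = ingest.parse_readcounts(str(p), "htseq")
        assert len(rows) == 3
        assert specials == {"__no_feature": 50, "__ambiguous": 3}

    def test_featurecounts_vector_matches_ledger(self, study_tree):
        outdir, ledger = study_tree
        done = 0
        for name, entry in ledger["samples"].items():
            if entry["counter"] != "featurecounts":
                continue
            path = str(outdir / "samples" / name / "sample.featureCounts.txt")
            rows, _ = ingest.parse_readcounts(path, "featurecounts")
            assert {r["genename"]: r["readcount"] for r in rows} == entry["counts"]
            done += 1
        assert done >= 1

    def test_star_counts_use_unstranded_column(self, tmp_path):
        p = tmp_path / "s.ReadsPerGene.out.tab"
        p.write_text("N_unmapped\t5\t5\t5\nG1\t10\t4\t6\n")
        rows, specials = ingest.parse_readcounts(str(p), "star_quantmode")
        assert rows == [dict(genename="G1", readcount=10)]
        assert specials == {"N_unmapped": 5}

    def test_non_integer_count_rejected(self, tmp_path):
        p = tmp_path / "s.counts"
        p.write_text("G1\t1.5\n")
        with pytest.raises(ValidationError, match="non-integer"):
            ingest.parse_readcounts(str(p), "htseq")

    def test_empty_file_yields_zero_rows(self, tmp_path):
        p = tmp_path / "s.counts"
        p.write_text("")
        rows, specials = ingest.parse_readcounts(str(p), "htseq")
        assert rows == [] and specials == {}


VCF_HEADER = (
    "##fileformat=VCFv4.2\n##source=GATK\n"
    "##contig=<ID=1,length=100000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


class TestVcf:
    def test_basic_line_field_semantics(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_HEADER + "1\t1000\trs123\tA\tG\t50\tPASS\t.\tGT\t0/1\n")
        recs = ingest.parse_vcf(str(p))
        assert len(recs) == 1
        r = recs[0]
        assert (r.chrom, r.position, r.ref, r.alt) == ("1", 1000, "A", "G")
        assert r.quality == 50.0
        assert r.dbsnpvariant == "rs123"
        assert r.genotype == "0/1"

    def test_multiallelic_exploded(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_HEADER + "1\t1000\t.\tA\tG,T\t50\tPASS\t.\tGT\t1/2\n")
        recs = ingest.parse_vcf(str(p))
        assert [r.alt for r in recs] == ["G", "T"]
        assert all(r.position == 1000 for r in recs)

    def test_missing_chrom_header(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text("##fileformat=VCFv4.2\n1\t1000\t.\tA\tG\t50\tPASS\t.\n")
        with pytest.raises(ValidationError, match="#CHROM"):
            ingest.parse_vcf(str(p))

    def test_generated_vcf_record_total_matches_ledger(self, study_tree):
        outdir, ledger = study_tree
        name, entry = next(iter(ledger["samples"].items()))
        recs = ingest.parse_vcf(str(outdir / "samples" / name / f"{name}.vcf"))
        assert len(recs) == entry["variant_records"]


class TestVariantClassification:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "G", "SNP"),
            ("A", "AT", "insertion"),
            ("AT", "A", "deletion"),
            ("AT", "GC", "complex"),
            ("A", "TG", "complex"),
        ],
    )
    def test_classify_by_allele_lengths(self, ref, alt, expected):
        assert ingest.classify_variant(ref, alt) == expected

    def test_empty_allele_rejected(self):
        with pytest.raises(ValidationError):
            ingest.classify_variant("", "A")

    @pytest.mark.parametrize(
        "gt,expected",
        [("1/1", "homozygous"), ("0/1", "heterozygous"), ("0|1", "heterozygous"),
         ("./1", None), ("./.", None), (None, None)],
    )
    def test_zygosity_from_gt(self, gt, expected):
        assert ingest.call_zygosity(gt) == expected

    def test_malformed_gt(self):
        with pytest.raises(ValidationError):
            ingest.call_zygosity("0/1/2x")


class TestAnnotationParsers:
    def test_vep_field_mapping(self, tmp_path):
        p = tmp_path / "s.vep.txt"
        p.write_text(
            "## VEP\n#Uploaded_variation\tLocation\tAllele\tGene\tFeature\tFeature_type\t"
            "Consequence\tcDNA_position\tCDS_position\tProtein_position\tAmino_acids\t"
            "Codons\tExisting_variation\tExtra\n"
            ".\t1:1000\tG\tENSG1\tENST1\tTranscript\tsynonymous_variant\t-\t-\t45\tK\t"
            "aaA/aaG\t-\tSYMBOL=OPTN;BIOTYPE=protein_coding\n"
            ".\t1:2000-2001\tTA\tENSG2\tENST2\tTranscript\tframeshift_variant\t-\t-\t-\t-\t-\t-\t-\n"
        )
        recs = ingest.parse_vep(str(p))
        assert recs[0].position == 1000
        assert recs[0].consequence == "synonymous_variant"
        assert recs[0].proteinposition == 45
        assert recs[0].aachange == "K"
        assert recs[0].codonchange == "aaA/aaG"
        assert recs[0].genename == "OPTN"
        assert recs[0].source == "VEP"
        # indel range takes the range start; dashes become NULL
        assert recs[1].position == 2000
        assert recs[1].proteinposition is None

    def test_vep_wrong_header(self, tmp_path):
        p = tmp_path / "s.vep.txt"
        p.write_text("a\tb\tc\n1\t2\t3\n")
        with pytest.raises(DialectError):
            ingest.parse_vep(str(p))

    def test_annovar_field_mapping(self, tmp_path):
        p = tmp_path / "s.multianno.txt"
        p.write_text(
            "Chr\tStart\tEnd\tRef\tAlt\tFunc.refGene\tGene.refGene\tGeneDetail.refGene\t"
            "ExonicFunc.refGene\tAAChange.refGene\n"
            "1\t1000\t1000\tA\tG\texonic\tOPTN\t.\tsynonymous SNV\t"
            "OPTN:NM_001:c.135A>G:p.K45K\n"
            "2\t500\t500\tC\tT\tintergenic\tNONE\t.\t.\t.\n"
        )
        recs = ingest.parse_annovar(str(p))
        assert recs[0].consequence == "synonymous SNV"
        assert recs[0].genename == "OPTN"
        assert recs[0].transcript == "NM_001"
        assert recs[0].proteinposition == 45
        assert recs[0].aachange == "K45K"
        assert recs[0].codonchange == "c.135A>G"
        assert recs[0].source == "ANNOVAR"
        # intergenic: consequence NULL, genetype retained from Func column
        assert recs[1].consequence is None
        assert recs[1].genetype == "intergenic"

    def test_generated_vep_joins_to_vcf(self, optn_tree):
        outdir, _ = optn_tree
        name = "GGA_UD_1014"
        sdir = str(outdir / "samples" / name)
        annos = ingest.parse_vep(os.path.join(sdir, f"{name}.vep.txt"))
        variants = ingest.parse_vcf(os.path.join(sdir, f"{name}.vcf"))
        keys = {(v.chrom, v.position, v.alt) for v in variants}
        assert len(annos) >= 1
        assert all((a.chrom, a.position, a.alt) in keys for a in annos)


class TestDiscovery:
    def test_roles_and_dialect_detection(self, optn_tree):
        outdir, _ = optn_tree
        sdir = str(outdir / "samples" / "GGA_UD_1004")
        m = ingest.discover_sample_dir(sdir, "GGA_UD_1004")
        assert m.quantifier == "cufflinks"
        assert m.counter == "htseq"
        assert "vcf" in m.roles and "vep" in m.roles
        assert "alignment_summary" in m.roles

    def test_ambiguous_expression_role(self, tmp_path):
        (tmp_path / "abundance.tsv").write_text("target_id\tlength\teff_length\test_counts\ttpm\n")
        (tmp_path / "quant.sf").write_text("Name\tLength\tEffectiveLength\tTPM\tNumReads\n")
        with pytest.raises(ValidationError, match="ambiguous expression"):
            ingest.discover_sample_dir(str(tmp_path), "X_Y_1")

    def test_variant_scope_requires_vcf(self, tmp_path, optn_tree):
        outdir, _ = optn_tree
        store = Store.install(str(tmp_path / "st"))
        ingest.import_metadata(store, str(outdir / "metadata.tsv"))
        d = tmp_path / "empty"
        d.mkdir()
        m = ingest.discover_sample_dir(str(d), "GGA_UD_1004")
        with pytest.raises(ValidationError, match="variant file absent"):
            ingest.import_sample(store, m, scope="variant")


class TestImportSample:
    def test_full_import_counts_match_ledger(self, study_store):
        store, ledger = study_store
        con = store.connection
        for name, entry in ledger["samples"].items():
            ctx = relational.sample_context(con, name)
            gs = con.execute(
                "SELECT genesquantified, quantifiername FROM GeneStats WHERE sampleid=?",
                (ctx["sampleid"],),
            ).fetchone()
            assert gs["genesquantified"] == entry["gene_count"]
            assert gs["quantifiername"] == entry["quantifier"]
            vs = con.execute(
                "SELECT * FROM VarSummary WHERE sampleid=?", (ctx["sampleid"],)
            ).fetchone()
            assert vs["totalvariants"] == entry["variant_records"]
            assert vs["snpcount"] == entry["class_counts"]["SNP"]
            assert vs["insertioncount"] == entry["class_counts"]["insertion"]
            assert vs["deletioncount"] == entry["class_counts"]["deletion"]
            ms = con.execute(
                "SELECT * FROM MapStats WHERE sampleid=?", (ctx["sampleid"],)
            ).fetchone()
            assert ms["totalreads"] == entry["total_reads"]
            assert ms["mappedreads"] == entry["mapped_reads"]
            assert ms["alignmentrate"] == pytest.approx(entry["alignment_rate"], abs=1e-9)

    def test_varsummary_arithmetic_recomputed_from_partition(self, study_store):
        store, _ = study_store
        import pandas as pd

        part = store.partition("variant")
        df = pd.DataFrame(part.rows(
            ["sampleid", "chrom", "position", "refallele", "altallele", "variantclass"]
        )).drop_duplicates()
        by_class = df.groupby(["sampleid", "variantclass"]).size().unstack(fill_value=0)
        con = store.connection
        for name, row in by_class.iterrows():
            vs = con.execute(
                "SELECT v.* FROM VarSummary v JOIN Sample s USING(sampleid)"
                " WHERE s.samplename=?",
                (name,),
            ).fetchone()
            assert vs["snpcount"] == row.get("SNP", 0)
            assert vs["insertioncount"] == row.get("insertion", 0)
            assert vs["deletioncount"] == row.get("deletion", 0)
            assert vs["snpcount"] + vs["insertioncount"] + vs["deletioncount"] \
                + vs["complexcount"] == vs["totalvariants"]

    def test_denormalization_matches_relational_join(self, study_store):
        store, _ = study_store
        con = store.connection
        expected = {
            r["samplename"]: (r["organism"], r["tissue"])
            for r in con.execute(
                """SELECT s.samplename, o.organism, t.tissue FROM Sample s
                   JOIN Animal a ON a.animalid=s.animalid
                   JOIN Organism o ON o.organismid=a.organismid
                   JOIN Tissue t ON t.tissueid=s.tissueid"""
            )
        }
        for pname in ("variant", "expression", "readcount"):
            part = store.partition(pname)
            for row in part.rows(["sampleid", "organism", "tissue"]):
                assert expected[row["sampleid"]] == (row["organism"], row["tissue"])

    def test_second_import_rejected(self, tmp_path, optn_tree):
        outdir, _ = optn_tree
        store = Store.install(str(tmp_path / "st"))
        ingest.import_metadata(store, str(outdir / "metadata.tsv"))
        sdir = str(outdir / "samples" / "GGA_UD_1004")
        m = ingest.discover_sample_dir(sdir, "GGA_UD_1004")
        assert ingest.import_sample(store, m, scope="all").ok
        with pytest.raises(ValidationError, match="already imported"):
            ingest.import_sample(store, ingest.discover_sample_dir(sdir, "GGA_UD_1004"))

    def test_unknown_sample_directs_to_metadata(self, tmp_path, optn_tree):
        outdir, _ = optn_tree
        store = Store.install(str(tmp_path / "st"))
        sdir = str(outdir / "samples" / "GGA_UD_1004")
        m = ingest.discover_sample_dir(sdir, "GGA_UD_1004")
        with pytest.raises(ValidationError, match="metadata first"):
            ingest.import_sample(store, m)


def _copy_sample_tree(outdir, tmp_path):
    import shutil

    dst = tmp_path / "tree"
    shutil.copytree(outdir, dst)
    return dst


class TestAtomicity:
    def test_truncated_vcf_leaves_no_partial_rows(self, tmp_path, optn_tree):
        outdir, _ = optn_tree
        tree = _copy_sample_tree(outdir, tmp_path)
        store = Store.install(str(tmp_path / "st"))
        ingest.import_metadata(store, str(tree / "metadata.tsv"))
        vcf = tree / "samples" / "GGA_UD_1004" / "GGA_UD_1004.vcf"
        text = vcf.read_text().rstrip("\n")
        vcf.write_text(text[: text.rfind("\t") - 3])  # cut mid data line
        pre = {n: store.partition(n).row_count for n in ("variant", "expression", "readcount")}
        pre_rel = store.connection.execute("SELECT COUNT(*) FROM GeneStats").fetchone()[0]
        m = ingest.discover_sample_dir(str(tree / "samples" / "GGA_UD_1004"), "GGA_UD_1004")
        with pytest.raises(ValidationError):
            ingest.import_sample(store, m, scope="all")
        post = {n: store.partition(n).row_count for n in ("variant", "expression", "readcount")}
        assert pre == post
        assert store.connection.execute("SELECT COUNT(*) FROM GeneStats").fetchone()[0] == pre_rel
        assert relational.check_referential_integrity(store.connection) == []

    def test_unjoinable_annotation_rolls_back_columnar_writes(self, tmp_path, optn_tree):
        """A double-entry mismatch after columnar appends must truncate the
        partitions back to their pre-import state."""
        outdir, _ = optn_tree
        tree = _copy_sample_tree(outdir, tmp_path)
        store = Store.install(str(tmp_path / "st"))
        ingest.import_metadata(store, str(tree / "metadata.tsv"))
        vep = tree / "samples" / "GGA_UD_1004" / "GGA_UD_1004.vep.txt"
        with vep.open("a") as fh:  # annotation with no matching variant
            fh.write(".\t9:99999\tA\tENSGX\tENSTX\tTranscript\tmissense_variant\t-\t-\t-\t-\t-\t-\t-\n")
        m = ingest.discover_sample_dir(str(tree / "samples" / "GGA_UD_1004"), "GGA_UD_1004")
        with pytest.raises(ValidationError, match="double-entry"):
            ingest.import_sample(store, m, scope="all")
        for n in ("variant", "expression", "readcount"):
            assert store.partition(n).row_count == 0
        assert store.connection.execute("SELECT COUNT(*) FROM VarResult").fetchone()[0] == 0


class TestDeleteSample:
    def test_delete_preserves_other_samples(self, tmp_path, optn_tree):
        outdir, _ = optn_tree
        store = Store.install(str(tmp_path / "st"))
        fixtures.import_study(store, str(outdir))
        keep = "GGA_UD_1014"
        before = {
            n: sum(1 for v in store.partition(n).column("sampleid") if v == keep)
            for n in ("variant", "expression", "readcount")
        }
        ingest.delete_sample(store, "GGA_UD_1004")
        for n in ("variant", "expression", "readcount"):
            col = store.partition(n).column("sampleid")
            assert all(v == keep for v in col)
            assert len(col) == before[n]
        assert relational.check_referential_integrity(store.connection) == []

    def test_delete_then_reimport_succeeds(self, tmp_path, optn_tree):
        outdir, _ = optn_tree
        store = Store.install(str(tmp_path / "st"))
        fixtures.import_study(store, str(outdir))
        ingest.delete_sample(store, "GGA_UD_1004")
        # metadata row is gone too: re-import metadata, then results
        con = store.connection
        relational.insert_sample(con, relational.SampleRecord(
            sample_name="GGA_UD_1004", derived_from="GGA_UD_A1004",
            organism="Gallus gallus", organism_part="Pituitary gland"))
        con.commit()
        sdir = str(outdir / "samples" / "GGA_UD_1004")
        report = ingest.import_sample(
            store, ingest.discover_sample_dir(sdir, "GGA_UD_1004"), scope="all"
        )
        assert report.ok

    def test_delete_unknown_sample(self, tmp_path):
        store = Store.install(str(tmp_path / "st"))
        with pytest.raises(ValidationError, match="unknown sample"):
            ingest.delete_sample(store, "NOPE_X_1")
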
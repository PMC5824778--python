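"""Views, variant selectors, the four research exports, TSV/VCF writers."""

import math

import pandas as pd
import pytest

from transatlasdb import export, fixtures, ingest, relational
from transatlasdb.errors import TadUserError, ValidationError
from transatlasdb.query import execute_query, parse_query
from transatlasdb.store import Store


class TestViews:
    def test_sampleinfo_one_row_per_sample(self, optn_store):
        store, _ = optn_store
        df = export.run_view(store, "vw_sampleinfo")
        assert len(df) == 2
        assert set(df["samplename"]) == {"GGA_UD_1004", "GGA_UD_1014"}

    def test_metadata_only_sample_has_null_alignment(self, tmp_path):
        store = Store.install(str(tmp_path / "st"))
        con = store.connection
        relational.insert_sample(con, relational.SampleRecord(
            sample_name="X_Y_1", derived_from="X_Y_A1",
            organism="Sus scrofa", organism_part="Liver"))
        con.commit()
        df = export.run_view(store, "vw_sampleinfo")
        assert len(df) == 1
        assert df.loc[0, "totalreads"] is None or math.isnan(df.loc[0, "totalreads"])

    def test_vanno_counts_annotated_variants(self, optn_store):
        store, _ = optn_store
        vanno = export.run_view(store, "vw_vanno")
        n_annotated = store.connection.execute(
            "SELECT COUNT(*) FROM VarResult r WHERE EXISTS "
            "(SELECT 1 FROM VarAnnotation a WHERE a.varid = r.varid)"
        ).fetchone()[0]
        # one vw_vanno row per (variant, annotation) pair; here 1:1
        assert len(vanno) == n_annotated

    def test_unknown_view(self, optn_store):
        store, _ = optn_store
        with pytest.raises(TadUserError, match="unknown view"):
            export.run_view(store, "vw_missing")


class TestVariantsSelect:
    def test_all_scope_equals_partition_rows(self, optn_store):
        store, _ = optn_store
        df = export.variants_select(store, ("all",))
        assert len(df) == store.partition("variant").row_count

    def test_region_inclusive_bounds(self, optn_store):
        store, _ = optn_store
        one = export.variants_select(store, ("all",)).iloc[0]
        hit = export.variants_select(
            store, ("region", one["chrom"], one["position"], one["position"])
        )
        assert len(hit) >= 1
        assert (hit["position"] == one["position"]).all()

    def test_region_start_after_stop(self, optn_store):
        store, _ = optn_store
        with pytest.raises(ValidationError, match="start"):
            export.variants_select(store, ("region", "1", 10, 5))

    def test_gene_scope_reproduces_use_case_counts(self, optn_store):
        store, ledger = optn_store
        df = export.variants_select(store, ("gene", "OPTN"))
        syn = df[df["consequence"] == "synonymous_variant"]
        counts = syn.groupby("sampleid").size().to_dict()
        assert counts["GGA_UD_1004"] == 1
        assert counts["GGA_UD_1014"] == ledger["k"]

    def test_fuzzy_matching_is_substring_case_insensitive(self, optn_store):
        store, _ = optn_store
        assert len(export.variants_select(store, ("gene", "opt"))) == \
            len(export.variants_select(store, ("gene", "OPTN")))

    def test_selector_equals_columnar_query(self, study_store):
        """Procedure/columnar equivalence on mirrored data."""
        store, _ = study_store
        part = store.partition("variant")
        part.build_default_indexes()
        for chrom in ("1", "3"):
            sel = export.variants_select(store, ("chrom", chrom))
            res = execute_query(part, parse_query(f"select * where chrom = '{chrom}'"))
            df = res.to_dataframe()
            assert len(sel) == len(df)
            a = sorted(zip(sel["sampleid"], sel["position"], sel["altallele"]))
            b = sorted(zip(df["sampleid"], df["position"], df["altallele"]))
            assert a == b


class TestAvgFpkm:
    def test_mean_of_three_values(self, tmp_path):
        store = Store.install(str(tmp_path / "st"))
        con = store.connection
        for i, name in enumerate(["P_Q_1", "P_Q_2", "P_Q_3"]):
            relational.insert_sample(con, relational.SampleRecord(
                sample_name=name, derived_from=f"P_Q_A{i}",
                organism="Sus scrofa", organism_part="Liver"))
        con.commit()
        part = store.partition("expression")
        for name, v in zip(["P_Q_1", "P_Q_2", "P_Q_3"], [10.0, 20.0, 30.0]):
            part.append_rows([dict(sampleid=name, genename="MYOG", fpkm=v,
                                   organism="Sus scrofa", tissue="Liver")])
        df = export.export_avgfpkm(store, ["MYOG"])
        row = df.iloc[0]
        assert (row["min_fpkm"], row["avg_fpkm"], row["max_fpkm"]) == (10.0, 20.0, 30.0)
        assert row["sample_count"] == 3

    def test_equal_values_collapse_min_avg_max(self, optn_store):
        store, _ = optn_store
        df = export.export_avgfpkm(store, ["ACTB"])
        row = df.iloc[0]
        assert row["min_fpkm"] == row["avg_fpkm"] == row["max_fpkm"] == 33.0
        assert row["sample_count"] == 2

    def test_brute_force_recomputation(self, study_store):
        store, ledger = study_store
        df = export.export_avgfpkm(store, ["GENE00"])  # fuzzy: matches all genes
        # brute force from the ledger
        by_group: dict = {}
        for sname, entry in ledger["samples"].items():
            for gene, v in entry["fpkm"].items():
                if entry["quantifier"] in ("kallisto", "salmon"):
                    continue  # those dialects carry no FPKM
                by_group.setdefault((gene, entry["tissue"]), []).append(v)
        checked = 0
        for _, row in df.iterrows():
            vals = by_group.get((row["genename"], row["tissue"]))
            if vals is None:
                assert math.isnan(row["min_fpkm"]) or row["min_fpkm"] is None
                continue
            assert row["min_fpkm"] == pytest.approx(min(vals), abs=1e-9)
            assert row["avg_fpkm"] == pytest.approx(sum(vals) / len(vals), abs=1e-9)
            assert row["max_fpkm"] == pytest.approx(max(vals), abs=1e-9)
            assert row["min_fpkm"] <= row["avg_fpkm"] <= row["max_fpkm"]
            checked += 1
        assert checked >= 10

    def test_no_match_returns_empty_with_columns(self, optn_store):
        store, _ = optn_store
        df = export.export_avgfpkm(store, ["ZZZNOPE"])
        assert df.empty
        assert "avg_fpkm" in df.columns

    def test_empty_gene_list_rejected(self, optn_store):
        store, _ = optn_store
        with pytest.raises(ValidationError):
            export.export_avgfpkm(store, [])


class TestGenexp:
    def test_optn_expressed_only_in_one_sample(self, optn_store):
        store, _ = optn_store
        df = export.export_genexp(store, "Gallus gallus")
        row = df[df["genename"] == "OPTN"].iloc[0]
        assert row["GGA_UD_1004"] == 12.5
        assert row["GGA_UD_1014"] == 0.0

    def test_single_sample_selection(self, optn_store):
        store, _ = optn_store
        df = export.export_genexp(store, "Gallus gallus", samples=["GGA_UD_1004"])
        assert list(df.columns) == ["genename", "GGA_UD_1004"]

    def test_unknown_organism(self, optn_store):
        store, _ = optn_store
        with pytest.raises(ValidationError, match="unknown organism"):
            export.export_genexp(store, "Homo sapiens")

    def test_sample_of_other_organism_rejected(self, study_store):
        store, _ = study_store
        with pytest.raises(ValidationError, match="not available"):
            export.export_genexp(store, "Gallus gallus", samples=["CFA_UD_1004"])

    def test_matrix_cells_equal_ledger_values(self, study_store):
        store, ledger = study_store
        for organism in ("Gallus gallus", "Canis familiaris"):
            df = export.export_genexp(store, organism).set_index("genename")
            for sname, entry in ledger["samples"].items():
                if entry["organism"] != organism:
                    continue
                source = entry["fpkm"] if entry["quantifier"] in ("cufflinks", "stringtie") \
                    else entry["tpm"]
                for gene, v in source.items():
                    assert df.loc[gene, sname] == pytest.approx(v, abs=1e-9)


class TestChrvar:
    def test_totals_conserved_against_varsummary(self, study_store):
        store, _ = study_store
        df = export.export_chrvar(store)
        totals = df.groupby("sampleid")["variantcount"].sum().to_dict()
        vs = dict(store.connection.execute(
            "SELECT s.samplename, v.totalvariants FROM VarSummary v "
            "JOIN Sample s USING(sampleid)"
        ).fetchall())
        assert totals == vs
        # and against distinct variant sites in the columnar partition
        part = store.partition("variant")
        pdf = pd.DataFrame(part.rows(
            ["sampleid", "chrom", "position", "refallele", "altallele"]
        )).drop_duplicates()
        assert pdf.groupby("sampleid").size().to_dict() == totals

    def test_restriction_matches_full_scan_counts(self, study_store):
        store, _ = study_store
        df = export.export_chrvar(store, chroms=["2"])
        assert set(df["chrom"]) <= {"2"}
        part = store.partition("variant")
        pdf = pd.DataFrame(part.rows(
            ["sampleid", "chrom", "position", "refallele", "altallele"]
        )).drop_duplicates()
        expected = pdf[pdf["chrom"] == "2"].groupby("sampleid").size().to_dict()
        assert df.set_index("sampleid")["variantcount"].to_dict() == expected

    def test_empty_store(self, tmp_path):
        store = Store.install(str(tmp_path / "st"))
        assert export.export_chrvar(store).empty


class TestVarannoAndWriters:
    def test_vcf_round_trip(self, optn_store, tmp_path):
        store, _ = optn_store
        path = str(tmp_path / "out.vcf")
        export.export_varanno(store, {"organism": "Gallus gallus"}, "vcf", path)
        parsed = ingest.parse_vcf(path)  # strict reader accepts the file
        back = export.read_csq(path)
        original = export.variants_select(store, ("all",))
        orig_tuples = sorted(
            (r["chrom"], r["position"], r["refallele"], r["altallele"], r["consequence"])
            for _, r in original.iterrows()
        )
        back_tuples = sorted(
            (r["chrom"], r["position"], r["refallele"], r["altallele"], r.get("consequence"))
            for r in back
        )
        assert back_tuples == orig_tuples
        # one VCF record per (sample, site): MTD is single-valued
        sites = {(r.get("sampleid"), r["chrom"], r["position"], r["refallele"], r["altallele"])
                 for r in back}
        assert len(parsed) == len(sites)

    def test_vcf_header_and_arity(self, optn_store, tmp_path):
        store, _ = optn_store
        path = str(tmp_path / "o.vcf")
        export.export_varanno(store, {"genes": ["OPTN"]}, "vcf", path)
        lines = open(path).read().splitlines()
        assert lines[0].startswith("##fileformat=VCFv4")
        csq_header = next(l for l in lines if l.startswith("##INFO=<ID=CSQ"))
        arity = csq_header.split("Format: ")[1].rstrip('">').count("|")
        for line in lines:
            if line.startswith("#"):
                continue
            info = dict(kv.split("=", 1) for kv in line.split("\t")[7].split(";"))
            for entry in info["CSQ"].split(","):
                assert entry.count("|") == arity

    def test_records_sorted_by_chrom_then_position(self, study_store, tmp_path):
        store, _ = study_store
        path = str(tmp_path / "s.vcf")
        export.export_varanno(store, {}, "vcf", path)
        keys = []
        for line in open(path):
            if line.startswith("#"):
                continue
            c = line.split("\t")
            keys.append((export._chrom_sort_key(c[0]), int(c[1])))
        assert keys == sorted(keys)

    def test_empty_result_yields_header_only_vcf(self, tmp_path):
        store = Store.install(str(tmp_path / "st"))
        path = str(tmp_path / "e.vcf")
        export.export_varanno(store, {}, "vcf", path)
        lines = open(path).read().splitlines()
        assert lines[0].startswith("##fileformat=VCFv4")
        assert all(l.startswith("#") for l in lines)

    def test_gene_selector_matches_variants_select(self, optn_store, tmp_path):
        store, _ = optn_store
        path = str(tmp_path / "g.tsv")
        export.export_varanno(store, {"genes": ["OPTN"]}, "tsv", path)
        got = pd.read_csv(path, sep="\t")
        want = export.variants_select(store, ("gene", "OPTN"))
        assert len(got) == len(want)
        assert sorted(got["position"]) == sorted(want["position"])

    def test_write_tsv_contract(self, tmp_path):
        df = pd.DataFrame({"a": [1, None], "b": ["x", "NULL"]})
        path = str(tmp_path / "t.tsv")
        export.write_tsv(df, path)
        lines = open(path).read().splitlines()
        assert lines[0] == "a\tb"
        assert len(lines) == 3
        assert lines[2].split("\t") == ["NULL", "NULL"]

    def test_write_tsv_rejects_embedded_tabs(self, tmp_path):
        df = pd.DataFrame({"a": ["x\ty"]})
        with pytest.raises(ValidationError, match="tab"):
            export.write_tsv(df, str(tmp_path / "bad.tsv"))

    def test_write_tsv_header_only_for_empty_table(self, tmp_path):
        df = pd.DataFrame(columns=["a", "b"])
        path = str(tmp_path / "h.tsv")
        export.write_tsv(df, path)
        assert open(path).read() == "a\tb\n"
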
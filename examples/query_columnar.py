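"""Query a columnar partition with the SQL subset and bitmap indexes.

Loads the two-sample scenario, builds equality bitmap indexes on the
low-cardinality columns of the variant partition, runs a FROM-less query,
and cross-checks the engine against the naive full-scan evaluator.
"""

import tempfile

from transatlasdb import Store, execute_query, fixtures, naive_evaluate, parse_query

with tempfile.TemporaryDirectory() as work:
    store = Store.install(f"{work}/store")
    fixtures.generate_optn_scenario(1, f"{work}/study")
    fixtures.import_study(store, f"{work}/study")

    part = store.partition("variant")
    part.build_default_indexes()          # key columns: chrom, variantclass, zygosity
    part.build_bitmap_index("genename")

    ast = parse_query(
        "select sampleid, chrom, position, genename, consequence "
        "where genename = 'OPTN' and consequence like 'synonymous%' "
        "order by position limit 10"
    )
    result = execute_query(part, ast)
    print("\t".join(result.columns))
    for row in result.rows:
        print("\t".join(map(str, row)))
    print(f"{len(result.rows)} synonymous OPTN variant rows "
          "(one sample carries 1, the other several)")

    reference = naive_evaluate(part, ast)
    print("engine == naive full scan:", result.rows == reference.rows)
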
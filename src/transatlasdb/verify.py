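"""Randomized verification workloads for the columnar query engine.

Generates seeded random partitions and random SQL-subset statements, and
measures agreement between the bitmap-index engine path and the naive
full-scan reference evaluator.  Used by the test suite and by the
reproduction script; all randomness comes from the caller's seed.
"""

from __future__ import annotations

import random

from .columnar import ColumnSchema, Partition
from .query import execute_query, naive_evaluate, parse_query

_COLUMNS = ["sampleid", "chrom", "genename", "position", "fpkm"]


def random_partition(rng: random.Random, path: str, nrows: int) -> Partition:
    """A partition shaped like the warehouse's result tables, random content."""
    schema = [
        ColumnSchema("sampleid", "text"),
        ColumnSchema("chrom", "key"),
        ColumnSchema("genename", "text"),
        ColumnSchema("position", "int"),
        ColumnSchema("fpkm", "double"),
    ]
    p = Partition.create(str(path), schema)
    rows = [
        dict(
            sampleid=rng.choice(["GGA_UD_1004", "GGA_UD_1014", "CFA_UD_2001"]),
            chrom=rng.choice(["1", "2", "3", "10", "MT"]),
            genename=rng.choice(["OPTN", "ACTB", "GAPDH", "NULL", "optn2"]),
            position=rng.randint(1, 5000) if rng.random() > 0.05 else None,
            fpkm=round(rng.uniform(0, 50), 3) if rng.random() > 0.1 else None,
        )
        for _ in range(nrows)
    ]
    p.append_rows(rows)
    return p


def random_query(rng: random.Random) -> str:
    """One random statement over the supported grammar (AND-conjunctions,
    optional grouping/aggregation, ordering, limit)."""
    parts = []
    grouped = rng.random() < 0.3
    if grouped:
        key = rng.choice(["chrom", "genename", "sampleid"])
        fn = rng.choice(["count", "sum", "avg", "min", "max"])
        arg = "*" if fn == "count" and rng.random() < 0.5 else rng.choice(["position", "fpkm"])
        parts.append(f"select {key}, {fn}({arg})")
        group = f" group by {key}"
        order_candidates = [key]
    else:
        proj = (
            rng.sample(_COLUMNS, rng.randint(1, len(_COLUMNS)))
            if rng.random() > 0.2
            else ["*"]
        )
        parts.append("select " + ", ".join(proj))
        group = ""
        order_candidates = _COLUMNS
    preds = []
    for _ in range(rng.randint(0, 3)):
        c = rng.choice(_COLUMNS)
        if c in ("position", "fpkm"):
            op = rng.choice(["=", "!=", "<", "<=", ">", ">="])
            preds.append(f"{c} {op} {rng.randint(0, 5000)}")
        else:
            lit = rng.choice(["OPTN", "optn%", "%1004", "NULL", "1", "%a%"])
            preds.append(f"{c} {rng.choice(['=', '!=', '<', '>', 'like'])} '{lit}'")
    if preds:
        parts.append(" where " + " and ".join(preds))
    parts.append(group)
    if rng.random() < 0.6:
        parts.append(f" order by {rng.choice(order_candidates)} "
                     f"{rng.choice(['', 'asc', 'desc'])}")
    if rng.random() < 0.4:
        parts.append(f" limit {rng.randint(0, 30)}")
    return "".join(parts)


def oracle_agreement(seed: int, n_queries: int = 200, workdir: str = ".",
                     max_rows: int = 1000) -> dict:
    """Run ``n_queries`` random statements over random partitions and compare
    the engine (with and without indexes) to the naive scan.

    Returns ``{"queries": n, "agreeing": m, "mismatches": [...]}``.
    """
    import os

    rng = random.Random(seed)
    per_part = max(1, n_queries // 4)
    mismatches = []
    agreeing = 0
    total = 0
    trial = 0
    while total < n_queries:
        path = os.path.join(workdir, f"oracle-part-{seed}-{trial}")
        p = random_partition(rng, path, rng.randint(50, max_rows))
        p.build_default_indexes()
        p.build_bitmap_index("genename")
        p.build_bitmap_index("sampleid")
        for _ in range(min(per_part, n_queries - total)):
            q = random_query(rng)
            ast = parse_query(q)
            ref = naive_evaluate(p, ast)
            ok = True
            for use_idx in (True, False):
                got = execute_query(p, ast, use_indexes=use_idx)
                if got.columns != ref.columns or got.rows != ref.rows:
                    ok = False
                    mismatches.append({"query": q, "indexed": use_idx})
            agreeing += ok
            total += 1
        trial += 1
    return {"queries": total, "agreeing": agreeing, "mismatches": mismatches}
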
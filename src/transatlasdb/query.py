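"""SQL-subset parser and evaluators for the columnar partitions.

The columnar store answers ``SELECT`` statements without a ``FROM`` clause
(the partition is chosen separately; a ``FROM`` clause is tolerated and
ignored).  The supported grammar is::

    select <item> [, <item>]*
        [where <col> <op> <literal> [and ...]*]
        [group by <col> [, <col>]*]
        [order by <col> [asc|desc]]
        [limit <n>]

    item ::= '*' | column | fn '(' ('*' | column) ')'
    fn   ::= count | sum | avg | min | max
    op   ::= = | != | < | <= | > | >= | like

Only conjunctive (AND) predicates are supported; ``OR`` and ``JOIN`` are
rejected explicitly.  ``LIKE`` is case-insensitive with ``%`` matching any
(possibly empty) substring; ``=`` is case-sensitive.  Comparisons on int and
double columns are numeric (a NULL value fails every predicate); on string
columns they are lexicographic, and the stored literal ``'NULL'`` is an
ordinary comparable value.  ``ORDER BY`` is ascending by default with stable
ties in row insertion order and numeric NULLs sorting last; ``LIMIT`` applies
after ordering; ``avg`` is ``sum/count`` as double.

Two evaluators are provided.  ``execute_query`` is the engine path: equality
predicates on indexed columns are answered through the compressed bitmap
indexes, the rest by scanning.  ``naive_evaluate`` is an intentionally plain
row-at-a-time reference evaluator kept free of any indexing or column-wise
shortcuts; the two must agree row-for-row on every supported query.
"""

from __future__ import annotations

import functools
import math
import re
from dataclasses import dataclass, field

from .columnar import NULL, Partition, STRING_KINDS
from .errors import QuerySyntaxError, TadUserError, UnsupportedConstructError

AGG_FNS = ("count", "sum", "avg", "min", "max")
OPS = ("=", "!=", "<", "<=", ">", ">=", "like")

# ---------------------------------------------------------------------------
# AST


@dataclass
class QueryAST:
    """Parsed statement: projection items, predicates, grouping, ordering."""

    items: list = field(default_factory=list)  # ('star',) | ('col', name) | ('agg', fn, arg)
    predicates: list = field(default_factory=list)  # (column, op, literal)
    group_by: list = field(default_factory=list)
    order_by: tuple | None = None  # (column-or-label, 'asc'|'desc')
    limit: int | None = None

    @property
    def star(self) -> bool:
        return any(it[0] == "star" for it in self.items)

    @property
    def projection(self) -> list[str]:
        return [it[1] for it in self.items if it[0] == "col"]

    @property
    def aggregates(self) -> list[tuple[str, str]]:
        return [(it[1], it[2]) for it in self.items if it[0] == "agg"]


@dataclass
class Result:
    """A small result table: column labels plus row tuples."""

    columns: list[str]
    rows: list[tuple]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=self.columns)


# ---------------------------------------------------------------------------
# tokenizer

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>\d+\.\d*|\.\d+|\d+)
  | (?P<string>'(?:[^']|'')*')
  | (?P<op>!=|<=|>=|=|<|>)
  | (?P<punct>[,()*])
  | (?P<ident>[A-Za-z_][A-Za-z0-9_.]*)
""",
    re.VERBOSE,
)


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise QuerySyntaxError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        if kind != "ws":
            tokens.append((kind, m.group(), pos))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


class _Parser:
    KEYWORDS = {
        "select", "from", "where", "and", "or", "group", "by",
        "order", "asc", "desc", "limit", "like", "join", "not",
    }

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def _is_kw(self, tok, word: str) -> bool:
        return tok[0] == "ident" and tok[1].lower() == word

    def expect_kw(self, word: str):
        tok = self.next()
        if not self._is_kw(tok, word):
            raise QuerySyntaxError(f"expected {word!r}, found {tok[1]!r}", tok[2])

    def parse(self) -> QueryAST:
        ast = QueryAST()
        self.expect_kw("select")
        ast.items = self._select_items()
        # tolerated-and-ignored FROM (columnar targets need no table name)
        if self._is_kw(self.peek(), "from"):
            self.next()
            tok = self.next()
            if tok[0] != "ident":
                raise QuerySyntaxError(f"expected table name, found {tok[1]!r}", tok[2])
        if self._is_kw(self.peek(), "where"):
            self.next()
            ast.predicates = self._predicates()
        if self._is_kw(self.peek(), "group"):
            self.next()
            self.expect_kw("by")
            ast.group_by = self._column_list()
        if self._is_kw(self.peek(), "order"):
            self.next()
            self.expect_kw("by")
            tok = self.next()
            if tok[0] != "ident":
                raise QuerySyntaxError(f"expected column name, found {tok[1]!r}", tok[2])
            direction = "asc"
            if self._is_kw(self.peek(), "asc") or self._is_kw(self.peek(), "desc"):
                direction = self.next()[1].lower()
            ast.order_by = (tok[1], direction)
        if self._is_kw(self.peek(), "limit"):
            self.next()
            tok = self.next()
            if tok[0] != "number" or "." in tok[1]:
                raise QuerySyntaxError(f"expected integer limit, found {tok[1]!r}", tok[2])
            ast.limit = int(tok[1])
        tok = self.peek()
        if tok[0] != "eof":
            if self._is_kw(tok, "or"):
                raise UnsupportedConstructError("OR predicates are not supported (AND only)")
            if self._is_kw(tok, "join"):
                raise UnsupportedConstructError("JOIN is not supported in columnar queries")
            raise QuerySyntaxError(f"syntax error at token {tok[1]!r}", tok[2])
        return ast

    def _select_items(self):
        items = []
        while True:
            tok = self.next()
            if tok[0] == "punct" and tok[1] == "*":
                items.append(("star",))
            elif tok[0] == "ident":
                word = tok[1].lower()
                if word in self.KEYWORDS:
                    raise QuerySyntaxError(f"syntax error at token {tok[1]!r}", tok[2])
                if word in AGG_FNS and self.peek()[0] == "punct" and self.peek()[1] == "(":
                    self.next()  # (
                    arg = self.next()
                    if arg[0] == "punct" and arg[1] == "*":
                        argname = "*"
                    elif arg[0] == "ident":
                        argname = arg[1]
                    else:
                        raise QuerySyntaxError(
                            f"expected column or *, found {arg[1]!r}", arg[2]
                        )
                    close = self.next()
                    if close[1] != ")":
                        raise QuerySyntaxError(f"expected ')', found {close[1]!r}", close[2])
                    if word != "count" and argname == "*":
                        raise QuerySyntaxError(f"{word}(*) is not supported", tok[2])
                    items.append(("agg", word, argname))
                else:
                    items.append(("col", tok[1]))
            else:
                raise QuerySyntaxError(f"expected column name, found {tok[1]!r}", tok[2])
            if self.peek()[0] == "punct" and self.peek()[1] == ",":
                self.next()
                continue
            break
        return items

    def _column_list(self):
        cols = []
        while True:
            tok = self.next()
            if tok[0] != "ident":
                raise QuerySyntaxError(f"expected column name, found {tok[1]!r}", tok[2])
            cols.append(tok[1])
            if self.peek()[0] == "punct" and self.peek()[1] == ",":
                self.next()
                continue
            break
        return cols

    def _predicates(self):
        preds = []
        while True:
            tok = self.next()
            if tok[0] != "ident":
                raise QuerySyntaxError(f"expected column name, found {tok[1]!r}", tok[2])
            col = tok[1]
            op_tok = self.next()
            if op_tok[0] == "op":
                op = op_tok[1]
            elif self._is_kw(op_tok, "like"):
                op = "like"
            elif self._is_kw(op_tok, "not"):
                raise UnsupportedConstructError("NOT is not supported")
            else:
                raise QuerySyntaxError(f"expected operator, found {op_tok[1]!r}", op_tok[2])
            lit_tok = self.next()
            if lit_tok[0] == "string":
                literal = lit_tok[1][1:-1].replace("''", "'")
            elif lit_tok[0] == "number":
                literal = float(lit_tok[1]) if "." in lit_tok[1] else int(lit_tok[1])
            else:
                raise QuerySyntaxError(f"expected literal, found {lit_tok[1]!r}", lit_tok[2])
            if op == "like" and not isinstance(literal, str):
                raise QuerySyntaxError("LIKE requires a string literal", lit_tok[2])
            preds.append((col, op, literal))
            nxt = self.peek()
            if self._is_kw(nxt, "and"):
                self.next()
                continue
            if self._is_kw(nxt, "or"):
                raise UnsupportedConstructError("OR predicates are not supported (AND only)")
            break
        return preds


def parse_query(text: str) -> QueryAST:
    """Parse an SQL-subset statement into a :class:`QueryAST`."""
    if not text or not text.strip():
        raise QuerySyntaxError("empty query", 0)
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# shared predicate semantics (also used by Partition.delete_rows)


def _like_regex(pattern: str):
    parts = [re.escape(p) for p in pattern.split("%")]
    return re.compile("(?s)" + ".*".join(parts) + r"\Z", re.IGNORECASE)


def match_value(value, op: str, literal, kind: str) -> bool:
    if kind in STRING_KINDS:
        if op == "like":
            return _like_regex(literal).match(str(value)) is not None
        lit = str(literal)
        s = str(value)
        return {
            "=": s == lit, "!=": s != lit,
            "<": s < lit, "<=": s <= lit, ">": s > lit, ">=": s >= lit,
        }[op]
    # numeric column: NULL fails everything
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    if op == "like":
        raise TadUserError("LIKE is only valid on string columns")
    try:
        lit = float(literal)
    except (TypeError, ValueError):
        raise TadUserError(f"non-numeric literal {literal!r} for numeric column") from None
    v = float(value)
    return {
        "=": v == lit, "!=": v != lit,
        "<": v < lit, "<=": v <= lit, ">": v > lit, ">=": v >= lit,
    }[op]


def match_row(row: dict, predicates, kinds: dict) -> bool:
    for col, op, lit in predicates:
        if col not in kinds:
            raise TadUserError(f"unknown column {col!r}")
        if not match_value(row[col], op, lit, kinds[col]):
            return False
    return True


def _is_null(value) -> bool:
    return (
        value is None
        or (isinstance(value, float) and math.isnan(value))
        or (isinstance(value, str) and value == NULL)
    )


def _agg_label(fn: str, arg: str) -> str:
    return f"{fn}({arg})"


def _aggregate(fn: str, arg: str, rows: list[dict], kinds: dict):
    if fn == "count":
        if arg == "*":
            return len(rows)
        return sum(1 for r in rows if not _is_null(r[arg]))
    vals = [r[arg] for r in rows if not _is_null(r[arg])]
    if fn in ("sum", "avg") and kinds[arg] in STRING_KINDS:
        raise TadUserError(f"{fn}() requires a numeric column, {arg!r} is {kinds[arg]}")
    if not vals:
        return None
    if fn == "sum":
        return float(sum(vals))
    if fn == "avg":
        return float(sum(vals)) / len(vals)
    if fn == "min":
        return min(vals)
    if fn == "max":
        return max(vals)
    raise TadUserError(f"unknown aggregate {fn!r}")


def _sort_cmp(a, b) -> int:
    an, bn = _is_null(a), _is_null(b)
    if an and bn:
        return 0
    if an:
        return 1  # NULLs last ascending
    if bn:
        return -1
    if a < b:
        return -1
    if a > b:
        return 1
    return 0


def _order_rows(rows: list[dict], keycol: str, direction: str) -> list[dict]:
    sign = 1 if direction == "asc" else -1
    indexed = list(enumerate(rows))

    def cmp(x, y):
        c = _sort_cmp(x[1][keycol], y[1][keycol]) * sign
        if c:
            return c
        return -1 if x[0] < y[0] else (1 if x[0] > y[0] else 0)

    return [r for _, r in sorted(indexed, key=functools.cmp_to_key(cmp))]


def _validate(ast: QueryAST, kinds: dict):
    for it in ast.items:
        if it[0] == "col" and it[1] not in kinds:
            raise TadUserError(f"unknown column {it[1]!r}")
        if it[0] == "agg" and it[2] != "*" and it[2] not in kinds:
            raise TadUserError(f"unknown column {it[2]!r}")
    for col, _, _ in ast.predicates:
        if col not in kinds:
            raise TadUserError(f"unknown column {col!r}")
    for col in ast.group_by:
        if col not in kinds:
            raise TadUserError(f"unknown column {col!r}")
    if ast.group_by:
        for col in ast.projection:
            if col not in ast.group_by:
                raise TadUserError(f"column {col!r} must appear in GROUP BY")
        if ast.star:
            raise TadUserError("'*' projection is invalid with GROUP BY")
    elif ast.aggregates and (ast.projection or ast.star):
        raise TadUserError("non-aggregated columns require GROUP BY")


def _project_plain(ast: QueryAST, rows: list[dict], all_columns: list[str]):
    if ast.star:
        cols = all_columns
    else:
        cols = ast.projection
    return cols, [tuple(r[c] for c in cols) for r in rows]


def _group_result(ast: QueryAST, rows: list[dict], kinds: dict) -> Result:
    labels = [it[1] if it[0] == "col" else _agg_label(it[1], it[2]) for it in ast.items]
    if ast.group_by:
        groups: dict[tuple, list[dict]] = {}
        order: list[tuple] = []
        for r in rows:
            k = tuple(r[c] for c in ast.group_by)
            if k not in groups:
                groups[k] = []
                order.append(k)
            groups[k].append(r)
        out_rows = []
        for k in order:
            grp = groups[k]
            keymap = dict(zip(ast.group_by, k))
            row = []
            for it in ast.items:
                if it[0] == "col":
                    row.append(keymap[it[1]])
                else:
                    row.append(_aggregate(it[1], it[2], grp, kinds))
            out_rows.append(tuple(row))
    else:
        out_rows = [tuple(_aggregate(it[1], it[2], rows, kinds) for it in ast.items)]
    return Result(labels, out_rows)


def _finish(ast: QueryAST, result_or_rows, kinds, all_columns) -> Result:
    """Apply grouping/projection, ordering and limit to filtered row dicts."""
    rows = result_or_rows
    if ast.aggregates or ast.group_by:
        res = _group_result(ast, rows, kinds)
        if ast.order_by:
            keycol, direction = ast.order_by
            if keycol not in res.columns:
                raise TadUserError(f"ORDER BY column {keycol!r} is not in the result")
            dict_rows = [dict(zip(res.columns, r)) for r in res.rows]
            dict_rows = _order_rows(dict_rows, keycol, direction)
            res = Result(res.columns, [tuple(r[c] for c in res.columns) for r in dict_rows])
        if ast.limit is not None:
            res = Result(res.columns, res.rows[: ast.limit])
        return res
    if ast.order_by:
        keycol, direction = ast.order_by
        if keycol not in kinds:
            raise TadUserError(f"unknown column {keycol!r}")
        rows = _order_rows(rows, keycol, direction)
    if ast.limit is not None:
        rows = rows[: ast.limit]
    cols, tuples = _project_plain(ast, rows, all_columns)
    return Result(cols, tuples)


# ---------------------------------------------------------------------------
# engine evaluator (bitmap-index aware)


def execute_query(partition: Partition, ast: QueryAST, use_indexes: bool = True) -> Result:
    """Evaluate ``ast`` against a partition, using bitmap indexes where built.

    Equality predicates on columns with a built index are answered by
    decoding the value's compressed bitmap; remaining predicates are applied
    by scanning only the candidate rows.
    """
    kinds = partition.kinds
    _validate(ast, kinds)
    all_columns = [c.name for c in partition.schema]

    candidates: list[int] | None = None  # None = all rows
    residual = []
    for col, op, lit in ast.predicates:
        idx = partition.indexes.get(col) if use_indexes else None
        if idx is not None and op == "=" and idx.nrows == partition.row_count:
            rows = idx.rows_for(str(lit))
            if candidates is None:
                candidates = rows
            else:
                rs = set(rows)
                candidates = [i for i in candidates if i in rs]
        else:
            residual.append((col, op, lit))
    if candidates is None:
        candidates = list(range(partition.row_count))

    needed = set(all_columns) if ast.star else set()
    needed.update(c for c, _, _ in residual)
    needed.update(ast.projection)
    needed.update(ast.group_by)
    for fn, arg in ast.aggregates:
        if arg != "*":
            needed.add(arg)
    if ast.order_by:
        needed.add(ast.order_by[0]) if ast.order_by[0] in kinds else None
    if not needed:
        needed = {all_columns[0]}
    data = {c: partition.column(c) for c in needed}

    rows: list[dict] = []
    for i in candidates:
        row = {c: data[c][i] for c in needed}
        if all(match_value(row[c], op, lit, kinds[c]) for c, op, lit in residual):
            rows.append(row)
    return _finish(ast, rows, kinds, all_columns)


# ---------------------------------------------------------------------------
# naive reference evaluator


def naive_evaluate(partition: Partition, ast: QueryAST) -> Result:
    """Plain row-at-a-time reference evaluation (no indexes, no shortcuts).

    Used as the independent oracle the engine must agree with row-for-row.
    """
    kinds = partition.kinds
    _validate(ast, kinds)
    all_columns = [c.name for c in partition.schema]
    selected = []
    for row in partition.rows():
        ok = True
        for col, op, lit in ast.predicates:
            if not match_value(row[col], op, lit, kinds[col]):
                ok = False
                break
        if ok:
            selected.append(row)
    return _finish(ast, selected, kinds, all_columns)
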
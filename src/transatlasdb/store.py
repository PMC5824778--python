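"""Store handle: one directory holding both databases, settings and logs.

Layout::

    <root>/
        settings.txt      key=value: relational, columnar, logs paths
        relational.db     embedded relational database
        transatlasfb/     columnar root (default name), one dir per partition
            variant/  expression/  readcount/
        logs/
            transactions.log   one line per state-changing action
            <timestamp>-<action>.log   per-transaction detail

Installation is carried out once per store directory; a reconnect operation
rewrites only the settings file (for relocated columnar roots or logs).
"""

from __future__ import annotations

import os
from datetime import datetime, timezone

from . import relational
from .columnar import ColumnSchema, Partition
from .errors import StoreExistsError, TadUserError

SETTINGS_FILENAME = "settings.txt"
DEFAULT_COLUMNAR = "transatlasfb"

VARIANT_SCHEMA = [
    ColumnSchema("sampleid", "text"),
    ColumnSchema("chrom", "key"),
    ColumnSchema("position", "int"),
    ColumnSchema("refallele", "char"),
    ColumnSchema("altallele", "char"),
    ColumnSchema("quality", "double"),
    ColumnSchema("dbsnpvariant", "text"),
    ColumnSchema("variantclass", "key"),
    ColumnSchema("zygosity", "key"),
    ColumnSchema("source", "text"),
    ColumnSchema("consequence", "text"),
    ColumnSchema("geneid", "text"),
    ColumnSchema("genename", "text"),
    ColumnSchema("transcript", "text"),
    ColumnSchema("feature", "text"),
    ColumnSchema("genetype", "text"),
    ColumnSchema("proteinposition", "int"),
    ColumnSchema("aachange", "text"),
    ColumnSchema("codonchange", "text"),
    ColumnSchema("organism", "text"),
    ColumnSchema("tissue", "text"),
]

EXPRESSION_SCHEMA = [
    ColumnSchema("sampleid", "text"),
    ColumnSchema("chrom", "key"),
    ColumnSchema("start", "int"),
    ColumnSchema("stop", "int"),
    ColumnSchema("genename", "text"),
    ColumnSchema("geneid", "text"),
    ColumnSchema("coverage", "double"),
    ColumnSchema("tpm", "double"),
    ColumnSchema("fpkm", "double"),
    ColumnSchema("fpkmconflow", "double"),
    ColumnSchema("fpkmconfhigh", "double"),
    ColumnSchema("fpkmstatus", "char"),
    ColumnSchema("organism", "text"),
    ColumnSchema("tissue", "text"),
]

READCOUNT_SCHEMA = [
    ColumnSchema("sampleid", "text"),
    ColumnSchema("genename", "text"),
    ColumnSchema("readcount", "int"),
    ColumnSchema("organism", "text"),
    ColumnSchema("tissue", "text"),
]

PARTITION_SCHEMAS = {
    "variant": VARIANT_SCHEMA,
    "expression": EXPRESSION_SCHEMA,
    "readcount": READCOUNT_SCHEMA,
}


def _now() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


class Store:
    """Open handle on an installed store directory."""

    def __init__(self, root: str, settings: dict[str, str]):
        self.root = os.path.abspath(root)
        self.settings = settings
        self._con = None
        self._partitions: dict[str, Partition] = {}

    # -- lifecycle ----------------------------------------------------------

    @classmethod
    def install(
        cls, root: str, columnar: str | None = None, overwrite: bool = False
    ) -> "Store":
        root = os.path.abspath(root)
        os.makedirs(root, exist_ok=True)
        settings_path = os.path.join(root, SETTINGS_FILENAME)
        if os.path.exists(settings_path) and not overwrite:
            raise StoreExistsError(f"store exists: {root}")
        db_path = os.path.join(root, relational.DB_FILENAME)
        relational.create_schema(db_path, overwrite=overwrite)
        columnar_root = os.path.abspath(columnar or os.path.join(root, DEFAULT_COLUMNAR))
        os.makedirs(columnar_root, exist_ok=True)
        for name, schema in PARTITION_SCHEMAS.items():
            pdir = os.path.join(columnar_root, name)
            if overwrite and os.path.isdir(pdir):
                for f in os.listdir(pdir):
                    os.remove(os.path.join(pdir, f))
            Partition.create(pdir, schema)
        logs = os.path.join(root, "logs")
        os.makedirs(logs, exist_ok=True)
        settings = {"relational": db_path, "columnar": columnar_root, "logs": logs}
        cls._write_settings(settings_path, settings)
        return cls(root, settings)

    @classmethod
    def open(cls, root: str) -> "Store":
        settings_path = os.path.join(os.path.abspath(root), SETTINGS_FILENAME)
        if not os.path.exists(settings_path):
            raise TadUserError(f"no store installed at {root} (run install first)")
        settings: dict[str, str] = {}
        with open(settings_path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line and "=" in line:
                    k, v = line.split("=", 1)
                    settings[k] = v
        return cls(root, settings)

    @classmethod
    def reconnect(
        cls, root: str, columnar: str | None = None, logs: str | None = None
    ) -> "Store":
        """Rewrite the settings file only; databases are untouched."""
        store = cls.open(root)
        if columnar:
            store.settings["columnar"] = os.path.abspath(columnar)
        if logs:
            store.settings["logs"] = os.path.abspath(logs)
        cls._write_settings(os.path.join(store.root, SETTINGS_FILENAME), store.settings)
        return store

    @staticmethod
    def _write_settings(path: str, settings: dict[str, str]):
        with open(path, "w", encoding="utf-8") as fh:
            for k, v in settings.items():
                fh.write(f"{k}={v}\n")

    def close(self):
        if self._con is not None:
            self._con.close()
            self._con = None

    # -- components ---------------------------------------------------------

    @property
    def connection(self):
        if self._con is None:
            self._con = relational.connect(self.settings["relational"])
        return self._con

    def partition(self, name: str) -> Partition:
        if name not in PARTITION_SCHEMAS:
            raise TadUserError(f"unknown partition {name!r} (variant/expression/readcount)")
        if name not in self._partitions:
            self._partitions[name] = Partition.open(os.path.join(self.settings["columnar"], name))
        return self._partitions[name]

    # -- logging ------------------------------------------------------------

    def log_action(self, action: str, detail_lines: list[str] | None = None) -> str:
        """Record one state-changing action: one master-log line, and one
        per-transaction detail file when detail lines are given."""
        logs = self.settings["logs"]
        os.makedirs(logs, exist_ok=True)
        stamp = _now()
        with open(os.path.join(logs, "transactions.log"), "a", encoding="utf-8") as fh:
            fh.write(f"({stamp}) {action}\n")
        path = ""
        if detail_lines:
            safe = "".join(c if c.isalnum() or c in "-_" else "_" for c in action)[:80]
            path = os.path.join(logs, f"{stamp.replace(':', '')}-{safe}.log")
            with open(path, "a", encoding="utf-8") as fh:
                for line in detail_lines:
                    fh.write(f"({stamp}) {line}\n")
        return path
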
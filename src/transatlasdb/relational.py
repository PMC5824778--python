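"""Embedded relational store: schema, dimensions, samples, integrity.

The relational side of the warehouse holds sample metadata, analysis
summaries and per-variant detail, organized in four sections (sample,
alignment, expression, variant information) with parent→child foreign keys
radiating from ``Sample``.  It is implemented on the embedded SQLite engine:
a single database file per store, foreign keys enforced, the six reporting
views registered as real SQL views, and the four "stored procedures"
registered as named parameterized queries (SQLite has no procedure objects;
the observable contract is the query surface).

Lookup dimensions (Organism, Breed, Sex, DevelopmentalStage, HealthStatus,
Material, Tissue, Organization) use get-or-create semantics with
case-sensitive exact matching, so N samples sharing an organism produce one
Organism row.  Internal keys are monotonically increasing integers; external
identity is always the sample name.
"""

from __future__ import annotations

import os
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timezone

from .errors import StoreExistsError, TadUserError, ValidationError

DB_FILENAME = "relational.db"

# Order matters only for creation (parents before children).
TABLE_DDL: dict[str, str] = {
    "Organism": "CREATE TABLE Organism (organismid INTEGER PRIMARY KEY, organism TEXT NOT NULL UNIQUE)",
    "Breed": "CREATE TABLE Breed (breedid INTEGER PRIMARY KEY, breed TEXT NOT NULL UNIQUE)",
    "Sex": "CREATE TABLE Sex (sexid INTEGER PRIMARY KEY, sex TEXT NOT NULL UNIQUE)",
    "DevelopmentalStage": "CREATE TABLE DevelopmentalStage (stageid INTEGER PRIMARY KEY, stage TEXT NOT NULL UNIQUE)",
    "HealthStatus": "CREATE TABLE HealthStatus (healthid INTEGER PRIMARY KEY, status TEXT NOT NULL UNIQUE)",
    "Material": "CREATE TABLE Material (materialid INTEGER PRIMARY KEY, material TEXT NOT NULL UNIQUE)",
    "Tissue": "CREATE TABLE Tissue (tissueid INTEGER PRIMARY KEY, tissue TEXT NOT NULL UNIQUE)",
    "Animal": """CREATE TABLE Animal (
        animalid INTEGER PRIMARY KEY,
        animalname TEXT NOT NULL UNIQUE,
        organismid INTEGER NOT NULL REFERENCES Organism(organismid),
        breedid INTEGER REFERENCES Breed(breedid),
        sexid INTEGER REFERENCES Sex(sexid),
        stageid INTEGER REFERENCES DevelopmentalStage(stageid),
        healthid INTEGER REFERENCES HealthStatus(healthid))""",
    "AnimalStats": """CREATE TABLE AnimalStats (
        animalstatid INTEGER PRIMARY KEY,
        animalid INTEGER NOT NULL REFERENCES Animal(animalid),
        attribute TEXT NOT NULL,
        value TEXT)""",
    "Sample": """CREATE TABLE Sample (
        sampleid INTEGER PRIMARY KEY,
        samplename TEXT NOT NULL UNIQUE,
        animalid INTEGER NOT NULL REFERENCES Animal(animalid),
        tissueid INTEGER NOT NULL REFERENCES Tissue(tissueid),
        materialid INTEGER REFERENCES Material(materialid),
        description TEXT,
        loaddate TEXT NOT NULL)""",
    "SampleStats": """CREATE TABLE SampleStats (
        samplestatid INTEGER PRIMARY KEY,
        sampleid INTEGER NOT NULL REFERENCES Sample(sampleid),
        attribute TEXT NOT NULL,
        value TEXT)""",
    "Person": """CREATE TABLE Person (
        personid INTEGER PRIMARY KEY,
        firstname TEXT,
        middleinitial TEXT,
        lastname TEXT)""",
    "Organization": """CREATE TABLE Organization (
        organizationid INTEGER PRIMARY KEY,
        organizationname TEXT NOT NULL UNIQUE)""",
    "SamplePerson": """CREATE TABLE SamplePerson (
        sampleid INTEGER NOT NULL REFERENCES Sample(sampleid),
        personid INTEGER NOT NULL REFERENCES Person(personid),
        PRIMARY KEY (sampleid, personid))""",
    "SampleOrganization": """CREATE TABLE SampleOrganization (
        sampleid INTEGER NOT NULL REFERENCES Sample(sampleid),
        organizationid INTEGER NOT NULL REFERENCES Organization(organizationid),
        PRIMARY KEY (sampleid, organizationid))""",
    "MapStats": """CREATE TABLE MapStats (
        sampleid INTEGER PRIMARY KEY REFERENCES Sample(sampleid),
        totalreads INTEGER NOT NULL CHECK (totalreads >= 0),
        mappedreads INTEGER NOT NULL CHECK (mappedreads >= 0),
        alignmentrate REAL NOT NULL,
        mappername TEXT,
        mapdate TEXT,
        loaddate TEXT NOT NULL,
        CHECK (mappedreads <= totalreads))""",
    "Metadata": """CREATE TABLE Metadata (
        metadataid INTEGER PRIMARY KEY,
        sampleid INTEGER NOT NULL REFERENCES Sample(sampleid),
        stage TEXT NOT NULL,
        toolname TEXT NOT NULL,
        loaddate TEXT NOT NULL)""",
    "CommandSyntax": """CREATE TABLE CommandSyntax (
        commandid INTEGER PRIMARY KEY,
        sampleid INTEGER NOT NULL REFERENCES Sample(sampleid),
        stage TEXT NOT NULL,
        toolname TEXT NOT NULL,
        invocation TEXT,
        loaddate TEXT NOT NULL)""",
    "GeneStats": """CREATE TABLE GeneStats (
        sampleid INTEGER PRIMARY KEY REFERENCES Sample(sampleid),
        genesquantified INTEGER NOT NULL CHECK (genesquantified >= 0),
        quantifiername TEXT NOT NULL,
        units TEXT NOT NULL,
        loaddate TEXT NOT NULL)""",
    "ReadCounts": """CREATE TABLE ReadCounts (
        sampleid INTEGER PRIMARY KEY REFERENCES Sample(sampleid),
        genescounted INTEGER NOT NULL CHECK (genescounted >= 0),
        totalcounts INTEGER NOT NULL CHECK (totalcounts >= 0),
        countername TEXT NOT NULL,
        specialcounts INTEGER NOT NULL DEFAULT 0,
        loaddate TEXT NOT NULL)""",
    "VarSummary": """CREATE TABLE VarSummary (
        sampleid INTEGER PRIMARY KEY REFERENCES Sample(sampleid),
        totalvariants INTEGER NOT NULL,
        snpcount INTEGER NOT NULL,
        insertioncount INTEGER NOT NULL,
        deletioncount INTEGER NOT NULL,
        complexcount INTEGER NOT NULL DEFAULT 0,
        callername TEXT,
        annotationsource TEXT NOT NULL DEFAULT 'none',
        loaddate TEXT NOT NULL,
        CHECK (snpcount + insertioncount + deletioncount + complexcount = totalvariants))""",
    "VarResult": """CREATE TABLE VarResult (
        varid INTEGER PRIMARY KEY,
        sampleid INTEGER NOT NULL REFERENCES Sample(sampleid),
        chrom TEXT NOT NULL,
        position INTEGER NOT NULL CHECK (position >= 1),
        refallele TEXT NOT NULL,
        altallele TEXT NOT NULL,
        quality REAL,
        dbsnpvariant TEXT,
        variantclass TEXT NOT NULL,
        zygosity TEXT,
        loaddate TEXT NOT NULL)""",
    "VarAnnotation": """CREATE TABLE VarAnnotation (
        annotationid INTEGER PRIMARY KEY,
        varid INTEGER NOT NULL REFERENCES VarResult(varid),
        source TEXT NOT NULL,
        consequence TEXT,
        geneid TEXT,
        genename TEXT,
        transcript TEXT,
        feature TEXT,
        genetype TEXT,
        proteinposition INTEGER,
        aachange TEXT,
        codonchange TEXT,
        loaddate TEXT NOT NULL)""",
}

# Relationships checked by check_referential_integrity:
# (child table, child fk column, parent table, parent key column)
RELATIONSHIPS = [
    ("Animal", "organismid", "Organism", "organismid"),
    ("Animal", "breedid", "Breed", "breedid"),
    ("Animal", "sexid", "Sex", "sexid"),
    ("Animal", "stageid", "DevelopmentalStage", "stageid"),
    ("Animal", "healthid", "HealthStatus", "healthid"),
    ("AnimalStats", "animalid", "Animal", "animalid"),
    ("Sample", "animalid", "Animal", "animalid"),
    ("Sample", "tissueid", "Tissue", "tissueid"),
    ("Sample", "materialid", "Material", "materialid"),
    ("SampleStats", "sampleid", "Sample", "sampleid"),
    ("SamplePerson", "sampleid", "Sample", "sampleid"),
    ("SamplePerson", "personid", "Person", "personid"),
    ("SampleOrganization", "sampleid", "Sample", "sampleid"),
    ("SampleOrganization", "organizationid", "Organization", "organizationid"),
    ("MapStats", "sampleid", "Sample", "sampleid"),
    ("Metadata", "sampleid", "Sample", "sampleid"),
    ("CommandSyntax", "sampleid", "Sample", "sampleid"),
    ("GeneStats", "sampleid", "Sample", "sampleid"),
    ("ReadCounts", "sampleid", "Sample", "sampleid"),
    ("VarSummary", "sampleid", "Sample", "sampleid"),
    ("VarResult", "sampleid", "Sample", "sampleid"),
    ("VarAnnotation", "varid", "VarResult", "varid"),
]

_VANNO_SELECT = """
    SELECT s.samplename AS sampleid, r.chrom, r.position, r.refallele, r.altallele,
           r.quality, r.dbsnpvariant, r.variantclass, r.zygosity,
           a.source, a.consequence, a.geneid, a.genename, a.transcript, a.feature,
           a.genetype, a.proteinposition, a.aachange, a.codonchange,
           o.organism, t.tissue
    FROM VarResult r
    JOIN Sample s ON s.sampleid = r.sampleid
    JOIN Animal an ON an.animalid = s.animalid
    JOIN Organism o ON o.organismid = an.organismid
    JOIN Tissue t ON t.tissueid = s.tissueid
    {join} VarAnnotation a ON a.varid = r.varid
"""

VIEW_DDL: dict[str, str] = {
    "vw_sample": """CREATE VIEW vw_sample AS
        SELECT s.samplename, an.animalname, o.organism, t.tissue,
               m.material, s.description, s.loaddate
        FROM Sample s
        JOIN Animal an ON an.animalid = s.animalid
        JOIN Organism o ON o.organismid = an.organismid
        JOIN Tissue t ON t.tissueid = s.tissueid
        LEFT JOIN Material m ON m.materialid = s.materialid""",
    "vw_sampleinfo": """CREATE VIEW vw_sampleinfo AS
        SELECT s.samplename, o.organism, t.tissue,
               ms.totalreads, ms.mappedreads, ms.alignmentrate, ms.mappername,
               gs.genesquantified, gs.quantifiername,
               vs.totalvariants, vs.snpcount, vs.insertioncount, vs.deletioncount,
               vs.annotationsource
        FROM Sample s
        JOIN Animal an ON an.animalid = s.animalid
        JOIN Organism o ON o.organismid = an.organismid
        JOIN Tissue t ON t.tissueid = s.tissueid
        LEFT JOIN MapStats ms ON ms.sampleid = s.sampleid
        LEFT JOIN GeneStats gs ON gs.sampleid = s.sampleid
        LEFT JOIN VarSummary vs ON vs.sampleid = s.sampleid""",
    "vw_seqstats": """CREATE VIEW vw_seqstats AS
        SELECT s.samplename, ms.mappername, ms.totalreads, ms.mappedreads,
               ms.alignmentrate, ms.mapdate, ms.loaddate
        FROM Sample s
        LEFT JOIN MapStats ms ON ms.sampleid = s.sampleid""",
    "vw_vanno": "CREATE VIEW vw_vanno AS " + _VANNO_SELECT.format(join="JOIN"),
    "vw_vvcf": """CREATE VIEW vw_vvcf AS
        SELECT r.chrom, r.position, r.dbsnpvariant, r.refallele, r.altallele,
               r.quality, s.samplename AS sampleid, o.organism, t.tissue,
               a.source, a.consequence, a.geneid, a.genename, a.transcript,
               a.feature, a.genetype, a.proteinposition, a.aachange, a.codonchange
        FROM VarResult r
        JOIN Sample s ON s.sampleid = r.sampleid
        JOIN Animal an ON an.animalid = s.animalid
        JOIN Organism o ON o.organismid = an.organismid
        JOIN Tissue t ON t.tissueid = s.tissueid
        LEFT JOIN VarAnnotation a ON a.varid = r.varid""",
    "vw_nosql": "CREATE VIEW vw_nosql AS " + _VANNO_SELECT.format(join="LEFT JOIN"),
}

# Named parameterized queries playing the stored-procedure role.  All four
# select the Table-4A-shaped variant+annotation join (unannotated variants
# included with NULL annotation fields), mirroring the columnar partition.
PROCEDURES: dict[str, str] = {
    "usp_vall": "SELECT * FROM vw_nosql",
    "usp_vchrom": "SELECT * FROM vw_nosql WHERE chrom = :chrom",
    "usp_vchrposition": (
        "SELECT * FROM vw_nosql WHERE chrom = :chrom "
        "AND position >= :start AND position <= :stop"
    ),
    "usp_vgene": "SELECT * FROM vw_nosql WHERE genename LIKE :gene",
}


def _now() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


@dataclass
class SchemaReport:
    table_names: list[str] = field(default_factory=list)
    view_names: list[str] = field(default_factory=list)
    procedure_names: list[str] = field(default_factory=list)


@dataclass
class SampleRecord:
    """One specimen plus provenance — the hub every result references."""

    sample_name: str
    derived_from: str  # animal identification number/name
    organism: str
    organism_part: str  # tissue
    description: str | None = None
    first_name: str | None = None
    middle_initial: str | None = None
    last_name: str | None = None
    organization: str | None = None
    material: str | None = None

    REQUIRED = (
        ("sample_name", "Sample name"),
        ("derived_from", "Derived from"),
        ("organism", "Organism"),
        ("organism_part", "Organism part"),
    )

    def validate(self):
        for attr, header in self.REQUIRED:
            v = getattr(self, attr)
            if v is None or not str(v).strip():
                raise ValidationError(f"missing required field: {header}")


def connect(db_path: str) -> sqlite3.Connection:
    con = sqlite3.connect(db_path)
    con.execute("PRAGMA foreign_keys = ON")
    con.row_factory = sqlite3.Row
    return con


def create_schema(db_path: str, overwrite: bool = False) -> SchemaReport:
    """Create the full relational schema at ``db_path``.

    Registers 23 tables with primary/foreign keys, 6 views, and the 4 named
    procedure queries; returns their names.  Fails if a store already exists
    unless ``overwrite`` is set.
    """
    if os.path.exists(db_path):
        if not overwrite:
            raise StoreExistsError(f"store exists: {db_path}")
        os.remove(db_path)
    parent = os.path.dirname(os.path.abspath(db_path))
    os.makedirs(parent, exist_ok=True)
    con = connect(db_path)
    try:
        with con:
            for ddl in TABLE_DDL.values():
                con.execute(ddl)
            for ddl in VIEW_DDL.values():
                con.execute(ddl)
    finally:
        con.close()
    return schema_report(db_path)


def schema_report(db_path: str) -> SchemaReport:
    con = connect(db_path)
    try:
        tables = [
            r[0]
            for r in con.execute(
                "SELECT name FROM sqlite_master WHERE type='table' "
                "AND name NOT LIKE 'sqlite_%' ORDER BY name"
            )
        ]
        views = [
            r[0]
            for r in con.execute("SELECT name FROM sqlite_master WHERE type='view' ORDER BY name")
        ]
    finally:
        con.close()
    return SchemaReport(tables, views, sorted(PROCEDURES))


# ---------------------------------------------------------------------------
# dimension helpers


def get_or_create(con: sqlite3.Connection, table: str, column: str, value: str, key: str) -> int:
    """Case-sensitive exact-match get-or-create on a lookup dimension."""
    row = con.execute(f"SELECT {key} FROM {table} WHERE {column} = ?", (value,)).fetchone()
    if row is not None:
        return row[0]
    cur = con.execute(f"INSERT INTO {table} ({column}) VALUES (?)", (value,))
    return cur.lastrowid


def insert_sample(con: sqlite3.Connection, record: SampleRecord) -> int:
    """Insert one sample plus its dimension rows; returns the internal key.

    Animal, Organism, Tissue, Material, Person and Organization rows are
    get-or-created; cross-reference rows are written.  Duplicate sample
    names raise a uniqueness error.
    """
    record.validate()
    exists = con.execute(
        "SELECT 1 FROM Sample WHERE samplename = ?", (record.sample_name,)
    ).fetchone()
    if exists:
        raise ValidationError(f"sample name already present: {record.sample_name}")
    organismid = get_or_create(con, "Organism", "organism", record.organism, "organismid")
    tissueid = get_or_create(con, "Tissue", "tissue", record.organism_part, "tissueid")
    animal = con.execute(
        "SELECT animalid, organismid FROM Animal WHERE animalname = ?", (record.derived_from,)
    ).fetchone()
    if animal is None:
        animalid = con.execute(
            "INSERT INTO Animal (animalname, organismid) VALUES (?, ?)",
            (record.derived_from, organismid),
        ).lastrowid
    else:
        animalid = animal["animalid"]
    materialid = None
    if record.material:
        materialid = get_or_create(con, "Material", "material", record.material, "materialid")
    sampleid = con.execute(
        "INSERT INTO Sample (samplename, animalid, tissueid, materialid, description, loaddate)"
        " VALUES (?, ?, ?, ?, ?, ?)",
        (record.sample_name, animalid, tissueid, materialid, record.description, _now()),
    ).lastrowid
    if record.first_name or record.last_name:
        person = con.execute(
            "SELECT personid FROM Person WHERE firstname IS ? AND middleinitial IS ? "
            "AND lastname IS ?",
            (record.first_name, record.middle_initial, record.last_name),
        ).fetchone()
        personid = (
            person["personid"]
            if person
            else con.execute(
                "INSERT INTO Person (firstname, middleinitial, lastname) VALUES (?, ?, ?)",
                (record.first_name, record.middle_initial, record.last_name),
            ).lastrowid
        )
        con.execute(
            "INSERT INTO SamplePerson (sampleid, personid) VALUES (?, ?)", (sampleid, personid)
        )
    if record.organization:
        orgid = get_or_create(
            con, "Organization", "organizationname", record.organization, "organizationid"
        )
        con.execute(
            "INSERT INTO SampleOrganization (sampleid, organizationid) VALUES (?, ?)",
            (sampleid, orgid),
        )
    return sampleid


def sample_key(con: sqlite3.Connection, sample_name: str) -> int | None:
    row = con.execute("SELECT sampleid FROM Sample WHERE samplename = ?", (sample_name,)).fetchone()
    return row["sampleid"] if row else None


def sample_context(con: sqlite3.Connection, sample_name: str) -> dict | None:
    """Denormalization source: sampleid key, organism and tissue for a sample."""
    row = con.execute(
        """SELECT s.sampleid, s.samplename, o.organism, t.tissue
           FROM Sample s
           JOIN Animal a ON a.animalid = s.animalid
           JOIN Organism o ON o.organismid = a.organismid
           JOIN Tissue t ON t.tissueid = s.tissueid
           WHERE s.samplename = ?""",
        (sample_name,),
    ).fetchone()
    return dict(row) if row else None


@dataclass
class IntegrityViolation:
    child_table: str
    row_key: int
    missing_parent: str

    def __str__(self):
        return f"{self.child_table} row {self.row_key}: missing parent in {self.missing_parent}"


def check_referential_integrity(con: sqlite3.Connection) -> list[IntegrityViolation]:
    """Brute-force verification of every parent→child relationship.

    Returns an empty list iff every child foreign key resolves.  Implemented
    as explicit anti-joins (not the engine's own FK machinery) so it also
    catches rows introduced by raw access with enforcement disabled.
    """
    violations: list[IntegrityViolation] = []
    for child, fk, parent, pk in RELATIONSHIPS:
        rows = con.execute(
            f"SELECT c.rowid AS rk FROM {child} c "
            f"LEFT JOIN {parent} p ON c.{fk} = p.{pk} "
            f"WHERE c.{fk} IS NOT NULL AND p.{pk} IS NULL"
        ).fetchall()
        for r in rows:
            violations.append(IntegrityViolation(child, r["rk"], parent))
    return violations


def run_procedure(con: sqlite3.Connection, name: str, **params):
    """Execute one of the four registered named queries."""
    if name not in PROCEDURES:
        raise TadUserError(f"unknown procedure {name!r}")
    return con.execute(PROCEDURES[name], params).fetchall()
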
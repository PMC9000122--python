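"""Synthetic-source test bed.

Fabricates toy CERNER-flavoured relational sources (person, diagnosis,
problem, encounter …), the mapping YAML for them, and the expected OMOP
relations — computed independently in Python while the rows are being
generated.  Compiled scripts execute against an embedded SQL backend
(sqlite with one ATTACHed in-memory database per schema, speaking the
PostgreSQL subset the compiler emits), and results are compared as
multisets keyed on the target primary key.

The 16-case registry covers every language feature once: key
strategies, multi-source unions, multiple rules per column, join
constraints, inline SELECT sources, anchors/defaults, constants, NULL
keys, empty sources, and the three diagnostic cases.  None of this is
clinical data; values come from tiny fixed vocabularies so expected
outputs are exactly computable.
"""

from __future__ import annotations

import sqlite3
import zlib
from dataclasses import dataclass, field
from random import Random
from typing import Optional, Sequence

from .dml_model import MappingDocument
from .omop_catalogue import Catalogue, load_catalogue
from .sql_codegen import (
    CompiledScript,
    CompilerConfig,
    compile_project,
)
from .yaml_frontend import Diagnostic, has_errors, load_document

# --- relations and diffing ------------------------------------------------


@dataclass(frozen=True)
class Relation:
    """A named relation: ordered column names and a multiset of rows."""

    name: str
    columns: tuple[str, ...]
    rows: tuple[tuple, ...]


@dataclass
class DiffReport:
    """Differences between an actual and an expected relation, keyed on
    the first column (the target primary key).  Empty iff the relations
    are equal as multisets, with NULL comparing equal to NULL."""

    relation: str
    missing_rows: list[tuple] = field(default_factory=list)
    unexpected_rows: list[tuple] = field(default_factory=list)
    cell_mismatches: list[tuple] = field(default_factory=list)  # (key, column, actual, expected)

    @property
    def empty(self) -> bool:
        return not (self.missing_rows or self.unexpected_rows or self.cell_mismatches)

    def to_dict(self) -> dict:
        return {
            "relation": self.relation,
            "missing_rows": [list(r) for r in self.missing_rows],
            "unexpected_rows": [list(r) for r in self.unexpected_rows],
            "cell_mismatches": [list(m) for m in self.cell_mismatches],
        }

    def render(self) -> str:
        if self.empty:
            return f"{self.relation}: OK"
        lines = [f"{self.relation}:"]
        for r in self.missing_rows:
            lines.append(f"  missing   {r}")
        for r in self.unexpected_rows:
            lines.append(f"  unexpected {r}")
        for key, col, actual, expected in self.cell_mismatches:
            lines.append(f"  row {key}: {col} = {actual!r}, expected {expected!r}")
        return "\n".join(lines)


def diff_relations(actual: Relation, expected: Relation) -> DiffReport:
    """Compare two relations sharing a column set, keyed on the first
    (primary-key) column."""
    if set(actual.columns) != set(expected.columns):
        raise ValueError(
            f"column sets differ: {sorted(actual.columns)} vs {sorted(expected.columns)}"
        )
    # align actual's column order to expected's
    order = [actual.columns.index(c) for c in expected.columns]
    actual_rows = [tuple(row[i] for i in order) for row in actual.rows]
    report = DiffReport(expected.name)

    def by_key(rows):
        grouped: dict = {}
        for row in rows:
            grouped.setdefault(row[0], []).append(row)
        return grouped

    got, want = by_key(actual_rows), by_key(expected.rows)
    for key in sorted(set(got) | set(want), key=lambda k: (k is None, str(k))):
        g, w = got.get(key, []), want.get(key, [])
        for extra in g[len(w):]:
            report.unexpected_rows.append(extra)
        for miss in w[len(g):]:
            report.missing_rows.append(miss)
        for grow, wrow in zip(g, w):
            for col, a, e in zip(expected.columns, grow, wrow):
                if a != e:
                    report.cell_mismatches.append((key, col, a, e))
    return report


# --- embedded execution backend -------------------------------------------

_SQLITE_TYPES = {
    "bigint": "integer",
    "integer": "integer",
    "numeric": "numeric",
    "date": "text",
    "timestamp": "text",
    "text": "text",
}


def _sqlite_type(sql_type: str) -> str:
    return _SQLITE_TYPES.get(sql_type.split("(")[0].strip().lower(), "text")


class SqliteBackend:
    """Embedded engine accepting the compiler's PostgreSQL subset.

    Each logical schema is an ATTACHed in-memory database, so emitted
    ``schema.table`` references resolve unchanged.
    """

    DEFAULT_SCHEMAS = ("source", "omop", "etl_staging", "oracle")

    def __init__(self, schemas: Sequence[str] = DEFAULT_SCHEMAS, path: str = ":memory:"):
        self.connection = sqlite3.connect(path, isolation_level=None)
        self.schemas = tuple(schemas)
        for schema in self.schemas:
            # a file DSN gets one sidecar file per schema so state
            # persists across invocations; in-memory stays in-memory
            store = ":memory:" if path == ":memory:" else f"{path}.{schema}"
            self.connection.execute(f"ATTACH '{store}' AS {schema}")

    def execute(self, sql: str) -> int:
        """Run one statement; returns the affected-row count (-1 for DDL)."""
        cursor = self.connection.execute(sql)
        return cursor.rowcount

    def insert_rows(self, schema: str, table: str, columns: Sequence[str], rows) -> None:
        placeholders = ", ".join("?" for _ in columns)
        self.connection.executemany(
            f"INSERT INTO {schema}.{table} ({', '.join(columns)}) "
            f"VALUES ({placeholders})",
            rows,
        )

    def query(self, sql: str) -> list[tuple]:
        return list(self.connection.execute(sql).fetchall())

    def fetch_relation(self, schema: str, table: str, columns: Sequence[str]) -> Relation:
        rows = self.query(f"SELECT {', '.join(columns)} FROM {schema}.{table}")
        return Relation(table, tuple(columns), tuple(tuple(r) for r in rows))

    def create_target_tables(
        self, cat: Catalogue, tables: Sequence[str], schema: str = "omop"
    ) -> None:
        """Create catalogue tables without constraints: the skeleton
        insert fills only the primary key, so NOT NULL must not be
        enforced mid-load."""
        for table in tables:
            cols = ", ".join(
                f"{c.name} {_sqlite_type(c.sql_type)}" for c in cat.tables[table]
            )
            self.execute(f"CREATE TABLE {schema}.{table} ({cols})")

    def close(self) -> None:
        self.connection.close()


@dataclass(frozen=True)
class StatementResult:
    index: int
    label: str
    rowcount: int
    ok: bool
    error: Optional[str] = None


@dataclass(frozen=True)
class ExecutionReport:
    results: tuple[StatementResult, ...]
    success: bool

    @property
    def failure(self) -> Optional[StatementResult]:
        return next((r for r in self.results if not r.ok), None)


def execute_script(script: CompiledScript, backend: SqliteBackend) -> ExecutionReport:
    """Execute a compiled script statement by statement.

    On a backend error the report pinpoints the statement index, its
    YAML provenance label and the engine message; nothing after the
    failing statement is executed.
    """
    results: list[StatementResult] = []
    for i, stmt in enumerate(script.statements):
        try:
            rowcount = backend.execute(stmt.sql)
        except sqlite3.Error as exc:
            results.append(StatementResult(i, stmt.label, -1, False, str(exc)))
            return ExecutionReport(tuple(results), False)
        results.append(StatementResult(i, stmt.label, rowcount, True))
    return ExecutionReport(tuple(results), True)


# --- fixtures --------------------------------------------------------------


@dataclass(frozen=True)
class SourceFixture:
    """Everything one feature case needs: source DDL + rows, the mapping
    YAML, the expected OMOP relations (computed independently while
    generating the rows), a hand-written monolithic INSERT…SELECT oracle,
    and — for diagnostic cases — the codes the validator must emit."""

    case_id: str
    seed: int
    source_ddl: tuple[str, ...]
    source_rows: dict[str, tuple[Sequence[str], tuple[tuple, ...]]]  # table -> (columns, rows)
    mapping_yaml: tuple[tuple[str, str], ...]  # (filename, text)
    expected: dict[str, Relation]
    oracle_sql: tuple[str, ...] = ()
    expected_codes: tuple[str, ...] = ()
    config: CompilerConfig = CompilerConfig()

    @property
    def is_error_case(self) -> bool:
        return bool(self.expected_codes) and not self.expected


_SEX_CODES = ("M", "F", "U")
_ICD_CODES = ("I10", "E11.9", "J45", "K21.0", "M54.5")


def _rng(case_id: str, seed: int) -> Random:
    return Random((zlib.crc32(case_id.encode()) ^ seed) & 0x7FFFFFFF)


def _date(rng: Random, lo: int = 1940, hi: int = 2005) -> str:
    return (
        f"{rng.randint(lo, hi):04d}-{rng.randint(1, 12):02d}-"
        f"{rng.randint(1, 28):02d} 00:00:00"
    )


def _person_rows(rng: Random, n: int) -> tuple[tuple, ...]:
    ids = sorted(rng.sample(range(1, 400), n))
    rows = []
    for pid in ids:
        birth = _date(rng)
        deceased = _date(rng, 2006, 2020) if rng.random() < 0.3 else None
        rows.append((pid, birth, deceased, rng.choice(_SEX_CODES)))
    return tuple(rows)


_PERSON_DDL = (
    "CREATE TABLE source.person (person_id integer, birth_dt_tm text, "
    "deceased_dt_tm text, sex_cd text);"
)
_DIAGNOSIS_DDL = (
    "CREATE TABLE source.diagnosis (diagnosis_id integer, person_id integer, "
    "diag_dt_tm text, diag_cd text);"
)
_PROBLEM_DDL = (
    "CREATE TABLE source.problem (problem_id integer, person_id integer, "
    "onset_dt_tm text, problem_cd text);"
)

_PERSON_COLS = ("person_id", "birth_dt_tm", "deceased_dt_tm", "sex_cd")
_DIAGNOSIS_COLS = ("diagnosis_id", "person_id", "diag_dt_tm", "diag_cd")
_PROBLEM_COLS = ("problem_id", "person_id", "onset_dt_tm", "problem_cd")

_YOB_EXPR = "CAST(substr(person.birth_dt_tm, 1, 4) AS integer)"

_PERSON_YAML = f"""name: person
primary_key:
  table: person
  columns: [person_id]
columns:
  - name: year_of_birth
    tables: [person]
    expression: "{_YOB_EXPR}"
  - name: death_datetime
    tables: [person]
    expression: "person.deceased_dt_tm"
"""

_CONDITION_UNION_YAML = """name: condition_occurrence
primary_key:
  sources:
    - alias: DIAGNOSIS_PK
      table: diagnosis
      columns: [diagnosis_id]
    - alias: PROBLEM_PK
      table: problem
      columns: [problem_id]
columns:
  - name: condition_start_datetime
    rules:
      - tables: [diagnosis]
        expression: "diagnosis.diag_dt_tm"
        primary_key: DIAGNOSIS_PK
      - tables: [problem]
        expression: "problem.onset_dt_tm"
        primary_key: PROBLEM_PK
"""


def _diag_problem_rows(rng: Random, n_diag: int, n_prob: int, with_nulls: bool = False):
    person_ids = sorted(rng.sample(range(1, 200), max(4, min(8, n_diag + n_prob))))
    diag_ids = sorted(rng.sample(range(1, 500), n_diag))
    prob_ids = sorted(rng.sample(range(1, 500), n_prob))
    diag_rows = [
        (did, rng.choice(person_ids), _date(rng, 2010, 2019), rng.choice(_ICD_CODES))
        for did in diag_ids
    ]
    prob_rows = [
        (pid, rng.choice(person_ids), _date(rng, 2010, 2019), rng.choice(_ICD_CODES))
        for pid in prob_ids
    ]
    if with_nulls:
        diag_rows.append((None, rng.choice(person_ids), _date(rng, 2010, 2019), "I10"))
        prob_rows.append((None, rng.choice(person_ids), _date(rng, 2010, 2019), "J45"))
    return tuple(diag_rows), tuple(prob_rows)


def _union_expected(diag_rows, prob_rows, start: int = 1) -> Relation:
    """Mirror of the staged-key semantics, computed independently:
    sources in declared order, distinct non-NULL keys ascending."""
    rows = []
    next_id = start
    for key_col, date_col, source_rows in (
        (0, 2, diag_rows),
        (0, 2, prob_rows),
    ):
        keyed = sorted(
            {r[key_col]: r for r in source_rows if r[key_col] is not None}.items()
        )
        for _, row in keyed:
            rows.append((next_id, row[date_col]))
            next_id += 1
    return Relation(
        "condition_occurrence",
        ("condition_occurrence_id", "condition_start_datetime"),
        tuple(rows),
    )


_UNION_ORACLE = (
    "INSERT INTO oracle.condition_occurrence "
    "(condition_occurrence_id, condition_start_datetime)\n"
    "SELECT ROW_NUMBER() OVER (ORDER BY u.ord, u.k), u.dt FROM (\n"
    "SELECT 1 AS ord, diagnosis_id AS k, diag_dt_tm AS dt FROM source.diagnosis "
    "WHERE diagnosis_id IS NOT NULL\n"
    "UNION ALL\n"
    "SELECT 2, problem_id, onset_dt_tm FROM source.problem "
    "WHERE problem_id IS NOT NULL) AS u;"
)


def _person_expected(rows, columns, value_of) -> Relation:
    out = tuple(
        (r[0],) + tuple(value_of(r)) for r in rows if r[0] is not None
    )
    return Relation("person", ("person_id",) + tuple(columns), out)


# --- the 16-case registry --------------------------------------------------


def _case_single_source_direct_pk(seed: int) -> SourceFixture:
    rng = _rng("single_source_direct_pk", seed)
    rows = _person_rows(rng, 6)
    expected = _person_expected(
        rows, ("year_of_birth", "death_datetime"), lambda r: (int(r[1][:4]), r[2])
    )
    oracle = (
        "INSERT INTO oracle.person (person_id, year_of_birth, death_datetime)\n"
        "SELECT person_id, CAST(substr(birth_dt_tm, 1, 4) AS integer), deceased_dt_tm\n"
        "FROM source.person WHERE person_id IS NOT NULL;"
    )
    return SourceFixture(
        "single_source_direct_pk",
        seed,
        (_PERSON_DDL,),
        {"person": (_PERSON_COLS, rows)},
        (("person.yaml", _PERSON_YAML),),
        {"person": expected},
        (oracle,),
    )


def _case_composite_source_pk(seed: int) -> SourceFixture:
    rng = _rng("composite_source_pk", seed)
    pairs = sorted(
        rng.sample([(e, p) for e in range(1, 40) for p in range(1, 20)], 7)
    )
    rows = tuple((e, p, _date(rng, 2012, 2019)) for e, p in pairs)
    expected = Relation(
        "visit_occurrence",
        ("visit_occurrence_id", "visit_start_datetime"),
        tuple((i + 1, row[2]) for i, row in enumerate(rows)),
    )
    yaml_text = """name: visit_occurrence
primary_key:
  table: encounter
  columns: [encntr_id, person_id]
columns:
  - name: visit_start_datetime
    tables: [encounter]
    expression: "encounter.arrive_dt_tm"
"""
    oracle = (
        "INSERT INTO oracle.visit_occurrence (visit_occurrence_id, visit_start_datetime)\n"
        "SELECT ROW_NUMBER() OVER (ORDER BY encntr_id, person_id), arrive_dt_tm\n"
        "FROM source.encounter WHERE encntr_id IS NOT NULL AND person_id IS NOT NULL;"
    )
    return SourceFixture(
        "composite_source_pk",
        seed,
        (
            "CREATE TABLE source.encounter (encntr_id integer, person_id integer, "
            "arrive_dt_tm text);",
        ),
        {"encounter": (("encntr_id", "person_id", "arrive_dt_tm"), rows)},
        (("visit_occurrence.yaml", yaml_text),),
        {"visit_occurrence": expected},
        (oracle,),
    )


def _case_multi_source_union(seed: int) -> SourceFixture:
    rng = _rng("multi_source_union", seed)
    diag_rows, prob_rows = _diag_problem_rows(rng, 5, 4)
    return SourceFixture(
        "multi_source_union",
        seed,
        (_DIAGNOSIS_DDL, _PROBLEM_DDL),
        {
            "diagnosis": (_DIAGNOSIS_COLS, diag_rows),
            "problem": (_PROBLEM_COLS, prob_rows),
        },
        (("condition_occurrence.yaml", _CONDITION_UNION_YAML),),
        {"condition_occurrence": _union_expected(diag_rows, prob_rows)},
        (_UNION_ORACLE,),
    )


def _case_foreign_key_column(seed: int) -> SourceFixture:
    rng = _rng("foreign_key_column", seed)
    mrns = sorted({f"MRN{rng.randint(100, 999)}" for _ in range(8)})[:6]
    client_rows = tuple((m, _date(rng)) for m in mrns)
    person_ids = {m: i + 1 for i, m in enumerate(mrns)}  # ORDER BY mrn, seq from 1
    diag_ids = sorted(rng.sample(range(1, 300), 7))
    diag_rows = tuple(
        (d, rng.choice(mrns), _date(rng, 2012, 2019)) for d in diag_ids
    )
    person_yaml = """name: person
primary_key:
  table: client
  columns: [mrn]
  key_type: text
columns:
  - name: year_of_birth
    tables: [client]
    expression: "CAST(substr(client.birth_dt_tm, 1, 4) AS integer)"
"""
    condition_yaml = """name: condition_occurrence
primary_key:
  table: diagnosis
  columns: [diagnosis_id]
columns:
  - name: person_id
    tables: [diagnosis, etl_staging.person_pk_map]
    expression: "person_pk_map.target_id"
    constraints: "person_pk_map.mrn = diagnosis.mrn AND person_pk_map.source_alias = 'CLIENT_PK'"
  - name: condition_start_datetime
    tables: [diagnosis]
    expression: "diagnosis.diag_dt_tm"
"""
    expected_person = Relation(
        "person",
        ("person_id", "year_of_birth"),
        tuple(
            (person_ids[m], int(birth[:4])) for m, birth in client_rows
        ),
    )
    expected_condition = Relation(
        "condition_occurrence",
        ("condition_occurrence_id", "person_id", "condition_start_datetime"),
        tuple((d, person_ids[m], dt) for d, m, dt in diag_rows),
    )
    oracle = (
        "INSERT INTO oracle.person (person_id, year_of_birth)\n"
        "SELECT ROW_NUMBER() OVER (ORDER BY mrn), CAST(substr(birth_dt_tm, 1, 4) AS integer)\n"
        "FROM source.client WHERE mrn IS NOT NULL;",
        "INSERT INTO oracle.condition_occurrence "
        "(condition_occurrence_id, person_id, condition_start_datetime)\n"
        "SELECT d.diagnosis_id, p.pid, d.diag_dt_tm\n"
        "FROM source.diagnosis AS d\n"
        "JOIN (SELECT mrn, ROW_NUMBER() OVER (ORDER BY mrn) AS pid FROM source.client "
        "WHERE mrn IS NOT NULL) AS p ON p.mrn = d.mrn\n"
        "WHERE d.diagnosis_id IS NOT NULL;",
    )
    return SourceFixture(
        "foreign_key_column",
        seed,
        (
            "CREATE TABLE source.client (mrn text, birth_dt_tm text);",
            "CREATE TABLE source.diagnosis (diagnosis_id integer, mrn text, "
            "diag_dt_tm text);",
        ),
        {
            "client": (("mrn", "birth_dt_tm"), client_rows),
            "diagnosis": (("diagnosis_id", "mrn", "diag_dt_tm"), diag_rows),
        },
        (("person.yaml", person_yaml), ("condition_occurrence.yaml", condition_yaml)),
        {"person": expected_person, "condition_occurrence": expected_condition},
        oracle,
    )


def _case_multiple_rules_per_column(seed: int) -> SourceFixture:
    rng = _rng("multiple_rules_per_column", seed)
    rows = _person_rows(rng, 8)
    gender = {"M": 8507, "F": 8532, "U": None}
    expected = _person_expected(rows, ("gender_concept_id",), lambda r: (gender[r[3]],))
    yaml_text = """name: person
primary_key:
  table: person
  columns: [person_id]
columns:
  - name: gender_concept_id
    rules:
      - tables: [person]
        expression: "8507"
        constraints: "person.sex_cd = 'M'"
      - tables: [person]
        expression: "8532"
        constraints: "person.sex_cd = 'F'"
"""
    oracle = (
        "INSERT INTO oracle.person (person_id, gender_concept_id)\n"
        "SELECT person_id, CASE WHEN sex_cd = 'M' THEN 8507 "
        "WHEN sex_cd = 'F' THEN 8532 ELSE NULL END\n"
        "FROM source.person WHERE person_id IS NOT NULL;"
    )
    return SourceFixture(
        "multiple_rules_per_column",
        seed,
        (_PERSON_DDL,),
        {"person": (_PERSON_COLS, rows)},
        (("person.yaml", yaml_text),),
        {"person": expected},
        (oracle,),
    )


def _case_two_table_join_constraints(seed: int) -> SourceFixture:
    rng = _rng("two_table_join_constraints", seed)
    rows = _person_rows(rng, 6)
    names = ("SMITH, JAN", "LEE, ALEX", "CHEN, SAM", "JONES, PAT", "KAUR, RAJ", "REED, KIM")
    name_rows = tuple((r[0], names[i % len(names)]) for i, r in enumerate(rows))
    full_name = dict(name_rows)
    expected = _person_expected(
        rows, ("person_source_value",), lambda r: (full_name[r[0]],)
    )
    yaml_text = """name: person
primary_key:
  table: person
  columns: [person_id]
columns:
  - name: person_source_value
    tables: [person, person_name]
    expression: "person_name.full_name"
    constraints: "person_name.person_id = person.person_id"
"""
    oracle = (
        "INSERT INTO oracle.person (person_id, person_source_value)\n"
        "SELECT p.person_id, n.full_name FROM source.person AS p\n"
        "LEFT JOIN source.person_name AS n ON n.person_id = p.person_id\n"
        "WHERE p.person_id IS NOT NULL;"
    )
    return SourceFixture(
        "two_table_join_constraints",
        seed,
        (
            _PERSON_DDL,
            "CREATE TABLE source.person_name (person_id integer, full_name text);",
        ),
        {
            "person": (_PERSON_COLS, rows),
            "person_name": (("person_id", "full_name"), name_rows),
        },
        (("person.yaml", yaml_text),),
        {"person": expected},
        (oracle,),
    )


def _case_inline_select_source(seed: int) -> SourceFixture:
    rng = _rng("inline_select_source", seed)
    rows = _person_rows(rng, 6)
    expected = _person_expected(rows, ("year_of_birth",), lambda r: (int(r[1][:4]),))
    yaml_text = """name: person
primary_key:
  table: person
  columns: [person_id]
columns:
  - name: year_of_birth
    tables:
      - alias: first_birth
        query: "SELECT person_id, MIN(birth_dt_tm) AS dt FROM source.person GROUP BY person_id"
    expression: "CAST(substr(first_birth.dt, 1, 4) AS integer)"
    constraints: "first_birth.person_id = person.person_id"
"""
    oracle = (
        "INSERT INTO oracle.person (person_id, year_of_birth)\n"
        "SELECT p.person_id, CAST(substr(q.dt, 1, 4) AS integer)\n"
        "FROM source.person AS p\n"
        "LEFT JOIN (SELECT person_id, MIN(birth_dt_tm) AS dt FROM source.person "
        "GROUP BY person_id) AS q ON q.person_id = p.person_id\n"
        "WHERE p.person_id IS NOT NULL;"
    )
    return SourceFixture(
        "inline_select_source",
        seed,
        (_PERSON_DDL,),
        {"person": (_PERSON_COLS, rows)},
        (("person.yaml", yaml_text),),
        {"person": expected},
        (oracle,),
    )


def _case_case_expression(seed: int) -> SourceFixture:
    rng = _rng("case_expression", seed)
    rows = _person_rows(rng, 8)
    gender = {"M": 8507, "F": 8532, "U": 0}
    expected = _person_expected(rows, ("gender_concept_id",), lambda r: (gender[r[3]],))
    yaml_text = """name: person
primary_key:
  table: person
  columns: [person_id]
columns:
  - name: gender_concept_id
    tables: [person]
    expression: "CASE WHEN person.sex_cd = 'M' THEN 8507 WHEN person.sex_cd = 'F' THEN 8532 ELSE 0 END"
"""
    oracle = (
        "INSERT INTO oracle.person (person_id, gender_concept_id)\n"
        "SELECT person_id, CASE WHEN sex_cd = 'M' THEN 8507 "
        "WHEN sex_cd = 'F' THEN 8532 ELSE 0 END\n"
        "FROM source.person WHERE person_id IS NOT NULL;"
    )
    return SourceFixture(
        "case_expression",
        seed,
        (_PERSON_DDL,),
        {"person": (_PERSON_COLS, rows)},
        (("person.yaml", yaml_text),),
        {"person": expected},
        (oracle,),
    )


#: Anchored and hand-expanded twins, formatted so every YAML node sits on
#: the same line in both files; they must load to equal trees and compile
#: byte-identically.
ANCHORED_PERSON_YAML = f"""name: person
definitions:
  defaults: &defaults
    tables: [person]
primary_key:
  table: person
  columns: [person_id]
columns:
  - name: year_of_birth
    <<: *defaults
    expression: "{_YOB_EXPR}"
  - name: death_datetime
    <<: *defaults
    expression: "person.deceased_dt_tm"
"""

EXPANDED_PERSON_YAML = f"""name: person
definitions:
  defaults:
    tables: [person]
primary_key:
  table: person
  columns: [person_id]
columns:
  - name: year_of_birth
    tables: [person]
    expression: "{_YOB_EXPR}"
  - name: death_datetime
    tables: [person]
    expression: "person.deceased_dt_tm"
"""


def _case_anchors_defaults(seed: int) -> SourceFixture:
    rng = _rng("anchors_defaults", seed)
    rows = _person_rows(rng, 6)
    expected = _person_expected(
        rows, ("year_of_birth", "death_datetime"), lambda r: (int(r[1][:4]), r[2])
    )
    oracle = (
        "INSERT INTO oracle.person (person_id, year_of_birth, death_datetime)\n"
        "SELECT person_id, CAST(substr(birth_dt_tm, 1, 4) AS integer), deceased_dt_tm\n"
        "FROM source.person WHERE person_id IS NOT NULL;"
    )
    return SourceFixture(
        "anchors_defaults",
        seed,
        (_PERSON_DDL,),
        {"person": (_PERSON_COLS, rows)},
        (("person.yaml", ANCHORED_PERSON_YAML),),
        {"person": expected},
        (oracle,),
    )


def _case_constant_expression(seed: int) -> SourceFixture:
    rng = _rng("constant_expression", seed)
    rows = _person_rows(rng, 5)
    expected = _person_expected(rows, ("race_concept_id",), lambda r: (8527,))
    yaml_text = """name: person
primary_key:
  table: person
  columns: [person_id]
columns:
  - name: race_concept_id
    tables: [person]
    expression: "8527"
"""
    oracle = (
        "INSERT INTO oracle.person (person_id, race_concept_id)\n"
        "SELECT person_id, 8527 FROM source.person WHERE person_id IS NOT NULL;"
    )
    return SourceFixture(
        "constant_expression",
        seed,
        (_PERSON_DDL,),
        {"person": (_PERSON_COLS, rows)},
        (("person.yaml", yaml_text),),
        {"person": expected},
        (oracle,),
    )


def _case_null_key_rows(seed: int) -> SourceFixture:
    rng = _rng("null_key_rows", seed)
    diag_rows, prob_rows = _diag_problem_rows(rng, 4, 3, with_nulls=True)
    return SourceFixture(
        "null_key_rows",
        seed,
        (_DIAGNOSIS_DDL, _PROBLEM_DDL),
        {
            "diagnosis": (_DIAGNOSIS_COLS, diag_rows),
            "problem": (_PROBLEM_COLS, prob_rows),
        },
        (("condition_occurrence.yaml", _CONDITION_UNION_YAML),),
        {"condition_occurrence": _union_expected(diag_rows, prob_rows)},
        (_UNION_ORACLE,),
    )


def _case_empty_source(seed: int) -> SourceFixture:
    expected = Relation(
        "person", ("person_id", "year_of_birth", "death_datetime"), ()
    )
    oracle = (
        "INSERT INTO oracle.person (person_id, year_of_birth, death_datetime)\n"
        "SELECT person_id, CAST(substr(birth_dt_tm, 1, 4) AS integer), deceased_dt_tm\n"
        "FROM source.person WHERE person_id IS NOT NULL;"
    )
    return SourceFixture(
        "empty_source",
        seed,
        (_PERSON_DDL,),
        {"person": (_PERSON_COLS, ())},
        (("person.yaml", _PERSON_YAML),),
        {"person": expected},
        (oracle,),
    )


def _case_not_null_unmapped_warning(seed: int) -> SourceFixture:
    rng = _rng("not_null_unmapped_warning", seed)
    rows = _person_rows(rng, 5)
    expected = _person_expected(rows, ("year_of_birth",), lambda r: (int(r[1][:4]),))
    yaml_text = """name: person
primary_key:
  table: person
  columns: [person_id]
columns:
  - name: year_of_birth
    tables: [person]
    expression: "CAST(substr(person.birth_dt_tm, 1, 4) AS integer)"
"""
    oracle = (
        "INSERT INTO oracle.person (person_id, year_of_birth)\n"
        "SELECT person_id, CAST(substr(birth_dt_tm, 1, 4) AS integer)\n"
        "FROM source.person WHERE person_id IS NOT NULL;"
    )
    return SourceFixture(
        "not_null_unmapped_warning",
        seed,
        (_PERSON_DDL,),
        {"person": (_PERSON_COLS, rows)},
        (("person.yaml", yaml_text),),
        {"person": expected},
        (oracle,),
        expected_codes=("NOT_NULL_UNMAPPED",),
    )


def _case_duplicate_alias_error(seed: int) -> SourceFixture:
    yaml_text = """name: condition_occurrence
primary_key:
  sources:
    - alias: DIAGNOSIS_PK
      table: diagnosis
      columns: [diagnosis_id]
    - alias: DIAGNOSIS_PK
      table: problem
      columns: [problem_id]
columns: []
"""
    return SourceFixture(
        "duplicate_alias_error",
        seed,
        (_DIAGNOSIS_DDL, _PROBLEM_DDL),
        {},
        (("condition_occurrence.yaml", yaml_text),),
        {},
        expected_codes=("DUPLICATE_ALIAS",),
    )


def _case_unknown_column_error(seed: int) -> SourceFixture:
    yaml_text = """name: person
primary_key:
  table: person
  columns: [person_id]
columns:
  - name: yearr_of_birth
    tables: [person]
    expression: "CAST(substr(person.birth_dt_tm, 1, 4) AS integer)"
"""
    return SourceFixture(
        "unknown_column_error",
        seed,
        (_PERSON_DDL,),
        {},
        (("person.yaml", yaml_text),),
        {},
        expected_codes=("UNKNOWN_COLUMN",),
    )


def _case_missing_pk_alias_error(seed: int) -> SourceFixture:
    yaml_text = """name: condition_occurrence
primary_key:
  sources:
    - alias: DIAGNOSIS_PK
      table: diagnosis
      columns: [diagnosis_id]
    - alias: PROBLEM_PK
      table: problem
      columns: [problem_id]
columns:
  - name: condition_start_datetime
    tables: [diagnosis]
    expression: "diagnosis.diag_dt_tm"
"""
    return SourceFixture(
        "missing_pk_alias_error",
        seed,
        (_DIAGNOSIS_DDL, _PROBLEM_DDL),
        {},
        (("condition_occurrence.yaml", yaml_text),),
        {},
        expected_codes=("MISSING_PK_ALIAS",),
    )


_REGISTRY = {
    f.__name__.removeprefix("_case_"): f
    for f in (
        _case_single_source_direct_pk,
        _case_composite_source_pk,
        _case_multi_source_union,
        _case_foreign_key_column,
        _case_multiple_rules_per_column,
        _case_two_table_join_constraints,
        _case_inline_select_source,
        _case_case_expression,
        _case_anchors_defaults,
        _case_constant_expression,
        _case_null_key_rows,
        _case_empty_source,
        _case_not_null_unmapped_warning,
        _case_duplicate_alias_error,
        _case_unknown_column_error,
        _case_missing_pk_alias_error,
    )
}

CASE_IDS: tuple[str, ...] = tuple(_REGISTRY)
ERROR_CASE_IDS: tuple[str, ...] = (
    "duplicate_alias_error",
    "unknown_column_error",
    "missing_pk_alias_error",
)


def generate_fixture(case_id: str, seed: int = 0) -> SourceFixture:
    """Deterministic fixture for one registry case: same (case_id, seed)
    always yields an identical fixture."""
    if case_id not in _REGISTRY:
        raise KeyError(
            f"unknown case {case_id!r}; registry: {', '.join(CASE_IDS)}"
        )
    return _REGISTRY[case_id](seed)


# --- running a case end to end ---------------------------------------------


@dataclass
class CaseResult:
    case_id: str
    seed: int
    diagnostics: list[Diagnostic]
    report: Optional[ExecutionReport]
    diffs: dict[str, DiffReport]
    oracle_diffs: dict[str, DiffReport]
    passed: bool


def load_fixture(fixture: SourceFixture, backend: SqliteBackend, cat: Catalogue) -> None:
    """Create source DDL + rows and empty (constraint-free) target and
    oracle tables for every table the fixture expects."""
    for ddl in fixture.source_ddl:
        backend.execute(ddl)
    for table, (columns, rows) in fixture.source_rows.items():
        if rows:
            backend.insert_rows("source", table, columns, rows)
    targets = sorted(fixture.expected)
    backend.create_target_tables(cat, targets, "omop")
    for table in targets:
        cols = ", ".join(fixture.expected[table].columns)
        backend.execute(f"CREATE TABLE oracle.{table} ({cols})")


def run_case(
    case_id: str,
    seed: int = 0,
    run_oracle: bool = True,
    cfg: Optional[CompilerConfig] = None,
) -> CaseResult:
    """Generate, validate, compile, execute and diff one registry case.

    For diagnostic cases, passing means every expected code was emitted
    (and, if the case still executes, that its relations also match).
    """
    fixture = generate_fixture(case_id, seed)
    cat = load_catalogue("v6")
    cfg = cfg or fixture.config

    docs: list[MappingDocument] = []
    diagnostics: list[Diagnostic] = []
    for fname, text in fixture.mapping_yaml:
        doc, diags = load_document(text, fname, catalogue=cat)
        diagnostics.extend(diags)
        if doc is not None:
            docs.append(doc)

    observed_codes = {d.code for d in diagnostics}
    codes_ok = set(fixture.expected_codes) <= observed_codes

    if has_errors(diagnostics) or not docs:
        passed = bool(fixture.expected_codes) and codes_ok
        return CaseResult(case_id, seed, diagnostics, None, {}, {}, passed)

    backend = SqliteBackend()
    try:
        load_fixture(fixture, backend, cat)
        script = compile_project(docs, cat, cfg)
        report = execute_script(script, backend)
        diffs: dict[str, DiffReport] = {}
        oracle_diffs: dict[str, DiffReport] = {}
        if report.success:
            for table, expected in fixture.expected.items():
                actual = backend.fetch_relation("omop", table, expected.columns)
                diffs[table] = diff_relations(actual, expected)
            if run_oracle and fixture.oracle_sql:
                for sql in fixture.oracle_sql:
                    backend.execute(sql)
                for table, expected in fixture.expected.items():
                    actual = backend.fetch_relation("omop", table, expected.columns)
                    oracle = backend.fetch_relation("oracle", table, expected.columns)
                    oracle_diffs[table] = diff_relations(actual, oracle)
        passed = (
            report.success
            and all(d.empty for d in diffs.values())
            and all(d.empty for d in oracle_diffs.values())
            and codes_ok
        )
        return CaseResult(case_id, seed, diagnostics, report, diffs, oracle_diffs, passed)
    finally:
        backend.close()


# --- randomized structural fixtures for property checks --------------------


def random_structure_fixture(structure: str, seed: int) -> SourceFixture:
    """Random-size fixture (0–50 rows, NULL keys and duplicates included)
    for one key-strategy shape: direct, composite, or union.

    Expected relations carry only the primary-key column — these
    fixtures exist to check cardinality conservation and key bijection,
    not column values.
    """
    rng = Random(seed & 0x7FFFFFFF)
    if structure == "direct":
        n = rng.randint(0, 50)
        ids = [rng.choice([None, rng.randint(1, 40)]) for _ in range(n)]
        rows = tuple((pid, _date(rng), None, rng.choice(_SEX_CODES)) for pid in ids)
        keys = sorted({pid for pid in ids if pid is not None})
        expected = Relation("person", ("person_id",), tuple((k,) for k in keys))
        return SourceFixture(
            "random_direct",
            seed,
            (_PERSON_DDL,),
            {"person": (_PERSON_COLS, rows)},
            (("person.yaml", _PERSON_YAML),),
            {"person": expected},
        )
    if structure == "composite":
        n = rng.randint(0, 50)
        pairs = [
            (
                rng.choice([None, rng.randint(1, 15)]),
                rng.choice([None, rng.randint(1, 10)]),
            )
            for _ in range(n)
        ]
        rows = tuple((e, p, _date(rng, 2012, 2019)) for e, p in pairs)
        keys = sorted({(e, p) for e, p in pairs if e is not None and p is not None})
        expected = Relation(
            "visit_occurrence",
            ("visit_occurrence_id",),
            tuple((i + 1,) for i in range(len(keys))),
        )
        yaml_text = """name: visit_occurrence
primary_key:
  table: encounter
  columns: [encntr_id, person_id]
columns:
  - name: visit_start_datetime
    tables: [encounter]
    expression: "encounter.arrive_dt_tm"
"""
        return SourceFixture(
            "random_composite",
            seed,
            (
                "CREATE TABLE source.encounter (encntr_id integer, "
                "person_id integer, arrive_dt_tm text);",
            ),
            {"encounter": (("encntr_id", "person_id", "arrive_dt_tm"), rows)},
            (("visit_occurrence.yaml", yaml_text),),
            {"visit_occurrence": expected},
        )
    if structure == "union":
        n_d, n_p = rng.randint(0, 25), rng.randint(0, 25)
        diag = [
            (rng.choice([None, rng.randint(1, 30)]), rng.randint(1, 9),
             _date(rng, 2010, 2019), rng.choice(_ICD_CODES))
            for _ in range(n_d)
        ]
        prob = [
            (rng.choice([None, rng.randint(1, 30)]), rng.randint(1, 9),
             _date(rng, 2010, 2019), rng.choice(_ICD_CODES))
            for _ in range(n_p)
        ]
        n_keys = len({r[0] for r in diag if r[0] is not None}) + len(
            {r[0] for r in prob if r[0] is not None}
        )
        expected = Relation(
            "condition_occurrence",
            ("condition_occurrence_id",),
            tuple((i + 1,) for i in range(n_keys)),
        )
        return SourceFixture(
            "random_union",
            seed,
            (_DIAGNOSIS_DDL, _PROBLEM_DDL),
            {"diagnosis": (_DIAGNOSIS_COLS, tuple(diag)),
             "problem": (_PROBLEM_COLS, tuple(prob))},
            (("condition_occurrence.yaml", _CONDITION_UNION_YAML),),
            {"condition_occurrence": expected},
        )
    raise ValueError(f"unknown structure {structure!r}")


def check_structure_invariants(structure: str, seed: int) -> dict:
    """Execute a random fixture and verify cardinality conservation and
    (for staged plans) the key bijection on the mapping table.

    Returns a dict of booleans plus the sizes involved.
    """
    fixture = random_structure_fixture(structure, seed)
    cat = load_catalogue("v6")
    backend = SqliteBackend()
    try:
        docs = []
        for fname, text in fixture.mapping_yaml:
            doc, diags = load_document(text, fname, catalogue=cat)
            assert doc is not None, [d.render() for d in diags if d.severity == "error"]
            docs.append(doc)
        load_fixture(fixture, backend, cat)
        script = compile_project(docs, cat, fixture.config)
        report = execute_script(script, backend)
        target = next(iter(fixture.expected))
        expected_count = len(fixture.expected[target].rows)
        pk_col = cat.primary_key_of(target)
        (actual_count,) = backend.query(
            f"SELECT COUNT(*) FROM omop.{target}"
        )[0]
        (distinct_pks,) = backend.query(
            f"SELECT COUNT(DISTINCT {pk_col}) FROM omop.{target}"
        )[0]
        out = {
            "executed": report.success,
            "cardinality_ok": actual_count == expected_count,
            "pks_unique": actual_count == distinct_pks,
            "rows": actual_count,
        }
        if structure in ("composite", "union"):
            map_table = f"etl_staging.{target}_pk_map"
            (map_rows,) = backend.query(f"SELECT COUNT(*) FROM {map_table}")[0]
            (distinct_ids,) = backend.query(
                f"SELECT COUNT(DISTINCT target_id) FROM {map_table}"
            )[0]
            (distinct_keys,) = backend.query(
                f"SELECT COUNT(*) FROM (SELECT DISTINCT source_alias, "
                f"{'encntr_id, person_id' if structure == 'composite' else 'diagnosis_id, problem_id'} "
                f"FROM {map_table}) AS k"
            )[0]
            out["bijection_ok"] = map_rows == distinct_ids == distinct_keys
            out["cardinality_ok"] = out["cardinality_ok"] and actual_count == map_rows
        return out
    finally:
        backend.close()


def export_fixture(fixture: SourceFixture, directory) -> list[str]:
    """Write a fixture's DDL+rows (.sql) and YAML documents to a
    directory for manual inspection; returns written paths."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    sql_lines = list(fixture.source_ddl)
    for table, (columns, rows) in fixture.source_rows.items():
        for row in rows:
            values = ", ".join(
                "NULL" if v is None else (str(v) if isinstance(v, (int, float)) else "'" + str(v).replace("'", "''") + "'")
                for v in row
            )
            sql_lines.append(
                f"INSERT INTO source.{table} ({', '.join(columns)}) VALUES ({values});"
            )
    sql_path = directory / f"{fixture.case_id}.sql"
    sql_path.write_text("\n".join(sql_lines) + "\n", encoding="utf-8")
    written.append(str(sql_path))
    for fname, text in fixture.mapping_yaml:
        path = directory / fname
        path.write_text(text, encoding="utf-8")
        written.append(str(path))
    return written


__all__ = [
    "Relation",
    "DiffReport",
    "diff_relations",
    "SqliteBackend",
    "StatementResult",
    "ExecutionReport",
    "execute_script",
    "SourceFixture",
    "CASE_IDS",
    "ERROR_CASE_IDS",
    "generate_fixture",
    "load_fixture",
    "run_case",
    "CaseResult",
    "random_structure_fixture",
    "check_structure_invariants",
    "export_fixture",
    "ANCHORED_PERSON_YAML",
    "EXPANDED_PERSON_YAML",
]
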
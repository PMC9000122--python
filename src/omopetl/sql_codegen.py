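"""The compiler: mapping documents to a phase-ordered ETL SQL script.

The executable shape is *skeleton insert then one UPDATE per rule*:

1. (staged keys only) build a staging mapping table relating each
   source row's key tuple to a freshly minted target surrogate key;
2. insert the target table's primary-key column only (the "skeleton");
3. for every column rule, emit one UPDATE joining the rule's tables to
   the key linkage and setting the column from the rule's expression.

This preserves the language's column independence literally: the
statements generated for one column are a pure function of that
column's rules, so edits to one column never change the SQL of another.

Emitted SQL is a PostgreSQL subset also accepted by common embeddable
engines (no sequences — surrogate keys come from ``ROW_NUMBER()`` over
the ordered key tuples plus the current staging-table maximum; no
TRUNCATE — targets are cleared with DELETE).  Author-supplied snippets
pass through verbatim.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from . import __version__
from .dml_model import (
    ColumnDef,
    ColumnRule,
    DmlError,
    MappingDocument,
    PrimaryKeySource,
    TableRef,
    document_to_tree,
    resolve_rule_pk,
)
from .omop_catalogue import Catalogue, table_order

PHASES = ("setup", "mapping", "skeleton", "column", "teardown")
_PHASE_RANK = {p: i for i, p in enumerate(PHASES)}


@dataclass(frozen=True)
class CompilerConfig:
    """Code-generation options.

    Schemas must be pairwise distinct unless ``allow_shared_schemas`` is
    set — accidentally pointing source and target at the same schema is
    the most destructive misconfiguration an ETL run can have.
    """

    source_schema: str = "source"
    target_schema: str = "omop"
    staging_schema: str = "etl_staging"
    truncate_targets: bool = True
    sequence_start: int = 1
    wrap_transaction: bool = True
    strict_overlap: bool = False
    drop_staging: bool = False
    allow_shared_schemas: bool = False

    def __post_init__(self):
        if self.sequence_start < 1:
            raise ValueError("sequence_start must be >= 1")
        schemas = (self.source_schema, self.target_schema, self.staging_schema)
        if len(set(schemas)) != 3 and not self.allow_shared_schemas:
            raise ValueError(
                "source/target/staging schemas must be pairwise distinct "
                "(set allow_shared_schemas to override)"
            )


@dataclass(frozen=True)
class PrimaryKeyPlan:
    """How the target table's surrogate key is produced.

    ``direct``: the single source key column is copied verbatim.
    ``staged``: a mapping table ``<target>_pk_map`` in the staging
    schema assigns sequential ids to the distinct key tuples of every
    source, in declared source order.
    """

    strategy: str  # direct | staged
    target_table: str
    target_pk_column: str
    sources: tuple[PrimaryKeySource, ...]

    def __post_init__(self):
        assert self.strategy in ("direct", "staged")
        if self.strategy == "direct":
            assert len(self.sources) == 1 and self.sources[0].directly_reusable

    @property
    def mapping_table(self) -> str:
        return f"{self.target_table}_pk_map"

    @property
    def sequence_name(self) -> str:
        return f"{self.target_table}_id_seq"

    def source_for(self, alias: Optional[str]) -> PrimaryKeySource:
        if alias is None:
            return self.sources[0]
        for s in self.sources:
            if s.alias == alias:
                return s
        raise DmlError(f"no primary-key source with alias {alias!r}")


@dataclass(frozen=True)
class CompiledStatement:
    sql: str
    phase: str
    label: str

    def __post_init__(self):
        assert self.phase in PHASES
        assert self.sql.rstrip().endswith(";")
        assert self.label


@dataclass(frozen=True)
class CompiledScript:
    statements: tuple[CompiledStatement, ...]
    header: str = ""

    def render(self) -> str:
        """The .sql artifact: UTF-8, LF line endings, bit-exact across runs."""
        parts = []
        if self.header:
            parts.append(self.header.rstrip("\n"))
        for stmt in self.statements:
            parts.append(f"-- {stmt.label}")
            parts.append(stmt.sql)
        return "\n".join(parts) + "\n"


def _qualify(schema: str, name: str) -> str:
    return f"{schema}.{name}"


def _source_table_sql(ref: TableRef, cfg: CompilerConfig) -> str:
    schema = ref.schema or cfg.source_schema
    return _qualify(schema, ref.name)  # type: ignore[arg-type]


def plan_primary_key(
    doc: MappingDocument, cat: Optional[Catalogue] = None
) -> PrimaryKeyPlan:
    """Choose the key strategy for a document.

    The source key is reused directly only when there is exactly one
    source whose key is a single unconstrained integer column; any
    composite, non-integer, constrained, or multi-source key is staged
    through a mapping table.
    """
    if cat is not None and doc.target_table in cat.tables:
        pk_column = cat.primary_key_of(doc.target_table)
    else:
        pk_column = f"{doc.target_table}_id"
    sources = doc.primary_key.sources
    direct = len(sources) == 1 and sources[0].directly_reusable
    return PrimaryKeyPlan(
        "direct" if direct else "staged", doc.target_table, pk_column, sources
    )


def _key_tuple_subquery(src: PrimaryKeySource, cfg: CompilerConfig) -> str:
    """DISTINCT non-NULL key tuples of one source, ordered deterministically."""
    cols = ", ".join(src.key_columns)
    where = [f"{c} IS NOT NULL" for c in src.key_columns]
    if src.constraints is not None:
        where.append(f"({src.constraints.text})")
    return (
        f"SELECT DISTINCT {cols} FROM {_source_table_sql(src.table, cfg)}"
        f" WHERE {' AND '.join(where)}"
    )


def render_mapping_tables(
    plan: PrimaryKeyPlan, cfg: CompilerConfig, file: str = "<memory>"
) -> list[CompiledStatement]:
    """DDL + loads for the staging mapping table of a staged plan.

    The table is a bijection between (source_alias, key tuple) and
    target_id.  IDs are assigned deterministically: sources in declared
    order, and within a source the distinct key tuples in ascending key
    order; rows with any NULL key component cannot be identified and are
    excluded.
    """
    if plan.strategy == "direct":
        return []
    map_table = _qualify(cfg.staging_schema, plan.mapping_table)

    # union of key columns across sources, first-seen order; type from the
    # first source declaring the column (conflicts fall back to text)
    key_cols: list[str] = []
    col_types: dict[str, str] = {}
    for src in plan.sources:
        for col, typ in zip(src.key_columns, src.key_types):
            if col not in col_types:
                key_cols.append(col)
                col_types[col] = typ
            elif col_types[col] != typ:
                col_types[col] = "text"

    col_defs = ", ".join(
        ["target_id integer", "source_alias text"]
        + [f"{c} {col_types[c]}" for c in key_cols]
    )
    out = [
        CompiledStatement(
            f"DROP TABLE IF EXISTS {map_table};",
            "mapping",
            f"{file}:{plan.sources[0].line} {plan.target_table}.primary_key drop",
        ),
        CompiledStatement(
            f"CREATE TABLE {map_table} ({col_defs});",
            "mapping",
            f"{file}:{plan.sources[0].line} {plan.target_table}.primary_key create",
        ),
    ]
    for src in plan.sources:
        cols = ", ".join(src.key_columns)
        order_by = ", ".join(f"k.{c}" for c in src.key_columns)
        select_keys = ", ".join(f"k.{c}" for c in src.key_columns)
        sql = (
            f"INSERT INTO {map_table} (target_id, source_alias, {cols})\n"
            f"SELECT o.base + ROW_NUMBER() OVER (ORDER BY {order_by}),"
            f" '{src.alias}', {select_keys}\n"
            f"FROM ({_key_tuple_subquery(src, cfg)}) AS k\n"
            f"CROSS JOIN (SELECT COALESCE(MAX(target_id), {cfg.sequence_start - 1})"
            f" AS base FROM {map_table}) AS o;"
            # rows with NULL key components are excluded above: no surrogate
            # key can be minted for an unidentifiable row
        )
        out.append(
            CompiledStatement(
                sql,
                "mapping",
                f"{file}:{src.line} {plan.target_table}.primary_key {src.alias}",
            )
        )
    return out


def render_skeleton_insert(
    plan: PrimaryKeyPlan,
    doc: MappingDocument,
    cfg: CompilerConfig,
    file: str = "<memory>",
) -> list[CompiledStatement]:
    """Clear the target (optional) and insert its primary-key column only."""
    target = _qualify(cfg.target_schema, doc.target_table)
    out = []
    if cfg.truncate_targets:
        out.append(
            CompiledStatement(
                f"DELETE FROM {target};",
                "setup",
                f"{file}:{doc.line} {doc.target_table}.clear",
            )
        )
    if plan.strategy == "direct":
        src = plan.sources[0]
        key = src.key_columns[0]
        sql = (
            f"INSERT INTO {target} ({plan.target_pk_column})\n"
            f"SELECT DISTINCT {key} FROM {_source_table_sql(src.table, cfg)}"
            f" WHERE {key} IS NOT NULL;"
        )
    else:
        map_table = _qualify(cfg.staging_schema, plan.mapping_table)
        sql = (
            f"INSERT INTO {target} ({plan.target_pk_column})\n"
            f"SELECT target_id FROM {map_table};"
        )
    out.append(
        CompiledStatement(
            sql, "skeleton", f"{file}:{doc.line} {doc.target_table}.skeleton"
        )
    )
    return out


def _rule_from_and_where(
    rule: ColumnRule,
    src: PrimaryKeySource,
    plan: PrimaryKeyPlan,
    cfg: CompilerConfig,
) -> tuple[list[str], list[str]]:
    """FROM items and WHERE conjuncts linking the rule's tables to the
    target rows keyed by the rule's primary-key source."""
    from_items: list[str] = []
    names_in_from: set[str] = set()
    pk_table_listed = False
    for t in rule.tables:
        if t.variant == "inline":
            from_items.append(f"({t.query.text}) AS {t.alias}")
            names_in_from.add(t.alias)
        else:
            from_items.append(f"{_source_table_sql(t, cfg)} AS {t.name}")
            names_in_from.add(t.name)
            if t.name == src.table.name and (
                t.schema is None or t.schema == (src.table.schema or cfg.source_schema)
            ):
                pk_table_listed = True
    if not pk_table_listed:
        if src.table.name in names_in_from:
            raise DmlError(
                f"rule cannot be linked to its primary-key source "
                f"{src.alias}: the name {src.table.name!r} is already taken "
                "by another FROM entry",
                rule.line,
                "NO_LINKAGE",
            )
        from_items.append(f"{_source_table_sql(src.table, cfg)} AS {src.table.name}")

    where: list[str] = []
    if plan.strategy == "direct":
        where.append(
            f"t.{plan.target_pk_column} = {src.table.name}.{src.key_columns[0]}"
        )
    else:
        map_table = _qualify(cfg.staging_schema, plan.mapping_table)
        map_name = plan.mapping_table
        if map_name not in names_in_from:
            from_items.append(f"{map_table} AS {map_name}")
        where.append(f"t.{plan.target_pk_column} = {map_name}.target_id")
        where.append(f"{map_name}.source_alias = '{src.alias}'")
        for kc in src.key_columns:
            where.append(f"{map_name}.{kc} = {src.table.name}.{kc}")
    if rule.constraints is not None:
        where.append(f"({rule.constraints.text})")
    return from_items, where


def render_rule_update(
    rule: ColumnRule,
    col: ColumnDef,
    plan: PrimaryKeyPlan,
    cfg: CompilerConfig,
    file: str = "<memory>",
    rule_number: int = 1,
) -> CompiledStatement:
    """One UPDATE setting ``col`` from the rule's expression.

    The FROM list contains exactly the rule's tables, the rule's
    primary-key source table (added when not listed), and — for staged
    plans — the mapping table; nothing else.
    """
    src = plan.source_for(rule.pk_alias)
    from_items, where = _rule_from_and_where(rule, src, plan, cfg)
    target = _qualify(cfg.target_schema, plan.target_table)
    sql = (
        f"UPDATE {target} AS t\n"
        f"SET {col.name} = {rule.expression.text}\n"
        f"FROM {', '.join(from_items)}\n"
        f"WHERE {' AND '.join(where)};"
    )
    return CompiledStatement(
        sql, "column", f"{file}:{rule.line} {plan.target_table}.{col.name}#rule{rule_number}"
    )


def _overlap_guard(
    col: ColumnDef, plan: PrimaryKeyPlan, cfg: CompilerConfig, file: str
) -> list[CompiledStatement]:
    """Strict-mode check: fail when two rules update the same row.

    Each rule's matched target ids are inserted into a single-column
    PRIMARY KEY table; a doubly-updated row violates uniqueness, so the
    script aborts at exactly the offending column.
    """
    guard = _qualify(cfg.staging_schema, f"{plan.target_table}_overlap_{col.name}")
    label = f"{file}:{col.line} {plan.target_table}.{col.name}#overlap_guard"
    out = [
        CompiledStatement(f"DROP TABLE IF EXISTS {guard};", "column", label),
        CompiledStatement(
            f"CREATE TABLE {guard} (target_id integer PRIMARY KEY);", "column", label
        ),
    ]
    for rule in col.rules:
        src = plan.source_for(rule.pk_alias)
        from_items, where = _rule_from_and_where(rule, src, plan, cfg)
        target = _qualify(cfg.target_schema, plan.target_table)
        sql = (
            f"INSERT INTO {guard} (target_id)\n"
            f"SELECT DISTINCT t.{plan.target_pk_column}\n"
            f"FROM {target} AS t, {', '.join(from_items)}\n"
            f"WHERE {' AND '.join(where)};"
        )
        out.append(CompiledStatement(sql, "column", label))
    out.append(CompiledStatement(f"DROP TABLE {guard};", "column", label))
    return out


def document_digest(doc: MappingDocument) -> str:
    """Digest of the *normalized* document: stable under anchor/alias
    expansion and whitespace-only edits of the YAML source."""
    canonical = json.dumps(document_to_tree(doc), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


def _document_statements(
    doc: MappingDocument, cat: Optional[Catalogue], cfg: CompilerConfig
) -> list[CompiledStatement]:
    plan = plan_primary_key(doc, cat)
    file = doc.source_file
    statements: list[CompiledStatement] = []
    statements += render_mapping_tables(plan, cfg, file)
    statements += render_skeleton_insert(plan, doc, cfg, file)
    for col in doc.columns:
        for i, rule in enumerate(col.rules, 1):
            statements.append(render_rule_update(rule, col, plan, cfg, file, i))
        if cfg.strict_overlap and len(col.rules) > 1:
            statements += _overlap_guard(col, plan, cfg, file)
    statements.sort(key=lambda s: _PHASE_RANK[s.phase])  # stable: keeps doc order
    return statements


def compile_document(
    doc: MappingDocument, cat: Optional[Catalogue] = None, cfg: CompilerConfig = CompilerConfig()
) -> CompiledScript:
    """Compile one validated document; byte-deterministic given
    (document, config, tool version)."""
    header = (
        f"-- omopetl {__version__}\n"
        f"-- document {doc.target_table} {doc.source_file} "
        f"digest:{document_digest(doc)}"
    )
    return CompiledScript(tuple(_document_statements(doc, cat, cfg)), header)


def compile_project(
    docs: Sequence[MappingDocument],
    cat: Catalogue,
    cfg: CompilerConfig = CompilerConfig(),
    order_override: Optional[Sequence[str]] = None,
) -> CompiledScript:
    """Compile a set of documents into one script, ordered so that
    foreign-key-referenced tables load first."""
    ordered, order_diags = table_order(cat, docs, order_override)
    lines = [f"-- omopetl {__version__}"]
    for doc in ordered:
        lines.append(
            f"-- document {doc.target_table} {doc.source_file} "
            f"digest:{document_digest(doc)}"
        )
    for d in order_diags:
        lines.append(f"-- warning {d.code} {d.message}")
    statements: list[CompiledStatement] = []
    if cfg.wrap_transaction:
        statements.append(CompiledStatement("BEGIN;", "setup", "transaction begin"))
    for doc in ordered:
        statements += _document_statements(doc, cat, cfg)
    if cfg.drop_staging:
        for doc in ordered:
            plan = plan_primary_key(doc, cat)
            if plan.strategy == "staged":
                statements.append(
                    CompiledStatement(
                        f"DROP TABLE IF EXISTS "
                        f"{_qualify(cfg.staging_schema, plan.mapping_table)};",
                        "teardown",
                        f"{doc.source_file}:{doc.line} {doc.target_table}.teardown",
                    )
                )
    if cfg.wrap_transaction:
        statements.append(CompiledStatement("COMMIT;", "teardown", "transaction commit"))
    return CompiledScript(tuple(statements), "\n".join(lines))


__all__ = [
    "CompilerConfig",
    "PrimaryKeyPlan",
    "CompiledStatement",
    "CompiledScript",
    "plan_primary_key",
    "render_mapping_tables",
    "render_skeleton_insert",
    "render_rule_update",
    "compile_document",
    "compile_project",
    "document_digest",
    "PHASES",
]
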
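"""Object model of the YAML mapping language.

One YAML document maps one target OMOP table.  A document has three
sections: the target table ``name``, a ``primary_key`` section declaring
which source table(s) supply the rows of the target table, and a
``columns`` section holding one or more SQL mapping rules per target
column.  Every keyword of the language lives in exactly one type here;
parsing and validation live in :mod:`omopetl.yaml_frontend`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional

IDENTIFIER_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

#: Source-key SQL types that can be reused verbatim as an OMOP integer
#: surrogate key (anything else forces a staged mapping table).
INTEGER_KEY_TYPES = frozenset(
    {"integer", "int", "int4", "int8", "bigint", "smallint", "serial", "bigserial"}
)


class DmlError(ValueError):
    """A structural defect in a mapping document.

    Carries the 1-based source line so front ends can point at the
    offending YAML node.
    """

    def __init__(self, message: str, line: int = 1, code: str = "STRUCTURE"):
        super().__init__(message)
        self.message = message
        self.line = line
        self.code = code


def is_identifier(text: object) -> bool:
    return isinstance(text, str) and bool(IDENTIFIER_RE.match(text))


def fold_identifier(name: str, line: int = 1, what: str = "identifier") -> str:
    """Lowercase-fold an unquoted SQL identifier (PostgreSQL folding)."""
    if not is_identifier(name):
        raise DmlError(f"invalid {what}: {name!r}", line, "BAD_IDENTIFIER")
    return name.lower()


@dataclass(frozen=True)
class SqlSnippet:
    """A verbatim PostgreSQL fragment supplied by the mapping author.

    ``role`` records where the fragment may appear: a value
    ``expression``, a ``boolean_constraint`` joined into a WHERE clause,
    or a ``select_query`` used as an inline source table.  Snippets are
    never parsed or rewritten; they pass through to the emitted SQL
    byte-for-byte.
    """

    text: str
    role: str  # expression | boolean_constraint | select_query
    line: int = 1

    def __post_init__(self):
        if self.role not in ("expression", "boolean_constraint", "select_query"):
            raise DmlError(f"unknown snippet role {self.role!r}", self.line)
        if not isinstance(self.text, str) or not self.text.strip():
            raise DmlError(
                f"empty SQL snippet ({self.role})", self.line, "BAD_SNIPPET"
            )
        if self.role == "select_query":
            lead = self.text.strip().lstrip("(").strip()
            if not re.match(r"(?i)^(select|with)\b", lead):
                raise DmlError(
                    "inline source query must begin with SELECT or WITH",
                    self.line,
                    "BAD_SNIPPET",
                )


@dataclass(frozen=True)
class TableRef:
    """An entry of a rule's ``tables`` list.

    Either a named table (optionally schema-qualified, e.g.
    ``etl_staging.person_pk_map``) or an inline SELECT with an alias.
    """

    variant: str  # named | inline
    name: Optional[str] = None
    schema: Optional[str] = None
    alias: Optional[str] = None
    query: Optional[SqlSnippet] = None
    line: int = 1

    def __post_init__(self):
        if self.variant == "named":
            if self.name is None:
                raise DmlError("named table requires a name", self.line)
        elif self.variant == "inline":
            if self.alias is None or self.query is None:
                raise DmlError(
                    "inline source requires both alias and query",
                    self.line,
                    "BAD_SNIPPET",
                )
            if self.query.role != "select_query":
                raise DmlError("inline source query must be a select_query", self.line)
        else:
            raise DmlError(f"unknown table variant {self.variant!r}", self.line)

    @property
    def ref_name(self) -> str:
        """The name by which SQL snippets refer to this source."""
        return self.alias if self.variant == "inline" else self.name  # type: ignore[return-value]


@dataclass(frozen=True)
class PrimaryKeySource:
    """One source table contributing rows to the target table.

    ``alias`` (e.g. ``DIAGNOSIS_PK``) names the source so column rules
    can declare which source they apply to.  ``key_columns`` is the
    source table's (possibly composite) unique key; ``key_type`` is the
    declared SQL type of a single-column key and decides whether the
    key can be reused directly as the target primary key.
    """

    alias: str
    table: TableRef
    key_columns: tuple[str, ...]
    constraints: Optional[SqlSnippet] = None
    key_types: tuple[str, ...] = ()
    line: int = 1

    def __post_init__(self):
        if self.table.variant != "named":
            raise DmlError("primary-key source must be a named table", self.line)
        if not self.key_columns:
            raise DmlError(
                f"source {self.alias!r} declares no key columns", self.line
            )
        if len(set(self.key_columns)) != len(self.key_columns):
            raise DmlError(
                f"source {self.alias!r} repeats a key column", self.line
            )
        if not self.key_types:
            object.__setattr__(
                self, "key_types", ("integer",) * len(self.key_columns)
            )
        if len(self.key_types) != len(self.key_columns):
            raise DmlError(
                f"source {self.alias!r}: key_type list must match key columns",
                self.line,
            )

    @property
    def directly_reusable(self) -> bool:
        """True when the key can be copied verbatim into an OMOP integer
        surrogate key: a single integer-typed column, unconstrained."""
        return (
            len(self.key_columns) == 1
            and self.key_types[0] in INTEGER_KEY_TYPES
            and self.constraints is None
        )


@dataclass(frozen=True)
class PrimaryKeyDef:
    sources: tuple[PrimaryKeySource, ...]
    line: int = 1

    def __post_init__(self):
        if not self.sources:
            raise DmlError("primary_key requires at least one source", self.line)
        aliases = [s.alias for s in self.sources]
        if len(set(aliases)) != len(aliases):
            dupes = sorted({a for a in aliases if aliases.count(a) > 1})
            raise DmlError(
                f"duplicate primary-key alias(es): {', '.join(dupes)}",
                self.line,
                "DUPLICATE_ALIAS",
            )

    def by_alias(self, alias: str) -> Optional[PrimaryKeySource]:
        for s in self.sources:
            if s.alias == alias:
                return s
        return None


@dataclass(frozen=True)
class ColumnRule:
    """One mapping rule: which tables feed the column, the value
    expression, an optional join/filter constraint, and (when the
    document declares several primary-key sources) the alias of the
    source whose rows this rule updates."""

    tables: tuple[TableRef, ...]
    expression: SqlSnippet
    constraints: Optional[SqlSnippet] = None
    pk_alias: Optional[str] = None
    line: int = 1

    def __post_init__(self):
        if not self.tables:
            raise DmlError("rule requires at least one source table", self.line)


@dataclass(frozen=True)
class ColumnDef:
    name: str
    rules: tuple[ColumnRule, ...]
    line: int = 1

    def __post_init__(self):
        if not self.rules:
            raise DmlError(f"column {self.name!r} has no rules", self.line)


@dataclass(frozen=True)
class MappingDocument:
    """Parsed, normalized representation of one YAML mapping file."""

    target_table: str
    primary_key: PrimaryKeyDef
    columns: tuple[ColumnDef, ...]
    source_file: str = "<memory>"
    line: int = 1
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            lines = [c.line for c in self.columns if c.name in dupes]
            raise DmlError(
                f"duplicate column name(s): {', '.join(dupes)}"
                f" (lines {', '.join(str(l) for l in lines)})",
                lines[0] if lines else self.line,
                "DUPLICATE_COLUMN",
            )

    @property
    def line_index(self) -> dict[tuple, int]:
        """Map from model-node path to the 1-based YAML source line."""
        idx: dict[tuple, int] = {("document",): self.line}
        for s in self.primary_key.sources:
            idx[("source", s.alias)] = s.line
        for c in self.columns:
            idx[("column", c.name)] = c.line
            for i, r in enumerate(c.rules):
                idx[("rule", c.name, i)] = r.line
        return idx


def implicit_pk_alias(source_table: str) -> str:
    """Alias minted for the single-source shorthand: <TABLE>_PK."""
    return f"{source_table.upper()}_PK"


# --- normalization: parsed YAML tree -> MappingDocument ----------------

#: The closed keyword vocabulary, per nesting level.  `definitions` is a
#: reserved container for YAML anchors (shared default blocks); its
#: contents are ignored by normalization.
TOP_KEYS = ("name", "primary_key", "columns", "definitions")
SOURCE_KEYS = ("alias", "table", "columns", "constraints", "key_type")
PK_KEYS = ("sources",) + SOURCE_KEYS
RULE_KEYS = ("tables", "expression", "constraints", "primary_key")
COLUMN_KEYS = ("name", "rules") + RULE_KEYS
ALL_KEYS = tuple(sorted(set(TOP_KEYS + PK_KEYS + RULE_KEYS + COLUMN_KEYS)))


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance, used for did-you-mean suggestions."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def suggest_key(key: str, vocabulary=ALL_KEYS) -> Optional[str]:
    best = min(vocabulary, key=lambda k: (edit_distance(key, k), k))
    return best if edit_distance(key, best) <= max(2, len(key) // 3) else None


def _node_line(node, default: int = 1) -> int:
    return getattr(node, "line", default)


def _key_line(mapping, key: str, default: int = 1) -> int:
    return getattr(mapping, "key_lines", {}).get(key, _node_line(mapping, default))


def _item_line(seq, i: int, default: int = 1) -> int:
    lines = getattr(seq, "item_lines", None)
    if lines and i < len(lines):
        return lines[i]
    return _node_line(seq, default)


class _Sink:
    """Collects (severity, code, message, line) tuples, or raises when
    normalization is invoked in fail-fast mode."""

    def __init__(self, collect):
        self.items = collect
        self.failed = False

    def error(self, code: str, message: str, line: int):
        self.failed = True
        if self.items is None:
            raise DmlError(message, line, code)
        self.items.append(("error", code, message, line))

    def warning(self, code: str, message: str, line: int):
        if self.items is not None:
            self.items.append(("warning", code, message, line))


def _check_unknown_keys(mapping, known, context: str, sink: _Sink):
    for key in mapping:
        if key not in known:
            hint = suggest_key(str(key), known)
            msg = f"unknown key {key!r} in {context}"
            if hint:
                msg += f"; did you mean {hint!r}?"
            sink.error("UNKNOWN_KEY", msg, _key_line(mapping, key))


def _lint_snippet(text: str, role: str, line: int, sink: _Sink) -> None:
    if ";" in text:
        sink.error("BAD_SNIPPET", f"{role} must not contain ';'", line)
    if text.count("(") != text.count(")"):
        sink.error("BAD_SNIPPET", f"unbalanced parentheses in {role}", line)


def _snippet(value, role: str, line: int, sink: _Sink, lint: bool) -> Optional[SqlSnippet]:
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        value = str(value)  # bare numeric literal, e.g. a constant concept id
    if not isinstance(value, str) or not value.strip():
        sink.error("BAD_SNIPPET", f"{role} must be a non-empty SQL string", line)
        return None
    if lint:
        _lint_snippet(value, role, line, sink)
    try:
        return SqlSnippet(value, role, line)
    except DmlError as e:
        sink.error(e.code, e.message, line)
        return None


def _named_table(text: str, line: int, sink: _Sink) -> Optional[TableRef]:
    parts = text.split(".")
    try:
        if len(parts) == 1:
            return TableRef("named", name=fold_identifier(parts[0], line, "table"), line=line)
        if len(parts) == 2:
            return TableRef(
                "named",
                schema=fold_identifier(parts[0], line, "schema"),
                name=fold_identifier(parts[1], line, "table"),
                line=line,
            )
    except DmlError as e:
        sink.error(e.code, e.message, line)
        return None
    sink.error("BAD_IDENTIFIER", f"invalid table reference {text!r}", line)
    return None


def _table_ref(entry, line: int, sink: _Sink, lint: bool) -> Optional[TableRef]:
    if isinstance(entry, str):
        return _named_table(entry, line, sink)
    if isinstance(entry, dict):
        _check_unknown_keys(entry, ("alias", "query"), "inline source", sink)
        alias = entry.get("alias")
        if not is_identifier(alias):
            sink.error("BAD_IDENTIFIER", "inline source requires a valid alias", line)
            return None
        q = _snippet(entry.get("query"), "select_query", _key_line(entry, "query", line), sink, lint)
        if q is None:
            return None
        return TableRef("inline", alias=alias.lower(), query=q, line=line)
    sink.error("STRUCTURE", "tables entries must be names or {alias, query} mappings", line)
    return None


def _key_columns(value, line: int, sink: _Sink) -> tuple[str, ...]:
    if isinstance(value, str):
        value = [value]
    if not isinstance(value, list) or not value:
        sink.error("STRUCTURE", "source 'columns' must list one or more key columns", line)
        return ()
    out = []
    for i, col in enumerate(value):
        try:
            out.append(fold_identifier(col, _item_line(value, i, line), "key column"))
        except DmlError as e:
            sink.error(e.code, e.message, e.line)
    return tuple(out)


def _pk_source(node, line: int, sink: _Sink, lint: bool) -> Optional[PrimaryKeySource]:
    if not isinstance(node, dict):
        sink.error("STRUCTURE", "primary-key source must be a mapping", line)
        return None
    _check_unknown_keys(node, SOURCE_KEYS, "primary-key source", sink)
    table_text = node.get("table")
    if not isinstance(table_text, str):
        sink.error("MISSING_SECTION", "primary-key source requires 'table'", line)
        return None
    table = _named_table(table_text, _key_line(node, "table", line), sink)
    if table is None:
        return None
    keys = _key_columns(node.get("columns"), _key_line(node, "columns", line), sink)
    if not keys:
        return None
    alias = node.get("alias")
    if alias is None:
        alias = implicit_pk_alias(table.name)
    elif not is_identifier(alias):
        sink.error("BAD_IDENTIFIER", f"invalid source alias {alias!r}", line)
        return None
    constraints = None
    if "constraints" in node:
        constraints = _snippet(
            node["constraints"], "boolean_constraint",
            _key_line(node, "constraints", line), sink, lint,
        )
    raw_types = node.get("key_type", "integer")
    if isinstance(raw_types, str):
        key_types = (raw_types.lower(),) * len(keys)
    elif isinstance(raw_types, list) and all(isinstance(t, str) for t in raw_types):
        key_types = tuple(t.lower() for t in raw_types)
    else:
        sink.error("STRUCTURE", "'key_type' must be a type name or list of them", line)
        return None
    try:
        return PrimaryKeySource(alias, table, keys, constraints, key_types, line)
    except DmlError as e:
        sink.error(e.code, e.message, e.line)
        return None


def _primary_key(node, line: int, sink: _Sink, lint: bool) -> Optional[PrimaryKeyDef]:
    if not isinstance(node, dict):
        sink.error("STRUCTURE", "'primary_key' must be a mapping", line)
        return None
    if "sources" in node:
        _check_unknown_keys(node, ("sources",), "primary_key", sink)
        raw_sources = node["sources"]
        if not isinstance(raw_sources, list) or not raw_sources:
            sink.error("STRUCTURE", "'sources' must be a non-empty list", _key_line(node, "sources", line))
            return None
        sources = []
        for i, s in enumerate(raw_sources):
            src = _pk_source(s, _node_line(s, _item_line(raw_sources, i, line)), sink, lint)
            if src is not None:
                sources.append(src)
        if len(sources) != len(raw_sources):
            return None
    else:
        # single-source shorthand: the section itself is the source
        src = _pk_source(node, line, sink, lint)
        if src is None:
            return None
        sources = [src]
    try:
        return PrimaryKeyDef(tuple(sources), line)
    except DmlError as e:
        sink.error(e.code, e.message, line)
        return None


def _rule(node, line: int, sink: _Sink, lint: bool) -> Optional[ColumnRule]:
    raw_tables = node.get("tables")
    if isinstance(raw_tables, str):
        raw_tables = [raw_tables]
    if not isinstance(raw_tables, list) or not raw_tables:
        sink.error("MISSING_SECTION", "rule requires a non-empty 'tables' list", line)
        return None
    tables = []
    for i, t in enumerate(raw_tables):
        ref = _table_ref(t, _node_line(t, _item_line(raw_tables, i, line)), sink, lint)
        if ref is not None:
            tables.append(ref)
    if len(tables) != len(raw_tables):
        return None
    if "expression" not in node:
        sink.error("MISSING_SECTION", "rule requires 'expression'", line)
        return None
    expr = _snippet(node["expression"], "expression", _key_line(node, "expression", line), sink, lint)
    if expr is None:
        return None
    if expr.text.strip().upper() == "TODO":
        sink.warning("TODO_STUB", "rule expression is a TODO placeholder", expr.line)
    constraints = None
    if "constraints" in node:
        constraints = _snippet(
            node["constraints"], "boolean_constraint",
            _key_line(node, "constraints", line), sink, lint,
        )
    pk_alias = node.get("primary_key")
    if pk_alias is not None and not is_identifier(pk_alias):
        sink.error("BAD_IDENTIFIER", f"invalid primary_key alias {pk_alias!r}", _key_line(node, "primary_key", line))
        return None
    try:
        return ColumnRule(tuple(tables), expr, constraints, pk_alias, line)
    except DmlError as e:
        sink.error(e.code, e.message, e.line)
        return None


def _column(node, line: int, sink: _Sink, lint: bool) -> Optional[ColumnDef]:
    if not isinstance(node, dict):
        sink.error("STRUCTURE", "column entry must be a mapping", line)
        return None
    _check_unknown_keys(node, COLUMN_KEYS, "column", sink)
    name = node.get("name")
    if not is_identifier(name):
        sink.error("MISSING_SECTION", "column requires a valid 'name'", line)
        return None
    if "rules" in node:
        raw_rules = node["rules"]
        if not isinstance(raw_rules, list) or not raw_rules:
            sink.error("STRUCTURE", f"column {name!r}: 'rules' must be a non-empty list", _key_line(node, "rules", line))
            return None
        if any(k in node for k in RULE_KEYS):
            sink.error("STRUCTURE", f"column {name!r} mixes 'rules' with inline rule keys", line)
            return None
        rules = []
        for i, r in enumerate(raw_rules):
            if not isinstance(r, dict):
                sink.error("STRUCTURE", "rule must be a mapping", _item_line(raw_rules, i, line))
                continue
            _check_unknown_keys(r, RULE_KEYS, f"rule of column {name!r}", sink)
            rule = _rule(r, _node_line(r, _item_line(raw_rules, i, line)), sink, lint)
            if rule is not None:
                rules.append(rule)
        if len(rules) != len(raw_rules):
            return None
    else:
        # single-rule shorthand: rule fields live on the column itself
        rule = _rule(node, line, sink, lint)
        if rule is None:
            return None
        rules = [rule]
    try:
        return ColumnDef(name.lower(), tuple(rules), line)
    except DmlError as e:
        sink.error(e.code, e.message, e.line)
        return None


def normalize_document(
    raw,
    file: str = "<memory>",
    collect: Optional[list] = None,
    lint: bool = True,
) -> Optional[MappingDocument]:
    """Normalize a parsed YAML tree into a :class:`MappingDocument`.

    Shorthands are expanded: a ``primary_key`` without a ``sources``
    list becomes a one-element source list with the implicit alias
    ``<TABLE>_PK``; a column carrying rule fields directly becomes a
    one-element ``rules`` list.

    With ``collect`` given, all diagnostics are appended to it as
    ``(severity, code, message, line)`` tuples and ``None`` is returned
    when any error was recorded; without it the first error raises
    :class:`DmlError`.
    """
    sink = _Sink(collect)
    line = _node_line(raw)
    if not isinstance(raw, dict):
        sink.error("STRUCTURE", "mapping document must be a YAML mapping", line)
        return None
    _check_unknown_keys(raw, TOP_KEYS, "document", sink)

    name = raw.get("name")
    if not is_identifier(name):
        sink.error("MISSING_SECTION", "document requires a valid 'name' (target OMOP table)", line)
        target = None
    else:
        target = name.lower()

    if "primary_key" not in raw:
        sink.error("MISSING_SECTION", "document requires a 'primary_key' section", line)
        pk = None
    else:
        pk = _primary_key(raw["primary_key"], _key_line(raw, "primary_key", line), sink, lint)

    columns: list[ColumnDef] = []
    if "columns" not in raw:
        sink.error("MISSING_SECTION", "document requires a 'columns' section", line)
    else:
        raw_cols = raw["columns"]
        if raw_cols is None:
            raw_cols = []
        if not isinstance(raw_cols, list):
            sink.error("STRUCTURE", "'columns' must be a list", _key_line(raw, "columns", line))
            raw_cols = []
        if not raw_cols:
            sink.warning("EMPTY_COLUMNS", "document defines no column rules", _key_line(raw, "columns", line))
        for i, c in enumerate(raw_cols):
            col = _column(c, _node_line(c, _item_line(raw_cols, i, line)), sink, lint)
            if col is not None:
                columns.append(col)

    seen: dict[str, int] = {}
    for col in columns:
        if col.name in seen:
            sink.error(
                "DUPLICATE_COLUMN",
                f"duplicate column name {col.name!r} (lines {seen[col.name]} and {col.line})",
                col.line,
            )
        else:
            seen[col.name] = col.line

    if sink.failed or target is None or pk is None:
        return None
    warns = tuple(
        f"{code}: {msg}" for sev, code, msg, _ in (collect or []) if sev == "warning"
    ) if collect is not None else ()
    doc = MappingDocument(target, pk, tuple(columns), file, line, warns)

    for col in doc.columns:
        for rule in col.rules:
            try:
                resolve_rule_pk(rule, doc)
            except DmlError as e:
                sink.error(e.code, e.message, e.line)
    return None if sink.failed else doc


def document_to_tree(doc: MappingDocument) -> dict:
    """Canonical raw-tree form of a document (the inverse of
    :func:`normalize_document` up to shorthand expansion)."""

    def table_entry(t: TableRef):
        if t.variant == "inline":
            return {"alias": t.alias, "query": t.query.text}
        return f"{t.schema}.{t.name}" if t.schema else t.name

    def rule_entry(r: ColumnRule) -> dict:
        out: dict = {
            "tables": [table_entry(t) for t in r.tables],
            "expression": r.expression.text,
        }
        if r.constraints is not None:
            out["constraints"] = r.constraints.text
        if r.pk_alias is not None:
            out["primary_key"] = r.pk_alias
        return out

    sources = []
    for s in doc.primary_key.sources:
        entry: dict = {
            "alias": s.alias,
            "table": table_entry(s.table),
            "columns": list(s.key_columns),
            "key_type": list(s.key_types),
        }
        if s.constraints is not None:
            entry["constraints"] = s.constraints.text
        sources.append(entry)
    return {
        "name": doc.target_table,
        "primary_key": {"sources": sources},
        "columns": [{"name": c.name, "rules": [rule_entry(r) for r in c.rules]} for c in doc.columns],
    }


def resolve_rule_pk(rule: ColumnRule, doc: MappingDocument) -> PrimaryKeySource:
    """Find the primary-key source a rule's UPDATE is keyed on.

    With a single declared source the rule may omit the alias; with
    several, the alias is mandatory and must name a declared source.
    """
    sources = doc.primary_key.sources
    if rule.pk_alias is None:
        if len(sources) == 1:
            return sources[0]
        raise DmlError(
            "rule must name a primary_key alias when the document declares "
            f"{len(sources)} primary-key sources",
            rule.line,
            "MISSING_PK_ALIAS",
        )
    src = doc.primary_key.by_alias(rule.pk_alias)
    if src is None:
        declared = ", ".join(s.alias for s in sources)
        raise DmlError(
            f"unknown primary_key alias {rule.pk_alias!r}; declared aliases: "
            f"{{{declared}}}",
            rule.line,
            "UNKNOWN_PK_ALIAS",
        )
    return src


def check_rule_aliases(doc: MappingDocument) -> None:
    """Resolve every rule's primary-key source, raising on the first defect."""
    for col in doc.columns:
        for rule in col.rules:
            resolve_rule_pk(rule, doc)


__all__ = [
    "DmlError",
    "SqlSnippet",
    "TableRef",
    "PrimaryKeySource",
    "PrimaryKeyDef",
    "ColumnRule",
    "ColumnDef",
    "MappingDocument",
    "implicit_pk_alias",
    "normalize_document",
    "document_to_tree",
    "edit_distance",
    "suggest_key",
    "resolve_rule_pk",
    "check_rule_aliases",
    "fold_identifier",
    "is_identifier",
    "INTEGER_KEY_TYPES",
]
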
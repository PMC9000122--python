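"""YAML reading and diagnostics.

Mapping files are ordinary YAML (anchors, aliases, and ``<<`` merge keys
are supported, so shared default blocks can be written once and reused).
The loader retains the 1-based source line of every mapping, sequence
and key so that every diagnostic — and every provenance label in the
compiled SQL — can point back into the file.

All validation is total: every defect in a file is reported, not just
the first one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import yaml

from .dml_model import (
    DmlError,
    MappingDocument,
    normalize_document,
    resolve_rule_pk,
    suggest_key,
)

if TYPE_CHECKING:  # pragma: no cover
    from .omop_catalogue import Catalogue

#: Closed set of diagnostic codes emitted anywhere in the package.
DIAGNOSTIC_CODES = frozenset(
    {
        "YAML_SYNTAX",
        "STRUCTURE",
        "MISSING_SECTION",
        "UNKNOWN_KEY",
        "BAD_IDENTIFIER",
        "BAD_SNIPPET",
        "DUPLICATE_COLUMN",
        "DUPLICATE_ALIAS",
        "MISSING_PK_ALIAS",
        "UNKNOWN_PK_ALIAS",
        "EMPTY_COLUMNS",
        "TODO_STUB",
        "UNKNOWN_TABLE",
        "UNKNOWN_COLUMN",
        "PK_COLUMN_MAPPED",
        "NOT_NULL_UNMAPPED",
        "SCHEMA_MISMATCH",
        "ORDER_OVERRIDE",
        "NO_LINKAGE",
        "FK_CYCLE",
    }
)


@dataclass(frozen=True, order=True)
class Diagnostic:
    """One validation finding, printable as ``file:line: severity CODE message``."""

    file: str
    line: int
    code: str
    severity: str  # error | warning
    message: str

    def __post_init__(self):
        assert self.severity in ("error", "warning")
        assert self.code in DIAGNOSTIC_CODES, self.code
        assert self.line >= 1

    def render(self) -> str:
        return f"{self.file}:{self.line}: {self.severity} {self.code} {self.message}"


def has_errors(diagnostics: list[Diagnostic]) -> bool:
    return any(d.severity == "error" for d in diagnostics)


class YamlParseError(Exception):
    """YAML-level failure (syntax error, undefined alias)."""

    def __init__(self, diagnostic: Diagnostic):
        super().__init__(diagnostic.render())
        self.diagnostic = diagnostic


# --- located loader -----------------------------------------------------


class LocatedDict(dict):
    """A dict remembering its node line and the line of each key."""

    __slots__ = ("line", "key_lines")

    def __init__(self, *a, **kw):
        super().__init__(*a, **kw)
        self.line = 1
        self.key_lines: dict = {}


class LocatedList(list):
    __slots__ = ("line", "item_lines")

    def __init__(self, *a, **kw):
        super().__init__(*a, **kw)
        self.line = 1
        self.item_lines: list[int] = []


class _LocatedLoader(yaml.SafeLoader):
    """SafeLoader variant producing Located containers.

    ``flatten_mapping`` resolves ``<<`` merge keys, so a document using
    an anchored block of defaults loads to the same tree as its
    hand-expanded equivalent.
    """


def _construct_mapping(loader: _LocatedLoader, node):
    loader.flatten_mapping(node)
    out = LocatedDict()
    out.line = node.start_mark.line + 1
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=True)
        out[key] = loader.construct_object(value_node, deep=True)
        out.key_lines[key] = key_node.start_mark.line + 1
    return out


def _construct_sequence(loader: _LocatedLoader, node):
    out = LocatedList(loader.construct_object(child, deep=True) for child in node.value)
    out.line = node.start_mark.line + 1
    out.item_lines = [child.start_mark.line + 1 for child in node.value]
    return out


_LocatedLoader.add_constructor("tag:yaml.org,2002:map", _construct_mapping)
_LocatedLoader.add_constructor("tag:yaml.org,2002:seq", _construct_sequence)


def parse_mapping(text: str, file: str = "<memory>"):
    """Parse one YAML mapping document into a located tree.

    Raises :class:`YamlParseError` (carrying a line-accurate
    ``YAML_SYNTAX`` diagnostic) on malformed YAML or undefined aliases.
    """
    if not text.strip():
        raise YamlParseError(
            Diagnostic(file, 1, "YAML_SYNTAX", "error", "empty document")
        )
    try:
        return yaml.load(text, Loader=_LocatedLoader)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None) or getattr(exc, "context_mark", None)
        line = (mark.line + 1) if mark is not None else 1
        message = getattr(exc, "problem", None) or str(exc)
        context = getattr(exc, "context", None)
        if context:
            message = f"{context}: {message}"
        raise YamlParseError(
            Diagnostic(file, line, "YAML_SYNTAX", "error", message)
        ) from exc


# --- structural validation ----------------------------------------------


def validate_structure(
    tree, file: str = "<memory>"
) -> tuple[Optional[MappingDocument], list[Diagnostic]]:
    """Normalize a parsed tree, collecting every diagnostic.

    Returns the normalized document only when no error-severity
    diagnostic was produced; warnings may accompany a document.
    """
    collected: list[tuple] = []
    doc = normalize_document(tree, file, collect=collected)
    diagnostics = sorted(
        Diagnostic(file, line, code, severity, message)
        for severity, code, message, line in collected
    )
    return doc, diagnostics


def validate_against_catalogue(
    doc: MappingDocument, cat: "Catalogue"
) -> list[Diagnostic]:
    """Check a normalized document against the OMOP catalogue.

    Unknown target tables or columns are errors; catalogue NOT NULL
    columns left unmapped are warnings (they will surface as database
    errors at load time if the target schema enforces them).
    """
    out: list[Diagnostic] = []
    file = doc.source_file
    if doc.target_table not in cat.tables:
        hint = suggest_key(doc.target_table, tuple(sorted(cat.tables)))
        msg = f"unknown target table {doc.target_table!r}"
        if hint:
            msg += f"; did you mean {hint!r}?"
        out.append(Diagnostic(file, doc.line, "UNKNOWN_TABLE", "error", msg))
        return out

    cat_columns = {c.name: c for c in cat.tables[doc.target_table]}
    pk_column = cat.primary_key_of(doc.target_table)
    mapped = set()
    for col in doc.columns:
        if col.name not in cat_columns:
            hint = suggest_key(col.name, tuple(sorted(cat_columns)))
            msg = f"column {col.name!r} not in {doc.target_table!r}"
            if hint:
                msg += f"; nearest is {hint!r}"
            out.append(Diagnostic(file, col.line, "UNKNOWN_COLUMN", "error", msg))
            continue
        if col.name == pk_column:
            out.append(
                Diagnostic(
                    file,
                    col.line,
                    "PK_COLUMN_MAPPED",
                    "error",
                    f"column {col.name!r} is the target primary key; it is "
                    "populated by the primary_key section, not by rules",
                )
            )
            continue
        mapped.add(col.name)
        for rule in col.rules:
            try:
                src = resolve_rule_pk(rule, doc)
            except DmlError:
                continue  # reported structurally
            for t in rule.tables:
                if (
                    t.variant == "named"
                    and t.name == src.table.name
                    and t.schema is not None
                    and t.schema != src.table.schema
                ):
                    out.append(
                        Diagnostic(
                            file,
                            rule.line,
                            "SCHEMA_MISMATCH",
                            "warning",
                            f"rule lists {t.schema}.{t.name} but its primary-key "
                            f"source {src.alias} reads {t.name} from a different schema",
                        )
                    )
    for cat_col in cat.tables[doc.target_table]:
        if cat_col.is_primary_key or cat_col.nullable:
            continue
        if cat_col.name not in mapped:
            out.append(
                Diagnostic(
                    file,
                    doc.line,
                    "NOT_NULL_UNMAPPED",
                    "warning",
                    f"NOT NULL column {cat_col.name!r} of {doc.target_table!r} "
                    "has no mapping rule",
                )
            )
    return sorted(out)


def load_document(
    text: str,
    file: str = "<memory>",
    catalogue: Optional["Catalogue"] = None,
) -> tuple[Optional[MappingDocument], list[Diagnostic]]:
    """Parse + validate in one call; never raises on bad input."""
    try:
        tree = parse_mapping(text, file)
    except YamlParseError as exc:
        return None, [exc.diagnostic]
    doc, diagnostics = validate_structure(tree, file)
    if doc is not None and catalogue is not None:
        cat_diags = validate_against_catalogue(doc, catalogue)
        if has_errors(cat_diags):
            doc = None
        diagnostics = sorted(diagnostics + cat_diags)
    return doc, diagnostics


__all__ = [
    "Diagnostic",
    "DIAGNOSTIC_CODES",
    "YamlParseError",
    "parse_mapping",
    "validate_structure",
    "validate_against_catalogue",
    "load_document",
    "has_errors",
]
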
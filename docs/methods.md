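# Methods

## The mapping language and its execution model

`omopetl` treats source-to-OMOP mapping as a set of per-table YAML
documents, each organizing verbatim PostgreSQL snippets into three
sections: the target table `name`, a `primary_key` section declaring
the source table(s) whose rows become target rows, and `columns` —
one or more rules per target column, each with source `tables`, an
`expression`, optional `constraints`, and (when several primary-key
sources exist) the alias of the source the rule applies to.

The compiled execution shape is **skeleton-then-update**:

1. *Staging (staged keys only).* A mapping table
   `<staging>.<target>_pk_map(target_id, source_alias, key columns…)`
   is created and loaded with the distinct non-NULL key tuples of each
   source, in declared source order, keys ascending; `target_id` is
   `ROW_NUMBER()` over that order plus the table's current maximum (or
   `sequence_start − 1` when empty). The table is a bijection between
   `(source_alias, key tuple)` and `target_id`.
2. *Skeleton.* One INSERT fills only the target primary-key column:
   direct plans copy the distinct non-NULL source key; staged plans
   select `target_id` from the mapping table.
3. *Columns.* One UPDATE per rule sets one column. The FROM list is
   exactly the rule's tables plus the key linkage (the rule's
   primary-key source table, added automatically if not listed, and
   the mapping table for staged plans); the rule's `constraints` join
   the WHERE clause as one conjunct.

This shape makes the language's central maintainability claim a
mechanical property: the statements emitted for a column are a pure
function of that column's rules, so they are byte-invariant under any
edit to other columns, and full recompiles are byte-identical.

### Key-strategy decision

A source key is reused directly iff the document declares exactly one
source with a single-column, unconstrained key whose declared type is
integer-like (`integer`, `bigint`, `smallint`, `serial`, …); anything
else is staged. Because the compiler never inspects the live source
database, the key's type is declared in the document via an optional
`key_type` field (default `integer`; a list for composite keys). This
is a deliberate convention: it keeps compilation a pure function of
the YAML inputs.

### Semantics choices for degenerate inputs

- **Overlapping rules** on one column: later rules win (UPDATEs run in
  document order). An opt-in strict mode (`strict_overlap`) emits a
  guard per multi-rule column — each rule's matched target ids are
  inserted into a single-column PRIMARY KEY table, so a doubly-updated
  row aborts the script at exactly that column.
- **Rows matched by no rule** keep NULL; unmapped NOT NULL catalogue
  columns are flagged as compile-time warnings (`NOT_NULL_UNMAPPED`).
- **NULL key components**: no surrogate key can be minted for an
  unidentifiable row, so such rows are excluded from mapping tables and
  skeletons. (Exclusion is noted in the generated SQL; exact excluded
  counts are only knowable at run time.)
- **Empty `columns`** is a warning, not an error, so teams can commit
  skeleton documents early and fill them in incrementally.

### Identifier and alias handling

SQL-object identifiers (schemas, tables, columns) are folded to
lowercase, matching PostgreSQL's unquoted-identifier folding. Primary
key *aliases* (e.g. `DIAGNOSIS_PK`) are DML-level names, not SQL
identifiers: they are kept verbatim and compared exactly; the implicit
alias for the single-source shorthand is `<TABLE>_PK` upper-cased. SQL
snippets are never case-folded, parsed, or rewritten — only linted
(non-empty, balanced parentheses, no semicolons; inline sources must
begin with SELECT/WITH).

### YAML dialect

Anchors, aliases, and YAML-1.1 `<<` merge keys are accepted, because
shared default blocks are the language's main repetition-removal
device. A reserved top-level `definitions` section may hold anchored
blocks; its contents are otherwise ignored. Unknown keys are errors
with minimum-edit-distance suggestions: in a language with ~10
keywords, a silently ignored typo is worse than a rejection.
Validation is total (all diagnostics collected, ordered by
file/line/code), and a document is returned only when no error was
found.

Provenance labels on compiled statements use each YAML *node's*
starting line. Script headers identify inputs by a digest of the
*normalized* document rather than the raw file bytes, so an anchored
document and its hand-expanded equivalent — which load to identical
trees — compile byte-identically, and whitespace-only edits do not
churn the header.

### Emitted dialect

The generated SQL is restricted to a PostgreSQL subset that common
embeddable engines also accept: `DELETE FROM` rather than `TRUNCATE`,
and `ROW_NUMBER()`-based id assignment rather than sequences (the plan
still records the conventional `<target>_id_seq` name). Author
snippets pass through verbatim and may use anything the execution
engine supports. Targets are cleared before load by default
(`truncate_targets`), the whole project script is wrapped in one
transaction (`wrap_transaction`), and staging tables persist unless
`drop_staging` is set — downstream tables reference upstream key maps
for foreign-key columns, so dropping them mid-project would break FK
population.

## The OMOP catalogue

OMOP CDM v6.0 metadata (columns, types, nullability, primary keys,
foreign keys) is shipped as a CSV transcription of the official v6.0
DDL for the five tables the suite exercises: person (19 columns: the
surrogate key plus 18 target fields, with death_datetime folded into
person as v6 specifies), observation_period, visit_occurrence,
condition_occurrence, drug_exposure. Foreign-key edges are restricted
to tables present in the catalogue; vocabulary (concept) references
are out of scope, as is concept mapping generally. The catalogue
drives semantic validation, template scaffolding, and the
foreign-key-aware compile order (Kahn's algorithm, alphabetical
tie-breaks, self-references ignored; an explicit override replaces the
computed order with a warning when it contradicts FK edges).
Compilation also works without a catalogue — validation is skipped and
the target key column falls back to the `<table>_id` convention — so
non-OMOP targets can be compiled.

## The synthetic test bed

The fixture harness emulates the structure of a CERNER-like relational
source: person/diagnosis/problem/encounter tables with integer or text
keys, ISO-formatted timestamp strings, and small code vocabularies
(sex codes, a handful of ICD-style codes). It deliberately does **not**
emulate clinical realism: no vocabulary mapping, no visit hierarchies,
no type coercion edge cases beyond text keys, no volume. Passing tests
therefore demonstrate the correctness of the *mapping machinery* —
key staging, unions, joins, rule dispatch, ordering, determinism — not
fitness of any particular clinical mapping.

Sixteen registry cases cover the language's feature matrix, three of
them deliberate-error cases asserting diagnostic codes
(`DUPLICATE_ALIAS`, `UNKNOWN_COLUMN`, `MISSING_PK_ALIAS`). Fixtures
are deterministic functions of `(case_id, seed)`; expected OMOP
relations are computed *in the generator*, independently of the
compiler, and each executable case also carries a hand-written
monolithic INSERT…SELECT oracle whose result the compiled script's
output must equal as a multiset. Fixture sizes are small (5–10 rows
per table; the randomized invariant fixtures use 0–50 rows with NULL
keys and duplicates) — the properties checked are size-independent
set/cardinality identities, so small relations exercise them fully
while keeping the whole suite in seconds.

The execution backend is the stdlib sqlite engine with one ATTACHed
in-memory database per logical schema, so emitted `schema.table`
references resolve unchanged. The backend contract is dialect-based:
anything accepting the emitted PostgreSQL subset can be substituted.
Target tables are created without NOT NULL constraints in the harness,
since the skeleton-then-update shape necessarily passes through
intermediate states where only the key column is filled; against a
constrained production schema the same scripts should run inside one
transaction with deferred constraints, or against staging copies.

## Numerical / ordering conventions

- Surrogate ids start at `sequence_start` (default 1) per target table
  and are dense and reproducible: declared source order, then
  ascending key order (text keys compare by byte order, so fixture
  vocabularies are ASCII).
- Relation comparison is multiset equality keyed on the target primary
  key, with NULL comparing equal to NULL; cell mismatches are reported
  per (row key, column).
- Diagnostics sort by (file, line, code); compile output is
  byte-stable across runs and platforms (LF endings, no timestamps).

## Known limitations

- Snippets are trusted verbatim; the linter catches only unbalanced
  parentheses and semicolons, not SQL errors (those surface at run
  time with file:line provenance).
- One YAML document per target table; a table cannot be split across
  documents.
- No incremental/delta loads: scripts rebuild their targets.
- The CLI `run` subcommand executes against the embedded backend; a
  production PostgreSQL run would take the generated .sql file to
  `psql` unchanged.
- Catalogue completeness is data entry: five v6 tables ship today; the
  format is versioned so v5.4 or the remaining v6 tables can be added
  without code changes.
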
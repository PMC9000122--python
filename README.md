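# omopetl

A YAML data-manipulation language, compiled to an ETL SQL script, for
loading relational health data into the OMOP Common Data Model (CDM v6).

Mapping an EHR extract to OMOP is usually done with monolithic
"spaghetti" SQL — one multi-join INSERT per target table in which every
column's logic is entangled with every other's. `omopetl` replaces that
with one small YAML document per target OMOP table, in which mapping
logic is written **column by column** as short PostgreSQL snippets. A
compiler turns a set of documents into a single deterministic SQL
script. The intended users are data-engineering teams standardizing
CERNER-like (or any relational) health databases to OMOP, who want
mapping logic that is reviewable, diffable, and editable per column by
several developers at once.

## The language

Each document has three sections:

```yaml
name: person                 # (1) the target OMOP table
primary_key:                 # (2) which source rows become target rows
  table: person
  columns: [person_id]
columns:                     # (3) one block of rules per OMOP column
  - name: year_of_birth
    tables: [person]
    expression: "CAST(substr(person.birth_dt_tm, 1, 4) AS integer)"
  - name: death_datetime
    tables: [person]
    expression: "person.deceased_dt_tm"
```

A rule lists its source `tables` (names, or inline `SELECT` queries
with an alias), an `expression` (any PostgreSQL expression, passed
through verbatim), and optional `constraints` (a boolean expression
defining joins/filters). YAML anchors, aliases and `<<` merge keys are
supported so shared defaults are written once.

**Primary keys.** A single unconstrained integer source key is reused
*directly* as the target key. Anything else — composite keys,
non-integer keys, constrained sources, or several source tables
feeding one OMOP table — is *staged*: the compiler builds a mapping
table `<target>_pk_map` in the staging schema that assigns each
distinct non-NULL source key tuple a fresh surrogate id
(deterministically: sources in declared order, keys ascending). With
several sources, each one gets an alias (e.g. `DIAGNOSIS_PK`,
`PROBLEM_PK`) and each column rule says which source its rows come
from via `primary_key: DIAGNOSIS_PK`.

**Compiled shape.** Per target table: staging mapping table (if
staged), a *skeleton* INSERT filling only the primary-key column, then
one UPDATE per rule. Because every statement is a pure function of its
own column's rules, editing one column never changes the SQL emitted
for another; recompiles are byte-identical. Documents are ordered so
foreign-key-referenced tables load first.

## Worked example

```
python examples/02_union_with_staged_keys.py
```

compiles the two-source condition_occurrence document above, loads 3
diagnosis and 2 problem rows, executes the script, and prints:

```
omop.condition_occurrence:
  (1, '2015-03-01')
  (2, '2016-07-09')
  (3, '2017-01-20')
  (4, '2018-02-02')
  (5, '2019-11-30')
```

The 3 + 2 distinct source keys became exactly 5 target rows; ids 1–3
were minted for diagnosis keys (ascending), 4–5 for problem keys, and
each per-source rule updated only its own rows. The other examples
compile a single document, scaffold and validate a template, and run a
two-table project with a foreign-key column end to end.

## Command line

```
omopetl validate person.yaml condition_occurrence.yaml
omopetl compile  person.yaml condition_occurrence.yaml --out etl.sql
omopetl scaffold --table person --cdm v6 > person.yaml
omopetl run etl.sql --dsn ./etl.db --i-understand-this-writes
```

`validate` exits 1 on any error; diagnostics are printed to stderr as
`file:line: severity CODE message` (or `--format json`). `compile`
accepts a `--config` key-value file (schemas, `sequence_start`,
`truncate_targets`, `wrap_transaction`, …); flags override file values.
stdout only ever carries artifacts (SQL or YAML), so commands pipe
safely.

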
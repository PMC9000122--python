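"""Two source tables united into one OMOP table via a staging key map.

condition_occurrence is fed by both diagnosis and problem rows.  The
compiler builds etl_staging.condition_occurrence_pk_map assigning each
distinct source key a fresh surrogate id (diagnosis keys first, then
problem keys, each ascending), then the per-source rules update only
the rows that came from their source.
"""

from omopetl import compile_project, load_catalogue, load_document
from omopetl.fixture_harness import SqliteBackend, execute_script

CONDITION_YAML = """name: condition_occurrence
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

catalogue = load_catalogue("v6")
doc, _ = load_document(CONDITION_YAML, "condition_occurrence.yaml", catalogue=catalogue)
script = compile_project([doc], catalogue)

backend = SqliteBackend()
backend.execute("CREATE TABLE source.diagnosis (diagnosis_id integer, diag_dt_tm text)")
backend.execute("CREATE TABLE source.problem (problem_id integer, onset_dt_tm text)")
backend.insert_rows("source", "diagnosis", ("diagnosis_id", "diag_dt_tm"),
                    [(11, "2015-03-01"), (12, "2016-07-09"), (13, "2017-01-20")])
backend.insert_rows("source", "problem", ("problem_id", "onset_dt_tm"),
                    [(5, "2018-02-02"), (9, "2019-11-30")])
backend.create_target_tables(catalogue, ["condition_occurrence"])

report = execute_script(script, backend)
print("executed:", report.success)
for r in report.results:
    print(f"  rows={r.rowcount:>3}  {r.label}")

rows = backend.query(
    "SELECT condition_occurrence_id, condition_start_datetime "
    "FROM omop.condition_occurrence ORDER BY 1"
)
print("\nomop.condition_occurrence:")
for row in rows:
    print(" ", row)
print("# ids 1-3 are diagnosis rows, 4-5 problem rows: 3 + 2 distinct "
      "source keys became exactly 5 target rows.")
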
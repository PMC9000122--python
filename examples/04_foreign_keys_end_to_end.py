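"""A two-table project with a foreign-key column, run end to end.

person gets surrogate keys staged from a text medical-record number;
condition_occurrence.person_id is then populated by joining the
persisted person key map — exactly how downstream tables reference
upstream surrogate keys.  The harness compares the loaded OMOP rows
with expectations computed independently while generating the rows.
"""

from omopetl.fixture_harness import generate_fixture, run_case

fixture = generate_fixture("foreign_key_column", seed=42)
for fname, _ in fixture.mapping_yaml:
    print("document:", fname)

result = run_case("foreign_key_column", seed=42)
print("executed:", result.report.success)
for table, diff in result.diffs.items():
    print(f"  diff vs expected [{table}]:", "empty" if diff.empty else diff.render())
for table, diff in result.oracle_diffs.items():
    print(f"  diff vs hand-written SQL oracle [{table}]:",
          "empty" if diff.empty else diff.render())
print("passed:", result.passed)
print("# every condition row points at the surrogate person id minted for "
      "its medical-record number.")
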
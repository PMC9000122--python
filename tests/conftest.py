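import pytest

from omopetl.omop_catalogue import load_catalogue
from omopetl.yaml_frontend import load_document

PERSON_YAML = """name: person
primary_key:
  table: person
  columns: [person_id]
columns:
  - name: year_of_birth
    tables: [person]
    expression: "CAST(substr(person.birth_dt_tm, 1, 4) AS integer)"
  - name: death_datetime
    tables: [person]
    expression: "person.deceased_dt_tm"
"""

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


@pytest.fixture(scope="session")
def catalogue():
    return load_catalogue("v6")


@pytest.fixture()
def person_doc(catalogue):
    doc, diags = load_document(PERSON_YAML, "person.yaml", catalogue=catalogue)
    assert doc is not None, [d.render() for d in diags]
    return doc


@pytest.fixture()
def condition_doc(catalogue):
    doc, diags = load_document(CONDITION_YAML, "condition_occurrence.yaml", catalogue=catalogue)
    assert doc is not None, [d.render() for d in diags]
    return doc
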
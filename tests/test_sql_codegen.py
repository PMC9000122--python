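"""Compiler core: key planning, staging tables, skeletons, rule UPDATEs."""

import pytest

from omopetl.dml_model import DmlError
from omopetl.fixture_harness import SqliteBackend, execute_script
from omopetl.sql_codegen import (
    CompilerConfig,
    compile_document,
    compile_project,
    plan_primary_key,
    render_mapping_tables,
    render_rule_update,
    render_skeleton_insert,
)
from omopetl.yaml_frontend import load_document, parse_mapping, validate_structure

from conftest import CONDITION_YAML, PERSON_YAML


def _doc(text, file="doc.yaml"):
    doc, diags = validate_structure(parse_mapping(text, file), file)
    assert doc is not None, [d.render() for d in diags]
    return doc


COMPOSITE_YAML = """name: visit_occurrence
primary_key:
  table: encounter
  columns: [encntr_id, person_id]
columns: []
"""

TEXT_KEY_YAML = """name: person
primary_key:
  table: client
  columns: [mrn]
  key_type: text
columns: []
"""


class TestPlanPrimaryKey:
    def test_single_integer_key_is_direct(self, catalogue):
        plan = plan_primary_key(_doc(PERSON_YAML), catalogue)
        assert plan.strategy == "direct"
        assert plan.target_pk_column == "person_id"

    def test_multi_source_union_is_staged_with_documented_names(self, catalogue):
        plan = plan_primary_key(_doc(CONDITION_YAML), catalogue)
        assert plan.strategy == "staged"
        assert plan.mapping_table == "condition_occurrence_pk_map"
        assert plan.sequence_name == "condition_occurrence_id_seq"

    def test_composite_key_is_staged(self):
        assert plan_primary_key(_doc(COMPOSITE_YAML)).strategy == "staged"

    def test_non_integer_key_is_staged(self):
        assert plan_primary_key(_doc(TEXT_KEY_YAML)).strategy == "staged"

    def test_constrained_source_is_staged(self):
        text = PERSON_YAML.replace(
            "  columns: [person_id]\n",
            "  columns: [person_id]\n  constraints: \"person.sex_cd <> 'U'\"\n",
        )
        assert plan_primary_key(_doc(text)).strategy == "staged"

    def test_pk_column_falls_back_to_naming_convention_without_catalogue(self):
        assert plan_primary_key(_doc(PERSON_YAML)).target_pk_column == "person_id"


class TestMappingTables:
    def test_direct_plan_needs_no_staging(self, catalogue):
        plan = plan_primary_key(_doc(PERSON_YAML), catalogue)
        assert render_mapping_tables(plan, CompilerConfig()) == []

    def test_union_emits_create_plus_one_insert_per_source_in_declared_order(self, catalogue):
        plan = plan_primary_key(_doc(CONDITION_YAML), catalogue)
        stmts = render_mapping_tables(plan, CompilerConfig())
        inserts = [s for s in stmts if s.sql.startswith("INSERT")]
        assert len(stmts) == 4
        assert stmts[0].sql.startswith("DROP") and stmts[1].sql.startswith("CREATE")
        assert len(inserts) == 2
        assert "'DIAGNOSIS_PK'" in inserts[0].sql and "'PROBLEM_PK'" in inserts[1].sql

    def test_executed_mapping_table_matches_hand_written_oracle(self, catalogue):
        """3 diagnosis + 2 problem rows -> 5 mapping rows with ids 1..5,
        each (alias, key) pair unique; checked against an independent
        hand-written SQL oracle on the same rows."""
        doc = _doc(CONDITION_YAML)
        plan = plan_primary_key(doc, catalogue)
        backend = SqliteBackend()
        backend.execute("CREATE TABLE source.diagnosis (diagnosis_id integer, diag_dt_tm text)")
        backend.execute("CREATE TABLE source.problem (problem_id integer, onset_dt_tm text)")
        backend.insert_rows("source", "diagnosis", ("diagnosis_id", "diag_dt_tm"),
                            [(30, "a"), (10, "b"), (20, "c")])
        backend.insert_rows("source", "problem", ("problem_id", "onset_dt_tm"),
                            [(7, "d"), (3, "e")])
        for stmt in render_mapping_tables(plan, CompilerConfig()):
            backend.execute(stmt.sql)
        rows = backend.query(
            "SELECT target_id, source_alias, diagnosis_id, problem_id "
            "FROM etl_staging.condition_occurrence_pk_map ORDER BY target_id"
        )
        # independent oracle: declared source order, keys ascending
        oracle = backend.query(
            "SELECT ROW_NUMBER() OVER (ORDER BY ord, k), alias, d, p FROM ("
            "SELECT 1 AS ord, 'DIAGNOSIS_PK' AS alias, diagnosis_id AS k, "
            "diagnosis_id AS d, NULL AS p FROM source.diagnosis "
            "UNION ALL SELECT 2, 'PROBLEM_PK', problem_id, NULL, problem_id "
            "FROM source.problem) AS u"
        )
        assert rows == oracle
        assert [r[0] for r in rows] == [1, 2, 3, 4, 5]
        assert len({(r[1], r[2], r[3]) for r in rows}) == 5

    def test_sequence_start_offsets_assigned_ids(self, catalogue):
        plan = plan_primary_key(_doc(CONDITION_YAML), catalogue)
        backend = SqliteBackend()
        backend.execute("CREATE TABLE source.diagnosis (diagnosis_id integer)")
        backend.execute("CREATE TABLE source.problem (problem_id integer)")
        backend.insert_rows("source", "diagnosis", ("diagnosis_id",), [(1,), (2,)])
        cfg = CompilerConfig(sequence_start=100)
        for stmt in render_mapping_tables(plan, cfg):
            backend.execute(stmt.sql)
        ids = [r[0] for r in backend.query(
            "SELECT target_id FROM etl_staging.condition_occurrence_pk_map ORDER BY 1")]
        assert ids == [100, 101]


class TestSkeletonInsert:
    def test_direct_skeleton_selects_the_source_key(self, catalogue):
        doc = _doc(PERSON_YAML, "person.yaml")
        plan = plan_primary_key(doc, catalogue)
        stmts = render_skeleton_insert(plan, doc, CompilerConfig(), "person.yaml")
        insert = stmts[-1].sql
        assert "INSERT INTO omop.person (person_id)" in insert
        assert "FROM source.person" in insert

    def test_truncate_flag_off_means_no_clear_statement(self, catalogue):
        doc = _doc(PERSON_YAML)
        plan = plan_primary_key(doc, catalogue)
        cfg = CompilerConfig(truncate_targets=False)
        stmts = render_skeleton_insert(plan, doc, cfg)
        assert len(stmts) == 1
        assert not any("DELETE FROM" in s.sql for s in stmts)

    def test_staged_skeleton_reads_the_mapping_table(self, catalogue):
        doc = _doc(CONDITION_YAML)
        plan = plan_primary_key(doc, catalogue)
        insert = render_skeleton_insert(plan, doc, CompilerConfig())[-1].sql
        assert "SELECT target_id FROM etl_staging.condition_occurrence_pk_map" in insert


class TestRuleUpdate:
    def test_case_expression_passes_through_verbatim(self, catalogue):
        expr = "CASE WHEN person.sex_cd = 'M' THEN 8507 ELSE 0 END"
        text = PERSON_YAML.replace(
            'expression: "CAST(substr(person.birth_dt_tm, 1, 4) AS integer)"',
            f'expression: "{expr}"',
        )
        doc = _doc(text)
        plan = plan_primary_key(doc, catalogue)
        stmt = render_rule_update(doc.columns[0].rules[0], doc.columns[0], plan, CompilerConfig())
        assert expr in stmt.sql

    def test_staged_update_filters_on_the_rule_alias(self, catalogue):
        doc = _doc(CONDITION_YAML)
        plan = plan_primary_key(doc, catalogue)
        stmt = render_rule_update(doc.columns[0].rules[0], doc.columns[0], plan, CompilerConfig())
        assert "condition_occurrence_pk_map.source_alias = 'DIAGNOSIS_PK'" in stmt.sql
        assert "t.condition_occurrence_id = condition_occurrence_pk_map.target_id" in stmt.sql

    def test_rule_locality_from_list_is_minimal(self, catalogue):
        doc = _doc(CONDITION_YAML)
        plan = plan_primary_key(doc, catalogue)
        stmt = render_rule_update(doc.columns[0].rules[0], doc.columns[0], plan, CompilerConfig())
        from_clause = stmt.sql.split("FROM ", 1)[1].split("\nWHERE")[0]
        assert from_clause == (
            "source.diagnosis AS diagnosis, "
            "etl_staging.condition_occurrence_pk_map AS condition_occurrence_pk_map"
        )

    def test_pk_source_table_added_when_not_listed(self, catalogue):
        text = """name: person
primary_key:
  table: person
  columns: [person_id]
columns:
  - name: person_source_value
    tables: [person_name]
    expression: "person_name.full_name"
    constraints: "person_name.person_id = person.person_id"
"""
        doc = _doc(text)
        plan = plan_primary_key(doc, catalogue)
        stmt = render_rule_update(doc.columns[0].rules[0], doc.columns[0], plan, CompilerConfig())
        assert "source.person AS person" in stmt.sql

    def test_inline_alias_colliding_with_pk_table_is_a_compile_error(self, catalogue):
        text = """name: person
primary_key:
  table: person
  columns: [person_id]
columns:
  - name: year_of_birth
    tables:
      - alias: person
        query: "SELECT 1 AS x"
    expression: "person.x"
"""
        doc = _doc(text)
        plan = plan_primary_key(doc, catalogue)
        with pytest.raises(DmlError, match="person"):
            render_rule_update(doc.columns[0].rules[0], doc.columns[0], plan, CompilerConfig())

    def test_rule_constraints_join_the_where_clause_as_a_conjunct(self, catalogue):
        text = PERSON_YAML.replace(
            'expression: "person.deceased_dt_tm"',
            'expression: "person.deceased_dt_tm"\n    constraints: "person.deceased_dt_tm IS NOT NULL"',
        )
        doc = _doc(text)
        plan = plan_primary_key(doc, catalogue)
        stmt = render_rule_update(doc.columns[1].rules[0], doc.columns[1], plan, CompilerConfig())
        assert "AND (person.deceased_dt_tm IS NOT NULL)" in stmt.sql


class TestCompileDocument:
    def test_person_script_is_skeleton_plus_two_updates(self, catalogue, person_doc):
        script = compile_document(person_doc, catalogue)
        phases = [s.phase for s in script.statements]
        assert phases == ["setup", "skeleton", "column", "column"]

    def test_phases_are_monotone(self, catalogue, condition_doc):
        script = compile_document(condition_doc, catalogue)
        order = {"setup": 0, "mapping": 1, "skeleton": 2, "column": 3, "teardown": 4}
        ranks = [order[s.phase] for s in script.statements]
        assert ranks == sorted(ranks)

    def test_every_statement_carries_file_line_provenance(self, catalogue, condition_doc):
        script = compile_document(condition_doc, catalogue)
        assert all(
            s.label.startswith("condition_occurrence.yaml:") for s in script.statements
        )

    def test_empty_columns_compile_to_skeleton_only(self, catalogue):
        doc = _doc(COMPOSITE_YAML)
        script = compile_document(doc, catalogue, CompilerConfig(truncate_targets=False))
        assert [s.phase for s in script.statements] == ["mapping"] * 3 + ["skeleton"]

    def test_column_statements_invariant_under_edits_to_other_columns(self, catalogue):
        """Adding/removing another column's rules never changes the SQL
        emitted for this column (the refactoring-safety property)."""
        base = compile_document(_doc(PERSON_YAML, "p.yaml"), catalogue)
        extended_yaml = PERSON_YAML + (
            "  - name: gender_concept_id\n"
            "    tables: [person]\n"
            "    expression: \"0\"\n"
        )
        extended = compile_document(_doc(extended_yaml, "p.yaml"), catalogue)

        def column_sql(script, column):
            return [s.sql for s in script.statements if f".{column}#" in s.label]

        for column in ("year_of_birth", "death_datetime"):
            assert column_sql(base, column) == column_sql(extended, column)

    def test_recompilation_is_byte_identical(self, catalogue, person_doc):
        assert (
            compile_document(person_doc, catalogue).render()
            == compile_document(person_doc, catalogue).render()
        )


class TestCompileProject:
    def test_fk_order_person_block_first(self, catalogue, person_doc, condition_doc):
        script = compile_project([condition_doc, person_doc], catalogue)
        text = script.render()
        assert text.index("omop.person") < text.index("omop.condition_occurrence")

    def test_transaction_wrapping(self, catalogue, person_doc):
        script = compile_project([person_doc], catalogue)
        assert script.statements[0].sql == "BEGIN;"
        assert script.statements[-1].sql == "COMMIT;"
        bare = compile_project([person_doc], catalogue, CompilerConfig(wrap_transaction=False))
        assert all(s.sql not in ("BEGIN;", "COMMIT;") for s in bare.statements)

    def test_header_records_document_digests(self, catalogue, person_doc):
        header = compile_project([person_doc], catalogue).header
        assert "digest:" in header and "person.yaml" in header

    def test_singleton_project_equals_document_compile_plus_wrapping(self, catalogue, person_doc):
        doc_script = compile_document(person_doc, catalogue)
        proj_script = compile_project([person_doc], catalogue)
        assert [s.sql for s in proj_script.statements[1:-1]] == [
            s.sql for s in doc_script.statements
        ]


class TestConfig:
    def test_equal_schemas_rejected_unless_allowed(self):
        with pytest.raises(ValueError):
            CompilerConfig(source_schema="x", target_schema="x")
        CompilerConfig(source_schema="x", target_schema="x", staging_schema="x",
                       allow_shared_schemas=True)

    def test_sequence_start_must_be_positive(self):
        with pytest.raises(ValueError):
            CompilerConfig(sequence_start=0)


class TestStrictOverlapMode:
    def test_overlapping_rules_fail_at_the_guard(self, catalogue):
        text = """name: person
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
        expression: "0"
"""
        doc, diags = load_document(text, "p.yaml", catalogue=catalogue)
        assert doc is not None
        backend = SqliteBackend()
        backend.execute(
            "CREATE TABLE source.person (person_id integer, sex_cd text)"
        )
        backend.insert_rows("source", "person", ("person_id", "sex_cd"),
                            [(1, "M"), (2, "F")])
        backend.create_target_tables(catalogue, ["person"])
        cfg = CompilerConfig(strict_overlap=True, wrap_transaction=False)
        script = compile_project([doc], catalogue, cfg)
        report = execute_script(script, backend)
        assert not report.success
        assert "overlap_guard" in report.failure.label

    def test_disjoint_rules_pass_the_guard(self, catalogue):
        from conftest import PERSON_YAML as _unused  # noqa: F401
        text = """name: person
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
        doc, _ = load_document(text, "p.yaml", catalogue=catalogue)
        backend = SqliteBackend()
        backend.execute("CREATE TABLE source.person (person_id integer, sex_cd text)")
        backend.insert_rows("source", "person", ("person_id", "sex_cd"),
                            [(1, "M"), (2, "F")])
        backend.create_target_tables(catalogue, ["person"])
        cfg = CompilerConfig(strict_overlap=True, wrap_transaction=False)
        report = execute_script(compile_project([doc], catalogue, cfg), backend)
        assert report.success
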
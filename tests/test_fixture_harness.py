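"""Execution backend, relation diffing, and the feature-case registry."""

import pytest
from hypothesis import given, settings, strategies as st

from omopetl.fixture_harness import (
    CASE_IDS,
    ERROR_CASE_IDS,
    Relation,
    SqliteBackend,
    diff_relations,
    execute_script,
    export_fixture,
    generate_fixture,
    run_case,
)
from omopetl.sql_codegen import CompiledScript, CompiledStatement


class TestDiffRelations:
    def _relation(self, rows):
        return Relation("person", ("person_id", "death_datetime"), tuple(rows))

    def test_identical_relations_give_empty_report(self):
        r = self._relation([(1, "2019-01-02"), (2, None)])
        report = diff_relations(r, r)
        assert report.empty

    def test_nulls_compare_equal(self):
        a = self._relation([(1, None)])
        assert diff_relations(a, self._relation([(1, None)])).empty

    def test_one_date_off_by_a_day_is_a_single_cell_mismatch(self):
        actual = self._relation([(1, "2019-01-02"), (2, "2020-05-05")])
        expected = self._relation([(1, "2019-01-03"), (2, "2020-05-05")])
        report = diff_relations(actual, expected)
        assert report.missing_rows == [] and report.unexpected_rows == []
        assert report.cell_mismatches == [(1, "death_datetime", "2019-01-02", "2019-01-03")]

    def test_extra_actual_row_is_unexpected(self):
        actual = self._relation([(1, None), (2, None)])
        expected = self._relation([(1, None)])
        report = diff_relations(actual, expected)
        assert report.unexpected_rows == [(2, None)]

    def test_mismatched_column_sets_are_a_structural_error(self):
        a = Relation("t", ("x",), ((1,),))
        b = Relation("t", ("y",), ((1,),))
        with pytest.raises(ValueError):
            diff_relations(a, b)

    def test_column_order_is_immaterial(self):
        a = Relation("t", ("x", "y"), ((1, "a"),))
        b = Relation("t", ("y", "x"), (("a", 1),))
        assert diff_relations(b, a).empty
        assert diff_relations(a, b).empty

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        rows=st.lists(
            st.tuples(st.integers(0, 20), st.one_of(st.none(), st.text(max_size=3))),
            max_size=15,
        )
    )
    def test_diff_of_a_relation_with_itself_is_always_empty(self, rows):
        r = Relation("t", ("k", "v"), tuple(rows))
        assert diff_relations(r, r).empty


class TestBackendAndExecution:
    def test_empty_script_succeeds_with_zero_statements(self):
        report = execute_script(CompiledScript(()), SqliteBackend())
        assert report.success and report.results == ()

    def test_skeleton_rowcount_equals_source_row_count(self):
        result = run_case("single_source_direct_pk", seed=3)
        fixture = generate_fixture("single_source_direct_pk", seed=3)
        skeleton = next(r for r in result.report.results if "skeleton" in r.label)
        assert skeleton.rowcount == len(fixture.source_rows["person"][1])

    def test_failure_pinpoints_statement_and_provenance(self):
        backend = SqliteBackend()
        script = CompiledScript(
            (
                CompiledStatement("CREATE TABLE omop.t (x integer);", "setup", "a.yaml:1 t.setup"),
                CompiledStatement("INSERT INTO omop.missing VALUES (1);", "skeleton", "a.yaml:2 t.skeleton"),
                CompiledStatement("INSERT INTO omop.t VALUES (1);", "skeleton", "a.yaml:3 t.more"),
            )
        )
        report = execute_script(script, backend)
        assert not report.success
        assert report.failure.index == 1
        assert report.failure.label == "a.yaml:2 t.skeleton"
        assert "missing" in report.failure.error
        # nothing after the failing statement ran
        assert len(report.results) == 2
        assert backend.query("SELECT COUNT(*) FROM omop.t") == [(0,)]


class TestRegistry:
    def test_registry_has_the_16_documented_cases(self):
        assert len(CASE_IDS) == 16
        assert set(ERROR_CASE_IDS) <= set(CASE_IDS)

    def test_unknown_case_id_lists_registry(self):
        with pytest.raises(KeyError, match="single_source_direct_pk"):
            generate_fixture("no_such_case", 0)

    def test_same_case_and_seed_is_deterministic(self):
        assert generate_fixture("multi_source_union", 7) == generate_fixture("multi_source_union", 7)

    def test_different_seeds_vary_the_rows(self):
        a = generate_fixture("multi_source_union", 1)
        b = generate_fixture("multi_source_union", 2)
        assert a.source_rows != b.source_rows

    def test_union_expected_count_is_sum_of_distinct_source_keys(self):
        fixture = generate_fixture("multi_source_union", 7)
        diag = fixture.source_rows["diagnosis"][1]
        prob = fixture.source_rows["problem"][1]
        n = len({r[0] for r in diag if r[0] is not None}) + len(
            {r[0] for r in prob if r[0] is not None}
        )
        assert len(fixture.expected["condition_occurrence"].rows) == n

    def test_foreign_key_values_come_from_the_person_mapping(self):
        fixture = generate_fixture("foreign_key_column", 5)
        person_ids = {r[0] for r in fixture.expected["person"].rows}
        fk_values = {r[1] for r in fixture.expected["condition_occurrence"].rows}
        assert fk_values <= person_ids

    def test_error_cases_carry_expected_codes_and_no_relations(self):
        for case_id in ERROR_CASE_IDS:
            fixture = generate_fixture(case_id, 0)
            assert fixture.is_error_case and fixture.expected_codes

    def test_export_fixture_writes_sql_and_yaml(self, tmp_path):
        paths = export_fixture(generate_fixture("multi_source_union", 1), tmp_path)
        assert any(p.endswith(".sql") for p in paths)
        assert any(p.endswith(".yaml") for p in paths)
        sql_text = (tmp_path / "multi_source_union.sql").read_text()
        assert "INSERT INTO source.diagnosis" in sql_text


class TestRunCase:
    @pytest.mark.parametrize("case_id", [c for c in CASE_IDS if c not in ERROR_CASE_IDS])
    def test_green_cases_execute_and_match(self, case_id):
        result = run_case(case_id, seed=11)
        assert result.passed, (
            [d.render() for d in result.diagnostics],
            {t: d.render() for t, d in result.diffs.items() if not d.empty},
        )

    @pytest.mark.parametrize("case_id", ERROR_CASE_IDS)
    def test_error_cases_emit_their_codes(self, case_id):
        result = run_case(case_id, seed=11)
        assert result.passed
        fixture = generate_fixture(case_id, 11)
        observed = {d.code for d in result.diagnostics}
        assert set(fixture.expected_codes) <= observed
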
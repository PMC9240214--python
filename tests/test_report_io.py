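import datetime as dt
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.report_io import (CaseReport, Dialect, StudyWindow, deduplicate,
                                filter_primary_suspect, filter_window,
                                normalize_drug, read_reports, remove_aberrant,
                                write_reports)
from pvsignal.synthetic import default_config, generate

from conftest import make_report


class TestReadReports:
    def test_well_formed_rows_parse_with_brand_normalization(self, tmp_path):
        p = tmp_path / "reports.tsv"
        p.write_text(
            "report_id\tprimary_suspect_drug\tevent_pts\treceipt_date\n"
            "A1\tLynparza\tMyelodysplastic syndrome|10028533\t2019-01-02\n"
            "A2\t  NIRAPARIB \tNausea;Fatigue\t2019-01-03\n"
            "A3\tcarboplatin\tAcute myeloid leukaemia|10000846\t2019-01-04\n"
        )
        res = read_reports(p)
        assert len(res.reports) == 3
        assert res.rejects == []
        assert res.reports[0].primary_suspect_drug == "olaparib"
        assert res.reports[0].event_pts == frozenset({("Myelodysplastic syndrome", 10028533)})
        assert res.reports[1].primary_suspect_drug == "niraparib"
        assert res.reports[1].event_pts == frozenset({("Nausea", None), ("Fatigue", None)})

    def test_rows_with_missing_mandatory_fields_are_rejected_not_dropped(self, tmp_path):
        p = tmp_path / "reports.tsv"
        p.write_text(
            "report_id\tprimary_suspect_drug\tevent_pts\treceipt_date\n"
            "A1\tolaparib\tNausea\t2019-01-02\n"
            "\tolaparib\tNausea\t2019-01-02\n"
            "A3\tolaparib\t\t2019-01-02\n"
        )
        res = read_reports(p)
        assert len(res.reports) == 1
        reasons = [r.reason for r in res.rejects if r.fatal]
        assert reasons == ["missing report_id", "missing event term"]

    def test_missing_receipt_date_is_flagged_but_report_kept(self, tmp_path):
        p = tmp_path / "reports.tsv"
        p.write_text("report_id\tprimary_suspect_drug\tevent_pts\treceipt_date\n"
                     "A1\tolaparib\tNausea\t\n")
        res = read_reports(p)
        assert len(res.reports) == 1
        assert res.reports[0].receipt_date is None
        assert [(r.reason, r.fatal) for r in res.rejects] == [("missing receipt_date", False)]

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_reports(tmp_path / "nope.tsv")

    def test_unmappable_header_names_missing_columns(self, tmp_path):
        p = tmp_path / "reports.tsv"
        p.write_text("id\tdrug\n1\tolaparib\n")
        with pytest.raises(ValueError, match="event_pts"):
            read_reports(p)

    def test_synthetic_database_round_trips_field_by_field(self, tmp_path):
        reports, _ = generate(default_config(seed=5, n_reports=1000))
        path = tmp_path / "db.tsv"
        write_reports(reports, path)
        back = read_reports(path).reports
        assert len(back) == len(reports)
        for orig, rt in zip(reports, back):
            assert orig == rt


def test_normalize_drug_lowercases_and_collapses_whitespace():
    assert normalize_drug("  Olaparib  ") == "olaparib"
    assert normalize_drug("ZEJULA") == "niraparib"
    assert normalize_drug("some  drug") == "some drug"


class TestDeduplicate:
    def test_highest_version_wins(self):
        v1 = make_report("X", version_seq=1)
        v2 = make_report("X", version_seq=2, sex="female")
        assert deduplicate([v1, v2]) == [v2]
        assert deduplicate([v2, v1]) == [v2]

    def test_distinct_ids_pass_through_as_permutation(self):
        reports = [make_report(f"R{i}") for i in range(10)]
        out = deduplicate(reports)
        assert sorted(r.report_id for r in out) == sorted(r.report_id for r in reports)
        assert len(out) == 10

    def test_receipt_date_breaks_version_ties(self):
        older = make_report("X", receipt_date=dt.date(2018, 1, 1), sex="male")
        newer = make_report("X", receipt_date=dt.date(2019, 1, 1), sex="female")
        assert deduplicate([newer, older]) == [newer]

    def test_matches_brute_force_group_by_on_synthetic_duplicates(self):
        import dataclasses
        cfg = dataclasses.replace(default_config(seed=7, n_reports=500), duplicate_rate=0.1)
        reports, truth = generate(cfg)
        assert len(reports) == 550 and len(truth.duplicates) == 50
        # oracle: group by report_id, keep max (version, receipt, position)
        groups = {}
        for idx, r in enumerate(reports):
            groups.setdefault(r.report_id, []).append(
                (r.version_seq, r.receipt_date or dt.date.min, idx))
        expected = [reports[max(g)[2]] for _, g in sorted(groups.items())]
        assert deduplicate(reports) == expected
        assert len(deduplicate(reports)) == 500

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from("abc"), st.integers(0, 3)), max_size=20))
    def test_idempotent(self, spec):
        reports = [make_report(rid, version_seq=v) for rid, v in spec]
        once = deduplicate(reports)
        assert deduplicate(once) == once


class TestRemoveAberrant:
    @pytest.mark.parametrize("start, onset, removed", [
        (dt.date(2019, 1, 2), dt.date(2019, 1, 1), True),   # onset the day before start
        (dt.date(2019, 1, 2), dt.date(2019, 1, 2), False),  # same day is plausible
        (dt.date(2019, 1, 2), None, False),                 # missing onset kept
        (None, dt.date(2019, 1, 1), False),                 # missing start kept
    ])
    def test_boundary_rules(self, start, onset, removed):
        rep = make_report(therapy_start_date=start, event_onset_date=onset)
        kept, dropped = remove_aberrant([rep])
        assert (rep in dropped) is removed

    def test_partitions_input(self, small_db):
        reports, _ = small_db
        kept, removed = remove_aberrant(reports)
        assert len(kept) + len(removed) == len(reports)


class TestFilters:
    def test_concomitant_only_mention_does_not_qualify(self):
        rep = make_report(drug="carboplatin", concomitant_drugs=("olaparib",))
        assert filter_primary_suspect([rep], {"olaparib"}) == []

    def test_full_vocabulary_is_identity(self, small_db):
        reports, _ = small_db
        vocab = {r.primary_suspect_drug for r in reports}
        assert filter_primary_suspect(reports, vocab) == list(reports)

    def test_empty_drug_set_rejected(self):
        with pytest.raises(ValueError):
            filter_primary_suspect([], set())

    def test_matches_brute_force_membership(self, small_db):
        reports, _ = small_db
        drugs = {"olaparib", "rucaparib"}
        assert filter_primary_suspect(reports, drugs) == [
            r for r in reports if r.primary_suspect_drug in drugs]

    def test_window_bounds_inclusive(self, study_window):
        at_end = make_report(receipt_date=study_window.end_date)
        past_end = make_report(receipt_date=study_window.end_date + dt.timedelta(days=1))
        at_start = make_report(receipt_date=study_window.start_date)
        assert filter_window([at_end, past_end, at_start], study_window) == [at_end, at_start]

    def test_window_matches_brute_force_on_straddling_dates(self):
        window = StudyWindow(dt.date(2018, 1, 1), dt.date(2018, 12, 31))
        reports = [make_report(f"R{i}", receipt_date=dt.date(2017, 6, 1) + dt.timedelta(days=4 * i))
                   for i in range(200)]
        expected = [r for r in reports if window.start_date <= r.receipt_date <= window.end_date]
        assert filter_window(reports, window) == expected

    def test_filters_commute_after_dedup(self, small_db, study_window):
        reports, _ = small_db
        base = deduplicate(reports)
        drugs = {"olaparib", "niraparib"}

        def aberrant(rs):
            return remove_aberrant(rs)[0]

        def suspect(rs):
            return filter_primary_suspect(rs, drugs)

        def window(rs):
            return filter_window(rs, study_window)

        outcomes = set()
        for perm in itertools.permutations([aberrant, suspect, window]):
            rs = base
            for f in perm:
                rs = f(rs)
            outcomes.add(frozenset(r.report_id for r in rs))
        assert len(outcomes) == 1
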
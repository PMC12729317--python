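"""Session metrics: CCT rule, summaries, log round trips, table schema."""

import numpy as np
import pytest

from tremorbench.metrics import (
    MalformedLogError,
    SchemaError,
    SessionEvent,
    compute_cct,
    compute_metrics,
    export_metrics_excel,
    metrics_frame,
    read_metrics_csv,
    read_session_log,
    write_metrics_csv,
    write_session_log,
)
from tremorbench.tremor import simulate_session_logs

A, B = (0, 0), (1, 1)


def ev(t, type_, cell=None, value=None, correct=None):
    return SessionEvent(t=t, type=type_, cell=cell, value=value, correct=correct)


class TestComputeCCT:
    def test_wrong_entry_does_not_reset_episode(self):
        events = [
            ev(1.0, "select", A),
            ev(2.0, "entry", A, 4, False),
            ev(3.5, "entry", A, 7, True),
        ]
        assert compute_cct(events) == {A: pytest.approx(2.5)}

    def test_final_target_rule_binds_to_last_selected_cell(self):
        events = [
            ev(0.0, "select", A),
            ev(1.0, "select", B),
            ev(4.0, "entry", B, 2, True),
        ]
        ccts = compute_cct(events)
        assert ccts == {B: pytest.approx(3.0)}
        assert A not in ccts

    def test_reselecting_same_cell_keeps_first_episode_time(self):
        events = [
            ev(0.0, "select", A),
            ev(0.5, "select", A),
            ev(2.0, "entry", A, 3, True),
        ]
        assert compute_cct(events) == {A: pytest.approx(2.0)}

    def test_zero_interval_degenerate(self):
        events = [ev(1.0, "select", A), ev(1.0, "entry", A, 3, True)]
        assert compute_cct(events) == {A: 0.0}

    def test_correct_entry_without_selection_is_malformed(self):
        with pytest.raises(MalformedLogError, match="preceding selection"):
            compute_cct([ev(1.0, "entry", A, 3, True)])

    def test_decreasing_timestamps_are_malformed(self):
        with pytest.raises(MalformedLogError, match="decrease"):
            compute_cct([ev(1.0, "select", A), ev(0.5, "entry", A, 3, True)])


class TestComputeMetrics:
    def make_session(self):
        events = [
            ev(0.0, "countdown", value="3"),
            ev(3.0, "countdown", value="Start"),
            ev(4.0, "select", A),
            ev(5.0, "entry", A, 1, False),
            ev(6.0, "entry", A, 2, True),
            ev(7.0, "select", B),
            ev(8.0, "entry", B, 9, False),
            ev(9.5, "entry", B, 3, True),
            ev(10.0, "select", (2, 2)),
            ev(11.0, "entry", (2, 2), 4, True),
            ev(12.0, "complete"),
        ]
        return events

    def test_counts_and_clock_origin(self):
        m = compute_metrics(self.make_session(), "no_tremor", "s01")
        assert m.n_completed == 3
        assert m.n_errors == 2
        assert m.total_time_s == pytest.approx(9.0)  # from the Start cue
        assert m.cct_mean_s == pytest.approx(np.mean([2.0, 2.5, 1.0]))
        assert m.cct_sd_s == pytest.approx(np.std([2.0, 2.5, 1.0], ddof=1))

    def test_cct_sum_bounded_by_total_time(self):
        m = compute_metrics(self.make_session(), "no_tremor")
        assert sum(m.cct_values) <= m.total_time_s

    def test_missing_complete_censors_total_time_only(self):
        events = [e for e in self.make_session() if e.type != "complete"]
        m = compute_metrics(events, "no_tremor")
        assert m.total_time_s is None
        assert m.n_completed == 3

    def test_empty_log_no_crash(self):
        m = compute_metrics([], "no_tremor")
        assert m.total_time_s is None and m.cct_mean_s is None
        assert m.n_errors == 0 and m.n_completed == 0

    def test_invariant_to_ignored_voice_events(self):
        events = self.make_session()
        noisy = sorted(
            events + [ev(4.5, "voice", value="banana"), ev(8.2, "voice", value="zece")],
            key=lambda e: e.t,
        )
        a = compute_metrics(events, "no_tremor")
        b = compute_metrics(noisy, "no_tremor")
        assert (a.cct_mean_s, a.total_time_s, a.n_errors, a.n_completed) == (
            b.cct_mean_s, b.total_time_s, b.n_errors, b.n_completed,
        )

    def test_generator_effects_recovered(self):
        # condition means follow the generator's effect profile to MC error
        conds = ["no_tremor", "tremor_filtered"]
        logs = simulate_session_logs(
            30, conds, [0.0, 2.0], seed=5, subject_sd=0.5, within_sd=0.2
        )
        means = {
            c: np.mean(
                [
                    compute_metrics(l.events, l.condition).cct_mean_s
                    for l in logs
                    if l.condition == c
                ]
            )
            for c in conds
        }
        assert means["tremor_filtered"] - means["no_tremor"] == pytest.approx(2.0, abs=0.4)


class TestPersistence:
    def test_session_log_round_trip(self, tmp_path):
        events = TestComputeMetrics().make_session()
        record = compute_metrics(events, "tremor_filtered", "s07")
        path = tmp_path / "session.jsonl"
        write_session_log(record, events, path)
        back_record, back_events = read_session_log(path)
        assert back_record.subject == "s07"
        assert back_record.cct_mean_s == pytest.approx(record.cct_mean_s)
        assert len(back_events) == len(events)
        assert [e.t for e in back_events] == [e.t for e in events]

    def test_parse_error_reports_line_number(self, tmp_path):
        events = TestComputeMetrics().make_session()
        record = compute_metrics(events, "no_tremor")
        path = tmp_path / "bad.jsonl"
        write_session_log(record, events, path)
        with open(path, "a", encoding="utf-8") as fh:
            fh.write("{not json}\n")
        with pytest.raises(MalformedLogError, match=f"line {len(events) + 2}"):
            read_session_log(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "headless.jsonl"
        path.write_text('{"t": 0.0, "type": "complete"}\n')
        with pytest.raises(MalformedLogError, match="header"):
            read_session_log(path)

    def test_metrics_csv_45_rows_and_round_trip(self, tmp_path):
        logs = simulate_session_logs(
            15,
            ["no_tremor", "tremor_unfiltered", "tremor_filtered"],
            [0.0, 2.0, 1.0],
            seed=1,
        )
        records = [compute_metrics(l.events, l.condition, l.subject) for l in logs]
        path = tmp_path / "metrics.csv"
        write_metrics_csv(records, path)
        df = read_metrics_csv(path)
        assert len(df) == 45
        assert df["condition"].nunique() == 3

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "broken.csv"
        path.write_text("subject,condition\ns01,no_tremor\n")
        with pytest.raises(SchemaError, match="missing columns"):
            read_metrics_csv(path)

    def test_excel_export_readable(self, tmp_path):
        import pandas as pd

        logs = simulate_session_logs(2, ["no_tremor"], [0.0], seed=2)
        records = [compute_metrics(l.events, l.condition, l.subject) for l in logs]
        path = tmp_path / "metrics.xlsx"
        export_metrics_excel(records, path)
        df = pd.read_excel(path)
        assert len(df) == 2 and "cct_mean_s" in df.columns
        assert metrics_frame(records)["cct_mean_s"].tolist() == pytest.approx(
            df["cct_mean_s"].tolist()
        )
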
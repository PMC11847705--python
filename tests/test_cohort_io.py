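"""Event loading, observation windows, and cohort assembly."""

import logging
import math

import numpy as np
import pytest

from comet.cohort_io import (AnchorDates, FormatError, LinkageError,
                             PatientRecord, assemble_cohort, cancer_window,
                             load_bundle, load_events, pregnancy_window,
                             save_bundle)


def write_events(tmp_path, rows, name="events.csv"):
    path = tmp_path / name
    lines = ["patient_id,concept_id,date,source_table"]
    lines += [",".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadEvents:
    def test_drops_concept_id_zero(self, tmp_path):
        path = write_events(tmp_path, [
            ("p1", 101, 5, "measurement"),
            ("p1", 0, 6, "measurement"),
            ("p2", 102, 7, "drug_exposure"),
        ])
        ev = load_events(path)
        assert len(ev) == 2
        assert "0" not in set(ev["concept_id"])

    def test_empty_file_gives_empty_collection(self, tmp_path):
        ev = load_events(write_events(tmp_path, []))
        assert len(ev) == 0

    def test_unknown_source_table_dropped_with_warning(self, tmp_path, caplog):
        path = write_events(tmp_path, [
            ("p1", 101, 5, "measurement"),
            ("p1", 102, 5, "visit_occurrence"),
        ])
        with caplog.at_level(logging.WARNING):
            ev = load_events(path)
        assert len(ev) == 1
        assert any("visit_occurrence" in m for m in caplog.messages)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,concept_id,source_table\np1,1,measurement\n")
        with pytest.raises(FormatError, match="date"):
            load_events(path)

    def test_unparseable_date_reports_line(self, tmp_path):
        path = write_events(tmp_path, [("p1", 101, "notadate", "measurement")])
        with pytest.raises(FormatError, match="line 2"):
            load_events(path)

    def test_iso_dates_become_ordinal_days(self, tmp_path):
        path = write_events(tmp_path, [("p1", 101, "2020-01-02", "observation"),
                                       ("p1", 102, "2020-01-01", "observation")])
        ev = load_events(path)
        assert ev["event_date"].max() - ev["event_date"].min() == 1


class TestWindows:
    def test_pregnancy_omics_window_spans_280_days_to_sampling(self):
        a = AnchorDates(delivery_date=280, sampling_date=240)
        assert pregnancy_window(a, "omics", np.random.default_rng(0)) == (0, 240)

    def test_pregnancy_sampling_at_delivery_boundary(self):
        a = AnchorDates(delivery_date=300, sampling_date=300)
        assert pregnancy_window(a, "omics", np.random.default_rng(0)) == (20, 300)

    def test_pretraining_cut_is_within_last_100_days_and_reproducible(self):
        a = AnchorDates(delivery_date=280)
        ends = {pregnancy_window(a, "pretraining",
                                 np.random.default_rng(s))[1]
                for s in range(200)}
        assert all(180 <= e <= 280 for e in ends)
        assert len(ends) > 50  # spreads across the span
        w1 = pregnancy_window(a, "pretraining", np.random.default_rng(42))
        w2 = pregnancy_window(a, "pretraining", np.random.default_rng(42))
        assert w1 == w2

    def test_sampling_before_pregnancy_start_rejected(self):
        a = AnchorDates(delivery_date=280, sampling_date=-10)
        with pytest.raises(ValueError, match="invalid cohort"):
            pregnancy_window(a, "omics", np.random.default_rng(0))

    def test_cancer_windows_keep_all_history(self):
        assert cancer_window(AnchorDates(sampling_date=500), "omics") == \
            (-math.inf, 500)
        assert cancer_window(AnchorDates(diagnosis_date=400), "pretraining") == \
            (-math.inf, 400)

    def test_cancer_window_requires_an_anchor(self):
        with pytest.raises(ValueError):
            cancer_window(AnchorDates(), "pretraining")


@pytest.fixture()
def pregnancy_inputs(tmp_path):
    import pandas as pd
    rows = []
    anchors = {}
    for i in range(10):
        pid = f"p{i}"
        anchors[pid] = AnchorDates(delivery_date=280)
        rows += [(pid, 100 + i, 150, "condition_occurrence"),
                 (pid, 200 + i, 260, "measurement")]
    events = load_events(write_events(tmp_path, rows))
    samples = pd.DataFrame({
        "sample_id": ["s0", "s1", "s2", "s3"],
        "patient_id": ["p0", "p1", "p2", "p2"],
        "sampling_date": [240, 250, 230, 260],
    })
    omics = pd.DataFrame({"sample_id": ["s0", "s1", "s2", "s3"],
                          "prot1": [1.0, 2.0, 3.0, 4.0],
                          "prot2": [0.5, 0.6, 0.7, 0.8]})
    return events, anchors, omics, samples


class TestAssemble:
    def test_partition_counts(self, pregnancy_inputs):
        events, anchors, omics, samples = pregnancy_inputs
        bundle = assemble_cohort(events, anchors, omics, samples, None,
                                 "pregnancy", rng=np.random.default_rng(0))
        assert len(bundle.pretraining) == 7
        assert len(bundle.omics) == 4  # p2 has two samples
        patients = {r.patient_id for r in bundle.records}
        assert patients == set(anchors)

    def test_pregnancy_outcome_is_days_to_delivery(self, pregnancy_inputs):
        events, anchors, omics, samples = pregnancy_inputs
        bundle = assemble_cohort(events, anchors, omics, samples, None,
                                 "pregnancy", rng=np.random.default_rng(0))
        s0 = next(r for r in bundle.omics if r.record_id == "s0")
        assert s0.outcome == 280 - 240 == 40

    def test_multi_sample_patient_yields_multiple_records(self, pregnancy_inputs):
        events, anchors, omics, samples = pregnancy_inputs
        bundle = assemble_cohort(events, anchors, omics, samples, None,
                                 "pregnancy", rng=np.random.default_rng(0))
        p2 = [r for r in bundle.omics if r.patient_id == "p2"]
        assert len(p2) == 2 and len({r.record_id for r in p2}) == 2

    def test_no_event_leaks_past_window_end(self, pregnancy_inputs):
        events, anchors, omics, samples = pregnancy_inputs
        bundle = assemble_cohort(events, anchors, omics, samples, None,
                                 "pregnancy", rng=np.random.default_rng(1))
        for r in bundle.records:
            if r.windowed_events:
                assert max(d for d, _ in r.windowed_events) <= r.window[1]

    def test_unlinked_sample_raises(self, pregnancy_inputs):
        import pandas as pd
        events, anchors, omics, samples = pregnancy_inputs
        bad = pd.concat([omics, pd.DataFrame({"sample_id": ["sX"],
                                              "prot1": [9.9],
                                              "prot2": [9.9]})])
        with pytest.raises(LinkageError, match="sX"):
            assemble_cohort(events, anchors, bad, samples, None,
                            "pregnancy", rng=np.random.default_rng(0))

    def test_windowing_is_deterministic_given_seed(self, pregnancy_inputs):
        events, anchors, omics, samples = pregnancy_inputs
        b1 = assemble_cohort(events, anchors, omics, samples, None,
                             "pregnancy", rng=np.random.default_rng(3))
        b2 = assemble_cohort(events, anchors, omics, samples, None,
                             "pregnancy", rng=np.random.default_rng(3))
        assert [r.window for r in b1.pretraining] == \
            [r.window for r in b2.pretraining]


def test_bundle_roundtrip(tmp_path, tiny_bundle):
    bundle, _ = tiny_bundle
    save_bundle(bundle, tmp_path / "bundle")
    back = load_bundle(tmp_path / "bundle")
    assert len(back.pretraining) == len(bundle.pretraining)
    assert len(back.omics) == len(bundle.omics)
    assert back.analyte_names == bundle.analyte_names
    for a, b in zip(bundle.omics, back.omics):
        assert a.record_id == b.record_id
        assert a.windowed_events == b.windowed_events
        assert np.allclose(a.omics_vector, b.omics_vector)
        assert a.outcome == pytest.approx(b.outcome)


def test_record_invariant_omics_vector_matches_cohort():
    with pytest.raises(ValueError):
        PatientRecord(patient_id="p", windowed_events=[], outcome=0.0,
                      cohort="omics", omics_vector=None)
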
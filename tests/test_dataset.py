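"""Event-record I/O, unit handling and the predose-outlier rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meropk.dataset import (
    CovariateSet,
    DatasetFormatError,
    DatasetValidationError,
    DoseEvent,
    Observation,
    PKDataset,
    SubjectRecord,
    exclude_predose_positive,
    read_dataset,
    write_dataset,
)

from conftest import make_subject


def _write_csv(tmp_path, text, name="data.csv"):
    p = tmp_path / name
    p.write_text(text.strip() + "\n")
    return p


BASIC = """
ID,TIME,AMT,RATE,DV,EVID,MDV,ALB
1,0,1000,1000,.,1,1,24.6
1,0.5,.,.,12.3,0,0,24.6
1,2,.,.,6.1,0,0,24.6
"""


class TestReadDataset:
    def test_three_row_table(self, tmp_path):
        ds = read_dataset(_write_csv(tmp_path, BASIC), lloq=0.1)
        assert len(ds) == 1
        s = ds.subjects[0]
        assert len(s.doses) == 1 and len(s.observations) == 2
        assert s.doses[0].duration == pytest.approx(1.0)
        assert s.covariates.albumin == 24.6

    def test_minutes_converted_to_hours(self, tmp_path):
        text = BASIC.replace("1,0.5,.,.,12.3,0,0,24.6", "1,30,.,.,12.3,0,0,24.6").replace(
            "1,2,.,.,6.1,0,0,24.6", "1,480,.,.,6.1,0,0,24.6"
        )
        # RATE in mg/min for a 60-min infusion of 1000 mg
        text = text.replace("1,0,1000,1000,.,1,1,24.6", "1,0,1000,16.6666666666666667,.,1,1,24.6")
        ds = read_dataset(_write_csv(tmp_path, text), time_unit="min")
        s = ds.subjects[0]
        assert s.observations[1].time == pytest.approx(8.0)
        assert s.observations[0].time == pytest.approx(0.5)
        assert s.doses[0].duration == pytest.approx(1.0)

    def test_below_lloq_flagged(self, tmp_path):
        text = BASIC.replace("1,2,.,.,6.1,0,0,24.6", "1,2,.,.,0.05,0,0,24.6")
        ds = read_dataset(_write_csv(tmp_path, text), lloq=0.1)
        o = ds.subjects[0].observations[1]
        assert o.below_lloq and o.concentration == 0.05

    def test_missing_column_is_format_error(self, tmp_path):
        lines = [",".join(row.split(",")[1:]) for row in BASIC.strip().splitlines()]
        with pytest.raises(DatasetFormatError):
            read_dataset(_write_csv(tmp_path, "\n".join(lines)))

    def test_negative_dv_is_validation_error(self, tmp_path):
        text = BASIC.replace("12.3", "-1.0")
        with pytest.raises(DatasetValidationError):
            read_dataset(_write_csv(tmp_path, text))

    def test_mdv_rows_ignored(self, tmp_path):
        text = BASIC.replace("1,2,.,.,6.1,0,0,24.6", "1,2,.,.,6.1,0,1,24.6")
        ds = read_dataset(_write_csv(tmp_path, text))
        assert len(ds.subjects[0].observations) == 1


class TestDomainTypes:
    def test_dose_rate_identity(self):
        d = DoseEvent(start_time=0.0, amount=1000.0, duration=0.5)
        assert d.rate * d.duration == pytest.approx(d.amount, rel=1e-9)

    @pytest.mark.parametrize("kwargs", [
        dict(start_time=0.0, amount=-1.0, duration=1.0),
        dict(start_time=0.0, amount=1000.0, duration=0.0),
    ])
    def test_invalid_dose_rejected(self, kwargs):
        with pytest.raises(DatasetValidationError):
            DoseEvent(**kwargs)

    def test_negative_concentration_rejected(self):
        with pytest.raises(DatasetValidationError):
            Observation(time=1.0, concentration=-0.5)

    def test_unsorted_times_rejected(self):
        with pytest.raises(DatasetValidationError):
            make_subject("X", [2.0, 1.0], [5.0, 8.0])

    def test_duplicate_ids_rejected(self):
        s = make_subject("A", [1.0], [5.0])
        with pytest.raises(DatasetValidationError):
            PKDataset(subjects=(s, s))


class TestExcludePredosePositive:
    def test_first_dose_positive_time_zero_excluded(self):
        s = make_subject("A", [0.0, 1.0], [1.2, 20.0])
        ds = PKDataset(subjects=(s,))
        out, report = exclude_predose_positive(ds)
        o = out.subjects[0].observations[0]
        assert o.excluded and o.exclusion_reason == "predose-positive"
        assert len(report) == 1
        assert report.records[0] == ("A", 0.0, 1.2)

    def test_ongoing_therapy_time_zero_kept(self):
        doses = tuple(DoseEvent(8.0 * k, 1000.0, 1.0) for k in range(4))
        s = make_subject("B", [24.0, 25.0], [8.0, 30.0], doses=doses)
        out, report = exclude_predose_positive(PKDataset(subjects=(s,)))
        assert len(report) == 0
        assert not any(o.excluded for o in out.subjects[0].observations)

    def test_no_time_zero_records_unchanged(self):
        s = make_subject("C", [0.5, 1.0], [10.0, 20.0])
        ds = PKDataset(subjects=(s,))
        out, report = exclude_predose_positive(ds)
        assert len(report) == 0
        assert out.subjects[0].observations == s.observations

    def test_idempotent_and_preserves_other_records(self):
        s = make_subject("A", [0.0, 1.0, 2.0], [0.7, 20.0, 12.0])
        ds = PKDataset(subjects=(s,))
        once, r1 = exclude_predose_positive(ds)
        twice, r2 = exclude_predose_positive(once)
        assert once == twice
        assert len(r1) == len(r2) == 1
        for o1, o2 in zip(once.subjects[0].observations[1:], s.observations[1:]):
            assert o1 == o2


cov_strategy = st.fixed_dictionaries(
    {"albumin": st.floats(15.0, 32.0), "weight": st.floats(60.0, 100.0)}
)


@st.composite
def dataset_strategy(draw):
    n_sub = draw(st.integers(1, 4))
    subjects = []
    for i in range(n_sub):
        n_dose = draw(st.integers(1, 3))
        doses = tuple(
            DoseEvent(start_time=8.0 * k, amount=draw(st.floats(100.0, 2000.0)),
                      duration=draw(st.floats(0.25, 3.0)))
            for k in range(n_dose)
        )
        n_obs = draw(st.integers(0 if i else 1, 5))
        times = sorted(draw(st.lists(st.floats(0.0, 30.0), min_size=n_obs, max_size=n_obs)))
        obs = tuple(
            Observation(
                time=t,
                concentration=draw(st.floats(0.0, 100.0)),
                below_lloq=False,
                excluded=draw(st.booleans()),
                exclusion_reason="",
            )
            for t in times
        )
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i}", doses=doses, observations=obs,
                covariates=CovariateSet(draw(cov_strategy)),
            )
        )
    return PKDataset(subjects=tuple(subjects), lloq=0.1)


class TestRoundTrip:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(ds=dataset_strategy())
    def test_write_read_identity(self, ds, tmp_path_factory):
        path = tmp_path_factory.mktemp("rt") / "ds.csv"
        write_dataset(ds, path)
        back = read_dataset(path, lloq=ds.lloq)
        assert len(back) == len(ds)
        for s0, s1 in zip(ds.subjects, back.subjects):
            assert s0.subject_id == s1.subject_id
            assert len(s0.doses) == len(s1.doses)
            for d0, d1 in zip(s0.doses, s1.doses):
                assert d0.start_time == pytest.approx(d1.start_time, abs=1e-12)
                assert d0.amount == pytest.approx(d1.amount, abs=1e-12)
                assert d0.duration == pytest.approx(d1.duration, rel=1e-12)
            assert len(s0.observations) == len(s1.observations)
            for o0, o1 in zip(s0.observations, s1.observations):
                assert o0.time == pytest.approx(o1.time, abs=1e-12)
                assert o0.concentration == pytest.approx(o1.concentration, abs=1e-12)
                assert o0.excluded == o1.excluded
            for k, v in s0.covariates.values.items():
                assert s1.covariates.get(k) == pytest.approx(v, abs=1e-12)

    def test_excluded_flag_round_trip(self, tmp_path):
        s = make_subject("A", [0.0, 1.0], [1.2, 20.0])
        ds, _ = exclude_predose_positive(PKDataset(subjects=(s,)))
        path = tmp_path / "excl.csv"
        write_dataset(ds, path)
        back = read_dataset(path)
        o = back.subjects[0].observations[0]
        assert o.excluded and o.exclusion_reason == "predose-positive"

    def test_empty_observation_subject_round_trip(self, tmp_path):
        s1 = make_subject("A", [1.0], [5.0])
        s2 = SubjectRecord(
            subject_id="B", doses=(DoseEvent(0.0, 1000.0, 1.0),), observations=(),
            covariates=CovariateSet({"albumin": 20.0}),
        )
        path = tmp_path / "empty.csv"
        write_dataset(PKDataset(subjects=(s1, s2)), path)
        back = read_dataset(path)
        assert len(back.subject("B").observations) == 0
        assert len(back.subject("B").doses) == 1
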
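"""Beat-series data model, unit conversion, and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avec import (
    BeatSeries,
    CorrectionLog,
    Edit,
    convert_unit,
    read_csv,
    read_hrm,
    read_log,
    write_csv,
    write_hrm,
    write_log,
)
from avec.io import read_manual_edits
from avec.synthetic import SyntheticConfig, generate_clean


class TestBeatSeries:
    def test_rejects_nonpositive_and_nonfinite(self):
        with pytest.raises(ValueError, match="positive"):
            BeatSeries(values=np.array([600.0, 0.0]), unit="ms")
        with pytest.raises(ValueError, match="positive"):
            BeatSeries(values=np.array([600.0, -5.0]), unit="ms")
        with pytest.raises(ValueError, match="finite"):
            BeatSeries(values=np.array([600.0, np.nan]), unit="ms")
        with pytest.raises(ValueError, match="unit"):
            BeatSeries(values=np.array([600.0]), unit="seconds")

    def test_device_range_enforced_in_bpm_terms(self):
        # 60000/5000 = 12 bpm < 15 bpm floor of the Polar logger
        with pytest.raises(ValueError, match="device range"):
            BeatSeries(
                values=np.array([5000.0]), unit="ms", device_range=(15.0, 240.0)
            )
        BeatSeries(values=np.array([600.0]), unit="ms", device_range=(15.0, 240.0))

    def test_values_are_read_only(self):
        s = BeatSeries(values=np.array([600.0]), unit="ms")
        with pytest.raises(ValueError):
            s.values[0] = 700.0


class TestUnitConversion:
    def test_ms_to_bpm(self):
        s = BeatSeries(values=np.array([600.0]), unit="ms")
        assert convert_unit(s, "bpm").values[0] == pytest.approx(100.0)

    def test_bpm_to_ms(self):
        s = BeatSeries(values=np.array([120.0]), unit="bpm")
        assert convert_unit(s, "ms").values[0] == pytest.approx(500.0)

    def test_same_unit_is_identity(self):
        s = BeatSeries(values=np.array([600.0]), unit="ms")
        assert convert_unit(s, "ms") is s

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=250.0, max_value=4000.0, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_conversion_is_an_involution(self, values):
        s = BeatSeries(values=np.array(values), unit="ms")
        back = s.to("bpm").to("ms")
        rel = np.abs(back.values - s.values) / s.values
        assert rel.max() < 1e-12


class TestCsv:
    def test_read_simple_rows(self, tmp_path):
        p = tmp_path / "rr.csv"
        p.write_text("rr_ms\n600\n650\n600\n")
        s = read_csv(p, unit="ms")
        assert s.unit == "ms"
        np.testing.assert_allclose(s.values, [600, 650, 600])

    def test_zero_value_reports_row(self, tmp_path):
        p = tmp_path / "rr.csv"
        p.write_text("rr_ms\n600\n0\n")
        with pytest.raises(ValueError, match="row 3"):
            read_csv(p, unit="ms")

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "rr.csv"
        p.write_text("rr_ms\n")
        with pytest.raises(ValueError, match="no data"):
            read_csv(p, unit="ms")

    def test_named_and_positional_columns(self, tmp_path):
        p = tmp_path / "two.csv"
        p.write_text("hr,rr\n100,600\n120,500\n")
        np.testing.assert_allclose(read_csv(p, "ms", column="rr").values, [600, 500])
        np.testing.assert_allclose(read_csv(p, "bpm", column=0).values, [100, 120])
        with pytest.raises(ValueError, match="no column"):
            read_csv(p, "ms", column="missing")

    def test_roundtrip_of_generated_series(self, tmp_path):
        series = generate_clean(SyntheticConfig(n_beats=300, seed=7))
        p = tmp_path / "series.csv"
        write_csv(series, p)
        back = read_csv(p, unit="bpm")
        np.testing.assert_array_equal(back.values, series.values)


class TestHrm:
    def test_minimal_hrdata_section(self, tmp_path):
        p = tmp_path / "f.hrm"
        p.write_text("[HRData]\n600\n650\n")
        s = read_hrm(p)
        assert s.unit == "ms"
        np.testing.assert_allclose(s.values, [600, 650])

    def test_headers_before_hrdata_are_ignored(self, tmp_path):
        p = tmp_path / "f.hrm"
        p.write_text("[Params]\nVersion=106\n\n[HRData]\n600\n650\n")
        np.testing.assert_allclose(read_hrm(p).values, [600, 650])

    def test_missing_section_is_format_error(self, tmp_path):
        p = tmp_path / "f.hrm"
        p.write_text("[Params]\nVersion=106\n600\n")
        with pytest.raises(ValueError, match=r"\[HRData\]"):
            read_hrm(p)

    def test_non_integer_line_is_parse_error(self, tmp_path):
        p = tmp_path / "f.hrm"
        p.write_text("[HRData]\n600\nsix-fifty\n")
        with pytest.raises(ValueError, match="non-integer"):
            read_hrm(p)

    def test_multicolumn_rows_rejected(self, tmp_path):
        p = tmp_path / "f.hrm"
        p.write_text("[HRData]\n600 12 0\n")
        with pytest.raises(ValueError, match="multi-column"):
            read_hrm(p)

    def test_roundtrip_of_generated_series(self, tmp_path):
        series = generate_clean(SyntheticConfig(n_beats=200, seed=11)).to("ms")
        rounded = series.with_values(np.rint(series.values))
        p = tmp_path / "f.hrm"
        write_hrm(rounded, p)
        np.testing.assert_array_equal(read_hrm(p).values, rounded.values)


class TestCorrectionLog:
    def _log(self):
        return CorrectionLog(
            edits=(
                Edit(index=2, original_value=110.0, action="delete", method="visual"),
                Edit(
                    index=5,
                    original_value=95.0,
                    action="replace",
                    replacement_value=100.5,
                    method="algorithm",
                ),
            ),
            source_length=8,
        )

    def test_replay_reproduces_corrections(self):
        src = BeatSeries(
            values=np.array([100, 101, 110, 99, 100, 95, 101, 100], dtype=float),
            unit="bpm",
        )
        out = self._log().replay(src)
        np.testing.assert_allclose(out.values, [100, 101, 99, 100, 100.5, 101, 100])

    def test_replay_never_lengthens(self):
        src = BeatSeries(values=np.linspace(90, 110, 8), unit="bpm")
        log = CorrectionLog(
            edits=(Edit(index=0, original_value=90.0, action="delete"),),
            source_length=8,
        )
        assert len(log.replay(src)) <= len(src)

    def test_duplicate_or_out_of_range_index_rejected(self):
        e = Edit(index=2, original_value=1.0, action="delete")
        with pytest.raises(ValueError, match="unique"):
            CorrectionLog(edits=(e, e), source_length=8)
        with pytest.raises(ValueError, match="outside"):
            CorrectionLog(edits=(e,), source_length=2)

    def test_replay_checks_original_values(self):
        src = BeatSeries(values=np.full(8, 50.0), unit="bpm")
        with pytest.raises(ValueError, match="does not match"):
            self._log().replay(src)

    def test_edit_validation(self):
        with pytest.raises(ValueError, match="replacement_value"):
            Edit(index=0, original_value=1.0, action="replace")
        with pytest.raises(ValueError, match="delete"):
            Edit(index=0, original_value=1.0, action="delete", replacement_value=2.0)

    def test_log_roundtrip(self, tmp_path):
        log = self._log()
        p = tmp_path / "log.csv"
        write_log(log, p)
        assert read_log(p) == log

    def test_empty_log_roundtrip(self, tmp_path):
        log = CorrectionLog(edits=(), source_length=5, excluded=True)
        p = tmp_path / "log.csv"
        write_log(log, p)
        back = read_log(p)
        assert back == log and back.excluded

    def test_random_log_roundtrip(self, tmp_path, rng):
        for trial in range(20):
            n = int(rng.integers(5, 60))
            k = int(rng.integers(0, min(n, 6)))
            idx = rng.choice(n, size=k, replace=False)
            edits = []
            for i in idx:
                if rng.random() < 0.5:
                    edits.append(
                        Edit(int(i), float(rng.uniform(60, 180)), "delete",
                             method="manual")
                    )
                else:
                    edits.append(
                        Edit(int(i), float(rng.uniform(60, 180)), "replace",
                             replacement_value=float(rng.uniform(60, 180)))
                    )
            log = CorrectionLog(edits=tuple(edits), source_length=n)
            p = tmp_path / f"log{trial}.csv"
            write_log(log, p)
            assert read_log(p) == log


def test_manual_edit_file(tmp_path):
    p = tmp_path / "edits.csv"
    p.write_text("index,reason\n14,sharp peak\n239,discontinuity\n")
    assert read_manual_edits(p) == [14, 239]
    bad = tmp_path / "bad.csv"
    bad.write_text("beat\n3\n")
    with pytest.raises(ValueError, match="index"):
        read_manual_edits(bad)
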
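"""WFDB round trips, lead scaling, windowing and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecggan import (
    DegenerateInputError,
    ECGRecord,
    FormatError,
    SynthConfig,
    ValidationError,
    extract_lead,
    generate_ecg,
    minmax_normalize,
    read_sequence_text,
    read_wfdb_record,
    segment_windows,
    to_ecg_record,
    write_sequence_text,
    write_wfdb_record,
)


class TestWFDB:
    def test_two_lead_650000_sample_round_trip(self, tmp_path, rng):
        """A full-length two-lead record (650,000 samples per lead, the
        MIT-BIH size) survives a format-212 write/read cycle bit-for-bit."""
        n = 650_000
        leads = [
            rng.integers(-2048, 2048, size=n, dtype=np.int32),
            rng.integers(-2048, 2048, size=n, dtype=np.int32),
        ]
        record = ECGRecord(record_id="r650k", sampling_rate=360.0, leads=leads)
        header = write_wfdb_record(record, tmp_path)
        back = read_wfdb_record(header)
        assert back.n_leads == 2
        assert back.n_samples == n
        assert back.sampling_rate == 360.0
        for orig, rt in zip(leads, back.leads):
            np.testing.assert_array_equal(orig, rt)

    @pytest.mark.parametrize("fmt", [212, 16])
    def test_single_lead_round_trip_with_annotations(self, tmp_path, rng, fmt):
        samples = rng.integers(-500, 500, size=1001, dtype=np.int32)
        anns = [(10, "N"), (400, "V"), (990, "N")]
        record = ECGRecord("s1", 360.0, [samples], annotations=anns)
        back = read_wfdb_record(write_wfdb_record(record, tmp_path, fmt=fmt))
        np.testing.assert_array_equal(back.leads[0], samples)
        assert back.annotations == anns

    def test_annotation_large_interval_uses_skip(self, tmp_path):
        record = ECGRecord(
            "s2", 360.0, [np.arange(10, dtype=np.int32)],
            annotations=[(5, "N"), (90_000, "V")],
        )
        back = read_wfdb_record(write_wfdb_record(record, tmp_path))
        assert back.annotations == [(5, "N"), (90_000, "V")]

    def test_missing_dat_raises_io_error(self, tmp_path):
        header = tmp_path / "x.hea"
        header.write_text("x 1 360 100\nx.dat 212 200(0)/mV 12 0 0 0 0 lead0\n")
        with pytest.raises(FileNotFoundError, match="x.dat"):
            read_wfdb_record(header)

    def test_missing_header_raises_io_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_wfdb_record(tmp_path / "nothere.hea")

    def test_corrupt_checksum_raises_format_error(self, tmp_path, rng):
        samples = rng.integers(-100, 100, size=64, dtype=np.int32)
        header = write_wfdb_record(ECGRecord("c1", 360.0, [samples]), tmp_path)
        lines = header.read_text().splitlines()
        tokens = lines[1].split()
        tokens[6] = str(int(tokens[6]) + 1)
        lines[1] = " ".join(tokens)
        header.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match="checksum"):
            read_wfdb_record(header)

    def test_truncated_dat_raises_format_error(self, tmp_path, rng):
        samples = rng.integers(-100, 100, size=100, dtype=np.int32)
        header = write_wfdb_record(ECGRecord("t1", 360.0, [samples]), tmp_path)
        dat = tmp_path / "t1.dat"
        dat.write_bytes(dat.read_bytes()[:30])
        with pytest.raises(FormatError, match="fewer samples"):
            read_wfdb_record(header)

    def test_synthetic_record_round_trip(self, tmp_path):
        """A quantized synthetic PQRST record written by this package's own
        writer reads back to identical samples."""
        cfg = SynthConfig(duration=5.0, seed=4)
        record = to_ecg_record(generate_ecg(cfg), cfg, "synth-rt")
        back = read_wfdb_record(write_wfdb_record(record, tmp_path))
        np.testing.assert_array_equal(back.leads[0], record.leads[0])

    def test_unequal_lead_lengths_rejected(self):
        with pytest.raises(ValidationError, match="unequal"):
            ECGRecord("bad", 360.0, [np.zeros(10), np.zeros(11)])


class TestExtractLead:
    def test_divides_by_gain_constant(self):
        record = ECGRecord("g", 360.0, [np.array([400, 0, 200, -200, 100])])
        np.testing.assert_allclose(
            extract_lead(record, 0), [2.0, 0.0, 1.0, -1.0, 0.5]
        )

    def test_linearity_exact(self, rng):
        # integer sample values, the ADC domain: 200*x / 200 recovers x exactly
        x = rng.integers(-2048, 2048, size=256).astype(np.float64)
        record = ECGRecord("lin", 360.0, [200.0 * x])
        np.testing.assert_array_equal(extract_lead(record, 0), x)

    def test_custom_gain(self):
        record = ECGRecord("cg", 360.0, [np.array([100])])
        assert extract_lead(record, 0, adc_gain=100.0)[0] == 1.0

    def test_out_of_range_lead_raises(self):
        record = ECGRecord("one", 360.0, [np.zeros(4)])
        with pytest.raises(IndexError):
            extract_lead(record, 1)


class TestSegmentWindows:
    def test_full_record_window_count(self):
        """floor(650000 / 3120) = 208 non-overlapping training windows."""
        windows = segment_windows(np.zeros(650_000), 3120)
        assert len(windows) == 208
        assert windows[0].start_index == 0
        assert windows[-1].start_index == 207 * 3120

    @pytest.mark.parametrize(
        "n,expected", [(3120, 1), (3119, 0), (6240, 2), (6239, 1)]
    )
    def test_boundary_counts(self, n, expected):
        assert len(segment_windows(np.zeros(n), 3120)) == expected

    def test_nonoverlapping_windows_partition_prefix(self, rng):
        x = rng.normal(size=1000)
        windows = segment_windows(x, 64)
        reconstructed = np.concatenate([w.values for w in windows])
        np.testing.assert_array_equal(reconstructed, x[: len(reconstructed)])

    def test_overlapping_hop(self, rng):
        x = rng.normal(size=100)
        windows = segment_windows(x, 40, hop=20)
        assert [w.start_index for w in windows] == [0, 20, 40, 60]
        np.testing.assert_array_equal(windows[1].values, x[20:60])

    def test_invalid_params_raise(self):
        with pytest.raises(ValidationError):
            segment_windows(np.zeros(10), 0)
        with pytest.raises(ValidationError):
            segment_windows(np.zeros(10), 5, hop=0)


class TestMinmaxNormalize:
    def test_default_maps_to_unit_interval(self):
        np.testing.assert_allclose(
            minmax_normalize([0.0, 5.0, 10.0]), [0.0, 0.5, 1.0]
        )

    def test_as_printed_maps_to_negative_unit_interval(self):
        np.testing.assert_allclose(
            minmax_normalize([0.0, 5.0, 10.0], mode="as_printed"),
            [-1.0, -0.5, 0.0],
        )

    def test_constant_sequence_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            minmax_normalize([3.0, 3.0, 3.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=40,
        ).filter(lambda v: max(v) > min(v))
    )
    def test_unit_mode_attains_endpoints_and_is_idempotent(self, values):
        out = minmax_normalize(values)
        assert out.min() == 0.0
        assert out.max() == 1.0
        np.testing.assert_allclose(minmax_normalize(out), out, atol=1e-12)


class TestSequenceText:
    def test_round_trip_with_sidecar(self, tmp_path, rng):
        values = rng.normal(size=100)
        path = write_sequence_text(
            tmp_path / "seq.txt", values, {"record_id": "abc", "sampling_rate": 360}
        )
        back, meta = read_sequence_text(path)
        np.testing.assert_allclose(back, values, atol=1e-9)
        assert meta["record_id"] == "abc"
        assert meta["n_samples"] == 100

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_sequence_text(tmp_path / "none.txt")
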
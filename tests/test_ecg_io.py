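import numpy as np
import pandas as pd
import pytest

import vcgtwist as v
from vcgtwist.errors import (
    FilterConfigError,
    FormatError,
    LeadSetError,
    ResampleError,
    SignalQualityError,
)


def _record(n_leads=8, n_samples=5000, fs=500.0, rng=None, labels=None):
    rng = rng or np.random.default_rng(0)
    labels = labels or v.INDEPENDENT_LEADS[:n_leads]
    return v.EcgRecord(labels, 100 * rng.standard_normal((n_leads, n_samples)), fs)


class TestRecordValidation:
    def test_rejects_nonfinite_samples(self):
        sig = np.zeros((3, 100))
        sig[1, 50] = np.nan
        with pytest.raises(SignalQualityError):
            v.EcgRecord(("I", "II", "V1"), sig, 500.0)

    def test_rejects_duplicate_labels(self):
        with pytest.raises(LeadSetError):
            v.EcgRecord(("I", "I", "V1"), np.zeros((3, 10)), 500.0)

    def test_rejects_fewer_than_three_leads(self):
        with pytest.raises(LeadSetError):
            v.EcgRecord(("I", "II"), np.zeros((2, 10)), 500.0)


class TestReadWrite:
    def test_round_trip_is_bit_identical(self, tmp_path):
        rec = _record()
        path = tmp_path / "rec.csv"
        v.write_ecg(rec, path)
        back = v.read_ecg(path)
        assert back.lead_labels == rec.lead_labels
        assert back.fs == rec.fs
        np.testing.assert_array_equal(back.signal, rec.signal)

    def test_fs_inferred_from_time_column(self, tmp_path):
        rec = _record(n_samples=5000, fs=500.0)
        path = tmp_path / "rec.csv"
        v.write_ecg(rec, path)
        back = v.read_ecg(path)
        assert back.fs == 500.0 and back.n_samples == 5000

    def test_csv_without_time_column_needs_fs(self, tmp_path):
        rec = _record()
        path = tmp_path / "rec.csv"
        v.write_ecg(rec, path, include_time=False)
        with pytest.raises(FormatError):
            v.read_ecg(path)
        back = v.read_ecg(path, fs=500.0)
        np.testing.assert_array_equal(back.signal, rec.signal)

    def test_unknown_units_need_gain(self, tmp_path):
        rec = _record()
        path = tmp_path / "rec.csv"
        v.write_ecg(rec, path)
        with pytest.raises(FormatError):
            v.read_ecg(path, units="mV")
        back = v.read_ecg(path, units="mV", gain_to_uv=1000.0)
        np.testing.assert_allclose(back.signal, rec.signal * 1000.0)

    def test_wfdb_format_is_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            v.read_ecg(tmp_path / "x.dat", format="wfdb")

    def test_nan_in_file_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"I": [1.0, np.nan], "II": [0, 0], "V1": [0, 0]}).to_csv(
            path, index=False
        )
        with pytest.raises(SignalQualityError):
            v.read_ecg(path, fs=500.0)


class TestResample:
    def test_identity_at_target_rate(self):
        rec = _record(fs=1000.0)
        assert v.resample_cubic_spline(rec) is rec

    def test_sine_recovered_within_1uv(self):
        t = np.arange(5000) / 500.0
        sine = 1000.0 * np.sin(2 * np.pi * 5.0 * t)
        rec = v.EcgRecord(("I", "II", "V1"), np.tile(sine, (3, 1)), 500.0)
        out = v.resample_cubic_spline(rec, 1000.0)
        t_out = np.arange(out.n_samples) / 1000.0
        expected = 1000.0 * np.sin(2 * np.pi * 5.0 * t_out)
        # spline endpoints extrapolate; check the interior
        err = np.abs(out.signal[0][5:-5] - expected[5:-5])
        assert err.max() < 1.0

    def test_duration_preserved(self):
        rec = _record(n_samples=5000, fs=500.0)  # 10 s
        out = v.resample_cubic_spline(rec, 1000.0)
        assert out.fs == 1000.0
        assert abs(out.n_samples - 10000) <= 2

    def test_energy_preserved_for_bandlimited_signal(self):
        t = np.arange(5000) / 500.0
        x = 500 * np.sin(2 * np.pi * 7 * t) + 200 * np.sin(2 * np.pi * 19 * t)
        rec = v.EcgRecord(("I", "II", "V1"), np.tile(x, (3, 1)), 500.0)
        out = v.resample_cubic_spline(rec, 1000.0)
        e_in = np.mean(np.square(rec.signal[0]))
        e_out = np.mean(np.square(out.signal[0]))
        assert abs(e_out - e_in) / e_in < 0.005

    def test_low_rate_rejected(self):
        rec = _record(fs=500.0)
        rec = v.EcgRecord(rec.lead_labels, rec.signal, 50.0)
        with pytest.raises(ResampleError):
            v.resample_cubic_spline(rec)


class TestFilter:
    def test_dc_offset_removed(self):
        sig = np.full((3, 10000), 500.0)
        rec = v.EcgRecord(("I", "II", "V1"), sig, 1000.0)
        out = v.filter_record(rec)
        assert np.abs(out.signal).mean() < 1.0

    def test_zero_phase_impulse_response_is_symmetric(self):
        sig = np.zeros((3, 20001))
        sig[:, 10000] = 1000.0
        rec = v.EcgRecord(("I", "II", "V1"), sig, 1000.0)
        out = v.filter_record(rec)
        h = out.signal[0]
        # symmetric up to the residual edge transients of the long
        # high-pass tail (~1e-3 of the 1 mV impulse)
        np.testing.assert_allclose(h, h[::-1], atol=1e-3)

    def test_baseline_wander_attenuated_without_qrs_distortion(self, default_loop):
        clean_spec = v.SyntheticEcgSpec(seed=5)
        wander_spec = v.SyntheticEcgSpec(seed=5, baseline_wander_uv=200.0,
                                         baseline_wander_hz=0.3)
        clean, truth = v.project_and_assemble(clean_spec, default_loop)
        noisy, _ = v.project_and_assemble(wander_spec, default_loop)
        out = v.filter_record(noisy)
        wander_in = noisy.signal - clean.signal
        wander_out = out.signal - v.filter_record(clean).signal
        atten_db = 10 * np.log10(np.mean(wander_in**2) / np.mean(wander_out**2))
        assert atten_db > 20
        # peak-to-peak within the QRS is offset-invariant: the high-pass may
        # shift the local baseline but must not distort the QRS shape
        r = int(truth.beat_times_ms[3])
        peak_in = np.ptp(clean.signal[:, r - 60 : r + 60], axis=1).max()
        peak_out = np.ptp(v.filter_record(clean).signal[:, r - 60 : r + 60], axis=1).max()
        assert abs(peak_out - peak_in) / peak_in < 0.02

    @pytest.mark.parametrize(
        "cfg",
        [
            v.FilterSettings(highpass_hz=600.0),
            v.FilterSettings(lowpass_hz=600.0),
            v.FilterSettings(highpass_hz=200.0, lowpass_hz=150.0),
            v.FilterSettings(notch_hz=700.0),
        ],
    )
    def test_bad_configurations_rejected(self, cfg):
        rec = _record(fs=1000.0)
        with pytest.raises(FilterConfigError):
            v.filter_record(rec, cfg)


class TestLeadReduction:
    def _twelve_lead(self, rng):
        eight = 100 * rng.standard_normal((8, 1000))
        labels = list(v.INDEPENDENT_LEADS)
        i, ii = eight[0], eight[1]
        extra = {
            "III": ii - i,
            "aVR": -(i + ii) / 2,
            "aVL": i - ii / 2,
            "aVF": ii - i / 2,
        }
        sig = np.vstack([eight] + [extra[l] for l in extra])
        return v.EcgRecord(tuple(labels + list(extra)), sig, 1000.0)

    def test_twelve_to_eight(self):
        rec = self._twelve_lead(np.random.default_rng(1))
        out = v.to_independent_leads(rec)
        assert out.lead_labels == v.INDEPENDENT_LEADS
        np.testing.assert_allclose(
            rec.lead("III"), out.lead("II") - out.lead("I"), atol=1e-9
        )

    def test_eight_lead_input_unchanged(self):
        rec = _record(fs=1000.0)
        assert v.to_independent_leads(rec) is rec

    def test_mislabelled_redundant_lead_detected(self):
        rec = self._twelve_lead(np.random.default_rng(1))
        sig = rec.signal.copy()
        sig[rec.lead_labels.index("III")] += 50.0  # breaks Einthoven by 50 µV
        bad = v.EcgRecord(rec.lead_labels, sig, 1000.0)
        with pytest.raises(LeadSetError, match="III"):
            v.to_independent_leads(bad)

    def test_missing_leads_rejected(self):
        rec = _record(n_leads=3, labels=("I", "II", "V1"))
        with pytest.raises(LeadSetError):
            v.to_independent_leads(rec)


class TestBeltLeads:
    def test_identical_precordials_give_zero(self):
        x = np.sin(np.linspace(0, 10, 1000)) * 100
        sig = np.tile(x, (4, 1))
        rec = v.EcgRecord(("V1", "V2", "V5", "V6"), sig, 1000.0)
        out = v.to_belt_leads(rec)
        assert out.lead_labels == v.BELT_LEADS
        np.testing.assert_array_equal(out.signal, 0.0)

    def test_constant_offset_difference(self):
        x = np.zeros(100)
        sig = np.vstack([x, x + 100.0, x, x])
        rec = v.EcgRecord(("V1", "V2", "V5", "V6"), sig, 1000.0)
        out = v.to_belt_leads(rec)
        np.testing.assert_array_equal(out.lead("V2-V1"), 100.0)

    def test_telescoping_identity(self):
        rng = np.random.default_rng(3)
        rec = _record(rng=rng, fs=1000.0)
        out = v.to_belt_leads(rec)
        np.testing.assert_allclose(
            out.signal.sum(axis=0), rec.lead("V6") - rec.lead("V1"), atol=1e-10
        )

    def test_missing_precordial_rejected(self):
        rec = _record(n_leads=3, labels=("I", "II", "V1"))
        with pytest.raises(LeadSetError):
            v.to_belt_leads(rec)
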
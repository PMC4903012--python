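"""ECG signal chain: I/O, segmenting, filtering, QRS detection, labelling."""

import numpy as np
import pytest

import edchest as e
from edchest.signal import ECTOPIC, NORMAL
from edchest.simulate import match_beats, noise_sd_for_snr


# ---------------------------------------------------------------------------
# read_ecg


def test_read_csv_uniform_grid(tmp_path):
    p = tmp_path / "rec.csv"
    p.write_text("0.0,0.1\n0.004,0.2\n0.008,0.1\n")
    rec = e.read_ecg(p)
    assert rec.n_samples == 3
    assert rec.sampling_rate == pytest.approx(250.0)
    assert rec.samples == pytest.approx([0.1, 0.2, 0.1])


def test_read_csv_nonuniform_rejected(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("0.0,0.1\n0.004,0.2\n0.012,0.1\n")
    with pytest.raises(ValueError, match="non-uniform sampling"):
        e.read_ecg(p)


def test_read_csv_single_column_needs_fs(tmp_path):
    p = tmp_path / "v.csv"
    p.write_text("0.1\n0.2\n0.1\n")
    with pytest.raises(ValueError, match="sampling_rate"):
        e.read_ecg(p)
    rec = e.read_ecg(p, sampling_rate=500)
    assert rec.sampling_rate == 500


def test_csv_round_trip(tmp_path):
    rr = e.simulate_rr(e.RRSimSpec(duration=30, seed=4))
    ecg = e.simulate_ecg(rr)
    p = tmp_path / "sim.csv"
    from edchest.signal import write_ecg_csv

    write_ecg_csv(ecg, p)
    back = e.read_ecg(p)
    assert back.sampling_rate == pytest.approx(ecg.sampling_rate, rel=1e-6)
    np.testing.assert_allclose(back.samples, ecg.samples, atol=1e-6)


def test_read_wfdb_format16(tmp_path):
    fs, gain = 250.0, 200.0
    mv = np.sin(np.arange(1000) / 10.0)
    raw = np.round(mv * gain).astype("<i2")
    (tmp_path / "rec.dat").write_bytes(raw.tobytes())
    (tmp_path / "rec.hea").write_text(
        f"rec 1 {fs:g} {raw.size}\nrec.dat 16 {gain:g}(0)/mV 12 0 0 0 0 II\n")
    rec = e.read_ecg(tmp_path / "rec", format="wfdb")
    assert rec.sampling_rate == fs
    np.testing.assert_allclose(rec.samples, raw / gain, atol=1e-9)


# ---------------------------------------------------------------------------
# select_segment / bandpass


def test_select_segment_six_minutes():
    fs = 250.0
    rec = e.ECGRecord(fs, np.zeros(int(600 * fs)) + np.arange(int(600 * fs)))
    seg = e.select_segment(rec, start=0, duration=360)
    assert seg.n_samples == int(360 * fs)
    seg2 = e.select_segment(rec, start=100, duration=360)
    assert seg2.t0 == pytest.approx(100.0)
    assert seg2.samples[0] == rec.samples[int(100 * fs)]


@pytest.mark.parametrize("start,duration,msg", [
    (0, 0, "empty segment"),
    (700, 10, "beyond end"),
    (300, 360, "exceeds record"),
])
def test_select_segment_errors(start, duration, msg):
    rec = e.ECGRecord(250.0, np.zeros(int(600 * 250)))
    with pytest.raises(ValueError, match=msg):
        e.select_segment(rec, start=start, duration=duration)


def _sine_record(freq, fs=250.0, dur=30.0):
    t = np.arange(int(dur * fs)) / fs
    return e.ECGRecord(fs, np.sin(2 * np.pi * freq * t))


def test_bandpass_rejects_baseline_wander():
    out = e.bandpass(_sine_record(0.3))
    interior = out.samples[1000:-1000]
    assert np.max(np.abs(interior)) < 0.05


def test_bandpass_passes_qrs_band():
    out = e.bandpass(_sine_record(15.0))
    interior = out.samples[1000:-1000]
    assert np.max(np.abs(interior)) > 0.70


def test_bandpass_removes_dc():
    rec = e.ECGRecord(250.0, np.full(5000, 3.7))
    out = e.bandpass(rec)
    assert np.max(np.abs(out.samples)) < 1e-6 * 3.7 + 1e-9


def test_bandpass_invalid_edges():
    rec = _sine_record(10.0, fs=50.0)
    with pytest.raises(ValueError, match="band edges"):
        e.bandpass(rec, low=5, high=28)  # 28 Hz above Nyquist of 50 Hz


def test_segment_filter_commute_in_interior(clean_ecg):
    _, ecg = clean_ecg
    a = e.bandpass(e.select_segment(ecg, start=10, duration=60))
    b = e.select_segment(e.bandpass(ecg), start=10, duration=60)
    fs = int(ecg.sampling_rate)
    np.testing.assert_allclose(a.samples[fs:-fs], b.samples[fs:-fs],
                               atol=1e-5)


# ---------------------------------------------------------------------------
# detect_qrs


def test_detect_qrs_noise_free_counts_and_accuracy(clean_ecg):
    rr, ecg = clean_ecg
    beats = e.detect_qrs(e.bandpass(ecg))
    assert abs(beats.beat_indices.size - rr.beat_times.size) <= 1
    # every detected peak within one sample of a true template centre
    _, frac = match_beats(rr.beat_times, beats.beat_times,
                          tol=1.5 / ecg.sampling_rate)
    assert frac == pytest.approx(1.0)


def test_detect_qrs_flat_input():
    rec = e.ECGRecord(250.0, np.zeros(250 * 20))
    with pytest.raises(e.NoQRSError, match="no QRS found"):
        e.detect_qrs(rec)


def test_detect_qrs_requires_ten_seconds():
    rec = e.ECGRecord(250.0, np.random.default_rng(0).normal(size=500))
    with pytest.raises(ValueError, match="10 s"):
        e.detect_qrs(rec)


def test_detect_qrs_snr_10db(clean_ecg):
    rr, clean = clean_ecg
    sd = noise_sd_for_snr(clean.samples, 10.0)
    noisy = e.simulate_ecg(rr, e.ECGSimSpec(noise_sd=sd, seed=99))
    beats = e.detect_qrs(e.bandpass(noisy))
    _, frac = match_beats(rr.beat_times, beats.beat_times, tol=0.020)
    assert frac >= 0.99


def test_detect_qrs_amplitude_invariant(clean_ecg):
    _, ecg = clean_ecg
    filt = e.bandpass(ecg)
    ref = e.detect_qrs(filt).beat_indices
    for c in (0.01, 7.3, 1000.0):
        scaled = e.ECGRecord(filt.sampling_rate, c * filt.samples)
        np.testing.assert_array_equal(e.detect_qrs(scaled).beat_indices, ref)


# ---------------------------------------------------------------------------
# to_rr / label_beats / eligibility


def test_to_rr_arithmetic():
    beats = e.BeatSequence(np.array([0, 250, 500]), 250.0)
    rr = e.to_rr(beats)
    assert rr.intervals == pytest.approx([1.0, 1.0])
    assert list(rr.labels) == [NORMAL, NORMAL]


def test_to_rr_single_beat():
    with pytest.raises(ValueError, match="2 beats"):
        e.to_rr(e.BeatSequence(np.array([100]), 250.0))


def test_round_trip_recovers_intervals(clean_ecg):
    rr, ecg = clean_ecg
    rec = e.to_rr(e.detect_qrs(e.bandpass(ecg)))
    assert rec.intervals.size == rr.intervals.size
    np.testing.assert_allclose(rec.intervals, rr.intervals,
                               atol=2.0 / ecg.sampling_rate)


def _rr_from_intervals(intervals):
    return e.RRSeries.from_beat_times(np.concatenate([[0.0],
                                                      np.cumsum(intervals)]))


def test_label_beats_constant_all_normal():
    rr = e.label_beats(_rr_from_intervals([0.8] * 50))
    assert np.all(rr.labels == NORMAL)


def test_label_beats_flags_single_short_interval():
    iv = [0.8] * 20
    iv[10] = 0.4
    rr = e.label_beats(_rr_from_intervals(iv))
    assert rr.labels[10] == ECTOPIC
    assert np.count_nonzero(rr.labels == ECTOPIC) == 1


def test_label_beats_bigeminy_mostly_flagged():
    iv = [0.6, 1.0] * 25
    rr = e.label_beats(_rr_from_intervals(iv))
    assert np.mean(rr.labels != NORMAL) >= 0.30


def test_label_beats_degenerate_unchanged():
    rr = e.label_beats(_rr_from_intervals([0.8, 0.4]))
    assert np.all(rr.labels == NORMAL)


def test_eligibility_boundary():
    rr = _rr_from_intervals([0.8] * 100)
    rr.labels[:31] = ECTOPIC
    rep = e.eligibility(rr)
    assert rep.fraction_abnormal == pytest.approx(0.31)
    assert not rep.eligible

    rr.labels[:] = NORMAL
    rr.labels[:30] = ECTOPIC
    assert e.eligibility(rr).eligible

    rr.labels[:] = NORMAL
    rep = e.eligibility(rr)
    assert rep.fraction_abnormal == 0.0 and rep.eligible


def test_eligibility_monotone_in_abnormal_labels(rng):
    rr = _rr_from_intervals([0.8] * 60)
    flip = rng.permutation(60)
    was_ineligible = False
    for i in flip:
        rr.labels[i] = ECTOPIC
        rep = e.eligibility(rr)
        if was_ineligible:
            assert not rep.eligible  # adding labels never restores eligibility
        was_ineligible = was_ineligible or not rep.eligible
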
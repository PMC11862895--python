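"""Call synthesis, detection, and per-pulse parameter recovery."""

import numpy as np
import pytest

from chiromito.bioacoustics import (
    AnalysisConfig,
    BioacousticsError,
    CallRecording,
    PulseParams,
    detect_pulses,
    gen_fm_call,
    measure_pulse,
    measure_recording,
    summarize_calls,
)

CFG = AnalysisConfig()
FS = 384_000.0
BIN_KHZ = CFG.bin_width_hz(FS) / 1e3  # resolution bandwidth, 1.5 kHz
HOP_MS = CFG.hop_s(FS) * 1e3  # frame hop, ~0.167 ms


def test_generator_validation():
    with pytest.raises(BioacousticsError):
        gen_fm_call(29.0, 33.0, 2.4, 250.0, 3)  # ascending sweep
    with pytest.raises(BioacousticsError):
        gen_fm_call(33.0, 30.0, -1.0, 250.0, 3)
    with pytest.raises(BioacousticsError):
        gen_fm_call(200.0, 30.0, 2.4, 250.0, 3)  # above Nyquist


def test_silence_yields_no_detections():
    rec = CallRecording(np.zeros(int(0.2 * FS)), FS)
    assert detect_pulses(rec) == []


def test_zero_pulses_is_pure_noise():
    rec, truth = gen_fm_call(33.0, 30.0, 2.4, 250.0, 0, snr_db=30, seed=1)
    assert truth == []
    assert np.std(rec.samples) > 0


def test_pulse_count_and_ipi_recovery():
    """5 pulses at 250 ms spacing detect as 5 windows with IPI ~250 ms."""
    rec, _ = gen_fm_call(33.0, 30.0, 2.4, 250.0, 5, snr_db=30, seed=2)
    det = detect_pulses(rec)
    assert len(det) == 5
    onsets = [a for a, _ in det]
    ipis = 1e3 * np.diff(onsets)
    assert np.allclose(ipis, 250.0, atol=1.0)


def test_single_pulse_detection():
    rec, _ = gen_fm_call(33.0, 30.0, 2.4, 250.0, 1, snr_db=30, seed=3)
    assert len(detect_pulses(rec)) == 1


def test_threshold_must_be_negative():
    rec, _ = gen_fm_call(33.0, 30.0, 2.4, 250.0, 1, snr_db=30, seed=3)
    with pytest.raises(BioacousticsError):
        detect_pulses(rec, threshold_db=3.0)


def test_noise_free_measurement_close_to_truth(clean_train):
    rec, truth = clean_train
    pulses = measure_recording(rec)
    assert len(pulses) == len(truth)
    for p, t in zip(pulses, truth):
        assert p.start_freq == pytest.approx(t.start_freq, abs=0.5)
        assert p.end_freq == pytest.approx(t.end_freq, abs=0.5)
        assert t.end_freq - 0.5 <= p.peak_freq <= t.start_freq + 0.5
        assert p.duration == pytest.approx(t.duration, abs=HOP_MS)


def test_constant_frequency_tone_degenerate_fm():
    rec, _ = gen_fm_call(31.0, 31.0, 2.4, 250.0, 1, snr_db=np.inf, seed=0)
    (p,) = measure_recording(rec)
    assert p.start_freq == pytest.approx(31.0, abs=0.2)
    assert p.end_freq == pytest.approx(31.0, abs=0.2)
    assert p.peak_freq == pytest.approx(31.0, abs=0.2)
    assert p.bandwidth < 0.5


def test_measurement_is_deterministic(clean_train):
    rec, _ = clean_train
    (a, b), *_ = detect_pulses(rec)
    assert measure_pulse(rec, a, b) == measure_pulse(rec, a, b)


def test_time_shift_moves_onsets_only():
    rec, _ = gen_fm_call(33.0, 30.0, 2.4, 250.0, 2, snr_db=np.inf, seed=4)
    shift_samples = 10 * CFG.hop
    shifted = CallRecording(
        np.concatenate([np.zeros(shift_samples), rec.samples]), rec.sample_rate
    )
    p0 = measure_recording(rec)
    p1 = measure_recording(shifted)
    assert len(p0) == len(p1) == 2
    for a, b in zip(p0, p1):
        assert b.onset_time - a.onset_time == pytest.approx(
            shift_samples / rec.sample_rate, abs=2 * CFG.hop_s(rec.sample_rate)
        )
        assert b.start_freq == pytest.approx(a.start_freq, abs=0.1)
        assert b.end_freq == pytest.approx(a.end_freq, abs=0.1)
        assert b.duration == pytest.approx(a.duration, abs=0.05)


def test_parameter_recovery_at_snr20():
    """Seeded draws across the observed call-parameter ranges recover
    start/end within one resolution bin and duration within one hop."""
    rng = np.random.default_rng(77)
    for i in range(5):
        sf = rng.uniform(30.0, 34.6)
        ef = rng.uniform(28.99, min(30.19, sf - 0.5))
        du = rng.uniform(2.05, 2.74)
        ip = rng.uniform(232.0, 266.0)
        rec, truth = gen_fm_call(sf, ef, du, ip, 4, snr_db=20, seed=900 + i)
        pulses = measure_recording(rec)
        assert len(pulses) == 4  # exact count at SNR >= 20, IPI >> duration
        for p, t in zip(pulses, truth):
            assert abs(p.start_freq - t.start_freq) <= BIN_KHZ
            assert abs(p.end_freq - t.end_freq) <= BIN_KHZ
            assert abs(p.duration - t.duration) <= HOP_MS


def test_summary_statistics():
    mk = lambda i: PulseParams(33.0, 30.0, 31.5, 3.0, 2.4, 0.05 + 0.25 * i)
    s = summarize_calls([mk(i) for i in range(4)])
    assert s.n_pulses == 4
    assert s.stats["start_freq"]["sd"] == 0.0  # identical pulses
    assert s.stats["ipi"]["mean"] == pytest.approx(250.0)
    assert s.stats["duration"]["min"] <= s.stats["duration"]["mean"] <= s.stats["duration"]["max"]


def test_summary_single_pulse_sd_absent():
    s = summarize_calls([PulseParams(33.0, 30.0, 31.5, 3.0, 2.4, 0.05)])
    assert s.stats["start_freq"]["sd"] is None
    assert s.ipi_ms == [] and "ipi" not in s.stats


def test_summary_rejects_empty():
    with pytest.raises(BioacousticsError):
        summarize_calls([])


def test_seeded_jitter_train_means_recovered():
    """A 20-pulse train with per-pulse jitter: measured means land within
    2 standard errors of the planted means."""
    rng = np.random.default_rng(31)
    pulses = []
    sf0, ef0, du0 = 33.15, 29.82, 2.43
    recs = []
    for k in range(20):
        sf = sf0 + rng.normal(0, 0.3)
        ef = ef0 + rng.normal(0, 0.1)
        du = du0 + rng.normal(0, 0.1)
        rec, _ = gen_fm_call(sf, ef, du, 50.0, 1, snr_db=30, seed=2000 + k, lead_ms=10.0)
        p = measure_recording(rec)
        assert len(p) == 1
        pulses.append(p[0])
    s = summarize_calls(pulses)
    assert s.stats["start_freq"]["mean"] == pytest.approx(sf0, abs=2 * 0.3 / np.sqrt(20) + 0.35)
    assert s.stats["end_freq"]["mean"] == pytest.approx(ef0, abs=2 * 0.1 / np.sqrt(20) + 0.35)
    assert s.stats["duration"]["mean"] == pytest.approx(du0, abs=2 * 0.1 / np.sqrt(20) + HOP_MS)


def test_wav_round_trip(tmp_path, clean_train):
    rec, _ = clean_train
    p = tmp_path / "train.wav"
    rec.to_wav(p)
    back = CallRecording.from_wav(p)
    assert back.sample_rate == rec.sample_rate
    assert len(back.samples) == len(rec.samples)
    # 16-bit round trip preserves the waveform up to scale
    a = rec.samples / np.abs(rec.samples).max()
    b = back.samples / np.abs(back.samples).max()
    assert np.corrcoef(a, b)[0, 1] > 0.9999


def test_window_too_short_rejected(clean_train):
    rec, _ = clean_train
    with pytest.raises(BioacousticsError):
        measure_pulse(rec, 0.05, 0.0501, AnalysisConfig(nperseg=4096))
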
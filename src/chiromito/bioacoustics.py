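"""FM echolocation-call synthesis and per-pulse parameter extraction.

A frequency-modulated (FM) bat call is a train of short downward
frequency sweeps separated by long inter-pulse intervals (IPI).  Six
quantities are measured per pulse, following the conventions of
bat-call analysis software:

* start (initial) and end (terminal) frequency of the sweep, kHz;
* peak frequency — the frequency of maximum energy in the pulse's mean
  spectrum ("frequency of most energy"), kHz;
* bandwidth — the extent of the spectrogram ridge, kHz;
* duration, ms, and onset time, s; IPI is onset-to-onset.

Measurement pipeline (all constants exposed in :class:`AnalysisConfig`):
pulses are detected on a band-limited short-time spectral energy
envelope (threshold relative to the recording's peak, default -24 dB);
each detection window is then re-measured: duration and onset come from
the -20 dB crossings of the smoothed analytic (Hilbert) envelope of the
band-passed signal, and frequencies from the spectrogram ridge
(per-frame argmax with parabolic interpolation), keeping frames whose
ridge power is within 20 dB of the window maximum.  Everything is
deterministic: the same recording yields the same parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from scipy import signal
from scipy.io import wavfile


class BioacousticsError(ValueError):
    pass


@dataclass
class CallRecording:
    samples: np.ndarray  # float, mono
    sample_rate: float  # Hz

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise BioacousticsError("recording must be mono")
        if self.sample_rate <= 0:
            raise BioacousticsError("sample rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    @classmethod
    def from_wav(cls, path: str | Path) -> "CallRecording":
        rate, data = wavfile.read(str(path))
        if data.ndim > 1:
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            data = data / float(np.iinfo(data.dtype).max)
        return cls(samples=np.asarray(data, dtype=float), sample_rate=float(rate))

    def to_wav(self, path: str | Path) -> None:
        peak = float(np.max(np.abs(self.samples))) or 1.0
        scaled = np.clip(self.samples / peak, -1.0, 1.0)
        wavfile.write(str(path), int(self.sample_rate), (scaled * 32767).astype(np.int16))


@dataclass(frozen=True)
class AnalysisConfig:
    """Spectrogram and detection constants.

    ``nperseg`` sets the resolution bandwidth (fs/nperseg, the "bin
    width" quoted in recovery guarantees); ``nfft`` zero-pads for finer
    peak interpolation; ``hop`` is the frame step ("frame hop", the
    duration/onset granularity of the spectrogram stage)."""

    nperseg: int = 256
    hop: int = 64
    nfft: int = 2048
    detect_threshold_db: float = -24.0  # envelope threshold rel. recording peak
    ridge_cutoff_db: float = -20.0  # ridge/envelope inclusion rel. window max
    merge_gap_ms: float = 1.0
    min_duration_ms: float = 0.3
    band_khz: Optional[tuple[float, float]] = None  # None = estimate per recording
    band_pad_khz: float = 2.0
    band_extent_db: float = -26.0
    smooth_ms: float = 0.05

    def bin_width_hz(self, fs: float) -> float:
        return fs / self.nperseg

    def hop_s(self, fs: float) -> float:
        return self.hop / fs


@dataclass(frozen=True)
class PulseParams:
    start_freq: float  # kHz
    end_freq: float  # kHz
    peak_freq: float  # kHz
    bandwidth: float  # kHz
    duration: float  # ms
    onset_time: float  # s


_PARAM_FIELDS = ("start_freq", "end_freq", "peak_freq", "bandwidth", "duration")


@dataclass
class CallSummary:
    """Per-parameter min/max/mean/sample-SD over a pulse train, plus the
    onset-to-onset IPI series (ms).  SD uses the n-1 denominator and is
    None for a single observation."""

    n_pulses: int
    stats: dict[str, dict[str, Optional[float]]]
    ipi_ms: list[float]

    def to_tsv(self, path: str | Path, header_comment: str = "") -> None:
        lines = []
        if header_comment:
            lines.extend(f"# {l}" for l in header_comment.splitlines())
        lines.append("Item\tRange\tMean ± SD\tn")
        units = {
            "start_freq": "Initial frequency (kHz)",
            "end_freq": "Terminate frequency (kHz)",
            "bandwidth": "Frequency bandwidth (kHz)",
            "peak_freq": "Main frequency (kHz)",
            "duration": "Duration time (ms)",
            "ipi": "Interval time (ms)",
        }
        for key, label in units.items():
            s = self.stats.get(key)
            if s is None:
                continue
            sd = f"{s['sd']:.2f}" if s["sd"] is not None else "-"
            lines.append(
                f"{label}\t{s['min']:.2f}-{s['max']:.2f}\t{s['mean']:.2f} ± {sd}\t{s['n']}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

def gen_fm_call(
    start_f: float,
    end_f: float,
    duration: float,
    ipi: float,
    n_pulses: int,
    snr_db: float = 30.0,
    sweep: Literal["linear", "hyperbolic"] = "linear",
    seed: int = 0,
    sample_rate: float = 384_000.0,
    lead_ms: float = 50.0,
) -> tuple[CallRecording, list[PulseParams]]:
    """Synthesise an FM pulse train with known ground truth.

    ``start_f``/``end_f`` in kHz (descending sweep), ``duration`` and
    ``ipi`` in ms.  Pulses carry a Tukey (tapered raised-cosine, 25%
    taper) amplitude envelope; white Gaussian noise is added at
    ``snr_db`` (peak pulse power over noise power; ``inf`` disables
    noise).  Returns the recording and the planted per-pulse truth; the
    truth peak frequency is the sweep midpoint.
    """
    if not (start_f >= end_f > 0):
        raise BioacousticsError("need start_f >= end_f > 0 for a descending FM sweep")
    if duration <= 0 or ipi <= 0:
        raise BioacousticsError("duration and ipi must be positive")
    if start_f * 1e3 >= sample_rate / 2:
        raise BioacousticsError(
            f"start frequency {start_f} kHz at or above Nyquist "
            f"({sample_rate / 2000:.0f} kHz)"
        )
    rng = np.random.default_rng(seed)
    dur_s, ipi_s, lead_s = duration / 1e3, ipi / 1e3, lead_ms / 1e3
    n_total = int(round((lead_s * 2 + max(n_pulses - 1, 0) * ipi_s + dur_s) * sample_rate))
    samples = np.zeros(n_total)
    n_pulse = int(round(dur_s * sample_rate))
    t = np.arange(n_pulse) / sample_rate
    phi = rng.uniform(0, 360)
    pulse = signal.chirp(
        t, f0=start_f * 1e3, t1=dur_s, f1=end_f * 1e3, method=sweep, phi=phi
    ) * signal.windows.tukey(n_pulse, alpha=0.25)
    truth: list[PulseParams] = []
    for k in range(n_pulses):
        onset = lead_s + k * ipi_s
        i0 = int(round(onset * sample_rate))
        samples[i0 : i0 + n_pulse] += pulse
        truth.append(
            PulseParams(
                start_freq=start_f,
                end_freq=end_f,
                peak_freq=0.5 * (start_f + end_f),
                bandwidth=start_f - end_f,
                duration=duration,
                onset_time=onset,
            )
        )
    if np.isfinite(snr_db):
        sigma = np.sqrt(0.5 * 10.0 ** (-snr_db / 10.0))
        samples = samples + rng.normal(0.0, sigma, size=n_total)
    return CallRecording(samples=samples, sample_rate=sample_rate), truth


# ---------------------------------------------------------------------------
# Detection and measurement
# ---------------------------------------------------------------------------

def _spectrogram(x: np.ndarray, fs: float, cfg: AnalysisConfig):
    f, t, sxx = signal.spectrogram(
        x,
        fs=fs,
        window=signal.windows.hann(cfg.nperseg),
        noverlap=cfg.nperseg - cfg.hop,
        nfft=cfg.nfft,
        mode="psd",
        detrend=False,
    )
    return f, t, sxx


def _estimate_band(f: np.ndarray, mean_psd: np.ndarray, cfg: AnalysisConfig) -> tuple[float, float]:
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(np.maximum(mean_psd, 1e-300))
    peak = int(np.argmax(db))
    # stay above the noise floor (median of the mean spectrum) so the
    # extent walk cannot wander off into broadband noise at low SNR
    cutoff = max(db[peak] + cfg.band_extent_db, float(np.median(db)) + 6.0)
    lo = peak
    while lo > 0 and db[lo - 1] >= cutoff:
        lo -= 1
    hi = peak
    while hi < len(db) - 1 and db[hi + 1] >= cutoff:
        hi += 1
    pad = cfg.band_pad_khz * 1e3
    return max(f[lo] - pad, 500.0), min(f[hi] + pad, f[-1])


def _band(rec: CallRecording, cfg: AnalysisConfig) -> tuple[float, float]:
    if cfg.band_khz is not None:
        return cfg.band_khz[0] * 1e3, cfg.band_khz[1] * 1e3
    f, _, sxx = _spectrogram(rec.samples, rec.sample_rate, cfg)
    return _estimate_band(f, sxx.mean(axis=1), cfg)


def detect_pulses(
    rec: CallRecording,
    threshold_db: Optional[float] = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[tuple[float, float]]:
    """Detect pulse windows on the band-limited spectral energy envelope.

    Returns (onset, offset) second pairs with strictly increasing onsets;
    a silent recording yields an empty list.  ``threshold_db`` (< 0,
    relative to the envelope peak) overrides the config default.
    """
    thr = threshold_db if threshold_db is not None else config.detect_threshold_db
    if thr >= 0:
        raise BioacousticsError("threshold_db must be negative (relative to peak)")
    if len(rec.samples) < config.nperseg or not np.any(rec.samples):
        return []
    f, t, sxx = _spectrogram(rec.samples, rec.sample_rate, config)
    if config.band_khz is not None:
        lo, hi = config.band_khz[0] * 1e3, config.band_khz[1] * 1e3
    else:
        lo, hi = _estimate_band(f, sxx.mean(axis=1), config)
    band = (f >= lo) & (f <= hi)
    env = sxx[band].sum(axis=0)
    peak = env.max()
    if peak <= 0:
        return []
    with np.errstate(divide="ignore"):
        env_db = 10.0 * np.log10(np.maximum(env / peak, 1e-300))
    mask = env_db > thr
    # contiguous runs -> candidate windows
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    runs = list(zip(edges[::2], edges[1::2] - 1))
    # fuse runs separated by less than the merge gap
    merged: list[list[int]] = []
    gap_frames = config.merge_gap_ms / 1e3 / config.hop_s(rec.sample_rate)
    for a, b in runs:
        if merged and a - merged[-1][1] <= gap_frames:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    min_frames = config.min_duration_ms / 1e3 / config.hop_s(rec.sample_rate)
    return [
        (float(t[a]), float(t[b]))
        for a, b in merged
        if b - a + 1 >= min_frames
    ]


def _refine_envelope(
    window: np.ndarray, fs: float, lo: float, hi: float, cfg: AnalysisConfig
) -> tuple[int, int]:
    """Sample indices of the ridge-cutoff crossings of the smoothed
    analytic envelope of the band-passed window."""
    nyq = fs / 2
    sos = signal.butter(4, [max(lo, 100.0) / nyq, min(hi, nyq * 0.99) / nyq],
                        btype="bandpass", output="sos")
    filtered = signal.sosfiltfilt(sos, window)
    env = np.abs(signal.hilbert(filtered))
    k = max(int(cfg.smooth_ms / 1e3 * fs), 1)
    env = np.convolve(env, np.ones(k) / k, mode="same")
    peak_i = int(np.argmax(env))
    level = env[peak_i] * 10.0 ** (cfg.ridge_cutoff_db / 20.0)
    i0 = peak_i
    while i0 > 0 and env[i0 - 1] >= level:
        i0 -= 1
    i1 = peak_i
    while i1 < len(env) - 1 and env[i1 + 1] >= level:
        i1 += 1
    return i0, i1


def _parabolic(db: np.ndarray, i: int, f: np.ndarray) -> float:
    if i <= 0 or i >= len(db) - 1:
        return float(f[i])
    denom = db[i - 1] - 2 * db[i] + db[i + 1]
    if denom >= 0:
        return float(f[i])
    delta = 0.5 * (db[i - 1] - db[i + 1]) / denom
    return float(f[i] + delta * (f[1] - f[0]))


def measure_pulse(
    rec: CallRecording,
    onset: float,
    offset: float,
    config: AnalysisConfig = AnalysisConfig(),
    band_hz: Optional[tuple[float, float]] = None,
) -> PulseParams:
    """Measure one detected pulse.

    Duration and refined onset come from the envelope crossings; start,
    end, peak frequency and bandwidth from the spectrogram ridge over
    frames within the ridge-power cutoff of the window maximum.
    ``band_hz`` short-circuits the per-recording band estimate (used by
    :func:`measure_recording` to avoid recomputing it per pulse).
    """
    fs = rec.sample_rate
    pad = 1.0e-3  # s of context on each side of the detection window
    i0 = max(int((onset - pad) * fs), 0)
    i1 = min(int((offset + pad) * fs), len(rec.samples))
    window = rec.samples[i0:i1]
    if len(window) < config.nperseg + 2 * config.hop:
        raise BioacousticsError("detection window shorter than two spectrogram frames")
    lo, hi = band_hz if band_hz is not None else _band(rec, config)
    e0, e1 = _refine_envelope(window, fs, lo, hi, config)
    duration_ms = (e1 - e0 + 1) / fs * 1e3
    onset_s = (i0 + e0) / fs

    f, t, sxx = _spectrogram(window, fs, config)
    band = (f >= lo) & (f <= hi)
    fb = f[band]
    sb = sxx[band, :]
    with np.errstate(divide="ignore"):
        sb_db = 10.0 * np.log10(np.maximum(sb, 1e-300))
    ridge_idx = sb.argmax(axis=0)
    ridge_power = sb.max(axis=0)
    included = np.flatnonzero(
        ridge_power >= ridge_power.max() * 10.0 ** (config.ridge_cutoff_db / 10.0)
    )
    ridge_f = np.array(
        [_parabolic(sb_db[:, j], int(ridge_idx[j]), fb) for j in included]
    )
    mean_db = 10.0 * np.log10(np.maximum(sb[:, included].mean(axis=1), 1e-300))
    peak_f = _parabolic(mean_db, int(np.argmax(mean_db)), fb)
    return PulseParams(
        start_freq=float(ridge_f[0]) / 1e3,
        end_freq=float(ridge_f[-1]) / 1e3,
        peak_freq=peak_f / 1e3,
        bandwidth=float(ridge_f.max() - ridge_f.min()) / 1e3,
        duration=duration_ms,
        onset_time=onset_s,
    )


def measure_recording(
    rec: CallRecording, config: AnalysisConfig = AnalysisConfig()
) -> list[PulseParams]:
    detections = detect_pulses(rec, config=config)
    if not detections:
        return []
    band = _band(rec, config)
    return [measure_pulse(rec, a, b, config, band_hz=band) for a, b in detections]


def summarize_calls(pulses: list[PulseParams]) -> CallSummary:
    """Aggregate per-pulse parameters into min/max/mean/SD plus the IPI
    series."""
    if not pulses:
        raise BioacousticsError("no pulses to summarize")

    def agg(values: list[float]) -> dict[str, Optional[float]]:
        arr = np.asarray(values, dtype=float)
        return {
            "min": float(arr.min()),
            "max": float(arr.max()),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else None,
            "n": len(arr),
        }

    stats = {name: agg([getattr(p, name) for p in pulses]) for name in _PARAM_FIELDS}
    onsets = [p.onset_time for p in pulses]
    ipi = [(b - a) * 1e3 for a, b in zip(onsets, onsets[1:])]
    if ipi:
        stats["ipi"] = agg(ipi)
    return CallSummary(n_pulses=len(pulses), stats=stats, ipi_ms=ipi)
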
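"""The nine per-response acoustic features from raw audio.

Framewise normalized-autocorrelation pitch tracking (F0 mean/median/std and
voiced fraction), linear-prediction formant estimation (F1/F2 means),
autocorrelation harmonics-to-noise ratio (median, dB), and energy-based
pause detection (pause fraction, mean pause duration). The algorithms are
the standard ones from the phonetics toolchain, re-implemented on numpy so
they can be validated against synthesis ground truth.

All thresholds are energy-relative, so features are invariant to overall
recording gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from speechstate.corpus_io import AudioSegment

#: Canonical order of the nine acoustic features.
ACOUSTIC_FEATURES: tuple[str, ...] = (
    "f0_mean",
    "f0_median",
    "f0_std",
    "f1_mean",
    "f2_mean",
    "hnr_median",
    "pause_fraction",
    "mean_pause_duration",
    "voiced_fraction",
)


@dataclass(frozen=True)
class AcousticConfig:
    """Frame and threshold parameters for the acoustic extractors.

    Defaults target telephone-grade speech: F0 searched in 75-500 Hz with
    40 ms / 10 ms pitch frames, 25 ms / 10 ms energy frames, a 0.45
    voicing threshold on the normalized autocorrelation peak, speech
    activity at 5% of the 95th-percentile RMS, and pauses of at least
    150 ms between speech segments.
    """

    f0_min: float = 75.0
    f0_max: float = 500.0
    pitch_window_s: float = 0.040
    pitch_step_s: float = 0.010
    voicing_threshold: float = 0.45
    energy_window_s: float = 0.025
    energy_step_s: float = 0.010
    vad_threshold: float = 0.05
    min_pause_s: float = 0.150
    preemphasis: float = 0.97
    max_formant_bandwidth: float = 400.0
    min_formant_hz: float = 90.0


@dataclass
class F0Track:
    """Framewise fundamental-frequency estimates (NaN marks unvoiced)."""

    times: np.ndarray
    f0: np.ndarray
    frame_step: float
    search_range: tuple[float, float]
    peak_correlation: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0)

    @property
    def n_frames(self) -> int:
        return self.f0.size

    @property
    def voiced_fraction(self) -> float:
        return float(self.voiced.mean()) if self.f0.size else 0.0


@dataclass
class PauseFeatures:
    """Between-speech pause structure from energy-based voice activity."""

    pause_fraction: float
    mean_pause_duration: float
    segments: list[tuple[float, float]]
    has_speech: bool


@dataclass
class AcousticFeatureSet:
    """The nine named per-response acoustic features (NaN = missing)."""

    f0_mean: float
    f0_median: float
    f0_std: float
    f1_mean: float
    f2_mean: float
    hnr_median: float
    pause_fraction: float
    mean_pause_duration: float
    voiced_fraction: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ACOUSTIC_FEATURES}


def _frame(x: np.ndarray, window: int, step: int) -> np.ndarray:
    """Strided (n_frames, window) view of the signal; empty if too short."""
    if x.size < window:
        return np.empty((0, window))
    return sliding_window_view(x, window)[::step]


def _autocorr_pitch(
    audio: AudioSegment, config: AcousticConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Framewise (times, f0, peak_correlation) via normalized autocorrelation.

    The correlation at lag L is the normalized cross-correlation of the
    frame with itself shifted by L (unbiased with respect to the shrinking
    overlap), searched over the lag range of the F0 band; the peak is
    refined by parabolic interpolation. Frames whose refined peak falls
    below the voicing threshold, or that carry no energy, are unvoiced.
    """
    sr = audio.sample_rate
    window = int(round(config.pitch_window_s * sr))
    step = max(1, int(round(config.pitch_step_s * sr)))
    frames = _frame(audio.samples, window, step)
    n = frames.shape[0]
    if n == 0:
        empty = np.empty(0)
        return empty, empty, empty
    frames = frames - frames.mean(axis=1, keepdims=True)

    lag_lo = max(2, int(math.floor(sr / config.f0_max)))
    lag_hi = min(window - 2, int(math.ceil(sr / config.f0_min)))
    if lag_hi <= lag_lo:
        raise ValueError("F0 search range incompatible with window length")
    lags = np.arange(lag_lo - 1, lag_hi + 2)  # pad one lag each side
    corr = np.empty((n, lags.size))
    sq = frames**2
    csum = np.concatenate([np.zeros((n, 1)), np.cumsum(sq, axis=1)], axis=1)
    total = csum[:, -1]
    for j, lag in enumerate(lags):
        head = frames[:, : window - lag]
        tail = frames[:, lag:]
        num = np.einsum("ij,ij->i", head, tail)
        e_head = csum[:, window - lag]
        e_tail = total - csum[:, lag]
        denom = np.sqrt(e_head * e_tail)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr[:, j] = np.where(denom > 0, num / denom, 0.0)

    # Candidate selection with an octave cost: the correlation at twice the
    # true period nearly ties with the true peak, so longer lags pay
    # 0.05 per octave and the best-scoring local maximum wins.
    inner = corr[:, 1:-1]
    inner_lags = lags[1:-1].astype(np.float64)
    octave_cost = 0.05 * np.log2(inner_lags / inner_lags[0])
    is_local_max = (inner >= corr[:, :-2]) & (inner >= corr[:, 2:])
    scores = np.where(is_local_max, inner - octave_cost[None, :], -np.inf)
    has_candidate = np.isfinite(scores).any(axis=1)
    best = np.where(has_candidate, scores.argmax(axis=1), inner.argmax(axis=1))
    peak_idx = best + 1
    rows = np.arange(n)
    r_l = corr[rows, peak_idx - 1]
    r_c = corr[rows, peak_idx]
    r_r = corr[rows, peak_idx + 1]
    denom = r_l - 2.0 * r_c + r_r
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(np.abs(denom) > 1e-12, 0.5 * (r_l - r_r) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    peak_val = r_c - 0.25 * (r_l - r_r) * delta
    peak_lag = lags[peak_idx] + delta

    has_energy = total > 1e-12
    voiced = has_energy & (peak_val >= config.voicing_threshold)
    f0 = np.where(voiced, sr / peak_lag, np.nan)
    # keep voiced estimates inside the search band
    out_of_band = np.isfinite(f0) & ((f0 < config.f0_min) | (f0 > config.f0_max))
    f0[out_of_band] = np.nan
    peak_val = np.where(has_energy, np.clip(peak_val, 0.0, 1.0), 0.0)
    times = (np.arange(n) * step + window / 2.0) / sr
    return times, f0, peak_val


def estimate_f0_track(
    audio: AudioSegment,
    f0_min: float | None = None,
    f0_max: float | None = None,
    config: AcousticConfig = AcousticConfig(),
) -> F0Track:
    """Track F0 with framewise normalized autocorrelation (40 ms / 10 ms)."""
    if f0_min is not None or f0_max is not None:
        config = AcousticConfig(
            **{
                **config.__dict__,
                "f0_min": f0_min if f0_min is not None else config.f0_min,
                "f0_max": f0_max if f0_max is not None else config.f0_max,
            }
        )
    if not config.f0_min < config.f0_max < audio.sample_rate / 2:
        raise ValueError(
            f"need f0_min < f0_max < Nyquist, got "
            f"({config.f0_min}, {config.f0_max}) at {audio.sample_rate} Hz"
        )
    times, f0, peak = _autocorr_pitch(audio, config)
    return F0Track(
        times=times,
        f0=f0,
        frame_step=config.pitch_step_s,
        search_range=(config.f0_min, config.f0_max),
        peak_correlation=peak,
    )


def harmonicity(
    audio: AudioSegment, config: AcousticConfig = AcousticConfig()
) -> float:
    """Median harmonics-to-noise ratio (dB) over voiced frames.

    Per voiced frame, HNR = 10 log10(r / (1 - r)) where r is the
    normalized autocorrelation at the F0 lag (clipped away from 0 and 1).
    NaN when no frame is voiced.
    """
    track = estimate_f0_track(audio, config=config)
    return _hnr_from_track(track)


def _hnr_from_track(track: F0Track) -> float:
    voiced = track.voiced
    if not voiced.any():
        return math.nan
    r = np.clip(track.peak_correlation[voiced], 1e-6, 1.0 - 1e-6)
    return float(np.median(10.0 * np.log10(r / (1.0 - r))))


def _levinson(acov: np.ndarray, order: int) -> np.ndarray:
    """Batched Levinson-Durbin: (n, order+1) autocovariances -> LPC coeffs.

    Returns prediction polynomials a with a[:, 0] = 1 such that the
    prediction error is minimized; frames with zero energy get a zero
    polynomial tail.
    """
    n = acov.shape[0]
    a = np.zeros((n, order + 1))
    a[:, 0] = 1.0
    err = acov[:, 0].copy()
    alive = err > 1e-14
    for m in range(1, order + 1):
        acc = acov[:, m].copy()
        for i in range(1, m):
            acc += a[:, i] * acov[:, m - i]
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(alive, -acc / err, 0.0)
        new_a = a.copy()
        new_a[:, m] = k
        for i in range(1, m):
            new_a[:, i] = a[:, i] + k * a[:, m - i]
        a = new_a
        err = err * (1.0 - k**2)
        alive = alive & (err > 1e-14)
    return a


def _roots_batch(poly: np.ndarray) -> np.ndarray:
    """Roots of a batch of monic polynomials via batched companion eigvals."""
    n, p1 = poly.shape
    order = p1 - 1
    comp = np.zeros((n, order, order))
    comp[:, 0, :] = -poly[:, 1:]
    idx = np.arange(order - 1)
    comp[:, idx + 1, idx] = 1.0
    return np.linalg.eigvals(comp)


def estimate_formants(
    audio: AudioSegment,
    n_formants: int = 2,
    config: AcousticConfig = AcousticConfig(),
    voiced_mask: np.ndarray | None = None,
) -> list[float]:
    """Mean F1..Fn (Hz) over voiced frames via linear-prediction analysis.

    Per voiced frame: pre-emphasis (0.97), Hamming window, LPC of order
    2 + sample_rate/1000, polynomial roots, keep resonances with bandwidth
    below 400 Hz inside (90 Hz, Nyquist - 50 Hz), sorted ascending. The
    response-level value is the mean over voiced frames; a formant absent
    in every voiced frame is NaN.
    """
    sr = audio.sample_rate
    window = int(round(config.pitch_window_s * sr))
    step = max(1, int(round(config.pitch_step_s * sr)))
    if voiced_mask is None:
        _, f0, _ = _autocorr_pitch(audio, config)
        voiced_mask = np.isfinite(f0)
    if voiced_mask.size == 0 or not voiced_mask.any():
        return [math.nan] * n_formants

    emphasized = np.append(
        audio.samples[0], audio.samples[1:] - config.preemphasis * audio.samples[:-1]
    )
    frames = _frame(emphasized, window, step)[: voiced_mask.size][voiced_mask]
    frames = frames * np.hamming(window)

    order = int(2 + sr / 1000)
    nfft = 1 << int(window * 2 - 1).bit_length()
    spec = np.fft.rfft(frames, nfft)
    acov = np.fft.irfft(np.abs(spec) ** 2, nfft)[:, : order + 1]
    lpc = _levinson(acov, order)
    roots = _roots_batch(lpc)

    angles = np.angle(roots)
    freqs = angles * sr / (2.0 * math.pi)
    with np.errstate(divide="ignore"):
        bandwidths = -(sr / math.pi) * np.log(np.abs(roots))
    valid = (
        (angles > 0)
        & (freqs > config.min_formant_hz)
        & (freqs < sr / 2.0 - 50.0)
        & (bandwidths < config.max_formant_bandwidth)
        & (bandwidths > 0)
    )
    per_frame = np.full((frames.shape[0], n_formants), np.nan)
    for i in range(frames.shape[0]):
        fs = np.sort(freqs[i][valid[i]])
        take = min(n_formants, fs.size)
        per_frame[i, :take] = fs[:take]
    means = []
    for j in range(n_formants):
        col = per_frame[:, j]
        col = col[np.isfinite(col)]
        means.append(float(col.mean()) if col.size else math.nan)
    return means


def detect_pauses(
    audio: AudioSegment, config: AcousticConfig = AcousticConfig()
) -> PauseFeatures:
    """Pause structure from framewise RMS energy (25 ms / 10 ms).

    Speech frames exceed ``vad_threshold`` times the 95th-percentile frame
    RMS; pauses are maximal non-speech runs of at least ``min_pause_s``
    strictly between speech segments (leading/trailing silence is not a
    pause). pause_fraction = pause time / (speech + pause time).
    """
    sr = audio.sample_rate
    window = int(round(config.energy_window_s * sr))
    step = max(1, int(round(config.energy_step_s * sr)))
    frames = _frame(audio.samples, window, step)
    if frames.shape[0] == 0:
        return PauseFeatures(0.0, 0.0, [], has_speech=False)
    rms = np.sqrt((frames**2).mean(axis=1))
    ref = np.percentile(rms, 95)
    speech = rms > config.vad_threshold * ref
    if ref <= 0 or not speech.any():
        return PauseFeatures(0.0, 0.0, [], has_speech=False)
    first, last = np.flatnonzero(speech)[[0, -1]]
    min_pause_frames = max(1, int(round(config.min_pause_s / config.energy_step_s)))
    segments: list[tuple[float, float]] = []
    run_start = None
    inner = speech[first : last + 1]
    for i, is_speech in enumerate(inner):
        if not is_speech and run_start is None:
            run_start = i
        elif is_speech and run_start is not None:
            if i - run_start >= min_pause_frames:
                t0 = (first + run_start) * config.energy_step_s
                t1 = (first + i) * config.energy_step_s
                segments.append((t0, t1))
            run_start = None
    pause_time = sum(t1 - t0 for t0, t1 in segments)
    active_time = (last - first + 1) * config.energy_step_s
    speech_time = active_time - pause_time
    total = speech_time + pause_time
    return PauseFeatures(
        pause_fraction=pause_time / total if total > 0 else 0.0,
        mean_pause_duration=(pause_time / len(segments)) if segments else 0.0,
        segments=segments,
        has_speech=True,
    )


def acoustic_feature_set(
    audio: AudioSegment, config: AcousticConfig = AcousticConfig()
) -> AcousticFeatureSet:
    """Compose the nine acoustic features for one response.

    F0 statistics, formant means, and HNR are missing (NaN) when no frame
    is voiced; pause features are missing when no speech activity is
    detected. Deterministic: two calls on the same audio give identical
    output.
    """
    track = estimate_f0_track(audio, config=config)
    voiced_f0 = track.f0[track.voiced]
    if voiced_f0.size:
        f0_mean = float(voiced_f0.mean())
        f0_median = float(np.median(voiced_f0))
        f0_std = float(voiced_f0.std())
        f1_mean, f2_mean = estimate_formants(
            audio, 2, config=config, voiced_mask=track.voiced
        )
        hnr = _hnr_from_track(track)
    else:
        f0_mean = f0_median = f0_std = f1_mean = f2_mean = hnr = math.nan
    pauses = detect_pauses(audio, config=config)
    return AcousticFeatureSet(
        f0_mean=f0_mean,
        f0_median=f0_median,
        f0_std=f0_std,
        f1_mean=f1_mean,
        f2_mean=f2_mean,
        hnr_median=hnr,
        pause_fraction=pauses.pause_fraction if pauses.has_speech else math.nan,
        mean_pause_duration=(
            pauses.mean_pause_duration if pauses.has_speech else math.nan
        ),
        voiced_fraction=track.voiced_fraction,
    )
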
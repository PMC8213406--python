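"""Fixed-size, normalized log-spectrogram images.

Every syllable, whatever its duration, becomes a 128 x 128 image with
values in [0, 1] — the unit the VAE consumes and produces.  The pipeline
is: log modulus of the short-time Fourier transform (Hann windows),
interpolation onto a fixed grid of mel- or linearly-spaced frequencies and
a time grid spanning the syllable, amplitude clipping, linear rescaling to
[0, 1], and symmetric zero-padding of the unoccupied time extent.

Short syllables are stretched in time by sqrt(t_max / t), which preserves
relative duration ordering while devoting more pixels to fine temporal
detail of brief syllables.  Syllables longer than ``t_max`` (default
200 ms) are discarded; :func:`batch_spectrograms` reports the counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

LOG_EPSILON = 1e-12  # numerical floor inside the log


class SyllableTooLong(ValueError):
    """Raised when a segment exceeds ``t_max`` — a discard signal, not a failure."""


@dataclass(frozen=True)
class SpectrogramConfig:
    """Spectrogram parameters.

    Defaults follow the songbird settings: Hann windows of 512 samples with
    256 overlap, mel-spaced frequencies 0.4-10 kHz, 128 x 128 pixels,
    maximum syllable duration ``t_max`` = 200 ms with sqrt time stretching.
    For mouse ultrasonic recordings use window 1024 / overlap 512 and
    linear spacing 30-110 kHz.

    ``clip_min`` / ``clip_max`` bound the log magnitudes before rescaling
    to [0, 1].  When left ``None`` they are calibrated from data quantiles
    (2nd and 99.8th percentile of log magnitudes over a calibration
    sample); see :func:`calibrate_clip`.
    """

    stft_window: int = 512
    stft_overlap: int = 256
    freq_spacing: str = "mel"  # "mel" | "linear"
    f_min: float = 400.0
    f_max: float = 10_000.0
    t_max: float = 0.2
    clip_min: float | None = None
    clip_max: float | None = None
    n_freq_bins: int = 128
    n_time_bins: int = 128
    stretch: bool = True

    def __post_init__(self):
        if not 0 < self.f_min < self.f_max:
            raise ValueError("need 0 < f_min < f_max")
        if self.stft_overlap >= self.stft_window:
            raise ValueError("stft_overlap must be < stft_window")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.freq_spacing not in ("mel", "linear"):
            raise ValueError(f"unknown freq_spacing {self.freq_spacing!r}")

    def target_frequencies(self) -> np.ndarray:
        """The image's frequency rows in Hz, low to high."""
        if self.freq_spacing == "linear":
            return np.linspace(self.f_min, self.f_max, self.n_freq_bins)
        return mel_to_hz(
            np.linspace(hz_to_mel(self.f_min), hz_to_mel(self.f_max), self.n_freq_bins)
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def stft_log_spectrogram(audio, rate, config: SpectrogramConfig):
    """Log modulus of the STFT.

    Returns ``(log_mag, freqs_hz, times_s)`` where ``log_mag`` has shape
    (frequencies, frames); natural log of (magnitude + 1e-12).  Frame times
    are window centers, starting at 0.
    """
    audio = np.asarray(audio, dtype=float)
    if len(audio) < config.stft_window:
        raise ValueError(
            f"audio has {len(audio)} samples; need at least one STFT window "
            f"({config.stft_window} samples)"
        )
    hop = config.stft_window - config.stft_overlap
    sft = ShortTimeFFT(
        hann(config.stft_window, sym=False), hop=hop, fs=rate, mfft=config.stft_window
    )
    mag = np.abs(sft.stft(audio))
    freqs = sft.f
    times = sft.t(len(audio))
    return np.log(mag + LOG_EPSILON), freqs, times


def _interpolate_image(log_mag, freqs, times, target_f, target_t):
    """Bilinear interpolation of the STFT grid at target freqs x times."""
    if log_mag.shape[1] < 2:  # degenerate: single frame; duplicate it
        log_mag = np.repeat(log_mag, 2, axis=1)
        times = np.array([times[0], times[0] + 1e-6])
    interp = RegularGridInterpolator(
        (freqs, times), log_mag, bounds_error=False, fill_value=None, method="linear"
    )
    ff, tt = np.meshgrid(target_f, target_t, indexing="ij")
    return interp(np.stack([ff.ravel(), tt.ravel()], axis=-1)).reshape(ff.shape)


def _normalize(image, clip_min, clip_max):
    if clip_min is None or clip_max is None:
        clip_min = float(np.quantile(image, 0.02)) if clip_min is None else clip_min
        clip_max = float(np.quantile(image, 0.998)) if clip_max is None else clip_max
    if clip_max <= clip_min:
        raise ValueError("degenerate clip range: clip_max <= clip_min")
    return (np.clip(image, clip_min, clip_max) - clip_min) / (clip_max - clip_min)


def occupied_columns(t: float, config: SpectrogramConfig) -> int:
    """Number of signal (non-padding) time columns for a syllable of duration t.

    The stretched duration is ``t * sqrt(t_max / t) = sqrt(t * t_max)``, so
    the occupied fraction of the t_max frame is ``sqrt(t / t_max)``.
    """
    frac = np.sqrt(t / config.t_max) if config.stretch else t / config.t_max
    return int(np.clip(round(config.n_time_bins * frac), 1, config.n_time_bins))


def syllable_to_image(audio, rate, onset_s, offset_s, config: SpectrogramConfig):
    """Render one syllable as a normalized fixed-size spectrogram image.

    Raises :class:`SyllableTooLong` for durations above ``config.t_max``
    (the caller is expected to discard these) and ``ValueError`` for other
    invalid inputs.  The occupied time extent is centered in the frame and
    the remainder zero-padded symmetrically.
    """
    t = offset_s - onset_s
    if t <= 0:
        raise ValueError("segment duration must be positive")
    if t > config.t_max * (1 + 1e-9):  # relative slack for float roundoff
        raise SyllableTooLong(
            f"syllable duration {t:.4f}s exceeds t_max={config.t_max}s"
        )
    i0 = max(0, int(onset_s * rate) - config.stft_window)
    i1 = min(len(audio), int(offset_s * rate) + config.stft_window)
    log_mag, freqs, times = stft_log_spectrogram(audio[i0:i1], rate, config)
    n_occ = occupied_columns(t, config)
    # sample at frame centers within [onset, offset), relative to the slice
    local_onset = onset_s - i0 / rate
    target_t = local_onset + (np.arange(n_occ) + 0.5) * t / n_occ
    target_f = config.target_frequencies()
    occupied = _interpolate_image(log_mag, freqs, times, target_f, target_t)
    occupied = _normalize(occupied, config.clip_min, config.clip_max)
    image = np.zeros((config.n_freq_bins, config.n_time_bins))
    left = (config.n_time_bins - n_occ) // 2
    image[:, left : left + n_occ] = occupied
    return image


def window_to_image(audio, rate, onset_s, duration_s, config: SpectrogramConfig):
    """Full-frame spectrogram of a fixed-duration window (no stretch, no padding).

    Used by the shotgun sampler: every column is signal, spanning exactly
    ``[onset_s, onset_s + duration_s)``.
    """
    i0 = max(0, int(onset_s * rate) - config.stft_window)
    i1 = min(len(audio), int((onset_s + duration_s) * rate) + config.stft_window)
    log_mag, freqs, times = stft_log_spectrogram(audio[i0:i1], rate, config)
    local_onset = onset_s - i0 / rate
    n = config.n_time_bins
    target_t = local_onset + (np.arange(n) + 0.5) * duration_s / n
    occupied = _interpolate_image(
        log_mag, freqs, times, config.target_frequencies(), target_t
    )
    return _normalize(occupied, config.clip_min, config.clip_max)


def calibrate_clip(
    audio_set: dict,
    segments,
    config: SpectrogramConfig,
    max_segments: int = 64,
    quantiles=(0.02, 0.998),
) -> SpectrogramConfig:
    """Resolve ``clip_min``/``clip_max`` from data quantiles.

    A reproducible surrogate for per-dataset manual tuning: log magnitudes
    are pooled over up to *max_segments* segments (evenly subsampled) and
    the 2nd / 99.8th percentiles become the clip bounds.
    """
    idx = np.linspace(0, len(segments) - 1, min(max_segments, len(segments))).astype(int)
    pool = []
    for _, row in segments.iloc[idx].iterrows():
        wave, rate = audio_set[row["recording"]]
        i0 = max(0, int(row["onset_s"] * rate))
        i1 = min(len(wave), int(row["offset_s"] * rate) + config.stft_window)
        log_mag, _, _ = stft_log_spectrogram(wave[i0:i1], rate, config)
        pool.append(log_mag.ravel())
    pool = np.concatenate(pool)
    lo, hi = np.quantile(pool, quantiles)
    return replace(config, clip_min=float(lo), clip_max=float(hi))


def batch_spectrograms(audio_set: dict, segments, config: SpectrogramConfig):
    """Render all segments; returns ``(images, report)``.

    ``images`` is an array of shape (kept, n_freq_bins, n_time_bins) in the
    original segment order; ``report`` holds kept/discarded counts and the
    boolean keep mask.  Unknown recording ids raise ``KeyError`` listing
    all offenders.  ``clip_min``/``clip_max`` left unset are calibrated
    once over the batch, so all images share one normalization.
    """
    missing = sorted(set(segments["recording"]) - set(audio_set))
    if missing:
        raise KeyError(f"segments reference unknown recordings: {missing}")
    if len(segments) == 0:
        return np.zeros((0, config.n_freq_bins, config.n_time_bins)), {
            "kept": 0,
            "discarded": 0,
            "keep_mask": np.zeros(0, dtype=bool),
        }
    if config.clip_min is None or config.clip_max is None:
        durs = segments["offset_s"] - segments["onset_s"]
        ok = segments[durs <= config.t_max]
        config = calibrate_clip(audio_set, ok if len(ok) else segments, config)
    images, keep = [], []
    for _, row in segments.iterrows():
        wave, rate = audio_set[row["recording"]]
        try:
            images.append(
                syllable_to_image(wave, rate, row["onset_s"], row["offset_s"], config)
            )
            keep.append(True)
        except SyllableTooLong:
            keep.append(False)
    keep = np.array(keep, dtype=bool)
    images = np.stack(images) if images else np.zeros(
        (0, config.n_freq_bins, config.n_time_bins)
    )
    report = {
        "kept": int(keep.sum()),
        "discarded": int((~keep).sum()),
        "keep_mask": keep,
        "config": config,
    }
    return images, report
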
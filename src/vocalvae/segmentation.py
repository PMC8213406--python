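"""Template-based motif detection and rule-based motif cleanup.

Stereotyped song motifs are found by normalized cross-correlation between a
template spectrogram (the blurred average of a few representative motif
renditions) and the running log-STFT of each recording.  Matches are local
maxima of the correlation trace exceeding the per-file
median + 1.8 median-absolute-deviations.  A separate cleanup pass merges
sub-50 ms gaps inside motifs and discards merged segments with durations
outside 0.4-1.5 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from vocalvae.segments import make_segment_table, validate_segment_table
from vocalvae.spectrogram import SpectrogramConfig, stft_log_spectrogram

DEFAULT_THRESHOLD_MADS = 1.8
DEFAULT_MAX_GAP_S = 0.05
DEFAULT_DURATION_BOUNDS = (0.4, 1.5)


@dataclass
class MotifTemplate:
    """A motif spectrogram template at raw log-STFT resolution."""

    pixels: np.ndarray  # (freq bins, frames)
    duration_s: float
    provenance: tuple = ()

    def __post_init__(self):
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("template contains non-finite values")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


def build_template(
    example_segments,
    audio_set: dict,
    config: SpectrogramConfig,
    blur_sigma_px: float = 0.5,
    duration_tolerance: float = 0.1,
) -> MotifTemplate:
    """Average example motif spectrograms into a matched-filter template.

    Per-example log-STFTs (no fixed-size resampling) are cropped to the
    shortest frame count, averaged elementwise, and blurred with an
    isotropic Gaussian of 0.5 pixel standard deviation.  Examples whose
    durations spread more than *duration_tolerance* (relative) raise.
    """
    validate_segment_table(example_segments)
    if len(example_segments) == 0:
        raise ValueError("need at least one example segment")
    durs = (example_segments["offset_s"] - example_segments["onset_s"]).to_numpy()
    if (durs.max() - durs.min()) > duration_tolerance * durs.mean():
        raise ValueError(
            f"example durations spread {durs.min():.3f}-{durs.max():.3f}s exceeds "
            f"tolerance {duration_tolerance:.0%} of the mean"
        )
    specs = []
    for _, row in example_segments.iterrows():
        wave, rate = audio_set[row["recording"]]
        i0, i1 = round(row["onset_s"] * rate), round(row["offset_s"] * rate)
        log_mag, _, _ = stft_log_spectrogram(wave[i0:i1], rate, config)
        specs.append(log_mag)
    n_frames = min(s.shape[1] for s in specs)
    mean = np.mean([s[:, :n_frames] for s in specs], axis=0)
    if blur_sigma_px > 0:
        mean = gaussian_filter(mean, sigma=blur_sigma_px)
    return MotifTemplate(
        pixels=mean,
        duration_s=float(durs.mean()),
        provenance=tuple(example_segments.index),
    )


def _normalized_xcorr(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Pearson correlation of the template against each time offset of image.

    Zero-mean, unit-norm over the template support; degenerate (constant)
    patches or template yield correlation 0 rather than dividing by zero.
    """
    f, w = template.shape
    n_offsets = image.shape[1] - w + 1
    if n_offsets < 1:
        raise ValueError("audio spectrogram shorter than template")
    t = template - template.mean()
    t_norm = np.linalg.norm(t)
    if t_norm == 0:
        return np.zeros(n_offsets)
    # sliding-window view over time offsets: (n_offsets, f, w)
    patches = np.lib.stride_tricks.sliding_window_view(image, (f, w))[0]
    p = patches - patches.mean(axis=(1, 2), keepdims=True)
    p_norm = np.linalg.norm(p.reshape(n_offsets, -1), axis=1)
    num = np.einsum("ofw,fw->o", p, t)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(p_norm > 0, num / (p_norm * t_norm), 0.0)
    return corr


def _local_maxima(trace: np.ndarray) -> np.ndarray:
    """Strict one-neighbor maxima; plateaus credit the earliest offset."""
    if len(trace) < 3:
        return np.array([], dtype=int)
    left = trace[1:-1] > trace[:-2]
    right = trace[1:-1] >= trace[2:]
    strict_somewhere = (trace[1:-1] > trace[2:]) | (trace[1:-1] > trace[:-2])
    idx = np.where(left & right & strict_somewhere)[0] + 1
    return idx


def match_template(
    template: MotifTemplate,
    audio,
    rate,
    config: SpectrogramConfig,
    threshold_mads: float = DEFAULT_THRESHOLD_MADS,
    recording: str = "rec0",
) -> pd.DataFrame:
    """Find motif onsets by thresholded normalized cross-correlation.

    The correlation trace is sampled once per STFT hop.  Matches are local
    maxima whose score exceeds ``median + threshold_mads * MAD`` (median and
    raw MAD computed over this file's trace).  Returns a match list with
    columns ``recording, time_s, score``.
    """
    log_mag, _, times = stft_log_spectrogram(audio, rate, config)
    corr = _normalized_xcorr(log_mag, template.pixels)
    if len(corr) == 0 or np.allclose(corr, corr[0]):
        return pd.DataFrame(columns=["recording", "time_s", "score"])
    med = np.median(corr)
    mad = np.median(np.abs(corr - med))
    cutoff = med + threshold_mads * mad
    peaks = _local_maxima(corr)
    peaks = peaks[corr[peaks] > cutoff]
    return pd.DataFrame(
        {"recording": recording, "time_s": times[peaks], "score": corr[peaks]}
    )


def matches_to_segments(matches: pd.DataFrame, duration_s: float) -> pd.DataFrame:
    """Expand match onset times into fixed-duration segments."""
    return make_segment_table(
        [
            (row["recording"], row["time_s"], row["time_s"] + duration_s, "motif")
            for _, row in matches.iterrows()
        ],
        extra_columns=("label",),
    )


def rank_cutoff(matches: pd.DataFrame, keep_top: int) -> pd.DataFrame:
    """Retain the *keep_top* highest-scoring matches.

    A non-interactive stand-in for manual curation of match clusters.
    """
    return matches.nlargest(keep_top, "score").sort_values("time_s").reset_index(
        drop=True
    )


def clean_motif_segments(
    segments,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    duration_bounds=DEFAULT_DURATION_BOUNDS,
) -> pd.DataFrame:
    """Merge short gaps inside motifs, then filter by duration.

    Consecutive same-recording segments separated by less than *max_gap_s*
    are merged; merged segments with durations outside *duration_bounds*
    are discarded.  Idempotent, never increases the segment count, and
    never produces overlapping output.
    """
    validate_segment_table(segments)
    out = []
    for rec, group in segments.groupby("recording", sort=False):
        group = group.sort_values("onset_s")
        cur_on, cur_off = None, None
        for _, row in group.iterrows():
            if cur_on is None:
                cur_on, cur_off = row["onset_s"], row["offset_s"]
            elif row["onset_s"] - cur_off < max_gap_s:
                cur_off = max(cur_off, row["offset_s"])
            else:
                out.append((rec, cur_on, cur_off))
                cur_on, cur_off = row["onset_s"], row["offset_s"]
        if cur_on is not None:
            out.append((rec, cur_on, cur_off))
    lo, hi = duration_bounds
    out = [(r, a, b) for r, a, b in out if lo <= b - a <= hi]
    return make_segment_table(out)
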
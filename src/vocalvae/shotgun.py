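"""Segmentation-free ("shotgun") window sampling and time warping.

Instead of training on segmented syllables, fixed-duration windows are
drawn uniformly at random from annotated regions of active vocalization
(120 ms for zebra finch, 200 ms for mouse, 60 ms for tutor/pupil
comparisons) and converted to full-frame spectrograms on the fly, so the
model effectively never sees the same image twice.  For time-resolved
variability analysis, renditions of a motif are aligned by a piecewise-
linear warp onto a common [0, 1] clock and latents are collected on a grid
equally spaced in *warped* time.

The default warp is the 2-knot linear map of each rendition's extent onto
[0, 1]; externally fitted multi-knot piecewise-linear warps can be
supplied as knot tables and are validated and consumed but not fitted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vocalvae.segments import validate_segment_table
from vocalvae.spectrogram import SpectrogramConfig, window_to_image

DEFAULT_GRID_POINTS = 200
DEFAULT_STRIDE_S = 0.008  # 8 ms step between successive tutor/pupil windows


@dataclass(frozen=True)
class WindowSpec:
    """Fixed-duration random-window sampling plan over vocal regions."""

    duration_s: float
    regions: pd.DataFrame  # segment table of vocal bouts
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        validate_segment_table(self.regions)

    def admissible(self) -> pd.DataFrame:
        """Regions long enough to hold a full window, with slack lengths."""
        regions = self.regions.copy()
        slack = regions["offset_s"] - regions["onset_s"] - self.duration_s
        ok = slack >= -1e-12  # regions exactly window-sized admit onset = start
        return regions[ok].assign(slack=slack[ok].clip(lower=0.0))


def draw_window(spec: WindowSpec, rng=None):
    """Draw one (recording, onset_s) uniformly over admissible positions.

    The onset is uniform over the union of intervals
    [region start, region end - duration], each region weighted by its
    admissible length, so the window always lies wholly inside one region.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    adm = spec.admissible()
    if len(adm) == 0:
        raise ValueError("no region admits a full window")
    total = adm["slack"].sum()
    if total == 0:  # all regions exactly window-sized
        row = adm.iloc[rng.integers(len(adm))]
        return row["recording"], float(row["onset_s"])
    pos = rng.uniform(0.0, total)
    cum = 0.0
    for _, row in adm.iterrows():
        if pos <= cum + row["slack"]:
            return row["recording"], float(row["onset_s"] + (pos - cum))
        cum += row["slack"]
    row = adm.iloc[-1]
    return row["recording"], float(row["onset_s"] + row["slack"])


def shotgun_stream(spec: WindowSpec, audio_set: dict, config: SpectrogramConfig):
    """Infinite generator of freshly computed window spectrograms.

    Reproducible: a fixed spec.seed reproduces the same window sequence.
    """
    rng = np.random.default_rng(spec.seed)
    while True:
        rec, onset = draw_window(spec, rng)
        wave, rate = audio_set[rec]
        yield window_to_image(wave, rate, onset, spec.duration_s, config)


def make_sampler(spec: WindowSpec, audio_set: dict, config: SpectrogramConfig):
    """A batch sampler suitable for :func:`vocalvae.vae.train`."""

    def sampler(batch_size, rng):
        out = []
        for _ in range(batch_size):
            rec, onset = draw_window(spec, rng)
            wave, rate = audio_set[rec]
            out.append(window_to_image(wave, rate, onset, spec.duration_s, config))
        return np.stack(out)

    return sampler


@dataclass
class WarpMap:
    """Piecewise-linear map from real time (s) to warped time in [0, 1]."""

    knots: np.ndarray  # (n_knots, 2): (real_s, warped), strictly increasing

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.ndim != 2 or self.knots.shape[0] < 2:
            raise ValueError("need at least 2 knots")
        real, warped = self.knots[:, 0], self.knots[:, 1]
        if np.any(np.diff(real) <= 0) or np.any(np.diff(warped) <= 0):
            raise ValueError("warp knots must be strictly increasing in both axes")
        if not (np.isclose(warped[0], 0.0) and np.isclose(warped[-1], 1.0)):
            raise ValueError("warped time must span 0 to 1")

    def warp(self, t):
        return np.interp(t, self.knots[:, 0], self.knots[:, 1])

    def inverse(self, w):
        return np.interp(w, self.knots[:, 1], self.knots[:, 0])


def fit_linear_warp(renditions) -> list:
    """Default 2-knot warps mapping each rendition's [start, end] to [0, 1]."""
    validate_segment_table(renditions)
    return [
        WarpMap(np.array([[row["onset_s"], 0.0], [row["offset_s"], 1.0]]))
        for _, row in renditions.iterrows()
    ]


def read_warp_knots(path, renditions) -> list:
    """Load externally fitted warps from CSV (rendition, real_s, warped)."""
    df = pd.read_csv(path)
    warps = []
    for i, (_, row) in enumerate(renditions.iterrows()):
        sub = df[df["rendition"] == i].sort_values("real_s")
        warps.append(WarpMap(sub[["real_s", "warped"]].to_numpy()))
    return warps


def warped_grid_windows(
    audio,
    rate,
    rendition,
    warp: WarpMap,
    config: SpectrogramConfig,
    n_points: int = DEFAULT_GRID_POINTS,
    window_s: float = 0.12,
):
    """Window spectrograms centered at a warped-time grid over one rendition.

    Centers are ``warp^{-1}`` of n_points equally spaced warped times —
    generally nonlinearly spaced in real time.  Edge windows are shifted
    inward so every window lies inside the rendition (no zero-padding).
    Returns ``(images, onsets)``.
    """
    start, end = rendition["onset_s"], rendition["offset_s"]
    if window_s > end - start:
        raise ValueError("window_s longer than the rendition")
    centers = warp.inverse(np.linspace(0.0, 1.0, n_points))
    onsets = np.clip(centers - window_s / 2.0, start, end - window_s)
    images = np.stack(
        [window_to_image(audio, rate, o, window_s, config) for o in onsets]
    )
    return images, onsets


def strided_windows(rendition, window_s: float, stride_s: float = DEFAULT_STRIDE_S):
    """Fixed-stride window onsets spanning a rendition (8 ms default step)."""
    start, end = rendition["onset_s"], rendition["offset_s"]
    if window_s > end - start:
        raise ValueError("window_s longer than the rendition")
    return np.arange(start, end - window_s + 1e-12, stride_s)
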
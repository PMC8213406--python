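"""Seeded synthetic vocal datasets with known ground truth.

Syllables are synthesized as frequency-modulated chirps: an instantaneous
frequency trajectory is defined by a few (time-fraction, Hz) knots, smoothly
interpolated (monotone cubic) and integrated by phase accumulation, which
yields band-limited tones resembling ultrasonic vocalization contours or
song syllable sweeps.  A repertoire is a set of such *archetypes*; the
clustered regime draws an archetype per syllable and jitters its knots,
while the continuum regime interpolates knots between adjacent archetypes
along a one-dimensional coordinate, producing a gapless manifold of shapes.

Every generator is a pure function of its specification and seed, and every
emitted syllable carries its ground truth (archetype id or continuum
coordinate), so downstream parameter-recovery tests can score themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.io import wavfile

from vocalvae.segments import make_segment_table


@dataclass(frozen=True)
class SyllableArchetype:
    """A parametric syllable shape.

    Parameters
    ----------
    id : str
        Label recorded as ground truth.
    freq_knots : sequence of (float, float)
        (time fraction in [0, 1], frequency in Hz) control points of the
        instantaneous-frequency trajectory.  Time fractions must increase
        strictly from 0 to 1.
    duration_s : float
        Nominal syllable duration in seconds.
    amplitude_env : sequence of (float, float)
        (time fraction, gain in [0, 1]) control points of the amplitude
        envelope, linearly interpolated.
    harmonics : int
        Number of harmonic stacks (>= 1); harmonics above Nyquist are
        omitted at synthesis time.
    """

    id: str
    freq_knots: tuple
    duration_s: float
    amplitude_env: tuple = ((0.0, 0.0), (0.1, 1.0), (0.9, 1.0), (1.0, 0.0))
    harmonics: int = 1

    def __post_init__(self):
        fracs = [t for t, _ in self.freq_knots]
        if len(fracs) < 2 or fracs[0] != 0.0 or fracs[-1] != 1.0:
            raise ValueError("freq_knots time fractions must span 0 to 1")
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("freq_knots time fractions must strictly increase")
        if any(f <= 0 for _, f in self.freq_knots):
            raise ValueError("knot frequencies must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.harmonics < 1:
            raise ValueError("harmonics must be >= 1")


@dataclass(frozen=True)
class RepertoireSpec:
    """Specification of a synthetic repertoire recording."""

    archetypes: tuple
    regime: str = "clustered"  # "clustered" | "continuum"
    jitter_scale: float = 0.05
    n_syllables: int = 100
    gap_s: tuple = (0.05, 0.15)
    noise_floor: float = 1e-3
    sample_rate: int = 32000
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ("clustered", "continuum"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_syllables < 1:
            raise ValueError("n_syllables must be >= 1")
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be >= 0")
        if self.regime == "continuum" and len(self.archetypes) < 2:
            raise ValueError("continuum regime requires >= 2 archetypes")
        if not self.archetypes:
            raise ValueError("at least one archetype required")


@dataclass
class SyntheticDataset:
    """Audio + segments + per-syllable ground truth.

    Attributes
    ----------
    audio : dict
        Maps recording id to ``(waveform, sample_rate)``.
    segments : pandas.DataFrame
        Segment table; one row per syllable, with a ``truth`` column
        (archetype id or continuum coordinate) and optionally ``condition``.
    motifs : pandas.DataFrame or None
        Motif-level segment table for motif datasets.
    """

    audio: dict
    segments: pd.DataFrame
    motifs: pd.DataFrame | None = None

    def write_wavs(self, directory):
        """Write one float32 WAV per recording into *directory*."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for rec, (wave, rate) in self.audio.items():
            wavfile.write(directory / f"{rec}.wav", rate, wave.astype(np.float32))


def _jittered_knots(archetype, jitter_scale, rng):
    """Multiplicatively perturb knot frequencies; returns (fracs, freqs, dur)."""
    fracs = np.array([t for t, _ in archetype.freq_knots])
    freqs = np.array([f for _, f in archetype.freq_knots], dtype=float)
    dur = archetype.duration_s
    if jitter_scale > 0:
        freqs = freqs * (1.0 + jitter_scale * rng.standard_normal(len(freqs)))
        freqs = np.clip(freqs, 1.0, None)
        dur = dur * max(0.2, 1.0 + jitter_scale * rng.standard_normal())
    return fracs, freqs, dur


def _synthesize(fracs, freqs, duration_s, amplitude_env, harmonics, sample_rate):
    """Phase-accumulation chirp synthesis from a knot trajectory."""
    nyquist = sample_rate / 2.0
    if np.any(freqs >= nyquist):
        raise ValueError(
            f"knot frequency {freqs.max():.1f} Hz at or above Nyquist ({nyquist:.1f} Hz)"
        )
    n = max(2, int(round(duration_s * sample_rate)))
    t = np.arange(n) / sample_rate
    # monotone cubic keeps the trajectory inside the knot range (no overshoot
    # past Nyquist between knots)
    inst_freq = PchipInterpolator(fracs * duration_s, freqs)(t)
    phase = 2.0 * np.pi * np.cumsum(inst_freq) / sample_rate
    env_t = np.array([a for a, _ in amplitude_env]) * duration_s
    env_g = np.array([g for _, g in amplitude_env])
    envelope = np.interp(t, env_t, env_g)
    wave = np.zeros(n)
    for h in range(1, harmonics + 1):
        if freqs.max() * h >= nyquist:
            break
        wave += np.sin(h * phase) / h
    return (envelope * wave).astype(np.float64)


def generate_syllable(
    archetype: SyllableArchetype,
    jitter_scale: float = 0.0,
    seed: int = 0,
    sample_rate: int = 32000,
) -> np.ndarray:
    """Synthesize one (jittered) syllable waveform.

    Deterministic: identical arguments produce bit-identical output.
    Raises ``ValueError`` for knot frequencies at or above Nyquist.
    """
    rng = np.random.default_rng(seed)
    fracs, freqs, dur = _jittered_knots(archetype, jitter_scale, rng)
    return _synthesize(
        fracs, freqs, dur, archetype.amplitude_env, archetype.harmonics, sample_rate
    )


def _interpolated_archetype(archetypes, u):
    """Linear knot-space interpolation at continuum coordinate u in [0, 1].

    Archetypes are ordered by id; u is scaled onto the [0, K-1] archetype
    axis and knots are blended between the two nearest neighbors.  All
    archetypes must share a common knot count for the blend to be defined.
    """
    ordered = sorted(archetypes, key=lambda a: a.id)
    k = len(ordered)
    x = u * (k - 1)
    lo = min(int(np.floor(x)), k - 2)
    w = x - lo
    a, b = ordered[lo], ordered[lo + 1]
    if len(a.freq_knots) != len(b.freq_knots):
        raise ValueError("continuum interpolation requires equal knot counts")
    fracs = np.array([t for t, _ in a.freq_knots])
    fa = np.array([f for _, f in a.freq_knots])
    fb = np.array([f for _, f in b.freq_knots])
    freqs = (1 - w) * fa + w * fb
    dur = (1 - w) * a.duration_s + w * b.duration_s
    return fracs, freqs, dur, a


def generate_repertoire(spec: RepertoireSpec) -> SyntheticDataset:
    """Generate a single-recording repertoire with ground truth.

    Clustered regime: archetype drawn uniformly per syllable, then knot
    jitter.  Continuum regime: coordinate ``u ~ Uniform[0, 1]`` selects an
    interpolated archetype.  Syllables are laid out sequentially with gaps
    drawn uniformly from ``spec.gap_s``; white Gaussian noise at
    ``spec.noise_floor`` covers the whole recording.
    """
    rng = np.random.default_rng(spec.seed)  # one stream per recording
    rate = spec.sample_rate
    pieces, rows = [], []
    cursor = rng.uniform(*spec.gap_s)
    pieces.append(np.zeros(int(cursor * rate)))
    for i in range(spec.n_syllables):
        if spec.regime == "clustered":
            arch = spec.archetypes[rng.integers(len(spec.archetypes))]
            fracs, freqs, dur = _jittered_knots(arch, spec.jitter_scale, rng)
            truth = arch.id
            env, harm = arch.amplitude_env, arch.harmonics
        else:
            u = float(rng.uniform())
            fracs, freqs, dur, proto = _interpolated_archetype(spec.archetypes, u)
            if spec.jitter_scale > 0:
                freqs = np.clip(
                    freqs * (1 + spec.jitter_scale * rng.standard_normal(len(freqs))),
                    1.0,
                    None,
                )
            truth = u
            env, harm = proto.amplitude_env, proto.harmonics
        wave = _synthesize(fracs, freqs, dur, env, harm, rate)
        onset = cursor
        offset = cursor + len(wave) / rate
        rows.append(("rec0", onset, offset, str(truth), truth))
        pieces.append(wave)
        gap = rng.uniform(*spec.gap_s)
        pieces.append(np.zeros(int(gap * rate)))
        cursor = offset + int(gap * rate) / rate
    audio = np.concatenate(pieces)
    if spec.noise_floor > 0:
        audio = audio + spec.noise_floor * rng.standard_normal(len(audio))
    segments = make_segment_table(rows, extra_columns=("label", "truth"))
    return SyntheticDataset(audio={"rec0": (audio, rate)}, segments=segments)


def generate_two_condition(
    spec: RepertoireSpec, variability_ratio: float
) -> SyntheticDataset:
    """Two-condition repertoire emulating directed vs. undirected song.

    Condition ``A`` uses ``jitter_scale * variability_ratio`` (the
    low-variability, "directed" analogue), condition ``B`` the full
    ``jitter_scale``.  Syllable counts are equal (``n_syllables // 2``
    each); a ``condition`` column is recorded.
    """
    if not 0 < variability_ratio <= 1:
        raise ValueError("variability_ratio must be in (0, 1]")
    half = spec.n_syllables // 2
    spec_a = replace(
        spec,
        n_syllables=half,
        jitter_scale=spec.jitter_scale * variability_ratio,
        seed=spec.seed,
    )
    spec_b = replace(spec, n_syllables=half, seed=spec.seed + 1)
    ds_a = generate_repertoire(spec_a)
    ds_b = generate_repertoire(spec_b)
    wave_a, rate = ds_a.audio["rec0"]
    wave_b, _ = ds_b.audio["rec0"]
    seg_a = ds_a.segments.assign(condition="A")
    seg_b = ds_b.segments.assign(condition="B")
    seg_b = seg_b.assign(
        onset_s=seg_b["onset_s"] + len(wave_a) / rate,
        offset_s=seg_b["offset_s"] + len(wave_a) / rate,
    )
    segments = pd.concat([seg_a, seg_b], ignore_index=True)
    return SyntheticDataset(
        audio={"rec0": (np.concatenate([wave_a, wave_b]), rate)}, segments=segments
    )


def generate_motif_dataset(
    archetype_sequence,
    n_renditions: int,
    tempo_jitter: float = 0.0,
    jitter_scale: float = 0.0,
    seed: int = 0,
    sample_rate: int = 32000,
    intra_gap_s: float = 0.02,
    inter_gap_s: float = 0.3,
    noise_floor: float = 0.0,
    corrupt_index: int | None = None,
    corrupt_freq_scale: float = 1.3,
) -> SyntheticDataset:
    """Renditions of a fixed syllable sequence with global tempo jitter.

    Each rendition concatenates ``archetype_sequence`` with a per-rendition
    tempo factor drawn uniformly from ``[1 - tempo_jitter, 1 + tempo_jitter]``
    (durations and intra-motif gaps scale together); ``jitter_scale``
    additionally perturbs each syllable's knot frequencies, giving
    rendition-to-rendition acoustic variability.  Setting
    ``corrupt_index`` shifts that archetype's knot frequencies by
    ``corrupt_freq_scale`` — the "pupil" variant emulating poor copying of
    one syllable; all other syllables are synthesized from seeds shared with
    the uncorrupted ("tutor") dataset, so at zero jitter they are
    bit-identical across the pair.
    """
    if not archetype_sequence:
        raise ValueError("archetype_sequence must be nonempty")
    rng = np.random.default_rng(seed)
    rate = sample_rate
    pieces, rows, motif_rows = [], [], []
    cursor = inter_gap_s
    pieces.append(np.zeros(int(cursor * rate)))
    for r in range(n_renditions):
        tempo = 1.0 + tempo_jitter * float(rng.uniform(-1, 1))
        motif_onset = cursor
        for j, arch in enumerate(archetype_sequence):
            if corrupt_index is not None and j == corrupt_index:
                knots = tuple(
                    (t, f * corrupt_freq_scale) for t, f in arch.freq_knots
                )
                arch = replace(arch, freq_knots=knots)
            arch = replace(arch, duration_s=arch.duration_s * tempo)
            # seed shared across tutor/pupil variants: depends only on
            # (dataset seed, rendition, position)
            syl_seed = seed + 100_003 * r + j
            wave = generate_syllable(arch, jitter_scale, syl_seed, rate)
            onset = cursor
            offset = cursor + len(wave) / rate
            rows.append(("rec0", onset, offset, arch.id, arch.id, r, j))
            pieces.append(wave)
            gap_n = int(intra_gap_s * tempo * rate)
            if j < len(archetype_sequence) - 1:
                pieces.append(np.zeros(gap_n))
                cursor = offset + gap_n / rate
            else:
                cursor = offset
        motif_rows.append(("rec0", motif_onset, cursor, f"motif{r}"))
        pieces.append(np.zeros(int(inter_gap_s * rate)))
        cursor += int(inter_gap_s * rate) / rate
    audio = np.concatenate(pieces)
    if noise_floor > 0:
        audio = audio + noise_floor * rng.standard_normal(len(audio))
    segments = make_segment_table(
        rows, extra_columns=("label", "truth", "motif", "position")
    )
    motifs = make_segment_table(motif_rows, extra_columns=("label",))
    return SyntheticDataset(
        audio={"rec0": (audio, rate)}, segments=segments, motifs=motifs
    )


def example_archetypes(
    n: int = 4, f_lo: float = 2000.0, f_hi: float = 9000.0, duration_s: float = 0.1
):
    """Well-separated chirp archetypes spanning [f_lo, f_hi].

    Shapes alternate among upsweep, downsweep, flat tone and U-shape, with
    center frequencies spread across the band — a miniature atlas of
    syllable shapes for recovery tests.
    """
    shapes = [
        lambda f: ((0.0, 0.7 * f), (0.5, f), (1.0, 1.3 * f)),
        lambda f: ((0.0, 1.3 * f), (0.5, f), (1.0, 0.7 * f)),
        lambda f: ((0.0, f), (0.5, 1.001 * f), (1.0, f)),
        lambda f: ((0.0, 1.25 * f), (0.5, 0.75 * f), (1.0, 1.25 * f)),
    ]
    centers = np.linspace(f_lo, f_hi, n)
    out = []
    for i, fc in enumerate(centers):
        knots = shapes[i % len(shapes)](fc)
        out.append(
            SyllableArchetype(
                id=f"arch{i}",
                freq_knots=tuple(knots),
                duration_s=duration_s * (0.8 + 0.4 * (i % 3) / 2),
            )
        )
    return tuple(out)
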
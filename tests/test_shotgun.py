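"""Shotgun window sampling and piecewise-linear time warps."""

import numpy as np
import pytest
from scipy.stats import chisquare, kstest

from vocalvae import shotgun, synth
from vocalvae import spectrogram as sg
from vocalvae.segments import make_segment_table


def _regions(rows):
    return make_segment_table(rows)


def test_exact_fit_region_onset_is_region_start():
    spec = shotgun.WindowSpec(0.2, _regions([("r", 1.0, 1.2)]), seed=0)
    for s in range(5):
        rec, onset = shotgun.draw_window(spec, np.random.default_rng(s))
        assert rec == "r" and onset == pytest.approx(1.0)


def test_length_weighted_region_choice():
    """Regions with admissible lengths L and 2L are chosen 1:2 (chi^2)."""
    spec = shotgun.WindowSpec(
        0.1, _regions([("r", 0.0, 0.6), ("r", 10.0, 11.1)]), seed=0
    )
    rng = np.random.default_rng(1)
    n = 6000
    hits = sum(shotgun.draw_window(spec, rng)[1] > 5 for _ in range(n))
    stat, p = chisquare([n - hits, hits], [n / 3, 2 * n / 3])
    assert p > 0.001


def test_window_never_crosses_region_boundary():
    regions = _regions([("r", 0.0, 0.5), ("r", 2.0, 2.3)])
    spec = shotgun.WindowSpec(0.12, regions, seed=3)
    rng = np.random.default_rng(3)
    for _ in range(200):
        _, onset = shotgun.draw_window(spec, rng)
        inside = ((onset >= 0.0) and (onset + 0.12 <= 0.5)) or (
            (onset >= 2.0) and (onset + 0.12 <= 2.3)
        )
        assert inside


def test_onset_uniformity_ks():
    """Window onsets over one region are uniform (KS, n=10^4, alpha=0.01)."""
    spec = shotgun.WindowSpec(0.1, _regions([("r", 0.0, 1.1)]), seed=0)
    rng = np.random.default_rng(7)
    onsets = np.array([shotgun.draw_window(spec, rng)[1] for _ in range(10_000)])
    assert kstest(onsets, "uniform", args=(0.0, 1.0)).pvalue > 0.01


def test_no_admissible_region_errors():
    spec = shotgun.WindowSpec(1.0, _regions([("r", 0.0, 0.5)]), seed=0)
    with pytest.raises(ValueError, match="admissible|admits"):
        shotgun.draw_window(spec)


def test_stream_reproducible_and_shaped(archetypes):
    ds = synth.generate_motif_dataset(archetypes[:3], 4, seed=2, noise_floor=1e-4)
    config = sg.SpectrogramConfig(clip_min=-20, clip_max=5)
    spec = shotgun.WindowSpec(0.12, ds.motifs, seed=9)
    first = [next(shotgun.shotgun_stream(spec, ds.audio, config)) for _ in range(1)]
    s1 = shotgun.shotgun_stream(spec, ds.audio, config)
    s2 = shotgun.shotgun_stream(spec, ds.audio, config)
    for _ in range(10):
        a, b = next(s1), next(s2)
        assert a.shape == (128, 128)
        np.testing.assert_array_equal(a, b)
        assert (a.max(axis=0) > 0).all()  # full-frame: no padding columns


class TestWarp:
    def test_linear_warps_identical_for_equal_durations(self):
        rend = _regions([("r", 0.0, 1.0), ("r", 5.0, 6.0)])
        w0, w1 = shotgun.fit_linear_warp(rend)
        t = np.linspace(0, 1, 11)
        np.testing.assert_allclose(w0.warp(t), w1.warp(t + 5.0))

    def test_double_duration_midpoint(self):
        rend = _regions([("r", 0.0, 2.0)])
        (w,) = shotgun.fit_linear_warp(rend)
        assert w.warp(1.0) == pytest.approx(0.5)

    def test_three_knot_piecewise_linearity(self):
        w = shotgun.WarpMap(np.array([[0.0, 0.0], [0.6, 0.4], [1.0, 1.0]]))
        probes = np.array([0.15, 0.3, 0.45])
        np.testing.assert_allclose(w.warp(probes), probes * (0.4 / 0.6), atol=1e-12)
        probes2 = np.array([0.7, 0.9])
        np.testing.assert_allclose(
            w.warp(probes2), 0.4 + (probes2 - 0.6) * (0.6 / 0.4), atol=1e-12
        )

    def test_round_trip(self):
        w = shotgun.WarpMap(np.array([[0.2, 0.0], [0.9, 0.35], [2.0, 1.0]]))
        t = np.linspace(0.2, 2.0, 57)
        np.testing.assert_allclose(w.inverse(w.warp(t)), t, atol=1e-9)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            shotgun.WarpMap(np.array([[0.0, 0.0], [0.5, 0.6], [1.0, 0.4]]))


def test_warped_grid_centers(archetypes):
    ds = synth.generate_motif_dataset(archetypes[:3], 2, seed=4, noise_floor=1e-4)
    config = sg.SpectrogramConfig(clip_min=-20, clip_max=5)
    rend = ds.motifs.iloc[0]
    (warp,) = shotgun.fit_linear_warp(ds.motifs.iloc[:1])
    images, onsets = shotgun.warped_grid_windows(
        *ds.audio["rec0"], rend, warp, config, n_points=21, window_s=0.1
    )
    assert images.shape == (21, 128, 128)
    # linear warp: interior centers equally spaced in real time
    interior = onsets[3:-3]
    np.testing.assert_allclose(np.diff(interior), np.diff(interior)[0], atol=1e-9)
    # all windows inside the rendition (edge windows shifted inward)
    assert (onsets >= rend["onset_s"] - 1e-9).all()
    assert (onsets + 0.1 <= rend["offset_s"] + 1e-9).all()

    # nonlinear 3-knot warp: spacing differs across the knot, matching the
    # numerically inverted map
    mid_w = 0.3
    w3 = shotgun.WarpMap(
        np.array([
            [rend["onset_s"], 0.0],
            [rend["onset_s"] + 0.25 * (rend["offset_s"] - rend["onset_s"]), mid_w],
            [rend["offset_s"], 1.0],
        ])
    )
    _, onsets3 = shotgun.warped_grid_windows(
        *ds.audio["rec0"], rend, w3, config, n_points=21, window_s=0.1
    )
    grid = np.linspace(0, 1, 21)
    expected = np.clip(
        w3.inverse(grid) - 0.05, rend["onset_s"], rend["offset_s"] - 0.1
    )
    np.testing.assert_allclose(onsets3, expected, atol=1e-9)


def test_window_longer_than_rendition_errors(archetypes):
    ds = synth.generate_motif_dataset(archetypes[:2], 1, seed=4)
    (warp,) = shotgun.fit_linear_warp(ds.motifs)
    with pytest.raises(ValueError, match="longer"):
        shotgun.warped_grid_windows(
            *ds.audio["rec0"], ds.motifs.iloc[0], warp,
            sg.SpectrogramConfig(), n_points=5, window_s=10.0,
        )


def test_strided_windows_step():
    rend = {"onset_s": 1.0, "offset_s": 1.5}
    onsets = shotgun.strided_windows(rend, window_s=0.06, stride_s=0.008)
    np.testing.assert_allclose(np.diff(onsets), 0.008)
    assert onsets[0] == 1.0 and onsets[-1] + 0.06 <= 1.5 + 1e-9


def test_time_resolved_variability_ordering(archetypes, default_model):
    """Lower-jitter motif renditions show lower per-timepoint variability."""
    from vocalvae import stats, vae

    config = sg.SpectrogramConfig(clip_min=-18, clip_max=5)
    lat = {}
    for name, jit in (("low", 0.02), ("high", 0.08)):
        ds = synth.generate_motif_dataset(
            archetypes[:3], n_renditions=12, tempo_jitter=0.05, jitter_scale=jit,
            seed=13, noise_floor=1e-4,
        )
        warps = shotgun.fit_linear_warp(ds.motifs)
        wave, rate = ds.audio["rec0"]
        per_point = []
        for (_, rend), warp in zip(ds.motifs.iterrows(), warps):
            images, _ = shotgun.warped_grid_windows(
                wave, rate, rend, warp, config, n_points=15, window_s=0.1
            )
            per_point.append(vae.latent_means(images, default_model).to_numpy())
        lat[name] = np.stack(per_point)  # (renditions, points, latent)
    vi_low = [stats.variability_index_fast(lat["low"][:, p]) for p in range(15)]
    vi_high = [stats.variability_index_fast(lat["high"][:, p]) for p in range(15)]
    assert np.mean(np.array(vi_low) < np.array(vi_high)) > 0.5
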
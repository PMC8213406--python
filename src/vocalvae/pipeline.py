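"""End-to-end orchestration with hash-keyed stage caching.

A run is declared by a nested configuration (YAML/JSON-compatible dict):
synthetic-data spec or dataset paths, spectrogram settings, model settings,
and analysis blocks.  ``run_pipeline`` executes the stages

    generate/ingest -> spectrograms -> train -> latents -> statistics

caching each stage's outputs under a key derived from the configuration
subtree it depends on (plus upstream keys), so an unchanged rerun is a
cache hit for every stage and a seed change regenerates only the
stochastic stages.  Every run writes a frozen copy of the resolved
configuration and a JSON manifest of stage keys and outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from vocalvae import stats as vstats
from vocalvae import synth, vae
from vocalvae.segments import read_segments, write_segments
from vocalvae.spectrogram import SpectrogramConfig, batch_spectrograms

DEFAULT_CONFIG = {
    "seed": 0,
    "synth": {
        "kind": "repertoire",  # repertoire | two_condition
        "n_archetypes": 4,
        "regime": "clustered",
        "n_syllables": 200,
        "jitter_scale": 0.05,
        "sample_rate": 32000,
        "noise_floor": 1e-3,
        "variability_ratio": 0.5,
    },
    "spectrogram": {},
    "model": {"epochs": 25, "hidden": [512, 128]},
    "stats": {"cluster_eval": {"k": 4, "folds": 10}, "mmd": True,
              "variability": True, "effective_dim": True},
}


def _stage_key(payload) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2^31) from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base.get(k, {}), v) if isinstance(v, dict) else v
    return out


class _Cache:
    def __init__(self, root: Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def dir_for(self, stage: str, key: str) -> Path:
        return self.root / f"{stage}-{key}"

    def hit(self, stage: str, key: str) -> bool:
        return (self.dir_for(stage, key) / ".done").exists()

    def finish(self, stage: str, key: str):
        (self.dir_for(stage, key) / ".done").write_text("ok")


def _stage_generate(cfg, cache, manifest):
    s = cfg["synth"]
    seed = stage_seed(cfg["seed"], "generate")
    key = _stage_key({"synth": s, "seed": seed})
    out = cache.dir_for("generate", key)
    if not cache.hit("generate", key):
        out.mkdir(parents=True, exist_ok=True)
        archetypes = synth.example_archetypes(s["n_archetypes"])
        spec = synth.RepertoireSpec(
            archetypes=archetypes,
            regime=s["regime"],
            jitter_scale=s["jitter_scale"],
            n_syllables=s["n_syllables"],
            sample_rate=s["sample_rate"],
            noise_floor=s["noise_floor"],
            seed=seed,
        )
        if s["kind"] == "two_condition":
            ds = synth.generate_two_condition(spec, s["variability_ratio"])
        else:
            ds = synth.generate_repertoire(spec)
        ds.write_wavs(out / "audio")
        write_segments(ds.segments, out / "segments.csv")
        cache.finish("generate", key)
    manifest["stages"]["generate"] = {"key": key, "dir": str(out)}
    return out, key


def _load_audio_dir(directory: Path) -> dict:
    from scipy.io import wavfile

    audio = {}
    for wav in sorted(Path(directory).glob("*.wav")):
        rate, wave = wavfile.read(wav)
        audio[wav.stem] = (np.asarray(wave, dtype=float), rate)
    return audio


def _stage_spectrograms(cfg, cache, manifest, gen_dir, gen_key):
    spec_cfg = SpectrogramConfig(**cfg["spectrogram"])
    key = _stage_key({"spec": asdict(spec_cfg), "upstream": gen_key})
    out = cache.dir_for("spectrograms", key)
    if not cache.hit("spectrograms", key):
        out.mkdir(parents=True, exist_ok=True)
        audio = _load_audio_dir(gen_dir / "audio")
        segments = read_segments(gen_dir / "segments.csv")
        images, report = batch_spectrograms(audio, segments, spec_cfg)
        np.savez_compressed(out / "spectrograms.npz", images=images,
                            keep_mask=report["keep_mask"])
        segments[report["keep_mask"]].to_csv(out / "kept_segments.csv", index=False)
        cache.finish("spectrograms", key)
    manifest["stages"]["spectrograms"] = {"key": key, "dir": str(out)}
    return out, key


def _stage_train(cfg, cache, manifest, spec_dir, spec_key):
    m = dict(cfg["model"])
    m.setdefault("seed", stage_seed(cfg["seed"], "train"))
    key = _stage_key({"model": m, "upstream": spec_key})
    out = cache.dir_for("train", key)
    if not cache.hit("train", key):
        out.mkdir(parents=True, exist_ok=True)
        images = np.load(spec_dir / "spectrograms.npz")["images"]
        config = vae.ModelConfig(
            **{**m, "hidden": tuple(m.get("hidden", (512, 128))),
               "input_shape": images.shape[1:]}
        )
        model = vae.train(images, config)
        model.save(out / "model.npz")
        pd.DataFrame(model.training_log, columns=["epoch", "mean_elbo"]).to_csv(
            out / "training_log.csv", index=False
        )
        cache.finish("train", key)
    manifest["stages"]["train"] = {"key": key, "dir": str(out)}
    return out, key


def _stage_latents(cache, manifest, spec_dir, train_dir, train_key):
    key = _stage_key({"upstream": train_key})
    out = cache.dir_for("latents", key)
    if not cache.hit("latents", key):
        out.mkdir(parents=True, exist_ok=True)
        images = np.load(spec_dir / "spectrograms.npz")["images"]
        model = vae.TrainedModel.load(train_dir / "model.npz")
        table = vae.latent_means(images, model)
        table.to_csv(out / "latents.csv")
        cache.finish("latents", key)
    manifest["stages"]["latents"] = {"key": key, "dir": str(out)}
    return out, key


def _stage_stats(cfg, cache, manifest, spec_dir, lat_dir, lat_key):
    sc = cfg["stats"]
    seed = stage_seed(cfg["seed"], "stats")
    key = _stage_key({"stats": sc, "seed": seed, "upstream": lat_key})
    out = cache.dir_for("stats", key)
    if not cache.hit("stats", key):
        out.mkdir(parents=True, exist_ok=True)
        latents = vstats.read_feature_table(lat_dir / "latents.csv")
        segments = pd.read_csv(spec_dir / "kept_segments.csv")
        results = {}
        if sc.get("effective_dim"):
            curve = vstats.effective_dimensionality_curve(latents)
            results["effective_dim_curve"] = curve.tolist()
            results["effective_dim"] = vstats.effective_dimensionality(latents)
        if sc.get("variability") and "condition" in segments.columns:
            za = latents[(segments["condition"] == "A").to_numpy()]
            zb = latents[(segments["condition"] == "B").to_numpy()]
            results["variability_reduction"] = vstats.variability_reduction(za, zb)
        if sc.get("mmd") and "truth" in segments.columns:
            groups = {
                str(t): latents[(segments["truth"] == t).to_numpy()]
                for t in segments["truth"].unique()
            }
            groups = {k: v for k, v in groups.items() if len(v) >= 2}
            if len(groups) >= 2:
                M = vstats.mmd_matrix(groups)
                M.to_csv(out / "mmd_matrix.csv")
                results["mmd_mean_offdiag"] = float(
                    M.to_numpy()[~np.eye(len(M), dtype=bool)].mean()
                )
        ce = sc.get("cluster_eval")
        if ce:
            res = vstats.cluster_eval(latents, k=ce["k"], folds=ce["folds"], seed=seed)
            res.differences.to_csv(out / "cluster_eval_differences.csv", index=False)
            results["silhouette_diff_mean"] = float(
                res.differences["silhouette"].mean()
            )
        (out / "summary.json").write_text(json.dumps(results, indent=2))
        cache.finish("stats", key)
    manifest["stages"]["stats"] = {"key": key, "dir": str(out)}
    return out, key


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the full synthetic pipeline; returns the run directory.

    Stage outputs live under ``out_dir/cache`` keyed by configuration
    hashes; the run directory holds the frozen config and a manifest
    pointing at each stage's cache entry.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cache = _Cache(out_dir / "cache")
    manifest = {"config_hash": _stage_key(cfg), "stages": {}}
    (out_dir / "config.json").write_text(json.dumps(cfg, indent=2, default=str))

    gen_dir, gen_key = _stage_generate(cfg, cache, manifest)
    spec_dir, spec_key = _stage_spectrograms(cfg, cache, manifest, gen_dir, gen_key)
    train_dir, train_key = _stage_train(cfg, cache, manifest, spec_dir, spec_key)
    lat_dir, lat_key = _stage_latents(cache, manifest, spec_dir, train_dir, train_key)
    _stage_stats(cfg, cache, manifest, spec_dir, lat_dir, lat_key)

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
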
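"""Variational autoencoder over spectrogram images, in pure numpy.

The model maps each fixed-size spectrogram image x (D pixels in [0, 1]) to
an approximate posterior over a latent vector z with a *low-rank plus
diagonal* Gaussian form,

    q(z | x) = N(z; mu, u u^T + diag(d)),

richer than a mean-field Gaussian at near-diagonal cost, and decodes z back
to pixel space under a fixed-variance spherical Gaussian observation model
N(x; decoder(z), v I) with v = 0.1 by default.  Training maximizes the
standard evidence lower bound (ELBO) with the reparameterization trick and
Adam, learning rate 1e-3, batch size 64, latent dimension 32.

The encoder and decoder are fully-connected ReLU networks with
config-declared hidden widths (linear heads for mu and u, a softplus head
for d); forward and backward passes and the optimizer are implemented
directly on numpy arrays, so training is deterministic under a fixed seed
and runs on a single CPU without any deep-learning framework.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_D_FLOOR = 1e-6  # keeps the posterior diagonal strictly positive


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the VAE.

    latent_dim=32, obs_variance=0.1, learning_rate=1e-3 and batch_size=64
    are the reference settings; ``hidden`` gives the encoder's hidden layer
    widths (the decoder mirrors them).
    """

    latent_dim: int = 32
    obs_variance: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 25
    seed: int = 0
    hidden: tuple = (512, 128)
    input_shape: tuple = (128, 128)
    steps_per_epoch: int = 50  # only used when training from a sampler

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.obs_variance <= 0:
            raise ValueError("obs_variance must be positive")

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.input_shape))


@dataclass
class LatentPosterior:
    """Per-datapoint Gaussian q(z) = N(mu, u u^T + diag(d)).

    Arrays have shape (n, latent_dim); a single posterior may use (latent_dim,).
    """

    mu: np.ndarray
    u: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        self.mu, self.u, self.d = (np.atleast_2d(a) for a in (self.mu, self.u, self.d))
        if not (self.mu.shape == self.u.shape == self.d.shape):
            raise ValueError("mu, u, d must share a shape")
        if np.any(self.d <= 0):
            raise ValueError("posterior diagonal d must be strictly positive")

    def covariance(self) -> np.ndarray:
        """Dense covariance matrices, shape (n, k, k)."""
        return self.u[:, :, None] * self.u[:, None, :] + np.apply_along_axis(
            np.diag, 1, self.d
        )


def _relu(x):
    return np.maximum(x, 0.0)


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _init_params(config: ModelConfig, rng) -> dict:
    """He-initialized weights for encoder trunk, heads, and decoder."""
    D, k = config.n_pixels, config.latent_dim
    sizes_enc = (D,) + tuple(config.hidden)
    sizes_dec = (k,) + tuple(reversed(config.hidden))
    params = {}

    def dense(name, n_in, n_out):
        params[f"{name}_W"] = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        params[f"{name}_b"] = np.zeros(n_out)

    for i, (a, b) in enumerate(zip(sizes_enc, sizes_enc[1:])):
        dense(f"enc{i}", a, b)
    h = sizes_enc[-1]
    dense("mu", h, k)
    dense("u", h, k)
    dense("d", h, k)
    for i, (a, b) in enumerate(zip(sizes_dec, sizes_dec[1:])):
        dense(f"dec{i}", a, b)
    dense("out", sizes_dec[-1], D)
    # start the posterior near the prior: d ~= softplus(0) with small u
    params["u_W"] *= 1e-2
    return params


@dataclass
class TrainedModel:
    """Encoder/decoder parameters plus config and per-epoch training log."""

    params: dict
    config: ModelConfig
    training_log: list = field(default_factory=list)  # [(epoch, mean ELBO)]

    # ---- forward passes -------------------------------------------------
    def _encode_forward(self, x):
        p = self.params
        h, cache = x, [x]
        i = 0
        while f"enc{i}_W" in p:
            h = _relu(h @ p[f"enc{i}_W"] + p[f"enc{i}_b"])
            cache.append(h)
            i += 1
        mu = h @ p["mu_W"] + p["mu_b"]
        u = h @ p["u_W"] + p["u_b"]
        d_raw = h @ p["d_W"] + p["d_b"]
        d = _softplus(d_raw) + _D_FLOOR
        return mu, u, d, d_raw, cache

    def _decode_forward(self, z):
        p = self.params
        h, cache = z, [z]
        i = 0
        while f"dec{i}_W" in p:
            h = _relu(h @ p[f"dec{i}_W"] + p[f"dec{i}_b"])
            cache.append(h)
            i += 1
        return h @ p["out_W"] + p["out_b"], cache

    # ---- public API ------------------------------------------------------
    def encode(self, x) -> LatentPosterior:
        """Posterior parameters for a batch of images (deterministic)."""
        x = _flatten_check(x, self.config)
        mu, u, d, _, _ = self._encode_forward(x)
        return LatentPosterior(mu=mu, u=u, d=d)

    def decode(self, z) -> np.ndarray:
        """Decoded mean images, shape (n, *input_shape)."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        out, _ = self._decode_forward(z)
        return out.reshape((-1,) + tuple(self.config.input_shape))

    def save(self, path):
        meta = json.dumps(
            {**self.config.__dict__, "training_log": self.training_log}, default=list
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path):
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        log = [tuple(e) for e in meta.pop("training_log")]
        meta["hidden"] = tuple(meta["hidden"])
        meta["input_shape"] = tuple(meta["input_shape"])
        params = {k: data[k] for k in data.files if k != "__meta__"}
        return cls(params=params, config=ModelConfig(**meta), training_log=log)


def _flatten_check(x, config: ModelConfig):
    x = np.asarray(x, dtype=float)
    if x.ndim == len(config.input_shape):
        x = x[None]
    flat = x.reshape(x.shape[0], -1)
    if flat.shape[1] != config.n_pixels:
        raise ValueError(
            f"input has {flat.shape[1]} pixels; model expects {config.n_pixels}"
        )
    return flat


def sample_posterior(q: LatentPosterior, seed=None, rng=None) -> np.ndarray:
    """Reparameterized draw z = mu + u * eps0 + sqrt(d) * eps.

    ``eps0`` is a per-row scalar standard normal (the rank-1 direction) and
    ``eps`` a vector standard normal.  Reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    eps0 = rng.standard_normal((q.mu.shape[0], 1))
    eps = rng.standard_normal(q.mu.shape)
    return q.mu + q.u * eps0 + np.sqrt(q.d) * eps


def kl_to_standard_normal(q: LatentPosterior) -> np.ndarray:
    """KL(q || N(0, I)) per row, in closed form.

    With Sigma = u u^T + diag(d):
      KL = 1/2 [ tr(Sigma) + mu^T mu - k - log det Sigma ]
      log det Sigma = sum(log d) + log(1 + u^T diag(d)^-1 u)   (matrix
      determinant lemma), so the cost stays linear in the latent dimension.
    """
    k = q.mu.shape[1]
    trace = np.sum(q.d, axis=1) + np.sum(q.u**2, axis=1)
    logdet = np.sum(np.log(q.d), axis=1) + np.log1p(np.sum(q.u**2 / q.d, axis=1))
    return 0.5 * (trace + np.sum(q.mu**2, axis=1) - k - logdet)


def _recon_log_density(x, x_hat, obs_variance):
    """log N(x; x_hat, v I) summed over pixels, per row."""
    D = x.shape[1]
    sq = np.sum((x - x_hat) ** 2, axis=1)
    return -0.5 * D * np.log(2.0 * np.pi * obs_variance) - sq / (2.0 * obs_variance)


def elbo(x, model: TrainedModel, seed=None, n_samples: int = 1) -> float:
    """Monte-Carlo ELBO (mean over the batch), in nats."""
    x = _flatten_check(x, model.config)
    q = model.encode(x)
    rng = np.random.default_rng(seed)
    recon = np.zeros(x.shape[0])
    for _ in range(n_samples):
        z = sample_posterior(q, rng=rng)
        x_hat, _ = model._decode_forward(z)
        recon += _recon_log_density(x, x_hat, model.config.obs_variance)
    recon /= n_samples
    return float(np.mean(recon - kl_to_standard_normal(q)))


def _backward_dense_chain(params, prefix, cache, d_out):
    """Backprop through a relu dense chain; returns (grads, d_input)."""
    grads = {}
    n_layers = len(cache) - 1
    grad = d_out
    for i in reversed(range(n_layers)):
        h_in, h_out = cache[i], cache[i + 1]
        grad = grad * (h_out > 0)  # relu mask (post-activation cached)
        grads[f"{prefix}{i}_W"] = h_in.T @ grad
        grads[f"{prefix}{i}_b"] = grad.sum(axis=0)
        grad = grad @ params[f"{prefix}{i}_W"].T
    return grads, grad


def _loss_and_grads(model: TrainedModel, x, rng):
    """Mean negative ELBO over the batch and gradients for every parameter."""
    p, cfg = model.params, model.config
    n = x.shape[0]
    v = cfg.obs_variance

    mu, u, d, d_raw, enc_cache = model._encode_forward(x)
    eps0 = rng.standard_normal((n, 1))
    eps = rng.standard_normal(mu.shape)
    z = mu + u * eps0 + np.sqrt(d) * eps
    x_hat, dec_cache = model._decode_forward(z)

    recon = _recon_log_density(x, x_hat, v)
    kl = kl_to_standard_normal(LatentPosterior(mu, u, d))
    loss = float(np.mean(kl - recon))

    grads = {}
    # reconstruction path (d/dx_hat of -recon, averaged over batch)
    d_xhat = (x_hat - x) / (v * n)
    h_last = dec_cache[-1]
    grads["out_W"] = h_last.T @ d_xhat
    grads["out_b"] = d_xhat.sum(axis=0)
    d_h = d_xhat @ p["out_W"].T
    dec_grads, dz = _backward_dense_chain(p, "dec", dec_cache, d_h)
    grads.update(dec_grads)

    # KL path (closed form) + reparameterization path through z
    s = np.sum(u**2 / d, axis=1, keepdims=True)
    d_mu = dz + mu / n
    d_u = dz * eps0 + (u - (u / d) / (1.0 + s)) / n
    d_d = dz * eps / (2.0 * np.sqrt(d)) + 0.5 * (
        1.0 - 1.0 / d + (u**2 / d**2) / (1.0 + s)
    ) / n
    d_draw = d_d * _sigmoid(d_raw)  # softplus'

    h_enc = enc_cache[-1]
    d_h_enc = np.zeros_like(h_enc)
    for name, g in (("mu", d_mu), ("u", d_u), ("d", d_draw)):
        grads[f"{name}_W"] = h_enc.T @ g
        grads[f"{name}_b"] = g.sum(axis=0)
        d_h_enc += g @ p[f"{name}_W"].T
    enc_grads, _ = _backward_dense_chain(p, "enc", enc_cache, d_h_enc)
    grads.update(enc_grads)
    return loss, grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(data, config: ModelConfig, callback=None) -> TrainedModel:
    """Train the VAE by mini-batch gradient ascent on the ELBO.

    *data* is either an array of spectrograms, shape (n, *input_shape), or a
    sampler: a callable ``sampler(batch_size, rng) -> batch`` (the shotgun
    regime, where spectrograms are drawn fresh every step).  One master seed
    derives independent streams for initialization, data order, and
    posterior sampling, so runs are bit-reproducible.

    Raises ``FloatingPointError`` with a diagnostic if the loss goes NaN.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_order, rng_sample = (np.random.default_rng(s) for s in ss.spawn(3))
    params = _init_params(config, rng_init)
    model = TrainedModel(params=params, config=config)
    opt = _Adam(params, config.learning_rate)

    is_sampler = callable(data)
    if not is_sampler:
        data = _flatten_check(np.asarray(data, dtype=float), config)
        if len(data) == 0:
            raise ValueError("empty training set")

    for epoch in range(config.epochs):
        losses = []
        if is_sampler:
            batches = (
                _flatten_check(data(config.batch_size, rng_order), config)
                for _ in range(config.steps_per_epoch)
            )
        else:
            order = rng_order.permutation(len(data))
            batches = (
                data[order[i : i + config.batch_size]]
                for i in range(0, len(data), config.batch_size)
            )
        for batch in batches:
            loss, grads = _loss_and_grads(model, batch, rng_sample)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss!r}; "
                    "try a lower learning rate or check input scaling"
                )
            opt.step(params, grads)
            losses.append(loss)
        mean_elbo = -float(np.mean(losses))
        model.training_log.append((epoch, mean_elbo))
        if callback is not None:
            callback(epoch, mean_elbo)
    return model


def latent_means(data, model: TrainedModel, ids=None) -> pd.DataFrame:
    """Encoder latent means as a feature table (one row per spectrogram).

    Columns are ``z0 .. z{k-1}``; row order matches the input.
    """
    q = model.encode(data)
    cols = [f"z{i}" for i in range(model.config.latent_dim)]
    index = ids if ids is not None else np.arange(q.mu.shape[0])
    return pd.DataFrame(q.mu, columns=cols, index=index)


def interpolate_latent(z_a, z_b, n_steps: int, model: TrainedModel) -> np.ndarray:
    """Decode n_steps points linearly spaced on the segment [z_a, z_b]."""
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    z_a, z_b = np.asarray(z_a, dtype=float), np.asarray(z_b, dtype=float)
    w = np.linspace(0.0, 1.0, n_steps)[:, None]
    return model.decode((1 - w) * z_a[None] + w * z_b[None])
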
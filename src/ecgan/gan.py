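"""Generator/discriminator architectures and adversarial value functions.

The flagship denoiser is an LSTM-DCGAN generator: a dense input stage maps
the 1024-sample noisy fragment to a short 32-step seed sequence with 256
channels, and five CNN-LSTM blocks — each a stride-2 transposed convolution
(kernel 16) followed by batch-norm, a leaky activation, an LSTM over the
time axis, dropout 0.5 and tanh — upsample it back to 1024 samples
(32 -> 64 -> 128 -> 256 -> 512 -> 1024). A final 1x1 transposed convolution
collapses to one channel. Ablation/baseline families share the registry:
a conv-only DCGAN generator, an LSTM-only generator, a dense GAN generator
(310-250-250-310, tanh hidden / sigmoid output) and a fully convolutional
denoising autoencoder (encoder 40-20-20-20-40-1, decoder 1-40-20-20-20-40-1,
kernel 16).

The generator minimizes an adversarial term plus two reconstruction
penalties with weights lambda1 = 0.7 and lambda2 = 0.2:

    L_dist = sum_i (xhat_i - x_i)^2        (global squared distance)
    L_max  = max_i |xhat_i - x_i|          (worst local deviation)

The discriminator is an LSTM(128) -> dropout -> conv(64, kernel 16,
stride 2) -> max-pool(3, 2) -> softmax two-class head trained with
cross-entropy to label clean fragments "real" and generator outputs
"generated".
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .errors import ConfigError, ShapeError

logger = logging.getLogger(__name__)

EPS_PROB = 1e-7

GENERATOR_FAMILIES = ("lstm_dcgan", "dcgan", "lstm_gan", "dnn_gan", "fcn_dae")
ACTIVATIONS = ("relu", "prelu", "leaky_relu")


@dataclass(frozen=True)
class GeneratorConfig:
    family: str = "lstm_dcgan"
    fragment_length: int = 1024
    seed_length: int = 32
    seed_channels: int = 256
    block_filters: tuple[int, ...] = (128, 64, 40, 20, 40)
    kernel_size: int = 16
    stride: int = 2
    activation: str = "leaky_relu"
    leaky_slope: float = 0.2
    dropout_rate: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "block_filters", tuple(self.block_filters))
        if self.family not in GENERATOR_FAMILIES:
            raise ConfigError(f"unknown generator family {self.family!r}")
        if self.activation not in ACTIVATIONS:
            raise ConfigError(f"unsupported activation {self.activation!r}; "
                              f"choose from {ACTIVATIONS}")
        if min(self.fragment_length, self.seed_length, self.seed_channels,
               self.kernel_size, self.stride) < 1:
            raise ConfigError("sizes must be positive")
        if any(f < 1 for f in self.block_filters):
            raise ConfigError("block_filters must be positive")
        if not 0 < self.leaky_slope < 1:
            raise ConfigError("leaky_slope must lie in (0, 1)")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.family in ("lstm_dcgan", "dcgan"):
            upsampled = self.seed_length * self.stride ** len(self.block_filters)
            if upsampled != self.fragment_length:
                raise ConfigError(
                    f"seed_length * stride^n_blocks = {upsampled} must equal "
                    f"fragment_length = {self.fragment_length}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["block_filters"] = list(self.block_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "block_filters" in d:
            d["block_filters"] = tuple(d["block_filters"])
        return cls(**d)


@dataclass(frozen=True)
class DiscriminatorConfig:
    lstm_units: int = 128
    dropout_rate: float = 0.5
    conv_filters: int = 64
    kernel_size: int = 16
    stride: int = 2
    pool_size: int = 3
    pool_stride: int = 2

    def __post_init__(self):
        if min(self.lstm_units, self.conv_filters, self.kernel_size,
               self.stride, self.pool_size, self.pool_stride) < 1:
            raise ConfigError("all discriminator sizes must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the reconstruction penalties in the generator objective."""

    lambda_dist: float = 0.7
    lambda_max: float = 0.2

    def __post_init__(self):
        if not (np.isfinite(self.lambda_dist) and np.isfinite(self.lambda_max)):
            raise ConfigError("loss weights must be finite")
        if self.lambda_dist < 0 or self.lambda_max < 0:
            raise ConfigError("loss weights must be non-negative")


class _Network:
    """Thin wrapper around a Sequential with its config and build seed."""

    def __init__(self, net: nn.Sequential, config, seed: int):
        self.net = net
        self.config = config
        self.seed = seed

    @property
    def params(self):
        return self.net.params

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params)

    def forward(self, x, training=False):
        return self.net.forward(np.asarray(x, dtype=float), training=training)

    def backward(self, dy):
        return self.net.backward(dy)

    def describe(self) -> str:
        lines = []
        for lay in self.net:
            n = sum(p.value.size for p in lay.params)
            lines.append(f"{type(lay).__name__:<18} params={n}")
        lines.append(f"{'TOTAL':<18} params={self.n_params()}")
        return "\n".join(lines)


class Generator(_Network):
    """Maps a batch of noisy fragments (B, L) to denoised fragments (B, L)."""

    def denoise_batch(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.config.fragment_length:
            raise ShapeError(
                f"expected (batch, {self.config.fragment_length}), got {x.shape}")
        return self.forward(x, training=False)


class Discriminator(_Network):
    """Maps a batch of fragments (B, L) to P(real) via a two-class softmax."""

    def __init__(self, net, config, seed, fragment_length):
        super().__init__(net, config, seed)
        self.fragment_length = fragment_length

    def predict_proba(self, x, training=False) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.fragment_length:
            raise ShapeError(
                f"expected (batch, {self.fragment_length}), got {x.shape}")
        return self.forward(x, training=training)  # (B, 2); column 0 = real

    def prob_real(self, x, training=False) -> np.ndarray:
        return self.predict_proba(x, training=training)[:, 0]


def _activation(config: GeneratorConfig) -> nn.Layer:
    if config.activation == "relu":
        return nn.ReLU()
    if config.activation == "prelu":
        return nn.PReLU()
    return nn.LeakyReLU(config.leaky_slope)


def build_generator(config: GeneratorConfig, seed: int = 0) -> Generator:
    """Instantiate a generator network of the configured family.

    All weights come from one seeded engine, so (config, seed) fully
    determines the initial network.
    """
    rng = np.random.default_rng(seed)
    L = config.fragment_length
    k, s = config.kernel_size, config.stride
    layers: list[nn.Layer] = []

    if config.family in ("lstm_dcgan", "dcgan"):
        layers += [nn.Dense(L, config.seed_length * config.seed_channels, rng),
                   nn.Reshape((config.seed_length, config.seed_channels)),
                   nn.BatchNorm(config.seed_channels),
                   _activation(config)]
        c = config.seed_channels
        for f in config.block_filters:
            layers += [nn.ConvTranspose1d(c, f, k, s, rng),
                       nn.BatchNorm(f),
                       _activation(config)]
            if config.family == "lstm_dcgan":
                layers += [nn.LSTM(f, f, rng),
                           nn.Dropout(config.dropout_rate, rng),
                           nn.Tanh()]
            c = f
        layers += [nn.ConvTranspose1d(c, 1, 1, 1, rng), nn.Reshape((L,))]
    elif config.family == "lstm_gan":
        layers.append(nn.Reshape((L, 1)))
        c = 1
        for f in config.block_filters:
            layers += [nn.LSTM(c, f, rng),
                       nn.Dropout(config.dropout_rate, rng),
                       nn.Tanh()]
            c = f
        layers += [nn.ConvTranspose1d(c, 1, 1, 1, rng), nn.Reshape((L,))]
    elif config.family == "dnn_gan":
        widths = (310, 250, 250, 310)
        prev = L
        for w in widths:
            layers += [nn.Dense(prev, w, rng), nn.Tanh()]
            prev = w
        layers += [nn.Dense(prev, L, rng), nn.Sigmoid()]
    elif config.family == "fcn_dae":
        enc = (40, 20, 20, 20, 40, 1)
        dec = (40, 20, 20, 20, 40)
        if L % (s ** len(enc)) != 0:
            raise ConfigError(
                f"fragment_length must be divisible by {s ** len(enc)} for fcn_dae")
        layers.append(nn.Reshape((L, 1)))
        c = 1
        for f in enc:
            layers += [nn.Conv1d(c, f, k, s, rng), _activation(config)]
            c = f
        for f in dec:
            layers += [nn.ConvTranspose1d(c, f, k, s, rng), _activation(config)]
            c = f
        layers += [nn.ConvTranspose1d(c, 1, k, s, rng), nn.Reshape((L,))]
    else:  # pragma: no cover - blocked by config validation
        raise ConfigError(config.family)
    return Generator(nn.Sequential(layers), config, seed)


def build_discriminator(config: DiscriminatorConfig, fragment_length: int = 1024,
                        seed: int = 0) -> Discriminator:
    """Instantiate the LSTM + conv + max-pool + softmax critic."""
    rng = np.random.default_rng(seed)
    L = fragment_length
    if L < config.kernel_size:
        raise ConfigError("fragment_length shorter than the conv kernel")
    t_conv = L // config.stride
    t_pool = (t_conv - config.pool_size) // config.pool_stride + 1
    if t_pool < 1:
        raise ConfigError("pooling leaves no time steps")
    layers = [nn.Reshape((L, 1)),
              nn.LSTM(1, config.lstm_units, rng),
              nn.Dropout(config.dropout_rate, rng),
              nn.Conv1d(config.lstm_units, config.conv_filters,
                        config.kernel_size, config.stride, rng),
              nn.MaxPool1d(config.pool_size, config.pool_stride),
              nn.Flatten(),
              nn.Dense(t_pool * config.conv_filters, 2, rng),
              nn.Softmax()]
    return Discriminator(nn.Sequential(layers), config, seed, L)


_clamp_warned = False


def clamp_probs(p: np.ndarray) -> np.ndarray:
    """Clamp probabilities into [eps, 1-eps] before taking logarithms.

    Boundary values are logged (loudly once, then at debug level), never
    raised: a saturated critic is a normal transient of adversarial training.
    """
    global _clamp_warned
    p = np.asarray(p, dtype=float)
    n_bad = int(np.sum((p <= 0.0) | (p >= 1.0)))
    if n_bad:
        level = logging.DEBUG if _clamp_warned else logging.WARNING
        logger.log(level, "clamping %d boundary probabilities to eps=%g",
                   n_bad, EPS_PROB)
        _clamp_warned = True
    return np.clip(p, EPS_PROB, 1.0 - EPS_PROB)


def reconstruction_penalties(denoised, clean) -> tuple[np.ndarray, np.ndarray]:
    """Per-fragment (L_dist, L_max) for batches shaped (B, L)."""
    denoised = np.atleast_2d(np.asarray(denoised, dtype=float))
    clean = np.atleast_2d(np.asarray(clean, dtype=float))
    if denoised.shape != clean.shape:
        raise ShapeError(f"shape mismatch {denoised.shape} vs {clean.shape}")
    resid = denoised - clean
    return np.sum(resid ** 2, axis=1), np.max(np.abs(resid), axis=1)


def generator_loss(critic_scores_on_denoised, denoised, clean,
                   weights: LossWeights = LossWeights(),
                   adversarial: str = "non_saturating") -> float:
    """Composite generator objective, averaged over the batch.

    ``adversarial="non_saturating"`` uses -log D(G(x~)) (healthier gradients
    early in training); ``"literal"`` uses log(1 - D(G(x~))), the value
    function as written.
    """
    scores = clamp_probs(critic_scores_on_denoised)
    l_dist, l_max = reconstruction_penalties(denoised, clean)
    if scores.shape[0] != l_dist.shape[0]:
        raise ShapeError("batch size of scores and fragments differ")
    if adversarial == "non_saturating":
        adv = -np.log(scores)
    elif adversarial == "literal":
        adv = np.log(1.0 - scores)
    else:
        raise ConfigError(f"unknown adversarial mode {adversarial!r}")
    per_fragment = adv + weights.lambda_dist * l_dist + weights.lambda_max * l_max
    return float(np.mean(per_fragment))


def generator_loss_grads(critic_scores_on_denoised, denoised, clean,
                         weights: LossWeights = LossWeights(),
                         adversarial: str = "non_saturating"
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`generator_loss`.

    Returns ``(d_loss/d_score, d_loss/d_denoised)``; the score gradient still
    has to be pushed through the discriminator to reach the generator.
    """
    scores = clamp_probs(critic_scores_on_denoised)
    denoised = np.atleast_2d(np.asarray(denoised, dtype=float))
    clean = np.atleast_2d(np.asarray(clean, dtype=float))
    b = denoised.shape[0]
    resid = denoised - clean
    if adversarial == "non_saturating":
        d_score = -1.0 / (b * scores)
    elif adversarial == "literal":
        d_score = -1.0 / (b * (1.0 - scores))
    else:
        raise ConfigError(f"unknown adversarial mode {adversarial!r}")
    d_den = (weights.lambda_dist * 2.0 * resid) / b
    # subgradient of the max-deviation penalty: sign at the (first) argmax
    arg = np.argmax(np.abs(resid), axis=1)
    rows = np.arange(b)
    d_den[rows, arg] += weights.lambda_max * np.sign(resid[rows, arg]) / b
    return d_score, d_den


def discriminator_loss(critic_scores_on_clean, critic_scores_on_denoised) -> float:
    """Two-class cross-entropy of the critic, averaged over the batch.

    ``critic_scores_*`` are P(real | input). The critic should assign "real"
    to clean fragments and "generated" to denoised ones; perfect labelling
    drives the loss to 0, maximal confusion (both 0.5) gives 2 ln 2.
    """
    p_clean = np.asarray(critic_scores_on_clean, dtype=float)
    p_fake = np.asarray(critic_scores_on_denoised, dtype=float)
    if p_clean.shape != p_fake.shape:
        raise ShapeError(f"batch mismatch {p_clean.shape} vs {p_fake.shape}")
    p_clean = clamp_probs(p_clean)
    p_fake = clamp_probs(p_fake)
    return float(np.mean(-np.log(p_clean) - np.log(1.0 - p_fake)))


def discriminator_loss_grads(critic_scores_on_clean, critic_scores_on_denoised
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of :func:`discriminator_loss` w.r.t. the two score vectors."""
    p_clean = clamp_probs(critic_scores_on_clean)
    p_fake = clamp_probs(critic_scores_on_denoised)
    if p_clean.shape != p_fake.shape:
        raise ShapeError(f"batch mismatch {p_clean.shape} vs {p_fake.shape}")
    b = p_clean.shape[0]
    return -1.0 / (b * p_clean), 1.0 / (b * (1.0 - p_fake))


def save_generator(generator: Generator, path) -> None:
    """Write weights (npz) plus a JSON sidecar with the full config."""
    path = Path(path)
    arrays = {f"param_{i}": p.value for i, p in enumerate(generator.params)}
    stats = {}
    for i, lay in enumerate(generator.net):
        if isinstance(lay, nn.BatchNorm):
            stats[f"bn_{i}_mean"] = lay.running_mean
            stats[f"bn_{i}_var"] = lay.running_var
    np.savez(path.with_suffix(".npz"), **arrays, **stats)
    sidecar = {"config": generator.config.to_dict(), "seed": generator.seed}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_generator(path) -> Generator:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    gen = build_generator(GeneratorConfig.from_dict(sidecar["config"]),
                          seed=sidecar["seed"])
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(gen.params):
        p.value[...] = data[f"param_{i}"]
    for i, lay in enumerate(gen.net):
        if isinstance(lay, nn.BatchNorm):
            lay.running_mean = data[f"bn_{i}_mean"]
            lay.running_var = data[f"bn_{i}_var"]
    return gen
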
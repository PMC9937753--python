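"""Adversarial training loop, inference, experiment grids and model boosting.

Training alternates one (configurable) discriminator step and one generator
step per minibatch with Adam (default learning rate 1e-4, batch 64). The
generator step combines the adversarial gradient, pushed through the frozen
discriminator, with the gradients of the two reconstruction penalties.

Because GAN runs at full scale take GPU-days, the module also carries
"desk-scale" presets — a reduced LSTM-DCGAN (blocks 32-16-8-8-16) and a
reduced critic — that train on a few hundred synthetic fragments on one CPU
in minutes while exercising exactly the same code path.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as met
from .errors import (ConfigError, DivergenceError, EmptyDatasetError,
                     ShapeError)
from .gan import (Discriminator, DiscriminatorConfig, Generator,
                  GeneratorConfig, LossWeights, build_discriminator,
                  build_generator, discriminator_loss,
                  discriminator_loss_grads, generator_loss,
                  generator_loss_grads)
from .nn import Adam, BatchNorm as _BatchNorm, zero_grads
from .preprocess import (NoiseSpec, PairedDataset, SignalFragment, make_pairs,
                         split_dataset)
from .synth import EcgSimParams, synth_ecg, synth_noise_mixture


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; ``epochs`` is deliberately not defaulted."""

    epochs: int
    learning_rate: float = 1e-4
    disc_learning_rate: float | None = None  # None -> same as learning_rate
    batch_size: int = 64
    optimizer: str = "adam"
    loss_weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    steps_per_generator_update: int = 1
    adversarial_weight: float = 1.0
    adversarial_mode: str = "non_saturating"
    eval_subsample: int = 64
    patience: int | None = None  # stop after this many epochs without a new
    # best test SNR_imp and restore the best weights; None disables

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.disc_learning_rate is not None and self.disc_learning_rate <= 0:
            raise ConfigError("disc_learning_rate must be positive")
        if self.batch_size < 1 or self.steps_per_generator_update < 1:
            raise ConfigError("batch_size and update ratio must be >= 1")
        if self.optimizer != "adam":
            raise ConfigError("only the adam optimizer is supported")
        if self.adversarial_weight < 0:
            raise ConfigError("adversarial_weight must be >= 0")
        if self.patience is not None and self.patience < 1:
            raise ConfigError("patience must be >= 1 (or None)")


@dataclass
class TrainHistory:
    """Per-epoch bookkeeping of losses and held-out denoising quality."""

    per_epoch: list = field(default_factory=list)

    def append(self, **row) -> None:
        self.per_epoch.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_epoch)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.per_epoch)


# Desk-scale presets: same architecture family and code path as the full
# model, reduced widths so an adversarial run fits in CPU minutes. Dropout
# 0.2 (not 0.5): at 8-16 channels per layer the full rate removes too much
# capacity.
DESK_GENERATOR = GeneratorConfig(block_filters=(32, 16, 8, 8, 16),
                                 seed_channels=32, dropout_rate=0.2)
DESK_DISCRIMINATOR = DiscriminatorConfig(lstm_units=32, conv_filters=16)


def desk_train_config(epochs: int = 30, seed: int = 0, **overrides) -> TrainConfig:
    """Training preset for the reduced model: a few hundred gradient steps
    need a larger generator step (1e-3) than the full-scale default, and a
    slower critic (1e-4) that does not saturate against the small
    generator."""
    kwargs = dict(epochs=epochs, learning_rate=1e-3, disc_learning_rate=1e-4,
                  batch_size=32, seed=seed, eval_subsample=32, patience=6)
    kwargs.update(overrides)
    return TrainConfig(**kwargs)


def _stack(fragments) -> np.ndarray:
    return np.stack([f.samples for f in fragments]) if fragments else np.empty((0, 0))


def _recon_grad(denoised, clean, w: LossWeights) -> np.ndarray:
    b = denoised.shape[0]
    resid = denoised - clean
    d = (w.lambda_dist * 2.0 * resid) / b
    arg = np.argmax(np.abs(resid), axis=1)
    rows = np.arange(b)
    d[rows, arg] += w.lambda_max * np.sign(resid[rows, arg]) / b
    return d


def _fit(gen: Generator, disc: Discriminator | None,
         clean_tr: np.ndarray, noisy_tr: np.ndarray,
         clean_te, noisy_te, cfg: TrainConfig,
         history: TrainHistory | None = None) -> TrainHistory:
    """Run the alternating update loop in place; returns the history."""
    n = clean_tr.shape[0]
    if n == 0:
        raise EmptyDatasetError("no training fragments")
    rng = np.random.default_rng(cfg.seed)
    opt_g = Adam(gen.params, cfg.learning_rate)
    d_lr = cfg.disc_learning_rate if cfg.disc_learning_rate is not None \
        else cfg.learning_rate
    opt_d = Adam(disc.params, d_lr) if disc is not None else None
    w = cfg.loss_weights
    adv_on = cfg.adversarial_weight > 0 and disc is not None
    history = history if history is not None else TrainHistory()

    def _snapshot():
        params = [p.value.copy() for p in gen.params]
        stats = [(lay.running_mean.copy(), lay.running_var.copy())
                 for lay in gen.net if isinstance(lay, _BatchNorm)]
        return params, stats

    def _restore(snap):
        params, stats = snap
        for p, v in zip(gen.params, params):
            p.value[...] = v
        bns = [lay for lay in gen.net if isinstance(lay, _BatchNorm)]
        for lay, (mean, var) in zip(bns, stats):
            lay.running_mean, lay.running_var = mean.copy(), var.copy()

    best_imp, best_snap, stale = -np.inf, None, 0
    watch = cfg.patience is not None and clean_te is not None and len(clean_te)

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        g_losses, d_losses = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            clean_b, noisy_b = clean_tr[idx], noisy_tr[idx]
            den = gen.forward(noisy_b, training=True)

            if adv_on:
                for _ in range(cfg.steps_per_generator_update):
                    # one concatenated pass scores clean and denoised together
                    zero_grads(disc.params)
                    both = np.concatenate([clean_b, den], axis=0)
                    p_real = disc.forward(both, training=True)[:, 0]
                    p_clean, p_fake = p_real[:len(idx)], p_real[len(idx):]
                    d_pc, d_pf = discriminator_loss_grads(p_clean, p_fake)
                    dprobs = np.zeros((2 * len(idx), 2))
                    dprobs[:len(idx), 0] = d_pc
                    dprobs[len(idx):, 0] = d_pf
                    disc.backward(dprobs)
                    opt_d.step()
                    d_losses.append(discriminator_loss(p_clean, p_fake))

                zero_grads(disc.params)
                p_fake = disc.forward(den, training=True)[:, 0]
                d_score, d_den = generator_loss_grads(
                    p_fake, den, clean_b, w, cfg.adversarial_mode)
                dprobs = np.zeros((len(idx), 2))
                dprobs[:, 0] = cfg.adversarial_weight * d_score
                d_den = d_den + disc.backward(dprobs)
                g_losses.append(generator_loss(p_fake, den, clean_b, w,
                                               cfg.adversarial_mode))
            else:
                d_den = _recon_grad(den, clean_b, w)
                resid = den - clean_b
                g_losses.append(float(np.mean(
                    w.lambda_dist * np.sum(resid ** 2, axis=1)
                    + w.lambda_max * np.max(np.abs(resid), axis=1))))

            zero_grads(gen.params)
            gen.backward(d_den)
            opt_g.step()

        g_loss = float(np.mean(g_losses))
        d_loss = float(np.mean(d_losses)) if d_losses else float("nan")
        if not np.isfinite(g_loss) or (d_losses and not np.isfinite(d_loss)):
            raise DivergenceError(epoch)

        sub = rng.permutation(n)[:cfg.eval_subsample]
        den_tr = gen.forward(noisy_tr[sub], training=False)
        train_rmse = float(np.sqrt(np.mean((den_tr - clean_tr[sub]) ** 2)))
        if clean_te is not None and len(clean_te):
            den_te = gen.forward(noisy_te, training=False)
            imps = [met.snr_improvement(c, ny, dn)
                    for c, ny, dn in zip(clean_te, noisy_te, den_te)]
            test_imp = float(np.mean(imps))
        else:
            test_imp = float("nan")
        history.append(epoch=epoch, generator_loss=g_loss,
                       discriminator_loss=d_loss, train_rmse=train_rmse,
                       test_snr_imp_db=test_imp)
        if watch:
            if test_imp > best_imp:
                best_imp, best_snap, stale = test_imp, _snapshot(), 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    if watch and best_snap is not None:
        _restore(best_snap)
    return history


def train(dataset: PairedDataset, gen_cfg: GeneratorConfig,
          disc_cfg: DiscriminatorConfig | None,
          train_cfg: TrainConfig) -> tuple[Generator, TrainHistory]:
    """Adversarially train a denoiser on the dataset's train split.

    Fully reproducible for a fixed ``train_cfg.seed``: network init, batch
    order and dropout all derive from it.
    """
    tr = dataset.subset("train")
    te = dataset.subset("test")
    if len(tr) == 0:
        raise EmptyDatasetError("dataset has no fragments labelled 'train'")
    gen = build_generator(gen_cfg, seed=train_cfg.seed)
    disc = None
    if disc_cfg is not None and train_cfg.adversarial_weight > 0:
        disc = build_discriminator(disc_cfg, gen_cfg.fragment_length,
                                   seed=train_cfg.seed + 1)
    history = _fit(gen, disc, _stack(tr.clean), _stack(tr.noisy),
                   _stack(te.clean) if len(te) else None,
                   _stack(te.noisy) if len(te) else None,
                   train_cfg)
    return gen, history


def denoise(generator: Generator, fragments) -> list[SignalFragment]:
    """Run inference on a list of fragments (dropout off, deterministic)."""
    out = []
    for start in range(0, len(fragments), 64):
        chunk = fragments[start:start + 64]
        den = generator.denoise_batch(_stack(chunk))
        for frag, row in zip(chunk, den):
            out.append(replace(frag, samples=row))
    return out


def evaluate(generator, dataset: PairedDataset, label: str = "test",
             prd_denominator: str = "denoised") -> met.MetricsReport:
    """Denoise one split of a paired dataset and score it."""
    part = dataset.subset(label)
    if len(part) == 0:
        raise EmptyDatasetError(f"no fragments labelled {label!r}")
    den = denoise(generator, part.noisy)
    return met.evaluate_pairs(part.clean, part.noisy, den,
                              prd_denominator=prd_denominator)


class OracleDenoiser:
    """Test double that returns the exact clean partner of each noisy
    fragment (lookup by content); RMSE against it is identically zero."""

    def __init__(self, *datasets: PairedDataset):
        self._table = {}
        for ds in datasets:
            for c, ny in zip(ds.clean, ds.noisy):
                self._table[ny.samples.tobytes()] = c.samples
        self.config = None

    def denoise_batch(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.stack([self._table[row.tobytes()] for row in x])


def make_synthetic_dataset(n_fragments: int, noise_spec: NoiseSpec, seed: int,
                           fragment_length: int = 1024,
                           sampling_rate_hz: float = 360.0,
                           test_fraction: float = 0.05,
                           source_id: str = "synthetic",
                           ecg_overrides: dict | None = None) -> PairedDataset:
    """Simulate one subject and return a split paired dataset."""
    duration = n_fragments * fragment_length / sampling_rate_hz
    ecg_kwargs = dict(sampling_rate_hz=sampling_rate_hz, duration_s=duration,
                      seed=seed)
    ecg_kwargs.update(ecg_overrides or {})
    clean = synth_ecg(EcgSimParams(**ecg_kwargs))
    components = {k: synth_noise_mixture([k], sampling_rate_hz, duration,
                                         seed=seed + 7919)
                  for k in noise_spec.kinds}
    ds = make_pairs(clean, components, noise_spec, fragment_length,
                    sampling_rate_hz=sampling_rate_hz, source_id=source_id)
    return split_dataset(ds, test_fraction, seed + 13)


def run_grid(noise_kind_sets, snr_levels_db, architectures,
             base: TrainConfig, *, disc_cfg: DiscriminatorConfig | None = None,
             n_fragments: int = 60, fragment_length: int = 1024,
             test_fraction: float = 0.05, data_seed: int = 0, train_fn=None,
             prd_denominator: str = "denoised") -> pd.DataFrame:
    """Sweep noise kinds x SNR levels x architectures; one row per cell.

    ``train_fn(dataset, gen_cfg, disc_cfg, base) -> denoiser`` may be
    injected (e.g. an oracle) — the default trains with :func:`train`.
    Returns a long-format table with the aggregate metrics of each cell.
    """
    noise_kind_sets = [tuple(ks) for ks in noise_kind_sets]
    snr_levels_db = list(snr_levels_db)
    architectures = list(architectures)
    if not noise_kind_sets or not snr_levels_db or not architectures:
        raise ConfigError("noise kinds, SNR levels and architectures must be non-empty")

    rows = []
    for kinds in noise_kind_sets:
        for level in snr_levels_db:
            spec = NoiseSpec(kinds=kinds, target_snr_db=level)
            ds = make_synthetic_dataset(n_fragments, spec, seed=data_seed,
                                        fragment_length=fragment_length,
                                        test_fraction=test_fraction)
            if not ds.split.count("test"):
                raise EmptyDatasetError(
                    "test split is empty; raise n_fragments or test_fraction")
            for gen_cfg in architectures:
                if train_fn is not None:
                    model = train_fn(ds, gen_cfg, disc_cfg, base)
                else:
                    model, _ = train(ds, gen_cfg, disc_cfg, base)
                part = ds.subset("test")
                den = [replace(f, samples=row) for f, row in
                       zip(part.noisy, model.denoise_batch(_stack(part.noisy)))]
                report = met.evaluate_pairs(part.clean, part.noisy, den,
                                            prd_denominator=prd_denominator)
                family = getattr(getattr(model, "config", None), "family", None) \
                    or getattr(gen_cfg, "family", "injected")
                rows.append({"kinds": "+".join(kinds), "snr_db": level,
                             "family": family, "n_test": report.n_fragments,
                             **report.aggregates})
    return pd.DataFrame(rows)


def subject_holdout(records, held_out_index: int, gen_cfg: GeneratorConfig,
                    disc_cfg: DiscriminatorConfig | None,
                    train_cfg: TrainConfig) -> met.MetricsReport:
    """Train on all subjects but one; score the held-out subject.

    ``records`` is a list of per-subject :class:`PairedDataset`; looping
    ``held_out_index`` over all of them gives the full k-fold design.
    """
    records = list(records)
    if len(records) < 2:
        raise ConfigError("subject holdout needs at least 2 subjects")
    if not 0 <= held_out_index < len(records):
        raise ConfigError(f"held_out_index {held_out_index} out of range")
    train_ds = PairedDataset(
        clean=[f for i, r in enumerate(records) if i != held_out_index
               for f in r.clean],
        noisy=[f for i, r in enumerate(records) if i != held_out_index
               for f in r.noisy],
        noise_spec=records[0].noise_spec)
    gen, _ = train(train_ds, gen_cfg, disc_cfg, train_cfg)
    held = records[held_out_index]
    den = denoise(gen, held.noisy)
    return met.evaluate_pairs(held.clean, held.noisy, den)


def boost(generator: Generator, new_subject_fragments: PairedDataset,
          train_fraction: float, train_cfg: TrainConfig,
          disc_cfg: DiscriminatorConfig | None = None
          ) -> tuple[Generator, tuple[met.MetricsReport, met.MetricsReport]]:
    """Fine-tune a trained denoiser on a slice of a new subject's data.

    ``floor(train_fraction * n)`` fragments (seeded shuffle) go into
    fine-tuning; the remainder is scored before and after. Returns the
    boosted generator (the input generator is left untouched) and the
    (before, after) report pair.
    """
    if not 0 < train_fraction < 1:
        raise ConfigError("train_fraction must lie strictly between 0 and 1")
    n = len(new_subject_fragments)
    if n < 2:
        raise EmptyDatasetError("need at least 2 fragments to boost")
    n_tune = int(np.floor(train_fraction * n))
    perm = np.random.default_rng(train_cfg.seed).permutation(n)
    tune_idx, test_idx = perm[:n_tune], perm[n_tune:]

    clean = _stack([new_subject_fragments.clean[i] for i in tune_idx])
    noisy = _stack([new_subject_fragments.noisy[i] for i in tune_idx])
    test_clean = [new_subject_fragments.clean[i] for i in test_idx]
    test_noisy = [new_subject_fragments.noisy[i] for i in test_idx]

    boosted = copy.deepcopy(generator)
    before = met.evaluate_pairs(test_clean, test_noisy,
                                denoise(boosted, test_noisy))
    disc = None
    if disc_cfg is not None and train_cfg.adversarial_weight > 0:
        disc = build_discriminator(disc_cfg, boosted.config.fragment_length,
                                   seed=train_cfg.seed + 1)
    _fit(boosted, disc, clean, noisy, None, None, train_cfg)
    after = met.evaluate_pairs(test_clean, test_noisy,
                               denoise(boosted, test_noisy))
    return boosted, (before, after)
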
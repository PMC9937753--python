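"""Segmentation, normalization, SNR-calibrated noise mixing and splitting.

Pipeline order: long signals are cut into non-overlapping fragments of
``fragment_length`` samples (default 1024, trailing remainder dropped), each
clean fragment is min-max normalized to [0, 1], and noise is then scaled and
added to the *normalized* clean fragment so that the input SNR equals the
requested level. The noisy fragment is deliberately not re-normalized:
clean, noisy and denoised fragments share one amplitude scale, which keeps
SNR/RMSE/PRD comparable across the three.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (ConfigError, DataError, DegenerateFragmentError,
                     DegenerateInputError, ShapeError)
from .synth import NOISE_KINDS

DEFAULT_FRAGMENT_LENGTH = 1024


@dataclass(frozen=True)
class SignalFragment:
    """A fixed-length window of a 1-D signal with its provenance."""

    samples: np.ndarray
    sampling_rate_hz: float = 360.0
    source_id: str = "synthetic"
    fragment_index: int = 0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ShapeError("fragment samples must be a 1-D vector")
        if not np.all(np.isfinite(samples)):
            raise DataError("fragment contains non-finite samples")
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        if self.fragment_index < 0:
            raise ConfigError("fragment_index must be non-negative")

    def __len__(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class NoiseSpec:
    """Which noise kinds pollute the signal and at which total input SNR."""

    kinds: tuple[str, ...] = ("BW", "MA", "EM")
    target_snr_db: float = -1.0

    def __post_init__(self):
        kinds = tuple(self.kinds)
        object.__setattr__(self, "kinds", kinds)
        if not kinds:
            raise ConfigError("NoiseSpec.kinds must be non-empty")
        for k in kinds:
            if k not in NOISE_KINDS:
                raise ConfigError(f"unknown noise kind {k!r}")
        if not np.isfinite(self.target_snr_db):
            raise ConfigError("target_snr_db must be finite")


@dataclass
class PairedDataset:
    """Aligned clean/noisy fragment pairs with a train/test split label."""

    clean: list
    noisy: list
    noise_spec: NoiseSpec
    split: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.clean) != len(self.noisy):
            raise ShapeError("clean and noisy lists must have equal length")
        if not self.split:
            self.split = ["train"] * len(self.clean)
        if len(self.split) != len(self.clean):
            raise ShapeError("split labels must match the number of pairs")
        for c, n in zip(self.clean, self.noisy):
            if (c.source_id, c.fragment_index) != (n.source_id, n.fragment_index):
                raise DataError("paired fragments must share source_id and index")

    def __len__(self) -> int:
        return len(self.clean)

    def subset(self, label: str) -> "PairedDataset":
        idx = [i for i, s in enumerate(self.split) if s == label]
        return PairedDataset(clean=[self.clean[i] for i in idx],
                             noisy=[self.noisy[i] for i in idx],
                             noise_spec=self.noise_spec,
                             split=[label] * len(idx))


def segment(signal, fragment_length: int = DEFAULT_FRAGMENT_LENGTH, *,
            sampling_rate_hz: float = 360.0,
            source_id: str = "synthetic") -> list[SignalFragment]:
    """Cut a long signal into consecutive non-overlapping fragments.

    Produces ``floor(len(signal) / fragment_length)`` fragments; the trailing
    remainder is discarded. An empty signal yields an empty list.
    """
    if fragment_length < 1:
        raise ConfigError("fragment_length must be >= 1")
    signal = np.asarray(signal, dtype=float)
    n_frag = len(signal) // fragment_length
    return [SignalFragment(samples=signal[i * fragment_length:(i + 1) * fragment_length],
                           sampling_rate_hz=sampling_rate_hz,
                           source_id=source_id, fragment_index=i)
            for i in range(n_frag)]


def normalize(fragment: SignalFragment) -> SignalFragment:
    """Min-max normalize a fragment to the [0, 1] range.

    ``out[i] = (x[i] - min x) / (max x - min x)``. A constant fragment has no
    amplitude range and raises :class:`DegenerateFragmentError`.
    """
    x = fragment.samples
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise DegenerateFragmentError(
            f"fragment {fragment.source_id}/{fragment.fragment_index} is constant")
    return replace(fragment, samples=(x - lo) / (hi - lo))


def noise_scale_for_snr(clean, noise, target_snr_db: float) -> float:
    """Closed-form scale so that clean + scale*noise has the target input SNR.

    ``scale = sqrt( sum(clean^2) / (10^(SNR/10) * sum(noise^2)) )``.
    """
    clean = np.asarray(clean, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if clean.shape != noise.shape:
        raise ShapeError(f"clean {clean.shape} and noise {noise.shape} differ")
    e_clean = float(np.sum(clean ** 2))
    e_noise = float(np.sum(noise ** 2))
    if e_clean == 0.0:
        raise DegenerateInputError("clean signal has zero energy")
    if e_noise == 0.0:
        raise DegenerateInputError("noise signal has zero energy")
    return float(np.sqrt(e_clean / (10.0 ** (target_snr_db / 10.0) * e_noise)))


def mix_noise(clean: SignalFragment, noise,
              target_snr_db: float) -> tuple[SignalFragment, float]:
    """Add SNR-calibrated noise to a clean fragment.

    Returns ``(noisy, scale)`` where ``noisy = clean + scale * noise`` and the
    input SNR of the pair equals ``target_snr_db`` (to floating-point
    accuracy, far inside 1e-6 dB).
    """
    noise = np.asarray(noise, dtype=float)
    scale = noise_scale_for_snr(clean.samples, noise, target_snr_db)
    noisy = replace(clean, samples=clean.samples + scale * noise)
    return noisy, scale


def split_dataset(dataset: PairedDataset, test_fraction: float,
                  seed: int) -> PairedDataset:
    """Label exactly ``round(test_fraction * n)`` fragments as test.

    The selection is a seeded shuffle, so a fixed seed gives a fixed split.
    Returns a new dataset; the input is left untouched.
    """
    if not 0 < test_fraction < 1:
        raise ConfigError("test_fraction must lie strictly between 0 and 1")
    n = len(dataset)
    n_test = int(round(test_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    split = ["train"] * n
    for i in perm[:n_test]:
        split[i] = "test"
    return PairedDataset(clean=list(dataset.clean), noisy=list(dataset.noisy),
                         noise_spec=dataset.noise_spec, split=split)


def make_pairs(clean_signal, noise_components: dict, noise_spec: NoiseSpec,
               fragment_length: int = DEFAULT_FRAGMENT_LENGTH, *,
               sampling_rate_hz: float = 360.0,
               source_id: str = "synthetic") -> PairedDataset:
    """Build a paired dataset from one clean trace and per-kind noise traces.

    ``noise_components`` maps each kind in ``noise_spec.kinds`` to a noise
    vector at least as long as ``clean_signal``. The kinds are summed with
    equal weight and one global scale per fragment hits the target SNR.
    """
    clean_signal = np.asarray(clean_signal, dtype=float)
    for kind in noise_spec.kinds:
        if kind not in noise_components:
            raise DataError(f"missing noise component for kind {kind!r}")
        if len(noise_components[kind]) < len(clean_signal):
            raise ShapeError(f"noise component {kind!r} shorter than the signal")
    mixture = np.sum([np.asarray(noise_components[k], dtype=float)[:len(clean_signal)]
                      for k in noise_spec.kinds], axis=0)
    clean_frags, noisy_frags = [], []
    for frag in segment(clean_signal, fragment_length,
                        sampling_rate_hz=sampling_rate_hz, source_id=source_id):
        frag = normalize(frag)
        start = frag.fragment_index * fragment_length
        noisy, _ = mix_noise(frag, mixture[start:start + fragment_length],
                             noise_spec.target_snr_db)
        clean_frags.append(frag)
        noisy_frags.append(noisy)
    return PairedDataset(clean=clean_frags, noisy=noisy_frags, noise_spec=noise_spec)
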
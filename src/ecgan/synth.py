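"""Synthetic ECG and noise generation.

Provides a download-free stand-in for real ambulatory recordings: a
quasi-periodic ECG built from five Gaussian deflections per beat
(P, Q, R, S, T), and the three canonical contamination processes seen in
Holter recordings —

* **BW** (baseline wander): slow sub-0.5 Hz drift of the isoelectric line,
  modelled as a sum of low-frequency sinusoids with random phases.
* **MA** (muscle artifact): broadband high-frequency EMG contamination,
  modelled as band-pass filtered white noise gated by a burst envelope.
* **EM** (electrode motion): transient electrode-skin events, modelled as
  smoothed random steps plus sharp biphasic spikes; the step component gives
  EM the low-frequency, ectopic-beat-like character it has in practice.

All generators are pure functions of their parameter dataclass (which
includes the seed): identical parameters give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.special import expit as sps_expit

from .errors import ConfigError, UnsupportedNoiseKindError

NOISE_KINDS = ("BW", "MA", "EM")

# (P, Q, R, S, T) defaults; the R amplitude dominates every other wave by
# >= 3x so R-peak-preservation assertions are meaningful.
_DEF_AMPL = (0.12, -0.1, 1.0, -0.15, 0.3)
_DEF_WIDTH_S = (0.025, 0.010, 0.012, 0.012, 0.045)
_DEF_OFFSET_S = (-0.18, -0.035, 0.0, 0.035, 0.28)


@dataclass(frozen=True)
class EcgSimParams:
    """Parameters of the sum-of-Gaussians ECG simulator.

    Each beat is a superposition of five Gaussian bumps placed relative to
    the R peak; beat-to-beat RR intervals are jittered uniformly by
    ``rr_jitter_frac`` around ``60 / heart_rate_bpm`` seconds.
    """

    sampling_rate_hz: float = 360.0
    duration_s: float = 10.0
    heart_rate_bpm: float = 75.0
    rr_jitter_frac: float = 0.05
    wave_amplitudes: tuple[float, ...] = _DEF_AMPL
    wave_widths_s: tuple[float, ...] = _DEF_WIDTH_S
    wave_offsets_s: tuple[float, ...] = _DEF_OFFSET_S
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.heart_rate_bpm <= 0:
            raise ConfigError("heart_rate_bpm must be positive")
        if not 0 <= self.rr_jitter_frac < 1:
            raise ConfigError("rr_jitter_frac must lie in [0, 1)")
        if len(self.wave_amplitudes) != 5 or len(self.wave_widths_s) != 5 \
                or len(self.wave_offsets_s) != 5:
            raise ConfigError("wave parameters must have five entries (P,Q,R,S,T)")
        if any(w <= 0 for w in self.wave_widths_s):
            raise ConfigError("wave widths must be strictly positive")
        if round(self.sampling_rate_hz * self.duration_s) < 1:
            raise ConfigError("sampling_rate_hz * duration_s must be >= 1 sample")


@dataclass(frozen=True)
class NoiseSimParams:
    """Parameters of the BW/MA/EM noise simulators.

    Only the fields relevant to ``kind`` are consulted:

    * BW: ``bw_freqs_hz`` (all < 0.5 Hz), ``bw_n_components``
    * MA: ``ma_band_hz`` (low, high) in Hz, ``ma_burst_duty`` in [0, 1]
    * EM: ``em_event_rate_hz`` events/second, ``em_step_spike_ratio`` the
      relative magnitude of step vs. spike events
    """

    kind: str = "BW"
    sampling_rate_hz: float = 360.0
    duration_s: float = 10.0
    seed: int = 0
    bw_freqs_hz: tuple[float, ...] = (0.05, 0.12, 0.25, 0.4)
    ma_band_hz: tuple[float, float] = (15.0, 120.0)
    ma_burst_duty: float = 0.5
    em_event_rate_hz: float = 0.5
    em_step_spike_ratio: float = 1.5

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise UnsupportedNoiseKindError(
                f"unknown noise kind {self.kind!r}; expected one of {NOISE_KINDS}")
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be positive")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        nyq = self.sampling_rate_hz / 2.0
        if self.kind == "BW":
            if any(f <= 0 or f >= 0.5 for f in self.bw_freqs_hz):
                raise ConfigError("BW drift frequencies must lie in (0, 0.5) Hz")
        if self.kind == "MA":
            lo, hi = self.ma_band_hz
            if not (0 < lo < hi < nyq):
                raise ConfigError(
                    f"MA band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz)")
            if not 0 <= self.ma_burst_duty <= 1:
                raise ConfigError("ma_burst_duty must lie in [0, 1]")
        if self.kind == "EM" and self.em_event_rate_hz < 0:
            raise ConfigError("em_event_rate_hz must be >= 0")


def _n_samples(fs: float, duration: float) -> int:
    return int(round(fs * duration))


def synth_ecg(params: EcgSimParams) -> np.ndarray:
    """Generate a synthetic clean ECG trace.

    Returns a float64 vector of length ``round(fs * duration)``. Beats are
    laid down at quasi-regular R-peak times; each beat adds five Gaussian
    bumps with the configured amplitudes, widths and offsets.
    """
    fs = params.sampling_rate_hz
    n = _n_samples(fs, params.duration_s)
    rng = np.random.default_rng(params.seed)
    t = np.arange(n) / fs

    rr_mean = 60.0 / params.heart_rate_bpm
    # First R sits half a mean RR in so the preceding P wave fits.
    r_times = []
    t_r = 0.5 * rr_mean
    while t_r < params.duration_s:
        r_times.append(t_r)
        jitter = rng.uniform(-params.rr_jitter_frac, params.rr_jitter_frac)
        t_r += rr_mean * (1.0 + jitter)

    x = np.zeros(n)
    for t_r in r_times:
        for amp, width, off in zip(params.wave_amplitudes,
                                   params.wave_widths_s,
                                   params.wave_offsets_s):
            x += amp * np.exp(-0.5 * ((t - t_r - off) / width) ** 2)
    return x


def _bw_noise(params: NoiseSimParams, rng: np.random.Generator, n: int) -> np.ndarray:
    t = np.arange(n) / params.sampling_rate_hz
    x = np.zeros(n)
    for f in params.bw_freqs_hz:
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0) / np.sqrt(f / min(params.bw_freqs_hz))
        x += amp * np.sin(2 * np.pi * f * t + phase)
    return x


def _ma_noise(params: NoiseSimParams, rng: np.random.Generator, n: int) -> np.ndarray:
    fs = params.sampling_rate_hz
    white = rng.standard_normal(n)
    lo, hi = params.ma_band_hz
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, white)
    # Burst envelope: random on/off gate at ~0.5 s resolution, smoothed, with a
    # small floor so the noise never vanishes entirely.
    seg = max(1, int(0.5 * fs))
    n_seg = int(np.ceil(n / seg))
    gate = (rng.uniform(size=n_seg) < params.ma_burst_duty).astype(float)
    env = np.repeat(gate, seg)[:n]
    win = max(1, int(0.1 * fs))
    env = np.convolve(env, np.ones(win) / win, mode="same")
    env = 0.1 + 0.9 * env
    return band * env


def _em_noise(params: NoiseSimParams, rng: np.random.Generator, n: int) -> np.ndarray:
    fs = params.sampling_rate_hz
    expected = params.em_event_rate_hz * params.duration_s
    n_events = int(rng.poisson(expected))
    if expected >= 1 and n_events == 0:
        n_events = 1  # post-condition: at least one transient when rate*T >= 1
    x = np.zeros(n)
    t = np.arange(n) / fs
    for _ in range(n_events):
        t0 = rng.uniform(0, params.duration_s)
        sign = rng.choice([-1.0, 1.0])
        if rng.uniform() < 0.5:
            # baseline step with smoothed (sigmoid) edge, decaying back slowly
            rise = 0.05  # s
            decay = rng.uniform(1.0, 3.0)
            x += sign * params.em_step_spike_ratio \
                * sps_expit((t - t0) / rise) * np.exp(-np.maximum(t - t0, 0) / decay)
        else:
            # sharp biphasic spike that can imitate an ectopic beat
            w = rng.uniform(0.01, 0.03)
            x += sign * (np.exp(-0.5 * ((t - t0) / w) ** 2)
                         - 0.6 * np.exp(-0.5 * ((t - t0 - 2 * w) / w) ** 2))
    return x


def synth_noise(params: NoiseSimParams) -> np.ndarray:
    """Generate one synthetic noise trace of the requested kind.

    The output is zero-mean and has length ``round(fs * duration)``.
    """
    n = _n_samples(params.sampling_rate_hz, params.duration_s)
    rng = np.random.default_rng(params.seed)
    if params.kind == "BW":
        x = _bw_noise(params, rng, n)
    elif params.kind == "MA":
        x = _ma_noise(params, rng, n)
    elif params.kind == "EM":
        x = _em_noise(params, rng, n)
    else:  # pragma: no cover - blocked by __post_init__
        raise UnsupportedNoiseKindError(params.kind)
    return x - x.mean()


def synth_noise_mixture(kinds, sampling_rate_hz: float, duration_s: float,
                        seed: int, **kind_params) -> np.ndarray:
    """Sum the requested noise kinds with equal weight (unscaled mixture).

    The caller applies one global scale afterwards to hit a target SNR; only
    the total SNR of the mixture is specified, not per-kind levels.
    """
    kinds = list(kinds)
    if not kinds:
        raise ConfigError("at least one noise kind is required")
    total = None
    for i, kind in enumerate(kinds):
        p = NoiseSimParams(kind=kind, sampling_rate_hz=sampling_rate_hz,
                           duration_s=duration_s, seed=seed + 1000 * i,
                           **kind_params)
        x = synth_noise(p)
        total = x if total is None else total + x
    return total - total.mean()
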
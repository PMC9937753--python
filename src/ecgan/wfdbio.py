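"""Minimal WFDB (PhysioNet waveform database) record reader/writer.

Supports the header format plus signal formats 16 (little-endian int16) and
212 (packed 12-bit pairs) — the formats used by the MIT-BIH Arrhythmia and
Noise Stress Test databases. All channels are assumed to live in one
interleaved ``.dat`` file, as they do in those databases. Samples are
converted to physical units via ``(adc - baseline) / gain``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ChannelNotFoundError, ConfigError, DataError


@dataclass
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    description: str


def _parse_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    record_name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else None
    specs = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        file_name = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = tok[2] if len(tok) > 2 else "200"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain_str, base_str = gain_part.rstrip(")").split("(")
            baseline = int(base_str)
        else:
            gain_str = gain_part
            baseline = int(tok[4]) if len(tok) > 4 else 0  # adc_zero
        gain = float(gain_str) if float(gain_str) != 0 else 200.0
        description = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(specs)}"
        specs.append(_SignalSpec(file_name, fmt, gain, baseline, description))
    return record_name, n_sig, fs, n_samples, specs


def _decode_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    b = b[:(len(b) // 3) * 3].reshape(-1, 3).astype(np.int32)
    s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * len(b), dtype=np.int32)
    out[0::2], out[1::2] = s1, s2
    out[out >= 2048] -= 4096
    return out[:n_values]


def _encode_212(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int32)
    if v.size % 2:
        v = np.append(v, 0)
    v = np.where(v < 0, v + 4096, v)
    pairs = v.reshape(-1, 2)
    out = np.empty((len(pairs), 3), dtype=np.uint8)
    out[:, 0] = pairs[:, 0] & 0xFF
    out[:, 1] = ((pairs[:, 0] >> 8) & 0x0F) | (((pairs[:, 1] >> 8) & 0x0F) << 4)
    out[:, 2] = pairs[:, 1] & 0xFF
    return out.tobytes()


def read_record(record_path, channel: str | None = None
                ) -> tuple[np.ndarray, float]:
    """Read one channel of a WFDB record in physical units.

    ``record_path`` is the path without extension; ``channel`` is the signal
    description (e.g. ``"MLII"``, ``"V1"``). Returns ``(samples, fs)``.
    """
    record_path = Path(record_path)
    hea = record_path.with_suffix(".hea")
    if not hea.exists():
        raise DataError(f"header not found: {hea}")
    _, n_sig, fs, n_samples, specs = _parse_header(hea)
    if channel is None:
        if n_sig != 1:
            raise ChannelNotFoundError(
                f"record has {n_sig} channels; specify one of "
                f"{[s.description for s in specs]}")
        ch = 0
    else:
        names = [s.description for s in specs]
        if channel not in names:
            raise ChannelNotFoundError(
                f"channel {channel!r} not in record (has {names})")
        ch = names.index(channel)
    spec = specs[ch]
    dat = record_path.parent / spec.file_name
    raw = dat.read_bytes()
    if spec.fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2").astype(np.int32)
    elif spec.fmt == 212:
        total = n_samples * n_sig if n_samples else (len(raw) // 3) * 2
        adc = _decode_212(raw, total)
    else:
        raise ConfigError(f"unsupported WFDB signal format {spec.fmt}")
    adc = adc[:(len(adc) // n_sig) * n_sig].reshape(-1, n_sig)
    if n_samples:
        adc = adc[:n_samples]
    return (adc[:, ch] - specs[ch].baseline) / specs[ch].gain, fs


def write_record(record_path, signals, fs: float, channel_names,
                 fmt: int = 16, gain: float = 200.0, baseline: int = 0,
                 units: str = "mV") -> None:
    """Write physical signals (n_samples, n_channels) as a WFDB record."""
    record_path = Path(record_path)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[0] < signals.shape[1]:
        pass  # caller's orientation is trusted: rows are samples
    n, n_sig = signals.shape
    if len(channel_names) != n_sig:
        raise ConfigError("one channel name per column is required")
    if fmt not in (16, 212):
        raise ConfigError(f"unsupported WFDB signal format {fmt}")
    adc = np.rint(signals * gain + baseline).astype(np.int32)
    lim = 32767 if fmt == 16 else 2047
    adc = np.clip(adc, -lim - 1, lim)
    dat_name = record_path.with_suffix(".dat").name
    lines = [f"{record_path.stem} {n_sig} {fs:g} {n}"]
    for name in channel_names:
        lines.append(f"{dat_name} {fmt} {gain:g}({baseline})/{units} "
                     f"12 {baseline} 0 0 0 {name}")
    record_path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    flat = adc.reshape(-1)
    if fmt == 16:
        payload = flat.astype("<i2").tobytes()
    else:
        payload = _encode_212(flat)
    record_path.with_suffix(".dat").write_bytes(payload)
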
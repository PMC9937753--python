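"""Denoising evaluation metrics: SNR_in/SNR_out/SNR_imp, RMSE and PRD.

With clean signal x, noisy signal x~, denoised signal x^ and fragment
length N:

    SNR_in  = 10 log10( sum x_i^2 / sum (x~_i - x_i)^2 )        [dB]
    SNR_out = 10 log10( sum x_i^2 / sum (x^_i - x_i)^2 )        [dB]
    SNR_imp = SNR_out - SNR_in                                  [dB]
    RMSE    = sqrt( (1/N) sum (x_i - x^_i)^2 )
    PRD     = 100 sqrt( sum (x_i - x^_i)^2 / sum x^_i^2 )       [%]

PRD divides by the energy of the *denoised* signal by default (the form used
here); ``prd(..., denominator="clean")`` selects the conventional variant
that divides by the clean signal's energy instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, EmptyDatasetError, ShapeError

METRIC_COLUMNS = ["snr_in_db", "snr_out_db", "snr_imp_db", "rmse", "prd"]


def _vec(x) -> np.ndarray:
    samples = getattr(x, "samples", x)
    return np.asarray(samples, dtype=float)


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = _vec(a), _vec(b)
    if a.shape != b.shape:
        raise ShapeError(f"length mismatch: {a.shape} vs {b.shape}")
    return a, b


def snr_db(reference, corrupted) -> float:
    """Signal-to-noise ratio of ``corrupted`` against ``reference`` in dB.

    Zero error energy (corrupted == reference) returns ``+inf`` rather than
    raising; a zero-energy reference is a degenerate input.
    """
    ref, cor = _pair(reference, corrupted)
    e_ref = float(np.sum(ref ** 2))
    if e_ref == 0.0:
        raise DegenerateInputError("reference signal has zero energy")
    e_err = float(np.sum((cor - ref) ** 2))
    if e_err == 0.0:
        return math.inf
    return 10.0 * math.log10(e_ref / e_err)


def snr_improvement(clean, noisy, denoised) -> float:
    """SNR_imp = SNR_out - SNR_in, in dB; positive means noise was removed."""
    return snr_db(clean, denoised) - snr_db(clean, noisy)


def rmse(clean, denoised) -> float:
    """Root-mean-square error between the clean and denoised fragments."""
    c, d = _pair(clean, denoised)
    return float(np.sqrt(np.mean((c - d) ** 2)))


def prd(clean, denoised, denominator: str = "denoised") -> float:
    """Percent root-mean-square difference.

    ``denominator="denoised"`` (default) normalizes by the denoised signal's
    energy; ``"clean"`` selects the conventional normalization.
    """
    c, d = _pair(clean, denoised)
    if denominator == "denoised":
        e_den = float(np.sum(d ** 2))
        if e_den == 0.0:
            raise DegenerateInputError("denoised signal has zero energy")
    elif denominator == "clean":
        e_den = float(np.sum(c ** 2))
        if e_den == 0.0:
            raise DegenerateInputError("clean signal has zero energy")
    else:
        raise ValueError("denominator must be 'denoised' or 'clean'")
    return float(100.0 * np.sqrt(np.sum((c - d) ** 2) / e_den))


@dataclass
class MetricsReport:
    """Per-fragment metric rows plus their arithmetic means.

    Rows with infinite SNR (perfect reconstruction) are kept in
    ``per_fragment`` but excluded from the dB means; ``n_infinite_snr``
    counts them.
    """

    per_fragment: pd.DataFrame
    aggregates: dict
    n_fragments: int
    n_infinite_snr: int = 0

    def to_csv(self, path) -> None:
        self.per_fragment.to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {"aggregates": self.aggregates,
                   "n_fragments": self.n_fragments,
                   "n_infinite_snr": self.n_infinite_snr}
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return None


def evaluate_pairs(clean_list, noisy_list, denoised_list,
                   prd_denominator: str = "denoised") -> MetricsReport:
    """Score a denoiser over aligned (clean, noisy, denoised) fragment lists."""
    if not (len(clean_list) == len(noisy_list) == len(denoised_list)):
        raise ShapeError("clean/noisy/denoised lists must have equal length")
    if len(clean_list) == 0:
        raise EmptyDatasetError("cannot evaluate an empty set of fragments")
    rows = []
    for c, ny, dn in zip(clean_list, noisy_list, denoised_list):
        s_in = snr_db(c, ny)
        s_out = snr_db(c, dn)
        rows.append({"snr_in_db": s_in, "snr_out_db": s_out,
                     "snr_imp_db": s_out - s_in,
                     "rmse": rmse(c, dn),
                     "prd": prd(c, dn, denominator=prd_denominator)})
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    finite = df.replace([np.inf, -np.inf], np.nan)
    n_inf = int(np.isinf(df[["snr_in_db", "snr_out_db", "snr_imp_db"]]).any(axis=1).sum())
    aggregates = {col: float(finite[col].mean()) for col in METRIC_COLUMNS}
    return MetricsReport(per_fragment=df, aggregates=aggregates,
                         n_fragments=len(df), n_infinite_snr=n_inf)
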
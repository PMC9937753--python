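"""CSV serialization for fragments and paired datasets.

Fragment files carry a comment header with the fragment length and sampling
rate, then one fragment per row: ``source_id, fragment_index, [split,]
s0 ... s{L-1}``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .preprocess import NoiseSpec, PairedDataset, SignalFragment


def write_fragments_csv(fragments, path, split=None) -> None:
    if not fragments:
        raise DataError("no fragments to write")
    L = len(fragments[0])
    fs = fragments[0].sampling_rate_hz
    rows = []
    for i, f in enumerate(fragments):
        if len(f) != L:
            raise DataError("fragments of mixed length cannot share a file")
        row = {"source_id": f.source_id, "fragment_index": f.fragment_index}
        if split is not None:
            row["split"] = split[i]
        row.update({f"s{j}": v for j, v in enumerate(f.samples)})
        rows.append(row)
    with open(path, "w") as fh:
        fh.write(f"# fragment_length={L} sampling_rate_hz={fs:g}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_fragments_csv(path) -> tuple[list[SignalFragment], list | None]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise DataError(f"{path} lacks the fragment-file header line")
    fields = dict(tok.split("=") for tok in header[1:].split())
    L = int(fields["fragment_length"])
    fs = float(fields["sampling_rate_hz"])
    df = pd.read_csv(path, comment=None, skiprows=1)
    sample_cols = [f"s{j}" for j in range(L)]
    fragments = [SignalFragment(samples=row[sample_cols].to_numpy(dtype=float),
                                sampling_rate_hz=fs,
                                source_id=str(row["source_id"]),
                                fragment_index=int(row["fragment_index"]))
                 for _, row in df.iterrows()]
    split = list(df["split"]) if "split" in df.columns else None
    return fragments, split


def save_paired_dataset(dataset: PairedDataset, prefix) -> None:
    prefix = Path(prefix)
    write_fragments_csv(dataset.clean, prefix.parent / f"{prefix.name}_clean.csv",
                        split=dataset.split)
    write_fragments_csv(dataset.noisy, prefix.parent / f"{prefix.name}_noisy.csv",
                        split=dataset.split)
    meta = prefix.parent / f"{prefix.name}_noise.txt"
    meta.write_text(f"kinds={'+'.join(dataset.noise_spec.kinds)} "
                    f"target_snr_db={dataset.noise_spec.target_snr_db:g}\n")


def load_paired_dataset(prefix) -> PairedDataset:
    prefix = Path(prefix)
    clean, split = read_fragments_csv(prefix.parent / f"{prefix.name}_clean.csv")
    noisy, _ = read_fragments_csv(prefix.parent / f"{prefix.name}_noisy.csv")
    meta_path = prefix.parent / f"{prefix.name}_noise.txt"
    spec = NoiseSpec()
    if meta_path.exists():
        fields = dict(tok.split("=") for tok in meta_path.read_text().split())
        spec = NoiseSpec(kinds=tuple(fields["kinds"].split("+")),
                         target_snr_db=float(fields["target_snr_db"]))
    return PairedDataset(clean=clean, noisy=noisy, noise_spec=spec,
                         split=split or ["train"] * len(clean))
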
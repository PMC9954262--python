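"""Delimited-text readers/writers for epochs, flat matrices and features.

CSV dialect: comma-separated, '.' decimal, mandatory header, UTF-8, floats
written with 17 significant digits so every round-trip is exact at double
precision.  Each EpochSet is a CSV of channel-epoch rows plus a JSON sidecar
carrying labels, sampling rate, channel names and row bookkeeping.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureTable
from .preprocess import EpochSet, FlatMatrix, flatten, unflatten

__all__ = [
    "write_epochs",
    "read_epochs",
    "write_flat",
    "read_flat",
    "write_features",
    "read_features",
    "write_modes",
]

_FLOAT_FMT = "%.17g"


def _write_matrix(path: Path, arr: np.ndarray, header: list[str]) -> None:
    df = pd.DataFrame(arr, columns=header)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_matrix(path: Path, expected_header: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if expected_header is not None and list(df.columns) != expected_header:
        unknown = [c for c in df.columns if c not in expected_header]
        raise ValueError(
            f"{path}: unexpected column(s) {unknown}; expected {expected_header}"
        )
    vals = df.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        bad = int(np.argwhere(~np.isfinite(vals))[0][0]) + 2  # +header, 1-based
        raise ValueError(f"{path}: non-finite value near line {bad}")
    return df


def write_epochs(epochs: EpochSet, out_dir) -> None:
    """EpochSet -> data.csv (flattened rows) + meta.json sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    flat = flatten(epochs)
    header = [f"s{i}" for i in range(flat.rows.shape[1])]
    _write_matrix(out / "data.csv", flat.rows, header)
    sidecar = {
        "fs": epochs.fs,
        "channel_names": list(epochs.channel_names),
        "n_epochs": epochs.n_epochs,
        "labels": epochs.labels.tolist(),
        "row_order": "epoch_major_channel_minor",
    }
    (out / "meta.json").write_text(json.dumps(sidecar, indent=1))
    if epochs.meta is not None:
        epochs.meta.to_csv(out / "epoch_meta.csv", index=False)


def read_epochs(in_dir) -> EpochSet:
    src = Path(in_dir)
    sidecar = json.loads((src / "meta.json").read_text())
    df = _read_matrix(src / "data.csv")
    rows = df.to_numpy(dtype=float)
    c = len(sidecar["channel_names"])
    e = int(sidecar["n_epochs"])
    if rows.shape[0] != c * e:
        raise ValueError(
            f"{src / 'data.csv'}: {rows.shape[0]} rows, expected {c}x{e}={c * e}"
        )
    labels = np.asarray(sidecar["labels"], dtype=int)
    flat = FlatMatrix(
        rows=rows,
        row_labels=labels[np.repeat(np.arange(e), c)],
        row_epochs=np.repeat(np.arange(e), c),
        row_channels=np.tile(np.arange(c), e),
        fs=float(sidecar["fs"]),
        channel_names=tuple(sidecar["channel_names"]),
    )
    epochs = unflatten(flat)
    meta_path = src / "epoch_meta.csv"
    if meta_path.exists():
        epochs.meta = pd.read_csv(meta_path)
    return epochs


def write_flat(flat: FlatMatrix, path) -> None:
    """FlatMatrix rows + label/provenance columns in one CSV."""
    header = ["label", "epoch", "channel"] + [
        f"s{i}" for i in range(flat.rows.shape[1])
    ]
    arr = np.column_stack(
        [flat.row_labels, flat.row_epochs, flat.row_channels, flat.rows]
    )
    _write_matrix(Path(path), arr, header)


def read_flat(path, fs: float = 250.0) -> FlatMatrix:
    df = _read_matrix(Path(path))
    need = {"label", "epoch", "channel"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: missing column(s) {sorted(need - set(df.columns))}")
    sample_cols = [c for c in df.columns if c.startswith("s")]
    return FlatMatrix(
        rows=df[sample_cols].to_numpy(dtype=float),
        row_labels=df["label"].to_numpy(dtype=int),
        row_epochs=df["epoch"].to_numpy(dtype=int),
        row_channels=df["channel"].to_numpy(dtype=int),
        fs=fs,
    )


def write_features(table: FeatureTable, path) -> None:
    header = list(table.names) + ["label", "mode_id", "synthetic"]
    synth = (
        table.synthetic
        if table.synthetic is not None
        else np.zeros(table.n_rows, dtype=bool)
    )
    arr = np.column_stack(
        [
            table.values,
            table.labels,
            np.full(table.n_rows, table.mode_id),
            synth.astype(int),
        ]
    )
    _write_matrix(Path(path), arr, header)


def read_features(path) -> FeatureTable:
    expected = list(FEATURE_NAMES) + ["label", "mode_id", "synthetic"]
    df = _read_matrix(Path(path), expected_header=expected)
    return FeatureTable(
        values=df[list(FEATURE_NAMES)].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        mode_id=int(df["mode_id"].iloc[0]) if len(df) else 0,
        synthetic=df["synthetic"].to_numpy(dtype=bool),
    )


def write_modes(modes: np.ndarray, center_freqs: np.ndarray, out_dir, config=None) -> None:
    """(rows, M, samples) mode stack -> one CSV per mode + JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_modes = modes.shape[1]
    header = [f"s{i}" for i in range(modes.shape[2])]
    for m in range(n_modes):
        _write_matrix(out / f"mode{m + 1}.csv", modes[:, m, :], header)
    sidecar = {"center_freqs": np.asarray(center_freqs).tolist()}
    if config is not None:
        sidecar["config"] = {
            k: getattr(config, k)
            for k in ("alpha", "tau", "tol", "n_modes", "max_iter", "mode_order")
        }
    (out / "modes.json").write_text(json.dumps(sidecar, indent=1))
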
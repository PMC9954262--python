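"""Raw oddball EEG -> normalised channel-epoch matrix.

The pipeline mirrors standard P300-BCI preprocessing: 50 Hz notch, 2-30 Hz
zero-phase band-pass, epoching from stimulus onset to +1000 ms (the 200 ms
pre-stimulus baseline is dropped), block-wise averaging of the events that
share a stimulus object, per-channel z-scoring pooled over all epochs and
samples, and finally vertical concatenation of the channels into a 2-D
matrix (one 250-sample row per channel-epoch) for row-wise decomposition.

Filters are zero-phase second-order-section IIR: a 4th-order Butterworth
band-pass and a quality-factor-30 notch, applied forward-backward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNEL_NAMES",
    "EpochSet",
    "FlatMatrix",
    "notch_filter",
    "bandpass_filter",
    "extract_epoch",
    "block_average",
    "channel_normalize",
    "flatten",
    "unflatten",
]

#: the eight central/parietal electrodes of the recording montage
CHANNEL_NAMES: tuple[str, ...] = ("C3", "Cz", "C4", "CPz", "P3", "Pz", "P4", "POz")


@dataclass
class EpochSet:
    """Labelled 3-D epoch array: (channels, samples, epochs), in uV."""

    data: np.ndarray
    labels: np.ndarray  # (epochs,) 1 = target / P300
    fs: float = 250.0
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    meta: pd.DataFrame | None = None  # subject/session/block/object per epoch

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels).astype(int)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D, got shape {self.data.shape}")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} channels but "
                f"{len(self.channel_names)} channel names"
            )
        if self.labels.shape[0] != self.data.shape[2]:
            raise ValueError("labels length must equal number of epochs")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]


@dataclass
class FlatMatrix:
    """Channel-epoch rows ready for row-wise VMD.

    Row order is epoch-major, channel-minor: row = epoch * n_channels +
    channel.  The order is load-bearing downstream (SMOTE and CV folds act
    on row identity) and is fixed here.
    """

    rows: np.ndarray  # (channels*epochs, samples)
    row_labels: np.ndarray  # (rows,)
    row_epochs: np.ndarray  # epoch index per row
    row_channels: np.ndarray  # channel index per row
    fs: float = 250.0
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def notch_filter(x, fs: float, notch_freq: float = 50.0, q: float = 30.0):
    """Zero-phase IIR notch (quality factor ``q``) at ``notch_freq`` Hz."""
    x = np.asarray(x, dtype=float)
    if fs <= 2 * notch_freq:
        raise ValueError(
            f"sampling rate {fs} Hz cannot represent a {notch_freq} Hz notch"
        )
    b, a = sps.iirnotch(notch_freq, q, fs=fs)
    return sps.filtfilt(b, a, x, axis=-1)


def bandpass_filter(
    x, fs: float, low: float = 2.0, high: float = 30.0, order: int = 4
):
    """Zero-phase Butterworth band-pass (``order``-th order, SOS form)."""
    x = np.asarray(x, dtype=float)
    if not 0 < low < high < fs / 2:
        raise ValueError(f"invalid band ({low}, {high}) Hz at fs={fs} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


# ---------------------------------------------------------------------------
# epoching and averaging
# ---------------------------------------------------------------------------

def extract_epoch(continuous, event_time: float, fs: float) -> np.ndarray:
    """Slice [stimulus onset, onset + 1 s) from a continuous record.

    ``continuous`` may be 1-D (samples) or 2-D (channels, samples); the
    epoch has exactly ``round(fs)`` samples.  Any pre-stimulus baseline in
    the record is simply not part of the slice.
    """
    x = np.asarray(continuous, dtype=float)
    n_samples = int(round(fs * 1.0))
    start = int(round(event_time * fs))
    if start < 0 or start + n_samples > x.shape[-1]:
        raise ValueError(
            f"epoch [{start}, {start + n_samples}) exceeds record of "
            f"length {x.shape[-1]} (event_time={event_time} s)"
        )
    return x[..., start:start + n_samples]


def block_average(
    events: np.ndarray, objects: np.ndarray, target_object: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average a block's events per stimulus object.

    events : (n_events, channels, samples) epochs of one block.
    objects : (n_events,) object id shown at each event.
    target_object : the block's single target id.

    Returns ``(averages, labels, object_ids)`` with one averaged epoch per
    distinct object and label 1 only for the target object.
    """
    events = np.asarray(events, dtype=float)
    objects = np.asarray(objects)
    uniq = np.unique(objects)
    if target_object not in uniq:
        raise ValueError(
            f"target object {target_object} has no events in this block "
            f"(objects present: {uniq.tolist()})"
        )
    avgs = np.stack([events[objects == o].mean(axis=0) for o in uniq])
    labels = (uniq == target_object).astype(int)
    return avgs, labels, uniq


def channel_normalize(epochs: EpochSet) -> EpochSet:
    """Per-channel z-score pooled over every epoch and sample."""
    data = epochs.data
    mean = data.mean(axis=(1, 2), keepdims=True)
    std = data.std(axis=(1, 2), keepdims=True)
    flat = std[:, 0, 0] == 0
    if flat.any():
        bad = [epochs.channel_names[i] for i in np.flatnonzero(flat)]
        raise ValueError(f"zero-variance channel(s): {bad}")
    return EpochSet(
        data=(data - mean) / std,
        labels=epochs.labels.copy(),
        fs=epochs.fs,
        channel_names=epochs.channel_names,
        meta=None if epochs.meta is None else epochs.meta.copy(),
    )


# ---------------------------------------------------------------------------
# reshaping
# ---------------------------------------------------------------------------

def flatten(epochs: EpochSet) -> FlatMatrix:
    """(channels, samples, epochs) -> (channels*epochs, samples) rows."""
    c, s, e = epochs.data.shape
    # epoch-major, channel-minor: row = epoch * c + channel
    rows = np.ascontiguousarray(epochs.data.transpose(2, 0, 1).reshape(c * e, s))
    row_epochs = np.repeat(np.arange(e), c)
    row_channels = np.tile(np.arange(c), e)
    return FlatMatrix(
        rows=rows,
        row_labels=epochs.labels[row_epochs],
        row_epochs=row_epochs,
        row_channels=row_channels,
        fs=epochs.fs,
        channel_names=epochs.channel_names,
    )


def unflatten(flat: FlatMatrix) -> EpochSet:
    """Inverse of :func:`flatten` (exact round-trip)."""
    c = len(flat.channel_names)
    e = flat.n_rows // c
    if e * c != flat.n_rows:
        raise ValueError("row count is not a multiple of the channel count")
    data = flat.rows.reshape(e, c, -1).transpose(1, 2, 0)
    labels = flat.row_labels[::c]
    return EpochSet(
        data=np.ascontiguousarray(data),
        labels=labels,
        fs=flat.fs,
        channel_names=flat.channel_names,
    )
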
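"""Synthetic oddball-ERP EEG with the multisession block/run/event structure.

The generator emulates a visual-oddball P300 recording from an 8-channel
central/parietal montage: a subject sees 8 stimulus objects flash; one
pseudorandomly chosen object per block is the target (1/8 target event
probability) and elicits a P300 — modelled as a positive half-cosine bump
whose default amplitude (2.0 uV) and latency (450 ms) sit in the attenuated/
delayed range typical of ASD recordings.  Non-target events are background
noise only.

A subject's data are organised as sessions x blocks x runs x events:
each run flashes all 8 objects once; each event is a 1.2 s segment
(-200 ms .. +1000 ms around stimulus onset).  A calibration phase (20
blocks of 10 runs) and an online phase (50 blocks of 3-10 runs) per session
reproduce the bookkeeping of public P300-BCI benchmarks, so that block
averaging over 7 sessions yields 7 x 70 x 8 = 3,920 averaged epochs.

Background noise is band-limited (2-30 Hz) pink noise plus an alpha-band
sinusoid of random frequency and phase, independent per event and channel.
The P300 template is scaled per channel by a parietal-maximal topography
(largest at Pz).  Everything is driven by one seeded generator: identical
config => identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .preprocess import (
    CHANNEL_NAMES,
    EpochSet,
    bandpass_filter,
    block_average,
    extract_epoch,
    notch_filter,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "SimBlock",
    "SimOutput",
    "p300_template",
    "simulate_subject",
    "simulate_epochset",
    "grand_average",
]

#: relative P300 scalp weights per channel (parietal-maximal)
DEFAULT_TOPOGRAPHY: tuple[float, ...] = (0.3, 0.6, 0.3, 0.8, 0.6, 1.0, 0.6, 0.7)

_BASELINE_S = 0.2  # pre-stimulus interval retained in the raw event
_EPOCH_S = 1.0


@dataclass(frozen=True)
class SimConfig:
    fs: float = 250.0
    n_channels: int = 8
    n_sessions: int = 7
    calib_blocks: int = 20
    online_blocks: int = 50
    n_objects: int = 8
    calib_runs: int = 10
    online_runs: tuple[int, int] = (3, 10)  # inclusive range, drawn per block
    p300_amplitude: float = 2.0  # uV, peak at the strongest channel
    p300_latency_ms: float = 450.0
    p300_width_ms: float = 300.0
    target_weights: tuple[float, ...] = DEFAULT_TOPOGRAPHY
    noise_rms: float = 1.0  # uV RMS of the band-limited pink background
    alpha_amp: float = 0.5  # uV amplitude of the alpha-band sinusoid
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels != len(self.target_weights):
            raise ValueError("target_weights must have one entry per channel")
        if not 0 < self.online_runs[0] <= self.online_runs[1]:
            raise ValueError("online_runs must be a positive (lo, hi) range")
        if self.p300_amplitude < 0 or self.noise_rms <= 0:
            raise ValueError("amplitude must be >= 0 and noise_rms > 0")

    @property
    def blocks_per_session(self) -> int:
        return self.calib_blocks + self.online_blocks

    @property
    def n_blocks(self) -> int:
        return self.n_sessions * self.blocks_per_session

    @property
    def n_epochs(self) -> int:
        """Block-averaged epochs per subject (blocks x objects)."""
        return self.n_blocks * self.n_objects

    @property
    def event_samples(self) -> int:
        return int(round((_BASELINE_S + _EPOCH_S) * self.fs))


@dataclass
class SimBlock:
    """Raw events of one block: (n_events, channels, event_samples) in uV."""

    session: int
    phase: str  # 'calibration' | 'online'
    block: int
    target_object: int
    objects: np.ndarray  # (n_events,) object id per event
    events: np.ndarray


@dataclass
class SimOutput:
    """Raw blocks plus the block-averaged EpochSet derived from them."""

    config: SimConfig
    blocks: list[SimBlock]
    epochs: EpochSet


def p300_template(
    fs: float,
    amplitude: float,
    latency_ms: float,
    width_ms: float,
    n_samples: int,
    t0_ms: float = -_BASELINE_S * 1000.0,
) -> np.ndarray:
    """Positive half-cosine (Hann-shaped) bump peaking at ``latency_ms``."""
    t = t0_ms + 1000.0 * np.arange(n_samples) / fs
    phase = (t - latency_ms) / width_ms  # bump spans phase in [-0.5, 0.5]
    bump = np.where(np.abs(phase) <= 0.5, 0.5 * (1.0 + np.cos(2.0 * np.pi * phase)), 0.0)
    return amplitude * bump


def _pink_band_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n: int, fs: float, rms: float
) -> np.ndarray:
    """Band-limited (2-30 Hz) 1/f-amplitude noise with exact per-signal RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    band = (freqs >= 2.0) & (freqs <= 30.0)
    gain[band] = 1.0 / np.sqrt(freqs[band])
    spec = rng.standard_normal(shape + (freqs.size,)) + 1j * rng.standard_normal(
        shape + (freqs.size,)
    )
    x = np.fft.irfft(spec * gain, n, axis=-1)
    cur = np.sqrt((x**2).mean(axis=-1, keepdims=True))
    cur[cur == 0] = 1.0
    return x * (rms / cur)


def _simulate_block_events(
    config: SimConfig, rng: np.random.Generator, n_runs: int, target: int
) -> tuple[np.ndarray, np.ndarray]:
    """Events of one block: per run each object flashes once, random order."""
    n_ev = n_runs * config.n_objects
    ns = config.event_samples
    objects = np.concatenate(
        [rng.permutation(config.n_objects) + 1 for _ in range(n_runs)]
    )
    noise = _pink_band_noise(
        rng, (n_ev, config.n_channels), ns, config.fs, config.noise_rms
    )
    # alpha-band sinusoid, random frequency/phase per event and channel
    f_alpha = rng.uniform(8.0, 12.0, size=(n_ev, config.n_channels, 1))
    ph = rng.uniform(0.0, 2.0 * np.pi, size=(n_ev, config.n_channels, 1))
    t = np.arange(ns) / config.fs
    events = noise + config.alpha_amp * np.sin(2.0 * np.pi * f_alpha * t + ph)
    template = p300_template(
        config.fs, config.p300_amplitude, config.p300_latency_ms,
        config.p300_width_ms, ns,
    )
    weights = np.asarray(config.target_weights)
    is_target = objects == target
    events[is_target] += weights[:, None] * template[None, :]
    return objects, events


def _iter_blocks(config: SimConfig) -> Iterator[SimBlock]:
    rng = np.random.default_rng(config.seed)
    for session in range(config.n_sessions):
        for block in range(config.blocks_per_session):
            phase = "calibration" if block < config.calib_blocks else "online"
            n_runs = (
                config.calib_runs
                if phase == "calibration"
                else int(rng.integers(config.online_runs[0], config.online_runs[1] + 1))
            )
            target = int(rng.integers(1, config.n_objects + 1))
            objects, events = _simulate_block_events(config, rng, n_runs, target)
            yield SimBlock(
                session=session,
                phase=phase,
                block=block,
                target_object=target,
                objects=objects,
                events=events,
            )


def _block_to_epochs(
    blk: SimBlock, config: SimConfig, apply_filters: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ev = blk.events
    if apply_filters:
        ev = notch_filter(ev, config.fs)
        ev = bandpass_filter(ev, config.fs)
    epochs = extract_epoch(ev, _BASELINE_S, config.fs)
    return block_average(epochs, blk.objects, blk.target_object)


def simulate_epochset(config: SimConfig, apply_filters: bool = True) -> EpochSet:
    """Simulate one subject and return the block-averaged EpochSet.

    Raw events are filtered (50 Hz notch, 2-30 Hz band-pass), epoched to
    [0, 1000) ms and block-averaged on the fly, so a full-size subject never
    holds all raw events in memory.  The result is NOT yet channel-
    normalised; run :func:`vmdp300.preprocess.channel_normalize` next.
    """
    data_parts, labels, meta_rows = [], [], []
    for blk in _iter_blocks(config):
        avgs, lab, objs = _block_to_epochs(blk, config, apply_filters)
        data_parts.append(avgs)
        labels.append(lab)
        for o in objs:
            meta_rows.append(
                {
                    "session": blk.session,
                    "phase": blk.phase,
                    "block": blk.block,
                    "object": int(o),
                    "target_object": blk.target_object,
                }
            )
    data = np.concatenate(data_parts, axis=0).transpose(1, 2, 0)  # (C, S, E)
    return EpochSet(
        data=np.ascontiguousarray(data),
        labels=np.concatenate(labels),
        fs=config.fs,
        channel_names=CHANNEL_NAMES[: config.n_channels],
        meta=pd.DataFrame(meta_rows),
    )


def simulate_subject(config: SimConfig, apply_filters: bool = True) -> SimOutput:
    """Simulate one subject, retaining the raw events of every block.

    Suitable for reduced configurations (tests, demos); for a full-size
    subject prefer :func:`simulate_epochset`, which streams.
    """
    blocks = list(_iter_blocks(config))
    data_parts, labels, meta_rows = [], [], []
    for blk in blocks:
        avgs, lab, objs = _block_to_epochs(blk, config, apply_filters)
        data_parts.append(avgs)
        labels.append(lab)
        for o in objs:
            meta_rows.append(
                {
                    "session": blk.session,
                    "phase": blk.phase,
                    "block": blk.block,
                    "object": int(o),
                    "target_object": blk.target_object,
                }
            )
    data = np.concatenate(data_parts, axis=0).transpose(1, 2, 0)
    epochs = EpochSet(
        data=np.ascontiguousarray(data),
        labels=np.concatenate(labels),
        fs=config.fs,
        channel_names=CHANNEL_NAMES[: config.n_channels],
        meta=pd.DataFrame(meta_rows),
    )
    return SimOutput(config=config, blocks=blocks, epochs=epochs)


def grand_average(epochs: EpochSet, label: int) -> np.ndarray:
    """Sample-wise mean over all epochs of one label: (channels, samples)."""
    sel = epochs.labels == label
    if not sel.any():
        raise ValueError(f"no epochs with label {label}")
    return epochs.data[:, :, sel].mean(axis=2)
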
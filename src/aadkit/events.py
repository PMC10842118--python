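"""From continuous signals to discrete events and binned network activity.

Events are the extreme points of threshold excursions: within every maximal
run of samples beyond ``+h`` (or below ``-h``, in SD units of the
z-normalized signal) exactly one event is placed at the most extreme sample.
Binning with an integer number of samples per bin then yields the network
activity n(t), the number of events per bin summed over channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import MultichannelRecording


class DegenerateChannelError(ValueError):
    pass


@dataclass
class EventRaster:
    """Discrete events: parallel arrays sorted by (sample, channel)."""

    channels: np.ndarray  # int, channel index per event
    samples: np.ndarray  # int, sample index per event
    amplitudes: np.ndarray  # float, signed amplitude in SD units
    n_channels: int
    n_samples: int
    fs: float
    h: float

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.int64)
        self.samples = np.asarray(self.samples, dtype=np.int64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        order = np.lexsort((self.channels, self.samples))
        self.channels = self.channels[order]
        self.samples = self.samples[order]
        self.amplitudes = self.amplitudes[order]

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Event times in seconds."""
        return self.samples / self.fs


@dataclass
class BinnedRaster:
    """Network activity per bin and per-channel bin occupancies."""

    n_of_t: np.ndarray  # int, events per bin over all channels
    per_channel_bins: np.ndarray  # int, (n_channels, n_bins)
    eps_samples: int
    fs: float

    @property
    def eps_seconds(self) -> float:
        return self.eps_samples / self.fs

    @property
    def n_bins(self) -> int:
        return self.n_of_t.size


def z_normalize(rec: MultichannelRecording) -> MultichannelRecording:
    """Per-channel z-score with the population-SD convention.

    Raises :class:`DegenerateChannelError` naming any zero-variance channel.
    """
    sd = rec.data.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DegenerateChannelError(
            f"zero-variance channel(s): {[rec.channel_ids[i] for i in zero]}"
        )
    z = (rec.data - rec.data.mean(axis=1, keepdims=True)) / sd[:, None]
    return MultichannelRecording(z, rec.fs, rec.channel_ids, units="sd")


def _excursion_events(x: np.ndarray, above: np.ndarray, sign: int,
                      drop_boundary: bool) -> tuple[list[int], list[float]]:
    """One event per maximal run of ``above``; extreme sample, first on ties."""
    idx, amps = [], []
    if not above.any():
        return idx, amps
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(x.size)
    for s, e in zip(starts, ends):
        if drop_boundary and (s == 0 or e == x.size):
            continue
        seg = x[s:e]
        k = int(np.argmax(seg) if sign > 0 else np.argmin(seg))  # first extreme
        idx.append(s + k)
        amps.append(float(seg[k]))
    return idx, amps


def detect_events(rec: MultichannelRecording, h: float,
                  drop_boundary_excursions: bool = False) -> EventRaster:
    """Detect one event per suprathreshold excursion of each channel.

    ``h`` is the threshold in SD units; the recording must already be
    z-normalized (amplitudes are stored in SD units).  Excursions truncated
    by the record boundary are kept unless ``drop_boundary_excursions``.
    """
    if h <= 0:
        raise ValueError("threshold h must be positive")
    chans, samps, amps = [], [], []
    for ch in range(rec.n_channels):
        x = rec.data[ch]
        for sign, above in ((1, x > h), (-1, x < -h)):
            idx, a = _excursion_events(x, above, sign, drop_boundary_excursions)
            samps.extend(idx)
            amps.extend(a)
            chans.extend([ch] * len(idx))
    return EventRaster(
        channels=np.asarray(chans, dtype=np.int64),
        samples=np.asarray(samps, dtype=np.int64),
        amplitudes=np.asarray(amps, dtype=float),
        n_channels=rec.n_channels,
        n_samples=rec.n_samples,
        fs=rec.fs,
        h=h,
    )


def bin_events(raster: EventRaster, eps_samples: int) -> BinnedRaster:
    """Count events in windows of ``eps_samples`` samples (trailing partial kept)."""
    eps = int(eps_samples)
    if eps < 1:
        raise ValueError("eps_samples must be >= 1")
    n_bins = int(np.ceil(raster.n_samples / eps)) if raster.n_samples else 0
    per_ch = np.zeros((raster.n_channels, n_bins), dtype=np.int64)
    if len(raster):
        bins = raster.samples // eps
        np.add.at(per_ch, (raster.channels, bins), 1)
    return BinnedRaster(per_ch.sum(axis=0), per_ch, eps, raster.fs)


def instantaneous_activity(rec: MultichannelRecording, h: float,
                           eps_samples: int) -> np.ndarray:
    """Per-bin sum of |signal| over all suprathreshold (channel, sample) pairs."""
    if h <= 0:
        raise ValueError("threshold h must be positive")
    eps = int(eps_samples)
    if eps < 1:
        raise ValueError("eps_samples must be >= 1")
    n_bins = int(np.ceil(rec.n_samples / eps))
    mask = np.abs(rec.data) > h
    contrib = np.where(mask, np.abs(rec.data), 0.0).sum(axis=0)
    out = np.zeros(n_bins)
    np.add.at(out, np.arange(rec.n_samples) // eps, contrib)
    return out
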
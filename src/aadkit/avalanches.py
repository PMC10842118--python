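"""Avalanche segmentation and derived sequences.

An avalanche is a maximal run of time bins each containing at least one
event on any channel, bounded by empty bins.  Two size measures are kept:
``size_count`` (number of events) and ``size_amp`` (sum of absolute event
amplitudes, SD units).  Quiet times are the empty-gap durations between
consecutive avalanches; size increments couple consecutive sizes to the
quiet time separating them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import BinnedRaster, EventRaster


@dataclass
class AvalancheSequence:
    """Ordered avalanches with start/end bins (inclusive) and sizes."""

    start_bin: np.ndarray
    end_bin: np.ndarray
    size_count: np.ndarray
    size_amp: np.ndarray
    eps_seconds: float
    #: True where the avalanche touches the record boundary (censored size)
    boundary: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.start_bin = np.asarray(self.start_bin, dtype=np.int64)
        self.end_bin = np.asarray(self.end_bin, dtype=np.int64)
        self.size_count = np.asarray(self.size_count)
        self.size_amp = np.asarray(self.size_amp, dtype=float)
        if self.boundary is None:
            self.boundary = np.zeros(self.start_bin.size, dtype=bool)
        self.boundary = np.asarray(self.boundary, dtype=bool)
        if np.any(self.end_bin < self.start_bin):
            raise ValueError("end_bin < start_bin")
        if np.any(self.start_bin[1:] - self.end_bin[:-1] < 2):
            raise ValueError("avalanches must be separated by >= 1 empty bin")
        if self.eps_seconds <= 0:
            raise ValueError("eps_seconds must be positive")

    def __len__(self) -> int:
        return self.start_bin.size

    def sizes(self, measure: str = "count") -> np.ndarray:
        if measure == "count":
            return np.asarray(self.size_count, dtype=float)
        if measure == "amp":
            return self.size_amp
        raise ValueError("size measure must be 'count' or 'amp'")


def segment(binned: BinnedRaster, raster: EventRaster | None = None) -> AvalancheSequence:
    """Segment the binned raster into avalanches.

    ``size_amp`` is the sum of |event amplitudes| within each run when the
    originating :class:`EventRaster` is supplied, else 0.  An all-empty
    raster yields an empty sequence.
    """
    occ = binned.n_of_t > 0
    if not occ.any():
        z = np.zeros(0)
        return AvalancheSequence(z, z, z, z, binned.eps_seconds)
    d = np.diff(occ.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)  # inclusive
    if occ[0]:
        starts = np.r_[0, starts]
    if occ[-1]:
        ends = np.r_[ends, occ.size - 1]
    csum = np.r_[0, np.cumsum(binned.n_of_t)]
    size_count = csum[ends + 1] - csum[starts]
    if raster is not None and len(raster):
        amp_per_bin = np.zeros(binned.n_bins)
        np.add.at(amp_per_bin, raster.samples // binned.eps_samples,
                  np.abs(raster.amplitudes))
        acs = np.r_[0, np.cumsum(amp_per_bin)]
        size_amp = acs[ends + 1] - acs[starts]
    else:
        size_amp = np.zeros_like(size_count, dtype=float)
    boundary = np.zeros(starts.size, dtype=bool)
    if occ[0]:
        boundary[0] = True
    if occ[-1]:
        boundary[-1] = True
    return AvalancheSequence(starts, ends, size_count, size_amp,
                             binned.eps_seconds, boundary)


def quiet_times(seq: AvalancheSequence) -> np.ndarray:
    """Empty-gap durations Δt_i = (start_{i+1} - end_i - 1) * eps, in seconds."""
    if len(seq) < 2:
        return np.zeros(0)
    gaps = seq.start_bin[1:] - seq.end_bin[:-1] - 1
    return gaps * seq.eps_seconds


def size_increments(seq: AvalancheSequence, size_measure: str = "count",
                    exclude_boundary: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Pairs (Δs_i, Δt_i) for consecutive avalanches.

    Pairs involving a boundary-censored avalanche are dropped by default.
    Returns ``(ds, dt)`` arrays of equal length.
    """
    if len(seq) < 2:
        return np.zeros(0), np.zeros(0)
    s = seq.sizes(size_measure)
    ds = np.diff(s)
    dt = quiet_times(seq)
    if exclude_boundary:
        ok = ~(seq.boundary[:-1] | seq.boundary[1:])
        ds, dt = ds[ok], dt[ok]
    return ds, dt


def conditional_quiet_times(seq: AvalancheSequence, sc: float,
                            size_measure: str = "count") -> np.ndarray:
    """Quiet times between consecutive avalanches of size > sc.

    Avalanches with s <= sc are removed and gaps recomputed over the thinned
    sequence as (start_j - end_i - 1) * eps.
    """
    if sc < 0:
        raise ValueError("sc must be >= 0")
    keep = np.flatnonzero(seq.sizes(size_measure) > sc)
    if keep.size < 2:
        return np.zeros(0)
    gaps = seq.start_bin[keep[1:]] - seq.end_bin[keep[:-1]] - 1
    return gaps * seq.eps_seconds


def main_avalanche_indices(seq: AvalancheSequence, s_star: float,
                           size_measure: str = "count") -> np.ndarray:
    """Ascending indices of avalanches with size > s_star (the A* set)."""
    if s_star <= 0:
        raise ValueError("s_star must be positive")
    return np.flatnonzero(seq.sizes(size_measure) > s_star)


def from_quiet_times(dt: np.ndarray, sizes: np.ndarray,
                     eps_seconds: float = 0.001) -> AvalancheSequence:
    """Build a one-bin-duration sequence from quiet times and sizes.

    Gaps are rounded to whole bins (at least one); used by the synthetic
    generators, where avalanche durations are not under test.
    """
    dt = np.asarray(dt, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size != dt.size + 1:
        raise ValueError("need len(sizes) == len(dt) + 1")
    gap_bins = np.maximum(1, np.rint(dt / eps_seconds).astype(np.int64))
    starts = np.zeros(sizes.size, dtype=np.int64)
    starts[1:] = np.cumsum(gap_bins + 1)
    return AvalancheSequence(starts, starts.copy(), sizes, sizes.astype(float),
                             eps_seconds)
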
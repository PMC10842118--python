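"""Recording and table I/O, analysis configuration, run provenance.

A recording is a plain ``channels x samples`` real matrix with a sampling
rate.  On disk it lives either as delimited text (rows = channels) next to a
JSON sidecar holding the sampling rate and channel labels, as a compressed
NumPy ``.npz`` container, or (optionally, via :mod:`mne`) as EDF.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("aadkit")

#: default conditional-probability size grid (integer s0 from -30 to 30)
DEFAULT_S0_GRID = tuple(range(-30, 31))
#: default t0 grid in seconds (the figure grid, quoted in ms)
DEFAULT_T0_GRID_MS = (30, 50, 70, 90, 100, 110, 130, 150, 200, 300, 500, 1000)
DEFAULT_T0_GRID = tuple(t / 1000.0 for t in DEFAULT_T0_GRID_MS)


class ConfigurationError(ValueError):
    """Missing or inconsistent configuration (e.g. absent sampling rate)."""


class ParseError(ValueError):
    """Malformed input data; the message names the offending location."""


class SchemaError(ValueError):
    """Heterogeneous row keys passed to the table writer."""


@dataclass
class MultichannelRecording:
    """Continuous multichannel signal.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    channel_ids
        One label per channel.
    units
        Free-text amplitude unit tag (``"au"`` for arbitrary units,
        ``"sd"`` after z-normalization).
    """

    data: np.ndarray
    fs: float
    channel_ids: Sequence[str] = ()
    units: str = "au"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        n_ch, n_s = self.data.shape
        if n_ch < 1 or n_s < 2:
            raise ValueError(f"need >=1 channel and >=2 samples, got {self.data.shape}")
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ParseError(
                f"non-finite value at channel {bad[0]}, sample {bad[1]}"
            )
        if not (self.fs > 0):
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i}" for i in range(n_ch)]
        self.channel_ids = list(map(str, self.channel_ids))
        if len(self.channel_ids) != n_ch:
            raise ValueError(
                f"{len(self.channel_ids)} channel_ids for {n_ch} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline.

    Thresholds are in units of the signal's standard deviation; the bin
    width ``bin_samples`` is an integer number of samples so binning is
    exact; times are seconds internally (the CLI accepts milliseconds where
    the literature quotes them).
    """

    threshold_sd: float = 3.0
    bin_samples: int = 2
    n_surrogates: int = 10_000
    seed: int = 0
    s_star: float = 30.0
    s0_grid: Sequence[float] = field(default_factory=lambda: list(DEFAULT_S0_GRID))
    t0_grid: Sequence[float] = field(default_factory=lambda: list(DEFAULT_T0_GRID))
    w1: float = 0.010
    c_window: float = 0.1
    size_measure: str = "count"
    drop_boundary_excursions: bool = False

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise ConfigurationError("threshold_sd must be positive")
        if int(self.bin_samples) != self.bin_samples or self.bin_samples < 1:
            raise ConfigurationError("bin_samples must be a positive integer")
        if self.n_surrogates < 100:
            raise ConfigurationError(
                "n_surrogates >= 100 is required for a stable sigma*"
            )
        for name in ("s0_grid", "t0_grid"):
            g = np.asarray(getattr(self, name), dtype=float)
            if g.size and np.any(np.diff(g) <= 0):
                raise ConfigurationError(f"{name} must be strictly increasing")
        if self.w1 <= 0 or self.c_window <= 0:
            raise ConfigurationError("w1 and c_window must be positive")
        if self.size_measure not in ("count", "amp"):
            raise ConfigurationError("size_measure must be 'count' or 'amp'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["s0_grid"] = list(map(float, d["s0_grid"]))
        d["t0_grid"] = list(map(float, d["t0_grid"]))
        return d


# ---------------------------------------------------------------------------
# recordings


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_recording(path: str | Path, format: str | None = None) -> MultichannelRecording:
    """Read a recording from ``delimited`` text, an ``npz`` container or ``edf``.

    For delimited text a JSON sidecar ``<file>.json`` with at least ``fs``
    must sit next to the data file.
    """
    path = Path(path)
    if format is None:
        format = {".npz": "npz", ".edf": "edf"}.get(path.suffix.lower(), "delimited")
    if format == "npz":
        with np.load(path, allow_pickle=False) as z:
            return MultichannelRecording(
                data=z["data"],
                fs=float(z["fs"]),
                channel_ids=[str(c) for c in z["channel_ids"]],
                units=str(z["units"]) if "units" in z else "au",
            )
    if format == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ConfigurationError("EDF support requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return MultichannelRecording(
            data=raw.get_data(), fs=float(raw.info["sfreq"]), channel_ids=raw.ch_names
        )
    if format != "delimited":
        raise ConfigurationError(f"unknown recording format {format!r}")

    side = _sidecar_path(path)
    if not side.exists():
        raise ConfigurationError(f"missing sampling-rate sidecar {side}")
    meta = json.loads(side.read_text())
    if "fs" not in meta:
        raise ConfigurationError(f"sidecar {side} lacks 'fs'")
    rows = []
    for r, line in enumerate(path.read_text().splitlines()):
        if not line.strip():
            continue
        vals = []
        for c, tok in enumerate(line.replace(",", "\t").split()):
            try:
                v = float(tok)
            except ValueError:
                raise ParseError(f"non-numeric cell at row {r}, column {c}: {tok!r}")
            if not np.isfinite(v):
                raise ParseError(f"non-finite cell at row {r}, column {c}: {tok!r}")
            vals.append(v)
        rows.append(vals)
    if len({len(r) for r in rows}) > 1:
        raise ParseError("ragged rows in delimited recording")
    return MultichannelRecording(
        data=np.asarray(rows, dtype=float),
        fs=float(meta["fs"]),
        channel_ids=meta.get("channel_ids") or (),
        units=meta.get("units", "au"),
    )


def write_recording(rec: MultichannelRecording, path: str | Path, format: str | None = None) -> None:
    """Write a recording; ``npz`` round-trips bitwise, text at 17 digits."""
    path = Path(path)
    if format is None:
        format = "npz" if path.suffix.lower() == ".npz" else "delimited"
    if format == "npz":
        np.savez(
            path,
            data=rec.data,
            fs=rec.fs,
            channel_ids=np.asarray(rec.channel_ids),
            units=rec.units,
        )
        return
    np.savetxt(path, rec.data, fmt="%.17g", delimiter="\t")
    _sidecar_path(path).write_text(
        json.dumps({"fs": rec.fs, "channel_ids": list(rec.channel_ids), "units": rec.units})
    )


# ---------------------------------------------------------------------------
# tables


def write_table(records: Iterable[Mapping], path: str | Path) -> None:
    """Write keyed rows as a TSV with header; floats at 10 significant digits."""
    records = list(records)
    if records:
        keys = set(records[0].keys())
        for i, r in enumerate(records):
            if set(r.keys()) != keys:
                raise SchemaError(f"row {i} keys {sorted(r.keys())} != {sorted(keys)}")
        df = pd.DataFrame(records, columns=list(records[0].keys()))
    else:
        df = pd.DataFrame()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# provenance


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(run_dir: str | Path, params: Mapping, inputs: Sequence[str | Path] = ()) -> Path:
    """Record every parameter, the seed and input hashes for exact reruns."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "params": dict(params),
        "inputs": {str(p): file_sha256(p) for p in inputs},
    }
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out
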
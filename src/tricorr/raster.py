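"""Binary spike rasters, spike-time tables, and their text formats.

The raster text dialect is a plain matrix — rows are channels (spatial
cells flattened row-major), columns are time bins, entries 0/1,
whitespace- or comma-delimited — with optional ``#``-prefixed header
lines carrying ``spatial_shape``, ``bin_width_s`` and ``channel_labels``.
Spike-time tables are two-column delimited text (channel id, time in
seconds); an electrode layout file maps channel ids to integer grid
coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RasterFormatError",
    "SpikeRaster",
    "SpikeTimesTable",
    "read_raster",
    "write_raster",
    "read_spike_times",
    "read_layout",
    "bin_spike_times",
]


class RasterFormatError(ValueError):
    """Malformed raster or table text."""


@dataclass
class SpikeRaster:
    """A binary occupancy grid with >=1 spatial dimensions and one time axis.

    ``values`` has shape ``(*spatial_shape, n_time_bins)`` and entries in
    {0, 1}.  ``bin_width_s`` is the temporal bin width in seconds if known;
    ``channel_labels`` optionally names each spatial cell (row-major).
    """

    values: np.ndarray
    bin_width_s: float | None = None
    channel_labels: tuple[str, ...] | None = field(default=None)

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim < 2:
            raise ValueError("raster needs at least one spatial and one time dim")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.values = values.astype(np.uint8)
        if self.bin_width_s is not None and not self.bin_width_s > 0:
            raise ValueError("bin_width_s must be positive")
        if self.channel_labels is not None:
            self.channel_labels = tuple(str(c) for c in self.channel_labels)
            if len(self.channel_labels) != self.n_channels:
                raise ValueError(
                    f"{len(self.channel_labels)} labels for {self.n_channels} channels"
                )

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.values.shape[:-1]

    @property
    def d_s(self) -> int:
        return self.values.ndim - 1

    @property
    def n_time_bins(self) -> int:
        return self.values.shape[-1]

    @property
    def n_channels(self) -> int:
        """N: the number of spatial cells (product of spatial_shape)."""
        return int(np.prod(self.spatial_shape))

    @property
    def size(self) -> int:
        """NT: channels times time bins."""
        return self.n_channels * self.n_time_bins

    @property
    def n_spikes(self) -> int:
        return int(self.values.sum())

    @property
    def rate(self) -> float:
        """p: spikes per bin, n_spikes / NT."""
        return self.n_spikes / self.size

    def flat_values(self) -> np.ndarray:
        """The grid as a 2-D (n_channels, n_time_bins) matrix."""
        return self.values.reshape(self.n_channels, self.n_time_bins)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeRaster):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and bool((self.values == other.values).all())
            and (self.bin_width_s or None) == (other.bin_width_s or None)
            and self.channel_labels == other.channel_labels
        )


@dataclass
class SpikeTimesTable:
    """Already-detected spike times plus an electrode layout.

    ``records`` is a DataFrame with columns ``channel_id`` (str) and
    ``time_s`` (non-negative float); ``layout`` maps every channel id to
    its 0-based integer grid coordinates.
    """

    records: pd.DataFrame
    layout: dict[str, tuple[int, ...]]

    def __post_init__(self):
        records = pd.DataFrame(self.records)
        missing = {"channel_id", "time_s"} - set(records.columns)
        if missing:
            raise ValueError(f"spike-time table missing columns {sorted(missing)}")
        records = records.assign(
            channel_id=records["channel_id"].astype(str),
            time_s=records["time_s"].astype(float),
        )
        if len(records) and not np.isfinite(records["time_s"]).all():
            raise ValueError("spike times must be finite")
        if len(records) and (records["time_s"] < 0).any():
            raise ValueError("spike times must be non-negative")
        self.layout = {str(k): tuple(int(c) for c in v) for k, v in self.layout.items()}
        dims = {len(v) for v in self.layout.values()}
        if len(dims) > 1:
            raise ValueError("layout coordinates have inconsistent dimensionality")
        unknown = set(records["channel_id"]) - set(self.layout)
        if unknown:
            raise KeyError(f"channels missing from layout: {sorted(unknown)}")
        self.records = records

    @property
    def d_s(self) -> int:
        return len(next(iter(self.layout.values()))) if self.layout else 1


def _split_fields(line: str) -> list[str]:
    line = line.replace(",", " ")
    return line.split()


def read_raster(path, dialect: str = "matrix_text") -> SpikeRaster:
    """Read a raster matrix text file.

    Entries > 0 are clipped to 1 (with a logged warning) — the binary
    raster contract.  Ragged rows and empty files raise
    :class:`RasterFormatError`.
    """
    if dialect != "matrix_text":
        raise ValueError(f"unknown dialect {dialect!r}")
    headers: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    headers[key.strip()] = value.strip()
                continue
            try:
                row = [float(tok) for tok in _split_fields(stripped)]
            except ValueError as exc:
                raise RasterFormatError(f"{path}: line {lineno}: {exc}") from None
            if rows and len(row) != len(rows[0]):
                raise RasterFormatError(
                    f"{path}: row at line {lineno} has {len(row)} entries, "
                    f"expected {len(rows[0])} (ragged matrix)"
                )
            rows.append(row)
    if not rows:
        raise RasterFormatError(f"{path}: no data rows")
    matrix = np.array(rows)
    if (matrix > 1).any() or ((matrix > 0) & (matrix < 1)).any():
        logger.warning(
            "%s: %d entries outside {0,1} clipped to binary",
            path,
            int(((matrix != 0) & (matrix != 1)).sum()),
        )
    if (matrix < 0).any():
        raise RasterFormatError(f"{path}: negative entries are not spike counts")
    values = (matrix > 0).astype(np.uint8)
    spatial_shape = (values.shape[0],)
    if "spatial_shape" in headers:
        spatial_shape = tuple(int(v) for v in _split_fields(headers["spatial_shape"]))
        if int(np.prod(spatial_shape)) != values.shape[0]:
            raise RasterFormatError(
                f"{path}: spatial_shape {spatial_shape} does not match "
                f"{values.shape[0]} rows"
            )
    bin_width = float(headers["bin_width_s"]) if "bin_width_s" in headers else None
    labels = None
    if "channel_labels" in headers:
        labels = tuple(headers["channel_labels"].split(","))
    return SpikeRaster(
        values.reshape(*spatial_shape, values.shape[1]),
        bin_width_s=bin_width,
        channel_labels=labels,
    )


def write_raster(raster: SpikeRaster, path) -> None:
    """Write a raster as matrix text; inverse of :func:`read_raster`.

    Rasters with >= 2 spatial dims are flattened row-major with the
    layout recorded in a ``# spatial_shape`` header line.
    """
    with open(path, "w") as fh:
        fh.write(f"# spatial_shape: {' '.join(map(str, raster.spatial_shape))}\n")
        if raster.bin_width_s is not None:
            fh.write(f"# bin_width_s: {raster.bin_width_s!r}\n")
        if raster.channel_labels is not None:
            fh.write(f"# channel_labels: {','.join(raster.channel_labels)}\n")
        for row in raster.flat_values():
            fh.write(" ".join(str(int(v)) for v in row))
            fh.write("\n")


def read_spike_times(path, layout_path) -> SpikeTimesTable:
    """Read a spike-time table and its electrode layout."""
    records = pd.read_csv(
        path, sep=None, engine="python", comment="#",
        names=["channel_id", "time_s"], dtype={"channel_id": str},
    )
    layout = read_layout(layout_path)
    return SpikeTimesTable(records=records, layout=layout)


def read_layout(path) -> dict[str, tuple[int, ...]]:
    """Read a channel layout file: ``channel_id x [y]`` per line."""
    layout: dict[str, tuple[int, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = _split_fields(stripped)
            if len(fields) < 2:
                raise RasterFormatError(
                    f"{path}: line {lineno}: need channel_id plus >=1 coordinate"
                )
            layout[fields[0]] = tuple(int(v) for v in fields[1:])
    return layout


def bin_spike_times(
    table: SpikeTimesTable, bin_rate_hz: float, duration_s: float
) -> SpikeRaster:
    """Bin spike times into a binary raster at the given sampling rate.

    Bins are half-open ``[k/rate, (k+1)/rate)``; multiple spikes falling
    into the same channel-bin are counted as a single spike.
    """
    if not bin_rate_hz > 0:
        raise ValueError("bin_rate_hz must be positive")
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")
    n_bins = math.floor(duration_s * bin_rate_hz)
    coords = np.array(sorted(table.layout.values()) or [(0,)])
    spatial_shape = tuple(int(coords[:, d].max()) + 1 for d in range(coords.shape[1]))
    values = np.zeros((*spatial_shape, n_bins), dtype=np.uint8)
    for channel, time_s in zip(table.records["channel_id"], table.records["time_s"]):
        if time_s >= duration_s:
            raise ValueError(
                f"spike at {time_s} s on channel {channel!r} is outside the "
                f"{duration_s} s recording"
            )
        pos = table.layout[channel]  # KeyError for unknown channels
        values[(*pos, math.floor(time_s * bin_rate_hz))] = 1
    return SpikeRaster(values, bin_width_s=1.0 / bin_rate_hz)
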
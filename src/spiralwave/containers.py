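"""Shared in-memory containers for HD-MEA recordings and snapshot stacks.

Coordinate convention (used everywhere in the package)
------------------------------------------------------
The electrode grid is indexed by (row, col). Rows increase downward and
columns increase rightward, matching how the 64 x 64 array is displayed.
Reported (fractional) grid coordinates such as wave centers are **1-based**,
i.e. the first electrode is (1, 1) and a uniform frame on a 64-grid has its
center of mass at (32.5, 32.5). Internally arrays are 0-based numpy arrays.

Angles around a point are measured as ``theta = atan2(row - r0, col - c0)``
in array coordinates. Because rows grow downward, increasing ``theta`` is
visually *clockwise* on a row-down display; a wave whose pattern advances in
the direction of decreasing ``theta`` therefore appears counter-clockwise.
A spiral with positive arm index (and hence positive phase winding number,
see :func:`spiralwave.waves.winding_number`) rotates counter-clockwise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ElectrodeLayout",
    "VoltageRecording",
    "SnapshotStack",
    "derive_seed",
]


def derive_seed(global_seed: int, name: str) -> int:
    """Derive a per-stage seed deterministically from a global seed and a label.

    The result is always in ``[0, 2**31)`` so it can be fed to any RNG API.
    """
    return (int(global_seed) * 1_000_003 + zlib.crc32(name.encode())) % (2**31)


@dataclass(frozen=True)
class ElectrodeLayout:
    """Rectangular electrode grid with a fixed pitch.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; the channel count is ``n_rows * n_cols``.
    pitch_um
        Center-to-center electrode spacing in micrometres.
    """

    n_rows: int = 64
    n_cols: int = 64
    pitch_um: float = 42.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def channel_to_rc(self, channel: np.ndarray | int):
        """Map flat channel index -> (row, col), row-major, 0-based."""
        ch = np.asarray(channel)
        return ch // self.n_cols, ch % self.n_cols

    def rc_to_channel(self, row, col):
        return np.asarray(row) * self.n_cols + np.asarray(col)

    def positions_um(self) -> np.ndarray:
        """(n_channels, 2) array of (x, y) positions in um.

        x = col * pitch, y = row * pitch for the regular grid.
        """
        rows, cols = self.channel_to_rc(np.arange(self.n_channels))
        return np.column_stack([cols * self.pitch_um, rows * self.pitch_um]).astype(float)

    def active_area_mm2(self) -> float:
        """Active sensing area in mm^2 (grid extent x pitch, squared)."""
        return (self.n_rows * self.pitch_um * 1e-3) * (self.n_cols * self.pitch_um * 1e-3)

    def electrode_density_per_mm2(self) -> float:
        return self.n_channels / self.active_area_mm2()


@dataclass
class VoltageRecording:
    """A (channels x time) extracellular voltage matrix in microvolts.

    Channels are in row-major grid order (row 0 col 0, row 0 col 1, ...).
    ``provenance`` tracks the processing stages applied so far.
    """

    voltage: np.ndarray
    sampling_rate: float
    layout: ElectrodeLayout
    provenance: tuple = ("raw",)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage)
        if self.voltage.ndim != 2:
            raise ValueError("voltage must be a 2-D (channels x time) array")
        if self.voltage.shape[0] != self.layout.n_channels:
            raise ValueError(
                f"channel count {self.voltage.shape[0]} does not match layout "
                f"size {self.layout.n_channels}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.voltage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_voltage(self, voltage: np.ndarray, tag: str) -> "VoltageRecording":
        return replace(self, voltage=voltage, provenance=self.provenance + (tag,))


@dataclass
class SnapshotStack:
    """Time-ordered stack of (n_rows x n_cols) voltage frames.

    ``frames`` has shape (n_frames, n_rows, n_cols) in uV; ``frame_interval``
    is the time between frames in seconds (default 1 ms).
    """

    frames: np.ndarray
    frame_interval: float = 0.001
    start_s: float = 0.0
    layout: ElectrodeLayout | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, n_rows, n_cols)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.layout is None:
            self.layout = ElectrodeLayout(
                n_rows=self.frames.shape[1], n_cols=self.frames.shape[2]
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def end_s(self) -> float:
        return self.start_s + self.n_frames * self.frame_interval

    def as_channels_time(self) -> np.ndarray:
        """Return a (channels, time) view of the stack (row-major channels)."""
        f = self.frames
        return f.reshape(f.shape[0], -1).T

    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.n_frames) * self.frame_interval
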
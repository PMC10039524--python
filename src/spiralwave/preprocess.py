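"""Filtering, artifact removal, and snapshot extraction.

Raw voltages are delta band-pass filtered with a zero-phase (forward +
backward) second-order Butterworth filter, cleaned of large-amplitude
artifacts, and binned into 1 ms snapshot frames on the electrode grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import SnapshotStack, VoltageRecording

__all__ = [
    "BAND_EDGES_HZ",
    "BandTable",
    "bandpass_delta",
    "bandpass",
    "remove_artifacts",
    "extract_snapshots",
    "select_evenly_spaced",
    "band_amplitudes",
]

#: Canonical EEG-style band edges in Hz. Delta is listed as 0-4 Hz for the
#: band-amplitude table; the spiral detection pipeline filters at 1-4 Hz.
BAND_EDGES_HZ = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (7.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 80.0),
}

#: High-pass substituted for a 0 Hz band edge, for numerical stability.
_MIN_HIGHPASS_HZ = 0.1


def bandpass(rec: VoltageRecording, low: float, high: float,
             order: int = 2) -> VoltageRecording:
    """Zero-phase Butterworth band-pass applied per channel.

    Uses ``sosfiltfilt`` (forward and reverse) so the group delay is zero.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz at/above Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate,
                        output="sos")
    # filter in channel blocks to bound the float64 working set
    out = np.empty_like(rec.voltage, dtype=np.float32)
    block = max(1, 2**25 // max(rec.n_samples, 1))
    for i in range(0, rec.n_channels, block):
        out[i:i + block] = signal.sosfiltfilt(
            sos, rec.voltage[i:i + block], axis=1).astype(np.float32)
    return rec.with_voltage(out, f"bandpass[{low}-{high}Hz]")


def bandpass_delta(rec: VoltageRecording, low: float = 1.0, high: float = 4.0,
                   order: int = 2) -> VoltageRecording:
    """Delta-range (default 1-4 Hz) zero-phase band-pass."""
    return bandpass(rec, low, high, order)


def remove_artifacts(rec: VoltageRecording, threshold: float = 200.0,
                     replacement: str = "clean-mean") -> VoltageRecording:
    """Replace samples with |v| > threshold (uV) by the channel mean.

    ``replacement='clean-mean'`` (default) computes each channel's mean over
    its non-artifact samples only, so the artifact does not contaminate its
    own replacement; ``'all-mean'`` uses the mean over all samples. A channel
    whose samples are all artifacts is zeroed with a warning.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if replacement not in ("clean-mean", "all-mean"):
        raise ValueError("replacement must be 'clean-mean' or 'all-mean'")
    v = rec.voltage.astype(np.float32, copy=True)
    bad = np.abs(v) > threshold
    n_bad = bad.sum(axis=1)
    if not n_bad.any():
        return rec.with_voltage(v, "artifact-clean")

    n = v.shape[1]
    if replacement == "all-mean":
        means = v.mean(axis=1)
    else:
        good_sum = np.where(bad, 0.0, v).sum(axis=1)
        n_good = n - n_bad
        with np.errstate(invalid="ignore", divide="ignore"):
            means = good_sum / n_good
    dead = n_bad == n
    if dead.any():
        warnings.warn(f"{int(dead.sum())} channel(s) were entirely artifactual; "
                      "replaced by zeros")
        means = np.where(dead, 0.0, means)
    rows = np.nonzero(n_bad)[0]
    for ch in rows:
        v[ch, bad[ch]] = means[ch]
    return rec.with_voltage(v, "artifact-clean")


def extract_snapshots(rec: VoltageRecording, window: tuple | None = None,
                      frame_interval: float = 0.001) -> SnapshotStack:
    """Bin a window of the recording into grid frames.

    Each frame is the per-channel mean over one ``frame_interval`` bin,
    reshaped to the layout grid; bin-averaging (rather than decimation)
    avoids aliasing. The frame count is ``floor(window_length /
    frame_interval)``.
    """
    if window is None:
        window = (0.0, rec.duration_s)
    start, end = window
    if not (0 <= start < end <= rec.duration_s + 1e-9):
        raise ValueError(f"window {window} outside recording (0, {rec.duration_s})")
    samples_per_frame = rec.sampling_rate * frame_interval
    if samples_per_frame < 1 - 1e-9:
        raise ValueError("frame_interval shorter than one sample")

    i0 = int(round(start * rec.sampling_rate))
    n_frames = int(np.floor((end - start) / frame_interval + 1e-9))
    if n_frames < 1:
        raise ValueError("empty window")

    layout = rec.layout
    spf_int = int(round(samples_per_frame))
    if abs(samples_per_frame - spf_int) < 1e-9:
        # integer bin division: exact block means
        n_used = n_frames * spf_int
        block = rec.voltage[:, i0:i0 + n_used]
        frames = block.reshape(layout.n_channels, n_frames, spf_int).mean(axis=2)
    else:
        # non-integer rate ratio (e.g. 7.7 kHz -> 1 ms): variable bin edges
        edges = i0 + np.round(np.arange(n_frames + 1) * samples_per_frame).astype(int)
        edges = np.minimum(edges, rec.n_samples)
        csum = np.concatenate(
            [np.zeros((layout.n_channels, 1)),
             np.cumsum(rec.voltage, axis=1, dtype=np.float64)], axis=1)
        counts = np.diff(edges)
        if np.any(counts < 1):
            raise ValueError("window extends past the recording")
        frames = (csum[:, edges[1:]] - csum[:, edges[:-1]]) / counts
    frames = frames.T.reshape(n_frames, layout.n_rows, layout.n_cols)
    return SnapshotStack(frames.astype(np.float32), frame_interval, start, layout)


def select_evenly_spaced(stack: SnapshotStack, k: int = 6) -> SnapshotStack:
    """Keep ``k`` evenly spaced frames, always including the first and last."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if stack.n_frames < k:
        raise ValueError(f"stack has {stack.n_frames} frames, need >= {k}")
    idx = np.round(np.linspace(0, stack.n_frames - 1, k)).astype(int)
    frames = stack.frames[idx]
    interval = (stack.frame_interval * (stack.n_frames - 1) / (k - 1)
                if stack.n_frames > 1 else stack.frame_interval)
    return SnapshotStack(frames, interval, stack.start_s, stack.layout)


@dataclass
class BandTable:
    """Mean band-filtered voltage amplitude (uV) per frequency band."""

    amplitudes: dict

    def argmax_band(self) -> str:
        return max(self.amplitudes, key=self.amplitudes.get)

    def __getitem__(self, band: str) -> float:
        return self.amplitudes[band]


def band_amplitudes(rec: VoltageRecording, order: int = 2) -> BandTable:
    """Mean absolute band-filtered voltage per band (delta ... gamma).

    A 0 Hz lower edge is implemented as a 0.1 Hz high-pass for stability.
    Bands whose upper edge reaches Nyquist are dropped with a warning.
    """
    nyq = rec.sampling_rate / 2.0
    if rec.sampling_rate <= 160:
        raise ValueError("sampling rate too low to resolve the gamma band")
    amplitudes = {}
    for band, (lo, hi) in BAND_EDGES_HZ.items():
        lo = max(lo, _MIN_HIGHPASS_HZ)
        if hi >= nyq:
            warnings.warn(f"band {band} ({lo}-{hi} Hz) above Nyquist; dropped")
            continue
        filtered = bandpass(rec, lo, hi, order)
        amplitudes[band] = float(np.abs(filtered.voltage).mean())
    return BandTable(amplitudes)
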
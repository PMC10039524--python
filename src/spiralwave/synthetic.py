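"""Seeded synthetic HD-MEA recordings: spiral waves, planar waves, baseline.

The generator is phenomenological, not biophysical. It emulates the main
signatures of disinhibited cortical slice activity on a 64 x 64 array:

* **Spiral waves** — delta-band (1-4 Hz) rotation about a fixed center with
  an amplitude dip at the core, an Archimedean phase profile
  ``2*pi*f*t + m*theta + k*rho``, a smooth random "domain" envelope, and a
  compact spatial extent so the activity-weighted center of mass coincides
  with the rotation core.
* **Planar waves** — a single travelling plane wave.
* **Baseline** — a spatiotemporally correlated Gaussian field standing in
  for healthy ongoing activity (no phase singularities programmed).
* **Artifacts** — large-amplitude excursions exceeding the 200 uV cleaning
  threshold, for exercising artifact removal.

``generate_dataset`` concatenates events separated by baseline gaps and
returns the ground truth needed to score detection, center, direction and
cycle-count recovery.

Sign convention: a spiral with positive arm index ``m`` has phase winding
number ``+m`` around its core and rotates counter-clockwise on a row-down
display (see :mod:`spiralwave.containers`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .containers import ElectrodeLayout, SnapshotStack, VoltageRecording, derive_seed

__all__ = [
    "SpiralParams",
    "PlanarParams",
    "BaselineParams",
    "DatasetSpec",
    "GroundTruthEvent",
    "GroundTruth",
    "generate_spiral_wave",
    "generate_planar_wave",
    "generate_baseline",
    "plan_dataset",
    "generate_dataset",
    "add_gaussian_noise",
    "inject_artifacts",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class SpiralParams:
    """Parameters of one synthetic spiral wave.

    ``center`` is a 1-based fractional (row, col) grid coordinate. ``arms``
    is the signed arm count ``m``; its sign sets the rotation direction
    (positive = counter-clockwise). ``cycles`` is the programmed number of
    full oscillation cycles, which must fit in the window
    (``duration * frequency >= cycles``).
    """

    center: tuple = (32.5, 32.5)
    frequency: float = 2.0            # Hz, delta band
    arms: int = 1                     # signed; + = CCW
    cycles: int = 2
    core_dip_um: float = 300.0        # amplitude half-saturation radius
    # radial wavelength far larger than the array, so the phase gradient is
    # rotation-dominated and vector fields circulate about the core
    wavenumber: float = 2 * np.pi / 20000.0  # rad/um, radial phase
    amplitude: float = 100.0          # uV
    # activation-domain envelope: a positive multiplicative field with a
    # power-law spatial spectrum (knee at the smoothness scale, scale-free
    # texture below it), lognormal depth, and slow temporal evolution
    envelope_smoothness_um: float = 250.0    # spectral knee (domain scale)
    envelope_depth: float = 0.8       # log-SD of the domain modulation
    envelope_time_corr_s: float = 0.3 # evolution time constant
    envelope_spectral_exponent: float = 0.75
    domain_radius_um: float = 600.0   # Gaussian extent of the active domain
    noise_sd: float = 5.0             # uV, additive white noise
    duration: float = 1.15            # s
    frame_rate: float = 1000.0        # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.arms == 0:
            raise ValueError("arm count must be nonzero")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.duration * self.frequency < self.cycles:
            raise ValueError(
                "duration x frequency must be >= cycles: the programmed "
                "rotations must fit in the window"
            )
        if self.frame_rate < 2 * self.frequency:
            raise ValueError("frame rate below Nyquist of the temporal frequency")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def for_cycles(cls, cycles: int, frequency: float = 2.0, margin: float = 0.4,
                   **kwargs) -> "SpiralParams":
        """Build params whose duration yields exactly ``cycles`` full cycles.

        The duration is ``(cycles + margin) / frequency`` so the floor of the
        total phase advance is unambiguous despite analytic-signal edge
        effects.
        """
        duration = (cycles + margin) / frequency
        return cls(frequency=frequency, cycles=cycles, duration=duration, **kwargs)


@dataclass
class PlanarParams:
    """Parameters of one synthetic planar travelling wave."""

    direction_angle: float = 0.0       # rad, propagation direction in array coords
    frequency: float = 2.0             # Hz
    wavenumber: float = 2 * np.pi / 2000.0  # rad/um
    amplitude: float = 80.0            # uV
    noise_sd: float = 5.0              # uV
    duration: float = 2.0              # s
    frame_rate: float = 1000.0         # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.duration <= 0:
            raise ValueError("amplitude and duration must be positive")
        if self.frame_rate < 2 * self.frequency:
            raise ValueError("frame rate below Nyquist of the temporal frequency")


@dataclass
class BaselineParams:
    """Parameters of the correlated-noise baseline field.

    With ``spectral_exponent`` = 0 (default) the field is Gaussian-smoothed
    white noise with correlation length ``spatial_corr_um``. A positive
    exponent ``a`` instead shapes the spatial spectrum with a power-law
    tail below the knee scale (eigenvalue of the n-th spatial mode decaying
    like n^-a), giving scale-free texture down to the electrode pitch.
    """

    noise_sd: float = 8.0              # uV
    spatial_corr_um: float = 500.0     # correlation length / spectral knee
    temporal_corr_s: float = 0.15      # Gaussian smoothing time constant
    duration: float = 10.0             # s
    frame_rate: float = 1000.0         # Hz
    spectral_exponent: float = 0.0     # 0 = smoothed white noise
    seed: int = 0


@dataclass
class DatasetSpec:
    """Mixture specification for :func:`generate_dataset`.

    Durations of spiral events are drawn from a normal distribution with
    mean ``duration_mean_s`` and SD ``duration_sd_s`` truncated to
    ``[duration_min_s, duration_max_s]``, emulating slow multi-second wave
    events. Events are separated by ``gap_s`` seconds of baseline so that
    event rates of roughly 7 per minute arise at the default duration.
    """

    n_spirals_cw: int = 3
    n_spirals_ccw: int = 3
    n_planar: int = 0
    duration_mean_s: float = 2.52
    duration_sd_s: float = 1.00
    duration_min_s: float = 0.8
    duration_max_s: float = 6.0
    gap_s: float = 5.0
    frequency_range_hz: tuple = (1.2, 3.0)
    spiral_amplitude_uv: float = 100.0
    planar_amplitude_uv: float = 80.0
    # spiral cores are pinned to one tissue locus per recording: the locus is
    # drawn once inside a central box and individual waves jitter around it
    center_box_halfwidth: float = 6.0  # grid units around the array middle
    center_jitter: float = 0.7         # per-event SD, grid units
    baseline: BaselineParams = field(default_factory=BaselineParams)
    sensor_noise_sd: float = 2.0       # white noise over the whole recording
    n_artifacts: int = 0
    frame_rate: float = 1000.0

    @property
    def n_events(self) -> int:
        return self.n_spirals_cw + self.n_spirals_ccw + self.n_planar


@dataclass
class GroundTruthEvent:
    event_id: int
    kind: str                          # spiral | planar | baseline
    start_s: float
    end_s: float
    center_row: float = np.nan         # 1-based grid units
    center_col: float = np.nan
    direction: str = "none"            # CW | CCW | none
    cycles: int = 0


@dataclass
class GroundTruth:
    """Per-event ground truth annotations with disjoint windows."""

    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        windows = sorted((e.start_s, e.end_s) for e in self.events)
        for (s0, e0), (s1, e1) in zip(windows, windows[1:]):
            if s1 < e0:
                raise ValueError("ground-truth windows must be disjoint")

    def of_kind(self, kind: str) -> list:
        return [e for e in self.events if e.kind == kind]

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["event_id", "kind", "start_s", "end_s", "center_row",
                "center_col", "direction", "cycles"]
        return pd.DataFrame([asdict(e) for e in self.events], columns=cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(e) for e in self.events], fh, indent=2)


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _polar_grid(layout: ElectrodeLayout, center):
    """Return (rho_um, theta) arrays of shape (n_rows, n_cols).

    ``center`` is 1-based (row, col); theta = atan2(row - r0, col - c0).
    """
    r0 = float(center[0]) - 1.0
    c0 = float(center[1]) - 1.0
    rows = np.arange(layout.n_rows)[:, None] - r0
    cols = np.arange(layout.n_cols)[None, :] - c0
    rho = np.hypot(rows, cols) * layout.pitch_um
    theta = np.arctan2(rows, cols)
    return rho, theta


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def generate_spiral_wave(params: SpiralParams,
                         layout: ElectrodeLayout | None = None) -> VoltageRecording:
    """Render one spiral wave as a (channels x time) voltage recording.

    The voltage is ``A(rho) * E(x, t) * cos(2 pi f t + m theta + k rho) +
    noise`` where ``A(rho) = A_max * rho / (rho + rho_dip) *
    exp(-rho^2 / (2 sigma_dom^2))`` enforces the central amplitude dip and
    a compact activity domain around the core. ``E`` is a positive
    multiplicative envelope — a clipped lognormal of a unit-SD power-law
    field, slowly evolving in time — that creates the delimited activation
    "domains" observed within waves at all scales below the knee. Because
    the envelope is multiplicative and positive, the instantaneous phase of
    the noiseless wave is exactly ``2 pi f t + m theta + k rho``.
    """
    layout = layout or ElectrodeLayout()
    r, c = params.center
    if not (1 <= r <= layout.n_rows and 1 <= c <= layout.n_cols):
        raise ValueError(f"spiral center {params.center} outside the grid")

    rng = np.random.default_rng(params.seed)
    rho, theta = _polar_grid(layout, params.center)
    radial = rho / (rho + params.core_dip_um)
    radial *= np.exp(-0.5 * (rho / params.domain_radius_um) ** 2)
    amp = (params.amplitude * radial).astype(np.float32).ravel()

    spatial_phase = (params.arms * theta + params.wavenumber * rho).astype(np.float32).ravel()
    n = int(round(params.duration * params.frame_rate))
    t = np.arange(n, dtype=np.float32) / params.frame_rate
    # (channels, time); cos argument = 2 pi f t + m theta + k rho
    v = amp[:, None] * np.cos(2 * np.pi * params.frequency * t[None, :]
                              + spatial_phase[:, None])
    if params.envelope_depth > 0:
        g = generate_baseline(BaselineParams(
            noise_sd=1.0, spatial_corr_um=params.envelope_smoothness_um,
            temporal_corr_s=params.envelope_time_corr_s,
            duration=params.duration, frame_rate=params.frame_rate,
            spectral_exponent=params.envelope_spectral_exponent,
            seed=derive_seed(params.seed, "envelope")), layout)
        d = params.envelope_depth
        env = np.exp(np.clip(d * g.voltage[:, :n], -2 * d, 2 * d))
        env /= env.mean()
        v *= env
        del env, g
    if params.noise_sd > 0:
        v += rng.normal(0.0, params.noise_sd, size=v.shape).astype(np.float32)
    return VoltageRecording(v.astype(np.float32), params.frame_rate, layout,
                            provenance=("synthetic-spiral",))


def generate_planar_wave(params: PlanarParams | None = None,
                         layout: ElectrodeLayout | None = None,
                         **kwargs) -> VoltageRecording:
    """Render a planar travelling wave propagating along ``direction_angle``.

    ``v = A cos(2 pi f t - k (x cos a + y sin a)) + noise`` with x = col
    pitch, y = row pitch; the phase-velocity field points along angle ``a``.
    """
    if params is None:
        params = PlanarParams(**kwargs)
    layout = layout or ElectrodeLayout()
    rng = np.random.default_rng(params.seed)

    pos = layout.positions_um()        # (channels, 2) -> x, y
    proj = (pos[:, 0] * np.cos(params.direction_angle)
            + pos[:, 1] * np.sin(params.direction_angle))
    n = int(round(params.duration * params.frame_rate))
    t = np.arange(n, dtype=np.float32) / params.frame_rate
    v = params.amplitude * np.cos(
        2 * np.pi * params.frequency * t[None, :]
        - params.wavenumber * proj[:, None].astype(np.float32))
    if params.noise_sd > 0:
        v += rng.normal(0.0, params.noise_sd, size=v.shape).astype(np.float32)
    return VoltageRecording(v.astype(np.float32), params.frame_rate, layout,
                            provenance=("synthetic-planar",))


_CONTROL_RATE = 50.0   # Hz; internal rate for long correlated-noise stretches


def generate_baseline(params: BaselineParams | None = None,
                      layout: ElectrodeLayout | None = None,
                      **kwargs) -> VoltageRecording:
    """Spatiotemporally correlated Gaussian baseline field.

    White noise is smoothed with Gaussian kernels of width
    ``spatial_corr_um`` (space) and ``temporal_corr_s`` (time), then rescaled
    to the requested SD. Long recordings are synthesized on a coarse time
    grid and linearly interpolated, which is exact for the slow (sub-4 Hz)
    content the field is meant to emulate.
    """
    if params is None:
        params = BaselineParams(**kwargs)
    if params.noise_sd < 0 or params.duration <= 0 or params.frame_rate <= 0:
        raise ValueError("baseline parameters must be positive")
    layout = layout or ElectrodeLayout()
    rng = np.random.default_rng(params.seed)

    n_out = int(round(params.duration * params.frame_rate))
    use_coarse = (params.temporal_corr_s * _CONTROL_RATE >= 1.0
                  and params.frame_rate > _CONTROL_RATE)
    rate = _CONTROL_RATE if use_coarse else params.frame_rate
    n_ctrl = max(int(round(params.duration * rate)) + 1, 2)

    field = rng.standard_normal((n_ctrl, layout.n_rows, layout.n_cols))
    sigma_t = params.temporal_corr_s * rate
    if params.spectral_exponent > 0:
        # power-law spatial spectrum with a knee at the correlation length
        qy = 2 * np.pi * np.fft.fftfreq(layout.n_rows, d=layout.pitch_um)
        qx = 2 * np.pi * np.fft.rfftfreq(layout.n_cols, d=layout.pitch_um)
        q2 = qy[:, None] ** 2 + qx[None, :] ** 2
        q0 = 2 * np.pi / max(params.spatial_corr_um, 1e-9)
        amp = (q2 + q0 * q0) ** (-params.spectral_exponent / 2.0)
        spec = np.fft.rfft2(field, axes=(1, 2)) * amp[None]
        field = np.fft.irfft2(spec, s=(layout.n_rows, layout.n_cols),
                              axes=(1, 2))
        if sigma_t > 0:
            field = ndimage.gaussian_filter1d(field, sigma_t, axis=0,
                                              mode="reflect")
    else:
        sigma_s = params.spatial_corr_um / layout.pitch_um
        if sigma_t > 0 or sigma_s > 0:
            field = ndimage.gaussian_filter(field, (sigma_t, sigma_s, sigma_s),
                                            mode="reflect")
    sd = field.std()
    if sd > 0:
        field *= params.noise_sd / sd
    field = field.reshape(n_ctrl, -1).astype(np.float32)   # (time, channels)

    if rate == params.frame_rate:
        v = np.ascontiguousarray(field[:n_out].T)
    else:
        # linear interpolation from the control grid to the output grid,
        # chunked in time to bound the working set
        v = np.empty((field.shape[1], n_out), dtype=np.float32)
        pos = np.arange(n_out) * (rate / params.frame_rate)
        i0 = np.minimum(pos.astype(int), n_ctrl - 2)
        w = (pos - i0).astype(np.float32)
        chunk = 8192
        for s in range(0, n_out, chunk):
            e = min(s + chunk, n_out)
            ww = w[s:e, None]
            v[:, s:e] = ((1 - ww) * field[i0[s:e]] + ww * field[i0[s:e] + 1]).T
    return VoltageRecording(v, params.frame_rate, layout,
                            provenance=("synthetic-baseline",))


def add_gaussian_noise(stack: SnapshotStack, mean: float, sd: float,
                       seed: int = 0) -> SnapshotStack:
    """Add seeded i.i.d. Gaussian values elementwise to a snapshot stack."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    frames = stack.frames + mean
    if sd > 0:
        frames = frames + rng.normal(0.0, sd, size=stack.frames.shape)
    return SnapshotStack(frames, stack.frame_interval, stack.start_s, stack.layout)


def inject_artifacts(rec: VoltageRecording, n_artifacts: int, seed: int = 0,
                     amplitude: float = 400.0, width_s: float = 0.005) -> VoltageRecording:
    """Add brief large-amplitude excursions (> 200 uV) to random channels."""
    if n_artifacts <= 0:
        return rec
    rng = np.random.default_rng(seed)
    v = rec.voltage.copy()
    w = max(int(width_s * rec.sampling_rate), 1)
    for _ in range(n_artifacts):
        ch = rng.integers(0, rec.n_channels)
        t0 = rng.integers(0, max(rec.n_samples - w, 1))
        sign = rng.choice([-1.0, 1.0])
        v[ch, t0:t0 + w] += sign * amplitude
    return rec.with_voltage(v, "artifacts-injected")


# --------------------------------------------------------------------------
# dataset assembly
# --------------------------------------------------------------------------

def _sample_duration(spec: DatasetSpec, rng: np.random.Generator) -> float:
    a = (spec.duration_min_s - spec.duration_mean_s) / spec.duration_sd_s
    b = (spec.duration_max_s - spec.duration_mean_s) / spec.duration_sd_s
    return float(stats.truncnorm.rvs(a, b, loc=spec.duration_mean_s,
                                     scale=spec.duration_sd_s, random_state=rng))


def plan_dataset(spec: DatasetSpec, seed: int = 0,
                 layout: ElectrodeLayout | None = None):
    """Draw all per-event parameters and windows without rendering voltage.

    Returns ``(ground_truth, event_params, total_duration_s)``. Event order
    is a seeded shuffle of the requested spiral/planar mixture; each window
    is preceded by a baseline gap of ``spec.gap_s`` and a trailing gap closes
    the recording.
    """
    if spec.n_events == 0 and spec.gap_s <= 0:
        raise ValueError("dataset spec is empty")
    layout = layout or ElectrodeLayout()
    rng = np.random.default_rng(derive_seed(seed, "dataset-plan"))

    kinds = (["spiral-cw"] * spec.n_spirals_cw
             + ["spiral-ccw"] * spec.n_spirals_ccw
             + ["planar"] * spec.n_planar)
    rng.shuffle(kinds)

    mid_r = (layout.n_rows + 1) / 2.0
    mid_c = (layout.n_cols + 1) / 2.0
    hw = spec.center_box_halfwidth
    locus = (mid_r + rng.uniform(-hw, hw), mid_c + rng.uniform(-hw, hw))

    events, params_list = [], []
    t = spec.gap_s
    lo, hi = spec.frequency_range_hz
    for i, kind in enumerate(kinds):
        if kind.startswith("spiral"):
            d = _sample_duration(spec, rng)
            f = rng.uniform(lo, hi)
            # nudge the duration so f*d sits safely between integers and the
            # programmed cycle count is unambiguous under floor()
            frac = (f * d) % 1.0
            if frac < 0.2:
                d = (np.floor(f * d) + 0.4) / f
            elif frac > 0.75:
                d = (np.floor(f * d) + 0.6) / f
            cycles = int(np.floor(f * d))
            if cycles < 1:
                cycles, d = 1, 1.4 / f
            m = 1 if kind.endswith("ccw") else -1
            center = (
                float(np.clip(locus[0] + rng.normal(0, spec.center_jitter),
                              mid_r - hw - 2, mid_r + hw + 2)),
                float(np.clip(locus[1] + rng.normal(0, spec.center_jitter),
                              mid_c - hw - 2, mid_c + hw + 2)))
            p = SpiralParams(center=center, frequency=f, arms=m, cycles=cycles,
                             amplitude=spec.spiral_amplitude_uv, noise_sd=0.0,
                             duration=d, frame_rate=spec.frame_rate,
                             seed=int(rng.integers(2**31)))
            events.append(GroundTruthEvent(
                event_id=i, kind="spiral", start_s=t, end_s=t + d,
                center_row=center[0], center_col=center[1],
                direction="CCW" if m > 0 else "CW", cycles=cycles))
        else:
            d = float(rng.uniform(1.5, 3.0))
            p = PlanarParams(direction_angle=float(rng.uniform(0, 2 * np.pi)),
                             frequency=float(rng.uniform(lo, hi)),
                             amplitude=spec.planar_amplitude_uv, noise_sd=0.0,
                             duration=d, frame_rate=spec.frame_rate,
                             seed=int(rng.integers(2**31)))
            events.append(GroundTruthEvent(event_id=i, kind="planar",
                                           start_s=t, end_s=t + d))
        params_list.append(p)
        t += events[-1].end_s - events[-1].start_s + spec.gap_s
    return GroundTruth(events=events), params_list, t


def generate_dataset(spec: DatasetSpec, seed: int = 0,
                     layout: ElectrodeLayout | None = None):
    """Render a full recording of events superimposed on continuous baseline.

    Returns ``(VoltageRecording, GroundTruth)``. Events are added on top of
    the ongoing baseline field (as in a slice, where waves ride on background
    activity), plus white sensor noise everywhere.
    """
    layout = layout or ElectrodeLayout()
    truth, params_list, total = plan_dataset(spec, seed, layout)

    base = BaselineParams(**{**asdict(spec.baseline),
                             "duration": total,
                             "frame_rate": spec.frame_rate,
                             "seed": derive_seed(seed, "dataset-baseline")})
    rec = generate_baseline(base, layout)
    v = rec.voltage

    for ev, p in zip(truth.events, params_list):
        if ev.kind == "spiral":
            sub = generate_spiral_wave(p, layout)
        else:
            sub = generate_planar_wave(p, layout)
        i0 = int(round(ev.start_s * spec.frame_rate))
        i1 = min(i0 + sub.n_samples, v.shape[1])
        v[:, i0:i1] += sub.voltage[:, : i1 - i0]

    if spec.sensor_noise_sd > 0:
        rng = np.random.default_rng(derive_seed(seed, "dataset-sensor"))
        chunk = 8192
        for s in range(0, v.shape[1], chunk):
            e = min(s + chunk, v.shape[1])
            v[:, s:e] += rng.normal(
                0.0, spec.sensor_noise_sd, size=(v.shape[0], e - s)
            ).astype(np.float32)

    out = VoltageRecording(v, spec.frame_rate, layout, provenance=("synthetic-dataset",))
    if spec.n_artifacts:
        out = inject_artifacts(out, spec.n_artifacts,
                               seed=derive_seed(seed, "dataset-artifacts"))
    return out, truth
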
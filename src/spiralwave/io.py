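"""File formats, pipeline configuration, and the end-to-end runner.

Recordings travel in an HDF5 container::

    /voltage            (channels x time, float32, uV)
    /layout/rows        per-channel row index (0-based)
    /layout/cols        per-channel column index
    /layout/x_um        per-channel x position (um)
    /layout/y_um        per-channel y position (um)
    attrs: sampling_rate_hz, units, pitch_um

Wave tables are CSV (one row per event), summaries JSON, configuration
YAML. ``run_pipeline`` executes simulate -> preprocess -> detect ->
complexity -> (optional) gan and emits a manifest with per-file checksums
so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import complexity, gan as gan_mod, preprocess, synthetic, waves
from .containers import ElectrodeLayout, SnapshotStack, VoltageRecording, derive_seed

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "RunManifest",
    "read_recording",
    "write_recording",
    "write_snapshots",
    "read_snapshots",
    "events_to_dataframe",
    "save_frames_png",
    "save_quiver_png",
    "run_pipeline",
    "default_config",
]

logger = logging.getLogger("spiralwave")


class SchemaError(ValueError):
    """An input file or configuration is missing a required field."""


# --------------------------------------------------------------------------
# HDF5 recordings
# --------------------------------------------------------------------------

def write_recording(rec: VoltageRecording, path) -> None:
    """Write a recording to the HDF5 container (bit-reproducible)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("voltage", data=rec.voltage.astype(np.float32),
                          track_times=False)
        lay = rec.layout
        rows, cols = lay.channel_to_rc(np.arange(lay.n_channels))
        grp = fh.create_group("layout")
        grp.create_dataset("rows", data=rows.astype(np.int32), track_times=False)
        grp.create_dataset("cols", data=cols.astype(np.int32), track_times=False)
        pos = lay.positions_um()
        grp.create_dataset("x_um", data=pos[:, 0], track_times=False)
        grp.create_dataset("y_um", data=pos[:, 1], track_times=False)
        fh.attrs["sampling_rate_hz"] = float(rec.sampling_rate)
        fh.attrs["units"] = "uV"
        fh.attrs["pitch_um"] = float(lay.pitch_um)
        fh.attrs["provenance"] = ",".join(rec.provenance)


def read_recording(path) -> VoltageRecording:
    """Read a recording, validating the container schema."""
    with h5py.File(path, "r") as fh:
        for key in ("voltage", "layout/rows", "layout/cols",
                    "layout/x_um", "layout/y_um"):
            if key not in fh:
                raise SchemaError(f"missing dataset '{key}' in {path}")
        for attr in ("sampling_rate_hz", "units"):
            if attr not in fh.attrs:
                raise SchemaError(f"missing attribute '{attr}' in {path}")
        voltage = fh["voltage"][()]
        rows = fh["layout/rows"][()]
        cols = fh["layout/cols"][()]
        pitch = float(fh.attrs.get("pitch_um", 42.0))
        n_rows = int(rows.max()) + 1
        n_cols = int(cols.max()) + 1
        layout = ElectrodeLayout(n_rows, n_cols, pitch)
        if layout.n_channels != voltage.shape[0]:
            raise SchemaError(
                f"channel count {voltage.shape[0]} does not equal "
                f"rows x cols = {layout.n_channels}")
        prov = tuple(str(fh.attrs.get("provenance", "raw")).split(","))
        return VoltageRecording(voltage, float(fh.attrs["sampling_rate_hz"]),
                                layout, provenance=prov)


def write_snapshots(stack: SnapshotStack, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("snapshots", data=stack.frames.astype(np.float32),
                          track_times=False)
        fh.attrs["frame_interval_s"] = stack.frame_interval
        fh.attrs["start_s"] = stack.start_s
        fh.attrs["pitch_um"] = stack.layout.pitch_um


def read_snapshots(path) -> SnapshotStack:
    with h5py.File(path, "r") as fh:
        if "snapshots" not in fh:
            raise SchemaError(f"missing dataset 'snapshots' in {path}")
        frames = fh["snapshots"][()]
        layout = ElectrodeLayout(frames.shape[1], frames.shape[2],
                                 float(fh.attrs.get("pitch_um", 42.0)))
        return SnapshotStack(frames, float(fh.attrs["frame_interval_s"]),
                             float(fh.attrs.get("start_s", 0.0)), layout)


# --------------------------------------------------------------------------
# tables and figures
# --------------------------------------------------------------------------

def events_to_dataframe(events) -> pd.DataFrame:
    rows = []
    for i, ev in enumerate(events):
        row = {
            "event_id": i, "kind": ev.kind, "start_s": ev.start_s,
            "end_s": ev.end_s, "duration_s": ev.duration_s,
            "center_row": ev.center.r if ev.center else np.nan,
            "center_col": ev.center.c if ev.center else np.nan,
            "direction": ev.direction, "cycles": ev.cycles,
        }
        for key in ("broad_phases", "rotating", "core_dip",
                    "distance_correlations"):
            row[key] = bool(ev.criteria.get(key, False))
        rows.append(row)
    return pd.DataFrame(rows)


def save_frames_png(stack: SnapshotStack, out_dir, prefix: str = "frame",
                    vmax: float | None = None) -> list:
    """Export each frame as a PNG image; returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vmax = vmax or float(np.abs(stack.frames).max() or 1.0)
    paths = []
    for i, frame in enumerate(stack.frames):
        p = out_dir / f"{prefix}_{i:05d}.png"
        plt.imsave(p, frame, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        paths.append(p)
    return paths


def save_quiver_png(vf: "waves.VectorField", path, step: int = 2) -> None:
    """Quiver render of a vector field (arrows point along propagation)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    u = vf.u[::step, ::step]
    v = vf.v[::step, ::step]
    y, x = np.mgrid[0:vf.u.shape[0]:step, 0:vf.u.shape[1]:step]
    ax.quiver(x, y, u, v, angles="xy")
    ax.invert_yaxis()
    ax.set_aspect("equal")
    fig.savefig(path, dpi=100)
    plt.close(fig)


# --------------------------------------------------------------------------
# pipeline configuration
# --------------------------------------------------------------------------

#: Required top-level keys of a pipeline configuration.
_REQUIRED_KEYS = ("seed", "out_dir", "simulate", "preprocess", "detect",
                  "complexity", "gan")


def default_config(out_dir: str = "spiralwave-run", seed: int = 0) -> dict:
    """A small demo configuration exercising all stages (GAN reduced)."""
    return {
        "seed": seed,
        "out_dir": out_dir,
        "log_level": "INFO",
        "simulate": {
            "n_spirals_cw": 2, "n_spirals_ccw": 2, "n_planar": 1,
            "gap_s": 4.0, "n_artifacts": 2,
        },
        "preprocess": {"band": [1.0, 4.0], "artifact_uv": 200.0},
        "detect": {},
        "complexity": {"mode": "stacked-svd", "k_snapshots": 6},
        "gan": {"enabled": False, "image_side": 16, "planes": 1,
                "iterations": 200, "base_width": 8, "batch_size": 16,
                "n_samples": 32},
    }


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (one YAML file drives all stages)."""

    raw: dict

    def __post_init__(self) -> None:
        for key in _REQUIRED_KEYS:
            if key not in self.raw:
                raise SchemaError(f"missing configuration key '{key}'")
        if not isinstance(self.raw["seed"], int):
            raise SchemaError("'seed' must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.raw["seed"], stage)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    started_at: float
    finished_at: float = 0.0
    outputs: dict = field(default_factory=dict)   # name -> {path, sha256}

    def add(self, name: str, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[name] = {"path": str(path), "sha256": digest}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


# --------------------------------------------------------------------------
# pipeline runner
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig | dict) -> RunManifest:
    """Execute simulate -> preprocess -> detect -> complexity -> (gan).

    Every stochastic stage receives a seed derived deterministically from
    the global seed and the stage name; rerunning with the same
    configuration reproduces identical output checksums.
    """
    if isinstance(config, dict):
        config = PipelineConfig(config)
    cfg = config.raw
    logging.basicConfig(level=getattr(logging, cfg.get("log_level", "INFO")))
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__
    manifest = RunManifest(config.hash(), __version__, time.time())

    def _stage(name):
        logger.info("stage %s (seed %d)", name, config.stage_seed(name))

    try:
        # -- simulate -----------------------------------------------------
        _stage("simulate")
        spec = synthetic.DatasetSpec(**cfg["simulate"])
        rec, truth = synthetic.generate_dataset(spec, seed=config.stage_seed("simulate"))
        rec_path = out / "recording.h5"
        write_recording(rec, rec_path)
        truth.to_csv(out / "ground_truth.csv")
        truth.to_json(out / "ground_truth.json")
        manifest.add("recording", rec_path)
        manifest.add("ground_truth", out / "ground_truth.csv")

        # -- preprocess ---------------------------------------------------
        _stage("preprocess")
        band = cfg["preprocess"].get("band", [1.0, 4.0])
        clean = preprocess.bandpass_delta(rec, band[0], band[1])
        clean = preprocess.remove_artifacts(
            clean, cfg["preprocess"].get("artifact_uv", 200.0))
        clean_path = out / "clean.h5"
        write_recording(clean, clean_path)
        manifest.add("clean", clean_path)

        # -- detect -------------------------------------------------------
        _stage("detect")
        result = waves.detect_waves(clean, waves.WaveCriteria(**cfg["detect"]))
        table = events_to_dataframe(result.events)
        table_path = out / "waves.csv"
        table.to_csv(table_path, index=False)
        manifest.add("waves", table_path)
        logger.info("detected %d events (%d spirals), rate %.2f/min",
                    len(result.events), len(result.spirals()), result.rate_per_min)

        # -- complexity ---------------------------------------------------
        _stage("complexity")
        mode = cfg["complexity"].get("mode", "stacked-svd")
        k = cfg["complexity"].get("k_snapshots", 6)
        rows = []
        for i, ev in enumerate(result.events):
            if ev.stack is None or ev.stack.n_frames < k:
                continue
            sel = preprocess.select_evenly_spaced(ev.stack, k)
            res = complexity.pr_of_stack(sel, mode, label=f"event-{i}")
            rows.append({"event_id": i, "kind": ev.kind, "mode": mode,
                         "pr": res.pr,
                         "pr_per_sqrt_n": res.pr_per_sqrt_channels,
                         "pr_per_sqrt_k": res.pr_per_sqrt_snapshots})
        pr_path = out / "pr.csv"
        pd.DataFrame(rows).to_csv(pr_path, index=False)
        manifest.add("pr", pr_path)

        summary = {
            "n_events": len(result.events),
            "n_spirals": len(result.spirals()),
            "rate_per_min": result.rate_per_min,
            "duration_mean_s": result.duration_mean_s,
            "duration_sd_s": result.duration_sd_s,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        manifest.add("summary", out / "summary.json")

        # -- gan (optional) ----------------------------------------------
        if cfg["gan"].get("enabled", False):
            _stage("gan")
            g = cfg["gan"]
            side, planes = g.get("image_side", 16), g.get("planes", 1)
            stacks = [_downscale_stack(ev.stack, side, planes, k)
                      for ev in result.spirals() if ev.stack is not None
                      and ev.stack.n_frames >= k]
            if stacks:
                gcfg = gan_mod.GANConfig(
                    image_shape=(side, side, planes),
                    base_width=g.get("base_width", 8),
                    iterations=g.get("iterations", 200),
                    batch_size=g.get("batch_size", 16),
                    seed=config.stage_seed("gan"))
                data = gan_mod.build_training_set(stacks, k=planes if planes > 1 else 2)
                # for single-plane models keep each plane as its own item
                if planes == 1:
                    items = data.items.reshape(-1, 1, side, side)
                    data = gan_mod.TrainingSet(
                        items,
                        np.repeat(data.offsets, data.items.shape[1]),
                        np.repeat(data.scales, data.items.shape[1]),
                        np.repeat(data.degenerate, data.items.shape[1]))
                model = gan_mod.GANModel(gcfg)
                model, history = gan_mod.train(model, data, gcfg)
                ckpt = out / "gan.ckpt.npz"
                gan_mod.save_checkpoint(model, ckpt)
                history.to_dataframe().to_csv(out / "gan_scores.csv", index=False)
                manifest.add("gan_checkpoint", ckpt)
                manifest.add("gan_scores", out / "gan_scores.csv")
            else:
                logger.warning("gan stage enabled but no spiral events found")
    except Exception:
        logger.exception("pipeline stage failed")
        raise

    manifest.finished_at = time.time()
    manifest.to_json(out / "manifest.json")
    return manifest


def _downscale_stack(stack: SnapshotStack, side: int, planes: int,
                     k: int) -> SnapshotStack:
    """Select k evenly spaced frames and block-average to a small grid."""
    sel = preprocess.select_evenly_spaced(stack, max(planes, 2) if planes > 1 else k)
    frames = sel.frames
    if planes == 1:
        frames = frames[:2]
    factor = frames.shape[1] // side
    if factor > 1:
        n = frames.shape[0]
        frames = frames[:, :side * factor, :side * factor]
        frames = frames.reshape(n, side, factor, side, factor).mean(axis=(2, 4))
    return SnapshotStack(frames, sel.frame_interval, sel.start_s)
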
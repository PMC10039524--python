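"""Shared fixtures: synthetic events, datasets, and a smoke-trained GAN.

Expensive objects are session-scoped so the recovery, detection, and
adversarial-training tests reuse them.
"""

import numpy as np
import pytest

import spiralwave as sw
from spiralwave import gan as gan_mod
from spiralwave.containers import ElectrodeLayout, VoltageRecording, derive_seed
from spiralwave.synthetic import BaselineParams, DatasetSpec, PlanarParams, SpiralParams

try:
    from hypothesis import settings

    settings.register_profile("suite", max_examples=25, deadline=None,
                              derandomize=True)
    settings.load_profile("suite")
except ImportError:                                    # pragma: no cover
    pass


def spiral_on_background(seed, arms=1, cycles=2, frequency=2.0, center=None,
                         noise_sd=2.0, **kwargs):
    """One spiral wave superimposed on ongoing baseline activity.

    Returns (params, snapshot stack). Centers default to the pinned central
    region used by the dataset generator.
    """
    center = center or (float(26.5 + (seed * 7) % 13),
                        float(26.5 + (seed * 11) % 13))
    params = SpiralParams.for_cycles(cycles, frequency=frequency, center=center,
                                     arms=arms, seed=seed, noise_sd=noise_sd,
                                     **kwargs)
    rec = sw.generate_spiral_wave(params)
    bg = sw.generate_baseline(BaselineParams(duration=params.duration,
                                             seed=derive_seed(seed, "bg")))
    v = rec.voltage + bg.voltage[:, :rec.n_samples]
    return params, sw.extract_snapshots(
        VoltageRecording(v, params.frame_rate, rec.layout))


def planar_on_background(seed, direction_angle=0.7):
    params = PlanarParams(direction_angle=direction_angle, seed=seed,
                          noise_sd=0.0)
    rec = sw.generate_planar_wave(params)
    bg = sw.generate_baseline(BaselineParams(duration=params.duration,
                                             seed=derive_seed(seed, "pbg")))
    v = rec.voltage + bg.voltage[:, :rec.n_samples]
    return params, sw.extract_snapshots(
        VoltageRecording(v, params.frame_rate, rec.layout))


@pytest.fixture(scope="session")
def layout():
    return ElectrodeLayout()


@pytest.fixture(scope="session")
def noiseless_spiral():
    """Noiseless spiral (m = +1, 2 cycles) and its snapshot stack."""
    params = SpiralParams.for_cycles(2, frequency=2.0, center=(30.0, 34.0),
                                     noise_sd=0.0, envelope_depth=0.0, seed=1)
    rec = sw.generate_spiral_wave(params)
    return params, sw.extract_snapshots(rec)


@pytest.fixture(scope="session")
def spiral_event():
    """A default-condition spiral riding on baseline, plus its parameters."""
    return spiral_on_background(1, arms=1, cycles=2)


@pytest.fixture(scope="session")
def long_spiral_event():
    """A 4-cycle (2.2 s) spiral event used by the scaling analyses."""
    return spiral_on_background(41, cycles=4, center=(31.0, 34.0))


@pytest.fixture(scope="session")
def noiseless_planar():
    params = PlanarParams(direction_angle=0.7, noise_sd=0.0, seed=2)
    rec = sw.generate_planar_wave(params)
    return params, sw.extract_snapshots(rec)


@pytest.fixture(scope="session")
def baseline_stack():
    rec = sw.generate_baseline(BaselineParams(duration=2.5, seed=4))
    return sw.extract_snapshots(rec)


@pytest.fixture(scope="session")
def demo_dataset():
    """A small mixed dataset (6 spirals, 2 planar) and its ground truth."""
    spec = DatasetSpec(n_spirals_cw=3, n_spirals_ccw=3, n_planar=2, gap_s=4.0)
    rec, truth = sw.generate_dataset(spec, seed=11)
    return spec, rec, truth


@pytest.fixture(scope="session")
def detection_result(demo_dataset):
    _, rec, _ = demo_dataset
    clean = sw.bandpass_delta(rec)
    clean = sw.remove_artifacts(clean)
    return sw.detect_waves(clean)


def smoke_frames(n_sources=17, frames_per_source=12):
    """16 x 16 block-averaged spiral snapshots for reduced-scale training."""
    out = []
    for s in range(n_sources):
        _, stack = spiral_on_background(s, cycles=2, center=(31.0, 34.0))
        sel = sw.select_evenly_spaced(stack, frames_per_source)
        out.append(sel.frames.reshape(frames_per_source, 16, 4, 16, 4)
                   .mean(axis=(2, 4)))
    return np.concatenate(out)


def smoke_training_set(frames):
    items, offs, scales = [], [], []
    for f in frames:
        off, sc = (f.max() + f.min()) / 2, max((f.max() - f.min()) / 2, 1e-9)
        items.append((f - off) / sc)
        offs.append(off)
        scales.append(sc)
    return gan_mod.TrainingSet(np.stack(items)[:, None].astype(np.float32),
                               np.asarray(offs), np.asarray(scales),
                               np.zeros(len(items), dtype=bool))


def smoke_config(seed=3, iterations=300):
    return gan_mod.GANConfig(image_shape=(16, 16, 1), base_width=8,
                             disc_width=4, iterations=iterations,
                             batch_size=16, log_every=25, seed=seed)


@pytest.fixture(scope="session")
def smoke_data():
    return smoke_training_set(smoke_frames())


@pytest.fixture(scope="session")
def trained_smoke_gan(smoke_data):
    """A 16 x 16 model trained long enough to emit structured samples."""
    cfg = smoke_config(seed=3, iterations=1200)
    model = gan_mod.GANModel(cfg)
    model, history = gan_mod.train(model, smoke_data, cfg)
    return model, history
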
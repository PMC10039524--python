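# spiralwave

Spiral-wave analysis for high-density multi-electrode array (HD-MEA)
recordings of disinhibited cortical tissue.

In pharmacologically disinhibited cortical slices, activity organizes into
propagating waves. A prominent form is the **spiral wave**: delta-band
(1–4 Hz) activity rotating about a fixed spatial locus (a phase
singularity), with a broad distribution of instantaneous phases across
electrodes, reduced voltage at the core, and distance-dependent pairwise
correlations. This package provides, for 64 × 64-electrode recordings
(4096 channels, 42 µm pitch):

- **Wave identification** — zero-phase delta-band Butterworth filtering,
  200 µV artifact removal, 1 ms snapshot binning, instantaneous phase via
  the Hilbert analytic signal, phase-gradient vector fields, winding
  numbers, center of mass (activity-weighted mean row/column,
  `r = Σ i·a_ij / Σ a_ij`), automated event segmentation, and the four
  spiral criteria: (i) broad phases, (ii) rotating vector fields,
  (iii) core amplitude dip, (iv) spatially dependent correlations.
- **Complexity statistics** — eigenspectrum decompositions of snapshot
  sets and the participation ratio `PR = (Σλ_i)² / Σλ_i²` with √N and √k
  normalizations; the Levina–Bickel maximum-likelihood intrinsic-dimension
  estimator; correlation-versus-distance regressions; two-sample t
  comparisons between conditions.
- **A generative adversarial network** — a numpy implementation of the
  deep-convolutional recipe (generator: six hidden convolution + ReLU
  layers with a tanh output; discriminator: eight hidden convolution +
  leaky-ReLU layers), trained with Adam on the minimax objective
  `min_G max_D E[log D(x)] + E[log(1 − D(G(z)))]`, with the balance scores
  `S_G = mean(p_generated)` and
  `S_D = ½ mean(p_real) + ½ mean(1 − p_generated)`, latent-noise sweeps,
  and pluggable-embedding Fréchet-distance / inception-style evaluation.
- **A seeded synthetic-data generator** that emulates such recordings —
  spiral and planar waves, correlated baseline activity, artifacts — with
  ground truth, so every stage is testable without access to recordings.

## Worked example

```python
import spiralwave as sw

# generate one spiral wave riding on baseline activity
params = sw.SpiralParams.for_cycles(2, frequency=2.0, center=(30.0, 34.0),
                                    seed=7, noise_sd=2.0)
wave = sw.generate_spiral_wave(params)
background = sw.generate_baseline(
    sw.BaselineParams(duration=params.duration, seed=8))
rec = sw.VoltageRecording(
    wave.voltage + background.voltage[:, :wave.n_samples],
    params.frame_rate, wave.layout)

stack = sw.extract_snapshots(rec)          # 1 ms frames on the 64 x 64 grid
event = sw.classify_wave(stack)
pr = sw.pr_of_stack(sw.select_evenly_spaced(stack, 6))

print(f"kind={event.kind} direction={event.direction} cycles={event.cycles}")
print(f"center of mass (row, col) = ({event.center.r:.1f}, {event.center.c:.1f})")
print(f"participation ratio (6 snapshots) = {pr.pr:.2f}")
```

prints

```
kind=spiral direction=CCW cycles=2
center of mass (row, col) = (31.0, 32.7)
participation ratio (6 snapshots) = 3.36
```

The event is recovered as a counter-clockwise spiral completing its two
programmed rotation cycles; the activity-weighted center lands within about
one electrode of the programmed core at (30, 34); and the six-snapshot
participation ratio sits above what the same analysis yields for baseline
segments (≈ 2.2) and planar waves (≈ 2.0), reproducing the ordering
spiral > baseline > planar.

A command-line pipeline covers the same stages
(`spiralwave simulate|preprocess|detect|complexity|gan-train|gan-sample|sweep|run`);
`spiralwave run` executes everything from one YAML configuration and writes
a checksum manifest, so identical configurations reproduce identical
outputs.

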
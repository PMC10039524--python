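# Methods

This note documents the models, estimators, and synthetic study conditions
implemented in `spiralwave`, the parameters that matter, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Setting and conventions

The package operates on extracellular voltage from a 64 × 64 electrode
grid (4096 channels, 42 µm pitch, ~7.22 mm² active area) sampled at up to
7.7 kHz, in microvolts. The grid is indexed by (row, col) with rows
increasing downward; reported fractional coordinates are 1-based, so a
uniform frame has its center of mass at (32.5, 32.5). Angles about a point
are `theta = atan2(Δrow, Δcol)`; because rows grow downward, a wave whose
phase winding number is **positive** appears **counter-clockwise** on a
row-down display. This single convention is used by the generator, the
winding-number estimator, and the CW/CCW mapping, and is covered by a
mirror-parity test.

## Identification pipeline

1. **Filtering.** Per channel, a second-order Butterworth band-pass in the
   delta range (default 1–4 Hz) applied forward and backward
   (`sosfiltfilt`), giving zero phase delay. For the per-band amplitude
   table the delta band is 0–4 Hz, implemented with a 0.1 Hz high-pass for
   numerical stability; both band definitions are exposed. Filtering is
   applied before artifact removal by default (configurable), and runs in
   channel blocks to bound the float64 working set.
2. **Artifact removal.** Samples with |v| > 200 µV are replaced by that
   channel's mean over its *non-artifact* samples; computing the mean over
   all samples (selectable) would let the artifact contaminate its own
   replacement. A channel that is entirely artifactual is zeroed with a
   warning.
3. **Snapshots.** 1 ms frames are per-channel bin averages (not decimated
   samples, to avoid aliasing), reshaped to the grid; non-integer
   rate/interval ratios (e.g. 7.7 kHz → 1 ms) use variable bin edges of 7
   or 8 samples. Bin-averaging conserves the window mean exactly for
   integer ratios; for non-integer ratios the unequal bin weights make it
   approximate.
4. **Instantaneous phase.** Per electrode, the angle of the Hilbert
   analytic signal of the mean-subtracted frame series, wrapped to
   [−π, π). The transform is applied along time (the standard reading for
   1 ms-resolution band-filtered data); constant traces are flagged
   degenerate with phase 0.
5. **Vector fields.** The phase-gradient velocity
   `v = −(∂φ/∂t) ∇φ / |∇φ|²`, with the temporal difference wrapped across
   a 10 ms lag and wrapped central differences in space. Optional circular
   spatial smoothing of the phase maps (smoothing the unit-complex field,
   default σ = 1.5 grid units inside classification) stabilizes gradient
   *directions* against per-electrode phase noise; it is off by default in
   the raw operation.
6. **Core location.** The rotation locus is found from a winding-number
   map: the winding number around a radius-8 circle is ±1 exactly when the
   circle encloses the phase singularity (noise-born singularity pairs
   inside the loop cancel), so candidate centers with consistent winding
   form a disk centered on the core. Sites must wind in ≥ 60% of probed
   frames; the largest connected region (≥ 12 candidate sites) wins, and
   its persistence-weighted centroid is the core. Transient rotors in
   smooth background drift and fail the persistence requirement. If no
   region qualifies (planar or disordered activity), a windowed-centroid
   refinement of the activity center is used instead.
7. **Criteria.** An event is a spiral iff all four hold
   (thresholds are package defaults, configurable; the reference analysis
   used visual verification, so automated thresholds are necessarily a
   design choice):
   (i) *broad phases* — mean circular resultant length of per-frame phase
   maps < 0.4; (ii) *rotation* — |median winding number| ≥ 1 at radius 8
   about the core; (iii) *core dip* — mean |v| in a radius-3 disk < 0.8 ×
   mean |v| in a 6–12 annulus; (iv) *distance-dependent correlations* —
   negative correlation-versus-distance slope with p < 0.05, computed over
   channels within 16 grid units of the core (where the wave's
   deterministic phase structure, not slowly-varying background, drives
   the decay). An event is planar iff the vector-field angle resultant
   exceeds 0.8 with zero median winding. Classification is deterministic.
8. **Direction and cycles.** Direction is the sign of the median winding
   number (positive = CCW). The cycle count is
   `floor(advance / 2π + 0.1)` where the advance is the median, over a
   thinned annulus of probe electrodes at 0.5–1.5 × the probe radius
   (8 grid units inside classification, a quarter of the array width as
   the generic default), of the robust linear slope of the unwrapped probe
   phase (central 80% of frames) times the event duration. The small
   additive guard keeps an exactly-integer advance from flooring down; the
   probe phase is the angle of a locally averaged analytic signal (5 × 5),
   which suppresses unwrap glitches.
9. **Segmentation.** Candidate windows are runs where the array-RMS
   envelope exceeds the robust baseline level (median + 3 scaled MADs) for
   ≥ 0.5 s, merged across gaps < 0.25 s, then classified. Event duration
   is the window length. (The reference workflow segmented windows by
   visual inspection; automated segmentation is a deliberate replacement.)

## Complexity

**Participation ratio.** `PR = (Σλ_i)² / Σλ_i²` over ranked non-negative
eigenvalues: 1 for a single dominant mode, the number of nonzero values
for a flat spectrum, invariant to rescaling. Four eigenspectrum
conventions are implemented, and every result records its mode:

- `stacked-svd` (package default): squared singular values of the k
  snapshot frames stacked row-wise into a (64k × 64) matrix — equivalently
  the pooled column Gram. Bounded by the grid side, grows toward
  saturation with snapshot count, and scores a planar wave (whose columns
  are scaled copies of one profile) near 2 regardless of frame count. This
  is the only convention we found consistent simultaneously with per-wave
  values of a few tens from six snapshots, with planar waves scoring far
  below baseline, and with square-root-of-k flattening; the alternatives
  fail at least one of these (a 6-sample covariance has rank ≤ 5; pooled
  per-frame SVD grows linearly in k and pins planar waves at ~2 values per
  frame × k).
- `spatial-svd-pooled`: per-frame SVD values pooled over frames.
- `channel-covariance`: eigenvalues of the channels × channels covariance
  across frames — the only convention defined on arbitrary channel
  subsets, hence used by the channel-subsampling analysis.
- `snapshot-gram`: eigenvalues of the frames × frames Gram matrix.

Normalizations divide PR by √N (channels) or √k (snapshots).
Condition comparisons (spiral vs baseline vs planar) always use matched
snapshot counts, enforced by the analysis code.

**Levina–Bickel dimension.** For each point, the local estimate at
neighborhood size k is the inverse mean log ratio of the k-th
nearest-neighbor distance to the j-th (j < k), using the bias-corrected
1/(k − 2) normalizer (the uncorrected maximum-likelihood form
overestimates by (k − 1)/(k − 2) under Poisson sampling); estimates are
averaged over points and over k ∈ [5, 15]. Exact duplicates are collapsed.
For event data, frames are subsampled (default every 25 ms) before
flattening so nearest neighbors reflect the state distribution rather than
adjacency along the trajectory.

**Correlations.** Pearson correlations between channel frame-series;
zero-variance channels are recorded as missing. Distance dependence is
summarized by binning pair distances (20 equal-width bins), regressing a
line on the bin means, and reporting slope, R², and p; a center-referenced
variant uses only pairs formed with the center-nearest electrode. For a
rotating wave the center-referenced correlation is not monotone in
distance (it oscillates with the angular phase difference), so monotone
decay is only guaranteed — and only tested — for the pairwise variant and
for smooth fields. Condition comparisons use the two-sample pooled-variance
Student's t-test.

## Adversarial model

A deep-convolutional-style GAN in pure numpy (im2col convolutions,
explicit backward passes, hand-written Adam), fully seeded. Generator:
dense projection of a Gaussian latent (length 100, mean 0, SD 25) to a
4 × 4 feature map, then six hidden 3 × 3 convolution layers with batch
normalization and ReLU (the first layers preceded by 2× nearest-neighbor
upsampling until the target side is reached), and a tanh output volume
(64 × 64 × 6 planes at full scale — one plane per evenly spaced snapshot
of a wave). Discriminator: eight hidden convolution layers with leaky
ReLU (4 × 4 stride-2 until the map reaches 4 × 4, then 3 × 3), batch
normalization except on the first layer, and a dense tanh head mapped to a
probability by `p = (h + 1)/2` (a sigmoid head is selectable — a tanh head
cannot feed `log D(x)` directly). Training alternates one discriminator
and one generator Adam step (discriminator rate 2 × 10⁻⁴, generator
1 × 10⁻³, betas (0.5, 0.999)) on the minimax objective; the generator uses
the non-saturating gradient by default (the literal minimax term is
selectable). Stabilizers, all standard practice for this family: batch
normalization, one-sided label smoothing (real target 0.9), and a brief
discriminator-only warm-up (default 100 steps) so the adversarial phase
starts against a meaningful discriminator — this is also why the logged
generator loss starts high and falls. Training aborts on non-finite
losses. Sampling uses the stored batch-norm running statistics, so samples
are independent of batch composition, and inverts the training
normalization with the mean per-item affine transform. Checkpoints are a
single `.npz` with the configuration as JSON plus flat parameter and
running-statistic vectors.

Training volumes are the six evenly spaced snapshots of each wave,
linearly rescaled per item to [−1, 1] with the transform recorded for
inversion; constant items map to 0 and are flagged. "Input strength"
sweeps vary the latent noise mean; SD sweeps vary the latent SD (latent
units are raw, pre-normalization). Evaluation avoids any pretrained
backbone: the Fréchet distance
`|μ_a − μ_b|² + Tr(Σ_a + Σ_b − 2(Σ_a Σ_b)^{1/2})` operates on features from
a pluggable embedder (a PCA embedder is provided), and the
inception-style score `exp(mean KL(p(y|x) ‖ p̄(y)))` on posteriors from a
pluggable classifier (a soft k-means prototype classifier is provided).

The reduced profile used by the tests and the acceptance script trains
16 × 16 single-plane volumes (block-averaged snapshots), generator width 8
and discriminator width 4, batch 16, 300 iterations for the loss-trend
check and 1200 for sample analyses. The full-scale configuration
(64 × 64 × 6, width 32, 10,000 iterations) is provided but is a
multi-hour CPU run.

## Synthetic study conditions

The generator is phenomenological — no conductance-based or mean-field
tissue model — and its defaults define the study conditions.

**Spiral waves.** Voltage
`A(ρ)·E(x,t)·cos(2πft + mθ + kρ) + noise`, with:

- `A(ρ) = A_max · ρ/(ρ + ρ_dip) · exp(−ρ²/2σ_dom²)`; amplitude 100 µV,
  core dip half-saturation ρ_dip = 300 µm, domain radius σ_dom = 600 µm.
  The dip reproduces the reduced voltage at the core; the compact domain
  makes the activity-weighted centroid coincide with the rotation core on
  a finite array (a spatially unbounded profile biases the centroid toward
  the array middle through edge truncation).
- Archimedean phase `mθ + kρ` with signed arm count m (|m| = 1 by
  default) and radial wavelength 20 mm — much larger than the array, so
  the phase gradient is rotation-dominated and vector fields circulate, as
  required by the tangential-field and winding signatures. The rotation
  frequency f lies in the delta band; the programmed cycle count is
  `f × duration` with a 0.4-cycle margin so the floor is unambiguous.
- `E(x, t)`: the activation-domain envelope — `exp(clip(d·g, ±2d))` of a
  unit-SD field `g` with a power-law spatial spectrum (knee at 250 µm,
  mode-eigenvalue decay exponent 0.75) evolving with a 0.3 s time
  constant; depth d = 0.8, normalized to mean 1. This creates delimited
  activation domains at all scales below the knee and gives spiral
  snapshots their high spatial complexity, while — being positive and
  multiplicative — leaving the noiseless instantaneous phase *exactly*
  `2πft + mθ + kρ`, so phase-based estimators stay calibrated. (A static
  envelope, as a time-frozen special case, is obtained by setting the
  time constant large.) The clip keeps domain lows above the background
  floor so the winding circle never crosses phase-unreadable regions.
- Additive white sensor noise (default 5 µV standalone, 2 µV in
  datasets).

**Planar waves.** `A·cos(2πft − k(x cos α + y sin α))` with amplitude
80 µV and wavelength 2 mm; the phase-velocity field points along α.

**Baseline.** Gaussian-smoothed white noise with spatial correlation
length 500 µm, temporal correlation 0.15 s, SD 8 µV (a power-law spectral
variant with the same knee is available via `spectral_exponent`). The
smoothness is what separates baseline from spirals in both classification
(its phase maps are too coherent to count as "broad", and its transient
rotors drift rather than persist) and complexity (fewer comparable
spatial modes). Long stretches are synthesized on a 50 Hz control grid
and linearly interpolated — exact for the sub-4 Hz content emulated.

**Datasets.** Events separated by 5 s baseline gaps (yielding event rates
near 7/min at the mean duration), superimposed on a continuous baseline
field plus white sensor noise. Spiral durations are drawn from a normal
distribution with mean 2.52 s and SD 1.0 s truncated to [0.8, 6] s;
rotation frequencies from U[1.2, 3] Hz; durations are nudged by at most
~0.3 s so `f × duration` sits safely between integers and the programmed
cycle count is well defined. Spiral cores are pinned to one locus per
recording, drawn within ±6 grid units of the array middle with 0.7-unit
per-event jitter — matching the observed tight clustering of cores within
a recording, and keeping domain truncation by the array edge small.
Optional artifact spikes (±400 µV, 5 ms) exercise the cleaning stage.

**What the generator does not emulate.** No saddle waves or colliding
multi-wave patterns; no biophysics (no synaptic or conductance dynamics,
no pharmacology); constant oscillation frequency within an event (no
drift or meander of the core); cycle counts tied to `f × duration` with
f ≥ 1 Hz, so multi-second waves necessarily complete several cycles — the
combination of second-long durations with single-cycle rotation reported
for real slices implies sub-1 Hz rotation rates that a single-frequency
delta-band carrier cannot represent. Passing tests therefore demonstrate
correctness of the estimators under these conditions, not performance on
real recordings.

## Numerical and design choices

- Center-of-mass weights default to |a| (signed and squared variants are
  selectable): the signed denominator can vanish for oscillatory data.
- Criteria are *anchored* at the located core, but the reported event
  center remains the plain activity-weighted mean of per-frame centers.
- The duration nudging, the 0.1-cycle floor guard, and the 0.4-cycle
  generation margin together make cycle counting exact at low noise.
- Detection uses a scaled MAD (×1.4826) so the threshold reads as
  median + 3 robust SDs.
- Degenerate inputs: all-zero frames raise on center computation;
  zero-variance channels are flagged (phase 0; correlations missing);
  all-zero eigenspectra raise; duplicate points are collapsed before
  intrinsic-dimension estimation; non-PSD covariance square roots get
  diagonal jitter with a warning.
- Every stochastic stage derives its seed deterministically from a global
  seed and the stage name (CRC-based, always below 2³¹); pipeline reruns
  with identical configuration produce bit-identical outputs (HDF5 written
  without timestamps).
- Problem sizes in the tests and the acceptance script are scaled-down
  choices of this package: datasets of 6–8 events, 16–20 recovery seeds,
  20 baseline-specificity segments, 16 × 16 adversarial training, 2000
  points for dimension recovery.

## Known limitations

- **Scaling-stabilization windows.** The analyses reproduce monotone PR
  growth with channel count and with snapshot count, and the √N/√k
  normalizations are implemented; but under these study conditions the
  normalized curves do not stay within the tight constancy windows that
  real recordings show. The reason is structural: any emulation whose
  spiral has a dominant phase-coherent carrier — required for the phase,
  winding, and vector-field signatures — has top covariance eigenvalues
  that scale extensively with channel count, so subset-covariance PR
  saturates at the intrinsic dimension instead of growing like √N.
  Real recordings evidently combine phase coherence with scale-free
  amplitude structure in a way this single-carrier model cannot; several
  alternative constructions (additive fine-grained flicker, power-law
  envelopes of varying depth) were implemented and measured before
  settling on the retained design.
- The four criteria cannot perfectly separate spiral waves from transient
  rotors in smooth background fields — a rotor that persists for a whole
  short segment passes them honestly. Specificity is therefore a rate
  (≥ 95% on matched-duration segments), and in the full pipeline the
  amplitude-envelope segmentation excludes baseline before classification.
- The center-referenced correlation profile of a rotating wave is not
  monotone in distance (angular cosine structure), so only the pairwise
  variant is given a slope criterion.
- The GAN is a CPU numpy implementation: the full 64 × 64 × 6 /
  10,000-iteration configuration is provided for completeness but is slow;
  all quantitative claims in this package are made at the reduced scale.
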
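# Methods

## Event model and I/O

A recording is a timestamp-sorted sequence of DVS address events
`(t µs, x, y, polarity)` on a 128 × 128 grid, origin at the top-left,
x = column, y = row.  Two dialects are read and written: the binary
AER-DAT format used for DVS128 recordings (v1: big-endian 16-bit
address + 32-bit timestamp; v2: `#!AER-DAT2.0` header, 32-bit address;
DVS128 bit fields pol = bit 0 with 1 → +1, x = bits 1–7, y = bits
8–14) and a plain CSV dialect (`timestamp_us,x,y,polarity`).
Headerless binary files are disambiguated by record-size divisibility
(6 vs 8 bytes), defaulting to v1 when both divide.  Out-of-order
input is sorted with a logged warning; out-of-bounds coordinates are
rejected.

Screen-captured recordings can carry a periodic timestamp artifact at
the monitor refresh frequency.  `filter_periodic_artifact` folds
timestamps modulo the artifact period into a 20-bin phase histogram
and drops the events of the fullest bin when it holds more than 3× the
mean bin count; otherwise the stream passes unchanged.  This is a
functional design, not a reproduction of any particular preprocessing
script.  It is a single-pass rule: a stream containing *two* distinct
phase-locked components needs two applications; with at most one
component the filter is idempotent, which is what the tests exercise.

## Receptive-field geometry

For a square sensor of side `w` (multiple of 32; default 128), in
canonical cell order:

| cells   | group | cell size | tiled extent (centered) |
|---------|-------|-----------|--------------------------|
| 1–16    | g1    | w/4       | full frame               |
| 17–32   | g2    | w/8       | central w/2 square       |
| 33–48   | g3    | w/16      | central w/4 square       |
| 49–64   | g4    | w/32      | central w/8 square       |
| 65–128  | fovea | 1 × 1     | central 8 × 8 pixels     |

Each group tiles its extent 4 × 4, row-major; the fovea tiles its
8 × 8 patch row-major.  Fields deliberately overlap (the concentric
extents are nested), so one central pixel is seen by up to five cells;
for `w = 128` the areas sum to 21,824 px and average exactly 170.5 px
per cell.  Rectangles are half-open, so the tilings partition each
extent without double counting.

## Encoding

Events are counted per field in half-open 10 ms bins (`[kΔ, (k+1)Δ)`,
Δ = 10,000 µs), ignoring polarity; one second of recording gives
exactly 100 bins.  A foveal cell spikes in a bin iff its pixel saw ≥ 1
event.  A group cell spikes iff its count strictly exceeds
`θ_g · A_g`, i.e. at `⌊θ_g·A_g⌋ + 1` events — at θ = 10 % that is 2
events for a g4 cell (16 px) and 103 for a g1 cell (1024 px).  The
default threshold schedule doubles from periphery to center,
`(θ, 2θ, 4θ, 8θ)`, with base θ = 0.005 (0.5/1/2/4 %); base 0 makes
every cell fire on any event in its field.  Since the raster is
binary per 10 ms bin, no cell can exceed 100 Hz, matching the
sustained-rate ceiling of real ganglion cells.

## Reservoir

Neurons sit at 3D coordinates; the packaged synthetic V1-like cloud
(732 neurons) is a curved bilaterally-symmetric posterior→anterior
slab, rescaled so the median nearest-neighbor distance is 1.0, making
the wiring radius `d_max = 2.5` a local neighborhood.  Its posterior
fifth keeps a midline gap wider than `d_max`, so initial wiring cannot
connect the two sides at the occipital pole — only learning can.
Units are therefore relative to the cloud's own nearest-neighbor
scale; any `x,y,z` CSV can be substituted.

Initialization (fully determined by one seed): every ordered pair
within `d_max` connects with probability `p_connect = 0.15`, magnitude
`U(0, 0.2)/distance`; each neuron is excitatory with probability 0.8
and all its outgoing synapses take its sign.  This keeps signs
Dale-consistent; setting `per_connection_signs=True` draws each
initial connection's sign independently (80/20) instead, trading
biological plausibility for the literal per-connection randomization.
`p_connect` and the weight scale are free parameters of the wiring
model, exposed with those defaults.

LIF update per 10 ms bin, in order: a refractory neuron only
decrements its countdown (potential frozen, input ignored); otherwise
`v ← v·(1 − λ) + Σᵢ wᵢⱼ·sᵢ(t−1) + Iⱼ(t)`, and if `v ≥ 0.5` the neuron
spikes, resets to 0 and becomes refractory for 6 bins.  Defaults:
threshold 0.5, refractory 6 bins, leak λ = 0.002 per bin
(multiplicative).  Input channels inject `Iⱼ = threshold` into their
assigned neuron on a spike, forcing it to fire unless it is
refractory or concurrently inhibited — input neurons act as spike
relays inside the network.

Retinotopic input mapping is deterministic and seed-free: neurons are
ranked along the anterior axis; the 64 foveal channels are assigned
within the most-posterior half (cortical magnification: ~50 % of V1
serves the fovea) and the 64 pooled channels within the anterior half.
Within each half a channel's field center, negated relative to the
sensor center (the retinal image arrives in V1 flipped and mirrored),
is min–max-scaled into the half's extent in the plane orthogonal to
the anterior axis and matched greedily to the nearest unused neuron,
channels ordered by increasing eccentricity.  Greedy matching keeps
neighboring channels on neighboring neurons without solving a global
assignment problem, and makes the map injective by construction.

### STDP

Pair-based with nearest-neighbor pairing: at bin `t`, a neuron's most
recent earlier spike within `window = 6` bins pairs with each current
spike.  Causal pair i→j (i earlier): `|w| ← |w| + η·e^{−Δt/τ}`
(additive).  Anti-causal: `|w| ← |w|·(1 − η·e^{−Δt/τ})`
(multiplicative, so depression can never flip a sign or overshoot
zero).  η = 0.01; τ = 2 bins and the window are not constrained by
the worked values and are exposed in `STDPConfig`.  Magnitudes clip
to `[0, w_max = 1]`; inhibitory synapses update on `|w|` and keep
their sign.  A silent synapse between neurons within `2·d_max` is
created at `|w| = η` on its first causal pairing, signed by the
presynaptic neuron; this minimal growth rule is what lets training
build long-range connections — e.g. across the posterior midline gap
— which the before/after connectivity snapshots (CSV/GraphML) make
visible.

## deSNN output stage

One output neuron per sample, trained on the reservoir's (frozen)
spike record for that sample: neuron *j*'s initial weight is
`Mod^order(j)` with `order` counting neurons by ascending first-spike
bin (ties by index); afterwards `w_j` drifts by +Drift for each later
bin where *j* spikes and −Drift where it does not.  Defaults Mod 0.8,
Drift 0.005.  Neurons that never spike get weight 0 and no drift —
deSNN weights come into existence at the first spike, and no rule for
silent neurons follows from the scheme, so zero is the neutral
choice.  No error feedback (anti-STDP) is applied.

Classification is KNN over output weight vectors (default K = 1,
Euclidean; Manhattan selectable).  Ties break by vote count, then by
smaller summed distance, then by lower class id.  Cross-validation is
stratified k-fold with seeded shuffling (stratification reduces
fold-to-fold variance; plain k-fold would add label-imbalance noise at
these sample sizes); each fold gets a freshly initialized reservoir,
STDP on the training rasters only, and a pooled confusion matrix is
reported alongside per-fold accuracies.

## Synthetic data

`generate_recording` renders a binary glyph at 1 ms frames along a
diagonal triangle-wave trajectory (two full bottom-left↔top-right
cycles over 2.5 s, amplitude 24 px).  Pixels whose occupancy changes
between consecutive frames emit `Poisson(event_rate)` events with
uniform microsecond offsets in the frame and polarity = sign of the
change; background noise is uniform at `noise_rate` per pixel per
second.  Defaults: event_rate 1.0 per changed pixel per frame,
noise_rate 0.05 Hz/px (a typical DVS background activity level),
giving ~20–25 k events per 2.5 s recording.  1 ms rendering is ample
given the encoder's 10 ms bins.  Class glyphs are parametric shapes
(bar, ring, cross, wedge) at 40 px; the two-class benchmark (bar vs
ring, 50 recordings each, per-sample jitter of amplitude, position
and event seed) is separable by design.

What the benchmark shows — and does not.  Passing it demonstrates
that encoding preserves class structure, that the reservoir + deSNN
stack learns it, that shuffling labels destroys it (accuracy falls to
chance), and that the whole chain is deterministic.  It does *not*
emulate real benchmark recordings' event statistics, sensor noise
correlations, or ten-way digit confusability, so its accuracies are
not comparable to published figures on real DVS datasets.  In
particular, the reported trend on moving-digit data that accuracy
rises with the encoder's average spike rate does not transfer to this
benchmark: with zero thresholds, background noise fires peripheral
cells for *both* classes and accuracy is slightly lower than at
moderate thresholds.  That trend is a property of the original data
(where high thresholds leave nearly silent rasters), not of the
architecture.

## Numerical and scale choices

- All randomness flows through `numpy.random.default_rng` seeds;
  generators, wiring and CV are pure functions of (config, seed).
  Reports serialize with sorted keys so reruns are byte-identical.
- The acceptance-style end-to-end checks run the 100-sample benchmark
  with the 732-neuron cloud and 10-fold CV (~1 minute on one core);
  unit tests use a 200-neuron cloud, 16 px glyphs and 0.3 s
  recordings, which exercise identical code paths at second scale.
- Degenerate inputs: empty streams encode to empty rasters; an
  all-silent reservoir record yields an all-zero output neuron (with
  a warning); `duration_us` may exceed the last event to pad bins.
- Tie-breaks are deterministic everywhere: stable sorts, neuron /
  channel index order, lowest class id.

## Known limitations

- Polarity is parsed and preserved by I/O but deliberately ignored by
  the encoder (no on/off-center cell model, no signed spikes).
- No saccade simulation: the foveal channels only see what crosses
  the screen center.
- No axonal delays or conductance-based dynamics; one global 10 ms
  clock.
- The coordinate fixture is a synthetic stand-in shaped like V1, not
  anatomical coordinates; conclusions about spatial patterns of
  learned connectivity are qualitative.
- The jAER reader covers the v1/v2 DVS128 dialects only (no AEDAT 3/4,
  no timestamp-wrap handling).
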
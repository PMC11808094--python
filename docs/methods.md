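# Methods

## Signal model and conventions

The forward model is the single-isochromat steady-state pc-bSSFP signal
(README, "The model") with M0 = 1. Angles are stored in degrees at the
interface and converted to radians internally; the off-resonance state
is carried as the phase accumulated per TR, θ (radians), with
ΔB0 = θ/(2π·TR) available for reporting in Hz. The default protocol is
TR = 4.8 ms, TE = 2.4 ms, α_nom = 15°, N_pc = 12.

Configuration modes use the DFT convention
F_n = (1/N_pc)Σ_j S(φ_j)·e^{−i n φ_j}, so F_0 is the across-cycle mean.
The opposite sign convention would swap F_−1 and F_1; this one is fixed
and anchored by the signal-to-noise convention below, which is defined
on |F_0|.

**Average-phase removal.** Constant (receiver-like) phase offsets are
removed by rotating each voxel's phase-cycle series by the negative
phase of its complex across-cycle mean — the F_0 phase. Two properties
motivated choosing the phase-of-the-mean over the arithmetic mean of
the elementwise phases: (i) the imaginary part of F_0 vanishes
identically afterwards, for every θ and N_pc, which is what the feature
layout assumes when it omits Im F_0; (ii) the operation is continuous
in θ, whereas a mean of wrapped elementwise angles jumps by 2π/N_pc
whenever one element crosses the ±π branch cut, which injects
discontinuities into every quantity downstream (including the
physics-informed training loss). The operation is idempotent, makes
feature vectors exactly 2π-periodic in θ, and leaves a zero-mean signal
untouched (with a warning) since its phase is undefined.

**Features.** After phase removal and mode extraction, the estimator
input is either the magnitude triple (|F_−1|, |F_0|, |F_1|) or the
complex layout (Re F_−1, Re F_0, Re F_1, Im F_−1, Im F_1); the vector
is Euclidean-normalized (making it independent of M0 and receive gain)
and the transmit-field scaling B1 is appended unnormalized, for input
lengths 4 and 6. One code path (`features_from_signal`) serves
training, inference, the physics-informed loss and the volume pipeline.

**Noise.** Additive zero-mean Gaussian noise of standard deviation
η = 0.074/(√2·SNR) is applied independently to the real and imaginary
part of every phase-cycle sample; SNR = ∞ means no noise. The constant
0.074 is treated as a protocol-level signal-scale constant (it is close
to the mean tissue |F_0| for M0 = 1 at the default protocol, making
the SNR definition "mean tissue |F_0| over complex noise amplitude"
self-consistent); it is exposed as a parameter rather than derived.

## Sampling distributions and datasets

Tissue parameters are drawn from one of three distributions: uniform
(T1 ∈ [360, 2080] ms, T2 ∈ [20, 120] ms), uniform-extended
(T1 ∈ [360, 5000] ms, T2 ∈ [20, 2500] ms) and a brain-like 2D density
on the tissue-range support. Combinations with T1 < T2 are rejected
everywhere; B1 is uniform in [0.7, 1.3]; θ is 0 for magnitude-layout
(on-resonant) data and uniform in the open interval (−π, π) for
complex-layout data, excluding the wrap exactly.

The brain-like density is a synthetic stand-in: a mixture of two
anisotropic Gaussian clusters — white-matter-like centred at
(900, 60) ms with σ = (80, 8) ms and gray-matter-like at (1400, 75) ms
with σ = (130, 10) ms, weights 0.6/0.4 — truncated to the support and
to T1 ≥ T2 and renormalized on a 200×200 bin grid. Only its support and
tissue-concentrated, bimodal character matter for the experiments
reproduced here; it does not claim subject realism.

Datasets store clean complex64 signals (n × N_pc) and float32 targets
(n × 4: T1, T2, θ, B1) in HDF5 with JSON metadata; at 400,000 samples
and N_pc = 12 the payloads are exactly 38.4 MB and 6.4 MB (decimal).
Noise is never stored: it is drawn freshly inside each training batch.
Evaluation sets are an inclusive 200×200 linear grid over the tissue
ranges (filtered to T1 ≥ T2, B1 = 1, θ = 0) and 40,000 density draws.

## Estimators

**Golden-section fit (MIRACLE-style).** A training-free least-squares
inversion: find (T1, T2) minimizing the squared Euclidean distance
between the measured normalized magnitude modes and those of the
on-resonance forward model at matched N_pc and measured B1, by
alternating 1-D golden-section searches over T2 (T1 fixed, starting at
T1 = 1000 ms) and T1 (T2 fixed, lower bracket raised to T2 so T1 ≥ T2),
until the relative change of both estimates falls below 1e−4 (at most
50 outer iterations; non-convergence is flagged, and the last iterate
returned). Each outer iteration ends with a Powell-style third golden
search along the direction of the step just taken: plain alternation
crawls in the near-degenerate diagonal valleys that arise at long
T1/T2 (the modes then constrain mostly the T1/T2 ratio — a CSF-like
voxel is the canonical case), while the combined-direction search
restores convergence to the global minimum there, which an exhaustive
grid search confirms to be unique. Search bounds default to the extended ranges, since the fit
has no training-range restriction. This is a least-squares inversion of
the identical simulation kernel — deliberately so, because every
experiment here compares estimators on data generated by that kernel —
not a reimplementation of the original mode-ratio recursion. All
searches are vectorized over voxel batches. Matched-N_pc (aliased)
model modes at θ = 0 are used for N_pc < 12 as well, for consistency
with the on-resonance assumption of the magnitude networks.

**Neural networks.** Two hidden ReLU layers (64 units for the
magnitude layout, 256 for the complex layout) and a sigmoid output
layer mapped affinely to per-parameter ranges — predictions cannot
leave the configured range, so there is no extrapolation beyond the
training support. Output ranges default to the training distribution's
ranges, with θ ∈ (−π, π) for the complex layout. Weights and biases are
initialized uniform ±1/√fan_in (the standard dense-layer default),
seeded. Training uses Adam at a fixed learning rate 2e−4, batch 128, a
90/10 random train/validation split, early stopping with patience 25
epochs, at most 300 epochs, and returns the best-validation-loss
checkpoint. When a finite training SNR is configured, fresh noise is
applied to the stored clean signals inside every batch before the
feature pipeline; the validation loss is then likewise computed on
freshly-noised features, keeping validation consistent with the
training condition.

The supervised loss is the MSE between predictions and targets with
each parameter affinely normalized to [0, 1] by its output range
(a raw-millisecond MSE would weight T1 ~300× over T2; normalized
coordinates balance the parameters and match the sigmoid outputs — a
raw-unit variant was tried and degraded T2 badly). The physics-informed
loss regenerates the pc-bSSFP signal from the predicted parameters
(θ̂ = 0 for the magnitude layout) with the measured B1, pushes it
through the identical feature pipeline, and takes the MSE to the input
feature vector, excluding the appended B1 entry from the residual. Its
gradient with respect to the 2–3 predicted parameters is computed by
central finite differences (step 1e−3 in normalized output
coordinates; verified against high-precision numerical differentiation
to 2e−5 relative) and chained into the network backpropagation. The
whole training loop — forward, backward, Adam, and the in-loss physics
— is compiled with numba for single-CPU throughput (~1 ms per batch for
the complex architecture).

**Conditioning note.** After Euclidean normalization the feature vector
changes by only ~1e−3 per percent of T1, while it changes by ~0.45 per
radian of θ. The physics-informed loss surface is therefore extremely
flat in T1/T2 (and dominated by θ in the complex layout), and under the
fixed small learning rate its parameter accuracy improves slowly,
roughly as a power law in optimization steps. The supervised loss
avoids the imbalance but converges gradually for the same reason. The
consequence for the off-resonance experiments is quantified below.

## Validation machinery

`monte_carlo` simulates each test point's clean signal, draws n_mc
noisy replicates, runs the estimator per replicate, and aggregates the
MC mean, standard deviation, relative standard deviation (undefined —
NaN — where the mean is zero) and signed relative error in percent,
plus a global per-parameter coefficient of determination
CoD = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² of MC means against truth. `delta_cod`
compares two estimators under a paired design (identical noise
replicates, for variance reduction). `theta_sweep` traces noise-free
relative-error curves over a cell-centred θ grid spanning the open
interval (−π, π). Every estimator runs through the same harness via its
feature layout. Scaled-down defaults (10×10 subgrid, n_mc = 200) are
used in tests; the full protocol (200×200 grid, n_mc = 5000, SNR ladder
∞..10) is a matter of arguments.

## Digital phantom

Concentric ellipsoids on a configurable grid (default 48×48×32 voxels
at 1.3 mm): gray-matter-like shell (1400/80 ms), white-matter-like
interior (939/62 ms — the 3 T white-matter reference), CSF-like core
(3500/1800 ms), each with 2% multiplicative voxelwise jitter (clipped
to keep T1 ≥ T2 > 0). A smooth low-order polynomial θ field spans
(−π, π) across the volume, emulating static-field inhomogeneity, and a
smooth B1 profile stays inside [0.7, 1.3]. Volumes are simulated
voxelwise with the forward kernel (background stays zero before
noise) and written as NIfTI — either one complex-valued file or paired
magnitude/phase files, since scanner exports differ. Background
masking for map fitting defaults to 5% of the 99th-percentile |F_0|.
Registration, ringing removal and B1 filtering are deliberately absent:
synthetic volumes are born aligned and artifact-free.

What the phantom does *not* emulate: realistic anatomy, partial-volume
mixing, multi-compartment relaxation, profile asymmetry, chemical
shift or magnetization transfer. Passing phantom tests therefore
demonstrates pipeline correctness and the off-resonance/aliasing
phenomenology, not in-vivo fidelity.

## Desk-scale experiment sizes and what they show

The acceptance script and test suite run on one CPU within minutes, so
the training experiments are scaled down relative to the full protocol
(400,000 samples × up to 300 epochs ≈ 0.9M Adam steps per network):
the script trains each complex-layout network on 100,000 samples with
the epoch cap at 200; the test suite uses 50,000 samples × 120 epochs,
and the qualitative property tests use 20,000–30,000 samples. Because
network accuracy at a fixed learning rate improves steadily with
optimization steps (measured here as an approximate power law), the
absolute error levels reached at desk scale are materially higher than
after full-scale training — e.g. the supervised complex network at
N_pc = 12 reaches a ~2% maximum off-resonance-sweep error at 100k × 300
epochs, with the trend indicating ~1% near the full step count, while
the physics-informed complex variant remains an order of magnitude
away at desk scale owing to the conditioning note above. The
qualitative orderings (aliasing growth at low N_pc, complex-vs-
magnitude off-resonance robustness, distribution-sensitivity of the
supervised loss, noise monotonicity) are stable at these sizes and are
what the test suite asserts.

## Numerical choices and degenerate inputs

Single precision for network weights and features; float64 for the
physics pipeline inside losses and oracles. Golden-section inner
iterations are fixed by the bracket-reduction count needed for the
relative tolerance. Zero-magnitude signals: phase removal leaves them
unchanged (warning); all-zero mode vectors raise on normalization.
T1 < T2 draws are rejected at sampling; the forward model itself
accepts any positive pair. In-bin jitter when sampling the brain-like
density can cross the T1 = T2 diagonal in diagonal bins; such draws are
reflected back by swapping. Estimator determinism is guaranteed by a
single seed driving initialization, the train/validation split,
shuffling and batch noise.
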
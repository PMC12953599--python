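# Methods

This note documents the models, numerical choices and calibrations behind
`spikeskin`, and what the synthetic benchmark does and does not show.

## Skin geometry

The skin is a sector of a truncated cone (forearm-like): apex half-angle
with sin α = 0.2, slant heights 200–320 mm, angular sector 2.1635 rad,
giving a region of interest of 135 cm².  Because a cone is developable,
all distances are computed exactly by unrolling to the plane; the decoder,
the training targets and the error metric all use this geodesic (a 3-D
Euclidean switch exists in `DecoderParams.error_metric`).  The 21 sensors
sit on a 7 × 3 staggered serpentine (single optical fibre), median
nearest-neighbour spacing ≈ 16.5 mm — the yardstick for super-resolution.

## Synthetic e-skin generator

Each sensor's mean response to a contact at geodesic distance d is
R(d) = R0⁺ e^(−d/6.1 mm) − R0⁻ e^(−d/25.6 mm) (1 + gᵢ(bearing)), with
R0⁺ = 1.2 nm/N and R0⁻ = 0.06 nm/N, additive sensor noise of 2 pm, and a
smooth per-sensor angular gain field gᵢ (three fixed-phase harmonics,
amplitude 2.5) that makes the negative (stretch, SA2-like) component
irregular while the positive (compression, SA1-like) component stays
rotationally regular.  The R0⁻ and irregularity values were calibrated
once so that (i) the positive component dominates the signal throughout
its own 3·d₀ range and (ii) the fitted coefficient-of-variation profile
orders as in slowly adapting afferents (positive more regular than
negative).  Forces follow quasi-static ramp–hold–release profiles
(200/200/600/200 ms at 100 Hz, amplitudes 1–4 N, zero-order held to the
1 ms simulation grid); a manual-variability factor adds low-pass-filtered
within-hold force fluctuations, which measurably raises the rate of
relative change of the signals, mimicking hand-delivered stimuli.
Responses superpose linearly across simultaneous contacts.

What the generator does *not* model: mechanical cross-coupling and
saturation of the silicone, interrogator spectral artefacts, and the true
force nonlinearity of the physical patch.  Tests passing on this
benchmark show the algorithms are correct and that the pipeline
super-resolves *this* statistical structure; absolute errors on a
physical skin will differ.

## Neuron model and integration

Current-based LIF with exponential synapses in a pA/pF/nS/mV/ms unit
system (τ_m = Cm/gL = 20 ms).  The membrane uses forward Euler at a fixed
1 ms step; the threshold test runs after the update and spikes are
recorded on the end-of-step grid point, giving O(dt) first-spike-time
error.  Synaptic currents decay *exactly* between grid points
(exponential Euler), and each background Poisson event is drawn with a
uniform sub-step arrival time and partially decayed to the end of its
step.  With this scheme the sampled background current follows the
filtered-Poisson statistics with no discretization bias: mean
ω ν τ_ex = 16 pA and std ω √(ν τ_ex/2) = 4 pA.  (The symbolic expression
sometimes quoted for the std, ω √(ν τ_ex) = 5.66 pA, is inconsistent with
the printed 4 pA; Campbell's theorem for this process gives exactly
4 pA, which is what the simulator reproduces.)  During refractoriness the
membrane is pinned at V_res while synaptic currents keep integrating.
Spikes are delivered exactly t_r = 2 ms after emission through a ring
buffer; the minimum effective delay is one step.  The inner loop is a
numba kernel with a pure-numpy fallback; a single seeded generator drives
all randomness, with background events drawn as one homogeneous Poisson
process over (step, neuron) cells — distributionally identical to
per-cell draws and much faster.

## Encoding

Rectified positive/negative components are compressed with
f(x) = gain · ln(1 + x/LF), LF = 0.5 nm, gain = 50 pA, and fed to two
dedicated input neurons per sensor.  The constants were calibrated so a
mid-range (≈2 N) indentation drives the best-placed input neurons at
roughly 30–80 Hz on top of the 16 pA background mean — the regime where
the LIF FI curve is informative but far from saturation.

## Training rule

Activities are spike counts in a W = 500 ms window evaluated every
t_s = 100 ms; output targets are Gaussian kernels (σ = 10 mm, peak 50 Hz,
pointwise max over contacts) around the true position while force is
applied, zero otherwise.  Updates follow
Δω_ji = −λ Σ m(I_j) H(y_j) τ_ji y_i Ẽ_j and
ΔI_j = −λ Σ m(I_j) H(y_j) W Ẽ_j, batched over 10 indentations, with the
generalized error chained through layers as
Ẽ_i = Σ_j ω_ji m(I_j) H(y_j) τ_ji Ẽ_j.  Two unit conventions make this
rule *exactly* the gradient of the mean-field window-count loss (verified
by finite differences in the tests): m is the FI slope per millisecond
(kHz/pA), evaluated at the neuron's measured mean input current over the
window, and τ_ji is the time constant selected by the weight's sign
(τ_ex if ω > 0 else τ_in).  The gate H(x) is 1 for x > 0 and h_leak
otherwise (the alternative printed convention "x > 1" is not used).

Numerical choices that matter:

- **Surrogate slope at rheobase.**  The exact FI slope is zero below
  rheobase and unbounded just above it, so silent neurons would never
  recover.  The slope is therefore evaluated no closer to rheobase than
  m_smooth = 2 pA *for every current*, giving sub-threshold neurons a
  small positive surrogate gradient.  Together with a leaky gate
  h_leak = 0.3 this cures the dead-unit problem that otherwise stalls
  training after the initial spontaneous activity is pruned.
- **Initialization.**  Weights start uniform in ±1 pA (magnitudes,
  sign-projected per block); baseline currents start at 20 pA — just
  below rheobase once the 16 pA background mean is added — so neurons are
  silent at rest but immediately recruitable.  Spontaneous activity then
  *emerges* through training where the task benefits from it.
- **Learning-rate schedule.**  λ is piecewise linear in the epoch-error
  improvement between λ_m = 2·10⁻³ and λ_M = 2·10⁻² with knees
  (δE_m, δE_M) = (0, 1): effectively full speed while improving, a
  ten-fold back-off on regression.  These values, like everything the
  published parameter table does not pin down (κ_decay,0 = 2·10⁻⁴,
  M_decay = 1, s_decay = 10 counts, I_MAX = 25 pA), were calibrated once
  on the synthetic task.
- **Constraints.**  Sign masks are enforced by projection (clip at zero)
  after each batch update; baseline currents are clamped to [0, I_MAX].
- **Divergence guard.**  Training aborts if the epoch error exceeds 10×
  its initial value.

### Energy constraint

A single level ε ∈ [0, 1] linearly tightens I_MAX from 25 to 5 pA, scales
the weight-decay base by (1 + 4ε), and shrinks the interneuron pool
linearly to 25 % of its base count.  The cap range was chosen to cut
through the trained baseline-current distribution, so resting activity
falls monotonically with ε (strongly: caps below rheobase−⟨background⟩
silence the network at rest).

## Decoding

Leaky rate: causal exponential kernel, τ_out = 100 ms, evaluated
recursively on the 1 ms grid.  The instantaneous barycentre averages the
unrolled positions of neurons above the 0.9-quantile of strictly positive
rates (linear-interpolation quantile, strict inequality; if all positive
rates tie, the tie set is used).  Undefined frames (no activity) hold the
previous estimate.  The bias-corrected EMA (α = 0.9975) reproduces
constant inputs exactly at every step.  Detection requires the mean
output rate to exceed 0.02 Hz continuously for a 50 ms debounce window;
detection always uses the *raw* rates — the optional 4-nearest-neighbour
spatial filter (yᵢ → yᵢ · mean of neighbours, neighbours by unrolled
distance even at borders) reshapes only the map fed to the barycentre,
mirroring its role as a despiking stage.  Undetected trials score the
skin-centre penalty.  Multi-touch extraction iterates: global argmax →
register if above 3 Hz → multiply the map by 1 − exp(−d²/2σ²) with
σ = 1.5 cm → repeat; it terminates within one iteration per neuron.

The default somatotopic grid is 12 × 9 (0.8 neurons/cm²); the multi-touch
and hardware studies use 27 × 20 (4 neurons/cm², ≈ 4.3 mm pitch), the
density at which localization performance saturates and at which the
suppression and filter scales are well-resolved by the lattice.

## Hardware emulation

Deployment constraints of mixed-signal neuromorphic processors are
emulated in three composable steps (`hardware.deploy`): (1) weights snap
to the nearest of two shared efficacies per sign (plus pruning to zero;
ties to the smaller magnitude) — the 2-bit regime; (2) per-neuron
log-normal mismatch (CV 20 %) on membrane gain, effective weight gain and
baseline current, with only 5 % CV on synaptic time constants (shared
per-core bias circuits), restricted to the layers that live on the chip —
the input conversion stage stays in software; (3) each on-chip neuron is
assigned, by optimal matching of FI-curve responses over a probe-current
grid (Hungarian algorithm), the unit from a 6× larger analog pool that
best mimics its nominal behaviour, which cancels most of the
membrane-gain spread.  Chip-in-the-loop fine-tuning is *not* reproduced;
the conservative output baseline (12 pA) plays its hot-neuron-suppressing
role instead.  Under this pipeline the filtered decoder consistently
outperforms the raw one and the deployed network stays in the
super-resolution regime on the synthetic benchmark.

## Statistics

Localization errors are spatially correlated, so uncertainty on medians
uses a blocked bootstrap: square tiles of the unrolled surface, blocks
drawn with replacement until each replicate reaches the original sample
size (this keeps the estimator consistent with the naive bootstrap for
independent data; with one trial per block the two coincide).  The block
size is selected as the smallest candidate at the bootstrap-std plateau.
Architecture comparisons use a one-sided Wilcoxon signed-rank test on
block-median paired differences with effect size r = z/√n.  The
quantization study fits error(n_bits) = a·e^(−n/τ_bit) + c; its
chi-square is discounted by the effective sample size
N_eff = N (1−e^(−1/τ_ACF))/(1+e^(−1/τ_ACF)), which can only reduce
apparent significance.  No multiple-testing correction is applied (single
planned comparisons).  Power is modelled as
P = Σᵢ rᵢ (E_spike + E_enc + N_cores(E_br + E_rt) + N_post,i E_pulse);
the per-event energies default to placeholder values of a plausible
order — relative comparisons are meaningful, absolute wattage requires
device-measured constants.

## Problem sizes

The repository's own test runs use desk-scale sizes chosen as a
reasonable compromise for a single CPU: 500-trial single-touch benchmark
(400 train / 100 test), 15 training epochs, 12 × 9 output grid for
training studies; 100 trials × 6 epochs × 3 seeds for the
energy-constraint sweep; 200 constructed trials for multi-touch; 6
mismatch seeds × 10 trials for the hardware study.

## Known limitations

- The generator's force–response linearity and irregularity mechanism are
  stylized; only the published receptive-field statistics constrain them.
- Hidden-layer error propagation follows the standard chain-rule form of
  the mean-field loss; the spiking network obeys it only on average.
- Feedback architectures (`SC_BIO_FB`, `SC_BIO_COMBINED`) are trained
  with the same feedforward error chaining; recurrent credit assignment
  is approximated.
- The mean-field forward pass used by the gradient checks resolves
  recurrent loops only via damped sweeps and is exact only for
  feedforward graphs.
- Latency is measured from force onset to the first detection at or
  after it and includes the 50 ms debounce by construction; in regimes
  whose spontaneous output activity exceeds the 0.02 Hz detection
  threshold the flag is already up at onset and the latency reads zero,
  so it is informative only for energy-constrained (rest-silent)
  networks.
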
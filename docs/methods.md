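# Methods

`neurovasc` simulates a closed loop between a ring network of vascular
oscillators and a rate-coded autoencoder.  The vessels gate the
autoencoder's hidden units (perfusion-dependent firing thresholds, realized
as a binary dropout mask), and the autoencoder's reconstruction error feeds
back to the vessels as a neuronal energy demand.  This note records the
model equations as implemented, the parameter choices the source equations
leave open, and what the package's synthetic experiments do and do not
establish.

## Vascular ring

Each of `n` vessels carries a supporting variable `g_j`, a history variable
`u_j`, and a state `S_j = tanh(lambda_v * g_j)` in (-1, 1) read as its
perfusion level.  The dynamics are

    dg_j/dt = -g_j - u_j + sum_k T_jk S_k + I
    tau_v du_j/dt = -u_j + S_j

integrated with explicit Euler at `dt = 0.01` time units (validated by a
step-halving test; trajectories at `dt` and `dt/10` agree to 0.02 over 10
time units).  Vessels sit evenly on a ring of radius `rho`; the lateral
coupling is

    T_jk = epsilon - 2 exp(-d_jk^2 / sigma^2)   for d_jk < 3 sigma, else 0

with chord distances `d_jk`.  `epsilon` in [0, 2] is the
excitation/inhibition balance: at `epsilon = 0` all interactions are
inhibitory and the ring oscillates chaotically and desynchronized; by
`epsilon = 1` neighbouring excitation locks the ring into synchronous
oscillation.  Synchrony is measured by the average pairwise Pearson
correlation (APC) of the `S_j` time series over all ordered vessel pairs.

Two formulation details deserve note.  First, the kernel exponent is
implemented as `d^2/sigma^2` by default; the variant `d/sigma^2` is
available behind the `kernel="printed"` switch, but with `sigma` of the
order of one inter-vessel spacing it makes every off-diagonal coupling
numerically zero (`exp(-16)` for adjacent vessels), leaving a ring that
cannot desynchronize — we treat the squared form as the intended one.
Second, the diagonal is zeroed by default (`self_coupling=False`): a
self-coupling of `epsilon - 2` adds strong self-inhibition that stabilizes
every eigenmode of the ring and abolishes the `epsilon = 0` oscillatory
regime entirely; with it removed, lateral inhibition destabilizes the
anti-phase modes and the chaotic regime exists.  Both switches are exposed
for sensitivity analysis.

The drive `I` is common to all vessels and closes the supply-demand loop:

    N_s = sum_j S_j                (vascular supply)
    e = N_d - N_s                  (instantaneous deficit)
    tau_e dE/dt = tanh(lambda_e e) (accumulated deficit)
    I = E - n/2

`E` is initialized at `n/2` so the run starts with `I = 0`; starting at
`E = 0` would impose `I = -n/2`, saturating every vessel OFF for hundreds
of time units, which contradicts the intended all-ON start (demand at its
maximum, dropout fraction q = 0).

### Default constants

| parameter  | default             | role |
|------------|---------------------|------|
| `n`        | 100                 | vessel count |
| `rho`      | 1                   | ring radius (length unit) |
| `sigma`    | 1.5 * 2 pi rho / n  | kernel width = 1.5 inter-vessel spacings |
| `lambda_v` | 7                   | vessel nonlinearity slope |
| `tau_v`    | 5                   | vessel history time constant (time units) |
| `tau_e`    | 10                  | deficit accumulation time constant |
| `lambda_e` | 1                   | deficit nonlinearity slope |
| `dt`       | 0.01                | Euler step |

The source equations fix none of these values.  `lambda_v` and `sigma`
were chosen by scanning the `epsilon = 0` attractor for *dropout-pattern
diversity*: the number of distinct hidden-layer ON/OFF patterns the ring
generates varies by orders of magnitude across nearby settings (from ~10
to ~3500 distinct 16-neuron patterns per 10,000 gating intervals), with
interleaved periodic windows — the classic signature of a chaotic system's
parameter space.  The defaults sit in the most strongly chaotic window
found; both APC regimes (|APC| < 0.02 at `epsilon = 0`, APC = 1.00 at
`epsilon = 1`, five seeds) are preserved there.  Standalone synchrony runs
use a constant demand `N_d = n/2`; at demand near 0 or n the `epsilon = 0`
ring can settle into a static equilibrium instead of oscillating.

## Autoencoder

A single-hidden-layer network `M -> H -> M` with rectified-linear hidden
and output units:

    h = W x + b,  v = relu(h),  v_new = v * r,  y = relu(Z v_new + B)

`r` is the externally supplied binary dropout mask.  There is no
inverted-dropout rescaling, and the reported reconstruction error

    mse = 1/(2 bt M) sum_P sum_m (x_m - y_m)^2

is measured with the mask in force (a mask-free diagnostic evaluation is
available separately).  Training is plain minibatch SGD; gradients are
validated against central finite differences to 1e-5 relative error with
and without dropout.  ReLU uses the `f(0) = 0`, subgradient-0 convention.
Weights initialize uniformly in `[-1/sqrt(fan_in), +1/sqrt(fan_in)]`.

Defaults: learning rate 0.2, batch size 20, 16 hidden units for the 8x8
bar task, 300 epochs.  Rate and epoch budget were set with a Bernoulli
dropout control: single-bar features emerge reliably only after roughly
300 epochs at rate 0.2 (at 50 epochs no dropout regime, vascular or
Bernoulli, has localized yet).

## Neurovascular coupling

Each hidden neuron `i` listens to a projective field of exactly `z`
vessels chosen uniformly at random (rows of the binary `H x n` matrix `A`),
and is ON for an interval iff the mean state of its vessels is strictly
positive: `r_i = H((1/z) sum_j a_ij S_j)`, with the OFF-on-tie convention
`H(0) = 0`.  With `z = 1` every neuron follows one vessel; with `z = n`
all neurons receive the identical signal and the mask is spatially uniform.

Time is organized in vascular intervals.  Each input pattern occupies 0.05
time units of vascular dynamics; one interval advances the ring by
`TR * 0.05` time units under the current demand, freezes the mask, and
presents `TR` patterns (grouped into minibatches).  `TR`, the temporal
ratio, defaults to 20 (= one minibatch per interval).

The demand follows a finite-difference gradient step once per interval:

    N_d <- N_d - beta * (Delta mse / Delta N_d)

with `beta = 10`, the ratio magnitude clipped to `10/beta` (bounding any
step by 10 demand units), a fixed probe step of -1 on the first interval,
a probe of magnitude 0.1 against the sign of `Delta mse` whenever
`|Delta N_d| < 1e-6`, and the result clipped to `[0, n]` — demand cannot
be negative and `n` is the most a saturated supply can deliver.  `N_d`
starts at `n` (all vessels ON, q = 0).

Because successive intervals present different minibatches, the
finite-difference ratio is noise-dominated and the demand performs a
bounded random walk with a weak drift toward lower error, rather than a
clean descent.  This is a property of the published update rule, not an
implementation artifact, and it is what sustains a nonzero time-average
dropout fraction: a noiseless descent would drive q to 0 (its in-force-mse
optimum) and erase the contrast between regimes.  The converged error of a
run is therefore reported as the mean over the final 15,000 intervals
(60 epochs), a window long enough to average over several sojourns of the
walk.  Step-control variants evaluated during development (caps of 1 or 3
demand units, signed range `[-n, n]`) either let the demand park at the
all-ON boundary (collapsing the desynchronized arm to an undropped
autoencoder with mse far below the reported levels) or allowed long
negative-demand excursions that inverted the arm ordering in some seeds.

## What the experiments show — and what they do not

With the defaults above, five paired seeds give: desynchronized arm
converged mse 0.031-0.043 versus synchronized 0.053-0.058 (ordering 5/5),
and mean pairwise mutual information (MII) of the learned weight images
around 1.0-1.3 bits versus 1.5-1.6 bits (ordering at least 4/5).  The
desynchronized arm's
vessels are uncorrelated (|APC| < 0.02) while the synchronized arm's APC
is 1.0.  Widening the projective field or raising the temporal ratio
raises MII, reproducing the qualitative degradation of feature
independence.

Two published observations do **not** emerge from this implementation,
and the package reports them as measured rather than encoding the expected
direction:

* **Full single-bar localization.**  Ideal independent (Bernoulli) dropout
  at q ~ 0.4 drives 16/16 hidden units to single-bar features (>= 80% of
  rectified weight mass on one bar).  Ring-generated masks reach only
  2-5/16 at any parameterization found.  Controlled mask-surgery
  experiments locate the cause in the *stationary pattern distribution*
  of the attractor: time-shuffling the recorded vascular masks (destroying
  temporal order, keeping the patterns) changes nothing, while shuffling
  neuron identities within each interval (destroying the patterns, keeping
  everything else) restores 16/16.  Snapshots of a spatially structured
  attractor — even a highly diverse one with mean absolute pairwise mask
  correlation 0.11 — carry higher-order dependence that lets subsets of
  units co-adapt.  The localization score itself is computed on the
  rectified weight image, because a trained encoder necessarily carries a
  distributed inhibitory surround (it compensates the saturating overlap
  of crossing bars) that caps the unrectified concentration near 0.65 for
  even a perfectly localized unit.
* **The SSI direction.**  The single-window structural similarity between
  two *different* single-bar images is slightly negative (disjoint
  structure), while entangled, diffuse weight images score near zero or
  positive.  SSI therefore *rises* as features degrade with z or TR in
  this formulation, opposite to the reported downward trend.  The metric
  is reported without encoding a direction.

The bar dataset (binary 8x8 images, 1-4 bars drawn uniformly without
replacement from the 8 rows + 8 columns, overlaps saturating at 1) is the
classic sparse-coding benchmark; it emulates inputs whose generative
factors are known and enumerable.  Passing these tests shows the coupled
mechanism regularizes learning on such factorizable data; it says nothing
about natural images, about biophysical vessel mechanics (lumen diameter,
myogenic response), or about chaos in any formal sense (no Lyapunov
exponents are computed).  MNIST support is provided as an IDX reader plus
configuration, but no MNIST claim is tested — the data is an external
download.

## Numerical and reporting conventions

* Histogram entropies use 16 equal-width bins over the pooled min-max
  range of the image pair, log base 2; weight images are min-max
  normalized to [0, 1] before MII/SSI since raw weights are unbounded.
* SSI constants: `C1 = (0.01 L)^2`, `C2 = (0.03 L)^2`, `L` = pooled
  dynamic range (the standard choices for this index).
* Convergence is declared when the 100-interval smoothed mse changes by
  less than 0.1% between epochs; runs always complete their epoch budget
  and the flag is recorded in the report.
* Experiments use a paired design: contrasted arms share the dataset, the
  initial weights, the vessel-to-neuron wiring and the presentation order;
  only the manipulated variable differs.  All randomness flows from
  per-run seeds through `numpy.random.Generator`; reruns of the same
  configuration are bit-identical.
* Problem sizes in the test suite: the synchrony contrast runs the full
  study (5000 images, 300 epochs, five paired seeds); the projective-field
  and temporal-ratio sweeps run at 2500 images and 80 epochs, where the
  MII trends are already stable.
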
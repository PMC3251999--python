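# Methods

This note documents the models implemented in `actikit`, the defaults
and numerical choices, what the synthetic generators do and do not
emulate, and the design decisions taken where the problem left the
design genuinely open.

## Level-set segmentation

**Model.** Two-region segmentation of a grayscale image I: Ω → [0, 1]
by minimizing

E(C) = γ·Perimeter(C) + η·Area_in(C) + β·F(C) + (1−β)·B(C)·|Ω|,

where F is the Chan–Vese within-region variance with region means
(c_in, c_out), and B = Σ_z √(p_in p_out) is the Bhattacharyya
coefficient of the inside/outside intensity histograms. B is multiplied
by the image area |Ω| because B ∈ [0, 1] while F integrates over the
image plane; without that scaling the separation term is numerically
invisible. The region is carried by a level-set field φ with inside
= {φ < 0}; region integrals use the smoothed Heaviside
H_ε(v) = ½(1 + (2/π)·arctan(v/ε)) with δ_ε = H_ε′, applied as
H_ε(−φ) for the inside. Pixel grids are row-major, origin top-left,
0-based.

**Histograms.** Hard binning, `n_bins = 64` over `value_range`
(default [0, 1]); each region's histogram is normalized by its smoothed
region mass. A Parzen/kernel density option is out of scope. Shifting
the image and `value_range` together leaves the segmentation unchanged
(tested).

**Evolution.** The PDE form of the descent is
∂φ/∂t = |∇φ|·{γκ + V0 + β[(I−c_in)² − (I−c_out)²] − (1−β)·|Ω|·[B/2(1/A_in − 1/A_out) + ½∫δ₀(z−I)(√(p_in/p_out)/A_out − √(p_out/p_in)/A_in)dz]},
with κ the curvature of φ (central differences, 1e-8 gradient guard)
and the histogram integral evaluated per bin at each pixel's intensity.
`evolution_step` implements exactly this explicit step. The constant
V0 is the speed contributed by the η·Area_in term; differentiating that
term gives +η in the bracket (raising φ shrinks the inside region,
which is what an area *penalty* must do — the opposite sign would
increase the energy). η defaults to 0.

**Driver.** `segment` does not iterate the PDE step naively: explicit
|∇φ|-form updates steepen φ, which (a) makes the smoothed perimeter
and Heaviside terms underestimate their sharp-limit values and (b)
stalls the CFL-limited step size. Instead the driver performs
backtracking gradient flow with the variational direction
δ_ε(φ)·bracket — the actual functional derivative of E, of which the
|∇φ| form is a positive pointwise rescaling, so both are descent
directions of the same energy. Each step is CFL-scaled so no pixel's φ
moves more than 0.45 per step and is accepted only if the energy does
not increase (step halved up to 10 times otherwise). The recorded
energy trace is therefore monotone non-increasing by construction.
Signed-distance reinitialization is available (`reinit_every > 0`,
adopted only when it does not raise the energy) but off by default —
the variational flow does not need it.

**Velocity guard.** Where one histogram vanishes the shape derivative
of B contains √(p_in/p_out) ratios that blow up; for the velocity only,
probability masses are floored at 1e-3 (B itself is computed
unfloored). This bounds the CFL step without changing stationary
points in practice.

**Convergence and degeneracy.** Iteration stops when the relative
energy change stays below `tol = 1e-5` for 30 consecutive accepted
steps (the energy can crawl through near-flat stretches while the
contour still moves sub-pixel, so a short patience window stops too
early), or at `max_iters = 1500`. A region whose smoothed mass falls
below one pixel-equivalent, and the nothing-to-segment case
(c_in = c_out and B = 1, e.g. a constant image), terminate with
`degenerate=True` and the last valid mask.

**Defaults.** β = 0.5 (equal mixing), γ = 0.2 (mild length penalty on
the [0,1] intensity scale of 64×64-ish frames), ε = 1.0, dt cap 0.45/‖v‖∞.
On the synthetic body fixture the full model reaches IoU ≈ 0.99 while
β = 1 plateaus near 0.77 by splitting off only the brighter clothing
intensity — the inhomogeneity failure the separation term exists to fix.

## Silhouette HMM classifier

Motion features are ICA projections (FastICA, unit-variance whitening,
`ica_k = 10` components) of vectorized consecutive-frame difference
images; raw-frame mode is available behind `use_differences=False`.
Differences respond to *motion* rather than pose, which is what
separates periodic activities. Features are quantized against a shared
k-means codebook (`codebook_size = 16`, seeded, ties to the lowest
index) and each activity gets an ergodic `n_states = 4` discrete HMM
trained by Baum–Welch. Training runs EM one iteration at a time to
expose the per-iteration log-likelihood (monotone, tested); rows get
additive smoothing 1e-3 afterwards so unseen symbols keep small but
finite probability. Classification is argmax of the forward
log-likelihood with lexicographic tie-break.

**Unknown floor.** With a shared codebook and smoothed ergodic models,
a fixed floor like log(1/K) − 2 per frame is effectively unreachable —
junk sequences still score near log(1/K) because their symbols are
*some* class's symbols. The default floor is therefore calibrated from
training: the worst per-frame log-likelihood any training sequence
achieves under its own class model, minus 0.75 nat. Sequences below it
are labelled `"Unknown"`. The fixed rule remains available
(`default_unknown_threshold`, or pass `unknown_threshold=`).

Frames are resized to 100×70 by nearest neighbour and re-binarized at
0.5 before feature extraction.

## Semi-Markov CRF with null activities

**State space.** A segmentation S = [(y, b, e), …] with 1-based
inclusive boundaries, strictly increasing with gaps allowed
(b_{i+1} > e_i). Per-time label sequences are encoded by taking maximal
runs of non-null labels; null runs become gaps. Gaps — including
leading/trailing stretches and the whole sequence for the empty
segmentation — are charged with the inactivity (IA) observation
weights w_o(IA, ·), which is what makes eliminated null activities
first-class rather than an unmodelled hole: the empty segmentation is
a member of the hypothesis space with weight exp(Σ_t w_o(IA, x_t)).

**Potentials.** Transition w_tr(y′, y) with a distinguished START label
for the first segment (the i = 1 case is otherwise undefined);
duration w_d(y)·(d − m_y)²/(2σ_y²) with per-label duration means and
variances estimated from training segmentations (population convention,
variances floored at 0.25 to avoid division blow-ups) — the sign of the
duration term is carried entirely by the learned w_d(y); observation
sums of w_o over segment symbols plus IA terms over the preceding gap.

**Recursions.** All scoring is in log-space with max-shifted
log-sum-exp. The forward pass runs over (end time, label, duration)
with two per-label prefix accumulators that absorb the
sum-over-previous-end-times (gaps make predecessors non-adjacent), so
one pass costs O(T·M·(M+D)) elementary potential evaluations instead of
O(T²·…). The backward pass mirrors it; segment marginals
P((y,b,e) ∈ S | X) come from seg-start × body × completion products,
occupancy probabilities from a difference-array sweep, and expected
feature counts — hence gradients ∂L/∂w = observed − expected — from one
forward–backward shared by *all* parameters. IA observation
expectations use complementarity: every time step is either inside a
segment or IA, so E[count(IA, o)] = count(o) − Σ_y E[in-segment count].

**Reference paths.** `gradients_bruteforce` enumerates every valid
segmentation (guarded to T ≤ 10) and is the correctness oracle.
`gradients_naive` is the instrumented reference algorithm this design
improves on: one expectation-semiring forward pass *per parameter*,
with an explicit inner sum over predecessor labels — O(T·M²·D)
potential evaluations per gradient, O(N·T·M²·D) for N gradients. Both
are tested against enumeration; the operation counters of the naive
and fast paths (bulk-incremented where the code is vectorized, always
counting elementary ψ-terms) document a ratio of several hundred at
N=100, M=7, D=256, T=100.

**Decoding.** Semi-Markov Viterbi over (end, label, duration) with gap
transitions. Exact score ties break deterministically: fewer segments,
then lexicographically earlier (begin, label-index) sequences — with
all-zero weights the empty segmentation wins every tie.

**Training.** Full-batch ascent on the L2-regularized conditional
log-likelihood (λ = 0.1 default) with backtracking line search
(Armijo condition, step halved up to 30 times, grown 1.5× after
success), zero initialization, deterministic. The objective over
accepted steps is non-decreasing (tested). Divergence is impossible by
construction (steps are only accepted on improvement); stopping is by
gradient norm, relative-change patience, or `max_iter`.

**Windowed features.** Per axis and 512-sample window (50 % overlap):
mean, standard deviation, and mean-crossing rate (sign changes of the
mean-centered window divided by window length), plus the window
mid-time. Averaging 0.4-s blocks of a 100 Hz stream yields an effective
2.5 Hz rate, so one window spans 512/2.5/60 ≈ 3.41 min. Continuous
features can be quantized through the same codebook machinery as the
video path; the discrete-symbol corpus generator feeds the CRF
directly. Absolute versus within-day time encoding is left to the
caller (the window mid-time is reported on the caller's time axis).

## Rule engine

Events are plain records (id, name, type, ISO-8601 time, person,
location); the ontology storage of the original deployment is replaced
by this event log plus an explicit knowledge base. The default catalog
holds 18 activities (every activity the rules and recognizers name);
matching is case- and spacing-insensitive; out-of-catalog events go to
the unknown log and participate only in Rule 4. Rule parameters:
exercise session window 30 min and "at least 2 distinct motion
contents" for Rule 1; Rule 4 successor timeout 5 min; match-making
tolerance 60 s; obligation flags (medicine, exercise, reminders) reset
at local midnight per person. Satisfied obligations update the
knowledge base so replays never duplicate reminders; device commands
(TV, lights) are state-conditioned rather than flag-gated. Match-making
is greedy earliest-first one-to-one on (name equality, |Δt| ≤
tolerance); precision/recall use the convention that an empty
denominator reports 1.0 with an explicit `*_defined = False` flag.

## Synthetic data

The generators produce the statistical structure each consumer assumes,
with ground truth attached and byte-identical output per seed:

* **Body images** — torso ellipse + head circle at a requested area
  fraction (default 0.25 of a 64×64 frame), upper/lower halves at two
  foreground intensities (0.3/0.8) on a 0.05 background with Gaussian
  pixel noise σ = 0.02: a bimodal foreground on a distinct background,
  the regime that separates the two energies.
* **Silhouette videos** — a body shape under class-specific periodic
  deformations (arm wave, vertical jump, tilt, width stretch; ~8-frame
  period with per-sequence phase and ±10 % frequency jitter), plus
  `static` and an incoherent-junk `noise` kind for unknown-activity
  tests.
* **Sensor corpora** — per-time (symbol, label) sequences: activity
  segments with durations ~ round(N(m_y, σ_y)) clipped to ≥ 1
  (defaults m linearly spaced 6–12, σ = 1.5), never repeating the
  previous label (adjacent same-label runs would silently merge into
  one long segment), interleaved with null stretches at rate 0.3
  (duration ~ N(4, 1)); label y emits its preferred symbol with
  probability `emission_sharpness` (default 0.9), nulls prefer symbol
  M the same way.
* **Event logs** — scripts of (offset, name, location) entries plus
  declared expected decisions; the default script is a morning routine
  (enter kitchen → sit → watch TV → eat without prior medicine → read)
  whose ground-truth decisions are lights-on, a medicine reminder and
  TV-off.

What they do **not** emulate: real segmentation inputs have texture,
shadows, occlusion and non-Gaussian noise; real silhouettes have
extraction errors and person-specific style; real wearable symbols are
quantized continuous features with label noise and non-Gaussian
durations; real event streams carry detector errors and timing jitter
beyond the injected offsets. Passing tests therefore demonstrate
correctness of the algorithms and recoverability under the stated
generative assumptions, not field performance.

## Problem sizes used in tests and the acceptance script

Segmentation runs on 64×64 fixtures; the video classifier trains on
8 sequences × 3 classes of 20 frames (100×70) and tests on 6 per
class; the CRF trains on 16 and tests on 8 sequences of length 120
(M = 3, alphabet 8, D = 32, 30 ascent iterations); enumeration checks
use T ≤ 6, M ≤ 3, D ≤ 3 over 100 seeded instances; the complexity
comparison runs at N = 100, M = 7, D = 256, T = 100. These sizes keep
the full suite and the acceptance script to a few minutes on one CPU
while leaving every measured margin wide.

## Known limitations

* Segmentation is two-region, intensity-only (no color/texture
  features, no multi-phase extension) and first-order explicit; very
  low-contrast or heavily textured scenes will need more bins, a
  kernel density, or a different feature.
* The Bhattacharyya velocity floor (1e-3) biases the velocity where a
  histogram is truly empty; the energy is unaffected.
* The HMM classifier assumes a shared codebook is expressive enough
  across activities; the Unknown floor is calibrated on training data
  and inherits its coverage.
* CRF training is full-batch; very large corpora would want stochastic
  or quasi-Newton optimization. Decoding stores explicit tie-break
  keys, which favours exactness over speed on megasample sequences.
* The rule engine's lookahead for Rule 4 requires the full stream (it
  is an offline/batch engine, not a streaming one).
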
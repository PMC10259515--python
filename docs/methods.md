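# Methods

This note records the models, conventions and numerical choices behind
`dyadrot`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where design latitude existed.

## Coordinate and angle conventions

All computation is in micrometres, degrees and minutes.  Coordinates
are continuous 2-D with x increasing posteriorly — the anteroposterior
(A-P) axis — and y increasing dorsally.  Frames are 0-based and times
default to `frame × frame_interval` (200 s, the acquisition interval
of the videomicroscopy the pipeline targets) unless an explicit time
column is present, in which case the column wins.  Pixel-space inputs
require an explicit µm/px factor: pixel size is acquisition-specific
and a silent default would corrupt every length-bearing statistic, so
there is none.  Observation is capped at 500 min after division; later
rows are dropped and logged.

The positional angle of a pair is the direction of the cell-1 → cell-2
vector against +x, in (−180°, 180°], after centering the pair on its
per-frame centroid (which removes any common drift exactly).
Frame-to-frame changes take the minimal representative in
(−180°, 180°]: the wrap assumes no rotation exceeds 180° between
consecutive frames, safe because observed rotations take tens of
minutes per 90° while frames are 200 s apart.  Anti-clockwise is
positive.

## Phase segmentation

The cumulative angle of an inverting pair is fitted with the
four-parameter logistic f(t) = c + (d − c)/(1 + exp(−b(t − a))): a is
the midpoint (min), b the steepness (min⁻¹), c and d the asymptotes
(deg).  This is the standard 4PL family — midpoint, steepness and two
asymptotes are exactly the quantities the phase analysis needs — and
the tangent-line construction below is derived for this form.  Negative
(clockwise) rotations are handled by letting d < c rather than by a
sign switch, keeping b > 0 identifiable.

Fitting is bounded Levenberg–Marquardt (`scipy.optimize.curve_fit`)
with a deterministic 12-point multi-start — a over the observed time
quartiles, b over {0.01, 0.05, 0.1, 0.5} min⁻¹, c/d from the first and
last decile means — selected by lowest residual RMS, ties broken by
the lowest b.  Identical inputs therefore always give identical fits.
Constant series, series shorter than 10 frames, and all-start failures
are flagged as fit failures, never silently passed.

The tangent through the inflection point (t = a, slope b(d − c)/4)
meets the asymptotes at **Ic = a − 2/b** and **Id = a + 2/b**; these
delimit Phase 1 / Phase 2 / Phase 3 and give Phase 2 the duration 4/b.
Boundaries outside the observed time range are clamped and flagged.

## Scalar rotation statistics

* **Inversion**: final |Σ| strictly greater than the 90° critical
  angle (configurable); exactly 90° is not an inversion.
* **Turn / arc**: |Σ(t)| and Σ|Δα|; turn ≤ arc with equality only for
  angularly monotone trajectories.
* **Overshoot** = max turn − final turn; **wobbling** = final arc −
  final turn.  Both are nonnegative by construction, which is the only
  reading of "cumulative angle changes minus final turn" that is zero
  for monotone rotations.
* **Start/final angles**: circular (unit-vector) means of the first
  and last ten positional angles; arithmetic means would fail at the
  ±180° branch cut.  Shorter series use all frames and are flagged.
* **Noise** = (path₁ + path₂)/(chord₁ + chord₂) over the first
  200 frames of the centered trajectories; ≥ 1, equal to 1 exactly for
  straight-line motion.  Pairs in which either cell's chord is below
  2 µm are excluded.  The aggregation over the two cells is a design
  choice: the default pools paths and chords; a per-cell-ratio mean is
  available (`noise_aggregation="mean_ratio"`) and the mode is written
  to the run manifest.
* **Final axis angle**: the undirected inter-cell axis folded into
  [0°, 90°] via absolute vector components, so the arbitrary labelling
  of the siblings cannot affect it.
* Group comparisons name each test and its sidedness in the output:
  two-sided exact binomial for inversion frequency against the
  reference frequency, k-sample Anderson-Darling plus one-sided WMW
  (reference stochastically less) for noise, unpaired two-sided t for
  onset/duration/final turn, two-sided KS for final angles.  Absolute
  (not signed) final turns enter the mutant comparisons.

## Morphology

Pair circularity is the isoperimetric ratio C = 4πA/P² of the fused
outline: A = A₁ + A₂, P = P₁ + P₂ − 2L with L the shared junction
length.  It is 1 for two half-discs sharing their diameter, scale
invariant, and only defined on frames with a shared bond.  Values
marginally above 1 (possible with segmentation noise) are clamped to 1
and flagged.

Interface polylines are rigidly moved so their endpoints sit at
(±L/2, 0) — rotation and translation only, preserving traversal
orientation — then resampled to 64 arc-length-uniform points so the
scores cannot depend on vertex density.  With s the centered arc
parameter, the **chirality score** is the mean |y(s) − y(−s)|/2 (the
odd component, zero for any mirror-symmetric profile) and the **bowing
score** the mean |y|, both normalized by the endpoint separation.
Precedence: chirality score > τ_S → S or Ƨ, by the sign of the
trailing lobe of the odd component (positive for y = A sin(2πx/L),
whose mirror is Ƨ); else bowing score > τ_C → C; else I.  No
principled value exists for either threshold; both default to 0.05 of
the endpoint separation and are configurable for sensitivity
analysis.  Mirror reflection provably swaps S↔Ƨ and fixes
I and C; reversing the traversal direction changes nothing.

## Topology

Cells are adjacent at a frame iff a bond row links them at that frame.
D(T) = Σ_{t≤T}(N_t − M_t) accumulates the neighbor-count difference
between the sibling that finishes anterior (retrospectively the
Notch-off/Emx2⁺ cell, assigned from the final track positions) and its
posterior-finishing sibling.  Swapping the labels negates D exactly;
whether the sibling–sibling edge is counted shifts both counts equally
and leaves D unchanged (tested).  A *popular* cell is called when a
two-sided sign test on the nonzero per-frame differences rejects
symmetry at α = 0.05, the side given by the least-squares slope of
D(T); the decision rule is a package convention chosen for its simple
sampling behaviour — only the divergence itself carries biological
meaning.  Group curves are
LOESS-smoothed |D(T)| (span configurable; signed D is also emitted,
since the plotted quantity could be read either way).

## Flow correlation

Movement, not position, is correlated: confined cells have trivially
autocorrelated positions, so Pearson R is computed on frame-to-frame
x-displacements (the A-P component only), optionally after subtracting
a reference track's displacement (the organ center).  Pairings are
classed HC-HC / HC-other / other-other relative to the rotating pair;
zero-variance series and pairings with fewer than 3 common intervals
are skipped with a recorded reason.  Both pooled and median summaries
are emitted.

## The two-cell Metropolis model

Each sibling is a particle on a circle, its angle θ against the A-P
axis the only degree of freedom.  The energy is

    H = ρ (d / Δ(θ₁, θ₂))¹² + [wells on] Σⱼ ωⱼ · (−exp(−Δ(θⱼ, μⱼ)²/2σ²))

with Δ the circular distance, d = 180° so the soft-sphere repulsion
(the r⁻¹² Lennard-Jones term) acts across the whole domain — the dyad
is in contact throughout — and one Gaussian well of depth ωⱼ ≥ 0 and
width σ per cell.  Sampling: one cell at a time proposes ±0.25° (the
lattice interval), accepted with probability min(1, exp(−β ΔH));
rejected proposals leave the cell in place; coincident positions have
infinite energy.  Wells are off during an initial breaking time.  The
pair axis is initialized from N(180°, 50°) with the cells placed
diametrically opposed (siblings in contact on opposite sides of their
centroid); independent per-cell initialization is available behind
`init_mode="independent"`.

The *asymmetric* configuration puts the wells at opposite poles
(μ = 0° and 180°, default depths 50 and 0: a single active attractor,
the partner following through the exclusion).  The *symmetric*
configuration puts both wells at one pole (μ₁ = μ₂ = 180°, default
depths 50 and 20, relative depth min ω/max ω = 0.4).  Replicate sweeps
fix the reference depth at 50 and vary the second well.

**Parameter choices.**  σ, β, ρ and the step budget are free
parameters of the model.  They were fixed once by the calibration
sweep in `scripts/calibrate_sim.py`, against three requirements: a
lone particle must be captured by its well well inside the step
budget; the asymmetric model's final-axis deviation must be flat
across relative depths while the symmetric model's varies; and
ensemble medians must be stable across seeds.  The defaults are
**σ = 140°, β = 0.25, ρ = 1, 10⁶ steps** with a 10⁴-step breaking time
and frames recorded every 4000 steps (≈250 frames per run, matching
the empirical recording length).  Narrow wells (σ ≲ 2·σ_thermal of the
starting distance) leave both cells diffusing for most of the budget
and erase the depth-ratio sensitivity of the symmetric model; the
wide-well regime is where the competition between attractors is
expressed.  Readouts (final-axis deviation folded into [0°, 90°],
trajectory noise) are computed by the same `trajectory` pipeline used
for tracked data, on the recorded frames mapped to a 4 µm-radius
circle.  The compiled (numba) and numpy update kernels implement the
identical rule and are seed-for-seed deterministic.

## Synthetic data: what it does and does not emulate

The generators are pure functions of (parameters, seed) and produce
the exact CSV dialects the readers parse.  Inverting pairs follow the
logistic in angle with independent Gaussian angular wobble per frame
(injected in angle space so angular-path statistics are analytically
predictable); non-inverting pairs rock sinusoidally below the 90°
criterion — a descriptive stand-in for the "transient rocking" of real
non-inverting dyads, for which no mechanistic model is claimed.
Morphology series are piecewise-smooth templates anchored to [Ic, Id]
(areas constant; circularity, junction length and closeness peaking in
Phase 2; interface polylines of selectable shape class): they emulate
the qualitative Phase-2 structure of real recordings, not cell
mechanics.  Neighbor exchange is alternating-compensated when
balanced (keeping |D| ≤ 1) and exactly biased otherwise.  Background
epithelia are stationary cells with iid positional jitter — no
collective flow, division, death or segmentation error.  Passing tests
therefore demonstrate the correctness and statistical behaviour of the
analysis code under its stated assumptions, not the biological
fidelity of any generator.

## Numerical details and degenerate inputs

Angle wrap uses the exact modular form mapping to (−180°, 180°];
circular means use atan2 of averaged unit vectors.  The logistic
exponent is clipped at ±700 to avoid overflow far from the midpoint.
Coincident centroids raise an undefined-angle error with the frame
index; zero-length interfaces and single-point polylines are rejected;
frames without a sibling bond yield NaN circularity and zero junction
length (distance remains defined).  Exactly zero net rotation has no
handedness.  TSVs are written with fixed 4-decimal floats so identical
inputs reproduce byte-identical outputs; every run writes a manifest
with the configuration, seed and library versions.

## Known limitations

* The pipeline is strictly 2-D per exported slice; no 3-D interface
  reconstruction across focal planes.
* The logistic family assumes a single monotone inversion; double
  inversions or full reversals fit poorly and are only captured by the
  overshoot/wobbling statistics.
* The popularity rule and the interface-asymmetry thresholds are
  package conventions, configurable but not biologically derived.
* The simulator is exactly two particles with passive confinement; it
  does not model the surrounding epithelium, and its σ, β, ρ are
  calibrated package defaults rather than measured quantities, so only
  contrasts between its variants — not absolute numbers — should be
  interpreted.
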
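# Methods

This note records the models implemented in `sspt`, the conventions and
defaults chosen where the underlying study leaves the design open, and
what the synthetic benchmark does and does not establish about real data.

## PVM trace analysis

A transition event is read off an intensity trace in four steps: average
the pixels of a region (whole ROI, or square superpixels of 1–2 px),
smooth with a centered boxcar (reflection padding at the edges),
differentiate by central differences (one-sided at the ends, local Δt so
non-uniform sampling is tolerated), and characterize the primary peak of
the derivative:

* **Direction** is auto-detected from the sign of the net intensity
  change; transitions may brighten or darken the crystal.
* **T1** is the time of the global extremum of the signed derivative.
  The discrete argmax is refined by a quadratic least-squares fit to the
  contiguous samples above 75% of the peak height — exact for symmetric
  peaks, and with sub-sample precision under noise (the 3-point parabola
  leaves ~0.2 s quantization error at 0.5 s sampling; the regional fit
  removes it and averages the noise).
* **HWHM** is half of the full width between the half-height crossings of
  the two flanks, each located by linear interpolation between samples.
  If a flank never reaches half height inside the trace, the one-sided
  width is used and the event carries a flag.
* **Shoulders** are local maxima before T1 exceeding a configurable
  fraction (default 0.2) of the peak height, at least 5 samples apart.
* **No-transition guard**: the peak must exceed 3× a robust (MAD-based)
  standard deviation of the derivative's first and last 10% of samples.
  Traces that never transition are reported as failures, not fabricated
  events.

Boxcar smoothing before differentiation broadens the derivative peak: a
window of `w` frames at interval Δt adds variance `(w²−1)Δt²/12`, so the
expected HWHM of a transition of intrinsic width σ is
`sqrt(σ² + (w²−1)Δt²/12)·sqrt(2 ln 2)`.  This quadrature prediction is
accurate while the boxcar width stays comparable to σ (at window 39 and
Δt = 0.5 s against σ = 8 s the residual shape error is ~10%); for windows
much wider than σ the smoothed peak tends toward a plateau of width
`w·Δt` and the quadrature form undershoots.  The positional analysis
(window 65) therefore reports wider HWHM values than the ROI-size
analysis (window 39) on identical data — widths are only comparable
within one smoothing configuration.

Two study designs wrap this machinery: `analyze_positions` (up to seven
10×10 px ROIs, one mean trace each; summary is mean ± sample sd over
ROIs) and `roi_size_sweep` (concentric squares of 2–42 px, ~0.1–3 µm at
14 px/µm, analysed per superpixel).  k-means classification of T1 values
uses k-means++ with 10 restarts and a fixed seed; k defaults to 2 with an
optional silhouette-based chooser over k ∈ {2..4}.

## Four-state kinetics

The ligand-induced conversion is modelled as an irreversible cascade

    apo1 →(k_op) apo2 —ade→(k_on) IB·ade →(k_f) B·ade

with mass-action rates and all reverse constants fixed at zero.  The
observable tied to PVM is the inflection time of [B·ade](t) (maximum of
its first derivative, computed on a dense uniform grid with parabolic
refinement).  Integration uses LSODA with rtol 1e-8 / atol 1e-12 mM and
dense output; trajectories are validated against RNA conservation
(apo1+apo2+IB+B = 2·R0 to 1e-6 relative), forward monotonicity, a
matrix-exponential solution of the clamped linear chain, and a fixed-step
RK4 reference at 1 ms steps (agreement to 1e-4 relative).

**Rate-law conventions.**  The published parameter table prints all three
forward constants in M⁻¹s⁻¹ although two steps are written as
unimolecular, and it does not state whether the free-ligand pool depletes
or how the RNA pool is partitioned at t = 0.  Rather than guessing
silently, `Convention` makes six choices explicit (order of the opening
and conversion steps, whether each bimolecular step consumes ligand,
clamped vs. depleting ligand, unit scale, initial apo partition) and
`calibrate_convention` ranks every admissible combination by how well the
resulting inflection times reproduce the observed transition times
(55.7 / 60.4 / 72.1 s) from the three printed parameter columns.  The
shipped default is the winner of that calibration:

* concentrations in mM with the printed constants applied numerically;
* ligand depletes from an initial free pool B0 (closed);
* the whole RNA pool (2·R0 = 32 mM) starts as apo1 — the
  binding-competent apo2 state is initially unpopulated, every molecule
  passing through the ligand-promoted opening step;
* opening is bimolecular and consumes ligand
  (r = k_op·[apo1]·[ade]); binding consumes ligand; the final
  conformational switch is ligand-promoted but catalytic
  (r = k_f·[IB·ade]·[ade]).

Under this convention the three crystals' printed parameters give
inflection times of 56.5, 62.2 and 71.1 s (all within ~3% of the observed
values, with the correct ordering and spacing); every convention with the
RNA split evenly between apo1 and apo2 at t = 0 misses by an order of
magnitude, because a pre-populated 16 mM apo2 pool consumes the ~0.45 mM
ligand within seconds.  The calibration, including the full enumeration,
is executed in the test suite; alternative conventions remain available
through the `convention` field.

A consequence of this convention worth noting: T1 is *not* insensitive to
k_on here (scaling k_on by 0.3–3× moves T1 by ~±35%).  The fitting
routine nevertheless holds k_on fixed at the published 3.00×10⁻² and fits
(B0, k_op, k_f), matching the study's protocol.

**Fitting.**  The study fit parameters manually; `fit_parameters`
replaces this with a deterministic coarse log-grid search (5³ points over
B0 ∈ [0.05, 5] mM, k_op ∈ [1e-5, 1e-2], k_f ∈ [0.02, 20]) followed by
bounded least squares in log-parameter space from the five best grid
seeds.  Multi-start matters: the SSR surface has a shallow valley along
which a smaller B0 trades off against larger rate constants with almost
identical normalized curves.  On noiseless regenerated curves all three
parameters are recovered to <5%; under 1% additive noise the individual
parameters can wander along the valley while the refitted inflection time
stays within ~2 s — T1 is the robustly identified quantity.

## Synthetic videos

`SyntheticCrystalSpec` renders a polygonal crystal on a dark background.
Each crystal pixel follows a two-component normal-CDF mixture in time:

    I(t) = baseline + ΔI·[ f·Φ((t−(T1−lead))/σ_s) + (1−f)·Φ((t−T1)/σ_p) ]

a small early "shoulder" component (fraction f) followed by the primary
Gaussian-like transition at the pixel's T1.  The T1 field is a mean plus
a linear spatial gradient plus a smooth correlated Gaussian random field
(white noise convolved with a Gaussian kernel of the stated correlation
length, rescaled to the target sd over the crystal mask).  Frames get
additive Gaussian sensor noise, clipping to [0, 255] and 8-bit
quantization; optional drift is a rigid per-frame translation rounded to
whole pixels, with a `truncated` flag if the crystal leaves the frame.
One seed drives two independent substreams (field, noise); renders are
bit-reproducible.

Defaults emulate the study conditions: 14 px/µm, 0.5 s/frame (no frame
rate is published; recordings span 6–8 min, so 0.5 s puts the published
boxcar windows of 65/39 frames at 32.5/19.5 s — wide enough to matter but
narrower than a transition), 360 s duration, T1 ≈ 60 s, primary σ = 8 s
(HWHM ≈ 9.4 s before smoothing, at the low end of the published 10–18 s
per-crystal widths), shoulder fraction 0.2 with a 25 s lead and σ = 4 s —
chosen so the derivative shows the described morphology: a smaller early
peak, a genuine slow-down dip, then the Gaussian-like primary.  Noise sd
is 2 gray levels on a 170-level intensity swing.

**What the benchmark does not emulate:** optics of birefringence and
cross-polarization, crystal cracking and edge effects, rotation or
non-rigid motion, intensity flicker, multiple transition waves with
distinct fronts, and ligand-diffusion coupling between neighbouring
pixels.  Passing the round-trip tests therefore demonstrates that the
analysis pipeline is unbiased and precise *given* the assumed trace
shape; it does not certify performance on crystals whose transition
profile deviates strongly from a CDF-mixture (e.g. multi-wave traces,
where only the primary peak is characterized and earlier waves surface as
shoulders).

## Numerical choices and degenerate inputs

* Boxcar edges use reflection padding; windows must be odd and no longer
  than the trace (the error names the largest usable window).
* Normalization is min–max; constant traces raise a degenerate-trace
  error rather than dividing by zero.
* ROIs use a half-open [top, top+side) convention; out-of-bounds crops
  name the offending edge; oversized concentric ROIs are clipped with a
  warning; single-superpixel statistics report sd = 0 with an n = 1 flag.
* The ODE right-hand side clamps free ligand at 0 to keep the closed-mode
  depletion from driving concentrations negative between solver steps;
  post-hoc negativity beyond 1e-6 mM raises a solver-failure error.
* k-means on n < k points raises; permutation invariance is provided by
  the 10-restart k-means++ initialization at fixed seed.

## Problem sizes

Test and acceptance runs use 128×128 px videos of 180–240 s at 0.5
s/frame (361–481 frames), superpixel sweeps of up to 441 traces, kinetic
integrations over 400 s at ~2000 output points, and fits over 5³ grid +
5 local refinements.  These sizes keep the full suite in the low minutes
on one CPU while leaving every statistical check (recovery fractions,
conservation tolerances) at its stated strength; they are a deliberate
desk-scale choice, as the per-pixel analyses scale linearly and bring no
new behaviour at larger frames.
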
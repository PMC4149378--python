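# Methods

## Model and assumptions

The package treats contrast uptake as a local first-order saturation
process: at transmural depth *d* the slice intensity over staining time
*t* follows

    I(d, t) = Imax(d) − (Imax(d) − I₀) · exp(−t / τ(d)).

Assumptions: the unstained intensity *I₀* is depth-constant; the
saturated ceiling *Imax(d)* may decline with depth (beam hardening is
deliberately left uncorrected, since a grey-level-based correction would
be inconsistent across scans whose grey levels change with staining);
the stain reaches interior tissue by diffusion from the outer surface,
so the time constant τ grows with depth. The saturation *ratio*
*I/Imax* is used as the staining marker precisely because it cancels the
depth-dependent ceiling.

The time to reach a target ratio *s* follows in closed form,

    T = τ · ln((Imax − I₀) / ((1 − s) · Imax)),

clamped to 0 if the tissue already satisfies I₀ ≥ s·Imax (never the
case for the reference data, but possible for tissue with high native
intensity). Across depths T is modelled as T(d) = A·exp(B·d), fitted by
ordinary least squares of ln T on d. The log-linear route was chosen
over direct nonlinear fitting of T because the relation is presented and
interpreted on a semi-log scale, where it is a straight line, and
because log-OLS is exactly invertible on noiseless data — a property the
round-trip tests exploit.

## Pipeline stages and numerical choices

**Line profile.** Sampled at one-voxel spacing along a user-placed ray
(ray placement is manual, as in practice); each sample averages
`width_px = 5` nearest pixels perpendicular to the ray. Nearest-pixel
(not interpolated) sampling is used so that the averaging is exactly
"the pixels in the band", which the brute-force oracle in the tests
enumerates directly.

**Edge detection.** Three steps on the profile: Gaussian smoothing
(`sigma_px`), maximal forward-difference gradient (first index on ties —
deterministic and consistent with the outside-in scanning direction),
then the first subsequent index whose gradient is ≤ `drop_fraction` ×
the maximum. The criterion is a gradient ratio, hence invariant to
affine intensity rescaling. Defaults are `sigma_px = 1.0`,
`drop_fraction = 0.25`: for a sharp step smoothed with sd σ the gradient
decays to fraction f of its peak about σ·√(2·ln(1/f)) samples past the
peak, so these defaults localise the edge ~2 voxels inside the true
boundary; a larger σ would displace the reported edge proportionally
(e.g. σ = 5 with f = 0.1 puts it ~11 voxels deep). At the phantom's
contrast (step amplitude ≫ noise) σ = 1 still suppresses voxel noise:
100/100 noisy rays at 2 % of dynamic range land within 3 voxels of
truth. Smoothing uses reflect padding, which conserves the local mean
near the profile ends.

**Depth segments.** Twenty 0.1 mm half-open bins [k·0.1, (k+1)·0.1)
beyond the detected edge; each sample belongs to exactly one bin
(membership by sample centre, no sub-voxel interpolation), so the
n-weighted mean of segment means equals the plain mean of the covered
samples exactly. The segment's depth coordinate is the bin *start*.

**Saturation fit.** Derivative-free Nelder–Mead simplex on
(I₀, ln(Imax − I₀), ln τ); the log parameterisation enforces
Imax > I₀ and τ > 0 without constraints. Initialisation: I₀ from the
first sample, Imax from the last (inflated 5 % for non-increasing
series), τ at a third of the time span; one restart from a perturbed
start on non-convergence, then a polish run from the solution so
refitting is a fixed point. Loss is unweighted least squares. Series
with intensity range below 1e-6 of their mean magnitude are flagged
degenerate rather than fitted. No confidence intervals are produced.

**Edge reference timepoint.** The edge is detected once, on the last
(most-stained) timepoint where boundary contrast is strongest, and
reused for all timepoints; per-timepoint detection is configurable. No
re-registration between timepoints is attempted.

## Synthetic phantom

The generator renders a circular annulus (outer radius 3 mm, wall
2.2 mm) on an 11 µm voxel grid at staining times {0, 6, 13, 26, 39, 58} h,
the design of the reference experiment. Inside the wall the exact
saturation model supplies intensity with τ(d) = τ₀·exp(β·d) — chosen
because it makes T(d) exactly exponential when I₀/Imax is
depth-constant, giving closed-form ground truth for end-to-end tests —
and a linearly decaying ceiling (default 2000 counts/mm) as the simplest
monotone emulation of beam hardening. Outside the wall sits a flat
low-contrast background (1000 counts) standing in for the holder.
Additive zero-mean Gaussian noise (default 200 counts ≈ 1 % of the
20000-count dynamic range) is drawn from a stream seeded by
(master seed, timepoint index), so images are bit-reproducible and
adding a timepoint never perturbs earlier ones. Intensities are
quantized to unsigned 16-bit on write (typical micro-CT detector depth);
all internal computation is double precision. A physically motivated
alternative field driven by the semi-infinite 1-D diffusion solution
C(d,t) = C₀·erfc(d / 2√(Dt)) is provided for sensitivity studies.

The wall default is 2.2 mm rather than 2.0 mm so the full 2.0 mm segment
span stays inside tissue even after the detected edge lands a voxel or
two inside the true boundary; with an exactly 2.0 mm wall the deepest
bin would sample lumen background.

What the phantom does **not** emulate: papillary muscles and lumen
chambers (a single transmural ray only crosses the wall), reconstruction
artifacts beyond the monotone ceiling gradient (no projection-space
simulation or Radon machinery), correlated noise, tissue shrinkage, or
inter-scan misalignment. Passing tests therefore demonstrate the
correctness of the numerical procedure under the model's assumptions,
not robustness to real-scan registration or artifact conditions.

## Known limitations and deliberate bias

The segment mean estimates the intensity near the bin *centre*, while
the depth covariate is the bin *start*; together with the edge sitting
1–2 voxels inside the true boundary this shifts all depths by a constant
δ ≈ 0.05–0.07 mm. A constant depth shift leaves B unbiased (measured
end-to-end B̂ within 2–5 % of β for β ∈ {0.5, 1.0, 1.5}) but inflates
the intercept A by exp(β·δ) (≈ +7 % at β = 1). The tests therefore
compare A after the analytic half-segment correction exp(−β·seg_len/2).
Users comparing absolute A values across analyses with different
segment conventions should apply the same correction.

Coefficients apply to the staining conditions they were fitted under
(agent concentration, temperature, species, fixation); the package does
not model dependence on any of these. Problem sizes in the test suite
(200 noisy saturation-fit replicates, 500 depth-time replicates, 100
noisy edge rays, one full-resolution end-to-end stack) were chosen to
make median-recovery statements stable at the few-percent level.
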
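# Methods

## Model

The simulator is a single-layer, feedforward rate model of early spatial
vision: an array of N = 4000 neurons covering a 10° field (400 samples per
degree; Nyquist 200 cpd, comfortably above the 100 cpd sweep ceiling).
Each neuron sees the luminance profile through an on-center/off-surround
receptive field built as a difference of two concentric Gaussians, and its
rate obeys a shunting membrane equation whose multiplicative gating bounds
activity in (−C, B).  The single layer stands in for the accumulated
center-surround processing of retina → LGN → V1; there is no recurrence,
no feedback, no orientation and no temporal dynamics.

All reported quantities use the closed-form equilibrium
`x_eq = (B·I_ex − C·I_inh)/(A + I_ex + I_inh)`.  A time-domain integrator
(`integrate_dynamics`, scipy RK45) exists purely as an independent oracle:
per neuron the equation is linear with relaxation rate `A + I_ex + I_inh`,
so integration from rest must land on `x_eq`; tests require sup-norm
agreement below 1e−6 at `t_end = 20/A` (the measured worst deviation
across the catalog is ~1e−8).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| A, B, C | decay, upper and lower activity bounds | 1, 10.1, 5 | fixed across all conditions |
| Amp_ex, σ_ex | excitatory center strength, spread | 1, 1 | σ in model units |
| Amp_inh, σ_inh | inhibitory surround strength, spread | 1, 1.6 | 1:1.6 width ratio for optimal contrast registration |
| a | grating modulation amplitude | 0.1 | zero-mean sinusoid, phase 0 |
| deg_per_unit | degrees per model σ-unit | 0.05 | sets the frequency scale; places the base peak at ~1.7 cpd |
| grid | samples, extent | 4000, 10° | cell-centered lattice |
| sweep | frequencies | 200 log-spaced, 0.1–100 cpd | linear spacing available |

## Kernel convention

The profile form of each subfield is the raw Gaussian with its peak equal
to `Amp`, truncated at ±5σ on the grid lattice.  For the *drive* onto the
neurons each subfield is normalized to unit tap-sum, scaled by `Amp` and
by a fixed pair gain of 0.5, so that the base center + surround together
have exactly unit DC gain.  Two reasons:

1. **Independence of strength and spread.**  With raw Gaussians the
   integrated weight grows with σ, so widening a subfield also strengthens
   it; narrowing the excitatory center would then *reduce* low-frequency
   drive, the opposite of its documented effect.  Unit-integral kernels
   make `Amp` the integrated strength and `σ` pure spread, and give the
   base profile the canonical positive center with negative flanks.
   A subfield's grating transfer becomes
   `0.5·Amp·exp(−2π²σ_deg²f²)`.
2. **Magnitude of the pair gain.**  The gain sets how strongly the drives
   load the shunting denominator, i.e. the strength of the model's only
   nonlinearity.  Unit total gain (0.5 per subfield at base amplitudes)
   keeps the model in the small-signal regime at `a = 0.1` — halving the
   stimulus amplitude halves every sensitivity to within 0.8% — while
   retaining enough denominator modulation to reproduce the observed
   nonlinear effects of joint amplitude scaling: scaling both amplitudes
   ×1.5 deepens the troughs preferentially at low frequencies and shifts
   the sensitivity peak measurably downward, whereas ×0.5 leaves the peak
   in place.  Substantially larger gains break small-signal linearity
   (and overshoot those peak shifts); much smaller gains erase them.

The stimulus is the zero-mean sinusoid itself (no mean-luminance term).
A positive `dc_offset` is exposed as an option; adding one large enough to
visibly sharpen the base peak provably reverses the joint
amplitude-scaling behaviour above (the operating-point shift then
dominates the trough-deepening effect), so the zero-baseline form is kept.

## Readout and descriptors

Sensitivity per frequency is max − min of `x_eq` over the valid interior
(a 5σ_inh margin at each field edge is excluded; convolution is
zero-padded "same").  Peak frequency is the sampled argmax; a
log-parabolic interpolation through the three samples around the maximum
supplies a sub-step refined estimate used for peak-shift comparisons.
Peakedness is `prominence = 1 − max(S_first, S_last)/S_max` over the
analysis range (0.1–25 cpd); a peak is *distinct* when interior and
prominence ≥ 0.05.  Note the base curve itself sits below this threshold
(prominence ≈ 0.031): with A, B, C and the 1:1.6 ratio fixed, the
equilibrium's low-frequency shoulder is analytically pinned at
`(B−C)/max_f(B·E(f) − C·I(f)) ≈ 0.965` of the maximum, so the base peak is
real but shallow; the threshold is meaningful mainly for *changes* in
peakedness between conditions.

## Numerical validity floor

Truncating the kernels at ±5σ leaves transfer-function sidelobes of order
`exp(−12.5) ≈ 4e−6` of DC gain.  Wherever the true Gaussian transfer falls
below that — the inhibitory surround beyond ~10 cpd, the excitatory center
beyond ~15 cpd at default units — the computed sensitivities are
truncation artifacts of order 1e−8 of the curve maximum.  The package
therefore treats sensitivities below 1e−4 of the curve maximum as
unresolvable (`resolvable_mask`), and the replication battery:

* applies pointwise sign checks only on resolvable frequencies, capped at
  10 cpd for manipulations of the inhibitory surround;
* carries band-level claims through the sign of the band NDI (norms are
  insensitive to the sidelobe floor), omitting the high band for
  surround manipulations whose true effect there is below the floor;
* compares peak frequencies through the refined estimates with a
  one-log-step (≈3.5%) relative tolerance, so the same battery passes
  under both logarithmic and linear sweeps (a linear grid's 0.5 cpd step
  cannot resolve the genuine ~4–7% peak shifts near 1.7 cpd);
* evaluates "more pronounced at low-to-medium frequencies" as band-mean
  relative change in low+medium exceeding high — except for the
  ratio-preserving width rescaling, which is a pure frequency rescaling of
  the curve: its relative change grows monotonically with frequency by
  construction, so band-mean *absolute* change is used there instead.

Resolution stability: doubling the grid density changes resolvable
sensitivities by < 0.03%; in the sidelobe zone values change by orders of
magnitude, which is why comparisons are floored.

## Replication battery

`builtin_catalog()` holds 25 conditions: the eight isolated
width/strength manipulations, eight joint center or surround pairs, four
ratio-preserving rescalings, and five patient best-fit signatures.
Expectations follow the documented qualitative outcomes (direction per
band, pronounced bands, peak shifts, peak distinctness).  Four joint
conditions carry reported sub-claims that do not reproduce, or are
marginal, at these magnitude choices — most notably the
widened-and-strengthened surround (σ_inh, Amp_inh) = (2.0, 2.0), whose
reported medium-band decrease simulates as a small increase (NDI ≈ +0.025:
at these values the surround's withdrawal from the medium band outweighs
its doubled strength, while the low band decreases as reported,
NDI ≈ −0.38) — such conditions are simulated and reported but excluded
from the asserted pass fraction; the remaining 21 pass under both sweep
spacings.  Best-fit magnitude choices where only directions are
documented: ↑ values use the corresponding figure-condition magnitudes
(σ_inh→2.0, Amp_inh→2.0, σ_ex→1.2, Amp_ex→1.2), ↓ values likewise
(σ_inh→1.2, Amp_inh→0.6, σ_ex→0.8, Amp_ex→0.8).

## Statistics

NDI uses the Euclidean norm.  The per-band significance test is a
two-sided paired t-test across frequencies within the band (scipy
`ttest_rel`), with conventions t = 0, p = 1 for identical curves and
p = 0 for a zero-variance nonzero shift; this construction — frequencies
as the pairing unit — is this package's choice, and no multiple-testing
correction is applied across the catalog.  Cosine similarity is clamped to
[−1, 1] before `arccos`.  Band membership is half-open `[lo, hi)` with the
high band closed at 25 cpd.

## Limitations

The model is 1-D, linear up to a single divisive nonlinearity, and
deliberately collapses multiple visual stages into one layer; absolute
sensitivity units are arbitrary (only curve shapes and relative changes
are meaningful), there is no observer/decision stage, and conclusions
about patient groups rest on qualitative directional agreement with
perceptual data, not on fits to individual CSFs.
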
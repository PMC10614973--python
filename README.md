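# dogcsf

A rate-based simulator of early visual contrast sensitivity built from
on-center/off-surround (difference-of-Gaussians) receptive fields and
shunting membrane dynamics.  It is aimed at computational and clinical
vision researchers who want to ask: *which changes in the balance of
excitation and inhibition reproduce the contrast-sensitivity signatures
seen in medicated and unmedicated patients with schizophrenia?*

## The model

A 1-D array of 4000 rate neurons spans 10° of visual angle.  Each neuron
receives the luminance input `I` through an excitatory center and an
inhibitory surround, both Gaussian:

    G_ex(x)  = Amp_ex  · exp(−x² / 2σ_ex²),      x ∈ [−5σ_ex,  +5σ_ex]
    G_inh(x) = Amp_inh · exp(−x² / 2σ_inh²),     x ∈ [−5σ_inh, +5σ_inh]

(for the drive onto the neurons each subfield is normalized to unit
integral and scaled by its amplitude, so `Amp` sets integrated strength
and `σ` pure spread; see `docs/methods.md`).  Neuron activity `x` follows
the shunting equation

    dx/dt = −A·x + (B − x)·I_ex − (C + x)·I_inh,
    I_ex = I * G_ex,   I_inh = I * G_inh,

with decay `A = 1`, upper bound `B = 10.1` and lower bound `C = 5`; all
results use its closed-form equilibrium

    x_eq = (B·I_ex − C·I_inh) / (A + I_ex + I_inh).

Stimuli are sinusoidal gratings `y = a·sin(2πf·i)` with amplitude
`a = 0.1`, swept over 200 spatial frequencies from 0.1 to 100 cycles per
degree (cpd).  Model contrast sensitivity at each frequency is the
peak-minus-trough of `x_eq` across the array; sweeping `f` yields a
contrast-sensitivity function (CSF).  The base receptive field uses unit
amplitudes and the classical 1:1.6 center:surround width ratio.

Curves are compared to the base curve band-wise (low 0.1–4 cpd, medium
4–10 cpd, high 10–25 cpd) with cosine similarity `cosSim = MSV·MBCSV /
(|MSV||MBCSV|)` and its angle `θ = arccos(cosSim)`, the normalized
difference index `NDI = (|MSV| − |MBCSV|) / (|MSV| + |MBCSV|)`, and a
paired t-test on per-frequency differences.

A builtin catalog encodes 25 named manipulations of
`(σ_ex, Amp_ex, σ_inh, Amp_inh)` with their expected directional outcomes,
including five patient-signature best fits (medicated: broader/stronger
inhibition, jointly widened subfields, or jointly weakened amplitudes;
unmedicated: narrowed/weakened inhibition or narrowed-but-strengthened
excitation).

## Worked example

Simulate the base curve and a widened inhibitory surround
(σ_inh 1.6 → 2.0), then compare:

```sh
$ dogcsf run --out base.csv
INFO dogcsf: wrote base.csv (200 rows, ...); peak 1.72 cpd, prominence 0.0313
$ dogcsf run --condition sigma_inh_2.0 --out cond.csv
INFO dogcsf: wrote cond.csv (200 rows, ...); peak 2.12 cpd, prominence 0.148
$ dogcsf compare cond.csv base.csv
   band   n  cos_sim  theta_deg      ndi        t            p   outcome
    low 107 0.998561   3.074004 0.026572 9.829950 1.351770e-16 increased
 medium  26 0.999658   1.499477 0.036145 3.871927 6.879090e-04 increased
   high  27 1.000000   0.005313 0.000068 1.540872 1.354320e-01 unchanged
overall 160 0.998594   3.038194 0.026919 9.502537 3.078561e-17 increased
```

Widening the surround spreads inhibition over space and pulls it out of
the low/medium frequency bands, so sensitivity rises there (positive NDI,
p << 0.05) while the high band — beyond the surround's passband — is
untouched; the peak also sharpens (prominence 0.031 → 0.148) and moves
slightly toward higher frequencies (1.72 → 2.12 cpd), the signature of a
*more distinct* tuning peak.

Other commands: `dogcsf conditions` runs the whole replication battery and
writes per-condition reports (exit code 0 only if every asserted
directional expectation holds), and `dogcsf dynamics-check` verifies the
time-domain integrator against the closed-form equilibrium.

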
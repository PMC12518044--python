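# dporkin

In-situ UV-vis kinetics of dark-operative protochlorophyllide
oxidoreductase (DPOR).

DPOR is a two-component, nitrogenase-like metalloenzyme (BchL + BchNB)
that reduces protochlorophyllide (Pchlide, S) to chlorophyllide
(Chlide, P) during bacteriochlorophyll biosynthesis. Because the free
substrate (Q-band at 651 nm), the Pchlide:BchNB enzyme–substrate
complex (633 nm) and the product (670 nm) are spectroscopically
distinct, the whole reaction can be followed in a cuvette. This package
is for enzymologists and biophysicists who want to turn such
time-resolved absorbance spectra into species concentrations and rate
constants, and to validate every step of that analysis on synthetic
data with known ground truth.

## What it computes

**Spectral unmixing.** Each spectrum A(λ) on the 600–700 nm analysis
window is fitted with

    f(λ) = p₁·S_S(λ−p₆) + p₂·S_P(λ−p₇) + p₃·S_ES(λ−p₈) + p₄ + p₅·λ³

where S_S, S_P, S_ES are spline-smoothed single-species reference
spectra recorded at known concentrations (8, 5 and 3.5 μM), p₄ is a
baseline offset, p₅ a scattering term and p₆–p₈ wavelength shifts
(fixed at 0 by default). The proportionality factors convert directly
to concentrations, c_X = p_X · c_ref,X, and the conserved sum
c_S + c_ES + c_P validates the decomposition. The ES extinction
coefficient can be calibrated from a donor-free series by requiring
free + bound Pchlide to stay constant.

**Kinetics.** Concentration traces are summarized by plateau
one-phase association, y(t) = y₀ + (plateau − y₀)(1 − e^(−kt)), or
two-phase association with k_fast ≥ k_slow enforced by construction,
after truncating the ~10 s instrument dead time; AICc selects between
them. Initial rates and endpoint (acetone-quench) specific activities
with turnover frequencies are also provided.

**Mechanism simulation and synthetic data.** A deterministic ODE model
of E + S ⇌ ES → E + P (with site pools, a sequential two-site variant
for cooperative binding, and a single-turnover mode for stalled product
release) generates ground-truth trajectories; a forward Beer–Lambert
model with Gaussian bands, baseline, scattering and noise produces
complete synthetic experiments, bit-reproducible under a fixed seed.

## Worked example

`python examples/preincubation_binding_rate.py` generates the
pre-incubation experiment (0.5 μM BchNB, 20 μM Pchlide, no electron
donor, 5 s sampling for 600 s, 0.002 AU noise), unmixes all 118 usable
spectra and fits the ES trace:

```
spectra analyzed : 118 (5 s sampling, 10 s dead time)
ES plateau       : 1.004 uM (site capacity 1.0 uM for 0.5 uM BchNB)
k_ES             : 22.0 +- 0.6 x10^-3 s^-1 (generated at 23.0)
R^2              : 0.9783
```

The plateau matches the two Pchlide-binding sites per BchNB tetramer
(2 × 0.5 μM), and the one-phase rate constant recovers the generating
pseudo-first-order value to within a few percent (the small deficit is
real: binding 1 μM of substrate depletes the 20 μM pool slightly over
the rise). The other scripts in `examples/` walk through single-spectrum
unmixing, biphasic turnover kinetics with model selection, direct
mechanism simulation, ES-reference calibration, and endpoint assays —
including the turnover-frequency worked example, 3.01 nmol min⁻¹ mg⁻¹
× 206 kDa → TOF = 37.2 per hour.

A thin CLI wraps the same library calls:

```
dporkin simulate --scenario preincubation --seed 1 --out run1
dporkin unmix --spectra run1/spectra.csv --refs run1/references.csv --out series.csv
dporkin fit --series series.csv --species ES --model auto --dead-time 10
```

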
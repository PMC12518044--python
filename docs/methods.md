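# Methods

## Spectral model and unmixing

Every recorded spectrum on the analysis window (600–700 nm by default;
the red Q-band region is preferred over the Soret region because it is
less affected by scattering from precipitating material) is modelled as

    f(λ) = p₁·S_S(λ−p₆) + p₂·S_P(λ−p₇) + p₃·S_ES(λ−p₈) + p₄ + p₅·λᵉ

with the reference spectra S_X stored at their recording concentrations
(S: 8 μM, ES: 3.5 μM, P: 5 μM, 1 cm path), so that c_X = p_X · c_ref,X —
mathematically identical to dividing fitted absorbance amplitudes by
molar absorptivities. Assumptions: Beer–Lambert additivity of the three
chromophores, band shapes independent of composition, and no long-lived
EP intermediate with its own spectrum.

Numerical choices:

* The solver is bounded trust-region nonlinear least squares
  (`scipy.optimize.least_squares`, ftol 1e-10, xtol 1e-13, max 500
  evaluations). With shifts fixed (the default, p₆=p₇=p₈=0) the model
  is linear and the Jacobian is the constant design matrix; the test
  suite requires agreement with a direct linear least-squares solution
  to 1e-8 relative on noise-free input.
* p₁–p₃ are bounded ≥ 0 by default (concentrations are physical); an
  unconstrained mode exists for diagnostics.
* The scatter exponent e defaults to +3, with −3 and −4 available for
  the physically motivated turbidity forms. Internally the scatter
  column is scaled by (λ/650)ᵉ for conditioning; the reported p₅ is in
  literal AU·nm⁻ᵉ units. Over a 600–700 nm window the scatter column
  and the constant baseline are strongly correlated, so p₄ and p₅ are
  individually soft but their sum (the total baseline) is well
  determined; concentrations are unaffected.
* Start values: p₁–p₃ from a nonnegative linear pre-fit, p₄ from the
  red-tail median, p₅ = 0; series fits warm-start from the previous
  spectrum. On convex noise-free problems warm starting changes
  iteration counts, not solutions.
* Free shifts are bounded by ±3 nm; a shifted reference leaving the
  grid is clamped to its edge value and the result flagged. A shift
  belonging to an absent species (zero amplitude) is unidentifiable and
  its value meaningless — shifts should be freed only when all species
  are present.
* Non-convergence never raises: the per-spectrum result carries
  `converged=False` and series assembly preserves the flag.

Reference preparation: raw single-species spectra are smoothed with a
cubic smoothing spline whose roughness penalty is chosen by generalized
cross-validation (`scipy.interpolate.make_smoothing_spline`); an
explicit penalty can be supplied, and 0 disables smoothing. The spline
degree/criterion is a package decision — any smoother that preserves
the band shapes works, since the same references are used for
generation and unmixing in validation. The ES extinction coefficient
can be recalibrated by a single scalar α (assumed wavelength
independent) chosen to minimize the relative standard deviation of
c_S + c_ES across a donor-free series — a scale-free objective robust
to the absolute concentration; α outside [0.2, 5] or a calibrated total
off the stated Pchlide amount by more than 5 % signals inconsistent
references and raises instead of returning.

## Kinetic models

Traces are fitted unweighted (matching common graphing-software
defaults; inverse-variance weights optional) with:

* one-phase: y(t) = y₀ + (plateau − y₀)(1 − e^(−kt))
* two-phase: y(t) = y₀ + span_f(1 − e^(−k_f t)) + span_s(1 − e^(−k_s t)),
  parameterized as (k_slow, ratio ≥ 1) so k_fast ≥ k_slow holds by
  construction and label switching cannot occur. Span collapse
  (either span < 1e-6 of the total) or ratio pinned at 1 flags the data
  as effectively one-phase.
* linear initial-rate fits over a caller-chosen window, reported in
  μM s⁻¹ and (given the assay volume, 2 mL by default in the
  scenarios) nmol s⁻¹.

Time zero is the mixing event (reagent addition); the first ~10 s are
unobservable and are truncated, not deconvolved, and y₀ is always
fitted because the first observed point is not the true start. For a
one-phase truth at k ≈ 0.023 s⁻¹ sampled every 5 s, removing t < 10 s
biases the recovered k by well under 5 % (tested). Model choice uses
AICc with a "simpler model within 2" tie rule. Fits use lmfit
(Levenberg–Marquardt, xtol/ftol/gtol 1e-12); standard errors come from
the fit covariance, with the k_fast error propagated from the
(k_slow, ratio) covariance.

## Mechanism simulator

The core scheme is E + S ⇌ ES → E + P, where E is a Pchlide-binding
site (two per BchNB tetramer), integrated with LSODA at rtol 1e-10 /
atol 1e-12 so that mass conservation (S + ES + P = S_total; free +
complexed + blocked sites = E_total) holds to ~1e-9 relative, as the
conservation tests demand. Units: μM, s, μM⁻¹s⁻¹.

Extensions, all phenomenological and chosen to reproduce observed
progress-curve shapes without claiming mechanism:

* **Site pools** split E_total into classes with independent k_cat
  (and optionally k_on/k_off). Two equal pools with distinct catalytic
  constants generate exactly biphasic product formation when sites are
  saturated (spans = pool occupancies) — verifiable against the
  two-phase closed form.
* **Two-site sequential (Adair-type) model**: an explicit 6-state
  machine over site pairs (s substrates, p products bound; s + p ≤ 2)
  with macroscopic first/second binding constants k_on1/k_on2. With
  k_on1 ≫ k_on2 the bound-substrate trace is biphasic with rates
  ≈ k_on1·S and k_on2·S — the cooperative-binding scenario. Catalysis
  converts each bound substrate independently at k_cat.
* **Single-turnover mode** (`release_product=False`): a site that
  converts its substrate retains the product and is blocked. This is
  the simplest hook for the observed stalling of turnover (product
  plateau while free substrate remains, ES decaying toward zero) and
  makes the product trace follow the association closed forms with the
  catalytic constants exactly. The default (`True`) is the classic
  catalytic cycle.
* Super-stoichiometric ES plateaus can be emulated by adding a
  nonspecific-site pool with its own k_on and k_cat = 0; the canonical
  presets do not include one.

Event sequences (stage lists) carry concentrations across boundaries;
patches may change rate constants (donor addition sets k_cat > 0) or
inject substrate/enzyme as step increases in that species only.

`pseudo_first_order_kobs` returns k_on·S_total + k_off, the expected
one-phase constant when S ≫ E and k_cat = 0; at S_total = 20×E_total
the simulated ES trace stays within 1 % of E_total·(1 − e^(−k_obs t)).

## Synthetic experiments

The generator emulates the in-situ measurement: Gaussian Q-bands
(σ = 12 nm, a package default — any smooth unimodal shape works because
the same reference set is used to generate and to unmix; peak
absorptivities 23.4 / 31.1 / 44.7 mM⁻¹cm⁻¹ at 651 / 633 / 670 nm for
S / ES / P), concentrations from the mechanism simulator, plus a
constant baseline offset (0.002 AU), optional linear drift, a
λ-power scattering term (≈0.005 AU at 650 nm with exponent 3), and
additive Gaussian noise (0.002 AU, small relative to the 0.1–0.9 AU
signals but non-trivial for fitting). Spectra within the 10 s dead
time of each stage's mixing event are omitted. Output is
bit-reproducible under a fixed seed. Optional Soret-region bands
(440–500 nm) can be emitted but lie outside the default window.

Four presets mirror the published experiment layouts at 20 μM Pchlide,
parameterized by the observed rate constants they emulate (one table,
`OBSERVED_RATE_CONSTANTS`), using k_on = k_obs/S_total with k_off = 0:

| preset | layout | observables emulated (×10⁻³ s⁻¹) |
|---|---|---|
| `preincubation` | 1 μM sites; 600 s no donor, then 1200 s donor | k_ES 23; k_P 4 / 0.6 |
| `pchlide_initiated` | single 1200 s turnover stage | k_ES 230; k_P 12.2 / 1.2 |
| `bchnb_initiated` | single 1200 s turnover stage | k_P 9 / 1 |
| `high_enzyme` | 4 μM sites, two-site binding 1200 s, then 120 s donor (2 s sampling) | k_ES 18 / 2.2; k_P 132.2 |

What the generator does **not** emulate: super-stoichiometric ES
plateaus (nonspecific binding), product-release deceleration beyond the
binary single-turnover switch, wavelength-calibration drift,
photobleaching, or real band asymmetries. Passing recovery tests
therefore demonstrates that the analysis chain is unbiased and
correctly propagates noise under Beer–Lambert conditions with known
band shapes — not that real instrument data would yield identical
constants.

Two systematic effects are visible in recoveries and are properties of
the study conditions, not estimator defects: substrate depletion (1 μM
bound of 20 μM) lowers the fitted pre-incubation k_ES by ~3 % relative
to k_obs, and at the 0.002 AU noise level the per-seed scatter of that
constant sits at its Cramér–Rao bound (~7×10⁻⁴ s⁻¹ for 5 s sampling
over 600 s with a 10 s dead time).

## Endpoint assays

Chlide is quantified from A666 (ε = 74.9 mM⁻¹cm⁻¹ in 80 % acetone;
Pchlide from A626 with ε = 30.4). The no-enzyme control is subtracted
at the absorbance level (equivalent to subtracting concentrations, by
linearity); a control exceeding the sample floors activity at zero and
flags the record. The quench dilution (default 5×: 100 μL reaction +
400 μL acetone) converts quench concentration to reaction amount.
Turnover frequency is specific activity × molar mass (206 kDa for
BchNB): 3.01 nmol min⁻¹ mg⁻¹ → 0.620 min⁻¹ = 37.2 h⁻¹. The per-hour
basis is reported explicitly because it is the only basis on which
that widely quoted pairing of numbers is dimensionally consistent;
results carry both min⁻¹ and h⁻¹ fields so no ambiguity propagates.

## Problem sizes

The validation suite and the acceptance script use 50 seeded replicates
per scenario (118–240 spectra each, 101 wavelengths), sizes at which
the medians of recovered constants are stable to well under the
published uncertainties while a full run stays around a minute on one
CPU.

## Known limitations

* Each spectrum is fitted independently; no global spectrotemporal
  analysis.
* No EP-complex species; biphasic behaviour is emulated, not derived
  from a microscopic cooperative mechanism.
* k_on/k_off are not separately identifiable from the emulated
  observables (only their pseudo-first-order combination); the
  simulator exposes them for forward studies.
* The cooperativity presets do not reproduce the observed
  super-stoichiometric ES plateau or the stalling of turnover at low
  substrate beyond the single-turnover approximation.
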
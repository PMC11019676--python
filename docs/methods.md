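# Methods

## Problem and scope

`eemquant` models a miniaturised fiber-optic probe that quantifies three
fluorophores — NADH, FAD and protoporphyrin IX (PpIX) — inside a turbid
liquid tissue phantom, and implements the analysis chain that recovers their
concentrations from the probe's raw measurements.  The instrument emits
eight pulsed sources (300, 340, 390, 440, 470, 515, 590 and 680 nm) and
records, per sample, nine illumination states: one dark state capturing the
ambient background, then one state per source.  Each state yields a
photodiode diffuse-reflectance (DRS) reading and eight SiPMT channel
voltages behind a multi-dichroic prism whose cut-offs coincide with the
source wavelengths.  The package contains a forward simulator of that
acquisition, the inverse pipeline (background subtraction → anti-Stokes
masking → DRS normalisation → PLS2 regression with leave-one-out
cross-validation), and characterisation diagnostics (crosstalk matrix,
excitation specificity, prediction independence, linear detector range).

## Forward model

**Light transport.**  Transport through the intralipid/ink phantom is
closed with a modified Beer–Lambert law: every path attenuates by
`exp(-mu_eff * rho)` with the diffusion-theory effective attenuation
coefficient `mu_eff = sqrt(3 mu_a (mu_a + mu_s'))` and a fixed effective
path `rho` per collection geometry (`sd_separation_fluor = 0.05 cm` for the
tightly packed fluorescence fibres, `sd_separation_drs = 0.15 cm` for the
offset DRS fibre).  This is the simplest closure that reproduces the
attenuation phenomena the analysis must cope with; full radiative-transport
or Monte-Carlo simulation is deliberately out of scope.  The reference
medium is calibrated to `mu_s'(470 nm) = 8.3 cm⁻¹` at 4 % intralipid and
`mu_a(470 nm) = 0.32 cm⁻¹` at 0.5 % ink, both scaling linearly in their
volume fractions; scattering follows `mu_s'(λ) = mu_s'(470) (λ/470)^-2.4`
(a typical intralipid scatter power), and the ink spectrum is flat — India
ink is nearly grey over 300–700 nm and only one calibration point is
available.

Because the DRS fibre sits farther from the source than the fluorescence
fibres (`rho_drs > rho_fluor`), increasing the absorber fraction attenuates
the DRS reference faster than the fluorescence itself.  The Ex·Em
normalisation below therefore over-corrects, producing a residual,
monotonically increasing absorber dependence of the normalised response —
the over-estimation the absorber-series study is designed to expose — while
leaving linearity in concentration intact.

**Fluorescence.**  Excitation and emission spectra are peak-normalised
Gaussians (NADH 340/460 nm, FAD 450/525 nm, PpIX 405/635 nm; FWHM 60 nm
excitation, 80 nm emission — literature-typical shapes).  The pre-noise
SiPMT voltage for source s and channel c is

    FL(s,c) = Σ_f S_s · c_f · m_f · ε_f(λ_s) · QY_f · Φ_f(c)
              · exp(-mu_eff(λ_s) ρ_x) · exp(-mu_eff(λ_c) ρ_m) · g

with `ε_f` the excitation Gaussian, `Φ_f(c)` the emission fraction captured
by the 40 nm channel passband (an erf integral), `m_f` the per-fluorophore
response scale and `g` the detector gain.  The signal is exactly linear in
every concentration; fluorophore self-absorption (inner-filter effects) is
not modelled.  Matched (source, channel) designations follow the
instrument's channel assignment — NADH (340, 470), FAD (440, 590), PpIX
(340, 680) — not the spectral peaks; note the PpIX pair excites the 405 nm
absorption band only in its wing, so PpIX information travels mostly
through the 390/440 nm excitation rows, as it does on the bench.

**Detector and noise.**  The SiPMT gain maps the detector's linear range
(0.03–37 nW) onto ≈0–5 V (`g = 5/37 V/nW`), and every channel voltage is
clipped at `v_max = 5 V` — top clip only, so detector-noise negatives
survive into background subtraction.  Reflected excitation light reaching
the prism (`refl_excitation_gain = 50 nW` per unit source power, attenuated
over the round trip) passes the leakage matrix `L[channel, source]`:
the matched channel receives it in full (the 100 % reference, and the cause
of the saturated diagonal cells in the factorial EEMs — four of the eight
channels reach the 5 V ceiling under the default design, the regime the
analysis must tolerate), while fluorescence channels receive the small
characterised fractions (1×10⁻³ % at (340, 470), 2.5×10⁻² % at (440, 590),
2×10⁻³ % at (340, 680); other redward cells decay exponentially in spectral
distance, blueward cells carry the large short-pass leak but are masked
out).  Per illuminated state one lognormal flash factor (CV 0.02) scales
the DRS reading and all eight SiPMT voltages together — source fluctuation
is common to the flash — plus additive Gaussian detector noise
(sd 1e-4 V) and a constant ambient background (0.05 V) shared by all
states.  Molar response scales are calibrated so matched-pair fluorescence
at the top of the concentration ladders sits in the low-volt range, with
the two strongest FAD emission cells reaching the clip at the highest FAD
levels.

**Randomness.**  A run seed spawns one child stream per sample
(`SeedSequence.spawn`), so frames are bit-reproducible and extending a
design never perturbs earlier samples' draws.

## Phantom designs

* `fluorophore_factorial()` — the 5×5×5 factorial over NADH {0, 12.5, 25, 50, 100},
  FAD {0, 1.25, 2.5, 5, 10} and PpIX {0, 1.25, 2.5, 5, 10} µg/ml (n = 125)
  at fixed 0.5 % ink / 4 % intralipid.
* `absorber_series()` — 5 FAD levels × 4 ink fractions (0.5–4 %, doubling
  ladder; n = 20) at fixed intralipid, the absorber-dependence study.
* Fraction semantics: "intralipid (20 %)" and "ink (1 %)" are read as stock
  concentrations; the design columns store the volume fraction of stock
  added.  Both are configurable.

## Inverse pipeline

1. **Background subtraction** — each detector's dark value is subtracted
   from that detector's reading in every illuminated state; adding any
   constant to a whole frame is exactly invisible downstream.
2. **Masking** — pairs with channel centre below the source wavelength
   cannot carry Stokes-shifted fluorescence and are dropped, keeping
   k(k+1)/2 = 36 of the 64 cells.  The 300 nm excitation row is retained
   (the 36-column layout requires it); a drop-list is configurable.
3. **Normalisation** — `nFL = FL / (Ex · Em)`, with Ex the DRS reading
   under the pair's source and Em the DRS reading under the source whose
   wavelength equals the channel centre (source and channel wavelengths
   coincide by construction; this is the only reading that yields a fully
   normalised 36-column matrix).  The division compensates phantom
   attenuation at both wavelengths and cancels the flash factor shared
   between FL and Ex.  Non-positive DRS readings invalidate the sample row,
   which is excluded with a warning rather than imputed; saturated cells
   are flagged and carried through as-is.
4. **Regression** — NIPALS PLS2 on mean-centred X (125×36) and Y (125×3).
   No unit-variance scaling by default: the features share units after
   normalisation (autoscaling is a flag).  NIPALS tolerance 1e-10, max 500
   iterations, deterministic initialisation from the residual-Y column of
   largest variance; exhausted residuals terminate extraction early instead
   of failing.  LOOCV refits the model n times; one k_max-component fit per
   fold supplies nested predictions for every smaller k.
5. **Component selection** — smallest k with
   `(MSE(k) − MSE(k+1)) / MSE(1) < tau`, default `tau = 0.01`; the MSE is
   the LOOCV mean over rows and responses on natural concentration scales.
   On the default factorial the rule lands on k = 4: three components carry
   the three concentrations and the fourth mops up the saturation
   nonlinearity of the clipped FAD cells.
6. **Metrics** — per-response coefficient of determination (R²) of the
   LOOCV predictions; squared Pearson correlation is also available but R²
   is the headline number.

## Characterisation

* **Crosstalk** — per source, background-subtracted channel values on a
  fluorophore-free standard, as a percentage of the matched channel
  (100 % by definition; the only convention that makes "leakage into
  fluorescence channels" well defined).  A noiseless round trip recovers
  the configured leakage matrix to machine precision.
* **Specificity** — least-squares slope of intensity vs concentration per
  (fluorophore, pair); pairs are flagged responsive when the slope exceeds
  3 standard errors (the paperless operationalisation of "significant").
* **Independence** — slope of LOOCV-predicted f1 against true f2 over the
  factorial; balance makes these exactly zero for any prediction that
  depends only on its own target.
* **Linear range** — longest contiguous sweep segment within 5 % of the
  line fitted to the central decade of the sweep (5 % and "central decade"
  are this package's criteria; only the range endpoints are externally
  specified).

## Problem sizes and runtime

All studies run at their natural sizes (125- and 20-sample designs, 36
features, LOOCV with k_max = 8); the complete test suite and the
acceptance script each finish in seconds on one CPU.

## What the simulator does and does not show

The generator reproduces the measurement structure: linear
concentration response, attenuation and its residual after normalisation,
illumination-leakage crosstalk, shared-flash noise, ambient background and
detector saturation.  It does not model photobleaching, fluorophore
self-absorption, spectral calibration error, probe-contact variation, or
real tissue heterogeneity — so recovery scores here are upper bounds on
bench performance, and passing tests demonstrate correctness of the
analysis chain, not field accuracy of the instrument.

## Known limitations

* The Beer–Lambert/mu_eff closure is a far-field approximation; at
  source–detector separations of ~1 mm it is qualitative, which is
  acceptable because the pipeline only requires monotone, wavelength- and
  absorber-dependent attenuation.
* The elbow rule's selected k depends on the noise and saturation regime;
  `tau` is exposed for other regimes.
* Saturated cells are used as-is in the regression (matching bench
  practice); heavily clipped designs degrade FAD recovery first, since its
  brightest emission cells clip first.
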
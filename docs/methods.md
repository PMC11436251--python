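# Methods

`glucosens` evaluates how sensitively near-infrared (NIR) diffuse
reflectance from human skin responds to blood glucose, over the
1000–1700 nm band and source–detector separations (SDS) of 1.7–2.9 mm.
This note documents the models, the defaults and why, the numerical
choices, and the limits of what the synthetic experiments can show.

## Physical model

Light entering skin is attenuated by absorption (`mu_a`, mm⁻¹) and
redirected by scattering (`mu_s`, mm⁻¹, with anisotropy `g`). The
detected fraction `I/I0` at an SDS `r` defines the absorbance
`A(r) = −ln(I/I0)` (arbitrary units, a.u.). Glucose perturbs both
coefficients, so the absorbance sensitivity decomposes as

    S_A = dA/dCg = (∂A/∂mu_a)(dmu_a/dCg) + (∂A/∂mu_s)(dmu_s/dCg)
        = S_mua + S_mus

with `Cg` the glucose concentration in mmol/L. The dominant in-vivo
effect is refractive-index matching: glucose raises the refractive
index of the interstitial fluid toward that of the cellular scatterers,
lowering `mu_s`. For spherical scatterers, `mu_s' = K (n_s/n_0 − 1)²`,
whose logarithmic derivative with respect to the medium index is
independent of `K`; since both the index contrast and `dn_0/dCg` are
nearly flat over the NIR window, the *relative* scattering change per
mmol/L, `rho = (dmu_s/dCg)/mu_s`, is treated as one wavelength-flat
scalar. Measured at a single anchor wavelength (1314 nm, chosen for its
weak glucose/water/hemoglobin absorption), it extends to the whole band
by multiplying the `mu_s(λ)` spectrum. Anisotropy is taken
glucose-invariant, so the relative change of `mu_s` equals that of
`mu_s'`.

## Photon transport

`photon_transport` implements a weighted-photon Monte Carlo in
plane-parallel layers (MCML-style): dimensionless step sampling with
optical-depth carry-over across boundaries, weight attenuation by the
single-scattering albedo, Henyey–Greenstein direction sampling,
unpolarized Fresnel reflection/refraction with total internal
reflection at index mismatches, and Russian roulette (threshold 1e-4,
survival 0.1) for low-weight photons. Exiting photons are tallied into
annular rings (half-width 0.15 mm, centers 1.7/2.0/2.3/2.6/2.9 mm) by
exit radius. Runs are split into batches (default 10) with child seeds
derived from one master seed via `numpy.random.SeedSequence`; the batch
spread yields the standard error reported with every tally, and
identical inputs give bit-identical records.

Two deliberate idealizations: the source is index-matched into the
glass window and the detector is index-matched at the glass top, so no
specular or detection Fresnel loss occurs there. These constant
multiplicative losses would cancel in every derivative and differential
quantity the pipeline reports, so omitting them changes nothing
downstream while keeping `A(r)` well-defined. Roulette-killed weight is
not tallied anywhere: the survivors' 1/p boost compensates in
expectation, so energy conservation
(reflectance + transmittance + absorption + specular = 1) holds
statistically, and is asserted within 3 batch standard errors.

The engine is validated against the closed-form steady-state diffusion
approximation (dipole solution with extrapolated boundary) on a
semi-infinite homogeneous medium with `mu_s'/mu_a = 50`: ring
reflectance agrees within 15% for SDS ≥ 2 mm, the expected accuracy of
the diffusion formula at a few transport mean free paths.

## Tissue model and bundled tables

The skin is three layers under a 0.2-mm glass window (n = 1.4):
epidermis 0.1 mm, dermis 1.0 mm, subcutis 10.0 mm. Per-wavelength
properties come from a bundled CSV table
(`wavelength_nm, layer, mu_a_mm-1, mu_s_mm-1, g, n`; 10-nm grid,
1000–1700 nm, linear interpolation between nodes, exact at nodes). The
dermis row at 1314 nm is pinned to `mu_a = 2.05 mm⁻¹` and
`mu_s = 13 mm⁻¹`; all other entries are *representative*: a water-shaped
absorption curve plus a flat background, scattering following a
`1/λ` Mie-like power law, `g = 0.9` and `n = 1.4` throughout. They are
package data, regenerable with `scripts/make_tables.py`, and any run
can substitute its own table via configuration. Every band-shaped
output (sensitivity spectra, floating-reference positions per
wavelength) inherits the uncertainty of these representative entries;
the anchor-wavelength results do not.

A homogeneous semi-infinite 2% intralipid phantom is bundled likewise
(van Staveren-shaped scattering, water absorption, n = 1.33), with its
glucose response fixed at the phantom literature value
`rho = −0.02%` per mmol/L.

## Sensitivity estimation and inversion

`∂A/∂mu_s` and `∂A/∂mu_a` are slopes of ordinary-least-squares lines
fitted to `A(ring)` across parameter sweeps of the dermis only
(`mu_s ∈ {5,7,9,11,13} mm⁻¹`; `mu_a` = baseline + {0,…,1} mm⁻¹), one
seeded MC run per sweep point. Unweighted OLS is used: the MC standard
errors are near-homoscedastic across the sweep.

The differential absorbance uses the ring pair `(r_A, r_B) = (2.0, 1.7)`
mm, i.e. `A_D = A(far) − A(near)`. With this ordering the three
reference quantities are sign-consistent: simulated `dA_D/dmu_s ≈
+0.0102 a.u.·mm⁻¹`, measured `dA_D/dCg ≈ −0.00039 a.u./(mmol/L)`, and
their quotient `dmu_s/dCg ≈ −0.038 mm⁻¹` per mmol/L. The roles are
configurable; swapping them flips the sign of both numerator and
denominator, so only the quotient's sign is physically meaningful.
Dividing by the dermis reference `mu_s = 13 mm⁻¹` gives
`rho ≈ −0.29%` per mmol/L, about 14.5× the intralipid phantom response
(the ratio is quoted from the rate at its two-decimal printed
precision, the field's convention).

The inversion refuses differential slopes below 1e-4 a.u.·mm⁻¹: near a
floating-reference ring pair the quotient explodes and no calibration
is possible. Uncertainty propagates first-order: the quotient's
relative uncertainty is the root-sum-square of the inputs', verified
against a resampling oracle.

`floating_reference` interpolates `S_A` linearly across the SDS grid
and reports the zero crossing per wavelength, or absence; it never
extrapolates outside [min SDS, max SDS].

## Synthetic OGTT cohort

The generator emulates a 25-subject oral-glucose-tolerance-test study:
groups elderly-male/elderly-female/young-male/young-female split
6/7/6/6; 13 samples at exactly 10-min spacing over 120 min. The glucose
excursion is a gamma-type kernel
`baseline + amplitude (t/t_p)^(t_p/τ) exp((t_p−t)/τ)` — fasting
baseline at t = 0 (default 5.2 mmol/L, jittered per subject), peak of
`baseline + amplitude` at `t_p` (defaults 3.5 mmol/L at 40 min), tail
timescale τ (default 45 min). The optical response is affine:
`A_D = offset + s·Cg + drift·t + N(0, noise_sd)`.

Cohort-mean true sensitivity at 1314 nm is −0.00039 a.u./(mmol/L) and
at 1550 nm −0.00107 (the reference cohort means); the other four
instrument wavelengths carry representative values preserving the
longer-wavelengths-stronger ordering. Between-subject spread is a
lognormal factor with CV 25%, shared across wavelengths (skin structure
affects all wavelengths together). `noise_sd = 3.0e-4 a.u.` was
calibrated once by a seed-pinned pilot (400 synthetic subjects) so the
cohort-mean |Pearson R| at 1314 nm is ≈ 0.79; per-subject drift rates
are N(0, 1e-6) a.u./min.

What passing tests show: the estimation pipeline is consistent
(noise→0 and dense-sampling limits recover truth), unbiased at cohort
scale (mean estimate within 2 SE of generator truth over ≥200
subjects), correctly calibrated under the null (95% CI coverage), and
produces the intended correlation level. What they do not show:
anything about real skin — the generator has no physiological lag
between blood and interstitial glucose, no temperature, posture,
hydration or sweating confounders, Gaussian independent noise rather
than structured instrumental drift, and an exactly linear A_D–Cg
response.

## Problem sizes and numerical choices

Anchor-wavelength sweeps default to 1e7 photons per run (the
reproduction script uses 2e7 per sweep point, putting the Monte Carlo
error of the differential slope near 8% of its value); band-grid
sweeps default to 2e5 photons at a coarse 100-nm step plus the six
instrument wavelengths, enough for spectrum shapes but not for
publication-grade error bars. Rings that collect zero weight are
flagged and absorbance on them raises with the photon count named as
the remedy. All stages exchange data only through serialized CSV/JSON
artifacts, so a deleted late artifact regenerates without re-running
upstream stages, and a full rerun with the same configuration is
byte-identical.

## Known limitations

- Band-shaped outputs depend on representative (not literature-exact)
  optical tables; only the 1314-nm anchor values are pinned.
- The diffusion oracle itself is approximate at SDS of a few transport
  mean free paths; the 15% agreement band reflects both errors.
- The Mie medium defaults (n_s = 1.45, n_0 = 1.35, dn_0/dCg = 2.5e-5)
  are illustrative; the pipeline relies only on the K-independence and
  near-constancy of the relative change, not on their absolute values.
- Group-level cohort scenarios (e.g. higher female scattering) are
  generator multipliers for recovery testing, not physiological claims.
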
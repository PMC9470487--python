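# Methods

This note documents the models, conventions and design choices behind
`elytherm`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Band-weighted optics

Reflectivity and transmissivity are source-weighted band means,
`∫ I F X dλ / ∫ I F dλ`, with X the reflectance E(λ) or transmittance S(λ)
spectrum in percent; absorptivity is the complement A = 100 − (T + R).
Consequences worth noting:

* **Energy closure is exact by construction** (R + T + A = 100); the tests
  treat any drift beyond 1e−9 as a numerics bug.
* **Partition mixture.** When the same filter applies across bands, the
  TOTAL value is the ∫IF-weighted mean of the VIS and NIR values; this is
  used as an internal consistency check.
* **Quadrature.** All three spectra are linearly interpolated onto a common
  grid (default 1 nm) spanning the band. Within a cell each interpolant is
  linear, so their product is at most cubic; cells are integrated with
  two-point Gauss–Legendre quadrature, which is *exact* for cubics. The
  band value is therefore the exact integral of the gridded interpolants —
  plain trapezoid on the product would carry an O(h²) error of order 1e−4,
  visible against a fine-grid oracle. Grid refinement consequently changes
  results only through interpolation of sub-grid structure.
* **Step filters as data.** Ideal band-pass edges are represented as data
  points (1-nm ramps); there is no special edge handling beyond linear
  interpolation. A filter whose support lies inside a band makes
  integration over a wider band identical to integration over that band.
* **No clamping.** Percent values outside [0, 100] (calibration artifacts)
  are retained and flagged (`values_outside_0_100`,
  `out_of_physical_range`), never silently clipped; QC flags propagate to
  the optics table.
* **UV (< 400 nm) is excluded by construction**: bands start at 400 nm and
  the shipped irradiance stand-in is only evaluated where a band requests
  it.
* The **irradiance spectrum is an input**. The bundled stand-in (a 5800-K
  Planck curve scaled so the 400–1700 nm band carries 500 W/m², i.e. 0.5
  Sun) is a smooth synthetic surrogate for a solar-simulator calibration
  table; any measured or AM1.5-like two-column table can be substituted.
  Because published "percent of solar energy in band X" figures depend on
  both the reference spectrum and the denominator range,
  `band_energy_fraction` exposes the denominator as an explicit choice
  rather than hard-coding one.

## Heating metrics

Trials follow the seven-phase cycle (cool, TOTAL, cool, NIR, cool, VIS,
cool; nominally 300 s per phase, 20-s logging).

* **Segmentation.** A sample on a shared phase boundary belongs to the
  later phase; each slice is padded with the first sample at/after its end
  so the 300-s mark can always be bracketed.
* **ΔT₅ baseline.** Default: the phase's first sample ("phase_onset").
  Alternative: the mean of the last three samples of the preceding cooling
  phase ("cooling_plateau"), useful when cooling does not quite return the
  sample to the chamber temperature. The rule used is logged with every
  run; with well-equilibrated cooling the two agree closely.
* **The 300-s value** is taken from a sample within ±1 s of onset + 300 s,
  else linearly interpolated from bracketing samples (robust to logger
  jitter).
* **maxHR** is the maximum of raw adjacent-sample slopes using the actual
  timestamp gaps — deliberately unsmoothed, because the metric is defined
  on the raw logger output; this fine-scale derivative is intrinsically
  noisy, which is exactly why its repeatability is expected to be lower
  than ΔT₅'s. Ties go to the earliest pair; a monotone cooling slice
  yields a negative maximum, by contract.
* **Reference channels** (chamber, water bath) can be QC-checked: drift
  beyond 0.5 °C within a trial is flagged.

## Statistics

* **Heating models** are OLS with additive terms
  `absorptivity + size + side` and no interactions: under even
  illumination, absorbed power is additive in absorptivity per unit area
  and exposed area, so no a-priori interaction exists. `side` (platform
  left/right) is a two-level fixed effect with reference `left`. Partial
  R² uses the extra sum of squares when the term is added last, over the
  total SS; partial R²s add to the overall R² only under orthogonality,
  which is not forced. Residual normality is summarised (Shapiro–Wilk)
  rather than gate-kept.
* **Pearson correlations** use the product-moment formula, Fisher-z 95%
  CIs and the two-sided t test on n−2 df. |r| = 1 is returned with a
  degenerate-CI flag.
* **Repeatability** fits the one-way Gaussian random-intercept model by
  maximum likelihood, with the grand mean profiled out and two variance
  parameters (log σ²_e, σ²_g ≥ 0) optimised directly — written in-house
  because it must be refit thousands of times inside the parametric
  bootstrap; for balanced designs the optimum has a closed form
  (σ̂²_e = MSW, σ̂²_e + n₀σ̂²_g = SSB/k) used as an independent oracle in
  the tests. The 95% CI is a percentile interval over parametric-bootstrap
  refits (default 1000); the p-value is an LRT of σ²_g = 0 against the
  boundary mixture ½χ²₀ + ½χ²₁. Note the mixture gives p an atom at 1
  under the null — p-values are valid (size ≈ α at small α) but not
  globally uniform. The reported CI is clipped to contain the point
  estimate. Singleton groups are dropped with a warning.
* **Paired bootstrap.** D_i = ΔT₅(closed) − ΔT₅(open); individuals are
  resampled with replacement (default 10 000) and the CI is the *expanded*
  percentile interval: percentile levels widened by the t-versus-z and
  n/(n−1) small-sample corrections (Hesterberg's adjustment). At the
  n ≈ 11 scale of elytra-open/closed experiments the plain 2.5/97.5
  interval covers a true mean only ≈ 91–92% of the time, while the
  expanded interval restores ≈ 95%; the plain interval remains available
  via `method="percentile"`. The sign convention makes a negative interval
  mean "the body heats more when the elytra do not cover it".
* **No multiple-testing correction and no phylogenetic correction** are
  applied: the analyses mirror a design in which heating is a physical
  consequence of optics rather than an independently evolving trait.
  Users running many bands/responses should interpret marginal p-values
  accordingly.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical and physical structure* the
analysis assumes, at the published study scale: 28 species × 2 specimens,
lengths 1.6–3 cm, platform side alternating, 1-nm spectra on 400–1700 nm,
and the seven-phase trial sampled every 20 s.

* **Spectra** come from four smooth optical families (broadband metallic,
  narrowband green, melanin brown, high-NIR transmitter) with species-level
  parameter draws and small within-species jitter, spanning roughly
  5–30% VIS reflectivity, 25–90% NIR reflectivity and up to ≈ 55% NIR
  transmissivity, with E + S ≤ 100 enforced pointwise (parameters implying
  a violation error out before generation; measurement noise is clipped
  against the bound).
* **Traces** follow the single-compartment (lumped-capacitance) balance —
  the minimal model producing the observed saturating curves — with the
  analytic solution sampled directly (no integrator error) plus iid
  Gaussian logger noise (default 0.05 °C, which realistically degrades
  maxHR repeatability more than ΔT₅'s). Under a band filter the incident
  power density is the band's share of the source output, so VIS/NIR
  phases heat less than TOTAL, as in real trials.
* **Thermal constants.** Exposed area comes from body length via an
  ellipse of fixed aspect 0.55 (elytral shape is conserved in this group).
  Heat-loss conductance is h = h₀ + h_areal·area with h₀ = 0.008 W/°C
  (fixed paths: thermocouple contact, mount) and h_areal = 40 W·m⁻²·°C⁻¹;
  heat capacity is C = 6000 J·m⁻²·°C⁻¹ × area, giving τ ≈ 55–100 s.
  These were chosen once, from the analytic formulas, so that the cohort
  spans ΔT₅ ≈ 0.7–5.3 °C and maxHR ≈ 0.01–0.1 °C/s over the realistic
  absorptivity and size ranges — the scale of real single-elytron
  experiments at 0.5 Sun. The partly-fixed conductance is what lets size
  influence ΔT₅ (ΔT∞ = (A/100)·I·area/h grows with area when h does not
  scale fully with it).
* **Ground truth** (per-band A, ΔT∞, τ, constants, incident power) is
  emitted alongside the data for parameter-recovery tests; pipeline
  absorptivities equal generator absorptivities because both use the same
  band integrals — disagreement signals a quadrature bug, not biology.

Not emulated: iridescence/angular effects, multilayer interference, UV,
chamber drift, logger dropout, conduction/convection structure, or
mid-/long-wave emissivity. Passing tests therefore certify the
computational pipeline under idealised measurements, not instrument
behaviour or real cuticle optics.

## Pipeline and reproducibility

Runs are configured by a validated `RunConfig` (YAML-loadable, CLI-
overridable), serialised into every results bundle. All bootstrap seeds
derive deterministically from the run seed; reruns with the same inputs,
config and seed produce byte-identical CSVs. Specimens with missing or
unusable data are skipped with a logged reason; QC warnings (out-of-range
absorptivity, reference-channel drift) go to the log at WARN level. The
species-level repeatability stage uses species as the grouping factor
(each with ≥ 2 specimens); with repeated trials of the same specimen the
same estimator applies with specimen as the group.

Problem sizes in the test suite and acceptance script (100 spectra, 10
oracle fixtures, 1000 traces, 200 Monte-Carlo repeatability replicates per
ICC level, 1000 paired datasets × 10 000 bootstraps, one 56-specimen
cohort) were chosen as the smallest scales at which the Monte-Carlo error
of each check is comfortably below its tolerance.

## Known limitations

* Hemispherical reflectance and directional transmittance are taken at
  face value; no BRDF or geometry corrections.
* The expanded percentile interval assumes approximate normality of the
  mean; for heavily skewed paired differences a BCa interval would be
  preferable (not implemented).
* Partial R² by extra SS is one of several conventions (semi-partial
  correlations differ); comparisons across software should check which is
  in use.
* The lumped-capacitance generator is a single compartment: it cannot
  produce the two-timescale curves of bodies with internal gradients.
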
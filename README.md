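# elytherm

Radiative heating of beetle elytra from band-weighted optical properties.

Many day-active beetles (e.g. Australian Christmas beetles, Rutelinae) face
intense summer radiation, and the optics of their elytra — how much visible
(VIS, 400–700 nm) and near-infrared (NIR, 700–1700 nm) light they reflect,
transmit or absorb — set how fast and how far they heat under the sun.
`elytherm` is a reusable pipeline for the laboratory version of that
question: given per-specimen reflectance/transmittance spectra, a light
source, band filters and thermocouple heating traces, it quantifies elytral
optics, extracts heating metrics, and runs the statistics that link them,
for ecophysiologists analysing integrating-sphere + solar-simulator
experiments.

## The quantities and models

**Band optics.** A reflectance spectrum E(λ) (percent, against a white
standard) is reduced to a scalar band reflectivity by weighting with the
source irradiance I(λ) and filter transmittance F(λ):

    R = ∫ I(λ) F(λ) E(λ) dλ / ∫ I(λ) F(λ) dλ

transmissivity T likewise with the transmittance spectrum S(λ), and
absorptivity by energy bookkeeping, A = 100 − (T + R). Bands are
VIS 400–700, NIR 700–1700, TOTAL 400–1700 nm.

**Heating metrics.** Thermocouple trials alternate 5-min illumination and
cooling phases (cool, TOTAL, cool, NIR, cool, VIS, cool; 20-s sampling).
Per illumination phase: ΔT₅ = T(onset + 300 s) − T(onset) (a proxy for the
steady-state excess) and maxHR = the maximum slope between adjacent samples
(°C/s).

**Statistics.** Additive OLS models `ΔT₅ (or maxHR) ~ absorptivity + size +
side` with per-term partial R² by extra sum of squares; Pearson correlations
with Fisher-z CIs; Gaussian repeatability R = σ²_group/(σ²_group +
σ²_residual) from a random-intercept model fitted by maximum likelihood,
with a parametric-bootstrap CI and a boundary-corrected (½χ²₀ + ½χ²₁)
likelihood-ratio test; and a paired bootstrap CI for the mean
within-individual difference D_ΔT = ΔT₅(elytra closed) − ΔT₅(elytra open),
where a negative interval excluding zero means the body heats more without
its elytra.

**Synthetic data.** A first-class generator emulates the study design:
1-nm spectra from four optical families (broadband metallic, narrowband
green, melanin brown, high-NIR transmitter) spanning realistic ranges, and
heating traces from a lumped-capacitance balance
T(t) = T_air + ΔT∞(1 − e^(−t/τ)) with ΔT∞ = (A/100)·I·S/h, τ = C/h, so the
whole pipeline runs and is testable without any instrument data.

## Worked example

```python
import elytherm as et

params = et.SpectrumFamilyParams(family="broadband_metallic",
                                 amplitude=70, baseline=10, noise_sd=0.3)
E, S = et.gen_spectrum_family(params, seed=42, label="demo")
irr, filters = et.default_irradiance(), et.default_filters()
for s in et.summarize_optics([("demo", E, S)], irr, filters):
    print(f"{s.band:6s} R={s.reflectivity_R:5.1f}%  "
          f"T={s.transmissivity_T:5.1f}%  A={s.absorptivity_A:5.1f}%")

hp = et.HeatSimParams.for_specimen(absorptivity_A=45.0, length_cm=2.2, noise_sd=0.0)
trace = et.simulate_heating_trace(hp, 320.0, seed=0)
print(f"dT5   = {et.delta_t5(trace):.2f} C over 5 min")
print(f"maxHR = {et.max_heating_rate(trace):.4f} C/s")
```

prints

```
VIS    R= 15.5%  T=  6.0%  A= 78.6%
NIR    R= 63.1%  T= 11.9%  A= 25.0%
TOTAL  R= 40.8%  T=  9.1%  A= 50.0%
dT5   = 2.82 C over 5 min
maxHR = 0.0330 C/s
```

The metallic specimen reflects four times more NIR than VIS energy, so its
absorptivity is low where most solar power resides; a 2.2-cm specimen
absorbing 45% of a 500 W/m² beam warms 2.8 °C in five minutes, essentially
its steady-state excess.

The same analysis from the shell, end to end on a synthetic cohort of
28 species × 2 specimens:

```sh
elytherm simulate --n-species 28 --seed 42 --out cohort/
elytherm all --input cohort/ --out results/ --seed 42
```

which writes `optics.csv`, `heating_metrics.csv`, `heating_models.csv`
(six models: 2 responses × 3 bands), `correlations.csv`,
`repeatability.csv`, `paired_bootstrap.csv` and a `results.json` bundle
recording the configuration and seeds. In `heating_models.csv` the
ΔT₅–TOTAL block shows a positive, highly significant absorptivity slope —
hotter elytra are the more absorptive ones, after controlling for size —
with size also positive, matching the physics planted by the generator.
Individual stages are available as `elytherm optics|heating|fit|correlate|
repeatability|paired`.

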
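# Methods

## Measurement chain

The ¹⁸O-water technique infers community growth from the incorporation of
¹⁸O from soil water into newly synthesised DNA. The chain implemented in
`soilcue.measurement` makes the following assumptions explicit:

- **Soil-water enrichment.** The realised at% ¹⁸O of the total soil water
  is a two-pool mass balance of native water (natural abundance, default
  0.2005 at%, VSMOW) and added label. We normalise DNA enrichment by this
  *realised* mixing value rather than the nominal 25 at% target, because
  the realised value is what the microbes experienced; the inverse helper
  `label_enrichment_for_target` supports assay planning and the simulator.
- **Fraction of new DNA.** `f = (at%_DNA,labelled − at%_DNA,control) /
  (at%_water − at%_natural)`. The at% excess of the *measured*
  natural-abundance control (not the nominal constant) is used in the
  numerator, so any extraction-induced offset cancels. No isotope
  fractionation or DNA-extraction-efficiency correction is applied.
- **Oxygen-to-DNA conversion.** Average DNA is 31.21 % oxygen by weight;
  oxygen incorporated into new DNA divided by 0.3121 gives µg new DNA.
  `total_oxygen` input is expected already scaled from the dried IRMS
  aliquot to the whole extract per g dry soil; no blank correction for
  residual water in the aliquot is applied.
- **Respiration.** Two-point headspace CO₂ with a correction for the air
  withdrawn at t₀ and replaced by air of known CO₂ concentration: the
  effective start concentration is the volume-weighted mixture. ppm → µg C
  uses the ideal gas law at 1 atm (pressure overridable) and the
  incubation temperature.
- **MBC.** Chloroform fumigation–extraction with extraction-efficiency
  factor k_EC = 0.45 (overridable per sample).
- **Dry-mass basis.** dry mass = fresh mass × (1 − gravimetric water
  content, g water per g *fresh* soil). All per-DM rates use it.

**QC policy.** Instrument noise can produce physically impossible
intermediate values: negative isotope excess (negative DNA production),
negative fumigation differences (negative MBC), or CO₂ depletion. These
are returned *as computed* and tagged with QC flags
(`NEGATIVE_DNA_P`, `NEGATIVE_MBC`, `NEGATIVE_RESPIRATION`,
`MISSING_*`, `UNDEFINED_CUE`) rather than clipped or dropped in place;
CUE is only defined for G ≥ 0, R ≥ 0, G + R > 0. The statistics exclude
flagged rows by default (`qc.drop_flagged`), keeping every exclusion
auditable in `physiology.csv`.

## Experimental design

The layout crosses warming {0, +1.5, +3 °C} with CO₂ {0, +150, +300 ppm}
(a 3 × 3 surface-response grid) and shelters a subset of plots in the two
"corner" cells (ambient and +3 °C/+300 ppm). Defaults: 54 plots total, 34
analysed — 26 never-sheltered plots for the response surfaces plus 4 + 4
sheltered plots; the drought factorial comprises those 8 plus the 12
unsheltered corner-cell plots (20 in total). The exact per-cell replicate
numbers of the original field site are not published in machine-readable
form, so the default allocation (6 unsheltered analysed plots in each
corner cell, 2 in each of the other 7 cells) is a documented assumption,
fully overridable through `DesignConfig` / the `[design]` config section.

Coded units: eT = warming/1.5 − 1 and eCO₂ = co₂/150 − 1, mapping the
grid onto {−1, 0, +1}². This puts both factors on a comparable scale and
centres the quadratic surface; the coding is a package choice (the
alternative `physical_units` coding rescales coefficients but not tests).

## Synthetic-data generator

The simulator emulates the study top-down:

1. **Latent surfaces.** Per date, log G_m and log R_m follow the
   second-order polynomial in (eT, eCO₂). Default coefficients are
   field-plausible values for temperate managed grassland: May carries the
   full surface including an eT × eCO₂ interaction and curvature, July a
   warming-driven depression, October a modest warming stimulation.
   Intercepts (May −0.90, July −1.10, October −1.50 for log G_m;
   R_m intercepts 0.45 higher) put centre-of-design G_m near
   0.4 mg C h⁻¹ g⁻¹ MBC, declining through the season, with
   R_m/G_m ≈ e^0.45 ≈ 1.57 so that CUE sits near 0.39.
2. **Error structure.** Residuals are heteroscedastic by date
   (σ = 0.45 / 0.12 / 0.10 on the log scale — spring noisiest) and share a
   within-plot component across dates with correlation ρ = 0.3,
   implemented as ε = σ_d(√ρ·z_plot + √(1−ρ)·e). Sheltered plots receive
   additive July log-scale shifts (G_m: −0.15 ambient, +0.80 future
   climate; R_m: 0 / +1.0), i.e. drought accelerates metabolism only under
   the future-climate treatment. MBC and the DNA pool are lognormal
   (medians 600 µg C g⁻¹ and 40 µg DNA g⁻¹, log-SD 0.25).
3. **Instrument layer.** The latent physiology is inverted through the
   measurement equations into the five raw tables (IRMS, GC, CFE,
   fluorometry, gravimetry) under fixed bench constants (0.4 g fresh soil
   at 0.25 g/g water, 0.04 g label targeting 25 at% soil water, 25 ml
   headspace, 420 ppm ambient CO₂, 24 h). Noise defaults: IRMS 0.005 at%
   absolute, GC 1 % relative, EOC 5 % relative, DNA 5 % relative — chosen
   as typical instrument precisions and overridable. At zero noise the
   inversion is exact: `compute_physiology(latent_to_raw(L)) = L` to
   floating-point precision, which is the core correctness proof tying the
   two modules together.

Randomness: one root seed; each table draws from its own child stream
(PCG64 with a fixed spawn key), so adding a table never shifts existing
draws and equal seeds give byte-identical CSVs.

What the generator does **not** emulate: spatial layout and blocking,
within-day temperature dynamics, soil-moisture trajectories, community
composition shifts, correlated errors between the labelled and control
IRMS aliquots, or drift in any instrument. Passing tests therefore
demonstrate the correctness of the computational chain and the calibration
of the statistics under the assumed error model — not robustness to every
pathology of real field data.

## Statistics

- **Response surfaces.** OLS per date on the full second-order model;
  G_m and R_m on the natural-log scale (positive, right-skewed), CUE
  untransformed. Backward elimination drops, one at a time, the
  higher-order term (interaction or a quadratic) with the largest p-value
  above α = 0.05 and refits; the linear main effects and intercept are
  never dropped (marginality). Ties are broken by dropping the interaction
  first, then alphabetically — deterministic output.
- **Seasonal model.** Fixed effects: date (categorical), eCO₂, eT, eCO₂²,
  date:eCO₂, date:eT, eCO₂:eT, date:eCO₂:eT. Estimation is iterative
  feasible GLS: OLS start → per-date residual variances → correlation
  parameter from standardised within-plot residual products (all pairs for
  compound symmetry, lag-1 pairs for AR1) → blockwise-whitened GLS refit,
  iterated to a relative parameter change < 1e-8 (max 100 iterations;
  non-convergence raises with the iteration trace). ρ is clipped to keep
  the 3 × 3 block covariance positive definite. Structures {none, CS, AR1}
  are compared by Gaussian AIC (k = fixed effects + date variances + ρ).
  With three time points, richer structures (unstructured, continuous-time
  AR) are under-identified for this estimator and are deliberately not
  offered. Term tests are Wald F with denominator df = n − p; published
  nlme-style tables may differ slightly in df convention.
- **Drought factorial.** Two-way ANOVA (climate, drought, interaction)
  with Type-I SS in that order on the corner-cell subset, per date,
  log-transforming G_m/R_m (config `stats.anova_log`). Tukey's HSD uses
  the studentized-range distribution with the ANOVA residual MS/df and the
  Tukey–Kramer correction for unequal group sizes; the compact letter
  display uses insert-and-absorb, which guarantees that two groups share a
  letter exactly when they are not significantly different.

## Verification harness and problem sizes

The Monte-Carlo harness (`parameter_recovery_experiment`) runs the whole
chain — simulate → invert → measure → fit — per replicate. The packaged
checks use: 2000 replicates of a single date for the null (type-I)
simulation of the surface eT test, 500 replicates over all three dates for
95 % CI coverage per coefficient, 200 replicates for the seasonal date-term
power check, and 60 replicates × 3 noise levels (common random numbers)
for the noise-monotonicity property. These sizes give binomial Monte-Carlo
standard errors of ~0.005–0.01 on the estimated rates, comfortably inside
the asserted bands.

## Known limitations

- No uncertainty propagation from instrument noise to per-sample G/R/CUE
  (QC flags only); a delta-method extension would be natural.
- Growth is not corrected for DNA-extraction efficiency, and CUE follows
  the operational G/(G+R) definition — exudates and extracellular products
  count as neither growth nor uptake.
- The feasible GLS uses ML-style variance estimates (no REML correction);
  with 26 plots × 3 dates the difference is small but nonzero.
- The drought ANOVA treats plots as independent within a date; any
  within-season carry-over is handled only by the seasonal GLS.
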
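# Methods

## Scope and data model

The package analyses three assay layers of a phototoxicity screen —
singlet-oxygen chemistry (DMA probe), light dosimetry, and cellular
photo-cytotoxicity (SRB) — and combines them into per-extract calls. Plates
are represented as a validated layout (well → sample/arm/replicate) plus a
long-format table of absorbance readings indexed by well, wavelength and
cumulative light dose. All interchange formats are plain CSV (UTF-8, header
row, `.` decimals); well coordinates are the plate convention A1–H12.
Blank correction subtracts the mean blank OD per wavelength and dose step;
negative corrected ODs are kept (they carry noise information) but wells
below −0.01 OD are flagged.

## Dosimetry

Fluence is irradiance × time: the default schedule (468 ± 27.3 nm,
20.6 mW cm⁻², four 300 s steps) gives 6.18 J cm⁻² per step and
24.72 J cm⁻² in total, displayed at 0.1 J cm⁻² resolution (6.2 / 24.7).
Ferrioxalate actinometry converts moles of photoproduct to irradiance via
photon flux n/(Φ·t) and photon energy hc/λ; the ferrioxalate quantum yield
at the working wavelength is a parameter (default 0.9) because literature
values are wavelength-dependent. Field homogeneity is the CV (sample SD /
mean) of per-well doses over the inner 60 wells (rows B–G × columns 2–11,
the only contiguous 60-well interior of a 96-well plate); pass threshold
CV ≤ 10 % by default.

## DMA singlet-oxygen scoring

Per extract, four arms are read at 377 nm across the dose series: DMA +
extract (signal), extract alone (absorbance at 468 nm and spectral
evolution), DMA + extract + ascorbate (quench control), extract + ascorbate
(side-reaction control); the plate also carries a solvent control (direct
DMA photolysis) and the reference photosensitizer.

The bleaching signal ΔOD has three estimators:

* **endpoint** (default): OD(0) − OD(H_final) — the conventional "after
  20 min" readout;
* **slope**: −(least-squares slope vs dose) × H_final, more robust to
  single-read noise;
* **kinetic**: log-linear rate fit assuming first-order bleaching
  OD(H) = OD₀·e^(−κH), reporting OD₀·κ·H_final. Because the solvent
  signal subtracts at the rate level, this estimator recovers efficiency
  *ratios* exactly on noise-free first-order data, whereas the endpoint
  estimator carries a small saturation bias (≈ (κH/2)·(ratio − 1)
  relative, ~4 % at the default conditions).

The solvent-control signal is subtracted from sample, quencher and reference
signals, so an extract indistinguishable from solvent scores 0 %. The
relative yield is

yield % = 100 · (ΔOD_s / ΔOD_ref) · (f(A_ref) / f(A_s)),  f(A) = 1 − 10⁻ᴬ,

the standard relative-comparison method given the absorption-probability
correction; this exact algebraic form is the package's own choice (reported
descriptions of the assay state the correction but not a closed formula),
and every report header carries that caveat. The absorbances A are taken at
the irradiation wavelength from the extract-alone and reference arms at dose
zero. A transparent sample (A below the noise floor) with real bleaching is
rejected as inconsistent rather than scored.

Standard errors come from replicate aggregation (SE = SD/√n, triplicates by
default) propagated first-order through the ratio; the absorbance factors
enter multiplicatively and contribute negligibly at plate-reader SEs, so
they are not propagated.

Controls: quench ratio = ΔOD(with ascorbate)/ΔOD(without), defined as 1 when
there is no signal to quench; the ¹O₂ mechanism counts as confirmed when the
ratio ≤ 0.5 (default). A drift of the extract+ascorbate arm beyond 0.02 OD
flags a side reaction. An extract is DMA-positive when its yield is ≥ 5 % of
the reference *and* the quench is confirmed; 5 % sits just below the
smallest activity treated as minimal-but-real in comparable screens, and all
three cutoffs are configurable.

## Photo-cytotoxicity

SRB viability is normalized as 100·(OD − blank)/(untreated − blank). Each
arm is fitted with the four-parameter logistic
v(c) = bottom + (top − bottom)/(1 + (c/EC50)^h) on log₁₀ concentration with
`scipy.optimize.curve_fit`, multistart from three EC50 guesses (min,
geometric mean, max of the tested range), top bounded [80, 120] %, bottom
[−10, 40] %, Hill slope effectively unconstrained (log-parameterized,
10⁻³–50). A fit is **censored** — reported as "EC50 > max tested",
inactive — when the fitted EC50 exceeds the highest tested concentration or
the fitted span (top − bottom) is under 25 percentage points; a censored arm
never yields a point estimate. The activity cap defaults to 50 µg mL⁻¹.

The 95 % EC50 interval is a case-resampling bootstrap over replicates within
each concentration. Plain within-group resampling with triplicates shrinks
the variance by (n−1)/n, which measurably under-covers, so resampled
deviations are inflated by √(n/(n−1)) and the interval is a t interval on
log EC50 (df = N_obs − 4) using the bootstrap SE; measured coverage in the
package's simulations is ≈ 93 % with triplicates and ≈ 98 % with 9
replicates per concentration (three biological × three technical replicates,
the usual design for this assay). Default 1000 resamples; the coverage test
suite and acceptance script use B = 199 as their simulation size.

Selectivity index S.I. = EC50,dark / EC50,irradiated. A censored dark arm
with an active irradiated arm gives a lower bound (cap / EC50,irr); an
irradiated-censored arm gives an upper bound treated as not photo-enhanced;
both censored leaves the index undefined. Photo-enhancement threshold:
S.I. ≥ 2 (configurable; the screen's qualitative ⊕/⊖ has no printed cutoff).

## Classification and ranking

The decision table is total over the evidence booleans. A DMA-positive
signal without quench confirmation is demoted (possible Type I mechanism or
artifact). Evidence combinations outside the five canonical cases —
dark-only cytotoxicity with or without ¹O₂ — are reported honestly as
`dark_cytotoxic_only` rather than forced into a case. Ranking sorts by case
priority (case 5 > 2 > 4 > 3 > 1 > dark-only > inactive; configurable,
reflecting PDT-lead interest), then selectivity index (a bound "> x" above
the exact value x), then DMA yield. UV-Vis evolution is `max_λ |A_final −
A_0| > 0.05 OD` on the overlap of the wavelength grids.

## Synthetic data generator

The generator defines the conditions every stochastic test runs under:

* DMA kinetics: OD₃₇₇(H) = OD₀·e^(−κH) + ε with
  κ = κ₀ · φ_eff · (1 − 10^(−A₄₆₈)) + κ_solv. Defaults: OD₀ = 1.0,
  κ₀ = 0.005 (J cm⁻²)⁻¹, κ_solv = 2×10⁻⁴ (J cm⁻²)⁻¹, reference A₄₆₈ = 0.5,
  schedule 4 × 6.2 J cm⁻². These put the reference bleach at ≈ 0.08 OD over
  the full dose and a 2× sensitizer at ≈ 0.16 OD — the regime where endpoint
  scoring is near-linear — and give triplicate yield SEs of roughly ±10–18 %
  points, the precision typical of published relative-yield tables.
  Ascorbate multiplies the sensitized rate by (1 − quenchable); it is a rate
  suppression, not a modelled species. Extract-only arms drift linearly by
  `side_reaction_drift` per full dose.
* Noise: additive Gaussian on OD, SD 0.005 (typical plate-reader
  repeatability), independent across wells and doses; a constant 0.04 OD
  background is added everywhere and removed by blank correction.
* Dose–response: 4PL + Gaussian noise (default 5 % points) truncated to
  [−20, 150] %; EC50 = ∞ yields flat-at-top (inactive) curves.

What the generator does **not** emulate: spectral overlap between extract
pigments and the DMA band, oxygen depletion or probe exhaustion
(non-first-order kinetics), edge effects and dose inhomogeneity, pipetting
(well-to-well systematic) error, and correlated biological replicate
structure. Passing tests therefore demonstrate correctness of the estimators
under the stated statistical model, not robustness to those real-world
artifacts.

## Numerical and degenerate-input choices

* Doses are exact internally; display rounds to 0.1 J cm⁻².
* ΔOD below the noise floor (0.01 OD) is treated as no signal; the quench
  ratio is then defined as 1.
* A reference arm that does not bleach beyond the solvent control aborts
  scoring (the 100 % anchor would be meaningless).
* 4PL fits that fail from every start return `fit_ok = False` with the
  optimizer message, never a silent number.
* Single replicates yield SE = 0 with a warning rather than NaN.
* Bit-identical CSV round-trips require `float_precision="round_trip"`
  parsing, which the readers use.

## Problem sizes

Stochastic suites use: 200 simulated experiments for CI coverage (7
concentrations, 9 replicates, B = 199), 10 seeded plates per relative-yield
estimate in the acceptance script, and triplicate plates elsewhere. The full
test suite runs in under two minutes on one CPU.

## Known limitations

* The relative-yield formula's exact published form could not be confirmed;
  the implemented expression is the standard one consistent with the stated
  absorption correction (flagged in every report).
* EC50s near the top of the tested range are weakly identified; expect
  single-experiment scatter (the censoring rules exist for this reason).
* The classifier's case priority encodes screening intent, not a validated
  utility function.
* Mass-vs-molar concentration for crude extracts is inherently ambiguous;
  the data model stores mass concentration (µg mL⁻¹) only.
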
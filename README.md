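# photoscreen

Analysis toolkit for microplate **phototoxicity screening** of natural-product
extracts — the workflow used to hunt for new photodynamic-therapy (PDT)
photosensitizers in pigmented organisms such as fungi. It covers the three
sub-assays of the screen and the decision logic that combines them:

1. **DMA singlet-oxygen assay.** 9,10-dimethylanthracene (DMA) is a selective
   ¹O₂ probe: photosensitized [4+2] oxidation destroys its 377 nm absorption
   band, so the drop ΔOD₃₇₇ over an irradiation series measures ¹O₂
   production. Because samples absorb different fractions of the incident
   light, the signal is corrected by the probability of absorption
   f(A) = 1 − 10⁻ᴬ at the irradiation wavelength and expressed relative to a
   reference photosensitizer (berberine ≡ 100 %):

   yield % = 100 · (ΔOD_s / ΔOD_ref) · (f(A_ref) / f(A_s))

   Ascorbate-quench and side-reaction controls guard against false positives.
2. **Light dosimetry.** Fluence arithmetic for the 468 nm LED array
   (20.6 mW cm⁻², four 5-min steps of 6.2 J cm⁻² each), ferrioxalate
   actinometry (irradiance from moles of Fe²⁺ formed), and a
   coefficient-of-variation homogeneity check over the inner 60 wells.
3. **SRB photo-cytotoxicity.** Four-parameter-logistic (4PL) dose–response
   fits of sulforhodamine-B viability data for dark and irradiated arms,
   bootstrap 95 % EC50 confidence intervals, censoring ("EC50 > max tested")
   for inactive curves, and the selectivity index
   **S.I. = EC50,dark / EC50,irradiated**.

A rule engine folds the evidence (DMA ±, quench confirmation, UV-Vis
evolution, CT ±, PCT ±) into five interpretation cases (sun-protector /
non-¹O₂ photochemical / broadly toxic / aPDI candidate / PDT candidate) and
ranks extracts. Because the original raw plates are not deposited, a
synthetic generator produces plates with known ground truth (first-order DMA
bleaching whose rate scales with absorbed fraction × effective ¹O₂
efficiency; 4PL viability data) for every test.

## Worked example

Simulate a plate carrying one strong sensitizer (`hot`, OD₄₆₈ = 0.5,
effective ¹O₂ efficiency 2.05× the reference) and one inert extract, then
score it:

```bash
cat > spec.json <<'EOF'
{"sensitizers": [{"sample_id": "hot", "a_irr": 0.5, "effective_phi": 2.05},
                 {"sample_id": "dud", "a_irr": 0.3, "effective_phi": 0.0}],
 "cytotox": [{"sample_id": "hot", "ec50_dark": "inf", "ec50_irr": 1.0}]}
EOF
photoscreen simulate --spec-file spec.json --seed 5 --out sim
photoscreen dma --layout sim/layout.csv --readings sim/readings.csv
```

```
sample_id  delta_od377   a_468  absorbed_fraction  relative_yield_pct  quench_ratio  dma_positive
      hot       0.1467  0.4989             0.6830               198.9         0.077          True
      dud      -0.0038  0.3045             0.5039                 0.0         1.000         False
```

`hot` bleached 0.147 OD of DMA, absorbed 68 % of the incident light, and
scores 199 % of the berberine reference (ground truth 205 %); ascorbate
suppressed its bleaching to 8 % (quench confirmed → genuine ¹O₂). The inert
extract scores 0 %. The cytotoxicity stage and full pipeline:

```bash
photoscreen cytotox --data sim/dose_response.csv
photoscreen screen --config screen.yaml --seed 5
```

```
sample_id        arm    ec50  censored  active    si  si_censored
      hot       dark     NaN      True   False  54.6         True
      hot irradiated   0.915     False    True  54.6         True

sample_id                case  rank    si  relative_yield_pct
      hot case5_pdt_candidate     1  >54.6              198.9
      dud            inactive     2                       0.0
```

The dark arm never killed cells below the 50 µg mL⁻¹ cap (censored), the
irradiated EC50 is ≈ 0.9 µg mL⁻¹ (truth 1), so the selectivity index is a
lower bound "> 54.6": a ¹O₂ producer toxic **only under light** — the PDT
lead profile (case 5).

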
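# marrowquant

Ratiometric quantification of absolute pH and extracellular calcium
concentration ([Ca²⁺]ₑ) in the calvarial bone marrow from intravital
two-photon z-stacks.

## The problem

Cell-impermeable dye pairs (SNARF-1 for pH; Rhod-5N referenced against
AF488 for calcium) label the marrow vasculature and the ~1 µm interstitial
gaps between densely packed marrow cells. The red/green emission ratio R/G
encodes the ion concentration — but the signal is collected through
cortical bone and blood-rich marrow, which attenuate the two emission bands
differently. The apparent ratio therefore drifts with imaging depth, and
the raw images mix spectral bleed-through, dye washout and detector
background on top. `marrowquant` implements the full analysis chain that
turns such stacks into calibrated pH / [Ca²⁺]ₑ maps:

1. **Bone geometry** — Otsu bone mask from the second-harmonic (SHG)
   channel; per-column bone-thickness map `Z₁` and depth-from-endosteum map
   `Z₂`.
2. **Segmentation** — histogram equalization (10% saturated), per-plane
   top-hat, Gaussian-weighted adaptive thresholding, a morphological split
   of tubular vessels from interstitial sheets, osteoid detection and
   exclusion of low-SNR / autofluorescent voxels.
3. **Corrections**, in fixed order: (i) background subtraction; (ii)
   two-step depth correction `I₀ = I · exp(C₁Z₁ + C₂Z₂)` with all four
   attenuation coefficients (C₁ᴳ, C₁ᴿ in bone; C₂ᴳ, C₂ᴿ in marrow)
   estimated from the stack itself — C₁ᴳ from bone autofluorescence decay,
   C₁ᴿ by converging endosteal-vessel ratios across bone thickness, C₂
   from intravascular intensity decay with marrow depth; (iii) exact 2×2
   crosstalk unmixing (defaults 12% red→green, 1.3% green→red); (iv)
   dye-clearance correction from two-timepoint stacks, fitted per
   20×20-pixel subregion and referenced to 10 s after injection.
4. **Calibration** — sigmoidal pH titration
   `pH = pKa + log₁₀((R−R₀)/(Rᴹ−R)) + log₁₀(S_b/S_a)` and Hill-generalised
   calcium isotherm `[Ca²⁺] = K_eff · ((R−R₀)/(Rᴹ−R))^(1/h)`, fitted from
   in vitro series, plus a day-to-day reference adjustment.
5. **Quantification** — masked ratio maps, seeded ROI subregions (5×5 µm
   intravascular, 20×20 µm interstitial), depth profiles,
   deposition/mixed/resorption (D/M/R) cavity classification from
   two-stain bone fronts (>75% / 25–75% / <25% retained old front), marked
   stem-cell neighbourhood statistics, and exact small-sample Mann–Whitney
   group comparisons.

Because in vivo stacks ship no ground truth, the package includes a
first-class forward simulator (`marrowquant.synthetic_data`) that renders
calvarial scenes — bone plate of varying thickness, tubular vessels (~25%
of marrow volume), dark cells with dye-filled gaps, osteoid patches,
per-compartment pH/[Ca²⁺] fields — and distorts them with clearance,
crosstalk, two-layer attenuation and shot/read noise. Every stage is
validated by parameter recovery against that truth.

## Worked example

```bash
marrowquant run-all --preset bm_baseline --seed 1 --out out/
```

simulates a 128×128×40 baseline scene (two timepoints, 300 s apart), runs
the full chain and writes `out/summary.json`. On this scene the fitted
attenuation coefficients come out as

```
"attenuation": {
 "c1_green": 0.03333,   # 1/30 um^-1 generated
 "c1_red":   0.02457,   # 1/40 um^-1 generated
 "c2_green": 0.04982,   # 1/20 um^-1 generated
 "c2_red":   0.04626    # 0.04635 um^-1 generated
},
"vessel_fraction": 0.252
```

i.e. the bone attenuation lengths (30 / 40 µm), the marrow attenuation and
the ~25% vascular volume fraction are recovered from the distorted stack
within a few percent, and the calibrated interstitial [Ca²⁺]ₑ summary in
the same file reads back the ~1 mM field the preset generated. Other
commands (`simulate`, `segment`, `correct`, `calibrate`, `quantify`,
`classify`, `simulate-bonefront`, `report`) expose the individual stages;
every run writes its effective configuration and a provenance log.

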
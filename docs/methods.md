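# Methods

This note records the models, defaults and design choices behind
`marrowquant`, in the order the pipeline runs them.

## Optical model

Fluorescence emitted at depth inside the marrow is assumed to travel
vertically through the remaining marrow and the overlying cortical bone,
attenuating exponentially in each layer:

    I = I₀ · exp(−(C₁ Z₁ + C₂ Z₂))

per collection channel, where Z₁ is the bone material in the voxel's x–y
column (µm), Z₂ its depth below the endosteum (µm), and C₁, C₂ the bone and
marrow attenuation coefficients of that channel (µm⁻¹). The vertical-ray
approximation ignores the oblique collection cone; it is what makes the
correction separable into a 2D thickness map and a 3D depth map. Bone may
be porous, so Z₁ counts bone voxels rather than top-to-bottom extent. The
endosteum of a column is its deepest bone voxel; whether a fitted smooth
surface would serve better is an open question we resolved in favour of the
simpler convention, which also makes the depth map exactly reproducible
from a perfect mask.

Default coefficients in the simulator (and the values the estimators are
validated against): bone attenuation lengths 1/C₁ᴳ = 30 µm and
1/C₁ᴿ = 40 µm; marrow 1/C₂ᴳ = 20 µm, with C₂ᴳ − C₂ᴿ = ln(1.2)/50 µm⁻¹ so
that the uncorrected intravascular R/G ratio rises to 1.2 at 50 µm of
marrow depth. Marrow attenuates more strongly than bone because of its
~25% blood volume; the green band sits on the haemoglobin absorption peak,
which is why C₂ᴳ > C₂ᴿ and the ratio red-shifts with depth.

## Coefficient estimation

* **C₁ᴳ** — bone autofluorescence is green and originates inside the
  plate, attenuated only by the bone above it; the slope of log(mean green)
  against depth-into-bone gives the coefficient directly.
* **C₁ᴿ** — intravascular ratios are systemically constant, so endosteal
  vessel voxels (first marrow plane, where the marrow term is a constant
  offset) grouped by overlying bone thickness must converge after
  thickness correction. The weighted least-squares slope of
  log(meanR/meanG) per thickness group is the closed-form minimiser of the
  group-variance objective. Group means (not voxel log-ratios) keep
  low-SNR voxels from dominating. The vessel mask is eroded in-plane by
  1.2 µm first — stray perivascular voxels carry a different ratio and
  would otherwise tilt the slope. Once C₂ is known, a refinement pass
  repeats the fit over the three shallowest marrow planes with the marrow
  term compensated, roughly tripling the data behind the estimate.
* **C₂ᴳ, C₂ᴿ** — per channel, log-linear fit of mean intravascular
  intensity against Z₂ on the thickness-corrected stack (equivalently:
  minimising the spread of depth-corrected bin means), with the same
  eroded-mask purification; bins need ≥20 voxels.

Correction factors are capped at e⁶ per voxel (capped voxels are counted
in provenance): deeper, darker voxels would otherwise amplify noise
without bound. Voxels inside bone are corrected with their partial
overlying thickness only, which keeps the autofluorescence fit
self-consistent.

## Order of operations

The chain is background → depth correction → crosstalk unmixing →
clearance, and the forward simulator distorts in exactly the reverse
order (emission → clearance → spectral mixing → attenuation → noise).
With that convention the noise-free chain inverts the forward model to
machine precision, which the test suite asserts at ≤10⁻⁶ relative error
voxelwise. Unmixing before depth correction would not be exact, because
the mixing couples channels that subsequently attenuate at different
rates — the same reason the clearance fit runs on corrected stacks.

## Clearance

Two stacks of the same field 5–10 min apart give a per-dye, per
20×20-pixel-subregion decay rate k = ln(I₁/I₂)/Δt (the exact two-point
solution of a one-component exponential; ordinary least squares on log
intensities would generalise to more timepoints). Tile means use one
joint voxel selection for both timepoints so the dimmer stack does not
lose its faintest voxels and bias the rate; bone (non-clearing
autofluorescence) and excluded voxels are masked out. Subregions with
non-positive means — perfusion still rising — are flagged and filled from
neighbouring tiles. Intensities are referenced back to 10 s after
injection. Simulator defaults: half-lives 900 s (green) and 600 s (red),
with a lognormal 10% tile-to-tile spread; stacks are acquired at 120 s
and 420 s.

## Segmentation

Runs on the raw (background-subtracted) red channel, where dye contrast
is strongest and autofluorescence weakest: global histogram equalization
with a 10% saturated fraction, per-plane white top-hat (radius 20 µm —
wide enough not to carve the interiors of merged vessel complexes while
still flattening illumination gradients), Gaussian-weighted local
adaptive threshold (window 25 µm, offset 0; a voxel is foreground iff it
exceeds the local mean by more than the offset, so a constant image
yields an empty mask). Vessels are then the morphological opening (ball
radius 2 µm) of the hole-filled foreground — only holes far below a cell
cross-section are filled, so dark cells survive — minus a 1 µm
perivascular trim that returns the dye-filled sheet hugging the vessel
wall to the interstitium. Osteoids are bright endosteal foreground
(red > 3× the interstitial median of the endosteal shell *under
comparable bone thickness*, so attenuation is not mistaken for dimness)
within 5 µm of bone. Excluded voxels: below the SNR floor in both
channels (default 15 counts ≈ background mean + 3 SD), or green-only
objects (autofluorescent cells). Re-segmenting on depth-corrected data
was tried and rejected: correction amplifies deep noise, which then
dominates the equalization.

## Calibration

The pH curve is the standard two-plateau titration; pKa and the spectral
term log₁₀(S_basic/S_acid) enter the model only as a sum, so the S-ratio
is treated as a known constant (measured separately from the plateau
emissions) and pKa, R₀, Rᴹ are fitted. Defaults pKa 7.5, R₀ 0.2, Rᴹ 2.0
centre the sigmoid on the physiological window. The calcium isotherm uses
K_eff = 0.85 mM and Hill slope 1 by default, reproducing the probe's
characteristic shape — near-linear below 0.5 mM, near-saturated above
1 mM — and its consequence, the asymmetric uncertainty of high
concentrations, which `propagate_ratio_uncertainty` maps explicitly. The
90% confidence intervals come from a seeded parametric bootstrap (200
resamples). Pooled (multi-pH) and per-pH calcium fits are both available;
the pooled fit is the default. Eq.-style day-to-day reference adjustment
is evaluated verbatim with K_d kept distinct from K_eff.

## Quantification

Subregion ratios are ratios of summed intensities, not means of voxel
ratios: the single-voxel ratio is biased upward at low SNR (E[R/G] ≈
r·(1+var(G)/G²)), and summing first removes that bias. Conversion of a
subregion to pH/[Ca²⁺] happens at 2 µm sub-tiles whose values are then
averaged: the tiles are small against the ion fields' 10 µm correlation
length (so the concave response curve is evaluated on locally homogeneous
data) yet large enough to average out voxel noise. Converting one
20 µm-subregion-wide ratio instead understates a heterogeneous calcium
field by up to ~8%. Interstitial ROIs (20×20 µm, 25 per cavity, seeded)
accept a patch when ≥8% of its voxels (≥25 voxels) are usable
interstitium — a sheet network can never fill half a 20 µm square — and
sample clear of a 1.2 µm perivascular guard band; vessel ROIs (5×5 µm, 20
per cavity) require 50% coverage. Saturated detector-ceiling voxels are
excluded automatically. Marked-cell neighbourhoods use 5 seeded 3 µm
interstitial patches within a 15 µm radius ("3-cell radius" read as ~2
cell diameters, and consistent with stem cells sitting within 15 µm of
bone; configurable). D/M/R cavity classes apply the 75%/25% thresholds to
the retained old-bone-front fraction, with boundary values assigned to M.
Group comparisons use the two-sided Mann–Whitney U test, exact by
exhaustive enumeration (midranks for ties) up to 16 pooled samples,
normal approximation with tie and continuity correction beyond.

## The simulator, and what passing tests do not show

The generator emulates: a bone plate whose thickness field (20–60 µm,
15 µm correlation) drives the two-step geometry; tubular vessels packed to
25% of marrow volume, including sinusoids hugging the endosteum (they
anchor the C₁ᴿ fit, as in real calvarial marrow); a Voronoi-style cell
packing (7 µm cells, 1 µm lateral gap sheets — at a 3 µm z-step the
horizontal gaps are below axial resolution and are not generated); osteoid
patches with 5 mM calcium and 3× dye accumulation; 2% green-only
autofluorescent cells; per-compartment fields (vessel pH 7.3 /
Ca 1.0 mM; interstitial pH 7.1 ± 0.117 — the SD chosen so the 10–90% span
is 0.30 pH units; interstitial Ca lognormal 1.0 ± 0.54 mM at baseline,
0.7 mM in deposition-type, 1.3 mM in aged mixed-type cavities; hotspots of
1.5 ± 0.57 mM within 18 µm of marked cells, a radius chosen to enclose the
15 µm neighbourhood sampling); Poisson photon noise plus Gaussian read
noise (SD 3 counts) and a 10-count background offset. SHG is rendered
with its own 60 µm attenuation length — the forward-directed harmonic at
~470 nm loses far less than the dye bands.

It does **not** model: the microscope PSF (labels are voxel-sharp, so
partial-volume mixing at compartment boundaries is absent and real
segmentation will be harder than the Dice scores here suggest), vascular
network topology, photobleaching (negligible for perfused free dyes),
oblique collection paths, or wavefront distortion beyond its net SNR
effect. Parameter-recovery results therefore validate the *computation* —
that the chain inverts the stated optical model and recovers the stated
fields — not the biological accuracy of the model itself.

## Problem sizes

Full-scale validation scenes are 128×128×40 voxels at 0.4 µm × 3 µm
sampling (a ~51×51×120 µm field containing one marrow cavity, a scale at
which a single pipeline run takes a few seconds); unit tests use 64×64×28
scenes with a thinner bone plate. Statistics that the acceptance script
reports average 3–6 independent scenes, mirroring the per-cavity structure
of the in vivo measurements.
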
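# Methods

This note documents the models, algorithms and numerical choices in the
package, in the order data flows through it: materials and spectra,
the CT simulator, the digital phantoms, the automatic beam-hardening
correction (ABHC), and kinetic blood-flow estimation.

## Beam hardening and the residual polynomial correction

A polychromatic x-ray beam hardens as it penetrates tissue: low-energy
photons are absorbed preferentially, so the log-projection

P = −ln ∫ Ω(E) exp(−∫ μ(E, x) dl) dE

is sublinear in material thickness. After the water pre-correction that
every clinical scanner applies (which linearizes P for water paths),
the residual error comes from materials whose energy dependence differs
from water — bone and concentrated iodine, the "highly attenuating
materials" (HAM). Writing λ for the projection through the HAM
component alone, the residual error is well approximated by a quadratic
polynomial a·λ + b·λ², and by linearity of filtered back projection
(FBP) the image-domain correction is

I_C = I − a·FBP(λ) − b·FBP(λ²) = I − a·B₁ − b·B₂.

λ is obtained by thresholding the reconstructed image at the HAM
threshold (default 200 HU) and forward-projecting the thresholded
image; the two base images B₁, B₂ are computed once per input image, so
evaluating a candidate (a, b) is a cheap linear blend. B₁ reproduces
the HAM structures themselves (the linear term can rescale their
intensity and cupping but, being an image of the HAM, cannot touch
streaks between them); B₂ concentrates along the lines joining HAM
structures — exactly where dark BH streaks live.

Units: the HAM image is forward-projected in linear-attenuation units
(HU-excess converted through μ_water at the reference energy) and the
base images are rescaled back to HU, with B₂ additionally normalized by
max λ so a and b have comparable magnitudes. Any fixed unit convention
is absorbed by (a, b); parameter values are therefore comparable only
within this package's convention.

## The cost function and its optimization

The correction weights are found, calibration-free, by minimizing an
artifact-sensitive cost on the corrected image:

ψ = α · TV_myo(f̂(I_C)) / TV⁰ + (1 − α) · F_LV(f̂(I_C)) / F⁰

* **TV_myo** — mean gradient magnitude over the myocardium mask of the
  Gaussian-smoothed image (σ = 0.7 mm ≈ 3 px at clinical pixel sizes),
  with gradients above a threshold (10 HU/px) zeroed so anatomic edges
  do not dominate the gentle BH shading. This term senses streaks and
  is what determines b.
* **F_LV** — mean squared deviation of the LV blood-pool pixels from
  LV_max, the mean of the 20 highest values on a 4-pixel rim band along
  the cavity circumference minus the rim noise estimate (rim SD), which
  removes the upward selection bias of a top-k mean. This flatness /
  anti-cupping term is what stabilizes a.
* α = 0.47, the empirical optimum reported for this family of costs;
  TV⁰ and F⁰ are the two terms' values on the uncorrected image, so α
  weighs *fractional* improvements (the raw terms differ by two orders
  of magnitude, HU/px versus HU²).

Three numerical choices matter and were made deliberately:

1. **Both terms are evaluated on the smoothed image.** High-frequency
   noise and reconstruction ringing otherwise swamp the low-frequency
   BH signal; smoothing commutes with the (a, b) blend, so the smoothed
   input and base images are precomputed and every candidate costs one
   array blend.
2. **LV_max is frozen while (a, b) are searched** and the search is
   iterated three times with the target refreshed from the current best
   correction. If LV_max is recomputed per candidate, the noise-free
   objective is homogeneous of degree 2 in (1 − a, b): uniformly
   shrinking all HAM-correlated content scales every term down, and the
   optimizer runs away to the parameter bound, leaving the corrected
   HAM intensities tens of percent low. Noise hides this in clinical
   images (the noise floor in F_LV is scale-invariant), but a noise-free
   phantom exposes it. Freezing the target anchors the corrected level
   at the least-artifact-affected part of the cavity (its rim); the
   iteration converges in 2–3 passes.
3. **Optimization is a 21×21 coarse grid over a ∈ [−0.6, 0.6] (b scaled
   to the λ² image's dynamic range) followed by Nelder–Mead refinement**
   confined to the searched box. The post-smoothing surface is a single
   curved valley; the grid guards against capture away from it. Because
   the valley floor is nearly flat along its length, the simplex may
   legitimately end below the grid's argmin at a different location —
   the optimizer is validated by cost (≤ brute force) rather than by
   coordinates.

The smoothing step's role is verified operationally: with σ = 0.7 mm
the fitted (a, b) varies ~3× less across noise realizations and lands
~2× closer to the noise-free fit than without smoothing.

### Dynamic series

For a dynamic acquisition the cardiac structures are segmented from
per-pixel temporal variation: static tissue varies like noise, the
myocardium's modest enhancement gives intermediate SD, and iodine-filled
blood pools vary most. The LV is the largest connected high-SD
component; the myocardium is the intermediate-SD part of a disk-dilated
shell around it (dilation sized to cover the wall, ~10 mm); bone is
static and above the HAM threshold. The two SD cuts are data-adaptive —
3× the median SD (noise floor) for the static cut, with a floor at one
sixth of the blood cut, and 30% of the 99.5th-percentile SD for the
blood cut — because enhancement and noise scale together across tube
voltages. A 3-pixel guard band around blood pools excludes
partial-volume pixels whose diluted arterial curves would otherwise fit
as spuriously high flow.

Correction modes: `single` fits every iodinated frame and applies
per-frame parameters; `average` fits all iodinated frames and applies
their mean; `peak` fits the peak-enhancement frame only; `hybrid`
(default) fits the peak frame and its two temporal neighbours and
averages — the robustness of averaging at three fits' cost. One
parameter set is applied to every frame (each frame's own HAM
segmentation supplies its λ).

## CT simulator

Parallel-beam geometry with analytic forward projection: phantoms are
nested elliptical primitives, each contributing its closed-form chord
length times its attenuation contrast against the enclosing material,
so sinograms carry no rasterization error. Four sub-rays per detector
bin are averaged in intensity (a finite detector aperture); without
this, the unbounded-bandwidth analytic projections of sharp
high-contrast edges alias into azimuthal streaks of a few HU.
Polyenergetic projection integrates Beer's law over the spectrum;
a single-bin spectrum reduces exactly to the monoenergetic case.

Water pre-correction maps each measured P through the water
polychromatic-to-monochromatic transfer curve (4th-order polynomial
with zero intercept, fitted over 0–60 cm of water; projections beyond
the calibrated range are clamped with a warning). Poisson noise draws
transmitted counts at the spectrum's fluence I₀ per detector bin and
re-logs them, clamping zero counts to one. Reconstruction is
scikit-image's `iradon` with a Hann-apodized ramp (clinical kernels are
apodized; the pure ramp's Gibbs ringing inside small high-contrast
inserts also destabilizes the noise-free flatness term) and HU
conversion against μ_water at the reference energy. The analytic
projector matches scikit-image's rotation convention (centre pixel
n//2, s = x·cosθ + y·sinθ with y up); a half-pixel mismatch here puts a
±8 HU bipolar halo around every high-contrast disk and was the largest
single fidelity bug found during development (caught by the BH-free
monoenergetic control, whose flow maps must be homogeneous).

### Spectra and the reference energy

Tube spectra are filtered Kramers bremsstrahlung continua (tungsten
anode) hardened by aluminium filtration, 9 mm Al default
(bowtie-centre-equivalent total filtration of a body protocol), on a
1 keV grid from 10 keV to the tube potential. Embedded mass-attenuation
tables (water, elemental iodine with K-edge points, ICRU-44 cortical
bone, aluminium) are interpolated log-log from the standard published
grids. This model is deliberately generic: the correction is
calibration-free by design, so only a realistic degree of spectral
hardening matters.

The HU reference energy is the spectrum's *effective monoenergy*: the
energy at which a monoenergetic reconstruction reproduces the dilute-
iodine HU of the full polyenergetic pipeline, found by bisection on a
small calibration simulation (water cylinder, 10 mgI/ml central insert
— the arterial-peak concentration). This mirrors how virtual-
monoenergetic comparators are chosen on spectral scanners: the energy
whose HU align with the conventional reconstruction. For the default
120 kVp spectrum it is 61 keV (52 keV at 80 kVp, 64 keV at 140 kVp);
the monoenergetic ground-truth series is simulated at the same energy,
so "BH-free reference" and "conventional" share one HU scale.

## Digital phantoms and the dynamic study

* **Cylinder phantom** — 100 mm water disk with four 8 mm-radius iodine
  inserts at 90° spacing, 7 / 10.5 / 14 / 17.5 mgI/ml. The
  concentrations are chosen so every insert clears the HAM threshold
  while the worst inter-insert streak of the uncorrected 120 kVp
  reconstruction is ~−13 HU — the digital-phantom regime, an order of
  magnitude below a high-concentration physical phantom.
* **Cardiac phantom** — thorax ellipse (110×84 mm), LV cavity (14 mm
  radius) inside a 10 mm myocardial annulus, RV cavity, descending
  aorta, and spine + sternum cortical bone: the structures that
  generate myocardial BH streaks in contrast-enhanced cardiac CT.
* **Dynamic series** — 40 frames at 1 s spacing. The arterial input
  function is a gamma variate (onset 4 s, peak 12 s, peak 10 mgI/ml
  ≈ 400 HU of LV enhancement at 120 kVp, shape 3, 15% recirculation);
  the RV leads by 3 s. The myocardium follows the Johnson–Wilson
  tissue curve at the ground-truth flow (100 ml/min/100 g homogeneous
  by default; an optional angular sector can carry reduced flow for
  ischemia experiments, painted as a post-reconstruction enhancement
  delta — the sector's sub-threshold iodine contributes negligible BH
  of its own). Photon fluence is calibrated per protocol so the
  peak-frame myocardial SNR (mean enhancement / noise SD) is ≈ 9.8.

Because the tissue curves are generated by the same impulse-response
family the estimator fits, flow recovery is well-posed by construction;
the inverse crime is mitigated by Poisson noise, by the reconstruction
pipeline between generation and fitting, and by the different time
discretizations of generation and fit. Passing tests therefore
demonstrate the *pipeline's* fidelity (simulation, correction,
segmentation, fitting), not that the Johnson–Wilson family describes
real myocardium; and the phantoms omit cardiac motion, scatter,
cone-beam effects and anatomical texture, so absolute artifact
magnitudes in real scans will differ from the simulated ones.

## Blood-flow estimation

Tissue enhancement is modelled as the arterial input function convolved
with the adiabatic Johnson–Wilson impulse response: a plateau of
duration ITT (intravascular transit) followed by an extraction-weighted
exponential tail,

R(t) = F′·[1 for t₀ ≤ t < t₀+ITT; E·e^(−k(t−t₀−ITT)) for t ≥ t₀+ITT],

with F′ = F/6000 converting ml/min/100 g to s⁻¹ at unit tissue density.
ITT = 2 s and E = 0.6 are fixed in the physiologic range, leaving three
free parameters (delay t₀, flow F, decay k). The convolution runs on a
100 ms grid with the AIF linearly interpolated; the IRF is averaged
analytically over each grid bin — pointwise sampling of the plateau
edges makes the cost discontinuous in the delay, which traps simplex
optimizers. The sum of squared differences at the measured times is
minimized by Nelder–Mead in scaled variables (delay, F/100, 10k — the
raw scales differ by three orders of magnitude), from two starts (delay
at the AIF-onset estimate and at zero), with a restart at the optimum
and a trust-region least-squares polish; the SSD valley is narrow and
curved in (F, k), where a collapsed simplex can stall a few percent
from the optimum. Both AIF and tissue curves are used as baseline-
subtracted HU enhancement, so the iodine HU-per-concentration constant
cancels and flow estimates are independent of the HU scale.

Flow maps average TACs over 5×5-pixel super-pixel regions of the
myocardium and fit each region; regions with no enhancement or failed
fits are flagged missing. The map is fitted one pixel inside the
segmented myocardium: boundary pixels carry partial-volume-diluted
curves that read as spuriously low flow. Homogeneity is scored as the
coefficient of variation (100·SD/mean) of the region flows, and
regional deficits as the ratio of the lowest to the highest mean sector
flow in six angular sectors about the LV centre (below ~0.8 reads as a
hemodynamically significant defect).

## Artifact metrics

Streak artifact: mean HU of the affected ROI minus a remote unaffected
ROI (negative = darkening); in the cylinder experiment the affected ROI
is the worst inter-insert chord midpoint and the remote ROI is the ring
candidate whose uncorrected value is closest to the known water
background. Cupping: darkest-minus-brightest 3×3 ROI means within a
region, extremes located on a median-filtered copy so single noisy
pixels do not define them; percent reduction is |original−corrected| /
|original|. Myocardial homogeneity: SD of per-ROI means. All measures
except the percent reduction are invariant to a global HU offset.

## Problem sizes

Default experiment sizes, chosen as the package's desk-scale operating
points: static cylinder 256² pixels / 360 angles / 0.5 mm; dynamic
studies 192² / 240 angles / 0.65 mm (acceptance script) or 160² / 200
angles (test suite), with the tube-voltage study at 128² / 160 angles.
Between 128² and 256² the flow statistics change by about one
coefficient-of-variation point; the spatial grids trade only runtime
against partial-volume granularity at the myocardial boundaries.

## Known limitations

* The quadratic polynomial cannot represent water–iodine cross terms
  exactly; residual myocardial error after correction is a few HU at
  this package's spectral hardness, which is what separates the
  corrected flow CoV (~10%) from the monoenergetic floor (~3%).
* Iodine below the HAM threshold (myocardial enhancement, early/late
  blood-pool frames) is invisible to λ and its artifacts are not
  corrected; bone-only residuals are ~1 HU.
* The absolute fitted (a, b) depend on the λ unit convention and the
  spectrum model and are not portable across implementations.
* Sub-0.8 false-positive flow ratios before correction reproduce at
  140 kVp but only marginally at 80 kVp with this spectrum model, where
  the artifact-to-enhancement ratio is intrinsically smaller.
* Temporal registration, cardiac motion, scatter and cone-beam
  geometry are out of scope; synthetic series are registered by
  construction.
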
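# Methods

## Measurement model

A film piece is scanned before exposure and again 24 h after (the response
of radiochromic film stabilizes on that time scale; no post-irradiation
kinetics are modelled). Scans are 48-bit RGB TIFFs, 16 bits per color, at
0.2 mm/pixel. Dose information is taken from the red channel; green and
blue are retained for diagnostics only. Pixel statistics are sampled over
axis-aligned square ROIs: a pixel belongs to the ROI iff its centre lies in
the closed square (a deterministic, resolution-independent rule), so the
protocol's 1×1 mm² ROI at 0.2 mm/pixel contains exactly 5×5 pixels. The
coordinate frame has its origin at the centre of the top-left pixel, x
rightward and y downward, in millimetres. ROIs that would leave the image
raise an error rather than clip. The ROI spread is the population SD; the
standard error of the ROI mean is sd/√n under an independent-pixel
assumption (spatial noise correlation is not modelled).

Film responses:

* XRQA2 (reflective, kV): netΔR = (PV_before − PV_after)/2¹⁶. The 2¹⁶
  normalization follows the 16-bit convention of the reference read-out
  protocol; using 65535 instead would change values by < 0.002% and nothing
  in the package depends on the choice.
* EBT3 (transmission, MV): netΔOD = log₁₀(PV_before/PV_after).

Response uncertainties are first-order propagations of the two ROI-mean
standard errors; an optional additive term can fold in inter-film (lot)
variation and defaults to zero.

## Calibration

Dose→response is modelled by the rational function y = (a + c·x)/(1 + b·x),
x being air kerma in air (XRQA2, calibrated up to 10 cGy) or dose to water
(EBT3, calibrated up to 100 cGy). Two forms are supported: the general
three-parameter form and the constrained form with a ≡ 0. The constraint
encodes the physical boundary condition that an unexposed film shows zero
net response; empirically the general fit returns a consistent with zero
but with a relative uncertainty orders of magnitude above those of b and c,
and that poorly determined intercept dominates the dose uncertainty at low
dose.

Fitting is weighted least squares (weights 1/σ_y²) with an analytic
Jacobian, via `scipy.optimize.least_squares` (Levenberg–Marquardt).
Starting values come from the model's low-dose linearization: c from the
slope through the low-dose half, b from the top-dose curvature, a = 0.
Parameter covariance is the inverse Gauss–Newton information matrix at the
optimum; for unweighted fits it is scaled by the reduced chi-square,
for weighted fits it is used unscaled (the weights already carry the noise
scale — stated explicitly because the provenance of quoted parameter
uncertainties is software-dependent). Fits must be monotone increasing on
the fitted dose range (c − a·b > 0 and 1 + b·x > 0); violations raise a
model-rejection error. Doses outside the fitted range produce an
extrapolation *warning*, not an error, because imaging doses legitimately
sit near the bottom of the calibrated range.

The inverse is closed-form, x = (y − a)/(c − b·y); responses at or beyond
the saturation asymptote y = c/b raise an error. Calibrations serialize to
JSON losslessly (doubles round-trip via repr), with a schema version and
strict validation on load.

## Uncertainty budgets

With x(y; θ) the closed-form inverse, the one-sigma dose variance is

σ_x² = (∂x/∂y)² σ_y² + g C gᵀ,

where g = ∂x/∂θ over the free parameters and C the fit covariance
*including off-diagonals* — b and c are strongly correlated in rational
fits and dropping the cross terms biases σ low. Response noise and
parameter uncertainty are treated as independent (calibration films are not
measurement films). The two variance components are reported separately and
add exactly.

Delta-method budgets are validated in the test suite against Monte-Carlo
resampling (10⁵ draws of response noise and of correlated parameters),
agreeing within 5% whenever relative input uncertainties are below ~10%.

Threshold statistics ("uncertainty ≤ p% for all doses above D") are
evaluated on a 200-point log-spaced grid, by default spanning two decades
up to the top calibrated dose; the bound must hold at *every* grid dose
above the reported threshold. Note that under constant response noise and
zero parameter covariance the relative dose uncertainty of the constrained
model is proportional to (1 + b·x)²/x: it decreases with dose only up to
x = 1/b (5 cGy at the default b = 0.2) and turns back up beyond, so
"uncertainty improves with dose" holds on the low-dose side only.

## Dose conversion, scaling, aggregation

kV film readings are air kerma in air and are converted to dose to water by
a single multiplication with the spectrum-averaged water-to-air
mass-energy-absorption-coefficient ratio, free in air, looked up by beam
quality (first HVL in mm Al) per the TG-61 in-air method. The packaged
table spans 2–10 mm Al with ratios 1.031–1.061 and linear interpolation.
A design alternative — mapping HVL to a mono-energetic effective energy and
using mono-energetic μen/ρ ratios — was evaluated and rejected: over the
qualities used here (4.9–7.7 mm Al, effective energies ≈ 42–53 keV) the
mono-energetic ratio varies by ~1.7%, whereas the spectrum-averaged TG-61
ratios vary by < 1%, which is the behaviour the conversion is supposed to
guarantee. EBT3 is calibrated directly in dose to water in Solid Water with
a 4 MV beam, so the MV (MVCT) path applies no conversion factor; the
4 MV-calibration vs ~3.5 MV-imaging energy mismatch is treated as
negligible given the EBT family's weak MV energy dependence.

Because single-acquisition imaging doses are small, exposures are
accumulated: five CBCT scans (OBI) or five MVCT scans (TomoTherapy), scaled
back per scan (dose and sigma divided by five); CyberKnife exposures of 100
image pairs are reported per 100 image pairs as acquired. Measurements are
repeated in triplicate and pooled to mean ± standard error, using the
unbiased (n−1) sample SD inside the SE (three repeats). The twelve imaging
protocols (machine × site with technique, kVp, HVL, mAs/MU, scaling rule)
ship as a packaged JSON registry.

## Profiles and reporting

Film-strip measurements become ordered 1D profiles (strictly increasing
positions; duplicates are an error). Positions are millimetres from the
machine isocenter projected onto the strip; positive is anterior (vertical
axis) or left (lateral axis). The asymmetry statistic is
(mean dose at positive positions − mean at negative)/overall mean, so an
anterior-loaded profile (sources mounted above the patient) scores
positive and mirroring a profile flips the sign exactly. The surface-dose
report is a (site, aspect) × machine table of cells formatted
"mean±SE" to two decimals with half-up rounding, with a plain-text renderer;
missing cells are left blank with a warning.

## Synthetic generator

The generator runs the physics forwards so the analysis can be checked
backwards. A truth calibration (constrained form) maps dose to response;
defaults are b = 0.2, c = 0.105 for XRQA2-like film (response 0.35 at
10 cGy, saturating curve, near-linear below 1 cGy) and b = 0.01, c = 0.004
for EBT3-like film (netΔOD 0.2 at 100 cGy). Scanner model: a uniform
unexposed baseline pv0 = 52000 with independent per-pixel Gaussian noise
σ_pv = 130 on both scans; the exposed red channel is
PV_after = PV_before − 2¹⁶·y(dose) (XRQA2) or PV_before·10^(−y(dose))
(EBT3). These noise defaults put the 5×5-pixel ROI netΔR noise at ≈ 5×10⁻⁴
— a model assumption chosen to represent a well-behaved flatbed scanner,
not a measured property. Pixel values are clipped to [0, 65535] (the clip
fraction is reported and is < 10⁻⁶ at defaults) and rounded to integers
when noise is present; noiseless pairs keep float pixel values so that the
zero-noise pipeline round trip is exact to better than 10⁻⁶ relative
(16-bit quantization alone would floor the round-trip error near 10⁻⁴).
TIFFs written to disk are always 16-bit integers.

Calibration-set generation adds Gaussian noise σ_y (default 3×10⁻⁴ per
point, the regime of a careful triplicate film read-out) to the truth curve
at 10 doses spanning the calibrated range. All randomness flows through a
single seeded `numpy` Generator.

Phantom fixtures program a ground-truth dose distribution per machine/site:
per-acquisition surface doses for the four aspects (Ant/Post/Left/Right),
a profile peak, and piecewise-monotone profile shapes built from two
half-cosine arcs meeting at the peak. Shapes encode the acquisition
geometry qualitatively: anterior-loaded vertical profiles for the
ceiling-mounted CyberKnife sources, posterior-loaded for the OBI head scan
(posterior tube arc), near-flat with a slight posterior excess for the
helical MVCT, and a 5 mm lateral peak offset where the phantom midplane is
iso-shifted. Interior profile values between the programmed endpoints are
fixture-defined, not measured quantities. Repeat-to-repeat scatter
(film piece, positioning) defaults to 3.5% relative SD, putting triplicate
standard errors near 0.01 cGy for sub-cGy surface doses.

What passing the synthetic round trips does **not** show about real films:
scanner lateral-response nonuniformity, orientation effects and film-scan
registration are not modelled (before/after scans are assumed
manifest-co-registered); scanner noise is white and Gaussian; inter-lot
response variation defaults to zero; film energy dependence within a
protocol's spectrum is absorbed into the calibration. The round trips
validate the analysis chain, not the film physics.

## Problem sizes and numerical choices

Test and acceptance runs use small images (25×25 to 50×300 pixels at
0.2 mm/pixel), 10-point calibration sets, 200-point log dose grids,
10⁵-draw Monte-Carlo oracles, and 200-replicate parameter-recovery
ensembles; everything completes in seconds. Fit convergence tolerances are
xtol = ftol = 10⁻¹⁴; the algebraic inverse identity holds to 10⁻¹⁰; ROI
boundary membership uses a 10⁻⁹ guard against float jitter at exact
pixel-centre boundaries. Ties in profile extrema resolve to the smallest
position. The profile maximum recovered from noisy scans carries a small
upward extreme-value bias (max over ~60 ROIs with ≲1% per-ROI noise),
well inside the 2% round-trip tolerance.
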
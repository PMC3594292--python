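# Methods

This note documents the models behind `talbotct`, the parameter choices
that matter, and what the synthetic experiments do and do not demonstrate.

## Interferometer geometry

Wavelength uses `λ = hc/E` with `hc = 12.39842 keV·Å`; all geometry is
double precision and only presentation layers round. A π/2-shifting phase
grating self-images with period `s = p1` at fractional Talbot distances
`d_n = n·p1²/(2λ)`; a π-shifting grating with `s = p1/2` at
`d_n = n·p1²/(8λ)`. Only odd orders are accepted — even orders have no
self-image contrast for phase gratings, and silently accepting them would
hide configuration mistakes. The three-grating (Talbot-Lau) cone geometry
solves `M = p0/(p0 − s)`, `p2 = M·s`, `d = M·d_n`, `l = d·p0/p2`; the
plane-wave two-grating bench is the `p0 → ∞` limit (`M = 1`), which the
code treats as the design with `p0` absent.

For the reference three-grating design (23 keV, p0 = 10.0 µm,
p1 = 3.51 µm, order 3, π/2) this gives p2 = 5.408 µm and d = 528.2 mm,
within 0.25% of the quoted 527 mm bench value. For the plane-wave 35 keV
design (p1 = 4.79 µm, order 5, π) the formula gives 404.8 mm where the
bench quotes 408 mm; the ~0.8% difference would be explained by a slightly
different effective wavelength or a small cone correction that is not
recoverable from the quoted numbers, so the package reports the formula
value and does not treat 408 as a check.

## Silicon coefficients and dosimetry

The embedded silicon grid covers 10–40 keV in 5 keV steps with three
columns (cm²/g): total mass attenuation (with coherent scattering),
photoelectric, and incoherent (Compton). Totals follow the NIST x-ray
mass-attenuation tables; the photoelectric column follows Cromer-Liberman
f″ values, and the incoherent column XCOM-magnitude values — the three
columns are mutually consistent with the totals to ~1% once coherent
scattering (≈ E⁻² from 1.37 cm²/g at 10 keV) is added. Interpolation is
log-log between bracketing nodes, because photon cross sections are near
power-law over this range; queries outside the grid raise rather than
extrapolate. User materials load from CSV with the same columns.

Detector DQE is modelled at zero spatial frequency as the absorbed
fraction `1 − exp(−µ_dep·t)` of the sensor layer using the
*energy-depositing* coefficient, photoelectric + incoherent: a Compton
interaction deposits energy (and removes the photon from the coherent
channel), whereas coherent scattering merely redirects it without
triggering a count. With this model a 450 µm silicon sensor at 23 keV has
DQE 0.25. Photoelectric alone would give 0.24 — the Compton term is small
but not negligible at these energies, and including it is both the better
physics for "absorbed fraction" and consistent with how such sensor DQEs
are quoted. Wafer transmission uses the *total* coefficient: any
interaction removes a photon from the useful collimated beam.

The feasible-dose scaling assumes the scan needs a fixed number of
detected photons:

```
feasible = actual · (DQE_actual / DQE_target) · [T(t_actual)/T(t_feasible)]^n
```

with n the number of grating wafers in the beam. For the tube scenario
(6.9 Gy measured, DQE 0.25 → 0.70, three wafers 500 → 100 µm at 23 keV)
this yields 1.06 Gy ≈ 1.1 Gy. The dose uncertainty is quoted as the ±25%
band of the underlying dosimetry (instrument energy dependence plus
calibration), not re-derived from its components. Two deliberate scope
notes: the skin-to-air conversion factor 1.4 is exposed with an explicit
divide/multiply mode because dosimeter conventions differ; and the
analyzer grating's ~2× dose penalty for pure attenuation imaging is
documented but not part of the scaling, since both the actual and the
feasible scenario keep all gratings.

## The phantom

`mouse_abdomen` is a 2-D axial slice: an elliptical soft-tissue body with
one solid-tumor blob, one cystic lesion (fluid core inside a two-sector
wall of fibrotic and cell-rich stroma), one vertebral bone disc and 2–5
air bubbles; `bone_streak` keeps only body + bone; `cylinder` is a single
centered disc with closed-form chords, used as the analytic oracle scene.
Placements are defined as fractions of the grid and jittered by the seed
(centers ±1–2%, body axes ±0.5%, so the total cross-section is
seed-independent to well under 2%); an air border of ≥5% of the width is
enforced and violations raise a layout error. Shapes are painted
back-to-front with 4× supersampled area-weighted edges (a one-pixel
anti-aliasing band); the label grid stores the majority tissue, so the
δ/µ maps are exact label lookups everywhere except that band.

The per-tissue values at 23 keV are configuration, not physics claims.
They preserve the realistic *structure* of soft-tissue contrast — δ of
order 1e-7, bone severalfold higher, a ~10% δ step for tumor vs soft
tissue against a ~2% µ step, a positive δ contrast between the two stroma
types — but the absolute δ scale is set so that the differential phase of
the default (most sensitive, tube-design) interferometer stays inside
(−π, π) for grids up to ~1024²: the package implements no phase
unwrapping, so the no-wrap condition is a documented precondition,
asserted in tests, rather than a runtime fix-up. The closed-form bound
used to set the scale is `φ_edge ≈ 2π(d/p2)·δ·√(D_px)` for a disc edge of
diameter `D_px` pixels. Bone additionally carries a small-angle-scattering
(dark-field extinction) strength of 30 cm⁻¹, chosen so that a
vertebra-sized disc suppresses fringe visibility to ~0.1–0.4 — the regime
where bone rays are visibility-starved and phase-noisy, which is the
phenomenon the streak suppression exists for. A 35 keV table is provided
by scaling (δ ∝ E⁻², µ roughly halved, bone faster); both tables are fully
overridable per tissue.

## Forward model and retrieval

Projection is the parallel-beam rotate-and-sum Radon transform
(scikit-image, bilinear interpolation, detector pixel = phantom pixel,
detector spanning the padded grid diagonal, angles `θ_j = jπ/N` over
[0, π)). Parallel beam is used for both virtual settings: the sample is
tiny against the source distance and both are reconstructed with standard
FBP. The interferometer converts the wavefront gradient via
`φ = (λd/p2)·∂Φ/∂x`, discretized as central differences over the detector
pitch (one-sided at the edges); exceeding |φ| > π emits a wrap warning.
Phase steps sample exactly one period endpoint-exclusive (k/K), which
makes the first discrete Fourier coefficient of a noiseless stepping curve
exact, so noiseless round trips recover T and φ to machine precision.
Poisson noise draws from one root seed with an independent spawned
sub-seed for the flat field. Flux (photons/pixel/step) is a free
parameter: ~1e3 emulates the visibly noisy dose-reduced regime, ~1e4–1e5
the cleaner high-dose regime; absolute exposure times are not modelled.

Retrieval is the standard Fourier analysis: `a0` (mean over steps), `c1`
(first DFT coefficient), `T = a0_s/a0_f`, `φ = arg(c1_s·conj(c1_f))`
(wrapped), `v = (|c1|/a0)_s / (|c1|/a0)_f`. Noisy flats can push T
slightly above 1, so T is clipped to (0, 1.5] with the clip count recorded
in the metadata.

## Reconstruction

Both FBPs share one backprojector (linear interpolation, Δθ = π/N
weighting) and frequency-domain filtering with zero-padding to the next
power of two ≥ 2× the detector width; no apodization by default (bare
Ram-Lak and Hilbert responses), with an optional Hann window behind a
flag. Attenuation: ramp |f| on −ln T, output in 1/cm. Phase: the
differential phase is rescaled to the transverse derivative of the δ line
integral, `g = φ·p2/(2πd)`, and filtered with `sgn(f)/(2πi)` — the ramp
divided by the `2πif` that differentiation contributed — so the output is
δ directly. The equivalence is tested against a brute-force oracle
(cumulative-sum g into line integrals, then ordinary ramp FBP), which
agrees to <1% RMS inside the object on the noiseless cylinder.

Streak suppression multiplies the phase sinogram element-wise by
`clip(v, 0, 1)²`. The weighted sinogram is *not* renormalized: the step
reduces the magnitude of the streaks radiating from strong scatterers at
the price of a local bias (the true bone signal is partially discarded),
so all quantitative-accuracy paths use the unweighted reconstruction. The
paired-seed experiments show the off-bone δ noise strictly decreases with
weighting in the low-dose regime (flux ~1e3, where low-visibility bone
rays are noise-dominated); at high photon counts the bias term wins and
the weighting no longer helps — a real limitation of the method worth
knowing before applying it to clean data.

Sharpening is a plain unsharp mask `out = in + amount·(in − G_radius(in))`
(defaults amount 1.0, radius 1.0 px, applied only on request); its
parameters are explicit configuration since no canonical values exist.

## ROI statistics

ROIs are circles specified by center (mm from image center) and area
(mm²); pixels count as inside when their centers fall in the circle — at
the pixel sizes used the mask area is accurate to <2%, and partial-area
weighting would complicate the n used in the error propagation for no
measurable benefit. Means use the sample sd (n−1); the SE of the noise sd
is the large-sample `s/√(2(n−1))`. The gain's uncertainty combines the two
CNR uncertainties in quadrature on the relative scale, and a gain is
suppressed (reported undefined) whenever the attenuation CNR's uncertainty
reaches the CNR itself, since a ratio against a value consistent with zero
is meaningless. Gains round to the nearest integer in reports only.

## Problem sizes and what the tests show

The acceptance-level recovery experiment runs the full noiseless chain at
512² pixels and 720 projections and recovers every tissue's mean µ and δ
within 3% (measured ≤0.7%); stochastic properties (φ noise ∝ 1/√flux,
reconstruction noise ∝ 1/√flux, CNR growth with flux, streak reduction)
use 128–256² grids with 180–301 projections and fixed seeds — sizes chosen
as the smallest that leave the Monte-Carlo estimates comfortably inside
their tolerances. Passing these tests shows the chain is internally
consistent and statistically well-calibrated under the stated model. It
does not validate against real tissue: the phantom has piecewise-constant
tissues with no texture, no beam hardening or scatter background, no
detector blur, a monochromatic beam, 2-D parallel-beam geometry, and a
δ scale deliberately kept inside the no-wrap regime, so absolute CNR and
gain values from simulations characterize the virtual bench, not the
animal experiment.
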
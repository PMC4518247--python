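# Methods

`betaxct` reimplements, end to end, the quantitative computation chain of a
propagation-based phase-contrast microtomography experiment driven by a
laser-plasma (betatron) X-ray source: synthetic beamline simulation, source
characterization, raw-image treatment, single-material phase retrieval, and
filtered back projection into absolute electron density.  This note records
the models, the defaults and their provenance, the numerical choices, and
the known limits of what the synthetic studies demonstrate.

## Physical model

**Source.** Electrons accelerated in a laser wakefield oscillate
transversely at the betatron frequency ω_β = ω_p/√(2γ), where
ω_p = √(n_e e²/ε₀ m_e) is the plasma frequency.  At the betatron-optimised
operating point (n_e = 1.1×10¹⁹ cm⁻³, 200 MeV electrons) the plasma
wavelength is ≈10 μm, a 1 μm oscillation amplitude gives a wiggler parameter
K = γθ ≈ 8.7 (order 10), and the emission merges into a synchrotron-like
continuum E_c = (3/2)ħKγ²ω_β ≈ 8.8 keV.  The spectrum is modelled by the
universal synchrotron function S(x) = x∫ₓ^∞K₅⁄₃(t)dt (peak at 0.286·E_c),
evaluated once by quadrature and cached as a spline.

**Imaging.** A point-projection arm with source–sample distance l and
sample–detector distance d has magnification M = (l+d)/l and defocusing
distance D = dl/(d+l); free-space propagation over D turns transverse phase
gradients into measurable intensity fringes provided the transverse
coherence length l_t = λR/σ exceeds the Fresnel feature scale √(λD).  At
the experiment's arm (l = 0.73 m, d = 1.99 m, M = 3.73) with a 1.8 μm
r.m.s. source, l_t ≈ 100 μm against ≈12 μm — comfortably coherent.

**Material.** The single-material constraint fixes one δ(E)/β(E) ratio for
the whole object.  The demo material is a chitin-like biopolymer
(C₈H₁₃NO₅, ρ = 2.2 g/cm³, n_e = 7.04×10²³ cm⁻³).  δ(E) is computed exactly
from the electron density (valid away from edges), μ(E) is log-log
interpolated from a small built-in mass-attenuation grid (1–20 keV);
measured tables can be plugged in as CSV.  The built-in grids for Al, W, Si
and the chitin-like material follow the standard photoelectric E⁻³ trend
plus a Compton floor with the K/L edge structure sketched at ~10% fidelity —
adequate for methodological round trips, not for metrology against real
filters.

## Synthetic beamline

`polychromatic_radiograph` works in demagnified sample-plane coordinates:
per energy bin, the exit wave exp(ikδ(E)T − μ(E)T/2) of the projected
thickness T is propagated over D by the paraxial transfer function (checked
unitary and, for a knife edge, against the closed-form Fresnel-integral
pattern to <1% r.m.s. over the first three fringes), and the intensities
are summed with weights spectrum × detector response — incoherent
polychromatic superposition, no mutual-intensity formalism.  Finite source
size is a Gaussian blur of σ(M−1) referred to the detector, the projected-
source model behind the wire fit.

Two numerical guards matter.  (i) *Exit-wave sampling*: the phase gradient
scales as δ/λ ∝ 1/E, so soft bins alias on the pixel grid; the grid is
refined per bin until the largest per-sample phase step is below π/2
(capped at 8×), then bin-averaged back — the cap leaves the steepest edge
pixels under-resolved, which is the dominant residual of the forward model.
(ii) *Transfer-function sampling*: propagation raises an explicit error
when λD > NΔx².  Padding is edge-replicating and skipped when the Fresnel
kernel √(λD) is below 1% of the field width.  Polychromatic sums run in
single precision; the knife-edge oracle path stays double.

`acquire_tilt_series` adds the measured shot statistics: Gaussian source
pointing jitter of 12/18 μm r.m.s. (vertical/horizontal) that translates
the image by (M−1)×offset on the detector; a flux factor drawn from a
Gaussian of σ/μ = 0.20 truncated at zero (the data constrain only the
r.m.s.); a Gaussian beam envelope on the chip (FWHM = 2× the field of view
— a free parameter, the measured footprint width being unreported) scaled
to the per-shot photon number; and Poisson counting noise.  The stored
flat reference is the nominal unit-flux envelope, so the per-shot flux is
*not* leaked to the processing chain — it must be (and is) recovered by the
background normalization, as in the real analysis.  Every generator draws
from one mandatory seed; identical seeds give bit-identical series.

## Source characterization

**Spectrum.** The filter-cake transmissions (stepped Al thicknesses, 20–630
μm) are fitted with the one-parameter synchrotron shape: predicted
transmission Σ S(E;E_c)·resp(E)·B(E)·e^(−μ(E)t) / Σ S·resp·B, with B the
always-present blocking foil.  The amplitude is solved analytically per
trial E_c and E_c by bounded 1-D minimization in log E_c.  Noiseless round
trips return E_c to <0.1%; with 5% Gaussian measurement noise the median
error over 100 repeats is ≈8%.

**Source size.** The wire pattern is modelled per energy bin with the
closed-form opaque-strip Fresnel integrals at the demagnified coordinate,
blurred by σ(M−1) and pixel-integrated.  Measured rows are aligned by 1-D
cross-correlation (3-point parabolic sub-pixel peak) to undo wire
curvature, summed, normalized to the far field, and matched in least
squares over a σ grid restricted to the first-overshoot window (geometric
edge to the first minimum past the first maximum), where the source-size
information is concentrated; the grid minimum is refined parabolically.
The round trip against the FFT-simulated wire image (an independent route)
recovers 1.8 μm to within ±0.1 μm.  The quoted confidence half-width is a
curvature heuristic (misfit rise by the per-window residual), floored at
half the grid step.

## Raw-image treatment

Each shot is divided by the nominal flat, background-normalized by a
*divide-mode* second-order polynomial fitted outside the sample mask
(gradient-magnitude edge map, Otsu threshold, dilation, hole filling) —
this absorbs the unknown per-shot flux and residual envelope wander in one
step — and registered to the first shot of its projection by FFT-based
normalized cross-correlation with two orthogonal parabolas through the 3×3
peak, plus one refinement pass after shifting back (≤0.05 px on smooth
fixtures).  Shifts are applied as Fourier phase ramps.  Shots are averaged
per projection and mean-pooled by the bin factor (mean pooling keeps
flat-field ratios normalized).  Vertical stack alignment cross-correlates
row-integrated profiles against the stack median; the horizontal
(rotation-axis) offset is a single user constant.  Whether registration
should chain across angles is left open by the protocol; this
implementation registers within projections only, so residual per-angle
horizontal jitter (≈0.3 binned px at the short arm) remains as
reconstruction noise.

## Phase retrieval

The canonical single-material TIE filter is applied in sample-plane
coordinates: F[I/I0] is divided by 1 + (R/M)(δ_poly/μ_poly)|k|² (unit DC
gain; edge-replicated padding; non-positive filtered intensities clipped at
machine epsilon and counted).  Two inversions of the filtered intensity are
provided:

* `paganin_retrieve` — the classical −ln(·)/μ_poly, exact in the contact
  limit, kept as the reference form and for oracle tests.
* `retrieve_thickness_polychromatic` — the filtered intensity is inverted
  through the *known* detector-weighted transmission curve
  I(T) = Σ w(E)e^(−μ(E)T) (a 2048-point lookup), the standard
  beam-hardening linearization.  Over the soft 1–20 keV band no single
  μ_poly is exact across a 0–900 μm path spread (conventions shift
  reconstructed density by ±10%); the lookup is unbiased at every depth.

Effective constants support two conventions: plain response-weighted means,
and transmission matching at a reference thickness solved self-consistently
from the darkest measured region (3×3 median + σ=2 px Gaussian suppress
Poisson outliers and fringe dips before the fixed point).  The matched
constants feed the filter's δ/μ ratio, to which the result is only weakly
sensitive.  With the parametric deep-depletion CCD response (50 μm silicon,
×E energy weighting, 10 μm Al window) the mean-convention constants come
out at μ_poly ≈ 66 cm⁻¹ and δ_poly ≈ 1.35×10⁻⁵ for the chitin-like
material — close to the values the original analysis derived from its
measured response.

Validity: the filter kernel scale √(D·δ/μ) (≈30–50 μm at the long arm)
must be small against the object.  Objects spanning less than a few kernel
widths sit in the holographic regime where any single-distance TIE method
is strongly biased (measured: −23% on a 64³-limited body at M = 3.7); this
is a regime boundary, not an implementation defect.

Projected thickness converts linearly to phase, φ = −2π δ_poly T/λ_mean,
and to areal electron density.

## Tomography

Row-wise sinograms are inverted with standard FBP (skimage's `iradon`:
frequency-domain ramp, Hann-apodized by default, pure ramp for oracle
tests; linear-interpolation back projection).  Full-turn data are folded to
180° by averaging opposing-angle pairs (using all photons), with the column
flip respecting the FBP centre convention.  Each retrieved projection is
re-zeroed on its measured void (projected thickness in empty beam is zero
by definition) before FBP.  The reconstructed slice is the local material
volume fraction; multiplying by the material's stoichiometric electron
density gives absolute n_e in cm⁻³.  The δ-based bridge
n_e = 2πδ_poly/(r_e λ_mean²) is also implemented but is Jensen-biased
(⟨λ²⟩ > λ(⟨E⟩)² by ~25% over the broad hardened band), so the pipeline uses
the stoichiometric scale.

The density sensitivity is the standard deviation of the void grey values
(≥10³ voxels enforced) — a conservative detectability limit.  Segmentation
is simple thresholding.

## The scaled tomography study

The full protocol (360 projections × 4 shots at 1234×1139 pixels) is
demonstrated on a scaled stand-in: a 64³ insect-like phantom (ellipsoidal
body segments with carved internal voids, kept plump so every projection
spans many retrieval-kernel widths), 90 projections × 2 shots, bin 2.  A
consistent scale-down must preserve the imaging regime: the real specimen
spans ~10–20 Paganin-kernel widths, so the study shrinks the defocusing
distance with the specimen — l = 0.73 m, d = 0.26 m (M = 1.36, kernel
≈25 μm against an ≈800 μm body) — while keeping every stated beam
condition (22.5 μm pixels, 12/18 μm jitter, 20% flux r.m.s., E_c = 4.9 keV
behind 20 μm Al, CCD response).  Photons per shot into the field of view
(1.0×10⁷) follow from the measured 1.2×10⁹ msr⁻¹ fluence and the FOV solid
angle.  Under these conditions the reconstructed in-body median density is
within ~3% of the phantom's 7.04×10²³ cm⁻³.

The void spread combines photon noise with a deterministic streak floor
(≈3×10²¹ cm⁻³ at 90 angles; residual model systematics).  At
fluence-consistent flux the raw void sensitivity lands at a few 10²¹ cm⁻³,
the same order as the full study's quoted 1×10²² cm⁻³ limit.  The
photon-statistics law is demonstrated in the photon-limited regime (4×10⁵
photons/shot): the noise component, isolated by differencing against a
noise-free reconstruction, falls as 1/√(shots averaged) (measured ratios
1.34/1.33 against √2 = 1.41), while the raw sensitivity decreases
monotonically in shots.

## What the synthetic studies do and do not show

The generator emulates the documented statistics (jitter, flux spread,
Poisson noise, Gaussian envelope, polychromatic Fresnel contrast) but not
detector point-spread beyond pixel integration, coherent speckle,
scattering, ring artifacts, or rotation-stage runout; its optics tables are
sketches.  Passing round trips therefore demonstrate the correctness and
internal consistency of the computation chain under the stated noise model
— not the accuracy of the optics tables nor robustness to unmodelled
hardware systematics.  The published tomogram itself is not reproducible:
no raw data are deposited, so all image-level results here are synthetic
by construction.

## Default parameters

| parameter | default | origin |
| --- | --- | --- |
| l, d (tomography arm) | 0.73 m, 1.99 m | protocol |
| wire arm | l = 0.26 m, detector at 3.26 m | protocol |
| detector pixel | 22.5 μm | protocol |
| projections × shots, bin | 360 × 4, 2 | protocol |
| jitter (v, h) | 12, 18 μm r.m.s. | protocol |
| flux fluctuation | 20% r.m.s., truncated Gaussian | r.m.s. documented; law chosen |
| E_c | 4.9 keV | spectral-peak scale of the beam |
| beam filter / CCD foil | 20 μm / 10 μm Al | protocol |
| CCD depletion | 50 μm Si, ×E weighting | typical deep-depletion chip |
| source size | 1.8 μm r.m.s. | measured value |
| envelope FWHM | 2 × field of view | free (unreported) |
| photons per shot | 1.6×10⁷ (full arm) | measured circle count |
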
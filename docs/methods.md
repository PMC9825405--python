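# Methods

This note records the models behind `spectoct`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic tests do and
do not demonstrate about real instrument data.

## Energy calibration

Monochromatisation follows Bragg's law in first order, `E = K / (2 d sin θ)`
with `K = hc = 12.39842 keV·Å` and `d = a / √(h²+k²+l²)` for a cubic
crystal. Defaults are the Si(953) reflection with `a = 5.4309 Å` at room
temperature, giving `d = 0.5064 Å`; both are overridable per call. No
refraction or thermal-expansion corrections are applied — at the precision
the instrument protocol quotes (0.01 keV, 0.1°) they are unresolvable.
The Rowland source–analyser distance is the ideal `R sin θ` (R = 0.5 m
bending radius). At the mid-range Bragg angle 75.15° this evaluates to
48.3 cm, ~1 mm short of the surveyed value quoted for the physical
instrument (48.4 cm); surveyed stage positions include mounting offsets the
ideal Johann geometry does not, so the package reports the ideal figure.

## Near-edge spectra

Each species' mass attenuation is

µ/ρ(E) = (pre-edge line) + J·(½ + arctan((E−E₀)/w)/π) + A·exp(−(E−E_wl)²/2σ²)

with the jump `J`, arctan half-width `w` (eV), and a Gaussian white line of
amplitude `A`, centre `E_wl` and width `σ` (eV). This is standard XANES
phenomenology — smooth, differentiable, adequate for energy selection and
for driving the simulator; it contains no EXAFS oscillations or ab-initio
structure.

Default Se parameters put the edges/white lines at

| species | E₀ (keV) | white line (keV) |
|---------|----------|------------------|
| Se(0)   | 12.6525  | 12.6555          |
| Se(IV)  | 12.6590  | 12.6605          |
| Se(VI)  | 12.6625  | 12.6640          |

about 3 eV per oxidation-state step. These are *plausible placements, not
measurements*: they are constrained only by the acquisition-energy
bracketing (12.645 < all E₀; WL(0) < 12.658 < WL(IV); WL(IV) < 12.662 <
WL(VI); 12.685 above all) and by the qualitative behaviour of adjacent-
energy subtraction (B−A dominated by Se(0), with nonzero residuals from
the higher species — which is why subtraction alone cannot unmix them).
Pre-edge level 7 cm²/g and jump 39 cm²/g reproduce the tabulated ≈46 cm²/g
for elemental Se just above its K edge.

Off-edge anchors (elemental Se above/below edge, PMMA, boron nitride,
cellulose near 12.66 keV) ship as a bundled CSV with standard-table values
rounded to two significant figures; matrix spectra scale between grid
points with the photoelectric `E⁻³` law (variation < 1 % across the
0.26 keV band of interest). XANES normalisation fits a straight line to the
pre-edge region (below `E₀ − 3w`), subtracts it, and scales to unit
trapezoidal area over the plot range; the result is invariant under overall
rescaling of the input.

Column loading uses the areal-density identity `m = µx/(µ/ρ) · π(d/2)²`:
µx = 1 above the Se edge in a 2 mm column gives 0.68 mg ≈ 0.7 mg of Se,
independent of how deep the powder is packed.

## Digital phantom and simulator

The phantom is a PMMA cuboid (8.3 × 8.4 × 13.2 mm, ρ = 1.19 g/cm³) with
three vertical 2 mm holes, 9.6 mm deep; the bottom 7.6 mm of each holds a
BN + Se-species powder mixture, then a 0.5 mm cellulose "tissue" cap and a
2 mm empty margin. The mixture density defaults to 0.5 g/cm³ (loose packed
powder) with the Se mass fraction fixed by the µx ≈ 1 loading
(f = 1/((µ/ρ)·h·ρ_mix) ≈ 0.057, i.e. ≈ 0.68 mg Se per hole). An optional
mass-conserving linear axial gradient on the Se(VI) hole emulates
solvent-transport inhomogeneity toward the cap. Voxelisation uses
fractional-coverage (supersampled) membership, so masses match analytic
volumes to well under 2 % at 50 µm voxels.

Every component is stored as a sum of separable parts
(2-D density map) × (axial profile). Forward projection therefore needs one
parallel-beam sinogram per part (scikit-image's radon transform), reused
across energies; projections at θ ≥ 180° are generated as the *exact
mirror* of θ − 180°, which is the parallel-beam physics and makes the
half-sinogram redundancy exact in expectation mode. A "cone" mode
approximates the divergent secondary-source beam as an in-plane fan from a
point source (sample at ≈ 20 cm, detector at 21 cm), which breaks that
redundancy the way a real divergent beam does; axial divergence and exact
cone-beam reconstruction are out of scope.

The detector model: 256×256 pixels at 55 µm pitch (53 µm effective at the
sample plane, inferred from the instrument's quoted 1.6 px edge resolution
— a calibration, not a printed value), mean flat-field rate 2.6 ph s⁻¹ px⁻¹
with a ±15 % linear horizontal gradient (span 2.2–3.0), strip-gap columns
at x = 60 and 180 at 0.8 relative sensitivity, 30 fixed defunct pixels, and
a Gaussian system PSF of σ = 36 µm (85 µm FWHM). Counts are Poisson with
expectation `flat · exp(−µx)` blurred by the PSF; the PSF is applied before
the gap/defunct sensitivity pattern since the blur originates upstream of
the sensor. All randomness derives from one master seed through per-energy
/ per-angle `SeedSequence` substreams, so any subset of an acquisition
re-simulates bit-identically. The simulator does not model scatter,
fluorescence, analyser bandwidth, charge sharing, or the slowly varying
stray background the real instrument shows — the background-correction
stage is therefore exercised on constructed ramps in the tests, and on real
data it absorbs exactly that kind of structure.

## Reconstruction chain

Conventions: images are (row, col) from the top left; detector row = axial
slice; angles counterclockwise from above; rotation axis at column
`n_cols // 2`.

* **Defunct repair** replaces masked pixels by the median of their valid
  3×3 neighbours, sweeping until interior masked clusters fill in.
* **Flat-field correction**: flats (2 before + 2 after, 1000 s each) are
  averaged and repaired; `µx = −ln(max(N, 0.5) / (flat · t_proj/t_flat))`.
  The 0.5-count floor keeps zero-count pixels finite; at ≥ 20 expected
  counts through the phantom its bias is negligible.
* **Background correction** fits a straight line µx(column) per projection
  angle over configured air margins and subtracts it row-wide; columns
  whose µx exceeds a threshold (default 0.2) before the fit are flagged as
  possible sample overlap (warning, not error). Per-angle fitting was
  chosen over a single global fit because it also absorbs slow drifts.
* **FBP** delegates to scikit-image's `iradon` (frequency-domain ramp
  filter with power-of-two zero padding, linear-interpolation
  backprojection, optional raised-cosine-family apodisation), scaled by
  the sample-plane pixel size to yield µ in 1/cm. An optional rotation-axis
  offset can be estimated by opposing-view cross-correlation.
* **Half-sinogram check** maps [180°, 360°) onto [0°, 180°) by the mirror
  convention above, reconstructs the halves separately and reports the
  normalised RMS difference: exactly zero for ideal parallel data, positive
  under beam divergence or noise.

## Speciation

Tomograms at the four energies form `y = C x` per voxel. C is estimated by
summing each tomogram over one ROI per component (axis-aligned boxes,
explicit in the configuration and echoed to the run log); the solve is a
rank-revealing least-squares (`lstsq`), exact inverse in the square case,
with the condition number reported and a warning threshold at 10⁶.
Component maps are written unclipped — negative values are retained so the
linear model stays verifiable downstream.

Because the ROI sums *define* the columns of C, the ROI means of the
decomposed maps over those same ROIs equal unit vectors identically — that
is an algebraic property, not evidence of recovery. The pipeline therefore
holds out the second half of the reconstructed slices: C is estimated on
the first half and recovery is quantified on the held-out half as the
per-component Pearson correlation between ROI means of x and the
ground-truth densities. At the default photon budget (≈ 35 counts through
the phantom centre) the per-voxel maps are noise-dominated (voxelwise SNR
below 1 after unmixing); recovery is meaningful at ROI scale, which is how
such data are read in practice.

## Resolution metrology

Edge profiles inside a configured box are differentiated row by row
(adjacent differences), a Gaussian + offset is fitted to each line spread
function (moment-based initial values), and the FWHM = 2.355 σ is averaged
with its standard error. The adjacent-difference operator is a 1 px box
filter adding 1/12 px² of variance, which is subtracted before reporting —
without this the estimator is biased +4 % at σ = 1 px. Rows are rejected
(and counted) when the fit diverges, the amplitude is non-positive, the
centre leaves the window, or the FWHM exceeds the window; spike-like LSFs
narrower than the sampling floor fall back to moment widths and the result
is flagged resolution-limited (≤ 2 px). On simulated projections with the
36 µm PSF the estimator reports ≈ 1.8 px FWHM: the phantom's antialiased
edge and pixel sampling broaden the ideal 1.6 px slightly.

## Problem sizes and limitations

The shipped presets are `full-scale` (full protocol: 4 energies ×
200 angles × 256×256 at 100 s, reconstructing five axial slices across the
filled section — the five-slice choice keeps a full-scale end-to-end run
interactive while sampling the whole fill), `smoke` (64×64, 40 angles,
4× coarser voxels) and `cone-demo` (smoke-sized, fan-beam mode,
noise-free). Tests run on these synthetic conditions; passing them shows
the chain is internally consistent and recovers known ground truth under
the modelled physics. It does not certify behaviour under un-modelled
effects of real data — scatter backgrounds, spectral bandwidth, detector
nonuniformity beyond the gradient/gap/defunct model, or axis wobble. The
published measured resolutions of the physical instrument (85 µm
projection, 226 µm tomogram) come from its deposited dataset and are not
reproduced here; the metrology is instead validated against known
synthetic blurs.
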
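# Methods

This note documents the models behind each pipeline, the parameters that
matter, what the synthetic scenes do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Design calculus (`lfspim.design`)

All relations are closed-form:

* Etendue `G = (π/4)(FOV·NA)²` (mm²), quadratically homogeneous in the
  FOV·NA product. Note that for one published large-field metrology lens
  (FOV 16.8 mm, NA 0.305) a figure of 19.65 mm² circulates that is
  inconsistent with this formula, which gives 20.62 mm²; the toolkit always
  reports the formula value and makes no special case.
* Object sampling `pitch/M` (µm/px); Nyquist-limited resolution `2·pitch/M`.
* Voxel rate `pixels_per_row / line_time` for a single-sided rolling
  shutter. Reported integer rates truncate to whole megavoxels/s, matching
  the convention used when such rates are quoted (14192 px / 15.00 µs →
  946 × 10⁶; / 45.44 µs → 312 × 10⁶). The 14-bit mode (20.15 µs) computes to
  704.07 × 10⁶ and is reported as 704.
* Effective resolution `optical/expansion`; native extents `extent/expansion`.
  Reported lengths round half-up at the quoted precision; raw values are
  always retained in outputs.
* Light-collection ratio `(NA_ref/NA_test)²`.
* Depth of field `λ·n/NA²` — the classical diffraction convention, adopted
  here so field curvature can be expressed in DoF units. Other conventions
  (e.g. including a pixel term) exist; this one is used consistently.
* Tile planning: per axis, `n = 1` if the extent fits one FOV, else
  `⌈(extent − FOV)/(FOV·(1 − overlap))⌉ + 1`, with the step then relaxed to
  `(extent − FOV)/(n − 1)` so the grid exactly spans the extent — this can
  only increase overlap beyond the requested fraction. Tiles are
  axis-aligned with origin at the sample bounding-box corner; the z axis is
  covered by the stage scan, not tiling. Two working-distance figures
  circulate for the excitation lens of the reference instrument (39 mm in
  air / ~52 mm in water vs. 53 mm); both are recorded here, neither is used
  in any computation.

Internally lengths are carried in the units of their argument names
(mm at lens/stage scale, µm at sensor/voxel scale); conversions happen at
the few mm↔µm boundaries only.

## Camera noise model (`lfspim.synth.CameraNoiseModel`)

Counts = `gain · Poisson(signal/gain) + N(0, read_noise) + offset`, rounded
and clipped to the bit-depth range. A uniform patch then satisfies the
photon-transfer relation `var = gain·(mean − offset) + read_noise²` (tested
at 10⁶ samples, 5%). Defaults (offset 100, read noise 2 counts RMS, gain 1
count/e⁻) are generic sCMOS-like figures chosen once for realism; they
describe no particular physical camera.

## Bead phantoms and PSF quantification

**Generator.** Beads are rendered as *integrated* anisotropic Gaussians —
each voxel receives the cell-averaged value (difference of error functions
per axis) at the bead's sub-voxel position. A Gaussian of matched FWHM is
the standard surrogate when the quantity measured is FWHM; no diffraction
structure (Airy rings, axial side lobes) is modelled. Default scene
parameters emulate a dispersed sub-diffraction bead gel: peak 10,000 counts,
uniform background 200 counts, FWHM at or above ~2 voxels per axis (the
generator refuses FWHM below 1 voxel as unresolvable). Placement is uniform
by default; `jittered_grid` jitters beads around a 3-D lattice, which keeps
high-density phantoms within the separation constraint the way a
well-dispersed, non-aggregated bead sample would. If more than 5% of beads
have a neighbour within 3× their FWHM (3-D distance), the generator refuses
rather than producing a phantom whose fits would be silently corrupted.

**Pipeline.** Detection: volume median as background, scaled median absolute
deviation as the noise floor, 3³ local maxima above
`background + snr_threshold·noise`, then greedy non-maximum suppression in
physical units (brighter peak wins); candidates are returned in (z, y, x)
order so runs are deterministic. Fitting: per bead, the ROI's outer
one-voxel shell provides a robust (median) background; the centroid is
refined by intensity weighting; 1-D profiles along x, y, z through the
centroid are each fit by `a·exp(−(x−µ)²/2σ²) + c`. FWHM = 2√(2 ln 2)·σ,
converted to µm by the voxel size. Because voxel values are cell averages,
the fitted variance is inflated by ≈ 1/12 voxel²; the pipeline subtracts
this pixel-integration term before reporting. Saturated (any ROI voxel at
the bit-depth maximum), edge-clipped, clumped (closer than 3× FWHM), and
non-converging beads are flagged — never exceptions — and excluded from
field maps. Fit weighting across beads is a simple (unweighted) mean per
field bin; bins with no beads are NaN and marked empty, never zero.

A 1-D-profile fit was chosen over a full 3-D Gaussian fit: it is what the
FWHM definition operationally measures, it is ~10× faster at equal accuracy
on well-separated beads (closed-loop recovery is better than 1% median
error at realistic noise), and its failure modes are per-axis and therefore
diagnosable. Users who need joint fits can treat the module's measurements
as initial values.

## Through-focus contrast and field curvature

**Generator.** A binary square-wave ruling (period ≥ 4 px, bars along y)
is blurred along the modulation axis by a Gaussian whose width follows
`σ(dz) = σ₀ + slope·|z − z₀(x, y)|` around a configurable best-focus
surface `z₀`. This guarantees a symmetric contrast-versus-depth curve
peaked at `z₀` — the property the estimator depends on — without modelling
the instrument's true through-focus optical transfer function. Blur σ is
quantized to 256 levels and the focus surface to 1024 depth levels so each
frame reduces to two table lookups; both quanta are far below the fit
precision at a 1 µm z step. A constant σ produces the degenerate
contrast-flat scene the estimator must reject.

**Pipeline.** The frame stack is split into a grid of contiguous ROIs
(default 16×16; remainder pixels go to the last row/column — a
14192×10640 frame yields exactly 887×665-px ROIs). Per ROI and frame the
percentile contrast `C = (I₉₅ − I₅)/(I₉₅ + I₅)` is computed (invariant
under gain changes; undefined and an error for all-zero frames). C(z) is
fit by a Gaussian **plus baseline** — a pure normal PDF cannot represent
the nonzero background contrast a real curve has far from focus. The fit
runs in a window of ±8 half-widths around the observed peak: the scan range
(2 mm) is two orders of magnitude wider than the contrast peak, and a
global fit over the flat baseline is poorly conditioned. `fit_ok` is false
for flat curves (fitted amplitude below 3× residual RMS), centres outside
the scan, or non-convergence.

Best-focus depths are radially averaged about the field centre in one ring
per ROI ring (8 rings for 16×16; ring binning was chosen over continuous
radius for robustness at 256 samples). Shifts are reported relative to the
innermost ring — the profile is 0 at the centre by construction — and
optionally in DoF units via `design.depth_of_field`. Wavebands are
independent runs; no joint chromatic fit. The recovered focus of an ROI is
a pooled property of its pixels: where the surface varies strongly *within*
one ROI the pooled peak can differ from the centre-pixel depth by a
fraction of that internal spread, which bounds accuracy for very steep
surfaces.

## Dot-grid distortion

**Generator.** Dark dots on a bright background (trans-illuminated target
polarity), anti-aliased linearly over one pixel, placed on a square lattice
anchored at the image centre and displaced radially by
`r → r(1 + k1·r² + k2·r⁴)`. Dots whose distorted footprint would leave the
frame cause a refusal — dots are never rendered partially. The default test
geometry mirrors a 125 µm-dot / 250 µm-pitch target sampled at 0.75 µm/px
(≈167/333 px), scaled down proportionally where speed matters.

**Pipeline.** Otsu threshold → connected components → area filter; border-
touching components are rejected into a diagnostics list. Centroids are
intensity-weighted using background-subtracted absorption, which recovers
the dots' coverage function and gives sub-0.05 px accuracy on clean
renderings. The theoretical lattice is anchored at the detected dot nearest
the image centre (where radial distortion vanishes to first order); axes
take their *directions* from that dot's nearest neighbours and their
*length* from the nominal spacing, so distortion at large radii cannot leak
into the lattice estimate. (A global least-squares lattice fit is the
obvious alternative; it was rejected as the default because the distortion
itself would bias it, but the per-dot table retains everything needed to
apply one downstream.) Assignments to nearest lattice nodes must be
injective; collisions flag both dots. Percent distortion is
`100·(r_meas − r_theo)/r_theo` with radii measured from the distortion
centre — a scalar radial normalization, matching the radially averaged
scalar profile; tangential residuals remain available in the table as
diagnostics. The centre dot (r_theo = 0) is excluded. `k1` (and optionally
`k2`) are recovered by least squares of `percent/100` against `r²` (`r⁴`).
Coordinates are pixel-centred, (0, 0) at the top-left pixel centre.

## Camera sensitivity

SNR of a bead is `(signal − background mean)/background RMS`, with signal
the **peak voxel** in a sphere around the bead (an integrated mode exists
behind a flag; peak was chosen as the default because single-voxel peak
height is what axon-scale features live or die by). The background annulus
must hold ≥ 100 voxels and no other bead; noiseless input is an error
because the ratio is undefined. `snr_vs_rate` sweeps the rolling-shutter
line time (= per-row dwell), scaling expected photon counts linearly with
dwell and pairing each point with `pixels_per_row/line_time`. In the
shot-noise limit this yields SNR ∝ √dwell; at low counts read noise makes
the curve steeper than √dwell. Using the peak voxel introduces a small
positive bias (the maximum of noisy voxels) that is negligible at the
default photon budgets but grows at very low counts. The instrument-level
camera comparison is reproduced *directionally* — a 14192-px-row sensor
reaches a given SNR at several times the voxel rate of a 2048-px-row sensor
with equal per-pixel noise — not numerically, which would require the
physical cameras.

## I/O and provenance

Stacks move as `Volume3D` (z, y, x; voxel sizes in µm). TIFF round-trips
voxel size through a JSON description tag; OME-Zarr groups carry
`multiscales` metadata with a full-resolution level "0" and a 2×-strided
level "1" (small chunks suited to fixtures, not production). A missing
voxel size is an explicit error, never a silent default. Every JSON report
carries a schema version and a provenance block (package version, seed,
config echo) and is written with sorted keys so identical runs are
byte-identical.

## Problem sizes used in validation

Closed-loop validation uses: a 1,000-bead phantom on a 48×1024×1024 grid at
(1.0, 0.75, 0.75) µm voxels (median FWHM recovery error < 5% per axis,
typically < 1%); twenty random parabolic/quartic focus surfaces within
±50 µm, scanned at 1 µm steps over 2 mm on 512×512 frames with a 16×16 ROI
grid (max recovery error ≤ 2 µm); dot grids at 130 px spacing spanning
`k1·r_max² ∈ [10⁻⁴, 10⁻²]` (k1 within 10%); and SNR sweeps over a decade of
dwell times (√dwell within 5%). The large through-focus stacks are
generated noiseless: percentile contrast over ≥ 1,000-pixel ROIs is
insensitive to photon noise, and noise robustness of the focus fit is
covered separately by a 500-replicate Monte-Carlo test and a noisy
end-to-end scene.

## Known limitations

* Bead rendering is Gaussian; diffraction side lobes, aberration-induced
  PSF asymmetry, and chromatic PSF differences are not emulated.
* Defocus blur of the ruling is 1-D Gaussian with σ linear in |dz|; no
  pupil-based through-focus model.
* Distortion is radial (k1, k2) only — no tangential/decentering terms, and
  the toolkit measures but never resamples images.
* Field curvature is measured per waveband; chromatic focal shift between
  wavebands is reported only implicitly by comparing runs.
* No aberration (Strehl) model: the observation that lower-NA systems
  degrade more slowly with index inhomogeneity is noted qualitatively in
  the design module's documentation, not modelled.
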
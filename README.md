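# lfspim

Design calculus and image-based characterization for **large-field selective
plane illumination microscopes** (SPIM) — instruments that pair low-NA,
very-large-etendue detection lenses (often from the electronics-metrology
world) with large-format CMOS sensors to image expanded, cleared,
centimeter-scale tissue.

The toolkit serves two audiences:

* **Instrument designers**, who need the closed-form arithmetic that relates
  lens, sensor, and tissue-expansion choices to resolution, coverage, and
  speed;
* **Instrument builders**, who need reproducible image-based pipelines to
  characterize a finished system: PSF size across the field, field
  curvature, geometric distortion, and camera sensitivity.

Every measurement pipeline ships with a seeded synthetic-scene generator
producing ground-truthed phantoms, so the whole toolkit is testable without
a microscope.

## The quantities at the core

* **Etendue** `G = (π/4)(FOV·NA)²` — the optical throughput of a lens,
  proportional to its number of resolvable elements. A lens with FOV
  = 6 mm and NA = 0.47 has G = 6.25 mm²; FOV = 14 mm at NA = 0.35 gives
  G = 18.86 mm².
* **Object sampling** `pitch/M` and **Nyquist-limited resolution**
  `2·pitch/M` — e.g. a 3.76 µm-pitch sensor behind 5.0× magnification
  samples at 0.75 µm/px, for a sampling-limited resolution of 1.5 µm.
* **Voxel rate** `pixels_per_row / line_time` for a rolling-shutter sensor —
  14192-pixel rows read in 15.00 µs stream 946 × 10⁶ voxels/s.
* **Effective resolution** `optical resolution / expansion factor` — 1.5 µm
  optics at 3× tissue expansion resolve 0.5 µm in native tissue units.
* **PSF FWHM** `2√(2 ln 2)·σ` per axis from Gaussian fits to detected beads.
* **Percentile contrast** `C = (I₉₅ − I₅)/(I₉₅ + I₅)` per frame of a
  through-focus Ronchi-ruling scan; a Gaussian-plus-baseline fit of C(z)
  locates best focus per field position.
* **Percent distortion** `100·(r_meas − r_theo)/r_theo` per dot of a
  calibration grid, radially averaged.
* **SNR** `(signal − background mean)/background noise` for a bead, swept
  against imaging speed.

## Worked example

Design report for a 16.8 mm-FOV, NA 0.305, 5.0× metrology lens on a
151-megapixel rolling-shutter sensor, imaging 3×-expanded tissue:

```bash
lfspim design --fov-mm 16.8 --na 0.305 --mag 5.0 \
              --pitch-um 3.76 --rows 10640 --cols 14192 \
              --line-time-us 15.0 --expansion 3.0
```

prints (abridged):

```json
{
  "etendue_mm2_rounded": 20.62,
  "megapixels_rounded": 151,
  "sensor_fov_mm": {"width": 10.672384, "height": 8.00128, "diagonal_rounded": 13.3},
  "object_sampling_rounded": 0.75,
  "nyquist_resolution_rounded": 1.5,
  "readout": {"12": {"line_time_us": 15.0, "megavoxels_per_s": 946}},
  "effective_lateral_resolution_um": 0.5013
}
```

i.e. this lens/sensor pair covers a 10.6 × 8.0 mm field (13.3 mm diagonal)
at 0.75 µm/px, is Nyquist-limited to 1.5 µm, streams 946 megavoxels/s in
12-bit mode, and reaches ~0.5 µm effective lateral resolution in the
un-expanded tissue frame.

Characterizing a (synthetic) instrument from Python:

```python
import lfspim
from lfspim.synth import CameraNoiseModel, make_bead_phantom

vol, truth = make_bead_phantom(
    (48, 512, 512), 300, (1.5, 1.5, 3.0), peak_counts=10000,
    background_counts=200, noise=CameraNoiseModel(), seed=1,
    voxel_size_um=(1.0, 0.75, 0.75), placement="jittered_grid")
mapper = lfspim.PSFFieldMapper(n_bins=(4, 4), min_separation_um=4.0).fit(vol)
print(mapper.n_used_, "beads;",
      round(float(mapper.field_map_.mean_lateral_um.mean()), 2), "um lateral FWHM")
# -> 300 beads; 1.5 um lateral FWHM
```

The equivalent CLI pipelines are `lfspim simulate`, `lfspim psf`,
`lfspim curvature`, `lfspim distortion`, and `lfspim snr`; each reads
TIFF/OME-Zarr input and writes a schema-versioned JSON report plus CSV
tables.

## Layout

| module | contents |
| --- | --- |
| `lfspim.design` | lens/sensor/expansion specs, etendue, sampling, voxel rates, tile planning |
| `lfspim.synth` | seeded generators: bead phantoms, through-focus Ronchi stacks, dot grids, camera noise |
| `lfspim.psf` | bead detection, per-bead FWHM fits, `PSFFieldMapper` |
| `lfspim.curvature` | percentile contrast, best-focus fits, `FieldCurvatureMapper` |
| `lfspim.distortion` | dot segmentation, lattice matching, `DotGridDistortion` |
| `lfspim.snr` | bead SNR, SNR-vs-rate sweeps, relative SNR |
| `lfspim.io` | `Volume3D`, TIFF/OME-Zarr readers and writers, JSON/CSV reports |
| `lfspim.cli` | `lfspim` command-line entry point |

Estimators follow scikit-learn conventions (constructor parameters,
`fit`, fitted attributes with trailing underscores, `get_params`/
`set_params`), so they compose with sklearn tooling.

See `docs/methods.md` for the measurement models, their assumptions, and
known limitations.
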
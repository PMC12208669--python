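"""Closed-form design calculus for large-field selective plane illumination microscopes.

The functions here relate detection-lens parameters (field of view, numerical
aperture), camera sensor geometry (pixel counts, pitch, rolling-shutter line
time), and tissue expansion factor to the quantities a designer actually cares
about: optical throughput (etendue), object-space sampling and Nyquist-limited
resolution, voxel rates, effective resolution in native tissue units, and the
tile grid needed to cover a specimen.

Conventions
-----------
* Lengths are carried in the units their argument names state: ``_mm`` for
  lens/stage-scale quantities, ``_um`` for sensor/voxel-scale ones.
* ``round_half_up`` reproduces the half-up rounding used for printed lengths;
  voxel rates are reported truncated to whole megavoxels per second.  Raw
  (unrounded) values are always what the functions return; rounding is applied
  only by the reporting helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, NamedTuple, Sequence

import yaml

__all__ = [
    "LensSpec",
    "SensorSpec",
    "ExpansionSpec",
    "TilePlan",
    "SensorGeometry",
    "etendue",
    "object_sampling",
    "nyquist_resolution",
    "sensor_geometry",
    "voxel_rate",
    "megavoxel_rate",
    "effective_resolution",
    "native_volume",
    "light_collection_ratio",
    "plan_tiles",
    "depth_of_field",
    "design_report",
    "round_half_up",
    "load_specs",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used for printed lengths)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Static specification records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LensSpec:
    """Detection (or excitation) lens parameters.

    Parameters
    ----------
    fov_mm : field-of-view diameter in the object plane, mm.
    na : numerical aperture, ``0 < na < medium_ri``.
    magnification : lateral magnification onto the sensor, > 0.
    wd_mm : working distance, mm (informational; not used in the calculus).
    medium_ri : refractive index of the immersion medium, >= 1.
    """

    fov_mm: float
    na: float
    magnification: float = 1.0
    wd_mm: float | None = None
    medium_ri: float = 1.33

    def __post_init__(self) -> None:
        if self.fov_mm <= 0:
            raise ValueError(f"fov_mm must be > 0, got {self.fov_mm}")
        if self.medium_ri < 1:
            raise ValueError(f"medium_ri must be >= 1, got {self.medium_ri}")
        if not 0 < self.na < self.medium_ri:
            raise ValueError(
                f"na must satisfy 0 < na < medium_ri ({self.medium_ri}), got {self.na}"
            )
        if self.magnification <= 0:
            raise ValueError(f"magnification must be > 0, got {self.magnification}")


@dataclass(frozen=True)
class SensorSpec:
    """Camera sensor geometry and rolling-shutter timing.

    ``line_time_us`` maps bit-depth mode (12 | 14 | 16) to the time needed to
    read one sensor row, in microseconds.
    """

    pixels_h: int
    pixels_v: int
    pitch_um: float
    line_time_us: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixels_h <= 0 or self.pixels_v <= 0:
            raise ValueError("pixel counts must be positive integers")
        if self.pitch_um <= 0:
            raise ValueError(f"pitch_um must be > 0, got {self.pitch_um}")
        for mode, lt in self.line_time_us.items():
            if lt <= 0:
                raise ValueError(f"line time for {mode}-bit mode must be > 0, got {lt}")

    @property
    def megapixels(self) -> float:
        return self.pixels_h * self.pixels_v / 1e6


@dataclass(frozen=True)
class ExpansionSpec:
    """Linear tissue expansion factor (1 = no expansion)."""

    factor: float = 1.0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError(f"expansion factor must be >= 1, got {self.factor}")


# ---------------------------------------------------------------------------
# Scalar design relations
# ---------------------------------------------------------------------------


def etendue(fov_mm: float, na: float) -> float:
    """Optical throughput G = (pi/4) * (FOV * NA)**2 in mm^2.

    G is proportional to the number of resolvable elements the lens can
    deliver; it is quadratically homogeneous in the FOV*NA product.
    """
    if fov_mm < 0 or na < 0:
        raise ValueError("fov_mm and na must be non-negative")
    return math.pi / 4.0 * (fov_mm * na) ** 2


def object_sampling(pitch_um: float, magnification: float) -> float:
    """Object-plane sampling in micrometres per pixel: pitch / magnification."""
    if pitch_um <= 0 or magnification <= 0:
        raise ValueError("pitch_um and magnification must be > 0")
    return pitch_um / magnification


def nyquist_resolution(object_sampling_um: float) -> float:
    """Sampling-limited resolution (Nyquist criterion): 2 x object sampling."""
    if object_sampling_um <= 0:
        raise ValueError("object sampling must be > 0")
    return 2.0 * object_sampling_um


class SensorGeometry(NamedTuple):
    fov_w_mm: float
    fov_h_mm: float
    diag_mm: float
    megapixels: float


def sensor_geometry(sensor: SensorSpec, lens: LensSpec) -> SensorGeometry:
    """Object-plane field of view and pixel count implied by sensor + lens."""
    w_mm = sensor.pixels_h * sensor.pitch_um / lens.magnification / 1000.0
    h_mm = sensor.pixels_v * sensor.pitch_um / lens.magnification / 1000.0
    return SensorGeometry(
        fov_w_mm=w_mm,
        fov_h_mm=h_mm,
        diag_mm=math.hypot(w_mm, h_mm),
        megapixels=sensor.megapixels,
    )


def voxel_rate(pixels_per_row: float, line_time_us: float) -> float:
    """Voxels per second from a rolling-shutter readout: row width / line time."""
    if pixels_per_row <= 0 or line_time_us <= 0:
        raise ValueError("pixels_per_row and line_time_us must be > 0")
    return pixels_per_row / (line_time_us * 1e-6)


def megavoxel_rate(pixels_per_row: float, line_time_us: float) -> int:
    """Voxel rate truncated to whole megavoxels/s (the printed convention)."""
    return int(voxel_rate(pixels_per_row, line_time_us) / 1e6)


def effective_resolution(optical_resolution_um: float, expansion: ExpansionSpec | float) -> float:
    """Resolution in native tissue units: optical resolution / expansion factor."""
    factor = expansion.factor if isinstance(expansion, ExpansionSpec) else float(expansion)
    if optical_resolution_um <= 0:
        raise ValueError("optical_resolution_um must be > 0")
    if factor < 1:
        raise ValueError(f"expansion factor must be >= 1, got {factor}")
    return optical_resolution_um / factor


def native_volume(
    extent_mm_xyz: Sequence[float], expansion: ExpansionSpec | float
) -> tuple[float, ...]:
    """Native tissue extents (mm): each gel-state extent / expansion factor."""
    factor = expansion.factor if isinstance(expansion, ExpansionSpec) else float(expansion)
    if factor < 1:
        raise ValueError(f"expansion factor must be >= 1, got {factor}")
    if any(e <= 0 for e in extent_mm_xyz):
        raise ValueError("extents must be > 0")
    return tuple(e / factor for e in extent_mm_xyz)


def light_collection_ratio(na_ref: float, na_test: float) -> float:
    """Fold change in collected signal between two apertures: (na_ref/na_test)**2."""
    if na_ref <= 0 or na_test <= 0:
        raise ValueError("numerical apertures must be > 0")
    return (na_ref / na_test) ** 2


def depth_of_field(na: float, wavelength_um: float, medium_ri: float = 1.33) -> float:
    """Classical diffraction depth of field: lambda * n / NA**2, in micrometres.

    Used to express field curvature in DoF units; the lambda*n/NA^2 form is a
    documented convention of this toolkit.
    """
    if not 0 < na < medium_ri:
        raise ValueError(f"na must satisfy 0 < na < medium_ri, got {na}")
    if wavelength_um <= 0:
        raise ValueError("wavelength_um must be > 0")
    return wavelength_um * medium_ri / na**2


# ---------------------------------------------------------------------------
# Tile planning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TilePlan:
    """Axis-aligned tile grid covering a rectangular extent.

    Tiles are placed with their lower-left corners at ``origins`` (mm, same
    frame as the requested extent, origin at the sample bounding-box corner).
    ``step_mm`` is the centre-to-centre step per axis; adjacent tiles overlap
    by at least ``overlap_frac`` of the FOV on that axis.  The z axis is
    covered by the stage scan, not by tiling.
    """

    nx: int
    ny: int
    step_mm: tuple[float, float]
    overlap_frac: float
    fov_mm: tuple[float, float]
    extent_mm: tuple[float, float]
    origins: tuple[tuple[float, float], ...]

    @property
    def n_tiles(self) -> int:
        return self.nx * self.ny


def _axis_tiles(extent: float, fov: float, overlap: float) -> tuple[int, float]:
    if extent <= fov:
        return 1, 0.0
    n = math.ceil((extent - fov) / (fov * (1.0 - overlap))) + 1
    # Spread tiles so the last one ends exactly at the extent; this can only
    # increase the realized overlap beyond the requested fraction.
    step = (extent - fov) / (n - 1)
    return n, step


def plan_tiles(
    extent_mm_xy: Sequence[float],
    fov_mm_xy: Sequence[float],
    overlap_frac: float = 0.15,
) -> TilePlan:
    """Minimal axis-aligned tile grid covering ``extent_mm_xy``.

    Per axis the tile count is 1 if the extent fits in one FOV, else
    ``ceil((extent - fov) / (fov * (1 - overlap))) + 1``.
    """
    ex, ey = float(extent_mm_xy[0]), float(extent_mm_xy[1])
    fx, fy = float(fov_mm_xy[0]), float(fov_mm_xy[1])
    if ex <= 0 or ey <= 0 or fx <= 0 or fy <= 0:
        raise ValueError("extents and FOV must be > 0")
    if not 0 <= overlap_frac < 1:
        raise ValueError(f"overlap_frac must be in [0, 1), got {overlap_frac}")
    nx, sx = _axis_tiles(ex, fx, overlap_frac)
    ny, sy = _axis_tiles(ey, fy, overlap_frac)
    origins = tuple(
        (i * sx, j * sy) for j in range(ny) for i in range(nx)
    )
    return TilePlan(
        nx=nx,
        ny=ny,
        step_mm=(sx, sy),
        overlap_frac=overlap_frac,
        fov_mm=(fx, fy),
        extent_mm=(ex, ey),
        origins=origins,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def design_report(
    lens: LensSpec,
    sensor: SensorSpec,
    expansion: ExpansionSpec | None = None,
    axial_resolution_um: float | None = None,
) -> dict:
    """Full design summary for one lens/sensor/expansion combination.

    Returns a plain dict (JSON-serializable) with raw values and, where the
    field convention rounds for reporting, the rounded counterparts.
    """
    expansion = expansion or ExpansionSpec(1.0)
    geom = sensor_geometry(sensor, lens)
    sampling = object_sampling(sensor.pitch_um, lens.magnification)
    nyq = nyquist_resolution(sampling)
    rates = {
        str(mode): {
            "line_time_us": lt,
            "voxel_rate_per_s": voxel_rate(sensor.pixels_h, lt),
            "megavoxels_per_s": megavoxel_rate(sensor.pixels_h, lt),
        }
        for mode, lt in sorted(sensor.line_time_us.items())
    }
    report = {
        "lens": {
            "fov_mm": lens.fov_mm,
            "na": lens.na,
            "magnification": lens.magnification,
            "wd_mm": lens.wd_mm,
            "medium_ri": lens.medium_ri,
        },
        "etendue_mm2": etendue(lens.fov_mm, lens.na),
        "etendue_mm2_rounded": round_half_up(etendue(lens.fov_mm, lens.na), 2),
        "sensor_fov_mm": {
            "width": geom.fov_w_mm,
            "height": geom.fov_h_mm,
            "diagonal": geom.diag_mm,
            "diagonal_rounded": round_half_up(geom.diag_mm, 1),
        },
        "megapixels": geom.megapixels,
        "megapixels_rounded": int(round_half_up(geom.megapixels, 0)),
        "object_sampling_um_per_px": sampling,
        "object_sampling_rounded": round_half_up(sampling, 2),
        "nyquist_resolution_um": nyq,
        "nyquist_resolution_rounded": round_half_up(nyq, 1),
        "readout": rates,
        "expansion_factor": expansion.factor,
        "effective_lateral_resolution_um": effective_resolution(nyq, expansion),
    }
    if axial_resolution_um is not None:
        report["effective_axial_resolution_um"] = effective_resolution(
            axial_resolution_um, expansion
        )
    return report


def load_specs(path) -> dict:
    """Load LensSpec/SensorSpec/ExpansionSpec from a YAML config file.

    The file may contain any of the top-level keys ``lens``, ``sensor``,
    ``expansion``; each maps to constructor keyword arguments.  Sensor line
    times may use integer or string bit-depth keys.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    if "lens" in raw:
        out["lens"] = LensSpec(**raw["lens"])
    if "sensor" in raw:
        s = dict(raw["sensor"])
        if "line_time_us" in s:
            s["line_time_us"] = {int(k): float(v) for k, v in s["line_time_us"].items()}
        out["sensor"] = SensorSpec(**s)
    if "expansion" in raw:
        exp = raw["expansion"]
        out["expansion"] = ExpansionSpec(**exp) if isinstance(exp, dict) else ExpansionSpec(float(exp))
    return out
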
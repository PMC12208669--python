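"""Bead detection, per-bead FWHM fitting, and PSF field maps.

The pipeline mirrors how large light-sheet instruments are characterized:
image a gel of sub-diffraction fluorescent microspheres, detect thousands of
beads across the field of view, fit each bead's lateral and axial full width
at half maximum, and aggregate the fits into a map of PSF size versus field
position.

Fits are 1-D Gaussians along the three axes through the refined centroid
(FWHM = 2*sqrt(2 ln 2) * sigma, converted to micrometres via the voxel
size).  Background is the median of the ROI's outer one-voxel shell, which is
robust to neighbouring beads.  Saturated, edge-clipped, clumped, and
non-converging beads are flagged and excluded from maps, never raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from lfspim.io import Volume3D
from lfspim.synth import FWHM_PER_SIGMA

__all__ = [
    "BeadMeasurement",
    "PSFFieldMap",
    "PSFFieldMapper",
    "detect_beads",
    "fit_bead",
    "flag_clumped",
    "aggregate_field_map",
    "measurements_to_frame",
]


@dataclass
class BeadMeasurement:
    """One bead's sub-voxel position, per-axis FWHM, and quality flags."""

    position_um: tuple[float, float, float]  # (x, y, z)
    position_vox: tuple[float, float, float]  # (z, y, x)
    fwhm_x_um: float
    fwhm_y_um: float
    fwhm_z_um: float
    peak: float
    fit_quality: tuple[float, float, float]  # R^2 per axis (x, y, z)
    flags: set[str] = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return not self.flags

    @property
    def lateral_fwhm_um(self) -> float:
        return 0.5 * (self.fwhm_x_um + self.fwhm_y_um)


@dataclass
class PSFFieldMap:
    """Binned field map of lateral and axial FWHM.

    Bins with no beads are NaN and marked in ``empty`` — they are never
    reported as zero.
    """

    x_edges_um: np.ndarray
    y_edges_um: np.ndarray
    mean_lateral_um: np.ndarray  # (ny_bins, nx_bins)
    std_lateral_um: np.ndarray
    mean_axial_um: np.ndarray
    std_axial_um: np.ndarray
    n_beads: np.ndarray
    empty: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        ny, nx = self.mean_lateral_um.shape
        xc = 0.5 * (self.x_edges_um[:-1] + self.x_edges_um[1:])
        yc = 0.5 * (self.y_edges_um[:-1] + self.y_edges_um[1:])
        rows = [
            {
                "x_um": xc[i],
                "y_um": yc[j],
                "mean_lateral_um": self.mean_lateral_um[j, i],
                "std_lateral_um": self.std_lateral_um[j, i],
                "mean_axial_um": self.mean_axial_um[j, i],
                "std_axial_um": self.std_axial_um[j, i],
                "n_beads": int(self.n_beads[j, i]),
            }
            for j in range(ny)
            for i in range(nx)
        ]
        return pd.DataFrame(rows)


def detect_beads(
    volume: Volume3D,
    min_separation_um: float = 5.0,
    snr_threshold: float = 10.0,
) -> np.ndarray:
    """Find candidate bead positions as local maxima above the noise floor.

    Background is the volume median; the noise scale is the median absolute
    deviation (scaled to Gaussian sigma).  Local maxima above
    ``background + snr_threshold * noise`` are kept and non-maximum
    suppressed at ``min_separation_um`` (the brighter of two close peaks
    wins).  Returns integer voxel coordinates ordered by (z, y, x); an empty
    volume yields an empty list, not an error.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    if min(data.shape) < 3:
        raise ValueError("volume must have >= 3 voxels per axis")
    background = float(np.median(data))
    noise = 1.4826 * float(np.median(np.abs(data - background)))
    if noise == 0.0:
        noise = float(data.std()) or 1.0
    threshold = background + snr_threshold * noise

    peaks = (data == ndimage.maximum_filter(data, size=3, mode="nearest")) & (data > threshold)
    coords = np.argwhere(peaks)
    if coords.size == 0:
        return coords.reshape(0, 3)

    # Greedy non-maximum suppression in physical units, brightest first.
    vs = np.asarray(volume.voxel_size_um)
    values = data[tuple(coords.T)]
    order = np.argsort(values)[::-1]
    coords = coords[order]
    pos_um = coords * vs
    keep: list[int] = []
    tree = cKDTree(pos_um)
    suppressed = np.zeros(len(coords), dtype=bool)
    for i in range(len(coords)):
        if suppressed[i]:
            continue
        keep.append(i)
        for j in tree.query_ball_point(pos_um[i], r=min_separation_um):
            if j != i:
                suppressed[j] = True
    result = coords[keep]
    order = np.lexsort((result[:, 2], result[:, 1], result[:, 0]))
    return result[order]


def _gauss(x, a, mu, sigma, c):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + c


def _fit_profile(profile: np.ndarray) -> tuple[float, float, float]:
    """Fit a 1-D Gaussian; returns (sigma, center, R^2); NaNs on failure."""
    x = np.arange(profile.size, dtype=np.float64)
    c0 = float(profile.min())
    a0 = float(profile.max() - c0)
    if a0 <= 0:
        return math.nan, math.nan, math.nan
    mu0 = float(np.argmax(profile))
    sigma0 = max(np.sum(profile - c0 > a0 / 2) / FWHM_PER_SIGMA, 0.5)
    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            profile,
            p0=(a0, mu0, sigma0, c0),
            bounds=((0, -1, 1e-3, -np.inf), (np.inf, profile.size, profile.size, np.inf)),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        return math.nan, math.nan, math.nan
    resid = profile - _gauss(x, *popt)
    ss_tot = float(np.sum((profile - profile.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
    return float(abs(popt[2])), float(popt[1]), r2


def fit_bead(
    volume: Volume3D,
    position: Sequence[int],
    roi_halfwidth: Sequence[int] | int = 6,
) -> BeadMeasurement:
    """Fit one bead at an integer voxel ``position`` (z, y, x).

    The ROI is background-subtracted (median of its outer shell), the
    centroid refined by intensity weighting, and 1-D profiles along x, y, z
    through the centroid are each fit by a Gaussian.  Failures flag the
    measurement rather than raising.
    """
    vz, vy, vx = volume.voxel_size_um
    if np.isscalar(roi_halfwidth):
        hw = (int(roi_halfwidth),) * 3
    else:
        hw = tuple(int(h) for h in roi_halfwidth)  # (z, y, x)
    zc, yc, xc = (int(p) for p in position)
    flags: set[str] = set()

    lo = np.array([zc - hw[0], yc - hw[1], xc - hw[2]])
    hi = np.array([zc + hw[0] + 1, yc + hw[1] + 1, xc + hw[2] + 1])
    if np.any(lo < 0) or np.any(hi > np.array(volume.data.shape)):
        flags.add("edge")
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, volume.data.shape)
    roi = np.asarray(
        volume.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]], dtype=np.float64
    )

    sat = volume.saturation_level
    if sat is not None and roi.max() >= sat:
        flags.add("saturated")

    shell = np.ones(roi.shape, dtype=bool)
    if all(s > 2 for s in roi.shape):
        shell[1:-1, 1:-1, 1:-1] = False
    background = float(np.median(roi[shell]))
    sub = roi - background
    pos_w = np.clip(sub, 0, None)
    total = pos_w.sum()
    if total > 0:
        idx = np.indices(roi.shape)
        cz, cy, cx = (float((pos_w * idx[k]).sum() / total) for k in range(3))
    else:
        cz, cy, cx = (float(p - l) for p, l in zip((zc, yc, xc), lo))
        flags.add("fit_failed")

    iz, iy, ix = (int(round(c)) for c in (cz, cy, cx))
    iz = min(max(iz, 0), roi.shape[0] - 1)
    iy = min(max(iy, 0), roi.shape[1] - 1)
    ix = min(max(ix, 0), roi.shape[2] - 1)
    sx, mx, r2x = _fit_profile(sub[iz, iy, :])
    sy, my, r2y = _fit_profile(sub[iz, :, ix])
    sz, mz, r2z = _fit_profile(sub[:, iy, ix])
    if any(math.isnan(v) for v in (sx, sy, sz)):
        flags.add("fit_failed")

    pos_vox = (lo[0] + (mz if not math.isnan(mz) else cz),
               lo[1] + (my if not math.isnan(my) else cy),
               lo[2] + (mx if not math.isnan(mx) else cx))
    # Pixel-integration correction: voxel values are cell averages, which
    # inflates the fitted variance by ~1/12 voxel^2 (boxcar convolution).
    sx, sy, sz = (
        math.sqrt(max(s * s - 1.0 / 12.0, 1e-6)) if not math.isnan(s) else s
        for s in (sx, sy, sz)
    )
    return BeadMeasurement(
        position_um=(pos_vox[2] * vx, pos_vox[1] * vy, pos_vox[0] * vz),
        position_vox=pos_vox,
        fwhm_x_um=FWHM_PER_SIGMA * sx * vx,
        fwhm_y_um=FWHM_PER_SIGMA * sy * vy,
        fwhm_z_um=FWHM_PER_SIGMA * sz * vz,
        peak=float(roi.max() - background),
        fit_quality=(r2x, r2y, r2z),
        flags=flags,
    )


def flag_clumped(measurements: list[BeadMeasurement], factor: float = 3.0) -> None:
    """Mutually flag beads closer than ``factor`` x their mean lateral FWHM."""
    valid = [m for m in measurements if not math.isnan(m.fwhm_x_um)]
    if len(valid) < 2:
        return
    pos = np.array([m.position_um for m in valid])
    fwhm = np.array([m.lateral_fwhm_um for m in valid])
    tree = cKDTree(pos)
    for i, j in tree.query_pairs(r=factor * float(np.nanmax(fwhm))):
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if d < factor * 0.5 * (fwhm[i] + fwhm[j]):
            valid[i].flags.add("clumped")
            valid[j].flags.add("clumped")


def aggregate_field_map(
    measurements: Sequence[BeadMeasurement],
    n_bins_xy: tuple[int, int] = (8, 8),
    extent_um: tuple[float, float] | None = None,
) -> PSFFieldMap:
    """Bin unflagged measurements by lateral (x, y) position.

    Per bin: mean and standard deviation of the lateral FWHM (per-bead mean
    of fwhm_x and fwhm_y) and of the axial FWHM.  Raises if no usable beads.
    """
    good = [m for m in measurements if m.ok]
    if not good:
        raise ValueError("zero usable beads: all measurements are flagged")
    nx_b, ny_b = n_bins_xy
    x = np.array([m.position_um[0] for m in good])
    y = np.array([m.position_um[1] for m in good])
    lat = np.array([m.lateral_fwhm_um for m in good])
    axi = np.array([m.fwhm_z_um for m in good])
    if extent_um is not None:
        x_edges = np.linspace(0.0, extent_um[0], nx_b + 1)
        y_edges = np.linspace(0.0, extent_um[1], ny_b + 1)
    else:
        x_edges = np.linspace(x.min(), x.max() + 1e-9, nx_b + 1)
        y_edges = np.linspace(y.min(), y.max() + 1e-9, ny_b + 1)
    ix = np.clip(np.digitize(x, x_edges) - 1, 0, nx_b - 1)
    iy = np.clip(np.digitize(y, y_edges) - 1, 0, ny_b - 1)

    shape = (ny_b, nx_b)
    mean_lat = np.full(shape, np.nan)
    std_lat = np.full(shape, np.nan)
    mean_axi = np.full(shape, np.nan)
    std_axi = np.full(shape, np.nan)
    n = np.zeros(shape, dtype=int)
    for j in range(ny_b):
        for i in range(nx_b):
            sel = (ix == i) & (iy == j)
            n[j, i] = int(sel.sum())
            if n[j, i]:
                mean_lat[j, i] = lat[sel].mean()
                std_lat[j, i] = lat[sel].std(ddof=0)
                mean_axi[j, i] = axi[sel].mean()
                std_axi[j, i] = axi[sel].std(ddof=0)
    return PSFFieldMap(
        x_edges_um=x_edges,
        y_edges_um=y_edges,
        mean_lateral_um=mean_lat,
        std_lateral_um=std_lat,
        mean_axial_um=mean_axi,
        std_axial_um=std_axi,
        n_beads=n,
        empty=n == 0,
    )


def measurements_to_frame(measurements: Sequence[BeadMeasurement]) -> pd.DataFrame:
    """Flatten measurements into a CSV-ready table."""
    return pd.DataFrame(
        {
            "x_um": [m.position_um[0] for m in measurements],
            "y_um": [m.position_um[1] for m in measurements],
            "z_um": [m.position_um[2] for m in measurements],
            "fwhm_x_um": [m.fwhm_x_um for m in measurements],
            "fwhm_y_um": [m.fwhm_y_um for m in measurements],
            "fwhm_z_um": [m.fwhm_z_um for m in measurements],
            "peak": [m.peak for m in measurements],
            "r2_x": [m.fit_quality[0] for m in measurements],
            "r2_y": [m.fit_quality[1] for m in measurements],
            "r2_z": [m.fit_quality[2] for m in measurements],
            "flags": ["|".join(sorted(m.flags)) for m in measurements],
        }
    )


class PSFFieldMapper(BaseEstimator):
    """Estimator mapping PSF FWHM across the field from a bead stack.

    Parameters
    ----------
    snr_threshold : detection threshold in noise sigmas above background.
    min_separation_um : non-maximum suppression radius for detection.
    roi_halfwidth : per-axis ROI half width in voxels for the fits.
    n_bins : (nx, ny) field bins for the aggregated map.
    clump_factor : beads closer than this multiple of their FWHM are flagged.

    Attributes (after ``fit``)
    --------------------------
    detections_ : integer voxel coordinates of candidate beads.
    measurements_ : list of :class:`BeadMeasurement`.
    field_map_ : :class:`PSFFieldMap` of lateral/axial FWHM vs (x, y).
    n_used_ : number of unflagged beads entering the map.
    """

    def __init__(
        self,
        snr_threshold: float = 10.0,
        min_separation_um: float = 5.0,
        roi_halfwidth: int | tuple[int, int, int] = 6,
        n_bins: tuple[int, int] = (8, 8),
        clump_factor: float = 3.0,
    ):
        self.snr_threshold = snr_threshold
        self.min_separation_um = min_separation_um
        self.roi_halfwidth = roi_halfwidth
        self.n_bins = n_bins
        self.clump_factor = clump_factor

    def fit(self, X: Volume3D, y=None) -> "PSFFieldMapper":
        if not isinstance(X, Volume3D):
            raise TypeError("X must be a Volume3D")
        self.detections_ = detect_beads(
            X, min_separation_um=self.min_separation_um, snr_threshold=self.snr_threshold
        )
        self.measurements_ = [fit_bead(X, pos, self.roi_halfwidth) for pos in self.detections_]
        flag_clumped(self.measurements_, factor=self.clump_factor)
        nz, ny, nx = X.shape
        extent = (nx * X.voxel_size_um[2], ny * X.voxel_size_um[1])
        self.field_map_ = aggregate_field_map(
            self.measurements_, n_bins_xy=self.n_bins, extent_um=extent
        )
        self.n_used_ = sum(m.ok for m in self.measurements_)
        return self

    def transform(self, X: Volume3D | None = None) -> pd.DataFrame:
        """Return the fitted field map as a tidy table."""
        if not hasattr(self, "field_map_"):
            raise AttributeError("PSFFieldMapper is not fitted yet; call fit first")
        return self.field_map_.to_dataframe()
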
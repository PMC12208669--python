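"""Field curvature from a through-focus scan of a Ronchi ruling.

The stack of frames (one per stage z position) is split into a grid of
regions of interest (default 16 x 16).  Within each ROI the contrast of each
frame is the percentile contrast

    C = (I95 - I5) / (I95 + I5)

with I95 and I5 the 95th and 5th intensity percentiles.  The contrast-vs-z
curve of each ROI is fit by a Gaussian plus baseline; the fitted centre is
the ROI's best-focus depth.  Best-focus depths are then radially averaged
about the field centre, giving focal shift versus field radius — optionally
in depth-of-field units.

A Gaussian-plus-baseline is used for the "normal distribution" fit because a
real contrast curve has a nonzero background contrast far from focus; a pure
normal PDF cannot represent that offset.  Shifts are reported relative to
the innermost radial ring; absolute stage depths are retained in outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator

from lfspim.io import Volume3D

__all__ = [
    "ContrastCurve",
    "FieldCurvatureMap",
    "FieldCurvatureMapper",
    "split_rois",
    "frame_contrast",
    "contrast_curves",
    "best_focus",
    "radial_average_map",
]


@dataclass
class ContrastCurve:
    """Percentile contrast versus depth for one ROI of the grid."""

    roi_index: tuple[int, int]  # (row, col) in the ROI grid
    z_positions_um: np.ndarray
    contrast: np.ndarray
    best_focus_um: float = math.nan
    fit_width_um: float = math.nan
    fit_ok: bool = False


@dataclass
class FieldCurvatureMap:
    """Grid of best-focus depths and the radially averaged focal-shift profile."""

    focus_grid_um: np.ndarray  # (gy, gx), NaN where the fit failed
    reference_um: float  # innermost-ring mean focus (centre of field)
    radius_um: np.ndarray  # radial bin centres
    mean_shift_um: np.ndarray
    std_shift_um: np.ndarray
    n_rois: np.ndarray
    dof_um: float | None = None
    mean_shift_dof: np.ndarray | None = None

    def to_dataframe(self) -> pd.DataFrame:
        d = {
            "radius_um": self.radius_um,
            "mean_shift_um": self.mean_shift_um,
            "std_shift_um": self.std_shift_um,
            "n_rois": self.n_rois,
        }
        if self.mean_shift_dof is not None:
            d["mean_shift_dof"] = self.mean_shift_dof
        return pd.DataFrame(d)


def split_rois(
    frame_shape: tuple[int, int], grid: tuple[int, int] = (16, 16)
) -> list[list[tuple[slice, slice]]]:
    """Contiguous, non-overlapping ROI tiling of a frame.

    ROI (j, i) covers rows ``[j*(ny//gy), ...)`` and analogously for columns;
    remainder pixels are assigned to the last row/column.  A 14192 x 10640
    frame split 16 x 16 yields 887 x 665-pixel ROIs exactly.
    """
    ny, nx = frame_shape
    gy, gx = grid
    if gy > ny or gx > nx:
        raise ValueError(f"grid {grid} larger than frame {frame_shape}")
    by, bx = ny // gy, nx // gx
    rois = []
    for j in range(gy):
        row = []
        y0 = j * by
        y1 = (j + 1) * by if j < gy - 1 else ny
        for i in range(gx):
            x0 = i * bx
            x1 = (i + 1) * bx if i < gx - 1 else nx
            row.append((slice(y0, y1), slice(x0, x1)))
        rois.append(row)
    return rois


def frame_contrast(frame: np.ndarray) -> float:
    """Percentile contrast C = (I95 - I5) / (I95 + I5) of one frame.

    Invariant under multiplicative intensity scaling.  An all-zero frame has
    undefined contrast and raises.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    i_min, i_max = np.percentile(frame, [5.0, 95.0])
    denom = i_max + i_min
    if denom <= 0:
        raise ValueError("contrast undefined: 5th + 95th percentile sum is not positive")
    return float((i_max - i_min) / denom)


def contrast_curves(
    stack: np.ndarray, z_positions_um: np.ndarray, grid: tuple[int, int] = (16, 16)
) -> list[ContrastCurve]:
    """Per-ROI contrast-vs-depth curves for a (nz, ny, nx) stack.

    Frames whose ROI is uniformly zero get NaN contrast (flagged downstream).
    """
    stack = np.asarray(stack)
    nz = stack.shape[0]
    rois = split_rois(stack.shape[1:], grid)
    curves = []
    for j, row in enumerate(rois):
        for i, (sy, sx) in enumerate(row):
            sub = stack[:, sy, sx].reshape(nz, -1)
            p5, p95 = np.percentile(sub, [5.0, 95.0], axis=1)
            denom = p95 + p5
            with np.errstate(divide="ignore", invalid="ignore"):
                c = np.where(denom > 0, (p95 - p5) / denom, np.nan)
            curves.append(
                ContrastCurve(roi_index=(j, i), z_positions_um=np.asarray(z_positions_um, float),
                              contrast=c)
            )
    return curves


def _gauss(z, a, mu, sigma, c):
    return a * np.exp(-0.5 * ((z - mu) / sigma) ** 2) + c


def best_focus(curve: ContrastCurve, flat_snr: float = 3.0) -> ContrastCurve:
    """Fit Gaussian + baseline to a contrast curve; the centre is best focus.

    ``fit_ok`` is False when the curve is flat (fitted peak minus baseline
    below ``flat_snr`` x residual RMS), the centre lies outside the scanned
    range, or the fit does not converge.  Requires >= 5 z samples.
    """
    z = np.asarray(curve.z_positions_um, dtype=np.float64)
    c = np.asarray(curve.contrast, dtype=np.float64)
    good = np.isfinite(c)
    if z.size < 5:
        raise ValueError("best_focus requires at least 5 z samples")
    z, c = z[good], c[good]
    if z.size < 5:
        curve.fit_ok = False
        return curve
    c0 = float(c.min())
    a0 = float(c.max() - c0)
    if a0 <= 1e-9:  # exactly flat curve: no focus anywhere
        curve.fit_ok = False
        return curve
    # Fit inside a window around the peak: the scan range can be orders of
    # magnitude wider than the contrast peak, and a global fit on a long
    # flat baseline is poorly conditioned.
    i_pk = int(np.argmax(c))
    half = c0 + a0 / 2.0
    left, right = i_pk, i_pk
    while left > 0 and c[left - 1] > half:
        left -= 1
    while right < c.size - 1 and c[right + 1] > half:
        right += 1
    w = max(right - left + 1, 3)
    i0, i1 = max(i_pk - 8 * w, 0), min(i_pk + 8 * w + 1, c.size)
    if i1 - i0 < 5:
        i0, i1 = 0, c.size
    zw, cw = z[i0:i1], c[i0:i1]
    dz = (z[-1] - z[0]) / (z.size - 1)
    sigma0 = max(w * dz / 2.3548, 1e-6)
    try:
        popt, _ = curve_fit(
            _gauss,
            zw,
            cw,
            p0=(a0, z[i_pk], sigma0, c0),
            bounds=((0, z[0] - (z[-1] - z[0]), 1e-9, -1),
                    (2.0, z[-1] + (z[-1] - z[0]), 10 * (z[-1] - z[0]), 1.5)),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        curve.fit_ok = False
        return curve
    a, mu, sigma, base = popt
    resid_rms = float(np.sqrt(np.mean((cw - _gauss(zw, *popt)) ** 2)))
    curve.best_focus_um = float(mu)
    curve.fit_width_um = float(abs(sigma))
    curve.fit_ok = bool(
        a > flat_snr * max(resid_rms, 1e-12) and z[0] <= mu <= z[-1]
    )
    return curve


def radial_average_map(
    focus_grid_um: np.ndarray,
    pixel_size_um: float = 1.0,
    roi_shape_px: tuple[float, float] | None = None,
    n_bins: int | None = None,
    dof_um: float | None = None,
) -> FieldCurvatureMap:
    """Radially average a grid of best-focus depths about the field centre.

    Each ROI is assigned the radius of its centre from the field centre
    (physical units when ``roi_shape_px`` and ``pixel_size_um`` are given,
    else grid-index units times one).  Focal shifts are taken relative to
    the innermost-ring mean and averaged in ``n_bins`` radial rings (default
    one per ROI ring, ``max(grid)/2``).  Raises when no valid fit exists.
    """
    grid = np.asarray(focus_grid_um, dtype=np.float64)
    if not np.isfinite(grid).any():
        raise ValueError("no valid ROI fits: cannot build a field-curvature map")
    gy, gx = grid.shape
    sy, sx = roi_shape_px if roi_shape_px is not None else (1.0, 1.0)
    jj, ii = np.mgrid[0:gy, 0:gx]
    x_um = (ii - (gx - 1) / 2.0) * sx * pixel_size_um
    y_um = (jj - (gy - 1) / 2.0) * sy * pixel_size_um
    r = np.hypot(x_um, y_um)

    n_bins = n_bins or max(gy, gx) // 2
    edges = np.linspace(0.0, r.max() * (1 + 1e-9), n_bins + 1)
    ring = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    valid = np.isfinite(grid)

    inner = valid & (ring == 0)
    if not inner.any():  # fall back to the innermost ring with any valid fit
        first = int(np.min(ring[valid]))
        inner = valid & (ring == first)
    reference = float(grid[inner].mean())
    shift = grid - reference

    radius = np.empty(n_bins)
    mean_s = np.full(n_bins, np.nan)
    std_s = np.full(n_bins, np.nan)
    n_rois = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = valid & (ring == b)
        radius[b] = 0.5 * (edges[b] + edges[b + 1])
        n_rois[b] = int(sel.sum())
        if n_rois[b]:
            mean_s[b] = float(shift[sel].mean())
            std_s[b] = float(shift[sel].std(ddof=0))
    # Shift is defined relative to the innermost populated ring.
    first = int(np.flatnonzero(n_rois)[0])
    offset = mean_s[first]
    mean_s = mean_s - offset
    return FieldCurvatureMap(
        focus_grid_um=grid,
        reference_um=reference + offset,
        radius_um=radius,
        mean_shift_um=mean_s,
        std_shift_um=std_s,
        n_rois=n_rois,
        dof_um=dof_um,
        mean_shift_dof=(mean_s / dof_um) if dof_um else None,
    )


class FieldCurvatureMapper(BaseEstimator):
    """Estimator of best-focus depth versus field position.

    Parameters
    ----------
    grid : ROI grid (rows, cols); the instrument convention is 16 x 16.
    n_radial_bins : radial rings in the profile (default one per ROI ring).
    dof_um : depth of field for expressing shifts in DoF units (optional).
    flat_snr : flatness criterion passed to :func:`best_focus`.

    Attributes (after ``fit``)
    --------------------------
    curves_ : list of fitted :class:`ContrastCurve`.
    focus_grid_um_ : (gy, gx) array of best-focus depths (NaN = no focus).
    map_ : :class:`FieldCurvatureMap`.
    n_failed_ : number of ROIs without a usable focus.
    """

    def __init__(
        self,
        grid: tuple[int, int] = (16, 16),
        n_radial_bins: int | None = None,
        dof_um: float | None = None,
        flat_snr: float = 3.0,
    ):
        self.grid = grid
        self.n_radial_bins = n_radial_bins
        self.dof_um = dof_um
        self.flat_snr = flat_snr

    def fit(self, X: Volume3D, y=None) -> "FieldCurvatureMapper":
        if not isinstance(X, Volume3D):
            raise TypeError("X must be a Volume3D")
        nz, ny, nx = X.shape
        z = np.arange(nz) * X.voxel_size_um[0]
        gy, gx = self.grid
        self.curves_ = [best_focus(c, flat_snr=self.flat_snr)
                        for c in contrast_curves(X.data, z, self.grid)]
        focus = np.full((gy, gx), np.nan)
        for c in self.curves_:
            if c.fit_ok:
                focus[c.roi_index] = c.best_focus_um
        self.focus_grid_um_ = focus
        self.n_failed_ = int(np.sum(~np.isfinite(focus)))
        if not np.isfinite(focus).any():
            raise ValueError("no focus found in any ROI (flat contrast everywhere)")
        self.map_ = radial_average_map(
            focus,
            pixel_size_um=X.voxel_size_um[2],
            roi_shape_px=(ny / gy, nx / gx),
            n_bins=self.n_radial_bins,
            dof_um=self.dof_um,
        )
        return self

    def transform(self, X: Volume3D | None = None) -> pd.DataFrame:
        if not hasattr(self, "map_"):
            raise AttributeError("FieldCurvatureMapper is not fitted yet; call fit first")
        return self.map_.to_dataframe()
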
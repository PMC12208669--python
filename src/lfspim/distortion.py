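"""Geometric distortion from a dot-grid calibration target.

A single image of a trans-illuminated grid of dots is segmented, dot
centroids are computed with sub-pixel precision, each centroid is matched to
its theoretical lattice position, and the per-dot percent distortion

    100 * (r_meas - r_theo) / r_theo

(r = distance from the distortion centre) is radially averaged into a
profile of distortion versus field radius.

The theoretical lattice is anchored at the detected dot nearest the image
centre (where radial distortion vanishes to first order); its axes are taken
from that dot's nearest neighbours, normalized to the nominal spacing, so
that distortion at larger radii does not leak into the lattice estimate.
Coordinates are pixel-centred with (0, 0) at the top-left pixel centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from sklearn.base import BaseEstimator

__all__ = [
    "DistortionProfile",
    "DotGridDistortion",
    "segment_dots",
    "match_lattice",
    "radial_distortion_profile",
    "fit_radial_coefficients",
]


@dataclass
class DistortionProfile:
    """Radially averaged percent distortion versus field radius (pixels)."""

    radius_px: np.ndarray
    mean_percent: np.ndarray
    std_percent: np.ndarray
    n_dots: np.ndarray
    center_px: tuple[float, float]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius_px": self.radius_px,
                "mean_percent_distortion": self.mean_percent,
                "std_percent_distortion": self.std_percent,
                "n_dots": self.n_dots,
            }
        )


def segment_dots(
    image: np.ndarray,
    polarity: str = "dark_on_bright",
    min_area_px: int = 9,
) -> tuple[np.ndarray, list[dict]]:
    """Segment calibration dots and compute intensity-weighted centroids.

    Otsu threshold -> connected components -> area filter; components
    touching the image border are rejected (returned in the second element).
    Weights are the background-subtracted absorption (bright background minus
    pixel value for ``dark_on_bright``), which recovers the dots' coverage
    function, so centroids of clean renderings are sub-pixel exact.

    Returns
    -------
    centroids : (n, 2) array of (x, y) positions ordered by (y, x).
    rejected : list of dicts describing excluded components.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if polarity not in {"dark_on_bright", "bright_on_dark"}:
        raise ValueError(f"unknown polarity {polarity!r}")
    work = -image if polarity == "dark_on_bright" else image
    thr = threshold_otsu(work)
    mask = work > thr
    if not mask.any():
        raise ValueError("no dots found")
    baseline = float(np.median(work[~mask])) if (~mask).any() else float(work.min())
    weights = np.clip(work - baseline, 0.0, None)

    labels = label(mask)
    ny, nx = image.shape
    centroids = []
    rejected: list[dict] = []
    for prop in regionprops(labels, intensity_image=weights):
        y0, x0, y1, x1 = prop.bbox
        entry = {"area_px": int(prop.area), "bbox": prop.bbox}
        if prop.area < min_area_px:
            entry["reason"] = "too_small"
            rejected.append(entry)
            continue
        if y0 == 0 or x0 == 0 or y1 == ny or x1 == nx:
            entry["reason"] = "touches_border"
            rejected.append(entry)
            continue
        cy, cx = prop.centroid_weighted
        centroids.append((cx, cy, prop.area))
    if not centroids:
        raise ValueError("no dots found")
    arr = np.array([(cx, cy) for cx, cy, _ in centroids])
    order = np.lexsort((arr[:, 0], arr[:, 1]))
    return arr[order], rejected


def match_lattice(
    centroids: np.ndarray,
    nominal_spacing_px: float,
    image_shape: tuple[int, int] | None = None,
    image_center: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Assign each centroid to a node of the theoretical lattice.

    The distortion centre is the centroid nearest the image centre.  Lattice
    axes are estimated from that dot's nearest neighbours (direction only;
    the length is the nominal spacing) and the ideal lattice is built outward
    from the centre dot.  Assignments are injective: if two dots map to one
    node, both are flagged ``ambiguous`` and excluded from profiles.

    Returns a table with columns x, y, i, j, x_theo, y_theo, r_meas, r_theo,
    percent_distortion, flag (empty string = usable).
    """
    pts = np.asarray(centroids, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 9:
        raise ValueError("need at least 9 (x, y) centroids")
    if image_center is not None:
        cx, cy = image_center
    elif image_shape is not None:
        ny, nx = image_shape
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    else:
        cx, cy = pts.mean(axis=0)

    i_center = int(np.argmin(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)))
    c0 = pts[i_center]

    # Local axis directions from the centre dot's nearest neighbours.
    d = pts - c0
    dist = np.hypot(d[:, 0], d[:, 1])
    near = (dist > 0.5 * nominal_spacing_px) & (dist < 1.5 * nominal_spacing_px)
    a_dir = np.array([1.0, 0.0])
    b_dir = np.array([0.0, 1.0])
    if near.any():
        cand = d[near] / dist[near, None]
        ax = cand[np.argmax(np.abs(cand[:, 0]))]
        a_dir = ax if ax[0] > 0 else -ax
        ay = cand[np.argmax(np.abs(cand[:, 1]))]
        b_dir = ay if ay[1] > 0 else -ay
    a = a_dir * nominal_spacing_px
    b = b_dir * nominal_spacing_px

    basis = np.column_stack([a, b])
    inv = np.linalg.inv(basis)
    ij = np.rint(inv @ d.T).T.astype(int)
    theo = c0 + ij @ basis.T

    resid = np.hypot(*(pts - theo).T)
    flags = np.array([""] * len(pts), dtype=object)
    flags[resid > 0.5 * nominal_spacing_px] = "unmatched"

    # Injectivity: any node claimed by two usable dots flags both.
    keys: dict[tuple[int, int], int] = {}
    for idx in range(len(pts)):
        if flags[idx]:
            continue
        key = (int(ij[idx, 0]), int(ij[idx, 1]))
        if key in keys:
            flags[idx] = "ambiguous"
            flags[keys[key]] = "ambiguous"
        else:
            keys[key] = idx

    r_meas = np.hypot(pts[:, 0] - c0[0], pts[:, 1] - c0[1])
    r_theo = np.hypot(theo[:, 0] - c0[0], theo[:, 1] - c0[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(r_theo > 0, 100.0 * (r_meas - r_theo) / r_theo, np.nan)

    df = pd.DataFrame(
        {
            "x": pts[:, 0],
            "y": pts[:, 1],
            "i": ij[:, 0],
            "j": ij[:, 1],
            "x_theo": theo[:, 0],
            "y_theo": theo[:, 1],
            "r_meas": r_meas,
            "r_theo": r_theo,
            "residual_px": resid,
            "percent_distortion": pct,
            "flag": flags,
        }
    )
    df.attrs["center_px"] = (float(c0[0]), float(c0[1]))
    df.attrs["axes_px"] = (tuple(a), tuple(b))
    return df


def radial_distortion_profile(
    assignments: pd.DataFrame, bin_width_px: float | None = None
) -> DistortionProfile:
    """Average per-dot percent distortion in radial bins of ``bin_width_px``.

    Only unflagged dots at r_theo > 0 enter the profile (the centre dot has
    undefined percent distortion).  Default bin width: r_max / 8.
    """
    ok = assignments[(assignments["flag"] == "") & (assignments["r_theo"] > 0)]
    if ok.empty:
        raise ValueError("no off-centre dots: distortion profile undefined")
    r = ok["r_theo"].to_numpy()
    pct = ok["percent_distortion"].to_numpy()
    rmax = float(r.max())
    width = bin_width_px or rmax / 8.0
    n_bins = max(int(math.ceil(rmax / width)), 1)
    edges = np.arange(n_bins + 1) * width
    idx = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    radius, mean_p, std_p, n_dots = [], [], [], []
    for bin_i in range(n_bins):
        sel = idx == bin_i
        if not sel.any():
            continue
        radius.append(0.5 * (edges[bin_i] + edges[bin_i + 1]))
        mean_p.append(float(pct[sel].mean()))
        std_p.append(float(pct[sel].std(ddof=0)))
        n_dots.append(int(sel.sum()))
    return DistortionProfile(
        radius_px=np.array(radius),
        mean_percent=np.array(mean_p),
        std_percent=np.array(std_p),
        n_dots=np.array(n_dots),
        center_px=assignments.attrs.get("center_px", (math.nan, math.nan)),
    )


def fit_radial_coefficients(
    assignments: pd.DataFrame, quartic: bool = False
) -> tuple[float, float]:
    """Least-squares fit of percent distortion = 100 (k1 r^2 [+ k2 r^4]).

    Returns (k1, k2); k2 is 0 when ``quartic`` is False.  Radii in pixels,
    so k1 has units px^-2.
    """
    ok = assignments[(assignments["flag"] == "") & (assignments["r_theo"] > 0)]
    if ok.empty:
        raise ValueError("no off-centre dots to fit")
    r = ok["r_theo"].to_numpy()
    y = ok["percent_distortion"].to_numpy() / 100.0
    cols = [r**2, r**4] if quartic else [r**2]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    k1 = float(coef[0])
    k2 = float(coef[1]) if quartic else 0.0
    return k1, k2


class DotGridDistortion(BaseEstimator):
    """Estimator of radial lens distortion from a dot-grid image.

    Parameters
    ----------
    spacing_px : nominal dot spacing in pixels (e.g. 250 um dots at
        0.75 um/px sampling give ~333 px).
    polarity : ``dark_on_bright`` (trans-illuminated target) or
        ``bright_on_dark``.
    min_area_px : smallest component accepted as a dot.
    bin_width_px : radial bin width of the profile (default r_max / 8).
    quartic : also fit the r^4 coefficient k2.

    Attributes (after ``fit``)
    --------------------------
    centroids_ : (n, 2) sub-pixel dot centres (x, y).
    table_ : per-dot assignment table with percent distortion.
    profile_ : :class:`DistortionProfile`.
    center_ : distortion centre (x, y) in pixels.
    k1_, k2_ : fitted radial coefficients (px^-2, px^-4).
    """

    def __init__(
        self,
        spacing_px: float = 100.0,
        polarity: str = "dark_on_bright",
        min_area_px: int = 9,
        bin_width_px: float | None = None,
        quartic: bool = False,
    ):
        self.spacing_px = spacing_px
        self.polarity = polarity
        self.min_area_px = min_area_px
        self.bin_width_px = bin_width_px
        self.quartic = quartic

    def fit(self, X: np.ndarray, y=None) -> "DotGridDistortion":
        image = np.asarray(X)
        self.centroids_, self.rejected_ = segment_dots(
            image, polarity=self.polarity, min_area_px=self.min_area_px
        )
        self.table_ = match_lattice(self.centroids_, self.spacing_px, image_shape=image.shape)
        self.center_ = self.table_.attrs["center_px"]
        self.profile_ = radial_distortion_profile(self.table_, self.bin_width_px)
        self.k1_, self.k2_ = fit_radial_coefficients(self.table_, quartic=self.quartic)
        return self

    def transform(self, X: np.ndarray | None = None) -> pd.DataFrame:
        if not hasattr(self, "profile_"):
            raise AttributeError("DotGridDistortion is not fitted yet; call fit first")
        return self.profile_.to_dataframe()
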
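"""Seeded synthetic scenes with paired ground truth for every measurement pipeline.

Three generators emulate the physical characterization targets:

* :func:`make_bead_phantom` — sub-diffraction fluorescent microspheres in a
  gel, rendered as integrated anisotropic Gaussians with field-dependent FWHM.
* :func:`make_ronchi_stack` — a through-focus scan of a binary Ronchi ruling
  whose local defocus blur follows a best-focus surface z0(x, y).
* :func:`make_dot_grid` — a trans-illuminated dot-grid calibration target
  (dark dots on bright background) with radial geometric distortion
  r_d = r (1 + k1 r^2 + k2 r^4).

All generators are deterministic given (parameters, seed) and return the
scene together with a ground-truth record, enabling closed-loop recovery
tests in the measurement modules.

Beads are rendered as Gaussians with matched FWHM rather than diffraction
patterns: the downstream pipeline measures FWHM, for which a Gaussian is the
standard surrogate.  Defocus blur of the ruling is Gaussian with width linear
in |z - z0|, which guarantees the symmetric, peaked contrast-versus-depth
curve the estimator fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.special import erf

from lfspim.io import Volume3D

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...

__all__ = [
    "CameraNoiseModel",
    "BeadGroundTruth",
    "RonchiGroundTruth",
    "DotGridGroundTruth",
    "make_bead_phantom",
    "make_ronchi_stack",
    "make_dot_grid",
    "FWHM_PER_SIGMA",
]


# ---------------------------------------------------------------------------
# Camera noise
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraNoiseModel:
    """Offset + shot + read noise camera model.

    Counts are generated as ``gain * Poisson(signal/gain) + N(0, read_noise)
    + offset``, rounded and clipped to the bit-depth range.  With this
    convention a uniform patch obeys the photon-transfer relation
    ``var = gain * (mean - offset) + read_noise**2``.

    Parameters
    ----------
    offset : baseline counts added after digitization.
    read_noise : Gaussian read noise, counts RMS.
    gain : counts per photoelectron.
    seed : default RNG seed used when ``apply`` is called without one.
    """

    offset: float = 100.0
    read_noise: float = 2.0
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise < 0:
            raise ValueError(f"read_noise must be >= 0, got {self.read_noise}")
        if self.gain <= 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")

    def apply(
        self,
        signal_counts: np.ndarray,
        rng: np.random.Generator | None = None,
        bit_depth: int = 16,
    ) -> np.ndarray:
        """Digitize an expected-signal image (counts above offset) to integers."""
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        lam = np.clip(np.asarray(signal_counts, dtype=np.float64), 0, None) / self.gain
        counts = self.gain * rng.poisson(lam).astype(np.float64)
        if self.read_noise > 0:
            counts += rng.normal(0.0, self.read_noise, size=counts.shape)
        counts += self.offset
        top = 2**bit_depth - 1
        return np.clip(np.rint(counts), 0, top).astype(np.uint16 if bit_depth <= 16 else np.uint32)


# ---------------------------------------------------------------------------
# Bead phantoms
# ---------------------------------------------------------------------------


@dataclass
class BeadGroundTruth:
    """Exact bead positions and FWHMs for a generated phantom.

    ``table`` columns: z_vox/y_vox/x_vox (sub-voxel positions), x_um/y_um/z_um
    (pixel-centre physical coordinates), fwhm_x_um/fwhm_y_um/fwhm_z_um, peak.
    """

    table: pd.DataFrame
    voxel_size_um: tuple[float, float, float]
    params: dict = field(default_factory=dict)


def _integrated_gaussian_1d(n: int, mu: float, sigma: float) -> np.ndarray:
    """Cell-averaged Gaussian profile normalized to 1.0 at a perfectly centred cell."""
    edges = np.arange(n + 1) - 0.5
    s = sigma * math.sqrt(2.0)
    cdf = erf((edges - mu) / s)
    cell = 0.5 * (cdf[1:] - cdf[:-1])
    center = erf(0.5 / s)  # integral over a cell centred on the peak
    return cell / center


def _jittered_grid(
    rng: np.random.Generator, lo: np.ndarray, hi: np.ndarray, n: int
) -> np.ndarray:
    """n points jittered around a regular lattice inside the box [lo, hi]."""
    span = hi - lo
    # Per-axis cell counts proportional to the box edge, product >= n.
    scale = (n / np.prod(span)) ** (1.0 / 3.0)
    counts = np.maximum(np.floor(span * scale), 1).astype(int)
    while np.prod(counts) < n:
        counts[np.argmax(span / counts)] += 1
    cells = np.stack(
        np.meshgrid(*(np.arange(c) for c in counts), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    rng.shuffle(cells)
    cells = cells[:n]
    cell_size = span / counts
    centers = lo + (cells + 0.5) * cell_size
    jitter = rng.uniform(-0.3, 0.3, size=(n, 3)) * cell_size
    return centers + jitter


def make_bead_phantom(
    shape: Sequence[int],
    n_beads: int,
    fwhm_model: Callable[[float, float], tuple[float, float, float]] | Sequence[float],
    peak_counts: float = 5000.0,
    noise: CameraNoiseModel | None = None,
    seed: int = 0,
    voxel_size_um: Sequence[float] = (1.0, 1.0, 1.0),
    background_counts: float = 0.0,
    margin_vox: float = 3.0,
    min_separation_fwhm: float = 3.0,
    max_overlap_frac: float = 0.05,
    bit_depth: int = 16,
    placement: str = "uniform",
) -> tuple[Volume3D, BeadGroundTruth]:
    """Render a 3-D bead phantom with known sub-voxel positions and FWHMs.

    Parameters
    ----------
    shape : (nz, ny, nx) volume dimensions.
    n_beads : number of beads to place (uniformly at random inside margins).
    fwhm_model : either a constant (fwhm_x, fwhm_y, fwhm_z) in micrometres or
        a callable ``f(x_um, y_um) -> (fwhm_x, fwhm_y, fwhm_z)`` giving the
        field-dependent PSF width at lateral position (x, y).
    peak_counts : expected counts of a perfectly centred bead above background.
    noise : camera model applied after rendering (Poisson, then read noise,
        then offset); None returns the noiseless float rendering.
    background_counts : uniform expected background added before noise.
    margin_vox : extra voxels beyond 3 sigma kept clear of each face.
    min_separation_fwhm, max_overlap_frac : pairs closer than
        ``min_separation_fwhm`` x their mean lateral FWHM count as
        overlapping; if more than ``max_overlap_frac`` of beads are in such
        pairs the generator refuses (density error).
    placement : ``"uniform"`` scatters beads independently;
        ``"jittered_grid"`` jitters them around a regular 3-D lattice,
        guaranteeing the separation constraint at high densities (the
        analogue of a well-dispersed, non-aggregated bead gel).

    Returns
    -------
    (volume, truth) — the rendered stack and a :class:`BeadGroundTruth`.
    """
    shape = tuple(int(s) for s in shape)
    vz, vy, vx = (float(v) for v in voxel_size_um)
    rng = np.random.default_rng(seed)

    if callable(fwhm_model):
        fwhm_fn = fwhm_model
    else:
        const = tuple(float(f) for f in fwhm_model)  # type: ignore[arg-type]
        fwhm_fn = lambda x, y: const  # noqa: E731

    # Worst-case sigma for margins: probe the model on a coarse field grid.
    xs = np.linspace(0, (shape[2] - 1) * vx, 5)
    ys = np.linspace(0, (shape[1] - 1) * vy, 5)
    probes = np.array([fwhm_fn(x, y) for y in ys for x in xs], dtype=float)
    max_sigma_vox = np.max(
        probes / FWHM_PER_SIGMA / np.array([vx, vy, vz]), axis=0
    )[::-1]  # (z, y, x)
    if np.any(probes / FWHM_PER_SIGMA / np.array([vx, vy, vz]) <= 1.0 / FWHM_PER_SIGMA):
        raise ValueError("FWHMs must exceed 1 voxel on every axis (sampling-resolvable)")
    lo = margin_vox + 3.0 * max_sigma_vox
    hi = np.array(shape, dtype=float) - 1.0 - lo
    if np.any(hi <= lo):
        raise ValueError("volume too small for the requested FWHM and margin")

    if n_beads == 0:
        pos_vox = np.empty((0, 3))
    elif placement == "uniform":
        pos_vox = rng.uniform(lo, hi, size=(n_beads, 3))
    elif placement == "jittered_grid":
        pos_vox = _jittered_grid(rng, lo, hi, n_beads)
    else:
        raise ValueError(f"unknown placement {placement!r}")
    pos_um = pos_vox * np.array([vz, vy, vx])
    fwhms = np.array(
        [fwhm_fn(p[2], p[1]) for p in pos_um], dtype=float
    ).reshape(n_beads, 3)  # (fwhm_x, fwhm_y, fwhm_z) um

    if n_beads >= 2:
        mean_fwhm_um = float(np.median(fwhms.mean(axis=1)))
        tree = cKDTree(pos_um)  # 3-D separation in physical units
        pairs = tree.query_pairs(r=min_separation_fwhm * mean_fwhm_um)
        crowded = {i for p in pairs for i in p}
        if len(crowded) > max_overlap_frac * n_beads:
            raise ValueError(
                f"bead density too high: {len(crowded)}/{n_beads} beads closer than "
                f"{min_separation_fwhm}x FWHM (limit {max_overlap_frac:.0%})"
            )

    canvas = np.full(shape, float(background_counts), dtype=np.float64)
    for (zc, yc, xc), (fx, fy, fz) in zip(pos_vox, fwhms):
        sig = np.array([fz / vz, fy / vy, fx / vx]) / FWHM_PER_SIGMA  # voxels, (z,y,x)
        half = np.ceil(4.0 * sig + 1).astype(int)
        z0, z1 = int(zc) - half[0], int(zc) + half[0] + 1
        y0, y1 = int(yc) - half[1], int(yc) + half[1] + 1
        x0, x1 = int(xc) - half[2], int(xc) + half[2] + 1
        z0, y0, x0 = max(z0, 0), max(y0, 0), max(x0, 0)
        z1, y1, x1 = min(z1, shape[0]), min(y1, shape[1]), min(x1, shape[2])
        pz = _integrated_gaussian_1d(z1 - z0, zc - z0, sig[0])
        py = _integrated_gaussian_1d(y1 - y0, yc - y0, sig[1])
        px = _integrated_gaussian_1d(x1 - x0, xc - x0, sig[2])
        canvas[z0:z1, y0:y1, x0:x1] += peak_counts * (
            pz[:, None, None] * py[None, :, None] * px[None, None, :]
        )

    if noise is not None:
        data = noise.apply(canvas, rng=rng, bit_depth=bit_depth)
        volume = Volume3D(data=data, voxel_size_um=(vz, vy, vx), bit_depth=bit_depth)
    else:
        volume = Volume3D(data=canvas, voxel_size_um=(vz, vy, vx))

    table = pd.DataFrame(
        {
            "z_vox": pos_vox[:, 0],
            "y_vox": pos_vox[:, 1],
            "x_vox": pos_vox[:, 2],
            "x_um": pos_um[:, 2],
            "y_um": pos_um[:, 1],
            "z_um": pos_um[:, 0],
            "fwhm_x_um": fwhms[:, 0] if n_beads else np.array([]),
            "fwhm_y_um": fwhms[:, 1] if n_beads else np.array([]),
            "fwhm_z_um": fwhms[:, 2] if n_beads else np.array([]),
            "peak": np.full(n_beads, peak_counts),
        }
    )
    truth = BeadGroundTruth(
        table=table,
        voxel_size_um=(vz, vy, vx),
        params={"seed": seed, "peak_counts": peak_counts, "background_counts": background_counts},
    )
    return volume, truth


# ---------------------------------------------------------------------------
# Through-focus Ronchi ruling stacks
# ---------------------------------------------------------------------------


@dataclass
class RonchiGroundTruth:
    """Best-focus surface and scan geometry for a generated through-focus stack."""

    z0_um: np.ndarray  # (ny, nx) best-focus depth per pixel, um
    z_positions_um: np.ndarray  # (nz,)
    params: dict = field(default_factory=dict)


def make_ronchi_stack(
    shape: Sequence[int],
    period_px: int = 8,
    z_step_um: float = 1.0,
    focus_surface: Callable[[np.ndarray, np.ndarray], np.ndarray] | float = 0.0,
    blur_slope_px_per_um: float = 0.25,
    sigma0_px: float = 0.5,
    contrast_max: float = 0.8,
    mean_level: float = 2000.0,
    noise: CameraNoiseModel | None = None,
    seed: int = 0,
    pixel_size_um: float = 1.0,
    sigma_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    n_sigma_bins: int = 256,
    bit_depth: int = 16,
) -> tuple[Volume3D, RonchiGroundTruth]:
    """Render a through-focus scan of a vertical-bar square-wave ruling.

    Each frame is the binary grating convolved (along the modulation axis x)
    with a Gaussian of width ``sigma(|z - z0(x, y)|)``; frame contrast is
    maximal at z = z0 and decays symmetrically with defocus.

    Parameters
    ----------
    shape : (nz, ny, nx).
    period_px : grating period, >= 4 px (two bars per period).
    focus_surface : scalar depth (um), a (ny, nx) array, or a callable
        ``z0(x_px, y_px) -> um`` evaluated on the pixel grid.  The whole
        surface must lie within the scanned range, else a range error.
    blur_slope_px_per_um, sigma0_px : default blur law
        ``sigma(dz) = sigma0 + slope * dz``; override with ``sigma_fn``.
    contrast_max : percentile contrast of the perfectly focused grating.
    mean_level : mean expected counts (the bright/dark levels are
        ``mean_level * (1 +/- contrast_max)``).
    noise : camera model, applied frame by frame; None keeps floats.

    Notes
    -----
    Blur is quantized into ``n_sigma_bins`` levels and applied via
    precomputed blurred 1-D profiles; with a 1 um z step the quantization is
    far below the fit precision of the downstream estimator.  A constant
    ``sigma_fn`` gives z-independent contrast, the degenerate scene the
    estimator must flag as "no focus found".
    """
    nz, ny, nx = (int(s) for s in shape)
    if period_px < 4:
        raise ValueError(f"period_px must be >= 4, got {period_px}")
    if not 0 < contrast_max <= 1:
        raise ValueError("contrast_max must be in (0, 1]")
    rng = np.random.default_rng(seed)
    z_positions = np.arange(nz, dtype=np.float64) * z_step_um

    yy, xx = np.mgrid[0:ny, 0:nx]
    if callable(focus_surface):
        z0 = np.asarray(focus_surface(xx.astype(float), yy.astype(float)), dtype=np.float64)
        z0 = np.broadcast_to(z0, (ny, nx)).copy()
    else:
        z0 = np.broadcast_to(np.asarray(focus_surface, dtype=np.float64), (ny, nx)).copy()
    if z0.min() < z_positions[0] or z0.max() > z_positions[-1]:
        raise ValueError(
            f"focus surface [{z0.min():.2f}, {z0.max():.2f}] um exits the scanned "
            f"range [{z_positions[0]:.2f}, {z_positions[-1]:.2f}] um"
        )

    if sigma_fn is None:
        sigma_fn = lambda dz: sigma0_px + blur_slope_px_per_um * dz  # noqa: E731

    # Base square wave in [0, 1]: duty 50%, bars along y, modulation along x.
    base = ((np.arange(nx) // (period_px // 2)) % 2).astype(np.float64)
    dz_max = max(float(z_positions[-1] - z0.min()), float(z0.max() - z_positions[0]))
    sig_max = float(np.max(sigma_fn(np.array([0.0, dz_max]))))
    sig_edges = np.linspace(0.0, max(sig_max, 1e-6), n_sigma_bins)
    profiles = np.empty((n_sigma_bins, nx), dtype=np.float64)
    for k, s in enumerate(sig_edges):
        profiles[k] = base if s < 1e-9 else ndimage.gaussian_filter1d(base, s, mode="nearest")

    lo = mean_level * (1.0 - contrast_max)
    hi = mean_level * (1.0 + contrast_max)
    col = np.arange(nx)
    out_dtype = np.float32 if noise is None else (np.uint16 if bit_depth <= 16 else np.uint32)
    stack = np.empty((nz, ny, nx), dtype=out_dtype)
    scale = (n_sigma_bins - 1) / sig_edges[-1]
    # Quantize the focus surface so each frame needs only two index gathers:
    # pixel -> z0 level -> blurred profile row.  The depth quantum is far
    # below the z step, hence below the fit precision.
    n_levels = 1024
    z0_min, z0_max = float(z0.min()), float(z0.max())
    if z0_max > z0_min:
        q = np.rint((z0 - z0_min) / (z0_max - z0_min) * (n_levels - 1)).astype(np.intp)
        levels = z0_min + np.arange(n_levels) * (z0_max - z0_min) / (n_levels - 1)
    else:
        q = np.zeros((ny, nx), dtype=np.intp)
        levels = np.array([z0_min])
    profiles_scaled = (lo + (hi - lo) * profiles).astype(
        np.float32 if noise is None else np.float64
    )
    lin = (q * nx + col).ravel()  # pixel -> (z0 level, column) flat index
    flat = stack.reshape(nz, -1)
    for iz, z in enumerate(z_positions):
        sig_k = np.asarray(sigma_fn(np.abs(z - levels)), dtype=np.float64)
        idx_k = np.clip(np.rint(sig_k * scale), 0, n_sigma_bins - 1).astype(np.intp)
        level_rows = profiles_scaled.take(idx_k, axis=0)  # (n_levels, nx)
        if noise is None:
            level_rows.ravel().take(lin, out=flat[iz])
        else:
            frame = level_rows.ravel().take(lin).reshape(ny, nx)
            stack[iz] = noise.apply(frame, rng=rng, bit_depth=bit_depth)

    volume = Volume3D(
        data=stack,
        voxel_size_um=(z_step_um, pixel_size_um, pixel_size_um),
        bit_depth=None if noise is None else bit_depth,
    )
    truth = RonchiGroundTruth(
        z0_um=z0,
        z_positions_um=z_positions,
        params={"seed": seed, "period_px": period_px, "contrast_max": contrast_max},
    )
    return volume, truth


# ---------------------------------------------------------------------------
# Dot-grid distortion targets
# ---------------------------------------------------------------------------


@dataclass
class DotGridGroundTruth:
    """Ideal lattice, distorted positions, and radial coefficients of a target.

    ``table`` columns: i, j (lattice indices), x_ideal, y_ideal, x_true,
    y_true (pixel-centre coordinates of the distorted dot centres).
    """

    table: pd.DataFrame
    k1: float
    k2: float
    center: tuple[float, float]  # (x, y) px
    params: dict = field(default_factory=dict)


def make_dot_grid(
    shape: Sequence[int],
    spacing_px: float = 100.0,
    dot_diameter_px: float = 50.0,
    k1: float = 0.0,
    k2: float = 0.0,
    center: tuple[float, float] | None = None,
    background: float = 3000.0,
    dot_depth: float = 2700.0,
    noise: CameraNoiseModel | None = None,
    seed: int = 0,
    margin_px: float = 4.0,
    bit_depth: int = 16,
) -> tuple[np.ndarray, DotGridGroundTruth]:
    """Render a trans-illuminated dot-grid target with radial distortion.

    Dark dots on a bright background are placed on a square lattice anchored
    at ``center`` (default: image centre, pixel-centred coordinates) and then
    displaced radially by ``r -> r (1 + k1 r^2 + k2 r^4)``.  Edges are
    anti-aliased linearly over one pixel.  Dots whose distorted footprint
    would leave the frame cause a refusal; dots are never rendered partially.

    Returns the 2-D image and a :class:`DotGridGroundTruth`.
    """
    ny, nx = (int(s) for s in shape)
    if spacing_px <= dot_diameter_px:
        raise ValueError("spacing_px must exceed dot_diameter_px")
    rng = np.random.default_rng(seed)
    cx, cy = center if center is not None else ((nx - 1) / 2.0, (ny - 1) / 2.0)
    radius = dot_diameter_px / 2.0

    # Ideal lattice points whose *ideal* positions are inside the frame.
    imax = int(math.floor((max(nx, ny)) / spacing_px)) + 1
    ij = np.array(
        [
            (i, j)
            for j in range(-imax, imax + 1)
            for i in range(-imax, imax + 1)
            if 0 <= cx + i * spacing_px < nx and 0 <= cy + j * spacing_px < ny
        ],
        dtype=int,
    )
    ideal = np.column_stack([cx + ij[:, 0] * spacing_px, cy + ij[:, 1] * spacing_px])
    vec = ideal - np.array([cx, cy])
    r = np.hypot(vec[:, 0], vec[:, 1])
    factor = 1.0 + k1 * r**2 + k2 * r**4
    distorted = np.array([cx, cy]) + vec * factor[:, None]

    safe = margin_px + radius + 1.0
    inside = (
        (distorted[:, 0] >= safe)
        & (distorted[:, 0] <= nx - 1 - safe)
        & (distorted[:, 1] >= safe)
        & (distorted[:, 1] <= ny - 1 - safe)
    )
    ideal_inside = (
        (ideal[:, 0] >= safe)
        & (ideal[:, 0] <= nx - 1 - safe)
        & (ideal[:, 1] >= safe)
        & (ideal[:, 1] <= ny - 1 - safe)
    )
    if np.any(ideal_inside & ~inside):
        raise ValueError("distortion pushes dots out of the frame; reduce k1/k2 or spacing")
    keep = ideal_inside & inside
    ij, ideal, distorted = ij[keep], ideal[keep], distorted[keep]

    image = np.full((ny, nx), float(background), dtype=np.float64)
    half = int(math.ceil(radius + 2))
    for (xd, yd) in distorted:
        x0, x1 = int(xd) - half, int(xd) + half + 1
        y0, y1 = int(yd) - half, int(yd) + half + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - xd, yy - yd)
        coverage = np.clip(radius + 0.5 - d, 0.0, 1.0)
        image[y0:y1, x0:x1] -= dot_depth * coverage

    if noise is not None:
        image = noise.apply(image, rng=rng, bit_depth=bit_depth).astype(np.float64)

    table = pd.DataFrame(
        {
            "i": ij[:, 0],
            "j": ij[:, 1],
            "x_ideal": ideal[:, 0],
            "y_ideal": ideal[:, 1],
            "x_true": distorted[:, 0],
            "y_true": distorted[:, 1],
        }
    ).sort_values(["j", "i"], ignore_index=True)
    truth = DotGridGroundTruth(
        table=table,
        k1=k1,
        k2=k2,
        center=(cx, cy),
        params={"seed": seed, "spacing_px": spacing_px, "dot_diameter_px": dot_diameter_px},
    )
    return image, truth
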
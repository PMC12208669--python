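"""Volumes and reports: TIFF / OME-Zarr readers and writers, JSON/CSV reports.

All stacks are carried as :class:`Volume3D` with axis order (z, y, x) and
physical voxel sizes in micrometres.  Physical coordinates are pixel-centre
micrometres with voxel (0, 0, 0) centred at the origin.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import zarr

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

__all__ = [
    "Volume3D",
    "read_volume",
    "write_volume",
    "write_report",
    "validate_report",
    "write_table",
]


@dataclass
class Volume3D:
    """A 3-D intensity stack with voxel-size metadata.

    Attributes
    ----------
    data : ndarray, shape (nz, ny, nx)
        Unsigned-integer or floating intensity values.
    voxel_size_um : (float, float, float)
        Physical voxel size per axis, ordered (z, y, x), micrometres.
    bit_depth : int or None
        Digitizer bit depth (12 | 14 | 16) for integer data; None for floats.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    bit_depth: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (z, y, x), got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_um must be 3 positive floats, got {self.voxel_size_um}")
        self.voxel_size_um = vs
        if self.bit_depth is not None and np.issubdtype(self.data.dtype, np.integer):
            top = 2 ** int(self.bit_depth) - 1
            if self.data.max(initial=0) > top:
                raise ValueError(f"integer intensities exceed {self.bit_depth}-bit range")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def saturation_level(self) -> int | None:
        return (2 ** int(self.bit_depth) - 1) if self.bit_depth is not None else None


def _is_zarr(path: Path) -> bool:
    return path.suffix == ".zarr" or (path.is_dir() and (
        (path / "zarr.json").exists() or (path / ".zgroup").exists()))


def write_volume(volume: Volume3D, path: str | Path) -> Path:
    """Write a volume to TIFF (``.tif``/``.tiff``) or OME-Zarr (``.zarr``).

    TIFF files carry the voxel size in a JSON description tag; OME-Zarr groups
    carry OME-style ``multiscales`` metadata with a full-resolution level "0"
    and, when every axis allows it, a 2x-downsampled level "1".
    """
    path = Path(path)
    meta = {
        "voxel_size_um": list(volume.voxel_size_um),
        "bit_depth": volume.bit_depth,
        "axes": "zyx",
    }
    if path.suffix in {".tif", ".tiff"}:
        tifffile.imwrite(path, volume.data, description=json.dumps(meta))
        return path
    if path.suffix == ".zarr":
        group = zarr.open_group(str(path), mode="w")
        group.attrs["lfspim"] = meta
        datasets = [_zarr_level(group, "0", volume.data, volume.voxel_size_um, 1)]
        if all(s >= 2 for s in volume.data.shape):
            datasets.append(
                _zarr_level(group, "1", volume.data[::2, ::2, ::2], volume.voxel_size_um, 2)
            )
        group.attrs["multiscales"] = [
            {
                "version": "0.4",
                "name": path.stem,
                "axes": [
                    {"name": n, "type": "space", "unit": "micrometer"} for n in "zyx"
                ],
                "datasets": datasets,
            }
        ]
        return path
    raise ValueError(f"unsupported volume format: {path.suffix!r} (use .tif/.tiff/.zarr)")


def _zarr_level(group, name: str, data: np.ndarray, voxel_size, factor: int) -> dict:
    arr = group.create_array(name, shape=data.shape, dtype=data.dtype,
                             chunks=tuple(min(s, 256) for s in data.shape))
    arr[:] = data
    return {
        "path": name,
        "coordinateTransformations": [
            {"type": "scale", "scale": [v * factor for v in voxel_size]}
        ],
    }


def read_volume(path: str | Path, voxel_size_um=None, bit_depth: int | None = None) -> Volume3D:
    """Read a TIFF (2-D or 3-D, incl. BigTIFF) or OME-Zarr group as Volume3D.

    Voxel size is taken from file metadata when present; otherwise
    ``voxel_size_um`` must be supplied explicitly — there is no silent
    default.  2-D images are promoted to a single-plane stack.
    """
    path = Path(path)
    meta: dict = {}
    if _is_zarr(path):
        group = zarr.open_group(str(path), mode="r")
        ms = group.attrs.get("multiscales")
        if ms:
            levels = [d["path"] for d in ms[0]["datasets"]]
            logger.info("OME-Zarr %s: levels %s; loading level %s", path, levels, levels[0])
            data = np.asarray(group[levels[0]][:])
            scale = ms[0]["datasets"][0]["coordinateTransformations"][0].get("scale")
            if scale is not None:
                meta["voxel_size_um"] = scale
        else:
            data = np.asarray(group["0"][:])
        meta.update(group.attrs.get("lfspim", {}))
    else:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    if data.ndim == 2:
        data = data[np.newaxis, ...]
    if data.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D image, got shape {data.shape}")
    vs = voxel_size_um or meta.get("voxel_size_um")
    if vs is None:
        raise ValueError(
            f"{path}: no voxel size in metadata; pass voxel_size_um explicitly"
        )
    bd = bit_depth if bit_depth is not None else meta.get("bit_depth")
    return Volume3D(data=data, voxel_size_um=tuple(float(v) for v in vs), bit_depth=bd)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

#: Minimal structural schema for toolkit JSON reports (checked by
#: :func:`validate_report`; kept in code so reports are self-contained text).
REPORT_SCHEMA: dict[str, type | tuple] = {
    "schema_version": str,
    "provenance": dict,
    "results": dict,
}
PROVENANCE_KEYS = ("package", "version", "seed", "config")


def write_report(
    results: Mapping[str, Any],
    path: str | Path,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> dict:
    """Write a schema-versioned JSON report with a provenance block.

    Keys are sorted so identical inputs produce byte-identical files.
    Returns the report dict that was written.
    """
    from lfspim import __version__

    report = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "package": "lfspim",
            "version": __version__,
            "seed": seed,
            "config": dict(config) if config else {},
        },
        "results": _jsonable(results),
    }
    path = Path(path)
    try:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    return report


def validate_report(report: Mapping[str, Any]) -> None:
    """Raise ValueError if a report does not match the shipped schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} must be {typ}, got {type(report[key])}")
    for key in PROVENANCE_KEYS:
        if key not in report["provenance"]:
            raise ValueError(f"provenance missing key {key!r}")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a flat CSV table with stable column order and no index."""
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays and NaN to JSON-safe values."""
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    return obj
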
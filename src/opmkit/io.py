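"""File formats: multi-page TIFF with JSON metadata sidecars, and a chunked
zarr store for large intermediates.

On disk, pages are z (or scan s), rows y, columns x (or x'); all coordinates
0-based, half-open.  Raw data and final exports are 16-bit unsigned TIFF;
floating-point intermediates go to the chunked store as 32-bit, or to TIFF
with a declared linear scaling recorded in the sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import zarr

from opmkit.geometry import AcquisitionGeometry, ObliqueStack, OrthoVolume

__all__ = [
    "write_stack",
    "read_stack",
    "write_volume",
    "read_volume",
    "to_zarr",
    "from_zarr",
    "zarr_compression_ratio",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _quantize(data: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Linear map of float data onto the uint16 range; returns (u16, scale, offset)."""
    lo = float(data.min())
    hi = float(data.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    u16 = np.round((data - lo) / scale).astype(np.uint16)
    return u16, scale, lo


def write_stack(path: str | Path, stack: ObliqueStack) -> Path:
    """Write an oblique stack as multi-page uint16 TIFF + geometry sidecar."""
    path = Path(path)
    data = np.asarray(stack.data)
    meta = {"kind": "oblique", "geometry": stack.geometry.to_dict()}
    if data.dtype == np.uint16:
        tifffile.imwrite(path, data)
    else:
        u16, scale, offset = _quantize(data.astype(np.float64))
        tifffile.imwrite(path, u16)
        meta["scale"] = scale
        meta["offset"] = offset
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> ObliqueStack:
    """Read an oblique stack written by :func:`write_stack`."""
    path = Path(path)
    meta = _read_sidecar(path, expected_kind="oblique")
    data = tifffile.imread(path)
    if "scale" in meta:
        data = data.astype(np.float64) * meta["scale"] + meta["offset"]
    geometry = AcquisitionGeometry.from_dict(meta["geometry"])
    return ObliqueStack(data, geometry)


def write_volume(path: str | Path, volume: OrthoVolume) -> Path:
    """Write a deskewed volume as multi-page uint16 TIFF + sidecar.

    Float data is linearly quantized to 16 bit; the scale and offset are
    declared in the sidecar so values round-trip to within one count.
    """
    path = Path(path)
    data = np.asarray(volume.data)
    meta = {
        "kind": "ortho",
        "voxel_size_um": list(volume.voxel_size_um),
        "origin_um": list(volume.origin_um),
    }
    if data.dtype == np.uint16:
        tifffile.imwrite(path, data)
    else:
        u16, scale, offset = _quantize(data.astype(np.float64))
        tifffile.imwrite(path, u16)
        meta["scale"] = scale
        meta["offset"] = offset
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_volume(path: str | Path) -> OrthoVolume:
    """Read a volume written by :func:`write_volume`."""
    path = Path(path)
    meta = _read_sidecar(path, expected_kind="ortho")
    data = tifffile.imread(path)
    if "scale" in meta:
        data = data.astype(np.float64) * meta["scale"] + meta["offset"]
    return OrthoVolume(
        data,
        voxel_size_um=tuple(meta["voxel_size_um"]),
        origin_um=tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
    )


def _read_sidecar(path: Path, expected_kind: str) -> dict:
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar: {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed metadata sidecar {sidecar}: {exc}") from exc
    kind = meta.get("kind")
    if kind != expected_kind:
        raise ValueError(f"{sidecar}: expected kind {expected_kind!r}, got {kind!r}")
    if expected_kind == "oblique" and "geometry" not in meta:
        raise ValueError(f"{sidecar}: missing 'geometry' field")
    if expected_kind == "ortho" and "voxel_size_um" not in meta:
        raise ValueError(f"{sidecar}: missing 'voxel_size_um' field")
    return meta


def to_zarr(path: str | Path, data: np.ndarray, chunk: int = 64) -> Path:
    """Store an array in a chunked, losslessly compressed zarr directory.

    Floating-point data is stored as 32-bit; integer data keeps its dtype.
    """
    path = Path(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    chunks = tuple(min(chunk, s) for s in data.shape)
    arr = zarr.create_array(
        store=str(path), shape=data.shape, dtype=data.dtype, chunks=chunks,
        overwrite=True,
    )
    arr[...] = data
    return path


def from_zarr(path: str | Path) -> np.ndarray:
    """Load an array stored by :func:`to_zarr`."""
    arr = zarr.open_array(store=str(Path(path)), mode="r")
    return arr[...]


def zarr_compression_ratio(path: str | Path, data: np.ndarray) -> float:
    """Uncompressed bytes of ``data`` divided by on-disk bytes of the store."""
    path = Path(path)
    on_disk = sum(p.stat().st_size for p in path.rglob("*") if p.is_file())
    data = np.asarray(data)
    nbytes = data.astype(np.float32).nbytes if np.issubdtype(
        data.dtype, np.floating
    ) else data.nbytes
    return nbytes / on_disk if on_disk else float("inf")
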
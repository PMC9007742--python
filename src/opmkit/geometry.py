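"""Coordinate conventions and the deskew transform for oblique-plane light-sheet data.

In an oblique-plane microscope the camera records planes tilted by the
light-sheet angle ``theta`` with respect to the coverslip.  A raw acquisition
is a stack of such frames indexed ``(s, y, x')`` where ``s`` is the scan
position, ``y`` the sheet-width axis and ``x'`` the in-sheet propagation
direction.  A camera sample maps to world (coverslip-aligned) coordinates as

    x = s * scan_step + sigma * x' * pixel * cos(theta)
    y = y * pixel
    z = x' * pixel * sin(theta)

with ``sigma = +1`` for view 1 (illumination at +theta) and ``-1`` for view 2
(-theta).  The world frame is right-handed: ``z`` is the optical axis (depth,
0 at the coverslip), ``x`` the scan axis, ``y`` the sheet-width axis.  All
grids are 0-based and half-open.

Deskewing resamples the oblique stack onto an orthogonal ``(z, y, x)`` voxel
grid; :func:`forward_sample` is the inverse operation used by the synthetic
forward model.  View 2 is mirrored along ``x`` by the instrument's image
flipping module; :func:`flip_view` undoes the mirror so both views share one
orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "AcquisitionGeometry",
    "ObliqueStack",
    "OrthoVolume",
    "deskew",
    "forward_sample",
    "flip_view",
    "overlap_crop",
]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Acquisition geometry of one oblique scan.

    Parameters
    ----------
    tilt_angle_deg:
        Light-sheet angle theta with respect to the coverslip plane, degrees.
    scan_step_um:
        Stage/galvo step along x between consecutive frames, micrometres.
    pixel_size_um:
        Camera pixel size at sample space, micrometres.
    scan_mode:
        ``"stage"`` or ``"galvo"``; metadata only, the mapping is identical.
    view_id:
        1 for illumination at +theta, 2 for -theta (mirrored view).
    frame_shape:
        Camera frame shape ``(rows=y, cols=x')``.
    scan_origin_um:
        World x position of scan index 0.  The sheet plane of view 1 leans
        toward +x with depth, so covering voxels near x = 0 at depth
        requires the scan to start at negative x; the synthetic forward
        model sets this automatically.
    """

    tilt_angle_deg: float = 45.0
    scan_step_um: float = 1.0
    pixel_size_um: float = 0.44
    scan_mode: str = "stage"
    view_id: int = 1
    frame_shape: tuple[int, int] = (64, 64)
    scan_origin_um: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.tilt_angle_deg < 90.0:
            raise ValueError(
                f"tilt_angle_deg must be strictly between 0 and 90, got {self.tilt_angle_deg}"
            )
        if self.scan_step_um <= 0:
            raise ValueError("scan_step_um must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.view_id not in (1, 2):
            raise ValueError(f"view_id must be 1 or 2, got {self.view_id}")
        if self.scan_mode not in ("stage", "galvo"):
            raise ValueError(f"scan_mode must be 'stage' or 'galvo', got {self.scan_mode!r}")

    @property
    def sigma(self) -> int:
        """Sign of the in-plane shear: +1 for view 1, -1 for view 2."""
        return 1 if self.view_id == 1 else -1

    @property
    def tilt_rad(self) -> float:
        return math.radians(self.tilt_angle_deg)

    def to_dict(self) -> dict:
        return {
            "tilt_angle_deg": self.tilt_angle_deg,
            "scan_step_um": self.scan_step_um,
            "pixel_size_um": self.pixel_size_um,
            "scan_mode": self.scan_mode,
            "view_id": self.view_id,
            "frame_shape": list(self.frame_shape),
            "scan_origin_um": self.scan_origin_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        return cls(
            tilt_angle_deg=float(d["tilt_angle_deg"]),
            scan_step_um=float(d["scan_step_um"]),
            pixel_size_um=float(d["pixel_size_um"]),
            scan_mode=str(d.get("scan_mode", "stage")),
            view_id=int(d.get("view_id", 1)),
            frame_shape=tuple(int(v) for v in d["frame_shape"]),
            scan_origin_um=float(d.get("scan_origin_um", 0.0)),
        )


@dataclass
class ObliqueStack:
    """Raw oblique camera frames indexed ``(scan s, row y, column x')``."""

    data: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D (s, y, x') data, got ndim={self.data.ndim}")
        if self.data.shape[1:] != tuple(self.geometry.frame_shape):
            raise ValueError(
                f"frame shape {self.data.shape[1:]} does not match geometry "
                f"{self.geometry.frame_shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("stack contains non-finite intensities")
        if self.data.min() < 0:
            raise ValueError("stack contains negative intensities")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass
class OrthoVolume:
    """Deskewed volume on an orthogonal coverslip-aligned grid.

    ``data`` is indexed ``(z, y, x)``; ``voxel_size_um`` is ``(vz, vy, vx)``
    and ``origin_um`` the world position of voxel ``(0, 0, 0)`` in the same
    axis order.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D (z, y, x) data, got ndim={self.data.ndim}")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        self.origin_um = tuple(float(v) for v in self.origin_um)
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_um}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_extent_um(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) spanned by the voxel grid, micrometres."""
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size_um))


def _check_geometry(geometry: AcquisitionGeometry) -> None:
    # dataclass validation already rejects theta outside (0, 90); guard against
    # values that slipped in via object.__setattr__ or direct construction
    if not 0.0 < geometry.tilt_angle_deg < 90.0:
        raise ValueError("degenerate tilt angle: shear undefined at 0 or 90 degrees")


def default_voxel_size(geometry: AcquisitionGeometry) -> tuple[float, float, float]:
    """Default deskewed voxel sizes ``(vz, vy, vx)``.

    ``vx`` equals the scan step, ``vy`` the camera pixel and ``vz`` the axial
    projection ``p * sin(theta)`` of one in-sheet pixel.
    """
    p = geometry.pixel_size_um
    return (p * math.sin(geometry.tilt_rad), p, geometry.scan_step_um)


def deskew(
    stack: ObliqueStack,
    target_voxel_um: tuple[float, float, float] | None = None,
) -> OrthoVolume:
    """Resample an oblique stack onto the orthogonal coverslip-aligned grid.

    Each camera sample at ``(s, y, x')`` maps to world
    ``(x, y, z) = (s*ds + sigma*x'*p*cos(t), y*p, x'*p*sin(t))``.  The output
    grid covers the world bounding box of the sampled sheet; voxels outside
    the sheared support are zero.  Linear interpolation.

    Parameters
    ----------
    stack:
        Raw oblique stack with geometry.
    target_voxel_um:
        Output voxel sizes ``(vz, vy, vx)``; default
        ``(p*sin(theta), p, scan_step)``.
    """
    g = stack.geometry
    _check_geometry(g)
    if target_voxel_um is None:
        target_voxel_um = default_voxel_size(g)
    vz, vy, vx = (float(v) for v in target_voxel_um)
    if min(vz, vy, vx) <= 0:
        raise ValueError("target voxel sizes must be positive")

    p = g.pixel_size_um
    ds = g.scan_step_um
    sigma = g.sigma
    cos_t = math.cos(g.tilt_rad)
    sin_t = math.sin(g.tilt_rad)
    n_s, n_y, n_xp = stack.data.shape

    # world bounding box of the camera samples
    s0 = g.scan_origin_um
    shear = sigma * (n_xp - 1) * p * cos_t
    x_min = s0 + min(0.0, shear)
    x_max = s0 + (n_s - 1) * ds + max(0.0, shear)
    y_max = (n_y - 1) * p
    z_max = (n_xp - 1) * p * sin_t

    nz = int(math.floor(z_max / vz)) + 1
    ny = int(math.floor(y_max / vy)) + 1
    nx = int(math.floor((x_max - x_min) / vx)) + 1

    # inverse map: world grid -> fractional (s, y, x') camera indices
    z_w = np.arange(nz) * vz
    y_w = np.arange(ny) * vy
    x_w = np.arange(nx) * vx + x_min

    xp_idx = z_w / (p * sin_t)  # (nz,)
    y_idx = y_w / p  # (ny,)
    # s depends on both x and z:  s = (x - s0 - sigma * x' * p * cos) / ds
    s_idx = (x_w[None, :] - s0 - sigma * xp_idx[:, None] * p * cos_t) / ds  # (nz, nx)

    coords = np.empty((3, nz, ny, nx), dtype=np.float64)
    coords[0] = s_idx[:, None, :]
    coords[1] = y_idx[None, :, None]
    coords[2] = xp_idx[:, None, None]

    out = ndimage.map_coordinates(
        stack.data.astype(np.float32, copy=False),
        coords,
        order=1,
        mode="constant",
        cval=0.0,
    )
    return OrthoVolume(out, voxel_size_um=(vz, vy, vx), origin_um=(0.0, 0.0, x_min))


def forward_sample(
    volume: OrthoVolume,
    geometry: AcquisitionGeometry,
    n_frames: int | None = None,
) -> ObliqueStack:
    """Sample a world-space volume along oblique sheet planes (inverse of deskew).

    The synthetic forward model of the microscope: for each scan position the
    camera frame is the volume interpolated on the tilted sheet plane.
    Samples falling outside the volume are zero.

    Parameters
    ----------
    volume:
        World-space scene, indexed (z, y, x).
    geometry:
        Acquisition geometry; ``frame_shape`` sets the camera frame.
    n_frames:
        Number of scan positions; default covers the volume's x extent so the
        full scene is swept.
    """
    _check_geometry(geometry)
    p = geometry.pixel_size_um
    ds = geometry.scan_step_um
    sigma = geometry.sigma
    cos_t = math.cos(geometry.tilt_rad)
    sin_t = math.sin(geometry.tilt_rad)
    n_y, n_xp = geometry.frame_shape
    vz, vy, vx = volume.voxel_size_um
    oz, oy, ox = volume.origin_um

    shear = (n_xp - 1) * p * cos_t
    x_lo = ox
    x_hi = ox + (volume.shape[2] - 1) * vx
    # start the scan early (or run it late) so every voxel of the volume is
    # crossed by a sheet plane: the plane through depth z sits at
    # x = s*ds + s0 + sigma * z * cot(theta)
    s0 = x_lo - max(0.0, sigma * shear)
    if n_frames is None:
        end = x_hi + max(0.0, -sigma * shear)
        n_frames = max(1, int(math.ceil((end - s0) / ds)) + 1)
    geometry = replace(geometry, scan_origin_um=s0)

    s = np.arange(n_frames, dtype=np.float64)
    y = np.arange(n_y, dtype=np.float64)
    xp = np.arange(n_xp, dtype=np.float64)

    x_w = s0 + s[:, None] * ds + sigma * xp[None, :] * p * cos_t  # (s, x')
    z_w = xp * p * sin_t  # (x',)
    y_w = y * p  # (y,)

    coords = np.empty((3, n_frames, n_y, n_xp), dtype=np.float64)
    coords[0] = ((z_w - oz) / vz)[None, None, :]
    coords[1] = ((y_w - oy) / vy)[None, :, None]
    coords[2] = ((x_w - ox) / vx)[:, None, :]

    frames = ndimage.map_coordinates(
        volume.data.astype(np.float32, copy=False),
        coords,
        order=1,
        mode="constant",
        cval=0.0,
    )
    frames = np.clip(frames, 0.0, None)
    return ObliqueStack(frames, geometry)


def overlap_crop(v1: OrthoVolume, v2: OrthoVolume) -> tuple[OrthoVolume, OrthoVolume]:
    """Crop two volumes to their common world-space region.

    The two deskewed views of a dual-illumination acquisition cover
    different world x ranges (the shear runs in opposite directions), so
    their grids share only an overlap window.  Both inputs must share voxel
    sizes; the overlap is rounded to the nearest voxel, leaving at most half
    a voxel of residual offset for the registration stage.
    """
    if not np.allclose(v1.voxel_size_um, v2.voxel_size_um):
        raise ValueError("volumes must share voxel sizes")
    lo_idx1 = []
    lo_idx2 = []
    n_common = []
    for ax in range(3):
        v = v1.voxel_size_um[ax]
        lo = max(v1.origin_um[ax], v2.origin_um[ax])
        hi = min(
            v1.origin_um[ax] + v1.shape[ax] * v,
            v2.origin_um[ax] + v2.shape[ax] * v,
        )
        if hi <= lo:
            raise ValueError(f"volumes do not overlap along axis {ax}")
        i1 = int(round((lo - v1.origin_um[ax]) / v))
        i2 = int(round((lo - v2.origin_um[ax]) / v))
        n = min(v1.shape[ax] - i1, v2.shape[ax] - i2)
        lo_idx1.append(i1)
        lo_idx2.append(i2)
        n_common.append(n)
    sl1 = tuple(slice(i, i + n) for i, n in zip(lo_idx1, n_common))
    sl2 = tuple(slice(i, i + n) for i, n in zip(lo_idx2, n_common))
    origin = tuple(
        v1.origin_um[ax] + lo_idx1[ax] * v1.voxel_size_um[ax] for ax in range(3)
    )
    return (
        OrthoVolume(v1.data[sl1].copy(), v1.voxel_size_um, origin),
        OrthoVolume(v2.data[sl2].copy(), v2.voxel_size_um, origin),
    )


def flip_view(volume: OrthoVolume) -> OrthoVolume:
    """Mirror the x axis so view-2 data lands in the view-1 orientation.

    The instrument's image flipping module reverses the image along the
    propagation-projected axis; undoing it here makes the two deskewed views
    overlap up to residual misregistration.  Applying the flip twice returns
    a bitwise-identical volume.
    """
    return OrthoVolume(
        volume.data[:, :, ::-1].copy(),
        voxel_size_um=volume.voxel_size_um,
        origin_um=volume.origin_um,
    )
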
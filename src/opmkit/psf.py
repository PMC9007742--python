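"""Bead detection and tilted-PSF FWHM characterization.

The point-spread function of an oblique-plane microscope is anisotropic and
slightly tilted: its long axis (z'') lies at roughly 20 degrees from the
optical axis z in the xz plane.  Characterization therefore proceeds per
bead: estimate the in-plane tilt from the intensity second-moment tensor,
rotate the crop so z'' aligns with z, take 1D line profiles through the peak
along each principal axis (x'', y, z''), and fit each with a 1D Gaussian.
FWHM = 2*sqrt(2*ln 2)*sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

from opmkit.geometry import OrthoVolume
from opmkit.synthesis import FWHM_PER_SIGMA

__all__ = [
    "PSFRecord",
    "PSFSummary",
    "detect_beads",
    "extract_crop",
    "crop_half_size",
    "fit_psf",
    "characterize_beads",
    "summarize_psf",
]


@dataclass
class PSFRecord:
    """Per-bead PSF measurement.

    ``fwhm_nm`` is ordered (x'', y, z''); ``tilt_deg`` is the fitted rotation
    of z'' away from z in the xz plane; ``r2`` the goodness of each 1D fit in
    the same axis order.  ``ok`` is False when any fit failed or fell below
    the r-squared floor; flagged records are excluded from summaries.
    """

    position_um: tuple[float, float, float]
    fwhm_nm: tuple[float, float, float]
    tilt_deg: float
    r2: tuple[float, float, float]
    crop_shape: tuple[int, int, int]
    ok: bool = True


@dataclass
class PSFSummary:
    """Mean +/- sample s.d. of the FWHM per principal axis over n beads."""

    mean_fwhm_nm: tuple[float, float, float]
    sd_fwhm_nm: tuple[float, float, float]
    n_beads: int


def detect_beads(
    volume: OrthoVolume,
    threshold: float,
    min_separation_voxels: int = 10,
    border_margin: int | tuple[int, int, int] = 0,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Find bead candidates as thresholded local intensity maxima.

    Maxima are located on a lightly smoothed copy (``smooth_sigma`` voxels)
    so shot noise cannot displace a peak, but the threshold applies to the
    raw intensity at the peak voxel.  Maxima closer than
    ``min_separation_voxels`` collapse to the brighter one; a border margin
    (scalar or per-axis) excludes beads whose crop window would leave the
    volume.  Result is an (n, 3) integer array of (z, y, x) voxel positions
    sorted by descending raw peak intensity; may be empty.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    smoothed = ndimage.gaussian_filter(data, smooth_sigma) if smooth_sigma > 0 else data
    if np.isscalar(border_margin):
        border = int(border_margin)
    else:
        border = tuple(int(b) for b in border_margin)
    coords = peak_local_max(
        smoothed,
        min_distance=int(min_separation_voxels),
        exclude_border=border if border != 0 else False,
    )
    if len(coords) == 0:
        return coords.reshape(0, 3)
    raw = data[tuple(coords.T)]
    keep = raw >= float(threshold)
    coords = coords[keep]
    raw = raw[keep]
    return coords[np.argsort(-raw)]


def extract_crop(
    volume: OrthoVolume, center_voxel, half_size
) -> np.ndarray | None:
    """Cut a (2*half+1)^3 window around a bead; None when it leaves the volume."""
    c = np.round(np.asarray(center_voxel)).astype(int)
    half = np.asarray(half_size, dtype=int)
    if np.isscalar(half_size):
        half = np.full(3, int(half_size))
    lo = c - half
    hi = c + half + 1
    if np.any(lo < 0) or np.any(hi > np.array(volume.shape)):
        return None
    return volume.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.float64)


def _gauss1d(x, amp, center, sigma, offset):
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2) + offset


def _fit_profile(profile: np.ndarray) -> tuple[float, float]:
    """Fit a 1D Gaussian to a line profile; returns (sigma, r2)."""
    x = np.arange(profile.size, dtype=np.float64)
    offset0 = float(np.median(np.concatenate([profile[:2], profile[-2:]])))
    amp0 = float(profile.max() - offset0)
    c0 = float(np.argmax(profile))
    w = np.clip(profile - offset0, 0, None)
    sigma0 = math.sqrt(max(np.sum(w * (x - c0) ** 2) / max(np.sum(w), 1e-12), 0.25))
    try:
        popt, _ = optimize.curve_fit(
            _gauss1d, x, profile, p0=(amp0, c0, sigma0, offset0), maxfev=5000
        )
    except RuntimeError:
        return math.nan, 0.0
    resid = profile - _gauss1d(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((profile - profile.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return abs(float(popt[2])), r2


def _estimate_tilt_deg(crop: np.ndarray, voxel_size_um) -> float:
    """In-plane tilt of the long PSF axis from the xz second-moment tensor.

    Works in physical coordinates so anisotropic voxels do not bias the
    angle.  Returns the angle of the major axis from z, in degrees, folded
    into [-45, 45) since the subsequent 1D fits are axis-symmetric.
    """
    vz, vy, vx = voxel_size_um
    w = np.clip(crop - np.median(crop), 0, None)
    # iso-intensity cut at 10% of the peak: truncating along the Gaussian's
    # own elliptical contours leaves the principal axes unbiased while
    # suppressing background noise that would dilute the cross-moment
    w[w < 0.1 * w.max()] = 0.0
    zz, _, xx = np.meshgrid(
        np.arange(crop.shape[0]) * vz,
        np.arange(crop.shape[1]) * vy,
        np.arange(crop.shape[2]) * vx,
        indexing="ij",
    )
    total = w.sum()
    if total <= 0:
        return 0.0
    zc = (w * zz).sum() / total
    xc = (w * xx).sum() / total
    czz = (w * (zz - zc) ** 2).sum() / total
    cxx = (w * (xx - xc) ** 2).sum() / total
    czx = (w * (zz - zc) * (xx - xc)).sum() / total
    # a nearly isotropic xz footprint has no meaningful principal axis;
    # report zero tilt rather than an arbitrary angle (and skip the lossy
    # rotation resampling downstream)
    if math.hypot(czz - cxx, 2.0 * czx) < 0.05 * (czz + cxx):
        return 0.0
    # principal angle of the 2x2 covariance [[czz, czx], [czx, cxx]]
    angle = 0.5 * math.atan2(2.0 * czx, czz - cxx)
    deg = math.degrees(angle)
    # fold to the equivalent axis orientation nearest zero
    while deg >= 45.0:
        deg -= 90.0
    while deg < -45.0:
        deg += 90.0
    return deg


def fit_psf(
    crop: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    r2_floor: float = 0.9,
    position_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> PSFRecord:
    """Characterize one bead crop: tilt, rotation, 1D Gaussian fits.

    The crop is first resampled to isotropic voxels (cubic), the in-plane
    tilt estimated from the second-moment tensor, and the crop rotated by
    -tilt in the xz plane so the long axis z'' lies along z.  Line profiles
    through the peak along each axis are then fitted with 1D Gaussians;
    FWHMs are reported in nanometres along (x'', y, z'').
    """
    crop = np.asarray(crop, dtype=np.float64)
    if crop.ndim != 3:
        raise ValueError("crop must be 3D")
    vz, vy, vx = (float(v) for v in voxel_size_um)

    # resample to isotropic voxels so the rotation is angle-true
    iso = min(vz, vy, vx)
    zoom = (vz / iso, vy / iso, vx / iso)
    if any(abs(f - 1.0) > 1e-9 for f in zoom):
        crop_iso = ndimage.zoom(crop, zoom, order=3)
    else:
        crop_iso = crop

    tilt = _estimate_tilt_deg(crop_iso, (iso, iso, iso))
    if abs(tilt) > 1e-3:
        rotated = ndimage.rotate(
            crop_iso, -tilt, axes=(2, 0), reshape=False, order=3, mode="nearest"
        )
    else:
        rotated = crop_iso

    # locate the peak on a lightly smoothed copy so a single upward noise
    # fluctuation cannot select the profile location
    smoothed = ndimage.gaussian_filter(rotated, 1.0)
    peak = np.unravel_index(np.argmax(smoothed), rotated.shape)

    def _profile(axis: int) -> np.ndarray:
        # average a 3x3 transverse neighbourhood: for an axis-aligned
        # Gaussian this reduces noise without changing the width along the
        # profiled axis
        sel: list = [slice(max(p - 1, 0), p + 2) for p in peak]
        sel[axis] = slice(None)
        block = rotated[tuple(sel)]
        other = tuple(i for i in range(3) if i != axis)
        return block.mean(axis=other)

    profiles = (_profile(2), _profile(1), _profile(0))  # x'', y, z''
    fwhm = []
    r2s = []
    ok = True
    for prof in profiles:
        sigma_vox, r2 = _fit_profile(prof)
        if not math.isfinite(sigma_vox) or r2 < r2_floor:
            ok = False
        fwhm.append(FWHM_PER_SIGMA * sigma_vox * iso * 1000.0)  # um -> nm
        r2s.append(r2)
    # fold tilt into [0, 90): report magnitude of the z'' rotation from z
    tilt_report = abs(tilt)
    return PSFRecord(
        position_um=tuple(float(v) for v in position_um),
        fwhm_nm=(fwhm[0], fwhm[1], fwhm[2]),
        tilt_deg=tilt_report,
        r2=(r2s[0], r2s[1], r2s[2]),
        crop_shape=tuple(crop.shape),
        ok=ok,
    )


def crop_half_size(
    expected_fwhm_um: tuple[float, float, float],
    expected_tilt_deg: float,
    voxel_size_um: tuple[float, float, float],
) -> np.ndarray:
    """Per-axis crop half-width, voxels: 2x the expected FWHM extent per axis.

    The tilted PSF projects onto the world axes with marginal widths mixing
    x'' and z''; the window is sized from those projections so it is 4 FWHM
    wide along each axis without ballooning the short axes.
    """
    fx2, fy, fz2 = expected_fwhm_um
    t = math.radians(expected_tilt_deg)
    ext_z = math.hypot(fz2 * math.cos(t), fx2 * math.sin(t))
    ext_x = math.hypot(fz2 * math.sin(t), fx2 * math.cos(t))
    ext = np.array([ext_z, fy, ext_x])
    return np.ceil(2.0 * ext / np.asarray(voxel_size_um)).astype(int)


def characterize_beads(
    volume: OrthoVolume,
    threshold: float,
    expected_fwhm_um: tuple[float, float, float],
    expected_tilt_deg: float = 20.0,
    min_separation_voxels: int = 10,
    r2_floor: float = 0.9,
) -> list[PSFRecord]:
    """Detect beads and fit every non-overlapping crop.

    The crop window is 4x the expected FWHM extent per axis; beads whose
    windows would overlap or leave the volume are skipped to avoid biased
    fits.
    """
    vz, vy, vx = volume.voxel_size_um
    half = crop_half_size(expected_fwhm_um, expected_tilt_deg, volume.voxel_size_um)
    coords = detect_beads(
        volume, threshold, min_separation_voxels, border_margin=tuple(half)
    )
    records = []
    for c in coords:
        # reject overlapping crop windows
        if any(
            np.all(np.abs(c - other) <= 2 * half)
            for other in coords
            if not np.array_equal(other, c)
        ):
            continue
        crop = extract_crop(volume, c, half)
        if crop is None:
            continue
        pos_um = (c[0] * vz, c[1] * vy, c[2] * vx)
        records.append(fit_psf(crop, volume.voxel_size_um, r2_floor, pos_um))
    return records


def summarize_psf(records: list[PSFRecord]) -> PSFSummary:
    """Per-axis mean and sample standard deviation over unflagged records."""
    good = [r for r in records if r.ok]
    if not good:
        raise ValueError("no unflagged PSF records to summarize")
    arr = np.array([r.fwhm_nm for r in good], dtype=np.float64)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if len(good) > 1 else np.zeros(3)
    return PSFSummary(
        mean_fwhm_nm=tuple(float(v) for v in mean),
        sd_fwhm_nm=tuple(float(v) for v in sd),
        n_beads=len(good),
    )
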
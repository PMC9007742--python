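"""Synthetic scenes with known ground truth.

Everything the rest of the package is tested against is generated here: bead
phantoms with anisotropic tilted Gaussian point-spread functions, two-view
scenes with Beer-Lambert illumination-path attenuation and opaque occluders,
Gaussian light-sheet intensity profiles, and drifting time series with known
trajectories.  All generators are pure functions of (spec, seed) and always
emit the ground truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from opmkit.geometry import AcquisitionGeometry, ObliqueStack, OrthoVolume, forward_sample

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

__all__ = [
    "FWHM_PER_SIGMA",
    "BeadPhantomSpec",
    "ScenePhantom",
    "LightSheetProfile",
    "DriftSeries",
    "blob_texture",
    "make_bead_phantom",
    "make_two_view_scene",
    "make_drift_series",
    "inject_outliers",
]


@dataclass(frozen=True)
class BeadPhantomSpec:
    """Recipe for a bead-calibration phantom.

    ``fwhm_um`` are the full widths at half maximum of the Gaussian PSF along
    its principal axes (x'', y, z''); ``psf_tilt_deg`` rotates the z'' axis
    away from z in the xz plane, emulating the slightly tilted PSF of oblique
    remote focusing.
    """

    n_beads: int = 20
    fwhm_um: tuple[float, float, float] = (0.48, 0.379, 1.865)
    psf_tilt_deg: float = 20.0
    min_separation_voxels: float = 16.0
    peak_counts: float = 1000.0
    background_counts: float = 10.0
    noise_model: str = "none"  # none | poisson | gaussian
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fwhm_um):
            raise ValueError("FWHMs must be positive")
        if not 0.0 <= self.psf_tilt_deg < 90.0:
            raise ValueError("psf_tilt_deg must be in [0, 90)")
        if self.noise_model not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.n_beads < 0:
            raise ValueError("n_beads must be nonnegative")


@dataclass(frozen=True)
class LightSheetProfile:
    """Gaussian illumination intensity profile of the light sheet along y."""

    sigma_y_um: float
    center_y_um: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_y_um <= 0:
            raise ValueError("sigma_y_um must be positive")

    def __call__(self, y_um: np.ndarray) -> np.ndarray:
        y = np.asarray(y_um, dtype=np.float64)
        return np.exp(-0.5 * ((y - self.center_y_um) / self.sigma_y_um) ** 2)


@dataclass
class ScenePhantom:
    """World-space scene with an absorption coefficient and opaque occluders.

    ``occluders`` is a list of ellipsoids ``(center_zyx_um, semiaxes_zyx_um)``
    that are fully opaque: they cast hard shadows along the illumination path.
    """

    truth: OrthoVolume
    attenuation_mu_per_um: float = 0.0
    occluders: list[tuple[tuple[float, float, float], tuple[float, float, float]]] = field(
        default_factory=list
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attenuation_mu_per_um < 0:
            raise ValueError("attenuation coefficient must be nonnegative")
        if self.truth.data.min() < 0:
            raise ValueError("truth volume must be nonnegative")


class PackingError(RuntimeError):
    """Raised when bead positions cannot satisfy the minimum separation."""


def _principal_axes(tilt_deg: float) -> np.ndarray:
    """Unit vectors of the (x'', y, z'') frame in (z, y, x) world components.

    z'' is z rotated by ``tilt_deg`` toward x in the xz plane; x'' is the
    in-plane perpendicular; y is unchanged.
    """
    t = math.radians(tilt_deg)
    z2 = np.array([math.cos(t), 0.0, math.sin(t)])  # (z, y, x)
    x2 = np.array([-math.sin(t), 0.0, math.cos(t)])
    y = np.array([0.0, 1.0, 0.0])
    return np.stack([x2, y, z2])  # rows: x'', y, z''


def _render_gaussian_bead(
    data: np.ndarray,
    center_voxel: np.ndarray,
    sigma_um: tuple[float, float, float],
    tilt_deg: float,
    voxel_size_um: tuple[float, float, float],
    peak: float,
) -> None:
    """Add one rotated anisotropic Gaussian to ``data`` in place."""
    axes = _principal_axes(tilt_deg)
    vz, vy, vx = voxel_size_um
    # window half-size: 4 sigma of the largest axis, in voxels per dimension
    smax = max(sigma_um)
    half = np.ceil(4.0 * smax / np.array([vz, vy, vx])).astype(int)
    c = np.round(center_voxel).astype(int)
    lo = np.maximum(c - half, 0)
    hi = np.minimum(c + half + 1, np.array(data.shape))
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    # physical offsets from the (subvoxel) centre
    d = np.stack(
        [
            (zz - center_voxel[0]) * vz,
            (yy - center_voxel[1]) * vy,
            (xx - center_voxel[2]) * vx,
        ]
    )
    # project onto principal axes and accumulate the quadratic form
    q = np.zeros(d.shape[1:], dtype=np.float64)
    for axis_vec, s in zip(axes, sigma_um):
        u = axis_vec[0] * d[0] + axis_vec[1] * d[1] + axis_vec[2] * d[2]
        q += (u / s) ** 2
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += peak * np.exp(-0.5 * q)


def _apply_noise(
    data: np.ndarray, noise_model: str, read_noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    if noise_model == "poisson":
        data = rng.poisson(np.clip(data, 0, None)).astype(np.float64)
    if read_noise_sd > 0 and noise_model in ("poisson", "gaussian"):
        data = data + rng.normal(0.0, read_noise_sd, size=data.shape)
    return data


def make_bead_phantom(
    spec: BeadPhantomSpec,
    shape: tuple[int, int, int],
    voxel_size_um: tuple[float, float, float],
) -> tuple[OrthoVolume, np.ndarray]:
    """Generate a bead-calibration volume plus the true bead positions.

    Beads are anisotropic Gaussians with exactly the requested FWHMs, the
    z'' axis rotated by ``psf_tilt_deg`` in the xz plane.  Positions are
    uniform at random subject to the minimum separation and a border margin
    wide enough for a 4-FWHM crop window; subvoxel positions are used so the
    phantom also exercises centroid recovery.

    Returns
    -------
    (volume, positions):
        ``positions`` is an (n, 3) float array of bead centres in voxel
        coordinates (z, y, x).
    """
    shape = tuple(int(s) for s in shape)
    vz, vy, vx = (float(v) for v in voxel_size_um)
    rng = np.random.default_rng(spec.seed)
    sigma_um = tuple(f / FWHM_PER_SIGMA for f in spec.fwhm_um)

    margin = np.ceil(2.0 * max(spec.fwhm_um) / np.array([vz, vy, vx])).astype(int) + 1
    lo = margin.astype(float)
    hi = np.array(shape, dtype=float) - margin - 1.0
    if spec.n_beads > 0 and np.any(hi <= lo):
        raise PackingError(
            f"shape {shape} too small for border margin {tuple(margin)}"
        )

    # greedy dart throwing with restarts: a single greedy fill can paint
    # itself into a corner at tight packings, so retry from scratch
    positions: list[np.ndarray] = []
    tries_per_fill = 100 * max(spec.n_beads, 1)
    for _attempt in range(50):
        positions = []
        for _ in range(tries_per_fill):
            if len(positions) == spec.n_beads:
                break
            cand = rng.uniform(lo, hi)
            if all(
                np.linalg.norm(cand - p) >= spec.min_separation_voxels
                for p in positions
            ):
                positions.append(cand)
        if len(positions) == spec.n_beads:
            break
    else:
        raise PackingError(
            f"could not place {spec.n_beads} beads with separation "
            f"{spec.min_separation_voxels} in shape {shape}"
        )

    data = np.full(shape, float(spec.background_counts), dtype=np.float64)
    for pos in positions:
        _render_gaussian_bead(
            data, pos, sigma_um, spec.psf_tilt_deg, (vz, vy, vx), spec.peak_counts
        )
    data = _apply_noise(data, spec.noise_model, spec.read_noise_sd, rng)
    vol = OrthoVolume(data, voxel_size_um=(vz, vy, vx))
    pos_arr = np.array(positions).reshape(-1, 3)
    return vol, pos_arr


def _path_transmittance(
    phantom: ScenePhantom, direction_x: int
) -> np.ndarray:
    """Beer-Lambert transmittance for a 45-degree sheet entering at z = 0.

    The path integral is discretized along the 45-degree diagonal with a step
    of one voxel diagonal; occluder voxels zero the transmittance at and
    beyond themselves (hard shadow).  ``direction_x`` is +1 or -1: the sign
    of the x component of propagation.
    """
    truth = phantom.truth
    nz, ny, nx = truth.shape
    vz, vy, vx = truth.voxel_size_um
    if abs(vz - vx) > 1e-9 * max(vz, vx):
        raise ValueError("diagonal path marching requires vz == vx")
    step_um = math.hypot(vz, vx)
    decay = math.exp(-phantom.attenuation_mu_per_um * step_um)

    occ = np.zeros(truth.shape, dtype=bool)
    oz0, oy0, ox0 = truth.origin_um
    if phantom.occluders:
        z_um = np.arange(nz) * vz + oz0
        y_um = np.arange(ny) * vy + oy0
        x_um = np.arange(nx) * vx + ox0
        zz, yy, xx = np.meshgrid(z_um, y_um, x_um, indexing="ij")
        for (cz, cy, cx), (az, ay, ax) in phantom.occluders:
            occ |= (
                ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
            ) <= 1.0

    trans = np.empty(truth.shape, dtype=np.float64)
    trans[0] = 1.0
    trans[0][occ[0]] = 0.0
    for z in range(1, nz):
        prev = trans[z - 1]
        shifted = np.ones_like(prev)
        if direction_x > 0:
            # light moved one voxel toward +x while descending one voxel in z
            shifted[:, 1:] = prev[:, :-1]
        else:
            shifted[:, :-1] = prev[:, 1:]
        trans[z] = shifted * decay
        trans[z][occ[z]] = 0.0
    return trans


def make_two_view_scene(
    phantom: ScenePhantom,
    geometry_view1: AcquisitionGeometry,
    geometry_view2: AcquisitionGeometry,
    profile: LightSheetProfile | None = None,
) -> tuple[ObliqueStack, ObliqueStack, OrthoVolume]:
    """Image one scene from both illumination sides.

    Per view, the scene intensity is multiplied by the Beer-Lambert
    transmittance ``exp(-mu * L)`` of the illumination path entering at the
    coverslip side along the +/-45-degree sheet direction (with occluders
    casting hard shadows), optionally weighted by the light-sheet y profile,
    then sampled onto oblique camera frames with the forward model.
    """
    if geometry_view1.view_id != 1 or geometry_view2.view_id != 2:
        raise ValueError("geometries must be view 1 and view 2 respectively")
    g1, g2 = geometry_view1, geometry_view2
    same = (
        g1.tilt_angle_deg == g2.tilt_angle_deg
        and g1.scan_step_um == g2.scan_step_um
        and g1.pixel_size_um == g2.pixel_size_um
        and g1.frame_shape == g2.frame_shape
    )
    if not same:
        raise ValueError("view geometries must differ only in view_id")

    truth = phantom.truth
    stacks = []
    for geom in (g1, g2):
        trans = _path_transmittance(phantom, direction_x=geom.sigma)
        lit = truth.data * trans
        if profile is not None:
            y_um = np.arange(truth.shape[1]) * truth.voxel_size_um[1] + truth.origin_um[1]
            lit = lit * profile(y_um)[None, :, None]
        vol = OrthoVolume(lit, truth.voxel_size_um, truth.origin_um)
        stacks.append(forward_sample(vol, geom))
    return stacks[0], stacks[1], truth


@dataclass
class DriftSeries:
    """A drifting time series plus its ground truth.

    ``volumes`` has shape (T, Z, Y, X); ``trajectory`` (T, 3) holds the true
    shift of each frame relative to frame 0, in voxels (z, y, x).  The
    outlier plan records which pairwise-shift measurements a test harness
    should corrupt; images themselves are never corrupted.
    """

    volumes: np.ndarray
    trajectory: np.ndarray
    outlier_frac: float
    outlier_mag: float
    seed: int


def _blob_template(shape: tuple[int, int, int], rng: np.random.Generator) -> np.ndarray:
    """High-contrast random scene with nuclei-scale granularity.

    Broadband content (smoothing just above the voxel scale) mimics the
    dense punctate structure of labelled embryos that correlation-based
    registration relies on in practice.
    """
    field = rng.normal(size=shape)
    field = ndimage.gaussian_filter(field, sigma=1.5)
    field -= field.min()
    field /= field.max()
    field = (field ** 2) * 1000.0
    # taper to zero at the borders: a specimen sits on dark background, and
    # an untapered texture would let the static image frame dominate
    # correlation-based shift measurements
    for ax, n in enumerate(shape):
        w = signal.windows.tukey(n, alpha=0.5)
        field = field * w.reshape([-1 if i == ax else 1 for i in range(3)])
    return field


# public name for the fixture texture used across examples and benchmarks
blob_texture = _blob_template


def make_drift_series(
    T: int,
    shape: tuple[int, int, int] = (32, 64, 64),
    drift: tuple = ("random_walk", 1.0),
    outlier_frac: float = 0.0,
    outlier_mag: float = 50.0,
    seed: int = 0,
) -> DriftSeries:
    """Generate a fixed template shifted by a known trajectory.

    ``drift`` is ``("random_walk", sd)`` for i.i.d. Gaussian steps of the
    given standard deviation per axis, or ``("linear", (vz, vy, vx))`` for a
    constant per-frame velocity in voxels.  Frame 0 is unshifted; subvoxel
    shifts use linear interpolation.
    """
    if T < 2:
        raise ValueError("need at least two time points")
    if not 0.0 <= outlier_frac < 1.0:
        raise ValueError("outlier_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    template = _blob_template(tuple(int(s) for s in shape), rng)

    kind = drift[0]
    if kind == "random_walk":
        sd = float(drift[1])
        steps = rng.normal(0.0, sd, size=(T - 1, 3))
        traj = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    elif kind == "linear":
        v = np.asarray(drift[1], dtype=float).reshape(3)
        traj = np.arange(T)[:, None] * v[None, :]
    else:
        raise ValueError(f"unknown drift model {kind!r}")

    half = np.array(shape, dtype=float) / 2.0
    if np.any(np.abs(traj) >= half):
        raise ValueError("trajectory exceeds half the volume extent")

    volumes = np.empty((T,) + tuple(shape), dtype=np.float64)
    for t in range(T):
        if np.allclose(traj[t], 0.0):
            volumes[t] = template
        else:
            volumes[t] = ndimage.shift(template, traj[t], order=1, mode="constant")
    return DriftSeries(volumes, traj, outlier_frac, outlier_mag, seed)


def inject_outliers(shifts, frac: float, mag: float, seed: int = 0):
    """Corrupt a fraction of pairwise shift measurements with gross errors.

    Emulates spurious phase-correlation matches: each selected entry gets a
    random +/-``mag`` offset per axis.  Returns a new measurement set; the
    input is untouched.
    """
    from opmkit.stabilization import RelativeShifts

    if not 0.0 <= frac < 1.0:
        raise ValueError("frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    entries = list(shifts.entries)
    n_bad = int(round(frac * len(entries)))
    bad_idx = rng.choice(len(entries), size=n_bad, replace=False)
    for i in bad_idx:
        t, u, vec, conf = entries[i]
        offset = rng.choice([-mag, mag], size=3)
        entries[i] = (t, u, np.asarray(vec, dtype=float) + offset, conf)
    return RelativeShifts(entries=entries, n=shifts.n, T=shifts.T)
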
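"""Translation estimation and iterative multi-scale warp registration.

The second (mirrored) view of a dual-illumination oblique-plane microscope
never lands exactly on the first: residual misalignment is a smooth,
position-dependent displacement.  It is recovered by an iterative
multi-scale scheme: at iteration ``i`` both volumes are divided into chunks
along all three axes, each chunk pair is registered with a pure translation
model by phase correlation, the per-chunk vectors are assembled into a
smooth (spline-interpolated) displacement field, and the moving view is
warped before the next, finer iteration.  Chunks with unreliable
correlation peaks are filled from their accepted neighbours.

Phase correlation itself — the translation estimator used both here and by
the temporal stabilizer — locates the peak of the inverse transform of the
normalized cross-power spectrum, refined to subvoxel precision with a
parabolic fit; the peak height serves as a confidence score in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RegistrationConfig",
    "RegistrationError",
    "WarpField",
    "phase_correlation",
    "multiscale_warp_register",
    "apply_warp",
]


class RegistrationError(RuntimeError):
    """Raised when no chunk produces a trustworthy translation vector."""


@dataclass(frozen=True)
class RegistrationConfig:
    """Settings of the multi-scale warp registration.

    ``split_base`` selects the chunk-division factor at iteration ``i``
    (1-based): ``"dyadic"`` gives 2, 4, 8, 16, ...; ``"linear"`` gives
    2, 4, 6, 8, ...; a sequence of ints is used verbatim.  Iteration stops at
    ``max_iterations`` or as soon as chunks would fall below
    ``min_chunk_voxels`` along any axis.
    """

    max_iterations: int = 4
    min_chunk_voxels: int = 32
    split_base: str | tuple[int, ...] = "dyadic"
    confidence_floor: float = 0.1
    overlap_frac: float = 0.25
    variance_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.min_chunk_voxels < 8:
            raise ValueError("min_chunk_voxels must be >= 8")

    def split_factor(self, iteration: int) -> int:
        if self.split_base == "dyadic":
            return 2**iteration
        if self.split_base == "linear":
            return 2 * iteration
        return int(self.split_base[iteration - 1])


@dataclass
class WarpField:
    """Displacement vectors on a grid of chunk-center nodes.

    ``node_grid`` has shape (gz, gy, gx, 3) in voxel units; ``node_coords``
    are the node positions (voxels) per axis; ``confidence`` in [0, 1] per
    node; ``shape`` is the full-resolution volume shape the field covers.
    The zero field acts as the identity under :func:`apply_warp`.
    """

    node_grid: np.ndarray
    node_coords: tuple[np.ndarray, np.ndarray, np.ndarray]
    confidence: np.ndarray
    shape: tuple[int, int, int]

    def dense(self) -> np.ndarray:
        """Spline-upsampled displacement field, shape (3, Z, Y, X)."""
        return _upsample_field(self.node_grid, self.node_coords, self.shape)


def _as_array(volume) -> np.ndarray:
    data = getattr(volume, "data", volume)
    return np.asarray(data, dtype=np.float32)


def phase_correlation(a, b, lowpass_sigma: float = 1.0) -> tuple[np.ndarray, float]:
    """Translation between two equally shaped volumes by phase correlation.

    Returns ``(shift, confidence)`` with the convention ``b ~= a`` translated
    by ``+shift``.  The shift maximizes the inverse transform of the
    normalized cross-power spectrum, refined per axis by a parabolic fit
    around the peak; confidence is the correlation-peak height normalized to
    its achievable maximum, a phase-coherence score in [0, 1].  Constant
    inputs yield a zero shift with confidence 0.

    ``lowpass_sigma`` (voxels) applies a Gaussian spectral weight to the
    whitened spectrum, equivalent to correlating smoothed images.  Pure
    translations stay exact (the weight is symmetric) and the smooth,
    unimodal peak keeps the parabolic refinement well conditioned; chunks
    whose displacement varies internally — the situation during warp
    registration — keep a dominant coherent peak because decohered high
    frequencies are attenuated instead of being re-equalized by the
    whitening.  Set 0 to disable.
    """
    a = _as_array(a).astype(np.float64)
    b = _as_array(b).astype(np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    a = a - a.mean()
    b = b - b.mean()
    if not np.any(a) or not np.any(b):
        return np.zeros(a.ndim), 0.0
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    cross = fb * np.conj(fa)
    mag = np.abs(cross)
    # whiten only frequencies carrying real signal: components at the
    # numerical noise floor hold garbage phase and must not contribute
    support = mag > 1e-6 * mag.max()
    weight = support.astype(np.float64)
    if lowpass_sigma > 0:
        for ax, n in enumerate(cross.shape):
            k = 2.0 * np.pi * np.fft.fftfreq(n)
            w1 = np.exp(-0.5 * (k * lowpass_sigma) ** 2)
            weight = weight * w1.reshape([-1 if i == ax else 1 for i in range(cross.ndim)])
    cross = weight * np.where(support, cross / np.maximum(mag, 1e-300), 0.0)
    corr = np.fft.ifftn(cross).real
    peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
    # normalize the peak by its achievable maximum (all weighted
    # frequencies phase-coherent) so confidence is a coherence score
    confidence = float(np.clip(corr[peak] * corr.size / weight.sum(), 0.0, 1.0))

    shift = np.empty(a.ndim)
    for ax, p in enumerate(peak):
        n = corr.shape[ax]
        sel = list(peak)
        sel[ax] = (p - 1) % n
        c_minus = corr[tuple(sel)]
        sel[ax] = (p + 1) % n
        c_plus = corr[tuple(sel)]
        c0 = corr[peak]
        denom = c_minus - 2.0 * c0 + c_plus
        delta = 0.5 * (c_minus - c_plus) / denom if abs(denom) > 1e-15 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        sp = p + delta
        if sp > n / 2:
            sp -= n
        shift[ax] = sp
    return shift, confidence


def _chunk_slices(n: int, factor: int, overlap_frac: float):
    """Chunk intervals and centers along one axis, with symmetric overlap."""
    base = n / factor
    half = 0.5 * base * (1.0 + overlap_frac)
    centers = (np.arange(factor) + 0.5) * base
    slices = []
    for c in centers:
        lo = max(0, int(round(c - half)))
        hi = min(n, int(round(c + half)))
        slices.append(slice(lo, hi))
    return slices, centers - 0.5  # centers as voxel indices


def _fill_low_confidence(vectors: np.ndarray, accepted: np.ndarray) -> np.ndarray:
    """Replace rejected node vectors by inverse-distance interpolation."""
    if accepted.all():
        return vectors
    filled = vectors.copy()
    good_idx = np.argwhere(accepted)
    bad_idx = np.argwhere(~accepted)
    good_vecs = vectors[accepted]
    for bad in bad_idx:
        d2 = np.sum((good_idx - bad) ** 2, axis=1).astype(np.float64)
        w = 1.0 / np.maximum(d2, 1e-12)
        filled[tuple(bad)] = (w[:, None] * good_vecs).sum(axis=0) / w.sum()
    return filled


def _upsample_field(
    node_grid: np.ndarray,
    node_coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Interpolate node vectors to a dense (3, Z, Y, X) field.

    Cubic spline when every axis has at least 4 nodes, linear otherwise;
    constant extrapolation beyond the outermost nodes.
    """
    order = 3 if all(len(c) >= 4 for c in node_coords) else 1
    idx_1d = []
    for ax, coords in enumerate(node_coords):
        if len(coords) == 1:
            idx_1d.append(np.zeros(shape[ax], dtype=np.float32))
        else:
            spacing = coords[1] - coords[0]
            idx_1d.append(
                ((np.arange(shape[ax]) - coords[0]) / spacing).astype(np.float32)
            )
    grid = np.meshgrid(*idx_1d, indexing="ij")
    coords_arr = np.stack([g for g in grid])
    dense = np.empty((3,) + tuple(shape), dtype=np.float32)
    for comp in range(3):
        dense[comp] = ndimage.map_coordinates(
            node_grid[..., comp].astype(np.float32),
            coords_arr,
            order=order,
            mode="nearest",
        )
    return dense


def _identity_coords(shape: tuple[int, int, int]) -> np.ndarray:
    return np.stack(
        np.meshgrid(*(np.arange(n, dtype=np.float32) for n in shape), indexing="ij")
    )


def _warp_dense(data: np.ndarray, dense_field: np.ndarray) -> np.ndarray:
    """Backward warp: output(x) = data(x + u(x)), linear interpolation."""
    coords = _identity_coords(data.shape) + dense_field
    return ndimage.map_coordinates(data, coords, order=1, mode="nearest")


def apply_warp(volume, field: WarpField):
    """Warp a volume by a displacement field (backward warping).

    The node grid is spline-upsampled to full resolution and the volume
    sampled at ``x + u(x)`` with linear interpolation.  A zero field returns
    the volume unchanged (bit-exact on integer grids).
    """
    data = _as_array(volume)
    if tuple(data.shape) != tuple(field.shape):
        raise ValueError("field does not cover this volume")
    warped = _warp_dense(data, field.dense())
    if hasattr(volume, "voxel_size_um"):
        from opmkit.geometry import OrthoVolume

        return OrthoVolume(warped, volume.voxel_size_um, volume.origin_um)
    return warped


def multiscale_warp_register(
    fixed, moving, config: RegistrationConfig | None = None
) -> WarpField:
    """Register ``moving`` onto ``fixed`` with the iterative chunked scheme.

    Iteration ``i`` splits both volumes into ``f_i`` chunks per axis
    (25% overlap), estimates one translation per chunk pair by phase
    correlation, discards vectors whose confidence falls below the floor
    (refilled from accepted neighbours), interpolates a smooth field over
    the chunk centers and warps the moving volume before the next iteration.
    Displacement fields are composed across iterations; the returned
    :class:`WarpField` holds the composed field sampled at the finest chunk
    centers.
    """
    if config is None:
        config = RegistrationConfig()
    fixed_arr = _as_array(fixed)
    moving_arr = _as_array(moving)
    if fixed_arr.shape != moving_arr.shape:
        raise ValueError("fixed and moving must share a shape")
    shape = fixed_arr.shape

    total = np.zeros((3,) + shape, dtype=np.float32)
    warped = moving_arr
    last_nodes = None
    last_coords = None
    last_conf = None

    for i in range(1, config.max_iterations + 1):
        factor = config.split_factor(i)
        if factor < 1:
            raise ValueError("split factor must be >= 1")
        if min(shape) / factor < config.min_chunk_voxels and factor > 1:
            break

        # coarser chunks hide more internal deformation; widen the spectral
        # low-pass proportionally so the correlation peak stays coherent
        lowpass = max(2.0, min(shape) / factor / 16.0)
        per_axis = [_chunk_slices(n, factor, config.overlap_frac) for n in shape]
        slices_per_axis = [p[0] for p in per_axis]
        centers_per_axis = [p[1] for p in per_axis]

        vectors = np.zeros((factor, factor, factor, 3), dtype=np.float64)
        conf = np.zeros((factor, factor, factor), dtype=np.float64)
        for jz, sz in enumerate(slices_per_axis[0]):
            for jy, sy in enumerate(slices_per_axis[1]):
                for jx, sx in enumerate(slices_per_axis[2]):
                    fc = fixed_arr[sz, sy, sx]
                    mc = warped[sz, sy, sx]
                    if fc.var() < config.variance_floor or mc.var() < config.variance_floor:
                        continue
                    vec, c = phase_correlation(fc, mc, lowpass_sigma=lowpass)
                    vectors[jz, jy, jx] = vec
                    conf[jz, jy, jx] = c

        accepted = conf >= config.confidence_floor
        if not accepted.any():
            raise RegistrationError(
                f"iteration {i}: all {factor}^3 chunks fell below the "
                f"confidence floor {config.confidence_floor}"
            )
        vectors = _fill_low_confidence(vectors, accepted)

        node_coords = tuple(c.astype(np.float64) for c in centers_per_axis)
        increment = _upsample_field(vectors, node_coords, shape)

        # compose: total_new(x) = inc(x) + total(x + inc(x))
        coords = _identity_coords(shape) + increment
        for comp in range(3):
            total[comp] = increment[comp] + ndimage.map_coordinates(
                total[comp], coords, order=1, mode="nearest"
            )
        warped = _warp_dense(moving_arr, total)
        last_nodes = vectors
        last_coords = node_coords
        last_conf = conf

    if last_nodes is None:
        # even the coarsest split would violate the chunk-size floor:
        # fall back to a single global translation
        vec, c = phase_correlation(fixed_arr, moving_arr)
        node_coords = tuple(
            np.array([(n - 1) / 2.0]) for n in shape
        )
        return WarpField(
            node_grid=vec.reshape(1, 1, 1, 3),
            node_coords=node_coords,
            confidence=np.array([[[c]]]),
            shape=shape,
        )

    # sample the composed dense field at the finest node centers
    gz, gy, gx = np.meshgrid(*last_coords, indexing="ij")
    sample = np.stack([gz, gy, gx]).astype(np.float32)
    node_grid = np.empty(last_nodes.shape, dtype=np.float64)
    for comp in range(3):
        node_grid[..., comp] = ndimage.map_coordinates(
            total[comp], sample, order=1, mode="nearest"
        )
    conf_filled = np.where(last_conf > 0, last_conf, 0.0)
    return WarpField(
        node_grid=node_grid,
        node_coords=last_coords,
        confidence=conf_filled,
        shape=shape,
    )
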
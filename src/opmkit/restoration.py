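"""Background removal (dehazing) and light-sheet flat-fielding.

Scattered illumination and out-of-focus light add a smooth, large-scale
background haze to each deskewed view; :func:`dehaze` removes it by
subtracting a lower-envelope estimate.  The illumination itself has a
Gaussian intensity profile across the sheet (the y axis);
:func:`correct_illumination` divides it out using the calibrated profile.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from opmkit.geometry import OrthoVolume
from opmkit.synthesis import LightSheetProfile

__all__ = ["dehaze", "correct_illumination"]


def dehaze(
    volume: OrthoVolume, scale_voxels: int = 40, smooth_sigma: float = 0.0
) -> OrthoVolume:
    """Remove large-scale background light.

    The background is the grey-scale morphological opening at
    ``scale_voxels`` (a lower envelope: it never exceeds the data), and the
    result is the white top-hat ``data - opening`` — exactly idempotent and
    nonnegative by construction.  ``scale_voxels`` must be well above the
    feature size so real structures survive the opening.

    ``smooth_sigma`` optionally smooths the envelope (clamped back below the
    data) to soften blocky artifacts of the flat structuring element on very
    noisy frames; it trades away exact idempotence and defaults to off.
    """
    scale = int(scale_voxels)
    if scale <= 0:
        raise ValueError("scale_voxels must be positive")
    data = np.asarray(volume.data, dtype=np.float64)
    background = ndimage.grey_opening(data, size=scale)
    if smooth_sigma > 0:
        background = ndimage.gaussian_filter(background, sigma=smooth_sigma)
        # smoothing can locally raise the envelope above the signal; keep it
        # a true lower bound so subtraction never inverts contrast
        background = np.minimum(background, data)
    out = np.clip(data - background, 0.0, None)
    return OrthoVolume(out, volume.voxel_size_um, volume.origin_um)


def correct_illumination(
    volume: OrthoVolume,
    profile: LightSheetProfile,
    epsilon: float = 0.05,
    return_flags: bool = False,
):
    """Divide out the Gaussian light-sheet profile along y.

    Each y plane is divided by the profile value at its world y coordinate
    (profile normalized to peak 1).  Where the profile falls below
    ``epsilon`` the gain is clamped to ``1/epsilon`` — those planes carry too
    little illumination to restore reliably and are flagged.

    Returns the corrected volume, plus a boolean per-plane clamp flag array
    when ``return_flags`` is True.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    vz, vy, vx = volume.voxel_size_um
    y_um = np.arange(volume.shape[1]) * vy + volume.origin_um[1]
    g = profile(y_um)
    clamped = g < epsilon
    gain = 1.0 / np.maximum(g, epsilon)
    out = volume.data * gain[None, :, None]
    result = OrthoVolume(out, volume.voxel_size_um, volume.origin_um)
    if return_flags:
        return result, clamped
    return result
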
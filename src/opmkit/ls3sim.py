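"""Scan-timing simulator for light-sheet stabilized stage scanning (LS3).

In stabilized stage scanning the stage moves continuously while a galvo
mirror translates the light sheet at the same rate during each camera
exposure, cancelling the relative motion between sample and imaging plane
(hence no motion blur); the galvo flies back during the readout interval and
restarts the compensation on the next exposure.  This module models the
timing: the sawtooth galvo waveform, the residual blur left by any rate
mismatch, and the acquisition throughput for a given scan range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScanTiming",
    "ScanSchedule",
    "residual_blur",
    "simulate_scan",
    "acquisition_rate",
]

GALVO_OPTICAL_RANGE_UM = 300.0  # total optical scan range achievable by the galvo


@dataclass(frozen=True)
class ScanTiming:
    """Timing of one LS3 frame cycle.

    The frame period is ``exposure_ms + readout_ms``; the galvo flyback must
    complete within the readout so compensation can restart on time.
    """

    exposure_ms: float = 10.0
    readout_ms: float = 10.0
    stage_speed_um_per_s: float = 100.0
    galvo_rate_um_per_s: float = 100.0
    flyback_ms: float = 5.0

    def __post_init__(self) -> None:
        for name in ("exposure_ms", "readout_ms", "stage_speed_um_per_s", "flyback_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.flyback_ms > self.readout_ms:
            raise ValueError("flyback_ms must not exceed readout_ms")

    @property
    def frame_period_ms(self) -> float:
        return self.exposure_ms + self.readout_ms

    @property
    def scan_step_um(self) -> float:
        """Effective stage travel per frame."""
        return self.stage_speed_um_per_s * self.frame_period_ms / 1000.0

    @property
    def duty_cycle(self) -> float:
        return self.exposure_ms / self.frame_period_ms


@dataclass
class ScanSchedule:
    """Event schedule and waveforms of a simulated scan.

    ``events`` lists per frame ``(exposure_start_ms, exposure_end_ms,
    readout_end_ms)``; ``time_ms``, ``galvo_um``, ``stage_um`` sample the
    galvo and stage positions; ``relative_um`` is the sample-sheet relative
    displacement accumulated within the current exposure (zero outside
    exposures and when perfectly compensated).
    """

    events: list[tuple[float, float, float]]
    time_ms: np.ndarray
    galvo_um: np.ndarray
    stage_um: np.ndarray
    relative_um: np.ndarray
    timing: ScanTiming


def residual_blur(timing: ScanTiming, compensated: bool = True) -> float:
    """Motion-blur length accumulated during one exposure, micrometres.

    Uncompensated, the sample moves ``stage_speed * exposure`` relative to
    the sheet; with galvo compensation only the rate mismatch remains:
    ``|stage_speed - galvo_rate| * exposure``.  Exactly zero when the rates
    match.
    """
    exposure_s = timing.exposure_ms / 1000.0
    if not compensated:
        return timing.stage_speed_um_per_s * exposure_s
    return abs(timing.stage_speed_um_per_s - timing.galvo_rate_um_per_s) * exposure_s


def simulate_scan(
    timing: ScanTiming,
    n_frames: int,
    sample_rate_khz: float = 100.0,
    compensated: bool = True,
    galvo_limit_um: float = GALVO_OPTICAL_RANGE_UM / 2.0,
) -> ScanSchedule:
    """Simulate the galvo/stage waveforms for ``n_frames`` frame cycles.

    The galvo ramps linearly during each exposure (rate ``galvo_rate``, or 0
    when ``compensated`` is False) and returns to its start position with a
    smooth raised-cosine flyback during the readout; the stage ramps
    continuously.  A warning is raised when the galvo sweep of one exposure
    exceeds its optical half-range limit.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    period = timing.frame_period_ms
    total_ms = n_frames * period
    dt = 1.0 / sample_rate_khz  # ms per sample
    t = np.arange(0.0, total_ms + dt / 2, dt)

    rate_um_per_ms = (timing.galvo_rate_um_per_s if compensated else 0.0) / 1000.0
    stage_rate_um_per_ms = timing.stage_speed_um_per_s / 1000.0
    sweep_um = rate_um_per_ms * timing.exposure_ms
    if sweep_um > galvo_limit_um:
        warnings.warn(
            f"galvo sweep {sweep_um:.1f} um per exposure exceeds the optical "
            f"half-range limit {galvo_limit_um:.1f} um",
            stacklevel=2,
        )

    phase = t % period
    galvo = np.empty_like(t)
    exposing = phase < timing.exposure_ms
    galvo[exposing] = rate_um_per_ms * phase[exposing]
    # raised-cosine return within the flyback window, then hold at start
    tau = (phase[~exposing] - timing.exposure_ms) / timing.flyback_ms
    tau = np.clip(tau, 0.0, 1.0)
    galvo[~exposing] = sweep_um * 0.5 * (1.0 + np.cos(math.pi * tau))

    stage = stage_rate_um_per_ms * t

    relative = np.zeros_like(t)
    exposure_start = np.floor(t / period) * period
    in_exp = phase < timing.exposure_ms
    relative[in_exp] = (
        stage_rate_um_per_ms * (t[in_exp] - exposure_start[in_exp])
        - galvo[in_exp]
    )

    events = []
    for f in range(n_frames):
        start = f * period
        events.append((start, start + timing.exposure_ms, start + period))

    return ScanSchedule(
        events=events,
        time_ms=t,
        galvo_um=galvo,
        stage_um=stage,
        relative_um=relative,
        timing=timing,
    )


def acquisition_rate(
    timing: ScanTiming, scan_range_um: float
) -> tuple[int, float, float]:
    """Throughput bookkeeping for one volume.

    Returns ``(frames, seconds_per_volume, duty_cycle)`` with
    ``frames = ceil(range / step)``; the step is the stage travel per frame
    period.
    """
    if scan_range_um <= 0:
        raise ValueError("scan_range_um must be positive")
    step = timing.scan_step_um
    frames = int(math.ceil(scan_range_um / step - 1e-12))
    seconds = frames * timing.frame_period_ms / 1000.0
    return frames, seconds, timing.duty_cycle
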
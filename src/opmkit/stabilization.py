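"""Temporal drift stabilization of volumetric time series.

Sample holders creep and stages drift over hours-long time-lapse sessions.
The drift is recovered by measuring, for each time point, the relative
displacement to its 2*n nearest neighbours in time (n = 7 by default) with
phase correlation, then solving the overdetermined band system

    R = M A

where A stacks the unknown absolute shift of every frame, R the measured
relative shifts, and each row of M has -1 at time t and +1 at time t+k.
Individual measurements can be grossly wrong (spurious correlation peaks),
so the inversion minimizes the L1 norm of the residual via iteratively
reweighted least squares, which tolerates a sizeable fraction of outliers
where plain least squares does not.  The gauge freedom (adding a constant
to A changes nothing) is fixed by anchoring A_0 = 0, i.e. stabilizing to the
first frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from opmkit.registration import phase_correlation

__all__ = [
    "RelativeShifts",
    "DriftTrajectory",
    "pairwise_shifts",
    "solve_trajectory",
    "stabilize",
]


@dataclass
class RelativeShifts:
    """Pairwise displacement measurements between nearby time points.

    ``entries`` holds ``(t, t+k, shift_vector, confidence)`` for
    ``k = 1..n`` (clipped at the series ends), one entry per unordered pair;
    interior time points therefore participate in 2n relations.
    """

    entries: list[tuple[int, int, np.ndarray, float]]
    n: int
    T: int

    def __post_init__(self) -> None:
        seen = set()
        for t, u, vec, conf in self.entries:
            if not (0 <= t < self.T and 0 <= u < self.T):
                raise ValueError(f"pair ({t}, {u}) outside series of length {self.T}")
            if (t, u) in seen:
                raise ValueError(f"duplicate pair ({t}, {u})")
            seen.add((t, u))

    def neighbor_count(self, t: int) -> int:
        """Number of relations time point ``t`` participates in."""
        return sum(1 for a, b, _, _ in self.entries if a == t or b == t)


@dataclass
class DriftTrajectory:
    """Absolute shift per time point, in voxels (z, y, x); gauge-anchored."""

    A: np.ndarray
    gauge: str = "first_frame_zero"

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        if self.A.ndim != 2 or self.A.shape[1] != 3:
            raise ValueError("trajectory must have shape (T, 3)")
        if not np.isfinite(self.A).all():
            raise ValueError("trajectory contains non-finite values")

    @property
    def T(self) -> int:
        return self.A.shape[0]


def pairwise_shifts(series: np.ndarray, n: int = 7) -> RelativeShifts:
    """Measure relative shifts of each frame to its 2n temporal neighbours.

    For every pair ``(t, t+k)``, ``k = 1..n`` (clipped at the ends), one
    phase-correlation measurement ``R ~ A[t+k] - A[t]`` is recorded together
    with its confidence.
    """
    series = np.asarray(series)
    T = series.shape[0]
    if T < 2:
        raise ValueError("need at least two time points")
    if n < 1:
        raise ValueError("neighbor radius n must be >= 1")
    entries = []
    for t in range(T):
        for k in range(1, n + 1):
            u = t + k
            if u >= T:
                break
            vec, conf = phase_correlation(series[t], series[u])
            entries.append((t, u, vec, conf))
    return RelativeShifts(entries=entries, n=n, T=T)


def _check_connected(shifts: RelativeShifts) -> None:
    adj: dict[int, set[int]] = {t: set() for t in range(shifts.T)}
    for t, u, _, _ in shifts.entries:
        adj[t].add(u)
        adj[u].add(t)
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    if len(seen) != shifts.T:
        missing = sorted(set(range(shifts.T)) - seen)
        raise ValueError(
            f"pair graph is disconnected: time points {missing[:5]}... unreachable from 0"
        )


def solve_trajectory(
    shifts: RelativeShifts,
    method: str = "l1",
    n_iterations: int = 50,
    epsilon: float = 1e-6,
) -> DriftTrajectory:
    """Invert the band system R = M A for the absolute trajectory.

    Each axis is solved independently (the system is separable).  With
    ``method="l1"`` the L1 residual norm is minimized by iteratively
    reweighted least squares (``n_iterations`` rounds, smoothing
    ``epsilon``); ``method="l2"`` is the plain least-squares baseline kept
    for comparison.  Phase-correlation confidences multiply the rows as soft
    prior weights.  The gauge is fixed by A_0 = 0.
    """
    if method not in ("l1", "l2"):
        raise ValueError(f"unknown method {method!r}")
    _check_connected(shifts)
    T = shifts.T
    m = len(shifts.entries)
    M = np.zeros((m, T - 1), dtype=np.float64)  # column t-1 holds A_t; A_0 = 0
    R = np.zeros((m, 3), dtype=np.float64)
    base_w = np.ones(m, dtype=np.float64)
    for row, (t, u, vec, conf) in enumerate(shifts.entries):
        if t > 0:
            M[row, t - 1] = -1.0
        if u > 0:
            M[row, u - 1] = 1.0
        R[row] = np.asarray(vec, dtype=np.float64)
        base_w[row] = max(float(conf), 1e-3)

    A = np.zeros((T, 3), dtype=np.float64)
    for axis in range(3):
        r = R[:, axis]
        w = base_w.copy()
        Mw = M * w[:, None]
        sol, *_ = np.linalg.lstsq(Mw, r * w, rcond=None)
        if method == "l1":
            for _ in range(n_iterations):
                resid = M @ sol - r
                irls = 1.0 / np.sqrt(resid**2 + epsilon**2)
                w = base_w * irls
                Mw = M * w[:, None]
                sol_new, *_ = np.linalg.lstsq(Mw, r * w, rcond=None)
                if np.max(np.abs(sol_new - sol)) < 1e-12:
                    sol = sol_new
                    break
                sol = sol_new
        A[1:, axis] = sol
    return DriftTrajectory(A=A)


def stabilize(series: np.ndarray, trajectory: DriftTrajectory) -> np.ndarray:
    """Translate every frame by minus its absolute shift.

    Subvoxel shifts use linear interpolation; integer shifts reproduce a
    plain roll in the interior.  Frames with zero shift are returned
    unchanged.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.shape[0] != trajectory.T:
        raise ValueError("series length does not match trajectory")
    out = np.empty_like(series)
    for t in range(series.shape[0]):
        shift = -trajectory.A[t]
        if np.allclose(shift, 0.0):
            out[t] = series[t]
        else:
            out[t] = ndimage.shift(series[t], shift, order=1, mode="constant")
    return out
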
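"""Dynamical summary statistics of network trajectories.

The SCN's collective output is summarized by the population-mean activity
trace (shifted into the positive quadrant), its per-cycle amplitude ``h``
and half-amplitude peak width ``w``, pairwise Pearson correlation matrices
of strided single-cell traces, and the circular distribution of single-cell
peak phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .simulate import Trajectory, _refined_peaks

__all__ = [
    "MeanFieldSeries",
    "ActivityShape",
    "CorrelationSummary",
    "PhaseDistribution",
    "mean_field",
    "activity_width_height",
    "correlation_matrix",
    "peak_phase_distribution",
]


@dataclass(frozen=True)
class MeanFieldSeries:
    """Population-mean activity, shifted so its minimum over the window is 0."""

    times: np.ndarray
    value: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, "mean_field": self.value})


@dataclass(frozen=True)
class ActivityShape:
    """Per-cycle mean-field amplitude h (max - min) and half-amplitude width w (h)."""

    w: float
    w_sd: float
    h: float
    h_sd: float
    w_per_cycle: np.ndarray
    h_per_cycle: np.ndarray
    flat: bool = False


@dataclass(frozen=True)
class CorrelationSummary:
    """Pairwise Pearson correlations; rho_bar averages signed rho over i != j
    among cells with non-degenerate (non-constant) traces."""

    matrix: np.ndarray
    rho_bar: float
    stride: int
    n_excluded: int


@dataclass(frozen=True)
class PhaseDistribution:
    """Per-cell median peak time (h, modulo the cycle) and circular spread.

    The spread is the circular (angular) deviation ``sqrt(2 (1 - R))`` of
    the peak phases, converted to hours; it is 0 for perfect synchrony and
    ``sqrt(2) * cycle / (2 pi)`` (about 5.40 h for a 24 h cycle) for a
    uniform phase distribution.
    """

    phases: np.ndarray
    spread: float
    n_excluded: int
    cycle_length: float


def mean_field(traj: Trajectory, post_only: bool = True) -> MeanFieldSeries:
    """Arithmetic mean of the activity coordinate over all cells, minus its
    minimum over the analysis window."""
    mask = traj.post_mask if post_only else np.ones_like(traj.times, dtype=bool)
    if not mask.any():
        raise ValueError("empty analysis window")
    mf = traj.activity[:, mask].mean(axis=0)
    return MeanFieldSeries(times=traj.times[mask], value=mf - mf.min())


def _above_threshold_time(t: np.ndarray, x: np.ndarray, thr: float) -> float:
    """Total time x(t) > thr, with linear interpolation of the crossings;
    possibly split super-threshold intervals are summed."""
    above = x > thr
    if not above.any():
        return 0.0
    total = 0.0
    start = None
    for m in range(len(t)):
        if above[m] and start is None:
            if m == 0:
                start = t[0]
            else:  # interpolate the upward crossing
                frac = (thr - x[m - 1]) / (x[m] - x[m - 1])
                start = t[m - 1] + frac * (t[m] - t[m - 1])
        elif not above[m] and start is not None:
            frac = (thr - x[m - 1]) / (x[m] - x[m - 1])
            total += t[m - 1] + frac * (t[m] - t[m - 1]) - start
            start = None
    if start is not None:
        total += t[-1] - start
    return total


def activity_width_height(
    mf: MeanFieldSeries, cycle_length: float = 24.0, amplitude_floor: float = 1e-6
) -> ActivityShape:
    """Cycle-wise amplitude and half-amplitude width of the mean field.

    Per cycle: ``h = max - min``; ``w`` = total time the signal exceeds
    ``min + h/2`` (split intervals summed).  Requires at least 3 full
    cycles; a flat signal (h below the floor) has undefined width and is
    flagged instead of raising.
    """
    t = mf.times
    n_cycles = int(np.floor((t[-1] - t[0]) / cycle_length))
    if n_cycles < 3:
        raise ValueError(f"need >= 3 full cycles, window covers {n_cycles}")
    ws, hs = [], []
    for c in range(n_cycles):
        sel = (t >= t[0] + c * cycle_length) & (t < t[0] + (c + 1) * cycle_length)
        xc, tc = mf.value[sel], t[sel]
        h = float(np.ptp(xc))
        hs.append(h)
        if h < amplitude_floor:
            ws.append(np.nan)
        else:
            ws.append(_above_threshold_time(tc, xc, xc.min() + h / 2))
    ws, hs = np.asarray(ws), np.asarray(hs)
    flat = bool(np.isnan(ws).all())
    return ActivityShape(
        w=float(np.nanmean(ws)) if not flat else float("nan"),
        w_sd=float(np.nanstd(ws)) if not flat else float("nan"),
        h=float(np.mean(hs)),
        h_sd=float(np.std(hs)),
        w_per_cycle=ws,
        h_per_cycle=hs,
        flat=flat,
    )


def correlation_matrix(traj: Trajectory, stride: int = 25) -> CorrelationSummary:
    """Pearson correlation of every cell pair on the strided activity series
    (every ``stride``-th post-transient output point is recorded)."""
    x = traj.activity[:, traj.post_mask][:, ::stride]
    if x.shape[1] < 3:
        raise ValueError("too few strided samples for correlation")
    sd = x.std(axis=1)
    ok = sd > 0
    n = traj.n_cells
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    if ok.sum() >= 2:
        sub = np.corrcoef(x[ok])
        mat[np.ix_(ok, ok)] = sub
    off = ~np.eye(n, dtype=bool) & np.outer(ok, ok)
    rho_bar = float(mat[off].mean()) if off.any() else float("nan")
    return CorrelationSummary(matrix=mat, rho_bar=rho_bar, stride=stride, n_excluded=int((~ok).sum()))


def _circular_mean(angles: np.ndarray) -> float:
    return math.atan2(np.sin(angles).mean(), np.cos(angles).mean())


def peak_phase_distribution(
    traj: Trajectory,
    reference: str = "mean_field_max",
    cycle_length: float | None = None,
) -> PhaseDistribution:
    """Per-cell peak phase (h, modulo the cycle) relative to the reference
    (the mean-field maximum, or lights-on of the schedule used), plus the
    circular spread of those phases.  Peakless cells are excluded and counted.

    The cycle length defaults to the schedule period under entrainment and
    to the measured mean-field inter-peak interval under free run (so a
    free-running period away from 24 h does not masquerade as phase spread);
    each cell's phase is the circular mean of its peak phases, which is
    wrap-around safe.
    """
    t = traj.times[traj.post_mask]
    dt = t[1] - t[0]
    mfp = _refined_peaks(t, traj.activity[:, traj.post_mask].mean(axis=0))
    if cycle_length is None:
        if traj.schedule is not None:
            cycle_length = traj.schedule.T
        elif len(mfp) >= 3:
            cycle_length = float(np.mean(np.diff(mfp)))
        else:
            cycle_length = 24.0
    two_pi = 2 * math.pi
    if reference == "mean_field_max":
        ref_angle = _circular_mean(mfp * two_pi / cycle_length) if len(mfp) else 0.0
    elif reference == "lights_on":
        ref_angle = (traj.schedule.phase0 if traj.schedule is not None else 0.0) * two_pi / cycle_length
    else:
        raise ValueError(f"unknown reference: {reference}")
    phases = np.full(traj.n_cells, np.nan)
    for i in range(traj.n_cells):
        x = traj.activity[i][traj.post_mask]
        span = np.ptp(x)
        if span < 1e-9:
            continue
        idx, _ = find_peaks(x, prominence=span * 0.2, distance=max(int(cycle_length / 2 / dt), 1))
        if len(idx) == 0:
            continue
        ang = _circular_mean(t[idx] * two_pi / cycle_length - ref_angle)
        phases[i] = (ang % two_pi) * cycle_length / two_pi
    ok = ~np.isnan(phases)
    if ok.any():
        ang = phases[ok] * 2 * math.pi / cycle_length
        R = float(np.hypot(np.cos(ang).mean(), np.sin(ang).mean()))
        spread = math.sqrt(max(2.0 * (1.0 - R), 0.0)) * cycle_length / (2 * math.pi)
    else:
        spread = float("nan")
    return PhaseDistribution(phases=phases, spread=spread, n_excluded=int((~ok).sum()), cycle_length=cycle_length)
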
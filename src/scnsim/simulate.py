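"""Coupled-network integration and dynamical protocols.

The full SCN model couples the single-cell oscillators on the two-region
graph with linear local mean-field coupling: cell *i* receives
``(g / k_i) * sum_j W_ij x_j`` (and the analogous y-term) added to its
Cartesian derivatives, where ``k_i`` is its neighbor count.  Photic forcing
is a 24 h square wave added to the x-coordinate of ventrolateral cells only.
On top of ``simulate_network`` this module implements the dynamical
protocols: entrainment and free-run, finite-pulse phase response curves,
adjoint-based infinitesimal PRCs, Arnold-tongue (entrainment-region) scans,
and the winter-to-summer topology-switch experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .core_models import angular_frequency, modulation_depth, named_rng
from .network import SCNNetwork

__all__ = [
    "LightSchedule",
    "SimConfig",
    "Trajectory",
    "PRCResult",
    "EntrainmentMap",
    "light_signal",
    "simulate_network",
    "free_run",
    "measure_periods",
    "measure_prc",
    "compute_iprc",
    "iprc_finite_difference",
    "is_entrained",
    "mean_field_peaks",
    "entrainment_region",
    "topology_switch_experiment",
]

#: Default coupling strength (1/h).  Calibrated once so that the entrained
#: winter network shows the ~10-fold single-cell amplitude expansion that is
#: the model's hallmark coupling effect; see docs/methods.md.
DEFAULT_G = 0.2

#: Default light amplitude (model units of dx/dt).
DEFAULT_B = 1.5


@dataclass(frozen=True)
class LightSchedule:
    """24 h square-wave photic forcing.

    ``value = b`` while ``(t - phase0) mod T < sigma_L`` (lights on), else 0.
    ``sigma_L`` is the photoperiod: long in summer, short in winter.
    """

    T: float = 24.0
    sigma_L: float = 12.0
    b: float = DEFAULT_B
    phase0: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sigma_L <= self.T):
            raise ValueError(f"sigma_L must be in [0, T]: {self}")
        if self.T <= 0 or self.b < 0:
            raise ValueError(f"invalid schedule: {self}")


def light_signal(t, schedule: LightSchedule | None):
    """Light amplitude at time(s) ``t`` (exactly periodic square wave)."""
    if schedule is None:
        return np.zeros_like(np.asarray(t, dtype=float))
    phase = np.mod(np.asarray(t, dtype=float) - schedule.phase0, schedule.T)
    return np.where(phase < schedule.sigma_L, schedule.b, 0.0)


@dataclass(frozen=True)
class SimConfig:
    """Integration settings for a network run."""

    g: float = DEFAULT_G
    cycles_total: int = 40
    cycles_transient: int = 15
    dt_out: float = 0.1
    rtol: float = 1e-6
    atol: float = 1e-8
    ic_mean: tuple[float, float] = (1.0, 0.0)
    ic_sd: float = 0.2
    seed: int = 0
    couple_y: bool = True   # couple both Cartesian coordinates (switchable)

    def __post_init__(self) -> None:
        if self.cycles_transient >= self.cycles_total:
            raise ValueError("cycles_transient must be < cycles_total")
        if self.rtol <= 0 or self.atol <= 0 or self.dt_out <= 0:
            raise ValueError(f"tolerances/stride must be positive: {self}")


@dataclass(frozen=True)
class Trajectory:
    """Per-cell state time series on a uniform output grid.

    ``states`` has shape (n_vars, N, n_times); the activity coordinate
    (Poincare x / Goodwin u) is ``states[0]``.  The transient window is
    flagged by ``transient_until`` (h), never silently dropped.
    """

    times: np.ndarray
    states: np.ndarray
    var_names: tuple[str, ...]
    transient_until: float
    model_kind: str
    schedule: LightSchedule | None = None
    network: SCNNetwork | None = None

    @property
    def activity(self) -> np.ndarray:
        return self.states[0]

    @property
    def post_mask(self) -> np.ndarray:
        return self.times >= self.transient_until

    @property
    def n_cells(self) -> int:
        return self.states.shape[1]

    def end_state(self) -> np.ndarray:
        return self.states[:, :, -1].ravel()


@dataclass(frozen=True)
class PRCResult:
    """Phase response curve: shift (h, advance > 0, in (-12, 12]) per CT."""

    ct: np.ndarray
    dphi: np.ndarray
    pulse_duration: float
    pulse_amplitude: float


@dataclass(frozen=True)
class EntrainmentMap:
    """Grid of (external period, amplitude) -> 1:1 entrainment flag."""

    T_values: np.ndarray
    b_values: np.ndarray
    entrained: np.ndarray  # shape (len(b_values), len(T_values))
    seed: int


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------


def _coupling_matrix(network: SCNNetwork) -> sp.csr_matrix:
    """Row-normalized weighted coupling matrix C = D^-1 W (zero rows for
    isolated cells, so k_i = 0 never divides by zero)."""
    n = network.n
    e = network.edges
    i = e["i"].to_numpy(dtype=int)
    j = e["j"].to_numpy(dtype=int)
    w = e["weight"].to_numpy(dtype=float)
    W = sp.coo_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n)).tocsr()
    deg = network.degrees.astype(float)
    inv = np.divide(1.0, deg, out=np.zeros(n), where=deg > 0)
    return sp.diags(inv) @ W


class _PoincareSystem:
    """Vectorized RHS/Jacobian of the coupled Poincare network."""

    def __init__(self, network, params, sim, schedule, pulse=None):
        self.n = network.n
        self.A = np.array([p.A for p in params])
        self.lam = np.array([p.lam for p in params])
        self.om = np.array([angular_frequency(p.tau, p.nu) for p in params])
        self.kd = np.array([modulation_depth(p.nu) for p in params])
        self.vl = network.cells.vl_mask.astype(float)
        self.C = _coupling_matrix(network)
        self.g = sim.g
        self.couple_y = sim.couple_y
        self.schedule = schedule
        self.pulse = pulse  # (t_on, t_off, amplitude) applied to VL x

    def _light(self, t: float) -> float:
        val = float(light_signal(t, self.schedule))
        if self.pulse is not None and self.pulse[0] <= t < self.pulse[1]:
            val += self.pulse[2]
        return val

    def rhs(self, t, yv):
        n = self.n
        x, y = yv[:n], yv[n:]
        r = np.hypot(x, y)
        rs = np.maximum(r, 1e-9)
        radial = self.lam * (self.A - r)
        om_eff = self.om * (1.0 + self.kd * x / rs)
        dx = radial * x - om_eff * y + self.g * (self.C @ x) + self._light(t) * self.vl
        dy = radial * y + om_eff * x
        if self.couple_y:
            dy = dy + self.g * (self.C @ y)
        return np.concatenate([dx, dy])

    def jac_blocks(self, yv):
        """Per-cell 2x2 Jacobian entries (a11, a12, a21, a22) of the local
        dynamics (coupling handled separately; light is additive)."""
        n = self.n
        x, y = yv[:n], yv[n:]
        r = np.maximum(np.hypot(x, y), 1e-9)
        lam, A, om, kd = self.lam, self.A, self.om, self.kd
        r3 = r**3
        a11 = lam * (A - r) - lam * x**2 / r - om * kd * y**3 / r3
        a12 = -lam * x * y / r - om - om * kd * x**3 / r3
        a21 = -lam * x * y / r + om + om * kd * x * (x**2 + 2 * y**2) / r3
        a22 = lam * (A - r) - lam * y**2 / r - om * kd * x**2 * y / r3
        return a11, a12, a21, a22

    def jac_transpose_apply(self, yv, Z):
        """J(yv)^T Z for the adjoint equation."""
        n = self.n
        a11, a12, a21, a22 = self.jac_blocks(yv)
        Zx, Zy = Z[:n], Z[n:]
        CT = self.C.T
        out_x = a11 * Zx + a21 * Zy + self.g * (CT @ Zx)
        out_y = a12 * Zx + a22 * Zy
        if self.couple_y:
            out_y = out_y + self.g * (CT @ Zy)
        return np.concatenate([out_x, out_y])


class _GoodwinSystem:
    """Vectorized RHS of the coupled Goodwin network.

    The neighbor mean field ``F_i = (1/k_i) sum_j W_ij V_j`` feeds each
    cell's transcription through ``vc F / (Kc + F)``; light is added to
    du/dt for VL cells.
    """

    def __init__(self, network, params, sim, schedule, pulse=None):
        self.n = network.n
        get = lambda name: np.array([getattr(p, name) for p in params])
        for name in ("v1", "K1", "v2", "K2", "k3", "v4", "K4", "k5", "v6", "K6", "k7", "v8", "K8", "vc", "Kc"):
            setattr(self, name, get(name))
        self.hill = get("n")
        self.vl = network.cells.vl_mask.astype(float)
        self.C = _coupling_matrix(network)
        self.schedule = schedule
        self.pulse = pulse

    def _light(self, t: float) -> float:
        val = float(light_signal(t, self.schedule))
        if self.pulse is not None and self.pulse[0] <= t < self.pulse[1]:
            val += self.pulse[2]
        return val

    def rhs(self, t, yv):
        n = self.n
        u, p, z, V = np.maximum(yv.reshape(4, n), 0.0)
        F = self.C @ V
        K1n = self.K1**self.hill
        du = (self.v1 * K1n / (K1n + z**self.hill) - self.v2 * u / (self.K2 + u)
              + self.vc * F / (self.Kc + F) + self._light(t) * self.vl)
        dp = self.k3 * u - self.v4 * p / (self.K4 + p)
        dz = self.k5 * p - self.v6 * z / (self.K6 + z)
        dV = self.k7 * u - self.v8 * V / (self.K8 + V)
        return np.concatenate([du, dp, dz, dV])


def _breakpoints(t0, t1, schedule, pulse):
    """Times of forcing discontinuities inside (t0, t1), for piecewise
    integration across the square-wave edges."""
    pts = set()
    if schedule is not None and 0.0 < schedule.sigma_L < schedule.T:
        k0 = math.floor((t0 - schedule.phase0) / schedule.T) - 1
        k1 = math.ceil((t1 - schedule.phase0) / schedule.T) + 1
        for k in range(k0, k1 + 1):
            pts.add(schedule.phase0 + k * schedule.T)
            pts.add(schedule.phase0 + k * schedule.T + schedule.sigma_L)
    if pulse is not None:
        pts.update(pulse[:2])
    return sorted(p for p in pts if t0 < p < t1)


def _integrate(system, y0, t_end, sim, schedule, pulse=None, t0=0.0):
    """Piecewise integration over forcing discontinuities; dense uniform output."""
    times = np.arange(t0, t_end + sim.dt_out / 2, sim.dt_out)
    edges = [t0, *_breakpoints(t0, t_end, schedule, pulse), t_end]
    ys = [np.asarray(y0, dtype=float)]
    out = np.empty((len(y0), len(times)))
    out[:, 0] = ys[0]
    filled = 1
    y = ys[0]
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (times > a) & (times <= b)
        t_eval = times[sel]
        # the continuation state must sit exactly at the segment boundary,
        # even when the output grid does not align with it
        t_solve = t_eval if len(t_eval) and t_eval[-1] == b else np.append(t_eval, b)
        sol = solve_ivp(system.rhs, (a, b), y, t_eval=t_solve,
                        rtol=sim.rtol, atol=sim.atol, method="RK45")
        if not sol.success:
            raise RuntimeError(f"integration failed at t={sol.t[-1] if len(sol.t) else a:.2f} h: {sol.message}")
        if len(t_eval):
            out[:, filled:filled + len(t_eval)] = sol.y[:, : len(t_eval)]
            filled += len(t_eval)
        y = sol.y[:, -1]
    return times, out


def _initial_state(n, sim, model_kind):
    rng = named_rng(sim.seed, "initial-conditions")
    if model_kind == "poincare":
        x = rng.normal(sim.ic_mean[0], sim.ic_sd, n)
        y = rng.normal(sim.ic_mean[1], sim.ic_sd, n)
        return np.concatenate([x, y])
    base = np.array([0.1, 0.2, 2.0, 0.1])
    vals = np.abs(rng.normal(base[:, None], 0.2 * base[:, None] + 1e-3, size=(4, n)))
    return vals.ravel()


_VAR_NAMES = {"poincare": ("x", "y"), "goodwin": ("u", "p", "z", "V")}
_SYSTEMS = {"poincare": _PoincareSystem, "goodwin": _GoodwinSystem}


def simulate_network(
    network: SCNNetwork,
    params: list,
    schedule: LightSchedule | None,
    sim: SimConfig,
    model_kind: str = "poincare",
    *,
    y0: np.ndarray | None = None,
    pulse: tuple[float, float, float] | None = None,
    cycle_length: float = 24.0,
) -> Trajectory:
    """Integrate the full coupled system under the given light schedule.

    ``y0`` continues from a supplied state (e.g. the end of an entrained
    run); ``pulse = (t_on, t_off, amplitude)`` adds a one-off square light
    pulse to the VL cells (PRC protocol).
    """
    if len(params) != network.n:
        raise ValueError(f"params length {len(params)} != network size {network.n}")
    if model_kind not in _SYSTEMS:
        raise ValueError(f"unknown model kind: {model_kind}")
    system = _SYSTEMS[model_kind](network, params, sim, schedule, pulse)
    nv = len(_VAR_NAMES[model_kind])
    if y0 is None:
        y0 = _initial_state(network.n, sim, model_kind)
    t_end = sim.cycles_total * cycle_length
    times, out = _integrate(system, y0, t_end, sim, schedule, pulse)
    states = out.reshape(nv, network.n, len(times))
    return Trajectory(
        times=times, states=states, var_names=_VAR_NAMES[model_kind],
        transient_until=sim.cycles_transient * cycle_length,
        model_kind=model_kind, schedule=schedule, network=network,
    )


def free_run(
    network: SCNNetwork,
    params: list,
    sim: SimConfig,
    model_kind: str = "poincare",
    *,
    from_state: np.ndarray | None = None,
) -> Trajectory:
    """Simulate without photic forcing, optionally continuing from the end
    state of a previous (entrained) run."""
    return simulate_network(network, params, None, sim, model_kind, y0=from_state)


def measure_periods(traj: Trajectory, min_amplitude: float = 1e-3) -> np.ndarray:
    """Per-cell period estimate (h) from post-transient inter-peak intervals;
    NaN for cells without detectable rhythm."""
    t = traj.times[traj.post_mask]
    dt = t[1] - t[0]
    periods = np.full(traj.n_cells, np.nan)
    for i in range(traj.n_cells):
        x = traj.activity[i][traj.post_mask]
        span = np.ptp(x)
        if span < min_amplitude:
            continue
        peaks, _ = find_peaks(x, prominence=span * 0.2, distance=max(int(6.0 / dt), 1))
        if len(peaks) >= 3:
            periods[i] = np.mean(np.diff(t[peaks]))
    return periods


# ---------------------------------------------------------------------------
# Entrainment classification and Arnold tongue scan
# ---------------------------------------------------------------------------


def _refined_peaks(t, x, min_distance=6.0, prominence_frac=0.2):
    """Peak times with parabolic sub-grid refinement."""
    dt = t[1] - t[0]
    span = np.ptp(x)
    if span <= 0:
        return np.array([])
    idx, _ = find_peaks(x, prominence=span * prominence_frac, distance=max(int(min_distance / dt), 1))
    idx = idx[(idx > 0) & (idx < len(x) - 1)]
    if len(idx) == 0:
        return np.array([])
    y0, y1, y2 = x[idx - 1], x[idx], x[idx + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-30, 0.5 * (y0 - y2) / denom, 0.0)
    return t[idx] + np.clip(shift, -1, 1) * dt


def mean_field_peaks(traj: Trajectory, post_only: bool = True) -> np.ndarray:
    """Peak times of the population-mean activity trace."""
    mask = traj.post_mask if post_only else slice(None)
    return _refined_peaks(traj.times[mask], traj.activity.mean(axis=0)[mask])


def is_entrained(
    traj: Trajectory,
    T_ext: float,
    tol_period: float = 0.1,
    tol_drift: float = 0.05,
    n_check: int = 10,
) -> bool:
    """1:1 entrainment test on the mean field.

    The rhythm phase is extracted cycle by cycle as the circular phase of
    the mean field at the forcing frequency (the angle of the
    fundamental-frequency Fourier coefficient over each of the last
    ``n_check`` cycles), which is robust to the output stride.  Entrained
    iff (a) the implied period matches ``T_ext``: the mean per-cycle phase
    shift converts to < ``tol_period`` h, (b) the phase relative to the
    forcing shows no secular drift beyond ``tol_drift`` h/cycle, and (c)
    the cycle-to-cycle phase wobble around the linear fit stays below half
    an hour (a locked rhythm is strictly periodic).
    """
    post_cycles = (traj.times[-1] - traj.transient_until) / T_ext
    if post_cycles < n_check:
        raise ValueError(f"trajectory covers only {post_cycles:.1f} post-transient cycles; need >= {n_check}")
    t = traj.times[traj.post_mask]
    mf = traj.activity[:, traj.post_mask].mean(axis=0)
    if np.ptp(mf) < 1e-9:
        return False
    t_end = t[-1]
    theta = []
    for c in range(n_check):
        lo = t_end - (n_check - c) * T_ext
        sel = (t >= lo) & (t < lo + T_ext)
        if sel.sum() < 4:
            raise ValueError("output stride too coarse to resolve one cycle")
        # least-squares harmonic fit: exact at any (even uneven) sampling
        w = 2 * np.pi * t[sel] / T_ext
        M = np.column_stack([np.cos(w), np.sin(w), np.ones(sel.sum())])
        a, b, _ = np.linalg.lstsq(M, mf[sel], rcond=None)[0]
        if np.hypot(a, b) < 1e-12:
            return False
        theta.append(np.arctan2(-b, a))  # phase of cos(w - theta)
    theta = np.unwrap(theta)
    k = np.arange(n_check)
    slope, intercept = np.polyfit(k, theta, 1)
    shift_h = slope * T_ext / (2 * np.pi)  # per-cycle phase shift in hours
    wobble_h = np.abs(theta - (slope * k + intercept)).max() * T_ext / (2 * np.pi)
    return bool(abs(shift_h) < min(tol_period, tol_drift) and wobble_h < 0.5)


def entrainment_region(
    network: SCNNetwork,
    params: list,
    T_grid,
    b_grid,
    sim: SimConfig,
    model_kind: str = "poincare",
    sigma_frac: float = 0.5,
    tol_period: float = 0.1,
    tol_drift: float = 0.05,
) -> EntrainmentMap:
    """Arnold-tongue scan: classify 1:1 entrainment for each combination of
    external period and light amplitude (photoperiod = sigma_frac * T_ext;
    one network realization per condition, as a numeric scan)."""
    T_grid = np.asarray(T_grid, dtype=float)
    b_grid = np.asarray(b_grid, dtype=float)
    flags = np.zeros((len(b_grid), len(T_grid)), dtype=bool)
    for ib, b in enumerate(b_grid):
        for it, T_ext in enumerate(T_grid):
            sched = LightSchedule(T=T_ext, sigma_L=sigma_frac * T_ext, b=b)
            traj = simulate_network(network, params, sched, sim, model_kind, cycle_length=T_ext)
            flags[ib, it] = is_entrained(traj, T_ext, tol_period, tol_drift)
    return EntrainmentMap(T_values=T_grid, b_values=b_grid, entrained=flags, seed=sim.seed)


# ---------------------------------------------------------------------------
# Phase response curves
# ---------------------------------------------------------------------------


def _asymptotic_shift(peaks_control, peaks_pulse, period, n_avg=3):
    """Phase shift (h, advance > 0) from the last ``n_avg`` peak pairs."""
    m = min(len(peaks_control), len(peaks_pulse), n_avg)
    d = peaks_control[-m:] - peaks_pulse[-m:]
    d = (d + period / 2) % period - period / 2  # wrap to (-T/2, T/2]
    return float(np.mean(d))


def measure_prc(
    network: SCNNetwork,
    params: list,
    sim: SimConfig,
    pulse_duration: float = 4.0,
    pulse_amplitude: float = DEFAULT_B,
    n_ct: int = 12,
    model_kind: str = "poincare",
    entrain_schedule: LightSchedule | None = None,
    free_cycles: int = 15,
    settle_cycles: int = 3,
) -> PRCResult:
    """Finite-pulse PRC of the network mean field.

    Protocol: entrain to a 24 h schedule to anchor CT0 at the mean-field
    maximum; release into free-run (the control); re-run the identical
    free-run (common random numbers -- same initial state) with one square
    light pulse to the VL cells starting at each circadian time on the grid;
    report the asymptotic shift of the mean-field peaks, in h, advance > 0,
    wrapped to (-12, 12].
    """
    if entrain_schedule is None:
        entrain_schedule = LightSchedule(T=24.0, sigma_L=12.0, b=DEFAULT_B)
    ent = simulate_network(network, params, entrain_schedule, sim, model_kind)
    state0 = ent.end_state()

    fr_sim = replace(sim, cycles_total=free_cycles, cycles_transient=min(settle_cycles, free_cycles - 11))
    control = simulate_network(network, params, None, fr_sim, model_kind, y0=state0)
    ctrl_peaks_all = mean_field_peaks(control, post_only=False)
    if len(ctrl_peaks_all) < 6:
        raise RuntimeError("unstable or peakless free-running reference rhythm")
    T_free = float(np.mean(np.diff(ctrl_peaks_all[-6:])))
    ctrl_peaks = mean_field_peaks(control)
    # CT0 = mean-field maximum; pick the first peak after the settle window
    anchor = ctrl_peaks_all[ctrl_peaks_all >= settle_cycles * 24.0][0]

    ct_grid = np.arange(n_ct) * 24.0 / n_ct
    shifts = np.empty(n_ct)
    for m, ct in enumerate(ct_grid):
        t_on = anchor + ct / 24.0 * T_free
        pulsed = simulate_network(
            network, params, None, fr_sim, model_kind,
            y0=state0, pulse=(t_on, t_on + pulse_duration, pulse_amplitude),
        )
        # control minus pulsed peak time: positive when the pulse advanced the clock
        shift = _asymptotic_shift(ctrl_peaks, mean_field_peaks(pulsed), T_free)
        shifts[m] = shift * 24.0 / T_free
    shifts = (shifts - 12.0) % -24.0 + 12.0  # wrap to (-12, 12]
    return PRCResult(ct=ct_grid, dphi=shifts, pulse_duration=pulse_duration, pulse_amplitude=pulse_amplitude)


# ---------------------------------------------------------------------------
# Adjoint infinitesimal PRCs
# ---------------------------------------------------------------------------


def _limit_cycle(system, n, sim, model_kind, converge_cycles=40):
    """Converged periodic orbit of the (possibly coupled) free-running
    system: returns (period T, spline of the state over one period)."""
    lc_sim = replace(sim, cycles_total=converge_cycles, cycles_transient=converge_cycles - 12, dt_out=0.05)
    y0 = _initial_state(n, lc_sim, model_kind)
    times, out = _integrate(system, y0, lc_sim.cycles_total * 24.0, lc_sim, None)
    mf = out[:n].mean(axis=0)
    mask = times >= (converge_cycles - 12) * 24.0
    pk = _refined_peaks(times[mask], mf[mask])
    if len(pk) < 3:
        raise RuntimeError("no stable limit cycle found")
    T = float(np.mean(np.diff(pk)))
    t0 = pk[-3]
    sel = (times >= t0 - 2 * lc_sim.dt_out) & (times <= t0 + T + 2 * lc_sim.dt_out)
    spline = CubicSpline(times[sel] - t0, out[:, sel], axis=1)
    return T, spline


def compute_iprc(
    network: SCNNetwork,
    params: list,
    sim: SimConfig,
    n_phase: int = 120,
    n_periods: int = 40,
    tol: float = 1e-8,
):
    """Adjoint (infinitesimal) PRC of the free-running Poincare system.

    Solves the adjoint variational equation dZ/dt = -J(x(t))^T Z backward in
    time around the converged limit cycle until the periodic left Floquet
    vector is reached, then applies the standard normalization
    ``Z(t) . f(x(t)) = 1`` so Z measures phase advance in hours per unit
    state perturbation.  Returns ``(ct_grid, Z_x)`` where ``Z_x`` has shape
    (N, n_phase): the x-direction (light-direction) phase sensitivity of
    every cell, sampled over one cycle of circadian time.

    Completely disconnected cells free-run at their own period and would
    make the collective orbit aperiodic; they are pruned first -- the same
    convention as the spectral analysis -- and reported as NaN rows.
    """
    keep = network.degrees > 0
    if network.n > 1 and not keep.all():
        from .network import subnetwork

        ct, Z_sub = compute_iprc(subnetwork(network, keep),
                                 [p for p, k in zip(params, keep) if k],
                                 sim, n_phase, n_periods, tol)
        Z = np.full((network.n, n_phase), np.nan)
        Z[keep] = Z_sub
        return ct, Z
    system = _PoincareSystem(network, params, sim, None)
    T, orbit = _limit_cycle(system, network.n, sim, "poincare")

    def adjoint_rhs(t, Z):  # integrate forward in s = -t
        y = orbit(T - (t % T))
        return system.jac_transpose_apply(y, Z)

    def backward_period(Z):
        sol = solve_ivp(adjoint_rhs, (0.0, T), np.asarray(Z, dtype=float),
                        rtol=1e-9, atol=1e-11, method="RK45")
        if not sol.success:
            raise RuntimeError(f"adjoint integration failed: {sol.message}")
        return sol.y[:, -1]

    n_state = 2 * network.n
    rng = named_rng(sim.seed, "adjoint-init")
    if n_state <= 6:
        # tiny systems: plain power iteration (spectra well separated)
        Z = rng.normal(size=n_state)
        Z /= np.linalg.norm(Z)
        prev = Z.copy()
        for _ in range(n_periods):
            Z = backward_period(Z)
            Z /= np.linalg.norm(Z)
            if np.linalg.norm(Z - prev) < tol:
                break
            prev = Z.copy()
        else:
            raise RuntimeError("adjoint iteration (monodromy power iteration) did not converge")
    else:
        # networks: the adjoint monodromy has eigenvalues clustered near 1
        # (slow community phase modes), so Arnoldi is used to isolate the
        # neutral left Floquet vector (eigenvalue exactly 1)
        import scipy.sparse.linalg as spla

        op = spla.LinearOperator((n_state, n_state), matvec=backward_period)
        k = min(5, n_state - 2)
        vals, vecs = spla.eigs(op, k=k, which="LM", v0=rng.normal(size=n_state),
                               maxiter=n_periods * 10, tol=1e-9)
        pick = int(np.argmin(np.abs(vals - 1.0)))
        if abs(vals[pick] - 1.0) > 0.05:
            raise RuntimeError(f"no neutral adjoint mode found (closest eigenvalue {vals[pick]:.4f})")
        Z = vecs[:, pick]
        Z = np.real(Z / Z[np.argmax(np.abs(Z))])  # rotate to the real axis
        Z /= np.linalg.norm(Z)

    # one more backward pass, sampling the periodic adjoint along the cycle
    s_grid = np.linspace(0.0, T, n_phase, endpoint=False)
    sol = solve_ivp(adjoint_rhs, (0.0, T), Z, t_eval=s_grid, rtol=1e-9, atol=1e-11, method="RK45", dense_output=True)
    Zs = sol.y[:, ::-1]                       # reorder to forward time
    t_grid = (T - s_grid)[::-1] % T
    # normalize: Z . f = 1 (phase in units of time)
    scale = np.empty(n_phase)
    for m, tm in enumerate(t_grid):
        scale[m] = Zs[:, m] @ system.rhs(tm, orbit(tm))
    Zs = Zs / scale
    ct = t_grid * 24.0 / T
    order = np.argsort(ct)  # the modulo wraps t = T back to ct 0
    return ct[order], Zs[: network.n][:, order]


def iprc_finite_difference(
    network: SCNNetwork,
    params: list,
    sim: SimConfig,
    cell: int,
    ct: float,
    eps: float = 1e-3,
    n_settle: int = 12,
):
    """Direct finite-difference oracle for the iPRC: apply a small impulse
    ``eps`` to one cell's x at circadian time ``ct`` and measure the
    asymptotic mean-field phase shift per unit impulse (h)."""
    system = _PoincareSystem(network, params, sim, None)
    T, orbit = _limit_cycle(system, network.n, sim, "poincare")
    t_kick = ct / 24.0 * T
    run = replace(sim, cycles_total=n_settle, cycles_transient=1)
    y_kick = orbit(t_kick).copy()
    y_pert = y_kick.copy()
    y_pert[cell] += eps
    times, base = _integrate(system, y_kick, run.cycles_total * 24.0, run, None)
    _, pert = _integrate(system, y_pert, run.cycles_total * 24.0, run, None)
    n = network.n
    pk_b = _refined_peaks(times[times > 48.0], base[:n].mean(axis=0)[times > 48.0])
    pk_p = _refined_peaks(times[times > 48.0], pert[:n].mean(axis=0)[times > 48.0])
    return _asymptotic_shift(pk_b, pk_p, T) / eps


# ---------------------------------------------------------------------------
# Topology-switch experiment
# ---------------------------------------------------------------------------


def topology_switch_experiment(
    winter: SCNNetwork,
    summer: SCNNetwork,
    params: list,
    sim: SimConfig,
    switch_cycle: int,
    schedule: LightSchedule | None = None,
    stable_frac: float = 0.05,
):
    """Integrate with the winter adjacency until ``switch_cycle``, then
    switch to the summer adjacency; report (trajectory, re-entrainment time
    in cycles until the per-cycle mean-field width w changes by less than
    ``stable_frac`` per cycle for the rest of the run)."""
    if winter.n != summer.n or not np.array_equal(winter.cells.region, summer.cells.region):
        raise ValueError("winter and summer networks must share the same cell table")
    from .measures import activity_width_height, mean_field

    pre_sim = replace(sim, cycles_total=switch_cycle, cycles_transient=min(sim.cycles_transient, switch_cycle - 1))
    pre = simulate_network(winter, params, schedule, pre_sim, "poincare")
    post_cycles = sim.cycles_total - switch_cycle
    post_sim = replace(sim, cycles_total=post_cycles, cycles_transient=0)
    post = simulate_network(summer, params, schedule, post_sim, "poincare", y0=pre.end_state())

    if np.array_equal(winter.adjacency(), summer.adjacency()):
        return post, 0
    mf = mean_field(post, post_only=False)
    shape = activity_width_height(mf, cycle_length=24.0)
    w = shape.w_per_cycle
    rel = np.abs(np.diff(w)) / np.maximum(w[:-1], 1e-12)
    stable_from = len(rel)
    for c in range(len(rel)):
        if np.all(rel[c:] < stable_frac):
            stable_from = c
            break
    return post, int(stable_from)
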
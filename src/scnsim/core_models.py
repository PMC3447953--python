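"""Single-cell circadian oscillator models and population samplers.

Two cell models are provided:

* a *spiking Poincare oscillator* -- a two-dimensional amplitude--phase
  limit-cycle model with radial relaxation rate ``lam``, limit-cycle
  amplitude ``A`` and a phase-velocity modulation parameter ``nu`` that
  sharpens the activity peak from a 12 h sinusoidal half-wave down to the
  4--5 h spike-like electrical-activity profile of SCN neurons;
* a *Goodwin gene-circuit oscillator* (Gonze-type) -- a four-variable
  transcriptional feedback loop (clock-gene mRNA ``u``, clock protein ``p``,
  transcriptional inhibitor ``z``, released neuropeptide ``V``) with Hill
  repression and Michaelis-type degradation.

Population heterogeneity is encoded by samplers: amplitudes and relaxation
rates are log-normal, intrinsic periods are Gaussian around 24 h (SD 3 h),
non-rhythmic cells have ``A = 0``, and Goodwin cells carry a rate-scaling
factor ``s ~ Normal(1.0, 0.05)`` dividing all production/degradation rates.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.signal import find_peaks

__all__ = [
    "PoincareParams",
    "PoincareState",
    "GoodwinParams",
    "GoodwinState",
    "modulation_depth",
    "phase_velocity",
    "angular_frequency",
    "poincare_derivatives",
    "polar_to_cartesian",
    "cartesian_to_polar",
    "sample_poincare_population",
    "sample_goodwin_population",
    "goodwin_derivatives",
    "intrinsic_period",
    "goodwin_focus_period",
    "calibrate_goodwin_degradation",
    "goodwin_region_defaults",
    "named_rng",
    "params_to_json",
    "params_from_json",
    "population_to_frame",
]

# ---------------------------------------------------------------------------
# RNG plumbing: one root seed per experiment, split into named streams so the
# parameter draw, the geometry, the long-range wiring and the initial
# conditions are independently reproducible.
# ---------------------------------------------------------------------------


def named_rng(seed: int, name: str) -> np.random.Generator:
    """Return an independent, reproducible generator for stream ``name``.

    The stream seed is derived from ``(seed, crc32(name))`` so the same root
    seed always yields the same stream for a given name, and different names
    give statistically independent streams.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# Poincare oscillator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoincareParams:
    """Parameters of one spiking Poincare oscillator.

    Attributes
    ----------
    A :
        Relative limit-cycle amplitude (dimensionless, >= 0).  ``A = 0``
        flags a non-rhythmic cell: the origin becomes the only attractor and
        the cell is a damped oscillator.
    lam :
        Radial relaxation rate in 1/h (> 0).  Small values make the cell a
        *weak* oscillator whose amplitude is easily deformed by inputs.
    tau :
        Intrinsic free-running period in h (> 0).
    nu :
        Phase-velocity modulation parameter (dimensionless, >= 0).  ``nu = 0``
        gives uniform rotation (sinusoidal activity); the default ``nu = 2``
        gives the spike-like 4--5 h activity peak.
    """

    A: float
    lam: float
    tau: float
    nu: float = 2.0

    def __post_init__(self) -> None:
        if not (self.A >= 0 and self.lam > 0 and self.tau > 0 and self.nu >= 0):
            raise ValueError(f"invalid PoincareParams: {self}")


@dataclass(frozen=True)
class PoincareState:
    """Cartesian state (x, y) of a Poincare cell; x is the activity coordinate."""

    x: float
    y: float


def modulation_depth(nu: float) -> float:
    """Relative depth k in [0, 1) of the phase-velocity modulation.

    ``k = 2 nu / (2 nu + 1)``: zero for ``nu = 0`` (uniform rotation),
    saturating below 1 for large ``nu`` so the phase always advances and the
    cycle never develops a spurious fixed point.
    """
    if nu < 0:
        raise ValueError("nu must be >= 0")
    return 2.0 * nu / (2.0 * nu + 1.0)


def angular_frequency(tau: float, nu: float) -> float:
    """Base angular velocity (rad/h) giving period exactly ``tau``.

    For ``dphi/dt = omega (1 + k cos phi)`` the period is
    ``2 pi / (omega sqrt(1 - k^2))``, so the offset parameter is
    ``omega = 2 pi / (tau sqrt(1 - k^2))``; at ``nu = 0`` this reduces to the
    uniform phase velocity ``2 pi / tau``.
    """
    k = modulation_depth(nu)
    return 2.0 * math.pi / (tau * math.sqrt(1.0 - k * k))


def phase_velocity(phi, tau: float, nu: float):
    """Instantaneous phase velocity dphi/dt (rad/h) at phase ``phi``.

    The cell moves fastest through the activity peak (phi = 0) and dwells
    near the trough (phi = pi), which compresses the time the activity
    coordinate spends above half of its peak-to-trough range from the 12 h of
    a sinusoid (nu = 0) down to 4--5 h at the default nu = 2.  Isolated here
    so the modulation law is swappable in one place.
    """
    return angular_frequency(tau, nu) * (1.0 + modulation_depth(nu) * np.cos(phi))


_R_EPS = 1e-12


def poincare_derivatives(
    state: PoincareState | tuple[float, float],
    params: PoincareParams,
    fx: float = 0.0,
    fy: float = 0.0,
) -> tuple[float, float]:
    """Cartesian time-derivatives (dx/dt, dy/dt) of one Poincare cell.

    Equivalent to the polar dynamics ``dr/dt = lam r (A - r)`` and
    ``dphi/dt = omega (1 + k cos phi)``; external forcings ``fx, fy`` (light,
    coupling) are added to the respective Cartesian derivatives.

    Raises
    ------
    ValueError
        If the state or forcing is not finite.
    """
    x, y = (state.x, state.y) if isinstance(state, PoincareState) else state
    if not all(np.isfinite(v) for v in (x, y, fx, fy)):
        raise ValueError(f"non-finite state or forcing: state=({x}, {y}), f=({fx}, {fy})")
    r = math.hypot(x, y)
    radial = params.lam * (params.A - r)
    omega = angular_frequency(params.tau, params.nu)
    k = modulation_depth(params.nu)
    cos_phi = x / r if r > _R_EPS else 0.0
    omega_eff = omega * (1.0 + k * cos_phi)
    return (radial * x - omega_eff * y + fx, radial * y + omega_eff * x + fy)


def polar_to_cartesian(r: float, phi: float) -> PoincareState:
    return PoincareState(r * math.cos(phi), r * math.sin(phi))


def cartesian_to_polar(state: PoincareState) -> tuple[float, float]:
    return math.hypot(state.x, state.y), math.atan2(state.y, state.x)


def sample_poincare_population(
    n: int,
    f_nonrhythmic: float,
    seed: int,
    *,
    mean_A: float = 1.0,
    sd_log_A: float = 0.5,
    mean_lam: float = 0.03,
    sd_log_lam: float = 0.4,
    tau_mean: float = 24.0,
    tau_sd: float = 3.0,
    tau_min: float = 6.0,
    nu: float = 2.0,
) -> list[PoincareParams]:
    """Draw a heterogeneous cell population.

    The first ``round(n * f_nonrhythmic)`` cells get ``A = 0`` (non-rhythmic,
    damped -- these are placed in the ventrolateral region by the network
    builder); the rest draw ``A`` and ``lam`` from log-normal distributions
    with means ``mean_A`` / ``mean_lam`` and underlying-normal SDs 0.5 / 0.4.
    Every cell draws its intrinsic period ``tau`` from Normal(24 h, 3 h),
    redrawn (truncated) to stay above ``tau_min``.  Identical seeds give
    bit-identical populations.
    """
    if not 0.0 <= f_nonrhythmic <= 1.0:
        raise ValueError(f"f_nonrhythmic must be in [0, 1], got {f_nonrhythmic}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = named_rng(seed, "poincare-params")
    n_flat = round(n * f_nonrhythmic)
    # log-normal with prescribed arithmetic mean m: mu_log = ln m - sd^2/2
    mu_A = math.log(mean_A) - sd_log_A**2 / 2.0
    mu_lam = math.log(mean_lam) - sd_log_lam**2 / 2.0
    A = np.concatenate([np.zeros(n_flat), rng.lognormal(mu_A, sd_log_A, n - n_flat)])
    lam = rng.lognormal(mu_lam, sd_log_lam, n)
    tau = rng.normal(tau_mean, tau_sd, n)
    while np.any(tau <= tau_min):  # truncation: redraw the rare far-left tail
        bad = tau <= tau_min
        tau[bad] = rng.normal(tau_mean, tau_sd, int(bad.sum()))
    return [PoincareParams(float(a), float(l), float(t), nu) for a, l, t in zip(A, lam, tau)]


# ---------------------------------------------------------------------------
# Goodwin (Gonze-type) oscillator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GoodwinParams:
    """Parameters of one Goodwin-type gene-circuit cell.

    Defaults are the published Gonze et al. constants.  ``s`` is the
    cell-specific rate-scaling factor; the production and degradation rates
    v1, v2, k3, v4, k5, v6, k7, v8 stored here are understood as *already
    divided* by ``s`` (the sampler performs the division).
    """

    v1: float = 0.7
    K1: float = 1.0
    v2: float = 0.35
    K2: float = 1.0
    k3: float = 0.7
    v4: float = 0.35
    K4: float = 1.0
    k5: float = 0.7
    v6: float = 0.35
    K6: float = 1.0
    k7: float = 0.35
    v8: float = 1.0
    K8: float = 1.0
    vc: float = 0.4
    Kc: float = 1.0
    n: float = 4.0
    s: float = 1.0

    def __post_init__(self) -> None:
        vals = asdict(self)
        if any(v <= 0 for f, v in vals.items() if f != "n") or self.n < 1:
            raise ValueError(f"invalid GoodwinParams: {self}")


@dataclass(frozen=True)
class GoodwinState:
    """Concentrations (nM): clock-gene mRNA u, protein p, inhibitor z, neuropeptide V."""

    u: float
    p: float
    z: float
    V: float


def goodwin_derivatives(
    state: GoodwinState | tuple[float, float, float, float],
    params: GoodwinParams,
    F: float = 0.0,
    light: float = 0.0,
) -> tuple[float, float, float, float]:
    """Time-derivatives (du, dp, dz, dV)/dt of one Goodwin cell.

    ``F`` is the mean neurotransmitter level of the cell's neighbors, feeding
    transcription through a Michaelis term ``vc F / (Kc + F)``; ``light`` is
    added directly to du/dt (ventrolateral cells only, in the network model).
    """
    u, p, z, V = (state.u, state.p, state.z, state.V) if isinstance(state, GoodwinState) else state
    if min(u, p, z, V) < 0 or F < 0 or light < 0:
        raise ValueError(f"negative state/input: {(u, p, z, V)}, F={F}, light={light}")
    q = params
    du = q.v1 * q.K1**q.n / (q.K1**q.n + z**q.n) - q.v2 * u / (q.K2 + u) + q.vc * F / (q.Kc + F) + light
    dp = q.k3 * u - q.v4 * p / (q.K4 + p)
    dz = q.k5 * p - q.v6 * z / (q.K6 + z)
    dV = q.k7 * u - q.v8 * V / (q.K8 + V)
    return du, dp, dz, dV


#: Hill coefficients making dorsomedial cells self-sustained and
#: ventrolateral cells damped.
HILL_DM = 4.0
HILL_VL = 2.0


def sample_goodwin_population(
    n: int,
    f_vl: float,
    seed: int,
    *,
    s_mean: float = 1.0,
    s_sd: float = 0.05,
    calibration: dict | None = None,
) -> list[GoodwinParams]:
    """Draw ``n`` Goodwin cells; the first ``round(n * f_vl)`` are VL cells.

    VL cells get the reduced Hill coefficient (damped); DM cells the full
    one (self-sustained).  Region calibrations (see
    :func:`calibrate_goodwin_degradation`) set the clock-gene degradation
    rate and overall rate scale so both populations have an inherent period
    of ~24 h.  Each cell's eight production/degradation rates are divided by
    its scaling factor ``s ~ Normal(s_mean, s_sd)``.
    """
    if not 0.0 <= f_vl <= 1.0 or n < 1:
        raise ValueError(f"invalid population request: n={n}, f_vl={f_vl}")
    if calibration is None:
        calibration = goodwin_region_defaults()
    rng = named_rng(seed, "goodwin-params")
    n_vl = round(n * f_vl)
    out = []
    rates = ("v1", "v2", "k3", "v4", "k5", "v6", "k7", "v8")
    for i in range(n):
        s = float(rng.normal(s_mean, s_sd))
        s = max(s, 0.5)  # guard the pathological far-left tail
        cal = calibration["VL"] if i < n_vl else calibration["DM"]
        base = GoodwinParams(n=HILL_VL if i < n_vl else HILL_DM, v2=cal["v2"])
        factor = cal.get("rate_scale", 1.0) / s
        out.append(replace(base, s=s, **{r: getattr(base, r) * factor for r in rates}))
    return out


# ---------------------------------------------------------------------------
# Period measurement and Goodwin calibration
# ---------------------------------------------------------------------------


def _single_cell_trajectory(params, model_kind: str, t_end: float, dt: float = 0.05):
    """Integrate one uncoupled cell; returns (t, activity coordinate)."""
    t_eval = np.arange(0.0, t_end, dt)
    if model_kind == "poincare":
        def rhs(t, yv):
            return poincare_derivatives((yv[0], yv[1]), params)
        y0 = [max(params.A, 0.5), 0.0]
    elif model_kind == "goodwin":
        def rhs(t, yv):
            return goodwin_derivatives(tuple(np.maximum(yv, 0.0)), params)
        y0 = [0.1, 0.2, 2.0, 0.1]
    else:
        raise ValueError(f"unknown model kind: {model_kind}")
    sol = solve_ivp(rhs, (0.0, t_eval[-1]), y0, t_eval=t_eval, rtol=1e-8, atol=1e-10, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"single-cell integration failed: {sol.message}")
    return sol.t, sol.y[0]


def goodwin_focus_period(params: GoodwinParams) -> tuple[float, float]:
    """Ringing period (h) and leading real part of a damped Goodwin cell.

    Linearizes the uncoupled cell at its stable fixed point and returns
    ``2 pi / max Im(eigenvalue)`` -- the inherent period of the decaying
    oscillation -- together with the largest real part (negative for a
    damped cell, positive if the cell is actually self-sustained).
    """
    from scipy.optimize import fsolve

    def f(s):
        return goodwin_derivatives(tuple(np.abs(s)), params)

    s0 = np.abs(fsolve(f, [0.5, 0.5, 0.5, 0.5]))
    J = np.empty((4, 4))
    f0 = np.asarray(f(s0))
    for k in range(4):
        sp = s0.copy()
        sp[k] += 1e-6
        J[:, k] = (np.asarray(f(sp)) - f0) / 1e-6
    ev = np.linalg.eigvals(J)
    im = float(ev.imag.max())
    if im <= 0:
        raise RuntimeError("fixed point has no oscillatory mode")
    return 2.0 * math.pi / im, float(ev.real.max())


def intrinsic_period(
    params,
    model_kind: str = "poincare",
    *,
    n_cycles: int = 12,
    transient_cycles: int = 4,
    amplitude_floor: float = 1e-3,
    include_decaying: bool = False,
) -> float | None:
    """Measured free-running period (h) of one uncoupled cell, or None if damped.

    Integrates ``n_cycles`` nominal 24 h cycles, discards the first
    ``transient_cycles``, and returns the mean inter-peak interval of the
    activity coordinate.  The cell counts as damped -- returning None -- if
    the post-transient peak-to-trough amplitude falls below
    ``amplitude_floor`` or keeps shrinking (late-window amplitude below half
    the early-window one, which also catches the algebraic decay of an
    ``A = 0`` cell); with ``include_decaying`` set the ringing period of the
    decaying oscillation (early inter-peak intervals) is returned instead --
    used to calibrate the damped ventrolateral Goodwin cells.
    """
    t, x = _single_cell_trajectory(params, model_kind, t_end=24.0 * n_cycles)
    post = t >= 24.0 * transient_cycles
    early = post & (t < 24.0 * (transient_cycles + 2))
    late = t >= 24.0 * (n_cycles - 2)
    decaying = np.ptp(x[late]) < 0.5 * np.ptp(x[early])
    if np.ptp(x[post]) < amplitude_floor or decaying:
        if not include_decaying:
            return None
        post = t >= 24.0  # measure the ringing before it dies out
        if np.ptp(x[post]) < amplitude_floor:
            post = t >= 0.0
    ts, xs = t[post], x[post]
    span = np.ptp(xs)
    peaks, _ = find_peaks(xs, prominence=max(span * 0.05, 1e-12), distance=int(6.0 / (ts[1] - ts[0])))
    if len(peaks) < 2:
        return None
    return float(np.mean(np.diff(ts[peaks])))


#: Clock-gene degradation rate fixed for VL cells: large enough that the
#: n = 2 cell is a robustly damped focus (the VL 24 h target is then met by
#: the one-dimensional rate rescaling below).
V2_VL_BASE = 1.0


def calibrate_goodwin_degradation(
    region: str,
    target_period: float = 24.0,
) -> dict[str, float]:
    """One-dimensional calibration giving an inherent period of ~24 h.

    DM (self-sustained, Hill n = 4): root-find on the clock-gene degradation
    rate v2 using the measured limit-cycle period.  VL (damped, Hill n = 2):
    v2 alone cannot reach 24 h -- the linearized ringing period saturates
    near 26.6 h at the baseline constants -- so with v2 fixed at
    ``V2_VL_BASE`` the calibration knob is a uniform scale on all eight
    production/degradation rates (a pure time rescaling, the same degree of
    freedom as the cell-variability factor s), root-found on the linearized
    focus period.  Returns {'v2': ..., 'rate_scale': ...}.
    """
    if region == "DM":

        def period_error(v2: float) -> float:
            per = intrinsic_period(GoodwinParams(n=HILL_DM, v2=v2), "goodwin")
            if per is None:
                raise RuntimeError(f"DM cell not oscillating at v2={v2}")
            return per - target_period

        # bracket stays well inside the oscillatory regime (Hopf loss ~0.45)
        return {"v2": float(brentq(period_error, 0.28, 0.40, xtol=1e-4)), "rate_scale": 1.0}
    if region == "VL":
        base_period, re_max = goodwin_focus_period(GoodwinParams(n=HILL_VL, v2=V2_VL_BASE))
        if re_max >= 0:
            raise RuntimeError("VL baseline cell is not damped")
        return {"v2": V2_VL_BASE, "rate_scale": base_period / target_period}
    raise ValueError(f"unknown region: {region}")


_REGION_CAL: dict[str, dict[str, float]] = {}


def goodwin_region_defaults() -> dict[str, dict[str, float]]:
    """Region calibrations (computed once per process, then cached)."""
    if not _REGION_CAL:
        _REGION_CAL["DM"] = calibrate_goodwin_degradation("DM")
        _REGION_CAL["VL"] = calibrate_goodwin_degradation("VL")
    return {k: dict(v) for k, v in _REGION_CAL.items()}


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_PARAM_TYPES = {"poincare": PoincareParams, "goodwin": GoodwinParams}


def params_to_json(params) -> str:
    kind = "poincare" if isinstance(params, PoincareParams) else "goodwin"
    return json.dumps({"kind": kind, **asdict(params)})


def params_from_json(text: str):
    d = json.loads(text)
    return _PARAM_TYPES[d.pop("kind")](**d)


def population_to_frame(params_list, regions=None):
    """Population as a pandas DataFrame (one row per cell), CSV-ready."""
    import pandas as pd

    rows = []
    for i, p in enumerate(params_list):
        row = {"id": i, **asdict(p)}
        if regions is not None:
            row["region"] = regions[i]
        if isinstance(p, PoincareParams):
            row["rhythmic"] = p.A > 0
        rows.append(row)
    return pd.DataFrame(rows)
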
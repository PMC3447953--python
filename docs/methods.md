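# Methods

`scnsim` simulates the mammalian suprachiasmatic nucleus (SCN) as a network
of heterogeneous circadian oscillators whose *topology*, not single-cell
physiology, carries the seasonal signal: the fraction of long-range
cell-to-cell connections `delta` is the control parameter, with a dense
long-range wiring ("winter topology") producing a narrow, high-amplitude
collective activity peak and a sparse wiring ("summer topology") a broad,
low one.  This note records the model equations as implemented, the
parameter choices and calibrations, the numerical conventions, and the known
limitations.

## Single-cell models

### Spiking Poincare oscillator

Each cell is a two-dimensional amplitude-phase oscillator.  In polar
coordinates (r, phi):

    dr/dt   = lam * r * (A - r)
    dphi/dt = omega * (1 + k * cos(phi)),     k = 2*nu / (2*nu + 1)

with the Cartesian activity coordinate x = r cos(phi) (the model's proxy for
electrical activity) and y = r sin(phi).  `A` is the limit-cycle amplitude
(`A = 0` marks a non-rhythmic, damped cell), `lam` the radial relaxation
rate -- small values make a *weak* oscillator whose amplitude is easily
deformed by inputs -- and `nu` controls the phase-velocity modulation.  The
base angular velocity is calibrated in closed form so the period is exactly
the cell's intrinsic `tau` for every `nu`:

    omega = 2*pi / (tau * sqrt(1 - k^2)).

The modulation makes the phase race through the activity peak (phi = 0) and
dwell near the trough, compressing the time x spends above half of its
peak-to-trough range from 12 h (sinusoid, `nu = 0`) to 4.9 h at the default
`nu = 2` -- the 4-5 h spike-like daily activity profile of SCN neurons.  The
mapping `nu -> k` saturates below 1, so the phase always advances and no
spurious fixed point can appear on the cycle at any `nu`.  This concrete
modulation law is this package's realization of "phase-velocity modulation";
it is isolated in `core_models.phase_velocity` so an alternative law can be
swapped in one place.

Population heterogeneity: `A` and `lam` are log-normal with arithmetic means
1.0 and 0.03 / h and underlying-normal SDs 0.5 and 0.4; `tau` is
Normal(24 h, 3 h) truncated below at 6 h (redrawn), which puts >= 95 % of
periods in the observed 18-30 h range.  One third of the cells (the
ventrolateral population, below) get `A = 0`.

### Goodwin (Gonze-type) gene circuit

For the generalization test each cell is a four-variable transcriptional
loop: clock-gene mRNA `u`, clock protein `p`, transcriptional inhibitor `z`,
and released neuropeptide `V`:

    du/dt = v1*K1^n/(K1^n + z^n) - v2*u/(K2 + u) + vc*F/(Kc + F) + L(t)
    dp/dt = k3*u - v4*p/(K4 + p)
    dz/dt = k5*p - v6*z/(K6 + z)
    dV/dt = k7*u - v8*V/(K8 + V)

with the published Gonze constants as defaults and the neighbor mean field
`F_i = (1/k_i) * sum_j W_ij V_j` as coupling input.  Dorsomedial (DM) cells
use Hill coefficient n = 4 (self-sustained); ventrolateral (VL) cells use
n = 2, which makes them damped.  Cell variability divides the eight
production/degradation rates by `s ~ Normal(1.0, 0.05)`.

Period calibration.  Both populations are brought to an inherent period of
~24 h by a one-dimensional root-find.  For DM cells the knob is the
clock-gene degradation rate `v2` (calibrated value ~0.343 vs the baseline
0.35), measured on the simulated limit cycle.  For VL cells `v2` alone
cannot reach 24 h: the ringing period of the damped focus saturates near
26.6 h as `v2` grows, so the calibration knob is instead a uniform scale on
all eight rates (a pure time rescaling -- the same degree of freedom as
`s`), with `v2` fixed at 1.0 to keep the cell robustly damped.  The damped
cell's inherent period is measured by linearization (2 pi / Im of the
leading eigenvalue at its stable fixed point), which stays well-defined at
strong damping where peak detection on the decaying trace fails.

## Network

Cells live in the unit square: round(N/3) VL cells uniformly in the band
y < 1/3, the DM rest above.  DM cells are wired as a random geometric graph
with radius `r = sqrt(k_mean / (pi * rho))` (`rho` = DM count / DM-band
area; default `k_mean = 6`); VL cells have no short-range edges.  The
boundary is hard (a bounded nucleus), so the realized mean DM degree
undershoots `k_mean` by the edge deficit (~5.6 realized at 6 nominal); this
is accepted and tested against the boundary-aware Monte-Carlo expectation.
Long-range edges are then added per unordered pair: probability `delta` for
VL-DM pairs and `delta/10` for same-region pairs, skipping pairs already
wired; "long-range" membership is defined by this construction stage, not by
a distance cut.  All edges are bidirectional with weight 1; the
weight-reduction experiment multiplies a seeded-random fraction of one edge
class by a factor without touching the pattern.

Defaults `delta = 0.005` (summer) and `0.01` (winter) at N = 600 were fixed
by the seasonal long-range budgets (~450 and ~900 connections); `delta`
scales as 1/N for other sizes, giving ~15 000 extra connections for the
summer-to-winter switch at the full SCN size of 20 000 neurons.

## Coupled dynamics

Coupling is linear local mean field: cell i receives
`(g / k_i) * sum_j W_ij x_j` added to dx/dt and the analogous term on dy/dt
(a config switch restricts coupling to x only for sensitivity checks);
isolated cells receive nothing.  Light is a square wave of period 24 h,
photoperiod width `sigma_L` (summer 16 h, winter 8 h by convention) and
amplitude `b`, added to dx/dt of VL cells only (du/dt with amplitude 0.01
for the Goodwin backend).

The coupling strength `g = 0.2 / h` and light amplitude `b = 1.5` are the
package's calibration pair, fixed once so that the entrained winter network
reproduces the model's hallmark coupling effect -- an approximately tenfold
expansion of single-cell activity amplitudes -- while both seasonal
topologies still entrain to 24 h at either photoperiod.  Because the
weak-oscillator amplitude expansion scales nearly linearly with g, the
entraining amplitude must be much larger than for a single cell (b = 0.3
suffices for one oscillator, b ~ 1.5 for the coupled network to lock
within the standard 40-cycle protocol at both photoperiods).

Runs integrate 40 cycles, discard 15 as transient (the attractor is reached
after a few cycles; statistics over cycles 16-40 and 21-40 agree within
2 %), start from x ~ Normal(1, 0.2), y ~ Normal(0, 0.2), and sample output
every 0.1 h.  Integration is piecewise RK45 (rtol 1e-6, atol 1e-8) between
light-switch discontinuities, carrying the state at the exact segment
boundary even when the output grid does not align with it.  One root seed
feeds independent named streams (parameters, geometry, long-range wiring,
initial conditions, weight scaling), so each stage is separately
reproducible.

## Analyses

* **Mean field**: population mean of the activity coordinate, shifted so
  its window minimum is zero.  Per cycle, `h` = max - min and `w` = total
  time above min + h/2 with linearly interpolated crossings; split
  super-threshold intervals are summed (robust to bimodal peaks), and flat
  cycles are flagged rather than given a width.
* **Correlations**: Pearson matrix of every cell pair on the output series
  strided by 25 samples; `rho_bar` averages the signed off-diagonal entries
  (cells with constant traces are excluded and counted).
* **Peak phases**: per-cell circular mean of post-transient peak times
  (parabolically refined local maxima with a half-cycle refractory window),
  relative to the mean-field maximum (or lights-on), modulo the cycle.  The
  cycle length is the schedule period under entrainment and the measured
  mean-field inter-peak interval under free run, so a free-running period
  away from 24 h does not masquerade as phase spread.  The spread scalar is
  the circular (angular) deviation `sqrt(2 (1 - R))`, converted to hours;
  it is sqrt(2) rad ~ 5.40 h for a uniform distribution.
* **Entrainment**: the rhythm phase is extracted cycle-by-cycle as the
  phase of a least-squares cos/sin fit of the mean field at the forcing
  frequency (exact under any output stride, immune to the harmonic leakage
  of a spiky waveform).  Entrained iff the per-cycle phase shift stays
  below 0.05 h/cycle over the last 10 cycles -- which bounds both the
  period mismatch and the secular drift -- and the cycle-to-cycle wobble
  around the linear fit stays below 0.5 h.  (An unlocked network drifts at
  the detuning rate, ~0.3 h/cycle here, an order of magnitude above the
  threshold.)  Arnold-tongue scans classify each (T_ext, b) pair from one
  network realization with photoperiod T_ext/2.
* **PRC**: entrain to 24 h to anchor CT0 at the mean-field maximum, release
  into free run (the control), and re-run the identical free run plus one
  4 h square pulse to the VL cells per circadian-time grid point (common
  random numbers: same initial state).  The shift is the asymptotic
  difference of mean-field peak times, scaled to circadian hours and
  wrapped to (-12, 12], advance positive.
* **iPRC**: the adjoint variational system is integrated backward around
  the converged free-running orbit; the periodic left Floquet vector is the
  phase sensitivity, normalized by Z . f = 1 (hours of phase per unit state
  perturbation).  For networks the adjoint monodromy has eigenvalues
  clustered at 1 (slow community phase modes), so the neutral vector is
  isolated by Arnoldi iteration on the backward-period propagator rather
  than plain power iteration.  Completely disconnected cells free-run at
  their own period and would make the orbit aperiodic; they are pruned
  (exactly as in the spectral analysis) and reported as NaN.  A network
  whose connected clusters do not mutually lock has no periodic orbit and
  raises a diagnostic instead of returning numbers.
* **Graph structure**: global efficiency E (mean inverse unweighted
  shortest-path length, 1/inf = 0) and average clustering C (fraction of
  realized neighbor pairs; degree < 2 contributes 0) via networkx,
  cross-checked against brute-force BFS and triangle enumeration in the
  test suite.  Structural metrics always use the unweighted pattern; the
  spectral Laplacian uses the weighted adjacency, so weight-reduction
  experiments move the spectrum without changing E or C.
* **Spectral communities**: the local-mean-field Laplacian
  `L = I - D^-1 W` (non-symmetric).  After removing completely disconnected
  cells, singular values below 1e-6 are counted; the count includes the
  trivial zero of each connected component, so a fully synchronizable
  network scores 1 and every extra near-zero value flags a community that
  fails to lock its phase.  Defaults: threshold 1e-6, 25 replicates.

## Synthetic-data scope

All inputs are generated; there is no external data.  The generator
reproduces the study conditions -- 600 cells (1800 for the size check), one
third ventrolateral, log-normal amplitude/relaxation heterogeneity,
Gaussian 24 +/- 3 h periods, seasonal `delta` values -- but it is not a
biophysical SCN: space is an abstract unit square rather than anatomy,
light input is a clean square wave, there is no intracellular noise, no
synaptic delay, and the VL/DM dichotomy is sharp.  Passing tests therefore
establish the *network-structural* mechanism (long-range density controls
phase-distribution width, PRC magnitude, entrainment range and spectral
community structure), not quantitative agreement with recordings.

## Problem sizes used in the test suite

The directional seasonal comparisons run the full 600-cell, 40-cycle
protocol.  Protocol-heavy analyses use reduced systems chosen so every
qualitative effect is preserved: Arnold-tongue scans N = 150 with `delta`
rescaled by 1/N, network iPRC comparisons N = 200, spectral/phase-spread
rank correlation N = 300 over five `delta` values, Goodwin seasonal runs
N = 300 over 30 cycles.  The acceptance script regenerates its quantities
at the paper-scale sizes (N = 600; n = 1000 cells for the period-sampler
recovery; the 20 000-neuron extrapolation is analytic).

## Known limitations

* The entrainment criterion is a (documented) choice; near tongue borders
  classifications can flip with the realization, and scans deliberately use
  a single realization per condition.
* The adjoint machinery requires a fully phase-locked network; realizations
  with non-locking connected clusters (rare at the default sizes, common
  for very sparse `delta`) are refused rather than approximated.
* At very long photoperiods the model keeps a unimodal phase distribution;
  bimodal splitting is outside this model's scope.
* Goodwin-backend synchrony at the default `vc = 0.4` is weaker than the
  Poincare backend's; all seasonal orderings hold, but absolute correlation
  levels are lower.
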
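# scnsim

Seasonal adaptation of the circadian clock through the network structure of
the suprachiasmatic nucleus (SCN).

The SCN — the ~20 000-neuron master clock of mammals — shortens its daily
electrical-activity peak in winter and broadens it in summer, even though
individual neurons fire in the same ~4–5 h bursts all year.  `scnsim`
implements a network explanation of that seasonal plasticity: heterogeneous
single-cell circadian oscillators coupled on a two-region graph in which the
**fraction of long-range cell-to-cell connections `δ`** is the seasonal
control knob.  Dense long-range wiring (the *winter topology*) synchronizes
the cells into a narrow, high-amplitude population rhythm; sparse wiring
(the *summer topology*) lets phases disperse into a broad, low one.  The
package is for computational chronobiologists and network-dynamics
researchers who want to simulate these regimes and reproduce the
accompanying analyses end to end.

## Model

Each of N cells (default 600; one third light-receiving, non-rhythmic
*ventrolateral* (VL) cells, the rest rhythmic *dorsomedial* (DM) cells) is a
spiking Poincaré oscillator

    dr/dt   = λ r (A − r)
    dφ/dt   = ω (1 + k cos φ),   k = 2ν/(2ν+1),   ω = 2π / (τ √(1−k²))

with activity x = r cos φ.  Amplitudes A and relaxation rates λ are
log-normal across cells (means 1.0 and 0.03 h⁻¹), intrinsic periods
τ ~ Normal(24 h, 3 h), and the phase-velocity modulation ν = 2 compresses
the activity peak to the observed 4–5 h per cycle (VL cells have A = 0 and
are purely driven).  A Goodwin-type gene-circuit backend (mRNA → protein →
inhibitor, plus a released neuropeptide) is provided for generalization
checks.

DM cells are wired as a random geometric graph (mean degree 6); long-range
edges are then added with probability δ per VL–DM pair and δ/10 per
same-region pair — δ = 0.005 ("summer", ~450 extra edges) vs δ = 0.01
("winter", ~900).  Coupling is linear local mean field,
(g/kᵢ) Σⱼ Wᵢⱼ xⱼ, and light is a 24 h square wave of adjustable photoperiod
applied to VL cells only.  Analyses include the mean-field peak width w and
amplitude h, pairwise correlation matrices, circular peak-phase spreads,
finite-pulse phase response curves (PRCs) and adjoint infinitesimal PRCs,
numeric Arnold-tongue scans, small-world metrics (efficiency E, clustering
C, product C·E), and the near-zero singular values of the local-mean-field
Laplacian L = I − D⁻¹W, which count weakly coupled oscillator communities.
See `docs/methods.md` for the full model and numerical conventions.

## Worked example

```python
from scnsim.core_models import sample_poincare_population
from scnsim.network import NetworkConfig, build_network
from scnsim.simulate import LightSchedule, SimConfig, simulate_network, is_entrained
from scnsim.measures import (mean_field, activity_width_height,
                             correlation_matrix, peak_phase_distribution)
from scnsim.graphstats import near_zero_singular_count

params = sample_poincare_population(600, 1/3, seed=1)
for season, delta, sigma in [("winter", 0.01, 8.0), ("summer", 0.005, 16.0)]:
    net = build_network(NetworkConfig(N=600, delta=delta, seed=1))
    n_long = int((net.edges["class"] == "long").sum())
    traj = simulate_network(net, params, LightSchedule(sigma_L=sigma), SimConfig(seed=1))
    shape = activity_width_height(mean_field(traj))
    rho = correlation_matrix(traj).rho_bar
    spread = peak_phase_distribution(traj).spread
    nz, _ = near_zero_singular_count(net)
    print(f"{season}: {n_long} long-range edges | entrained={is_entrained(traj, 24.0)} | "
          f"w={shape.w:.1f} h  h={shape.h:.1f}  rho_bar={rho:.2f}  "
          f"phase spread={spread:.1f} h  near-zero SVs={nz}")
```

prints

```
winter: 846 long-range edges | entrained=True | w=5.8 h  h=13.9  rho_bar=0.86  phase spread=1.1 h  near-zero SVs=1
summer: 437 long-range edges | entrained=True | w=7.4 h  h=10.7  rho_bar=0.66  phase spread=2.0 h  near-zero SVs=1
```

Doubling the long-range wiring (summer → winter) narrows the mean-field
activity peak from 7.4 h to 5.8 h, raises its amplitude, tightens the
cell-to-cell phase distribution from 2.0 h to 1.1 h circular spread, and
improves pairwise synchrony — the model's account of how the same neurons
produce a short winter day-signal and a long summer one.  The near-zero
singular-value count rises above 1 only when δ drops low enough to fragment
the network into poorly synchronizing communities.

A CLI mirrors the library for shell use:

```
scnsim build-net --n 600 --delta 0.01 --seed 1 --out out/
scnsim simulate --config experiment.yaml
scnsim prc | arnold | graphstats | spectra | season-scan ...
```

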
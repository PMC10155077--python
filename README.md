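# soycanopy

Mechanistic simulation of soybean canopy photosynthesis and growth, built
to answer one question: **how much does improving the two headline
photosynthetic capacities — the maximum Rubisco carboxylation rate
(V_cmax) and the maximum electron transport rate (J_max) — actually raise
canopy assimilation and pod yield under realistic field weather, at
current and elevated CO2?**

It is aimed at crop ecophysiologists and modellers who want a compact,
fully scriptable pipeline for capacity-scaling experiments: a
leaf-to-canopy-to-season simulator plus the sensitivity machinery around
it (scaling grids, response-surface gradient paths, bootstrap weather
ensembles, and partial-rank-correlation attribution of yield gains to
climate drivers).

## The model

**Leaf.** Steady-state FvCB photosynthesis: net assimilation
A_n = min(A_c, A_j, A_p) − R_d with

- A_c = V_cmax (C_i − Γ\*) / (C_i + K_c (1 + O / K_o))   (Rubisco-limited)
- A_j = J (C_i − Γ\*) / (4 C_i + 8 Γ\*)                  (RuBP-regeneration-limited)
- A_p = 3 · TPU                                          (triose-phosphate-limited)

J follows the non-rectangular hyperbola
θJ² − (I₂ + J_max)J + I₂J_max = 0 (smaller root, I₂ = 0.36125·Q).
Photorespiratory release obeys R_p = V_c · Γ\*/C_i, so
V_c − R_p − R_d = A_n. Stomata follow Ball–Berry,
g_s = m·A_n·RH/C_s + b, coupled to the supply function
C_i = C_a − 1.6·A_n/g_s and solved to 1e−6. All kinetic constants live in
one YAML file (`src/soycanopy/data/leaf_params.yaml`).

**Canopy.** Ten-layer sun/shade scheme: Beer-law decay of the direct beam
with a spherical leaf-angle projection (k_b = 0.5/cos z), diffuse and
scattered-beam profiles, one coupled leaf solve per layer per leaf class,
LAI-weighted aggregation, and Penman–Monteith canopy transpiration giving
WUE = A_n / E (µmol mmol⁻¹).

**Season.** Hourly growth: thermal-time development (base 10 °C),
logistic partitioning of net canopy carbon into leaf/stem/root/pod pools,
LAI from specific leaf area, leaf senescence past an onset stage, sowing
DOY 152 to physiological maturity.

**Sensitivity machinery.** Relative change of any season variable is
100·(VxJx − CTL)/|CTL|. Response surfaces over the (V_cmax, J_max)
scaling grid (−50%…+50% at 5% steps; CO2 at 400/600/800/1000 ppm) are
interpolated with tensor-product Akima splines; steepest paths follow
X_{n+1} = X_n ± α∇f(X_n) with central-difference gradients (α = 0.001,
h = 0.01). The bootstrap resampler builds synthetic years by drawing, for
every day of year, that day's full 24-hour multivariate block from a
random archive year. PRCC (rank-transform, residual-correlation) is
implemented in-package and attributes Δpod to per-phase climate drivers.

## Worked example

```python
from soycanopy import PhotosynthesisParams, generate_archive
from soycanopy.leaf import find_transition_ci, percent_gain_an
from soycanopy.canopy import CanopyArchitecture
from soycanopy.growth import PartitionSchedule, simulate_season

p = PhotosynthesisParams.from_yaml()       # Vcmax25=110, Jmax25=195

# Where does control switch from Rubisco- to RuBP-limitation?
print(find_transition_ci(1500, 25.0, p).ci_star)            # 313.1
print(find_transition_ci(1500, 25.0, p.scaled(1.0, 1.2)).ci_star)  # 432.1

# Leaf-level payoff of +20% in both capacities, Ci in [400, 600] ppm
print(percent_gain_an(1500, 25.0, p, 400, 600, 1.2, 1.2))   # 16.1 (%)
print(percent_gain_an(800, 25.0, p, 400, 600, 1.2, 1.2))    # 11.8 (%)

# One synthetic season at 400 ppm, control vs +20%/+20%
arc = generate_archive(2, seed=11)
arch, sched = CanopyArchitecture(), PartitionSchedule.from_config()
ctl = simulate_season(arc.year_frame(2001), 400.0, p, arch, sched)
v20 = simulate_season(arc.year_frame(2001), 400.0, p, arch, sched, 1.2, 1.2)
print(ctl.summary["pod"], ctl.summary["max_lai"])           # 8.13  7.89
print(100 * (v20.summary["pod"] / ctl.summary["pod"] - 1))  # 1.28 (%)
```

The transition C_i of ~313 ppm means that at current CO2 (hourly C_i
mostly 250–320 ppm) both capacities matter, while the +20% J_max variant
pushes the switch to ~432 ppm. The season run shows the attenuation chain:
a +20% capacity boost yields ~12% more peak canopy assimilation but only
~1–3% more pod, because shaded leaves gain little, respiration co-scales
with V_cmax, and carbon allocation dilutes the remainder.

There is also a CLI: `soycanopy aci`, `soycanopy weather-synth`,
`soycanopy simulate`, `soycanopy grid-run`, `soycanopy boot-run`, …
(`soycanopy --help`).

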
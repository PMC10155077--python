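# Methods

This note documents the model equations, the parameter choices behind the
defaults, the synthetic-weather generator, and the numerical decisions —
the things a user must know before trusting (or re-parameterizing) a
result.

## Leaf gas exchange

Net assimilation is the classical three-limitation minimum,
A_n = min(A_c, A_j, A_p) − R_d, with the Rubisco-limited,
RuBP-regeneration-limited, and TPU-limited rates in their canonical
forms. Electron transport uses the non-rectangular hyperbola in
PSII-effective irradiance I₂ = Q · α(1 − f)/2 with absorptance α = 0.85
and spectral loss f = 0.15 (so I₂ = 0.36125·Q) and curvature θ = 0.7.

The kinetic constants are the community-standard C3 set at 25 °C:
K_c = 405 µmol mol⁻¹, K_o = 278 mmol mol⁻¹, Γ\* = 42.75 µmol mol⁻¹,
O = 210 mmol mol⁻¹, with Arrhenius temperature scaling (activation
energies from the standard tobacco-derived tables; exact identity at
25 °C). All constants sit in `data/leaf_params.yaml`; nothing is
hard-coded. With V_cmax25 = 110 and J_max25 = 195 µmol m⁻² s⁻¹ this set
places the Ac/Aj transition at C_i ≈ 313 ppm (Q = 1500) and ≈ 232 ppm
(Q = 800), moving to ≈ 432 / ≈ 295 ppm under J_max +20% — the expected
behaviour of a modern soybean parameterization.

Dark respiration defaults to R_d25 = 0.015·V_cmax25 and, together with
the TPU capacity, **co-scales with the V_cmax scaling factor**. The R_d
coupling means capacity gains carry a respiration penalty (important for
daily-mean assimilation and yield); TPU tracking keeps the TPU limitation
rare across the whole −50%…+50% grid, which is its observed field role.

Stomata: Ball–Berry with slope 9 and intercept 0.01 mol m⁻² s⁻¹, with
leaf-surface CO2 taken equal to ambient (infinite boundary-layer
conductance — the simplest defensible closure; a boundary layer can be
emulated by lowering the slope). The coupled (A_n, g_s, C_i) state is a
damped fixed point on C_i (start 0.7·C_a, damping 0.5, tolerance
1e−7·C_a) with a deterministic vectorized-bisection fallback; negative
Ball–Berry conductance clamps to the intercept (dark closure). Agreement
with an independent bisection oracle is ~1e−8 relative.

Limiting-rate ties break in the order rubisco < rubp < tpu.
Photorespiration uses the oxygenation identity R_p = V_c·Γ\*/C_i
(V_c = (A_n + R_d)/(1 − Γ\*/C_i)); below Γ\*, R_p is reported 0 and V_c
clamps at A_n + R_d ≥ 0. A direct corollary used in the tests: under any
capacity scaling at fixed C_i, ΔR_p/ΔV_c = Γ\*/C_i exactly.

## Canopy

Ten layers of equal leaf area. Direct beam: spherical leaf-angle
projection k_b = 0.5/cos z (cos z floored at 0.05), sunlit fraction
exp(−k_b·L). Diffuse: k_d = 0.7 with exponential decay; scattered beam
adds σ/2 of the intercepted beam with hardened extinction
k_b·sqrt(1 − σ), σ = 0.2. The per-leaf beam flux uses the projection
factor capped at 1, so no leaf ever "receives" more than the above-canopy
flux; the cap binds only at solar zenith > 60°, where the beam is weak.
The diffuse share of incident light comes from an hourly clearness-index
rule (Spitters-type piecewise curve, floor 0.15).

Photosynthetic capacity (V_cmax, J_max, R_d, TPU jointly) declines with
canopy depth as exp(−k_N·L). The default k_N = 0.05 per unit LAI is
deliberately mild — a compromise inside the published range (0 for a
uniform canopy up to ~0.1–0.2 per unit LAI for strong nitrogen
gradients), chosen once so that the simulator sits in the observed
regime of the field system it emulates: a small positive pod-yield
response to joint capacity gains at 400 ppm, steepest-ascent paths
dominated by J_max at elevated CO2, and a (weak) negative association
between leaf-area gain and pod gain across weather ensembles. Both of the
latter two reproductions are *marginal* at this setting — see
Limitations.

No within-canopy gradients of temperature, humidity or CO2. Canopy
conductance for Penman–Monteith is the LAI-weighted sum of leaf g_s
(converted at 0.0245 m s⁻¹ per mol m⁻² s⁻¹); aerodynamic conductance uses
a log-profile with canopy height 1 m, measurement height 3 m, d = 0.67h,
z0m = 0.123h, z0h = 0.1·z0m, wind floored at 0.5 m s⁻¹. Net radiation is
(1 − 0.23) × shortwave, with shortwave = PPFD × 0.4376 W m⁻² per
µmol m⁻² s⁻¹ (PAR ≈ half of total shortwave); longwave exchange and soil
heat flux are neglected. WUE is undefined (NaN) when E ≤ 0 and season
summaries average it over daylight hours only.

## Crop growth

Thermal time accumulates as max(0, T − 10 °C)·dt/24 from sowing
(DOY 152). Stages (°C·d): emergence 60, reproductive onset 750 (pod
allocation is hard-gated to zero before this), senescence onset 1000,
maturity 1450, with a hard end-of-season at DOY 280 (frost/harvest
cutoff) for cool years that never reach the thermal target. Under the
default synthetic climate the reproductive phase opens near DOY 207–212.

Carbon: canopy A_n converts at 30 g CH₂O per mol CO2; positive net carbon
is discounted by a growth-respiration efficiency of 0.7, first refills a
labile pool (cap 0.3 Mg ha⁻¹), and the remainder follows normalized
logistic partition weights (leaf 0.40/900/120, stem 0.40/1000/120, root
0.15/800/150 falling; pod 0.80/1050/90 rising — amplitude/centre/width in
°C·d). Negative (night) carbon draws gross from labile, then from green
leaf. Senescence removes 0.003 of green leaf per °C·d past onset. LAI is
2.0 × green leaf biomass (Mg ha⁻¹ → m² m⁻²). Carbon is conserved exactly
at every step, and pool updates are linear in flux within a stage.

These coefficients were calibrated once so that a typical synthetic
Illinois year at 400 ppm yields a control pod harvest of ~7–8 Mg ha⁻¹ and
peak LAI ~7–8 — the observable regime of a modern high-yield soybean
canopy — and were then frozen. They are a plausible soybean, not a
fitted cultivar.

For speed, `simulate_season` solves each day's 24 hours × 10 layers × 2
leaf classes in one vectorized batch with LAI frozen at the day's start
(operator splitting); growth still integrates hourly. Within-day LAI
increments are < 0.1, so the splitting error is far below the other
structural uncertainties. One season runs in ~0.25 s, which sets the test
problem sizes: 2-year archives for grid experiments (5×5 scales × 2 CO2
levels) and a 10-year archive with 200 bootstrap replicates for ensemble
properties.

## Synthetic weather

The generator emulates a humid-continental corn-belt station at 40.04° N:

- PPFD = clear-sky envelope (2200 µmol m⁻² s⁻¹ overhead) × cos z ×
  day-level brightness, an AR(1) process on the logit scale mapped into
  (0.25, 1]; nighttime PPFD is exactly 0.
- Temperature = seasonal cosine (mean 10.5 °C, amplitude 14 °C, peak
  DOY 200) + AR(1) day anomalies + a brightness coupling (+3 °C per unit
  brightness) + a diurnal cosine (amplitude 6 °C, peak 15 h) + noise.
- Relative humidity = 0.78 − 0.018 × diurnal temperature departure +
  noise, clipped to [0.05, 1] — anti-correlated with temperature within
  the day, as observed.
- Precipitation: wet-day occurrence is a logistic function of cloudiness
  (wet days cluster with dim days), amounts gamma-distributed and spread
  over a random 1–6 h window.
- Wind: log-normal day level (median e¹ ≈ 2.7 m s⁻¹) with hourly jitter.
- Interannual variability: year-level temperature (σ 0.8 °C) and
  brightness anomalies.

What it does **not** emulate: fronts and multi-day synoptic structure,
heat waves, drought spells, leap days (years are 365 days), or any trend.
Consequently, ensemble spreads on synthetic weather are narrower than on
a real decade of station data, and tests that pass here demonstrate the
*machinery and the signs of the responses*, not field-calibrated
magnitudes.

The day-block bootstrap copies, for each day of year independently, the
full 24-hour record of **all** variables from one uniformly drawn archive
year — preserving diurnal shapes and cross-variable couplings exactly
(asserted record-wise in the tests). Sampling is independent across days
and with replacement across years; DOY 366 would be drawn only from leap
years and is dropped otherwise. Replicate seeds derive from the master
seed by a counter scheme (master × 1000003 + index, mod 2³¹).

## Sensitivity machinery

- Relative change: 100·(VxJx − CTL)/|CTL|; exactly 0 at the control cell
  of every surface; undefined (NaN) for a zero control.
- Surfaces: multi-year means per (scale_V, scale_J, CO2) cell; control
  and scaled runs always share weather. An optional JSON cache keyed by
  the SHA-256 of (weather, parameters, cell) makes the full 21×21×4 grid
  resumable.
- Interpolation: tensor-product Akima ("makima") splines — local,
  overshoot-resistant, exact at nodes and on planar data; a global
  bicubic is available behind `scheme="cubic"` (nodes reproduced only to
  solver precision, ~1e−5).
- Gradients: central differences with h = 0.01; steepest paths
  X_{n+1} = X_n ± α∇f with α = 0.001 on response surfaces, recording the
  termination reason (gradient tolerance, hull exit, step cap). The
  descent form with a direction switch reconciles the minus-sign
  convention with ascending-path use.
- PRCC: every column rank-transformed; coefficient = Pearson correlation
  of the residuals of the focal driver's ranks and the response ranks
  after regressing both (with intercept) on all other drivers' ranks;
  p-values from the t transform with n − k − 2 degrees of freedom,
  reported raw (no multiplicity correction). The precision-matrix
  formulation is kept as an independent cross-check in the tests
  (agreement 1e−10). Phase windows come from each replicate's own
  simulated development, not fixed dates; per-phase precipitation enters
  as a total, the other drivers as means.

## Known limitations

- The two ensemble-level reproductions — J_max-dominance of the ascent
  path at 800 ppm and the negative ΔLAI–Δpod correlation at 400 ppm —
  are weak at the default configuration and pull in opposite directions
  through the canopy respiration profile (k_N): a uniform canopy
  overstates the respiration saved by shedding V_cmax (making
  V_cmax-descent as attractive as J_max-ascent), while a steep capacity
  profile removes the self-shading penalty that makes large leaf-area
  gains counterproductive. The default k_N = 0.05 satisfies both signs,
  narrowly. Magnitudes (the field analysis reports a ΔLAI–Δpod
  correlation near −0.4) are not reproduced on synthetic weather.
- Leaf temperature equals air temperature (no energy balance); no
  mesophyll conductance; no water or nitrogen stress (precipitation is
  carried through to the attribution stage but does not modulate growth);
  no cultivar calibration.
- The Penman–Monteith closure shares one aerodynamic conductance across
  layers; soil evaporation is not split out, so E is transpiration only.
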
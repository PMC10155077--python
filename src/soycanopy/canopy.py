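"""Sun/shade multilayer canopy radiative transfer and flux integration.

The canopy is discretized into ``n_layers`` horizontal layers of equal
leaf area.  Each layer is split into a sunlit fraction (Beer-law decay of
the direct beam through a spherical leaf-angle distribution) and a shaded
fraction receiving diffuse plus scattered light only.  The coupled leaf
model is solved per layer per leaf class and aggregated per unit ground
area; canopy transpiration comes from a Penman–Monteith combination
equation driven by the LAI-weighted canopy conductance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .leaf import LeafFlux, _flux_from_candidates, solve_coupled_vec
from .params import PhotosynthesisParams, arrhenius

__all__ = [
    "CanopyArchitecture",
    "LayerMicroclimate",
    "CanopyFlux",
    "solar_zenith",
    "diffuse_fraction",
    "light_partition",
    "canopy_assimilation",
    "penman_monteith_et",
    "canopy_wue",
]


@dataclass(frozen=True)
class CanopyArchitecture:
    """Canopy optical/geometric constants (spherical leaf-angle defaults)."""

    n_layers: int = 10
    k_diffuse: float = 0.7
    scatter: float = 0.2
    k_nitrogen: float = 0.05  # exponential decline of photosynthetic capacity with depth
    latitude: float = 40.04
    min_cos_zenith: float = 0.05
    albedo: float = 0.23
    ppfd_to_sw: float = 0.4376     # W m-2 per umol m-2 s-1 PPFD (total shortwave)
    canopy_height_m: float = 1.0
    ref_height_m: float = 3.0
    min_wind_m_s: float = 0.5

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.k_diffuse <= 0:
            raise ValueError("k_diffuse must be positive")


@dataclass(frozen=True)
class LayerMicroclimate:
    """Per-layer light environment (fluxes per unit leaf area)."""

    layer: int
    cum_lai_above: float
    q_sunlit: float
    q_shaded: float
    f_sunlit: float


@dataclass(frozen=True)
class CanopyFlux:
    """Ground-area canopy fluxes plus the per-layer leaf solutions."""

    an_ground: float          # umol CO2 m-2 ground s-1
    rd_ground: float          # umol CO2 m-2 ground s-1
    e_ground: float           # mmol H2O m-2 ground s-1
    wue: float                # umol/mmol; NaN marks undefined (E ~ 0)
    gs_ground: float          # mol m-2 ground s-1 canopy conductance
    layers: tuple = ()        # ((LeafFlux sunlit, LeafFlux shaded), ...)
    microclimate: tuple = ()  # (LayerMicroclimate, ...)


def solar_zenith(doy, hour, latitude: float):
    """Solar zenith angle (degrees) from day-of-year and local solar hour.

    Standard declination formula; minimum zenith at solar noon.
    """
    doy = np.asarray(doy, dtype=float)
    hour = np.asarray(hour, dtype=float)
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError("doy must be in [1, 366]")
    if np.any((hour < 0) | (hour >= 24)):
        raise ValueError("hour must be in [0, 24)")
    decl = np.radians(23.45) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    hour_angle = np.radians(15.0 * (hour - 12.0))
    lat = np.radians(latitude)
    cosz = (np.sin(lat) * np.sin(decl)
            + np.cos(lat) * np.cos(decl) * np.cos(hour_angle))
    z = np.degrees(np.arccos(np.clip(cosz, -1.0, 1.0)))
    return float(z) if z.ndim == 0 else z


def diffuse_fraction(q_above, cosz, max_clear_sky_ppfd: float = 2600.0):
    """Diffuse share of incident PPFD from an hourly clearness-index rule.

    Piecewise Spitters-type: overcast hours are all-diffuse, clear hours
    approach a 0.15 diffuse floor.
    """
    q_above = np.asarray(q_above, dtype=float)
    cosz = np.asarray(cosz, dtype=float)
    i0 = max_clear_sky_ppfd * np.maximum(cosz, 1e-6)
    kt = np.clip(q_above / i0, 0.0, 1.0)
    fd = np.where(kt < 0.22, 1.0,
                  np.where(kt < 0.35, 1.0 - 6.4 * (kt - 0.22) ** 2,
                           1.47 - 1.66 * kt))
    fd = np.clip(fd, 0.15, 1.0)
    return fd


def _light_profile(q_above, cosz, lai: float, arch: CanopyArchitecture):
    """Vectorized per-layer light environment.

    ``q_above``/``cosz`` may be arrays (e.g. 24 hours); returns arrays of
    shape (..., n_layers) for f_sunlit, q_sunlit, q_shaded plus the
    midpoint cumulative LAI per layer.
    """
    q_above = np.atleast_1d(np.asarray(q_above, dtype=float))
    cosz = np.atleast_1d(np.asarray(cosz, dtype=float))
    n = arch.n_layers
    dlai = lai / n if n else 0.0
    l_mid = (np.arange(n) + 0.5) * dlai  # cumulative LAI above layer midpoints

    day = cosz > 0.0
    fd = np.where(day, diffuse_fraction(q_above, cosz), 1.0)
    i_diff = q_above * fd
    i_beam = q_above - i_diff
    kb = 0.5 / np.maximum(cosz, arch.min_cos_zenith)
    kb = np.where(day, kb, 0.0)
    i_beam = np.where(day, i_beam, 0.0)

    kd = arch.k_diffuse
    kb_s = kb * math.sqrt(1.0 - arch.scatter)

    f_sun = np.exp(-kb[..., None] * l_mid)
    # diffuse per leaf area at depth L
    q_diff = kd * i_diff[..., None] * np.exp(-kd * l_mid)
    # scattered-beam contribution per leaf area
    q_scat = (kb[..., None] * i_beam[..., None] * arch.scatter / 2.0
              * np.exp(-kb_s[..., None] * l_mid))
    q_shaded = q_diff + q_scat
    # beam on sunlit leaves: projection capped at full-beam interception so
    # per-leaf flux never exceeds the above-canopy flux at low sun
    q_dir = np.minimum(kb, 1.0)[..., None] * i_beam[..., None]
    q_sunlit = q_shaded + q_dir
    q_sunlit = np.minimum(q_sunlit, q_above[..., None])
    q_shaded = np.minimum(q_shaded, q_sunlit)
    return f_sun, q_sunlit, q_shaded, l_mid


def light_partition(q_above: float, zenith: float,
                    arch: CanopyArchitecture, lai: float) -> list[LayerMicroclimate]:
    """Partition above-canopy PPFD into per-layer sunlit/shaded fluxes.

    At zenith >= 90 degrees the partition is all-diffuse (night or twilight);
    an empty canopy (lai = 0) returns a single notional fully sunlit layer.
    """
    if q_above < 0:
        raise ValueError("q_above must be non-negative")
    cosz = math.cos(math.radians(zenith))
    if lai == 0.0:
        q_leaf = min(1.0, 0.5 / max(cosz, arch.min_cos_zenith)) * q_above \
            if cosz > 0 else q_above
        return [LayerMicroclimate(0, 0.0, min(q_leaf, q_above), 0.0, 1.0)]
    f_sun, q_sun, q_sh, l_mid = _light_profile(q_above, cosz, lai, arch)
    return [
        LayerMicroclimate(i, float(l_mid[i]), float(q_sun[0, i]),
                          float(q_sh[0, i]), float(f_sun[0, i]) if cosz > 0 else 0.0)
        for i in range(arch.n_layers)
    ]


def penman_monteith_et(t_air: float, rh: float, wind: float,
                       gs_canopy: float, net_radiation: float,
                       arch: CanopyArchitecture | None = None) -> float:
    """Canopy evapotranspiration (mmol H2O m-2 s-1), Penman–Monteith.

    ``gs_canopy`` is the LAI-integrated stomatal conductance in
    mol m-2 ground s-1; ``net_radiation`` in W m-2.  Aerodynamic
    conductance follows a log-profile rule with fixed canopy-height
    roughness.  Non-negative by clamping (condensation ignored).
    """
    arch = arch or CanopyArchitecture()
    if gs_canopy < 0:
        raise ValueError("gs_canopy must be non-negative")
    t = t_air
    es = 0.6108 * math.exp(17.27 * t / (t + 237.3))        # kPa
    delta = 4098.0 * es / (t + 237.3) ** 2                  # kPa/K
    vpd = es * max(0.0, 1.0 - rh)                           # kPa
    gamma = 0.0665                                          # kPa/K
    rho_cp = 1.2 * 1013.0                                   # J m-3 K-1
    h = arch.canopy_height_m
    z = arch.ref_height_m
    d, z0m = 0.67 * h, 0.123 * h
    z0h = 0.1 * z0m
    u = max(wind, arch.min_wind_m_s)
    ga = 0.41 ** 2 * u / (math.log((z - d) / z0m) * math.log((z - d) / z0h))
    gc = gs_canopy * 0.0245                                 # mol m-2 s-1 -> m s-1
    if gc <= 1e-9:
        return 0.0
    lam_e = (delta * max(net_radiation, 0.0) + rho_cp * vpd * ga) \
        / (delta + gamma * (1.0 + ga / gc))                 # W m-2
    lam_e = max(lam_e, 0.0)
    e_mol = lam_e / 2.45e6 / 0.018                          # mol m-2 s-1
    return e_mol * 1000.0                                   # mmol


def canopy_wue(an_ground: float, e_ground: float) -> float:
    """Canopy water-use efficiency An/E (umol mmol-1); NaN when E <= 0."""
    if e_ground <= 0.0:
        return float("nan")
    return an_ground / e_ground


def canopy_fluxes_vec(q_above, t_air, rh, wind, doy, hour, lai: float,
                      co2: float, params: PhotosynthesisParams,
                      arch: CanopyArchitecture):
    """Hour-batched canopy solve (all inputs 1-D arrays over hours).

    Returns dict of per-hour arrays: an_ground, rd_ground, gs_ground,
    e_ground, wue, plus top-sunlit-layer diagnostics (ci, limiting code,
    q_sunlit) for limiting-rate audits.  Fluxes per unit ground area.
    """
    q_above = np.asarray(q_above, dtype=float)
    nh = q_above.shape[0]
    t_air = np.broadcast_to(np.asarray(t_air, dtype=float), (nh,))
    rh = np.broadcast_to(np.asarray(rh, dtype=float), (nh,))
    wind = np.broadcast_to(np.asarray(wind, dtype=float), (nh,))
    zen = solar_zenith(doy, hour, arch.latitude)
    cosz = np.cos(np.radians(np.atleast_1d(zen)))

    n = arch.n_layers
    rd_leaf = arrhenius(params.rd25_effective, params.ha_rd, t_air)
    l_mid_full = (np.arange(n) + 0.5) * (lai / n if n else 0.0)
    cap_layers = np.exp(-arch.k_nitrogen * l_mid_full)        # (n,)
    rd_int = float(np.sum(cap_layers)) * (lai / n if n else 0.0)
    out = {
        "an_ground": np.zeros(nh), "rd_ground": rd_int * rd_leaf * np.ones(nh),
        "gs_ground": np.full(nh, params.bb_intercept * lai),
        "e_ground": np.zeros(nh), "wue": np.full(nh, np.nan),
        "top_ci": np.full(nh, np.nan), "top_limiting": np.full(nh, -1, dtype=int),
        "top_q_sunlit": np.zeros(nh),
    }
    if lai <= 0.0:
        out["rd_ground"][:] = 0.0
        out["gs_ground"][:] = 0.0
        return out

    f_sun, q_sun, q_sh, _ = _light_profile(q_above, cosz, lai, arch)
    dlai = lai / n
    # stack (hour, layer, class) -> leaf solve over flattened array
    q_leaf = np.stack([q_sun, q_sh], axis=-1)            # (nh, n, 2)
    t_b = t_air[:, None, None]
    rh_b = rh[:, None, None]
    an, gs, ci, ac, aj, ap, rd, gstar = solve_coupled_vec(
        q_leaf, t_b, rh_b, co2, params,
        capacity_scale=cap_layers[None, :, None])
    w_sun = f_sun * dlai
    w_sh = (1.0 - f_sun) * dlai
    w = np.stack([w_sun, w_sh], axis=-1)                 # (nh, n, 2)
    out["an_ground"] = np.sum(an * w, axis=(1, 2))
    out["rd_ground"] = np.sum(rd * w, axis=(1, 2))
    out["gs_ground"] = np.sum(gs * w, axis=(1, 2))
    # limiting-rate code for the top sunlit leaf: 0=rubisco, 1=rubp, 2=tpu
    cand = np.stack([ac[:, 0, 0], aj[:, 0, 0], ap[:, 0, 0]])
    out["top_limiting"] = np.argmin(cand, axis=0)
    out["top_ci"] = ci[:, 0, 0]
    out["top_q_sunlit"] = q_sun[:, 0]

    rn = (1.0 - arch.albedo) * q_above * arch.ppfd_to_sw
    e = np.array([
        penman_monteith_et(float(t_air[i]), float(rh[i]), float(wind[i]),
                           float(out["gs_ground"][i]), float(rn[i]), arch)
        for i in range(nh)
    ])
    out["e_ground"] = e
    with np.errstate(divide="ignore", invalid="ignore"):
        out["wue"] = np.where(e > 0, out["an_ground"] / e, np.nan)
    return out


def canopy_assimilation(weather_hour, lai: float, co2: float,
                        params: PhotosynthesisParams,
                        arch: CanopyArchitecture,
                        keep_layers: bool = True) -> CanopyFlux:
    """Solve one hour of canopy gas exchange.

    ``weather_hour`` is a mapping with keys doy, hour, q_umol_m2_s, t_c,
    rh_frac, ws_m_s.  Solves the coupled leaf model once per layer per
    sunlit/shaded class, aggregates with per-layer LAI weights, and adds
    Penman–Monteith transpiration.
    """
    if lai < 0:
        raise ValueError("lai must be non-negative")
    w = weather_hour
    res = canopy_fluxes_vec(
        np.array([w["q_umol_m2_s"]]), np.array([w["t_c"]]),
        np.array([w["rh_frac"]]), np.array([w["ws_m_s"]]),
        np.array([w["doy"]]), np.array([w["hour"]]), lai, co2, params, arch)
    layers: tuple = ()
    micro: tuple = ()
    if keep_layers and lai > 0:
        zen = solar_zenith(w["doy"], w["hour"], arch.latitude)
        mlist = light_partition(w["q_umol_m2_s"], zen, arch, lai)
        pairs = []
        for m in mlist:
            cap = math.exp(-arch.k_nitrogen * m.cum_lai_above)
            fluxes = []
            for q_leaf in (m.q_sunlit, m.q_shaded):
                an, gs, ci, ac, aj, ap, rd, gstar = solve_coupled_vec(
                    q_leaf, w["t_c"], w["rh_frac"], co2, params,
                    capacity_scale=cap)
                fluxes.append(_flux_from_candidates(
                    float(ci), float(ac), float(aj), float(ap), float(rd),
                    float(gstar), gs=float(gs)))
            pairs.append(tuple(fluxes))
        layers = tuple(pairs)
        micro = tuple(mlist)
    return CanopyFlux(
        an_ground=float(res["an_ground"][0]),
        rd_ground=float(res["rd_ground"][0]),
        e_ground=float(res["e_ground"][0]),
        wue=float(res["wue"][0]),
        gs_ground=float(res["gs_ground"][0]),
        layers=layers,
        microclimate=micro,
    )
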
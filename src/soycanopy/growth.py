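"""Hourly seasonal soybean growth.

Photothermal development (linear thermal time above a base temperature),
logistic partitioning of net canopy carbon into leaf/stem/root/pod pools,
LAI from specific leaf area, and leaf senescence past a thermal-time
onset.  Soil water is non-limiting; precipitation is carried through the
I/O and the climate-attribution stages but does not modulate growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .canopy import CanopyArchitecture, CanopyFlux, canopy_fluxes_vec
from .params import PhotosynthesisParams, load_crop_config

__all__ = [
    "PartitionSchedule",
    "CropState",
    "SeasonResult",
    "thermal_time_step",
    "development_phase",
    "partition_fractions",
    "grow_step",
    "simulate_season",
]

# umol CO2 m-2 s-1 sustained for 1 h -> Mg CH2O-equivalent biomass ha-1
_UMOL_H_TO_MG_HA = 3600.0 * 1e-6 * 30.0 * 0.01

_POOLS = ("leaf", "stem", "root", "pod")


@dataclass(frozen=True)
class PartitionSchedule:
    """Logistic partition weights vs thermal time plus stage thresholds.

    ``coeffs[pool] = (amplitude, center, width)``; leaf/stem/root use
    falling logistics, pod a rising one hard-gated to zero before
    ``tt_repro``.  Weights are normalized to fractions summing to 1.
    """

    coeffs: dict
    t_base: float = 10.0
    tt_emerge: float = 60.0
    tt_repro: float = 750.0
    tt_senesce: float = 1000.0
    tt_mature: float = 1450.0
    end_doy: int = 280
    senescence_rate_per_cd: float = 0.003
    sla_lai_per_mg_ha: float = 2.5
    growth_efficiency: float = 0.7
    labile_cap_mg_ha: float = 0.3
    sowing_doy: int = 152
    init_leaf_mg_ha: float = 0.04
    init_stem_mg_ha: float = 0.02
    init_root_mg_ha: float = 0.02
    init_labile_mg_ha: float = 0.10

    def __post_init__(self) -> None:
        missing = [p for p in _POOLS if p not in self.coeffs]
        if missing:
            raise ValueError(f"partition schedule missing pools: {missing}")
        for p, (amp, _, width) in self.coeffs.items():
            if amp <= 0 or width <= 0:
                raise ValueError(f"partition coefficients for {p} must be positive")

    @classmethod
    def from_config(cls, cfg: dict | None = None) -> "PartitionSchedule":
        cfg = cfg or load_crop_config()
        g = cfg["growth"]
        coeffs = {p: (v["amplitude"], v["center"], v["width"])
                  for p, v in cfg["partition"].items()}
        return cls(
            coeffs=coeffs,
            t_base=g["t_base"], tt_emerge=g["tt_emerge"],
            tt_repro=g["tt_repro"], tt_senesce=g["tt_senesce"],
            tt_mature=g["tt_mature"], end_doy=g["end_doy"],
            senescence_rate_per_cd=g["senescence_rate_per_cd"],
            sla_lai_per_mg_ha=g["sla_lai_per_mg_ha"],
            growth_efficiency=g["growth_efficiency"],
            labile_cap_mg_ha=g["labile_cap_mg_ha"],
            sowing_doy=g["sowing_doy"],
            init_leaf_mg_ha=g["init_leaf_mg_ha"],
            init_stem_mg_ha=g["init_stem_mg_ha"],
            init_root_mg_ha=g["init_root_mg_ha"],
            init_labile_mg_ha=g["init_labile_mg_ha"],
        )


@dataclass(frozen=True)
class CropState:
    """Biomass pools (Mg ha-1), thermal time (C d), and derived LAI."""

    biomass_leaf: float
    biomass_stem: float
    biomass_root: float
    biomass_pod: float
    labile: float
    senesced_leaf: float
    thermal_time: float
    sla: float

    @property
    def lai(self) -> float:
        return self.sla * self.biomass_leaf

    @property
    def shoot(self) -> float:
        """Shoot biomass: pod + leaf (green + senesced) + stem."""
        return (self.biomass_pod + self.biomass_leaf
                + self.senesced_leaf + self.biomass_stem)

    @classmethod
    def initial(cls, schedule: PartitionSchedule) -> "CropState":
        return cls(
            biomass_leaf=schedule.init_leaf_mg_ha,
            biomass_stem=schedule.init_stem_mg_ha,
            biomass_root=schedule.init_root_mg_ha,
            biomass_pod=0.0, labile=schedule.init_labile_mg_ha,
            senesced_leaf=0.0, thermal_time=0.0,
            sla=schedule.sla_lai_per_mg_ha,
        )


@dataclass
class SeasonResult:
    """Daily series and season summaries for one simulated season."""

    daily: pd.DataFrame                 # doy, an_mean, an_max, wue_mean, lai, pools
    summary: dict                       # pod, shoot, max_lai, mean_daily_max_an, ...
    phase_windows: dict                 # {"vegetative": (doy0, doy1), "reproductive": ...}
    traces: pd.DataFrame | None = None  # hourly top-sunlit diagnostics if retained


def thermal_time_step(t_air: float, dt: float, t_base: float) -> float:
    """Thermal-time increment (C d): max(0, t_air − t_base) · dt/24."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return max(0.0, t_air - t_base) * dt / 24.0


def development_phase(thermal_time: float, schedule: PartitionSchedule) -> str:
    """"vegetative" below the reproductive threshold, "reproductive" at/above."""
    if thermal_time < 0:
        raise ValueError("thermal_time must be non-negative")
    return "reproductive" if thermal_time >= schedule.tt_repro else "vegetative"


def partition_fractions(thermal_time: float,
                        schedule: PartitionSchedule) -> dict[str, float]:
    """Normalized carbon partition fractions at a development stage.

    Fractions are non-negative, sum to 1, and the pod fraction is exactly
    zero before the reproductive threshold.
    """
    weights = {}
    for pool, (amp, center, width) in schedule.coeffs.items():
        arg = (thermal_time - center) / width
        if pool == "pod":
            if thermal_time < schedule.tt_repro:
                weights[pool] = 0.0
            else:
                weights[pool] = amp / (1.0 + math.exp(-arg))
        else:
            weights[pool] = amp / (1.0 + math.exp(arg))
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("partition weights sum to zero; schedule unnormalizable")
    return {p: w / total for p, w in weights.items()}


def grow_step(state: CropState, canopy_flux: CanopyFlux, dt: float,
              t_air: float, schedule: PartitionSchedule) -> CropState:
    """Advance the crop state by one step of length ``dt`` hours.

    Positive net canopy carbon is discounted by the growth-respiration
    efficiency, refills the labile pool to capacity, and the remainder is
    allocated by the partition fractions at the step-start stage.
    Negative net carbon is drawn gross from the labile pool, then from
    green leaf.  Senescence removes green leaf past the onset stage at a
    rate proportional to the thermal-time increment.  Mass never goes
    negative; carbon is conserved exactly.
    """
    tt = state.thermal_time
    net_c = canopy_flux.an_ground * dt * _UMOL_H_TO_MG_HA  # Mg/ha this step
    leaf, stem, root, pod = (state.biomass_leaf, state.biomass_stem,
                             state.biomass_root, state.biomass_pod)
    labile = state.labile
    if net_c >= 0.0:
        avail = net_c * schedule.growth_efficiency
        refill = min(avail, max(0.0, schedule.labile_cap_mg_ha - labile))
        labile += refill
        avail -= refill
        frac = partition_fractions(tt, schedule)
        leaf += avail * frac["leaf"]
        stem += avail * frac["stem"]
        root += avail * frac["root"]
        pod += avail * frac["pod"]
    else:
        deficit = -net_c
        from_labile = min(labile, deficit)
        labile -= from_labile
        deficit -= from_labile
        from_leaf = min(leaf, deficit)
        leaf -= from_leaf

    tt_inc = thermal_time_step(t_air, dt, schedule.t_base)
    senesced = state.senesced_leaf
    if tt > schedule.tt_senesce:
        loss = min(leaf, schedule.senescence_rate_per_cd * tt_inc * leaf)
        leaf -= loss
        senesced += loss
    return replace(state, biomass_leaf=leaf, biomass_stem=stem,
                   biomass_root=root, biomass_pod=pod, labile=labile,
                   senesced_leaf=senesced, thermal_time=tt + tt_inc)


def _require_complete_days(df: pd.DataFrame, doys) -> None:
    gaps = []
    counts = df.groupby("doy")["hour"].nunique()
    for d in doys:
        if counts.get(d, 0) != 24:
            gaps.append(int(d))
    if gaps:
        raise ValueError(f"weather year missing hours for doy(s): {gaps[:10]}")


def simulate_season(weather_year: pd.DataFrame, co2: float,
                    params: PhotosynthesisParams,
                    arch: CanopyArchitecture,
                    schedule: PartitionSchedule,
                    scale_v: float = 1.0, scale_j: float = 1.0,
                    retain_traces: bool = False) -> SeasonResult:
    """Simulate one sowing-to-maturity season on an hourly weather year.

    The Vcmax/Jmax scaling factors are applied to the 25-degree parameters
    (with Rd and TPU tracking the Vcmax factor).  Canopy microclimate uses
    the LAI at the start of each day; growth integrates hourly.
    Deterministic for fixed inputs.
    """
    p = params.scaled(scale_v, scale_j)
    wy = weather_year.sort_values(["doy", "hour"]).reset_index(drop=True)
    season_doys = [d for d in sorted(wy["doy"].unique())
                   if d >= schedule.sowing_doy]
    if not season_doys:
        raise ValueError("weather year has no days at/after sowing")
    _require_complete_days(wy[wy["doy"].isin(season_doys)], season_doys)

    state = CropState.initial(schedule)
    rows, trace_rows = [], []
    phase_start: dict = {"vegetative": season_doys[0], "reproductive": None}
    last_doy = season_doys[0]
    by_doy = {d: g for d, g in wy[wy["doy"].isin(season_doys)].groupby("doy")}

    for doy in season_doys:
        day = by_doy[doy]
        q = day["q_umol_m2_s"].to_numpy()
        t = day["t_c"].to_numpy()
        rh = day["rh_frac"].to_numpy()
        ws = day["ws_m_s"].to_numpy()
        hours = day["hour"].to_numpy()
        lai_day = state.lai if state.thermal_time >= schedule.tt_emerge else 0.0
        res = canopy_fluxes_vec(q, t, rh, ws, float(doy), hours,
                                lai_day, co2, p, arch)
        for i in range(24):
            flux = CanopyFlux(an_ground=float(res["an_ground"][i]),
                              rd_ground=float(res["rd_ground"][i]),
                              e_ground=float(res["e_ground"][i]),
                              wue=float(res["wue"][i]),
                              gs_ground=float(res["gs_ground"][i]))
            pre_tt = state.thermal_time
            state = grow_step(state, flux, 1.0, float(t[i]), schedule)
            if (phase_start["reproductive"] is None
                    and development_phase(state.thermal_time, schedule) == "reproductive"):
                phase_start["reproductive"] = int(doy)
            if retain_traces and q[i] > 0 and lai_day > 0:
                trace_rows.append({
                    "doy": int(doy), "hour": int(hours[i]),
                    "ci": float(res["top_ci"][i]),
                    "limiting": int(res["top_limiting"][i]),
                    "q_sunlit": float(res["top_q_sunlit"][i]),
                })
        daylight = q > 0
        wue_day = res["wue"][daylight & np.isfinite(res["wue"])]
        rows.append({
            "doy": int(doy),
            "an_mean": float(np.mean(res["an_ground"])),
            "an_max": float(np.max(res["an_ground"])),
            "wue_mean": float(np.mean(wue_day)) if wue_day.size else float("nan"),
            "lai": state.lai,
            "leaf": state.biomass_leaf, "stem": state.biomass_stem,
            "root": state.biomass_root, "pod": state.biomass_pod,
            "thermal_time": state.thermal_time,
        })
        last_doy = int(doy)
        if state.thermal_time >= schedule.tt_mature or doy >= schedule.end_doy:
            break

    daily = pd.DataFrame(rows)
    repro0 = phase_start["reproductive"]
    phase_windows = {
        "vegetative": (int(season_doys[0]),
                       int(repro0 - 1 if repro0 else last_doy)),
        "reproductive": (int(repro0), last_doy) if repro0 else None,
    }
    wue_series = daily["wue_mean"].dropna()
    summary = {
        "pod": state.biomass_pod,
        "shoot": state.shoot,
        "max_lai": float(daily["lai"].max()),
        "mean_daily_max_an": float(daily["an_max"].mean()),
        "mean_daily_mean_an": float(daily["an_mean"].mean()),
        "mean_wue": float(wue_series.mean()) if len(wue_series) else float("nan"),
        "maturity_doy": last_doy,
    }
    traces = pd.DataFrame(trace_rows) if retain_traces else None
    return SeasonResult(daily=daily, summary=summary,
                        phase_windows=phase_windows, traces=traces)
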
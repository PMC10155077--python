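"""Steady-state C3 leaf gas exchange.

Farquhar–von Caemmerer–Berry (FvCB) assimilation with the three limiting
rates (Rubisco carboxylation Ac, RuBP regeneration Aj, triose-phosphate
utilization Ap), explicit photorespiration accounting, and Ball–Berry
stomatal conductance coupled to the CO2 supply function.

Net assimilation is An = min(Ac, Aj, Ap) − Rd.  Gross carboxylation Vc and
photorespiratory release Rp follow the oxygenation identity
Rp = Vc·Γ*/Ci, so that Vc − Rp − Rd = An wherever Ci > Γ*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .params import PhotosynthesisParams, arrhenius

__all__ = [
    "LeafEnvironment",
    "LeafFlux",
    "AdjustedRates",
    "TransitionResult",
    "temperature_adjust",
    "electron_transport",
    "rubisco_limited",
    "rubp_limited",
    "tpu_limited",
    "assimilation_at_ci",
    "solve_coupled",
    "find_transition_ci",
    "aci_curve",
    "percent_gain_an",
    "photoresp_gain_ratio",
]

_LIMITING_ORDER = ("rubisco", "rubp", "tpu")


@dataclass(frozen=True)
class LeafEnvironment:
    """Driving environment at the leaf: PPFD, temperature, humidity, CO2."""

    q: float          # umol m-2 s-1 incident PPFD
    t_leaf: float     # degrees C
    rh: float         # fraction 0-1
    ca: float         # umol mol-1 ambient CO2 at the leaf surface

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("q must be non-negative")
        if not 0.0 <= self.rh <= 1.0:
            raise ValueError("rh must be in [0, 1]")
        if self.ca <= 0:
            raise ValueError("ca must be positive")


@dataclass(frozen=True)
class LeafFlux:
    """Per-leaf-area fluxes from one solved leaf state (umol m-2 s-1)."""

    an: float
    ac: float
    aj: float
    ap: float
    rd: float
    vc: float         # gross carboxylation
    rp: float         # photorespiratory CO2 release
    gs: float         # mol m-2 s-1 stomatal conductance (water)
    ci: float         # umol mol-1 intercellular CO2
    limiting: str     # one of {"rubisco", "rubp", "tpu"}


@dataclass(frozen=True)
class AdjustedRates:
    """Temperature-adjusted rate set at a given leaf temperature."""

    vcmax: float
    jmax: float
    rd: float
    tpu: float
    kc: float
    ko: float
    gamma_star: float


@dataclass(frozen=True)
class TransitionResult:
    """Outcome of the Ac = Aj crossing search.

    ``status`` is "crossing" when a transition Ci exists in the search
    window, else "always_rubisco" or "always_rubp" (no crossing; the named
    rate is the argmin throughout).
    """

    ci_star: float | None
    status: str


def temperature_adjust(params: PhotosynthesisParams, t_leaf: float) -> AdjustedRates:
    """Arrhenius-adjust all rates and kinetic constants to ``t_leaf`` (C).

    At 25 C the 25-degree values are returned unchanged. Temperatures
    outside [-10, 50] C are rejected.
    """
    if not -10.0 <= t_leaf <= 50.0:
        raise ValueError(f"t_leaf {t_leaf} C outside supported range [-10, 50]")
    return AdjustedRates(
        vcmax=arrhenius(params.vcmax25, params.ha_vcmax, t_leaf),
        jmax=arrhenius(params.jmax25, params.ha_jmax, t_leaf),
        rd=arrhenius(params.rd25_effective, params.ha_rd, t_leaf),
        tpu=arrhenius(params.tpu25, params.ha_tpu, t_leaf),
        kc=arrhenius(params.kc25, params.ha_kc, t_leaf),
        ko=arrhenius(params.ko25, params.ha_ko, t_leaf),
        gamma_star=arrhenius(params.gamma_star25, params.ha_gamma_star, t_leaf),
    )


def electron_transport(q, jmax, theta: float, absorb_effective: float):
    """Potential electron transport J from the non-rectangular hyperbola.

    J is the smaller root of  theta·J² − (I2 + jmax)·J + I2·jmax = 0  with
    I2 = q · absorb_effective.  Accepts scalar or array ``q``/``jmax``.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must be in (0, 1)")
    q = np.asarray(q, dtype=float)
    i2 = q * absorb_effective
    b = i2 + jmax
    disc = b * b - 4.0 * theta * i2 * jmax
    j = (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * theta)
    if j.ndim == 0:
        return float(j)
    return j


def rubisco_limited(ci, vcmax, kc, ko, o2, gamma_star):
    """Rubisco-limited gross rate Ac = vcmax·(ci − Γ*)/(ci + kc·(1 + O/ko))."""
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= 0):
        raise ValueError("ci must be positive")
    km = kc * (1.0 + o2 / ko)
    ac = vcmax * (ci - gamma_star) / (ci + km)
    return float(ac) if ac.ndim == 0 else ac


def rubp_limited(ci, j, gamma_star):
    """RuBP-regeneration-limited rate Aj = J·(ci − Γ*)/(4·ci + 8·Γ*)."""
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= 0):
        raise ValueError("ci must be positive")
    aj = np.asarray(j, dtype=float) * (ci - gamma_star) / (4.0 * ci + 8.0 * gamma_star)
    return float(aj) if aj.ndim == 0 else aj


def tpu_limited(tpu):
    """TPU-limited rate Ap = 3·tpu (independent of ci and light)."""
    if np.any(np.asarray(tpu) <= 0):
        raise ValueError("tpu must be positive")
    out = 3.0 * np.asarray(tpu, dtype=float)
    return float(out) if out.ndim == 0 else out


def _candidates(ci, env_q, rates: AdjustedRates, params: PhotosynthesisParams):
    j = electron_transport(env_q, rates.jmax, params.theta, params.absorb_effective)
    ac = rubisco_limited(ci, rates.vcmax, rates.kc, rates.ko, params.o2, rates.gamma_star)
    aj = rubp_limited(ci, j, rates.gamma_star)
    ap = tpu_limited(rates.tpu)
    return ac, aj, ap


def _flux_from_candidates(ci: float, ac: float, aj: float, ap: float,
                          rd: float, gamma_star: float,
                          gs: float = float("nan")) -> LeafFlux:
    gross = min(ac, aj, ap)
    # tie-break: first of rubisco < rubp < tpu attaining the min
    for name, val in zip(_LIMITING_ORDER, (ac, aj, ap)):
        if val == gross:
            limiting = name
            break
    an = gross - rd
    if ci > gamma_star:
        vc = (an + rd) / (1.0 - gamma_star / ci)
        rp = vc * gamma_star / ci
    else:
        rp = 0.0
        vc = max(an + rd, 0.0)
    return LeafFlux(an=an, ac=ac, aj=aj, ap=ap, rd=rd, vc=vc, rp=rp,
                    gs=gs, ci=ci, limiting=limiting)


def assimilation_at_ci(ci: float, env: LeafEnvironment,
                       params: PhotosynthesisParams) -> LeafFlux:
    """Demand-side leaf flux at a prescribed intercellular CO2.

    An = min(Ac, Aj, Ap) − Rd with the limiting label set to the argmin
    (ties broken rubisco < rubp < tpu). Photorespiration follows
    Rp = Vc·Γ*/ci, so Vc − Rp − Rd = An whenever ci > Γ*.
    """
    if ci <= 0:
        raise ValueError("ci must be positive")
    rates = temperature_adjust(params, env.t_leaf)
    ac, aj, ap = _candidates(ci, env.q, rates, params)
    return _flux_from_candidates(ci, ac, aj, ap, rates.rd, rates.gamma_star)


def _gs_ball_berry(an, rh, cs, bb_slope, bb_intercept):
    """Ball-Berry conductance, clamped below at the intercept."""
    gs = bb_slope * np.asarray(an, dtype=float) * rh / cs + bb_intercept
    return np.maximum(gs, bb_intercept)


def solve_coupled_vec(q, t_leaf, rh, ca, params: PhotosynthesisParams,
                      tol: float = 1e-7, max_iter: int = 200,
                      capacity_scale=1.0):
    """Vectorized coupled FvCB / Ball-Berry solve.

    Damped fixed-point iteration on ci (start 0.7·ca, damping 0.5) with a
    bisection fallback for any element that fails to converge.
    ``capacity_scale`` multiplies vcmax/jmax/rd/tpu element-wise (used for
    within-canopy photosynthetic-capacity profiles).  Returns arrays
    (an, gs, ci, ac, aj, ap, rd, gamma_star) broadcast to the common
    shape.  Deterministic.
    """
    q, t_leaf, rh, ca, cap = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (q, t_leaf, rh, ca, capacity_scale)))
    shape = q.shape
    vcmax = arrhenius(params.vcmax25, params.ha_vcmax, t_leaf) * cap
    jmax = arrhenius(params.jmax25, params.ha_jmax, t_leaf) * cap
    rd = arrhenius(params.rd25_effective, params.ha_rd, t_leaf) * cap
    tpu = arrhenius(params.tpu25, params.ha_tpu, t_leaf) * cap
    kc = arrhenius(params.kc25, params.ha_kc, t_leaf)
    ko = arrhenius(params.ko25, params.ha_ko, t_leaf)
    gamma_star = arrhenius(params.gamma_star25, params.ha_gamma_star, t_leaf)
    km = kc * (1.0 + params.o2 / ko)
    j = electron_transport(q, jmax, params.theta, params.absorb_effective)
    ap = 3.0 * np.asarray(tpu, dtype=float)

    def an_of_ci(ci):
        ac = vcmax * (ci - gamma_star) / (ci + km)
        aj = np.asarray(j) * (ci - gamma_star) / (4.0 * ci + 8.0 * gamma_star)
        return np.minimum(np.minimum(ac, aj), ap) - rd, ac, aj

    def ci_supply(ci):
        an, _, _ = an_of_ci(ci)
        gs = _gs_ball_berry(an, rh, ca, params.bb_slope, params.bb_intercept)
        return ca - 1.6 * an / gs, an, gs

    ci = 0.7 * ca
    converged = np.zeros(shape, dtype=bool)
    for _ in range(max_iter):
        ci_new, _, _ = ci_supply(np.maximum(ci, 1e-3))
        step = ci_new - ci
        converged = np.abs(step) <= tol * ca
        if converged.all():
            ci = np.maximum(ci + step, 1e-3)
            break
        ci = np.maximum(ci + 0.5 * step, 1e-3)
    if not converged.all():
        # bisection on the residual r(ci) = ci - supply(ci) for the holdouts
        lo = np.full(shape, 1e-3)
        hi = ca + 1.6 * rd / params.bb_intercept + 10.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            r, _, _ = ci_supply(mid)
            resid = mid - r
            take_hi = resid > 0
            hi = np.where(take_hi & ~converged, mid, hi)
            lo = np.where(~take_hi & ~converged, mid, lo)
        ci = np.where(converged, ci, 0.5 * (lo + hi))
    ci_chk, an, gs = ci_supply(ci)
    if np.any(np.abs(ci_chk - ci) > 100 * tol * ca):
        bad = np.argwhere(np.abs(ci_chk - ci) > 100 * tol * ca)[0]
        raise RuntimeError(
            f"coupled leaf solve failed to converge at index {tuple(bad)} "
            f"(q={q[tuple(bad)]}, t={t_leaf[tuple(bad)]}, rh={rh[tuple(bad)]}, "
            f"ca={ca[tuple(bad)]})")
    _, ac, aj = an_of_ci(ci)
    return an, gs, ci, ac, aj, np.broadcast_to(ap, shape), \
        np.broadcast_to(rd, shape), np.broadcast_to(gamma_star, shape)


def solve_coupled(env: LeafEnvironment, params: PhotosynthesisParams,
                  tol: float = 1e-7) -> LeafFlux:
    """Solve the coupled demand (FvCB) / supply (Ball-Berry) leaf state.

    The returned (an, gs, ci) satisfy both balance equations to relative
    tolerance ``tol``; a Ball-Berry conductance below the intercept is
    clamped to the intercept (dark/negative-An closure).
    """
    an, gs, ci, ac, aj, ap, rd, gamma_star = solve_coupled_vec(
        env.q, env.t_leaf, env.rh, env.ca, params, tol=tol)
    return _flux_from_candidates(float(ci), float(ac), float(aj), float(ap),
                                 float(rd), float(gamma_star), gs=float(gs))


def find_transition_ci(q: float, t_leaf: float, params: PhotosynthesisParams,
                       ci_max: float = 2000.0) -> TransitionResult:
    """Intercellular CO2 at which Ac(ci) = Aj(ci).

    Searches (Γ*, ci_max]. Both curves vanish at Γ*, so the crossing is
    located on the nonzero branch via the rate *per unit (ci − Γ*)*:
    vcmax/(ci+Km) vs (J/4)/(ci+2Γ*). Returns a no-crossing status rather
    than raising when one rate dominates throughout.
    """
    rates = temperature_adjust(params, t_leaf)
    j = electron_transport(q, rates.jmax, params.theta, params.absorb_effective)
    km = rates.kc * (1.0 + params.o2 / rates.ko)
    gstar = rates.gamma_star

    def diff(ci):
        return rates.vcmax / (ci + km) - (j / 4.0) / (ci + 2.0 * gstar)

    lo, hi = gstar + 1e-6, ci_max
    dlo, dhi = diff(lo), diff(hi)
    if dlo == 0.0:
        return TransitionResult(lo, "crossing")
    if dlo * dhi > 0:
        # slope comparison near gamma_star decides who is the argmin
        status = "always_rubp" if dlo > 0 else "always_rubisco"
        return TransitionResult(None, status)
    ci_star = brentq(diff, lo, hi, xtol=1e-9, rtol=1e-12)
    return TransitionResult(float(ci_star), "crossing")


def aci_curve(q: float, t_leaf: float, params: PhotosynthesisParams,
              ci_grid: Sequence[float]) -> list[LeafFlux]:
    """A–Ci response: one demand-side LeafFlux per point of ``ci_grid``."""
    grid = list(ci_grid)
    if not grid:
        raise ValueError("ci_grid must be non-empty")
    if any(c <= 0 for c in grid):
        raise ValueError("ci_grid values must be positive")
    if sorted(grid) != grid:
        raise ValueError("ci_grid must be sorted ascending")
    env = LeafEnvironment(q=q, t_leaf=t_leaf, rh=0.7, ca=max(grid))
    return [assimilation_at_ci(ci, env, params) for ci in grid]


def percent_gain_an(q: float, t_leaf: float, params: PhotosynthesisParams,
                    ci_lo: float, ci_hi: float,
                    scale_v: float, scale_j: float, n: int = 201) -> float:
    """Mean percent change of leaf An over a dense ci grid in [ci_lo, ci_hi].

    The scaled scenario applies ``scale_v``/``scale_j`` (with Rd and TPU
    tracking the vcmax factor).  Zero when both scales are 1.
    """
    if ci_lo >= ci_hi:
        raise ValueError("ci_lo must be below ci_hi")
    grid = np.linspace(ci_lo, ci_hi, n)
    scaled = params.scaled(scale_v, scale_j)
    env = LeafEnvironment(q=q, t_leaf=t_leaf, rh=0.7, ca=ci_hi)
    an_ctl = np.array([assimilation_at_ci(ci, env, params).an for ci in grid])
    an_scl = np.array([assimilation_at_ci(ci, env, scaled).an for ci in grid])
    if np.any(an_ctl <= 0):
        raise ValueError("control An non-positive on the grid; percent change undefined")
    return float(np.mean(100.0 * (an_scl - an_ctl) / an_ctl))


def photoresp_gain_ratio(ci: float, q: float, t_leaf: float,
                         params: PhotosynthesisParams,
                         scale_v: float, scale_j: float) -> float:
    """ΔRp as a percentage of ΔVc under a (scale_v, scale_j) scaling.

    Because Rp = Vc·Γ*/ci at fixed ci, the ratio collapses to 100·Γ*/ci
    whenever the limitation regime is unchanged between the two scenarios.
    """
    rates = temperature_adjust(params, t_leaf)
    if ci <= rates.gamma_star:
        raise ValueError("ci must exceed gamma_star")
    env = LeafEnvironment(q=q, t_leaf=t_leaf, rh=0.7, ca=ci)
    ctl = assimilation_at_ci(ci, env, params)
    scl = assimilation_at_ci(ci, env, params.scaled(scale_v, scale_j))
    dvc = scl.vc - ctl.vc
    if dvc == 0.0:
        raise ValueError("carboxylation unchanged; ratio undefined")
    return float(100.0 * (scl.rp - ctl.rp) / dvc)
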
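"""Sensitivity machinery over the canopy/growth simulator.

Scaling grids of Vcmax/Jmax across CO2 levels with relative-change
surfaces, Akima-type surface interpolation with central-difference
gradients and steepest-gradient paths, limiting-rate frequency audits,
the paired bootstrap climate ensemble, and partial rank correlation
(PRCC) attribution of yield gains to per-phase climate drivers.  PRCC is
implemented here directly (rank transform + residual correlation).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import Akima1DInterpolator, RegularGridInterpolator

from .canopy import CanopyArchitecture
from .growth import PartitionSchedule, simulate_season
from .params import PhotosynthesisParams
from .weather import WeatherArchive, bootstrap_year, phase_driver_means

__all__ = [
    "ScalingGrid",
    "SensitivitySurface",
    "GradientPath",
    "PRCCResult",
    "BootstrapEnsemble",
    "relative_change",
    "run_grid",
    "interpolate_surface",
    "gradient",
    "steepest_path",
    "limiting_frequency",
    "run_bootstrap_ensemble",
    "prcc",
]

SEASON_VARIABLES = ("pod", "shoot", "max_lai", "mean_daily_max_an",
                    "mean_daily_mean_an", "mean_wue")

_LIMITING_NAMES = ("rubisco", "rubp", "tpu")


@dataclass(frozen=True)
class ScalingGrid:
    """Vcmax/Jmax scaling grid plus CO2 levels; the control is (1, 1)."""

    scales: tuple = tuple(np.round(np.arange(0.5, 1.5001, 0.05), 4))
    co2_levels: tuple = (400.0, 600.0, 800.0, 1000.0)

    def __post_init__(self) -> None:
        s = list(self.scales)
        if s != sorted(s) or len(set(s)) != len(s):
            raise ValueError("scales must be strictly increasing")
        if not any(abs(x - 1.0) < 1e-12 for x in s):
            raise ValueError("control scale 1.0 must be in the grid")


@dataclass
class SensitivitySurface:
    """Multi-year mean of one season variable over (scale_v, scale_j)."""

    variable: str
    co2: float
    scales_v: np.ndarray
    scales_j: np.ndarray
    values: np.ndarray      # shape (len(scales_v), len(scales_j))
    relchange: np.ndarray   # percent, exactly 0 at the control cell


@dataclass
class GradientPath:
    """Steepest-gradient path on an interpolated response surface."""

    points: np.ndarray      # (n, 2) in (scale_v, scale_j) coordinates
    alpha: float
    h: float
    direction: str          # "ascend" or "descend"
    termination: str        # "gradient_tol" | "hull_exit" | "max_steps"


@dataclass
class PRCCResult:
    """Partial rank correlation coefficients per driver column."""

    table: pd.DataFrame     # index driver, columns coefficient, p_value, n


@dataclass
class BootstrapEnsemble:
    """Paired CTL / scaled seasons on shared bootstrap weather years."""

    replicates: pd.DataFrame   # seed, dpod_pct, dlai_pct, pod_ctl, ... driver cols
    co2: float
    scales: tuple
    master_seed: int
    corr_dlai_dpod: float
    corr_p_value: float
    set25: np.ndarray          # replicate indices in the lower Δpod quartile
    set75: np.ndarray


def relative_change(value: float, control: float) -> float:
    """Percent change 100·(value − control)/|control|; NaN at control = 0."""
    if control == 0:
        return float("nan")
    return 100.0 * (value - control) / abs(control)


def _season_summary(weather_year, co2, params, arch, schedule, sv, sj,
                    retain_traces=False):
    res = simulate_season(weather_year, co2, params, arch, schedule,
                          scale_v=sv, scale_j=sj, retain_traces=retain_traces)
    return res


def _cache_key(archive: WeatherArchive, params, co2, sv, sj) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(archive.frame, index=False).values.tobytes())
    h.update(json.dumps([repr(params), co2, sv, sj], sort_keys=True).encode())
    return h.hexdigest()


def run_grid(archive: WeatherArchive, grid: ScalingGrid,
             params: PhotosynthesisParams, arch: CanopyArchitecture,
             schedule: PartitionSchedule,
             cache_dir: str | Path | None = None) -> dict:
    """Run the full (scale_v × scale_j × co2 × year) experiment.

    Returns ``{variable: {co2: SensitivitySurface}}`` of multi-year means;
    control and scaled runs share weather by construction (same archive
    years).  An optional on-disk JSON cache keyed by the input hash makes
    large grids resumable.
    """
    cache_path = Path(cache_dir) if cache_dir else None
    if cache_path:
        cache_path.mkdir(parents=True, exist_ok=True)
    sv_axis = np.asarray(grid.scales)
    sj_axis = np.asarray(grid.scales)
    years = archive.years
    out: dict = {v: {} for v in SEASON_VARIABLES}
    for co2 in grid.co2_levels:
        means = {v: np.zeros((len(sv_axis), len(sj_axis))) for v in SEASON_VARIABLES}
        for i, sv in enumerate(sv_axis):
            for jj, sj in enumerate(sj_axis):
                key = _cache_key(archive, params, co2, float(sv), float(sj))
                cfile = cache_path / f"{key}.json" if cache_path else None
                if cfile is not None and cfile.exists():
                    sums = json.loads(cfile.read_text())
                else:
                    sums = {v: 0.0 for v in SEASON_VARIABLES}
                    for y in years:
                        try:
                            res = _season_summary(archive.year_frame(y), co2,
                                                  params, arch, schedule,
                                                  float(sv), float(sj))
                        except Exception as exc:
                            raise RuntimeError(
                                f"season failed at cell (scale_v={sv}, "
                                f"scale_j={sj}, co2={co2}, year={y})") from exc
                        for v in SEASON_VARIABLES:
                            sums[v] += res.summary[v] / len(years)
                    if cfile is not None:
                        cfile.write_text(json.dumps(sums))
                for v in SEASON_VARIABLES:
                    means[v][i, jj] = sums[v]
        ic = int(np.argmin(np.abs(sv_axis - 1.0)))
        jc = int(np.argmin(np.abs(sj_axis - 1.0)))
        for v in SEASON_VARIABLES:
            ctl = means[v][ic, jc]
            rel = np.array([[relative_change(means[v][a, b], ctl)
                             for b in range(len(sj_axis))]
                            for a in range(len(sv_axis))])
            if ctl != 0:
                rel[ic, jc] = 0.0
            out[v][co2] = SensitivitySurface(
                variable=v, co2=co2, scales_v=sv_axis.copy(),
                scales_j=sj_axis.copy(), values=means[v], relchange=rel)
    return out


class _TensorAkima:
    """Tensor-product Akima spline on a rectilinear grid.

    Evaluation interpolates each grid row with an Akima 1-D spline along
    x, then the resulting column along y — local, overshoot-resistant,
    exact at the nodes and for planar data, with continuous first
    derivatives in the interior.
    """

    def __init__(self, x, y, z):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.z = np.asarray(z, dtype=float)
        self._rows = [Akima1DInterpolator(self.x, self.z[:, j], method="makima")
                      for j in range(len(self.y))]

    def __call__(self, xq, yq):
        xq_a, yq_a = np.asarray(xq, dtype=float), np.asarray(yq, dtype=float)
        if np.any(xq_a < self.x[0]) or np.any(xq_a > self.x[-1]) \
                or np.any(yq_a < self.y[0]) or np.any(yq_a > self.y[-1]):
            raise ValueError("evaluation point outside the surface hull")
        col = np.array([r(xq_a) for r in self._rows])   # (ny, ...)
        out = Akima1DInterpolator(self.y, col, axis=0, method="makima")(yq_a)
        return float(out) if np.ndim(out) == 0 else out


def interpolate_surface(surface: SensitivitySurface | tuple,
                        field_name: str = "relchange",
                        scheme: str = "akima"):
    """Continuous f(scale_v, scale_j) from a gridded surface.

    ``scheme`` is "akima" (tensor-product local spline, default) or
    "cubic" (global bicubic via RegularGridInterpolator).  Raises outside
    the convex hull of the grid.
    """
    if isinstance(surface, SensitivitySurface):
        x, y = surface.scales_v, surface.scales_j
        z = getattr(surface, field_name)
    else:
        x, y, z = surface
        x, y, z = np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least a 3x3 grid to interpolate")
    if scheme == "akima":
        return _TensorAkima(x, y, z)
    if scheme == "cubic":
        rgi = RegularGridInterpolator((x, y), z, method="cubic",
                                      bounds_error=True)

        def f(xq, yq):
            out = rgi(np.stack(np.broadcast_arrays(
                np.asarray(xq, float), np.asarray(yq, float)), axis=-1))
            return float(out.item()) if out.size == 1 else out
        return f
    raise ValueError(f"unknown interpolation scheme {scheme!r}")


def gradient(f, x: float, y: float, h: float = 0.01) -> tuple[float, float]:
    """Central-difference gradient of a surface function at (x, y)."""
    fx = (f(x + h, y) - f(x - h, y)) / (2.0 * h)
    fy = (f(x, y + h) - f(x, y - h)) / (2.0 * h)
    return float(fx), float(fy)


def steepest_path(f, start: tuple[float, float], alpha: float = 0.001,
                  direction: str = "ascend", max_steps: int = 2000,
                  stop_tol: float = 1e-6, h: float = 0.01) -> GradientPath:
    """Follow the steepest gradient from ``start`` on surface ``f``.

    X_{n+1} = X_n ± α·∇f(X_n) (+ for ascent).  Terminates when |∇f| drops
    below ``stop_tol``, the path would leave the evaluable hull, or
    ``max_steps`` is reached.
    """
    if direction not in ("ascend", "descend"):
        raise ValueError("direction must be 'ascend' or 'descend'")
    sign = 1.0 if direction == "ascend" else -1.0
    pts = [np.asarray(start, dtype=float)]
    f(*start)  # raises if start is outside the hull
    termination = "max_steps"
    for _ in range(max_steps):
        x, y = pts[-1]
        try:
            g = np.asarray(gradient(f, x, y, h=h))
        except ValueError:
            termination = "hull_exit"
            break
        gn = float(np.hypot(*g))
        if gn < stop_tol:
            termination = "gradient_tol"
            break
        nxt = pts[-1] + sign * alpha * g
        try:
            f(*nxt)
        except ValueError:
            termination = "hull_exit"
            break
        pts.append(nxt)
    return GradientPath(points=np.array(pts), alpha=alpha, h=h,
                        direction=direction, termination=termination)


def limiting_frequency(traces: pd.DataFrame,
                       ci_bin_width: float = 50.0) -> dict:
    """Audit hourly limiting-rate labels of the top sunlit layer.

    ``traces`` is the hourly trace frame from ``simulate_season(...,
    retain_traces=True)`` (daylight hours only).  Returns per-label counts
    and a Ci histogram with configurable bin width.
    """
    if traces is None or len(traces) == 0:
        raise ValueError("no traces retained; rerun simulate_season with "
                         "retain_traces=True")
    counts = {name: int((traces["limiting"] == code).sum())
              for code, name in enumerate(_LIMITING_NAMES)}
    ci = traces["ci"].to_numpy()
    lo = math.floor(ci.min() / ci_bin_width) * ci_bin_width
    hi = math.ceil(ci.max() / ci_bin_width) * ci_bin_width
    edges = np.arange(lo, hi + ci_bin_width, ci_bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + ci_bin_width])
    hist, edges = np.histogram(ci, bins=edges)
    return {"counts": counts, "ci_hist": hist, "ci_edges": edges,
            "n_hours": int(len(traces))}


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-replicate seed: (master·1000003 + index) mod 2^31."""
    return (master_seed * 1000003 + index) % (2 ** 31)


def run_bootstrap_ensemble(archive: WeatherArchive,
                           params: PhotosynthesisParams,
                           arch: CanopyArchitecture,
                           schedule: PartitionSchedule,
                           n: int = 1000, master_seed: int = 7,
                           co2: float = 400.0,
                           scales: tuple = (1.2, 1.2)) -> BootstrapEnsemble:
    """Paired CTL / scaled seasons on ``n`` bootstrap weather years.

    Each replicate resamples one weather year (day blocks from the
    archive), runs the control and the (scale_v, scale_j) season on that
    same year, and records Δpod and ΔLAI in percent plus the per-phase
    climate-driver summaries for the downstream PRCC stage.  The quartile
    split is on Δpod.
    """
    if n < 4:
        raise ValueError("need n >= 4 for the quartile split")
    if len(archive.years) < 2:
        raise ValueError("archive must hold at least 2 years to bootstrap")
    rows = []
    for i in range(n):
        seed = child_seed(master_seed, i)
        by = bootstrap_year(archive, seed)
        ctl = simulate_season(by.frame, co2, params, arch, schedule, 1.0, 1.0)
        scl = simulate_season(by.frame, co2, params, arch, schedule,
                              scales[0], scales[1])
        row = {
            "seed": seed,
            "pod_ctl": ctl.summary["pod"],
            "lai_ctl": ctl.summary["max_lai"],
            "dpod_pct": relative_change(scl.summary["pod"], ctl.summary["pod"]),
            "dlai_pct": relative_change(scl.summary["max_lai"],
                                        ctl.summary["max_lai"]),
        }
        drivers = phase_driver_means(by.frame, ctl.phase_windows)
        for phase_code, phase in (("1", "vegetative"), ("2", "reproductive")):
            if phase in drivers.index:
                for var in ("q", "t", "precip", "rh", "ws"):
                    row[f"{var}{phase_code}"] = drivers.loc[phase, var]
        rows.append(row)
    reps = pd.DataFrame(rows)
    q25, q75 = np.percentile(reps["dpod_pct"], [25, 75])
    order = np.argsort(reps["dpod_pct"].to_numpy(), kind="stable")
    k = n // 4
    set25 = np.sort(order[:k])
    set75 = np.sort(order[-k:])
    r, p = stats.pearsonr(reps["dlai_pct"], reps["dpod_pct"])
    return BootstrapEnsemble(replicates=reps, co2=co2, scales=tuple(scales),
                             master_seed=master_seed,
                             corr_dlai_dpod=float(r), corr_p_value=float(p),
                             set25=set25, set75=set75)


def prcc(drivers: pd.DataFrame, response) -> PRCCResult:
    """Partial rank correlation of each driver with the response.

    All columns are rank-transformed; for a focal driver the PRCC is the
    Pearson correlation between the residuals of its ranks and of the
    response ranks, each regressed (with intercept) on the ranks of all
    other drivers.  The p-value uses the t transform with n − k − 2
    degrees of freedom, k being the number of conditioning drivers.
    """
    X = drivers.copy()
    y = np.asarray(response, dtype=float)
    if len(X) < 10:
        raise ValueError("need at least 10 replicates for PRCC")
    ranks = X.apply(lambda c: stats.rankdata(c), axis=0).to_numpy(dtype=float)
    ry = stats.rankdata(y)
    n, m = ranks.shape
    # collinearity check on the rank matrix (with intercept)
    full = np.column_stack([np.ones(n), ranks])
    if np.linalg.matrix_rank(full) < m + 1:
        corr = np.corrcoef(ranks, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        bad = [X.columns[i] for i in range(m) if np.any(np.abs(corr[i]) > 0.999)]
        raise ValueError(f"rank-deficient driver matrix; collinear columns: {bad}")
    rows = {}
    for j, col in enumerate(X.columns):
        others = np.column_stack([np.ones(n), np.delete(ranks, j, axis=1)])
        beta_x, *_ = np.linalg.lstsq(others, ranks[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, ry, rcond=None)
        res_x = ranks[:, j] - others @ beta_x
        res_y = ry - others @ beta_y
        denom = math.sqrt(float(res_x @ res_x) * float(res_y @ res_y))
        r = float(res_x @ res_y) / denom if denom > 0 else 0.0
        dof = n - (m - 1) - 2
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt(dof / (1.0 - r * r))
            p = 2.0 * stats.t.sf(abs(t), dof)
        rows[col] = {"coefficient": r, "p_value": p, "n": n}
    return PRCCResult(table=pd.DataFrame.from_dict(rows, orient="index"))
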
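"""Scripted, assertable model-analysis experiments.

Reproduces the package's reference studies as deterministic functions:
sweeps of the motility coefficient K* = K/K0 and the proliferation rate
eta* = eta/eta0 at the standard formation conditions (C0/Ci = 1.5,
R0 = 0.01 cm, 210 h horizon), and the head-to-head comparison of the
analytic series solution against the Crank-Nicolson moving-boundary
solver on two named parameter sets:

* set 1: eta* = 1.6, C0/Ci = 1.5, K* = 1, R0 = 0.01 cm
* set 2: eta* = 2,   C0/Ci = 2,   K* = 1, R0 = 0.02 cm

Trajectories are reported in normalized coordinates R* = (R - R0)/R0 and
t* = t/t_max.  Every figure-level claim (ordering of minima, earlier
assembly at higher proliferation, contraction-phase agreement) is exposed
as recomputable summary numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .analytic import SeriesConfig, integrate_analytic_trajectory
from .params import ModelParameters, nondimensionalize
from .solver import MappedGrid, SolverConfig, Trajectory, simulate

#: Captioned sweep conditions.
SWEEP_ETA_STAR = 1.8
SWEEP_K_STARS = (1.0, 2.0, 3.0)
SWEEP_K_STAR = 1.0
SWEEP_ETA_STARS = (1.6, 1.8, 2.0)
SWEEP_C_RATIO = 1.5
SWEEP_R0_CM = 0.01

#: Named analytic-vs-numeric comparison sets.
COMPARISON_SETS = {
    1: dict(K_star=1.0, eta_star=1.6, C0_over_Ci=1.5, R0=0.01),
    2: dict(K_star=1.0, eta_star=2.0, C0_over_Ci=2.0, R0=0.02),
}


@dataclass
class TrajectorySummary:
    min_radius_cm: float
    t_min_h: float
    final_radius_cm: float


@dataclass
class SweepResult:
    varied_param: str
    values: list
    trajectories: list
    summaries: list = dc_field(default_factory=list)


@dataclass
class ComparisonReport:
    params: ModelParameters
    t_min_numeric: float
    max_rel_diff_contraction: float
    max_rel_diff_growth: float


def time_of_minimum(times: np.ndarray, radii: np.ndarray) -> tuple[float, float]:
    """Locate the radius minimum by parabolic interpolation through the
    three samples bracketing the discrete minimum (robust to the output
    cadence).  Returns (t_min, R_min); an endpoint minimum is returned
    as-is."""
    i = int(np.argmin(radii))
    if i == 0 or i == len(radii) - 1:
        return float(times[i]), float(radii[i])
    t0, t1, t2 = times[i - 1 : i + 2]
    r0, r1, r2 = radii[i - 1 : i + 2]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (r1 - r0) + t1 * (r0 - r2) + t0 * (r2 - r1)) / denom
    b = (t2**2 * (r0 - r1) + t1**2 * (r2 - r0) + t0**2 * (r1 - r2)) / denom
    if a <= 0:
        return float(t1), float(r1)
    t_min = -b / (2 * a)
    c = r1 - a * t1**2 - b * t1
    return float(t_min), float(a * t_min**2 + b * t_min + c)


def summarize(traj: Trajectory) -> TrajectorySummary:
    t_min, r_min = time_of_minimum(traj.times, traj.radii)
    return TrajectorySummary(
        min_radius_cm=r_min,
        t_min_h=t_min,
        final_radius_cm=float(traj.radii[-1]),
    )


def _sweep(
    varied: str,
    values: Sequence[float],
    fixed: dict,
    grid: Optional[MappedGrid],
    cfg: Optional[SolverConfig],
) -> SweepResult:
    trajectories = []
    summaries = []
    for v in values:
        kwargs = dict(fixed)
        kwargs[varied] = v
        params = ModelParameters.from_dimensionless(**kwargs)
        traj = simulate(params, grid, cfg)
        trajectories.append(traj)
        summaries.append(summarize(traj))
    return SweepResult(
        varied_param=varied,
        values=list(values),
        trajectories=trajectories,
        summaries=summaries,
    )


def run_motility_sweep(
    k_stars: Sequence[float] = SWEEP_K_STARS,
    grid: Optional[MappedGrid] = None,
    cfg: Optional[SolverConfig] = None,
) -> SweepResult:
    """Formation trajectories for K* in ``k_stars`` at eta* = 1.8,
    C0/Ci = 1.5, R0 = 0.01 cm.  Higher motility contracts faster and
    deeper: the minimum radius decreases and its time does not increase
    with K*."""
    fixed = dict(eta_star=SWEEP_ETA_STAR, C0_over_Ci=SWEEP_C_RATIO, R0=SWEEP_R0_CM)
    return _sweep("K_star", k_stars, fixed, grid, cfg)


def run_proliferation_sweep(
    eta_stars: Sequence[float] = SWEEP_ETA_STARS,
    grid: Optional[MappedGrid] = None,
    cfg: Optional[SolverConfig] = None,
) -> SweepResult:
    """Formation trajectories for eta* in ``eta_stars`` at K* = 1,
    C0/Ci = 1.5, R0 = 0.01 cm.  A spheroid with a higher proliferation
    rate assembles faster (earlier minimum) and ends larger."""
    fixed = dict(K_star=SWEEP_K_STAR, C0_over_Ci=SWEEP_C_RATIO, R0=SWEEP_R0_CM)
    return _sweep("eta_star", eta_stars, fixed, grid, cfg)


def run_analytic_numeric_comparison(
    set_id: int,
    grid: Optional[MappedGrid] = None,
    cfg: Optional[SolverConfig] = None,
    series_cfg: Optional[SeriesConfig] = None,
    *,
    rate: str = "simplified",
) -> ComparisonReport:
    """Run both solvers on a named parameter set and report the maximum
    relative radius discrepancy in the contraction phase (t before the
    numerical minimum) and in the growth phase.

    The analytic curve defaults to the separation-of-timescales
    (simplified) rate, the lineage of the elementary closed form; pass
    ``rate='series'`` for the full eigen-series."""
    if set_id not in COMPARISON_SETS:
        raise ValueError(f"set_id must be one of {sorted(COMPARISON_SETS)}")
    params = ModelParameters.from_dimensionless(**COMPARISON_SETS[set_id])
    numeric = simulate(params, grid, cfg)
    analytic = integrate_analytic_trajectory(
        params, series_cfg, times=numeric.times[:: max(1, len(numeric.times) // 2000)],
        rate=rate,
    )
    r_num = np.interp(analytic.times, numeric.times, numeric.radii)
    rel = np.abs(analytic.radii - r_num) / r_num
    t_min, _ = time_of_minimum(numeric.times, numeric.radii)
    contraction = analytic.times <= t_min
    return ComparisonReport(
        params=params,
        t_min_numeric=t_min,
        max_rel_diff_contraction=float(rel[contraction].max()),
        max_rel_diff_growth=float(rel[~contraction].max()) if np.any(~contraction) else 0.0,
    )


def normalize_trajectory(traj: Trajectory, params: ModelParameters):
    """Return (t_star, r_star) series: t* = t/t_max in [0, 1] and
    R* = (R - R0)/R0 with R*(0) = 0 exactly."""
    if abs(traj.radii[0] - params.R0) > 1e-12 * params.R0:
        raise ValueError(
            f"trajectory starts at {traj.radii[0]!r} cm, expected R0 = {params.R0!r}"
        )
    view = nondimensionalize(params)
    t_star = view.t_star(np.asarray(traj.times, dtype=float))
    r_star = view.r_star(np.asarray(traj.radii, dtype=float))
    r_star[0] = 0.0
    return t_star, r_star


def denormalize_trajectory(t_star, r_star, params: ModelParameters) -> Trajectory:
    """Inverse of :func:`normalize_trajectory`."""
    times = np.asarray(t_star, dtype=float) * params.t_max
    radii = (np.asarray(r_star, dtype=float) + 1.0) * params.R0
    return Trajectory(times=times, radii=radii)


# -- figure-style outputs ------------------------------------------------------


def run_figure(name: str, out_dir, plot: bool = False) -> dict:
    """Run one named experiment ('fig1a', 'fig1b' or 'fig2'), write
    per-trajectory CSVs and a summary JSON to ``out_dir``, optionally a
    PNG plot in normalized coordinates; returns the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"experiment": name}

    if name in ("fig1a", "fig1b"):
        sweep = run_motility_sweep() if name == "fig1a" else run_proliferation_sweep()
        summary["varied_param"] = sweep.varied_param
        summary["values"] = sweep.values
        summary["summaries"] = [
            {
                "value": v,
                "min_radius_cm": s.min_radius_cm,
                "t_min_h": s.t_min_h,
                "final_radius_cm": s.final_radius_cm,
            }
            for v, s in zip(sweep.values, sweep.summaries)
        ]
        curves = []
        for v, traj in zip(sweep.values, sweep.trajectories):
            params = ModelParameters(**{
                k: traj.metadata["parameters"][k]
                for k in ("K", "eta", "C0", "Ci")
            }, R0=traj.metadata["parameters"]["R0_cm"],
               t_max=traj.metadata["parameters"]["t_max_h"])
            stride = max(1, (len(traj.times) - 1) // 500)
            sub = Trajectory(times=traj.times[::stride], radii=traj.radii[::stride])
            sub.radii[0] = params.R0
            t_star, r_star = normalize_trajectory(sub, params)
            label = f"{sweep.varied_param}={v:g}"
            curves.append((label, t_star, r_star))
            np.savetxt(
                out / f"{name}_{sweep.varied_param}_{v:g}.csv",
                np.column_stack([sub.times, sub.radii]),
                delimiter=",",
                header="time_h,radius_cm",
                comments="",
            )
    elif name == "fig2":
        curves = []
        summary["sets"] = {}
        for set_id in (1, 2):
            report = run_analytic_numeric_comparison(set_id)
            params = report.params
            numeric = simulate(params)
            analytic = integrate_analytic_trajectory(params)
            summary["sets"][str(set_id)] = {
                "t_min_numeric_h": report.t_min_numeric,
                "max_rel_diff_contraction": report.max_rel_diff_contraction,
                "max_rel_diff_growth": report.max_rel_diff_growth,
            }
            stride = max(1, (len(numeric.times) - 1) // 500)
            sub = Trajectory(times=numeric.times[::stride], radii=numeric.radii[::stride])
            t_star, r_star = normalize_trajectory(sub, params)
            curves.append((f"set {set_id} numeric", t_star, r_star))
            t_star_a, r_star_a = normalize_trajectory(analytic, params)
            curves.append((f"set {set_id} analytic", t_star_a, r_star_a))
            np.savetxt(
                out / f"fig2_set{set_id}_numeric.csv",
                np.column_stack([sub.times, sub.radii]),
                delimiter=",", header="time_h,radius_cm", comments="",
            )
            np.savetxt(
                out / f"fig2_set{set_id}_analytic.csv",
                np.column_stack([analytic.times, analytic.radii]),
                delimiter=",", header="time_h,radius_cm", comments="",
            )
    else:
        raise ValueError(f"unknown experiment {name!r}; use fig1a, fig1b or fig2")

    (out / f"{name}_summary.json").write_text(json.dumps(summary, indent=2))

    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for label, t_star, r_star in curves:
            ax.plot(t_star, r_star, label=label)
        ax.set_xlabel("t* = t / t_max")
        ax.set_ylabel("R* = (R - R0) / R0")
        ax.legend(fontsize=8)
        ax.set_title(name)
        fig.tight_layout()
        fig.savefig(out / f"{name}.png", dpi=150)
        plt.close(fig)

    return summary
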
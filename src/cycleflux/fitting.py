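"""Joint estimation of perturbation-module parameters from FC/TL/count data.

The objective is a weighted sum of squared residuals over the replicate
means of each stream: flow-cytometry residuals in percentage points divided
by the replicate SD, time-lapse and cell-count residuals on log counts
divided by the replicate SD of the logs, so each stream enters with
inverse-variance weight and no stream dominates through its units.
Optimization is multi-start (Latin-hypercube starts inside the bounds)
Nelder-Mead; uncertainty intervals come from a residual bootstrap; nested
model variants are compared with an F-test on the weighted SSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import qmc

from .core import (
    CellCycleParameters,
    ObservableSeries,
    SimulationGrid,
    simulate,
    steady_state_init,
)
from .perturbation import DrugModel, TreatmentSchedule, _module_active

__all__ = [
    "ParameterSpec",
    "FitResult",
    "ModelComparison",
    "summarize_dataset",
    "objective",
    "fit",
    "uncertainty",
    "compare_models",
]

_LOG_FLOOR = 0.5  # cells; counts are floored before taking logs


@dataclass
class ParameterSpec:
    """One estimand: a named magnitude with bounds.

    ``targets`` are ``"drug/module"`` (or bare module-name) addresses; a
    spec with several targets ties those magnitudes to a single shared
    value (e.g. a recycling rate set equal in generations 0 and 1 lives in
    one module spanning both generations, while a rate shared between two
    structurally distinct modules uses two targets).
    """

    name: str
    targets: tuple[str, ...]
    bounds: tuple[float, float] = (0.0, 1.0)
    free: bool = True

    def __post_init__(self):
        if isinstance(self.targets, str):
            self.targets = (self.targets,)
        self.targets = tuple(self.targets)
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError(f"empty bounds for {self.name}")


def _resolve(models: list[DrugModel], target: str):
    if "/" in target:
        drug, modname = target.split("/", 1)
        for dm in models:
            if dm.name == drug:
                return dm.module(modname)
        raise KeyError(f"no drug named {drug!r}")
    hits = []
    for dm in models:
        for m in dm.modules:
            if m.name == target:
                hits.append(m)
    if len(hits) != 1:
        raise KeyError(
            f"module address {target!r} matched {len(hits)} modules; "
            "use 'drug/module'"
        )
    return hits[0]


def _set_values(models, specs, x):
    for spec, v in zip(specs, x):
        for t in spec.targets:
            _resolve(models, t).magnitude = float(v)


def _get_value(models, spec):
    return _resolve(models, spec.targets[0]).magnitude


@dataclass
class FitResult:
    estimates: dict[str, float]
    objective: float
    n_obs: int
    n_free: int
    models: list[DrugModel]
    intervals: dict[str, tuple[float, float]] | None = None
    start_objectives: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.intervals:
            for k, (lo, hi) in self.intervals.items():
                est = self.estimates[k]
                if not lo - 1e-9 <= est <= hi + 1e-9:
                    self.intervals[k] = (min(lo, est), max(hi, est))


@dataclass(frozen=True)
class ModelComparison:
    f_stat: float
    p_value: float
    reject_reduced: bool
    df_num: int
    df_den: int
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def summarize_dataset(dataset: pd.DataFrame) -> pd.DataFrame:
    """Replicate means and SDs per observation, on the fitting scale.

    FC rows stay in percentage points; TL and count rows are floored at
    0.5 cells and log-transformed before averaging.  With the study's few
    replicates a raw per-observation SD is a very noisy weight, so the
    variance is moderated toward the pooled per-stream variance
    (sd^2 <- (sd_raw^2 + sd_pooled^2)/2) and floored at a fraction of the
    pooled SD; missing SDs fall back to the pooled value entirely.
    """
    df = dataset.copy()
    is_log = df["stream"].isin(["tl", "count"])
    df.loc[is_log, "value"] = np.log(df.loc[is_log, "value"].clip(lower=_LOG_FLOOR))
    g = (
        df.groupby(["stream", "time_h", "variable", "generation"])["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"std": "sd", "count": "n"})
    )
    missing = g["sd"].isna()
    g["sd"] = g["sd"].fillna(0.0)
    for stream, sub in g.groupby("stream"):
        pooled = np.sqrt(np.mean(sub["sd"] ** 2))
        if pooled <= 0:
            pooled = 1.0
        sel = g["stream"] == stream
        moderated = np.sqrt(0.5 * (g.loc[sel, "sd"] ** 2 + pooled**2))
        g.loc[sel, "sd"] = moderated.clip(lower=0.3 * pooled)
        g.loc[sel & missing, "sd"] = pooled
    return g


def _predict(summary: pd.DataFrame, series: ObservableSeries) -> np.ndarray:
    t = series.times
    out = np.empty(len(summary))
    pct = {"pct_G1": series.pct_G1, "pct_S": series.pct_S, "pct_G2M": series.pct_G2M}
    for k, row in enumerate(summary.itertuples(index=False)):
        i = int(np.argmin(np.abs(t - row.time_h)))
        if row.stream == "fc":
            out[k] = pct[row.variable][i]
        elif row.stream == "tl":
            out[k] = np.log(max(series.n_by_generation[i, int(row.generation)], _LOG_FLOOR))
        else:
            out[k] = np.log(max(series.n_total[i], _LOG_FLOOR))
    return out


def _residuals(summary: pd.DataFrame, series: ObservableSeries) -> np.ndarray:
    pred = _predict(summary, series)
    return (pred - summary["mean"].to_numpy()) / summary["sd"].to_numpy()


class _Problem:
    """Caches everything needed to evaluate the objective for one dataset."""

    def __init__(self, dataset, params, models, schedule, grid=None, n0=1000.0):
        self.summary = summarize_dataset(dataset)
        self.params = params
        self.models = [m.copy() for m in models]
        self.schedule = schedule or TreatmentSchedule()
        tmax = float(self.summary["time_h"].max())
        self.grid = grid or SimulationGrid(horizon=max(96.0, tmax))
        if self.grid.horizon < tmax:
            raise ValueError("grid horizon shorter than the last observation")
        self.n0 = n0
        self.init = steady_state_init(params, n0, self.grid)
        self.record_times = np.unique(self.summary["time_h"].to_numpy())

    def series(self) -> ObservableSeries:
        states = simulate(
            self.params, self.models, self.schedule, self.grid, self.init,
            record_times=self.record_times,
        )
        return ObservableSeries.from_states(states)

    def value(self, specs=None, x=None, summary=None) -> float:
        if specs is not None:
            _set_values(self.models, specs, x)
        r = _residuals(self.summary if summary is None else summary, self.series())
        return float(np.sum(r**2))


def objective(
    dataset: pd.DataFrame,
    params: CellCycleParameters,
    models: list[DrugModel],
    schedule: TreatmentSchedule | None = None,
    grid: SimulationGrid | None = None,
    n0: float = 1000.0,
) -> float:
    """Weighted SSE of a candidate model against a tidy dataset."""
    n_streams = dataset.groupby("stream")["time_h"].nunique()
    if (n_streams < 2).any():
        raise ValueError("each stream needs at least 2 time points")
    return _Problem(dataset, params, models, schedule, grid, n0).value()


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _check_identifiable(specs, models, schedule, t_max):
    """Auto-fix parameters whose modules are never active before t_max."""
    kept = []
    for spec in specs:
        if not spec.free:
            kept.append(spec)
            continue
        active = False
        tgrid = np.linspace(0.0, t_max, 200)
        for target in spec.targets:
            mod = _resolve(models, target)
            drug = target.split("/", 1)[0] if "/" in target else None
            for dm in models:
                if drug is not None and dm.name != drug:
                    continue
                if not any(m is mod for m in dm.modules):
                    continue
                try:
                    start, end = schedule.interval_for(dm.name)
                except KeyError:
                    continue
                mask, _ = _module_active(mod, tgrid, start, end)
                if mask.any() and mod.profile.value(tgrid[mask] - start).max() > 0:
                    active = True
        if active:
            kept.append(spec)
        else:
            warnings.warn(
                f"parameter {spec.name!r} is never active before the last "
                "observation; fixing it at its current value"
            )
            kept.append(ParameterSpec(spec.name, spec.targets, spec.bounds, free=False))
    return kept


def fit(
    dataset: pd.DataFrame,
    params: CellCycleParameters,
    models: list[DrugModel],
    schedule: TreatmentSchedule | None,
    specs: list[ParameterSpec],
    grid: SimulationGrid | None = None,
    n0: float = 1000.0,
    seed: int = 0,
    n_starts: int = 8,
    maxiter: int | None = None,
    fatol: float = 1e-3,
) -> FitResult:
    """Multi-start Nelder-Mead estimation of the free parameters.

    Starts are Latin-hypercube samples within the bounds, plus the
    skeleton's current values; each start is refined locally and the best
    solution is returned.  With no free parameters the objective is simply
    evaluated.  Reproducible given ``seed``.
    """
    prob = _Problem(dataset, params, models, schedule, grid, n0)
    schedule = prob.schedule
    specs = _check_identifiable(specs, prob.models, schedule,
                                float(prob.summary["time_h"].max()))
    free = [s for s in specs if s.free]
    n_obs = len(prob.summary)

    if not free:
        val = prob.value()
        return FitResult(
            estimates={s.name: _get_value(prob.models, s) for s in specs},
            objective=val, n_obs=n_obs, n_free=0, models=prob.models,
        )

    d = len(free)
    if d > n_obs:
        warnings.warn(f"{d} free parameters but only {n_obs} observations")
    lo = np.array([s.bounds[0] for s in free])
    hi = np.array([s.bounds[1] for s in free])
    x_current = np.array([_get_value(prob.models, s) for s in free])
    starts = [np.clip(x_current, lo, hi)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=d, seed=seed)
        starts += list(lo + sampler.random(n_starts - 1) * (hi - lo))

    def fun(x):
        return prob.value(free, np.clip(x, lo, hi))

    maxiter = maxiter or 200 * d
    best_x, best_val, trace = None, np.inf, []
    for x0 in starts:
        # explicit simplex: the default one degenerates at parameters
        # starting exactly on a bound (zero coordinates get a tiny step)
        step = 0.05 * (hi - lo)
        simplex = np.vstack([x0] + [x0 + step * e for e in np.eye(d)])
        over = simplex > hi
        simplex[over] = np.broadcast_to((x0 - step), simplex.shape)[over]
        simplex = np.clip(simplex, lo, hi)
        res = optimize.minimize(
            fun, x0, method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxiter": maxiter, "fatol": fatol, "xatol": 1e-4,
                     "initial_simplex": simplex},
        )
        trace.append(float(res.fun))
        if res.fun < best_val:
            best_val, best_x = float(res.fun), np.clip(res.x, lo, hi)
    if best_x is None or not np.isfinite(best_val):
        raise RuntimeError(f"all starts failed; objective trace: {trace}")

    _set_values(prob.models, free, best_x)
    return FitResult(
        estimates={s.name: _get_value(prob.models, s) for s in specs},
        objective=best_val, n_obs=n_obs, n_free=d,
        models=prob.models, start_objectives=trace,
    )


def uncertainty(
    fit_result: FitResult,
    dataset: pd.DataFrame,
    params: CellCycleParameters,
    schedule: TreatmentSchedule | None,
    specs: list[ParameterSpec],
    grid: SimulationGrid | None = None,
    n0: float = 1000.0,
    n_boot: int = 50,
    seed: int = 0,
    maxiter: int = 120,
) -> dict[str, tuple[float, float]]:
    """Residual-bootstrap 2.5-97.5% intervals for the free parameters.

    Standardized residuals of the best fit are resampled within each
    stream, added back to the fitted curves, and the model is refit
    locally from the point estimate for each bootstrap dataset.
    """
    prob = _Problem(dataset, params, fit_result.models, schedule, grid, n0)
    free = [s for s in specs if s.free]
    if not free:
        return {}
    summary = prob.summary
    series = prob.series()
    pred = _predict(summary, series)
    z = (summary["mean"].to_numpy() - pred) / summary["sd"].to_numpy()
    streams = summary["stream"].to_numpy()
    if np.std(z) < 1e-12:
        warnings.warn("degenerate residuals; bootstrap intervals collapse")
    rng = np.random.default_rng(seed)
    lo = np.array([s.bounds[0] for s in free])
    hi = np.array([s.bounds[1] for s in free])
    x_hat = np.array([fit_result.estimates[s.name] for s in free])

    draws = []
    for _ in range(n_boot):
        z_star = np.empty_like(z)
        for s in np.unique(streams):
            m = streams == s
            pool = z[m]
            z_star[m] = rng.choice(pool, size=m.sum(), replace=True)
        boot = summary.copy()
        boot["mean"] = pred + z_star * summary["sd"].to_numpy()

        def fun(x):
            return prob.value(free, np.clip(x, lo, hi), summary=boot)

        # small explicit simplex: bootstrap perturbations move the optimum
        # by far less than the default 5% step on steep objectives
        step = 0.01 * (hi - lo)
        simplex = np.vstack([x_hat] + [x_hat + step * e for e in np.eye(len(free))])
        simplex = np.clip(simplex, lo, hi)
        res = optimize.minimize(
            fun, x_hat, method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxiter": maxiter, "fatol": 1e-6, "xatol": 1e-5,
                     "initial_simplex": simplex},
        )
        draws.append(np.clip(res.x, lo, hi))
    draws = np.array(draws)
    out = {}
    for j, s in enumerate(free):
        lo_q, hi_q = np.percentile(draws[:, j], [2.5, 97.5])
        out[s.name] = (float(lo_q), float(hi_q))
    fit_result.intervals = out
    fit_result.__post_init__()
    return out


def compare_models(
    fit_reduced: FitResult, fit_full: FitResult, alpha: float = 0.05
) -> ModelComparison:
    """F-test of nested fits on the weighted SSE.

    F = ((SSE_r - SSE_f)/dk) / (SSE_f/(n - k_f)) with dk = k_f - k_r.
    """
    if fit_reduced.n_obs != fit_full.n_obs:
        raise ValueError("fits use different datasets; cannot compare")
    dk = fit_full.n_free - fit_reduced.n_free
    if dk <= 0:
        raise ValueError("models are not nested (full must free more parameters)")
    n, kf = fit_full.n_obs, fit_full.n_free
    df_den = n - kf
    if df_den <= 0:
        raise ValueError("no residual degrees of freedom")
    num = max(fit_reduced.objective - fit_full.objective, 0.0) / dk
    den = fit_full.objective / df_den
    f_stat = num / den if den > 0 else np.inf
    p = float(stats.f.sf(f_stat, dk, df_den))
    return ModelComparison(f_stat=float(f_stat), p_value=p,
                           reject_reduced=p < alpha, df_num=dk, df_den=df_den,
                           alpha=alpha)


def report_table(fit_result: FitResult) -> str:
    """Plain-text parameter table: estimate [interval] per parameter."""
    lines = ["parameter            estimate   interval"]
    for name, est in fit_result.estimates.items():
        iv = (fit_result.intervals or {}).get(name)
        ivs = f"[{iv[0]:.3g}-{iv[1]:.3g}]" if iv else ""
        lines.append(f"{name:<20s} {est:8.4g}   {ivs}")
    lines.append(f"objective {fit_result.objective:.6g}  "
                 f"n_obs {fit_result.n_obs}  n_free {fit_result.n_free}")
    return "\n".join(lines)
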
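"""Synthetic noisy datasets emulating the study's four data streams.

Given any ground-truth model the generator produces (a) flow-cytometry
phase-percentage replicates with additive Gaussian noise renormalized to
100, (b) time-lapse per-generation counts from replicate wells with
lognormal multiplicative noise, (c) absolute cell-count replicates, and
(d) SRB growth-inhibition dose-response grids with replicate plates.
Noise magnitudes default to the replicate scatter typical of such
experiments (FC SD 2.5 percentage points, TL CV 8%, count CV 5%, SRB CV
7%) and everything is reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CellCycleParameters,
    ObservableSeries,
    SimulationGrid,
    simulate,
    steady_state_init,
)
from .io import DATASET_COLUMNS, GRID_COLUMNS
from .observables import ExperimentDesign
from .perturbation import DrugModel, TreatmentSchedule

__all__ = [
    "NoiseModel",
    "generate_dataset",
    "generate_srb_grid",
    "simulate_observables",
    "random_instance",
]


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-scatter magnitudes of the four data streams."""

    fc_sd: float = 2.5  # percentage points, additive
    tl_cv: float = 0.08  # lognormal multiplicative
    count_cv: float = 0.05
    srb_cv: float = 0.07
    seed: int = 0

    def __post_init__(self):
        if min(self.fc_sd, self.tl_cv, self.count_cv, self.srb_cv) < 0:
            raise ValueError("noise dispersions must be >= 0")


def _lognormal_factor(rng, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_observables(
    params: CellCycleParameters,
    drug_models: list[DrugModel] | None,
    schedule: TreatmentSchedule | None,
    grid: SimulationGrid | None = None,
    n0: float = 1000.0,
    record_times=None,
) -> ObservableSeries:
    """Noise-free observables of a model (convenience wrapper)."""
    grid = grid or SimulationGrid()
    init = steady_state_init(params, n0, grid)
    states = simulate(params, drug_models, schedule, grid, init, record_times)
    return ObservableSeries.from_states(states)


def generate_dataset(
    params: CellCycleParameters,
    drug_models: list[DrugModel] | None,
    schedule: TreatmentSchedule | None,
    design: ExperimentDesign | None = None,
    noise: NoiseModel | None = None,
    grid: SimulationGrid | None = None,
    n0: float = 1000.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tidy replicate dataset drawn around the simulated truth.

    FC replicates: truth percentages + N(0, fc_sd) per phase, clipped at 0
    and renormalized to sum 100.  TL wells and count replicates: truth
    counts times lognormal factors with the configured CV (unit mean).
    """
    design = design or ExperimentDesign()
    noise = noise or NoiseModel()
    grid = grid or SimulationGrid(horizon=max(96.0, design.max_time()))
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    series = simulate_observables(params, drug_models, schedule, grid, n0)

    t = series.times

    def idx_of(time):
        return int(np.argmin(np.abs(t - time)))

    rows = []
    for time in design.fc_times:
        i = idx_of(time)
        truth = np.array([series.pct_G1[i], series.pct_S[i], series.pct_G2M[i]])
        for r in range(design.fc_replicates):
            draw = truth + rng.normal(0.0, noise.fc_sd, size=3)
            draw = np.clip(draw, 0.0, None)
            s = draw.sum()
            draw = draw / s * 100.0 if s > 0 else truth
            for var, v in zip(("pct_G1", "pct_S", "pct_G2M"), draw):
                rows.append((t[i], "fc", var, -1, r, v))
    n_gen = series.n_by_generation.shape[1]
    for time in design.tl_times:
        i = idx_of(time)
        for r in range(design.tl_wells):
            fac = _lognormal_factor(rng, noise.tl_cv, n_gen)
            vals = series.n_by_generation[i] * fac
            for g in range(n_gen):
                rows.append((t[i], "tl", "n", g, r, vals[g]))
    for time in design.count_times:
        i = idx_of(time)
        for r in range(design.count_replicates):
            fac = float(_lognormal_factor(rng, noise.count_cv, 1)[0])
            rows.append((t[i], "count", "n_total", -1, r, series.n_total[i] * fac))
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def generate_srb_grid(
    truth,
    doses_A,
    doses_B,
    noise: NoiseModel | None = None,
    n_replicates: int = 8,
    seed: int | None = None,
) -> pd.DataFrame:
    """Factorial growth-inhibition grid with replicate plates.

    ``truth`` is a callable ``truth(a, b) -> inhibition fraction`` (build
    one from engine models with :func:`srb_truth_from_models`, or from
    Hill curves with :func:`cycleflux.isobologram.loewe_additive_surface`).
    Multiplicative lognormal noise is applied to the surviving fraction
    1 - inhibition, so the zero-dose corner scatters around zero
    inhibition.  Default replicate structure: two independent experiments
    of four plates each (8 replicates).
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    rows = []
    for a in np.asarray(doses_A, dtype=float):
        for b in np.asarray(doses_B, dtype=float):
            inhib = float(truth(a, b))
            if not 0.0 <= inhib <= 1.0:
                raise ValueError(f"truth inhibition {inhib} outside [0,1]")
            for r in range(n_replicates):
                fac = float(_lognormal_factor(rng, noise.srb_cv, 1)[0])
                rows.append((a, b, r, 1.0 - (1.0 - inhib) * fac))
    return pd.DataFrame(rows, columns=GRID_COLUMNS)


def random_instance(seed: int):
    """A randomized small treatment scenario for engine cross-validation.

    Draws plausible cycling parameters (phase means within the range of
    adherent carcinoma lines, CVs 0.1-0.3) and a drug with 2-4 random
    perturbation modules (delays, checkpoint blocks with optional
    recycling, death) under a random exposure interval.  Returns
    (CellCycleParameters, DrugModel, TreatmentSchedule).
    """
    from .perturbation import PerturbationModule, TimeProfile

    rng = np.random.default_rng(seed)
    params = CellCycleParameters(
        mean_G1=rng.uniform(7, 13),
        mean_S=rng.uniform(6, 10),
        mean_G2M=rng.uniform(3, 6),
        cv_G1=rng.uniform(0.1, 0.3),
        cv_S=rng.uniform(0.1, 0.3),
        cv_G2M=rng.uniform(0.1, 0.3),
    )
    duration = float(rng.choice([6.0, 24.0, 48.0]))
    phases = ("G1", "S", "G2M")
    profiles = [
        TimeProfile("constant"),
        TimeProfile("sigmoid", half_max=6.0, rise=6.0),
        TimeProfile("step_window", onset=float(rng.integers(0, 5) * 3)),
    ]
    mods = []
    block_pools: set[tuple] = set()
    for i in range(int(rng.integers(2, 5))):
        phase = str(rng.choice(phases))
        gens = tuple(sorted(rng.choice([0, 1, 2], size=int(rng.integers(1, 3)),
                                       replace=False).tolist()))
        effect = str(rng.choice(["delay", "block", "death"], p=[0.45, 0.35, 0.2]))
        profile = profiles[int(rng.integers(0, len(profiles)))]
        window = str(rng.choice(["during", "always"]))
        if effect == "block":
            # at most one block module per (phase, generation, window) pool
            keys = {(phase, g, w) for g in gens for w in ("during", "always")}
            if keys & block_pools:
                effect = "delay"
            else:
                block_pools |= keys
        if effect == "death":
            mag = float(rng.uniform(0.005, 0.03))
        else:
            mag = float(rng.uniform(0.2, 0.9))
        mods.append(PerturbationModule(effect, phase, gens, mag,
                                       profile=profile, window=window,
                                       name=f"m{i}_{effect}_{phase}"))
    # give half of the blocked pools a recycling path
    blocked = {(m.phase, m.generations) for m in mods if m.effect == "block"}
    for j, (phase, gens) in enumerate(sorted(blocked)):
        if rng.uniform() < 0.5:
            mods.append(PerturbationModule(
                "recycle", phase, gens, float(rng.uniform(0.05, 0.3)),
                name=f"r{j}_{phase}"))
    drug = DrugModel(name="drugX", concentration="synthetic", modules=mods)
    schedule = TreatmentSchedule(intervals=[("drugX", 0.0, duration)])
    return params, drug, schedule


def srb_truth_from_models(
    params: CellCycleParameters,
    models_by_dose: dict[tuple[float, float], list[DrugModel]],
    schedule_builder,
    readout_time: float = 168.0,
    grid: SimulationGrid | None = None,
    n0: float = 1000.0,
):
    """Engine-backed truth surface for :func:`generate_srb_grid`.

    ``models_by_dose[(a, b)]`` lists the drug models in play at that dose
    pair and ``schedule_builder(a, b)`` returns the treatment schedule.
    Inhibition is 1 - N_treated(readout)/N_control(readout).
    """
    grid = grid or SimulationGrid(dt=1.0, age_bin=1.0, horizon=readout_time)
    init = steady_state_init(params, n0, grid)
    control = simulate(params, [], None, grid, init, record_times=[readout_time])
    n_control = control[-1].n_live
    cache: dict[tuple[float, float], float] = {}

    def truth(a: float, b: float) -> float:
        key = (float(a), float(b))
        if key not in cache:
            if a == 0 and b == 0:
                cache[key] = 0.0
            else:
                models = models_by_dose[key]
                sched = schedule_builder(a, b)
                states = simulate(
                    params, models, sched, grid, init, record_times=[readout_time]
                )
                cache[key] = 1.0 - states[-1].n_live / n_control
        return cache[key]

    return truth
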
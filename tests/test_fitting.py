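"""Objective construction, estimation, bootstrap and model comparison."""

import numpy as np
import pandas as pd
import pytest

from cycleflux import (
    DrugModel,
    ExperimentDesign,
    NoiseModel,
    ParameterSpec,
    PerturbationModule,
    SimulationGrid,
    TimeProfile,
    TreatmentSchedule,
    compare_models,
    fit,
    generate_dataset,
    objective,
    uncertainty,
)
from cycleflux.fitting import summarize_dataset


@pytest.fixture(scope="module")
def cheap_design():
    return ExperimentDesign(
        fc_times=(0.0, 24.0, 48.0, 72.0),
        tl_times=tuple(float(t) for t in range(0, 73, 12)),
        count_times=(0.0, 24.0, 48.0, 72.0),
        fc_replicates=4,
        tl_wells=5,
        count_replicates=4,
    )


@pytest.fixture(scope="module")
def cheap_grid():
    return SimulationGrid(dt=1.0, age_bin=1.0, horizon=72.0)


def _delay_drug(mag_s=0.5, mag_g1=0.0):
    mods = [PerturbationModule("delay", "S", (0, 1), mag_s, name="dS",
                               window="during")]
    mods.append(PerturbationModule("delay", "G1", (0, 1), mag_g1, name="dG1",
                                   window="during"))
    return DrugModel(name="d", modules=mods)


SCHED = TreatmentSchedule(intervals=[("d", 0.0, 48.0)])


class TestObjective:
    def test_zero_on_self_generated_noiseless_data(self, bxpc3, cheap_design, cheap_grid):
        truth = _delay_drug(0.5, 0.3)
        ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                              NoiseModel(fc_sd=0, tl_cv=0, count_cv=0),
                              grid=cheap_grid, seed=0)
        assert objective(ds, bxpc3, [truth], SCHED, grid=cheap_grid) < 1e-12

    def test_row_order_invariance(self, bxpc3, cheap_design, cheap_grid):
        truth = _delay_drug(0.5, 0.3)
        ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                              grid=cheap_grid, seed=1)
        shuffled = ds.sample(frac=1.0, random_state=4).reset_index(drop=True)
        a = objective(ds, bxpc3, [truth], SCHED, grid=cheap_grid)
        b = objective(shuffled, bxpc3, [truth], SCHED, grid=cheap_grid)
        assert a == pytest.approx(b, rel=1e-12)

    def test_count_rescaling_invariance(self, bxpc3, cheap_design, cheap_grid):
        """TL/count residuals live on logs, so scaling all counts (a unit
        change) shifts means but leaves dispersions and fit quality alike;
        the objective of the matching truth stays identical when both
        data and simulated n0 are scaled together."""
        truth = _delay_drug(0.4, 0.2)
        ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                              grid=cheap_grid, seed=2)
        # drop observations near the half-cell log floor, where unit
        # invariance is deliberately broken by the floor itself
        means = ds.groupby(["stream", "time_h", "variable", "generation"])[
            "value"].transform("mean")
        ds = ds[(ds.stream == "fc") | (means >= 2.0)].reset_index(drop=True)
        scaled = ds.copy()
        counts = scaled.stream.isin(["tl", "count"])
        scaled.loc[counts, "value"] *= 1000.0
        a = objective(ds, bxpc3, [truth], SCHED, grid=cheap_grid, n0=1000.0)
        b = objective(scaled, bxpc3, [truth], SCHED, grid=cheap_grid, n0=1000.0 * 1000.0)
        assert a == pytest.approx(b, rel=1e-6)

    def test_inverse_variance_weighting(self, bxpc3, cheap_grid):
        """Doubling every FC replicate SD divides each FC residual's
        contribution by four."""
        truth = _delay_drug(0.5, 0.0)
        candidate = _delay_drug(0.6, 0.0)
        design = ExperimentDesign(fc_times=(0, 24, 48), tl_times=(0, 24, 48),
                                  count_times=(0, 24, 48), fc_replicates=4)
        ds = generate_dataset(bxpc3, [truth], SCHED, design,
                              grid=cheap_grid, seed=3)
        fc_only = ds[ds.stream == "fc"].copy()
        widened = fc_only.copy()
        means = widened.groupby(["time_h", "variable"])["value"].transform("mean")
        widened["value"] = means + 2.0 * (widened["value"] - means)
        a = objective(fc_only, bxpc3, [candidate], SCHED, grid=cheap_grid)
        b = objective(widened, bxpc3, [candidate], SCHED, grid=cheap_grid)
        assert b == pytest.approx(a / 4.0, rel=1e-6)

    def test_requires_two_time_points_per_stream(self, bxpc3, cheap_design, cheap_grid):
        truth = _delay_drug()
        ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                              grid=cheap_grid, seed=4)
        single = ds[ds.time_h == 24.0]
        with pytest.raises(ValueError):
            objective(single, bxpc3, [truth], SCHED, grid=cheap_grid)


class TestFit:
    def test_all_fixed_returns_plain_evaluation(self, bxpc3, cheap_design, cheap_grid):
        truth = _delay_drug(0.5, 0.3)
        ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                              grid=cheap_grid, seed=5)
        spec = ParameterSpec("dS", ("d/dS",), free=False)
        res = fit(ds, bxpc3, [truth], SCHED, [spec], grid=cheap_grid)
        assert res.n_free == 0
        assert res.objective == pytest.approx(
            objective(ds, bxpc3, [truth], SCHED, grid=cheap_grid))

    def test_recovers_planted_delay(self, bxpc3, cheap_design, cheap_grid):
        truth = _delay_drug(0.55, 0.0)
        ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                              grid=cheap_grid, seed=6)
        skeleton = _delay_drug(0.2, 0.0)
        spec = ParameterSpec("dS", ("d/dS",))
        res = fit(ds, bxpc3, [skeleton], SCHED, [spec], grid=cheap_grid,
                  seed=1, n_starts=4)
        assert res.estimates["dS"] == pytest.approx(0.55, abs=0.05)

    def test_seeded_reproducibility(self, bxpc3, cheap_design, cheap_grid):
        truth = _delay_drug(0.55, 0.0)
        ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                              grid=cheap_grid, seed=7)
        spec = ParameterSpec("dS", ("d/dS",))
        r1 = fit(ds, bxpc3, [_delay_drug(0.2)], SCHED, [spec], grid=cheap_grid,
                 seed=9, n_starts=3)
        r2 = fit(ds, bxpc3, [_delay_drug(0.2)], SCHED, [spec], grid=cheap_grid,
                 seed=9, n_starts=3)
        assert r1.estimates == r2.estimates

    def test_inactive_parameter_auto_fixed(self, bxpc3, cheap_design, cheap_grid):
        truth = _delay_drug(0.5, 0.0)
        # a module whose step window opens after the last observation
        late = PerturbationModule("delay", "G2M", (1,), 0.4, name="late",
                                  profile=TimeProfile("step_window", onset=200.0),
                                  window="always")
        skel = _delay_drug(0.5, 0.0)
        skel.modules.append(late)
        ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                              grid=cheap_grid, seed=8)
        specs = [ParameterSpec("late", ("d/late",))]
        with pytest.warns(UserWarning, match="never active"):
            res = fit(ds, bxpc3, [skel], SCHED, specs, grid=cheap_grid,
                      n_starts=2)
        assert res.n_free == 0


class TestUncertainty:
    def test_noiseless_intervals_collapse(self, bxpc3, cheap_design, cheap_grid):
        truth = _delay_drug(0.5, 0.0)
        ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                              NoiseModel(fc_sd=0, tl_cv=0, count_cv=0),
                              grid=cheap_grid, seed=10)
        spec = ParameterSpec("dS", ("d/dS",))
        res = fit(ds, bxpc3, [truth.copy()], SCHED, [spec], grid=cheap_grid,
                  n_starts=1)
        with pytest.warns(UserWarning, match="degenerate residuals"):
            iv = uncertainty(res, ds, bxpc3, SCHED, [spec], grid=cheap_grid,
                             n_boot=10, maxiter=40)
        lo, hi = iv["dS"]
        assert hi - lo < 0.02

    def test_intervals_widen_with_noise(self, bxpc3, cheap_design, cheap_grid):
        truth = _delay_drug(0.5, 0.0)
        spec = ParameterSpec("dS", ("d/dS",))
        widths = []
        for fc_sd, tl_cv in ((1.0, 0.03), (5.0, 0.20)):
            ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                                  NoiseModel(fc_sd=fc_sd, tl_cv=tl_cv,
                                             count_cv=0.05),
                                  grid=cheap_grid, seed=11)
            res = fit(ds, bxpc3, [truth.copy()], SCHED, [spec],
                      grid=cheap_grid, n_starts=1)
            iv = uncertainty(res, ds, bxpc3, SCHED, [spec], grid=cheap_grid,
                             n_boot=15, seed=2, maxiter=40)
            widths.append(iv["dS"][1] - iv["dS"][0])
        assert widths[1] > widths[0]

    def test_interval_contains_estimate(self, bxpc3, cheap_design, cheap_grid):
        truth = _delay_drug(0.5, 0.0)
        ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                              grid=cheap_grid, seed=12)
        spec = ParameterSpec("dS", ("d/dS",))
        res = fit(ds, bxpc3, [truth.copy()], SCHED, [spec], grid=cheap_grid,
                  n_starts=1)
        iv = uncertainty(res, ds, bxpc3, SCHED, [spec], grid=cheap_grid,
                         n_boot=12, seed=3, maxiter=40)
        lo, hi = iv["dS"]
        assert lo <= res.estimates["dS"] <= hi


class TestModelComparison:
    def test_identical_fits_never_reject(self, bxpc3, cheap_design, cheap_grid):
        truth = _delay_drug(0.5, 0.0)
        ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                              grid=cheap_grid, seed=13)
        red = fit(ds, bxpc3, [truth.copy()], SCHED,
                  [ParameterSpec("dS", ("d/dS",))], grid=cheap_grid, n_starts=1)
        full = fit(ds, bxpc3, [truth.copy()], SCHED,
                   [ParameterSpec("dS", ("d/dS",)),
                    ParameterSpec("dG1", ("d/dG1",))],
                   grid=cheap_grid, n_starts=1)
        # force identical objectives: comparison of equal fits cannot reject
        full.objective = red.objective
        cmp = compare_models(red, full)
        assert not cmp.reject_reduced
        assert cmp.f_stat == 0.0

    def test_detects_planted_g1_delay_at_low_noise(self, bxpc3, cheap_design, cheap_grid):
        truth = _delay_drug(0.5, 0.35)
        ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                              NoiseModel(fc_sd=0.25, tl_cv=0.008, count_cv=0.005),
                              grid=cheap_grid, seed=14)
        red = fit(ds, bxpc3, [_delay_drug(0.5, 0.0)], SCHED,
                  [ParameterSpec("dS", ("d/dS",))], grid=cheap_grid, n_starts=2)
        full = fit(ds, bxpc3, [_delay_drug(0.5, 0.0)], SCHED,
                   [ParameterSpec("dS", ("d/dS",)),
                    ParameterSpec("dG1", ("d/dG1",))],
                   grid=cheap_grid, n_starts=2)
        cmp = compare_models(red, full)
        assert cmp.reject_reduced

    def test_non_nested_rejected(self, bxpc3, cheap_design, cheap_grid):
        truth = _delay_drug(0.5, 0.0)
        ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                              grid=cheap_grid, seed=15)
        a = fit(ds, bxpc3, [truth.copy()], SCHED,
                [ParameterSpec("dS", ("d/dS",))], grid=cheap_grid, n_starts=1)
        with pytest.raises(ValueError):
            compare_models(a, a)


class TestSummary:
    def test_sd_floor_keeps_weights_finite(self, bxpc3, cheap_design, cheap_grid):
        truth = _delay_drug(0.5, 0.0)
        ds = generate_dataset(bxpc3, [truth], SCHED, cheap_design,
                              grid=cheap_grid, seed=16)
        s = summarize_dataset(ds)
        assert (s["sd"] > 0).all()
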
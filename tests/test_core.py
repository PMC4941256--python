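"""Tests of the population engine: growth, transport, oracle agreement."""

import numpy as np
import pytest

from cycleflux import (
    CellCycleParameters,
    DrugModel,
    ObservableSeries,
    PerturbationModule,
    PhaseDurationModel,
    SimulationGrid,
    TreatmentSchedule,
    balanced_growth,
    microsimulate,
    simulate,
    steady_state_init,
)


class TestPhaseDurationModel:
    def test_moments_match_specification(self):
        m = PhaseDurationModel(mean=8.0, cv=0.2)
        # gamma(shape k, scale s): mean = k s, CV = 1/sqrt(k)
        assert m.shape * m.scale == pytest.approx(8.0, rel=1e-9)
        assert 1 / np.sqrt(m.shape) == pytest.approx(0.2, rel=1e-9)

    def test_discrete_hazard_reproduces_survival(self):
        m = PhaseDurationModel(mean=8.0, cv=0.25)
        h = m.discrete_hazard(0.5)
        surv = np.cumprod(1 - h)
        ages = (np.arange(1, len(h) + 1)) * 0.5
        assert np.allclose(surv[:-1], m.survival(ages[:-1]), atol=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            PhaseDurationModel(mean=-1, cv=0.2)
        with pytest.raises(ValueError):
            PhaseDurationModel(mean=5, cv=1.5)


class TestBalancedGrowth:
    def test_deterministic_cycle_doubling_time(self):
        """CV -> 0 with phase means (10, 8, 6) h gives a 24 h doubling time.

        The discrete age clock rounds each phase transit up to whole bins,
        so the doubling time carries a +3*age_bin/2 offset that vanishes
        with the bin width.
        """
        p = CellCycleParameters(10, 8, 6, 0.05, 0.05, 0.05)
        for da in (0.25, 0.125):
            bg = balanced_growth(p, SimulationGrid(dt=da, age_bin=da))
            assert bg.doubling_time == pytest.approx(24.0 + 1.5 * da, abs=0.25)

    def test_initial_population_size_and_generation(self, bxpc3, grid):
        state = steady_state_init(bxpc3, 1000.0, grid)
        assert state.n_live == pytest.approx(1000.0)
        gen = state.live_by_generation()
        assert gen[0] == pytest.approx(1000.0)
        assert np.all(gen[1:] == 0)

    def test_no_transient_exponential_growth(self, bxpc3, grid, init_state):
        """From the balanced state the population grows exponentially from t=0."""
        bg = balanced_growth(bxpc3, grid)
        states = simulate(bxpc3, [], None, grid, init_state)
        series = ObservableSeries.from_states(states)
        expected = 1000.0 * 2 ** (series.times / bg.doubling_time)
        assert np.max(np.abs(series.n_total / expected - 1)) < 0.01
        # phase percentages are stationary
        assert np.ptp(series.pct_G1) < 0.01
        assert np.ptp(series.pct_S) < 0.01

    def test_rejects_nonpositive_n0(self, bxpc3):
        with pytest.raises(ValueError):
            steady_state_init(bxpc3, 0.0)


class TestDeterministicEngine:
    def test_first_division_at_cycle_time(self, grid):
        """An age-0 cohort with tiny CVs first divides at Tc within a bin."""
        p = CellCycleParameters(6, 5, 3, 0.02, 0.02, 0.02)
        grid = SimulationGrid(dt=0.25, age_bin=0.25, horizon=20.0)
        init = steady_state_init(p, 1000.0, grid)
        init.density[:] = 0.0
        init.density[0, 0, 0] = 1000.0  # all cells at G1 age 0
        states = simulate(p, [], None, grid, init)
        gen1 = np.array([s.live_by_generation()[1] for s in states])
        t_first = states[int(np.argmax(gen1 > 1.0))].time
        tc = 14.0
        assert abs(t_first - tc) <= 1.0

    def test_absorbing_g1_block(self, bxpc3, grid, init_state):
        """Block probability 1 at G1 for all generations empties S and G2M."""
        dm = DrugModel(name="d", modules=[
            PerturbationModule("block", "G1", tuple(range(6)), 1.0)])
        sched = TreatmentSchedule(intervals=[("d", 0, 96)])
        states = simulate(bxpc3, [dm], sched, grid, init_state, record_times=[96])
        series = ObservableSeries.from_states(
            simulate(bxpc3, [dm], sched, grid, init_state))
        assert series.pct_G1[-1] > 99.9
        # no cell ever re-enters S once the in-transit cells clear
        st = states[-1]
        assert st.density[1].sum() + st.density[2].sum() < 1e-6

    def test_conservation_without_death(self, bxpc3, grid, init_state, erl1):
        """With no death modules the live population never decreases and no
        cell is booked dead."""
        no_death = erl1.copy()
        no_death.modules = [m for m in no_death.modules if m.effect != "death"]
        sched = TreatmentSchedule(intervals=[("erlotinib", 0, 48)])
        states = simulate(bxpc3, [no_death], sched, grid, init_state)
        n = np.array([s.n_live for s in states])
        assert np.all(np.diff(n) >= -1e-9)
        assert states[-1].n_dead == 0.0

    def test_division_doubles_flux(self, bxpc3):
        """Every increase of the live population equals the doubled division
        flux: total growth matches the per-generation bookkeeping."""
        grid = SimulationGrid(horizon=48.0)
        init = steady_state_init(bxpc3, 1000.0, grid)
        states = simulate(bxpc3, [], None, grid, init)
        for s in states[::16]:
            gen = s.live_by_generation()
            # cells in generation g carry weight 2^-g of founding lineages;
            # without death the founding-lineage count is conserved
            founders = np.sum(gen * 0.5 ** np.arange(len(gen)))
            assert founders == pytest.approx(1000.0, rel=1e-9)

    def test_generation_index_never_decreases(self, bxpc3, grid, init_state):
        states = simulate(bxpc3, [], None, grid, init_state)
        gen0 = np.array([s.live_by_generation()[0] for s in states])
        assert np.all(np.diff(gen0) <= 1e-9)


class TestMicrosimulator:
    def test_reproducible_given_seed(self, bxpc3, gem20, gem_schedule):
        grid = SimulationGrid(horizon=48.0)
        a = microsimulate(bxpc3, [gem20], gem_schedule, 500, seed=7, grid=grid,
                          record_times=[0, 24, 48])
        b = microsimulate(bxpc3, [gem20], gem_schedule, 500, seed=7, grid=grid,
                          record_times=[0, 24, 48])
        assert np.array_equal(a.n_by_generation, b.n_by_generation)
        assert np.array_equal(a.pct_S, b.pct_S)

    def test_no_death_modules_population_never_shrinks(self, bxpc3):
        grid = SimulationGrid(horizon=48.0)
        s = microsimulate(bxpc3, [], None, 1000, seed=3, grid=grid,
                          record_times=[0, 12, 24, 36, 48])
        assert np.all(np.diff(s.n_total) >= 0)

    def test_untreated_agrees_with_engine(self, bxpc3, grid, init_state):
        """Generation counts and FC percentages match the deterministic
        engine within Monte-Carlo error (oracle cross-check)."""
        times = [24.0, 48.0, 72.0, 96.0]
        states = simulate(bxpc3, [], None, grid, init_state, record_times=times)
        engine = ObservableSeries.from_states(states)
        n_rep, n_cells = 6, 1000
        reps = [microsimulate(bxpc3, [], None, n_cells, seed=40 + r, grid=grid,
                              record_times=times) for r in range(n_rep)]
        scale = 1000.0 / n_cells
        gen = np.array([m.n_by_generation for m in reps]) * scale
        mean, se = gen.mean(0), gen.std(0, ddof=1) / np.sqrt(n_rep)
        big = mean > 20
        z = (engine.n_by_generation[big] - mean[big]) / se[big]
        assert np.abs(z).max() < 5.0
        pcts = np.array([[m.pct_G1, m.pct_S, m.pct_G2M] for m in reps])
        pm, pse = pcts.mean(0), pcts.std(0, ddof=1) / np.sqrt(n_rep)
        em = np.array([engine.pct_G1, engine.pct_S, engine.pct_G2M])
        assert np.abs((em - pm) / pse).max() < 5.0

    def test_phase_fraction_ordering_matches_oracle(self, bxpc3, grid):
        """%G1 > %S > %G2M ordering under balanced growth agrees between the
        eigenproblem and the stochastic oracle."""
        bg = balanced_growth(bxpc3, grid)
        fr = bg.phase_fractions()
        m = microsimulate(bxpc3, [], None, 20000, seed=11,
                          grid=SimulationGrid(horizon=12.0), record_times=[12.0])
        micro = np.array([m.pct_G1[-1], m.pct_S[-1], m.pct_G2M[-1]])
        assert list(np.argsort(-fr)) == list(np.argsort(-micro))
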
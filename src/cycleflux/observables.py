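"""Mapping population states to the measured quantities.

Three read-outs are modelled: flow-cytometric phase percentages (%G1, %S,
%G2M over live cells, blocked cells counted in their phase of arrest),
time-lapse live-cell counts per division generation, and the absolute live
cell number.  Dead cells are excluded from all three (debris-gated FC,
live-cell TL frames); this is configurable nowhere because the engine
removes dead cells from the live pool immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ObservableSeries, PopulationState

__all__ = [
    "ExperimentDesign",
    "fc_percentages",
    "tl_generation_counts",
    "total_cell_number",
    "series_from_states",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling times and replicate structure of a study.

    Defaults: FC sampled every 24 h and TL every 6 h over 0-96 h, with
    three independent FC experiments and five replicate TL wells.
    """

    fc_times: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0, 96.0)
    tl_times: tuple[float, ...] = tuple(float(t) for t in range(0, 97, 6))
    count_times: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0, 96.0)
    fc_replicates: int = 3
    tl_wells: int = 5
    count_replicates: int = 3

    def __post_init__(self):
        if min(self.fc_replicates, self.tl_wells, self.count_replicates) < 1:
            raise ValueError("replicate counts must be >= 1")

    def all_times(self) -> np.ndarray:
        return np.unique(
            np.concatenate([self.fc_times, self.tl_times, self.count_times])
        )

    def max_time(self) -> float:
        return float(self.all_times().max())


def fc_percentages(state: PopulationState) -> tuple[float, float, float]:
    """(%G1, %S, %G2M) over live cells; blocked cells count in their phase."""
    by_phase = state.live_by_phase()
    total = by_phase.sum()
    if total <= 0:
        raise ValueError("FC percentages undefined: zero live cells")
    pct = 100.0 * by_phase / total
    return float(pct[0]), float(pct[1]), float(pct[2])


def tl_generation_counts(state: PopulationState) -> np.ndarray:
    """Live cells per division generation (in-transit plus blocked)."""
    return state.live_by_generation()


def total_cell_number(state: PopulationState) -> float:
    """Total live cells (equals the sum of the TL generation counts)."""
    return state.n_live


def series_from_states(states: list[PopulationState]) -> ObservableSeries:
    """Bundle a recorded trajectory into an ObservableSeries."""
    return ObservableSeries.from_states(states)
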
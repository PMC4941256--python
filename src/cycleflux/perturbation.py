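"""Drug-effect grammar: perturbation modules, time profiles, drug models, schedules.

A treatment is described as a small set of typed modules, each acting on one
cell-cycle phase and a set of division generations:

* ``delay`` — fractional slow-down of transit through a phase (in S phase this
  is equivalent to fractional inhibition of the DNA synthesis rate);
* ``synthesis_inhibition`` — alias for an S-phase delay, kept as a separate
  effect tag so gemcitabine-style models are self-describing;
* ``block`` — probabilistic arrest of cohorts arriving at the checkpoint at
  the end of the phase;
* ``recycle`` — first-order rate at which arrested cells resume cycling;
* ``death`` — first-order per-hour removal of cells in the phase.

Each module carries a time-activation profile (constant, step window, or
logistic sigmoid) evaluated on time since the start of the drug's exposure
interval, and a window flag restricting it to the exposure interval itself
(``during``), to the washout period (``post``), or to both (``always``).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

PHASES = ("G1", "S", "G2M")
PHASE_INDEX = {p: i for i, p in enumerate(PHASES)}

EFFECTS = ("delay", "block", "death", "recycle", "synthesis_inhibition")
WINDOWS = ("during", "post", "always")

# logistic scale giving a 10% -> 90% rise over one `rise` span
_LOGISTIC_1090 = 2.0 * np.log(9.0)


@dataclass(frozen=True)
class TimeProfile:
    """Time activation of a perturbation module, valued in [0, 1].

    ``kind`` is one of ``constant`` (1 everywhere), ``step_window`` (1 on
    [onset, offset), else 0) or ``sigmoid`` (logistic in time, value 0.5 at
    ``half_max``, rising 10% -> 90% over ``rise`` hours; ``direction='fall'``
    mirrors it for effects that decay, e.g. recovery of DNA synthesis).
    Times are hours since the start of the owning drug's exposure interval.
    """

    kind: str = "constant"
    onset: float = 0.0
    offset: float | None = None
    half_max: float | None = None
    rise: float = 6.0
    direction: str = "rise"

    def __post_init__(self):
        if self.kind not in ("constant", "step_window", "sigmoid"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.kind == "sigmoid":
            if self.half_max is None:
                raise ValueError("sigmoid profile requires half_max")
            if self.rise <= 0:
                raise ValueError("sigmoid rise span must be > 0")
            if self.direction not in ("rise", "fall"):
                raise ValueError("sigmoid direction must be 'rise' or 'fall'")
        if self.kind == "step_window" and self.offset is not None:
            if self.offset <= self.onset:
                raise ValueError("step_window offset must exceed onset")

    def value(self, tau):
        """Profile value at time ``tau`` (hours since drug start); vectorized."""
        tau = np.asarray(tau, dtype=float)
        if self.kind == "constant":
            return np.ones_like(tau)
        if self.kind == "step_window":
            hi = np.inf if self.offset is None else self.offset
            return ((tau >= self.onset) & (tau < hi)).astype(float)
        scale = self.rise / _LOGISTIC_1090
        v = 1.0 / (1.0 + np.exp(-(tau - self.half_max) / scale))
        return 1.0 - v if self.direction == "fall" else v

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "step_window":
            d["onset"] = float(self.onset)
            if self.offset is not None:
                d["offset"] = float(self.offset)
        elif self.kind == "sigmoid":
            d["half_max"] = float(self.half_max)
            d["rise"] = float(self.rise)
            if self.direction != "rise":
                d["direction"] = self.direction
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TimeProfile":
        return cls(**d)


CONSTANT = TimeProfile("constant")


@dataclass
class PerturbationModule:
    """One drug effect on one phase and a set of generations.

    ``magnitude`` is a probability/fraction in [0, 1] for ``delay``, ``block``
    and ``synthesis_inhibition``, and a non-negative per-hour rate for
    ``death`` and ``recycle``.
    """

    effect: str
    phase: str
    generations: tuple[int, ...]
    magnitude: float
    profile: TimeProfile = field(default_factory=lambda: CONSTANT)
    window: str = "always"
    name: str = ""

    def __post_init__(self):
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.effect == "synthesis_inhibition" and self.phase != "S":
            raise ValueError("synthesis_inhibition only applies to S phase")
        if self.window not in WINDOWS:
            raise ValueError(f"unknown window {self.window!r}")
        self.generations = tuple(sorted(int(g) for g in self.generations))
        if not self.generations:
            raise ValueError("module must target at least one generation")
        if any(g < 0 for g in self.generations):
            raise ValueError("generations must be >= 0")
        m = float(self.magnitude)
        if self.effect in ("delay", "block", "synthesis_inhibition"):
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"{self.effect} magnitude must be in [0,1], got {m}")
        elif m < 0.0:
            raise ValueError(f"{self.effect} magnitude must be >= 0, got {m}")
        self.magnitude = m
        if not self.name:
            gens = "".join(str(g) for g in self.generations)
            self.name = f"{self.effect}_{self.phase}_g{gens}_{self.window}"

    def value(self, tau):
        """Instantaneous magnitude x profile at ``tau`` hours since drug start."""
        return self.magnitude * self.profile.value(tau)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "effect": self.effect,
            "phase": self.phase,
            "generations": list(self.generations),
            "magnitude": float(self.magnitude),
            "window": self.window,
            "profile": self.profile.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PerturbationModule":
        d = dict(d)
        prof = d.pop("profile", None)
        profile = TimeProfile.from_dict(prof) if prof else CONSTANT
        return cls(profile=profile, **{k: v for k, v in d.items()})


@dataclass
class DrugModel:
    """A named drug at one concentration: a bag of perturbation modules.

    Concentration is a label selecting a parameter set; there is no
    pharmacokinetic component.
    """

    name: str
    concentration: str = ""
    modules: list[PerturbationModule] = field(default_factory=list)
    cell_line: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self):
        seen_blocks: set[tuple] = set()
        seen_recycle: set[tuple] = set()
        names = set()
        for m in self.modules:
            if m.name in names:
                raise ValueError(f"duplicate module name {m.name!r} in {self.name}")
            names.add(m.name)
            if m.effect == "block":
                for g in m.generations:
                    key = (m.phase, g, m.window)
                    if key in seen_blocks:
                        raise ValueError(
                            f"multiple block modules for {key} in {self.name}"
                        )
                    seen_blocks.add(key)
            if m.effect == "recycle":
                for g in m.generations:
                    key = (m.phase, g, m.window)
                    if key in seen_recycle:
                        raise ValueError(
                            f"multiple recycle modules for pool {key} in {self.name}"
                        )
                    seen_recycle.add(key)

    def module(self, name: str) -> PerturbationModule:
        for m in self.modules:
            if m.name == name:
                return m
        raise KeyError(f"no module named {name!r} in drug {self.name!r}")

    def copy(self) -> "DrugModel":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "concentration": self.concentration,
            "cell_line": self.cell_line,
            "modules": [m.to_dict() for m in self.modules],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DrugModel":
        return cls(
            name=d["name"],
            concentration=d.get("concentration", ""),
            cell_line=d.get("cell_line", ""),
            modules=[PerturbationModule.from_dict(m) for m in d.get("modules", [])],
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "DrugModel":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            text = str(source)
            if "\n" in text or ":" in text.split("/")[-1]:
                try:
                    data = yaml.safe_load(text)
                except yaml.YAMLError:
                    with open(source) as fh:
                        data = yaml.safe_load(fh)
            else:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)


@dataclass
class TreatmentSchedule:
    """Exposure intervals per drug, hours from the start of the experiment."""

    intervals: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self):
        by_drug: dict[str, list[tuple[float, float]]] = {}
        norm = []
        for drug, start, end in self.intervals:
            start, end = float(start), float(end)
            if end <= start:
                raise ValueError(f"empty interval for {drug}: [{start}, {end})")
            by_drug.setdefault(drug, []).append((start, end))
            norm.append((drug, start, end))
        for drug, ivs in by_drug.items():
            ivs.sort()
            for (s0, e0), (s1, _) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping intervals for drug {drug!r}")
        self.intervals = norm

    def interval_for(self, drug: str) -> tuple[float, float]:
        ivs = [(s, e) for d, s, e in self.intervals if d == drug]
        if not ivs:
            raise KeyError(f"drug {drug!r} not in schedule")
        if len(ivs) > 1:
            raise ValueError(f"multiple intervals for drug {drug!r} not supported")
        return ivs[0]

    def drugs(self) -> list[str]:
        seen = []
        for d, _, _ in self.intervals:
            if d not in seen:
                seen.append(d)
        return seen

    def end(self) -> float:
        return max(e for _, _, e in self.intervals) if self.intervals else 0.0

    def to_dict(self) -> dict:
        return {
            "intervals": [
                {"drug": d, "start": s, "end": e} for d, s, e in self.intervals
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreatmentSchedule":
        return cls(
            intervals=[(i["drug"], i["start"], i["end"]) for i in d["intervals"]]
        )


# ---------------------------------------------------------------------------
# flux-level primitives (the arithmetic contracts of the grammar)
# ---------------------------------------------------------------------------

def speed_factor(delay_values) -> float:
    """Multiplicative transit-speed factor under simultaneous delays."""
    out = 1.0
    for d in delay_values:
        out *= 1.0 - d
    return out


def effective_exit_hazard(base_hazard, delay_values):
    """Exit hazard under active delay modules: base x prod(1 - d_i)."""
    base_hazard = np.asarray(base_hazard, dtype=float)
    if np.any(base_hazard < 0):
        raise ValueError("base hazard must be >= 0")
    return base_hazard * speed_factor(delay_values)


def apply_checkpoint_block(arriving_flux: float, block_value: float):
    """Split a checkpoint-arriving flux into (passing, blocked); conserves flux."""
    if arriving_flux < 0:
        raise ValueError("arriving flux must be >= 0")
    if not 0.0 <= block_value <= 1.0:
        raise ValueError("block value must be in [0,1]")
    blocked = block_value * arriving_flux
    return arriving_flux - blocked, blocked


def recycle_flux(blocked_pool: float, rate_value: float) -> float:
    """Instantaneous first-order outflow (cells/h) from a blocked pool."""
    if blocked_pool < 0:
        raise ValueError("blocked pool must be >= 0")
    if rate_value < 0:
        raise ValueError("recycle rate must be >= 0")
    return rate_value * blocked_pool


def apply_death(compartment: float, rate_value: float) -> float:
    """Instantaneous removal flux (cells/h) from a live compartment."""
    if compartment < 0:
        raise ValueError("compartment must be >= 0")
    if rate_value < 0:
        raise ValueError("death rate must be >= 0")
    return rate_value * compartment


# ---------------------------------------------------------------------------
# time-resolved rate tables consumed by the simulation engines
# ---------------------------------------------------------------------------

class OverlapError(RuntimeError):
    """Two drugs drive the same (effect, phase, generation) at the same time."""


def _module_active(mod: PerturbationModule, t, start: float, end: float):
    """Activity mask and values of one module at absolute times ``t``."""
    t = np.asarray(t, dtype=float)
    tau = t - start
    if mod.window == "during":
        mask = (t >= start) & (t < end)
    elif mod.window == "post":
        mask = t >= end
    else:
        mask = t >= start
    return mask, np.where(mask, mod.value(tau), 0.0)


def rate_tables(
    drug_models: list[DrugModel],
    schedule: TreatmentSchedule,
    times,
    n_generations: int,
    overlap_policy: str = "supersede",
) -> dict[str, np.ndarray]:
    """Per-step perturbation rates on the (time, phase, generation) lattice.

    Returns arrays keyed ``speed`` (transit-speed factor from delays),
    ``block`` (checkpoint arrest probability), ``death`` and ``recycle``
    (per-hour rates), each of shape (n_times, 3, n_generations).

    When two drugs' modules with the same (effect, phase, generation) are
    both active, ``overlap_policy='supersede'`` lets the later-starting
    drug's module replace the earlier one's from its own start time onward
    (the earlier drug's other modules persist); ``'error'`` raises.
    """
    if overlap_policy not in ("supersede", "error"):
        raise ValueError("overlap_policy must be 'supersede' or 'error'")
    times = np.asarray(times, dtype=float)
    nt = len(times)
    G = n_generations
    speed = np.ones((nt, 3, G))
    block_keep = np.ones((nt, 3, G))  # prod(1 - p_i), combined at the end
    death = np.zeros((nt, 3, G))
    recycle = np.zeros((nt, 3, G))

    # collect (start, drug, module, mask, values); sort drugs by start time
    entries = []
    for dm in drug_models:
        if not dm.modules:
            continue
        start, end = schedule.interval_for(dm.name)
        for mod in dm.modules:
            mask, vals = _module_active(mod, times, start, end)
            entries.append({"start": start, "drug": dm.name, "mod": mod,
                            "mask": mask.copy(), "vals": vals})

    # supersession: a later-starting drug's module silences same-key modules
    # of earlier-starting drugs from its start onward
    for e_late in entries:
        for e_early in entries:
            if e_early["drug"] == e_late["drug"]:
                continue
            if e_early["start"] >= e_late["start"]:
                continue
            m_l, m_e = e_late["mod"], e_early["mod"]
            same_key = (
                m_l.effect == m_e.effect
                and m_l.phase == m_e.phase
                and set(m_l.generations) & set(m_e.generations)
            )
            if not same_key:
                continue
            clash = e_early["mask"] & (times >= e_late["start"])
            if not clash.any():
                continue
            if overlap_policy == "error":
                raise OverlapError(
                    f"modules {m_e.name!r} ({e_early['drug']}) and "
                    f"{m_l.name!r} ({e_late['drug']}) overlap on "
                    f"({m_l.effect}, {m_l.phase})"
                )
            e_early["mask"] &= times < e_late["start"]
            e_early["vals"] = np.where(e_early["mask"], e_early["vals"], 0.0)

    for e in entries:
        mod, vals = e["mod"], e["vals"]
        p = PHASE_INDEX[mod.phase]
        for g in mod.generations:
            if g >= G:
                continue
            if mod.effect in ("delay", "synthesis_inhibition"):
                speed[:, p, g] *= 1.0 - vals
            elif mod.effect == "block":
                block_keep[:, p, g] *= 1.0 - vals
            elif mod.effect == "death":
                death[:, p, g] += vals
            elif mod.effect == "recycle":
                recycle[:, p, g] += vals

    return {
        "speed": speed,
        "block": 1.0 - block_keep,
        "death": death,
        "recycle": recycle,
    }


def null_drug(name: str = "vehicle") -> DrugModel:
    """A drug with no modules (untreated control)."""
    return DrugModel(name=name, concentration="0")


def scale_module(mod: PerturbationModule, magnitude: float) -> PerturbationModule:
    """Copy of a module with a new magnitude (used by the fitting layer)."""
    return replace(copy.deepcopy(mod), magnitude=magnitude)
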
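"""Access to the shipped parameter library (cell lines and drug models)."""

from __future__ import annotations

from importlib import resources

import yaml

from .core import CellCycleParameters
from .perturbation import DrugModel, TreatmentSchedule

_PKG = "cycleflux.params"


def _read(name: str) -> str:
    return resources.files(_PKG).joinpath(name).read_text()


def load_cell_line(name: str) -> CellCycleParameters:
    """Cycling parameters for 'BxPC-3' or 'Capan-1'."""
    data = yaml.safe_load(_read("cell_lines.yaml"))
    if name not in data:
        raise KeyError(f"unknown cell line {name!r}; have {sorted(data)}")
    return CellCycleParameters(name=name, **data[name])


def list_models() -> list[str]:
    out = []
    for entry in resources.files(_PKG).iterdir():
        if entry.name.endswith(".yaml") and entry.name != "cell_lines.yaml":
            out.append(entry.name[: -len(".yaml")])
    return sorted(out)


def load_drug_model(key: str) -> DrugModel:
    """Load a shipped drug model by key, e.g. 'bxpc3_gemcitabine_20nM'."""
    fname = f"{key}.yaml"
    try:
        text = _read(fname)
    except FileNotFoundError:
        raise KeyError(f"unknown model {key!r}; have {list_models()}") from None
    return DrugModel.from_dict(yaml.safe_load(text))


def single_drug_schedule(drug: str, start: float, end: float) -> TreatmentSchedule:
    return TreatmentSchedule(intervals=[(drug, start, end)])


def g_then_e_schedule(
    gem_hours: tuple[float, float] = (0.0, 6.0),
    erl_hours: tuple[float, float] = (24.0, 72.0),
) -> TreatmentSchedule:
    """Gemcitabine -> erlotinib sequence (default 0-6 h G, 24-72 h E)."""
    return TreatmentSchedule(
        intervals=[("gemcitabine", *gem_hours), ("erlotinib", *erl_hours)]
    )


def e_then_g_schedule(
    erl_hours: tuple[float, float] = (0.0, 48.0),
    gem_hours: tuple[float, float] = (66.0, 72.0),
) -> TreatmentSchedule:
    """Erlotinib -> gemcitabine sequence (default 0-48 h E, 66-72 h G)."""
    return TreatmentSchedule(
        intervals=[("erlotinib", *erl_hours), ("gemcitabine", *gem_hours)]
    )
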
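"""YAML scenario/simulation configuration loading."""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import yaml

from .popgen import DemographyModel, SelectionModel


@dataclass
class SimulationConfig:
    demography: DemographyModel
    selection: SelectionModel
    mutation_rate: float
    locus_length: int
    rescale: float
    n_pools: int


def _parse(doc: dict) -> SimulationConfig:
    dem_doc = doc["demography"]
    if dem_doc.get("kind") == "two_epoch":
        dem = DemographyModel.two_epoch(int(dem_doc["n_ancestral"]),
                                        int(dem_doc["n_current"]),
                                        int(dem_doc["duration"]))
    else:
        dem = DemographyModel(epochs=[(int(s), int(d))
                                      for s, d in dem_doc["epochs"]])
    sel_doc = doc.get("selection", {})
    sel = SelectionModel(**{k: float(v) for k, v in sel_doc.items()})
    return SimulationConfig(
        demography=dem,
        selection=sel,
        mutation_rate=float(doc.get("mutation_rate", 1.8e-8)),
        locus_length=int(doc.get("locus_length", 1500)),
        rescale=float(doc.get("rescale", 1.0)),
        n_pools=int(doc.get("n_pools", 100)),
    )


def load_simulation_config(path: str) -> SimulationConfig:
    with open(path) as fh:
        return _parse(yaml.safe_load(fh))


def builtin_simulation_config(name: str = "aa_two_epoch") -> SimulationConfig:
    """Load a shipped config (``aa_two_epoch`` or ``ea_bottleneck``)."""
    ref = importlib.resources.files("kbac.configs").joinpath(f"{name}.yaml")
    return _parse(yaml.safe_load(ref.read_text()))
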
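"""Shipped spread-graph fixtures, modality registry and reference parameters.

The reference parameter set holds the posterior-mean spread probabilities
from a fit of the evidence-maximizing ("winning") graph to a 686-patient
multi-institutional oropharyngeal-cancer cohort.  They let risk predictions
be made out of the box without re-running MCMC.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .graph import ModelParams, SpreadGraph, base_graph, winning_graph
from .likelihood import MODALITIES, DataError, Modality

__all__ = [
    "base_graph",
    "winning_graph",
    "load_graph",
    "load_modalities",
    "load_scenarios",
    "reference_params",
    "REFERENCE_PARAM_STDS",
]


def _data_path(*parts: str):
    return resources.files("lyspread").joinpath("data", *parts)


def load_graph(name_or_path: str | Path) -> SpreadGraph:
    """Load a spread graph: a shipped fixture name ("base", "winning") or a
    YAML file path with a node -> children mapping."""
    if str(name_or_path) in ("base", "winning"):
        with resources.as_file(_data_path("graphs", f"{name_or_path}.yaml")) as p:
            return SpreadGraph.from_yaml(p)
    return SpreadGraph.from_yaml(name_or_path)


def load_modalities(path: str | Path | None = None) -> dict[str, Modality]:
    """Modality registry (name -> sensitivity/specificity), from a YAML file
    or the shipped literature values."""
    if path is None:
        return dict(MODALITIES)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    registry = {}
    for name, spec in raw.items():
        try:
            registry[name] = Modality(name, spec["sensitivity"], spec["specificity"])
        except (KeyError, TypeError) as err:
            raise DataError(f"modality {name!r}: need sensitivity and specificity") from err
    return registry


def load_scenarios(
    lnl_names: tuple[str, ...] | None = None,
) -> dict[str, dict[str, int]]:
    """Shipped clinical-diagnosis scenarios as complete ternary patterns."""
    raw = yaml.safe_load(_data_path("scenarios.yaml").read_text())
    names = lnl_names or winning_graph().lnl_names
    scenarios = {}
    for label, spec in raw.items():
        involved = set(spec.get("involved", []))
        unknown = sorted(involved - set(names))
        if unknown:
            raise DataError(f"scenario {label!r} references unknown levels {unknown}")
        scenarios[label] = {lvl: (1 if lvl in involved else 0) for lvl in names}
    return scenarios


_REFERENCE_MEANS = {
    "b": {"I": 0.0265, "II": 0.3767, "III": 0.081, "IV": 0.011, "V": 0.0213, "VII": 0.0216},
    "t": {
        ("I", "II"): 0.6676,
        ("II", "III"): 0.0949,
        ("III", "IV"): 0.1448,
        ("IV", "V"): 0.1457,
    },
    "p_late": 0.3834,
}

#: Posterior standard deviations accompanying the reference means.
REFERENCE_PARAM_STDS = {
    "b_I": 0.0031, "b_II": 0.0181, "b_III": 0.0126, "b_IV": 0.0024,
    "b_V": 0.0028, "b_VII": 0.0031,
    "t_I->II": 0.2137, "t_II->III": 0.0304, "t_III->IV": 0.0243,
    "t_IV->V": 0.0529, "p_late": 0.0226,
}


def reference_params(p_early: float = 0.3, t_max: int = 10) -> ModelParams:
    """Posterior-mean parameters of the winning graph (multi-institutional
    OPSCC fit); valid for :func:`winning_graph`."""
    return ModelParams(
        b=dict(_REFERENCE_MEANS["b"]),
        t=dict(_REFERENCE_MEANS["t"]),
        p_late=_REFERENCE_MEANS["p_late"],
        p_early=p_early,
        t_max=t_max,
    )
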
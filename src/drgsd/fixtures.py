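"""Packaged scenario fixtures.

Two parameter sets ship with the package so that every analysis can run
offline: the worked example (a two-arm schizophrenia trial with a delayed
continuous endpoint, planned at a fixed-design total of 690 patients) and
the default comparison grid of parameter constellations.
"""

from __future__ import annotations

import json
from importlib import resources

from .design import DesignSpec

__all__ = [
    "load_practical_example",
    "load_scenario_grid_config",
    "load_example_reference",
]


def _load(name: str) -> dict:
    with resources.files("drgsd.data").joinpath(name).open() as fh:
        return json.load(fh)


def load_practical_example() -> tuple[DesignSpec, float]:
    """(design spec, assumed effect) of the packaged worked example.

    The design kind of the returned spec is GSD; use
    :meth:`DesignSpec.with_kind` for the delayed-response variants.
    """
    cfg = _load("practical_example.json")
    return DesignSpec.from_config(cfg["design"]), float(cfg["delta"])


def load_scenario_grid_config() -> dict:
    """Raw configuration of the default comparison grid."""
    return _load("scenario_grid.json")


def load_example_reference() -> dict:
    """Published reference values for the worked example (regression anchor)."""
    return _load("example_reference.json")
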
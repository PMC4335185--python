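"""Bundled attention-to-visual-motion network fixtures.

Two three-region models (V1, V5, SPC) driven by a Photic input with Motion
and Attention modulations: the *forward* variant has both modulations on the
forward connection V1 -> V5; the *backward* variant moves one of them to the
backward connection SPC -> V5.  Parameter values are documented plausible
choices, versioned in the bundled YAML configs — they are not estimates from
any real dataset (the original study's estimates are not public), so
quantities computed from these fixtures characterize the method, not the
original recordings.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .io import design_from_config, load_config, model_from_config
from .model import DCMModel, DesignSpec, ParameterVector

__all__ = ["Fixture", "load_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("forward", "backward")


@dataclass
class Fixture:
    name: str
    model: DCMModel
    default_params: ParameterVector
    default_design: DesignSpec
    snr: float
    seed: int
    note: str = (
        "rule-generated stimulus train and documented plausible parameter "
        "values; not estimates from real data"
    )


def load_fixture(name: str) -> Fixture:
    """Load a bundled fixture by name ('forward' or 'backward')."""
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture '{name}'; available fixtures: "
            + ", ".join(FIXTURE_NAMES)
        )
    path = resources.files("dcmident.data").joinpath(f"{name}.yaml")
    with resources.as_file(path) as p:
        cfg = load_config(p)
    model = model_from_config(cfg)
    design = design_from_config(cfg)
    return Fixture(
        name=name,
        model=model,
        default_params=model.pack(),
        default_design=design,
        snr=float(cfg.get("snr", 10.0)),
        seed=int(cfg.get("seed", 0)),
    )
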
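"""Bundled experiment presets (design + default observer).

``exp1`` and ``exp2`` are the color- and letter-flanker experiments: five
sessions of nine 132-trial blocks per participant (5,940 trials each), gaps
0-950 ms in 11 steps, no SOA, and a no-dip observer (the incongruent rise is
merely delayed). ``exp3`` is the processing-asymmetry experiment: five
sessions of four 264-trial blocks (5,280 trials), SOA of 0 or 120 ms, and an
observer whose dip depth is calibrated so the generative incongruent curve
(SOA > 0) bottoms out at 0.16 around 400 ms.

A preset file is a small YAML tree with ``design`` and ``observer``
sections; the observer may give ``dip_target_min`` instead of a literal
``dip_depth``, in which case the depth is solved at load time.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .design import DesignSpec
from .observer import ObserverModel, calibrate_dip_depth

__all__ = ["PRESET_NAMES", "load_preset", "load_config_file"]

PRESET_NAMES = ("exp1", "exp2", "exp3")


def _build(cfg: dict) -> tuple[DesignSpec, ObserverModel]:
    spec = DesignSpec.from_dict(cfg.get("design", {}))
    obs = dict(cfg.get("observer", {}))
    target_min = obs.pop("dip_target_min", None)
    model = ObserverModel.from_dict(obs)
    if target_min is not None:
        model = calibrate_dip_depth(model, float(target_min))
    return spec, model


def load_preset(name: str) -> tuple[DesignSpec, ObserverModel]:
    """Load one of the bundled presets by name (exp1 / exp2 / exp3)."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    text = resources.files("tachometric").joinpath(f"presets/{name}.yaml").read_text()
    return _build(yaml.safe_load(text))


def load_config_file(path) -> tuple[DesignSpec, ObserverModel]:
    """Load a user-supplied design/observer config (same YAML layout)."""
    with open(path) as fh:
        return _build(yaml.safe_load(fh))
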
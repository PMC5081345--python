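"""Structured configuration files bundling parameters and kinetics.

One YAML file carries the full model definition: the membrane parameters
(densities, reversals, geometry) and the channel-kinetics
parameterization including the identifier of the HCN time-constant
parse, so that every scan and measurement is reproducible from the
config alone.
"""

from __future__ import annotations

import yaml

from .kinetics import ChannelKinetics, KineticsError
from .parameters import ModelParameters

__all__ = ["save_config", "load_config"]


def save_config(path, params: ModelParameters,
                kinetics: ChannelKinetics | None = None) -> None:
    kinetics = kinetics if kinetics is not None else ChannelKinetics()
    payload = {
        "model_parameters": params.to_dict(),
        "channel_kinetics": kinetics.to_dict(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path) -> tuple[ModelParameters, ChannelKinetics]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not data or "model_parameters" not in data:
        raise KineticsError(f"{path}: missing 'model_parameters' section")
    params = ModelParameters.from_dict(data["model_parameters"])
    if "channel_kinetics" not in data:
        raise KineticsError(f"{path}: missing 'channel_kinetics' section")
    kinetics = ChannelKinetics.from_dict(data["channel_kinetics"])
    return params, kinetics
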
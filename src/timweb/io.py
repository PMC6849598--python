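"""Model serialisation (YAML/JSON) and tabular export.

Model exchange schema
---------------------
A model file is a mapping with four top-level keys mirroring the domain
types field for field:

``species``
    list of ``{id, role, intrinsic_rate, self_limitation, name}``
``links``
    list of ``{resource_id, consumer_id, fr_form, attack_rate,
    handling_time, interference, conversion_efficiency}``
``tims``
    list of ``{tim_id, modifier_id, target: [resource_id, consumer_id],
    affected_parameter, form, strength, form_params, mode,
    forced_density}``
``species_order``
    list of species ids fixing the vector/matrix index assignment

Files ending in ``.json`` are JSON; anything else is YAML.  Floats are
written at full precision so read -> write -> read is lossless, and all
invariant violations found while loading are reported together.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .exceptions import ModelValidationError
from .model_core import CommunityModel

__all__ = ["load_model", "save_model", "model_to_text", "model_from_text"]


def model_to_text(model: CommunityModel, fmt: str = "yaml") -> str:
    d = model.to_dict()
    if fmt == "json":
        return json.dumps(d, indent=2, sort_keys=False) + "\n"
    return yaml.safe_dump(d, sort_keys=False)


def model_from_text(text: str, fmt: str = "yaml") -> CommunityModel:
    d = json.loads(text) if fmt == "json" else yaml.safe_load(text)
    if not isinstance(d, dict):
        raise ModelValidationError(["model file must contain a mapping at top level"])
    unknown = set(d) - {"species", "links", "tims", "species_order"}
    if unknown:
        raise ModelValidationError([f"unknown top-level keys: {sorted(unknown)}"])
    for key in ("species", "links"):
        if key not in d:
            raise ModelValidationError([f"missing required top-level key {key!r}"])
    try:
        return CommunityModel.from_dict(d)
    except ModelValidationError:
        raise
    except (KeyError, TypeError, ValueError, IndexError) as e:
        raise ModelValidationError([f"malformed model file: {type(e).__name__}: {e}"]) from e


def _fmt_for(path: Path) -> str:
    return "json" if path.suffix.lower() == ".json" else "yaml"


def load_model(path) -> CommunityModel:
    """Read and validate a model file (YAML or JSON by extension)."""
    p = Path(path)
    return model_from_text(p.read_text(), fmt=_fmt_for(p))


def save_model(model: CommunityModel, path) -> None:
    p = Path(path)
    p.write_text(model_to_text(model, fmt=_fmt_for(p)))
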
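"""Loader for the versioned defaults file (constants, potentials, weights)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Any

import yaml


@lru_cache(maxsize=1)
def load_defaults() -> dict[str, Any]:
    text = resources.files("aomflux.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def default_parameters() -> dict[str, float]:
    return dict(load_defaults()["parameters"])
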
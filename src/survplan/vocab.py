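"""Closed code vocabularies (organs, radiotherapy fields, agents).

The code lists live in ``data/vocabulary.yaml`` and are versioned; unknown
codes are rejected by the validators, never silently coerced.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=1)
def _vocab() -> dict:
    text = resources.files("survplan.data").joinpath("vocabulary.yaml").read_text()
    return yaml.safe_load(text)


def vocabulary_version() -> str:
    return str(_vocab()["version"])


@lru_cache(maxsize=1)
def organs() -> frozenset[str]:
    return frozenset(_vocab()["organs"])


@lru_cache(maxsize=1)
def fields() -> frozenset[str]:
    return frozenset(_vocab()["fields"])


@lru_cache(maxsize=1)
def organ_systems() -> frozenset[str]:
    return frozenset(_vocab()["organ_systems"])


@lru_cache(maxsize=1)
def agents() -> frozenset[str]:
    return frozenset(_vocab()["agents"])


@lru_cache(maxsize=1)
def mg_per_kg_agents() -> frozenset[str]:
    """Agents whose cumulative dose is conventionally tracked in mg/kg."""
    return frozenset(_vocab()["mg_per_kg_agents"])


def default_units(agent: str) -> str:
    return "mg/kg" if agent in mg_per_kg_agents() else "mg/m2"
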
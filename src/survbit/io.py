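"""Configuration and strategy file handling.

Config files are YAML or JSON mappings with keys ``q01``, ``q10``, ``p01``,
``p11``, ``K`` (or raw ``k`` and ``c``) and ``S`` (list indexed from depth
0; or raw ``s`` together with ``c``).  Raw costs are normalized by ``c`` at
parse time, so the rest of the library only ever sees dimensionless values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .models import (
    ConfigurationError,
    CostModel,
    DetectorModel,
    ModelBundle,
    Strategy,
    SystemModel,
)

__all__ = ["load_config", "build_bundle", "load_strategy", "dump_strategy"]

_MODEL_KEYS = frozenset({"q01", "q10", "p01", "p11", "K", "k", "c", "S", "s"})


def load_config(path) -> dict:
    """Load a YAML/JSON config mapping, rejecting unknown keys."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"config {path} must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _MODEL_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return dict(data)


def build_bundle(params: Mapping) -> ModelBundle:
    """Resolve a parameter mapping into a :class:`ModelBundle`.

    Normalized costs (``K``, ``S``) and raw ones (``k``, ``c``, ``s``) are
    both accepted; mixing is allowed only where unambiguous.
    """
    missing = [key for key in ("q01", "q10", "p01", "p11") if params.get(key) is None]
    if missing:
        raise ConfigurationError(f"missing required parameters: {missing}")
    system = SystemModel(q01=params["q01"], q10=params["q10"])
    detector = DetectorModel(p01=params["p01"], p11=params["p11"])

    K, k, c = params.get("K"), params.get("k"), params.get("c")
    if K is None:
        if k is None or c is None:
            raise ConfigurationError("provide K, or raw costs k and c")
        if c <= 0:
            raise ConfigurationError(f"c must be positive, got {c!r}")
        K = k / c
    elif k is not None:
        raise ConfigurationError("provide either K or raw k, not both")

    S, s_raw = params.get("S"), params.get("s")
    if S is not None and s_raw is not None:
        raise ConfigurationError("provide either S or raw s, not both")
    if S is None:
        if s_raw is not None:
            if c is None or c <= 0:
                raise ConfigurationError("raw surveillance costs s require a positive c")
            S = tuple(si / c for si in s_raw)
        else:
            S = (0.0,)
    else:
        S = tuple(float(si) for si in S)
    return ModelBundle(system=system, detector=detector, costs=CostModel(K=K, S=S))


def load_strategy(source: str) -> Strategy:
    """Load a strategy from a JSON file path or an inline spec like ``n=1:01``."""
    path = Path(source)
    if path.suffix == ".json" or path.is_file():
        with open(path) as fh:
            return Strategy.from_dict(json.load(fh))
    return Strategy.from_spec(source)


def dump_strategy(strategy: Strategy, path) -> None:
    with open(path, "w") as fh:
        json.dump(strategy.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
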
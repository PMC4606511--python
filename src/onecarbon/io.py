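"""Configuration loading/validation and result serialization.

Configs are flat YAML mappings ``reaction.parameter -> value`` (numbers, in
the registry's units) plus an optional ``config_version`` field.  Results
are written as tidy CSV tables with a JSON metadata sidecar carrying the
full parameter echo, the software version, the seed and the toggle state, so
a run can be reproduced from its output directory alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .params import PARAMETER_REGISTRY, ParameterSet, default_parameters

__all__ = ["load_config", "save_config", "apply_overrides", "write_results"]

CONFIG_VERSION = 1


def load_config(path: str | Path | None = None) -> ParameterSet:
    """Load and validate a parameter config; defaults when ``path`` is None.

    Raises ``ValueError`` listing every missing, unknown or out-of-range
    parameter.
    """
    if path is None:
        return default_parameters()
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} does not contain a mapping")
    raw.pop("config_version", None)
    return ParameterSet(raw)


def save_config(p: ParameterSet, path: str | Path) -> None:
    """Write a config that round-trips through :func:`load_config`."""
    lines = [f"config_version: {CONFIG_VERSION}"]
    for key in sorted(PARAMETER_REGISTRY):
        _, unit, desc = PARAMETER_REGISTRY[key]
        lines.append(f"{key}: {p[key]!r}  # [{unit}] {desc}")
    Path(path).write_text("\n".join(lines) + "\n")


def apply_overrides(p: ParameterSet, overrides: Mapping[str, float]) -> ParameterSet:
    """Apply ``key=value`` overrides; unknown keys raise with the offender
    named."""
    return p.with_updates(overrides)


def write_results(
    tables: Mapping[str, pd.DataFrame],
    directory: str | Path,
    p: ParameterSet,
    *,
    seed: int | None = None,
    lri: bool = True,
    extra_meta: Mapping | None = None,
) -> None:
    """Write each table as ``<name>.csv`` plus ``metadata.json``."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    meta = {
        "software": "onecarbon",
        "version": __version__,
        "config_version": CONFIG_VERSION,
        "seed": seed,
        "lri": lri,
        "parameters": p.to_flat(),
    }
    if extra_meta:
        meta.update(extra_meta)
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
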
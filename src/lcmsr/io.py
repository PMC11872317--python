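"""CSV and configuration file handling.

Long format is canonical on disk: one row per person x wave with columns
``person_id, wave, fi, ls[, covariates...]`` and empty cells for missing
values. Wide tables (``FI1..FI14, LS1..LS14``) are the in-memory layout
used by the estimator; readers auto-pivot on the presence of a ``wave``
column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_spec import (
    ModelSpec,
    add_time_varying_covariate,
    build_bivariate,
    build_univariate,
)
from .synthetic import to_wide

__all__ = ["read_panel", "write_results", "load_model_config", "build_from_config"]


def read_panel(path: str | Path, variables=("fi", "ls")) -> pd.DataFrame:
    """Read a panel CSV; long input (with a ``wave`` column) is pivoted wide."""
    df = pd.read_csv(path)
    if "wave" in df.columns:
        present = [v for v in variables if v in df.columns]
        if not present:
            raise ValueError(f"long panel lacks variable columns {variables}")
        return to_wide(df, variables=tuple(present))
    return df


def load_model_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def build_from_config(cfg: dict) -> ModelSpec:
    """Build a ModelSpec from a declarative configuration mapping.

    Keys: ``constructs`` (list of names), ``n_waves``, ``bursts`` (list of
    [first, last] wave ranges), ``levels`` (construct -> 1..4),
    ``bivariate`` (bool), ``covariates`` (list of {name, target}).
    """
    constructs = cfg["constructs"]
    n_waves = int(cfg.get("n_waves", 14))
    ranges = cfg.get("bursts")
    if ranges is not None:
        bursts = [list(range(int(a), int(b) + 1)) for a, b in ranges]
    else:
        bursts = None
    levels = cfg.get("levels", {})
    specs = [
        build_univariate(c, int(levels.get(c, 2)), n_waves, bursts) for c in constructs
    ]
    if len(specs) == 1:
        spec = specs[0]
    elif len(specs) == 2 and cfg.get("bivariate", True):
        spec = build_bivariate(specs[0], specs[1])
    else:
        raise ValueError("config must name one construct, or two with bivariate: true")
    for cov in cfg.get("covariates", []) or []:
        spec = add_time_varying_covariate(spec, cov["name"], cov.get("target", "both"))
    return spec


def write_results(result, out_dir: str | Path, stem: str = "fit") -> None:
    """Write one fit as JSON (full) and CSV (flat parameter table)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"{stem}.json", "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
    if hasattr(result, "parameter_table"):
        result.parameter_table().to_csv(out / f"{stem}_parameters.csv", index=False)
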
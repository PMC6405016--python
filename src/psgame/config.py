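"""Configuration resolution and report serialization for the CLI.

Configs are flat ``key: value`` text (a YAML subset).  Recognised keys are
the model parameters (``lambda1 lambda2 alpha11 alpha12 alpha21 alpha22
gamma1 gamma2 theta G``) plus ``scenario`` and ``scrounger_theft``.
Precedence is flags > file > defaults, where the defaults are the field
baseline (lambda=0.6, gamma1=1.002, gamma2=1.914, theta=0.5, G=15) with
scenario A's stealing table.  Explicit alpha values override a scenario
preset, with a logged warning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .asymmetric import SCENARIOS, AsymmetricParams

__all__ = ["load_config", "write_report", "to_jsonable"]

log = logging.getLogger("psgame")

_PARAM_KEYS = {
    "lambda1": "lam1",
    "lambda2": "lam2",
    "alpha11": "alpha11",
    "alpha12": "alpha12",
    "alpha21": "alpha21",
    "alpha22": "alpha22",
    "gamma1": "gamma1",
    "gamma2": "gamma2",
    "theta": "theta",
    "G": "G",
    "scrounger_theft": "scrounger_theft",
}
_ALPHA_KEYS = ("alpha11", "alpha12", "alpha21", "alpha22")


def load_config(
    path: str | Path | None = None,
    scenario: str | None = None,
    **flag_overrides,
) -> AsymmetricParams:
    """Resolve an AsymmetricParams from a config file and/or flag overrides.

    ``flag_overrides`` uses the config-file key names; ``None`` values are
    treated as unset.  Unknown or out-of-range keys raise ValueError
    listing every offender.  The fully resolved parameters are echoed to
    the log.
    """
    file_values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} is not a flat key: value mapping")
        file_values = dict(raw)

    flag_values = {k: v for k, v in flag_overrides.items() if v is not None}
    merged = {**file_values, **flag_values}

    scenario = merged.pop("scenario", scenario)
    errors = [
        f"unknown key {k!r}" for k in merged if k not in _PARAM_KEYS
    ]
    if errors:
        raise ValueError("; ".join(errors))

    kwargs: dict = {}
    if scenario is not None:
        key = str(scenario).upper()
        if key not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {scenario!r}; choose from {sorted(SCENARIOS)}"
            )
        preset = dict(zip(_ALPHA_KEYS, SCENARIOS[key]))
        clashes = [k for k in _ALPHA_KEYS if k in merged and merged[k] != preset[k]]
        if clashes:
            log.warning(
                "explicit %s override scenario %s preset", ", ".join(clashes), key
            )
        for k, v in preset.items():
            merged.setdefault(k, v)

    for k, v in merged.items():
        kwargs[_PARAM_KEYS[k]] = v

    try:
        params = AsymmetricParams(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
    log.info("resolved parameters: %s", params)
    return params


def to_jsonable(obj):
    """Recursively convert dataclasses / arrays / numpy scalars for JSON."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):  # numpy array or scalar
        return to_jsonable(obj.tolist())
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    return obj


def write_report(result, path: str | Path | None, fmt: str = "json") -> None:
    """Serialize a result to JSON (stable key order, 12 significant digits)
    or CSV (DataFrames; one row per record).  ``path`` None means stdout.
    """
    if fmt == "csv":
        if not isinstance(result, pd.DataFrame):
            raise TypeError("csv output requires a DataFrame result")
        out = result.to_csv(index=False)
    elif fmt == "json":
        out = json.dumps(to_jsonable(result), indent=2) + "\n"
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if path is None:
        print(out, end="")
    else:
        Path(path).write_text(out, encoding="utf-8")
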
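"""Configuration parsing, shipped example fixtures and structured output.

The configuration file (YAML, of which JSON is a subset) has five
sections::

    growth:    {form: <name>, params: {...}}
    incidence: {form: <name>, params: {...}}
    removals:  {g1: {form: <name>, params: {...}}, g2: ..., g3: ..., g4: ...}
    rates:     {a, b, c, k, u, p, q, r, h, m1, m2}
    delays:    {tau1, tau2, tau3}

Unknown keys anywhere are errors; all schema violations found in one pass
are reported together.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .forms import FormError
from .model import ModelSpec, RateParameters

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "parse_config",
    "example_model",
    "fixture_path",
    "write_json",
    "write_trajectory_csv",
    "write_scan_csv",
    "read_scan_csv",
]

_RATE_KEYS = ("a", "b", "c", "k", "u", "p", "q", "r", "h", "m1", "m2")
_DELAY_KEYS = ("tau1", "tau2", "tau3")
_TOP_KEYS = ("growth", "incidence", "removals", "rates", "delays", "run")
_RUN_KEYS = ("t_end", "step", "history", "transient_fraction")


class ConfigError(ValueError):
    """Schema violation(s) in a model configuration."""


@dataclass(frozen=True)
class RunConfig:
    """A validated model plus optional simulation defaults."""

    model: ModelSpec
    t_end: float = 1000.0
    step: float | None = None
    history: tuple[float, ...] | None = None
    transient_fraction: float = 0.7


def parse_config(doc: dict) -> RunConfig:
    errors: list[str] = []
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    for key in doc:
        if key not in _TOP_KEYS:
            errors.append(f"unknown top-level key {key!r}")
    for key in ("growth", "incidence", "removals", "rates", "delays"):
        if key not in doc:
            errors.append(f"missing section {key!r}")
    if errors:
        raise ConfigError("; ".join(errors))

    def section_form(sec: dict, where: str) -> tuple[str, dict]:
        for key in sec:
            if key not in ("form", "params"):
                errors.append(f"{where}: unknown key {key!r}")
        if "form" not in sec:
            errors.append(f"{where}: missing 'form'")
            return "", {}
        return sec["form"], sec.get("params", {}) or {}

    g_form, g_params = section_form(doc["growth"], "growth")
    f_form, f_params = section_form(doc["incidence"], "incidence")

    removals = []
    rem = doc["removals"]
    for key in rem:
        if key not in ("g1", "g2", "g3", "g4"):
            errors.append(f"removals: unknown key {key!r}")
    for gname in ("g1", "g2", "g3", "g4"):
        if gname not in rem:
            errors.append(f"removals: missing {gname!r}")
            continue
        form, params = section_form(rem[gname], f"removals.{gname}")
        removals.append((form, params))

    rates_doc = dict(doc["rates"])
    for key in rates_doc:
        if key not in _RATE_KEYS:
            errors.append(f"rates: unknown key {key!r}")
    for key in _RATE_KEYS:
        if key not in rates_doc:
            errors.append(f"rates: missing {key!r}")
    delays_doc = dict(doc["delays"])
    for key in delays_doc:
        if key not in _DELAY_KEYS:
            errors.append(f"delays: unknown key {key!r}")
    for key in _DELAY_KEYS:
        if key not in delays_doc:
            errors.append(f"delays: missing {key!r}")
        elif float(delays_doc[key]) < 0.0:
            errors.append(f"delays: {key} = {delays_doc[key]} is negative")
    if errors:
        raise ConfigError("; ".join(errors))

    try:
        rates = RateParameters(**{k: float(rates_doc[k]) for k in _RATE_KEYS},
                               **{k: float(delays_doc[k]) for k in _DELAY_KEYS})
        model = ModelSpec.build(g_form, g_params, f_form, f_params,
                                [(form, params) for form, params in removals],
                                rates)
    except (FormError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    run = doc.get("run", {}) or {}
    for key in run:
        if key not in _RUN_KEYS:
            errors.append(f"run: unknown key {key!r}")
    if errors:
        raise ConfigError("; ".join(errors))
    history = run.get("history")
    if history is not None:
        history = tuple(float(v) for v in history)
        if len(history) != 5:
            raise ConfigError("run.history must have 5 entries (x, y, v, z, w)")
    return RunConfig(
        model,
        t_end=float(run.get("t_end", 1000.0)),
        step=float(run["step"]) if "step" in run else None,
        history=history,
        transient_fraction=float(run.get("transient_fraction", 0.7)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON model configuration file."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parse_config(doc)


def fixture_path(name: str) -> Path:
    """Path of a shipped example configuration ('example17'/'example18')."""
    ref = resources.files("virodyn") / "fixtures" / f"{name}.yaml"
    return Path(str(ref))


def example_model(name: str) -> ModelSpec:
    """Load one of the two shipped worked-example models."""
    return load_config(fixture_path(name)).model


# --------------------------------------------------------------------------
# structured outputs
# --------------------------------------------------------------------------

def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_trajectory_csv(traj, path: str | Path) -> None:
    """CSV with columns t, x, y, v, z, w at full precision."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "x", "y", "v", "z", "w"])
        for i, t in enumerate(traj.t):
            writer.writerow([repr(float(t))] +
                            [repr(float(val)) for val in traj.states[:, i]])


def write_scan_csv(result, path: str | Path) -> None:
    cols = ["tau3", "amplitude_x", "amplitude_y", "amplitude_v",
            "amplitude_z", "amplitude_w", "period", "classification"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for tau3, rep in zip(result.tau3_grid, result.reports):
            row = [repr(float(tau3))]
            row += [repr(float(a)) for a in rep.amplitudes]
            row.append(repr(float(rep.period)) if rep.period is not None else "")
            row.append(rep.classification)
            writer.writerow(row)


def read_scan_csv(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))
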
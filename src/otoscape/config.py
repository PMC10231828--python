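"""YAML configuration schema and run manifests.

One YAML file with sections ``baseline``, ``ensemble``, ``isoscape``,
``assignment``, ``synthetic`` drives the whole pipeline; unknown keys are
rejected so typos fail loudly. Defaults mirror the framework's standard
choices (abstention threshold 0.7, binarization quantile 0.75, 10 CV
folds, member accuracy cutoff 0.76, May–Jul / Jun–Aug seasons, error
components 0.1 / 0.29 ‰).
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "baseline": {
        "seed": 0,
        "max_baseline_age": {"southern": 1, "northern": 2},
        "equalize_year_classes": False,
        "strict_year_class": True,
    },
    "ensemble": {
        "folds": 10,
        "seed": 0,
        "accuracy_cutoff": 0.76,
        "top_k": None,
        "threshold": 0.7,
        "classifiers": None,   # None = full registry
        "grids": None,         # per-classifier overrides
    },
    "isoscape": {
        "gamma": -0.25,
        "beta": 4.46,
        "strict_months": True,
    },
    "assignment": {
        "sigma_analytical": 0.1,
        "sigma_within_pop": 0.29,
        "quantile": 0.75,
        "sweep_floor": 0.7,
    },
    "synthetic": {
        "seed": 0,
        "year_classes": [2013, 2014, 2015],
        "n_per_cell": 30,
        "n_adults_per_year_class": 40,
        "n_validation_fish": 100,
    },
}


class ConfigError(ValueError):
    """Raised on schema violations in the YAML config."""


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in user.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(defaults[key], dict) and isinstance(val, dict) \
                and key not in ("grids", "max_baseline_age"):
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Load and validate a YAML config, filling defaults. ``None`` gives
    pure defaults."""
    if path is None:
        return json.loads(json.dumps(DEFAULTS))
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return _merge(DEFAULTS, raw)


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run, sufficient to re-run identically."""

    config: dict
    inputs: dict = dc_field(default_factory=dict)     # path -> sha256
    outputs: dict = dc_field(default_factory=dict)    # path -> sha256
    timings: dict = dc_field(default_factory=dict)    # stage -> seconds
    warnings: list = dc_field(default_factory=list)   # (stage, message)
    versions: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if not self.versions:
            import numpy, pandas, sklearn, xarray

            from . import __version__

            self.versions = {
                "otoscape": __version__,
                "python": platform.python_version(),
                "numpy": numpy.__version__,
                "pandas": pandas.__version__,
                "scikit-learn": sklearn.__version__,
                "xarray": xarray.__version__,
            }

    def add_input(self, path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = file_digest(path)

    def warn(self, stage: str, message: str) -> None:
        self.warnings.append({"stage": stage, "message": message})

    def timed(self, stage: str):
        """Context manager recording a stage's wall time."""
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                manifest.timings[stage] = round(
                    time.perf_counter() - self.t0, 3)
                return False

        return _Timer()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps({
            "config": self.config,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "timings": self.timings,
            "warnings": self.warnings,
            "versions": self.versions,
        }, indent=2, default=str))
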
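"""Layered run configuration: built-in defaults ← INI file ← CLI flags.

The config file is flat INI with sections mirroring the pipeline stages::

    [filter]
    cutoff_hz = 60
    order = 4
    zero_phase = true

    [detect]
    rest_threshold_ms2 = 1.0
    min_rest_duration_s = 0.08
    min_stop_overlap_s = 1.0

    [dwa]
    foot_combine = mean

    [mla]
    step_convention = stride_per_two_steps

Unknown sections or keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import configparser
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .preprocess import FilterParams
from .stance import DetectionParams

__all__ = ["RunConfig", "load_config"]

_SCHEMA: dict[str, dict[str, type]] = {
    "filter": {"cutoff_hz": float, "order": int, "zero_phase": bool},
    "detect": {
        "rest_threshold_ms2": float,
        "min_rest_duration_s": float,
        "min_stop_overlap_s": float,
    },
    "dwa": {"foot_combine": str},
    "mla": {"step_convention": str},
}


@dataclass
class RunConfig:
    """All tunable parameters of a run, with a complete echo for outputs."""

    filter: FilterParams = field(default_factory=FilterParams)
    detect: DetectionParams = field(default_factory=DetectionParams)
    foot_combine: str = "mean"
    step_convention: str = "stride_per_two_steps"

    def echo(self) -> dict:
        return {
            "filter": asdict(self.filter),
            "detect": asdict(self.detect),
            "dwa": {"foot_combine": self.foot_combine},
            "mla": {"step_convention": self.step_convention},
        }


def _coerce(raw: str, typ: type, where: str):
    if typ is bool:
        lowered = raw.strip().lower()
        if lowered in ("1", "true", "yes", "on"):
            return True
        if lowered in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"{where}: cannot parse {raw!r} as a boolean")
    return typ(raw)


def load_config(path: str | Path | None) -> RunConfig:
    """Parse an INI config file into a :class:`RunConfig`.

    ``None`` returns the built-in defaults.  Unknown sections/keys raise
    ``ValueError``.
    """
    cfg = RunConfig()
    if path is None:
        return cfg
    parser = configparser.ConfigParser()
    read = parser.read(Path(path))
    if not read:
        raise FileNotFoundError(f"config file not found: {path}")
    values: dict[str, dict] = {}
    for section in parser.sections():
        if section not in _SCHEMA:
            raise ValueError(f"unknown config section [{section}]")
        values[section] = {}
        for key, raw in parser.items(section):
            if key not in _SCHEMA[section]:
                raise ValueError(f"unknown config key {key!r} in [{section}]")
            values[section][key] = _coerce(raw, _SCHEMA[section][key], f"[{section}] {key}")
    if "filter" in values:
        cfg.filter = FilterParams(**{**asdict(cfg.filter), **values["filter"]})
    if "detect" in values:
        cfg.detect = DetectionParams(**{**asdict(cfg.detect), **values["detect"]})
    cfg.foot_combine = values.get("dwa", {}).get("foot_combine", cfg.foot_combine)
    cfg.step_convention = values.get("mla", {}).get(
        "step_convention", cfg.step_convention
    )
    return cfg
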
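"""Run configuration: validated parameters for every CLI command.

A RunConfig collects the game, feedback and timescale parameters together
with command-specific settings (initial condition, duration, tolerances,
grid resolution, sweep ranges). Files may be YAML or JSON; flags override
file values; presets seed the game/feedback/eps blocks. Unknown keys are
rejected by name so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .dynamics import CoupledSystem, FeedbackSpec
from .game import GameParams
from .presets import preset_config

__all__ = ["RunConfig", "load_config"]

_GAME_KEYS = {"N", "M", "b", "c"}
_FEEDBACK_KEYS = {"variant", "u", "T", "beta"}


@dataclass
class RunConfig:
    """Validated configuration for one toolkit run."""

    game: dict
    feedback: dict
    eps: float = 0.1
    # simulate
    x0: float = 0.4
    r0: float = 0.3
    t_max: float = 2000.0
    rtol: float = 1e-10
    atol: float = 1e-10
    # basins
    grid_resolution: int = 11
    basin_t_max: float = 2000.0
    # regions sweep
    sweep_param_min: float = 0.1
    sweep_param_max: float = 5.0
    sweep_param_steps: int = 25
    sweep_cb_min: float = 0.02
    sweep_cb_max: float = 0.4
    sweep_cb_steps: int = 20
    # bifurcation
    ladder_points: int = 5
    ladder_span: float = 1e-3
    ladder_t_max: float = 2000.0

    def __post_init__(self) -> None:
        bad = set(self.game) - _GAME_KEYS
        if bad:
            raise ValueError(f"unknown game key(s): {', '.join(sorted(bad))}")
        bad = set(self.feedback) - _FEEDBACK_KEYS
        if bad:
            raise ValueError(f"unknown feedback key(s): "
                             f"{', '.join(sorted(bad))}")
        # constructing the domain objects enforces every model invariant
        self.system()
        if not (0 <= self.x0 <= 1 and 0 <= self.r0 <= 1):
            raise ValueError(f"initial condition ({self.x0}, {self.r0}) "
                             "must lie in [0,1]^2")
        if self.t_max <= 0 or self.basin_t_max <= 0 or self.ladder_t_max <= 0:
            raise ValueError("durations must be positive")
        if self.grid_resolution < 2:
            raise ValueError("grid_resolution must be >= 2")

    def game_params(self) -> GameParams:
        return GameParams(**self.game)

    def feedback_spec(self) -> FeedbackSpec:
        return FeedbackSpec(**self.feedback)

    def system(self) -> CoupledSystem:
        return CoupledSystem(game=self.game_params(),
                             feedback=self.feedback_spec(), eps=self.eps)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _read_file(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def _apply_override(cfg: dict, key: str, value: str) -> None:
    """Apply one dotted override like game.N=8 or eps=0.5."""
    parts = key.split(".")
    target = cfg
    for p in parts[:-1]:
        target = target.setdefault(p, {})
        if not isinstance(target, dict):
            raise ValueError(f"cannot override through non-mapping key {p!r}")
    try:
        parsed = json.loads(value)
    except json.JSONDecodeError:
        parsed = value
    target[parts[-1]] = parsed


def load_config(path: Optional[str] = None, preset: Optional[str] = None,
                overrides: tuple[str, ...] = ()) -> RunConfig:
    """Build a validated RunConfig from file, preset and overrides.

    Precedence: preset < file < overrides. Unknown top-level keys are
    rejected with the offending key named; model invariants (e.g.
    1 < M < N) are enforced before any computation runs.
    """
    cfg: dict = {}
    if preset is not None:
        cfg.update(preset_config(preset))
    if path is not None:
        file_cfg = _read_file(Path(path))
        for key, value in file_cfg.items():
            if key in ("game", "feedback") and isinstance(value, dict):
                cfg.setdefault(key, {}).update(value)
            else:
                cfg[key] = value
    for ov in overrides:
        if "=" not in ov:
            raise ValueError(f"override must look like key=value (got {ov!r})")
        key, _, value = ov.partition("=")
        _apply_override(cfg, key.strip(), value.strip())

    if "game" not in cfg or "feedback" not in cfg:
        raise ValueError("config requires 'game' and 'feedback' blocks "
                         "(supply --preset or a config file)")
    allowed = {f.name for f in fields(RunConfig)}
    bad = set(cfg) - allowed
    if bad:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(bad))}")
    return RunConfig(**cfg)
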
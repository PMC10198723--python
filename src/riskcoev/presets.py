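"""Named parameter presets for the study's reference scenarios.

All presets share the game N=6, M=3, b=1, c=0.1 and feedback speed
eps=0.1. The linear-feedback scenarios vary the risk-enhancement rate u
(above, at, and below the Hopf threshold u = (M-1)/(N-M) = 2/3, plus the
no-interior case u=4); the sigmoid-feedback scenarios vary the cooperation
threshold T around its Hopf value T = (M-1)/(N-1) = 0.4, with steepness
beta = 10 as the documented default.
"""

from __future__ import annotations

from .dynamics import CoupledSystem, FeedbackSpec
from .game import GameParams

__all__ = ["PRESETS", "get_preset", "preset_config"]

_GAME = {"N": 6, "M": 3, "b": 1.0, "c": 0.1}
_BETA = 10.0

PRESETS: dict[str, dict] = {
    # linear feedback (System I)
    "fig4-top": {"game": dict(_GAME),
                 "feedback": {"variant": "linear", "u": 2.0}, "eps": 0.1},
    "fig4-hopf": {"game": dict(_GAME),
                  "feedback": {"variant": "linear", "u": 2.0 / 3.0},
                  "eps": 0.1},
    "fig4-low": {"game": dict(_GAME),
                 "feedback": {"variant": "linear", "u": 0.5}, "eps": 0.1},
    "fig4-boundary": {"game": dict(_GAME),
                      "feedback": {"variant": "linear", "u": 4.0},
                      "eps": 0.1},
    # sigmoid feedback (System II)
    "fig6-top": {"game": dict(_GAME),
                 "feedback": {"variant": "exponential", "T": 0.5,
                              "beta": _BETA}, "eps": 0.1},
    "fig6-hopf": {"game": dict(_GAME),
                  "feedback": {"variant": "exponential", "T": 0.4,
                               "beta": _BETA}, "eps": 0.1},
    "fig6-low": {"game": dict(_GAME),
                 "feedback": {"variant": "exponential", "T": 0.2,
                              "beta": _BETA}, "eps": 0.1},
    "fig6-boundary": {"game": dict(_GAME),
                      "feedback": {"variant": "exponential", "T": 0.8,
                                   "beta": _BETA}, "eps": 0.1},
}


def preset_config(name: str) -> dict:
    """A deep-ish copy of the raw preset dictionary."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: "
                       f"{', '.join(sorted(PRESETS))}")
    raw = PRESETS[name]
    return {"game": dict(raw["game"]), "feedback": dict(raw["feedback"]),
            "eps": raw["eps"]}


def get_preset(name: str) -> CoupledSystem:
    """Build the CoupledSystem for a named preset."""
    cfg = preset_config(name)
    return CoupledSystem(game=GameParams(**cfg["game"]),
                         feedback=FeedbackSpec(**cfg["feedback"]),
                         eps=cfg["eps"])
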
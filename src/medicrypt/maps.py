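"""One-dimensional chaotic maps used as keystream primitives.

Four maps on the open unit interval: the logistic map, the piecewise
linear chaotic map (PWLCM), the logistic-tent system (LTS), and the
cubic map. Each single-step function is pure; a guarded :func:`iterate`
runs warm-up/discard trajectories. Every step is sanitized back into
(0, 1) so trajectories cannot die on the absorbing fixed points at the
interval's ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EPS",
    "LOGISTIC_RANGE",
    "PWLCM_RANGE",
    "LTS_RANGE",
    "CUBIC_LAMBDA",
    "MapParams",
    "step_logistic",
    "step_pwlcm",
    "step_lts",
    "step_cubic",
    "step",
    "iterate",
]

#: Clamp margin keeping sanitized states strictly inside (0, 1).
EPS = 2.0 ** -32

#: Chaotic regime of the logistic map's control parameter G.
LOGISTIC_RANGE = (3.58, 4.0)
#: PWLCM range-control parameter G lives in the open interval (0, 0.5).
PWLCM_RANGE = (0.0, 0.5)
#: LTS control parameter G; endpoints are degenerate and excluded.
LTS_RANGE = (0.0, 4.0)
#: Default cubic-map control parameter.
CUBIC_LAMBDA = 2.59

MAP_IDS = ("logistic", "pwlcm", "lts", "cubic")


def _sanitize(value: float) -> float:
    """Clamp a raw map output into [EPS, 1 - EPS].

    The logistic map sends T=0.5, G=4 to exactly 1.0 and every map fixes
    0; either would kill the trajectory. The clamp is far below the
    8-bit quantization used downstream, so statistics are unaffected.
    """
    if value <= 0.0:
        return EPS
    if value >= 1.0:
        return 1.0 - EPS
    return value


def _check_unit(t: float) -> None:
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"state must lie in [0, 1], got {t!r}")


def step_logistic(t: float, g: float) -> float:
    """One logistic-map step T -> G*T*(1-T), sanitized into (0, 1).

    G must lie in [3.58, 4], the map's chaotic regime.
    """
    if not LOGISTIC_RANGE[0] <= g <= LOGISTIC_RANGE[1]:
        raise ValueError(f"logistic control must be in [3.58, 4], got {g!r}")
    _check_unit(t)
    return _sanitize(g * t * (1.0 - t))


def step_pwlcm(t: float, g: float) -> float:
    """One PWLCM step, three linear branches symmetric about T = 0.5.

    For 0 <= T < G the slope is 1/G; for G <= T < 0.5 the segment maps
    [G, 0.5) onto [0, 1); for T >= 0.5 the map folds back, F(T) = F(1-T).
    The range-control parameter G must lie in the open interval (0, 0.5).
    """
    if not PWLCM_RANGE[0] < g < PWLCM_RANGE[1]:
        raise ValueError(f"pwlcm control must be in (0, 0.5), got {g!r}")
    _check_unit(t)
    if t >= 0.5:
        t = 1.0 - t
    if t < g:
        out = t / g
    else:
        out = (t - g) / (0.5 - g)
    return _sanitize(out)


def step_lts(t: float, g: float) -> float:
    """One logistic-tent-system step, modular mix of the two maps.

    For T < 0.5:  (G*T*(1-T) + (4-G)*T/2) mod 1
    For T >= 0.5: (G*T*(1-T) + (4-G)*(1-T)/2) mod 1
    G must lie in the open interval (0, 4).
    """
    if not LTS_RANGE[0] < g < LTS_RANGE[1]:
        raise ValueError(f"lts control must be in (0, 4), got {g!r}")
    _check_unit(t)
    if t < 0.5:
        out = (g * t * (1.0 - t) + (4.0 - g) * t / 2.0) % 1.0
    else:
        out = (g * t * (1.0 - t) + (4.0 - g) * (1.0 - t) / 2.0) % 1.0
    return _sanitize(out)


def step_cubic(t: float, lam: float = CUBIC_LAMBDA) -> float:
    """One cubic-map step T -> lam*T*(1-T^2), sanitized into (0, 1)."""
    _check_unit(t)
    return _sanitize(lam * t * (1.0 - t * t))


_STEPPERS = {
    "logistic": step_logistic,
    "pwlcm": step_pwlcm,
    "lts": step_lts,
    "cubic": step_cubic,
}


@dataclass(frozen=True)
class MapParams:
    """A map identity plus its control parameter (G or lambda)."""

    map_id: str
    control: float

    def __post_init__(self) -> None:
        if self.map_id not in MAP_IDS:
            raise ValueError(f"unknown map {self.map_id!r}; choose from {MAP_IDS}")
        # Delegate range validation to the stepper on a safe probe state.
        _STEPPERS[self.map_id](0.25, self.control)


def step(params: MapParams, t: float) -> float:
    """Dispatch a single sanitized step of the map named by *params*."""
    return _STEPPERS[params.map_id](t, params.control)


def iterate(params: MapParams, t0: float, n: int, discard: int = 0) -> list[float]:
    """Apply the map *n* times from *t0*; return the last ``n - discard`` states.

    The discard prefix is the standard warm-up that moves the trajectory
    off its transient before the states are consumed. Deterministic for
    fixed inputs.
    """
    if n < 0 or discard < 0:
        raise ValueError("n and discard must be non-negative")
    if n < discard:
        raise ValueError(f"need n >= discard, got n={n}, discard={discard}")
    fn = _STEPPERS[params.map_id]
    g = params.control
    t = t0
    out: list[float] = []
    for i in range(n):
        t = fn(t, g)
        if i >= discard:
            out.append(t)
    return out


def control_range(map_id: str) -> tuple[float, float]:
    """The open/closed interval of valid control parameters for *map_id*.

    For the cubic map the conventional chaotic band below ``CUBIC_LAMBDA``
    is returned; in practice the cubic control is pinned to 2.59.
    """
    if map_id == "logistic":
        return LOGISTIC_RANGE
    if map_id == "pwlcm":
        return PWLCM_RANGE
    if map_id == "lts":
        return LTS_RANGE
    if map_id == "cubic":
        return (2.0, CUBIC_LAMBDA)
    raise ValueError(f"unknown map {map_id!r}")
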
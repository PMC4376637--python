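"""PEST staircases, psychometric indifference-point fits, and the concavity rule.

The staircase titrates the magnitude of a costly option toward the point of
subjective indifference with a no-cost default: rejections raise the offer,
acceptances lower it, the step halves on every direction reversal and doubles
after sustained same-direction runs.  When the step has shrunk to a quarter
of its initial size the staircase re-initialises (magnitude re-jittered
around its starting value, step restored).

Pooled choices per cost level are then fitted with a two-parameter logistic
``P(accept | x) = 1 / (1 + exp(-slope * (x - x50)))`` whose 0.5 crossing
``x50`` is the indifference point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "DEFAULT_EFFORT_LEVELS",
    "StaircaseState",
    "BlockConfig",
    "StaircaseConfig",
    "IndifferenceCurve",
    "ConcavityResult",
    "pest_update",
    "estimate_indifference_points",
    "transform_indifference",
    "classify_concavity",
]

#: Default normalised effort levels of the six interleaved staircases.
DEFAULT_EFFORT_LEVELS = (0.15, 0.25, 0.4, 0.55, 0.75, 1.0)

_EPS = 1e-9


@dataclass(frozen=True)
class StaircaseState:
    """Bookkeeping of one staircase (one cost level)."""

    effort: float
    magnitude: float
    step: float
    initial_magnitude: float
    initial_step: float
    jitter: float = 0.0
    last_direction: int = 0  # +1 offer raised, -1 lowered, 0 fresh
    run_length: int = 0
    n_reinit: int = 0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("offered magnitude must be >= 0")
        if self.step <= 0 or self.initial_step <= 0:
            raise ValueError("step sizes must be positive")


def _reinitialize(state: StaircaseState, rng: np.random.Generator | None) -> StaircaseState:
    offset = 0.0
    if rng is not None and state.jitter > 0:
        offset = float(rng.uniform(-state.jitter, state.jitter))
    return replace(
        state,
        magnitude=max(0.0, state.initial_magnitude + offset),
        step=state.initial_step,
        last_direction=0,
        run_length=0,
        n_reinit=state.n_reinit + 1,
    )


def pest_update(
    state: StaircaseState, accepted: bool, rng: np.random.Generator | None = None
) -> StaircaseState:
    """Advance one staircase by one choice.

    ``accepted`` means the costly option was taken, so the next offer is
    lowered; a rejection raises it.  Step-size rules: halve on reversal
    (re-initialising once the step reaches a quarter of its initial size),
    double from the fourth consecutive same-direction step onward (capped at
    the initial step), keep it otherwise.  Run history restarts after a
    re-initialisation.  The offered magnitude is floored at zero.
    """
    direction = -1 if accepted else 1
    if state.last_direction == 0 or direction == state.last_direction:
        run = state.run_length + 1
        step = state.step
        if state.last_direction != 0 and run > 3:
            step = min(state.step * 2.0, state.initial_step)
    else:
        run = 1
        step = state.step / 2.0
        if step <= state.initial_step / 4.0 + _EPS:
            return _reinitialize(state, rng)
    magnitude = max(0.0, state.magnitude + direction * step)
    return replace(state, magnitude=magnitude, step=step, last_direction=direction, run_length=run)


@dataclass(frozen=True)
class BlockConfig:
    """Per-block staircase constants (display units)."""

    default_magnitude: float
    initial_magnitude: float
    initial_step: float
    jitter: float

    def __post_init__(self) -> None:
        if self.default_magnitude <= 0:
            raise ValueError("default magnitude must be positive")
        if self.initial_step <= 0:
            raise ValueError("initial step must be positive")


@dataclass(frozen=True)
class StaircaseConfig:
    """Session layout: six interleaved staircases, two blocks by default.

    Defaults follow the reference design: per block 96 trials (16 choices at
    each of six cost levels); block 1 uses a 40p default with offers started
    at 60 +- 6 and an 8p initial step, block 2 a 200p default with offers
    started at 260 +- 20 and a 24p step.
    """

    effort_levels: tuple[float, ...] = DEFAULT_EFFORT_LEVELS
    trials_per_level: int = 16
    blocks: tuple[BlockConfig, ...] = (
        BlockConfig(default_magnitude=40.0, initial_magnitude=60.0, initial_step=8.0, jitter=6.0),
        BlockConfig(default_magnitude=200.0, initial_magnitude=260.0, initial_step=24.0, jitter=20.0),
    )
    realized_fraction: float = 0.15

    def __post_init__(self) -> None:
        if len(self.effort_levels) != 6:
            raise ValueError(f"exactly six effort levels are required, got {len(self.effort_levels)}")
        if self.trials_per_level < 1:
            raise ValueError("trials_per_level must be >= 1")
        if not 0.0 <= self.realized_fraction <= 1.0:
            raise ValueError("realized_fraction must lie in [0, 1]")


@dataclass
class IndifferenceCurve:
    """Fitted indifference points for one block.

    ``status`` per level is ``"ok"`` (converged logistic fit), ``"separated"``
    (perfect separation; ``x50`` is the midpoint of the gap and the slope is
    unbounded) or ``"insufficient"`` (too few choices or a single outcome
    class; ``x50`` is NaN).
    """

    levels: np.ndarray
    x50: np.ndarray
    slope: np.ndarray
    n_choices: np.ndarray
    status: tuple[str, ...]
    default_magnitude: float


def _fit_level(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Bernoulli-MLE logistic fit of acceptances against offered magnitude."""
    if len(x) < 6 or y.all() or not y.any():
        return math.nan, math.nan, "insufficient"
    hi_rej = x[~y].max()
    lo_acc = x[y].min()
    if hi_rej < lo_acc:  # complete separation: every accepted offer beats every rejected one
        return float((hi_rej + lo_acc) / 2.0), math.inf, "separated"

    span = max(x.max() - x.min(), 1.0)

    def nll(theta):
        x50, log_slope = theta
        p = expit(np.exp(log_slope) * (x - x50))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -(np.log(p[y]).sum() + np.log(1 - p[~y]).sum())

    best = None
    for s0 in (4.0 / span, 0.5):
        res = minimize(nll, np.array([float(x.mean()), math.log(s0)]), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    x50, log_slope = best.x
    return float(x50), float(math.exp(log_slope)), "ok"


def estimate_indifference_points(
    choices: Mapping[float, Sequence[tuple[float, bool]]], default_magnitude: float
) -> IndifferenceCurve:
    """Fit one psychometric curve per cost level and extract its 0.5 crossing.

    ``choices`` maps each cost level to ``(offered magnitude, accepted)``
    pairs pooled across staircase re-initialisations.
    """
    if default_magnitude <= 0:
        raise ValueError("default magnitude must be positive")
    levels = np.array(sorted(choices), dtype=float)
    x50 = np.empty(len(levels))
    slope = np.empty(len(levels))
    n_choices = np.empty(len(levels), dtype=int)
    status: list[str] = []
    for i, level in enumerate(levels):
        pairs = list(choices[level])
        x = np.array([m for m, _ in pairs], dtype=float)
        y = np.array([bool(a) for _, a in pairs])
        n_choices[i] = len(pairs)
        x50[i], slope[i], st = _fit_level(x, y)
        status.append(st)
    return IndifferenceCurve(levels, x50, slope, n_choices, tuple(status), float(default_magnitude))


def transform_indifference(curve: IndifferenceCurve, mode: str = "raw") -> np.ndarray:
    """Per-level indifference values in one of three representations.

    ``raw``: the fitted x50; ``multiplicative``: default / x50 (a relative
    subjective value, 1 = no devaluation); ``additive``: default - (x50 -
    default) (the absolute value decrease, which can go negative once x50
    exceeds twice the default).
    """
    d = curve.default_magnitude
    if d <= 0:
        raise ValueError("default magnitude must be positive")
    if mode == "raw":
        return curve.x50.copy()
    if mode == "multiplicative":
        if np.any(curve.x50[np.isfinite(curve.x50)] <= 0):
            raise ValueError("multiplicative representation requires positive indifference points")
        return d / curve.x50
    if mode == "additive":
        return d - (curve.x50 - d)
    raise ValueError(f"unknown representation {mode!r}")


@dataclass(frozen=True)
class ConcavityResult:
    concave: bool
    n_above_chord: int


def classify_concavity(
    multiplicative_points: Iterable[float], levels: Iterable[float] = DEFAULT_EFFORT_LEVELS
) -> ConcavityResult:
    """Label a six-point multiplicative indifference curve concave or not.

    The chord runs from the implicit zero-cost anchor ``(0, 1)`` to the sixth
    point; the curve is concave when at least three of the first five points
    lie strictly above the chord.
    """
    v = np.asarray(list(multiplicative_points), dtype=float)
    e = np.asarray(list(levels), dtype=float)
    if v.shape != (6,) or e.shape != (6,):
        raise ValueError("six per-level values and six levels are required")
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(e))):
        raise ValueError("concavity classification requires finite inputs")
    chord = 1.0 + (v[5] - 1.0) * e[:5] / e[5]
    n_above = int(np.sum(v[:5] > chord))
    return ConcavityResult(concave=n_above >= 3, n_above_chord=n_above)
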
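"""Discounting value functions, the softmax choice rule, and the utility transform.

Five parametric models map a (magnitude, cost) offer to a subjective value:

========== =================================== ==========
name       value                               parameters
========== =================================== ==========
hyperbolic ``M / (1 + k*C)``                   k
linear     ``M - k*C``                         k
quadratic  ``M - k*C**2``                      k
sigmoidal  ``M * (1 - (s(k*(C-p)) - s(-k*p))   k, p
           * (1 + exp(-k*p)))``
power      ``M - k*C**p``                      k, p
========== =================================== ==========

with ``s`` the logistic function.  The sigmoidal correction terms force the
curve through ``(C, V) = (0, M)`` and make it converge to zero for large
costs.  All functions here are pure, vectorised over numpy arrays, and
deliberately accept costs outside ``[0, 1]`` (optimisers and oracles probe
there); domain validation of observed stimuli lives in the data layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "MODEL_NAMES",
    "Offer",
    "ModelSpec",
    "ChoiceParams",
    "get_model",
    "subjective_value",
    "discounted_value",
    "choice_probability",
    "apply_utility",
]

MODEL_NAMES = ("hyperbolic", "linear", "quadratic", "sigmoidal", "power")

#: smallest probability ever returned by the choice rule
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class Offer:
    """A single option: a reward magnitude and a normalised cost.

    Magnitudes are in display units (0-75 in the reference design); costs are
    normalised to [0, 1] (1 = the maximum cost of the session).  Observed
    stimuli must satisfy these ranges; the value functions themselves remain
    defined outside them.
    """

    magnitude: float
    cost: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.magnitude) or self.magnitude < 0:
            raise ValueError(f"offer magnitude must be finite and >= 0, got {self.magnitude}")
        if not np.isfinite(self.cost) or not 0.0 <= self.cost <= 1.0:
            raise ValueError(f"offer cost must lie in [0, 1], got {self.cost}")


@dataclass(frozen=True)
class ModelSpec:
    """Static description of one discounting model.

    ``params`` lists the native-space parameter names in canonical order;
    ``transforms`` maps each parameter to the transform linking estimation
    space to native space (``"log"`` or ``"identity"``); ``bounds`` are
    native-space sanity bounds used when validating simulated agents.
    """

    name: str
    params: tuple[str, ...]
    transforms: Mapping[str, str] = field(repr=False)
    bounds: Mapping[str, tuple[float, float]] = field(repr=False)

    def __post_init__(self) -> None:
        for par in self.params:
            if par not in self.transforms:
                raise ValueError(f"{self.name}: parameter {par!r} has no transform tag")
            if self.transforms[par] not in ("log", "identity"):
                raise ValueError(f"{self.name}: unknown transform {self.transforms[par]!r}")


_MODELS: dict[str, ModelSpec] = {
    "hyperbolic": ModelSpec("hyperbolic", ("k",), {"k": "log"}, {"k": (1e-6, 1e4)}),
    "linear": ModelSpec("linear", ("k",), {"k": "log"}, {"k": (1e-6, 1e5)}),
    "quadratic": ModelSpec("quadratic", ("k",), {"k": "log"}, {"k": (1e-6, 1e5)}),
    # p is intentionally not clipped at 1: turning points above the observed
    # cost range are conceptually possible.
    "sigmoidal": ModelSpec(
        "sigmoidal", ("k", "p"), {"k": "log", "p": "identity"}, {"k": (1e-6, 1e4), "p": (-5.0, 5.0)}
    ),
    "power": ModelSpec("power", ("k", "p"), {"k": "log", "p": "log"}, {"k": (1e-6, 1e5), "p": (1e-3, 50.0)}),
}


def get_model(name: str) -> ModelSpec:
    """Return the :class:`ModelSpec` registered under ``name``."""
    try:
        return _MODELS[name]
    except KeyError:
        raise ValueError(f"unknown model {name!r}; known models: {sorted(_MODELS)}") from None


@dataclass(frozen=True)
class ChoiceParams:
    """Native-space model parameters plus the choice-rule parameters.

    ``beta`` is the softmax temperature (>= 0; 0 yields coin-flip choices) and
    ``alpha`` the utility exponent applied to magnitudes (1 = no transform,
    0.8 in the generic-utility variant).
    """

    values: Mapping[str, float]
    beta: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"parameter {name!r} is not finite: {v}")
        if not np.isfinite(self.beta) or self.beta < 0:
            raise ValueError(f"softmax temperature beta must be >= 0, got {self.beta}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"utility exponent alpha must lie in (0, 1], got {self.alpha}")


def apply_utility(magnitude, alpha: float):
    """Map a reward magnitude to utility ``M**alpha``.

    Identity at ``alpha = 1``.  The transform is applied to magnitudes only,
    never to costs.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if np.any(magnitude < 0):
        raise ValueError("magnitudes must be >= 0")
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    out = magnitude**alpha
    return out if out.ndim else float(out)


def _sigmoidal_factor(cost, k, p):
    # 1 - (s(k(C-p)) - s(-kp)) * (1 + exp(-kp)) simplifies algebraically to
    # (1 + exp(-kp)) / (1 + exp(k(C-p))); evaluate it in log space so huge
    # k*(C-p) products cannot overflow.
    return np.exp(np.logaddexp(0.0, -k * p) - np.logaddexp(0.0, k * (cost - p)))


def discounted_value(model: str, magnitude, cost, params: Mapping[str, float], alpha: float = 1.0):
    """Vectorised subjective value of offers under a named model.

    ``magnitude`` and ``cost`` broadcast against each other and against the
    parameter values (which may themselves be arrays, as used by the evidence
    oracle's grids).  When ``alpha != 1`` the magnitude is replaced by
    ``M**alpha`` before discounting.
    """
    spec = get_model(model)
    for par in spec.params:
        if par not in params:
            raise ValueError(f"model {model!r} requires parameter {par!r}")
        if not np.all(np.isfinite(np.asarray(params[par], dtype=float))):
            raise ValueError(f"parameter {par!r} contains non-finite values")
    m = np.asarray(magnitude, dtype=float)
    c = np.asarray(cost, dtype=float)
    if alpha != 1.0:
        m = apply_utility(m, alpha)
    k = np.asarray(params["k"], dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        if model == "hyperbolic":
            out = m / (1.0 + k * c)
        elif model == "linear":
            out = m - k * c
        elif model == "quadratic":
            out = m - k * c**2
        elif model == "sigmoidal":
            out = m * _sigmoidal_factor(c, k, np.asarray(params["p"], dtype=float))
        else:  # power
            out = m - k * np.sign(c) * np.abs(c) ** np.asarray(params["p"], dtype=float)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def subjective_value(model: ModelSpec | str, params: ChoiceParams, offer: Offer) -> float:
    """Subjective value of a single :class:`Offer` under ``params``."""
    name = model.name if isinstance(model, ModelSpec) else model
    return float(discounted_value(name, offer.magnitude, offer.cost, params.values, params.alpha))


def choice_probability(beta: float, v1, v2):
    """Softmax probability of choosing option 1 over option 2.

    ``P = 1 / (1 + exp(-beta * (v1 - v2)))``.  ``beta = 0`` yields 0.5 for any
    pair of values.  The return value is clipped into the open interval
    (0, 1) so that downstream log-likelihoods stay finite.
    """
    if not np.isfinite(beta) or beta < 0:
        raise ValueError(f"softmax temperature beta must be finite and >= 0, got {beta}")
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if not (np.all(np.isfinite(v1)) and np.all(np.isfinite(v2))):
        raise ValueError("subjective values must be finite")
    with np.errstate(over="ignore"):  # beta*(v1-v2) may saturate; expit handles inf
        p = expit(beta * (v1 - v2))
    p = np.clip(p, _P_FLOOR, 1.0 - np.finfo(float).eps / 2)
    return p if p.ndim else float(p)
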
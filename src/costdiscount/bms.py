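"""Random-effects group Bayesian model selection over a table of log evidences.

Variational update for the Dirichlet posterior over population model
frequencies: subject responsibilities are softmax-normalised log evidences
shifted by the current digamma terms, and the Dirichlet counts accumulate the
responsibilities.  Exceedance probabilities come from the exact Beta formula
for two models and from seeded Dirichlet Monte Carlo otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc, digamma, logsumexp

__all__ = ["EvidenceTable", "BMSResult", "rfx_bms", "pairwise_exceedance_exact"]


@dataclass
class EvidenceTable:
    """Matrix of log model evidences, subjects by models."""

    free_energy: np.ndarray
    models: tuple[str, ...]
    subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        self.free_energy = np.atleast_2d(np.asarray(self.free_energy, dtype=float))
        n, k = self.free_energy.shape
        if n < 1 or k < 2:
            raise ValueError("evidence table needs >= 1 subject and >= 2 models")
        if len(self.models) != k or len(self.subjects) != n:
            raise ValueError("model/subject labels do not match the matrix shape")
        if not np.all(np.isfinite(self.free_energy)):
            raise ValueError("evidence table contains non-finite entries")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EvidenceTable":
        """Build from a tidy fit table with columns subject, model, free_energy."""
        wide = frame.pivot(index="subject", columns="model", values="free_energy")
        if wide.isna().any().any():
            raise ValueError("missing (subject, model) evidence entries")
        return cls(wide.to_numpy(), tuple(wide.columns), tuple(wide.index))


@dataclass
class BMSResult:
    """Dirichlet posterior over model frequencies with mp and xp per model."""

    models: tuple[str, ...]
    alpha: np.ndarray
    mp: np.ndarray
    xp: np.ndarray
    n_iter: int
    xp_method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"model": self.models, "alpha": self.alpha, "mp": self.mp, "xp": self.xp})


def pairwise_exceedance_exact(alpha1: float, alpha2: float) -> float:
    """P(r1 > 0.5) for r1 ~ Beta(alpha1, alpha2), via the regularised incomplete beta."""
    if alpha1 <= 0 or alpha2 <= 0:
        raise ValueError("Dirichlet concentrations must be positive")
    return float(1.0 - betainc(alpha1, alpha2, 0.5))


def _xp_monte_carlo(alpha: np.ndarray, n_samples: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(alpha))
    chunk = 200_000
    left = n_samples
    while left > 0:
        m = min(chunk, left)
        draws = rng.dirichlet(alpha, size=m)
        idx = np.argmax(draws, axis=1)
        counts += np.bincount(idx, minlength=len(alpha))
        left -= m
    return counts / n_samples


def rfx_bms(
    evidence: EvidenceTable,
    alpha0: float = 1.0,
    xp_samples: int = 10**6,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> BMSResult:
    """Random-effects model comparison across subjects.

    Iterates responsibilities ``u_nk proportional to exp(F_nk + psi(alpha_k) -
    psi(sum alpha))`` and counts ``alpha_k = alpha0 + sum_n u_nk`` until the
    concentration change falls below ``tol``.  Within-subject evidence
    differences are what matters: adding a constant to a subject's row leaves
    the result unchanged, and responsibilities are computed with log-sum-exp
    stabilisation so arbitrarily large spreads cannot overflow.
    """
    if alpha0 <= 0:
        raise ValueError("alpha0 must be positive")
    F = evidence.free_energy
    n, K = F.shape
    alpha = np.full(K, alpha0, dtype=float)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_u = F + digamma(alpha)[None, :] - digamma(alpha.sum())
        log_u = log_u - logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    mp = alpha / alpha.sum()
    if K == 2:
        xp1 = pairwise_exceedance_exact(alpha[0], alpha[1])
        xp = np.array([xp1, 1.0 - xp1])
        method = "exact-beta"
    else:
        xp = _xp_monte_carlo(alpha, xp_samples, seed)
        method = f"dirichlet-mc-{xp_samples}"
    return BMSResult(
        models=evidence.models, alpha=alpha, mp=mp, xp=xp, n_iter=n_iter, xp_method=method
    )
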
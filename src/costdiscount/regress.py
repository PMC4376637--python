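"""Auxiliary choice statistics: logistic regression, fatigue permutation
tests, and cross-task parameter correlations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import ChoiceDataset

__all__ = [
    "choice_logistic_regression",
    "fatigue_tests",
    "FatigueReport",
    "parameter_correlations",
]

_PREDICTORS = ("m1", "c1", "m2", "c2")


def choice_logistic_regression(dataset: ChoiceDataset) -> pd.DataFrame:
    """Logistic regression of choosing option 1 on both options' magnitudes and costs.

    Four predictors plus an intercept, fitted by iteratively reweighted least
    squares.  Under value-based choice, own-magnitude coefficients come out
    positive and own-cost coefficients negative.  Perfect separation (or
    non-convergence) falls back to a ridge-stabilised solution; the returned
    frame then carries ``attrs["separated"] = True`` and NaN standard errors.
    """
    if len(dataset) < 20:
        raise ValueError("need at least 20 trials for the choice regression")
    X = np.column_stack([getattr(dataset, p) for p in _PREDICTORS])
    if np.any(X.std(axis=0) == 0):
        degenerate = [p for p, s in zip(_PREDICTORS, X.std(axis=0)) if s == 0]
        raise ValueError(f"degenerate predictors (zero variance): {degenerate}")
    y = (dataset.chosen == 1).astype(float)
    X = sm.add_constant(X)
    names = ("const",) + _PREDICTORS
    separated = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params, bse = res.params, res.bse
        if not res.mle_retvals.get("converged", False) or np.any(np.abs(params) > 1e3):
            separated = True
    except Exception:
        separated = True
    if separated:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-3, L1_wt=0.0
            )
        params = np.asarray(res.params)
        bse = np.full_like(params, np.nan)
    with np.errstate(all="ignore"):
        z = params / bse
    out = pd.DataFrame({"estimate": params, "se": bse, "z": z}, index=list(names))
    out.attrs["separated"] = separated
    return out


def _hrhc_chosen(dataset: ChoiceDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per trial: is the higher-reward/higher-cost option defined, and was it chosen."""
    d_m = dataset.m1 - dataset.m2
    d_c = dataset.c1 - dataset.c2
    defined = d_m * d_c > 0  # one option dominates on both dimensions
    hrhc_option = np.where(d_m > 0, 1, 2)
    return defined, dataset.chosen == hrhc_option


@dataclass
class FatigueReport:
    """Permutation tests for trial-by-trial and accumulating fatigue."""

    applicable: bool
    tests: dict = field(default_factory=dict)
    note: str = ""


def _perm_test(a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator) -> dict:
    """Two-sided permutation test on the difference of group means.

    Add-one convention: p = (b + 1) / (n_perm + 1), never exactly zero.
    """
    pooled = np.concatenate([a, b]).astype(float)
    na = len(a)
    obs = abs(a.mean() - b.mean())
    count = 0
    chunk = 2000
    done = 0
    n = len(pooled)
    while done < n_perm:
        m = min(chunk, n_perm - done)
        u = rng.random((m, n))
        order = np.argsort(u, axis=1)
        perm = pooled[order]
        diff = np.abs(perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1))
        count += int(np.sum(diff >= obs - 1e-12))
        done += m
    return {
        "p_value": (count + 1) / (n_perm + 1),
        "observed_diff": float(a.mean() - b.mean()),
        "frac_a": float(a.mean()),
        "frac_b": float(b.mean()),
        "n_a": int(na),
        "n_b": int(len(b)),
    }


def fatigue_tests(dataset: ChoiceDataset, n_perm: int = 100_000, seed: int = 0) -> FatigueReport:
    """Three permutation screens for fatigue effects on HRHC choice rates.

    (a) trials following a realised-cost trial vs trials following a
    no-effort trial; (b) among post-realised trials, previous cost above vs
    below the median (hard vs easy); (c) first vs second half of the session.
    Requires realised flags; without any realised trial the report is marked
    inapplicable.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if not dataset.realized.any():
        return FatigueReport(applicable=False, note="no realized trials")
    rng = np.random.default_rng(seed)
    defined, hrhc = _hrhc_chosen(dataset)

    # previous trial within the same block
    prev_realized = np.zeros(len(dataset), dtype=bool)
    prev_cost = np.full(len(dataset), np.nan)
    same_block = np.zeros(len(dataset), dtype=bool)
    chosen_cost = np.where(dataset.chosen == 1, dataset.c1, dataset.c2)
    prev_realized[1:] = dataset.realized[:-1]
    prev_cost[1:] = chosen_cost[:-1]
    same_block[1:] = dataset.block[1:] == dataset.block[:-1]

    tests: dict = {}
    ok = defined & same_block
    post_eff = hrhc[ok & prev_realized]
    post_no = hrhc[ok & ~prev_realized]
    if len(post_eff) >= 2 and len(post_no) >= 2:
        tests["post_effort_vs_post_no_effort"] = _perm_test(post_eff, post_no, n_perm, rng)

    post_mask = ok & prev_realized
    if post_mask.sum() >= 4:
        med = np.nanmedian(prev_cost[post_mask])
        hard = hrhc[post_mask & (prev_cost > med)]
        easy = hrhc[post_mask & (prev_cost <= med)]
        if len(hard) >= 2 and len(easy) >= 2:
            t = _perm_test(hard, easy, n_perm, rng)
            t["median_split_cost"] = float(med)
            tests["post_hard_vs_post_easy"] = t

    half = len(dataset) // 2
    first = hrhc[defined & (np.arange(len(dataset)) < half)]
    second = hrhc[defined & (np.arange(len(dataset)) >= half)]
    if len(first) >= 2 and len(second) >= 2:
        tests["first_vs_second_half"] = _perm_test(first, second, n_perm, rng)

    return FatigueReport(applicable=bool(tests), tests=tests)


def parameter_correlations(fits_effort: pd.DataFrame, fits_delay: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between per-subject parameters across two tasks.

    Inputs are frames indexed by subject with one column per parameter (e.g.
    ``hyperbolic_k``, ``sigmoidal_k``, ``sigmoidal_p``).  Every (delay
    parameter, effort parameter) pair is tested; p-values are reported
    uncorrected.
    """
    if not fits_effort.index.equals(fits_delay.index):
        if set(fits_effort.index) != set(fits_delay.index):
            raise ValueError("effort and delay fits cover different subjects")
        fits_delay = fits_delay.loc[fits_effort.index]
    n = len(fits_effort)
    if n < 3:
        raise ValueError("need at least 3 matched subjects for a correlation")
    rows = []
    for dcol in fits_delay.columns:
        y = fits_delay[dcol].to_numpy(dtype=float)
        if y.std() == 0:
            raise ValueError(f"zero-variance delay parameter {dcol!r}")
        for ecol in fits_effort.columns:
            x = fits_effort[ecol].to_numpy(dtype=float)
            if x.std() == 0:
                raise ValueError(f"zero-variance effort parameter {ecol!r}")
            r, p = stats.pearsonr(x, y)
            rows.append({"delay_param": dcol, "effort_param": ecol, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows)
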
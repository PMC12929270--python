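"""Inferential outputs: condition summaries, posterior contrast probabilities,
and posterior-expected psychometric curves.

Condition-level population parameters are linear combinations of the group
means: the AT condition is the intercept, so its threshold / log10-slope are
(mu_alpha_AT, mu_beta_AT); the T and A conditions add the respective
difference-family means.  Hypothesis tests are draw-counting posterior
probabilities against zero: bilateral where no direction was predicted
(thresholds, and the A-vs-T slope contrast), unilateral for the
unimodal-vs-bimodal slope contrasts where the preregistered hypothesis is
that the bimodal slope is steeper.  The null is rejected when P < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .sampler import PosteriorDraws

__all__ = [
    "ContrastSpec",
    "ExpectedCurve",
    "STANDARD_CONTRASTS",
    "condition_summaries",
    "contrast_draws",
    "contrast_probability",
    "expected_curve",
    "contrast_table",
]

_COMPARISONS = ("T_vs_AT", "A_vs_AT", "A_vs_T")


@dataclass(frozen=True)
class ContrastSpec:
    """One condition contrast on threshold or slope with its test tail.

    ``unilateral_less`` computes P = fraction of resampled contrast draws <= 0,
    with the contrast oriented so the preregistered alternative (bimodal slope
    steeper) corresponds to negative values being evidence *against* the null;
    ``bilateral`` computes 2 * min(tail fractions), capped at 1.
    """

    target: Literal["threshold", "slope"]
    comparison: Literal["T_vs_AT", "A_vs_AT", "A_vs_T"]
    tail: Literal["bilateral", "unilateral_less"]

    def __post_init__(self) -> None:
        if self.target not in ("threshold", "slope"):
            raise ValueError("target must be 'threshold' or 'slope'")
        if self.comparison not in _COMPARISONS:
            raise ValueError(f"comparison must be one of {_COMPARISONS}")
        if self.tail not in ("bilateral", "unilateral_less"):
            raise ValueError("tail must be 'bilateral' or 'unilateral_less'")

    @property
    def name(self) -> str:
        return f"{self.target}:{self.comparison}"


#: The six standard tests in reporting order: thresholds bilateral,
#: unimodal-vs-bimodal slopes unilateral, the unimodal-vs-unimodal slope bilateral.
STANDARD_CONTRASTS = (
    ContrastSpec("threshold", "T_vs_AT", "bilateral"),
    ContrastSpec("threshold", "A_vs_AT", "bilateral"),
    ContrastSpec("threshold", "A_vs_T", "bilateral"),
    ContrastSpec("slope", "T_vs_AT", "unilateral_less"),
    ContrastSpec("slope", "A_vs_AT", "unilateral_less"),
    ContrastSpec("slope", "A_vs_T", "bilateral"),
)


@dataclass(frozen=True)
class ExpectedCurve:
    """Pointwise posterior percentiles of the population psychometric function."""

    condition: str
    x: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "median", "lower", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.x.shape == self.median.shape == self.lower.shape == self.upper.shape):
            raise ValueError("grid and percentile arrays must share a shape")
        if np.any(self.lower > self.median) or np.any(self.median > self.upper):
            raise ValueError("percentile envelope must be ordered lower <= median <= upper")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_cm": self.x, "lower": self.lower, "median": self.median, "upper": self.upper}
        )


def _required(draws: PosteriorDraws, name: str) -> np.ndarray:
    if name not in draws.params:
        raise KeyError(f"posterior draws are missing parameter {name!r}")
    return draws.flat(name)


def _condition_mu(draws: PosteriorDraws, condition: str, which: str) -> np.ndarray:
    """Pooled draws of the condition-level population mean (threshold or log10-slope)."""
    fam = "alpha" if which == "threshold" else "beta"
    base = _required(draws, f"mu_{fam}_AT")
    if condition == "AT":
        return base
    if condition == "T":
        return base + _required(draws, f"mu_{fam}_AT_minus_T")
    if condition == "A":
        return base + _required(draws, f"mu_{fam}_AT_minus_A")
    raise ValueError(f"unknown condition {condition!r}")


def condition_summaries(draws: PosteriorDraws, hdi_prob: float = 0.95) -> pd.DataFrame:
    """Posterior median and HDI of each condition's population threshold and log10-slope.

    Follows the parameter-estimate figure convention: dots are posterior
    medians, bars are 95% highest-density intervals.
    """
    rows = []
    for cond in ("AT", "T", "A"):
        for which, col in (("threshold", "threshold"), ("slope", "log10_slope")):
            d = _condition_mu(draws, cond, which)
            lo, hi = az.hdi(d, hdi_prob=hdi_prob)
            rows.append(
                {
                    "condition": cond,
                    "quantity": col,
                    "median": float(np.median(d)),
                    "hdi_low": float(lo),
                    "hdi_high": float(hi),
                }
            )
    return pd.DataFrame(rows)


def contrast_draws(draws: PosteriorDraws, spec: ContrastSpec) -> np.ndarray:
    """Pooled posterior draws of the contrast, oriented for its test.

    Bilateral contrasts use the plain condition difference (first-named minus
    AT, or A minus T).  Unilateral slope contrasts are oriented as
    bimodal minus unimodal so that values <= 0 support the null
    (unimodal slope at least as steep as the bimodal one).
    """
    fam = "alpha" if spec.target == "threshold" else "beta"
    d_T = _required(draws, f"mu_{fam}_AT_minus_T")
    d_A = _required(draws, f"mu_{fam}_AT_minus_A")
    if spec.comparison == "T_vs_AT":
        c = d_T
    elif spec.comparison == "A_vs_AT":
        c = d_A
    else:
        c = d_A - d_T
    if spec.tail == "unilateral_less":
        c = -c  # bimodal minus unimodal
    return c


def contrast_probability(
    draws: PosteriorDraws | np.ndarray,
    spec: ContrastSpec,
    n_draws: int = 100_000,
    seed: int = 0,
) -> tuple[float, bool]:
    """Posterior probability of the null by counting resampled draws against 0.

    Resamples ``n_draws`` values with replacement from the contrast's pooled
    posterior draws.  ``unilateral_less``: P = fraction <= 0; ``bilateral``:
    P = 2 * min(fraction > 0, fraction < 0), capped at 1.  Returns (P, rejected)
    with rejection at P < 0.05.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    c = draws if isinstance(draws, np.ndarray) else contrast_draws(draws, spec)
    rng = np.random.default_rng(seed)
    sample = rng.choice(c, size=n_draws, replace=True)
    if spec.tail == "unilateral_less":
        p = float(np.mean(sample <= 0))
    else:
        p = min(1.0, 2.0 * min(float(np.mean(sample > 0)), float(np.mean(sample < 0))))
    return p, p < 0.05


def contrast_table(
    draws: PosteriorDraws,
    specs: tuple[ContrastSpec, ...] = STANDARD_CONTRASTS,
    n_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """The six condition contrasts as a tidy table (contrast, tail, P, rejected)."""
    rows = []
    for i, spec in enumerate(specs):
        p, rejected = contrast_probability(draws, spec, n_draws=n_draws, seed=seed + i)
        rows.append(
            {
                "target": spec.target,
                "comparison": spec.comparison,
                "tail": spec.tail,
                "P": p,
                "rejected": rejected,
            }
        )
    return pd.DataFrame(rows)


def expected_curve(
    draws: PosteriorDraws,
    x_grid: np.ndarray,
    condition: str = "AT",
    n_functions: int = 10_000,
    seed: int = 0,
) -> ExpectedCurve:
    """Posterior-expected psychometric curve with a pointwise 95% envelope.

    Samples ``n_functions`` posterior draws (with replacement), builds each
    draw's population-level function for the condition (threshold and
    log10-slope from the condition mapping, lapse from the logistic of the
    group-mean logit-lapse), and takes the pointwise 2.5th/50th/97.5th
    percentiles.  Interpreted as the expected curve for a new, unobserved
    participant from the same population.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if x_grid.size == 0:
        raise ValueError("x_grid must be non-empty")
    alpha = _condition_mu(draws, condition, "threshold")
    log_beta = _condition_mu(draws, condition, "slope")
    lam = expit(_required(draws, "mu_lambda"))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, alpha.shape[0], size=n_functions)
    a, b, l = alpha[idx], 10.0 ** log_beta[idx], lam[idx]
    z = b[:, None] * (x_grid[None, :] - a[:, None])
    curves = l[:, None] + (1.0 - 2.0 * l[:, None]) * ndtr(z)
    lo, med, hi = np.percentile(curves, [2.5, 50.0, 97.5], axis=0)
    return ExpectedCurve(condition=condition, x=x_grid, median=med, lower=lo, upper=hi)
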
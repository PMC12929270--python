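"""Lapse-corrected cumulative-Gaussian (probit) response model for 2AFC localization.

The observer slides a fingertip left-to-right across a display and reports,
after a transient auditory (A), tactile (T) or auditory-tactile (AT) stimulus,
whether the finger was left or right of a visually displayed midline at
stimulus onset.  The probability of a "right" report at signed position ``x``
(cm, 0 at the midline, negative = left) is

    psi(x) = lambda + (1 - 2*lambda)/2 * erfc(-beta * (x - alpha) / sqrt(2))

i.e. a cumulative Gaussian with midpoint ``alpha`` (threshold, cm), rate
parameter ``beta`` (slope, per cm) and a single lapse rate ``lambda`` that
compresses the curve symmetrically into [lambda, 1 - lambda].

Condition structure: the AT condition is the intercept; the T and A conditions
add per-subject difference coefficients to the threshold and log10-slope linear
predictors.  The lapse rate is subject-specific but condition-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc, expit

__all__ = [
    "CONDITIONS",
    "PsychometricParams",
    "ConditionFlags",
    "SubjectCoefficients",
    "response_probability",
    "assemble_params",
]

#: Condition labels in the package-wide canonical order.
CONDITIONS = ("AT", "T", "A")

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class PsychometricParams:
    """One condition's psychometric-function triple.

    Attributes
    ----------
    alpha : float
        Threshold: the position (cm from the midline) where the "right"-report
        probability is 0.5.  Negative values mean a rightward response bias.
    beta : float
        Slope (per cm); larger is steeper, i.e. more precise localization.
        Must be positive.
    lapse : float
        Stimulus-independent error probability; the curve's asymptotes are
        ``lapse`` and ``1 - lapse``.  Values below 0.5 keep the curve strictly
        increasing; the container accepts [0, 1) because the logit-lapse
        linear predictor is unbounded, but fitted models keep it small via the
        prior and adaptive procedures cap it at 0.2.
    """

    alpha: float
    beta: float
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha):
            raise ValueError(f"alpha must be finite, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be finite and > 0, got {self.beta}")
        if not (0.0 <= self.lapse < 1.0):
            raise ValueError(f"lapse must be in [0, 1), got {self.lapse}")


@dataclass(frozen=True)
class ConditionFlags:
    """Dummy coding of the stimulus condition relative to the AT intercept.

    ``AT`` -> (0, 0); ``T`` -> (isT=1); ``A`` -> (isA=1).  Never both.
    """

    isT: int = 0
    isA: int = 0

    def __post_init__(self) -> None:
        if self.isT not in (0, 1) or self.isA not in (0, 1):
            raise ValueError("flags must be 0 or 1")
        if self.isT and self.isA:
            raise ValueError("isT and isA cannot both be set")

    @classmethod
    def from_label(cls, label: str) -> "ConditionFlags":
        try:
            return {"AT": cls(0, 0), "T": cls(1, 0), "A": cls(0, 1)}[label]
        except KeyError:
            raise ValueError(f"unknown condition label {label!r}; expected one of {CONDITIONS}") from None

    @property
    def label(self) -> str:
        return "T" if self.isT else ("A" if self.isA else "AT")


@dataclass(frozen=True)
class SubjectCoefficients:
    """The seven per-subject coefficients of the linear predictors.

    ``coef_alpha_AT`` is the AT-condition threshold (cm); ``coef_alpha_AT_minus_T``
    and ``coef_alpha_AT_minus_A`` are the additive differences entering the T and A
    predictors (they equal alpha_T - alpha_AT and alpha_A - alpha_AT respectively).
    The beta coefficients live on the log10 scale (slope = 10**predictor), and
    ``coef_lambda`` is the logit of the lapse rate.
    """

    coef_alpha_AT: float
    coef_alpha_AT_minus_T: float
    coef_alpha_AT_minus_A: float
    coef_beta_AT: float
    coef_beta_AT_minus_T: float
    coef_beta_AT_minus_A: float
    coef_lambda: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"all coefficients must be finite, got {vals}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.coef_alpha_AT,
                self.coef_alpha_AT_minus_T,
                self.coef_alpha_AT_minus_A,
                self.coef_beta_AT,
                self.coef_beta_AT_minus_T,
                self.coef_beta_AT_minus_A,
                self.coef_lambda,
            ]
        )

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "SubjectCoefficients":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (7,):
            raise ValueError(f"expected 7 coefficients, got shape {arr.shape}")
        return cls(*arr)


def response_probability(params: PsychometricParams, x) -> np.ndarray | float:
    """Probability of reporting "right" for a stimulus at position ``x`` (cm).

    Evaluates the lapse-corrected probit function.  Accepts a scalar or an
    array of positions; returns the matching shape.  Output is bounded in
    [lapse, 1 - lapse], strictly increasing in ``x``, and equals 0.5 at
    ``x = alpha`` for any lapse (erfc(0) = 1).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("stimulus position must be finite")
    z = -params.beta * (x - params.alpha) / _SQRT2
    p = params.lapse + (1.0 - 2.0 * params.lapse) / 2.0 * erfc(z)
    return p if p.ndim else float(p)


def assemble_params(coefs: SubjectCoefficients, flags: ConditionFlags) -> PsychometricParams:
    """Map subject coefficients + condition flags to the condition's (alpha, beta, lapse).

    alpha is linear in the flags; beta is 10 raised to its linear predictor
    (hence always positive); the lapse is the logistic of ``coef_lambda`` and
    does not depend on the condition.
    """
    alpha = (
        coefs.coef_alpha_AT
        + coefs.coef_alpha_AT_minus_T * flags.isT
        + coefs.coef_alpha_AT_minus_A * flags.isA
    )
    beta = 10.0 ** (
        coefs.coef_beta_AT
        + coefs.coef_beta_AT_minus_T * flags.isT
        + coefs.coef_beta_AT_minus_A * flags.isA
    )
    lapse = float(expit(coefs.coef_lambda))
    return PsychometricParams(alpha=alpha, beta=beta, lapse=lapse)
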
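"""Hierarchical likelihood and priors for the 2AFC localization model.

Data unit: aggregated binomial rows (subject, condition, position) -> (n, y).
Subject-level coefficients are drawn from population normal distributions
(one mean/SD pair per coefficient family); population means and SDs carry
normal / half-normal hyperpriors.  Both experiments use the same hyperprior
table and differ only in the stimulus (and adaptive-procedure) range:
+/-2 cm for the blocked experiment (1), +/-3 cm for the interleaved one (2).

The module exposes the spec-level operations (``aggregate_trials``,
``log_likelihood``, ``log_prior``, ``log_posterior``) on centered coefficients,
and a vectorized non-centered log-density-with-gradient (``HierarchicalModel``)
that is the sampler's target.  The non-centered form (coef = mu + sigma * z,
z ~ N(0,1)) leaves the posterior unchanged while avoiding funnel geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, ndtr

from .psychometric import ConditionFlags, SubjectCoefficients

__all__ = [
    "FAMILIES",
    "StimulusBatch",
    "PopulationParams",
    "HyperpriorSpec",
    "aggregate_trials",
    "batches_to_arrays",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "HierarchicalModel",
]

#: Coefficient families in canonical order (3 threshold, 3 log10-slope, lapse).
FAMILIES = (
    "alpha_AT",
    "alpha_AT_minus_T",
    "alpha_AT_minus_A",
    "beta_AT",
    "beta_AT_minus_T",
    "beta_AT_minus_A",
    "lambda",
)

_LN10 = np.log(10.0)
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class StimulusBatch:
    """One aggregated binomial observation: subject x condition x position.

    ``subject_index`` is zero-based; ``n`` trials at position ``x`` cm of which
    ``y`` drew a "right" report.
    """

    subject_index: int
    flags: ConditionFlags
    x: float
    n: int
    y: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0 <= self.y <= self.n):
            raise ValueError(f"y must be in [0, n], got y={self.y}, n={self.n}")
        if not np.isfinite(self.x):
            raise ValueError("x must be finite")


@dataclass(frozen=True)
class PopulationParams:
    """Group-level means and SDs for the seven coefficient families.

    ``mu`` and ``sigma`` are length-7 arrays ordered as :data:`FAMILIES`.
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        if mu.shape != (7,) or sigma.shape != (7,):
            raise ValueError("mu and sigma must each have 7 entries")
        if not np.all(sigma > 0):
            raise ValueError("all sigma must be > 0")

    def family(self, name: str) -> tuple[float, float]:
        i = FAMILIES.index(name)
        return float(self.mu[i]), float(self.sigma[i])


@dataclass(frozen=True)
class HyperpriorSpec:
    """Hyperprior table: per family, mu ~ Normal(loc, scale), sigma ~ half-Normal(0, scale).

    The table is identical for both experiments; ``experiment`` and
    ``stimulus_range_cm`` record which adaptive-procedure / stimulus range the
    dataset came from (2.0 cm or 3.0 cm half-range).
    """

    experiment: int = 2
    stimulus_range_cm: float = 3.0
    mu_loc: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0, 0.0, 0.0, -4.0]))
    mu_scale: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.5, 0.5, 0.5, 0.25, 0.25, 1.0]))
    sigma_scale: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.5, 0.5, 0.5, 0.25, 0.25, 1.0]))

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        for name in ("mu_loc", "mu_scale", "sigma_scale"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (7,):
                raise ValueError(f"{name} must have 7 entries")
        if not (np.all(self.mu_scale > 0) and np.all(self.sigma_scale > 0)):
            raise ValueError("hyperprior scales must be > 0")

    @classmethod
    def for_experiment(cls, experiment: int) -> "HyperpriorSpec":
        if experiment == 1:
            return cls(experiment=1, stimulus_range_cm=2.0)
        if experiment == 2:
            return cls(experiment=2, stimulus_range_cm=3.0)
        raise ValueError("experiment must be 1 or 2")

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "stimulus_range_cm": self.stimulus_range_cm,
            "families": {
                fam: {
                    "mu_loc": float(self.mu_loc[i]),
                    "mu_scale": float(self.mu_scale[i]),
                    "sigma_scale": float(self.sigma_scale[i]),
                }
                for i, fam in enumerate(FAMILIES)
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HyperpriorSpec":
        fams = d["families"]
        return cls(
            experiment=int(d["experiment"]),
            stimulus_range_cm=float(d["stimulus_range_cm"]),
            mu_loc=np.array([fams[f]["mu_loc"] for f in FAMILIES]),
            mu_scale=np.array([fams[f]["mu_scale"] for f in FAMILIES]),
            sigma_scale=np.array([fams[f]["sigma_scale"] for f in FAMILIES]),
        )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_trials(trials: pd.DataFrame | Iterable) -> list[StimulusBatch]:
    """Collapse trial-level records into binomial batches.

    One batch per unique (subject, condition, x): ``n`` = trial count,
    ``y`` = number of "right" (1) responses.  Accepts a DataFrame with columns
    ``subject``, ``condition``, ``x_cm``, ``response`` (extra columns ignored)
    or an iterable of objects/dicts with those attributes.  Subject indices are
    assigned by order of first appearance and stored zero-based.
    """
    df = _as_trial_frame(trials)
    if "experiment" in df.columns and df["experiment"].nunique() > 1:
        raise ValueError(
            f"trials mix experiment tags {sorted(df['experiment'].unique())}; aggregate one experiment at a time"
        )
    bad = ~df["response"].isin([0, 1])
    if bad.any():
        raise ValueError(f"response outside {{0,1}} at row {int(np.flatnonzero(bad)[0])}")
    subj_order = pd.unique(df["subject"])
    subj_idx = pd.Series(np.arange(len(subj_order)), index=subj_order)
    grouped = (
        df.assign(si=subj_idx[df["subject"]].to_numpy())
        .groupby(["si", "condition", "x_cm"], sort=True)["response"]
        .agg(n="count", y="sum")
        .reset_index()
    )
    return [
        StimulusBatch(
            subject_index=int(row.si),
            flags=ConditionFlags.from_label(row.condition),
            x=float(row.x_cm),
            n=int(row.n),
            y=int(row.y),
        )
        for row in grouped.itertuples(index=False)
    ]


def _as_trial_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    rows = []
    for t in trials:
        if isinstance(t, dict):
            rows.append(t)
        else:
            rows.append(
                {
                    "subject": t.subject,
                    "condition": t.condition,
                    "x_cm": t.x_cm,
                    "response": t.response,
                    **({"experiment": t.experiment} if hasattr(t, "experiment") else {}),
                }
            )
    return pd.DataFrame(rows)


def batches_to_arrays(batches: Sequence[StimulusBatch]) -> dict[str, np.ndarray]:
    """Column arrays (subject, isT, isA, x, n, y) for vectorized evaluation."""
    return {
        "subject": np.array([b.subject_index for b in batches], dtype=np.intp),
        "isT": np.array([b.flags.isT for b in batches], dtype=float),
        "isA": np.array([b.flags.isA for b in batches], dtype=float),
        "x": np.array([b.x for b in batches], dtype=float),
        "n": np.array([b.n for b in batches], dtype=float),
        "y": np.array([b.y for b in batches], dtype=float),
    }


# ---------------------------------------------------------------------------
# Log densities (spec surface, centered coefficients)
# ---------------------------------------------------------------------------

def _coef_matrix(coefs: Sequence[SubjectCoefficients] | np.ndarray) -> np.ndarray:
    if isinstance(coefs, np.ndarray):
        C = np.atleast_2d(np.asarray(coefs, dtype=float))
    else:
        C = np.array([c.as_array() for c in coefs], dtype=float)
    if C.size and C.shape[1] != 7:
        raise ValueError("coefficients must have 7 columns")
    return C


def _phi_from_coefs(C: np.ndarray, arr: dict[str, np.ndarray]) -> np.ndarray:
    s = arr["subject"]
    a = C[s, 0] + C[s, 1] * arr["isT"] + C[s, 2] * arr["isA"]
    b = 10.0 ** (C[s, 3] + C[s, 4] * arr["isT"] + C[s, 5] * arr["isA"])
    lam = expit(C[s, 6])
    z = b * (arr["x"] - a)
    # lambda + (1-2*lambda)/2 * erfc(-z/sqrt(2)) == lambda + (1-2*lambda) * Phi(z)
    return lam + (1.0 - 2.0 * lam) * ndtr(z)


def log_likelihood(
    batches: Sequence[StimulusBatch],
    coefs: Sequence[SubjectCoefficients] | np.ndarray,
) -> float:
    """Binomial log likelihood sum_i log Binom(y_i | n_i, phi_i).

    Includes the parameter-free normalizing constant log C(n, y).  Returns
    ``-inf`` (rather than raising) when some phi is 0 with y > 0 or 1 with
    y < n, which can only happen at lapse exactly 0 under extreme positions.
    """
    if len(batches) == 0:
        return 0.0
    C = _coef_matrix(coefs)
    arr = batches_to_arrays(batches)
    if arr["subject"].max() >= C.shape[0]:
        raise ValueError("batch references a subject index beyond the coefficient table")
    phi = _phi_from_coefs(C, arr)
    n, y = arr["n"], arr["y"]
    const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(phi), 0.0) + np.where(n - y > 0, (n - y) * np.log1p(-phi), 0.0)
    if np.isnan(term).any():
        return float("-inf")
    return float(np.sum(const + term))


def _normal_logpdf(x, loc, scale):
    z = (np.asarray(x) - loc) / scale
    return -0.5 * z * z - np.log(scale) - _LOG_SQRT_2PI


def _halfnormal_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    out = np.where(
        x >= 0,
        0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2,
        -np.inf,
    )
    return out


def log_prior(
    pop: PopulationParams,
    coefs: Sequence[SubjectCoefficients] | np.ndarray,
    spec: HyperpriorSpec,
) -> float:
    """Log prior: subject coefficients ~ Normal(mu_f, sigma_f), plus hyperpriors.

    Hyperpriors: mu_f ~ Normal(loc_f, scale_f); sigma_f ~ half-Normal(0, scale_f)
    (the positivity-constrained reading of the printed normal scales).
    Support violations (sigma <= 0) yield ``-inf`` rather than raising.
    """
    if np.any(pop.sigma <= 0):
        return float("-inf")
    lp = float(np.sum(_normal_logpdf(pop.mu, spec.mu_loc, spec.mu_scale)))
    lp += float(np.sum(_halfnormal_logpdf(pop.sigma, spec.sigma_scale)))
    C = _coef_matrix(coefs)
    if C.size:
        lp += float(np.sum(_normal_logpdf(C, pop.mu[None, :], pop.sigma[None, :])))
    return lp


def log_posterior(
    batches: Sequence[StimulusBatch],
    pop: PopulationParams,
    coefs: Sequence[SubjectCoefficients] | np.ndarray,
    spec: HyperpriorSpec,
) -> float:
    """Joint log density log p(y | coefs) + log p(coefs, pop | spec)."""
    lp = log_prior(pop, coefs, spec)
    if not np.isfinite(lp):
        return float("-inf")
    return lp + log_likelihood(batches, coefs)


# ---------------------------------------------------------------------------
# Vectorized non-centered target for the sampler
# ---------------------------------------------------------------------------

class HierarchicalModel:
    """The sampler's target: non-centered unconstrained parameterization.

    Parameter vector layout (dimension ``14 + 7 K``)::

        q = [mu (7), log_sigma (7), z (K, 7) row-major]

    with ``coef[k, f] = mu[f] + exp(log_sigma[f]) * z[k, f]``.  The density is
    the joint posterior with the half-normal sigma prior expressed on the log
    scale (Jacobian included), so the whole vector is unconstrained.
    ``logp_grad`` returns the log density and its analytic gradient; the
    gradient is verified against finite differences in the test suite.
    """

    def __init__(self, batches: Sequence[StimulusBatch], spec: HyperpriorSpec, n_subjects: int | None = None):
        self.spec = spec
        arr = batches_to_arrays(batches)
        self.arr = arr
        inferred = int(arr["subject"].max()) + 1 if len(batches) else 0
        self.K = int(n_subjects) if n_subjects is not None else inferred
        if inferred > self.K:
            raise ValueError("batches reference more subjects than n_subjects")
        self.dim = 14 + 7 * self.K
        # binomial constant, parameter-free
        n, y = arr["n"], arr["y"]
        self._binom_const = float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))
        self.param_names = self._make_names()

    # -- layout helpers ----------------------------------------------------
    def unpack(self, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mu = q[:7]
        log_sigma = q[7:14]
        z = q[14:].reshape(self.K, 7)
        return mu, log_sigma, z

    def pack(self, mu, log_sigma, z) -> np.ndarray:
        return np.concatenate([np.asarray(mu), np.asarray(log_sigma), np.asarray(z).ravel()])

    def coefs(self, q: np.ndarray) -> np.ndarray:
        mu, log_sigma, z = self.unpack(q)
        return mu[None, :] + np.exp(log_sigma)[None, :] * z

    def _make_names(self) -> list[str]:
        names = [f"mu_{f}" for f in FAMILIES] + [f"sigma_{f}" for f in FAMILIES]
        for k in range(self.K):
            names += [f"z_{f}[{k}]" for f in FAMILIES]
        return names

    # -- density -----------------------------------------------------------
    def logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        spec = self.spec
        mu, log_sigma, z = self.unpack(q)
        sigma = np.exp(log_sigma)
        C = mu[None, :] + sigma[None, :] * z  # (K, 7)

        arr = self.arr
        s = arr["subject"]
        isT, isA, x, n, y = arr["isT"], arr["isA"], arr["x"], arr["n"], arr["y"]

        a = C[s, 0] + C[s, 1] * isT + C[s, 2] * isA
        bexp = C[s, 3] + C[s, 4] * isT + C[s, 5] * isA
        with np.errstate(over="ignore", invalid="ignore"):
            b = 10.0 ** bexp
            lam = expit(C[s, 6])
            t = b * (x - a)
        Phi = ndtr(np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf))
        phi = lam + (1.0 - 2.0 * lam) * Phi
        # guard exact 0/1 (possible only in float underflow with tiny lam)
        phi = np.clip(phi, 1e-300, 1.0 - 1e-16)
        ll = float(np.sum(y * np.log(phi) + (n - y) * np.log1p(-phi))) + self._binom_const
        if not np.isfinite(ll) or np.isnan(t).any():
            # unreachable under any plausible posterior mass; tell the sampler to reject
            return float("-inf"), np.zeros_like(q)

        # d loglik / d phi
        g_phi = y / phi - (n - y) / (1.0 - phi)
        pdf = np.exp(-0.5 * t * t) / np.sqrt(2.0 * np.pi)
        common = g_phi * (1.0 - 2.0 * lam) * pdf
        d_a = -common * b
        d_bexp = common * (x - a) * b * _LN10
        d_clam = g_phi * (1.0 - 2.0 * Phi) * lam * (1.0 - lam)

        # accumulate into coefficient gradient (K, 7)
        gC = np.zeros_like(C)
        np.add.at(gC[:, 0], s, d_a)
        np.add.at(gC[:, 1], s, d_a * isT)
        np.add.at(gC[:, 2], s, d_a * isA)
        np.add.at(gC[:, 3], s, d_bexp)
        np.add.at(gC[:, 4], s, d_bexp * isT)
        np.add.at(gC[:, 5], s, d_bexp * isA)
        np.add.at(gC[:, 6], s, d_clam)

        # priors
        lp = ll
        zmu = (mu - spec.mu_loc) / spec.mu_scale
        lp += float(np.sum(-0.5 * zmu**2 - np.log(spec.mu_scale) - _LOG_SQRT_2PI))
        # sigma ~ halfN(scale), on log scale with Jacobian log_sigma
        lp += float(
            np.sum(
                0.5 * np.log(2.0 / np.pi)
                - np.log(spec.sigma_scale)
                - 0.5 * (sigma / spec.sigma_scale) ** 2
                + log_sigma
            )
        )
        lp += float(np.sum(-0.5 * z**2 - _LOG_SQRT_2PI))

        g_mu = -zmu / spec.mu_scale + gC.sum(axis=0)
        g_log_sigma = -((sigma / spec.sigma_scale) ** 2) + 1.0 + np.sum(gC * z, axis=0) * sigma
        g_z = -z + gC * sigma[None, :]

        return lp, self.pack(g_mu, g_log_sigma, g_z)

    def logp(self, q: np.ndarray) -> float:
        return self.logp_grad(q)[0]

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Jittered start near the hyperprior center (z near 0, sigma at half scale)."""
        mu = self.spec.mu_loc + 0.1 * self.spec.mu_scale * rng.standard_normal(7)
        log_sigma = np.log(0.5 * self.spec.sigma_scale) + 0.1 * rng.standard_normal(7)
        z = 0.1 * rng.standard_normal((self.K, 7))
        return self.pack(mu, log_sigma, z)

    # -- constrained views for reporting ------------------------------------
    def constrained_draws(self, Q: np.ndarray) -> dict[str, np.ndarray]:
        """Map an array of unconstrained draws (..., dim) to named arrays.

        Returns population means/SDs per family plus per-subject centered
        coefficients ``coef_<family>`` with trailing subject axis.
        """
        Q = np.asarray(Q)
        mu = Q[..., :7]
        sigma = np.exp(Q[..., 7:14])
        z = Q[..., 14:].reshape(Q.shape[:-1] + (self.K, 7))
        coef = mu[..., None, :] + sigma[..., None, :] * z
        out: dict[str, np.ndarray] = {}
        for i, f in enumerate(FAMILIES):
            out[f"mu_{f}"] = mu[..., i]
            out[f"sigma_{f}"] = sigma[..., i]
            out[f"coef_{f}"] = coef[..., :, i]
        return out
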
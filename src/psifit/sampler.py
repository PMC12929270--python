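"""Posterior sampling and convergence diagnostics.

The sampler is a No-U-Turn sampler (dynamic Hamiltonian Monte Carlo with
multiplicative trajectory expansion and slice acceptance) on the model's
unconstrained non-centered parameter vector, using the analytic gradient from
:class:`~psifit.model.HierarchicalModel`.  Warmup follows the usual windowed
scheme: dual-averaging step-size adaptation throughout, with a diagonal mass
matrix re-estimated over expanding memory windows.

Reference run configuration mirrors the analysis this package reproduces:
4 chains x 5,000 iterations each, of which the first 2,500 are warmup and
discarded, for 10,000 retained draws in total.

Convergence gate (all must hold for ``DiagnosticsReport.passed``):
no divergences, no tree-depth saturation, every chain's E-BFMI > 0.2,
bulk-ESS > 10% of total draws, mean-MCSE < 10% of the posterior SD, and
rank-normalized split-Rhat <= 1.01 — each evaluated per scalar parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import arviz as az
import numpy as np

from .model import HierarchicalModel, HyperpriorSpec, StimulusBatch

__all__ = [
    "RunSettings",
    "PosteriorDraws",
    "DiagnosticsReport",
    "sample_posterior",
    "compute_diagnostics",
    "nuts",
]

_MAX_TREEDEPTH = 10
_DIVERGENCE_THRESHOLD = 1000.0  # energy error triggering a divergence


@dataclass(frozen=True)
class RunSettings:
    """Sampler run configuration (defaults = the reference fit)."""

    chains: int = 4
    warmup: int = 2500
    draws: int = 2500
    seed: int = 0
    max_treedepth: int = _MAX_TREEDEPTH
    target_accept: float = 0.95


@dataclass
class PosteriorDraws:
    """Retained posterior draws plus sampler telemetry.

    ``params`` maps parameter names to arrays of shape (chains, draws) for
    scalars or (chains, draws, K) for per-subject coefficient families.
    ``unconstrained`` keeps the raw (chains, draws, dim) sample for reuse.
    """

    chain_count: int
    draws_per_chain: int
    params: dict[str, np.ndarray]
    unconstrained: np.ndarray
    energy: np.ndarray  # (chains, draws)
    divergences: np.ndarray  # (chains, draws) bool
    treedepth_hits: np.ndarray  # (chains, draws) bool
    accept_stat: np.ndarray  # (chains, draws)
    seed: int = 0
    n_subjects: int = 0

    @property
    def total_draws(self) -> int:
        return self.chain_count * self.draws_per_chain

    def flat(self, name: str) -> np.ndarray:
        """All chains pooled: shape (total_draws,) or (total_draws, K)."""
        a = self.params[name]
        return a.reshape(self.total_draws, *a.shape[2:])

    def scalar_params(self) -> dict[str, np.ndarray]:
        """Per-scalar view: subject-coefficient families expanded with [k] suffixes."""
        out: dict[str, np.ndarray] = {}
        for name, a in self.params.items():
            if a.ndim == 2:
                out[name] = a
            else:
                for k in range(a.shape[2]):
                    out[f"{name}[{k}]"] = a[:, :, k]
        return out


@dataclass
class DiagnosticsReport:
    """Convergence diagnostics with the pass/fail gate.

    ``None`` entries in the HMC-specific fields mean the backend did not expose
    them (they are then excluded from the gate).  ``failures`` lists the gate
    clauses that did not hold; the report never raises on failure.
    """

    divergence_count: int | None
    max_treedepth_hit: bool | None
    ebfmi: np.ndarray | None
    ess: dict[str, float]
    mcse: dict[str, float]
    posterior_sd: dict[str, float]
    rhat: dict[str, float]
    total_draws: int
    failures: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failures

    def to_dict(self) -> dict:
        return {
            "pass": self.passed,
            "failures": self.failures,
            "divergence_count": self.divergence_count,
            "max_treedepth_hit": self.max_treedepth_hit,
            "ebfmi": None if self.ebfmi is None else [float(v) for v in self.ebfmi],
            "total_draws": self.total_draws,
            "worst_rhat": max(self.rhat.values()) if self.rhat else None,
            "min_ess": min(self.ess.values()) if self.ess else None,
            "rhat": {k: float(v) for k, v in self.rhat.items()},
            "ess": {k: float(v) for k, v in self.ess.items()},
            "mcse": {k: float(v) for k, v in self.mcse.items()},
            "posterior_sd": {k: float(v) for k, v in self.posterior_sd.items()},
        }


# ---------------------------------------------------------------------------
# NUTS core
# ---------------------------------------------------------------------------

def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    lp, grad = logp_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, lp, grad


def _kinetic(p, inv_mass) -> float:
    with np.errstate(over="ignore"):
        return 0.5 * float(np.dot(p, inv_mass * p))


class _Tree:
    __slots__ = ("q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
                 "q_prop", "lp_prop", "g_prop", "n_valid", "stop", "diverged",
                 "alpha", "n_alpha")


def _build_tree(logp_grad, q, p, grad, log_u, direction, depth, eps, inv_mass, H0, rng):
    """Recursive doubling; slice-sampling variant of the no-U-turn tree."""
    t = _Tree()
    if depth == 0:
        q1, p1, lp1, g1 = _leapfrog(logp_grad, q, p, grad, direction * eps, inv_mass)
        H1 = lp1 - _kinetic(p1, inv_mass)
        t.q_minus = t.q_plus = t.q_prop = q1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = t.g_prop = g1
        t.lp_prop = lp1
        t.n_valid = int(log_u <= H1)
        t.diverged = (H0 - H1) > _DIVERGENCE_THRESHOLD or not np.isfinite(H1)
        t.stop = t.diverged
        # NaN-safe: a non-finite Hamiltonian counts as a rejected step
        t.alpha = float(np.exp(min(0.0, H1 - H0))) if np.isfinite(H1) else 0.0
        t.n_alpha = 1
        return t

    t = _build_tree(logp_grad, q, p, grad, log_u, direction, depth - 1, eps, inv_mass, H0, rng)
    if not t.stop:
        if direction == -1:
            t2 = _build_tree(logp_grad, t.q_minus, t.p_minus, t.g_minus, log_u,
                             direction, depth - 1, eps, inv_mass, H0, rng)
            t.q_minus, t.p_minus, t.g_minus = t2.q_minus, t2.p_minus, t2.g_minus
        else:
            t2 = _build_tree(logp_grad, t.q_plus, t.p_plus, t.g_plus, log_u,
                             direction, depth - 1, eps, inv_mass, H0, rng)
            t.q_plus, t.p_plus, t.g_plus = t2.q_plus, t2.p_plus, t2.g_plus
        if t2.n_valid > 0 and rng.random() < t2.n_valid / max(t.n_valid + t2.n_valid, 1):
            t.q_prop, t.lp_prop, t.g_prop = t2.q_prop, t2.lp_prop, t2.g_prop
        t.n_valid += t2.n_valid
        t.diverged = t.diverged or t2.diverged
        t.stop = t2.stop or _uturn(t.q_minus, t.q_plus, t.p_minus, t.p_plus, inv_mass)
        t.alpha += t2.alpha
        t.n_alpha += t2.n_alpha
    return t


def _uturn(q_minus, q_plus, p_minus, p_plus, inv_mass) -> bool:
    dq = q_plus - q_minus
    return (np.dot(dq, inv_mass * p_minus) < 0) or (np.dot(dq, inv_mass * p_plus) < 0)


def _find_reasonable_epsilon(logp_grad, q, inv_mass, rng) -> float:
    eps = 1.0
    lp, grad = logp_grad(q)
    p = rng.standard_normal(q.shape) / np.sqrt(inv_mass)
    H0 = lp - _kinetic(p, inv_mass)
    q1, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
    H1 = lp1 - _kinetic(p1, inv_mass)
    if not np.isfinite(H1):
        H1 = -np.inf
    direction = 1.0 if (H1 - H0) > np.log(0.5) else -1.0
    for _ in range(60):
        eps *= 2.0**direction
        q1, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
        H1 = lp1 - _kinetic(p1, inv_mass)
        if not np.isfinite(H1):
            H1 = -np.inf
        if direction * (H1 - H0) <= direction * np.log(0.5):
            break
    return eps


def nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    q0: np.ndarray,
    warmup: int,
    draws: int,
    rng: np.random.Generator,
    max_treedepth: int = _MAX_TREEDEPTH,
    target_accept: float = 0.95,
) -> dict[str, np.ndarray]:
    """Run one NUTS chain; returns draws and per-iteration telemetry.

    Warmup schedule: 75 step-size-only iterations, then expanding diagonal
    metric windows (25, 50, 100, ...), then a final 50 step-size-only stretch
    (proportionally shrunk when ``warmup`` is small).  Dual averaging follows
    the standard Hoffman–Gelman settings (gamma=0.05, t0=10, kappa=0.75).
    """
    dim = q0.shape[0]
    lp0, _ = logp_grad(q0)
    if not np.isfinite(lp0):
        raise RuntimeError(
            "non-finite log posterior at the initial point; "
            "check data/prior compatibility or supply a different seed"
        )
    inv_mass = np.ones(dim)
    q = q0.copy()

    # warmup window boundaries (Stan-like, scaled to the warmup length)
    init_frac, term_frac = 0.15, 0.10
    n_init = max(int(init_frac * warmup), 1)
    n_term = max(int(term_frac * warmup), 1)
    windows = []
    w, pos = max(25 * warmup // 500, 5), n_init
    while pos + w < warmup - n_term:
        if pos + 3 * w >= warmup - n_term:
            w = warmup - n_term - pos  # absorb remainder into the last window
        windows.append((pos, pos + w))
        pos += w
        w *= 2

    eps = _find_reasonable_epsilon(logp_grad, q, inv_mass, rng)
    mu_da = np.log(10.0 * eps)
    log_eps_bar, H_bar = np.log(eps), 0.0
    m_adapt = 0  # dual-averaging clock, restarted at each metric update
    gamma, t0, kappa = 0.05, 10.0, 0.75

    samples = np.empty((draws, dim))
    energy = np.empty(draws)
    divergent = np.zeros(draws, dtype=bool)
    depth_hit = np.zeros(draws, dtype=bool)
    accept = np.empty(draws)

    window_buf: list[np.ndarray] = []
    lp, grad = logp_grad(q)

    for it in range(warmup + draws):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        H0 = lp - _kinetic(p0, inv_mass)
        log_u = H0 + np.log1p(-rng.random())  # log of u ~ U(0, exp(H0))
        q_minus = q_plus = q
        p_minus = p_plus = p0
        g_minus = g_plus = grad
        q_prop, lp_prop, g_prop = q, lp, grad
        n_valid, depth, stopped, diverged = 1, 0, False, False
        alpha_sum, n_alpha = 0.0, 0

        while depth < max_treedepth and not stopped:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                t = _build_tree(logp_grad, q_minus, p_minus, g_minus, log_u,
                                direction, depth, eps, inv_mass, H0, rng)
                q_minus, p_minus, g_minus = t.q_minus, t.p_minus, t.g_minus
            else:
                t = _build_tree(logp_grad, q_plus, p_plus, g_plus, log_u,
                                direction, depth, eps, inv_mass, H0, rng)
                q_plus, p_plus, g_plus = t.q_plus, t.p_plus, t.g_plus
            if not t.stop and t.n_valid > 0 and rng.random() < min(1.0, t.n_valid / n_valid):
                q_prop, lp_prop, g_prop = t.q_prop, t.lp_prop, t.g_prop
            n_valid += t.n_valid
            alpha_sum += t.alpha
            n_alpha += t.n_alpha
            diverged = diverged or t.diverged
            stopped = t.stop or _uturn(q_minus, q_plus, p_minus, p_plus, inv_mass)
            depth += 1

        q, lp, grad = q_prop, lp_prop, g_prop
        accept_prob = alpha_sum / max(n_alpha, 1)

        if it < warmup:
            # dual averaging
            m_adapt += 1
            m = m_adapt
            H_bar = (1 - 1 / (m + t0)) * H_bar + (target_accept - accept_prob) / (m + t0)
            log_eps = mu_da - np.sqrt(m) / gamma * H_bar
            w_da = m**-kappa
            log_eps_bar = w_da * log_eps + (1 - w_da) * log_eps_bar
            eps = float(np.exp(log_eps))
            # metric windows
            for (a, b) in windows:
                if a <= it < b:
                    window_buf.append(q.copy())
                    if it == b - 1 and len(window_buf) >= 10:
                        X = np.asarray(window_buf)
                        var = np.var(X, axis=0, ddof=1)
                        n_w = X.shape[0]
                        # regularized variance estimate
                        inv_mass = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                        window_buf = []
                        eps = _find_reasonable_epsilon(logp_grad, q, inv_mass, rng)
                        mu_da = np.log(10.0 * eps)
                        log_eps_bar, H_bar = np.log(eps), 0.0
                        m_adapt = 0
                    break
            if it == warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            i = it - warmup
            samples[i] = q
            energy[i] = -(lp - _kinetic(p0, inv_mass))
            divergent[i] = diverged
            depth_hit[i] = depth >= max_treedepth and not stopped
            accept[i] = accept_prob

    return {
        "samples": samples,
        "energy": energy,
        "divergent": divergent,
        "treedepth_hit": depth_hit,
        "accept": accept,
        "step_size": np.array(eps),
        "inv_mass": inv_mass,
    }


# ---------------------------------------------------------------------------
# Public surface
# ---------------------------------------------------------------------------

def sample_posterior(
    batches: Sequence[StimulusBatch],
    spec: HyperpriorSpec,
    settings: RunSettings | None = None,
    n_subjects: int | None = None,
) -> PosteriorDraws:
    """Draw from the hierarchical model's posterior with the given run settings.

    Deterministic given ``settings.seed``.  Chains run sequentially with
    independent seeds spawned from the run seed.
    """
    settings = settings or RunSettings()
    model = HierarchicalModel(batches, spec, n_subjects=n_subjects)
    root = np.random.SeedSequence(settings.seed)
    chain_seeds = root.spawn(settings.chains)

    all_q = np.empty((settings.chains, settings.draws, model.dim))
    energy = np.empty((settings.chains, settings.draws))
    divergent = np.empty((settings.chains, settings.draws), dtype=bool)
    depth_hit = np.empty((settings.chains, settings.draws), dtype=bool)
    accept = np.empty((settings.chains, settings.draws))

    for c in range(settings.chains):
        rng = np.random.default_rng(chain_seeds[c])
        q0 = model.initial_point(rng)
        res = nuts(
            model.logp_grad,
            q0,
            warmup=settings.warmup,
            draws=settings.draws,
            rng=rng,
            max_treedepth=settings.max_treedepth,
            target_accept=settings.target_accept,
        )
        all_q[c] = res["samples"]
        energy[c] = res["energy"]
        divergent[c] = res["divergent"]
        depth_hit[c] = res["treedepth_hit"]
        accept[c] = res["accept"]

    params = model.constrained_draws(all_q)
    return PosteriorDraws(
        chain_count=settings.chains,
        draws_per_chain=settings.draws,
        params=params,
        unconstrained=all_q,
        energy=energy,
        divergences=divergent,
        treedepth_hits=depth_hit,
        accept_stat=accept,
        seed=settings.seed,
        n_subjects=model.K,
    )


def compute_diagnostics(draws: PosteriorDraws, include_subject_level: bool = True) -> DiagnosticsReport:
    """Evaluate the convergence gate on a posterior sample.

    Rank-normalized split-Rhat and bulk-ESS via arviz; mean-MCSE taken as
    posterior SD / sqrt(bulk-ESS).  Gate thresholds: zero divergences, no
    tree-depth saturation, E-BFMI > 0.2 per chain, ESS > 0.10 x total draws,
    MCSE < 0.10 x posterior SD, Rhat <= 1.01.  Failures are recorded, never
    raised.
    """
    if draws.chain_count < 2:
        raise ValueError("diagnostics require at least 2 chains (split-Rhat is undefined otherwise)")
    scalars = draws.scalar_params()
    if not include_subject_level:
        scalars = {k: v for k, v in scalars.items() if not k.startswith("coef_")}

    ess, rhat, mcse, sd = {}, {}, {}, {}
    for name, a in scalars.items():
        da = az.convert_to_dataset({name: a})
        rhat[name] = float(az.rhat(da, method="rank")[name].values)
        ess[name] = float(az.ess(da, method="bulk")[name].values)
        s = float(np.std(a, ddof=1))
        sd[name] = s
        mcse[name] = s / np.sqrt(ess[name]) if ess[name] > 0 else np.inf

    failures: list[str] = []
    div_count = int(draws.divergences.sum())
    if div_count > 0:
        failures.append(f"{div_count} divergent transitions")
    depth_hit = bool(draws.treedepth_hits.any())
    if depth_hit:
        failures.append("maximum tree depth reached")
    ebfmi = az.bfmi(draws.energy)
    if np.any(ebfmi <= 0.2):
        failures.append(f"E-BFMI <= 0.2 in some chain ({np.min(ebfmi):.3f})")
    total = draws.total_draws
    bad_ess = [k for k, v in ess.items() if not v > 0.10 * total]
    if bad_ess:
        failures.append(f"ESS <= 10% of {total} for: {', '.join(sorted(bad_ess)[:5])}")
    bad_mcse = [k for k, v in mcse.items() if sd[k] > 0 and not v < 0.10 * sd[k]]
    if bad_mcse:
        failures.append(f"MCSE >= 10% of posterior SD for: {', '.join(sorted(bad_mcse)[:5])}")
    bad_rhat = [k for k, v in rhat.items() if not v <= 1.01]
    if bad_rhat:
        failures.append(f"Rhat > 1.01 for: {', '.join(sorted(bad_rhat)[:5])}")

    return DiagnosticsReport(
        divergence_count=div_count,
        max_treedepth_hit=depth_hit,
        ebfmi=np.asarray(ebfmi),
        ess=ess,
        mcse=mcse,
        posterior_sd=sd,
        rhat=rhat,
        total_draws=total,
        failures=failures,
    )
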
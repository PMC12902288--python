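"""Power-posterior sampling, thermodynamic-integration marginal
likelihoods and Bayes-factor model choice.

The marginal likelihood M = ln p(x) of a model is written as the path
integral over the power posteriors p_beta ∝ prior x likelihood^beta,

    M = integral_0^1  E_beta[ ln f(x | theta) ]  d beta,

estimated by Gauss-Legendre quadrature: nodes x_k on (-1, 1) are mapped
to beta_k = (x_k + 1)/2 while the original weights w_k are kept, and

    M = sum_k  w_k * E_k / 2,

where E_k is the Metropolis-Hastings estimate of the posterior mean
log-likelihood at beta_k (the /2 performs the change of interval).  The
Bayes factor between two models is B = exp(M1 - M0), with B > cutoff
(default 100) read as decisive support for model 1.

The Monte-Carlo SE of each E_k is estimated by batch means (robust to
chain autocorrelation) and propagated as sqrt(sum (w_k/2)^2 SE_k^2),
which assumes independent chains across beta values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ModelInterface",
    "PowerPosteriorSchedule",
    "MarginalLikelihoodEstimate",
    "BayesFactorResult",
    "power_schedule",
    "mh_sample",
    "log_marginal_ti",
    "bayes_factor",
    "conjugate_normal_model",
    "conjugate_normal_log_evidence",
    "sfs_model",
]


@dataclass
class ModelInterface:
    """Pluggable target for power-posterior MCMC.

    ``log_prior`` and ``log_likelihood`` map a parameter vector to a
    float; ``sample_prior(rng)`` draws an initial state; ``bounds`` is a
    (dim, 2) array (use +-inf for unbounded); ``proposal_scales`` sets
    the initial componentwise random-walk step sizes.
    """

    log_prior: Callable[[np.ndarray], float]
    log_likelihood: Callable[[np.ndarray], float]
    sample_prior: Callable[[np.random.Generator], np.ndarray]
    dim: int
    bounds: np.ndarray | None = None
    proposal_scales: np.ndarray | None = None


@dataclass
class PowerPosteriorSchedule:
    beta: np.ndarray  # strictly increasing, in (0, 1)
    weights: np.ndarray  # Gauss-Legendre weights on (-1, 1); sum = 2

    @property
    def k(self) -> int:
        return len(self.beta)


@dataclass
class MarginalLikelihoodEstimate:
    log_marginal: float
    se: float
    beta: np.ndarray
    e_loglik: np.ndarray  # per-beta mean log-likelihood E_k
    se_loglik: np.ndarray
    acceptance: np.ndarray
    ess: np.ndarray
    monotonicity_violations: int = 0


@dataclass
class BayesFactorResult:
    m1: float
    m0: float
    log_bf: float
    bayes_factor: float
    cutoff: float
    call: str


def power_schedule(k: int = 16) -> PowerPosteriorSchedule:
    """Gauss-Legendre power-posterior schedule with ``k`` quadrature points.

    Nodes are mapped from (-1, 1) to beta in (0, 1); the weights are the
    untransformed Gauss-Legendre weights (summing to 2), so the
    estimator sum(w * E / 2) carries the interval change.
    """
    if k < 2:
        raise ValueError("need at least 2 quadrature points")
    nodes, weights = np.polynomial.legendre.leggauss(k)
    return PowerPosteriorSchedule(beta=(nodes + 1.0) / 2.0, weights=weights)


def _batch_se(x: np.ndarray) -> tuple[float, float]:
    """Batch-means SE of the mean and effective sample size."""
    n = len(x)
    if n < 4:
        return float(np.std(x) / np.sqrt(max(n, 1))), float(n)
    nb = max(int(np.sqrt(n)), 2)
    bs = n // nb
    means = x[: nb * bs].reshape(nb, bs).mean(axis=1)
    se = float(means.std(ddof=1) / np.sqrt(nb))
    var = float(np.var(x, ddof=1))
    ess = var / (se**2) if se > 0 else float(n)
    return se, min(ess, float(n))


def mh_sample(
    model: ModelInterface,
    beta: float,
    n_burn: int = 10_000,
    n_samples: int = 1000,
    thin: int = 15,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> dict:
    """Metropolis-Hastings targeting prior x likelihood^beta.

    Componentwise Gaussian random-walk proposals; scales adapt toward a
    ~30% acceptance rate during burn-in only and are frozen afterwards
    (preserving detailed balance for the recorded samples).  Returns the
    thinned samples, per-sample log-likelihoods, their mean and
    batch-means SE, and diagnostics.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    x = np.atleast_1d(np.asarray(init if init is not None else model.sample_prior(rng),
                                 dtype=float))
    scales = (np.array(model.proposal_scales, dtype=float)
              if model.proposal_scales is not None else np.ones(model.dim))
    lo = hi = None
    if model.bounds is not None:
        b = np.asarray(model.bounds, dtype=float)
        lo, hi = b[:, 0], b[:, 1]
    lp = model.log_prior(x)
    ll = model.log_likelihood(x)
    if not np.isfinite(lp) or (beta > 0 and not np.isfinite(ll)):
        raise ValueError("initial state has non-finite prior or likelihood")
    accepted = np.zeros(model.dim)
    proposed = np.zeros(model.dim)

    def step(adapt: bool):
        nonlocal x, lp, ll
        for d in range(model.dim):
            prop = x.copy()
            prop[d] += rng.normal(0.0, scales[d])
            proposed[d] += 1
            if lo is not None and (prop[d] < lo[d] or prop[d] > hi[d]):
                new_lp = -np.inf
            else:
                new_lp = model.log_prior(prop)
            if np.isfinite(new_lp):
                new_ll = model.log_likelihood(prop)
                # beta = 0 targets the prior even where the likelihood is -inf
                pow_new = beta * new_ll if beta > 0 else 0.0
                pow_cur = beta * ll if beta > 0 else 0.0
                log_alpha = (new_lp + pow_new) - (lp + pow_cur)
                if np.log(rng.random()) < log_alpha:
                    x, lp, ll = prop, new_lp, new_ll
                    accepted[d] += 1
            if adapt and proposed[d] % 50 == 0:
                rate = accepted[d] / proposed[d]
                scales[d] *= np.exp(0.3 * (rate - 0.3))

    for _ in range(n_burn):
        step(adapt=True)
    if n_burn > 0 and accepted.sum() == 0:
        raise RuntimeError("zero acceptance during burn-in; rescale the proposals")
    accepted[:] = 0
    proposed[:] = 0
    samples = np.empty((n_samples, model.dim))
    logliks = np.empty(n_samples)
    for i in range(n_samples):
        for _ in range(thin):
            step(adapt=False)
        samples[i] = x
        logliks[i] = ll
    se, ess = _batch_se(logliks)
    return {
        "samples": samples,
        "logliks": logliks,
        "mean_loglik": float(logliks.mean()),
        "se_loglik": se,
        "ess": ess,
        "acceptance": float(accepted.sum() / max(proposed.sum(), 1)),
        "scales": scales,
    }


def log_marginal_ti(
    model: ModelInterface,
    schedule: PowerPosteriorSchedule | None = None,
    n_burn: int = 1000,
    n_samples: int = 1000,
    thin: int = 5,
    seed: int = 0,
) -> MarginalLikelihoodEstimate:
    """Thermodynamic-integration log marginal likelihood.

    Runs one MH chain per beta_k and combines the per-beta mean
    log-likelihoods as M = sum(w_k * E_k / 2).  E_k should be
    non-decreasing in beta in expectation; violations beyond Monte-Carlo
    error are counted in ``monotonicity_violations`` (flagged, not
    failed — they indicate under-sampling).
    """
    schedule = schedule or power_schedule()
    k = schedule.k
    e = np.empty(k)
    se = np.empty(k)
    acc = np.empty(k)
    ess = np.empty(k)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]
    for i, beta in enumerate(schedule.beta):
        try:
            res = mh_sample(model, float(beta), n_burn=n_burn,
                            n_samples=n_samples, thin=thin, seed=child_seeds[i])
        except RuntimeError as exc:
            raise RuntimeError(f"MH failure at beta={beta:.4f}: {exc}") from exc
        e[i], se[i], acc[i], ess[i] = (res["mean_loglik"], res["se_loglik"],
                                       res["acceptance"], res["ess"])
    m = float((schedule.weights * e / 2.0).sum())
    m_se = float(np.sqrt(((schedule.weights / 2.0) ** 2 * se**2).sum()))
    viol = int(((e[1:] - e[:-1]) < -3.0 * np.hypot(se[1:], se[:-1])).sum())
    return MarginalLikelihoodEstimate(
        log_marginal=m, se=m_se, beta=schedule.beta, e_loglik=e, se_loglik=se,
        acceptance=acc, ess=ess, monotonicity_violations=viol,
    )


def bayes_factor(m1: float, m0: float, cutoff: float = 100.0) -> BayesFactorResult:
    """Bayes factor B = exp(M1 - M0) with a decisive-support call.

    ``call`` is "model 1" when B > cutoff, "model 0" when B < 1/cutoff,
    otherwise "undetermined".
    """
    if not (np.isfinite(m1) and np.isfinite(m0)):
        raise ValueError("log marginal likelihoods must be finite")
    log_bf = float(m1) - float(m0)
    b = float(np.exp(log_bf))
    if b > cutoff:
        call = "model 1"
    elif b < 1.0 / cutoff:
        call = "model 0"
    else:
        call = "undetermined"
    return BayesFactorResult(m1=float(m1), m0=float(m0), log_bf=log_bf,
                             bayes_factor=b, cutoff=cutoff, call=call)


# ---------------------------------------------------------------------------
# built-in models


def conjugate_normal_model(
    data: np.ndarray,
    sigma: float = 1.0,
    prior_mean: float = 0.0,
    prior_sd: float = 1.0,
) -> ModelInterface:
    """Normal likelihood with known sigma and a normal prior on the mean.

    The closed-form evidence (:func:`conjugate_normal_log_evidence`)
    makes this the validation target for the TI machinery.
    """
    y = np.asarray(data, dtype=float)
    n = len(y)
    sy, syy = y.sum(), (y**2).sum()
    const = -0.5 * n * np.log(2.0 * np.pi * sigma**2)

    def log_lik(theta: np.ndarray) -> float:
        mu = theta[0]
        return const - 0.5 * (syy - 2.0 * mu * sy + n * mu**2) / sigma**2

    def log_prior(theta: np.ndarray) -> float:
        z = (theta[0] - prior_mean) / prior_sd
        return -0.5 * np.log(2.0 * np.pi * prior_sd**2) - 0.5 * z * z

    return ModelInterface(
        log_prior=log_prior,
        log_likelihood=log_lik,
        sample_prior=lambda rng: np.array([rng.normal(prior_mean, prior_sd)]),
        dim=1,
        proposal_scales=np.array([prior_sd]),
    )


def conjugate_normal_log_evidence(
    data: np.ndarray, sigma: float = 1.0, prior_mean: float = 0.0, prior_sd: float = 1.0
) -> float:
    """Closed-form log marginal likelihood of the conjugate normal model:
    the data are jointly normal with mean ``prior_mean`` and covariance
    sigma^2 I + prior_sd^2 J."""
    y = np.asarray(data, dtype=float)
    n = len(y)
    cov = sigma**2 * np.eye(n) + prior_sd**2 * np.ones((n, n))
    diff = y - prior_mean
    sign, logdet = np.linalg.slogdet(cov)
    quad = diff @ np.linalg.solve(cov, diff)
    return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + quad))


def sfs_model(
    obs,
    template: str,
    priors: dict,
    fixed: dict | None = None,
    sims_per_eval: int = 150,
    sim_seed: int = 1,
    sampling: dict[str, int] | None = None,
) -> ModelInterface:
    """Adapter exposing the SFS composite log-likelihood to the TI sampler.

    ``priors`` maps parameter names to frozen scipy distributions (e.g.
    ``{"phi": scipy.stats.beta(6, 200)}``); remaining template
    parameters are pinned by ``fixed``.  The composite likelihood is
    treated as a likelihood, which is known to overstate evidence under
    linkage — interpret the resulting Bayes factors qualitatively.
    Common random numbers (``sim_seed``) keep the surface deterministic.
    """
    from . import demography

    names = list(priors)
    dists = [priors[n] for n in names]
    fixed = dict(fixed or {})
    tpl = demography.PAIR_TEMPLATES[template]
    samp = demography._sampling_for(obs, sampling)

    def log_prior(theta: np.ndarray) -> float:
        return float(sum(d.logpdf(t) for d, t in zip(dists, theta)))

    def log_lik(theta: np.ndarray) -> float:
        params = dict(fixed)
        params.update({n: float(t) for n, t in zip(names, theta)})
        try:
            probs = demography.expected_sfs(tpl["factory"](params), samp,
                                            n_sims=sims_per_eval, seed=sim_seed)
            return demography.composite_loglik(obs, probs)
        except Exception:
            return -np.inf

    def sample_prior(rng: np.random.Generator) -> np.ndarray:
        return np.array([d.rvs(random_state=rng) for d in dists], dtype=float)

    scales = np.array([max(d.std() / 2.0, 1e-6) for d in dists])
    return ModelInterface(log_prior=log_prior, log_likelihood=log_lik,
                          sample_prior=sample_prior, dim=len(names),
                          proposal_scales=scales)
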
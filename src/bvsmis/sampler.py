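"""Spike-and-slab Metropolis-Hastings-within-Gibbs sampler with profiled theta.

Hierarchical prior:

    theta ~ Dirichlet(1)                       (handled by profiling, see below)
    beta_p | gamma_p ~ gamma_p N(0, b^2) + (1 - gamma_p) delta_0
    gamma_p | omega ~ Bernoulli(omega)
    omega ~ Beta(w1, w2)

The baseline interval probabilities theta are nuisance parameters: at every proposal
they are profiled out (maximized, not sampled), so the chain targets an approximate
profiled posterior over (gamma, beta, omega).  Each iteration performs one add/delete
flip move, then for each currently included covariate independently with probability
``p_main`` one random-walk refine move, then a conjugate Gibbs draw of omega from
Beta(w1 + K, w2 + P - K).  Covariates are ranked by their posterior inclusion
probabilities (post-burn-in frequency of gamma_p = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kernels import PROFILE_MAXITER, PROFILE_TOL, profile_theta_kernel
from .likelihood import ModelData, ProfileError

logger = logging.getLogger("bvsmis")

__all__ = [
    "Hyperparameters",
    "SamplerState",
    "ChainSummary",
    "initialize_state",
    "flip_move",
    "flip_delta",
    "refine_move",
    "refine_delta",
    "gibbs_omega",
    "run_chain",
    "inclusion_probabilities",
]


@dataclass(frozen=True)
class Hyperparameters:
    """Prior and run-length settings for the spike-and-slab sampler.

    ``b`` is the slab standard deviation, ``(w1, w2)`` the Beta prior shapes for the
    inclusion probability omega, ``p_main`` the per-included-covariate refine
    probability.  Defaults follow the reference simulation configuration.
    """

    b: float = 1.0
    w1: float = 5.0
    w2: float = 100.0
    p_main: float = 0.30
    n_iter: int = 100_000
    burn_in: int = 20_000

    def __post_init__(self) -> None:
        if self.b <= 0 or self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("b, w1, w2 must be positive")
        if not (0.0 < self.p_main < 1.0):
            raise ValueError("p_main must lie in (0, 1)")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must be smaller than n_iter")


@dataclass
class SamplerState:
    """Current (gamma, beta, omega, theta) of the chain with cached quantities.

    ``eta`` caches the linear predictor Z @ beta so single-coordinate proposals cost
    O(N); ``loglik`` caches the profiled log-likelihood at (theta, beta).
    """

    gamma: np.ndarray
    beta: np.ndarray
    omega: float
    theta: np.ndarray
    loglik: float
    eta: np.ndarray

    @property
    def K_gamma(self) -> int:
        return int(self.gamma.sum())


@dataclass
class ChainSummary:
    """Post-burn-in inclusion counts plus run diagnostics."""

    inclusion_counts: np.ndarray
    kept_iterations: int
    seed: int | None
    hyper: Hyperparameters
    flip_acceptance: float
    refine_acceptance: float
    profile_failures: int
    names: list[str] = field(default_factory=list)
    trace: dict[str, np.ndarray] | None = None


def _profile_at(
    data: ModelData,
    eta: np.ndarray,
    warm: np.ndarray,
    fail_counter: list | None = None,
) -> tuple[np.ndarray, float, bool]:
    M = data.n_intervals
    # exp(700) is already astronomically beyond any plausible hazard ratio; the clip
    # only prevents overflow warnings for proposals the chain will reject anyway
    h = np.exp(np.minimum(eta, 700.0))
    try:
        theta, ll, status = profile_theta_kernel(data.raw, h, warm, PROFILE_TOL, PROFILE_MAXITER)
        if status == 1 and np.isfinite(ll):
            return theta, ll, True
        theta, ll, status = profile_theta_kernel(
            data.raw, h, np.full(M, 1.0 / M), PROFILE_TOL, PROFILE_MAXITER
        )
    except np.linalg.LinAlgError:
        theta, ll, status = np.full(M, 1.0 / M), -np.inf, 3
    ok = bool(status == 1 and np.isfinite(ll))
    # status 0 is a zero-likelihood proposal (correctly rejected), not an optimizer failure
    if not ok and status != 0 and fail_counter is not None:
        fail_counter[0] += 1
    return theta, ll, ok


def initialize_state(data: ModelData, hyper: Hyperparameters, rng: np.random.Generator) -> SamplerState:
    """Empty model start: gamma = beta = 0, omega ~ Beta(w1, w2), theta profiled at beta = 0."""
    P = data.n_covariates
    omega = float(rng.beta(hyper.w1, hyper.w2))
    eta = np.zeros(data.n_subjects)
    M = data.n_intervals
    theta, ll, ok = _profile_at(data, eta, np.full(M, 1.0 / M))
    if not ok:
        raise ProfileError(
            "theta profile failed at the null model: the data are impossible under the "
            "assumed sensitivity/specificity (check NTFP truncation for a perfect test)"
        )
    return SamplerState(
        gamma=np.zeros(P, dtype=np.int8),
        beta=np.zeros(P),
        omega=omega,
        theta=theta,
        loglik=float(ll),
        eta=eta,
    )


def flip_delta(
    state: SamplerState,
    data: ModelData,
    hyper: Hyperparameters,
    p: int,
    beta_p_new: float,
    _fail_counter: list | None = None,
) -> tuple[float, np.ndarray, float, np.ndarray, bool]:
    """Log acceptance ratio of flipping covariate p to coefficient ``beta_p_new``.

    Returns (delta, theta_new, ll_new, eta_new, ok).  Delta is the profiled
    log-likelihood difference plus the prior log-odds term
    (2 gamma*_p - 1) logit(omega): the N(0, b^2) slab prior of an entering
    coefficient cancels exactly against its proposal density, so neither appears.
    """
    turning_on = state.gamma[p] == 0
    eta_new = state.eta + (beta_p_new - state.beta[p]) * data.Z[:, p]
    theta_new, ll_new, ok = _profile_at(data, eta_new, state.theta, _fail_counter)
    if not ok:
        return -np.inf, theta_new, ll_new, eta_new, False
    sign = 1.0 if turning_on else -1.0
    delta = ll_new - state.loglik + sign * (np.log(state.omega) - np.log1p(-state.omega))
    return float(delta), theta_new, float(ll_new), eta_new, True


def flip_move(
    state: SamplerState,
    data: ModelData,
    hyper: Hyperparameters,
    rng: np.random.Generator,
    _fail_counter: list | None = None,
) -> tuple[SamplerState, bool]:
    """Add/delete move: flip the inclusion indicator of one random covariate.

    Turning a covariate on draws its coefficient from the slab N(0, b^2); turning it
    off sets the coefficient to exactly zero.  Theta is re-profiled at the proposal
    and the move is accepted with probability min(e^Delta, 1).
    """
    P = data.n_covariates
    p = int(rng.integers(P))
    turning_on = state.gamma[p] == 0
    beta_p_new = float(rng.normal(0.0, hyper.b)) if turning_on else 0.0
    delta, theta_new, ll_new, eta_new, ok = flip_delta(
        state, data, hyper, p, beta_p_new, _fail_counter
    )
    if not ok:
        logger.debug("profile failure on flip proposal for covariate %d: rejected", p)
        return state, False
    if np.log(rng.random()) < delta:
        gamma = state.gamma.copy()
        beta = state.beta.copy()
        gamma[p] = 1 - gamma[p]
        beta[p] = beta_p_new
        new = SamplerState(gamma, beta, state.omega, theta_new, ll_new, eta_new)
        return new, True
    return state, False


def refine_delta(
    state: SamplerState,
    data: ModelData,
    hyper: Hyperparameters,
    p: int,
    beta_p_new: float,
    _fail_counter: list | None = None,
) -> tuple[float, np.ndarray, float, np.ndarray, bool]:
    """Log acceptance ratio of moving included coefficient p to ``beta_p_new``.

    The random-walk proposal N(beta_p, b^2) is symmetric, so Delta is the profiled
    log-likelihood difference plus the slab-prior ratio
    (beta_p^2 - beta*_p^2) / (2 b^2).
    """
    if state.gamma[p] != 1:
        raise ValueError(f"refine move proposed for excluded covariate {p}")
    eta_new = state.eta + (beta_p_new - state.beta[p]) * data.Z[:, p]
    theta_new, ll_new, ok = _profile_at(data, eta_new, state.theta, _fail_counter)
    if not ok:
        return -np.inf, theta_new, ll_new, eta_new, False
    delta = (
        ll_new
        - state.loglik
        + (state.beta[p] ** 2 - beta_p_new**2) / (2.0 * hyper.b**2)
    )
    return float(delta), theta_new, float(ll_new), eta_new, True


def refine_move(
    state: SamplerState,
    data: ModelData,
    hyper: Hyperparameters,
    p: int,
    rng: np.random.Generator,
    _fail_counter: list | None = None,
) -> tuple[SamplerState, bool]:
    """Random-walk update of an included coefficient: beta*_p ~ N(beta_p, b^2)."""
    beta_p_new = float(rng.normal(state.beta[p], hyper.b))
    delta, theta_new, ll_new, eta_new, ok = refine_delta(
        state, data, hyper, p, beta_p_new, _fail_counter
    )
    if not ok:
        logger.debug("profile failure on refine proposal for covariate %d: rejected", p)
        return state, False
    if np.log(rng.random()) < delta:
        beta = state.beta.copy()
        beta[p] = beta_p_new
        new = SamplerState(state.gamma, beta, state.omega, theta_new, ll_new, eta_new)
        return new, True
    return state, False


def gibbs_omega(state: SamplerState, hyper: Hyperparameters, P: int, rng: np.random.Generator) -> float:
    """Conjugate update: omega ~ Beta(w1 + K_gamma, w2 + P - K_gamma)."""
    K = state.K_gamma
    return float(rng.beta(hyper.w1 + K, hyper.w2 + P - K))


def run_chain(
    data: ModelData,
    hyper: Hyperparameters,
    seed: int | np.random.Generator,
    keep_trace: bool = False,
) -> ChainSummary:
    """Run the full MH-within-Gibbs chain and tally post-burn-in inclusions.

    Each iteration: one flip move; for each included covariate (ascending index,
    snapshot taken after the flip) an independent Bernoulli(p_main) gate on a refine
    move; one Gibbs omega draw.  Fully reproducible from the seed.
    """
    if isinstance(seed, np.random.Generator):
        rng, seed_echo = seed, None
    else:
        rng, seed_echo = np.random.default_rng(seed), int(seed)
    P = data.n_covariates
    state = initialize_state(data, hyper, rng)
    counts = np.zeros(P, dtype=np.int64)
    flip_acc = 0
    refine_att = 0
    refine_acc = 0
    fails = [0]
    trace_K = np.empty(hyper.n_iter, dtype=np.int32) if keep_trace else None
    trace_ll = np.empty(hyper.n_iter) if keep_trace else None
    trace_om = np.empty(hyper.n_iter) if keep_trace else None
    p_main = hyper.p_main
    for t in range(hyper.n_iter):
        state, accepted = flip_move(state, data, hyper, rng, fails)
        flip_acc += accepted
        included = np.flatnonzero(state.gamma)
        for p in included:
            if rng.random() < p_main:
                refine_att += 1
                state, acc = refine_move(state, data, hyper, int(p), rng, fails)
                refine_acc += acc
        state.omega = gibbs_omega(state, hyper, P, rng)
        if t >= hyper.burn_in:
            counts += state.gamma
        if keep_trace:
            trace_K[t] = state.K_gamma
            trace_ll[t] = state.loglik
            trace_om[t] = state.omega
    kept = hyper.n_iter - hyper.burn_in
    trace = (
        {"K_gamma": trace_K, "loglik": trace_ll, "omega": trace_om} if keep_trace else None
    )
    return ChainSummary(
        inclusion_counts=counts,
        kept_iterations=kept,
        seed=seed_echo,
        hyper=hyper,
        flip_acceptance=flip_acc / hyper.n_iter,
        refine_acceptance=refine_acc / refine_att if refine_att else float("nan"),
        profile_failures=fails[0],
        names=list(data.names),
        trace=trace,
    )


def inclusion_probabilities(summary: ChainSummary) -> tuple[np.ndarray, np.ndarray]:
    """Posterior inclusion probabilities and the best-first covariate ranking.

    Ties are broken by ascending covariate index (stable), so with all-zero counts the
    ranking is simply index order.
    """
    if summary.kept_iterations <= 0:
        raise ValueError("no kept iterations: cannot form inclusion probabilities")
    probs = summary.inclusion_counts / summary.kept_iterations
    order = np.lexsort((np.arange(probs.size), -probs))
    return probs, order
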
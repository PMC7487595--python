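"""Interval-censored proportional-hazards likelihood with misclassified self-reports.

A subject's disease status is assessed by an error-prone binary self-report at each
scheduled visit.  The true event time X is never observed; the likelihood integrates
over which of the J+1 intervals defined by the pooled visit times contains X, weighting
interval j by the probability ``D_ij`` of the observed report sequence given X in that
interval.  Sensitivity ``phi1`` governs reports at or after X, specificity ``phi0``
reports strictly before X.  Under the proportional-hazards model the probability that
X falls in interval j for a subject with linear predictor eta is
``S_{j-1}^{exp(eta)} - S_j^{exp(eta)}`` where S_j is the baseline survival at tau_j,
a function of the interval-probability vector theta.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from ._kernels import (
    EPS,
    PROFILE_MAXITER,
    PROFILE_TOL,
    loglik_raw,
    profile_theta_kernel,
    subject_likelihoods,
)

logger = logging.getLogger("bvsmis")

__all__ = [
    "TestAccuracy",
    "SelfReportPanel",
    "IntervalPartition",
    "ObservationMatrix",
    "CovariateMatrix",
    "ModelData",
    "ProfileError",
    "FitResult",
    "build_partition",
    "observation_matrix",
    "log_likelihood",
    "profile_theta",
    "fit_ml",
    "univariate_screen",
    "validate_theta",
]


class ProfileError(RuntimeError):
    """Raised when the theta-profile optimizer fails even after restart."""


@dataclass(frozen=True)
class TestAccuracy:
    """Sensitivity/specificity of the binary self-report, both in (0, 1]."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for name, v in (("sensitivity", self.sensitivity), ("specificity", self.specificity)):
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")

    @property
    def perfect(self) -> bool:
        return self.sensitivity == 1.0 and self.specificity == 1.0


PERFECT = TestAccuracy(1.0, 1.0)


@dataclass
class SelfReportPanel:
    """One subject's visit times (years since enrollment) and binary self-reports."""

    subject_id: str
    times: np.ndarray
    results: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.results = np.asarray(self.results, dtype=np.int64)
        if self.times.shape != self.results.shape or self.times.ndim != 1:
            raise ValueError("times and results must be 1-d arrays of equal length")
        if self.times.size:
            if not np.all(np.isfinite(self.times)) or np.any(self.times <= 0.0):
                raise ValueError(
                    f"subject {self.subject_id}: visit times must be finite and > 0 "
                    "(time 0 is enrollment, all subjects event-free)"
                )
            if np.any(np.diff(self.times) <= 0.0):
                raise ValueError(f"subject {self.subject_id}: visit times must be strictly increasing")
        if not np.isin(self.results, (0, 1)).all():
            raise ValueError(f"subject {self.subject_id}: results must be 0/1")

    @property
    def n_visits(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class IntervalPartition:
    """Distinct ordered visit times tau_1 < ... < tau_J, defining J+1 intervals.

    Interval j is (tau_{j-1}, tau_j] for j = 1..J (tau_0 = 0) and interval J+1
    is (tau_J, inf); a subject who never has the event belongs to the last one.
    """

    tau: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        if tau.ndim != 1 or tau.size == 0:
            raise ValueError("partition needs at least one visit time")
        if not np.all(np.isfinite(tau)) or tau[0] <= 0.0 or np.any(np.diff(tau) <= 0.0):
            raise ValueError("tau must be strictly increasing, finite and positive")
        object.__setattr__(self, "tau", tau)

    @property
    def J(self) -> int:
        return int(self.tau.size)

    @property
    def n_intervals(self) -> int:
        return self.J + 1


@dataclass(frozen=True)
class ObservationMatrix:
    """N x (J+1) matrix of report-sequence probabilities per hypothesized interval.

    ``raw[i, j]`` is the probability of subject i's observed reports given the event
    in interval j+1 (0-based column j).  ``differenced`` holds the telescoped
    coefficients C_ij = raw_ij - raw_{i,j-1} appearing in the compact form of the
    log-likelihood.
    """

    raw: np.ndarray
    accuracy: TestAccuracy

    @property
    def n_subjects(self) -> int:
        return int(self.raw.shape[0])

    @property
    def n_intervals(self) -> int:
        return int(self.raw.shape[1])

    @property
    def differenced(self) -> np.ndarray:
        C = self.raw.copy()
        C[:, 1:] -= self.raw[:, :-1]
        return C


@dataclass
class CovariateMatrix:
    """Standardized N x P design matrix with column names and subject ids."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("covariate matrix must be 2-d")
        if not self.names:
            self.names = [f"V{p + 1}" for p in range(self.values.shape[1])]
        if not self.subject_ids:
            self.subject_ids = [f"s{i + 1}" for i in range(self.values.shape[0])]

    @property
    def n_subjects(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_covariates(self) -> int:
        return int(self.values.shape[1])

    def standardized(self) -> "CovariateMatrix":
        """Center and scale every column (sd with denominator N-1); reject constants."""
        Z = self.values
        mu = Z.mean(axis=0)
        sd = Z.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0.0)
        if bad.size:
            raise ValueError(f"constant column(s) cannot be standardized: {[self.names[b] for b in bad]}")
        return CovariateMatrix((Z - mu) / sd, list(self.names), list(self.subject_ids))


def build_partition(panels: Sequence[SelfReportPanel]) -> IntervalPartition:
    """Pool the distinct ordered visit times over all subjects."""
    if not panels:
        raise ValueError("no panels: cannot build a partition with no visits")
    times = np.concatenate([p.times for p in panels]) if panels else np.empty(0)
    if times.size == 0:
        raise ValueError("no visits in any panel")
    return IntervalPartition(np.unique(times))


def _visit_factors(results: np.ndarray, accuracy: TestAccuracy) -> tuple[np.ndarray, np.ndarray]:
    """Per-visit probabilities of the observed report pre-event (a0) and post-event (a1)."""
    phi1, phi0 = accuracy.sensitivity, accuracy.specificity
    a0 = np.where(results == 1, 1.0 - phi0, phi0)
    a1 = np.where(results == 1, phi1, 1.0 - phi1)
    return a0, a1


def observation_matrix(
    panels: Sequence[SelfReportPanel],
    partition: IntervalPartition,
    accuracy: TestAccuracy,
) -> ObservationMatrix:
    """Probability of each subject's report sequence under each event-interval hypothesis.

    A visit strictly before the hypothesized interval is pre-event (specificity rules),
    a visit at or after its right endpoint is post-event (sensitivity rules); intervals
    are (tau_{j-1}, tau_j] so an event exactly at a visit time is detectable there.
    """
    J = partition.J
    M = J + 1
    raw = np.ones((len(panels), M))
    for i, panel in enumerate(panels):
        if panel.n_visits == 0:
            continue  # empty product: a row of ones
        pos = np.searchsorted(partition.tau, panel.times)
        if np.any(pos >= J) or np.any(partition.tau[pos] != panel.times):
            raise ValueError(
                f"subject {panel.subject_id}: visit time not on the pooled partition grid"
            )
        a0, a1 = _visit_factors(panel.results, accuracy)
        # column j (0-based) hypothesizes X in interval j+1: visits with pos <= j-1
        # (0-based pos <= j-1 means tau_pos < tau_j... positions are 0-based indices
        # into tau, visit m sits at tau with 1-based index pos[m]+1)
        # pre-event  <=> 1-based visit index <= j   (0-based pos <= j-1)
        # post-event <=> 1-based visit index >= j+1 (0-based pos >= j)
        pre = np.concatenate(([1.0], np.cumprod(a0)))   # pre[k] = product of first k a0's
        post = np.concatenate((np.cumprod(a1[::-1])[::-1], [1.0]))  # post[k] = product a1[k:]
        # number of visits with 0-based pos <= j-1, i.e. pos < j:
        n_before = np.searchsorted(pos, np.arange(M), side="left")
        raw[i, :] = pre[n_before] * post[n_before]
    return ObservationMatrix(raw, accuracy)


def validate_theta(theta: np.ndarray, n_intervals: int) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (n_intervals,):
        raise ValueError(f"theta must have length {n_intervals}")
    if np.any(theta <= 0.0) or abs(theta.sum() - 1.0) > 1e-8:
        raise ValueError("theta must be strictly positive and sum to 1")
    return theta


def log_likelihood(
    theta: np.ndarray,
    beta: np.ndarray,
    Z: CovariateMatrix | np.ndarray,
    obs: ObservationMatrix,
) -> float:
    """Misclassification-aware interval-censored PH log-likelihood.

    Returns -inf (and logs the offending subjects) when some subject's data has zero
    probability under the model, e.g. a negative after a positive with a perfect test.
    """
    Zv = Z.values if isinstance(Z, CovariateMatrix) else np.asarray(Z, dtype=float)
    theta = validate_theta(theta, obs.n_intervals)
    beta = np.asarray(beta, dtype=float)
    if Zv.shape[0] != obs.n_subjects:
        raise ValueError("Z and observation matrix disagree on the number of subjects")
    if beta.shape != (Zv.shape[1],):
        raise ValueError("beta length must match the number of covariates")
    h = np.exp(Zv @ beta)
    value = loglik_raw(np.ascontiguousarray(obs.raw), h, theta)
    if not np.isfinite(value):
        Li = subject_likelihoods(np.ascontiguousarray(obs.raw), h, theta)
        flagged = np.flatnonzero(Li <= 1e-100)
        logger.warning("zero-probability observations for subject rows %s", flagged.tolist())
    return float(value)


def _profile(D: np.ndarray, h: np.ndarray, warm: np.ndarray | None) -> tuple[np.ndarray, float, bool]:
    M = D.shape[1]
    if not np.all(np.isfinite(h)):
        return np.full(M, 1.0 / M), -np.inf, False
    start = warm if warm is not None else np.full(M, 1.0 / M)
    try:
        theta, ll, status = profile_theta_kernel(
            D, h, np.asarray(start, dtype=float), PROFILE_TOL, PROFILE_MAXITER
        )
        if status == 1 and np.isfinite(ll):
            return theta, ll, True
        if warm is not None:  # one restart from the uniform vector
            theta, ll, status = profile_theta_kernel(
                D, h, np.full(M, 1.0 / M), PROFILE_TOL, PROFILE_MAXITER
            )
            if status == 1 and np.isfinite(ll):
                return theta, ll, True
    except np.linalg.LinAlgError:
        return np.full(M, 1.0 / M), -np.inf, False
    return theta, ll, False


def profile_theta(
    beta: np.ndarray,
    Z: CovariateMatrix | np.ndarray,
    obs: ObservationMatrix,
    warm_start: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Maximize the log-likelihood over theta at fixed beta (profile step).

    Deterministic given inputs and warm start.  Raises :class:`ProfileError` when the
    optimizer cannot find a finite maximum even after restarting from uniform.
    """
    Zv = Z.values if isinstance(Z, CovariateMatrix) else np.asarray(Z, dtype=float)
    h = np.exp(Zv @ np.asarray(beta, dtype=float))
    theta, ll, ok = _profile(np.ascontiguousarray(obs.raw), h, warm_start)
    if not ok:
        raise ProfileError("theta-profile optimization failed (likelihood unbounded below or -inf)")
    return theta, float(ll)


@dataclass
class ModelData:
    """Validated bundle of design matrix, partition and observation matrix.

    The sampler and the ML fitter work on this container; ``raw`` is the dense
    observation matrix, ``Z`` the standardized covariates.
    """

    Z: np.ndarray
    raw: np.ndarray
    partition: IntervalPartition
    accuracy: TestAccuracy
    names: list[str] = field(default_factory=list)

    @classmethod
    def from_panels(
        cls,
        panels: Sequence[SelfReportPanel],
        Z: CovariateMatrix | np.ndarray,
        accuracy: TestAccuracy,
    ) -> "ModelData":
        Zm = Z if isinstance(Z, CovariateMatrix) else CovariateMatrix(np.asarray(Z, dtype=float))
        if len(panels) != Zm.n_subjects:
            raise ValueError("panel count must equal the number of design-matrix rows")
        if accuracy.perfect:
            for p in panels:
                r = p.results
                if r.size and np.any((np.cumsum(r) >= 1) & (r == 0)):
                    raise ValueError(
                        f"subject {p.subject_id}: a negative report after a positive has zero "
                        "probability under a perfect test; truncate panels to the first "
                        "positive (NTFP) before analyzing with sensitivity=specificity=1"
                    )
        partition = build_partition(panels)
        obs = observation_matrix(panels, partition, accuracy)
        return cls(
            Z=np.ascontiguousarray(Zm.values),
            raw=np.ascontiguousarray(obs.raw),
            partition=partition,
            accuracy=accuracy,
            names=list(Zm.names),
        )

    @property
    def n_subjects(self) -> int:
        return int(self.Z.shape[0])

    @property
    def n_covariates(self) -> int:
        return int(self.Z.shape[1])

    @property
    def n_intervals(self) -> int:
        return int(self.raw.shape[1])


@dataclass
class FitResult:
    """Joint maximum-likelihood fit of (beta, theta) for a low-dimensional model."""

    beta: np.ndarray
    theta: np.ndarray
    se: np.ndarray
    loglik: float
    z_values: np.ndarray
    p_values: np.ndarray
    converged: bool
    names: list[str]


def _softmax_theta(u: np.ndarray) -> np.ndarray:
    v = np.concatenate([u, [0.0]])
    v -= v.max()
    e = np.exp(v)
    return e / e.sum()


def fit_ml(
    panels: Sequence[SelfReportPanel],
    Z: CovariateMatrix | np.ndarray,
    accuracy: TestAccuracy,
    max_covariates: int = 20,
) -> FitResult:
    """Numerical maximization of the joint log-likelihood over (beta, theta).

    Intended for the low-dimensional regime (P <= ``max_covariates`` enforced).
    Standard errors come from the inverse of a numerically differentiated Hessian
    at the maximum; per-coefficient Wald z statistics and two-sided p-values are
    reported.  With a singular Hessian the SEs are NaN with a warning.
    """
    from statsmodels.tools.numdiff import approx_hess

    data = ModelData.from_panels(panels, Z, accuracy)
    P = data.n_covariates
    if P > max_covariates:
        raise ValueError(f"fit_ml supports at most {max_covariates} covariates, got {P}")
    M = data.n_intervals
    D = data.raw
    Zv = data.Z

    def negloglik(x: np.ndarray) -> float:
        beta = x[:P]
        theta = _softmax_theta(x[P:])
        h = np.exp(Zv @ beta)
        return -loglik_raw(D, h, theta)

    # warm start: profile theta at beta = 0, mapped through the inverse logit transform
    theta0, _ = profile_theta(np.zeros(P), Zv, ObservationMatrix(D, accuracy))
    u0 = np.log(theta0[:-1]) - math.log(theta0[-1])
    x0 = np.concatenate([np.zeros(P), u0])
    res = optimize.minimize(negloglik, x0, method="L-BFGS-B", options={"maxiter": 500})
    beta_hat = res.x[:P]
    theta_hat = _softmax_theta(res.x[P:])
    loglik = -float(res.fun)

    Hn = approx_hess(res.x, negloglik)
    se = np.full(P, np.nan)
    try:
        cov = np.linalg.inv(Hn)
        var = np.diag(cov)[:P]
        if np.any(var <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        se = np.sqrt(var)
    except np.linalg.LinAlgError:
        warnings.warn("singular Hessian at the ML solution: standard errors unavailable")
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = beta_hat / se
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    return FitResult(
        beta=beta_hat,
        theta=theta_hat,
        se=se,
        loglik=loglik,
        z_values=zval,
        p_values=pval,
        converged=bool(res.success),
        names=data.names,
    )


def univariate_screen(
    panels: Sequence[SelfReportPanel],
    Z: CovariateMatrix,
    accuracy: TestAccuracy,
) -> "pd.DataFrame":
    """One-covariate-at-a-time ML fits (screening), ranked by Wald p-value."""
    import pandas as pd

    rows = []
    for p in range(Z.n_covariates):
        sub = CovariateMatrix(Z.values[:, [p]], [Z.names[p]], list(Z.subject_ids))
        fit = fit_ml(panels, sub, accuracy, max_covariates=1)
        rows.append(
            {
                "covariate": Z.names[p],
                "beta": fit.beta[0],
                "se": fit.se[0],
                "z": fit.z_values[0],
                "p_value": fit.p_values[0],
                "converged": fit.converged,
            }
        )
    frame = pd.DataFrame(rows).sort_values("p_value", kind="stable").reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame
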
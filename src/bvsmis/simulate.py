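"""Synthetic-data generator for error-prone self-reported time-to-event studies.

Emulates the reference simulation design: n subjects, P SNP-like covariates generated
under Hardy-Weinberg proportions with a two-bin minor-allele-frequency mixture (74% of
columns with MAF in (0.05, 0.35), 26% in (0.35, 0.5)), 5 true effects of size beta = 1.0,
exponential event times whose baseline hazard is calibrated so that the reference group
(Z = 0) reaches a target cumulative incidence over the study duration, four scheduled
visits over 8 years, and Bernoulli self-reports governed by sensitivity phi1 (visit at
or after the event) and specificity phi0 (visit before the event).  The NTFP design
discards all reports after the first positive; NMISS retains every scheduled report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .likelihood import CovariateMatrix, SelfReportPanel, TestAccuracy

__all__ = [
    "SimulationDesign",
    "SyntheticDataset",
    "baseline_hazard_from_cir",
    "generate_snp_matrix",
    "generate_continuous_matrix",
    "simulate_event_times",
    "simulate_self_reports",
    "apply_ntfp",
    "generate_dataset",
]

DEFAULT_SCHEDULE = (2.0, 4.0, 6.0, 8.0)


def baseline_hazard_from_cir(cir: float, duration: float) -> float:
    """Exponential baseline hazard reaching cumulative incidence ``cir`` by ``duration``."""
    if not (0.0 < cir < 1.0):
        raise ValueError(f"cumulative incidence rate must lie in (0, 1), got {cir}")
    if duration <= 0:
        raise ValueError("study duration must be positive")
    return -math.log1p(-cir) / duration


@dataclass(frozen=True)
class SimulationDesign:
    """Generative parameters of one simulated study."""

    n: int = 100
    P: int = 100
    n_true: int = 5
    beta_true: float = 1.0
    cir: float = 0.1
    duration: float = 8.0
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    accuracy: TestAccuracy = TestAccuracy(1.0, 1.0)
    design: str = "NMISS"
    covariate_kind: str = "snp"  # "snp" or "continuous"
    correlation: float = 0.0  # exchangeable correlation for continuous features

    def __post_init__(self) -> None:
        if self.design not in ("NMISS", "NTFP"):
            raise ValueError("design must be 'NMISS' or 'NTFP'")
        if self.covariate_kind not in ("snp", "continuous"):
            raise ValueError("covariate_kind must be 'snp' or 'continuous'")
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size == 0 or np.any(np.diff(sched) <= 0) or sched[0] <= 0 or sched[-1] > self.duration:
            raise ValueError("schedule must be strictly increasing within (0, duration]")
        if self.n_true > self.P:
            raise ValueError("cannot have more true effects than covariates")
        baseline_hazard_from_cir(self.cir, self.duration)  # validates cir

    @property
    def lambda0(self) -> float:
        return baseline_hazard_from_cir(self.cir, self.duration)


@dataclass
class SyntheticDataset:
    """One simulated study: standardized design matrix, latent event times, panels."""

    Z: CovariateMatrix
    event_times: np.ndarray
    panels: list[SelfReportPanel]
    true_idx: np.ndarray
    design: SimulationDesign


def _draw_snp_column(n: int, q: float, rng: np.random.Generator, max_tries: int = 100) -> np.ndarray:
    """Genotype dosages 0/1/2 under Hardy-Weinberg; monomorphic draws are resampled."""
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    for _ in range(max_tries):
        g = rng.choice(3, size=n, p=probs)
        if g.min() != g.max():
            return g.astype(float)
    raise RuntimeError(f"could not draw a polymorphic SNP column at MAF {q} in {max_tries} tries")


def generate_snp_matrix(
    n: int,
    P: int,
    rng: np.random.Generator,
    maf: Sequence[float] | None = None,
) -> CovariateMatrix:
    """HWE genotype matrix (dosage 0/1/2), standardized column-wise.

    Without an explicit per-column ``maf``, 74% of the columns draw their MAF from
    Uniform(0.05, 0.35) and the remaining 26% from Uniform(0.35, 0.5), mirroring the
    composition of the reference GWAS design matrix.
    """
    if maf is None:
        n_low = int(round(0.74 * P))
        mafs = np.concatenate(
            [rng.uniform(0.05, 0.35, size=n_low), rng.uniform(0.35, 0.5, size=P - n_low)]
        )
    else:
        mafs = np.asarray(maf, dtype=float)
        if mafs.shape != (P,):
            raise ValueError("maf must give one frequency per column")
        if np.any((mafs <= 0.0) | (mafs > 0.5)):
            raise ValueError("minor allele frequencies must lie in (0, 0.5]")
    G = np.column_stack([_draw_snp_column(n, q, rng) for q in mafs])
    names = [f"SNP{p + 1}" for p in range(P)]
    return CovariateMatrix(G, names).standardized()


def generate_continuous_matrix(
    n: int,
    P: int,
    rng: np.random.Generator,
    correlation: float = 0.0,
) -> CovariateMatrix:
    """Gaussian feature matrix with optional exchangeable correlation, standardized."""
    if not (0.0 <= correlation < 1.0):
        raise ValueError("exchangeable correlation must lie in [0, 1)")
    X = rng.standard_normal((n, P))
    if correlation > 0.0:
        shared = rng.standard_normal((n, 1))
        X = math.sqrt(correlation) * shared + math.sqrt(1.0 - correlation) * X
    names = [f"X{p + 1}" for p in range(P)]
    return CovariateMatrix(X, names).standardized()


def simulate_event_times(
    Z: np.ndarray,
    true_idx: np.ndarray,
    beta_true: float,
    lambda0: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exponential event times under the PH model: rate lambda0 * exp(beta' z).

    No administrative truncation is applied; censoring arises later from the visit
    schedule.  A subject without the event within finite simulation is representable
    because the exponential draw itself is finite but may exceed the last visit.
    """
    if lambda0 <= 0:
        raise ValueError("baseline hazard must be positive")
    Z = np.asarray(Z, dtype=float)
    eta = Z[:, np.asarray(true_idx, dtype=int)].sum(axis=1) * beta_true
    rate = lambda0 * np.exp(eta)
    return rng.exponential(1.0 / rate)


def simulate_self_reports(
    event_times: np.ndarray,
    schedule: Sequence[float],
    accuracy: TestAccuracy,
    rng: np.random.Generator,
) -> list[SelfReportPanel]:
    """Independent Bernoulli self-report at every scheduled visit.

    P(positive) = phi1 when the visit is at or after the true event time (a visit
    exactly at the event counts as post-event), else 1 - phi0.
    """
    sched = np.asarray(schedule, dtype=float)
    x = np.asarray(event_times, dtype=float)
    post = sched[None, :] >= x[:, None]
    p_pos = np.where(post, accuracy.sensitivity, 1.0 - accuracy.specificity)
    results = (rng.random(p_pos.shape) < p_pos).astype(np.int64)
    return [
        SelfReportPanel(f"s{i + 1}", sched.copy(), results[i]) for i in range(x.size)
    ]


def apply_ntfp(panel: SelfReportPanel) -> SelfReportPanel:
    """Discard all visits after the first positive report (the positive is retained)."""
    pos = np.flatnonzero(panel.results == 1)
    if pos.size == 0:
        return panel
    cut = pos[0] + 1
    return SelfReportPanel(panel.subject_id, panel.times[:cut].copy(), panel.results[:cut].copy())


def generate_dataset(design: SimulationDesign, rng: np.random.Generator | int) -> SyntheticDataset:
    """Draw a complete study: covariates, true effects, event times, self-reports."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if design.covariate_kind == "snp":
        Z = generate_snp_matrix(design.n, design.P, rng)
    else:
        Z = generate_continuous_matrix(design.n, design.P, rng, design.correlation)
    true_idx = np.sort(rng.choice(design.P, size=design.n_true, replace=False))
    x = simulate_event_times(Z.values, true_idx, design.beta_true, design.lambda0, rng)
    panels = simulate_self_reports(x, design.schedule, design.accuracy, rng)
    if design.design == "NTFP":
        panels = [apply_ntfp(p) for p in panels]
    return SyntheticDataset(Z=Z, event_times=x, panels=panels, true_idx=true_idx, design=design)
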
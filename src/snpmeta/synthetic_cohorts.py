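"""Synthetic case-control study sets with known truth.

The generator emulates the sampling model behind an allelic
case-control meta-analysis.  Each study draws its true log odds ratio
from Normal(ln OR, τ²); the control minor-allele frequency p0 is fixed
and the case frequency follows from the multiplicative allelic model,

    p1 = OR·p0 / (1 + p0·(OR − 1)),

so that the allele-level odds ratio between cases and controls equals
the study's true OR.  Genotypes are then drawn multinomially under
Hardy-Weinberg proportions at (p1, p0) in cases and controls.

Studies can report full genotype counts, only a Woolf odds ratio with a
95% CI rounded to two decimals (mimicking how small published studies
print their results), or a mixture.  An optional censoring rule
suppresses non-significant studies probabilistically, creating the
small-study asymmetry that the funnel-plot tests are meant to detect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np

from .study_data import (
    GenotypeCounts,
    StudyOutcome,
    StudyTableError,
    effect_from_counts,
)

__all__ = [
    "CensoringRule",
    "SimulationConfig",
    "SimulatedStudySet",
    "simulate_study_set",
    "simulate_null_funnel",
]

SizeSpec = Union[int, tuple[int, int]]


@dataclass(frozen=True)
class CensoringRule:
    """Small-study suppression rule emulating publication bias.

    One-sided (the default) suppresses a study with probability
    ``p_suppress`` when its signed z-score θ̂/se falls below
    ``z_cutoff`` — unimpressive results in the "wrong" direction stay
    unpublished, which is what bends a funnel.  Two-sided suppression
    (|z| < cutoff) thins the funnel symmetrically instead.
    """

    z_cutoff: float = 1.64
    p_suppress: float = 0.75
    one_sided: bool = True
    max_n: Optional[int] = None  # censor only studies with fewer subjects

    def suppressed(self, z: float, u: float, n_total: int) -> bool:
        if self.max_n is not None and n_total >= self.max_n:
            return False
        below = z < self.z_cutoff if self.one_sided else abs(z) < self.z_cutoff
        return below and u < self.p_suppress


@dataclass(frozen=True)
class SimulationConfig:
    """Study-set generating conditions.

    Defaults mirror a typical candidate-gene landscape: a handful of
    modest case-control panels at a common intermediate minor-allele
    frequency, no between-study variance, and full genotype reporting.
    """

    true_or: float = 1.0
    control_maf: float = 0.25
    n_cases: SizeSpec = 1000
    n_controls: SizeSpec = 1000
    k_studies: int = 5
    tau: float = 0.0
    reporting_mode: Literal["counts", "ci_only", "mixed"] = "counts"
    censoring: Optional[CensoringRule] = None
    seed: int = 0
    snp: str = "rs0000000"

    def __post_init__(self) -> None:
        if not 0 < self.control_maf < 1:
            raise StudyTableError("control_maf must be strictly inside (0, 1)")
        if self.k_studies < 1:
            raise StudyTableError("k_studies must be at least 1")
        if self.true_or <= 0:
            raise StudyTableError("true_or must be positive")
        if self.tau < 0:
            raise StudyTableError("tau must be non-negative")


@dataclass(frozen=True)
class SimulatedStudySet:
    """Generated outcomes plus the truth that produced them."""

    outcomes: tuple[StudyOutcome, ...]
    true_or: float
    tau: float
    true_log_ors: tuple[float, ...]  # per retained study


def _draw_size(rng: np.random.Generator, spec: SizeSpec) -> int:
    if isinstance(spec, tuple):
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    return int(spec)


def _case_frequency(p0: float, or_study: float) -> float:
    return or_study * p0 / (1.0 + p0 * (or_study - 1.0))


def _draw_genotypes(rng: np.random.Generator, n: int, p: float) -> GenotypeCounts:
    q = 1.0 - p
    probs = [q * q, 2 * p * q, p * p]  # major-hom, het, minor-hom
    counts = rng.multinomial(n, probs)
    return GenotypeCounts(int(counts[0]), int(counts[1]), int(counts[2]))


def simulate_study_set(config: SimulationConfig) -> SimulatedStudySet:
    """Generate one study set under the configured conditions.

    Deterministic for a fixed seed.  A warning is emitted when the
    expected minor-allele count in either group falls below 5 (sparse
    regime where the Woolf variance is unreliable).
    """
    rng = np.random.default_rng(config.seed)
    log_true = np.log(config.true_or)
    outcomes: list[StudyOutcome] = []
    true_thetas: list[float] = []
    for i in range(config.k_studies):
        theta_i = float(rng.normal(log_true, config.tau)) if config.tau > 0 else log_true
        p0 = config.control_maf
        p1 = _case_frequency(p0, float(np.exp(theta_i)))
        n_ca = _draw_size(rng, config.n_cases)
        n_co = _draw_size(rng, config.n_controls)
        if min(2 * n_ca * p1, 2 * n_co * p0) < 5:
            warnings.warn(
                f"study {i}: expected minor-allele count below 5 (sparse data)",
                stacklevel=2,
            )
        case = _draw_genotypes(rng, n_ca, p1)
        control = _draw_genotypes(rng, n_co, p0)
        effect = effect_from_counts(case, control)
        if config.censoring is not None:
            z = effect.log_or / effect.se_log_or
            if config.censoring.suppressed(z, float(rng.random()), n_ca + n_co):
                continue
        ci_only = config.reporting_mode == "ci_only" or (
            config.reporting_mode == "mixed" and i % 2 == 1
        )
        common = dict(
            study_id=f"sim{i:03d}",
            author_year=f"Simulated study {i}",
            year=2020,
            country="simulated",
            ancestry="other",
            snp=config.snp,
            design="case_control",
            n_cases=n_ca,
            n_controls=n_co,
        )
        if ci_only:
            # round like a published table would print it
            outcomes.append(
                StudyOutcome(
                    reported_or=round(effect.or_point, 2),
                    reported_ci_low=round(effect.ci_low, 2),
                    reported_ci_high=round(effect.ci_high, 2),
                    **common,
                )
            )
        else:
            outcomes.append(
                StudyOutcome(case_counts=case, control_counts=control, **common)
            )
        true_thetas.append(theta_i)
    return SimulatedStudySet(
        outcomes=tuple(outcomes),
        true_or=config.true_or,
        tau=config.tau,
        true_log_ors=tuple(true_thetas),
    )


def simulate_null_funnel(config: SimulationConfig) -> SimulatedStudySet:
    """Homogeneous null study set with strongly unequal sample sizes.

    For calibrating the funnel-asymmetry tests: τ must be 0, and study
    sizes are spread geometrically over a 9-fold range around the
    configured size so per-study standard errors span at least a
    3-fold range.  Censoring, when configured, is applied as in
    :func:`simulate_study_set` (useful for power checks; leave it off
    for type-I-error calibration).
    """
    if config.tau != 0:
        raise StudyTableError("null funnel simulation requires tau = 0")
    base_ca = _nominal_size(config.n_cases)
    base_co = _nominal_size(config.n_controls)
    sizes_ca = np.geomspace(base_ca / 3, base_ca * 3, config.k_studies)
    sizes_co = np.geomspace(base_co / 3, base_co * 3, config.k_studies)
    rng = np.random.default_rng(config.seed)
    outcomes: list[StudyOutcome] = []
    thetas: list[float] = []
    for i in range(config.k_studies):
        n_ca, n_co = int(round(sizes_ca[i])), int(round(sizes_co[i]))
        p0 = config.control_maf
        p1 = _case_frequency(p0, config.true_or)
        case = _draw_genotypes(rng, n_ca, p1)
        control = _draw_genotypes(rng, n_co, p0)
        effect = effect_from_counts(case, control)
        if config.censoring is not None:
            z = effect.log_or / effect.se_log_or
            if config.censoring.suppressed(z, float(rng.random()), n_ca + n_co):
                continue
        outcomes.append(
            StudyOutcome(
                study_id=f"sim{i:03d}",
                author_year=f"Simulated study {i}",
                year=2020,
                country="simulated",
                ancestry="other",
                snp=config.snp,
                design="case_control",
                case_counts=case,
                control_counts=control,
                n_cases=n_ca,
                n_controls=n_co,
            )
        )
        thetas.append(float(np.log(config.true_or)))
    return SimulatedStudySet(
        outcomes=tuple(outcomes),
        true_or=config.true_or,
        tau=0.0,
        true_log_ors=tuple(thetas),
    )


def _nominal_size(spec: SizeSpec) -> float:
    if isinstance(spec, tuple):
        return (spec[0] + spec[1]) / 2
    return float(spec)
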
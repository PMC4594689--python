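"""Fixed- and random-effects pooling of per-study odds ratios.

Pooling happens on the natural-log odds-ratio scale.  The fixed-effect
model uses inverse-variance weights w_i = 1/se_i²; the random-effects
model is DerSimonian-Laird, adding the moment estimate of the
between-study variance τ² to every study's sampling variance.
Heterogeneity is quantified by Cochran's Q (chi-square with k−1 df
under homogeneity) and I² = max(0, (Q − df)/Q)·100.

Model choice follows the conventional disjunctive screen: the
random-effects model is used when either the Q-test p-value falls below
0.05 or I² exceeds 50%; otherwise fixed-effect.  For genotype-count
data the Mantel-Haenszel stratified odds ratio is available as an
alternative fixed-effect estimator, with the Robins-Breslow-Greenland
variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as _dc_replace
from typing import Literal, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .study_data import (
    Z_DEFAULT,
    EffectEstimate,
    StudyOutcome,
    StudyTableError,
    allele_table,
    effect_for_outcome,
)

__all__ = [
    "MetaResult",
    "HeterogeneityResult",
    "PoolConfig",
    "fixed_effect_inverse_variance",
    "mantel_haenszel",
    "cochran_q",
    "dersimonian_laird",
    "select_model",
    "pool_snp",
    "group_by_snp",
    "format_p",
]


class HeterogeneityResult(NamedTuple):
    q_stat: float
    q_df: int
    p_q: float
    i_squared: float  # percent


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect for one SNP, with heterogeneity and weights."""

    snp: str
    k: int
    n_cases: int
    n_controls: int
    pooled_log_or: float
    pooled_se: float
    pooled_or: float
    ci_low: float
    ci_high: float
    z_stat: float
    p_value: float
    q_stat: float
    q_df: int
    p_q: float
    i_squared: float
    tau_squared: float
    model: Literal["FEM", "REM"]
    weights: tuple[float, ...]
    study_labels: tuple[str, ...] = ()
    alternate: Optional["MetaResult"] = None
    flags: tuple[str, ...] = ()

    @property
    def p_display(self) -> str:
        """p-value as printed in summary tables: '<10^-6' below 1e-6."""
        return "<10^-6" if self.p_value < 1e-6 else f"{self.p_value:.3g}"

    def significant(self) -> bool:
        """Whether the 95% CI excludes an odds ratio of 1."""
        return not (self.ci_low <= 1.0 <= self.ci_high)


@dataclass(frozen=True)
class PoolConfig:
    """Knobs shared by every pooling entry point."""

    effect_source: Literal["reported", "counts"] = "reported"
    z: float = Z_DEFAULT
    pq_threshold: float = 0.05
    i2_threshold: float = 50.0  # percent
    min_studies: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.pq_threshold < 1:
            raise ValueError("pq_threshold must be in (0, 1)")
        if not 0 < self.i2_threshold < 100:
            raise ValueError("i2_threshold must be in (0, 100)")


def _theta_se(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if len(effects) == 0:
        raise StudyTableError("cannot pool an empty list of effects")
    theta = np.array([e.log_or for e in effects], dtype=float)
    se = np.array([e.se_log_or for e in effects], dtype=float)
    return theta, se


def cochran_q(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q, its p-value, and the I² metric (percent).

    Q = Σ w_i (θ_i − θ̄)² with inverse-variance weights and the
    fixed-effect pooled θ̄; chi-square with k−1 df under homogeneity.
    """
    theta, se = _theta_se(effects)
    k = len(theta)
    if k < 2:
        raise StudyTableError("heterogeneity is undefined for fewer than 2 studies")
    w = 1.0 / se**2
    # fsum keeps every statistic exactly invariant to study order
    pooled = math.fsum(w * theta) / math.fsum(w)
    q = math.fsum(w * (theta - pooled) ** 2)
    df = k - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(q, df, p_q, i2)


def _assemble(
    snp: str,
    effects: Sequence[EffectEstimate],
    w: np.ndarray,
    model: str,
    tau2: float,
    het: Optional[HeterogeneityResult],
    z: float,
    n_cases: int = 0,
    n_controls: int = 0,
    flags: tuple[str, ...] = (),
) -> MetaResult:
    theta, _ = _theta_se(effects)
    sw = math.fsum(w)
    pooled = math.fsum(w * theta) / sw
    pooled_se = 1.0 / math.sqrt(sw)
    z_stat = pooled / pooled_se
    p = 2.0 * float(stats.norm.sf(abs(z_stat)))
    if het is None:
        het = HeterogeneityResult(0.0, 0, 1.0, 0.0)
    return MetaResult(
        snp=snp,
        k=len(effects),
        n_cases=n_cases,
        n_controls=n_controls,
        pooled_log_or=pooled,
        pooled_se=pooled_se,
        pooled_or=math.exp(pooled),
        ci_low=math.exp(pooled - z * pooled_se),
        ci_high=math.exp(pooled + z * pooled_se),
        z_stat=z_stat,
        p_value=p,
        q_stat=het.q_stat,
        q_df=het.q_df,
        p_q=het.p_q,
        i_squared=het.i_squared,
        tau_squared=tau2,
        model=model,
        weights=tuple(float(x) for x in w),
        study_labels=tuple(e.label for e in effects),
        flags=flags,
    )


def fixed_effect_inverse_variance(
    effects: Sequence[EffectEstimate],
    snp: str = "",
    z: float = Z_DEFAULT,
    n_cases: int = 0,
    n_controls: int = 0,
) -> MetaResult:
    """Inverse-variance fixed-effect pooled log odds ratio."""
    theta, se = _theta_se(effects)
    w = 1.0 / se**2
    het = cochran_q(effects) if len(effects) >= 2 else None
    return _assemble(snp, effects, w, "FEM", 0.0, het, z, n_cases, n_controls)


def dersimonian_laird(
    effects: Sequence[EffectEstimate],
    snp: str = "",
    z: float = Z_DEFAULT,
    n_cases: int = 0,
    n_controls: int = 0,
) -> MetaResult:
    """DerSimonian-Laird random-effects pooled log odds ratio.

    τ² = max(0, (Q − df) / (Σw − Σw²/Σw)) with fixed-effect weights w;
    studies are then re-weighted by 1/(se² + τ²).  When Q ≤ df the
    estimate truncates to τ² = 0 and the result coincides with the
    fixed-effect model.
    """
    theta, se = _theta_se(effects)
    if len(theta) < 2:
        raise StudyTableError("random-effects pooling needs at least 2 studies")
    w = 1.0 / se**2
    het = cochran_q(effects)
    c = math.fsum(w) - math.fsum(w**2) / math.fsum(w)
    tau2 = max(0.0, (het.q_stat - het.q_df) / c)
    w_star = 1.0 / (se**2 + tau2)
    return _assemble(snp, effects, w_star, "REM", tau2, het, z, n_cases, n_controls)


def mantel_haenszel(
    tables: Sequence[tuple[float, float, float, float]],
    snp: str = "",
    z: float = Z_DEFAULT,
) -> MetaResult:
    """Mantel-Haenszel pooled odds ratio over allele 2×2 tables.

    Each table is (a, b, c, d): effect/reference allele counts in cases
    then controls.  OR_MH = Σ(a_i d_i / n_i) / Σ(b_i c_i / n_i); the
    variance of its log is the Robins-Breslow-Greenland estimator.
    """
    if len(tables) == 0:
        raise StudyTableError("cannot pool an empty list of tables")
    arr = np.asarray(tables, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise StudyTableError("each stratum must be a 2x2 table (a, b, c, d)")
    a, b, c, d = arr.T
    n = a + b + c + d
    r = a * d / n
    s = b * c / n
    sr, ss = r.sum(), s.sum()
    if sr == 0 or ss == 0:
        raise StudyTableError("Mantel-Haenszel odds ratio degenerate (zero margin)")
    or_mh = sr / ss
    p_term = (a + d) / n
    q_term = (b + c) / n
    var = (
        float(np.sum(p_term * r)) / (2 * sr**2)
        + float(np.sum(p_term * s + q_term * r)) / (2 * sr * ss)
        + float(np.sum(q_term * s)) / (2 * ss**2)
    )
    log_or = math.log(or_mh)
    se = math.sqrt(var)
    z_stat = log_or / se
    p = 2.0 * float(stats.norm.sf(abs(z_stat)))
    return MetaResult(
        snp=snp,
        k=len(tables),
        n_cases=0,
        n_controls=0,
        pooled_log_or=log_or,
        pooled_se=se,
        pooled_or=or_mh,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        z_stat=z_stat,
        p_value=p,
        q_stat=0.0,
        q_df=max(0, len(tables) - 1),
        p_q=1.0,
        i_squared=0.0,
        tau_squared=0.0,
        model="FEM",
        weights=tuple(s / ss for s in np.atleast_1d(s)),
        flags=("mantel_haenszel",),
    )


def mantel_haenszel_outcomes(
    outcomes: Sequence[StudyOutcome], snp: str = "", z: float = Z_DEFAULT
) -> MetaResult:
    """Mantel-Haenszel pooling straight from genotype-count outcomes."""
    missing = [o.study_id for o in outcomes if not o.has_counts]
    if missing:
        raise StudyTableError(
            f"Mantel-Haenszel needs genotype counts for every study; missing for "
            f"{missing} — use the inverse-variance path for CI-only studies"
        )
    tables = [
        allele_table(o.case_counts, o.control_counts, o.effect_allele_orientation)
        for o in outcomes
    ]
    return mantel_haenszel(tables, snp=snp, z=z)


def select_model(
    het: HeterogeneityResult,
    pq_threshold: float = 0.05,
    i2_threshold: float = 50.0,
) -> Literal["FEM", "REM"]:
    """Random effects when either heterogeneity trigger fires.

    REM if p_Q < pq_threshold OR I² > i2_threshold (percent); the rule
    is disjunctive, so a large I² alone selects random effects even
    when the Q test is not formally significant.
    """
    return "REM" if (het.p_q < pq_threshold or het.i_squared > i2_threshold) else "FEM"


def pool_snp(
    outcomes: Sequence[StudyOutcome],
    config: Optional[PoolConfig] = None,
) -> MetaResult:
    """Pool all outcomes for one SNP, choosing FEM vs REM automatically.

    The result of the selected model is returned with the other model's
    result attached as ``.alternate`` so that sensitivity to the model
    choice is always inspectable.  Fewer than ``config.min_studies``
    outcomes triggers a warning (not an error); a single outcome is
    returned as-is, flagged ``single_study``.
    """
    cfg = config or PoolConfig()
    if len(outcomes) == 0:
        raise StudyTableError("no outcomes to pool")
    snps = {o.snp for o in outcomes}
    if len(snps) != 1:
        raise StudyTableError(f"outcomes must share one SNP, got {sorted(snps)}")
    snp = snps.pop()
    if len(outcomes) < cfg.min_studies:
        warnings.warn(
            f"{snp}: only {len(outcomes)} outcome(s); pooled estimate is fragile",
            stacklevel=2,
        )
    effects = [effect_for_outcome(o, source=cfg.effect_source, z=cfg.z) for o in outcomes]
    n_cases = sum(o.n_cases for o in outcomes)
    n_controls = sum(o.n_controls for o in outcomes)
    if len(effects) == 1:
        res = fixed_effect_inverse_variance(effects, snp, cfg.z, n_cases, n_controls)
        return _with(res, flags=("single_study",))
    het = cochran_q(effects)
    fem = fixed_effect_inverse_variance(effects, snp, cfg.z, n_cases, n_controls)
    rem = dersimonian_laird(effects, snp, cfg.z, n_cases, n_controls)
    model = select_model(het, cfg.pq_threshold, cfg.i2_threshold)
    chosen, other = (rem, fem) if model == "REM" else (fem, rem)
    return _with(chosen, alternate=other)


def _with(res: MetaResult, **kwargs) -> MetaResult:
    return _dc_replace(res, **kwargs)


def group_by_snp(outcomes: Sequence[StudyOutcome]) -> dict[str, list[StudyOutcome]]:
    """Group outcomes by rsID, preserving input order."""
    groups: dict[str, list[StudyOutcome]] = {}
    for o in outcomes:
        groups.setdefault(o.snp, []).append(o)
    return groups


def format_p(p: float) -> str:
    return "<10^-6" if p < 1e-6 else f"{p:.3g}"
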
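"""Funnel-plot asymmetry tests for small-study / publication bias.

Two classical tests operate on the per-study log odds ratios and their
standard errors:

* Egger's regression: OLS of the standardized effect θ_i/se_i on the
  precision 1/se_i.  Under no small-study effect the intercept is 0;
  it is tested with a t statistic on k−2 df.
* Begg-Mazumdar rank correlation: Kendall's tau between the variance-
  stabilized effect deviates and the sampling variances, with the
  normal approximation to the Kendall score.  A continuity correction
  is applied by default (the behaviour of common meta-analysis
  software); it can be disabled.

Both tests are meaningful only for k ≥ 3 studies and are low-powered at
the study counts typical of candidate-gene meta-analyses, so a
non-significant result is weak evidence of absence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .study_data import EffectEstimate, StudyTableError

__all__ = ["EggerResult", "BeggResult", "BiasReport", "egger_test", "begg_test",
           "bias_report", "funnel_data"]


class EggerResult(NamedTuple):
    intercept: float
    se: float
    t_stat: float
    p_value: float


class BeggResult(NamedTuple):
    tau: float
    z: float
    p_value: float


@dataclass(frozen=True)
class BiasReport:
    """Egger and Begg statistics for one SNP's study set."""

    snp: str
    k: int
    egger_intercept: float
    egger_se: float
    egger_p: float
    begg_tau: float
    begg_z: float
    begg_p: float


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's weighted regression test for funnel asymmetry.

    Regresses θ_i/se_i on 1/se_i by ordinary least squares; the
    intercept estimates the asymmetry and is tested two-sided against 0
    with k−2 degrees of freedom.
    """
    k = len(effects)
    if k < 3:
        raise StudyTableError("Egger's test needs at least 3 studies")
    se = np.array([e.se_log_or for e in effects])
    theta = np.array([e.log_or for e in effects])
    precision = 1.0 / se
    if np.ptp(precision) < 1e-12:
        raise StudyTableError(
            "Egger's test is degenerate when all standard errors are equal"
        )
    y = theta / se
    X = sm.add_constant(precision)
    fit = sm.OLS(y, X).fit()
    intercept = float(fit.params[0])
    se_int = float(fit.bse[0])
    t_stat = intercept / se_int
    p = 2.0 * float(stats.t.sf(abs(t_stat), df=k - 2))
    return EggerResult(intercept, se_int, t_stat, p)


def _kendall_score(x: np.ndarray, y: np.ndarray) -> int:
    """Kendall S = #concordant − #discordant pairs (ties contribute 0)."""
    s = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            s += int(np.sign(x[j] - x[i]) * np.sign(y[j] - y[i]))
    return s


def begg_test(
    effects: Sequence[EffectEstimate], continuity: bool = True
) -> BeggResult:
    """Begg-Mazumdar rank-correlation test for publication bias.

    Standardized deviates t_i = (θ_i − θ̄) / sqrt(v_i − 1/Σ(1/v_j)),
    where θ̄ is the inverse-variance pooled effect and v_i = se_i², are
    rank-correlated with the v_i by Kendall's tau.  The Kendall score S
    is referred to its null normal approximation with variance
    k(k−1)(2k+5)/18; with ``continuity`` (default) |S| is reduced by 1
    before standardization.
    """
    k = len(effects)
    if k < 3:
        raise StudyTableError("Begg's test needs at least 3 studies")
    theta = np.array([e.log_or for e in effects])
    v = np.array([e.se_log_or for e in effects]) ** 2
    w = 1.0 / v
    pooled = float(np.sum(w * theta) / np.sum(w))
    var_dev = v - 1.0 / np.sum(w)
    if np.any(var_dev <= 0):
        warnings.warn(
            "non-positive deviate variance for some study; using absolute value",
            stacklevel=2,
        )
        var_dev = np.abs(var_dev)
        var_dev[var_dev == 0] = np.finfo(float).tiny
    deviates = (theta - pooled) / np.sqrt(var_dev)
    s = _kendall_score(deviates, v)
    n_pairs = k * (k - 1) // 2
    tau = s / n_pairs
    var_s = k * (k - 1) * (2 * k + 5) / 18.0
    if continuity:
        z = math.copysign(max(0.0, abs(s) - 1.0), s) / math.sqrt(var_s)
    else:
        z = s / math.sqrt(var_s)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return BeggResult(tau, z, p)


def bias_report(
    snp: str, effects: Sequence[EffectEstimate], continuity: bool = True
) -> BiasReport:
    """Run both asymmetry tests on one SNP's effect set."""
    egger = egger_test(effects)
    begg = begg_test(effects, continuity=continuity)
    return BiasReport(
        snp=snp,
        k=len(effects),
        egger_intercept=egger.intercept,
        egger_se=egger.se,
        egger_p=egger.p_value,
        begg_tau=begg.tau,
        begg_z=begg.z,
        begg_p=begg.p_value,
    )


def funnel_data(
    effects: Sequence[EffectEstimate], z: float = 1.96
) -> dict[str, object]:
    """Numbers behind a funnel plot, without rendering it.

    Returns the per-study (log OR, se) scatter plus the pooled
    fixed-effect line and pseudo-confidence guide lines
    θ̄ ± z·se over the observed se range.
    """
    theta = np.array([e.log_or for e in effects])
    se = np.array([e.se_log_or for e in effects])
    w = 1.0 / se**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    se_grid = np.linspace(0.0, float(se.max()) * 1.05, 50)
    return {
        "study": [e.label for e in effects],
        "log_or": theta.tolist(),
        "se": se.tolist(),
        "pooled_log_or": pooled,
        "guide_se": se_grid.tolist(),
        "guide_low": (pooled - z * se_grid).tolist(),
        "guide_high": (pooled + z * se_grid).tolist(),
    }
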
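"""False-positive report probability (FPRP) for a pooled association.

FPRP asks: given that a test of association came out significant, what
is the probability the association is nonetheless false?  It combines
the observed significance level α, the test's power 1−β against a
stated alternative odds ratio, and a prior probability π that the
association is real:

    FPRP = α(1 − π) / (α(1 − π) + (1 − β)π)

A report is considered noteworthy when FPRP falls below a threshold
(0.2 by default).  Here α defaults to the pooled estimate's observed
two-sided p-value and power is computed for a two-sided Z-test on the
log odds ratio at the pooled estimate's standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .meta_engine import MetaResult
from .study_data import StudyTableError

__all__ = ["FprpGrid", "power_at_alternative", "fprp_value", "fprp_report"]

DEFAULT_PRIORS = (1e-5, 1e-4, 1e-3, 0.01, 0.1)
DEFAULT_NOTEWORTHY = 0.2


@dataclass(frozen=True)
class FprpGrid:
    """FPRP over a grid of alternative odds ratios × prior probabilities."""

    snp: str
    alpha: float
    alternatives: tuple[float, ...]
    priors: tuple[float, ...]
    power: tuple[float, ...]  # one per alternative
    fprp: tuple[tuple[float, ...], ...]  # [alternative][prior]
    noteworthy_threshold: float = DEFAULT_NOTEWORTHY

    def noteworthy(self) -> tuple[tuple[bool, ...], ...]:
        return tuple(
            tuple(v < self.noteworthy_threshold for v in row) for row in self.fprp
        )

    def to_frame(self) -> pd.DataFrame:
        """Rows = alternative ORs, columns = priors."""
        return pd.DataFrame(
            list(self.fprp),
            index=pd.Index(self.alternatives, name="or_alt"),
            columns=pd.Index(self.priors, name="prior"),
        )


def power_at_alternative(se: float, or_alt: float, alpha: float) -> float:
    """Power of the two-sided level-α Z-test at true OR ``or_alt``.

    With estimated log-OR ~ Normal(ln or_alt, se²),
    power = Φ(−z_{1−α/2} + |ln or_alt|/se) + Φ(−z_{1−α/2} − |ln or_alt|/se).
    At or_alt = 1 this reduces to α (size equals level).
    """
    if not se > 0:
        raise StudyTableError(f"standard error must be positive, got {se}")
    if not 0 < alpha < 1:
        raise StudyTableError(f"alpha must be strictly inside (0, 1), got {alpha}")
    if not or_alt > 0:
        raise StudyTableError(f"alternative odds ratio must be positive, got {or_alt}")
    z_crit = float(stats.norm.isf(alpha / 2))
    shift = abs(math.log(or_alt)) / se
    return float(stats.norm.cdf(-z_crit + shift) + stats.norm.cdf(-z_crit - shift))


def fprp_value(alpha: float, power: float, prior: float) -> float:
    """FPRP = α(1−π) / (α(1−π) + power·π).

    With zero power and positive α the association is unprovable and
    the FPRP is 1 by convention.
    """
    if not 0 < alpha <= 1:
        raise StudyTableError(f"alpha must be in (0, 1], got {alpha}")
    if not 0 <= power <= 1:
        raise StudyTableError(f"power must be in [0, 1], got {power}")
    if not 0 < prior < 1:
        raise StudyTableError(f"prior must be strictly inside (0, 1), got {prior}")
    if power == 0:
        return 1.0
    num = alpha * (1.0 - prior)
    return num / (num + power * prior)


def fprp_report(
    meta: MetaResult,
    priors: Sequence[float] = DEFAULT_PRIORS,
    alternatives: Optional[Sequence[float]] = None,
    alpha: Optional[float] = None,
    noteworthy_threshold: float = DEFAULT_NOTEWORTHY,
) -> FprpGrid:
    """FPRP grid for a pooled result.

    α defaults to the pooled estimate's observed two-sided p-value;
    alternatives default to odds ratios 1.2 and 1.5 (and their
    reciprocals' magnitude is irrelevant since power depends on
    |ln OR|) plus the observed pooled OR.
    """
    if len(priors) == 0:
        raise StudyTableError("at least one prior probability is required")
    if alpha is None:
        alpha = meta.p_value
    if not math.isfinite(alpha) or not 0 < alpha < 1:
        # p-values can underflow for very large pooled samples
        alpha = max(min(alpha, 1 - 1e-16), 1e-300)
    if alternatives is None:
        alternatives = (1.2, 1.5, round(meta.pooled_or, 4))
    power = tuple(
        power_at_alternative(meta.pooled_se, or_alt, alpha) for or_alt in alternatives
    )
    grid = tuple(
        tuple(fprp_value(alpha, pw, float(prior)) for prior in priors)
        for pw in power
    )
    return FprpGrid(
        snp=meta.snp,
        alpha=float(alpha),
        alternatives=tuple(float(a) for a in alternatives),
        priors=tuple(float(p) for p in priors),
        power=power,
        fprp=grid,
        noteworthy_threshold=noteworthy_threshold,
    )
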
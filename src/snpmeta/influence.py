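"""Leave-one-out influence analysis and heterogeneity-targeted sensitivity.

Influence analysis repeats the pooled analysis with each study omitted
in turn and flags omissions that change the selected model or flip the
statistical significance of the pooled odds ratio (the 95% CI crossing
1 in exactly one of the full and reduced analyses).

The sensitivity scan asks a narrower question: when the full study set
triggers the heterogeneity rules, is there a single study whose removal
de-triggers both of them?  If so, that study is reported as the likely
source of the heterogeneity, together with the de-triggered pooled
result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .meta_engine import MetaResult, PoolConfig, cochran_q, pool_snp, select_model
from .study_data import StudyOutcome, StudyTableError, effect_for_outcome

__all__ = ["InfluenceRow", "SensitivityReport", "leave_one_out", "sensitivity_scan"]


@dataclass(frozen=True)
class InfluenceRow:
    """Pooled result after omitting one study, with change flags."""

    omitted_study: str
    result: MetaResult
    model_changed: bool
    significance_changed: bool


@dataclass(frozen=True)
class SensitivityReport:
    """Outcome of the single-omission heterogeneity scan."""

    snp: str
    triggered: bool
    source_study: Optional[str] = None
    detriggered_result: Optional[MetaResult] = None
    candidates: tuple[str, ...] = ()
    notes: tuple[str, ...] = ()

    @property
    def empty(self) -> bool:
        return not self.triggered


def leave_one_out(
    outcomes: Sequence[StudyOutcome],
    config: Optional[PoolConfig] = None,
) -> list[InfluenceRow]:
    """Re-pool with each outcome omitted in turn.

    Model selection is re-applied on every reduced set.  Requires at
    least 3 outcomes so each reduced set still supports a heterogeneity
    estimate.  Output order follows input order.
    """
    cfg = config or PoolConfig()
    if len(outcomes) < 3:
        raise StudyTableError("leave-one-out needs at least 3 outcomes")
    full = pool_snp(outcomes, cfg)
    rows = []
    for i, omitted in enumerate(outcomes):
        reduced = list(outcomes[:i]) + list(outcomes[i + 1:])
        res = pool_snp(reduced, cfg)
        rows.append(
            InfluenceRow(
                omitted_study=omitted.study_id,
                result=res,
                model_changed=res.model != full.model,
                significance_changed=res.significant() != full.significant(),
            )
        )
    return rows


def sensitivity_scan(
    outcomes: Sequence[StudyOutcome],
    config: Optional[PoolConfig] = None,
) -> SensitivityReport:
    """Find the single omission that removes the observed heterogeneity.

    If the full set does not trigger either heterogeneity rule the scan
    is a no-op (an empty report).  Among omissions that bring both the
    Q-test p-value and I² back under their thresholds, the one leaving
    the least residual I² (ties broken by Q) is reported as the source.
    """
    cfg = config or PoolConfig()
    if len(outcomes) < 2:
        raise StudyTableError("sensitivity scan needs at least 2 outcomes")
    snp = outcomes[0].snp
    effects = [effect_for_outcome(o, source=cfg.effect_source, z=cfg.z) for o in outcomes]
    het = cochran_q(effects)
    if select_model(het, cfg.pq_threshold, cfg.i2_threshold) == "FEM":
        return SensitivityReport(snp=snp, triggered=False)
    if len(outcomes) == 2:
        # any omission leaves a single study: heterogeneity vacuously gone,
        # but the "pooled" result is just the survivor — flag, don't pretend
        return SensitivityReport(
            snp=snp,
            triggered=True,
            notes=("omitting either study leaves k=1; no meaningful reduced pooling",),
        )
    candidates: list[tuple[float, float, str, MetaResult]] = []
    for i, omitted in enumerate(outcomes):
        reduced = list(outcomes[:i]) + list(outcomes[i + 1:])
        reduced_eff = [e for j, e in enumerate(effects) if j != i]
        reduced_het = cochran_q(reduced_eff)
        if (
            reduced_het.p_q >= cfg.pq_threshold
            and reduced_het.i_squared <= cfg.i2_threshold
        ):
            res = pool_snp(reduced, cfg)
            candidates.append((reduced_het.i_squared, reduced_het.q_stat, omitted.study_id, res))
    if not candidates:
        return SensitivityReport(
            snp=snp,
            triggered=True,
            notes=("no single omission removes the heterogeneity",),
        )
    candidates.sort(key=lambda t: (t[0], t[1]))
    i2_best, _, study, res = candidates[0]
    return SensitivityReport(
        snp=snp,
        triggered=True,
        source_study=study,
        detriggered_result=res,
        candidates=tuple(c[2] for c in candidates),
    )
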
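"""Pooling estimators, heterogeneity statistics, and model selection."""

import itertools
import math
import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats

from snpmeta import (
    PoolConfig,
    StudyTableError,
    cochran_q,
    dersimonian_laird,
    effect_for_outcome,
    effect_from_ci,
    fixed_effect_inverse_variance,
    mantel_haenszel,
    pool_snp,
    select_model,
)
from snpmeta.meta_engine import HeterogeneityResult, mantel_haenszel_outcomes
from snpmeta.study_data import allele_table

from _oracles import brute_q_tau


class TestFixedEffect:
    def test_pooled_or_matches_published_summaries(self, effects_by_snp):
        res = fixed_effect_inverse_variance(effects_by_snp["rs11594656"])
        assert (round(res.pooled_or, 2), round(res.ci_low, 2), round(res.ci_high, 2)) == (
            0.87, 0.83, 0.91,
        )
        res = fixed_effect_inverse_variance(effects_by_snp["rs2104286"])
        assert (round(res.pooled_or, 2), round(res.ci_low, 2), round(res.ci_high, 2)) == (
            0.81, 0.77, 0.85,
        )

    def test_single_effect_passes_through(self):
        eff = effect_from_ci(0.8, 0.7, 0.9)
        res = fixed_effect_inverse_variance([eff])
        assert res.pooled_log_or == pytest.approx(eff.log_or, abs=1e-14)
        assert res.pooled_se == pytest.approx(eff.se_log_or, abs=1e-14)

    def test_empty_list_rejected(self):
        with pytest.raises(StudyTableError):
            fixed_effect_inverse_variance([])

    def test_pooling_never_less_precise_than_best_study(self, effects_by_snp):
        for effects in effects_by_snp.values():
            res = fixed_effect_inverse_variance(effects)
            assert res.pooled_se <= min(e.se_log_or for e in effects) + 1e-15

    def test_permutation_invariance(self, effects_by_snp):
        effects = effects_by_snp["rs41295061"]
        a = fixed_effect_inverse_variance(effects)
        b = fixed_effect_inverse_variance(effects[::-1])
        assert a.pooled_log_or == b.pooled_log_or
        assert a.pooled_se == b.pooled_se
        assert a.q_stat == b.q_stat
        assert tuple(a.weights) == tuple(b.weights[::-1])


class TestCochranQ:
    def test_heterogeneous_snp(self, effects_by_snp):
        het = cochran_q(effects_by_snp["rs41295061"])
        assert round(het.i_squared, 1) == 55.6
        assert het.p_q == pytest.approx(0.061, abs=0.002)

    def test_mildly_heterogeneous_snp(self, effects_by_snp):
        het = cochran_q(effects_by_snp["rs11594656"])
        assert round(het.i_squared, 1) == 10.0
        assert het.p_q == pytest.approx(0.352, abs=0.002)

    def test_identical_effects_have_zero_q(self):
        effs = [effect_from_ci(0.8, 0.7, 0.9) for _ in range(4)]
        het = cochran_q(effs)
        assert het.q_stat == pytest.approx(0.0, abs=1e-12)
        assert het.i_squared == 0.0

    def test_single_study_rejected(self):
        with pytest.raises(StudyTableError):
            cochran_q([effect_from_ci(0.8, 0.7, 0.9)])

    def test_brute_force_oracle_on_small_subsets(self, effects_by_snp):
        for effects in effects_by_snp.values():
            for k in (2, 3):
                for subset in itertools.combinations(effects, k):
                    thetas = [e.log_or for e in subset]
                    ses = [e.se_log_or for e in subset]
                    q_ref, tau_ref = brute_q_tau(thetas, ses)
                    het = cochran_q(subset)
                    rem = dersimonian_laird(subset)
                    assert het.q_stat == pytest.approx(q_ref, abs=1e-12)
                    assert rem.tau_squared == pytest.approx(tau_ref, abs=1e-12)

    def test_null_i_squared_exceeds_50_at_theoretical_rate(self):
        # under homogeneity Q ~ chi2(k-1), so P(I2 > 50) = P(Q > 2 df)
        rng = np.random.default_rng(3)
        se = np.array([0.05, 0.08, 0.1, 0.15, 0.2])
        hits = 0
        reps = 5000
        for _ in range(reps):
            th = rng.normal(0.0, se)
            effs = [
                effect_from_ci(
                    math.exp(t), math.exp(t - 1.96 * s), math.exp(t + 1.96 * s)
                )
                for t, s in zip(th, se)
            ]
            if cochran_q(effs).i_squared > 50:
                hits += 1
        theory = stats.chi2.sf(8, 4)
        assert hits / reps == pytest.approx(theory, abs=0.02)


class TestDersimonianLaird:
    def test_heterogeneous_snp_pooled_by_random_effects(self, effects_by_snp):
        res = dersimonian_laird(effects_by_snp["rs41295061"])
        assert (round(res.pooled_or, 2), round(res.ci_low, 2), round(res.ci_high, 2)) == (
            0.67, 0.60, 0.76,
        )
        assert res.tau_squared > 0

    def test_truncation_to_fixed_effect_when_q_below_df(self, effects_by_snp):
        effects = effects_by_snp["rs706778"]  # I2 = 0 here
        rem = dersimonian_laird(effects)
        fem = fixed_effect_inverse_variance(effects)
        assert rem.tau_squared == 0.0
        assert rem.pooled_log_or == pytest.approx(fem.pooled_log_or, abs=1e-12)
        assert rem.pooled_se == pytest.approx(fem.pooled_se, abs=1e-12)
        assert round(rem.pooled_or, 2) == 1.20

    def test_random_effects_never_more_precise_than_fixed(self, effects_by_snp):
        for effects in effects_by_snp.values():
            fem = fixed_effect_inverse_variance(effects)
            rem = dersimonian_laird(effects)
            assert rem.pooled_se >= fem.pooled_se - 1e-15
            if rem.tau_squared == 0:
                assert rem.pooled_se == pytest.approx(fem.pooled_se, abs=1e-15)

    def test_agrees_with_metafor_reference(self, effects_by_snp):
        """Independent cross-check against R metafor's DL implementation."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        effects = effects_by_snp["rs41295061"]
        yi = ",".join(repr(e.log_or) for e in effects)
        sei = ",".join(repr(e.se_log_or) for e in effects)
        script = (
            "suppressMessages(library(metafor));"
            f"r <- rma(yi=c({yi}), sei=c({sei}), method='DL');"
            "cat(r$b, r$tau2, r$I2)"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120,
        )
        assert out.returncode == 0, out.stderr
        b, tau2, i2 = map(float, out.stdout.split())
        res = dersimonian_laird(effects)
        assert res.pooled_log_or == pytest.approx(b, abs=1e-6)
        assert res.tau_squared == pytest.approx(tau2, abs=1e-6)
        assert res.i_squared == pytest.approx(i2, abs=0.01)


class TestMantelHaenszel:
    def test_single_stratum_equals_crude_odds_ratio(self, by_snp):
        fichna = [o for o in by_snp["rs11594656"] if o.study_id == "fichna2012"][0]
        table = allele_table(fichna.case_counts, fichna.control_counts)
        res = mantel_haenszel([table])
        assert round(res.pooled_or, 2) == 0.77

    def test_identical_strata_leave_estimate_unchanged(self):
        t = (100, 300, 130, 270)
        single = mantel_haenszel([t])
        double = mantel_haenszel([t, t])
        assert double.pooled_or == pytest.approx(single.pooled_or, abs=1e-12)

    def test_swapping_groups_inverts_odds_ratio(self):
        tables = [(100, 300, 130, 270), (50, 150, 80, 120)]
        swapped = [(c, d, a, b) for a, b, c, d in tables]
        prod = mantel_haenszel(tables).pooled_or * mantel_haenszel(swapped).pooled_or
        assert prod == pytest.approx(1.0, abs=1e-12)

    def test_requires_counts_for_every_study(self, by_snp):
        with pytest.raises(StudyTableError, match="inverse-variance"):
            mantel_haenszel_outcomes(by_snp["rs2104286"])

    def test_agrees_with_inverse_variance_on_large_strata(self, by_snp):
        for snp, rows in by_snp.items():
            with_counts = [o for o in rows if o.has_counts]
            if len(with_counts) < 2:
                continue
            mh = mantel_haenszel_outcomes(with_counts)
            effs = [effect_for_outcome(o, source="counts") for o in with_counts]
            iv = fixed_effect_inverse_variance(effs)
            assert abs(mh.pooled_or - iv.pooled_or) < 0.005


class TestModelSelection:
    @pytest.mark.parametrize(
        "p_q, i2, expected",
        [
            (0.061, 55.6, "REM"),  # I2 alone triggers
            (0.352, 10.0, "FEM"),
            (0.04, 30.0, "REM"),  # Q-test p alone triggers
            (0.5, 50.0, "FEM"),  # boundary: strictly greater than required
        ],
    )
    def test_disjunctive_rule(self, p_q, i2, expected):
        het = HeterogeneityResult(q_stat=1.0, q_df=1, p_q=p_q, i_squared=i2)
        assert select_model(het) == expected


class TestPoolSnp:
    @pytest.mark.parametrize(
        "snp, model, or_, lo, hi",
        [
            ("rs11594656", "FEM", 0.87, 0.83, 0.91),
            ("rs2104286", "FEM", 0.81, 0.77, 0.85),
            ("rs3118470", "FEM", 1.23, 1.16, 1.31),
            ("rs41295061", "REM", 0.67, 0.60, 0.76),
            ("rs706778", "FEM", 1.20, 1.08, 1.33),
        ],
    )
    def test_reproduces_published_pooled_table(self, by_snp, snp, model, or_, lo, hi):
        res = pool_snp(by_snp[snp])
        assert res.model == model
        assert (round(res.pooled_or, 2), round(res.ci_low, 2), round(res.ci_high, 2)) == (
            or_, lo, hi,
        )
        assert res.alternate is not None and res.alternate.model != model

    def test_alternate_model_is_similar(self, by_snp):
        # the sensitivity claim: pooling every SNP by REM tells the same story
        for snp, rows in by_snp.items():
            res = pool_snp(rows)
            assert res.significant() == res.alternate.significant()

    def test_mixed_snps_rejected(self, outcomes):
        with pytest.raises(StudyTableError, match="share one SNP"):
            pool_snp(outcomes[:3])

    def test_single_outcome_flagged(self, by_snp):
        single = by_snp["rs706778"][:1]
        with pytest.warns(UserWarning, match="fragile"):
            res = pool_snp(single)
        assert "single_study" in res.flags
        eff = effect_for_outcome(single[0])
        assert res.pooled_log_or == pytest.approx(eff.log_or, abs=1e-14)

    def test_sample_sizes_summed_from_rows(self, by_snp):
        res = pool_snp(by_snp["rs41295061"])
        assert (res.n_cases, res.n_controls) == (11253, 13834)

    def test_small_p_printed_as_bound(self, by_snp):
        assert pool_snp(by_snp["rs11594656"]).p_display == "<10^-6"
        assert pool_snp(by_snp["rs706778"]).p_display.startswith("0.0006")
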
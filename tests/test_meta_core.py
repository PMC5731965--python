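"""Effect estimation, pooling and heterogeneity, cross-checked against
closed forms, statsmodels' stratified-table MH machinery and R metafor."""

import math
import shutil
import subprocess

import numpy as np
import pytest

from genemeta.genetic_models import GeneticModel, TwoByTwo, derive_two_by_two
from genemeta.meta_core import (
    EffectEstimate,
    PoolingMethod,
    heterogeneity,
    pool_dl,
    pool_iv,
    pool_mh,
    pool_studies,
    power_hedges_pigott,
    select_method,
    study_effect,
    z_test,
)
from genemeta.study_io import ValidationError


def _tables(collection, model):
    return [derive_two_by_two(s.cases, s.controls, model) for s in collection]


def _effects(collection, model):
    return [study_effect(t) for t in _tables(collection, model)]


class TestStudyEffect:
    def test_hidaka_allele_arithmetic(self):
        t = TwoByTwo(191, 723, 180, 734)
        e = study_effect(t)
        assert e.or_ == pytest.approx(191 * 734 / (723 * 180), rel=1e-12)
        assert e.or_ == pytest.approx(1.0773, abs=5e-5)
        assert e.se == pytest.approx(math.sqrt(1 / 191 + 1 / 723 + 1 / 180 + 1 / 734),
                                     rel=1e-12)
        assert e.se == pytest.approx(0.1164, abs=1e-4)

    def test_symmetric_table_is_null(self):
        e = study_effect(TwoByTwo(114, 194, 114, 194))
        assert e.log_or == 0.0
        assert e.or_ == 1.0

    def test_balanced_small_table_closed_form(self):
        e = study_effect(TwoByTwo(10, 10, 10, 10))
        assert e.or_ == 1.0
        assert e.se == pytest.approx(math.sqrt(0.4))

    def test_zero_cell_directs_to_correction(self):
        with pytest.raises(ValidationError, match="continuity"):
            study_effect(TwoByTwo(5, 10, 0, 20))

    def test_ci_brackets_the_estimate(self):
        e = EffectEstimate.from_log_or(0.3, 0.1)
        assert e.ci_low < e.or_ < e.ci_high
        assert e.ci_low == pytest.approx(math.exp(0.3 - 1.96 * 0.1))
        assert e.ci_high == pytest.approx(math.exp(0.3 + 1.96 * 0.1))


class TestMantelHaenszel:
    def test_single_study_identity(self):
        t = TwoByTwo(20, 30, 15, 35)
        pooled = pool_mh([t])
        assert pooled.pooled.or_ == pytest.approx(study_effect(t).or_, rel=1e-12)
        assert pooled.k == 1

    def test_japan_allele_subgroup(self, table2):
        japan = table2.subset(lambda s: s.country == "Japan")
        pooled = pool_mh(_tables(japan, GeneticModel.ALLELE))
        assert round(pooled.pooled.or_, 3) == 1.138
        assert pooled.p == pytest.approx(0.034, abs=5e-4)

    def test_korea_recessive_subgroup(self, table2):
        korea = table2.subset(lambda s: s.country == "Korea")
        pooled = pool_mh(_tables(korea, GeneticModel.RECESSIVE))
        assert round(pooled.pooled.or_, 3) == 0.563

    def test_degenerate_all_zero_numerators(self):
        with pytest.raises(ValidationError, match="degenerate"):
            pool_mh([TwoByTwo(0, 5, 5, 0), TwoByTwo(0, 3, 3, 0)])

    @pytest.mark.parametrize("model", list(GeneticModel))
    def test_matches_statsmodels_stratified_table(self, table2, model):
        """MH pooled OR and RBG-based CI agree with the independent
        statsmodels implementation on every genetic model."""
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        tables = _tables(table2, model)
        strata = np.array([[[t.a, t.b], [t.c, t.d]] for t in tables])
        st = sm_ct.StratifiedTable(strata.transpose(1, 2, 0).astype(float))
        pooled = pool_mh(tables)
        assert pooled.pooled.or_ == pytest.approx(st.oddsratio_pooled, rel=1e-10)
        lo, hi = st.oddsratio_pooled_confint()
        assert pooled.pooled.ci_low == pytest.approx(lo, rel=1e-3)
        assert pooled.pooled.ci_high == pytest.approx(hi, rel=1e-3)

    @pytest.mark.parametrize("model", list(GeneticModel))
    def test_mh_and_iv_agree_on_large_balanced_studies(self, table2, model):
        tables = _tables(table2, model)
        mh = pool_mh(tables)
        iv = pool_iv([study_effect(t) for t in tables])
        assert mh.pooled.or_ == pytest.approx(iv.pooled.or_, rel=0.01)


class TestInverseVarianceAndDL:
    def test_iv_identical_effects(self):
        e = EffectEstimate.from_log_or(0.1, 0.2)
        pooled = pool_iv([e, e])
        assert pooled.pooled.log_or == pytest.approx(0.1)
        assert pooled.pooled.se == pytest.approx(0.2 / math.sqrt(2))

    def test_iv_equal_se_is_arithmetic_mean(self):
        effects = [EffectEstimate.from_log_or(y, 0.3) for y in (0.0, 0.2, 0.7)]
        assert pool_iv(effects).pooled.log_or == pytest.approx(0.3)

    def test_dl_reduces_to_iv_when_homogeneous(self):
        effects = [EffectEstimate.from_log_or(0.25, 0.1)] * 4
        dl, iv = pool_dl(effects), pool_iv(effects)
        assert dl.het.tau2 == 0.0
        assert dl.pooled.log_or == pytest.approx(iv.pooled.log_or, abs=1e-12)
        assert dl.pooled.se == pytest.approx(iv.pooled.se, abs=1e-12)

    def test_dl_two_point_closed_form(self):
        # y = {0, 1}, se = {0.1, 0.1}: Q = 50, tau2 = 49/100, w* = 2 each
        effects = [EffectEstimate.from_log_or(0.0, 0.1),
                   EffectEstimate.from_log_or(1.0, 0.1)]
        dl = pool_dl(effects)
        assert dl.het.q == pytest.approx(50.0)
        assert dl.het.tau2 == pytest.approx(0.49)
        assert dl.pooled.log_or == pytest.approx(0.5)
        assert dl.pooled.se == pytest.approx(0.5)
        assert dl.pooled.se > pool_iv(effects).pooled.se

    def test_dl_single_study_identity(self):
        e = EffectEstimate.from_log_or(0.3, 0.15)
        dl = pool_dl([e])
        assert dl.pooled.log_or == pytest.approx(0.3)
        assert dl.pooled.se == pytest.approx(0.15)

    def test_dl_ci_never_narrower_than_iv(self, table2):
        for model in GeneticModel:
            effects = _effects(table2, model)
            dl, iv = pool_dl(effects), pool_iv(effects)
            assert dl.pooled.se >= iv.pooled.se - 1e-12

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_dl_matches_r_metafor(self, table2):
        """DL pooled log OR, SE and tau^2 agree with metafor's rma(method='DL')."""
        effects = _effects(table2, GeneticModel.ALLELE)
        yi = ",".join(f"{e.log_or:.12f}" for e in effects)
        vi = ",".join(f"{e.se**2:.12f}" for e in effects)
        script = (
            "suppressMessages(library(metafor));"
            f"r <- rma(yi=c({yi}), vi=c({vi}), method='DL');"
            "cat(r$b, r$se, r$tau2, sep='\\n')"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True, timeout=120)
        b, se, tau2 = map(float, out.stdout.split())
        dl = pool_dl(effects)
        assert dl.pooled.log_or == pytest.approx(b, rel=1e-6)
        assert dl.pooled.se == pytest.approx(se, rel=1e-6)
        assert dl.het.tau2 == pytest.approx(tau2, rel=1e-6, abs=1e-10)


class TestHeterogeneity:
    def test_japan_allele_i2_zero(self, table2):
        japan = table2.subset(lambda s: s.country == "Japan")
        het = heterogeneity(_effects(japan, GeneticModel.ALLELE))
        assert het.i2 == 0.0

    def test_overall_allele_i2(self, table2):
        het = heterogeneity(_effects(table2, GeneticModel.ALLELE))
        assert round(het.i2, 1) == 10.9

    def test_identical_effects_no_dispersion(self):
        het = heterogeneity([EffectEstimate.from_log_or(0.2, 0.1)] * 5)
        assert het.q == pytest.approx(0.0)
        assert het.i2 == 0.0
        assert het.tau2 == 0.0

    def test_single_study_degenerate(self):
        het = heterogeneity([EffectEstimate.from_log_or(0.2, 0.1)])
        assert (het.q, het.df, het.i2, het.tau2) == (0.0, 0, 0.0, 0.0)


class TestMethodSelectionAndTests:
    @pytest.mark.parametrize("i2,expected", [
        (10.9, PoolingMethod.MH_FIXED),
        (93.9, PoolingMethod.DL_RANDOM),
        (50.0, PoolingMethod.MH_FIXED),   # tie goes to the fixed default
        (50.01, PoolingMethod.DL_RANDOM),
    ])
    def test_i2_rule(self, i2, expected):
        from genemeta.meta_core import Heterogeneity
        het = Heterogeneity(q=1.0, df=1, p_q=0.5, i2=i2, tau2=0.0)
        assert select_method(het) is expected

    def test_z_test_null_point(self):
        z, p = z_test(EffectEstimate.from_log_or(0.0, 0.2))
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_z_test_at_195996_se(self):
        z, p = z_test(EffectEstimate.from_log_or(1.96 * 0.2, 0.2))
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_pool_studies_selects_fixed_for_fixture(self, table2):
        pooled = pool_studies(table2.studies, GeneticModel.ALLELE)
        assert pooled.method is PoolingMethod.MH_FIXED
        assert pooled.model is GeneticModel.ALLELE


class TestPower:
    def test_size_under_null(self):
        assert power_hedges_pigott(0.0, 1.0, alpha=0.05) == pytest.approx(0.05)

    def test_canonical_eighty_percent_point(self):
        # lambda = 2.80 is the textbook 80%-power noncentrality at alpha=0.05
        assert power_hedges_pigott(2.80, 1.0, alpha=0.05) == pytest.approx(0.80, abs=0.005)

    def test_limit_to_one(self):
        assert power_hedges_pigott(50.0, 1.0) == pytest.approx(1.0)

    def test_monotone_in_effect(self):
        powers = [power_hedges_pigott(x, 0.5) for x in (0.0, 0.2, 0.5, 1.0, 2.0)]
        assert powers == sorted(powers)
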
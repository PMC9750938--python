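"""Collapsing, three-step burden fits, inflation lambda, heterogeneity Z and
gene summaries. The key oracles: closed-form 2x2 odds ratio with Woolf SE,
chi-square quantile arithmetic for lambda, and the normal CDF for Z."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from burdenmr import burden
from burdenmr.burden import CarrierMatrix, ScreenConfig
from burdenmr.errors import ConfigError, DataError, NumericalError
from burdenmr.genoqc import HET, HOM_REF, MISSING


class TestCollapse:
    def setup_method(self):
        # 3 variants x 4 samples; variants 0,1 in gene A, variant 2 in gene B
        self.genes = ["A", "A", "B"]
        self.gt = np.array(
            [
                [HET, HOM_REF, MISSING, HOM_REF],
                [HET, HOM_REF, HOM_REF, HOM_REF],
                [HOM_REF, HET, HOM_REF, HOM_REF],
            ],
            dtype=np.int8,
        )
        self.samples = ["s1", "s2", "s3", "s4"]

    def collapse(self, qualifying):
        return burden.collapse_gene_carriers(
            self.gt, self.genes, qualifying, self.samples, "m"
        )

    def test_multiple_variants_count_once(self):
        cm = self.collapse(np.array([True, True, True]))
        # s1 carries two qualifying variants in A: still coded 1
        assert cm.gene_vector("A").tolist() == [True, False, False, False]

    def test_missing_genotype_is_not_carrier(self):
        cm = self.collapse(np.array([True, False, False]))
        # s3's only qualifying site was set missing by QC
        assert cm.gene_vector("A")[2] == False  # noqa: E712

    def test_carrier_status_is_gene_specific(self):
        cm = self.collapse(np.array([True, True, True]))
        assert cm.gene_vector("B").tolist() == [False, True, False, False]

    def test_gene_without_qualifying_variants_omitted(self):
        cm = self.collapse(np.array([True, True, False]))
        assert cm.genes == ["A"]


def _two_by_two(carrier_cases, carrier_ctrls, noncarrier_cases, noncarrier_ctrls):
    n = carrier_cases + carrier_ctrls + noncarrier_cases + noncarrier_ctrls
    carriers = np.zeros(n, dtype=bool)
    y = np.zeros(n)
    carriers[: carrier_cases + carrier_ctrls] = True
    y[:carrier_cases] = 1
    y[carrier_cases + carrier_ctrls : carrier_cases + carrier_ctrls + noncarrier_cases] = 1
    return carriers, y


class TestFitBurden:
    def test_full_model_matches_closed_form_2x2(self):
        # carriers 50/50, non-carriers 1000/9000: OR = 9.0, Woolf SE
        carriers, y = _two_by_two(50, 50, 1000, 9000)
        res = burden.fit_burden(carriers, y, None, family="binomial", gate=1.0)
        assert res.stage == "full"
        woolf_se = np.sqrt(1 / 50 + 1 / 50 + 1 / 1000 + 1 / 9000)
        assert res.odds_ratio == pytest.approx(9.0, rel=5e-5)  # 4 sig figs
        assert res.se == pytest.approx(woolf_se, rel=1e-4)
        assert res.carriers == 100 and res.case_carriers == 50

    def test_no_contrast_raises(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        with pytest.raises(NumericalError):
            burden.fit_burden(np.ones(20, bool), y, None)

    def test_zero_carriers_is_skip_record(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        res = burden.fit_burden(np.zeros(20, bool), y, None)
        assert res.status == "skipped" and "zero carriers" in res.note

    def test_gate_controls_full_stage(self):
        carriers, y = _two_by_two(50, 50, 1000, 9000)
        prelim_only = burden.fit_burden(carriers, y, None, gate=1e-300)
        assert prelim_only.stage == "preliminary"
        full = burden.fit_burden(carriers, y, None, gate=1.0)
        assert full.stage == "full"
        # strong signal: both stages agree it is extreme
        assert prelim_only.p < 1e-10 and full.p < 1e-10

    def test_unknown_family_is_config_error(self):
        with pytest.raises(ConfigError):
            burden.fit_burden(np.ones(4, bool), np.ones(4), None, family="poisson")

    def test_gaussian_family_on_quantitative_trait(self, rng):
        n = 4000
        carriers = rng.uniform(size=n) < 0.05
        y = 0.5 * carriers + rng.normal(size=n)
        res = burden.fit_burden(carriers, y, None, family="gaussian", gate=1.0)
        assert res.stage == "full"
        assert res.beta == pytest.approx(0.5, abs=0.15)
        assert np.isnan(res.odds_ratio)  # OR only for binary traits


class TestPreliminaryCalibration:
    def test_null_rejection_rate_small_scale(self, rng):
        # small-scale version of the calibration run: 400 null genes, n=5,000
        n, g = 5_000, 400
        y = rng.binomial(1, 0.077, size=n).astype(float)
        resid = burden.null_residuals(y, None)
        carriers = rng.uniform(size=(g, n)) < rng.uniform(0.005, 0.05, size=(g, 1))
        scan = burden.preliminary_scan(carriers, resid)
        rate = (scan["p"] < 0.05).mean()
        assert 0.025 < rate < 0.075
        assert stats.kstest(scan["p"], "uniform").pvalue > 0.01

    def test_preliminary_and_full_rank_agreement(self, rng):
        # strong signals keep their ordering between the two stages
        n = 6_000
        y0 = rng.binomial(1, 0.1, size=n).astype(float)
        rows = []
        for beta in (1.2, 1.6, 2.0, 2.4, 2.8):
            carriers = rng.uniform(size=n) < 0.02
            y = y0.copy()
            flip = carriers & (rng.uniform(size=n) < (beta - 1) / 10)
            y[flip] = 1
            prelim = burden.fit_burden(carriers, y, None, gate=1e-300)
            full = burden.fit_burden(carriers, y, None, gate=1.0)
            rows.append((prelim.p, full.p))
        prelim_p, full_p = zip(*rows)
        rho = stats.spearmanr(prelim_p, full_p).statistic
        assert rho > 0.9


class TestInflationLambda:
    def test_all_half_gives_unity(self):
        assert burden.inflation_lambda([0.5] * 100) == pytest.approx(1.0, abs=1e-12)

    def test_chi2_quantile_arithmetic(self):
        expected = stats.chi2.ppf(0.95, 1) / stats.chi2.ppf(0.5, 1)
        lam = burden.inflation_lambda([0.05] * 10)
        assert lam == pytest.approx(expected, rel=1e-10)
        assert lam == pytest.approx(8.44, abs=0.01)

    def test_uniform_pvalues_give_unit_lambda(self, rng):
        p = rng.uniform(size=100_000)
        assert 0.98 < burden.inflation_lambda(p) < 1.02

    def test_order_invariant(self, rng):
        p = rng.uniform(size=999)
        assert burden.inflation_lambda(p) == burden.inflation_lambda(np.sort(p))

    def test_empty_or_invalid_input(self):
        with pytest.raises(DataError):
            burden.inflation_lambda([])
        with pytest.raises(DataError):
            burden.inflation_lambda([0.5, 0.0])


class TestHeterogeneityZ:
    def test_identical_effects(self):
        z, p = burden.heterogeneity_z(1.0, 0.5, 1.0, 0.5)
        assert z == 0.0 and p == 1.0

    @pytest.mark.parametrize(
        "b1,s1,b2,s2",
        [(1.0, 0.5, 0.0, 0.5), (2.0, 0.1, 1.0, 0.1), (0.3, 0.2, -0.4, 0.7)],
    )
    def test_matches_normal_oracle(self, b1, s1, b2, s2):
        z, p = burden.heterogeneity_z(b1, s1, b2, s2)
        z_expect = (b1 - b2) / np.sqrt(s1**2 + s2**2)
        assert z == pytest.approx(z_expect, rel=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z_expect)), rel=1e-10)

    def test_example_values(self):
        z, p = burden.heterogeneity_z(1.0, 0.5, 0.0, 0.5)
        assert z == pytest.approx(1.4142, abs=1e-4)
        assert p == pytest.approx(0.1573, abs=1e-4)

    def test_nonpositive_se_raises(self):
        with pytest.raises(DataError):
            burden.heterogeneity_z(1.0, 0.0, 1.0, 0.5)


class TestGeneSummary:
    def test_cmaf_is_sum_of_mafs(self):
        cmaf, _, _ = burden.gene_summary(
            np.zeros(10, bool), np.zeros(10), [1e-4, 2e-4]
        )
        assert cmaf == pytest.approx(3e-4)

    def test_penetrance_ratio(self):
        carriers = np.zeros(100, bool)
        carriers[:35] = True
        cases = np.zeros(100)
        cases[:27] = 1
        _, n, pen = burden.gene_summary(carriers, cases, [1e-4])
        assert n == 35 and pen == pytest.approx(27 / 35)

    def test_zero_carriers_penetrance_absent(self):
        _, n, pen = burden.gene_summary(np.zeros(5, bool), np.ones(5), [1e-4])
        assert n == 0 and pen is None


class TestScreen:
    def _screen(self, matrix, y, cfg=None):
        samples = [f"s{i}" for i in range(matrix.shape[1])]
        cm = CarrierMatrix("mask", [f"G{i}" for i in range(matrix.shape[0])],
                           samples, matrix)
        pheno = pd.DataFrame({"sample": samples, "t2d": y})
        return burden.run_exome_screen({"mask": cm}, pheno, None, cfg)

    def test_carrier_floor_blocks_small_genes(self, rng):
        n = 20_000
        y = rng.binomial(1, 0.03, size=n).astype(float)
        carriers = np.zeros(n, dtype=bool)
        carriers[:12] = True
        y[:12] = [1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0]  # OR ~ 32, p ~ 1e-9
        res, _ = self._screen(carriers[None, :], y)
        row = res.iloc[0]
        assert row["p"] < 6.9e-7 and row["carriers"] == 12
        assert not row["significant"]  # below the 30-carrier reporting floor

    def test_strong_gene_flagged_above_floor(self, rng):
        n = 20_000
        y = rng.binomial(1, 0.08, size=n).astype(float)
        carriers = np.zeros(n, dtype=bool)
        carriers[:120] = True
        y[:120] = rng.binomial(1, 0.5, 120)
        res, lam = self._screen(carriers[None, :], y)
        row = res.iloc[0]
        assert row["significant"] and row["stage"] == "full"
        assert row["odds_ratio"] > 2

    def test_sample_exclusion_rerun(self, rng):
        n = 2_000
        y = rng.binomial(1, 0.1, size=n).astype(float)
        carriers = (rng.uniform(size=n) < 0.05)[None, :]
        cfg = ScreenConfig(sample_exclusions=tuple(f"s{i}" for i in range(500)))
        res_excl, _ = self._screen(carriers, y, cfg)
        res_all, _ = self._screen(carriers, y)
        assert res_excl.iloc[0]["carriers"] == carriers[0, 500:].sum()
        assert res_all.iloc[0]["carriers"] == carriers[0].sum()


def test_domain_partition_identical_effects_not_heterogeneous(rng):
    n = 30_000
    y = rng.binomial(1, 0.08, size=n).astype(float)
    inside = rng.uniform(size=n) < 0.01
    outside = ~inside & (rng.uniform(size=n) < 0.01)
    boost = (inside | outside) & (rng.uniform(size=n) < 0.15)
    y[boost] = 1.0  # same enrichment inside and outside the domain
    res_in, res_out, z, p = burden.domain_partition_test(inside, outside, y, None)
    assert res_in.stage == res_out.stage == "full"
    assert p > 0.05
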
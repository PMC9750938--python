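"""MR estimator suite: harmonization algebra, estimator identities against
closed-form/WLS oracles, robustness filters, and null calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from burdenmr import mr, simcohort as sc
from burdenmr.errors import DataError, NumericalError


def _records(beta_x, beta_y, se_y, se_x=0.01, eaf=0.3, n_x=400_000, n_y=800_000):
    m = len(beta_x)
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(m)],
            "ea": ["A"] * m,
            "oa": ["G"] * m,
            "eaf": np.broadcast_to(eaf, m).astype(float),
            "beta_x": np.asarray(beta_x, float),
            "se_x": np.broadcast_to(se_x, m).astype(float),
            "n_x": n_x,
            "beta_y": np.asarray(beta_y, float),
            "se_y": np.broadcast_to(se_y, m).astype(float),
            "n_y": n_y,
        }
    )


class TestHarmonize:
    def _tables(self):
        exp = pd.DataFrame(
            {
                "snp": ["rs1", "rs2", "rs3", "rs4"],
                "ea": ["A", "C", "A", "C"],
                "oa": ["G", "G", "T", "A"],
                "eaf": [0.3, 0.4, 0.5, 0.2],
                "beta": [0.1, -0.1, 0.2, 0.15],
                "se": [0.01] * 4,
                "n": [1000] * 4,
            }
        )
        out = pd.DataFrame(
            {
                "snp": ["rs1", "rs2", "rs3", "rs4"],
                "ea": ["G", "C", "A", "C"],  # rs1 swapped
                "oa": ["A", "G", "T", "A"],
                "eaf": [0.7, 0.4, 0.5, 0.2],
                "beta": [0.05, 0.02, 0.03, 0.04],
                "se": [0.02] * 4,
                "n": [2000] * 4,
            }
        )
        return exp, out

    def test_swapped_alleles_flip_outcome_beta(self):
        exp, out = self._tables()
        rec, _ = mr.harmonize(exp, out)
        rs1 = rec.set_index("snp").loc["rs1"]
        assert rs1["beta_y"] == pytest.approx(-0.05)

    def test_negative_exposure_beta_reoriented(self):
        exp, out = self._tables()
        rec, _ = mr.harmonize(exp, out)
        rs2 = rec.set_index("snp").loc["rs2"]
        assert rs2["beta_x"] == pytest.approx(0.1)
        assert rs2["beta_y"] == pytest.approx(-0.02)
        assert (rs2["ea"], rs2["oa"]) == ("G", "C")
        assert rs2["eaf"] == pytest.approx(0.6)
        assert (rec["beta_x"] >= 0).all()

    def test_ambiguous_palindromic_dropped(self):
        exp, out = self._tables()
        rec, dropped = mr.harmonize(exp, out)
        assert "rs3" not in set(rec["snp"])  # A/T with EAF 0.5
        assert dropped.set_index("snp").loc["rs3", "reason"] == "palindromic_ambiguous"

    def test_irreconcilable_alleles_dropped_with_reason(self):
        exp, out = self._tables()
        out.loc[out["snp"] == "rs2", ["ea", "oa"]] = ["A", "T"]
        rec, dropped = mr.harmonize(exp, out)
        assert dropped.set_index("snp").loc["rs2", "reason"] == "irreconcilable_alleles"

    def test_strand_flip_resolved_by_complement(self):
        exp, out = self._tables()
        # rs2 reported on the other strand: C/G is palindromic, use rs4 C/A -> G/T
        out.loc[out["snp"] == "rs4", ["ea", "oa"]] = ["G", "T"]
        rec, _ = mr.harmonize(exp, out)
        assert rec.set_index("snp").loc["rs4", "beta_y"] == pytest.approx(0.04)

    def test_harmonization_is_involution(self):
        exp, out = self._tables()
        rec, _ = mr.harmonize(exp, out)
        exp2 = rec[["snp", "ea", "oa", "eaf", "beta_x", "se_x", "n_x"]].rename(
            columns={"beta_x": "beta", "se_x": "se", "n_x": "n"}
        )
        out2 = rec[["snp", "ea", "oa", "eaf", "beta_y", "se_y", "n_y"]].rename(
            columns={"beta_y": "beta", "se_y": "se", "n_y": "n"}
        )
        rec2, dropped2 = mr.harmonize(exp2, out2)
        assert len(dropped2) == 0
        pd.testing.assert_frame_equal(
            rec.reset_index(drop=True), rec2, check_dtype=False
        )

    def test_proxy_map_renames_outcome_snps(self):
        exp, out = self._tables()
        out.loc[out["snp"] == "rs1", "snp"] = "rs1_proxy"
        rec_no, _ = mr.harmonize(exp, out)
        assert "rs1" not in set(rec_no["snp"])
        rec, _ = mr.harmonize(exp, out, proxy_map={"rs1_proxy": "rs1"})
        assert "rs1" in set(rec["snp"])


class TestWaldIVW:
    def test_wald_ratio_arithmetic(self):
        theta, se = mr.wald_ratio(0.5, 0.1, 0.02)
        assert theta == pytest.approx(0.2) and se == pytest.approx(0.04)
        assert mr.wald_ratio(0.5, 0.0, 0.02)[0] == 0.0
        with pytest.raises(DataError):
            mr.wald_ratio(0.0, 0.1, 0.02)

    def test_single_instrument_ivw_equals_wald_ratio(self):
        rec = _records([0.07], [0.021], [0.015])
        res = mr.ivw(rec)
        theta, se = mr.wald_ratio(0.07, 0.021, 0.015)
        assert res.theta == pytest.approx(theta, rel=1e-14)
        assert res.se == pytest.approx(se, rel=1e-14)

    def test_identical_ratios_no_heterogeneity(self):
        rec = _records([0.05, 0.10], [0.015, 0.030], [0.01, 0.01])
        res = mr.ivw(rec)
        assert res.theta == pytest.approx(0.3, rel=1e-12)
        assert res.q == pytest.approx(0.0, abs=1e-20)
        assert res.i2 == 0.0

    def test_noiseless_exact_recovery(self, rng):
        bx = rng.uniform(0.02, 0.1, 50)
        rec = _records(bx, 0.123 * bx, 0.01)
        assert mr.ivw(rec).theta == pytest.approx(0.123, rel=1e-12)

    def test_order_invariance(self, rng):
        ins = sc.simulate_mr_instruments(sc.MRSimConfig(n_instruments=100, seed=2))
        shuffled = ins.sample(frac=1, random_state=1).reset_index(drop=True)
        for est in (mr.ivw, mr.egger):
            assert est(ins).theta == pytest.approx(est(shuffled).theta, rel=1e-12)
        wm1 = mr.weighted_median(ins, n_boot=50)
        wm2 = mr.weighted_median(shuffled, n_boot=50)
        assert wm1.theta == pytest.approx(wm2.theta, rel=1e-12)

    def test_null_ivw_p_uniform_over_seeds(self):
        ps = []
        for seed in range(200):
            ins = sc.simulate_mr_instruments(
                sc.MRSimConfig(n_instruments=50, theta=0.0, seed=1000 + seed)
            )
            ps.append(mr.ivw(ins).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_i2_bounds_and_q_additivity(self, rng):
        ins = sc.simulate_mr_instruments(
            sc.MRSimConfig(n_instruments=80, pleiotropy_sd=0.03, seed=3)
        )
        res = mr.ivw(ins)
        assert 0 <= res.i2 <= 100
        q_total, qj = mr.cochran_q(ins, res.theta)
        assert q_total == pytest.approx(qj.sum(), rel=1e-12)
        assert res.q == pytest.approx(q_total, rel=1e-12)


class TestEgger:
    def test_exact_linear_data_recovered_to_machine_precision(self, rng):
        bx = rng.uniform(0.02, 0.1, 30)
        sy = rng.uniform(0.005, 0.02, 30)
        a, theta = 0.013, 0.27
        rec = _records(bx, a + theta * bx, sy)
        # independent WLS oracle via the normal equations
        X = np.column_stack([np.ones(30), bx])
        W = np.diag(1 / sy**2)
        coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ rec["beta_y"].to_numpy())
        res = mr.egger(rec)
        assert res.intercept == pytest.approx(coef[0], rel=1e-10)
        assert res.theta == pytest.approx(coef[1], rel=1e-10)
        assert res.intercept == pytest.approx(a, rel=1e-9)
        assert res.theta == pytest.approx(theta, rel=1e-9)

    def test_zero_intercept_exact(self, rng):
        bx = rng.uniform(0.02, 0.1, 20)
        rec = _records(bx, 0.1 * bx, 0.01)
        assert mr.egger(rec).intercept == pytest.approx(0.0, abs=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(DataError):
            mr.egger(_records([0.1, 0.2], [0.01, 0.02], 0.01))


class TestWeightedMedian:
    def test_unweighted_odd_n_is_middle_ratio(self):
        rec = _records(np.ones(5), [1.0, 2.0, 3.0, 4.0, 5.0], 1.0)
        assert mr.weighted_median(rec, n_boot=10).theta == pytest.approx(3.0)

    def test_dominant_weight_returns_its_ratio(self):
        # one instrument with tiny ratio SE dominates the weighted median
        rec = _records(
            [1.0, 1.0, 1.0, 1.0, 1.0],
            [1.0, 2.0, 2.5, 4.0, 5.0],
            [1e-4, 1.0, 1.0, 1.0, 1.0],
        )
        assert mr.weighted_median(rec, n_boot=10).theta == pytest.approx(1.0, abs=0.01)

    def test_penalised_downweights_outlier(self, rng):
        bx = rng.uniform(0.05, 0.1, 20)
        by = 0.1 * bx + rng.normal(0, 0.002, 20)
        by[0] = 0.9 * bx[0]  # gross outlier
        rec = _records(bx, by, 0.002)
        pwm = mr.weighted_median(rec, penalised=True, n_boot=50)
        assert abs(pwm.theta - 0.1) < 0.02

    def test_bootstrap_se_deterministic_given_seed(self):
        rec = _records(
            np.linspace(0.03, 0.1, 10), np.linspace(0.003, 0.02, 10), 0.005
        )
        a = mr.weighted_median(rec, seed=4)
        b = mr.weighted_median(rec, seed=4)
        assert a.se == b.se


class TestRadial:
    def test_homogeneous_nothing_excluded(self, rng):
        bx = rng.uniform(0.03, 0.1, 30)
        rec = _records(bx, 0.1 * bx + rng.normal(0, 0.01, 30), 0.01)
        kept, excluded = mr.radial_filter(rec)
        assert excluded == [] and len(kept) == 30

    def test_gross_outlier_excluded_first_iteration(self, rng):
        bx = rng.uniform(0.03, 0.1, 20)
        by = 0.1 * bx + rng.normal(0, 0.005, 20)
        by[7] = 10 * 0.1 * bx[7] + 0.05
        rec = _records(bx, by, 0.005)
        kept, excluded = mr.radial_filter(rec)
        assert "rs7" in excluded

    def test_idempotent(self, rng):
        bx = rng.uniform(0.03, 0.1, 40)
        by = 0.1 * bx + rng.normal(0, 0.02, 40)
        rec = _records(bx, by, 0.005)  # overdispersed: some exclusions likely
        kept, _ = mr.radial_filter(rec)
        kept2, excluded2 = mr.radial_filter(kept)
        assert excluded2 == [] and len(kept2) == len(kept)


class TestSteiger:
    def test_strong_exposure_weak_outcome_retained(self):
        rec = _records([0.1], [0.01], 0.005, se_x=0.005)  # |z_x|=20, |z_y|=2
        kept, excluded, _ = mr.steiger_filter(rec)
        assert len(kept) == 1 and excluded == []

    def test_reverse_instrument_excluded(self):
        rec = _records([0.01, 0.1], [0.1, 0.01], 0.005)
        kept, excluded, _ = mr.steiger_filter(rec)
        assert excluded == ["rs0"] and list(kept["snp"]) == ["rs1"]

    def test_exact_tie_retained(self):
        rec = _records([0.05], [0.05], 0.005)
        kept, excluded, _ = mr.steiger_filter(rec)
        assert len(kept) == 1

    def test_missing_eaf_passes_with_tally(self):
        rec = _records([0.01], [0.1], 0.005)
        rec.loc[0, "eaf"] = np.nan
        kept, excluded, n_untested = mr.steiger_filter(rec)
        assert len(kept) == 1 and n_untested == 1


class TestMVMR:
    def test_single_exposure_reduces_to_ivw(self, rng):
        ins = sc.simulate_mr_instruments(sc.MRSimConfig(n_instruments=50, seed=5))
        res = mr.mvmr(ins, exposure_cols=("beta_x",))
        assert res.theta == pytest.approx(mr.ivw(ins).theta, rel=1e-12)

    def test_recovers_direct_effect_under_mediation(self, rng):
        # direct theta = 0.05 plus a height-mediated path biases univariable IVW
        m = 300
        bx = rng.normal(0.05, 0.02, m)
        bh = rng.normal(0.0, 0.05, m) + 0.5 * bx  # correlated height effects
        by = 0.05 * bx + 0.2 * bh + rng.normal(0, 0.005, m)
        rec = _records(bx, by, 0.005)
        rec["beta_height"] = bh
        res = mr.mvmr(rec, exposure_cols=("beta_x", "beta_height"))
        assert res.theta == pytest.approx(0.05, abs=0.02)
        assert abs(mr.ivw(rec).theta - 0.05) > 0.05  # univariable is biased

    def test_duplicated_exposure_column_is_rank_error(self, rng):
        rec = _records(rng.uniform(0.02, 0.1, 10), np.zeros(10), 0.01)
        rec["beta_dup"] = rec["beta_x"]
        with pytest.raises(NumericalError, match="beta_"):
            mr.mvmr(rec, exposure_cols=("beta_x", "beta_dup"))


def test_rescale_per_sd():
    res = mr.MRResult("IVW", 0.02, 0.005, 1e-4, 10)
    scaled = mr.rescale(res, mr.DEFAULT_SD_UNITS)
    assert scaled.theta == pytest.approx(0.11)
    assert scaled.se == pytest.approx(0.0275)
    assert scaled.p == res.p
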
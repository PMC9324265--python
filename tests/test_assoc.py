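import math

import numpy as np
import pytest

from mirpgs.assoc import (
    allelic_or,
    bonferroni_threshold,
    fit_logistic,
    snp_association,
)
from mirpgs.errors import (
    BoundaryFrequencyError,
    CollinearityError,
    DegenerateOutcomeError,
)
from mirpgs.simulate import SimConfig, SimVariant, simulate_conditional
from conftest import make_matrix


def two_by_two(a, b, c, d):
    """Outcome/predictor vectors for a 2x2 table (rows: case, control)."""
    y = np.array([1.0] * (a + b) + [0.0] * (c + d))
    x = np.array([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
    return y, np.column_stack([np.ones_like(x), x])


class TestFitLogistic:
    def test_slope_matches_closed_form_2x2_log_or(self):
        # counts (30,10;20,40): beta = ln(ad/bc), se from Woolf formula
        y, X = two_by_two(30, 10, 20, 40)
        beta, se, converged = fit_logistic(y, X)
        assert converged
        assert beta[1] == pytest.approx(math.log(6.0), rel=1e-6)
        assert se[1] == pytest.approx(math.sqrt(1 / 30 + 1 / 10 + 1 / 20 + 1 / 40), rel=1e-6)

    @pytest.mark.parametrize("a,b,c,d", [(12, 35, 27, 9), (50, 50, 50, 50), (5, 80, 40, 13)])
    def test_closed_form_oracle_over_tables(self, a, b, c, d):
        y, X = two_by_two(a, b, c, d)
        beta, se, _ = fit_logistic(y, X)
        assert beta[1] == pytest.approx(math.log(a * d / (b * c)), rel=1e-6)
        assert se[1] == pytest.approx(math.sqrt(1 / a + 1 / b + 1 / c + 1 / d), rel=1e-6)

    def test_null_predictor_gives_zero_slope(self):
        y, X = two_by_two(50, 50, 50, 50)
        beta, _, _ = fit_logistic(y, X)
        assert beta[1] == pytest.approx(0.0, abs=1e-10)

    def test_separation_flagged_not_silent(self):
        y = np.array([0.0, 0, 0, 1, 1, 1])
        X = np.column_stack([np.ones(6), y])
        _, _, converged = fit_logistic(y, X)
        assert not converged

    def test_constant_outcome_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(np.ones(10), np.ones((10, 1)))

    def test_collinear_design_names_column(self):
        y = np.array([0.0, 1, 0, 1, 0, 1])
        x = np.arange(6.0)
        X = np.column_stack([np.ones(6), x, 2 * x])
        with pytest.raises(CollinearityError, match="dup"):
            fit_logistic(y, X, column_names=["intercept", "x", "dup"])


@pytest.fixture(scope="module")
def sim():
    variants = (
        SimVariant(rsid="null_snp", eaf_case=0.33, eaf_control=0.33),
        SimVariant(rsid="risk_snp", eaf_case=0.44, eaf_control=0.29),
    )
    cfg = SimConfig(variants=variants, n_case=2000, n_control=4000, seed=21)
    return simulate_conditional(cfg)


class TestSnpAssociation:

    def test_equal_frequencies_give_or_near_one(self, sim):
        res = snp_association(sim).set_index("rsid")
        assert res.loc["null_snp", "or_"] == pytest.approx(1.0, abs=0.08)

    def test_or_matches_frequency_cross_product(self, sim):
        # EAF 0.44/0.29 -> allelic OR (0.44*0.71)/(0.56*0.29) ~= 1.92
        res = snp_association(sim).set_index("rsid")
        row = res.loc["risk_snp"]
        expected, _, _ = allelic_or(row.eaf_case, row.eaf_control, 2000, 4000)
        assert row.or_ == pytest.approx(expected, rel=0.02)

    def test_monomorphic_variant_flagged(self):
        m = make_matrix(np.zeros((40, 1)))
        res = snp_association(m)
        assert res.iloc[0]["flag"] == "monomorphic"
        assert res.iloc[0]["or_"] == 1.0
        assert res.iloc[0]["p"] == 1.0

    def test_eafs_computed_on_fitted_samples(self, tiny_matrix):
        res = snp_association(tiny_matrix).set_index("rsid")
        # rs2 has one missing control genotype: EAF over remaining samples
        assert res.loc["rs2", "n_used"] == 3
        assert res.loc["rs2", "eaf_control"] == pytest.approx(1.0)

    def test_covariate_adjustment_keeps_or_with_independent_covariates(self):
        from mirpgs.simulate import default_config, simulate

        m = simulate(default_config(seed=3, with_proxies=False, missing_rate=0.0))
        unadj = snp_association(m).set_index("rsid")
        adj = snp_association(m, covariates=("age", "sex", "ethnicity")).set_index("rsid")
        # covariates are generated independent of genotypes
        top = "rs1057035"
        assert adj.loc[top, "or_"] == pytest.approx(unadj.loc[top, "or_"], rel=0.05)
        assert set(adj.index) == set(unadj.index)


class TestAllelicOr:
    def test_equal_frequencies_unity(self):
        assert allelic_or(0.33, 0.33, 464, 1042)[0] == pytest.approx(1.0)
        assert allelic_or(0.5, 0.5, 10, 10)[0] == pytest.approx(1.0)

    def test_derived_example_study_size(self):
        or_, lo, hi = allelic_or(0.44, 0.29, 464, 1042)
        assert or_ == pytest.approx(1.9236, abs=5e-4)
        assert lo == pytest.approx(1.638, abs=5e-3)
        assert hi == pytest.approx(2.258, abs=5e-3)

    @pytest.mark.parametrize("f", [0.0, 1.0])
    def test_boundary_frequency_rejected(self, f):
        with pytest.raises(BoundaryFrequencyError):
            allelic_or(f, 0.3, 100, 100)

    def test_logistic_agrees_with_allelic_or_on_hwe_genotypes(self):
        cfg = SimConfig(
            variants=(SimVariant(rsid="v", eaf_case=0.4, eaf_control=0.3),),
            n_case=1500, n_control=1500, seed=9,
        )
        m = simulate_conditional(cfg)
        res = snp_association(m).iloc[0]
        closed, _, _ = allelic_or(res.eaf_case, res.eaf_control, 1500, 1500)
        assert res.or_ == pytest.approx(closed, rel=0.02)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 21, 0.05 / 21), (0.05, 1, 0.05), (0.01, 4, 0.0025)],
    )
    def test_threshold_values(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=1e-12)

    def test_study_threshold_prints_as_0023(self):
        thr = bonferroni_threshold(0.05, 21)
        assert math.floor(thr * 1e4) / 1e4 == pytest.approx(0.0023)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestParameterRecovery:
    def test_panel_eafs_and_ors_recovered_from_simulation(self):
        """Simulating at the packaged per-group EAFs and re-estimating
        recovers each frequency within 3 binomial SEs and each true allelic
        OR within the estimated 95% CI for nearly every variant."""
        from mirpgs.simulate import default_config, simulate_conditional

        cfg = default_config(seed=1, with_proxies=False)
        m = simulate_conditional(cfg)
        covered = 0
        for v in cfg.variants:
            for group, truth, n in (("case", v.eaf_case, cfg.n_case),
                                    ("control", v.eaf_control, cfg.n_control)):
                est = m.effect_allele_frequency(v.rsid, group)
                se = math.sqrt(truth * (1 - truth) / (2 * n))
                assert abs(est - truth) < 3 * se, (v.rsid, group)
            truth_or = (v.eaf_case * (1 - v.eaf_control)) / (
                (1 - v.eaf_case) * v.eaf_control
            )
            est_or, lo, hi = allelic_or(
                m.effect_allele_frequency(v.rsid, "case"),
                m.effect_allele_frequency(v.rsid, "control"),
                cfg.n_case, cfg.n_control,
            )
            covered += lo <= truth_or <= hi
        assert covered >= 18  # ~95% nominal coverage over 21 variants
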
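import math

import numpy as np
import pytest

from mirpgs.errors import ConfigError
from mirpgs.simulate import (
    SimConfig,
    SimVariant,
    add_missingness,
    case_genotype_probs,
    default_config,
    default_panel,
    simulate,
    simulate_conditional,
    simulate_covariates,
    simulate_logistic,
)


class TestDefaultConfig:
    def test_study_dimensions(self):
        cfg = default_config(seed=0)
        assert (cfg.n_case, cfg.n_control) == (464, 1042)
        assert len(cfg.variants) == 21
        assert len(cfg.proxies) == 7
        assert cfg.missing_rate == 0.02
        parents = {p.parent_rsid for p in cfg.proxies}
        assert len(parents) == 7  # proxies attach to distinct index variants

    def test_panel_carries_per_group_frequencies(self):
        panel = {v.rsid: v for v in default_panel()}
        top = panel["rs1057035"]
        assert (top.eaf_case, top.eaf_control) == (0.44, 0.29)
        assert (top.effect_allele, top.other_allele) == ("C", "T")

    def test_invalid_configs_rejected(self):
        v = SimVariant(rsid="a", eaf_case=0.3, eaf_control=0.3)
        with pytest.raises(ConfigError):
            SimConfig(variants=(v,), n_case=0).validate()
        with pytest.raises(ConfigError):
            SimConfig(variants=(SimVariant(rsid="a"),)).validate()  # no freqs
        with pytest.raises(ConfigError):
            SimConfig(variants=(v, v)).validate()  # duplicate rsid


class TestConditionalMode:
    def test_group_frequencies_recovered_within_3se(self):
        cfg = default_config(seed=5, with_proxies=False, missing_rate=0.0)
        m = simulate_conditional(cfg)
        for v in cfg.variants:
            for group, truth, n in (("case", v.eaf_case, 464), ("control", v.eaf_control, 1042)):
                est = m.effect_allele_frequency(v.rsid, group)
                se = math.sqrt(truth * (1 - truth) / (2 * n))
                assert abs(est - truth) < 3 * se, (v.rsid, group)

    def test_low_frequency_mean_dosage(self):
        cfg = SimConfig(
            variants=(SimVariant(rsid="rare", eaf_case=0.001, eaf_control=0.001),),
            n_case=30000, n_control=30000, seed=6,
        )
        m = simulate_conditional(cfg)
        g = m.dosages[:, 0]
        assert g.mean() == pytest.approx(0.002, abs=5e-4)

    def test_seed_determinism_byte_identical(self):
        cfg = default_config(seed=42)
        m1, m2 = simulate(cfg), simulate(cfg)
        assert np.array_equal(m1.dosages, m2.dosages, equal_nan=True)
        assert m1.samples == m2.samples
        assert m1.variants == m2.variants


class TestLogisticMode:
    def test_or_one_case_distribution_equals_control(self):
        probs = case_genotype_probs(0.3, 1.0)
        from scipy import stats

        assert np.allclose(probs, stats.binom.pmf([0, 1, 2], 2, 0.3))

    def test_case_probs_hand_example(self):
        # p=0.5, OR=2: weights (0.25,0.5,0.25)*(1,2,4) normalised by 2.25
        assert np.allclose(case_genotype_probs(0.5, 2.0), [1 / 9, 4 / 9, 4 / 9])

    def test_reestimated_or_self_consistent(self):
        from mirpgs.assoc import snp_association

        cfg = SimConfig(
            variants=(SimVariant(rsid="v", eaf=0.3, or_=2.0),),
            n_case=50000, n_control=50000, mode="logistic", seed=7,
        )
        m = simulate_logistic(cfg)
        res = snp_association(m).iloc[0]
        assert res.or_ == pytest.approx(2.0, rel=0.03)

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ConfigError):
            case_genotype_probs(0.3, 0.0)


class TestProxiesAndMissingness:
    def test_copy_probability_one_duplicates_parent(self):
        from mirpgs.simulate import plant_proxy

        cfg = SimConfig(
            variants=(SimVariant(rsid="p", eaf_case=0.4, eaf_control=0.4),),
            n_case=300, n_control=300, seed=8,
        )
        m = simulate_conditional(cfg)
        out = plant_proxy(m, "p", 1.0, np.random.default_rng(0))
        assert np.array_equal(out.dosage_vector("p"), out.dosage_vector("p_proxy"))

    def test_copy_probability_zero_independent(self):
        from mirpgs.ld import dosage_r2
        from mirpgs.simulate import plant_proxy

        cfg = SimConfig(
            variants=(SimVariant(rsid="p", eaf_case=0.4, eaf_control=0.4),),
            n_case=2000, n_control=2000, seed=9,
        )
        m = simulate_conditional(cfg)
        out = plant_proxy(m, "p", 0.0, np.random.default_rng(1))
        assert dosage_r2(out.dosage_vector("p"), out.dosage_vector("p_proxy")) < 0.01

    def test_unknown_parent_key_error(self, default_sim):
        from mirpgs.simulate import plant_proxy

        with pytest.raises(KeyError):
            plant_proxy(default_sim, "rs000", 0.5, np.random.default_rng(0))

    def test_missingness_rate_zero_is_identity(self, default_sim):
        out = add_missingness(default_sim, 0.0, np.random.default_rng(0))
        assert np.array_equal(out.dosages, default_sim.dosages, equal_nan=True)

    def test_missingness_count_within_binomial_bounds(self):
        from scipy import stats

        cfg = default_config(seed=10, with_proxies=False, missing_rate=0.0)
        m = simulate_conditional(cfg)
        out = add_missingness(m, 0.5, np.random.default_rng(3))
        n_cells = m.n_samples * m.n_variants
        missing = int((~np.isfinite(out.dosages)).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n_cells, 0.5)
        assert lo <= missing <= hi

    def test_overall_call_rate_near_098_at_default_rate(self, default_sim):
        assert np.isfinite(default_sim.dosages).mean() == pytest.approx(0.98, abs=0.005)


class TestCovariates:
    def test_group_compositions_within_3se(self):
        cfg = default_config(seed=12)
        cov = simulate_covariates(cfg, np.random.default_rng(12))
        cases = cov[cov["status"] == "case"]
        ctrls = cov[cov["status"] == "control"]
        se_male = math.sqrt(0.608 * 0.392 / 464)
        assert abs((cases["sex"] == "male").mean() - 0.608) < 3 * se_male
        for label, frac in (("Bashkir", 0.136), ("Tatar", 0.439), ("Russian", 0.425)):
            se = math.sqrt(frac * (1 - frac) / 1042)
            assert abs((ctrls["ethnicity"] == label).mean() - frac) < 3 * se, label
        assert cases["age"].mean() == pytest.approx(56.01, abs=1.5)
        assert (cov["age"] >= 18).all()

    def test_degenerate_single_ethnicity(self):
        from mirpgs.simulate import CovariateConfig, GroupCovariates

        grp = GroupCovariates(male_fraction=0.5, age_mean=50, age_sd=5,
                              ethnicity={"Tatar": 1.0})
        cfg = SimConfig(
            variants=(SimVariant(rsid="a", eaf_case=0.3, eaf_control=0.3),),
            n_case=50, n_control=50,
            covariates=CovariateConfig(case=grp, control=grp), seed=1,
        )
        cov = simulate_covariates(cfg, np.random.default_rng(1))
        assert (cov["ethnicity"] == "Tatar").all()

    def test_ethnicity_proportions_must_sum_to_one(self):
        from mirpgs.simulate import CovariateConfig, GroupCovariates

        bad = GroupCovariates(male_fraction=0.5, age_mean=50, age_sd=5,
                              ethnicity={"a": 0.5, "b": 0.4})
        cfg = SimConfig(
            variants=(SimVariant(rsid="a", eaf_case=0.3, eaf_control=0.3),),
            covariates=CovariateConfig(case=bad, control=bad),
        )
        with pytest.raises(ConfigError):
            cfg.validate()


class TestNullPipelineBehaviour:
    def test_all_or_one_gives_null_pgs_and_auc(self):
        """Logistic-mode simulation with every OR = 1 must show no signal
        for a data-independent score: OR per SD near 1, AUC near 0.5.

        The model is fixed in advance (unit weights on the declared effect
        alleles); an in-sample-oriented model would inflate apparent
        discrimination even under the null (winner's curse)."""
        import pandas as pd

        from mirpgs.roc import auc_mann_whitney
        from mirpgs.score import PGSModel, compute_pgs, pgs_association

        variants = tuple(
            SimVariant(rsid=f"n{j}", eaf=0.1 + 0.03 * j, or_=1.0) for j in range(21)
        )
        fixed_model = PGSModel(
            entries=pd.DataFrame(
                {
                    "rsid": [v.rsid for v in variants],
                    "risk_allele": [v.effect_allele for v in variants],
                    "weight": 1.0,
                }
            ),
            mode="unweighted",
        )
        ors, aucs = [], []
        for seed in range(10):
            cfg = SimConfig(variants=variants, mode="logistic", seed=100 + seed)
            m = simulate_logistic(cfg)
            res = compute_pgs(m, fixed_model)
            ors.append(pgs_association(res, m).or_per_sd)
            aucs.append(
                auc_mann_whitney(res.standardized[m.case_mask],
                                 res.standardized[m.control_mask])
            )
        assert np.mean(ors) == pytest.approx(1.0, abs=0.05)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)
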
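import numpy as np
import pytest

from hipokit.ldscore import compute_ld_scores
from hipokit.simulate import (
    STRAT_VARIANCE,
    SimulationConfig,
    draw_errors,
    draw_errors_from_genotypes,
    draw_joint_effects,
    draw_stratification,
    equicorrelation,
    error_covariance,
    lipid_config,
    make_ld_panel,
    marginal_effects,
    psychiatric_config,
    simulate_sumstats,
)

from conftest import make_panel


class TestMakeLdPanel:
    def test_zero_decay_gives_identity_blocks(self):
        panel = make_ld_panel(n_blocks=3, block_size=4, decay_rate=0.0, seed=1)
        for R in panel.blocks:
            np.testing.assert_array_equal(R, np.eye(4))

    def test_ar1_closed_form(self):
        panel = make_ld_panel(n_blocks=1, block_size=3, decay_rate=0.5, seed=1)
        assert panel.blocks[0][0, 2] == pytest.approx(0.25)

    def test_blocks_positive_definite_and_separated(self):
        panel = make_ld_panel(n_blocks=30, block_size=25, decay_rate=(0.1, 0.95),
                              seed=4, window_bp=1_000_000)
        for R in panel.blocks:
            assert np.min(np.linalg.eigvalsh(R)) > 0
        pos = panel.snps["pos_bp"].to_numpy()
        chrom = panel.snps["chrom"].to_numpy()
        for b in range(29):
            i, j = panel.block_slice(b).stop - 1, panel.block_slice(b + 1).start
            if chrom[i] == chrom[j]:
                assert pos[j] - pos[i] > 1_000_000

    def test_invalid_decay_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            make_ld_panel(n_blocks=1, block_size=3, decay_rate=1.0)

    def test_maf_within_range(self):
        panel = make_ld_panel(n_blocks=5, block_size=10, maf_range=(0.05, 0.5), seed=0)
        assert panel.snps["maf"].between(0.05, 0.5).all()


class TestDrawJointEffects:
    def test_no_causal_snps_gives_zero_effects(self):
        cfg = lipid_config(M=1000, causal_fraction=0.0, seed=0)
        panel = make_ld_panel(20, 50, seed=0)
        beta, causal = draw_joint_effects(cfg, panel, np.random.default_rng(0))
        np.testing.assert_array_equal(beta, 0.0)
        assert all(len(v) == 0 for v in causal.values())

    def test_full_overlap_shares_causal_set(self):
        cfg = lipid_config(M=1000, causal_fraction=0.05, seed=0)
        panel = make_ld_panel(20, 50, seed=0)
        beta, causal = draw_joint_effects(cfg, panel, np.random.default_rng(1))
        sets = [tuple(v) for v in causal.values()]
        assert len(set(sets)) == 1
        assert len(sets[0]) == 50

    def test_partial_overlap_fraction(self):
        cfg = lipid_config(M=2000, causal_fraction=0.05, causal_overlap=0.5, seed=0)
        beta, causal = draw_joint_effects(
            cfg, make_ld_panel(40, 50, seed=0), np.random.default_rng(2)
        )
        a, b = causal["LDL"], causal["HDL"]
        assert len(a) == len(b) == 100
        assert len(np.intersect1d(a, b)) == 50
        # entries outside a trait's causal set are exactly zero
        k = 0
        nonzero = np.flatnonzero(beta[:, k])
        assert set(nonzero) <= set(causal["LDL"])

    def test_causal_rows_match_target_covariance(self):
        cfg = lipid_config(h2max=0.35, M=50_000, causal_fraction=0.2, seed=0)
        beta, causal = draw_joint_effects(
            cfg, make_ld_panel(1000, 50, seed=0), np.random.default_rng(3)
        )
        idx = causal["LDL"]
        emp = np.cov(beta[idx].T) * len(idx)
        np.testing.assert_allclose(emp, cfg.sigma_g, atol=0.05)


class TestMarginalEffects:
    def test_identity_ld_passthrough(self, rng):
        panel = make_ld_panel(4, 10, decay_rate=0.0, seed=0)
        beta_j = rng.standard_normal((40, 2))
        np.testing.assert_array_equal(marginal_effects(beta_j, panel), beta_j)

    def test_two_snp_hand_case(self):
        panel = make_panel([np.array([[1.0, 0.5], [0.5, 1.0]])])
        beta_j = np.array([[1.0], [0.0]])
        np.testing.assert_allclose(marginal_effects(beta_j, panel),
                                   [[1.0], [0.5]])

    def test_matches_masked_matrix_product(self, rng):
        # 5-SNP AR(1) block vs dense R @ beta with sub-threshold r2 zeroed
        rho = 0.5
        R = rho ** np.abs(np.subtract.outer(np.arange(5), np.arange(5)))
        panel = make_panel([R])
        beta_j = rng.standard_normal((5, 3))
        expected = np.where(R**2 > 0.01, R, 0.0) @ beta_j
        np.testing.assert_allclose(marginal_effects(beta_j, panel, r2_min=0.01),
                                   expected)

    def test_window_limits_neighbourhood(self, rng):
        R = np.full((3, 3), 0.9)
        np.fill_diagonal(R, 1.0)
        panel = make_panel([R], positions=[1, 600_000, 1_200_000], window_bp=500_000)
        beta_j = np.array([[1.0], [0.0], [0.0]])
        out = marginal_effects(beta_j, panel, window_bp=500_000)
        np.testing.assert_allclose(out[:, 0], [1.0, 0.0, 0.0])


class TestErrorCovariance:
    def test_complete_overlap(self):
        sy = np.array([[1.0, 0.5], [0.5, 1.0]])
        se = error_covariance(sy, np.array([1000.0, 1000.0]))
        np.testing.assert_allclose(se, [[1e-3, 5e-4], [5e-4, 1e-3]])

    def test_no_overlap_is_diagonal(self):
        sy = np.array([[1.0, 0.5], [0.5, 1.0]])
        se = error_covariance(sy, np.array([1000.0, 2000.0]),
                              n_overlap=np.diag([1000.0, 2000.0]))
        assert se[0, 1] == 0.0
        np.testing.assert_allclose(np.diag(se), [1e-3, 5e-4])

    def test_partial_overlap_matches_individual_level_oracle(self, rng):
        # N1=N2=1000 with 500 shared subjects, rho_y=0.5: predicted
        # cov(beta1_hat, beta2_hat) = 500/(1000*1000)*0.5 = 2.5e-4, checked
        # against regressions on explicitly simulated overlapping samples
        se = error_covariance(
            np.array([[1.0, 0.5], [0.5, 1.0]]),
            np.array([1000.0, 1000.0]),
            n_overlap=np.array([[1000.0, 500.0], [500.0, 1000.0]]),
        )
        assert se[0, 1] == pytest.approx(2.5e-4)

        reps = 40_000
        n_total = 1500  # subjects 0-999 in study 1, 500-1499 in study 2
        x = rng.standard_normal((reps, n_total))
        L = np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 1.0]]))
        y = np.einsum("rnk,jk->rnj", rng.standard_normal((reps, n_total, 2)), L)
        b1 = np.einsum("rn,rn->r", x[:, :1000], y[:, :1000, 0]) / 1000
        b2 = np.einsum("rn,rn->r", x[:, 500:], y[:, 500:, 1]) / 1000
        emp = np.cov(b1, b2)[0, 1]
        assert emp == pytest.approx(2.5e-4, rel=0.15)


class TestDrawErrors:
    def test_zero_covariance_gives_zeros(self):
        panel = make_ld_panel(2, 5, seed=0)
        np.testing.assert_array_equal(
            draw_errors(panel, np.zeros((2, 2)), np.random.default_rng(0)), 0.0
        )

    def test_marginal_variance_single_trait(self):
        panel = make_ld_panel(2000, 50, decay_rate=0.0, seed=0)
        e = draw_errors(panel, np.array([[4.0]]), np.random.default_rng(1))
        assert e.var() == pytest.approx(4.0, rel=0.02)
        assert e.mean() == pytest.approx(0.0, abs=0.02)

    def test_kronecker_cross_moment(self):
        # cov(e_{snp1,trait1}, e_{snp2,trait2}) = r12 * Sigma_e[1,2]
        r12 = 0.6
        sigma_e = np.array([[1.0, 0.3], [0.3, 2.0]])
        R = np.array([[1.0, r12], [r12, 1.0]])
        panel = make_panel([R] * 100_000)
        e = draw_errors(panel, sigma_e, np.random.default_rng(5))
        e1 = e[0::2, 0]  # first SNP of each block, trait 1
        e2 = e[1::2, 1]  # second SNP, trait 2
        assert np.cov(e1, e2)[0, 1] == pytest.approx(r12 * 0.3, rel=0.05)
        same_snp = np.cov(e[0::2, 0], e[0::2, 1])[0, 1]
        assert same_snp == pytest.approx(0.3, rel=0.05)

    def test_non_psd_covariance_rejected(self):
        panel = make_ld_panel(1, 2, seed=0)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            draw_errors(panel, bad, np.random.default_rng(0))

    def test_genotype_resampling_mode_matches_target_law(self, rng):
        # resampling over an explicit genotype matrix reproduces Sigma_e
        n_ref, M, reps = 400, 3, 4000
        sigma_y = np.array([[1.0, 0.5], [0.5, 1.0]])
        N = np.array([10_000.0, 10_000.0])
        X = rng.standard_normal((n_ref, M))
        draws = np.array([
            draw_errors_from_genotypes(X, sigma_y, N, rng) for _ in range(reps)
        ])
        var1 = draws[:, 0, 0].var()
        assert var1 == pytest.approx(sigma_y[0, 0] / N[0], rel=0.1)
        cross = np.cov(draws[:, 0, 0], draws[:, 0, 1])[0, 1]
        assert cross == pytest.approx(sigma_y[0, 1] / N[0], rel=0.15)


class TestDrawStratification:
    def test_disabled_gives_zeros(self):
        np.testing.assert_array_equal(
            draw_stratification(None, 10, np.random.default_rng(0), K=3), 0.0
        )
        np.testing.assert_array_equal(
            draw_stratification(np.zeros((2, 2)), 10, np.random.default_rng(0)), 0.0
        )

    def test_reference_scale_variance(self):
        sigma_v = STRAT_VARIANCE * equicorrelation(4, 0.5)
        v = draw_stratification(sigma_v, 200_000, np.random.default_rng(7))
        np.testing.assert_allclose(v.var(axis=0), STRAT_VARIANCE, rtol=0.03)
        corr = np.corrcoef(v.T)
        np.testing.assert_allclose(corr[~np.eye(4, dtype=bool)], 0.5, atol=0.02)


class TestSimulateSumstats:
    def test_all_variance_components_zero(self):
        cfg = SimulationConfig(
            sigma_g_pattern=np.eye(2), sigma_y=np.eye(2), h2max=0.0,
            N=[1000.0, 1000.0], M=100, m_causal=0, seed=0,
        )
        cfg.sigma_y = np.zeros((2, 2))
        study = simulate_sumstats(cfg)
        np.testing.assert_array_equal(study.beta_hat, 0.0)

    def test_mean_chisq_matches_ldsc_expectation(self):
        # single trait: E[chi2] ~= 1 + N * h2 * mean_l_truncated / M
        cfg = psychiatric_config(h2max=0.35, N=100_000, M=100_000, seed=9)
        study = simulate_sumstats(cfg)
        ld = compute_ld_scores(study.panel)
        k = 2  # SCZ has the max diagonal
        expected = 1.0 + cfg.N[k] * cfg.sigma_g[k, k] * ld.mean_l / cfg.M
        assert (study.z[:, k] ** 2).mean() == pytest.approx(expected, rel=0.1)

    def test_determinism_same_seed(self):
        cfg = lipid_config(M=2000, N=10_000, seed=42)
        s1 = simulate_sumstats(cfg)
        s2 = simulate_sumstats(cfg)
        np.testing.assert_array_equal(s1.beta_hat, s2.beta_hat)
        np.testing.assert_array_equal(s1.truth.beta_joint, s2.truth.beta_joint)

    def test_null_snp_variance_is_strat_plus_error(self):
        # full-pipeline moment check on SNPs untouched by genetic signal
        cfg = lipid_config(h2max=0.35, N=10_000, M=100_000, stratification=True,
                           seed=17)
        study = simulate_sumstats(cfg)
        null = study.truth.null_mask
        assert null.sum() > 50_000
        emp = np.cov(study.beta_hat[null].T)
        target = cfg.sigma_v + study.sigma_e
        np.testing.assert_allclose(emp, target, rtol=0.05, atol=2e-6)

    def test_overlap_constraint_validated(self):
        with pytest.raises(ValueError, match="n_overlap"):
            lipid_config(N=1000, M=100, n_overlap=np.full((4, 4), 2000.0))

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = lipid_config(M=500, N=5000, stratification=True, seed=3)
        study = simulate_sumstats(cfg)
        study.write(tmp_path)
        cfg2 = SimulationConfig.from_yaml(tmp_path / "config.yaml")
        assert cfg2.to_dict() == cfg.to_dict()
        study2 = simulate_sumstats(cfg2)
        np.testing.assert_array_equal(study.beta_hat, study2.beta_hat)
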
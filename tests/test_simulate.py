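import numpy as np
import pytest

from prsbilevel.annotation import iou, make_overlap_assignment
from prsbilevel.datatypes import ValidationError
from prsbilevel.simulate import (
    SETTINGS,
    draw_effects,
    make_genotypes,
    make_phenotype,
    marginal_gwas,
    run_setting,
    scale_setting,
    true_per_snp_h2,
    variant_names,
)


class TestSettingsTable:
    def test_presets_match_design_table(self):
        s1 = SETTINGS[1]
        assert s1.m_k == [49750, 37500, 25125, 12625]
        assert s1.p_k == [0.5, 1, 1.5, 2]
        assert s1.q_k == [0, 0, 10, 90]
        assert SETTINGS[4].q_k == [25, 25, 25, 25]
        assert SETTINGS[5].n_groups == 10
        assert SETTINGS[5].q_k == [0] * 8 + [10, 90]
        assert SETTINGS[6].overlap == "overlap_I"
        assert SETTINGS[7].overlap == "overlap_II"
        for s in SETTINGS.values():
            assert sum(s.q_k) == 100
            assert s.h2 == 0.7
            assert s.n_sumstat == 50000 and s.n_test == 24000

    def test_desk_scale_dimensions(self):
        s = scale_setting(SETTINGS[1], 0.02)
        assert sum(s.m_k) == 2500
        assert s.m_k == [995, 750, 503, 252]
        assert s.n_sumstat == 1000 and s.n_test == 480
        assert s.p_k == SETTINGS[1].p_k and s.q_k == SETTINGS[1].q_k

    def test_too_small_scale_rejected(self):
        with pytest.raises(ValidationError):
            scale_setting(SETTINGS[1], 1e-5)


class TestGenotypes:
    def test_standardization(self):
        G, blocks, _ = make_genotypes(n=300, m=40, block_size=10, rho=0.5,
                                      seed=0)
        np.testing.assert_allclose(G.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(G.std(axis=0), 1, atol=1e-12)
        assert [len(b) for b in blocks] == [10, 10, 10, 10]

    def test_independent_blocks_near_identity(self):
        n = 3000
        G, blocks, _ = make_genotypes(n=n, m=20, block_size=10, rho=0.0,
                                      seed=1)
        r = np.corrcoef(G, rowvar=False)
        off = r[~np.eye(20, dtype=bool)]
        assert np.abs(off).max() < 3 / np.sqrt(n)

    def test_adjacent_correlation_matches_process(self):
        G, blocks, model = make_genotypes(n=2000, m=2, block_size=2, rho=0.9,
                                          seed=8)
        # large-sample oracle: an independent draw from the same process
        big = model.sample_dosages(100_000, np.random.default_rng(99))
        target = np.corrcoef(big[:, 0], big[:, 1])[0, 1]
        realized = np.corrcoef(G[:, 0], G[:, 1])[0, 1]
        assert realized == pytest.approx(target, abs=0.1)
        assert blocks[0].D[0, 1] == pytest.approx(target, abs=0.1)

    def test_ld_blocks_satisfy_invariants(self):
        _, blocks, _ = make_genotypes(n=100, m=30, block_size=15, rho=0.7,
                                      seed=3)
        for b in blocks:
            b.validate()


class TestDrawEffects:
    def test_causal_count_within_binomial_bounds(self):
        # group 1 of the balanced setting: 49750 variants at p = 0.5%,
        # expected count 248.75 (zero-heritability groups carry no causal
        # effects, so the count is checked where q_k > 0)
        s = SETTINGS[3]
        am = make_overlap_assignment(s.m_k, "none", seed=0)
        names = sorted(am.assignment)
        eff = draw_effects(s, am, names, seed=1)
        m1 = 49750
        count = sum(eff.causal_mask[i] for i, v in enumerate(names)
                    if "g1" in am.labels_for(v))
        mean, sd = m1 * 0.005, np.sqrt(m1 * 0.005 * 0.995)
        assert abs(count - mean) < 4 * sd

    def test_zero_heritability_group_all_zero(self):
        s = scale_setting(SETTINGS[1], 0.02)
        am = make_overlap_assignment(s.m_k, "none", seed=0)
        names = sorted(am.assignment)
        eff = draw_effects(s, am, names, seed=2)
        for i, v in enumerate(names):
            if am.labels_for(v)[0] in ("g1", "g2"):
                assert eff.beta_true[i] == 0.0

    def test_group_heritability_shares_match_printed_variance(self):
        """Across replicates, the per-group share of sum(beta^2) follows
        q_k * M_k / sum(q_l * M_l), the share implied by the printed
        point-normal variance."""
        s = scale_setting(SETTINGS[3], 0.1)
        am = make_overlap_assignment(s.m_k, "none", seed=0)
        names = sorted(am.assignment)
        group_of = np.array([am.groups.index(am.labels_for(v)[0])
                             for v in names])
        totals = np.zeros(4)
        for seed in range(50):
            eff = draw_effects(s, am, names, seed=seed)
            for k in range(4):
                totals[k] += float((eff.beta_true[group_of == k] ** 2).sum())
        shares = totals / totals.sum()
        qm = np.array(s.q_k) * np.array(s.m_k)
        expected = qm / qm.sum()
        np.testing.assert_allclose(shares, expected, rtol=0.1)

    def test_true_per_snp_h2_sums_to_printed_total(self):
        s = scale_setting(SETTINGS[3], 0.02)
        am = make_overlap_assignment(s.m_k, "none", seed=0)
        names = sorted(am.assignment)
        s2 = true_per_snp_h2(s, am, names)
        qm = np.array(s.q_k) * np.array(s.m_k)
        assert s2.sum() == pytest.approx(
            s.h2 * qm.sum() / (100.0 * sum(s.m_k)))


class TestPhenotype:
    def test_heritability_fixed_exactly(self, rng):
        from prsbilevel.simulate import TrueEffects

        G = rng.standard_normal((200, 30))
        beta = np.zeros(30)
        beta[:3] = [0.5, -0.2, 0.1]
        eff = TrueEffects(beta_true=beta, causal_mask=beta != 0)
        y = make_phenotype(G, eff, h2=0.7, seed=0)
        g = G @ beta
        assert np.corrcoef(g, y)[0, 1] ** 2 == pytest.approx(0.7, abs=1e-10)
        assert y.std() == pytest.approx(1.0)

    def test_boundary_h2_rejected(self, rng):
        from prsbilevel.simulate import TrueEffects

        G = rng.standard_normal((50, 5))
        eff = TrueEffects(beta_true=np.ones(5), causal_mask=np.ones(5, bool))
        for h2 in (0.0, 1.0):
            with pytest.raises(ValidationError):
                make_phenotype(G, eff, h2=h2)

    def test_no_causal_rejected(self, rng):
        from prsbilevel.simulate import TrueEffects

        G = rng.standard_normal((50, 5))
        eff = TrueEffects(beta_true=np.zeros(5),
                          causal_mask=np.zeros(5, bool))
        with pytest.raises(ValidationError):
            make_phenotype(G, eff, h2=0.5)


class TestMarginalGwas:
    def test_self_regression_unit_effect(self, rng):
        G = rng.standard_normal((500, 3))
        G = (G - G.mean(0)) / G.std(0)
        ss = marginal_gwas(G, G[:, 0])
        assert ss.beta_hat[0] == pytest.approx(1.0)
        assert ss.n_gwas == 500

    def test_independent_phenotype_near_zero(self, rng):
        n = 2000
        G = rng.standard_normal((n, 5))
        G = (G - G.mean(0)) / G.std(0)
        y = rng.standard_normal(n)
        y = (y - y.mean()) / y.std()
        ss = marginal_gwas(G, y)
        assert np.abs(ss.beta_hat).max() < 3 / np.sqrt(n)

    def test_duplicated_column_identical_estimate(self, rng):
        G = rng.standard_normal((100, 2))
        G[:, 1] = G[:, 0]
        y = rng.standard_normal(100)
        ss = marginal_gwas(G, y)
        assert ss.beta_hat[0] == ss.beta_hat[1]


class TestRunSetting:
    def test_deterministic_given_seed(self):
        a = run_setting(1, scale=0.004, seed=5)
        b = run_setting(1, scale=0.004, seed=5)
        np.testing.assert_array_equal(a.sumstats.beta_hat, b.sumstats.beta_hat)
        np.testing.assert_array_equal(a.y_test, b.y_test)
        np.testing.assert_array_equal(a.effects.beta_true, b.effects.beta_true)

    def test_bundle_consistency(self):
        b = run_setting(1, scale=0.004, seed=3)
        assert len(b.variant_ids) == sum(b.setting.m_k)
        assert b.G_test.shape == (b.setting.n_test, len(b.variant_ids))
        assert sum(len(blk) for blk in b.blocks) == len(b.variant_ids)
        assert b.sumstats.n_gwas == b.setting.n_sumstat

    def test_overlap_setting_has_target_iou_structure(self):
        b = run_setting(6, scale=0.02, seed=1)
        am = b.annotations
        assert iou(am, "g1", "g2") == pytest.approx(0.5, abs=0.05)
        assert iou(am, "g3", "g4") < 0.05
        b7 = run_setting(7, scale=0.02, seed=1)
        assert iou(b7.annotations, "g3", "g4") == pytest.approx(0.5, abs=0.05)
        assert iou(b7.annotations, "g1", "g2") < 0.05


def test_variant_names_stable_width():
    names = variant_names(2500)
    assert names[0] == "v000001" and names[-1] == "v002500"
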
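import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import treegenval as tg

from conftest import random_pedigree


def _result_from_chains(sigma, p0=None, r0=None, names=("a", "b")):
    sigma = np.asarray(sigma, dtype=float)
    n = sigma.shape[0]
    T = sigma.shape[1]
    p0 = np.zeros_like(sigma) if p0 is None else np.asarray(p0, dtype=float)
    r0 = np.zeros_like(sigma) if r0 is None else np.asarray(r0, dtype=float)
    return tg.GibbsResult(
        sigma_chain=sigma, p0_chain=p0, r0_chain=r0,
        ebv=pd.DataFrame(np.zeros((1, T)), columns=names[:T]),
        b_mean=np.zeros((1, T)), plot_mean=np.zeros((0, T)),
        trait_names=tuple(names[:T]), cfg=tg.GibbsConfig(), n_stored=n)


class TestBuildDesign:
    def test_rank_and_shapes(self, tiny_dataset):
        bundle = tg.build_relationship(tiny_dataset, "ablup")
        design = tg.build_design(tiny_dataset, bundle.ped)
        X = design.X
        assert X.shape[1] == design.n_blocks
        assert np.linalg.matrix_rank(X) == design.n_blocks  # full rank cell means
        assert design.n_records == tiny_dataset.n_phenotyped

    def test_missing_trait_pattern(self, tiny_dataset):
        data = tiny_dataset
        pheno = data.pheno.copy()
        pheno.loc[pheno.index[0], "dbh21"] = np.nan
        ds = tg.assemble_dataset(data.ped, pheno, data.geno)
        bundle = tg.build_relationship(ds, "ablup")
        design = tg.build_design(ds, bundle.ped)
        assert design.obs[0].tolist() == [1, 1, 0, 1]

    def test_plot_spanning_blocks_rejected(self, tiny_dataset):
        pheno = tiny_dataset.pheno.copy()
        pheno["plot"] = "p1"  # same plot label across all blocks of a site
        ds = tg.assemble_dataset(tiny_dataset.ped, pheno, tiny_dataset.geno)
        bundle = tg.build_relationship(ds, "ablup")
        with pytest.raises(ValueError, match="spanning"):
            tg.build_design(ds, bundle.ped)


class TestHpdInterval:
    def test_matches_central_interval_for_normal(self, rng):
        x = rng.standard_normal(20_000)
        lo, hi = tg.hpd_interval(x, 0.95)
        qlo, qhi = np.quantile(x, [0.025, 0.975])
        assert lo == pytest.approx(qlo, abs=0.08)
        assert hi == pytest.approx(qhi, abs=0.08)

    def test_constant_chain_zero_width(self):
        lo, hi = tg.hpd_interval(np.full(100, 3.3))
        assert lo == hi == 3.3

    def test_bimodal_spans_both_modes(self):
        x = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        lo, hi = tg.hpd_interval(x, 0.95)
        assert lo == 0.0 and hi == 10.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            tg.hpd_interval(np.arange(10))

    def test_matches_arviz_hdi(self, rng):
        az = pytest.importorskip("arviz")
        x = rng.gamma(3.0, 1.0, size=5000)
        lo, hi = tg.hpd_interval(x, 0.95)
        ref_lo, ref_hi = az.hdi(x, hdi_prob=0.95)
        assert lo == pytest.approx(ref_lo, abs=0.02)
        assert hi == pytest.approx(ref_hi, abs=0.05)


class TestSummaries:
    def test_heritability_closed_forms(self):
        res = _result_from_chains(np.full((60, 1, 1), 1.0),
                                  np.full((60, 1, 1), 1.0),
                                  np.full((60, 1, 1), 1.0), names=("x",))
        mean, (lo, hi) = res.heritability("x")
        assert mean == pytest.approx(1 / 3)
        res2 = _result_from_chains(np.full((60, 1, 1), 2.0), names=("x",))
        assert res2.heritability(0)[0] == pytest.approx(1.0)

    def test_heritability_two_sample_chain_mean(self):
        # variance triplets (1,1,2) and (2,1,1) give h2 samples 0.25 and 0.5
        sigma = np.array([[[1.0]], [[2.0]]] * 30)
        p0 = np.array([[[1.0]], [[1.0]]] * 30)
        r0 = np.array([[[2.0]], [[1.0]]] * 30)
        res = _result_from_chains(sigma, p0, r0, names=("x",))
        assert res.heritability("x")[0] == pytest.approx(0.375)

    @pytest.mark.parametrize("cov,expected", [(2.0, 1.0), (0.0, 0.0), (1.0, 0.5)])
    def test_genetic_correlation(self, cov, expected):
        S = np.array([[2.0, cov], [cov, 2.0]])
        res = _result_from_chains(np.tile(S, (60, 1, 1)))
        mean, _ = res.genetic_correlation("a", "b")
        assert mean == pytest.approx(expected)

    def test_effective_sample_size_iid(self, rng):
        x = rng.standard_normal(4000)
        assert tg.effective_sample_size(x) == pytest.approx(4000, rel=0.2)


def _single_trait_sim(rng, n=400, h2=0.5, mu=3.0):
    """Pedigree MVN trait with one fixed mean, no plots."""
    ped = random_pedigree(rng, n)
    A = tg.tabular_A(ped)
    u = np.linalg.cholesky(A * h2 + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
    y = mu + u + rng.normal(0, np.sqrt(1 - h2), n)
    design = tg.Design(
        y=y[:, None], obs=np.ones((n, 1), dtype=np.uint8),
        cat=np.zeros((n, 1), dtype=np.int8), trait_types=np.zeros(1, dtype=np.uint8),
        block_idx=np.zeros(n, dtype=np.int64), plot_idx=np.full(n, -1, dtype=np.int64),
        ind_idx=np.arange(n, dtype=np.int64), n_ind=n,
        block_labels=["mu"], plot_labels=[], trait_names=("y",))
    return ped, design, u


class TestGibbsSampler:
    def test_single_trait_h2_recovery(self, rng):
        ped, design, _ = _single_trait_sim(rng, n=500, h2=0.5)
        cfg = tg.GibbsConfig(n_samples=12_000, thin=10, burn_in=2_000, seed=2)
        res = tg.gibbs_run(design, tg.a_inverse(ped), cfg)
        h2 = res.sigma_chain[:, 0, 0] / (res.sigma_chain[:, 0, 0] + res.r0_chain[:, 0, 0])
        assert abs(h2.mean() - 0.5) < 3 * h2.std()

    def test_fixed_effects_match_gls_oracle(self, rng):
        """Linear trait at fixed variances: posterior means equal the exact
        mixed-model solution within Monte Carlo error."""
        ped, design, _ = _single_trait_sim(rng, n=200, h2=0.4)
        design.block_idx = (np.arange(200) % 4).astype(np.int64)
        design.block_labels = ["b0", "b1", "b2", "b3"]
        design.__post_init__()
        vc = tg.VarianceComponents([[0.4]], [[1e-6]], [[0.6]])
        cfg = tg.GibbsConfig(n_samples=20_000, thin=10, burn_in=2_000, seed=3,
                             mode="fixed_vc")
        res = tg.gibbs_run(design, tg.a_inverse(ped), cfg, start_vc=vc)
        b, _, u = tg.blup_solve(design.y[:, 0], design.block_idx, design.ind_idx,
                                tg.a_inverse(ped), var_u=0.4, var_e=0.6)
        assert np.abs(res.b_mean[:, 0] - b).max() < 0.02 * np.sqrt(0.4) * 3
        assert np.corrcoef(res.ebv.iloc[:, 0], u)[0, 1] > 0.99

    def test_threshold_trait_h2_recovery(self, rng):
        """3-category trait: liability-scale h2 recovered within 3 posterior sd."""
        n = 1200
        h2 = 0.8
        ped = random_pedigree(rng, n)
        A = tg.tabular_A(ped)
        u = np.linalg.cholesky(A * h2 + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
        liab = u + rng.normal(0, np.sqrt(1 - h2), n)
        t1, t2 = np.quantile(liab, [0.4, 0.8])
        cat = np.where(liab <= t1, 1, np.where(liab <= t2, 2, 3))
        design = tg.Design(
            y=cat[:, None].astype(float), obs=np.ones((n, 1), dtype=np.uint8),
            cat=cat[:, None].astype(np.int8), trait_types=np.ones(1, dtype=np.uint8),
            block_idx=np.zeros(n, dtype=np.int64), plot_idx=np.full(n, -1, np.int64),
            ind_idx=np.arange(n, dtype=np.int64), n_ind=n,
            block_labels=["mu"], plot_labels=[], trait_names=("cat",))
        cfg = tg.GibbsConfig(n_samples=12_000, thin=10, burn_in=2_000, seed=4)
        res = tg.gibbs_run(design, tg.a_inverse(ped), cfg)
        h2_chain = res.sigma_chain[:, 0, 0] / (res.sigma_chain[:, 0, 0]
                                               + res.r0_chain[:, 0, 0])
        assert abs(h2_chain.mean() - h2) < 3 * max(h2_chain.std(), 0.02)

    def test_bit_reproducible(self, rng):
        ped, design, _ = _single_trait_sim(rng, n=120)
        cfg = tg.GibbsConfig(n_samples=1_000, thin=10, burn_in=200, seed=11)
        r1 = tg.gibbs_run(design, tg.a_inverse(ped), cfg)
        r2 = tg.gibbs_run(design, tg.a_inverse(ped), cfg)
        assert np.array_equal(r1.sigma_chain, r2.sigma_chain)
        assert r1.ebv.equals(r2.ebv)

    def test_liability_category_consistency(self, tiny_dataset, tiny_pop):
        vc = tg.VarianceComponents(tiny_pop.truth.Sigma, tiny_pop.truth.P0,
                                   tiny_pop.truth.R0)
        res = tg.fit(tiny_dataset, "ssgblup",
                     tg.GibbsConfig(n_samples=1_500, thin=10, burn_in=300, seed=5),
                     start_vc=vc)
        assert res.consistency_violations == 0
        assert res.n_stored == 120

    def test_mf_mode_ebv_rebase(self, tiny_dataset, tiny_pop):
        gamma = tg.GammaMatrix(tiny_pop.truth.gamma, labels=("AUS", "URU", "SO96", "SO02"))
        res = tg.fit(tiny_dataset, "ablup_mf",
                     tg.fixed_vc_config(seed=6, n_samples=1_000, burn_in=200),
                     gamma=gamma,
                     start_vc=tg.VarianceComponents(tiny_pop.truth.Sigma,
                                                    tiny_pop.truth.P0,
                                                    tiny_pop.truth.R0))
        assert "MF:AUS" in res.ebv.index
        rebased = tg.rebase_ebv(res.ebv, tg.attach_metafounders(
            tg.renumber(tiny_dataset.ped), labels=gamma.labels), "AUS")
        assert np.allclose(rebased.loc["MF:AUS"], 0.0)


class TestConfigValidation:
    def test_burn_in_longer_than_chain(self):
        with pytest.raises(ValueError):
            tg.GibbsConfig(n_samples=1000, burn_in=2000)

    def test_stored_burn_in_unit(self):
        cfg = tg.GibbsConfig(n_samples=300_000, thin=50, burn_in=200,
                             burn_in_unit="stored")
        assert cfg.burn_in_iterations == 10_000

    def test_fixed_vc_protocol(self):
        cfg = tg.fixed_vc_config(seed=9)
        assert cfg.mode == "fixed_vc" and cfg.n_samples == 30_000
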
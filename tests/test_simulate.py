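"""Synthetic-data generator: pedigree structure, depth/error model,
determinism and parameter recovery."""

import numpy as np
import pytest

from pinegbs.calling import call_genotypes
from pinegbs.simulate import (
    SimConfig,
    perturb_genotypes,
    render_reads,
    simulate_dataset,
    simulate_family,
    simulate_founders,
    simulate_megagametophyte,
)


def founders_cfg(**kw):
    base = dict(
        n_sites=200,
        n_unrelated=20,
        families=[],
        n_mega_mothers=0,
        n_replicate_copies={},
        substitution_error=0.0,
        paralog_probe_fraction=0.0,
        triallelic_artifact_rate=0.0,
        seed=7,
    )
    base.update(kw)
    return SimConfig(**base)


class TestFounders:
    def test_degenerate_uniform_gives_exact_frequency(self):
        cfg = founders_cfg(maf_distribution=("uniform", 0.5, 0.5))
        truth = simulate_founders(cfg)
        assert np.allclose(truth.freqs[:, 1], 0.5)

    def test_mean_maf_recovered(self):
        # mean of uniform(0.35, 0.5) is 0.425; SE of the mean over n_sites
        # draws is (0.15/sqrt(12))/sqrt(n)
        cfg = founders_cfg(n_sites=10_000, n_unrelated=135, maf_distribution=("uniform", 0.35, 0.5), seed=3)
        truth = simulate_founders(cfg)
        se = (0.15 / np.sqrt(12)) / np.sqrt(cfg.n_sites)
        assert abs(truth.freqs[:, 1].mean() - 0.425) < 3 * se
        # observed founder allele frequency tracks the truth
        obs = (truth.genotypes == 1).sum(axis=(0, 2)) / (2 * cfg.n_unrelated)
        resid = obs - truth.freqs[:, 1]
        assert abs(resid.mean()) < 3 * resid.std() / np.sqrt(cfg.n_sites)

    def test_hardy_weinberg_proportions(self):
        cfg = founders_cfg(n_sites=1, n_unrelated=20_000, maf_distribution=("uniform", 0.5, 0.5), seed=5)
        truth = simulate_founders(cfg)
        dos = (truth.genotypes == 1).sum(axis=2)[:, 0]
        n = len(dos)
        for g, p_exp in ((0, 0.25), (1, 0.5), (2, 0.25)):
            se = np.sqrt(p_exp * (1 - p_exp) / n)
            assert abs((dos == g).mean() - p_exp) < 3 * se

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            simulate_founders(founders_cfg(maf_distribution=("uniform", 0.4, 0.6)))
        with pytest.raises(ValueError):
            simulate_founders(founders_cfg(maf_distribution=("beta", -1, 2)))


class TestFamily:
    def test_offspring_alleles_always_parental(self):
        cfg = founders_cfg(maf_distribution=("uniform", 0.35, 0.5))
        rng = np.random.default_rng(1)
        truth = simulate_founders(cfg, rng)
        truth = simulate_family(truth, "P0001", "P0002", 50, rng)
        gm = truth.genotypes[truth.sample_loc("P0001")]
        gf = truth.genotypes[truth.sample_loc("P0002")]
        for k in range(50):
            go = truth.genotypes[truth.sample_loc(f"P0001xP0002_o{k + 1:03d}")]
            # one allele from each parent: check containment per site
            a_in_m = (go[:, 0:1] == gm).any(axis=1) | (go[:, 1:2] == gm).any(axis=1)
            assert a_in_m.all()

    def test_het_by_het_segregation_ratio(self):
        cfg = founders_cfg(n_sites=100, maf_distribution=("uniform", 0.5, 0.5), seed=11)
        rng = np.random.default_rng(11)
        truth = simulate_founders(cfg, rng)
        truth = simulate_family(truth, "P0001", "P0002", 500, rng)
        dos = (truth.genotypes == 1).sum(axis=2)
        m, f = truth.sample_loc("P0001"), truth.sample_loc("P0002")
        both_het = (dos[m] == 1) & (dos[f] == 1)
        off = dos[20:, both_het]  # offspring rows follow the 20 founders
        n = off.size
        for g, p_exp in ((0, 0.25), (1, 0.5), (2, 0.25)):
            se = np.sqrt(p_exp * (1 - p_exp) / n)
            assert abs((off == g).mean() - p_exp) < 3 * se

    def test_unknown_parent_rejected(self):
        truth = simulate_founders(founders_cfg())
        with pytest.raises(KeyError):
            simulate_family(truth, "nope", "P0002", 1, np.random.default_rng(0))


class TestMegagametophyte:
    def test_maternal_allele_only(self):
        cfg = founders_cfg(maf_distribution=("uniform", 0.35, 0.5))
        rng = np.random.default_rng(2)
        truth = simulate_founders(cfg, rng)
        truth = simulate_megagametophyte(truth, "P0003", rng)
        gm = truth.genotypes[truth.sample_loc("P0003")]
        g = truth.genotypes[truth.sample_loc("P0003_mega1")]
        assert (g[:, 0] == g[:, 1]).all()  # haploid stores a duplicated allele
        assert ((g[:, 0] == gm[:, 0]) | (g[:, 0] == gm[:, 1])).all()

    def test_maternal_allele_segregation(self):
        cfg = founders_cfg(n_sites=400, maf_distribution=("uniform", 0.5, 0.5), seed=9)
        rng = np.random.default_rng(9)
        truth = simulate_founders(cfg, rng)
        for t in range(250):
            truth = simulate_megagametophyte(truth, "P0001", rng, tag=t + 1)
        gm = truth.genotypes[truth.sample_loc("P0001")]
        het = gm[:, 0] != gm[:, 1]
        megas = truth.genotypes[20:, het, 0]
        picked_second = megas == gm[het, 1]
        n = picked_second.size
        se = np.sqrt(0.25 / n)
        assert abs(picked_second.mean() - 0.5) < 3 * se


class TestRenderReads:
    def test_clean_haploids_have_single_allele_depth(self):
        cfg = founders_cfg(n_mega_mothers=10)
        table, sheet, truth = simulate_dataset(cfg)
        idx = table.sample_index(sheet.megagametophyte_ids)
        d = table.depths[idx]
        covered = d.sum(axis=2) > 0
        assert ((d > 0).sum(axis=2)[covered] == 1).all()

    def test_mean_depth_recovered(self):
        cfg = founders_cfg(n_sites=500, mean_depth=60.0, depth_dispersion=6.0, seed=13)
        table, _, _ = simulate_dataset(cfg)
        tot = table.total_depth().astype(float)
        n = tot.size
        var = 60 + 60**2 / 6.0  # negative-binomial variance
        assert abs(tot.mean() - 60) < 3 * np.sqrt(var / n)

    def test_substitution_error_rate_recovered(self):
        cfg = founders_cfg(
            n_sites=500, n_unrelated=40, substitution_error=0.002,
            maf_distribution=("uniform", 0.35, 0.5), seed=17,
        )
        table, _, truth = simulate_dataset(cfg)
        hom_ref = (truth.genotypes == 0).all(axis=2)
        tot = table.total_depth()[hom_ref].sum()
        err_reads = (table.depths[:, :, 1:].sum(axis=2))[hom_ref].sum()
        # non-ref reads at true hom-ref cells are Binomial(depth, e)
        rate = err_reads / tot
        se = np.sqrt(0.002 * 0.998 / tot)
        assert abs(rate - 0.002) < 3 * se

    def test_truth_recovery_with_no_error(self, clean_sim):
        _, table, sheet, truth = clean_sim
        m = call_genotypes(table, sheet, min_depth=1)
        diff = (m.calls != truth.genotypes).any(axis=2)
        # only low-depth binomial extremes can miscall; vanishing rate
        assert diff.mean() < 1e-3
        deep = table.total_depth() >= 40
        assert not (diff & deep).any()

    def test_missingness_decreases_with_depth(self):
        miss = []
        for depth in (5.0, 12.0, 25.0, 60.0):
            cfg = founders_cfg(n_sites=300, mean_depth=depth, seed=23)
            table, sheet, _ = simulate_dataset(cfg)
            m = call_genotypes(table, sheet, min_depth=10)
            miss.append(m.missing_mask().mean())
        assert all(a >= b for a, b in zip(miss, miss[1:]))

    def test_paralog_probes_make_pseudo_het_haploids(self):
        cfg = founders_cfg(
            n_sites=300, n_mega_mothers=15, paralog_probe_fraction=0.3,
            maf_distribution=("uniform", 0.35, 0.5), seed=29,
        )
        table, sheet, truth = simulate_dataset(cfg)
        assert truth.paralog_probes
        from pinegbs.filtering import haploid_het_site_fraction

        frac = haploid_het_site_fraction(table, sheet)
        on_paralog = table.sites["probe_id"].isin(truth.paralog_probes).to_numpy()
        assert frac[on_paralog].mean() > 0.3
        assert frac[~on_paralog].mean() < 0.05


class TestDeterminism:
    def test_identical_seeds_bitwise_identical(self):
        cfg = SimConfig(n_sites=150, n_unrelated=20, families=[("P0001", "P0002", 5)],
                        n_mega_mothers=5, seed=404)
        t1, s1, tr1 = simulate_dataset(cfg)
        t2, s2, tr2 = simulate_dataset(cfg)
        assert np.array_equal(t1.depths, t2.depths)
        assert t1.sites.equals(t2.sites)
        assert s1 == s2
        assert np.array_equal(tr1.genotypes, tr2.genotypes)

    def test_different_seed_differs(self):
        cfg1 = founders_cfg(seed=1)
        cfg2 = founders_cfg(seed=2)
        t1, _, _ = simulate_dataset(cfg1)
        t2, _, _ = simulate_dataset(cfg2)
        assert not np.array_equal(t1.depths, t2.depths)


class TestPerturb:
    def test_rates_and_haploid_integrity(self, clean_sim):
        _, _, sheet, truth = clean_sim
        m = truth.to_matrix()
        rng = np.random.default_rng(55)
        noisy = perturb_genotypes(m, error_rate=0.05, missing_rate=0.10, rng=rng)
        was_valid = m.calls[:, :, 0] >= 0
        now_missing = noisy.calls[:, :, 0] == -1
        miss_rate = (now_missing & was_valid).sum() / was_valid.sum()
        changed = was_valid & ~now_missing & (noisy.calls != m.calls).any(axis=2)
        err_rate = changed.sum() / was_valid.sum()
        n = was_valid.sum()
        assert abs(miss_rate - 0.10) < 3 * np.sqrt(0.1 * 0.9 / n)
        assert abs(err_rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)
        hap = noisy.ploidy == 1
        assert (noisy.calls[hap][:, :, 0] == noisy.calls[hap][:, :, 1]).all()
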